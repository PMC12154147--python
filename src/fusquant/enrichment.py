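"""Single-cell QC filtering, signed gene scoring, and preranked enrichment.

The differential-expression downstream path: cells pass quality control
under strict inequalities (genes detected > 200, 1000 < molecules < 50000,
mitochondrial percentage < 20); each gene in a DE table gets the signed
score

    score = -log10(p) * sign(log2 fold change)

so strongly significant up-regulated genes rank at the top and
down-regulated ones at the bottom; and gene sets are tested against the
ranked list with the classic weighted Kolmogorov-Smirnov enrichment score
(weight exponent 1): walking down the list, set members increment the
running sum by their absolute score over the summed absolute scores of all
members, non-members decrement by 1/(N - N_hits), and the enrichment score
(ES) is the signed extremum of the walk.  Significance comes from a
gene-label permutation null: nominal p from same-sign null ES, the
normalized ES (NES) from the same-sign null mean, and the FDR q value from
the standard NES-ratio estimator.  Sets with q <= 0.3 are flagged
significant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "QC_MIN_GENES",
    "QC_UMI_RANGE",
    "QC_MAX_MITO_PCT",
    "filter_cells_qc",
    "gene_score",
    "rank_genes",
    "enrichment_score",
    "permutation_fdr",
    "read_de_table",
    "write_rnk",
    "read_rnk",
    "read_gmt",
    "write_gmt",
]

QC_MIN_GENES = 200
QC_UMI_RANGE = (1000, 50000)
QC_MAX_MITO_PCT = 20.0

FDR_SIGNIFICANCE = 0.3


def filter_cells_qc(records: pd.DataFrame) -> tuple[list, pd.DataFrame]:
    """Apply the per-cell QC rules; all inequalities are strict.

    ``records`` needs columns ``cell_id``, ``n_genes``, ``n_molecules``,
    ``percent_mito``.  Returns the kept cell ids and a table of rejected
    cells where ``reasons`` lists every violated rule.
    """
    required = {"cell_id", "n_genes", "n_molecules", "percent_mito"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    if (records["n_genes"] < 0).any() or (records["n_molecules"] < 0).any():
        raise ValueError("counts must be >= 0")
    if ((records["percent_mito"] < 0) | (records["percent_mito"] > 100)).any():
        raise ValueError("percent_mito must lie in [0, 100]")
    reasons = []
    for _, row in records.iterrows():
        violated = []
        if not row["n_genes"] > QC_MIN_GENES:
            violated.append("genes")
        if not QC_UMI_RANGE[0] < row["n_molecules"] < QC_UMI_RANGE[1]:
            violated.append("molecules")
        if not row["percent_mito"] < QC_MAX_MITO_PCT:
            violated.append("mito")
        reasons.append(violated)
    keep = [not r for r in reasons]
    kept_ids = records.loc[keep, "cell_id"].tolist()
    rejected = records.loc[[not k for k in keep]].copy()
    rejected["reasons"] = [";".join(r) for r, k in zip(reasons, keep) if not k]
    return kept_ids, rejected


def gene_score(pval, log2fc, p_floor: float = 1e-300):
    """Signed significance score: -log10(p) * sign(log2fc).

    ``sign(0) = 0``, so genes with no fold change score 0 regardless of p.
    Zero p-values are clamped to ``p_floor`` (with a logged warning) to
    keep the score finite.  Accepts scalars or arrays.
    """
    p = np.asarray(pval, dtype=float)
    fc = np.asarray(log2fc, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(p == 0):
        logger.warning("p-value of 0 clamped to floor %g", p_floor)
    p = np.clip(p, p_floor, None)
    score = -np.log10(p) * np.sign(fc)
    return float(score) if score.ndim == 0 else score


def rank_genes(de: pd.DataFrame) -> pd.DataFrame:
    """Score and rank a DE table (columns ``gene``, ``pval``, ``log2fc``).

    Scores descend; ties break lexicographically on the gene symbol so the
    ordering is deterministic.  Duplicate symbols are an error.
    """
    required = {"gene", "pval", "log2fc"}
    missing = required - set(de.columns)
    if missing:
        raise ValueError(f"DE table missing columns: {sorted(missing)}")
    dupes = de["gene"][de["gene"].duplicated()].unique()
    if dupes.size:
        raise ValueError(f"duplicate gene symbols: {sorted(dupes.tolist())}")
    ranked = de.assign(score=gene_score(de["pval"].to_numpy(), de["log2fc"].to_numpy()))
    ranked = ranked.sort_values(
        ["score", "gene"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    return ranked[["gene", "score"]]


def enrichment_score(
    ranked: pd.DataFrame | Sequence[tuple[str, float]],
    gene_set: Sequence[str],
    weight: float = 1.0,
) -> tuple[float, bool]:
    """Classic weighted KS enrichment score of one set against a ranked list.

    Returns ``(es, defined)``; ``defined`` is False (and ``es`` NaN) when
    the set does not intersect the list, or when it swallows it whole so
    no miss step exists.
    """
    if isinstance(ranked, pd.DataFrame):
        genes = ranked["gene"].to_numpy()
        scores = ranked["score"].to_numpy(dtype=float)
    else:
        genes = np.array([g for g, _ in ranked])
        scores = np.array([s for _, s in ranked], dtype=float)
    hit = np.isin(genes, np.asarray(list(gene_set)))
    return _es_from_hits(scores, hit, weight)


def _es_from_hits(scores: np.ndarray, hit: np.ndarray, weight: float = 1.0) -> tuple[float, bool]:
    n = scores.size
    n_hit = int(hit.sum())
    if n_hit == 0 or n_hit == n:
        return float("nan"), False
    w = np.abs(scores[hit]) ** weight
    w_total = w.sum()
    steps = np.empty(n)
    if w_total == 0:
        # degenerate all-zero hit scores: fall back to equal hit steps
        steps[hit] = 1.0 / n_hit
    else:
        steps[hit] = np.abs(scores[hit]) ** weight / w_total
    steps[~hit] = -1.0 / (n - n_hit)
    running = np.cumsum(steps)
    return float(running[np.argmax(np.abs(running))]), True


@dataclass(frozen=True)
class _SetResult:
    name: str
    size: int
    es: float
    nes: float
    pval: float
    fdr_q: float
    significant: bool
    excluded: bool
    reason: str


def permutation_fdr(
    ranked: pd.DataFrame,
    gene_sets: Mapping[str, Sequence[str]],
    n_perm: int = 1000,
    max_size: int = 1500,
    min_size: int = 5,
    weight: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Gene-label permutation significance for preranked enrichment.

    For each admissible set (``min_size <= size-in-universe <= max_size``)
    the null distribution is the ES of ``n_perm`` random gene sets of the
    same size drawn from the ranked universe.  Nominal p is the fraction
    of same-sign null ES at least as extreme as the observed ES; NES is
    the observed ES divided by the mean magnitude of same-sign null ES;
    and the FDR q value uses the standard NES-ratio estimator (pooled null
    NES beyond each observed NES over observed NES beyond it, clipped to
    [0, 1] and made monotone).  Inadmissible sets are retained in the
    output with ``excluded=True`` and a reason.
    """
    if n_perm < 10:
        raise ValueError("n_perm must be >= 10")
    rng = np.random.default_rng(seed)
    genes = ranked["gene"].to_numpy()
    scores = ranked["score"].to_numpy(dtype=float)
    n = genes.size
    universe = set(genes.tolist())

    results: list[_SetResult] = []
    null_nes_pool: list[np.ndarray] = []
    admissible_idx: list[int] = []
    for name, members in gene_sets.items():
        member_set = set(members) & universe
        size = len(member_set)
        if size < min_size or size > max_size:
            reason = "too_small" if size < min_size else "too_large"
            logger.info("gene set %s excluded (%s, size %d)", name, reason, size)
            results.append(
                _SetResult(name, size, float("nan"), float("nan"), float("nan"),
                           float("nan"), False, True, reason)
            )
            continue
        hit = np.isin(genes, np.asarray(list(member_set)))
        es, defined = _es_from_hits(scores, hit, weight)
        if not defined:
            results.append(
                _SetResult(name, size, float("nan"), float("nan"), float("nan"),
                           float("nan"), False, True, "undefined_es")
            )
            continue
        null_es = np.empty(n_perm)
        hit_buf = np.zeros(n, dtype=bool)
        for k in range(n_perm):
            hit_buf[:] = False
            hit_buf[rng.choice(n, size=size, replace=False)] = True
            null_es[k], _ = _es_from_hits(scores, hit_buf, weight)
        same_sign = null_es >= 0 if es >= 0 else null_es < 0
        n_same = int(same_sign.sum())
        if n_same == 0:
            pval = 0.0
            nes = float("nan")
            null_nes = np.empty(0)
        else:
            pval = float(np.sum(np.abs(null_es[same_sign]) >= abs(es)) / n_same)
            mean_same = float(np.abs(null_es[same_sign]).mean())
            nes = es / mean_same if mean_same > 0 else float("nan")
            null_nes = null_es[same_sign] / mean_same
        null_nes_pool.append(null_nes)
        admissible_idx.append(len(results))
        results.append(
            _SetResult(name, size, es, nes, pval, float("nan"), False, False, "")
        )

    # NES-ratio FDR over admissible sets
    if admissible_idx:
        obs_nes = np.array([results[i].nes for i in admissible_idx])
        pooled = np.concatenate(null_nes_pool) if null_nes_pool else np.empty(0)
        qvals = _nes_ratio_fdr(obs_nes, pooled)
        for i, q in zip(admissible_idx, qvals):
            r = results[i]
            results[i] = _SetResult(
                r.name, r.size, r.es, r.nes, r.pval, q,
                bool(q <= FDR_SIGNIFICANCE), False, "",
            )

    return pd.DataFrame(
        [
            {
                "set": r.name,
                "size": r.size,
                "es": r.es,
                "nes": r.nes,
                "pval": r.pval,
                "fdr_q": r.fdr_q,
                "significant": r.significant,
                "excluded": r.excluded,
                "reason": r.reason,
            }
            for r in results
        ]
    )


def _nes_ratio_fdr(obs_nes: np.ndarray, null_nes: np.ndarray) -> np.ndarray:
    """Standard NES-ratio FDR estimator, per sign, monotone within sign."""
    q = np.full(obs_nes.size, np.nan)
    for sign in (+1, -1):
        sel = obs_nes >= 0 if sign > 0 else obs_nes < 0
        if not sel.any():
            continue
        null_side = null_nes[null_nes >= 0] if sign > 0 else null_nes[null_nes < 0]
        obs_side_all = obs_nes[sel & np.isfinite(obs_nes)]
        for i in np.nonzero(sel)[0]:
            nes = obs_nes[i]
            if not np.isfinite(nes):
                q[i] = 0.0
                continue
            if null_side.size == 0:
                q[i] = 0.0
                continue
            num = np.mean(np.abs(null_side) >= abs(nes))
            den = np.mean(np.abs(obs_side_all) >= abs(nes)) if obs_side_all.size else 1.0
            q[i] = min(1.0, num / den) if den > 0 else 1.0
        # enforce monotonicity: a more extreme NES never has a larger q
        idx = np.nonzero(sel)[0]
        order = np.argsort(-np.abs(obs_nes[idx]))
        running = np.inf
        for j in idx[order]:
            running = min(running, q[j]) if np.isfinite(q[j]) else running
            if np.isfinite(q[j]):
                q[j] = running
    return q


# ---------------------------------------------------------------------------
# file formats


def read_de_table(path) -> pd.DataFrame:
    """Tab-separated DE table with columns gene, pval, log2fc."""
    de = pd.read_csv(path, sep="\t")
    de.columns = [c.strip().lower() for c in de.columns]
    return de


def write_rnk(path, ranked: pd.DataFrame) -> None:
    """Two-column tab-separated RNK file, descending score."""
    ranked[["gene", "score"]].to_csv(path, sep="\t", header=False, index=False)


def read_rnk(path) -> pd.DataFrame:
    rnk = pd.read_csv(path, sep="\t", header=None, names=["gene", "score"])
    return rnk.sort_values(["score", "gene"], ascending=[False, True], kind="stable").reset_index(drop=True)


def read_gmt(path) -> dict[str, list[str]]:
    """GMT gene sets: name <tab> description <tab> members..."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_gmt(path, gene_sets: Mapping[str, Sequence[str]]) -> None:
    lines = [
        "\t".join([name, "synthetic"] + list(members))
        for name, members in gene_sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")
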