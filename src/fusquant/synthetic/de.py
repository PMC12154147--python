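"""Synthetic differential-expression tables with planted enriched sets.

Null genes draw p ~ Uniform(0, 1) and a log2 fold change symmetric around
zero; "true" up- and down-regulated genes draw small p-values
(log-uniform, well separated from the null range) and signed fold changes,
so by construction their scores dominate the ranking.  Planted gene sets
(defaulting to exactly the true up and true down genes) give enrichment
analyses a known positive control.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ..enrichment import write_gmt

__all__ = ["PlantedSet", "DESimSpec", "gen_de_table", "write_de_files"]


@dataclass(frozen=True)
class PlantedSet:
    name: str
    members: tuple[str, ...]
    direction: str  # "up" or "down"

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise ValueError("direction must be 'up' or 'down'")


@dataclass(frozen=True)
class DESimSpec:
    """DE simulation settings.

    True genes get ``p = 10**u`` with ``u ~ Uniform(*true_p_log10_range)``
    and fold-change magnitude ``~ Normal(effect_log2fc_mean,
    effect_log2fc_sd)`` (clipped at a small positive floor), signed by
    direction.  ``planted_sets=None`` plants one set per direction holding
    exactly the true genes.
    """

    n_genes: int = 5000
    n_true_up: int = 50
    n_true_down: int = 50
    effect_log2fc_mean: float = 2.0
    effect_log2fc_sd: float = 0.5
    null_log2fc_sd: float = 0.5
    true_p_log10_range: tuple[float, float] = (-12.0, -6.0)
    planted_sets: tuple[PlantedSet, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_true_up < 0 or self.n_true_down < 0:
            raise ValueError("true-gene counts must be >= 0")
        if self.n_true_up + self.n_true_down > self.n_genes:
            raise ValueError("true genes cannot exceed the gene universe")
        lo, hi = self.true_p_log10_range
        if not lo <= hi <= 0:
            raise ValueError("true_p_log10_range must be ordered and <= 0")

    def gene_names(self) -> list[str]:
        return [f"G{i:05d}" for i in range(self.n_genes)]


def _resolve_planted(spec: DESimSpec, up: list[str], down: list[str]) -> list[PlantedSet]:
    if spec.planted_sets is not None:
        universe = set(spec.gene_names())
        for ps in spec.planted_sets:
            extra = set(ps.members) - universe
            if extra:
                raise ValueError(f"planted set {ps.name} has members outside the universe: {sorted(extra)[:5]}")
        return list(spec.planted_sets)
    planted = []
    if up:
        planted.append(PlantedSet("planted_up", tuple(up), "up"))
    if down:
        planted.append(PlantedSet("planted_down", tuple(down), "down"))
    return planted


def gen_de_table(spec: DESimSpec) -> tuple[pd.DataFrame, dict]:
    """Generate the DE table and the planted-set ground truth."""
    rng = np.random.default_rng(spec.seed)
    genes = spec.gene_names()
    up = genes[: spec.n_true_up]
    down = genes[spec.n_true_up : spec.n_true_up + spec.n_true_down]
    n_true = len(up) + len(down)

    pvals = np.empty(spec.n_genes)
    log2fc = np.empty(spec.n_genes)
    lo, hi = spec.true_p_log10_range
    pvals[:n_true] = 10.0 ** rng.uniform(lo, hi, size=n_true)
    effects = np.clip(
        rng.normal(spec.effect_log2fc_mean, spec.effect_log2fc_sd, size=n_true), 0.1, None
    )
    log2fc[: len(up)] = effects[: len(up)]
    log2fc[len(up) : n_true] = -effects[len(up) :]
    pvals[n_true:] = rng.uniform(0.0, 1.0, size=spec.n_genes - n_true)
    log2fc[n_true:] = rng.normal(0.0, spec.null_log2fc_sd, size=spec.n_genes - n_true)

    table = pd.DataFrame({"gene": genes, "pval": pvals, "log2fc": log2fc})
    planted = _resolve_planted(spec, up, down)
    truth = {
        "true_up": up,
        "true_down": down,
        "planted_sets": [
            {"name": ps.name, "members": list(ps.members), "direction": ps.direction}
            for ps in planted
        ],
    }
    return table, truth


def write_de_files(out_dir, spec: DESimSpec) -> Path:
    """Write the DE TSV, the planted sets as GMT, and the truth JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table, truth = gen_de_table(spec)
    table.to_csv(out_dir / "de.tsv", sep="\t", index=False)
    write_gmt(
        out_dir / "sets.gmt",
        {ps["name"]: ps["members"] for ps in truth["planted_sets"]},
    )
    (out_dir / "truth.json").write_text(json.dumps(truth, indent=2))
    return out_dir
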