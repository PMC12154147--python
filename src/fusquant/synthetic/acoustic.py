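"""Synthetic passive-cavitation-detector (PCD) emission generator.

Emulates the received RF traces of a sonication: a block of baseline
(noise-only) pulses recorded before microbubble injection, followed by
``prf * duration`` treatment pulses, each a sum of sinusoids at the
requested harmonic (``n * f_c``) and ultraharmonic (``(n/2) * f_c``)
frequencies plus white Gaussian noise standing in for broadband inertial
emissions.  Tone phases are randomized per pulse; with the default timing
every tonal frequency falls exactly on a DFT bin of the pulse, so spectral
leakage is nil and the ground-truth tonal energies are exact.

Ground truth records, per tonal component, the expected time-domain energy
of a length-``T`` sinusoid of amplitude ``A``: ``A**2 * T / 2`` (units of
squared voltage times seconds), and for the broadband term its total
expected energy ``sigma**2 * T`` together with its flat spectral density.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import h5py
import numpy as np

from ..cavitation import PulseTrace

__all__ = ["SonicationSpec", "gen_pcd_sonication", "iter_pcd_pulses", "write_pcd_h5"]


def _default_harmonics() -> dict[int, float]:
    return {1: 1.0, 2: 0.8, 3: 0.6, 4: 0.45, 5: 0.35, 6: 0.25}


def _default_ultraharmonics() -> dict[int, float]:
    return {3: 0.2, 5: 0.15, 7: 0.1, 9: 0.06}


@dataclass(frozen=True)
class SonicationSpec:
    """Acoustic-emission simulation settings.

    Defaults mirror the treatment timing of the emulated experiments:
    1.5 MHz drive, 10 ms pulses at 10 Hz pulse-repetition frequency for
    120 s, digitized at 50 MHz.  Emission amplitudes are free parameters
    (arbitrary units); ``broadband_level`` is the per-sample standard
    deviation of the white-noise term.
    """

    center_frequency: float = 1.5e6
    prf: float = 10.0
    duration: float = 120.0
    pulse_length: float = 10e-3
    sampling_rate: float = 50e6
    harmonic_amplitudes: Mapping[int, float] = field(default_factory=_default_harmonics)
    ultraharmonic_amplitudes: Mapping[int, float] = field(
        default_factory=_default_ultraharmonics
    )
    broadband_level: float = 0.01
    baseline_pulses: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        n_pulses = self.prf * self.duration
        if abs(n_pulses - round(n_pulses)) > 1e-9 or n_pulses < 1:
            raise ValueError(
                f"prf * duration must be a positive integer pulse count, got {n_pulses}"
            )
        if self.pulse_length * self.sampling_rate < 2:
            raise ValueError("pulse_length * sampling_rate must give >= 2 samples")
        for name, amps in (
            ("harmonic_amplitudes", self.harmonic_amplitudes),
            ("ultraharmonic_amplitudes", self.ultraharmonic_amplitudes),
        ):
            if any(a < 0 for a in amps.values()):
                raise ValueError(f"{name} must be >= 0")
        if self.broadband_level < 0:
            raise ValueError("broadband_level must be >= 0")
        if self.baseline_pulses < 1:
            raise ValueError("baseline_pulses must be >= 1")

    @property
    def n_treatment_pulses(self) -> int:
        return int(round(self.prf * self.duration))

    @property
    def n_samples(self) -> int:
        return int(round(self.pulse_length * self.sampling_rate))

    def tonal_components(self) -> list[dict]:
        """Every tonal component with its frequency and exact energy."""
        comps = []
        for n, a in sorted(self.harmonic_amplitudes.items()):
            comps.append(
                {
                    "kind": "harmonic",
                    "order": n,
                    "frequency": n * self.center_frequency,
                    "amplitude": a,
                    "energy": a**2 * self.pulse_length / 2.0,
                }
            )
        for n, a in sorted(self.ultraharmonic_amplitudes.items()):
            comps.append(
                {
                    "kind": "ultraharmonic",
                    "half_order": n,
                    "frequency": n * self.center_frequency / 2.0,
                    "amplitude": a,
                    "energy": a**2 * self.pulse_length / 2.0,
                }
            )
        return comps

    def ground_truth(self) -> dict:
        fs = self.sampling_rate
        return {
            "n_treatment_pulses": self.n_treatment_pulses,
            "n_baseline_pulses": self.baseline_pulses,
            "tonal_components": self.tonal_components(),
            "broadband": {
                "level": self.broadband_level,
                "total_energy": self.broadband_level**2 * self.pulse_length,
                # white noise spreads its energy evenly over [0, fs/2]
                "energy_density_per_hz": self.broadband_level**2
                * self.pulse_length
                / (fs / 2.0),
            },
        }


def iter_pcd_pulses(spec: SonicationSpec) -> Iterator[PulseTrace]:
    """Yield baseline pulses (noise only) then treatment pulses.

    Lazy so that full-length sonications (1200 x 500k samples at the
    defaults) never need to be held in memory at once.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    t = np.arange(n) / spec.sampling_rate
    comps = [(c["frequency"], c["amplitude"]) for c in spec.tonal_components() if c["amplitude"] > 0]
    idx = 0
    for _ in range(spec.baseline_pulses):
        noise = (
            rng.standard_normal(n) * spec.broadband_level
            if spec.broadband_level > 0
            else np.zeros(n)
        )
        yield PulseTrace(samples=noise, sampling_rate=spec.sampling_rate, pulse_index=idx, is_baseline=True)
        idx += 1
    for _ in range(spec.n_treatment_pulses):
        x = np.zeros(n)
        for f, a in comps:
            phase = rng.uniform(0.0, 2.0 * np.pi)
            x += a * np.sin(2.0 * np.pi * f * t + phase)
        if spec.broadband_level > 0:
            x += rng.standard_normal(n) * spec.broadband_level
        yield PulseTrace(samples=x, sampling_rate=spec.sampling_rate, pulse_index=idx, is_baseline=False)
        idx += 1


def gen_pcd_sonication(spec: SonicationSpec) -> tuple[list[PulseTrace], dict]:
    """Materialize all pulses plus the exact ground-truth record."""
    return list(iter_pcd_pulses(spec)), spec.ground_truth()


def write_pcd_h5(path, spec: SonicationSpec) -> Path:
    """Write the sonication to HDF5 with a JSON ground-truth sidecar.

    Layout: datasets ``traces`` (n_pulses, n_samples) and ``is_baseline``;
    file attributes ``sampling_rate`` and ``center_frequency``.  The truth
    sidecar lands next to the file as ``<name>.truth.json``.
    """
    path = Path(path)
    n_total = spec.baseline_pulses + spec.n_treatment_pulses
    with h5py.File(path, "w") as h5:
        dset = h5.create_dataset("traces", shape=(n_total, spec.n_samples), dtype="f8")
        flags = np.zeros(n_total, dtype=bool)
        for i, trace in enumerate(iter_pcd_pulses(spec)):
            dset[i] = trace.samples
            flags[i] = trace.is_baseline
        h5.create_dataset("is_baseline", data=flags)
        h5.attrs["sampling_rate"] = spec.sampling_rate
        h5.attrs["center_frequency"] = spec.center_frequency
    sidecar = path.with_suffix(path.suffix + ".truth.json")
    sidecar.write_text(json.dumps(spec.ground_truth(), indent=2))
    return path
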