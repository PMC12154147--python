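"""Passive cavitation detector (PCD) spectral dose decomposition.

During focused-ultrasound blood-brain-barrier opening, circulating
microbubbles re-emit acoustic energy that a single-element passive
cavitation detector records once per transmitted pulse.  Stable (volumetric)
bubble oscillation emits tones at integer harmonics ``n * f_c`` and odd
half-integer ultraharmonics ``(n/2) * f_c`` of the driving frequency
``f_c``; inertial (collapse) cavitation emits broadband noise.  This module
turns each received pulse into a magnitude spectrum, isolates narrow windows
around every in-band tonal frequency, and reports three per-pulse doses,
each the root-mean-square (RMS) spectral amplitude over its frequency
region:

* ``scdh`` — stable cavitation dose, harmonic windows;
* ``scdu`` — stable cavitation dose, ultraharmonic windows;
* ``icd``  — inertial cavitation dose, every in-band frequency bin left
  over once the tonal windows are removed.

The three regions partition the analysis band exactly (harmonic windows
take precedence where windows would overlap), so the summed squared
amplitudes over the regions always reproduce the in-band total.  Per-pulse
doses are accumulated over a sonication and normalized to the mean
per-pulse dose of baseline pulses recorded before microbubble injection,
which makes the no-bubble condition read close to 1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import h5py
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PulseTrace",
    "SpectralSettings",
    "PulseSpectrum",
    "PulseDose",
    "SonicationDoseSummary",
    "compute_spectrum",
    "locate_tonal_peaks",
    "region_masks",
    "compute_pulse_dose",
    "accumulate_doses",
    "analyze_sonication",
    "load_traces",
]

DOSE_COMPONENTS = ("scdh", "scdu", "icd", "cd_total")


@dataclass(frozen=True)
class PulseTrace:
    """One received PCD pulse: voltage samples plus sampling rate."""

    samples: np.ndarray
    sampling_rate: float
    pulse_index: int = 0
    is_baseline: bool = False

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1 or samples.size < 2:
            raise ValueError("samples must be a 1-D array with >= 2 samples")
        if not self.sampling_rate > 0:
            raise ValueError(f"sampling_rate must be > 0, got {self.sampling_rate}")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate


@dataclass(frozen=True)
class SpectralSettings:
    """Tonal bookkeeping and band limits for the dose decomposition.

    ``peak_window_width`` is the *total* width of the window centered on
    each tonal frequency (20 kHz means +/- 10 kHz).  Harmonic frequencies
    are ``n * center_frequency`` for ``n`` in ``harmonic_orders``;
    ultraharmonics are ``(n / 2) * center_frequency`` for the odd
    ``ultraharmonic_half_orders``.  Tonal frequencies outside
    ``[band_low, band_high]`` are excluded from every dose bin (the band
    limit is applied first) and the exclusion is logged.
    """

    center_frequency: float = 1.5e6
    harmonic_orders: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    ultraharmonic_half_orders: tuple[int, ...] = (3, 5, 7, 9)
    peak_window_width: float = 20e3
    band_low: float = 3e6
    band_high: float = 9e6
    use_hann: bool = False

    def __post_init__(self) -> None:
        if not self.center_frequency > 0:
            raise ValueError("center_frequency must be > 0")
        if not self.band_low < self.band_high:
            raise ValueError("band_low must be < band_high")
        if not self.peak_window_width > 0:
            raise ValueError("peak_window_width must be > 0")
        for n in self.ultraharmonic_half_orders:
            if n % 2 == 0:
                raise ValueError(
                    f"ultraharmonic_half_orders must be odd (got {n}); even "
                    "half-orders duplicate integer harmonics"
                )

    def harmonic_frequencies(self) -> tuple[float, ...]:
        return tuple(n * self.center_frequency for n in self.harmonic_orders)

    def ultraharmonic_frequencies(self) -> tuple[float, ...]:
        return tuple(n * self.center_frequency / 2.0 for n in self.ultraharmonic_half_orders)

    def _in_band(self, f: float) -> bool:
        return self.band_low <= f <= self.band_high

    def tonal_frequencies(self) -> dict[str, tuple[float, ...]]:
        """In-band tonal frequencies by family, plus the excluded ones.

        Returns a dict with keys ``harmonic``, ``ultraharmonic`` (in-band,
        deduplicated, ascending) and ``excluded`` (out-of-band tonals).
        """
        harm = sorted({f for f in self.harmonic_frequencies() if self._in_band(f)})
        ultra = sorted(
            {f for f in self.ultraharmonic_frequencies() if self._in_band(f)} - set(harm)
        )
        excluded = sorted(
            {f for f in self.harmonic_frequencies() + self.ultraharmonic_frequencies()}
            - set(harm)
            - set(ultra)
        )
        if excluded:
            logger.info(
                "tonal frequencies outside the %.3g-%.3g Hz band excluded "
                "from dose bins: %s",
                self.band_low,
                self.band_high,
                ", ".join(f"{f:g}" for f in excluded),
            )
        return {
            "harmonic": tuple(harm),
            "ultraharmonic": tuple(ultra),
            "excluded": tuple(excluded),
        }


@dataclass(frozen=True)
class PulseSpectrum:
    """One-sided magnitude spectrum of a single pulse."""

    frequencies: np.ndarray
    amplitudes: np.ndarray
    band_mask: np.ndarray
    n_samples: int
    sampling_rate: float
    pulse_index: int = 0
    is_baseline: bool = False

    def __post_init__(self) -> None:
        if self.frequencies.shape != self.amplitudes.shape:
            raise ValueError("frequency grid and amplitudes must align")
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if np.any(self.amplitudes < 0):
            raise ValueError("spectral amplitudes must be >= 0")

    @property
    def frequency_resolution(self) -> float:
        return self.sampling_rate / self.n_samples

    def time_domain_energy(self) -> float:
        """Sum of squared samples reconstructed from the one-sided spectrum.

        Uses Parseval's relation for the real DFT: interior bins count
        twice, the DC bin once, and (for even ``n_samples``) the Nyquist
        bin once.
        """
        a2 = self.amplitudes**2
        weights = np.full(a2.size, 2.0)
        weights[0] = 1.0
        if self.n_samples % 2 == 0:
            weights[-1] = 1.0
        return float(np.sum(weights * a2) / self.n_samples)


@dataclass(frozen=True)
class PulseDose:
    """Per-pulse dose decomposition.

    ``scdh``/``scdu``/``icd``/``cd_total`` are RMS spectral amplitudes over
    the harmonic, ultraharmonic, residual and full-band regions.  The raw
    summed squared amplitudes per region (``energy_*``) are retained so the
    exact partition ``energy_harmonic + energy_ultraharmonic +
    energy_residual == energy_band`` can be checked and so that cumulative
    doses can also be reported on the energy scale.
    """

    scdh: float
    scdu: float
    icd: float
    cd_total: float
    peak_amplitudes: Mapping[float, float]
    energy_harmonic: float
    energy_ultraharmonic: float
    energy_residual: float
    energy_band: float
    pulse_index: int = 0
    is_baseline: bool = False

    def __post_init__(self) -> None:
        for name in DOSE_COMPONENTS:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def component(self, name: str) -> float:
        return float(getattr(self, name))


@dataclass(frozen=True)
class SonicationDoseSummary:
    """Cumulative and baseline-normalized doses over one sonication.

    ``cumulative`` sums the per-pulse RMS amplitudes over all treatment
    pulses (the primary, amplitude-scale accumulation);
    ``cumulative_energy`` sums the per-pulse squared-amplitude region
    energies (secondary, energy scale).  ``normalized`` divides the
    cumulative amplitude dose by (baseline per-pulse mean x number of
    treatment pulses) — the mean per-pulse dose in units of baseline.
    Components whose baseline mean is zero are flagged in ``undefined``
    and reported as NaN rather than infinity.
    """

    cumulative: Mapping[str, float]
    baseline_mean: Mapping[str, float]
    normalized: Mapping[str, float]
    undefined: tuple[str, ...]
    n_pulses: int
    n_baseline: int
    cumulative_energy: Mapping[str, float]


def compute_spectrum(trace: PulseTrace, settings: SpectralSettings) -> PulseSpectrum:
    """Magnitude spectrum of one pulse with the analysis-band mask.

    The band limit is applied as a frequency-domain mask (the energy
    spectral density is filtered, not the waveform).  A Hann window is
    applied first when ``settings.use_hann`` is set; the default is
    rectangular.
    """
    if trace.sampling_rate <= 2.0 * settings.band_high:
        raise ValueError(
            f"sampling_rate {trace.sampling_rate:g} Hz must exceed twice "
            f"band_high {settings.band_high:g} Hz to avoid aliasing"
        )
    x = trace.samples
    if settings.use_hann:
        x = x * np.hanning(x.size)
    amplitudes = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(x.size, d=1.0 / trace.sampling_rate)
    band_mask = (freqs >= settings.band_low) & (freqs <= settings.band_high)
    return PulseSpectrum(
        frequencies=freqs,
        amplitudes=amplitudes,
        band_mask=band_mask,
        n_samples=x.size,
        sampling_rate=trace.sampling_rate,
        pulse_index=trace.pulse_index,
        is_baseline=trace.is_baseline,
    )


def _window_mask(freqs: np.ndarray, center: float, width: float) -> np.ndarray:
    half = width / 2.0
    return (freqs >= center - half) & (freqs <= center + half)


def locate_tonal_peaks(
    spectrum: PulseSpectrum, settings: SpectralSettings
) -> dict[float, float]:
    """Peak spectral amplitude within the window centered on each tonal.

    Only tonal frequencies inside the analysis band are returned; the
    out-of-band ones are logged by :meth:`SpectralSettings.tonal_frequencies`.
    """
    df = spectrum.frequency_resolution
    if settings.peak_window_width < df:
        raise ValueError(
            f"peak window ({settings.peak_window_width:g} Hz) is narrower than "
            f"one frequency bin ({df:g} Hz); use longer pulses or zero-pad "
            "the trace before the FFT"
        )
    tonal = settings.tonal_frequencies()
    peaks: dict[float, float] = {}
    for f in tonal["harmonic"] + tonal["ultraharmonic"]:
        mask = _window_mask(spectrum.frequencies, f, settings.peak_window_width)
        peaks[f] = float(spectrum.amplitudes[mask].max()) if mask.any() else 0.0
    return peaks


def region_masks(
    spectrum: PulseSpectrum, settings: SpectralSettings
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Disjoint harmonic / ultraharmonic / residual masks within the band.

    Each in-band frequency bin belongs to exactly one region.  Harmonic
    windows take precedence over ultraharmonic windows on overlap, so the
    three regions always partition the band and the energy identity holds
    by construction.
    """
    tonal = settings.tonal_frequencies()
    freqs = spectrum.frequencies
    harm = np.zeros(freqs.size, dtype=bool)
    for f in tonal["harmonic"]:
        harm |= _window_mask(freqs, f, settings.peak_window_width)
    ultra = np.zeros(freqs.size, dtype=bool)
    for f in tonal["ultraharmonic"]:
        ultra |= _window_mask(freqs, f, settings.peak_window_width)
    harm &= spectrum.band_mask
    ultra &= spectrum.band_mask & ~harm
    resid = spectrum.band_mask & ~harm & ~ultra
    return harm, ultra, resid


def _rms(values: np.ndarray) -> float:
    if values.size == 0:
        return 0.0
    return float(np.sqrt(np.mean(values**2)))


def compute_pulse_dose(spectrum: PulseSpectrum, settings: SpectralSettings) -> PulseDose:
    """Decompose one pulse spectrum into SCDh, SCDu, ICD and total dose."""
    harm, ultra, resid = region_masks(spectrum, settings)
    if not resid.any():
        raise ValueError(
            "tonal windows cover the whole analysis band; the inertial "
            "(residual) region is empty — widen the band or narrow the windows"
        )
    a = spectrum.amplitudes
    return PulseDose(
        scdh=_rms(a[harm]),
        scdu=_rms(a[ultra]),
        icd=_rms(a[resid]),
        cd_total=_rms(a[spectrum.band_mask]),
        peak_amplitudes=locate_tonal_peaks(spectrum, settings),
        energy_harmonic=float(np.sum(a[harm] ** 2)),
        energy_ultraharmonic=float(np.sum(a[ultra] ** 2)),
        energy_residual=float(np.sum(a[resid] ** 2)),
        energy_band=float(np.sum(a[spectrum.band_mask] ** 2)),
        pulse_index=spectrum.pulse_index,
        is_baseline=spectrum.is_baseline,
    )


def accumulate_doses(
    doses: Sequence[PulseDose], baseline: Sequence[PulseDose]
) -> SonicationDoseSummary:
    """Accumulate per-pulse doses and normalize to the baseline mean."""
    if len(doses) < 1:
        raise ValueError("need at least one treatment pulse")
    if len(baseline) < 1:
        raise ValueError("need at least one baseline pulse")
    cumulative: dict[str, float] = {}
    baseline_mean: dict[str, float] = {}
    normalized: dict[str, float] = {}
    undefined: list[str] = []
    for name in DOSE_COMPONENTS:
        cum = float(sum(d.component(name) for d in doses))
        base = float(np.mean([d.component(name) for d in baseline]))
        cumulative[name] = cum
        baseline_mean[name] = base
        if base == 0.0:
            undefined.append(name)
            normalized[name] = math.nan
        else:
            normalized[name] = cum / (base * len(doses))
    energy_names = {
        "scdh": "energy_harmonic",
        "scdu": "energy_ultraharmonic",
        "icd": "energy_residual",
        "cd_total": "energy_band",
    }
    cumulative_energy = {
        name: float(sum(getattr(d, attr) for d in doses))
        for name, attr in energy_names.items()
    }
    return SonicationDoseSummary(
        cumulative=cumulative,
        baseline_mean=baseline_mean,
        normalized=normalized,
        undefined=tuple(undefined),
        n_pulses=len(doses),
        n_baseline=len(baseline),
        cumulative_energy=cumulative_energy,
    )


def analyze_sonication(
    traces: Iterable[PulseTrace], settings: SpectralSettings | None = None
) -> tuple[pd.DataFrame, SonicationDoseSummary]:
    """Full per-pulse pipeline: spectra, doses, accumulation.

    Traces flagged ``is_baseline`` form the normalization reference; the
    rest are treatment pulses.  Returns the per-pulse dose table (one row
    per pulse, baseline included and flagged) and the sonication summary.
    Traces are processed one at a time so long sonications never hold all
    waveforms in memory.
    """
    settings = settings or SpectralSettings()
    treatment: list[PulseDose] = []
    base: list[PulseDose] = []
    rows = []
    for trace in traces:
        dose = compute_pulse_dose(compute_spectrum(trace, settings), settings)
        (base if trace.is_baseline else treatment).append(dose)
        rows.append(
            {
                "pulse_index": dose.pulse_index,
                "is_baseline": dose.is_baseline,
                "scdh": dose.scdh,
                "scdu": dose.scdu,
                "icd": dose.icd,
                "cd_total": dose.cd_total,
            }
        )
    summary = accumulate_doses(treatment, base)
    return pd.DataFrame(rows), summary


def load_traces(path) -> list[PulseTrace]:
    """Read PCD pulses from the HDF5 layout written by the simulator.

    Layout: dataset ``traces`` of shape (n_pulses, n_samples), dataset
    ``is_baseline`` of per-pulse flags, file attributes ``sampling_rate``
    and ``center_frequency``.
    """
    with h5py.File(path, "r") as h5:
        traces = np.asarray(h5["traces"])
        flags = np.asarray(h5["is_baseline"]).astype(bool)
        fs = float(h5.attrs["sampling_rate"])
    return [
        PulseTrace(samples=row, sampling_rate=fs, pulse_index=i, is_baseline=bool(flags[i]))
        for i, row in enumerate(traces)
    ]
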