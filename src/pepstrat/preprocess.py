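"""Raw spectrum -> smoothed, baseline-corrected signal.

The pipeline order is fixed: variance-stabilising square-root
transform, Savitzky-Golay smoothing, then SNIP baseline estimation and
subtraction.  Each step appends to the spectrum's provenance so a
processed spectrum carries the full record of what produced it.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import savgol_filter

from .io import RawSpectrum


@dataclass
class ProcessedSpectrum:
    """A spectrum mid-pipeline: intensities in transformed units, the
    estimated baseline (if computed) and the ordered provenance of
    applied steps with their parameters."""

    mz: np.ndarray
    intensity: np.ndarray
    baseline: np.ndarray | None = None
    sample_id: str = ""
    group: str = ""
    replicate: int = 1
    provenance: list[tuple[str, dict]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must have equal length")

    def __len__(self) -> int:
        return int(self.mz.size)

    def with_step(self, name: str, params: dict, **changes) -> "ProcessedSpectrum":
        return replace(self, provenance=self.provenance + [(name, params)],
                       **changes)


def as_processed(s: RawSpectrum | ProcessedSpectrum) -> ProcessedSpectrum:
    """Lift a raw spectrum into the processed representation (no-op on
    an already processed one)."""
    if isinstance(s, ProcessedSpectrum):
        return s
    return ProcessedSpectrum(mz=s.mz.copy(), intensity=s.intensity.copy(),
                             sample_id=s.sample_id, group=s.group,
                             replicate=s.replicate)


def sqrt_transform(s: RawSpectrum | ProcessedSpectrum) -> ProcessedSpectrum:
    """Square-root transform the intensities (variance stabilisation
    for count-like detector noise).  m/z is unchanged."""
    p = as_processed(s)
    if np.any(p.intensity < 0):
        raise ValueError("sqrt transform requires non-negative intensities")
    return p.with_step("sqrt", {}, intensity=np.sqrt(p.intensity))


def tic_normalize(s: RawSpectrum | ProcessedSpectrum) -> ProcessedSpectrum:
    """Scale intensities to unit mean (total-ion-current style
    normalisation).  Off by default in the pipeline."""
    p = as_processed(s)
    total = p.intensity.mean()
    if total <= 0:
        raise ValueError("cannot TIC-normalise an all-zero spectrum")
    return p.with_step("tic", {}, intensity=p.intensity / total)


def savitzky_golay(s: RawSpectrum | ProcessedSpectrum, half_window: int,
                   polyorder: int) -> ProcessedSpectrum:
    """Savitzky-Golay smoothing: each point replaced by the centre
    value of the least-squares polynomial fit of degree ``polyorder``
    over a window of ``2*half_window + 1`` points; edges are handled by
    polynomial extrapolation from the first/last full window.

    Assumes a uniform (or near-uniform) m/z grid; warns if grid spacing
    varies by more than 1%.
    """
    p = as_processed(s)
    window = 2 * half_window + 1
    if window <= polyorder:
        raise ValueError("window length 2*half_window+1 must exceed polyorder")
    if len(p) < window:
        raise ValueError(f"spectrum of length {len(p)} shorter than smoothing "
                         f"window {window}")
    spacing = np.diff(p.mz)
    mean_step = spacing.mean()
    if mean_step > 0 and (spacing.max() - spacing.min()) / mean_step > 0.01:
        warnings.warn("m/z grid spacing varies by more than 1%; "
                      "Savitzky-Golay assumes a uniform grid", stacklevel=2)
    smoothed = savgol_filter(p.intensity, window_length=window,
                             polyorder=polyorder, mode="interp")
    return p.with_step("savitzky_golay",
                       {"half_window": half_window, "polyorder": polyorder},
                       intensity=smoothed)


def snip_baseline_curve(intensity: np.ndarray, iterations: int) -> np.ndarray:
    """SNIP baseline: iterative clipping with an increasing window.

    Starting from b = intensity, for window size i = 1..iterations each
    point is replaced by min(b_j, (b_{j-i} + b_{j+i}) / 2), boundary
    indices clamped.  No log-log-sqrt pre-transform is applied (the
    plain-intensity variant); the window grows with the iteration.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    n = intensity.size
    if iterations > n // 2:
        raise ValueError(f"iterations ({iterations}) exceed half the spectrum "
                         f"length ({n})")
    b = intensity.astype(float).copy()
    left = np.empty(n)
    right = np.empty(n)
    for i in range(1, iterations + 1):
        left[:i] = b[0]
        left[i:] = b[:-i]
        right[-i:] = b[-1]
        right[:-i] = b[i:]
        np.minimum(b, 0.5 * (left + right), out=b)
    return b


def snip_baseline(s: RawSpectrum | ProcessedSpectrum,
                  iterations: int) -> ProcessedSpectrum:
    """Estimate the baseline by SNIP clipping and subtract it; negative
    residuals are clipped to 0 (peak detection assumes a non-negative
    signal).  The baseline is stored on the returned spectrum."""
    p = as_processed(s)
    baseline = snip_baseline_curve(p.intensity, iterations)
    corrected = np.maximum(p.intensity - baseline, 0.0)
    return p.with_step("snip_baseline", {"iterations": iterations},
                       intensity=corrected, baseline=baseline)


def trim(s: RawSpectrum | ProcessedSpectrum, low: float,
         high: float) -> ProcessedSpectrum:
    """Keep only points with low <= m/z <= high (inclusive)."""
    if low >= high:
        raise ValueError("trim window low must be < high")
    p = as_processed(s)
    mask = (p.mz >= low) & (p.mz <= high)
    if not mask.any():
        raise ValueError(f"trim window [{low}, {high}] leaves no data points")
    baseline = p.baseline[mask] if p.baseline is not None else None
    return p.with_step("trim", {"low": low, "high": high},
                       mz=p.mz[mask], intensity=p.intensity[mask],
                       baseline=baseline)


def preprocess_spectrum(raw: RawSpectrum, config) -> ProcessedSpectrum:
    """Full preprocessing chain for one spectrum: trim to the analysis
    mass window, sqrt transform, smooth, SNIP baseline-correct."""
    s = trim(raw, *config.trim_range)
    s = sqrt_transform(s)
    if config.tic_normalize:
        s = tic_normalize(s)
    s = savitzky_golay(s, config.sg_half_window, config.sg_polyorder)
    s = snip_baseline(s, config.snip_iterations)
    return s
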