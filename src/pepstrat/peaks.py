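"""Peak detection, cross-spectrum binning, replicate averaging and
occurrence filtering.

Noise is one robust scalar per spectrum (scaled median absolute
deviation); a point is a peak when it is the strict maximum of its
+-half_window neighbourhood and at least SNR x noise high.  Peaks from
many spectra are aligned into shared bins by divisive gap-splitting
under a relative mass tolerance.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy.stats import median_abs_deviation

from .io import SampleManifest
from .preprocess import ProcessedSpectrum


@dataclass
class PeakList:
    """Detected peaks of one spectrum: (mz, intensity, snr) rows in
    ascending mass order."""

    sample_id: str
    replicate: int
    peaks: pd.DataFrame  # columns: mz, intensity, snr
    noise: float = np.nan

    def __post_init__(self) -> None:
        required = {"mz", "intensity", "snr"}
        if not required.issubset(self.peaks.columns):
            raise ValueError(f"peaks table needs columns {sorted(required)}")
        if len(self.peaks) > 1 and np.any(np.diff(self.peaks["mz"].values) <= 0):
            raise ValueError("peak m/z must be strictly increasing")

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def row_id(self) -> str:
        return f"{self.sample_id}::r{self.replicate}"


@dataclass
class PeakMatrix:
    """Samples x binned-peak intensity table.

    ``values``: rows indexed by row id, columns are bin reference
    masses (Da, floats); 0 marks an absent peak.  ``rows`` holds the
    per-row sample_id/replicate metadata (replicate is <NA> after
    averaging).
    """

    values: pd.DataFrame
    rows: pd.DataFrame  # columns: sample_id, replicate

    def __post_init__(self) -> None:
        refs = np.asarray(self.values.columns, dtype=float)
        if len(refs) > 1 and np.any(np.diff(refs) <= 0):
            raise ValueError("bin reference masses must be strictly increasing")
        if (self.values.values < 0).any():
            raise ValueError("peak intensities must be non-negative")
        if list(self.rows.index) != list(self.values.index):
            raise ValueError("rows metadata must align with the values index")

    @property
    def bin_refs(self) -> np.ndarray:
        return np.asarray(self.values.columns, dtype=float)

    @property
    def occurrence(self) -> pd.Series:
        """Per-bin fraction of rows in which the peak occurs
        (intensity > 0)."""
        return (self.values > 0).mean(axis=0)

    @property
    def n_samples(self) -> int:
        return len(self.values)

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def save(self, path) -> None:
        out = pd.concat([self.rows, self.values], axis=1)
        out.columns = (list(self.rows.columns)
                       + [f"{c:.6f}" for c in self.bin_refs])
        out.to_csv(path, index_label="row_id")

    @classmethod
    def load(cls, path) -> "PeakMatrix":
        raw = pd.read_csv(path, index_col="row_id")
        meta_cols = [c for c in ("sample_id", "replicate") if c in raw.columns]
        rows = raw[meta_cols].copy()
        rows["replicate"] = rows["replicate"].astype("Int64")
        values = raw.drop(columns=meta_cols)
        values.columns = [float(c) for c in values.columns]
        return cls(values=values, rows=rows)


# ---------------------------------------------------------------------------
# Noise and detection
# ---------------------------------------------------------------------------

def estimate_noise_mad(s: ProcessedSpectrum | np.ndarray) -> float:
    """Single-scalar spectrum noise: 1.4826 x median(|x - median(x)|),
    the Gaussian-consistent scaled MAD."""
    intensity = s.intensity if hasattr(s, "intensity") else np.asarray(s, float)
    if intensity.size < 3:
        raise ValueError("need at least 3 points to estimate noise")
    return float(median_abs_deviation(intensity, scale="normal"))


def detect_peaks(s: ProcessedSpectrum, snr: float,
                 half_window: int) -> PeakList:
    """Call peaks on a baseline-corrected spectrum.

    A point is a peak iff it is the strict maximum of the window of
    +-half_window points and its intensity is >= snr x noise (the
    "equal or higher" boundary convention).  Equal neighbouring maxima
    keep the lower-mass point.
    """
    x = s.intensity
    noise = estimate_noise_mad(x)
    padded = np.pad(x, half_window, constant_values=-np.inf)
    windows = sliding_window_view(padded, 2 * half_window + 1)
    left_max = windows[:, :half_window].max(axis=1)
    right_max = windows[:, half_window + 1:].max(axis=1)
    # strictly above the left neighbours, at-least the right ones:
    # a tie between neighbouring maxima resolves to the lower mass
    is_peak = (x > left_max) & (x >= right_max) & (x > 0)
    is_peak &= x >= snr * noise
    idx = np.flatnonzero(is_peak)
    table = pd.DataFrame({
        "mz": s.mz[idx],
        "intensity": x[idx],
        "snr": x[idx] / noise if noise > 0 else np.full(idx.size, np.inf),
    })
    return PeakList(sample_id=s.sample_id, replicate=s.replicate,
                    peaks=table, noise=noise)


# ---------------------------------------------------------------------------
# Binning
# ---------------------------------------------------------------------------

def _split_bins(masses: np.ndarray, tolerance: float) -> list[tuple[int, int]]:
    """Divisive binning of a sorted mass vector: recursively split at
    the largest gap until every bin satisfies
    max |mz - mean(bin)| / mean(bin) <= tolerance."""
    segments: list[tuple[int, int]] = []
    stack = [(0, masses.size)]
    while stack:
        lo, hi = stack.pop()
        seg = masses[lo:hi]
        mean = seg.mean()
        if np.abs(seg - mean).max() / mean <= tolerance or hi - lo == 1:
            segments.append((lo, hi))
            continue
        cut = int(np.argmax(np.diff(seg))) + 1
        stack.append((lo, lo + cut))
        stack.append((lo + cut, hi))
    return sorted(segments)


def bin_peaks(lists: list[PeakList], tolerance: float) -> PeakMatrix:
    """Align peaks across spectra into shared bins.

    Pooled peak masses are partitioned by divisive gap-splitting under
    the relative ``tolerance``; each bin's reference mass is the mean
    of its member masses.  If one spectrum contributes several peaks to
    a bin its most intense is kept; absent peaks are 0.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    if len(lists) < 2:
        raise ValueError("need at least 2 peak lists to bin")
    lists = sorted(lists, key=lambda pl: pl.row_id)
    records = []
    for li, pl in enumerate(lists):
        for mz, intensity in zip(pl.peaks["mz"].values,
                                 pl.peaks["intensity"].values):
            records.append((mz, li, intensity))
    if not records:
        raise ValueError("no peaks to bin in any input list")
    records.sort()
    masses = np.array([r[0] for r in records])
    segments = _split_bins(masses, tolerance)

    row_ids = [pl.row_id for pl in lists]
    refs = []
    values = np.zeros((len(lists), len(segments)))
    for j, (lo, hi) in enumerate(segments):
        refs.append(masses[lo:hi].mean())
        for mz, li, intensity in records[lo:hi]:
            if intensity > values[li, j]:  # keep the most intense per spectrum
                values[li, j] = intensity
    frame = pd.DataFrame(values, index=row_ids, columns=refs)
    rows = pd.DataFrame({
        "sample_id": [pl.sample_id for pl in lists],
        "replicate": pd.array([pl.replicate for pl in lists], dtype="Int64"),
    }, index=row_ids)
    return PeakMatrix(values=frame, rows=rows)


# ---------------------------------------------------------------------------
# Replicate averaging and occurrence filter
# ---------------------------------------------------------------------------

def average_replicates(m: PeakMatrix, manifest: SampleManifest) -> PeakMatrix:
    """Average replicate rows of each sample (absent peak = 0 in the
    mean); replicates flagged excluded in the manifest are dropped
    first.  One output row per sample, ordered as in the manifest."""
    key = manifest.table.set_index(
        manifest.table["sample_id"] + "::r" + manifest.table["replicate"].astype(str))
    averaged_input = m.rows["replicate"].isna().all()
    sample_rows: dict[str, list[str]] = {}
    for row_id, meta in m.rows.iterrows():
        sid = meta["sample_id"]
        if averaged_input:
            sample_rows.setdefault(sid, []).append(row_id)
            continue
        if row_id not in key.index:
            raise ValueError(f"matrix row {row_id!r} has no manifest entry")
        if key.loc[row_id, "excluded"]:
            continue
        sample_rows.setdefault(sid, []).append(row_id)
    order = [sid for sid in manifest.table["sample_id"].drop_duplicates()
             if sid in sample_rows]
    extra = [sid for sid in sample_rows if sid not in set(order)]
    values = pd.DataFrame(
        [m.values.loc[sample_rows[sid]].mean(axis=0) for sid in order + extra],
        index=order + extra)
    rows = pd.DataFrame({
        "sample_id": order + extra,
        "replicate": pd.array([pd.NA] * len(values), dtype="Int64"),
    }, index=values.index)
    return PeakMatrix(values=values, rows=rows)


def filter_occurrence(m: PeakMatrix, min_frac: float) -> PeakMatrix:
    """Drop bins occurring in fewer than ``min_frac`` of the rows
    (strictly-less-than convention); rows are unchanged."""
    if min_frac <= 0:
        return m
    keep = m.occurrence >= min_frac
    if not keep.any():
        raise ValueError(
            f"occurrence filter at {min_frac} removes every bin; lower "
            f"min_occurrence_frac (max occurrence is {m.occurrence.max():.3f})")
    return PeakMatrix(values=m.values.loc[:, keep].copy(), rows=m.rows.copy())
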