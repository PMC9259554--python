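"""Synthetic three-group MALDI-TOF spectrum datasets.

Generates whole-plasma-like linear-TOF profiles with controllable
class structure: every group shares a common peptidome backbone
(shared peaks) and carries its own enriched peaks with high in-group
and low out-group presence probability.  Biology is realised once per
sample (peak presences and lognormal intensities); each replicate adds
technical variation only (mass jitter, exponential matrix baseline,
additive Gaussian detector noise), which is what makes replicate
averaging meaningful downstream.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import RawSpectrum, SampleManifest

DEFAULT_GROUP_SIZES = {"CTL": 25, "IS": 22, "LPS": 29}


@dataclass
class GroupTemplate:
    """Per-group generative parameters over a common peak mass set."""

    group: str
    peak_mzs: np.ndarray          # Da, strictly increasing
    presence_probs: np.ndarray    # per-peak Bernoulli probability
    log_mean_intensity: np.ndarray
    log_sd: np.ndarray
    shared_mask: np.ndarray       # peaks common to all groups

    def __post_init__(self) -> None:
        self.peak_mzs = np.asarray(self.peak_mzs, dtype=float)
        self.presence_probs = np.asarray(self.presence_probs, dtype=float)
        self.log_mean_intensity = np.asarray(self.log_mean_intensity, dtype=float)
        self.log_sd = np.asarray(self.log_sd, dtype=float)
        self.shared_mask = np.asarray(self.shared_mask, dtype=bool)
        n = self.peak_mzs.size
        for name in ("presence_probs", "log_mean_intensity", "log_sd",
                     "shared_mask"):
            if getattr(self, name).size != n:
                raise ValueError(f"{name} must match peak_mzs length")
        if np.any(np.diff(self.peak_mzs) <= 0):
            raise ValueError("peak masses must be strictly increasing")
        if ((self.presence_probs < 0) | (self.presence_probs > 1)).any():
            raise ValueError("presence probabilities must be in [0, 1]")


@dataclass
class SimConfig:
    """Full description of a synthetic dataset.

    Defaults mirror the emulated study design: group sizes 25/22/29
    acquired in duplicate (152 spectra over 76 samples) on a
    2000-20000 Da axis.
    """

    templates: list[GroupTemplate]
    n_samples: dict[str, int]
    n_replicates: int = 2
    peak_width_sigma: float = 18.0   # Da, Gaussian peak shape
    mass_jitter_sd: float = 1.5      # Da, per-replicate apex jitter
    baseline_amplitude: float = 5.0  # counts at the low-mass edge
    baseline_decay: float = 3000.0   # Da, exponential decay constant
    noise_sd: float = 1.0            # counts, additive Gaussian
    grid_step: float = 3.0           # Da
    mass_range: tuple[float, float] = (2000.0, 20000.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.templates:
            raise ValueError("need at least one group template")
        for g, n in self.n_samples.items():
            if n < 2:
                raise ValueError(f"group {g!r} needs >= 2 samples")
        if set(self.n_samples) != {t.group for t in self.templates}:
            raise ValueError("n_samples groups must match template groups")
        for name in ("peak_width_sigma", "mass_jitter_sd", "noise_sd",
                     "grid_step", "baseline_amplitude", "baseline_decay"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.grid_step <= 0:
            raise ValueError("grid_step must be > 0")
        if self.grid_step > self.peak_width_sigma:
            raise ValueError("grid too coarse to resolve peak_width_sigma "
                             f"({self.grid_step} > {self.peak_width_sigma})")
        lo, hi = self.mass_range
        for t in self.templates:
            if t.peak_mzs.min() < lo or t.peak_mzs.max() > hi:
                raise ValueError("template peaks outside the mass range")
            if t.peak_mzs.size > 1:
                if np.diff(t.peak_mzs).min() <= 2 * self.peak_width_sigma:
                    raise ValueError("peak spacing must exceed the "
                                     "instrument peak width")

    def grid(self) -> np.ndarray:
        lo, hi = self.mass_range
        n = int(np.floor((hi - lo) / self.grid_step)) + 1
        return lo + self.grid_step * np.arange(n)


def default_study_config(seed: int = 0,
                              n_samples: dict[str, int] | None = None,
                              **overrides) -> SimConfig:
    """The reference study-like configuration.

    70 peaks on a 234-Da lattice from 2300 Da: 40 shared by all groups
    (presence 0.95) and 10 enriched per group (presence 0.9 in-group,
    mean 0.2 out-group); lognormal intensities around 150 counts
    (log-sd 0.35); duplicate spots per sample.  Enriched-peak presence
    is graded along the severity axis CTL < IS < LPS (0.3 in the
    adjacent state, 0.1 in the far one; IS-enriched peaks sit at 0.2 on
    both sides), mimicking inflammation markers that rise or fall
    monotonically with disease state rather than switching on in a
    single group.  Which lattice slots are shared vs enriched is a
    seeded permutation, so the template is deterministic given
    ``seed``.
    """
    if n_samples is None:
        n_samples = dict(DEFAULT_GROUP_SIZES)
    groups = sorted(n_samples)
    n_shared, per_group = 40, 10
    n_peaks = n_shared + per_group * len(groups)
    masses = 2300.0 + 234.0 * np.arange(n_peaks)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_peaks)
    shared_idx = perm[:n_shared]
    enriched_idx = {g: perm[n_shared + i * per_group:
                            n_shared + (i + 1) * per_group]
                    for i, g in enumerate(groups)}
    log_mean = np.log(150.0) + rng.normal(0.0, 0.25, size=n_peaks)
    shared_mask = np.zeros(n_peaks, dtype=bool)
    shared_mask[shared_idx] = True

    # out-group presence of enriched peaks, graded by severity
    # adjacency (defaults to the flat 0.2 for unknown label sets)
    out_group = {
        ("CTL", "IS"): 0.3, ("CTL", "LPS"): 0.1,
        ("IS", "CTL"): 0.2, ("IS", "LPS"): 0.2,
        ("LPS", "IS"): 0.3, ("LPS", "CTL"): 0.1,
    }
    templates = []
    for g in groups:
        probs = np.full(n_peaks, 0.2)
        probs[shared_idx] = 0.95
        for h in groups:
            if h != g:
                probs[enriched_idx[h]] = out_group.get((h, g), 0.2)
        probs[enriched_idx[g]] = 0.9
        templates.append(GroupTemplate(
            group=g, peak_mzs=masses, presence_probs=probs,
            log_mean_intensity=log_mean,
            log_sd=np.full(n_peaks, 0.35), shared_mask=shared_mask))
    return SimConfig(templates=templates, n_samples=dict(n_samples),
                     seed=seed, **overrides)


def _render_replicate(grid: np.ndarray, peak_mzs: np.ndarray,
                      heights: np.ndarray, sigma: float, baseline: np.ndarray,
                      noise: np.ndarray) -> np.ndarray:
    signal = baseline + noise
    step = grid[1] - grid[0]
    half = int(np.ceil(6 * sigma / step))
    for mz, h in zip(peak_mzs, heights):
        if h <= 0:
            continue
        center = int(round((mz - grid[0]) / step))
        lo = max(center - half, 0)
        hi = min(center + half + 1, grid.size)
        signal[lo:hi] += h * np.exp(-0.5 * ((grid[lo:hi] - mz) / sigma) ** 2)
    return np.maximum(signal, 0.0)


def generate_dataset(cfg: SimConfig, seed: int | None = None,
                     ) -> tuple[list[RawSpectrum], SampleManifest, pd.DataFrame]:
    """Draw a full dataset: spectra, their manifest, and the realised
    per-sample truth table (for recovery tests).

    Peak presences and intensities are drawn once per sample and shared
    across its replicates; each replicate gets its own mass jitter,
    baseline and noise.  Byte-identical output for the same seed.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    grid = cfg.grid()
    lo = cfg.mass_range[0]
    baseline = cfg.baseline_amplitude * np.exp(-(grid - lo) / cfg.baseline_decay)

    spectra: list[RawSpectrum] = []
    manifest_rows = []
    truth_rows = []
    templates = {t.group: t for t in cfg.templates}
    for g in sorted(cfg.n_samples):
        t = templates[g]
        for i in range(cfg.n_samples[g]):
            sample_id = f"{g}{i + 1:02d}"
            present = rng.random(t.peak_mzs.size) < t.presence_probs
            heights = np.where(
                present,
                rng.lognormal(t.log_mean_intensity, t.log_sd), 0.0)
            for mz, p, h in zip(t.peak_mzs, present, heights):
                truth_rows.append((sample_id, g, mz, int(p), h))
            for r in range(1, cfg.n_replicates + 1):
                jitter = rng.normal(0.0, cfg.mass_jitter_sd, t.peak_mzs.size)
                noise = rng.normal(0.0, cfg.noise_sd, grid.size)
                intensity = _render_replicate(grid, t.peak_mzs + jitter,
                                              heights, cfg.peak_width_sigma,
                                              baseline, noise)
                spectra.append(RawSpectrum(grid.copy(), intensity,
                                           sample_id=sample_id, group=g,
                                           replicate=r))
                manifest_rows.append({"sample_id": sample_id, "group": g,
                                      "replicate": r, "file_path": "",
                                      "excluded": False})
    manifest = SampleManifest(pd.DataFrame(manifest_rows))
    truth = pd.DataFrame(truth_rows, columns=["sample_id", "group", "peak_mz",
                                              "present", "intensity"])
    return spectra, manifest, truth
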