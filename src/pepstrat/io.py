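"""Spectrum and manifest I/O, pipeline configuration, run logging.

The native spectrum format is two-column delimited text (m/z in Da,
intensity in arbitrary counts); an mzML reader is provided for
interoperability with vendor-exported data.  All tabular artifacts are
CSV with headers so that every intermediate of a run can be inspected
and round-tripped.
"""
from __future__ import annotations

import dataclasses
import datetime
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("pepstrat")

MANIFEST_COLUMNS = ("sample_id", "group", "replicate")


# ---------------------------------------------------------------------------
# Raw spectrum
# ---------------------------------------------------------------------------

@dataclass
class RawSpectrum:
    """One acquisition: paired m/z (Da) and intensity vectors plus metadata.

    On construction the points are sorted by ascending m/z; duplicate
    masses or negative intensities are rejected rather than silently
    coerced.
    """

    mz: np.ndarray
    intensity: np.ndarray
    sample_id: str = ""
    group: str = ""
    replicate: int = 1

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.ndim != 1 or self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must be 1-D vectors of equal length")
        if self.mz.size < 2:
            raise ValueError("a spectrum needs at least 2 data points")
        order = np.argsort(self.mz, kind="stable")
        if not np.array_equal(order, np.arange(self.mz.size)):
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]
        if np.any(np.diff(self.mz) <= 0):
            raise ValueError("duplicate m/z values in spectrum")
        if np.any(self.intensity < 0):
            raise ValueError("negative intensities in spectrum")

    def __len__(self) -> int:
        return int(self.mz.size)


def _parse_delimited(path: Path, sep: str | None) -> tuple[np.ndarray, np.ndarray]:
    mz: list[float] = []
    intensity: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(sep)
            try:
                m, y = float(parts[0]), float(parts[1])
            except (ValueError, IndexError):
                if lineno == 1:  # tolerate a header row
                    continue
                raise ValueError(
                    f"{path}: cannot parse line {lineno}: {line!r}"
                ) from None
            mz.append(m)
            intensity.append(y)
    return np.asarray(mz), np.asarray(intensity)


def _decode_binary_array(node) -> np.ndarray | None:
    """Decode one <binaryDataArray>: returns the vector, or None when
    it is neither the m/z nor the intensity array."""
    import base64
    import zlib

    dtype, compressed, kind = np.float64, False, None
    payload = ""
    for child in node:
        tag = child.tag.rsplit("}", 1)[-1]
        if tag == "cvParam":
            acc = child.get("accession", "")
            if acc == "MS:1000523":
                dtype = np.float64
            elif acc == "MS:1000521":
                dtype = np.float32
            elif acc == "MS:1000574":
                compressed = True
            elif acc == "MS:1000514":
                kind = "mz"
            elif acc == "MS:1000515":
                kind = "intensity"
        elif tag == "binary":
            payload = child.text or ""
    if kind is None:
        return None
    raw = base64.b64decode(payload)
    if compressed:
        raw = zlib.decompress(raw)
    arr = np.frombuffer(raw, dtype=dtype).astype(float)
    return arr, kind


def _read_mzml(path: Path) -> tuple[np.ndarray, np.ndarray]:
    """First spectrum of an mzML file.

    pyteomics is preferred when its PSI-schema support is importable;
    otherwise a minimal built-in decoder handles plain profile mzML
    (64/32-bit float arrays, zlib or no compression).
    """
    try:
        from pyteomics import mzml

        with mzml.read(str(path)) as reader:
            for entry in reader:
                return (np.asarray(entry["m/z array"], dtype=float),
                        np.asarray(entry["intensity array"], dtype=float))
        raise ValueError(f"{path}: mzML file contains no spectra")
    except Exception as exc:  # fall back to the built-in decoder
        if isinstance(exc, ValueError):
            raise
        logger.debug("pyteomics mzML parsing unavailable (%s); using the "
                     "built-in decoder", exc)
    import xml.etree.ElementTree as ET

    tree = ET.parse(path)
    arrays: dict[str, np.ndarray] = {}
    for node in tree.iter():
        if node.tag.rsplit("}", 1)[-1] == "binaryDataArray":
            decoded = _decode_binary_array(node)
            if decoded is not None:
                arr, kind = decoded
                arrays.setdefault(kind, arr)
        if len(arrays) == 2:
            break
    if set(arrays) != {"mz", "intensity"}:
        raise ValueError(f"{path}: no m/z + intensity array pair found")
    return arrays["mz"], arrays["intensity"]


def read_spectrum(path: str | Path, format: str | None = None,
                  sample_id: str = "", group: str = "",
                  replicate: int = 1) -> RawSpectrum:
    """Read a spectrum from two-column text (tsv/csv) or mzML.

    ``format`` is inferred from the file suffix when not given.  Input
    rows out of mass order are sorted; duplicate masses raise.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        suffix = path.suffix.lower()
        format = {"mzml": "mzml", ".mzml": "mzml", ".csv": "csv"}.get(suffix, "tsv")
    if format == "mzml":
        mz, intensity = _read_mzml(path)
    elif format == "csv":
        mz, intensity = _parse_delimited(path, ",")
    elif format == "tsv":
        mz, intensity = _parse_delimited(path, None)
    else:
        raise ValueError(f"unknown spectrum format: {format!r}")
    if mz.size < 2:
        raise ValueError(f"{path}: fewer than 2 data points")
    return RawSpectrum(mz, intensity, sample_id=sample_id, group=group,
                       replicate=replicate)


def write_spectrum(spectrum, path: str | Path) -> None:
    """Write a spectrum (raw or processed) as tab-separated text."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("mz\tintensity\n")
        for m, y in zip(spectrum.mz, spectrum.intensity):
            fh.write(f"{m:.10g}\t{y:.10g}\n")


# ---------------------------------------------------------------------------
# Sample manifest
# ---------------------------------------------------------------------------

@dataclass
class SampleManifest:
    """Rows of (sample_id, group, replicate[, file_path, excluded]).

    ``excluded`` flags replicates dropped for quality before averaging.
    Group labels are arbitrary strings; a three-group CTL/IS/LPS design
    is just a special case.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in MANIFEST_COLUMNS if c not in t.columns]
        if missing:
            raise ValueError(f"manifest missing required columns: {missing}")
        if len(t) == 0:
            raise ValueError("manifest has no data rows")
        t = t.copy()
        t["sample_id"] = t["sample_id"].astype(str)
        t["group"] = t["group"].astype(str)
        t["replicate"] = t["replicate"].astype(int)
        if (t["replicate"] < 1).any():
            raise ValueError("replicate indices must be >= 1")
        if "excluded" not in t.columns:
            t["excluded"] = False
        t["excluded"] = t["excluded"].astype(bool)
        dup = t.duplicated(subset=["sample_id", "replicate"])
        if dup.any():
            pairs = t.loc[dup, ["sample_id", "replicate"]].values.tolist()
            raise ValueError(f"duplicated (sample_id, replicate) rows: {pairs}")
        ambiguous = t.groupby("sample_id")["group"].nunique()
        if (ambiguous > 1).any():
            raise ValueError("a sample_id maps to more than one group")
        self.table = t.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def active(self) -> pd.DataFrame:
        """Rows not flagged excluded."""
        return self.table[~self.table["excluded"]]

    @property
    def n_spectra(self) -> int:
        """Effective spectrum count after exclusions."""
        return int(len(self.active))

    def group_counts(self) -> dict[str, int]:
        """Unique samples per group (exclusion of one replicate does not
        remove the sample)."""
        g = self.table.drop_duplicates("sample_id").groupby("group").size()
        return g.to_dict()

    def sample_groups(self) -> pd.Series:
        """Map sample_id -> group label."""
        t = self.table.drop_duplicates("sample_id")
        return pd.Series(t["group"].values, index=t["sample_id"].values)


def read_manifest(path: str | Path, check_files: bool = False) -> SampleManifest:
    path = Path(path)
    table = pd.read_csv(path)
    if len(table) == 0:
        raise ValueError(f"{path}: manifest has no data rows")
    manifest = SampleManifest(table)
    if check_files and "file_path" in manifest.table.columns:
        base = path.parent
        missing = [p for p in manifest.table["file_path"]
                   if p and not (base / str(p)).exists() and not Path(str(p)).exists()]
        if missing:
            raise FileNotFoundError(f"manifest references missing files: {missing}")
    counts = manifest.group_counts()
    logger.info("manifest: %d rows, samples per group %s", len(manifest), counts)
    return manifest


def write_manifest(manifest: SampleManifest, path: str | Path) -> None:
    manifest.table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """All tunable constants of the analysis pipeline.

    Defaults follow the published analysis protocol (2000-20000 Da
    window, SNIP over 100 iterations, SNR 4, half window 40 points,
    33% occurrence filter, 60/40 split, 5-fold / 20-repeat CV) with two
    deliberate exceptions documented in the methods note: the binning
    tolerance defaults to the toolchain-conventional 0.002 (relative)
    and the cluster count defaults to 3.  ``protocol_profile`` restores
    the literal protocol values (tolerance 0.2, k=4).
    """

    trim_range: tuple[float, float] = (2000.0, 20000.0)
    sg_half_window: int = 10
    sg_polyorder: int = 3
    snip_iterations: int = 100
    snr: float = 4.0
    peak_half_window: int = 40
    bin_tolerance: float = 0.002
    min_occurrence_frac: float = 0.33
    top_k: int = 10
    n_clusters: int = 3
    cv_folds: int = 5
    cv_repeats: int = 20
    train_frac: float = 0.6
    seed: int = 0
    n_trees: int = 500
    tic_normalize: bool = False
    binarize_mode: str = "pooled"  # or "class_mean_mixture"
    positive_groups: tuple[str, ...] = ("IS", "LPS")

    def __post_init__(self) -> None:
        self.trim_range = tuple(float(v) for v in self.trim_range)
        if self.trim_range[0] >= self.trim_range[1]:
            raise ValueError("trim_range low must be < high")
        for name in ("sg_half_window", "peak_half_window", "snip_iterations",
                     "cv_folds", "cv_repeats", "n_clusters", "top_k", "n_trees"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 < self.min_occurrence_frac < 1:
            raise ValueError("min_occurrence_frac must be in (0, 1)")
        if not 0 < self.train_frac < 1:
            raise ValueError("train_frac must be in (0, 1)")
        if self.bin_tolerance <= 0:
            raise ValueError("bin_tolerance must be > 0")
        if self.binarize_mode not in ("pooled", "class_mean_mixture"):
            raise ValueError(f"unknown binarize_mode: {self.binarize_mode!r}")
        self.positive_groups = tuple(self.positive_groups)

    @classmethod
    def protocol_profile(cls, **overrides) -> "PipelineConfig":
        """Configuration with the literal protocol constants (binning
        tolerance 0.2 relative, k=4)."""
        params = dict(bin_tolerance=0.2, n_clusters=4)
        params.update(overrides)
        return cls(**params)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["trim_range"] = list(self.trim_range)
        data["positive_groups"] = list(self.positive_groups)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def write_run_log(outdir: str | Path, config: PipelineConfig, seed: int,
                  command: str = "") -> Path:
    """Record the resolved configuration and seed of a run.

    Every CLI invocation writes one of these; the file is the
    reproducibility contract of a run.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "run_log.txt"
    data = dataclasses.asdict(config)
    data["trim_range"] = list(config.trim_range)
    data["positive_groups"] = list(config.positive_groups)
    with open(path, "a") as fh:
        fh.write(f"# {datetime.datetime.now().isoformat()} command={command} "
                 f"seed={seed}\n")
        yaml.safe_dump(data, fh, sort_keys=False)
        fh.write("---\n")
    return path


# ---------------------------------------------------------------------------
# Generic tables
# ---------------------------------------------------------------------------

def write_table(table: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    table.to_csv(path, index=index)


def read_table(path: str | Path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, index_col=index_col)
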