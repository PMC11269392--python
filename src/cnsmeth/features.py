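"""Methylation-call handling and atlas-aligned binary features.

Nanopore low-pass WGS yields sparse per-CpG methylation fractions (beta
values). For classification these are binarized (methylated iff beta >= 0.6)
and aligned to a reference atlas of binary CpG profiles; the number of
atlas CpGs covered by a case is the quality-control quantity (minimum
1,000 overlapping sites for a meaningful call).

Coordinates are 0-based half-open (bedGraph/BED dialect) throughout, and a
CpG site is identified by (chrom, start).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ParseError",
    "MethylationCalls",
    "ReferenceAtlas",
    "BinaryFeatureVector",
    "QCVerdict",
    "read_methylation_calls",
    "write_methylation_calls",
    "binarize",
    "filter_zero_variance",
    "align_to_atlas",
    "qc_check",
    "DEFAULT_BETA_THRESHOLD",
    "DEFAULT_MIN_CPGS",
]

DEFAULT_BETA_THRESHOLD = 0.6
DEFAULT_MIN_CPGS = 1000

CALL_COLUMNS = ["chrom", "start", "end", "beta", "n_calls"]


class ParseError(ValueError):
    """Raised for malformed methylation-call input, with line numbers."""


@dataclass
class MethylationCalls:
    """Per-case sparse methylation calls, coordinate-sorted.

    ``df`` has columns (chrom, start, end, beta, n_calls); (chrom, start)
    is unique per record.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in CALL_COLUMNS if c not in self.df.columns]
        if missing:
            raise ParseError(f"methylation calls missing columns: {missing}")
        self.df = self.df[CALL_COLUMNS].sort_values(["chrom", "start"]).reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def sites(self) -> pd.MultiIndex:
        return pd.MultiIndex.from_arrays(
            [self.df["chrom"], self.df["start"]], names=["chrom", "start"]
        )


@dataclass
class ReferenceAtlas:
    """Binary CpG x sample reference with class labels and a class->family map.

    ``matrix`` is (n_samples, n_sites) with entries in {0, 1};
    ``cpg_index`` is a DataFrame (chrom, start) sorted by coordinate;
    ``labels`` assigns a methylation class (MC) to every sample and
    ``hierarchy`` maps each class to exactly one methylation class
    family (MCF).
    """

    cpg_index: pd.DataFrame
    matrix: np.ndarray
    labels: np.ndarray
    hierarchy: dict[str, str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.uint8)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.matrix.ndim != 2:
            raise ValueError("atlas matrix must be 2-D (samples x CpGs)")
        if self.matrix.shape != (len(self.labels), len(self.cpg_index)):
            raise ValueError(
                f"atlas shape {self.matrix.shape} inconsistent with "
                f"{len(self.labels)} labels x {len(self.cpg_index)} CpGs"
            )
        if not np.isin(self.matrix, (0, 1)).all():
            raise ValueError("atlas matrix entries must be binary")
        idx = self.cpg_index.reset_index(drop=True)
        if not idx.equals(idx.sort_values(["chrom", "start"]).reset_index(drop=True)):
            raise ValueError("cpg_index must be sorted by (chrom, start)")
        self.cpg_index = idx
        for cls in np.unique(self.labels):
            if cls not in self.hierarchy:
                raise ValueError(f"class {cls!r} missing from class->family hierarchy")

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.labels))

    def site_index(self) -> pd.MultiIndex:
        return pd.MultiIndex.from_frame(self.cpg_index[["chrom", "start"]])


@dataclass
class BinaryFeatureVector:
    """Atlas-aligned binary profile with missingness.

    ``values`` has one entry per atlas CpG: 0.0, 1.0 or NaN (missing);
    ``observed_count`` equals the number of non-missing entries.
    """

    values: np.ndarray
    observed_count: int = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        obs = ~np.isnan(self.values)
        if not np.isin(self.values[obs], (0.0, 1.0)).all():
            raise ValueError("observed feature values must be 0 or 1")
        self.observed_count = int(obs.sum())

    @property
    def observed_mask(self) -> np.ndarray:
        return ~np.isnan(self.values)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class QCVerdict:
    """CpG-overlap quality gate. Failing cases are flagged for an
    additional sequencing run, not dropped."""

    passed: bool
    observed_count: int
    min_cpgs: int

    @property
    def message(self) -> str:
        if self.passed:
            return f"QC pass: {self.observed_count} CpG sites overlap the atlas (>= {self.min_cpgs})"
        return (
            f"QC fail: only {self.observed_count} CpG sites overlap the atlas "
            f"(< {self.min_cpgs}); an additional sequencing run is recommended"
        )


def read_methylation_calls(path: str | Path | io.TextIOBase) -> MethylationCalls:
    """Parse a bedGraph-like methylation-call TSV.

    Expected header: chrom, start, end, beta, n_calls. Malformed rows are
    rejected with their line number.
    """
    if isinstance(path, (str, Path)):
        handle: io.TextIOBase = open(path)
        close = True
    else:
        handle, close = path, False
    try:
        header = handle.readline().rstrip("\n").split("\t")
        if header != CALL_COLUMNS:
            raise ParseError(
                f"bad header {header}; expected {CALL_COLUMNS} (tab-separated)"
            )
        rows = []
        seen: set[tuple[str, int]] = set()
        for lineno, line in enumerate(handle, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise ParseError(f"line {lineno}: expected 5 fields, got {len(parts)}")
            chrom, start_s, end_s, beta_s, n_s = parts
            try:
                start, end = int(start_s), int(end_s)
                beta = float(beta_s)
                n_calls = int(n_s)
            except ValueError as exc:
                raise ParseError(f"line {lineno}: {exc}") from None
            if not 0.0 <= beta <= 1.0:
                raise ParseError(f"line {lineno}: beta {beta} outside [0, 1]")
            if start >= end:
                raise ParseError(f"line {lineno}: start {start} >= end {end}")
            if n_calls < 0:
                raise ParseError(f"line {lineno}: negative call count {n_calls}")
            if (chrom, start) in seen:
                raise ParseError(f"line {lineno}: duplicate site ({chrom}, {start})")
            seen.add((chrom, start))
            rows.append((chrom, start, end, beta, n_calls))
    finally:
        if close:
            handle.close()
    df = pd.DataFrame(rows, columns=CALL_COLUMNS)
    return MethylationCalls(df)


def write_methylation_calls(calls: MethylationCalls, path: str | Path) -> None:
    calls.df.to_csv(path, sep="\t", index=False)


def binarize(calls: MethylationCalls, threshold: float = DEFAULT_BETA_THRESHOLD) -> pd.Series:
    """Binarize beta values: methylated iff beta >= threshold.

    The boundary is methylated by definition (a site at exactly the
    threshold counts as methylated). Returns a series of {0, 1} indexed by
    (chrom, start); the site set is unchanged.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    states = (calls.df["beta"].to_numpy() >= threshold).astype(np.uint8)
    return pd.Series(states, index=calls.sites, name="state")


def filter_zero_variance(atlas: ReferenceAtlas) -> ReferenceAtlas:
    """Drop CpG columns constant across all reference samples.

    Order of the remaining columns is preserved; applying the filter twice
    equals applying it once.
    """
    if atlas.n_sites == 0 or atlas.n_samples == 0:
        raise ValueError("cannot filter an empty atlas")
    col_min = atlas.matrix.min(axis=0)
    col_max = atlas.matrix.max(axis=0)
    keep = col_min != col_max
    if not keep.any():
        raise ValueError("degenerate atlas: every CpG column is constant")
    return ReferenceAtlas(
        cpg_index=atlas.cpg_index.loc[keep].reset_index(drop=True),
        matrix=atlas.matrix[:, keep],
        labels=atlas.labels,
        hierarchy=dict(atlas.hierarchy),
    )


def align_to_atlas(site_map: pd.Series | Mapping[tuple[str, int], int],
                   atlas: ReferenceAtlas) -> BinaryFeatureVector:
    """Project a case's binary site map onto the atlas CpG space.

    Atlas CpGs covered by the case take the case's binary state; all other
    atlas CpGs are missing (NaN). ``observed_count`` is the overlap size.
    """
    if not isinstance(site_map, pd.Series):
        if len(site_map) == 0:
            site_map = pd.Series(
                [], index=pd.MultiIndex.from_arrays([[], []], names=["chrom", "start"]),
                dtype=float,
            )
        else:
            site_map = pd.Series(
                list(site_map.values()),
                index=pd.MultiIndex.from_tuples(site_map.keys(), names=["chrom", "start"]),
            )
    values = np.full(atlas.n_sites, np.nan)
    pos = atlas.site_index().get_indexer(site_map.index)
    hit = pos >= 0
    values[pos[hit]] = site_map.to_numpy(dtype=float)[hit]
    return BinaryFeatureVector(values)


def save_atlas(atlas: ReferenceAtlas, path: str | Path) -> None:
    """Serialize an atlas to a single .npz (matrix, coordinates, labels,
    class->family hierarchy)."""
    import json

    np.savez_compressed(
        path,
        matrix=atlas.matrix,
        chrom=atlas.cpg_index["chrom"].to_numpy(dtype=object),
        start=atlas.cpg_index["start"].to_numpy(dtype=np.int64),
        labels=atlas.labels,
        hierarchy=np.frombuffer(json.dumps(atlas.hierarchy).encode(), dtype=np.uint8),
    )


def load_atlas(path: str | Path) -> ReferenceAtlas:
    import json

    with np.load(path, allow_pickle=True) as data:
        return ReferenceAtlas(
            cpg_index=pd.DataFrame({"chrom": data["chrom"], "start": data["start"]}),
            matrix=data["matrix"],
            labels=data["labels"],
            hierarchy=json.loads(bytes(data["hierarchy"]).decode()),
        )


def qc_check(vector: BinaryFeatureVector, min_cpgs: int = DEFAULT_MIN_CPGS) -> QCVerdict:
    """Overlap QC: pass iff at least ``min_cpgs`` atlas CpGs are observed
    (the minimum itself passes)."""
    return QCVerdict(
        passed=vector.observed_count >= min_cpgs,
        observed_count=vector.observed_count,
        min_cpgs=min_cpgs,
    )
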