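"""Copy-number profiling from binned low-pass WGS counts, and tumor-purity
estimation from segmented profiles.

Pipeline: fixed-width binning of read counts -> log2 normalization against
the autosomal median -> subtraction of a matched normal-reference profile
(log space) -> recursive binary segmentation with permutation-tested
breakpoints -> focal-event detection and cellularity/ploidy grid fitting.

A segment of integer copy number n in a tumor of cellularity alpha and
tumor ploidy P has expected log2 ratio

    log2( (alpha*n + 2*(1-alpha)) / (alpha*P + 2*(1-alpha)) )

relative to the diploid admixture; purity is the grid argmin of the
length-weighted squared distance of segment means to their nearest integer
copy state. Estimation requires numerical chromosomal alterations: a
near-flat profile is reported as unidentifiable rather than assigned a
default cellularity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import DEFAULT_BIN_SIZE, GenomeModel

__all__ = [
    "BinProfile",
    "SegmentSet",
    "FocalEvent",
    "PurityFit",
    "bin_counts",
    "normalize",
    "subtract_reference",
    "segment",
    "detect_focal_events",
    "estimate_purity",
    "plot_profile",
]

_LOG2_EPS = 1e-6


@dataclass
class BinProfile:
    """Ordered genome bins with one value per bin and a mask.

    ``stage`` tags the processing state: "raw" (counts), "normalized"
    (log2 ratio vs autosomal median) or "corrected" (reference-subtracted).
    Masked bins carry NaN values downstream.
    """

    bins: pd.DataFrame
    values: np.ndarray
    stage: str
    mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.bins = self.bins.reset_index(drop=True)
        self.values = np.asarray(self.values, dtype=float)
        if self.mask is None:
            self.mask = np.zeros(len(self.bins), dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if not (len(self.bins) == len(self.values) == len(self.mask)):
            raise ValueError("bins, values and mask must have equal length")
        if self.stage not in ("raw", "normalized", "corrected"):
            raise ValueError(f"unknown stage {self.stage!r}")
        for chrom, grp in self.bins.groupby("chrom", sort=False):
            starts, ends = grp["start"].to_numpy(), grp["end"].to_numpy()
            if (starts[1:] < ends[:-1]).any():
                raise ValueError(f"overlapping or unsorted bins on {chrom}")

    def __len__(self) -> int:
        return len(self.bins)

    @property
    def unmasked(self) -> np.ndarray:
        return ~self.mask

    def autosomal(self) -> np.ndarray:
        """Boolean selector for bins on numerically named chromosomes."""
        chroms = self.bins["chrom"].astype(str)
        return chroms.str.lstrip("chr").str.isdigit().to_numpy()

    def same_grid(self, other: "BinProfile") -> bool:
        return self.bins[["chrom", "start", "end"]].equals(
            other.bins[["chrom", "start", "end"]]
        )

    def to_frame(self) -> pd.DataFrame:
        out = self.bins.copy()
        out["value"] = self.values
        out["masked"] = self.mask
        return out

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class SegmentSet:
    """Piecewise-constant segmentation of a corrected profile.

    ``df`` columns: chrom, start, end, mean_log2, n_bins. Segments are
    contiguous per chromosome. ``residual_sd`` is the genome-wide SD of
    bin values around their segment means.
    """

    df: pd.DataFrame
    residual_sd: float

    def __post_init__(self) -> None:
        required = ["chrom", "start", "end", "mean_log2", "n_bins"]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise ValueError(f"segment table missing columns: {missing}")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def widths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy()

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


@dataclass
class FocalEvent:
    """A narrow copy-number event relative to its flanking segments."""

    chrom: str
    start: int
    end: int
    direction: str  # "gain" | "loss"
    mean_log2: float
    delta_log2: float  # vs length-weighted flank mean
    width: int
    annotation: str = ""


@dataclass
class PurityFit:
    """Cellularity/ploidy fit. When unidentifiable, cellularity is absent
    (None), never a default value."""

    identifiable: bool
    cellularity: float | None
    ploidy: float | None
    fit_error: float | None
    copy_assignments: np.ndarray | None
    reason: str = ""
    aneuploid_fraction: float = float("nan")


def _read_counts(source: str | Path | pd.DataFrame) -> pd.DataFrame:
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source, sep="\t")
    required = ["chrom", "start", "end", "count"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"count table missing columns: {missing}")
    return df


def bin_counts(
    counts: str | Path | pd.DataFrame,
    genome: GenomeModel,
    bin_size: int = DEFAULT_BIN_SIZE,
    min_count: int = 0,
) -> BinProfile:
    """Tile the genome with fixed-width bins and accumulate interval counts.

    Each input interval is assigned to the bin containing its midpoint.
    Bins with total count below ``min_count`` are masked (default: no
    floor; use a floor such as 10 for normal-reference profiles).
    """
    df = _read_counts(counts)
    if (df["count"] < 0).any():
        raise ValueError("negative counts in input")
    bins = genome.bins(bin_size)
    values = np.zeros(len(bins))
    offsets: dict[str, int] = {}
    n_chrom_bins: dict[str, int] = {}
    off = 0
    for chrom, grp in bins.groupby("chrom", sort=False):
        offsets[chrom] = off
        n_chrom_bins[chrom] = len(grp)
        off += len(grp)
    for chrom, start, end, count in df[["chrom", "start", "end", "count"]].itertuples(index=False):
        if chrom not in offsets:
            raise ValueError(f"unknown chromosome {chrom!r}")
        if not genome.contains(chrom, int(start), int(end)):
            raise ValueError(f"interval {chrom}:{start}-{end} outside genome model")
        mid = (int(start) + int(end)) // 2
        values[offsets[chrom] + min(mid // bin_size, n_chrom_bins[chrom] - 1)] += count
    mask = values < min_count
    return BinProfile(bins=bins, values=values, stage="raw", mask=mask)


def normalize(profile: BinProfile) -> BinProfile:
    """Convert raw counts to log2 ratios against the unmasked autosomal
    median count. Zero-count bins are masked (log2 undefined)."""
    if profile.stage != "raw":
        raise ValueError("normalize expects a raw count profile")
    mask = profile.mask | (profile.values <= 0)
    usable = ~mask & profile.autosomal()
    if not usable.any():
        raise ValueError("no unmasked autosomal bins to normalize against")
    med = float(np.median(profile.values[usable]))
    if med <= 0:
        raise ValueError("autosomal median count is zero")
    values = np.full(len(profile), np.nan)
    values[~mask] = np.log2(profile.values[~mask] / med)
    return BinProfile(bins=profile.bins, values=values, stage="normalized", mask=mask)


def subtract_reference(tumor: BinProfile, reference: BinProfile) -> BinProfile:
    """Subtract a normalized normal-reference profile (log space) to remove
    region- and platform-specific artifacts."""
    if tumor.stage != "normalized" or reference.stage != "normalized":
        raise ValueError("subtract_reference expects two normalized profiles")
    if not tumor.same_grid(reference):
        raise ValueError("tumor and reference bin grids differ")
    mask = tumor.mask | reference.mask
    values = np.where(mask, np.nan, tumor.values - reference.values)
    return BinProfile(bins=tumor.bins, values=values, stage="corrected", mask=mask)


def _t_statistics(x: np.ndarray, min_bins: int) -> np.ndarray:
    """Pooled two-sample t statistic for every admissible split of x.

    Entry k is the statistic for left part x[:k]; inadmissible splits are
    -inf. Maximizing |t| is equivalent to minimizing the two-segment SSE.
    """
    n = len(x)
    out = np.full(n, -np.inf)
    if n < 2 * min_bins:
        return out
    ks = np.arange(min_bins, n - min_bins + 1)
    cs = np.cumsum(x)
    css = np.cumsum(x * x)
    sl, sr = cs[ks - 1], cs[-1] - cs[ks - 1]
    ssl = css[ks - 1] - sl * sl / ks
    ssr = (css[-1] - css[ks - 1]) - sr * sr / (n - ks)
    diff = np.abs(sl / ks - sr / (n - ks))
    with np.errstate(divide="ignore", invalid="ignore"):
        sp2 = (ssl + ssr) / (n - 2)
        t = diff / np.sqrt(sp2 * (1.0 / ks + 1.0 / (n - ks)))
    # zero pooled variance: infinite t if the means differ, else no signal
    t = np.where(np.isnan(t) | np.isinf(t), np.where(diff > 0, np.inf, 0.0), t)
    out[ks] = t
    return out


def _best_split(x: np.ndarray, min_bins: int) -> tuple[int, float]:
    t = _t_statistics(x, min_bins)
    k = int(np.argmax(t))
    return k, float(t[k])


def _split_recursive(
    x: np.ndarray,
    lo: int,
    hi: int,
    alpha: float,
    min_bins: int,
    n_permutations: int,
    rng: np.random.Generator,
    boundaries: list[int],
) -> None:
    seg = x[lo:hi]
    if len(seg) < 2 * min_bins:
        return
    k, t_obs = _best_split(seg, min_bins)
    if not np.isfinite(t_obs) and t_obs > 0:
        p = 1.0 / (n_permutations + 1.0)  # perfect step, off-scale statistic
    elif t_obs <= 0:
        return
    else:
        exceed = 0
        for _ in range(n_permutations):
            _, t_perm = _best_split(rng.permutation(seg), min_bins)
            if t_perm >= t_obs:
                exceed += 1
        p = (1.0 + exceed) / (n_permutations + 1.0)
    if p < alpha:
        boundaries.append(lo + k)
        _split_recursive(x, lo, lo + k, alpha, min_bins, n_permutations, rng, boundaries)
        _split_recursive(x, lo + k, hi, alpha, min_bins, n_permutations, rng, boundaries)


def segment(
    profile: BinProfile,
    alpha: float = 0.01,
    min_bins: int = 5,
    n_permutations: int = 200,
    seed: int = 0,
) -> SegmentSet:
    """Recursive binary segmentation of a corrected (or normalized) profile.

    At each step the breakpoint maximizing the pooled two-sample t
    statistic is accepted if its within-segment permutation p-value is
    below ``alpha`` (fixed seed), then both halves are recursed. Segment
    means are the means of their member bins; segments are contiguous per
    chromosome (masked bins are carried by the enclosing segment but do
    not contribute to means).
    """
    if profile.stage not in ("normalized", "corrected"):
        raise ValueError("segment expects a normalized or corrected profile")
    rng = np.random.default_rng(seed)
    rows = []
    residuals: list[np.ndarray] = []
    for chrom, grp in profile.bins.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        keep = profile.unmasked[idx]
        if not keep.any():
            continue
        sub_idx = idx[keep]
        x = profile.values[sub_idx]
        boundaries: list[int] = []
        _split_recursive(x, 0, len(x), alpha, min_bins, n_permutations, rng, boundaries)
        cuts = [0, *sorted(boundaries), len(x)]
        chrom_start = int(grp["start"].iloc[0])
        chrom_end = int(grp["end"].iloc[-1])
        starts_of = profile.bins["start"].to_numpy()
        for i in range(len(cuts) - 1):
            lo, hi = cuts[i], cuts[i + 1]
            seg_start = chrom_start if i == 0 else int(starts_of[sub_idx[lo]])
            seg_end = (
                chrom_end if i == len(cuts) - 2 else int(starts_of[sub_idx[hi]])
            )
            mean = float(np.mean(x[lo:hi]))
            rows.append((chrom, seg_start, seg_end, mean, hi - lo))
            residuals.append(x[lo:hi] - mean)
    if not rows:
        raise ValueError("no unmasked bins to segment")
    resid = np.concatenate(residuals)
    sd = float(np.std(resid)) if len(resid) > 1 else 0.0
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "mean_log2", "n_bins"])
    return SegmentSet(df=df, residual_sd=sd)


def detect_focal_events(
    segments: SegmentSet,
    min_abs_log2: float = 0.15,
    max_width: int = 10_000_000,
    annotations: pd.DataFrame | None = None,
) -> list[FocalEvent]:
    """Report narrow segments deviating from their flanks.

    A segment qualifies when its width is at most ``max_width`` and its
    mean log2 differs from the length-weighted mean of its flanking
    segments by at least ``min_abs_log2``. Whole-chromosome changes are
    excluded by the width filter. ``annotations`` is a BED-like frame
    (chrom, start, end, name) used to label overlapping loci.
    """
    events: list[FocalEvent] = []
    df = segments.df
    for chrom, grp in df.groupby("chrom", sort=False):
        grp = grp.reset_index(drop=True)
        for i, row in grp.iterrows():
            width = int(row["end"] - row["start"])
            if width > max_width:
                continue
            flanks = []
            if i > 0:
                flanks.append(grp.iloc[i - 1])
            if i < len(grp) - 1:
                flanks.append(grp.iloc[i + 1])
            if not flanks:
                continue
            w = np.array([f["end"] - f["start"] for f in flanks], dtype=float)
            flank_mean = float(np.average([f["mean_log2"] for f in flanks], weights=w))
            delta = float(row["mean_log2"]) - flank_mean
            if abs(delta) < min_abs_log2:
                continue
            label = ""
            if annotations is not None:
                hits = annotations[
                    (annotations["chrom"] == chrom)
                    & (annotations["start"] < row["end"])
                    & (annotations["end"] > row["start"])
                ]
                label = ",".join(hits["name"].astype(str))
            events.append(
                FocalEvent(
                    chrom=str(chrom),
                    start=int(row["start"]),
                    end=int(row["end"]),
                    direction="gain" if delta > 0 else "loss",
                    mean_log2=float(row["mean_log2"]),
                    delta_log2=delta,
                    width=width,
                    annotation=label,
                )
            )
    return events


def expected_log2(n: np.ndarray | float, cellularity: float, ploidy: float) -> np.ndarray:
    """Expected log2 ratio of integer copy number n at the given
    cellularity and tumor ploidy (diploid admixture)."""
    num = cellularity * np.asarray(n, dtype=float) + 2.0 * (1.0 - cellularity)
    den = cellularity * ploidy + 2.0 * (1.0 - cellularity)
    return np.log2(np.maximum(num, _LOG2_EPS) / den)


def estimate_purity(
    segments: SegmentSet,
    cellularity_grid: np.ndarray | None = None,
    ploidy_grid: tuple[float, ...] = (2.0,),
    max_cn: int = 8,
    min_aneuploid_fraction: float = 0.05,
    aneuploid_log2_threshold: float = 0.1,
    flat_error_range: float = 1e-3,
    max_homozygous_loss_width: int = 30_000_000,
) -> PurityFit:
    """Grid fit of cellularity (and optionally ploidy) to segment means.

    Fit error at (alpha, P) is the length-weighted mean squared distance
    of each segment mean to its nearest integer copy state in 0..max_cn.
    Copy number 0 is disallowed for segments wider than
    ``max_homozygous_loss_width``: a homozygous deletion spanning tens of
    megabases is not viable, and permitting it lets the spurious
    half-cellularity solution (all states doubled away from diploid)
    absorb whole-chromosome losses. The fit is declared unidentifiable
    when the aneuploid genome fraction (length with |log2| >=
    ``aneuploid_log2_threshold``) is below ``min_aneuploid_fraction`` or
    the error profile is flat in alpha; ties prefer the lowest ploidy,
    then the highest cellularity.
    """
    if len(segments) == 0:
        raise ValueError("empty segment set")
    if cellularity_grid is None:
        cellularity_grid = np.round(np.arange(0.05, 1.0 + 1e-9, 0.01), 2)
    means = segments.df["mean_log2"].to_numpy()
    weights = segments.widths.astype(float)
    total = weights.sum()
    aneuploid_fraction = float(
        weights[np.abs(means) >= aneuploid_log2_threshold].sum() / total
    )
    if aneuploid_fraction < min_aneuploid_fraction:
        return PurityFit(
            identifiable=False,
            cellularity=None,
            ploidy=None,
            fit_error=None,
            copy_assignments=None,
            reason=(
                f"aneuploid genome fraction {aneuploid_fraction:.3f} below "
                f"floor {min_aneuploid_fraction}; estimation requires numerical "
                "chromosomal alterations"
            ),
            aneuploid_fraction=aneuploid_fraction,
        )
    ns = np.arange(0, max_cn + 1)
    wide = segments.widths > max_homozygous_loss_width
    candidates = []  # (error, ploidy, alpha, assignments)
    per_alpha_best: dict[float, float] = {}
    for ploidy in sorted(ploidy_grid):
        for alpha_c in cellularity_grid:
            exp = expected_log2(ns, float(alpha_c), float(ploidy))  # (max_cn+1,)
            d2 = (means[:, None] - exp[None, :]) ** 2
            d2[wide, 0] = np.inf  # no wide homozygous losses
            assign = np.argmin(d2, axis=1)
            err = float(np.sum(weights * d2[np.arange(len(means)), assign]) / total)
            a_key = round(float(alpha_c), 6)
            if a_key not in per_alpha_best or err < per_alpha_best[a_key]:
                per_alpha_best[a_key] = err
            candidates.append((err, float(ploidy), float(alpha_c), ns[assign]))
    # Exact lattice degeneracy: a fit at cellularity a is reproduced at a/2
    # with copy offsets doubled, so near-ties are broken toward the lowest
    # ploidy, then the highest (most parsimonious) cellularity.
    min_err = min(c[0] for c in candidates)
    tie_tol = 1e-9
    tied = [c for c in candidates if c[0] <= min_err + tie_tol]
    best = min(tied, key=lambda c: (c[1], -c[2]))
    errs = np.array(list(per_alpha_best.values()))
    if errs.max() - errs.min() < flat_error_range:
        return PurityFit(
            identifiable=False,
            cellularity=None,
            ploidy=None,
            fit_error=best[0],
            copy_assignments=None,
            reason="fit error is flat across cellularity; solution not identifiable",
            aneuploid_fraction=aneuploid_fraction,
        )
    err, ploidy, alpha_c, assign = best
    return PurityFit(
        identifiable=True,
        cellularity=alpha_c,
        ploidy=ploidy,
        fit_error=err,
        copy_assignments=assign,
        aneuploid_fraction=aneuploid_fraction,
    )


def plot_profile(
    profile: BinProfile,
    segments: SegmentSet | None = None,
    path: str | Path = "cnv_profile.png",
    title: str = "",
) -> None:
    """Scatter of per-bin log2 ratios with optional segment means."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(12, 3.5))
    offset = 0
    ticks, ticklabels = [], []
    for chrom, grp in profile.bins.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        mids = (grp["start"].to_numpy() + grp["end"].to_numpy()) / 2 + offset
        ax.scatter(mids, profile.values[idx], s=4, alpha=0.6)
        if segments is not None:
            seg = segments.df[segments.df["chrom"] == chrom]
            for _, s in seg.iterrows():
                ax.hlines(s["mean_log2"], s["start"] + offset, s["end"] + offset,
                          color="red", linewidth=2)
        span = int(grp["end"].iloc[-1])
        ticks.append(offset + span / 2)
        ticklabels.append(str(chrom))
        offset += span
        ax.axvline(offset, color="grey", linewidth=0.5)
    ax.set_xticks(ticks)
    ax.set_xticklabels(ticklabels)
    ax.set_ylabel("log2 ratio")
    ax.set_ylim(-2, 2)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
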