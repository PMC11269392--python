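"""Synthetic cohorts with known ground truth.

Emulates the three data layers of nanopore-based CNS tumor diagnostics:

* a labeled reference cohort of binary methylation profiles over a CpG
  atlas, each methylation class carrying a block of signature CpGs with
  elevated methylation probability;
* sparse per-case observations covering a variable subset of atlas CpGs
  (real low-pass runs cover anywhere from a few thousand to a few hundred
  thousand of the atlas sites), with optional truncated-Gaussian beta
  noise around the binary state;
* binned genome read counts with planted integer-copy segments diluted by
  tumor purity, drawn negative-binomially (Poisson in the zero-dispersion
  limit).

Everything is reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cnv import BinProfile
from .features import MethylationCalls, ReferenceAtlas, write_methylation_calls
from .genome import DEFAULT_BIN_SIZE, GenomeModel, toy_genome

__all__ = [
    "ConfigError",
    "SyntheticConfig",
    "CaseSpec",
    "GroundTruthCase",
    "generate_reference_atlas",
    "simulate_sparse_observation",
    "simulate_bin_counts",
    "simulate_cohort",
]

MANIFEST_COLUMNS = [
    "case_id", "age_years", "sex", "location", "reference_diagnosis",
    "lesion_type", "pretreatment",
]


class ConfigError(ValueError):
    """Invalid synthetic-cohort configuration; names the violated invariant."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Reference-cohort generator settings.

    Class signatures are disjoint CpG blocks of ``signature_size`` sites
    methylated with probability ``p_high`` (background ``p_low``), which
    makes the Bayes-optimal classification accuracy effectively zero
    error by construction. ``signature_overlap`` (fraction of a block
    shared with the previous class) controls difficulty.
    """

    n_classes: int = 8
    n_families: int = 3
    samples_per_class: int = 20
    atlas_size: int = 5000
    signature_size: int = 100
    p_high: float = 0.9
    p_low: float = 0.1
    signature_overlap: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 1:
            raise ConfigError("n_classes must be >= 1")
        if not 1 <= self.n_families <= self.n_classes:
            raise ConfigError("invariant violated: n_families <= n_classes (and >= 1)")
        if self.samples_per_class < 1:
            raise ConfigError("samples_per_class must be >= 1")
        if self.signature_size * self.n_classes > self.atlas_size:
            raise ConfigError(
                "invariant violated: signature_size * n_classes <= atlas_size"
            )
        if not 0.0 <= self.p_low < self.p_high <= 1.0:
            raise ConfigError("invariant violated: 0 <= p_low < p_high <= 1")
        if not 0.0 <= self.signature_overlap < 1.0:
            raise ConfigError("signature_overlap must be in [0, 1)")


@dataclass
class CaseSpec:
    """Requested properties of one simulated case."""

    case_id: str
    true_class: str
    n_observed: int
    beta_noise_sd: float = 0.0
    true_purity: float = 1.0
    true_segments: list[tuple[str, int, int, int]] = field(default_factory=list)
    age_years: int = 8
    sex: str = "F"
    location: str = "posterior fossa"
    lesion_type: str = "primary"
    pretreatment: str = "None"


@dataclass
class GroundTruthCase:
    """Ground truth persisted next to the generated files for assertions."""

    case_id: str
    true_class: str
    observed_cpg_count: int
    true_segments: list[tuple[str, int, int, int]]
    true_purity: float
    methylation_path: str = ""
    bin_counts_path: str = ""

    def __post_init__(self) -> None:
        if not 0.0 < self.true_purity <= 1.0:
            raise ConfigError("purity must be in (0, 1]")
        for chrom, start, end, cn in self.true_segments:
            if cn < 0 or int(cn) != cn:
                raise ConfigError(f"copy number must be a non-negative integer, got {cn}")
            if start >= end:
                raise ConfigError(f"empty segment {chrom}:{start}-{end}")


def _atlas_positions(atlas_size: int, genome: GenomeModel) -> pd.DataFrame:
    """Evenly spread CpG coordinates over the genome model, sorted."""
    per_chrom = np.full(len(genome.chroms), atlas_size // len(genome.chroms))
    per_chrom[: atlas_size % len(genome.chroms)] += 1
    rows = []
    for chrom, n_sites in zip(genome.chroms, per_chrom):
        size = genome.chrom_sizes[chrom]
        step = max(size // (n_sites + 1), 2)
        starts = (np.arange(n_sites) + 1) * step
        for s in starts:
            rows.append((chrom, int(s)))
    return pd.DataFrame(rows, columns=["chrom", "start"])


def generate_reference_atlas(
    config: SyntheticConfig, genome: GenomeModel | None = None
) -> ReferenceAtlas:
    """Draw a binary reference cohort with per-class signature blocks.

    Sample s of class c is Bernoulli(p_high) inside c's signature block
    and Bernoulli(p_low) elsewhere. Classes are named class_00.. and
    partitioned contiguously into family_00.. families.
    """
    genome = genome or toy_genome()
    rng = np.random.default_rng(config.seed)
    n_samples = config.n_classes * config.samples_per_class
    classes = [f"class_{i:02d}" for i in range(config.n_classes)]
    labels = np.repeat(classes, config.samples_per_class)

    stride = int(round(config.signature_size * (1.0 - config.signature_overlap)))
    stride = max(stride, 1)
    blocks = []
    for c in range(config.n_classes):
        lo = c * stride
        blocks.append((lo, lo + config.signature_size))

    matrix = (rng.random((n_samples, config.atlas_size)) < config.p_low).astype(np.uint8)
    for c in range(config.n_classes):
        lo, hi = blocks[c]
        sel = labels == classes[c]
        matrix[np.ix_(sel, np.arange(lo, hi))] = (
            rng.random((sel.sum(), hi - lo)) < config.p_high
        ).astype(np.uint8)

    # contiguous partition of classes into families, sizes as even as possible
    fam_sizes = np.full(config.n_families, config.n_classes // config.n_families)
    fam_sizes[: config.n_classes % config.n_families] += 1
    hierarchy: dict[str, str] = {}
    c = 0
    for f, size in enumerate(fam_sizes):
        for _ in range(size):
            hierarchy[classes[c]] = f"family_{f:02d}"
            c += 1

    return ReferenceAtlas(
        cpg_index=_atlas_positions(config.atlas_size, genome),
        matrix=matrix,
        labels=labels,
        hierarchy=hierarchy,
    )


def simulate_sparse_observation(
    atlas_profile: np.ndarray,
    cpg_index: pd.DataFrame,
    n_observed: int,
    beta_noise_sd: float = 0.0,
    seed: int = 0,
    mean_calls: float = 5.0,
) -> MethylationCalls:
    """Sample ``n_observed`` atlas CpGs uniformly without replacement and
    emit noisy beta values around the binary state.

    beta = clamp(state + Normal(0, beta_noise_sd), 0, 1); unsampled sites
    are absent from the output.
    """
    profile = np.asarray(atlas_profile, dtype=float)
    if len(profile) != len(cpg_index):
        raise ValueError("profile and cpg_index length mismatch")
    if n_observed > len(profile):
        raise ValueError(
            f"n_observed={n_observed} exceeds atlas size {len(profile)}"
        )
    if beta_noise_sd < 0:
        raise ValueError("beta_noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    chosen = np.sort(rng.choice(len(profile), size=n_observed, replace=False))
    beta = profile[chosen]
    if beta_noise_sd > 0:
        beta = beta + rng.normal(0.0, beta_noise_sd, size=n_observed)
    beta = np.clip(beta, 0.0, 1.0)
    n_calls = 1 + rng.poisson(max(mean_calls - 1.0, 0.0), size=n_observed)
    sub = cpg_index.iloc[chosen]
    df = pd.DataFrame(
        {
            "chrom": sub["chrom"].to_numpy(),
            "start": sub["start"].to_numpy(),
            "end": sub["start"].to_numpy() + 2,  # CpG dinucleotide
            "beta": beta,
            "n_calls": n_calls,
        }
    )
    return MethylationCalls(df)


def _validate_segments(
    segments: list[tuple[str, int, int, int]], genome: GenomeModel
) -> None:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end, cn in segments:
        if not genome.contains(chrom, start, end):
            raise ValueError(f"segment {chrom}:{start}-{end} outside genome model")
        if cn < 0 or int(cn) != cn:
            raise ValueError(f"copy number must be a non-negative integer, got {cn}")
        by_chrom.setdefault(chrom, []).append((start, end))
    for chrom, ivals in by_chrom.items():
        ivals.sort()
        for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping segments on {chrom}")


def simulate_bin_counts(
    true_segments: list[tuple[str, int, int, int]],
    true_purity: float,
    mean_count: float = 100.0,
    dispersion: float = 0.0,
    bin_size: int = DEFAULT_BIN_SIZE,
    genome: GenomeModel | None = None,
    seed: int = 0,
) -> BinProfile:
    """Forward model for binned low-pass WGS counts.

    A bin under tumor copy number CN at purity a has expected count
    mean_count * (a*CN + 2*(1-a)) / 2 (diploid elsewhere). Counts are
    negative binomial with variance mu + dispersion*mu^2; dispersion 0 is
    exactly Poisson.
    """
    if not 0.0 < true_purity <= 1.0:
        raise ValueError("purity must be in (0, 1]")
    if mean_count <= 0:
        raise ValueError("mean_count must be positive")
    if dispersion < 0:
        raise ValueError("dispersion must be non-negative")
    genome = genome or toy_genome()
    _validate_segments(true_segments, genome)
    rng = np.random.default_rng(seed)
    bins = genome.bins(bin_size)
    cn = np.full(len(bins), 2.0)
    mids = (bins["start"].to_numpy() + bins["end"].to_numpy()) / 2
    for chrom, start, end, seg_cn in true_segments:
        sel = (bins["chrom"] == chrom).to_numpy() & (mids >= start) & (mids < end)
        cn[sel] = seg_cn
    mu = mean_count * (true_purity * cn + 2.0 * (1.0 - true_purity)) / 2.0
    if dispersion > 0:
        lam = rng.gamma(shape=1.0 / dispersion, scale=mu * dispersion)
    else:
        lam = mu
    counts = rng.poisson(lam).astype(float)
    return BinProfile(bins=bins, values=counts, stage="raw")


def expected_bin_count(cn: float, purity: float, mean_count: float) -> float:
    """Closed-form expected count under the purity-dilution model."""
    return mean_count * (purity * cn + 2.0 * (1.0 - purity)) / 2.0


def simulate_cohort(
    config: SyntheticConfig,
    case_specs: list[CaseSpec],
    outdir: str | Path,
    genome: GenomeModel | None = None,
    mean_count: float = 100.0,
    dispersion: float = 0.0,
    bin_size: int = DEFAULT_BIN_SIZE,
) -> tuple[ReferenceAtlas, list[GroundTruthCase]]:
    """Write a full synthetic cohort to disk.

    Produces per-case methylation-call TSVs and bin-count TSVs plus a
    manifest mirroring the clinical cohort table; returns the atlas and
    the ground truth for test assertions. Each case uses the first
    reference sample of its true class as the underlying profile and a
    case-specific seed derived from the cohort seed.
    """
    genome = genome or toy_genome()
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {outdir}: {exc}") from exc
    atlas = generate_reference_atlas(config, genome)
    cases: list[GroundTruthCase] = []
    manifest_rows = []
    for i, spec in enumerate(case_specs):
        if spec.true_class not in atlas.classes:
            raise ConfigError(f"case {spec.case_id}: unknown class {spec.true_class}")
        profile = atlas.matrix[np.flatnonzero(atlas.labels == spec.true_class)[0]]
        case_seed = (config.seed * 100_003 + 7 * i + 1) % (2**31)
        calls = simulate_sparse_observation(
            profile, atlas.cpg_index, spec.n_observed,
            beta_noise_sd=spec.beta_noise_sd, seed=case_seed,
        )
        counts = simulate_bin_counts(
            spec.true_segments, spec.true_purity, mean_count=mean_count,
            dispersion=dispersion, bin_size=bin_size, genome=genome,
            seed=case_seed + 1,
        )
        meth_path = outdir / f"{spec.case_id}.methylation.tsv"
        bin_path = outdir / f"{spec.case_id}.bincounts.tsv"
        write_methylation_calls(calls, meth_path)
        frame = counts.bins.copy()
        frame["count"] = counts.values.astype(int)
        frame.to_csv(bin_path, sep="\t", index=False)
        cases.append(
            GroundTruthCase(
                case_id=spec.case_id,
                true_class=spec.true_class,
                observed_cpg_count=spec.n_observed,
                true_segments=list(spec.true_segments),
                true_purity=spec.true_purity,
                methylation_path=str(meth_path),
                bin_counts_path=str(bin_path),
            )
        )
        manifest_rows.append(
            (spec.case_id, spec.age_years, spec.sex, spec.location,
             spec.true_class, spec.lesion_type, spec.pretreatment)
        )
    manifest = pd.DataFrame(manifest_rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    truth = pd.DataFrame(
        [
            {
                "case_id": c.case_id,
                "true_class": c.true_class,
                "observed_cpg_count": c.observed_cpg_count,
                "true_purity": c.true_purity,
                "true_segments": ";".join(
                    f"{ch}:{s}-{e}:{n}" for ch, s, e, n in c.true_segments
                ),
            }
            for c in cases
        ]
    )
    truth.to_csv(outdir / "ground_truth.tsv", sep="\t", index=False)
    return atlas, cases
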