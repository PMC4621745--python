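"""Synthetic tumor-cohort generator.

Generates cohorts with the statistical structure the downstream analyses
assume, so every stage is testable without access to restricted patient
data:

* two latent instability classes that differ in their intrachromosomal
  rearrangement rate (negative-binomial counts; the interchromosomal rate
  is class-independent),
* a driver point lesion enriched in the high-instability class with a
  configurable odds ratio,
* per-sample copy-number segment profiles with a controllable fraction of
  genome altered, and
* a planted clonal hierarchy — the driver is clonal, region deletions are
  subclonal — realized as binomial allele read counts given purity, local
  copy number and multiplicity, and as purity-attenuated segment log2
  ratios.

Counts are negative-binomial rather than Poisson because observed
rearrangement burdens are heavily overdispersed across tumors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import (
    GenomeDef,
    MutationObservation,
    RearrangementEvent,
    Region,
    SampleSheet,
    Segment,
    SegmentProfile,
    make_event,
    write_rearrangements,
    write_segments,
)
from .burden import DELETION, INVERSION, TANDEM_DUPLICATION, INTERCHROMOSOMAL

__all__ = [
    "default_genome",
    "DeletionLesionSpec",
    "CohortConfig",
    "SyntheticCohort",
    "simulate_rearrangements",
    "simulate_segments",
    "simulate_mutation_reads",
    "simulate_cohort",
    "simulate_expression",
    "write_cohort",
]


def default_genome() -> GenomeDef:
    """A ten-autosome toy genome (~1.5 Gb) used by the simulator."""
    lengths = [200, 180, 170, 160, 150, 140, 130, 120, 110, 100]
    return GenomeDef(
        tuple((f"chr{i + 1}", mb * 1_000_000) for i, mb in enumerate(lengths))
    )


@dataclass(frozen=True)
class DeletionLesionSpec:
    """A recurrent deletion lesion: its region, class-conditional carrier
    probabilities, and the bounds of its (subclonal) CCF distribution."""

    name: str
    chrom: str
    start: int
    end: int
    p_low: float
    p_high: float
    ccf_bounds: tuple[float, float] = (0.4, 0.8)

    @property
    def region(self) -> Region:
        return Region(self.name, self.chrom, self.start, self.end)


def _default_deletions() -> tuple[DeletionLesionSpec, ...]:
    # two recurrent deletion peaks enriched in the high-instability class,
    # echoing recurrent 5q/6q deletion peaks co-occurring with the driver
    return (
        DeletionLesionSpec("del_chr5_A", "chr5", 40_000_000, 45_000_000, 0.10, 0.70),
        DeletionLesionSpec("del_chr6_A", "chr6", 60_000_000, 65_000_000, 0.10, 0.70),
    )


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions of a simulated cohort.

    Defaults describe a cohort of 100 tumors with a rarer (20%)
    high-rearrangement class, a ten-fold intrachromosomal rate separation,
    a clonal driver strongly enriched (OR 20) in the high class over a 5%
    baseline, subclonal deletion lesions, and mean depth 100x at purities
    0.4-0.9.
    """

    n_samples: int = 100
    p_high: float = 0.2
    intra_rate_low: float = 20.0
    intra_rate_high: float = 200.0
    inter_rate: float = 15.0
    dispersion: float = 10.0
    driver_gene: str = "DRIVER"
    driver_baseline: float = 0.05  # carrier probability in the low class
    driver_or: float = 20.0
    driver_ccf: float = 1.0
    passenger_genes: tuple[tuple[str, float], ...] = (
        ("PASS1", 0.15), ("PASS2", 0.15), ("PASS3", 0.10), ("PASS4", 0.10),
    )
    deletion_lesions: tuple[DeletionLesionSpec, ...] = field(
        default_factory=_default_deletions
    )
    fga_beta_low: tuple[float, float] = (2.0, 38.0)
    fga_beta_high: tuple[float, float] = (5.0, 15.0)
    depth: float = 100.0
    purity_range: tuple[float, float] = (0.4, 0.9)
    seed: int = 0

    def validate(self) -> "CohortConfig":
        if self.n_samples < 1:
            raise ValueError("n_samples must be positive")
        if not 0.0 <= self.p_high <= 1.0:
            raise ValueError("p_high must lie in [0, 1]")
        for name in ("intra_rate_low", "intra_rate_high", "inter_rate",
                     "dispersion", "depth", "driver_or"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.driver_ccf <= 1.0:
            raise ValueError("driver_ccf must lie in (0, 1]")
        if not 0.0 <= self.driver_baseline < 1.0:
            raise ValueError("driver_baseline must lie in [0, 1)")
        lo, hi = self.purity_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("purity_range must satisfy 0 < lo <= hi <= 1")
        for spec in self.deletion_lesions:
            clo, chi = spec.ccf_bounds
            if not (0.0 < clo <= chi <= 1.0):
                raise ValueError(f"{spec.name}: ccf bounds must lie in (0, 1]")
            if not (0.0 <= spec.p_low <= 1.0 and 0.0 <= spec.p_high <= 1.0):
                raise ValueError(f"{spec.name}: carrier probabilities in [0, 1]")
        for a, b in zip(self.fga_beta_low, self.fga_beta_high):
            if a <= 0 or b <= 0:
                raise ValueError("beta parameters must be positive")
        return self


@dataclass
class SyntheticCohort:
    """Generated data plus the ground truth it was generated from."""

    config: CohortConfig
    genome: GenomeDef
    events: list[RearrangementEvent]
    profiles: list[SegmentProfile]
    mutations: list[MutationObservation]
    sample_sheet: SampleSheet
    regions: list[Region]
    truth_samples: pd.DataFrame   # sample_id -> true_class, target_fga, purity
    truth_lesions: pd.DataFrame   # sample_id, lesion, true_ccf
    truth_order: list[tuple[str, str]]  # (earlier lesion, later lesion)


def _nb_counts(rng: np.random.Generator, mean: float, dispersion: float,
               size: int) -> np.ndarray:
    """Negative-binomial counts parameterized by mean and size (dispersion)."""
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def simulate_rearrangements(
    n_intra: int,
    n_inter: int,
    genome: GenomeDef,
    rng: np.random.Generator,
    sample_id: str = "S",
) -> list[RearrangementEvent]:
    """Random breakpoint pairs: ``n_intra`` same-chromosome events with
    subtype-consistent strand pairs (deletion / tandem duplication /
    inversion, uniformly) and ``n_inter`` interchromosomal events."""
    if n_intra < 0 or n_inter < 0:
        raise ValueError("event counts must be non-negative")
    names = list(genome.names)
    lengths = np.array([genome.length(c) for c in names], dtype=float)
    weights = lengths / lengths.sum()
    events: list[RearrangementEvent] = []
    strand_by_subtype = {
        DELETION: [("+", "-")],
        TANDEM_DUPLICATION: [("-", "+")],
        INVERSION: [("+", "+"), ("-", "-")],
    }
    intra_subtypes = [DELETION, TANDEM_DUPLICATION, INVERSION]
    for _ in range(n_intra):
        ci = rng.choice(len(names), p=weights)
        chrom, clen = names[ci], int(lengths[ci])
        span = int(rng.integers(1_000, 5_000_000))
        pos_a = int(rng.integers(0, max(1, clen - span - 1)))
        pos_b = pos_a + span
        subtype = intra_subtypes[rng.integers(0, 3)]
        pair = strand_by_subtype[subtype]
        strand_a, strand_b = pair[rng.integers(0, len(pair))]
        events.append(
            make_event(sample_id, chrom, pos_a, strand_a, chrom, pos_b, strand_b,
                       subtype=subtype)
        )
    for _ in range(n_inter):
        ci, cj = rng.choice(len(names), size=2, replace=False, p=weights)
        pos_a = int(rng.integers(0, lengths[ci] - 1))
        pos_b = int(rng.integers(0, lengths[cj] - 1))
        strand_a = "+" if rng.random() < 0.5 else "-"
        strand_b = "+" if rng.random() < 0.5 else "-"
        events.append(
            make_event(sample_id, names[ci], pos_a, strand_a, names[cj], pos_b,
                       strand_b, subtype=INTERCHROMOSOMAL)
        )
    return events


def simulate_segments(
    target_fga: float,
    genome: GenomeDef,
    rng: np.random.Generator,
    sample_id: str = "S",
    forced: Sequence[tuple[Region, float]] = (),
    log2_threshold: float = 0.2,
    min_segment: int = 100_000,
) -> SegmentProfile:
    """A segment profile whose realized fraction of genome altered is within
    +/-0.02 of ``target_fga`` at the given |log2| threshold.

    ``forced`` segments (region, log2) are planted verbatim — used for
    deletion lesions — and count toward the altered budget when their |log2|
    meets the threshold.  Neutral genome is covered by segments with small
    log2 noise; altered runs get |log2| in [0.3, 1.0] (losses more often
    than gains).
    """
    if not 0.0 <= target_fga <= 1.0:
        raise ValueError("target_fga must lie in [0, 1]")
    total = genome.total_length(include_sex=True)
    budget = target_fga * total
    if 0.0 < budget < min_segment:
        raise ValueError(
            f"target FGA {target_fga} unreachable: altered budget "
            f"{budget:.0f} bp is below the minimum segment size {min_segment}"
        )
    forced_by_chrom: dict[str, list[tuple[Region, float]]] = {}
    for region, log2 in forced:
        genome.length(region.chrom)
        forced_by_chrom.setdefault(region.chrom, []).append((region, log2))
    budget -= sum(
        region.end - region.start
        for region, log2 in forced
        if abs(log2) >= log2_threshold
    )
    budget = max(budget, 0.0)

    def altered_log2() -> float:
        mag = rng.uniform(max(0.3, log2_threshold + 0.05), 1.0)
        return -mag if rng.random() < 0.6 else mag

    def neutral_log2() -> float:
        bound = min(0.05, 0.5 * log2_threshold)
        return rng.uniform(-bound, bound)

    segments: list[Segment] = []
    for chrom, clen in genome.chromosomes:
        planted = sorted(forced_by_chrom.get(chrom, []), key=lambda rl: rl[0].start)
        # free intervals = chromosome minus planted regions
        free: list[tuple[int, int]] = []
        cursor = 0
        for region, _ in planted:
            if region.start > cursor:
                free.append((cursor, region.start))
            cursor = max(cursor, region.end)
        if cursor < clen:
            free.append((cursor, clen))
        free_total = sum(b - a for a, b in free)
        a_c = int(round(budget * clen / total))
        a_c = min(a_c, free_total)
        # choose where the altered run starts along the concatenated free space
        offset = int(rng.integers(0, free_total - a_c + 1)) if free_total > a_c else 0
        for region, log2 in planted:
            segments.append(Segment(sample_id, chrom, region.start, region.end, log2))
        pos_in_free = 0
        for lo, hi in free:
            length = hi - lo
            run_lo = max(offset, pos_in_free)
            run_hi = min(offset + a_c, pos_in_free + length)
            pieces: list[tuple[int, int, bool]] = []
            if run_lo < run_hi:  # altered run intersects this free interval
                alt_lo = lo + (run_lo - pos_in_free)
                alt_hi = lo + (run_hi - pos_in_free)
                if alt_lo > lo:
                    pieces.append((lo, alt_lo, False))
                pieces.append((alt_lo, alt_hi, True))
                if alt_hi < hi:
                    pieces.append((alt_hi, hi, False))
            else:
                pieces.append((lo, hi, False))
            for a, b, altered in pieces:
                if b > a:
                    segments.append(
                        Segment(sample_id, chrom, a, b,
                                altered_log2() if altered else neutral_log2())
                    )
            pos_in_free += length
    return SegmentProfile(sample_id, segments).validate()


def simulate_mutation_reads(
    ccf: float,
    purity: float,
    local_cn: int,
    multiplicity: int,
    depth_mean: float,
    rng: np.random.Generator,
) -> tuple[int, int]:
    """Binomial allele read counts for a lesion of the given cancer cell
    fraction: depth ~ Poisson(depth_mean), alt ~ Binomial(depth, v) with
    v = multiplicity * ccf * purity / (purity * local_cn + 2 * (1 - purity)).
    """
    if not 0.0 <= ccf <= 1.0:
        raise ValueError("ccf must lie in [0, 1]")
    if not 0.0 < purity <= 1.0:
        raise ValueError("purity must lie in (0, 1]")
    if not 1 <= multiplicity <= local_cn:
        raise ValueError("multiplicity must lie in [1, local_cn]")
    if depth_mean <= 0:
        raise ValueError("depth_mean must be positive")
    depth = max(int(rng.poisson(depth_mean)), 1)
    v = multiplicity * ccf * purity / (purity * local_cn + 2.0 * (1.0 - purity))
    alt = int(rng.binomial(depth, v))
    return depth - alt, alt


def simulate_cohort(
    config: CohortConfig,
    genome: GenomeDef | None = None,
) -> SyntheticCohort:
    """Generate a full cohort under ``config``; identical config and seed
    give identical output."""
    config.validate()
    genome = genome or default_genome()
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    sample_ids = [f"S{i:04d}" for i in range(n)]

    is_high = rng.random(n) < config.p_high
    purity = rng.uniform(*config.purity_range, size=n)
    intra_rates = np.where(is_high, config.intra_rate_high, config.intra_rate_low)
    n_intra = np.array(
        [_nb_counts(rng, mu, config.dispersion, 1)[0] for mu in intra_rates]
    )
    n_inter = _nb_counts(rng, config.inter_rate, config.dispersion, n)

    # driver carrier probability per class from the odds ratio
    base_odds = config.driver_baseline / (1.0 - config.driver_baseline)
    p_driver_high = (config.driver_or * base_odds) / (1.0 + config.driver_or * base_odds)
    p_driver = np.where(is_high, p_driver_high, config.driver_baseline)
    has_driver = rng.random(n) < p_driver

    events: list[RearrangementEvent] = []
    profiles: list[SegmentProfile] = []
    mutations: list[MutationObservation] = []
    lesion_rows: list[dict] = []

    # fixed synthetic loci for point lesions, on chromosomes without
    # planted deletion regions so local copy number stays 2
    point_loci = {config.driver_gene: ("chr2", 50_000_000)}
    for i, (gene, _) in enumerate(config.passenger_genes):
        point_loci[gene] = ("chr1", 10_000_000 + 5_000_000 * i)

    for i, sid in enumerate(sample_ids):
        events.extend(
            simulate_rearrangements(int(n_intra[i]), int(n_inter[i]), genome, rng, sid)
        )

        def add_point_mutation(gene: str, ccf: float) -> None:
            chrom, pos = point_loci[gene]
            ref, alt = simulate_mutation_reads(
                ccf, float(purity[i]), 2, 1, config.depth, rng
            )
            mutations.append(
                MutationObservation(sid, chrom, pos, gene, ref, alt,
                                    float(purity[i]), 2)
            )
            lesion_rows.append({"sample_id": sid, "lesion": gene, "true_ccf": ccf})

        if has_driver[i]:
            add_point_mutation(config.driver_gene, config.driver_ccf)
        for gene, prob in config.passenger_genes:
            if rng.random() < prob:
                add_point_mutation(gene, float(rng.uniform(0.3, 1.0)))

        forced: list[tuple[Region, float]] = []
        for spec in config.deletion_lesions:
            prob = spec.p_high if is_high[i] else spec.p_low
            if rng.random() < prob:
                lo, hi = spec.ccf_bounds
                if has_driver[i]:
                    # planted order: deletions arise after the clonal driver
                    hi = min(hi, config.driver_ccf - 1e-9)
                ccf = float(rng.uniform(min(lo, hi), hi))
                # mono-allelic loss in a purity-diluted specimen
                log2 = math.log2(1.0 - purity[i] * ccf / 2.0)
                forced.append((spec.region, log2))
                lesion_rows.append(
                    {"sample_id": sid, "lesion": spec.name, "true_ccf": ccf}
                )

        is_high_i = bool(is_high[i])
        alpha, beta = config.fga_beta_high if is_high_i else config.fga_beta_low
        target = float(np.clip(rng.beta(alpha, beta), 0.0, 0.95))
        profiles.append(
            simulate_segments(target, genome, rng, sample_id=sid, forced=forced)
        )

    sheet = SampleSheet(
        pd.DataFrame(
            {
                "purity": purity,
                "driver_status": np.where(has_driver, "mut", "wt"),
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )
    truth_samples = pd.DataFrame(
        {
            "true_class": np.where(is_high, "high", "low"),
            "purity": purity,
            "n_intra": n_intra,
            "n_inter": n_inter,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    truth_lesions = pd.DataFrame(
        lesion_rows, columns=["sample_id", "lesion", "true_ccf"]
    )
    truth_order = [
        (config.driver_gene, spec.name) for spec in config.deletion_lesions
    ]
    return SyntheticCohort(
        config=config,
        genome=genome,
        events=events,
        profiles=profiles,
        mutations=mutations,
        sample_sheet=sheet,
        regions=[spec.region for spec in config.deletion_lesions],
        truth_samples=truth_samples,
        truth_lesions=truth_lesions,
        truth_order=truth_order,
    )


def simulate_expression(
    n_samples: int,
    n_labeled: int,
    n_signature: int,
    effect: float,
    rng: np.random.Generator,
    n_background: int = 50,
    noise_sd: float = 1.0,
) -> tuple[pd.DataFrame, list[str], pd.Series]:
    """Synthetic genes x samples expression with a signature shifted in the
    labeled samples.

    Returns (expression, signature gene ids, binary labels).  The two
    classes sit at symmetric signature-gene means separated by ``effect``
    (in units of the noise SD), with alternating sign across genes — a
    signature mixes up- and down-regulated genes, which is what makes the
    pattern visible to correlation-based distances (a same-sign shift on
    every gene would cancel in a Pearson profile comparison).  Background
    genes are noise; ``effect=0`` gives a structureless null.
    """
    if n_labeled > n_samples:
        raise ValueError("n_labeled cannot exceed n_samples")
    samples = [f"S{i:04d}" for i in range(n_samples)]
    sig_genes = [f"SIG{i:03d}" for i in range(n_signature)]
    bg_genes = [f"BG{i:03d}" for i in range(n_background)]
    labeled_idx = rng.choice(n_samples, size=n_labeled, replace=False)
    labels = np.zeros(n_samples, dtype=int)
    labels[labeled_idx] = 1
    expr = rng.normal(0.0, noise_sd, size=(n_signature + n_background, n_samples))
    loadings = np.where(np.arange(n_signature) % 2 == 0, 1.0, -1.0)
    shift = 0.5 * effect * noise_sd * loadings[:, None]
    expr[: n_signature, labels == 1] += shift
    expr[: n_signature, labels == 0] -= shift
    df = pd.DataFrame(expr, index=sig_genes + bg_genes, columns=samples)
    return df, sig_genes, pd.Series(labels, index=pd.Index(samples, name="sample_id"),
                                    name="label")


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> dict[str, str]:
    """Write the cohort in the same formats the readers consume, plus truth."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "rearrangements": out_dir / "rearrangements.bedpe",
        "segments": out_dir / "segments.seg",
        "mutations": out_dir / "mutations.tsv",
        "samples": out_dir / "samples.tsv",
        "regions": out_dir / "regions.bed",
        "genome": out_dir / "genome.tsv",
        "truth_samples": out_dir / "truth_samples.tsv",
        "truth_lesions": out_dir / "truth_lesions.tsv",
    }
    write_rearrangements(cohort.events, paths["rearrangements"])
    write_segments(cohort.profiles, paths["segments"])
    mut = pd.DataFrame(
        {
            "sample_id": [m.sample_id for m in cohort.mutations],
            "chrom": [m.chrom for m in cohort.mutations],
            "pos": [m.pos + 1 for m in cohort.mutations],  # 1-based on disk
            "gene": [m.gene for m in cohort.mutations],
            "ref_count": [m.ref_count for m in cohort.mutations],
            "alt_count": [m.alt_count for m in cohort.mutations],
            "local_cn": [m.local_cn for m in cohort.mutations],
        }
    )
    mut.to_csv(paths["mutations"], sep="\t", index=False, lineterminator="\n")
    cohort.sample_sheet.samples.reset_index().to_csv(
        paths["samples"], sep="\t", index=False, lineterminator="\n",
        float_format="%.10g",
    )
    with open(paths["regions"], "w") as fh:
        for region in cohort.regions:
            fh.write(f"{region.chrom}\t{region.start}\t{region.end}\t{region.name}\n")
    with open(paths["genome"], "w") as fh:
        for name, length in cohort.genome.chromosomes:
            fh.write(f"{name}\t{length}\n")
    cohort.truth_samples.reset_index().to_csv(
        paths["truth_samples"], sep="\t", index=False, lineterminator="\n",
        float_format="%.10g",
    )
    cohort.truth_lesions.to_csv(
        paths["truth_lesions"], sep="\t", index=False, lineterminator="\n",
        float_format="%.10g",
    )
    return {k: str(v) for k, v in paths.items()}
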