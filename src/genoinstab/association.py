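"""Lesion-burden association: the samples x lesions presence matrix,
rank-sum association of each lesion with rearrangement burden,
Benjamini-Hochberg control, and pairwise mutual-exclusivity testing.

A "lesion" is either a recurrent point mutation (named by gene) or a
recurrent region deletion (named by its region, e.g. a cytoband).  Each
lesion is tested for association with per-sample rearrangement counts on a
chosen channel (intrachromosomal, interchromosomal, or total) by comparing
carriers with non-carriers, the same engine as the SCNA burden comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import MutationObservation, Region, SegmentProfile, ValidationError
from ._stats import bh_qvalues, rank_sum_test

__all__ = [
    "LesionMatrix",
    "build_lesion_matrix",
    "AssociationResult",
    "associate_lesion_with_burden",
    "associate_all",
    "rank_associations",
    "ExclusivityResult",
    "mutual_exclusivity",
]

logger = logging.getLogger(__name__)

POINT_MUTATION = "point_mutation"
REGION_DELETION = "deletion"

DEFAULT_MIN_RECURRENCE = 3
DEFAULT_DEL_THRESHOLD = 0.2  # deletion called when log2 <= -threshold


@dataclass
class LesionMatrix:
    """Binary samples x lesions presence matrix with a per-lesion kind."""

    presence: pd.DataFrame  # index: sample ids; columns: lesion ids; values 0/1
    kinds: pd.Series        # lesion id -> {point_mutation, deletion}

    @property
    def sample_ids(self) -> list[str]:
        return list(self.presence.index)

    @property
    def lesions(self) -> list[str]:
        return list(self.presence.columns)

    def column(self, lesion: str) -> pd.Series:
        return self.presence[lesion]


def build_lesion_matrix(
    mutations: Sequence[MutationObservation],
    profiles: Sequence[SegmentProfile],
    regions: Sequence[Region],
    sample_ids: Sequence[str],
    log2_del_threshold: float = DEFAULT_DEL_THRESHOLD,
    min_recurrence: int = DEFAULT_MIN_RECURRENCE,
) -> LesionMatrix:
    """Build the presence matrix over a fixed sample universe.

    A point-mutation lesion is present in a sample iff the sample has >= 1
    mutation in that gene; a region-deletion lesion is present iff any
    segment overlapping the region has log2 <= -``log2_del_threshold``.
    Lesions carried by fewer than ``min_recurrence`` samples are dropped
    (and logged) — they are not "recurrent".
    """
    for a, b in zip(regions, regions[1:]):
        if a.overlaps(b.chrom, b.start, b.end):
            raise ValidationError(f"regions {a.name} and {b.name} overlap")
    index = pd.Index(sample_ids, name="sample_id")
    columns: dict[str, pd.Series] = {}
    kinds: dict[str, str] = {}

    genes = sorted({m.gene for m in mutations})
    for gene in genes:
        col = pd.Series(0, index=index, dtype=np.int8)
        for m in mutations:
            if m.gene == gene:
                if m.sample_id not in index:
                    raise ValidationError(
                        f"mutation sample {m.sample_id!r} not in sample universe"
                    )
                col[m.sample_id] = 1
        columns[gene] = col
        kinds[gene] = POINT_MUTATION

    profile_map = {p.sample_id: p for p in profiles}
    for region in regions:
        col = pd.Series(0, index=index, dtype=np.int8)
        for sid in index:
            profile = profile_map.get(sid)
            if profile is None:
                continue
            for seg in profile.segments:
                if (
                    region.overlaps(seg.chrom, seg.start, seg.end)
                    and seg.log2_ratio <= -log2_del_threshold
                ):
                    col[sid] = 1
                    break
        columns[region.name] = col
        kinds[region.name] = REGION_DELETION

    presence = pd.DataFrame(columns, index=index)
    recurrent = presence.columns[presence.sum(axis=0) >= min_recurrence]
    dropped = [c for c in presence.columns if c not in set(recurrent)]
    if dropped:
        logger.info("dropping %d non-recurrent lesions: %s", len(dropped), dropped)
    presence = presence[list(recurrent)]
    return LesionMatrix(presence, pd.Series({c: kinds[c] for c in presence.columns},
                                            name="kind"))


@dataclass
class AssociationResult:
    """Rank-sum association of one lesion with one burden channel."""

    lesion: str
    channel: str
    n_carrier: int
    n_noncarrier: int
    direction: int  # +1: carriers have higher burden
    p_value: float
    minus_log10_p: float
    q_value: float = float("nan")


def associate_lesion_with_burden(
    presence: pd.Series,
    burden: pd.Series,
    lesion: str = "",
    channel: str = "",
) -> AssociationResult:
    """Compare burden between carriers and non-carriers of one lesion.

    Two-sided rank-sum p with the direction of the carrier shift; errors if
    either group is empty (a lesion carried by all or no samples is not
    testable).
    """
    presence, burden = presence.align(burden, join="inner")
    carriers = burden[presence == 1].to_numpy(dtype=float)
    noncarriers = burden[presence == 0].to_numpy(dtype=float)
    if carriers.size == 0 or noncarriers.size == 0:
        raise ValueError(
            f"lesion {lesion or presence.name}: carriers and non-carriers must both "
            "be non-empty"
        )
    res = rank_sum_test(carriers, noncarriers)
    return AssociationResult(
        lesion=lesion or str(presence.name),
        channel=channel,
        n_carrier=carriers.size,
        n_noncarrier=noncarriers.size,
        direction=res.direction,
        p_value=res.p_two,
        minus_log10_p=float(-np.log10(res.p_two)) if res.p_two > 0 else np.inf,
    )


def associate_all(
    matrix: LesionMatrix,
    burden_table: pd.DataFrame,
    channels: Sequence[str] = ("n_intra", "n_inter", "n_total"),
) -> pd.DataFrame:
    """Association of every lesion with every burden channel, BH-corrected."""
    results: list[AssociationResult] = []
    for channel in channels:
        burden = burden_table[channel]
        for lesion in matrix.lesions:
            results.append(
                associate_lesion_with_burden(
                    matrix.column(lesion), burden, lesion=lesion, channel=channel
                )
            )
    ranked = rank_associations(results)
    ranked["kind"] = ranked["lesion"].map(matrix.kinds)
    return ranked


def rank_associations(results: Sequence[AssociationResult]) -> pd.DataFrame:
    """Benjamini-Hochberg q-values per channel; sorted by p ascending."""
    if not results:
        raise ValueError("no association results to rank")
    df = pd.DataFrame(
        {
            "lesion": [r.lesion for r in results],
            "channel": [r.channel for r in results],
            "n_carrier": [r.n_carrier for r in results],
            "n_noncarrier": [r.n_noncarrier for r in results],
            "direction": [r.direction for r in results],
            "p_value": [r.p_value for r in results],
            "minus_log10_p": [r.minus_log10_p for r in results],
        }
    )
    df["q_value"] = np.nan
    for channel in df["channel"].unique():
        mask = df["channel"] == channel
        df.loc[mask, "q_value"] = bh_qvalues(df.loc[mask, "p_value"].to_numpy())
    return df.sort_values(["channel", "p_value", "lesion"]).reset_index(drop=True)


@dataclass
class ExclusivityResult:
    """One-tail Fisher test for mutual exclusivity of two lesions.

    The 2x2 table is (both, A only, B only, neither); the one-tail p is the
    probability of observing an overlap at most as large as seen, under the
    hypergeometric null with fixed margins.  Small p means the lesions
    co-occur less than chance — they are mutually exclusive.
    """

    n_both: int
    n_a_only: int
    n_b_only: int
    n_neither: int
    odds_ratio: float
    p_value: float
    degenerate: bool


def mutual_exclusivity(presence_a: pd.Series, presence_b: pd.Series) -> ExclusivityResult:
    a_vec, b_vec = presence_a.align(presence_b, join="inner")
    a_arr = a_vec.to_numpy(dtype=int)
    b_arr = b_vec.to_numpy(dtype=int)
    n = a_arr.size
    both = int(np.sum((a_arr == 1) & (b_arr == 1)))
    a_only = int(np.sum((a_arr == 1) & (b_arr == 0)))
    b_only = int(np.sum((a_arr == 0) & (b_arr == 1)))
    neither = n - both - a_only - b_only
    n_a, n_b = both + a_only, both + b_only
    degenerate = n_a == 0 or n_b == 0 or n_a == n or n_b == n
    if degenerate:
        p = 1.0
    else:
        # P(overlap <= observed) with margins (n, n_a, n_b) fixed
        p = float(stats.hypergeom.cdf(both, n, n_a, n_b))
    if a_only * b_only > 0:
        odds = (both * neither) / (a_only * b_only)
    else:
        odds = np.inf if both * neither > 0 else np.nan
    return ExclusivityResult(both, a_only, b_only, neither, float(odds), p, degenerate)
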