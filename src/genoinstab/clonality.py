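"""Clonality (cancer cell fraction) estimation and lesion-precedence graphs.

The cancer cell fraction (CCF) of a lesion is the fraction of tumor cells
that carry it; clonal lesions (CCF ~ 1) arose before the tumor's most recent
common ancestor, subclonal ones later.  For a point mutation observed with
``alt``/``ref`` read counts in a specimen of purity ``p`` at a locus of
total tumor copy number ``CN`` and mutated-copy multiplicity ``m``, the
expected variant allele fraction is

    E[VAF] = m * CCF * p / (p * CN + 2 * (1 - p))

so the estimator inverts this map at the observed VAF.  For a deletion, a
mono-allelic-loss two-population mixture relates the length-weighted mean
log2 ratio L over the region to the carrier fraction c:

    2 * 2^L = 2 - p * c     =>     c = 2 * (1 - 2^L) / p

Precedence between two lesions is decided by a one-sided binomial sign test
on CCF dominance across co-occurring samples; an acyclic evolution graph is
assembled by removing the weakest (largest-p) edges from any cycles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
from scipy import stats

from .io import MutationObservation, Region, SegmentProfile, ValidationError
from .association import LesionMatrix

__all__ = [
    "ClonalityEstimate",
    "estimate_multiplicity",
    "estimate_ccf",
    "deletion_clonality",
    "EdgeDecision",
    "precedence_test",
    "build_evolution_graph",
    "graph_to_edge_table",
    "graph_to_dot",
]

DEFAULT_DELTA = 0.1          # CCF tie zone for precedence
DEFAULT_ALPHA = 0.05         # sign-test significance for an edge
DEFAULT_MIN_COOCCURRENCE = 3


@dataclass(frozen=True)
class ClonalityEstimate:
    """A per-sample, per-lesion CCF point estimate with a central 95% interval."""

    sample_id: str
    lesion: str
    ccf: float
    ci_low: float
    ci_high: float
    method: str  # {snv_readcount, segment_logratio}
    multiplicity: int | None = None
    flag: str | None = None  # e.g. not_a_deletion, biallelic_suspected

    def __post_init__(self) -> None:
        if not (0.0 <= self.ccf <= 1.0):
            raise ValidationError(f"ccf {self.ccf} outside [0, 1]")
        if not (self.ci_low - 1e-12 <= self.ccf <= self.ci_high + 1e-12):
            raise ValidationError("ccf outside its own interval")


def _vaf_denominator(purity: float, local_cn: int) -> float:
    """Mean locus copies per cell in the tumor/normal mixture: p*CN + 2(1-p)."""
    return purity * local_cn + 2.0 * (1.0 - purity)


def estimate_multiplicity(vaf: float, purity: float, local_cn: int) -> int:
    """Mutated-copy multiplicity by rounding the copy-weighted VAF.

    m = round(vaf * (p*CN + 2(1-p)) / p), clamped to [1, CN].  Exact at the
    clonal extremes (m = 1 het, m = CN fully mutated).
    """
    if not 0.0 <= vaf <= 1.0:
        raise ValueError(f"vaf {vaf} outside [0, 1]")
    if purity <= 0:
        raise ValueError("purity must be positive")
    m = round(vaf * _vaf_denominator(purity, local_cn) / purity)
    return int(min(max(m, 1), local_cn))


def estimate_ccf(obs: MutationObservation, lesion: str | None = None) -> ClonalityEstimate:
    """CCF of a point mutation from its allele read counts.

    Inverts the expected-VAF map at the observed VAF with the rounded
    multiplicity; the 95% interval propagates a Beta(alt+1/2, ref+1/2)
    (Jeffreys) interval on the VAF through the same linear map.  Estimates
    and interval ends are clamped to [0, 1].
    """
    if obs.depth == 0:
        raise ValueError(f"zero-depth observation {obs.sample_id}/{obs.gene}")
    vaf = obs.vaf
    m = estimate_multiplicity(vaf, obs.purity, obs.local_cn)
    scale = _vaf_denominator(obs.purity, obs.local_cn) / (obs.purity * m)
    ccf = float(np.clip(vaf * scale, 0.0, 1.0))
    beta = stats.beta(obs.alt_count + 0.5, obs.ref_count + 0.5)
    lo, hi = beta.ppf(0.025), beta.ppf(0.975)
    ci_low = float(np.clip(lo * scale, 0.0, 1.0))
    ci_high = float(np.clip(hi * scale, 0.0, 1.0))
    return ClonalityEstimate(
        sample_id=obs.sample_id,
        lesion=lesion or obs.gene,
        ccf=ccf,
        ci_low=min(ci_low, ccf),
        ci_high=max(ci_high, ccf),
        method="snv_readcount",
        multiplicity=m,
    )


def deletion_clonality(
    profile: SegmentProfile,
    region: Region,
    purity: float,
    lesion: str | None = None,
) -> ClonalityEstimate:
    """CCF of a region deletion from segment log2 ratios.

    Uses the length-weighted mean log2 ratio L over the parts of segments
    overlapping the region and solves the mono-allelic-loss mixture
    2*2^L = 2 - purity*c for c, clamping to [0, 1].  c > 1 before clamping
    suggests bi-allelic loss and is flagged; L > 0 (a gain) yields CCF 0
    with a not-a-deletion flag.  The interval propagates the length-weighted
    standard error of the per-segment log2 ratios through the same map.
    """
    if purity <= 0:
        raise ValueError("purity must be positive")
    parts: list[tuple[int, float]] = []  # (overlap length, log2)
    for seg in profile.segments:
        if region.overlaps(seg.chrom, seg.start, seg.end):
            ov = min(seg.end, region.end) - max(seg.start, region.start)
            parts.append((ov, seg.log2_ratio))
    if not parts:
        raise ValueError(
            f"region {region.name} not covered by any segment of {profile.sample_id}"
        )
    lengths = np.array([p[0] for p in parts], dtype=float)
    log2s = np.array([p[1] for p in parts], dtype=float)
    weights = lengths / lengths.sum()
    L = float(np.dot(weights, log2s))
    name = lesion or region.name

    def solve(level: float) -> float:
        return 2.0 * (1.0 - 2.0 ** level) / purity

    if L > 0:
        return ClonalityEstimate(profile.sample_id, name, 0.0, 0.0, 0.0,
                                 "segment_logratio", flag="not_a_deletion")
    raw = solve(L)
    ccf = float(np.clip(raw, 0.0, 1.0))
    flag = "biallelic_suspected" if raw > 1.0 else None
    if len(parts) > 1:
        var_w = float(np.dot(weights, (log2s - L) ** 2))
        se = np.sqrt(var_w / len(parts))
    else:
        se = 0.0
    # solve() is decreasing in L, so the lower CCF bound comes from L + 1.96 se
    ci_low = float(np.clip(solve(L + 1.96 * se), 0.0, 1.0))
    ci_high = float(np.clip(solve(L - 1.96 * se), 0.0, 1.0))
    return ClonalityEstimate(profile.sample_id, name, ccf,
                             min(ci_low, ccf), max(ci_high, ccf),
                             "segment_logratio", flag=flag)


# ---------------------------------------------------------------------------
# precedence testing and the evolution graph
# ---------------------------------------------------------------------------


@dataclass
class EdgeDecision:
    """Outcome of the pairwise precedence test A -> B."""

    lesion_a: str
    lesion_b: str
    n_shared: int
    wins_a: int
    wins_b: int
    ties: int
    p_value: float
    mean_gap: float
    edge: bool
    flag: str | None = None


def precedence_test(
    estimates_a: Sequence[ClonalityEstimate],
    estimates_b: Sequence[ClonalityEstimate],
    delta: float = DEFAULT_DELTA,
    alpha: float = DEFAULT_ALPHA,
    min_cooccurrence: int = DEFAULT_MIN_COOCCURRENCE,
) -> EdgeDecision:
    """One-sided binomial sign test for "A precedes B" on shared samples.

    Within samples carrying both lesions, a win for A is ccf_a >= ccf_b +
    delta; samples within the delta tie zone are ignored.  The edge A -> B
    is called when the binomial tail P(X >= wins_a | wins, 1/2) falls below
    alpha.  Swapping A and B reverses any edge.
    """
    a_by_sample = {e.sample_id: e for e in estimates_a}
    b_by_sample = {e.sample_id: e for e in estimates_b}
    shared = sorted(set(a_by_sample) & set(b_by_sample))
    name_a = estimates_a[0].lesion if estimates_a else "A"
    name_b = estimates_b[0].lesion if estimates_b else "B"
    if len(shared) < min_cooccurrence:
        return EdgeDecision(name_a, name_b, len(shared), 0, 0, len(shared),
                            1.0, 0.0, False, flag="insufficient_data")
    gaps = np.array([a_by_sample[s].ccf - b_by_sample[s].ccf for s in shared])
    wins_a = int(np.sum(gaps >= delta))
    wins_b = int(np.sum(gaps <= -delta))
    ties = len(shared) - wins_a - wins_b
    informative = wins_a + wins_b
    if informative == 0:
        return EdgeDecision(name_a, name_b, len(shared), 0, 0, ties, 1.0,
                            float(gaps.mean()), False)
    p = float(stats.binom.sf(wins_a - 1, informative, 0.5))
    return EdgeDecision(name_a, name_b, len(shared), wins_a, wins_b, ties, p,
                        float(gaps.mean()), p < alpha)


def build_evolution_graph(
    matrix: LesionMatrix,
    estimates: Mapping[str, Sequence[ClonalityEstimate]],
    delta: float = DEFAULT_DELTA,
    alpha: float = DEFAULT_ALPHA,
    min_cooccurrence: int = DEFAULT_MIN_COOCCURRENCE,
) -> nx.DiGraph:
    """Directed acyclic graph of lesion precedence.

    Runs the precedence test for every ordered lesion pair with sufficient
    co-occurrence; cycles are resolved by repeatedly removing the cycle edge
    with the largest sign-test p until the graph is acyclic.  Deterministic
    given the input estimates.
    """
    graph = nx.DiGraph()
    lesions = matrix.lesions
    graph.add_nodes_from(lesions)
    presence = matrix.presence
    for a in lesions:
        for b in lesions:
            if a == b:
                continue
            co = presence.index[(presence[a] == 1) & (presence[b] == 1)]
            est_a = [e for e in estimates.get(a, []) if e.sample_id in set(co)]
            est_b = [e for e in estimates.get(b, []) if e.sample_id in set(co)]
            decision = precedence_test(est_a, est_b, delta, alpha, min_cooccurrence)
            if decision.edge:
                graph.add_edge(
                    a, b,
                    support=decision.wins_a,
                    n_shared=decision.n_shared,
                    p_value=decision.p_value,
                    mean_gap=decision.mean_gap,
                )
    _break_cycles(graph)
    return graph


def _break_cycles(graph: nx.DiGraph) -> None:
    """Remove the largest-p edge of each remaining cycle until acyclic."""
    while True:
        try:
            cycle = nx.find_cycle(graph, orientation="original")
        except nx.NetworkXNoCycle:
            return
        worst = max(
            (edge[:2] for edge in cycle),
            key=lambda uv: (graph.edges[uv]["p_value"], uv),
        )
        graph.remove_edge(*worst)


def graph_to_edge_table(graph: nx.DiGraph):
    import pandas as pd

    rows = [
        {
            "from": u,
            "to": v,
            "support": d["support"],
            "n_shared": d["n_shared"],
            "p_value": d["p_value"],
            "mean_ccf_gap": d["mean_gap"],
        }
        for u, v, d in sorted(graph.edges(data=True))
    ]
    return pd.DataFrame(rows, columns=["from", "to", "support", "n_shared",
                                       "p_value", "mean_ccf_gap"])


def graph_to_dot(graph: nx.DiGraph) -> str:
    """Minimal deterministic DOT export of the evolution graph."""
    lines = ["digraph evolution {"]
    for node in sorted(graph.nodes):
        lines.append(f'    "{node}";')
    for u, v, d in sorted(graph.edges(data=True)):
        lines.append(f'    "{u}" -> "{v}" [label="p={d["p_value"]:.3g}"];')
    lines.append("}")
    return "\n".join(lines) + "\n"
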