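"""End-to-end orchestration of the cohort analysis from one YAML config.

The stage chain mirrors the cohort analysis: read or simulate the cohort,
classify and count rearrangements, decompose the burden distribution,
compute SCNA burden (FGA) and its between-group comparison, test
lesion-burden associations and pairwise exclusivity, estimate clonality,
assemble the evolution graph, and (when expression inputs are present) run
signature segregation.  Every output table carries a metadata block with
the package version, a config hash and the seed, and identical config+seed
reruns produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from . import io as cio
from .association import (
    associate_all,
    build_lesion_matrix,
    mutual_exclusivity,
    REGION_DELETION,
)
from .burden import assign_subpopulation, classify_events, count_by_sample, \
    fit_two_component_mixture
from .clonality import (
    build_evolution_graph,
    deletion_clonality,
    estimate_ccf,
    graph_to_dot,
    graph_to_edge_table,
)
from .scna import DEFAULT_BIN_EDGES, bin_fga, compare_burden, fga_table
from .segregation import cluster_samples, cut_two, segregation_pvalue
from .synthetic import CohortConfig, DeletionLesionSpec, simulate_cohort, write_cohort

logger = logging.getLogger(__name__)

STAGES = ("cohort", "burden", "mixture", "fga", "associate", "exclusivity",
          "clonality", "evolve", "segregate")


@dataclass
class RunConfig:
    """Validated run configuration (one YAML document)."""

    out_dir: str
    seed: int = 0
    inputs: dict[str, str] | None = None
    synthetic: dict[str, Any] | None = None
    genome: str | None = None
    log2_threshold: float = 0.2
    log2_del_threshold: float = 0.2
    bin_edges: tuple[float, ...] = DEFAULT_BIN_EDGES
    min_recurrence: int = 3
    min_cooccurrence: int = 3
    delta: float = 0.1
    alpha: float = 0.05
    group_label: str = "driver_status"
    n_permutations: int = 10000
    include_sex: bool = False

    def __post_init__(self) -> None:
        if (self.inputs is None) == (self.synthetic is None):
            raise ValueError(
                "config must contain exactly one of an 'inputs' section and a "
                "'synthetic' section"
            )
        for name, lo, hi in (
            ("log2_threshold", 0.0, 2.0),
            ("log2_del_threshold", 0.0, 2.0),
            ("delta", 0.0, 1.0),
            ("alpha", 0.0, 1.0),
        ):
            value = getattr(self, name)
            if not lo < value <= hi:
                raise ValueError(f"{name}={value} outside ({lo}, {hi}]")
        if self.min_recurrence < 1 or self.min_cooccurrence < 1:
            raise ValueError("min_recurrence and min_cooccurrence must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(raw)
        if "bin_edges" in kwargs:
            kwargs["bin_edges"] = tuple(kwargs["bin_edges"])
        return cls(**kwargs)

    def cohort_config(self) -> CohortConfig:
        assert self.synthetic is not None
        raw = dict(self.synthetic)
        if "deletion_lesions" in raw:
            raw["deletion_lesions"] = tuple(
                DeletionLesionSpec(**d) if isinstance(d, dict) else d
                for d in raw["deletion_lesions"]
            )
        if "passenger_genes" in raw:
            raw["passenger_genes"] = tuple(
                tuple(p) for p in raw["passenger_genes"]
            )
        raw.setdefault("seed", self.seed)
        return CohortConfig(**raw).validate()

    def config_hash(self) -> str:
        """Hash of the scientific configuration (everything but out_dir)."""
        payload = dataclasses.asdict(self)
        payload.pop("out_dir")
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(
    config: RunConfig,
    stages: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Execute the stage chain and return the manifest of written files.

    ``stages`` restricts which stages write output; upstream stages a
    selected stage depends on still execute in memory.  A stage failure
    aborts the run with the stage name in the error; tables written before
    the failure are flagged as partial in the manifest.
    """
    selected = set(stages or STAGES)
    unknown = selected - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    out_dir = Path(config.out_dir)
    metadata = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": str(config.seed),
    }
    tables: dict[str, pd.DataFrame] = {}
    skipped: list[str] = []
    state: dict[str, Any] = {}
    current = "cohort"
    try:
        current = "cohort"
        _stage_cohort(config, state, write="cohort" in selected)
        current = "burden"
        _stage_burden(config, state, tables if "burden" in selected else {})
        current = "mixture"
        _stage_mixture(config, state, tables if "mixture" in selected else {})
        current = "fga"
        _stage_fga(config, state, tables if "fga" in selected else {})
        current = "associate"
        _stage_associate(config, state, tables if "associate" in selected else {})
        current = "exclusivity"
        _stage_exclusivity(config, state, tables if "exclusivity" in selected else {})
        current = "clonality"
        _stage_clonality(config, state, tables if "clonality" in selected else {})
        current = "evolve"
        _stage_evolve(config, state, tables if "evolve" in selected else {},
                      out_dir if "evolve" in selected else None)
        current = "segregate"
        if state.get("expression") is None:
            skipped.append("segregate")
            logger.info("segregate stage skipped: no expression inputs")
        else:
            _stage_segregate(config, state, tables if "segregate" in selected else {})
    except Exception as exc:
        manifest = cio.write_results(tables, out_dir, metadata)
        manifest["status"] = "partial"
        manifest.to_csv(out_dir / "manifest.tsv", sep="\t", index=False,
                        lineterminator="\n")
        raise RuntimeError(f"pipeline stage {current!r} failed: {exc}") from exc

    manifest = cio.write_results(tables, out_dir, metadata)
    manifest["status"] = "complete"
    for stage in skipped:
        manifest = pd.concat(
            [manifest, pd.DataFrame([{"file": f"({stage})", "rows": 0,
                                      "sha256": "", "status": "skipped"}])],
            ignore_index=True,
        )
    if "evolve" in selected and "evolution_dot" in state:
        (out_dir / "evolution.dot").write_text(state["evolution_dot"])
    manifest.to_csv(out_dir / "manifest.tsv", sep="\t", index=False,
                    lineterminator="\n")
    return manifest


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def _stage_cohort(config: RunConfig, state: dict, write: bool) -> None:
    if config.synthetic is not None:
        cohort = simulate_cohort(config.cohort_config())
        state.update(
            genome=cohort.genome,
            events=cohort.events,
            profiles=cohort.profiles,
            mutations=cohort.mutations,
            sheet=cohort.sample_sheet,
            regions=cohort.regions,
            cohort=cohort,
            expression=None,
            signature=None,
        )
        if write:
            write_cohort(cohort, Path(config.out_dir) / "cohort")
        return
    inputs = dict(config.inputs or {})
    if config.genome is None:
        raise ValueError("real-data runs require a genome definition path")
    genome = cio.read_genome(config.genome)
    sheet = cio.read_sample_sheet(inputs["samples"])
    state.update(
        genome=genome,
        sheet=sheet,
        events=cio.read_rearrangements(inputs["rearrangements"], genome),
        profiles=cio.read_segments(inputs["segments"], genome),
        mutations=cio.read_mutations(inputs["mutations"], sheet),
        regions=(
            cio.read_regions(inputs["regions"], genome)
            if "regions" in inputs else []
        ),
        expression=(
            cio.read_expression(inputs["expression"])
            if "expression" in inputs else None
        ),
        signature=None,
    )
    if "signature" in inputs:
        sets = cio.read_gmt(inputs["signature"])
        name = inputs.get("signature_set") or sorted(sets)[0]
        state["signature"] = sorted(sets[name])


def _stage_burden(config: RunConfig, state: dict, tables: dict) -> None:
    events = classify_events(state["events"])
    state["events"] = events
    table = count_by_sample(events, state["sheet"])
    state["burden"] = table
    tables["burden"] = table.reset_index()


def _stage_mixture(config: RunConfig, state: dict, tables: dict) -> None:
    table = state["burden"]
    fit = fit_two_component_mixture(
        table["n_total"].to_numpy(), seed=config.seed,
        sample_ids=list(table.index),
    )
    labels = assign_subpopulation(fit)
    state["mixture"] = fit
    state["subpopulation"] = labels
    tables["mixture_components"] = pd.DataFrame(
        {
            "component": ["low", "high"],
            "mean_log10": fit.means,
            "variance_log10": fit.variances,
            "weight": fit.weights,
            "delta_bic": [fit.delta_bic] * 2,
            "one_component_preferred": [fit.one_component_preferred] * 2,
            "n_iter": [fit.n_iter] * 2,
        }
    )
    tables["mixture_labels"] = pd.DataFrame(
        {
            "sample_id": fit.sample_ids,
            "log10_total_plus1": fit.log_counts,
            "resp_low": fit.responsibilities[:, 0],
            "resp_high": fit.responsibilities[:, 1],
            "subpopulation": labels.to_numpy(),
        }
    )


def _stage_fga(config: RunConfig, state: dict, tables: dict) -> None:
    fga = fga_table(state["profiles"], state["genome"], config.log2_threshold,
                    config.include_sex)
    fga = fga.reindex(state["sheet"].sample_ids).fillna(0.0)
    state["fga"] = fga
    tables["fga"] = fga.reset_index()
    tables["fga_histogram"] = (
        bin_fga(fga.to_numpy(), config.bin_edges).rename_axis("bin").reset_index()
    )
    groups = _binary_groups(config, state)
    if groups is not None:
        comparison = compare_burden(fga, groups, config.bin_edges)
        state["fga_comparison"] = comparison
        tables["burden_comparison"] = comparison.to_frame()
        hist = comparison.histograms.rename_axis("bin").reset_index()
        tables["fga_histogram_by_group"] = hist


def _binary_groups(config: RunConfig, state: dict) -> pd.Series | None:
    sheet = state["sheet"]
    if config.group_label in sheet.samples.columns:
        groups = sheet.samples[config.group_label]
        if groups.nunique() == 2:
            return groups
        logger.info("group label %r does not have two levels; using mixture "
                    "subpopulations", config.group_label)
    return state.get("subpopulation")


def _stage_associate(config: RunConfig, state: dict, tables: dict) -> None:
    matrix = build_lesion_matrix(
        state["mutations"],
        state["profiles"],
        state["regions"],
        sample_ids=state["sheet"].sample_ids,
        log2_del_threshold=config.log2_del_threshold,
        min_recurrence=config.min_recurrence,
    )
    state["matrix"] = matrix
    if not matrix.lesions:
        logger.warning("no recurrent lesions; association stage is empty")
        tables["associations"] = pd.DataFrame(
            columns=["lesion", "channel", "n_carrier", "n_noncarrier",
                     "direction", "p_value", "minus_log10_p", "q_value"]
        )
        return
    testable = [
        lesion for lesion in matrix.lesions
        if 0 < matrix.column(lesion).sum() < len(matrix.sample_ids)
    ]
    sub = LesionMatrixView(matrix, testable)
    associations = associate_all(sub, state["burden"])
    state["associations"] = associations
    tables["associations"] = associations


class LesionMatrixView:
    """A lesion-subset view with the LesionMatrix duck interface."""

    def __init__(self, matrix, lesions):
        self._matrix = matrix
        self.lesions = list(lesions)
        self.presence = matrix.presence[self.lesions]
        self.kinds = matrix.kinds[self.lesions]
        self.sample_ids = matrix.sample_ids

    def column(self, lesion):
        return self._matrix.column(lesion)


def _stage_exclusivity(config: RunConfig, state: dict, tables: dict) -> None:
    matrix = state["matrix"]
    rows = []
    lesions = matrix.lesions
    for i, a in enumerate(lesions):
        for b in lesions[i + 1:]:
            res = mutual_exclusivity(matrix.column(a), matrix.column(b))
            rows.append(
                {
                    "lesion_a": a, "lesion_b": b,
                    "n_both": res.n_both, "n_a_only": res.n_a_only,
                    "n_b_only": res.n_b_only, "n_neither": res.n_neither,
                    "odds_ratio": res.odds_ratio, "p_value": res.p_value,
                    "degenerate": res.degenerate,
                }
            )
    tables["exclusivity"] = pd.DataFrame(
        rows, columns=["lesion_a", "lesion_b", "n_both", "n_a_only", "n_b_only",
                       "n_neither", "odds_ratio", "p_value", "degenerate"]
    )


def _stage_clonality(config: RunConfig, state: dict, tables: dict) -> None:
    matrix = state["matrix"]
    sheet = state["sheet"]
    kinds = matrix.kinds
    estimates: dict[str, list] = {lesion: [] for lesion in matrix.lesions}
    seen: set[tuple[str, str]] = set()
    for obs in state["mutations"]:
        if obs.gene in estimates and (obs.sample_id, obs.gene) not in seen:
            if obs.depth > 0:
                estimates[obs.gene].append(estimate_ccf(obs))
                seen.add((obs.sample_id, obs.gene))
    region_by_name = {r.name: r for r in state["regions"]}
    profile_by_sample = {p.sample_id: p for p in state["profiles"]}
    for lesion in matrix.lesions:
        if kinds[lesion] != REGION_DELETION:
            continue
        region = region_by_name[lesion]
        col = matrix.column(lesion)
        for sid in col.index[col == 1]:
            profile = profile_by_sample.get(sid)
            if profile is None:
                continue
            estimates[lesion].append(
                deletion_clonality(profile, region, sheet.purity(sid))
            )
    state["clonality"] = estimates
    rows = [
        {
            "sample_id": e.sample_id, "lesion": lesion, "ccf": e.ccf,
            "ci_low": e.ci_low, "ci_high": e.ci_high, "method": e.method,
            "multiplicity": e.multiplicity if e.multiplicity is not None else "",
            "flag": e.flag or "",
        }
        for lesion in sorted(estimates)
        for e in sorted(estimates[lesion], key=lambda x: x.sample_id)
    ]
    tables["clonality"] = pd.DataFrame(
        rows, columns=["sample_id", "lesion", "ccf", "ci_low", "ci_high",
                       "method", "multiplicity", "flag"]
    )


def _stage_evolve(config: RunConfig, state: dict, tables: dict,
                  out_dir: Path | None) -> None:
    graph = build_evolution_graph(
        state["matrix"], state["clonality"],
        delta=config.delta, alpha=config.alpha,
        min_cooccurrence=config.min_cooccurrence,
    )
    state["graph"] = graph
    state["evolution_dot"] = graph_to_dot(graph)
    tables["evolution_edges"] = graph_to_edge_table(graph)


def _stage_segregate(config: RunConfig, state: dict, tables: dict) -> None:
    expr = state["expression"]
    signature = state["signature"]
    if signature is None:
        signature = list(expr.index)
    dendrogram = cluster_samples(expr, signature)
    clusters = cut_two(dendrogram)
    labels = state["sheet"].labels(config.group_label)
    binary = (labels == "mut").astype(int)
    result = segregation_pvalue(clusters, binary,
                                n_permutations=config.n_permutations,
                                seed=config.seed)
    tables["segregation"] = pd.DataFrame(
        [
            {
                "n_cluster1": result.cluster_sizes[0],
                "n_cluster2": result.cluster_sizes[1],
                "labeled_cluster1": result.labeled_per_cluster[0],
                "labeled_cluster2": result.labeled_per_cluster[1],
                "observed_min_hypergeom": result.observed_statistic,
                "permutation_p": result.p_value,
                "n_permutations": result.n_permutations,
                "statistic": "min_hypergeom_enrichment",
            }
        ]
    )
    tables["segregation_clusters"] = clusters.reset_index()
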