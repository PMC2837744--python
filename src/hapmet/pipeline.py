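"""End-to-end orchestration: simulate/load -> network -> permutation tests
-> model comparison, with one global seed, structured logging and a
machine-readable report.

The global seed fans out to per-stage seeds by hashing the stage name with
the seed, so each stage is reproducible in isolation; the report JSON is a
pure function of (config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import networkx as nx

from . import __version__
from .errors import InputError
from .io import (
    SequenceAlignment,
    TraitTable,
    TreeSet,
    categorize_rate,
    read_alignment,
    read_trait_table,
    read_tree_set,
)
from .network import (
    Haplotype,
    HaplotypeNetwork,
    RootedNetwork,
    build_network,
    collapse_haplotypes,
    export_network,
    root_network,
)
from .randtests import permutation_test
from .simulate import SimulationConfig, generate_study_dataset, write_dataset
from .trait_models import McmcConfig, compare_models

logger = logging.getLogger("hapmet")

__all__ = [
    "PipelineConfig",
    "AnalysisReport",
    "stage_seed",
    "validate_inputs",
    "run_full_analysis",
    "load_network_graphml",
]

REPORT_SCHEMA_VERSION = 1


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % 2**31


@dataclass
class PipelineConfig:
    """Inputs and settings for a full analysis run.

    In synthetic mode (``simulation`` set) the dataset is generated; in
    input mode the three file paths must exist.  ``root_individual`` picks
    the tip used to root the trees for the comparative analysis; by default
    the lexicographically first member of the commonest haplotype is used,
    and ``concordance_check`` reruns with the next such member.
    """

    simulation: SimulationConfig | None = None
    alignment_path: str | None = None
    traits_path: str | None = None
    trees_path: str | None = None
    burnin_fraction: float = 0.1
    k_values: tuple[int, ...] = (0, 1)
    n_perm: int = 1000
    mcmc: McmcConfig = field(default_factory=McmcConfig)
    max_trees: int | None = 100
    max_connection_steps: int | None = None
    root_individual: str | None = None
    concordance_check: bool = False
    seed: int = 0
    out_dir: str = "results"

    def __post_init__(self) -> None:
        if self.simulation is None:
            for name in ("alignment_path", "traits_path", "trees_path"):
                path = getattr(self, name)
                if path is None:
                    raise InputError(
                        f"{name} required when no simulation config is given"
                    )
                if not Path(path).exists():
                    raise InputError(f"{name} does not exist: {path}")

    @classmethod
    def from_toml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        sim = raw.pop("simulation", None)
        mcmc = raw.pop("mcmc", None)
        kw: dict = {}
        if sim is not None:
            if "base_freqs" in sim:
                sim["base_freqs"] = tuple(sim["base_freqs"])
            if "trait_range" in sim:
                sim["trait_range"] = tuple(sim["trait_range"])
            kw["simulation"] = SimulationConfig(**sim)
        if mcmc is not None:
            for key in ("alpha_bounds", "beta_bounds", "sigma2_bounds"):
                if key in mcmc:
                    mcmc[key] = tuple(mcmc[key])
            kw["mcmc"] = McmcConfig(**mcmc)
        if "k_values" in raw:
            raw["k_values"] = tuple(raw["k_values"])
        kw.update(raw)
        kw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**kw)


@dataclass
class AnalysisReport:
    """Everything a run produced, JSON-serialisable and seed-reproducible."""

    schema_version: int
    dataset: dict
    network_path: str
    permutation_tests: dict
    model_comparison: dict
    concordance: dict | None
    provenance: dict

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def validate_inputs(
    alignment: SequenceAlignment, traits: TraitTable, tree_set: TreeSet
) -> list[dict]:
    """Cross-check ids and invariants; returns itemised issues (empty when
    everything is consistent)."""
    issues: list[dict] = []
    aln_ids = set(alignment.ids)
    trait_ids = set(traits.ids)
    tip_ids = set(tree_set.tip_labels)
    for missing in sorted((trait_ids | tip_ids) - aln_ids):
        issues.append({"kind": "missing-in-alignment", "id": missing})
    for missing in sorted((aln_ids | tip_ids) - trait_ids):
        issues.append({"kind": "missing-in-traits", "id": missing})
    for missing in sorted((aln_ids | trait_ids) - tip_ids):
        issues.append({"kind": "missing-in-trees", "id": missing})
    for idx, tree in enumerate(tree_set):
        for edge in tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                issues.append(
                    {"kind": "invalid-branch-length", "tree_index": idx}
                )
                break
    return issues


def _reroot_at(tree_set: TreeSet, individual: str) -> TreeSet:
    """Root every tree with ``individual`` as the outgroup."""
    rerooted = []
    namespace = dendropy.TaxonNamespace()
    for tree in tree_set:
        clone = dendropy.Tree.get(
            data=tree.as_string(schema="newick"),
            schema="newick",
            rooting="force-rooted",
            taxon_namespace=namespace,
        )
        node = clone.find_node_with_taxon_label(individual)
        if node is None:
            raise InputError(f"root individual {individual!r} not in tree")
        clone.to_outgroup_position(node, update_bipartitions=False)
        rerooted.append(clone)
    return TreeSet(dendropy.TreeList(rerooted, taxon_namespace=namespace))


def _thin_trees(tree_set: TreeSet, max_trees: int | None) -> TreeSet:
    if max_trees is None or len(tree_set) <= max_trees:
        return tree_set
    step = len(tree_set) / max_trees
    idx = sorted({int(i * step) for i in range(max_trees)})
    return TreeSet(
        dendropy.TreeList(
            [tree_set[i] for i in idx],
            taxon_namespace=tree_set.trees.taxon_namespace,
        )
    )


def _root_candidates(haplotypes: list[Haplotype]) -> list[str]:
    """Members of the commonest haplotype, lexicographically ordered."""
    max_freq = max(h.frequency for h in haplotypes)
    best = min(
        (h for h in haplotypes if h.frequency == max_freq),
        key=lambda h: h.haplotype_id,
    )
    return sorted(best.members)


def _dataset_summary(
    alignment: SequenceAlignment,
    traits: TraitTable,
    rooted: RootedNetwork,
) -> dict:
    rates = list(traits.rates().values())
    graph = rooted.network.graph
    observed = rooted.network.observed_nodes
    max_steps = 0
    lengths = dict(nx.all_pairs_shortest_path_length(graph))
    for i, a in enumerate(observed):
        for b in observed[i + 1 :]:
            if b in lengths.get(a, {}):
                max_steps = max(max_steps, lengths[a][b])
    cats = [categorize_rate(r).value for r in rates]
    return {
        "n_individuals": len(alignment),
        "alignment_length": alignment.length,
        "n_haplotypes": len(rooted.network.haplotypes),
        "n_inferred_nodes": len(rooted.network.inferred_nodes),
        "max_network_steps": max_steps,
        "root_haplotype": rooted.root,
        "root_haplotype_frequency": next(
            h.frequency
            for h in rooted.network.haplotypes
            if h.haplotype_id == rooted.root
        ),
        "trait_min": min(rates),
        "trait_mean": sum(rates) / len(rates),
        "trait_max": max(rates),
        "rate_categories": {
            c: cats.count(c) for c in ("low", "medium", "high")
        },
    }


def _log_stage(stage: str, start: float, **info) -> None:
    logger.info(
        "stage=%s wall_time_s=%.2f %s",
        stage,
        time.perf_counter() - start,
        " ".join(f"{k}={v}" for k, v in info.items()),
    )


def run_full_analysis(config: PipelineConfig) -> AnalysisReport:
    """Execute all stages and write report.json, summary.md and
    network.graphml into the output directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    t0 = time.perf_counter()
    if config.simulation is not None:
        sim = dataclasses.replace(
            config.simulation, seed=stage_seed(config.seed, "simulate")
        )
        dataset = generate_study_dataset(sim)
        write_dataset(dataset, out / "dataset")
        alignment, traits = dataset.alignment, dataset.traits
        tree_set = dataset.posterior_trees
        _log_stage("simulate", t0, n=len(alignment))
    else:
        alignment = read_alignment(config.alignment_path)
        traits = read_trait_table(config.traits_path)
        tree_set = read_tree_set(config.trees_path, config.burnin_fraction)
        _log_stage("load", t0, n=len(alignment), trees=len(tree_set))

    t0 = time.perf_counter()
    issues = validate_inputs(alignment, traits, tree_set)
    if issues:
        raise InputError(f"input validation failed: {issues}")
    _log_stage("validate", t0)

    t0 = time.perf_counter()
    haplotypes = collapse_haplotypes(alignment)
    network = build_network(haplotypes, config.max_connection_steps)
    rooted = root_network(network)
    network_path = out / "network.graphml"
    export_network(rooted, traits, network_path)
    _log_stage("network", t0, haplotypes=len(haplotypes))

    t0 = time.perf_counter()
    perm_results = {}
    for k in config.k_values:
        res = permutation_test(
            "T1",
            rooted,
            traits,
            k=k,
            n_perm=config.n_perm,
            seed=stage_seed(config.seed, f"randtest-t1-{k}"),
        )
        perm_results[f"T1({k})"] = res.to_dict()
    res = permutation_test(
        "T2",
        rooted,
        traits,
        n_perm=config.n_perm,
        seed=stage_seed(config.seed, "randtest-t2"),
    )
    perm_results["T2"] = res.to_dict()
    _log_stage("randtests", t0, n_perm=config.n_perm)

    t0 = time.perf_counter()
    candidates = _root_candidates(haplotypes)
    root_individual = config.root_individual or candidates[0]
    mcmc = dataclasses.replace(config.mcmc, seed=stage_seed(config.seed, "mcmc"))
    thinned = _thin_trees(tree_set, config.max_trees)
    comparison = compare_models(
        _reroot_at(thinned, root_individual), traits, mcmc
    )
    model_comparison = {
        "root_individual": root_individual,
        **comparison.to_dict(),
    }
    _log_stage("models", t0, root=root_individual, trees=len(thinned))

    concordance = None
    if config.concordance_check:
        t0 = time.perf_counter()
        alternates = [c for c in candidates if c != root_individual]
        if alternates:
            alt = alternates[0]
            mcmc2 = dataclasses.replace(
                config.mcmc, seed=stage_seed(config.seed, "mcmc-concordance")
            )
            comparison2 = compare_models(
                _reroot_at(thinned, alt), traits, mcmc2
            )
            concordance = {"root_individual": alt, **comparison2.to_dict()}
            _log_stage("concordance", t0, root=alt)

    report = AnalysisReport(
        schema_version=REPORT_SCHEMA_VERSION,
        dataset=_dataset_summary(alignment, traits, rooted),
        network_path=network_path.name,  # relative to out_dir, keeps the
        # report a pure function of (config, seed)
        permutation_tests=perm_results,
        model_comparison=model_comparison,
        concordance=concordance,
        provenance={
            "package_version": __version__,
            "seed": config.seed,
            "n_perm": config.n_perm,
            "k_values": list(config.k_values),
            "mcmc": config.mcmc.to_dict(),
            "max_trees": config.max_trees,
            "simulation": (
                config.simulation.to_dict() if config.simulation else None
            ),
        },
    )
    with open(out / "report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    _write_summary(report, out / "summary.md")
    return report


def _write_summary(report: AnalysisReport, path: Path) -> None:
    ds = report.dataset
    lines = [
        "# Analysis summary",
        "",
        f"- individuals: {ds['n_individuals']}",
        f"- haplotypes: {ds['n_haplotypes']} "
        f"(root {ds['root_haplotype']}, n = {ds['root_haplotype_frequency']})",
        f"- max mutational steps between haplotypes: {ds['max_network_steps']}",
        f"- metabolic rate range: {ds['trait_min']:.4f} - {ds['trait_max']:.4f}",
        "",
        "## Permutation tests",
        "",
    ]
    for name, res in report.permutation_tests.items():
        lines.append(
            f"- {name}: observed = {res['observed']:.6g}, "
            f"p = {res['p_value']:.4g} ({res['tail']} tail, "
            f"n_perm = {res['n_perm']})"
        )
    mc = report.model_comparison
    lines += [
        "",
        "## Model comparison (Bayes factors, harmonic-mean log ML)",
        "",
        f"- root individual: {mc['root_individual']}",
        f"- directional (B vs A): BF = {mc['directional']['value']:.4f} "
        f"favouring {mc['directional']['better']} "
        f"({mc['directional']['interpretation']})",
        f"- phylogenetic signal (lambda est vs 0): "
        f"BF = {mc['phylogenetic_signal']['value']:.4f} favouring "
        f"{mc['phylogenetic_signal']['better']} "
        f"({mc['phylogenetic_signal']['interpretation']})",
        "",
    ]
    path.write_text("\n".join(lines))


def load_network_graphml(path: str | Path) -> RootedNetwork:
    """Rebuild a RootedNetwork from a GraphML export.

    Sequences are not stored in GraphML, so distance queries work but
    sequence-level operations do not.
    """
    dg = nx.read_graphml(str(path))
    haplotypes = []
    graph = nx.Graph()
    root = None
    for node, data in dg.nodes(data=True):
        members = tuple(m for m in data.get("members", "").split(",") if m)
        inferred = bool(data.get("is_inferred", False))
        graph.add_node(
            node,
            sequence="",
            frequency=int(data.get("frequency", 0)),
            members=members,
            is_inferred=inferred,
        )
        if not inferred:
            haplotypes.append(Haplotype(node, "", members))
        if data.get("is_root", False):
            root = node
    direction = {}
    for u, v in dg.edges():
        graph.add_edge(u, v)
        direction[(min(u, v), max(u, v))] = (u, v)
    if root is None:
        raise InputError(f"no root node flagged in {path}")
    haplotypes.sort(key=lambda h: (-h.frequency, h.haplotype_id))
    return RootedNetwork(HaplotypeNetwork(graph, tuple(haplotypes)), root, direction)
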