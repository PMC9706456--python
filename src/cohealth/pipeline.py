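"""End-to-end orchestration of the per-experiment analysis and the meta-study.

``run_experiment`` takes one experiment through preprocessing, network
construction, module selection and interaction export, returning either an
:class:`ExperimentBundle` or an :class:`ExclusionRecord` (inclusion-rule
failures, constant phenotype scores, or no scale-free network — the
'no modules found' case — are recorded, never raised to the caller).
``run_meta`` intersects the surviving experiments' ranked lists across
species, assembles the consensus graph and runs the permutation nulls.
Every experiment derives its own sub-seed from the study seed by stable
hashing of its ID, so per-experiment results are independent of which other
experiments are present.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from .consensus import (DEFAULT_QUANTILE, ExperimentGeneList, OrthologMap,
                        adjacency_threshold, cross_species_consensus,
                        export_interactions)
from .errors import CohealthError, ConstantPhenotypeError, ExperimentExcluded
from .graphs import build_consensus_graph, export_graph
from .network import CoexpressionNetwork, build_network
from .permutation import (DEFAULT_N_PERM, ModuleListSpec, PermutationNull,
                          consensus_count_null, degree_rank_sum_test)
from .preprocess import PreprocessOptions, preprocess
from .scoring import PhenotypeVector, ScoreCard, score_samples
from .selection import ModuleSelection, select_modules
from .simulate import ExpressionExperiment, derive_seed

log = logging.getLogger(__name__)


@dataclass
class NetworkOptions:
    """Per-experiment network stage knobs."""

    min_module_size: int = 30
    target_r2: float = 0.80
    power: Optional[int] = None  # None: automatic scale-free selection
    min_interaction_score: float = 0.2
    alpha: float = 0.05
    cut: int = 30
    adjacency_quantile: float = DEFAULT_QUANTILE
    deep_split: int = 2


@dataclass
class ExclusionRecord:
    """Why an experiment dropped out of the meta-study."""

    experiment_id: str
    species: str
    reason: str  # "inclusion-rule" | "constant-phenotype" | "no modules found" | ...
    detail: str = ""


@dataclass
class ExperimentBundle:
    """Everything one experiment contributes to the meta-study."""

    experiment_id: str
    species: str
    network: CoexpressionNetwork
    selection: ModuleSelection
    phenotype: PhenotypeVector
    threshold: float
    edges: pd.DataFrame
    preprocess_steps: dict = field(default_factory=dict)

    def hub_lists(self) -> list[ExperimentGeneList]:
        return [ExperimentGeneList(self.experiment_id, self.species, rl)
                for rl in self.selection.hub_lists]

    def membership_lists(self) -> list[ExperimentGeneList]:
        return [ExperimentGeneList(self.experiment_id, self.species, rl)
                for rl in self.selection.membership_lists]

    def fingerprint(self) -> str:
        """Deterministic digest of the bundle's scientific content."""
        h = hashlib.sha256()
        h.update(self.experiment_id.encode())
        h.update(self.network.modules.to_csv().encode())
        h.update(f"{self.network.power}:{self.threshold:.12g}".encode())
        for rl in self.selection.hub_lists + self.selection.membership_lists:
            h.update((rl.basis + ",".join(rl.genes) + ",".join(rl.directions)).encode())
        h.update(self.edges.to_csv(index=False).encode())
        return h.hexdigest()


def run_experiment(experiment: ExpressionExperiment, scorecard: ScoreCard,
                   preprocess_options: Optional[PreprocessOptions] = None,
                   network_options: Optional[NetworkOptions] = None,
                   ortholog_map: Optional[OrthologMap] = None,
                   ) -> ExperimentBundle | ExclusionRecord:
    """Per-experiment pipeline: preprocess -> network -> selection -> edges."""
    popts = preprocess_options or PreprocessOptions(gene_lengths=experiment.gene_lengths)
    nopts = network_options or NetworkOptions()
    omap = ortholog_map or OrthologMap.identity(experiment.expression.index,
                                                experiment.species)
    eid, sp = experiment.experiment_id, experiment.species
    try:
        if experiment.expression.shape[1] <= 6:
            raise ExperimentExcluded(
                "inclusion-rule",
                f"{experiment.expression.shape[1]} samples (need more than six)")
        phenotype = score_samples(experiment.metadata, scorecard)
        matrix, steps = preprocess(experiment.expression, popts,
                                   platform=experiment.platform)
        phenotype = PhenotypeVector(scores=phenotype.scores.loc[matrix.columns])
        if phenotype.constant:
            raise ConstantPhenotypeError(
                "scorecard yields identical health phenotype scores for all samples")
        net = build_network(
            matrix, min_module_size=nopts.min_module_size, target_r2=nopts.target_r2,
            min_interaction_score=nopts.min_interaction_score, power=nopts.power,
            deep_split=nopts.deep_split)
        if net.fit.not_scale_free:
            return ExclusionRecord(eid, sp, "no modules found",
                                   "no power yields a scale-free network "
                                   f"(best R^2 = {max(net.fit.r_squared):.3f})")
        selection = select_modules(net, phenotype, alpha=nopts.alpha, cut=nopts.cut)
        threshold = adjacency_threshold(net.adjacency, q=nopts.adjacency_quantile)
        edge_frames = [
            export_interactions(rl.genes, net.adjacency, threshold, omap, sp, eid, rl.label)
            for rl in selection.hub_lists
        ]
        nonempty = [f for f in edge_frames if len(f)]
        edges = (pd.concat(nonempty, ignore_index=True) if nonempty
                 else export_interactions([], net.adjacency, threshold, omap, sp, eid, 0))
        return ExperimentBundle(experiment_id=eid, species=sp, network=net,
                                selection=selection, phenotype=phenotype,
                                threshold=threshold, edges=edges,
                                preprocess_steps=steps)
    except ExperimentExcluded as exc:
        return ExclusionRecord(eid, sp, exc.reason, exc.detail)
    except ConstantPhenotypeError as exc:
        return ExclusionRecord(eid, sp, "constant-phenotype", str(exc))


@dataclass
class MetaResult:
    """Cross-species outputs of the meta-study."""

    hub_consensus: pd.DataFrame
    membership_consensus: pd.DataFrame
    consensus_graph: object  # networkx.Graph
    hub_count_null: Optional[PermutationNull]
    membership_count_null: Optional[PermutationNull]
    rank_sum_null: Optional[PermutationNull]
    exclusions: list[ExclusionRecord] = field(default_factory=list)
    skipped: Optional[str] = None  # reason the meta stage was skipped

    def provenance(self) -> pd.DataFrame:
        """Consensus gene -> backing experiments/modules (both list bases)."""
        frames = []
        for basis, df in (("hub", self.hub_consensus),
                          ("membership", self.membership_consensus)):
            if len(df):
                sub = df[["human_symbol", "source_modules", "n_experiments"]].copy()
                sub.insert(1, "basis", basis)
                frames.append(sub)
        if not frames:
            return pd.DataFrame(columns=["human_symbol", "basis", "source_modules",
                                         "n_experiments"])
        return pd.concat(frames, ignore_index=True)


def _symbol_lookup(omap: OrthologMap, universes: dict[str, Sequence[str]],
                   ) -> dict[str, dict[str, frozenset]]:
    out: dict[str, dict[str, frozenset]] = {}
    for sp, genes in universes.items():
        mapped, _ = omap.map_genes(list(genes), sp)
        out[sp] = {g: frozenset(s) for g, s in mapped.items()}
    return out


def run_meta(bundles: Sequence[ExperimentBundle | ExclusionRecord],
             ortholog_map: OrthologMap, universes: dict[str, Sequence[str]],
             n_perm: int = DEFAULT_N_PERM, seed: int = 0, min_species: int = 2,
             degree_table: Optional[pd.Series] = None) -> MetaResult:
    """Cross-species consensus, consensus graph and permutation nulls.

    ``universes`` maps species -> all measured gene IDs (the pool the
    consensus-count null draws from).  The degree rank-sum null runs only
    when a ``degree_table`` is supplied and covers the hub consensus genes.
    """
    exclusions = [b for b in bundles if isinstance(b, ExclusionRecord)]
    ok = [b for b in bundles if isinstance(b, ExperimentBundle)]
    species = {b.species for b in ok}
    if len(ok) < 2 or len(species) < 2:
        reason = (f"meta stage skipped: {len(ok)} usable experiments from "
                  f"{len(species)} species (need >= 2 of each)")
        log.warning(reason)
        empty = cross_species_consensus([], ortholog_map, min_species)
        return MetaResult(hub_consensus=empty, membership_consensus=empty.copy(),
                          consensus_graph=build_consensus_graph(
                              pd.DataFrame(columns=["experiment_id", "module", "gene_a",
                                                    "gene_b", "adjacency"]), set()),
                          hub_count_null=None, membership_count_null=None,
                          rank_sum_null=None, exclusions=exclusions, skipped=reason)

    hub_lists = [el for b in ok for el in b.hub_lists()]
    mem_lists = [el for b in ok for el in b.membership_lists()]
    hub_report = cross_species_consensus(hub_lists, ortholog_map, min_species)
    mem_report = cross_species_consensus(mem_lists, ortholog_map, min_species)

    edge_frames = [b.edges for b in ok if len(b.edges)]
    all_edges = (pd.concat(edge_frames, ignore_index=True) if edge_frames
                 else ok[0].edges.iloc[:0])
    hub_symbols: set[str] = set()
    for el in hub_lists:
        syms, _ = ortholog_map.map_genes(el.ranked.genes, el.species)
        hub_symbols |= {s for ss in syms.values() for s in ss}
    graph = build_consensus_graph(all_edges, hub_symbols)

    symbol_of = _symbol_lookup(ortholog_map, universes)
    specs_hub = [ModuleListSpec(b.experiment_id, b.species,
                                tuple(len(rl.genes) for rl in b.selection.hub_lists))
                 for b in ok if b.selection.hub_lists]
    specs_mem = [ModuleListSpec(b.experiment_id, b.species,
                                tuple(len(rl.genes) for rl in b.selection.membership_lists))
                 for b in ok if b.selection.membership_lists]
    hub_null = consensus_count_null(
        specs_hub, universes, symbol_of, observed=len(hub_report), n_perm=n_perm,
        seed=derive_seed(seed, "consensus-null-hub"), min_species=min_species,
    ) if specs_hub else None
    mem_null = consensus_count_null(
        specs_mem, universes, symbol_of, observed=len(mem_report), n_perm=n_perm,
        seed=derive_seed(seed, "consensus-null-membership"), min_species=min_species,
    ) if specs_mem else None

    rank_null = None
    if degree_table is not None and len(hub_report):
        genes = [g for g in hub_report["human_symbol"] if g in degree_table.index]
        if genes:
            rank_null = degree_rank_sum_test(genes, degree_table, n_perm=n_perm,
                                             seed=derive_seed(seed, "rank-sum"))
    return MetaResult(hub_consensus=hub_report, membership_consensus=mem_report,
                      consensus_graph=graph, hub_count_null=hub_null,
                      membership_count_null=mem_null, rank_sum_null=rank_null,
                      exclusions=exclusions)


# ---------------------------------------------------------------------------
# manifest-driven study (file based)
# ---------------------------------------------------------------------------

@dataclass
class ExperimentEntry:
    """One row of the study manifest."""

    experiment_id: str
    species: str
    platform: str
    expression_path: str
    metadata_path: str
    scorecard_path: Optional[str] = None
    gene_lengths_path: Optional[str] = None
    preprocess: dict = field(default_factory=dict)
    network: dict = field(default_factory=dict)


@dataclass
class StudyManifest:
    """Experiment roster plus study-level paths and the global seed."""

    experiments: list[ExperimentEntry]
    ortholog_map_path: Optional[str] = None
    degree_table_path: Optional[str] = None
    output_dir: str = "cohealth_out"
    seed: int = 0
    n_perm: int = DEFAULT_N_PERM

    def __post_init__(self):
        ids = [e.experiment_id for e in self.experiments]
        if len(set(ids)) != len(ids):
            raise CohealthError("duplicate experiment IDs in manifest")

    @classmethod
    def from_yaml(cls, path) -> "StudyManifest":
        base = Path(path).parent
        with open(path) as fh:
            raw = yaml.safe_load(fh)

        def _abs(p):
            return None if p is None else str((base / p) if not Path(p).is_absolute() else Path(p))

        entries = [ExperimentEntry(
            experiment_id=e["experiment_id"], species=e["species"],
            platform=e.get("platform", "log-intensity"),
            expression_path=_abs(e["expression_path"]),
            metadata_path=_abs(e["metadata_path"]),
            scorecard_path=_abs(e.get("scorecard_path")),
            gene_lengths_path=_abs(e.get("gene_lengths_path")),
            preprocess=e.get("preprocess", {}), network=e.get("network", {}),
        ) for e in raw["experiments"]]
        return cls(experiments=entries,
                   ortholog_map_path=_abs(raw.get("ortholog_map_path")),
                   degree_table_path=_abs(raw.get("degree_table_path")),
                   output_dir=_abs(raw.get("output_dir", "cohealth_out")),
                   seed=int(raw.get("seed", 0)), n_perm=int(raw.get("n_perm", DEFAULT_N_PERM)))


def _load_entry(entry: ExperimentEntry) -> tuple[ExpressionExperiment, ScoreCard]:
    expr = pd.read_csv(entry.expression_path, sep="\t", index_col=0)
    meta = pd.read_csv(entry.metadata_path, sep="\t", index_col=0)
    lengths = None
    if entry.gene_lengths_path:
        lengths = pd.read_csv(entry.gene_lengths_path, sep="\t", index_col=0).iloc[:, 0]
    card = (ScoreCard.from_yaml(entry.scorecard_path) if entry.scorecard_path
            else ScoreCard())
    exp = ExpressionExperiment(experiment_id=entry.experiment_id, species=entry.species,
                               platform=entry.platform, expression=expr, metadata=meta,
                               gene_lengths=lengths)
    return exp, card


def run_study(manifest: StudyManifest) -> MetaResult:
    """Run every manifest experiment, then the meta stage; write all artifacts."""
    outdir = Path(manifest.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    omap: Optional[OrthologMap] = (OrthologMap.from_tsv(manifest.ortholog_map_path)
                                   if manifest.ortholog_map_path else None)
    degree = None
    if manifest.degree_table_path:
        from .permutation import read_degree_table
        degree = read_degree_table(manifest.degree_table_path)

    bundles: list[ExperimentBundle | ExclusionRecord] = []
    universes: dict[str, list[str]] = {}
    for entry in manifest.experiments:
        exp, card = _load_entry(entry)
        popts = PreprocessOptions(gene_lengths=exp.gene_lengths, **entry.preprocess)
        nopts = NetworkOptions(**entry.network)
        entry_map = omap or OrthologMap.identity(exp.expression.index, exp.species)
        bundle = run_experiment(exp, card, popts, nopts, entry_map)
        bundles.append(bundle)
        seen = universes.setdefault(exp.species, [])
        seen.extend(g for g in exp.expression.index.astype(str) if g not in set(seen))
        if isinstance(bundle, ExperimentBundle):
            _write_bundle(bundle, outdir / entry.experiment_id)

    meta_map = omap or OrthologMap(pd.concat(
        [OrthologMap.identity(universes[sp], sp).table for sp in universes],
        ignore_index=True))
    meta = run_meta(bundles, meta_map, universes, n_perm=manifest.n_perm,
                    seed=manifest.seed, degree_table=degree)
    _write_meta(meta, bundles, outdir)
    return meta


def _write_bundle(b: ExperimentBundle, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    b.network.modules.to_csv(outdir / "modules.tsv", sep="\t", index_label="gene")
    b.selection.report().to_csv(outdir / "module_report.tsv", sep="\t", index=False)
    for rl in b.selection.hub_lists + b.selection.membership_lists:
        rl.to_frame().to_csv(outdir / f"module{rl.label}_{rl.basis}.tsv", sep="\t",
                             index=False)
    b.edges.to_csv(outdir / "edges.tsv", sep="\t", index=False)
    (outdir / "provenance.json").write_text(json.dumps({
        "experiment_id": b.experiment_id, "species": b.species,
        "power": b.network.power, "scale_free_r2": b.network.fit.r_squared,
        "threshold": b.threshold, "preprocess": b.preprocess_steps,
        "fingerprint": b.fingerprint(),
    }, indent=1, default=str))


def _write_meta(meta: MetaResult, bundles, outdir: Path) -> None:
    meta.hub_consensus.to_csv(outdir / "consensus_hub.tsv", sep="\t", index=False)
    meta.membership_consensus.to_csv(outdir / "consensus_membership.tsv", sep="\t",
                                     index=False)
    meta.provenance().to_csv(outdir / "consensus_provenance.tsv", sep="\t", index=False)
    export_graph(meta.consensus_graph, tsv_path=outdir / "consensus_graph.tsv",
                 graphml_path=outdir / "consensus_graph.graphml")
    nulls = {}
    for name, null in (("hub", meta.hub_count_null),
                       ("membership", meta.membership_count_null),
                       ("rank_sum", meta.rank_sum_null)):
        if null is not None:
            nulls[name] = null.to_json_dict()
            null.quantile_row().to_csv(outdir / f"null_{name}_quantiles.tsv", sep="\t",
                                       index=False)
    records = [dataclasses.asdict(b) for b in bundles if isinstance(b, ExclusionRecord)]
    (outdir / "meta.json").write_text(json.dumps(
        {"nulls": nulls, "exclusions": records, "skipped": meta.skipped}, indent=1))
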