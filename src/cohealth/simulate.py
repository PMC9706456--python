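"""Synthetic multi-species expression collections with planted modules.

Every downstream stage of the pipeline is exercised against data from this
module, because it carries ground truth: which genes form a co-expression
module, which of those modules track the per-sample health phenotype score,
which genes are hubs, and which genes are conserved across species.

The generative model is a one-factor model per module,

    x_gs = lambda_g * f_ms + noise_scale * sqrt(1 - lambda_g^2) * eps_gs,

with a per-module factor ``f_m`` across samples, loadings ``lambda_g`` in
(0, 1], and iid Gaussian noise.  Hub genes receive the largest loadings, so
soft connectivity under |cor|^beta provably ranks them first.  For a
health-associated module the factor is constructed so that its *realized*
in-sample Pearson correlation with the standardized latent health score
equals the configured target exactly (Gram-Schmidt construction); modules
without a health association draw their factor independently of the score.
Noise genes are independent of everything.

Two platforms are emulated: ``log-intensity`` (microarray-like log2 scale)
and ``counts`` (log-normal per-gene mean, Poisson sampling), the latter to
exercise TPM conversion and the low-count filter.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import CohealthError, InclusionRuleError
from .scoring import ScoreCard, TreatmentRule, score_samples

MIN_SAMPLES = 7  # inclusion rule: experiments must feature more than six samples
DEFAULT_MIN_MODULE_SIZE = 30


def derive_seed(global_seed: int, label: str) -> int:
    """Stable per-label sub-seed (< 2^31) derived from one global seed."""
    h = hashlib.sha256(f"{global_seed}:{label}".encode()).hexdigest()
    return int(h, 16) % (2**31)


@dataclass(frozen=True)
class ModuleSpec:
    """One planted co-expression module.

    ``cor_strength`` is the target within-module correlation between two
    ordinary members (loadings are sqrt of it, with a small jitter).
    ``score_cor`` is the realized eigengene-score correlation; ``None``
    plants no health association (a pure co-expression module).
    ``conserved`` marks the hub genes as shared across species through the
    ortholog map.
    """

    size: int = 30
    cor_strength: float = 0.55
    score_cor: Optional[float] = 0.8
    n_hubs: int = 5
    hub_loading: float = 0.95
    conserved: bool = True

    def __post_init__(self):
        if self.score_cor is not None and not -1.0 <= self.score_cor <= 1.0:
            raise CohealthError(f"score correlation target {self.score_cor} outside [-1, 1]")
        if not 0.0 < self.cor_strength <= 1.0:
            raise CohealthError("within-module correlation strength must be in (0, 1]")
        if not 0 <= self.n_hubs <= self.size:
            raise CohealthError("hub count must be between 0 and the module size")
        if not 0.0 < self.hub_loading <= 1.0:
            raise CohealthError("hub loading must be in (0, 1]")


@dataclass
class SimulationConfig:
    """Study-level configuration; all randomness flows from ``seed``."""

    species: list[str] = field(default_factory=lambda: ["worm", "fly"])
    experiments_per_species: int = 2
    n_samples: int = 12
    modules: list[ModuleSpec] = field(default_factory=lambda: [ModuleSpec()])
    n_noise_genes: int = 60
    platform: str = "log-intensity"  # or "counts"
    noise_scale: float = 1.0
    min_module_size: int = DEFAULT_MIN_MODULE_SIZE
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < MIN_SAMPLES:
            raise InclusionRuleError(
                f"experiments must feature more than six samples (got {self.n_samples})"
            )
        if self.platform not in ("log-intensity", "counts"):
            raise CohealthError(f"unknown platform kind: {self.platform!r}")
        for m in self.modules:
            if m.size < self.min_module_size:
                raise CohealthError(
                    f"module size {m.size} below the minimum module size {self.min_module_size}"
                )
        if self.n_genes <= 0:
            raise CohealthError("gene universe is empty")

    @property
    def n_genes(self) -> int:
        return sum(m.size for m in self.modules) + self.n_noise_genes

    @property
    def n_conserved_genes(self) -> int:
        return sum(m.n_hubs for m in self.modules if m.conserved)


@dataclass
class ExpressionExperiment:
    """One study: genes x samples matrix plus per-sample metadata."""

    experiment_id: str
    species: str
    platform: str
    expression: pd.DataFrame  # genes x samples
    metadata: pd.DataFrame  # samples x factor columns
    gene_lengths: Optional[pd.Series] = None  # bp, counts platform only

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.expression.to_csv(outdir / f"{self.experiment_id}.expression.tsv", sep="\t", index_label="gene")
        self.metadata.to_csv(outdir / f"{self.experiment_id}.metadata.tsv", sep="\t", index_label="sample")
        if self.gene_lengths is not None:
            self.gene_lengths.rename("length_bp").to_csv(
                outdir / f"{self.experiment_id}.gene_lengths.tsv", sep="\t", index_label="gene"
            )


@dataclass
class ExperimentTruth:
    """Planted structure behind one experiment."""

    module_of: pd.Series  # gene -> module label ("M1", ..., "noise")
    hub_genes: dict[str, list[str]]  # module label -> hub gene IDs
    health_module: dict[str, bool]  # module label -> planted health association
    latent_score: pd.Series  # per-sample health phenotype score
    human_symbol: pd.Series  # gene -> human symbol (noise genes: <NA>)


@dataclass
class CollectionTruth:
    """Ground truth for a whole multi-species collection."""

    experiments: dict[str, ExperimentTruth]
    ortholog_table: pd.DataFrame  # columns: species, gene_id, human_symbol
    conserved_symbols: list[str]  # human symbols planted in >=2 species
    species_universe: dict[str, list[str]]  # species -> measured gene IDs

    def to_json(self, path) -> None:
        payload = {
            "conserved_symbols": self.conserved_symbols,
            "species_universe": self.species_universe,
            "experiments": {
                eid: {
                    "module_of": t.module_of.to_dict(),
                    "hub_genes": t.hub_genes,
                    "health_module": t.health_module,
                    "latent_score": t.latent_score.to_dict(),
                }
                for eid, t in self.experiments.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def default_scorecard() -> ScoreCard:
    """The scorecard matching the generator's metadata vocabulary."""
    return ScoreCard(
        base_scores={"young": 1.0, "old": 0.0},
        age_column="age",
        treatment_rules=[
            TreatmentRule(column="treatment", value="boost", delta=0.2, note="health-improving"),
            TreatmentRule(column="treatment", value="stress", delta=-0.2, note="health-reducing"),
        ],
        note="synthetic default: young wildtype 1, old 0, +/-0.2 per treatment",
    )


def _species_gene_names(config: SimulationConfig, species: str) -> tuple[list[str], pd.Series, dict]:
    """Deterministic gene IDs, human symbols, and module bookkeeping for a species."""
    genes: list[str] = []
    symbols: dict[str, object] = {}
    module_of: dict[str, str] = {}
    hub_genes: dict[str, list[str]] = {}
    for mi, mod in enumerate(config.modules, start=1):
        label = f"M{mi}"
        hub_genes[label] = []
        for gi in range(mod.size):
            gid = f"{species}_m{mi:02d}g{gi + 1:03d}"
            genes.append(gid)
            module_of[gid] = label
            if gi < mod.n_hubs:
                hub_genes[label].append(gid)
                if mod.conserved:
                    symbols[gid] = f"HSM{mi:02d}H{gi + 1:02d}"
                else:
                    symbols[gid] = f"{species.upper()}M{mi:02d}G{gi + 1:03d}"
            else:
                symbols[gid] = f"{species.upper()}M{mi:02d}G{gi + 1:03d}"
    for gi in range(config.n_noise_genes):
        gid = f"{species}_noise{gi + 1:04d}"
        genes.append(gid)
        module_of[gid] = "noise"
        symbols[gid] = pd.NA
    return genes, pd.Series(symbols, dtype="object"), {"module_of": module_of, "hub_genes": hub_genes}


def _standardize(v: np.ndarray) -> np.ndarray:
    c = v - v.mean()
    nrm = np.linalg.norm(c)
    if nrm == 0:
        raise CohealthError("cannot standardize a constant vector")
    return c / nrm


def _planted_factor(score: np.ndarray, target: float, rng: np.random.Generator) -> np.ndarray:
    """Factor whose realized sample correlation with ``score`` is exactly ``target``."""
    e_s = _standardize(score)
    raw = rng.standard_normal(score.size)
    resid = raw - raw.mean() - (raw @ e_s) * e_s
    e_r = resid / np.linalg.norm(resid)
    f = target * e_s + np.sqrt(max(0.0, 1.0 - target**2)) * e_r
    return f * np.sqrt(score.size)  # unit sample variance


def _sample_metadata(n: int, rng: np.random.Generator) -> pd.DataFrame:
    ages = np.array(["young", "old"])[np.arange(n) % 2]
    treatments = rng.choice(["none", "boost", "stress"], size=n, p=[0.5, 0.25, 0.25])
    samples = [f"s{i + 1:02d}" for i in range(n)]
    return pd.DataFrame({"age": ages, "genotype": "wildtype", "treatment": treatments}, index=samples)


def generate_experiment(
    config: SimulationConfig, species: str, index: int
) -> tuple[ExpressionExperiment, ExperimentTruth]:
    """Simulate one experiment of a species (deterministic given config.seed)."""
    if config.n_samples < MIN_SAMPLES:  # re-check: configs may be constructed unsafely
        raise InclusionRuleError("experiments must feature more than six samples")
    exp_id = f"{species}-exp{index + 1}"
    rng = np.random.default_rng(derive_seed(config.seed, exp_id))

    metadata = _sample_metadata(config.n_samples, rng)
    score = score_samples(metadata, default_scorecard()).scores
    s = score.to_numpy(dtype=float)

    genes, symbols, bk = _species_gene_names(config, species)
    n, g = config.n_samples, config.n_genes
    X = np.empty((g, n))
    row = 0
    health_module: dict[str, bool] = {}
    for mi, mod in enumerate(config.modules, start=1):
        label = f"M{mi}"
        health_module[label] = mod.score_cor is not None
        if mod.score_cor is not None:
            f = _planted_factor(s, mod.score_cor, rng)
        else:
            f = rng.standard_normal(n)
            f = (f - f.mean()) / f.std()
        lam = np.empty(mod.size)
        lam[: mod.n_hubs] = mod.hub_loading
        lo = np.sqrt(mod.cor_strength) * 0.9
        hi = min(np.sqrt(mod.cor_strength) * 1.05, mod.hub_loading - 0.02)
        lam[mod.n_hubs :] = rng.uniform(lo, max(lo, hi), size=mod.size - mod.n_hubs)
        eps = rng.standard_normal((mod.size, n))
        X[row : row + mod.size] = lam[:, None] * f[None, :] + (
            config.noise_scale * np.sqrt(1.0 - lam**2)
        )[:, None] * eps
        row += mod.size
    if config.n_noise_genes:
        X[row:] = rng.standard_normal((config.n_noise_genes, n))

    lengths = None
    if config.platform == "counts":
        base = rng.lognormal(mean=np.log(100.0), sigma=1.0, size=g)
        mu = base[:, None] * np.exp(0.7 * X)
        X = rng.poisson(mu).astype(float)
        lengths = pd.Series(rng.integers(500, 5001, size=g), index=genes, name="length_bp")
    else:
        X = 8.0 + 2.0 * X  # typical log2 intensity scale

    expr = pd.DataFrame(X, index=genes, columns=metadata.index)
    exp = ExpressionExperiment(
        experiment_id=exp_id,
        species=species,
        platform=config.platform,
        expression=expr,
        metadata=metadata,
        gene_lengths=lengths,
    )
    truth = ExperimentTruth(
        module_of=pd.Series(bk["module_of"]),
        hub_genes=bk["hub_genes"],
        health_module=health_module,
        latent_score=score,
        human_symbol=symbols,
    )
    return exp, truth


def generate_collection(
    config: SimulationConfig,
) -> tuple[list[ExpressionExperiment], CollectionTruth, pd.DataFrame]:
    """Simulate the whole multi-species collection.

    Returns the experiments, the collection ground truth, and the ortholog
    table (columns: species, gene_id, human_symbol) covering every planted
    module gene; noise genes have no ortholog entry.  Within a species all
    experiments measure the same gene universe.
    """
    experiments: list[ExpressionExperiment] = []
    truths: dict[str, ExperimentTruth] = {}
    universe: dict[str, list[str]] = {}
    rows = []
    for sp in config.species:
        genes, symbols, _ = _species_gene_names(config, sp)
        universe[sp] = genes
        for gid, sym in symbols.items():
            if pd.notna(sym):
                rows.append({"species": sp, "gene_id": gid, "human_symbol": sym})
        for i in range(config.experiments_per_species):
            exp, truth = generate_experiment(config, sp, i)
            if exp.experiment_id in truths:
                raise CohealthError(f"duplicate experiment identifier: {exp.experiment_id}")
            experiments.append(exp)
            truths[exp.experiment_id] = truth
    ortholog = pd.DataFrame(rows, columns=["species", "gene_id", "human_symbol"])
    conserved = (
        ortholog.groupby("human_symbol")["species"].nunique().loc[lambda s: s >= 2].index.tolist()
        if len(ortholog)
        else []
    )
    truth = CollectionTruth(
        experiments=truths,
        ortholog_table=ortholog,
        conserved_symbols=sorted(conserved),
        species_universe=universe,
    )
    return experiments, truth, ortholog


def write_collection(experiments, truth: CollectionTruth, ortholog: pd.DataFrame, outdir) -> None:
    """Write the collection as plain-text artifacts (TSV + JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for exp in experiments:
        exp.write(outdir)
    ortholog.to_csv(outdir / "orthologs.tsv", sep="\t", index=False)
    truth.to_json(outdir / "ground_truth.json")
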