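"""Permutation null distributions for the meta-study statistics.

Two tests: (1) the *consensus-count null* — how many cross-species consensus
genes arise when every experiment's module lists are replaced by equally
sized uniform random gene draws from the same species' universe; and
(2) the *degree rank-sum test* — whether a selected gene set sits unusually
high in an interaction-degree table (e.g. derived from a protein-protein
interaction database), judged against equally sized random selections.

Both report the sampled distribution, a 14-probability quantile table
(0, 1, 5, 10, 25, 50, 75, 90, 95, 97.5, 99, 99.5, 99.9, 100 percent) and a
plain-fraction empirical p.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import CohealthError

QUANTILE_PROBS = (0.0, 0.01, 0.05, 0.10, 0.25, 0.50, 0.75, 0.90, 0.95,
                  0.975, 0.99, 0.995, 0.999, 1.0)
DEFAULT_N_PERM = 10_000


def quantile_table(samples: Sequence[float],
                   probabilities: Sequence[float] = QUANTILE_PROBS) -> pd.Series:
    """Linear-interpolation quantiles at the standard 14 report probabilities."""
    samples = np.asarray(list(samples), dtype=float)
    if samples.size == 0:
        raise CohealthError("quantile table needs at least one sample")
    qs = np.quantile(samples, probabilities, method="linear")
    return pd.Series(qs, index=[f"{100 * p:g}%" for p in probabilities], name="quantile")


@dataclass
class PermutationNull:
    """A sampled null distribution with its quantile table and empirical p."""

    observed: float
    n_perm: int
    samples: np.ndarray = field(repr=False)
    seed: Optional[int] = None
    statistic: str = ""
    alternative: str = "greater"  # p = fraction of null >= / > observed
    strict: bool = False  # True: strictly greater (rank-sum convention)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        self.quantiles = quantile_table(self.samples)
        if self.strict:
            extreme = self.samples > self.observed
        else:
            extreme = self.samples >= self.observed
        self.p_value = float(extreme.mean())

    def p_value_corrected(self) -> float:
        """Optional (b + 1) / (n + 1) empirical-p correction (off by default)."""
        b = int((self.samples > self.observed).sum() if self.strict
                else (self.samples >= self.observed).sum())
        return (b + 1) / (self.samples.size + 1)

    def to_json_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "observed": self.observed,
            "n_perm": int(self.samples.size),
            "p_value": self.p_value,
            "seed": self.seed,
            "quantiles": {k: float(v) for k, v in self.quantiles.items()},
        }

    def quantile_row(self) -> pd.DataFrame:
        """The 14-column one-row layout of the printed quantile tables."""
        return self.quantiles.to_frame().T.reset_index(drop=True)


@dataclass(frozen=True)
class ModuleListSpec:
    """Sizes of one experiment's exported module lists, for the null draws."""

    experiment_id: str
    species: str
    list_sizes: tuple[int, ...]  # one entry per retained module (usually <= 30 each)


def consensus_count_null(module_lists: Sequence[ModuleListSpec],
                         universes: dict[str, Sequence[str]],
                         symbol_of: dict[str, dict[str, frozenset]],
                         observed: int, n_perm: int = DEFAULT_N_PERM,
                         seed: int = 0, min_species: int = 2,
                         pool_within_experiment: bool = False) -> PermutationNull:
    """Null distribution of the cross-species consensus-gene count.

    Each permutation redoes the consensus determination with an equal
    number of randomly picked genes from the respective same species:
    for every experiment, each retained module list is replaced by a
    uniform draw (without replacement within a module; by default modules
    of one experiment draw independently, so a gene may serve two modules —
    set ``pool_within_experiment`` to draw all of an experiment's lists
    jointly without replacement).  The statistic is the number of human
    symbols present in >= ``min_species`` species; the upper-tail empirical
    p is the fraction of permutations with a count >= the observed one.

    ``symbol_of`` maps species -> native gene ID -> frozenset of human
    symbols (unmapped genes absent).
    """
    if n_perm < 1:
        raise CohealthError("need at least one permutation")
    rng = np.random.default_rng(seed)
    prepared = []
    for spec in module_lists:
        uni = list(universes[spec.species])
        for size in spec.list_sizes:
            if size > len(uni):
                raise CohealthError(
                    f"list size {size} exceeds the {spec.species} universe ({len(uni)} genes)")
        sym = symbol_of.get(spec.species, {})
        symbol_arr = [sym.get(str(g), frozenset()) for g in uni]
        prepared.append((spec, len(uni), symbol_arr))

    counts = np.empty(n_perm, dtype=int)
    for it in range(n_perm):
        species_symbols: dict[str, set] = {}
        for spec, n_uni, symbol_arr in prepared:
            bucket = species_symbols.setdefault(spec.species, set())
            if pool_within_experiment:
                total = sum(spec.list_sizes)
                idx = rng.choice(n_uni, size=min(total, n_uni), replace=False)
                for i in idx:
                    bucket |= symbol_arr[i]
            else:
                for size in spec.list_sizes:
                    idx = rng.choice(n_uni, size=size, replace=False)
                    for i in idx:
                        bucket |= symbol_arr[i]
        tally: dict[str, int] = {}
        for syms in species_symbols.values():
            for s in syms:
                tally[s] = tally.get(s, 0) + 1
        counts[it] = sum(1 for v in tally.values() if v >= min_species)
    return PermutationNull(observed=float(observed), n_perm=n_perm, samples=counts,
                           seed=seed, statistic="consensus_gene_count",
                           alternative="greater", strict=False)


def degree_rank_sum_test(selection: Sequence[str], degree_table: pd.Series,
                         n_perm: int = DEFAULT_N_PERM, seed: int = 0,
                         method: str = "monte-carlo",
                         exhaustive_limit: int = 200_000) -> PermutationNull:
    """Rank-sum test of a gene selection against an interaction-degree table.

    Genes are ranked ascending by degree (ties get the average rank), the
    selection's rank sum is computed, and equally sized random selections
    (without replacement) form the null.  The empirical p is the fraction
    of random selections with a *strictly higher* rank sum — small p means
    the selection is unusually well connected.

    ``method``: "monte-carlo" (default) or "exhaustive" (enumerates all
    C(n, k) selections; refused above ``exhaustive_limit``).
    """
    from scipy.stats import rankdata

    if degree_table.index.duplicated().any():
        raise CohealthError("degree table has duplicate gene symbols")
    if (degree_table < 0).any():
        raise CohealthError("degrees must be >= 0")
    selection = [str(g) for g in selection]
    missing = [g for g in selection if g not in degree_table.index]
    if missing:
        raise CohealthError(f"selection gene(s) missing from the degree table: {missing}")
    if len(set(selection)) != len(selection):
        raise CohealthError("selection contains duplicate genes")

    ranks = pd.Series(rankdata(degree_table.to_numpy(dtype=float), method="average"),
                      index=degree_table.index)
    observed = float(ranks.loc[selection].sum())
    k, n = len(selection), len(degree_table)
    rank_arr = ranks.to_numpy()

    if method == "exhaustive":
        total = math.comb(n, k)
        if total > exhaustive_limit:
            raise CohealthError(f"{total} selections exceed the exhaustive limit")
        sums = np.fromiter((rank_arr[list(c)].sum()
                            for c in itertools.combinations(range(n), k)),
                           dtype=float, count=total)
        return PermutationNull(observed=observed, n_perm=total, samples=sums, seed=None,
                               statistic="degree_rank_sum", strict=True)
    if method != "monte-carlo":
        raise CohealthError(f"unknown method: {method!r}")
    rng = np.random.default_rng(seed)
    sums = np.empty(n_perm, dtype=float)
    for it in range(n_perm):
        sums[it] = rank_arr[rng.choice(n, size=k, replace=False)].sum()
    return PermutationNull(observed=observed, n_perm=n_perm, samples=sums, seed=seed,
                           statistic="degree_rank_sum", strict=True)


def read_degree_table(path) -> pd.Series:
    """Two-column TSV (gene, degree) -> Series indexed by gene symbol."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise CohealthError("degree table needs two columns: gene, degree")
    return df.set_index(df.columns[0])[df.columns[1]].astype(float)
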