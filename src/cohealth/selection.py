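"""Health-associated module selection and ranked gene-list extraction.

A module is retained when its eigengene correlates with the health
phenotype score at p < 0.05 (two-sided Student t transform of Pearson r,
df = n - 2; no multiple-testing correction by default, an optional
Benjamini-Hochberg switch is provided).  From each retained module two
ranked lists of at most 30 genes are cut: the *hub* list (by soft
connectivity) and the *membership* list (by |kME|).  Each listed gene also
receives a direction versus the health score: sign(kME) x sign(module-trait
r), so a gene anti-correlated with the eigengene of a negatively
health-correlated module counts as positively health-associated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CohealthError, ConstantPhenotypeError
from .network import CoexpressionNetwork, EigengeneProfile
from .scoring import PhenotypeVector

log = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05
DEFAULT_CUT = 30


@dataclass
class ModuleTraitAssociation:
    """Eigengene vs health-score correlation for one module."""

    label: int
    r: float
    p_value: float
    n: int
    flagged: bool  # health-associated (p < alpha)
    alpha: float = DEFAULT_ALPHA


def correlation_p_value(r: float, n: int) -> float:
    """Two-sided p for a Pearson r via the Student t transform, df = n - 2."""
    if n < 3:
        raise CohealthError("p-value needs at least three samples")
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def module_trait_association(eigengene: EigengeneProfile, phenotype: PhenotypeVector,
                             alpha: float = DEFAULT_ALPHA) -> ModuleTraitAssociation:
    """Correlate a module eigengene with the health phenotype score."""
    if phenotype.constant:
        raise ConstantPhenotypeError(
            "all health phenotype scores are identical (see scorecard warning); "
            "module-trait correlation is undefined"
        )
    scores = phenotype.scores.reindex(eigengene.values.index)
    if scores.isna().any():
        raise CohealthError("phenotype vector does not cover the eigengene samples")
    e = eigengene.values.to_numpy(dtype=float)
    s = scores.to_numpy(dtype=float)
    n = e.size
    r = float(np.corrcoef(e, s)[0, 1])
    p = correlation_p_value(r, n)
    return ModuleTraitAssociation(label=eigengene.label, r=r, p_value=p, n=n,
                                  flagged=bool(p < alpha), alpha=alpha)


@dataclass
class RankedGeneList:
    """Top genes of one health-associated module, with direction."""

    label: int
    basis: str  # "soft-connectivity" | "module-membership"
    genes: list[str]
    scores: list[float]
    directions: list[str]  # per gene: positive | negative | undetermined
    cut: int = DEFAULT_CUT
    trait_r: float = float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "rank": np.arange(1, len(self.genes) + 1),
            "gene": self.genes,
            "basis": self.basis,
            "score": self.scores,
            "direction": self.directions,
            "module": self.label,
        })


def gene_direction(kme_sign: float, trait_r_sign: float) -> str:
    """Direction of a gene vs the health score: sign(kME) x sign(r).

    A gene positively following the eigengene of a module that is
    negatively correlated with the health score is *negatively*
    health-associated, and vice versa.  A zero sign is undetermined and is
    excluded from consensus aggregation.
    """
    prod = np.sign(kme_sign) * np.sign(trait_r_sign)
    if prod > 0:
        return "positive"
    if prod < 0:
        return "negative"
    return "undetermined"


def _require_flagged(association: ModuleTraitAssociation) -> None:
    if not association.flagged:
        raise CohealthError(
            f"module {association.label} is not health-associated "
            f"(p = {association.p_value:.3g} >= {association.alpha}); "
            "gene lists are only cut from retained modules"
        )


def _ranked(genes: pd.Series, keyname: str) -> tuple[list[str], list[float]]:
    df = genes.rename(keyname).rename_axis("gene").reset_index()
    df["gene"] = df["gene"].astype(str)
    df = df.sort_values([keyname, "gene"], ascending=[False, True], kind="mergesort")
    if df[keyname].duplicated(keep=False).any():
        log.info("ties in %s broken lexicographically by gene ID", keyname)
    return df["gene"].tolist(), df[keyname].tolist()


def top_hub_genes(network: CoexpressionNetwork, label: int,
                  association: ModuleTraitAssociation, cut: int = DEFAULT_CUT,
                  ) -> RankedGeneList:
    """The <=30 most connected genes (softConnectivity) of a retained module."""
    _require_flagged(association)
    members = network.module_genes(label)
    k = network.connectivity.loc[members]
    order, scores = _ranked(k, "k")
    kme = network.kme[label]
    dirs = [gene_direction(kme.loc[g], association.r) for g in order[:cut]]
    return RankedGeneList(label=label, basis="soft-connectivity", genes=order[:cut],
                          scores=scores[:cut], directions=dirs, cut=cut,
                          trait_r=association.r)


def top_membership_genes(network: CoexpressionNetwork, label: int,
                         association: ModuleTraitAssociation, cut: int = DEFAULT_CUT,
                         ) -> RankedGeneList:
    """The <=30 genes correlating the strongest (|kME|) with the eigengene.

    Ranking is by absolute module membership; the signed kME is retained
    for the direction computation.
    """
    _require_flagged(association)
    members = network.module_genes(label)
    kme = network.kme[label].loc[members].dropna()
    order, _ = _ranked(kme.abs(), "abs_kme")
    order = order[:cut]
    signed = [float(kme.loc[g]) for g in order]
    dirs = [gene_direction(v, association.r) for v in signed]
    return RankedGeneList(label=label, basis="module-membership", genes=order,
                          scores=signed, directions=dirs, cut=cut,
                          trait_r=association.r)


@dataclass
class ModuleSelection:
    """All associations plus the ranked lists of the retained modules."""

    associations: list[ModuleTraitAssociation]
    hub_lists: list[RankedGeneList] = field(default_factory=list)
    membership_lists: list[RankedGeneList] = field(default_factory=list)

    def report(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "module": a.label, "r": a.r, "p_value": a.p_value, "n": a.n,
            "flagged": a.flagged,
        } for a in self.associations])


def select_modules(network: CoexpressionNetwork, phenotype: PhenotypeVector,
                   alpha: float = DEFAULT_ALPHA, cut: int = DEFAULT_CUT,
                   bh_correct: bool = False) -> ModuleSelection:
    """Flag health-associated modules and cut both ranked lists from each.

    ``bh_correct`` applies Benjamini-Hochberg across the experiment's
    modules before flagging (off by default: the raw p < 0.05 filter).
    """
    assoc = [module_trait_association(network.eigengenes[lbl], phenotype, alpha=alpha)
             for lbl in network.module_labels()]
    if bh_correct and assoc:
        ps = np.array([a.p_value for a in assoc])
        m = len(ps)
        order = np.argsort(ps)
        adj = np.empty(m)
        running = 1.0
        for rank_idx in range(m - 1, -1, -1):
            i = order[rank_idx]
            running = min(running, ps[i] * m / (rank_idx + 1))
            adj[i] = running
        for a, q in zip(assoc, adj):
            a.flagged = bool(q < alpha)
    sel = ModuleSelection(associations=assoc)
    for a in assoc:
        if a.flagged:
            sel.hub_lists.append(top_hub_genes(network, a.label, a, cut=cut))
            sel.membership_lists.append(top_membership_genes(network, a.label, a, cut=cut))
    return sel
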