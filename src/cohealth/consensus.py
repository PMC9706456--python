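"""Cross-species consensus over ranked gene lists and interaction export.

Native gene IDs are mapped to human gene symbols through an ortholog table
(many-to-one and one-to-many both allowed, e.g. two worm myosin light
chains both mapping to MYL1).  A human symbol becomes a *consensus gene*
when it appears in ranked lists from at least two species.  Directions are
aggregated per symbol: unanimous across experiments -> that direction,
otherwise "mixed".  Per experiment, hub-pair interactions with adjacency
strictly above the experiment-wide 95% quantile are exported, with
self-interactions (distinct probesets collapsing to one symbol) removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import CohealthError
from .selection import RankedGeneList

log = logging.getLogger(__name__)

DEFAULT_QUANTILE = 0.95
DEFAULT_MIN_SPECIES = 2


class OrthologMap:
    """Species gene ID -> human gene symbol lookup.

    Backed by a three-column table (species, gene_id, human_symbol); a gene
    may map to several symbols and several genes may share one symbol.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"species", "gene_id", "human_symbol"}
        if not required.issubset(table.columns):
            raise CohealthError(f"ortholog table needs columns {sorted(required)}")
        table = table.dropna(subset=["human_symbol"])
        if (table["human_symbol"].astype(str).str.len() == 0).any():
            raise CohealthError("empty human symbols in ortholog table")
        self.table = table.reset_index(drop=True)
        self._lookup: dict[tuple[str, str], set[str]] = {}
        for sp, gid, sym in self.table.itertuples(index=False):
            self._lookup.setdefault((str(sp), str(gid)), set()).add(str(sym))

    def __len__(self) -> int:
        return len(self.table)

    @classmethod
    def from_tsv(cls, path) -> "OrthologMap":
        return cls(pd.read_csv(path, sep="\t", dtype=str))

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def identity(cls, genes: Iterable[str], species: str) -> "OrthologMap":
        """Identity mapping (e.g. a human experiment)."""
        genes = [str(g) for g in genes]
        return cls(pd.DataFrame({"species": species, "gene_id": genes, "human_symbol": genes}))

    def map_genes(self, genes: Sequence[str], species: str,
                  ) -> tuple[dict[str, set[str]], list[str]]:
        """Map native gene IDs of one species to human symbols.

        Returns (gene -> symbol set for the mapped genes, unmapped IDs);
        unmapped IDs are reported, never fatal.
        """
        if not len(self.table):
            raise CohealthError("ortholog map is empty")
        mapped: dict[str, set[str]] = {}
        unmapped: list[str] = []
        for g in genes:
            syms = self._lookup.get((str(species), str(g)))
            if syms:
                mapped[str(g)] = set(syms)
            else:
                unmapped.append(str(g))
        if unmapped:
            log.info("%d/%d gene IDs of %s have no ortholog entry", len(unmapped),
                     len(list(genes)), species)
        return mapped, unmapped


def map_to_human(genes: Sequence[str], species: str, ortholog_map: OrthologMap,
                 ) -> tuple[list[str], list[str]]:
    """Distinct human symbols for a gene list (duplicates collapsed) + unmapped IDs."""
    mapped, unmapped = ortholog_map.map_genes(genes, species)
    symbols = sorted({s for syms in mapped.values() for s in syms})
    return symbols, unmapped


@dataclass
class ExperimentGeneList:
    """One experiment's ranked list, annotated for consensus building."""

    experiment_id: str
    species: str
    ranked: RankedGeneList


def cross_species_consensus(lists: Sequence[ExperimentGeneList], ortholog_map: OrthologMap,
                            min_species: int = DEFAULT_MIN_SPECIES) -> pd.DataFrame:
    """Intersect ranked lists across species on the human-symbol level.

    A symbol is reported iff it occurs in lists from >= ``min_species``
    distinct species.  Per symbol the report records the species, the
    number of distinct experiments backing it, the per-species directions,
    the aggregate direction (unanimous or "mixed"; "undetermined" entries
    are excluded from aggregation) and the source modules for provenance.
    An empty frame (with a warning) results from single-species input.
    """
    species_seen = {e.species for e in lists}
    if len(species_seen) < 2:
        log.warning("consensus needs lists from at least two species (got %s); empty report",
                    sorted(species_seen))
        return _empty_report()

    per_symbol: dict[str, dict] = {}
    for entry in lists:
        mapped, _ = ortholog_map.map_genes(entry.ranked.genes, entry.species)
        seen_here: dict[str, str] = {}  # symbol -> direction within this experiment/module list
        for gene, direction in zip(entry.ranked.genes, entry.ranked.directions):
            for sym in mapped.get(gene, ()):  # one-to-many expansion: one evidence line
                seen_here.setdefault(sym, direction)
        for sym, direction in seen_here.items():
            rec = per_symbol.setdefault(sym, {"species": set(), "experiments": set(),
                                              "directions": [], "by_species": {},
                                              "modules": []})
            rec["species"].add(entry.species)
            rec["experiments"].add(entry.experiment_id)
            if direction != "undetermined":
                rec["directions"].append(direction)
                rec["by_species"].setdefault(entry.species, set()).add(direction)
            rec["modules"].append(f"{entry.experiment_id}:M{entry.ranked.label}")

    rows = []
    for sym in sorted(per_symbol):
        rec = per_symbol[sym]
        if len(rec["species"]) < min_species:
            continue
        dirs = set(rec["directions"])
        aggregate = dirs.pop() if len(dirs) == 1 else ("mixed" if dirs else "undetermined")
        rows.append({
            "human_symbol": sym,
            "species": ",".join(sorted(rec["species"])),
            "n_species": len(rec["species"]),
            "n_experiments": len(rec["experiments"]),
            "direction": aggregate,
            "directions_by_species": ";".join(
                f"{sp}:{'|'.join(sorted(ds))}" for sp, ds in sorted(rec["by_species"].items())),
            "source_modules": ";".join(sorted(set(rec["modules"]))),
        })
    if not rows:
        return _empty_report()
    return pd.DataFrame(rows)


def _empty_report() -> pd.DataFrame:
    return pd.DataFrame(columns=["human_symbol", "species", "n_species", "n_experiments",
                                 "direction", "directions_by_species", "source_modules"])


def adjacency_threshold(adj, q: float = DEFAULT_QUANTILE) -> float:
    """Linear-interpolation quantile of all off-diagonal adjacency values.

    ``adj`` may be a square adjacency DataFrame/array (each unordered gene
    pair contributes once) or a 1-D array of adjacency values.  Computed
    over the whole experiment's adjacency; restrict beforehand for the
    module-restricted variant.
    """
    a = np.asarray(adj, dtype=float)
    if a.ndim == 2:
        iu = np.triu_indices(a.shape[0], k=1)
        vals = a[iu]
    else:
        vals = a.ravel()
    if vals.size == 0:
        raise CohealthError("adjacency has no off-diagonal values")
    return float(np.quantile(vals, q, method="linear"))


def export_interactions(hub_genes: Sequence[str], adj: pd.DataFrame, threshold: float,
                        ortholog_map: OrthologMap, species: str, experiment_id: str,
                        module_label: int) -> pd.DataFrame:
    """Hub-pair edges with adjacency strictly above the experiment threshold.

    Endpoints are mapped to human symbols (IDs without an ortholog keep
    their native ID); pairs collapsing to the same symbol (probeset
    self-interactions) are dropped.
    """
    hubs = [str(g) for g in hub_genes]
    mapped, _ = ortholog_map.map_genes(hubs, species)
    rows = []
    for i, ga in enumerate(hubs):
        for gb in hubs[i + 1:]:
            a_val = float(adj.loc[ga, gb])
            if not a_val > threshold:  # strict: "above" the 95% quantile
                continue
            syms_a = sorted(mapped.get(ga, {ga}))
            syms_b = sorted(mapped.get(gb, {gb}))
            for sa in syms_a:
                for sb in syms_b:
                    if sa == sb:
                        continue  # self-interaction after probeset collapse
                    lo, hi = sorted((sa, sb))
                    rows.append({
                        "experiment_id": experiment_id,
                        "module": module_label,
                        "gene_a": lo,
                        "gene_b": hi,
                        "adjacency": a_val,
                        "above_threshold": True,
                    })
    df = pd.DataFrame(rows, columns=["experiment_id", "module", "gene_a", "gene_b",
                                     "adjacency", "above_threshold"])
    # the same symbol pair may arise from several probeset pairs: keep the strongest
    if len(df):
        df = (df.sort_values(["gene_a", "gene_b", "adjacency"], ascending=[True, True, False])
                .drop_duplicates(["experiment_id", "module", "gene_a", "gene_b"])
                .reset_index(drop=True))
    return df


def write_consensus_report(report: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    report.to_csv(path, sep="\t", index=False)
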