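import numpy as np
import pandas as pd
import pytest

import cohealth as ch
from cohealth.consensus import ExperimentGeneList
from cohealth.errors import CohealthError
from cohealth.selection import RankedGeneList


@pytest.fixture
def worm_human_map():
    return ch.OrthologMap(pd.DataFrame({
        "species": ["worm", "worm", "worm", "human", "human", "rat"],
        "gene_id": ["mlc-6", "mlc-5", "unc-54", "MYL1", "ACTN3", "Myl1"],
        "human_symbol": ["MYL1", "MYL1", "MYH7", "MYL1", "ACTN3", "MYL1"],
    }))


def _lst(experiment_id, species, genes, directions=None, label=1):
    rl = RankedGeneList(label=label, basis="soft-connectivity", genes=list(genes),
                        scores=[0.0] * len(genes),
                        directions=directions or ["positive"] * len(genes))
    return ExperimentGeneList(experiment_id, species, rl)


def test_many_to_one_ortholog_mapping(worm_human_map):
    symbols, unmapped = ch.map_to_human(["mlc-6", "mlc-5", "scn-3"], "worm",
                                        worm_human_map)
    assert symbols == ["MYL1"]  # both light chains collapse to one evidence line
    assert unmapped == ["scn-3"]


def test_identity_map_for_human_experiment():
    omap = ch.OrthologMap.identity(["MYL1", "ACTN3"], "human")
    symbols, unmapped = ch.map_to_human(["MYL1", "ACTN3"], "human", omap)
    assert symbols == ["ACTN3", "MYL1"] and unmapped == []


def test_consensus_requires_two_species(worm_human_map):
    report = ch.cross_species_consensus(
        [_lst("h1", "human", ["MYL1", "ACTN3"]), _lst("r1", "rat", ["Myl1"])],
        worm_human_map)
    assert report["human_symbol"].tolist() == ["MYL1"]
    row = report.iloc[0]
    assert row["species"] == "human,rat" and row["n_experiments"] == 2
    assert row["direction"] == "positive"


def test_disjoint_lists_give_empty_report(worm_human_map):
    report = ch.cross_species_consensus(
        [_lst("h1", "human", ["ACTN3"]), _lst("w1", "worm", ["unc-54"])],
        worm_human_map)
    assert report.empty


def test_disagreeing_directions_aggregate_to_mixed(worm_human_map):
    report = ch.cross_species_consensus(
        [_lst("h1", "human", ["MYL1"], ["positive"]),
         _lst("w1", "worm", ["mlc-6"], ["negative"])],
        worm_human_map)
    assert report.iloc[0]["direction"] == "mixed"


def test_single_species_input_warns_and_returns_empty(worm_human_map, caplog):
    report = ch.cross_species_consensus([_lst("h1", "human", ["MYL1"])],
                                        worm_human_map)
    assert report.empty


def test_consensus_symmetric_and_idempotent_under_duplication(worm_human_map):
    lists = [_lst("h1", "human", ["MYL1", "ACTN3"]), _lst("w1", "worm", ["mlc-6"])]
    fwd = ch.cross_species_consensus(lists, worm_human_map)
    rev = ch.cross_species_consensus(list(reversed(lists)), worm_human_map)
    assert fwd["human_symbol"].tolist() == rev["human_symbol"].tolist()
    # a second worm experiment with the same list adds experiments, not species
    dup = ch.cross_species_consensus(lists + [_lst("w2", "worm", ["mlc-6"])],
                                     worm_human_map)
    assert dup["human_symbol"].tolist() == fwd["human_symbol"].tolist()
    assert dup.iloc[0]["n_experiments"] == 3


# -- adjacency threshold -----------------------------------------------------

def test_adjacency_quantile_hand_value():
    vals = np.round(np.arange(0.01, 1.005, 0.01), 2)  # 0.01 .. 1.00
    # linear interpolation at index (n-1)*0.95 = 94.05: 0.95 + 0.05 * 0.01
    assert ch.adjacency_threshold(vals, q=0.95) == pytest.approx(0.9505)
    assert ch.adjacency_threshold(vals, q=1.0) == pytest.approx(1.0)


def test_adjacency_threshold_constant_and_max():
    n = 6
    a = np.full((n, n), 0.3)
    np.fill_diagonal(a, 1.0)
    df = pd.DataFrame(a)
    assert ch.adjacency_threshold(df, 0.95) == pytest.approx(0.3)
    assert ch.adjacency_threshold(df, 1.0) == pytest.approx(0.3)


def test_adjacency_threshold_95_on_1_to_100_grid():
    n = 15
    vals = np.arange(0.01, 1.005, 0.01)[:100]
    a = np.eye(n)
    iu = np.triu_indices(n, k=1)
    padded = np.concatenate([vals, vals[-1] * np.ones(iu[0].size - 100)])
    # build a matrix whose off-diagonal multiset is exactly the padded set
    a[iu] = padded
    a.T[iu] = padded
    got = ch.adjacency_threshold(pd.DataFrame(a), 0.95)
    assert got == pytest.approx(float(np.quantile(padded, 0.95)))


# -- interaction export ------------------------------------------------------

def test_export_strict_threshold_and_self_interaction_removal(worm_human_map):
    genes = ["mlc-6", "mlc-5", "unc-54"]
    a = pd.DataFrame([[1.0, 0.99, 0.95],
                      [0.99, 1.0, 0.97],
                      [0.95, 0.97, 1.0]], index=genes, columns=genes)
    edges = ch.export_interactions(genes, a, threshold=0.95, ortholog_map=worm_human_map,
                                   species="worm", experiment_id="w1", module_label=1)
    pairs = set(map(tuple, edges[["gene_a", "gene_b"]].to_numpy()))
    # mlc-6 x mlc-5 (0.99) collapses to MYL1-MYL1: removed as self-interaction;
    # mlc-6 x unc-54 (0.95) is AT the threshold: excluded by the strict rule;
    # mlc-5 x unc-54 (0.97) survives as MYH7-MYL1
    assert pairs == {("MYH7", "MYL1")}
    assert edges.iloc[0]["adjacency"] == pytest.approx(0.97)


def test_exported_edges_match_brute_force_filter():
    rng = np.random.default_rng(5)
    genes = [f"g{i:02d}" for i in range(12)]
    a = rng.uniform(0, 1, size=(12, 12))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 1.0)
    adj = pd.DataFrame(a, index=genes, columns=genes)
    omap = ch.OrthologMap.identity(genes, "human")
    thr = ch.adjacency_threshold(adj, 0.8)
    edges = ch.export_interactions(genes, adj, thr, omap, "human", "e1", 1)
    iu = np.triu_indices(12, k=1)
    assert len(edges) == int((a[iu] > thr).sum())


def test_empty_ortholog_map_rejected():
    with pytest.raises(CohealthError, match="empty"):
        empty = ch.OrthologMap(pd.DataFrame(columns=["species", "gene_id", "human_symbol"]))
        empty.map_genes(["x"], "worm")
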