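"""Consensus database exactness and the cluster-pair permutation test."""

import numpy as np
import pandas as pd
import pytest

import nichescore as ns
from nichescore.crosstalk import (
    build_consensus_db,
    differential_network,
    interaction_test,
    map_orthologs,
)
from nichescore.dataset import NichescoreError, ValidationError
from nichescore.preprocess import lognormalize
from tests.conftest import make_dataset


def _table(pairs):
    return pd.DataFrame(pairs, columns=["ligand", "receptor"])


class TestConsensusDb:
    def test_hand_worked_example(self):
        sources = [
            ("A", _table([("L1", "R1"), ("L2", "R2")])),
            ("B", _table([("L1", "R1")])),
            ("C", _table([("L1", "R1"), ("L3", "R3")])),
        ]
        db = build_consensus_db(sources, min_sources=2)
        assert set(db.pairs) == {("L1", "R1")}
        assert db.pairs[("L1", "R1")] == frozenset({"A", "B", "C"})

    def test_min_sources_one_is_union(self):
        sources = [
            ("A", _table([("L1", "R1")])),
            ("B", _table([("L2", "R2")])),
        ]
        db = build_consensus_db(sources, min_sources=1)
        assert set(db.pairs) == {("L1", "R1"), ("L2", "R2")}

    def test_duplicate_source_names_rejected(self):
        sources = [("A", _table([("L1", "R1")])), ("A", _table([("L2", "R2")]))]
        with pytest.raises(ValidationError, match="duplicate"):
            build_consensus_db(sources, min_sources=1)

    def test_fixture_matches_brute_force_filter(self):
        tables, key = ns.generate_lr_fixture(seed=5)
        support = {}
        for name, table in tables:
            for lig, rec in zip(table["ligand"], table["receptor"]):
                support.setdefault((lig, rec), set()).add(name)
        for k in (1, 2, 3, 4, 5):
            db = build_consensus_db(tables, min_sources=k)
            expected = {p for p, s in support.items() if len(s) >= k}
            assert set(db.pairs) == expected

    def test_monotone_in_min_sources(self):
        tables, _ = ns.generate_lr_fixture(seed=8)
        previous = None
        for k in (1, 2, 3, 4, 5):
            current = set(build_consensus_db(tables, min_sources=k).pairs)
            if previous is not None:
                assert current <= previous
            previous = current


class TestMapOrthologs:
    def _db(self):
        return build_consensus_db(
            [
                ("A", _table([("l1", "r1"), ("l2", "r2"), ("l3", "r3")])),
            ],
            min_sources=1,
        )

    def test_identity_mapping_keeps_db(self):
        mapping = pd.DataFrame(
            {"from": ["l1", "r1", "l2", "r2", "l3", "r3"],
             "to": ["l1", "r1", "l2", "r2", "l3", "r3"]}
        )
        out = map_orthologs(self._db(), mapping)
        assert set(out.pairs) == set(self._db().pairs)
        assert out.n_dropped_unmapped == 0

    def test_unmapped_member_drops_pair(self):
        mapping = pd.DataFrame(
            {"from": ["l1", "r1", "l2", "r2", "r3"],
             "to": ["L1", "R1", "L2", "R2", "R3"]}
        )  # l3 missing
        out = map_orthologs(self._db(), mapping)
        assert set(out.pairs) == {("L1", "R1"), ("L2", "R2")}
        assert out.n_dropped_unmapped == 1

    def test_one_to_many_rejected(self):
        mapping = pd.DataFrame({"from": ["l1", "l1"], "to": ["A", "B"]})
        with pytest.raises(ValidationError, match="one-to-many"):
            map_orthologs(self._db(), mapping)


def _crosstalk_fixture(rng):
    """Clusters A (ligand-high) and B (receptor-high) plus a silent gene."""
    genes = ["LigX", "RecX", "LigSilent", "Filler1", "Filler2"]
    n = 120
    counts = rng.poisson(2.0, size=(len(genes), n)) + 1
    counts[2] = 0  # silent ligand everywhere
    clusters = np.array(["A"] * 60 + ["B"] * 60)
    counts[0, clusters == "A"] *= 6
    counts[1, clusters == "B"] *= 6
    return make_dataset(counts, gene_ids=genes, clusters=clusters, lognormed=True)


class TestInteractionTest:
    def test_silent_ligand_gated_out(self, rng):
        ds = _crosstalk_fixture(rng)
        db = build_consensus_db(
            [("S", _table([("LigSilent", "RecX")]))], min_sources=1
        )
        res = interaction_test(ds, db, n_perm=200, seed=0)
        assert not res["expressed"].any()
        assert res["p_perm"].isna().all()

    def test_directional_planted_interaction(self, rng):
        ds = _crosstalk_fixture(rng)
        db = build_consensus_db([("S", _table([("LigX", "RecX")]))], min_sources=1)
        res = interaction_test(ds, db, n_perm=500, seed=1).set_index(
            ["sender", "receiver"]
        )
        assert res.loc[("A", "B"), "p_perm"] < 0.05
        assert res.loc[("B", "A"), "p_perm"] > 0.05

    def test_p_floor_and_missing_gene_warning(self, rng):
        ds = _crosstalk_fixture(rng)
        db = build_consensus_db(
            [("S", _table([("LigX", "RecX"), ("Ghost", "RecX")]))], min_sources=1
        )
        with pytest.warns(UserWarning, match="Ghost"):
            res = interaction_test(ds, db, n_perm=300, seed=2)
        assert set(res["ligand"]) == {"LigX"}
        tested = res[res["expressed"]]
        assert (tested["p_perm"] >= 1 / 301).all()

    def test_null_p_values_approximately_uniform(self):
        import scipy.stats as st

        tables, _ = ns.generate_lr_fixture(seed=3)
        db = build_consensus_db(tables, min_sources=1)
        ds, _ = ns.generate_dataset(ns.preset("null_crosstalk", seed=7))
        ds = lognormalize(ds)
        res = interaction_test(ds, db, n_perm=500, seed=11)
        tested = res[res["expressed"]]
        assert len(tested) >= 200
        ks = st.kstest(tested["p_perm"], "uniform")
        assert ks.pvalue > 0.01


def _result_frame(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "sender", "receiver", "ligand", "receptor", "expressed",
            "mean_lr", "p_perm", "expressed_fraction_l",
            "expressed_fraction_r", "significant",
        ],
    )


class TestDifferentialNetwork:
    def _row(self, sender, receiver, lig, rec, mean_lr, significant=True):
        return {
            "sender": sender, "receiver": receiver, "ligand": lig,
            "receptor": rec, "expressed": True, "mean_lr": mean_lr,
            "p_perm": 0.01 if significant else 0.5,
            "expressed_fraction_l": 1.0, "expressed_fraction_r": 1.0,
            "significant": significant,
        }

    def test_identical_inputs_give_null_network(self):
        res = _result_frame([self._row("A", "B", "L1", "R1", 1.0)])
        edges, sets_ = differential_network(res, res.copy())
        assert (edges["delta_weight"] == 0).all()
        assert all(len(v) == 0 for v in sets_.values())

    def test_single_new_interaction(self):
        base = _result_frame(
            [self._row("A", "B", "L1", "R1", 1.2, significant=False)]
        )
        tac = _result_frame([self._row("A", "B", "L1", "R1", 1.2)])
        edges, sets_ = differential_network(base, tac)
        edge = edges.set_index(["sender", "receiver"]).loc[("A", "B")]
        assert edge["delta_weight"] == pytest.approx(1.2)
        assert sets_["ligand_up"] == ["L1"]
        assert sets_["receptor_up"] == ["R1"]
        assert sets_["ligand_down"] == []

    def test_conflicting_ligand_removed_from_both_sets(self):
        sham = _result_frame(
            [
                self._row("A", "B", "L1", "R1", 2.0),
                self._row("C", "D", "L1", "R2", 0.5, significant=False),
            ]
        )
        tac = _result_frame(
            [
                self._row("A", "B", "L1", "R1", 0.5, significant=False),
                self._row("C", "D", "L1", "R2", 2.0),
            ]
        )
        _, sets_ = differential_network(sham, tac)
        assert "L1" not in sets_["ligand_up"]
        assert "L1" not in sets_["ligand_down"]

    def test_antisymmetry_under_condition_swap(self, rng):
        rows_a, rows_b = [], []
        for i in range(6):
            sig_a = bool(rng.integers(2))
            sig_b = bool(rng.integers(2))
            pair = ("A", "B") if i % 2 else ("B", "A")
            rows_a.append(
                self._row(*pair, f"L{i}", f"R{i}", float(rng.uniform(0.5, 3)), sig_a)
            )
            rows_b.append(
                self._row(*pair, f"L{i}", f"R{i}", float(rng.uniform(0.5, 3)), sig_b)
            )
        fa, fb = _result_frame(rows_a), _result_frame(rows_b)
        e_ab, s_ab = differential_network(fa, fb)
        e_ba, s_ba = differential_network(fb, fa)
        merged = e_ab.merge(e_ba, on=["sender", "receiver"])
        assert np.allclose(merged["delta_weight_x"], -merged["delta_weight_y"])
        assert s_ab["ligand_up"] == s_ba["ligand_down"]
        assert s_ab["receptor_up"] == s_ba["receptor_down"]

    def test_cluster_vocabulary_mismatch_rejected(self):
        a = _result_frame([self._row("A", "B", "L1", "R1", 1.0)])
        b = _result_frame([self._row("A", "C", "L1", "R1", 1.0)])
        with pytest.raises(ValidationError, match="C"):
            differential_network(a, b)
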