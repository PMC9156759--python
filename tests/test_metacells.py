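"""Meta-cell construction oracle and correlation-ranking conventions."""

import numpy as np
import pandas as pd
import pytest

from nichescore.dataset import NichescoreError, ValidationError
from nichescore.metacells import (
    MetaCellTable,
    Regulon,
    build_metacells,
    regulon_activity,
    score_gene_correlation,
    score_score_correlation,
)
from tests.conftest import make_dataset


def _blob_dataset(rng, n_per_blob=50, n_genes=40, separation=40.0):
    mu_a = np.full(n_genes, 2.0)
    mu_b = np.full(n_genes, 2.0)
    mu_a[:10] = separation
    mu_b[10:20] = separation
    means = np.vstack(
        [np.tile(mu_a, (n_per_blob, 1)), np.tile(mu_b, (n_per_blob, 1))]
    )
    counts = rng.poisson(means).T
    counts[0] += 1
    return make_dataset(counts, lognormed=True)


class TestBuildMetacells:
    def test_two_blobs_match_nearest_centroid(self, rng):
        ds = _blob_dataset(rng)
        mc = build_metacells(ds, resolution=0.1, n_var_genes=40, seed=0)
        assert mc.n_metacells == 2
        # oracle: nearest-centroid assignment on the log-normalized data
        dense = np.asarray(ds.lognorm.todense()).T
        assign = mc.assignment.reindex(ds.cell_ids).to_numpy()
        centroids = np.vstack([dense[assign == m].mean(axis=0) for m in (0, 1)])
        nearest = np.argmin(
            ((dense[:, None, :] - centroids[None]) ** 2).sum(axis=2), axis=1
        )
        assert np.array_equal(nearest, assign)

    def test_high_resolution_fragments_heterogeneous_data(self):
        import nichescore as ns
        from nichescore.preprocess import lognormalize

        ds, _ = ns.generate_dataset(ns.preset("ecm", seed=5))
        ds = lognormalize(ds)
        mc = build_metacells(ds, resolution=10.0, seed=0)
        assert mc.n_metacells >= 50

    def test_small_metacells_dropped_with_cells(self, rng):
        ds = _blob_dataset(rng, n_per_blob=30)
        # plant 3 outlier cells forming their own community
        counts = ds.counts.toarray()
        counts[:, :3] = 0
        counts[25:28, :3] = 200
        ds = make_dataset(counts, lognormed=True)
        mc = build_metacells(
            ds, resolution=0.5, min_size=5, n_var_genes=40, seed=0
        )
        assert (mc.sizes >= 5).all()
        dropped = set(ds.cell_ids) - set(mc.assignment.index)
        for cid in dropped:
            assert cid not in mc.assignment.index

    def test_too_few_metacells_is_error(self, rng):
        counts = rng.poisson(3.0, size=(20, 30)) + 1
        ds = make_dataset(counts, lognormed=True)
        with pytest.raises(NichescoreError, match="resolution"):
            build_metacells(ds, resolution=0.001, min_size=10, n_var_genes=20, seed=0)


def _toy_table(rng, n_mc=20, n_genes=30):
    profiles = pd.DataFrame(
        rng.normal(size=(n_mc, n_genes)) + 3.0,
        index=pd.RangeIndex(n_mc, name="metacell"),
        columns=[f"G{i:02d}" for i in range(n_genes)],
    )
    profiles["G00"] = np.linspace(0, 1, n_mc) * 2 + 1  # tracks the score
    profiles["G01"] = 1.5  # constant gene
    scores = pd.DataFrame(
        {"ECM": np.linspace(0, 1, n_mc) * 2 + 1}, index=profiles.index
    )
    return MetaCellTable(
        assignment=pd.Series(dtype=int),
        profiles=profiles,
        score_means=scores,
        sizes=pd.Series(5, index=profiles.index),
    )


class TestScoreGeneCorrelation:
    def test_self_correlated_gene_ranks_first(self, rng):
        mc = _toy_table(rng)
        out = score_gene_correlation(mc, "ECM", top_n=10)
        assert out.iloc[0]["gene"] == "G00"
        assert out.iloc[0]["r"] == pytest.approx(1.0)

    def test_excluded_genes_absent(self, rng):
        mc = _toy_table(rng)
        out = score_gene_correlation(mc, "ECM", exclude_genes=["G00"], top_n=30)
        assert "G00" not in set(out["gene"])
        assert not (set(out["gene"]) & {"G00"})

    def test_constant_gene_gets_zero(self, rng):
        mc = _toy_table(rng)
        out = score_gene_correlation(mc, "ECM", top_n=30).set_index("gene")
        assert out.loc["G01", "r"] == 0.0

    def test_metacell_order_invariance(self, rng):
        mc = _toy_table(rng)
        perm = rng.permutation(len(mc.profiles))
        mc_perm = MetaCellTable(
            assignment=mc.assignment,
            profiles=mc.profiles.iloc[perm].reset_index(drop=True),
            score_means=mc.score_means.iloc[perm].reset_index(drop=True),
            sizes=mc.sizes.iloc[perm].reset_index(drop=True),
        )
        a = score_gene_correlation(mc, "ECM", top_n=30)
        b = score_gene_correlation(mc_perm, "ECM", top_n=30)
        pd.testing.assert_frame_equal(a, b)

    def test_needs_three_metacells(self, rng):
        mc = _toy_table(rng, n_mc=2)
        with pytest.raises(NichescoreError, match="3 meta-cells"):
            score_gene_correlation(mc, "ECM")

    def test_planted_drivers_recovered_through_metacells(self):
        import nichescore as ns
        from nichescore.preprocess import lognormalize
        from nichescore.scoring import score_battery
        from nichescore.simulate import DRIVER_GENES, ECM_PROGRAM_GENES

        ds, truth = ns.generate_dataset(ns.preset("drivers", seed=2))
        ds = lognormalize(ds)
        scores = score_battery(ds, ns.default_gene_sets(), seed=2)
        mc = build_metacells(ds, scores=scores, resolution=10.0, seed=2)
        top = score_gene_correlation(
            mc, "ECM", exclude_genes=ECM_PROGRAM_GENES, top_n=100
        )
        hits = len(set(top["gene"]) & set(DRIVER_GENES))
        assert hits >= 18
        assert not (set(top["gene"]) & set(ECM_PROGRAM_GENES))

    def test_metacell_averaging_strengthens_driver_correlation(self):
        import nichescore as ns
        from nichescore.preprocess import lognormalize
        from nichescore.scoring import score_battery
        from nichescore.simulate import DRIVER_GENES

        ds, truth = ns.generate_dataset(ns.preset("drivers", seed=9))
        ds = lognormalize(ds)
        scores = score_battery(ds, ns.default_gene_sets(), seed=9)
        mc = build_metacells(ds, scores=scores, resolution=10.0, seed=9)
        dense = np.asarray(ds.lognorm.todense())
        score_cells = scores["ECM"].to_numpy()
        ratios = []
        for gene in DRIVER_GENES:
            gi = ds.gene_index(gene)
            r_cell = np.corrcoef(dense[gi], score_cells)[0, 1]
            r_mc = np.corrcoef(
                mc.profiles[gene], mc.score_means["ECM"]
            )[0, 1]
            ratios.append(abs(r_mc) - abs(r_cell))
        assert np.median(ratios) > 0


class TestRegulonActivity:
    def test_single_target_is_z_profile(self, rng):
        mc = _toy_table(rng)
        act = regulon_activity(mc, [Regulon("TF1", (("G00", 1, 1.0),))])
        g = mc.profiles["G00"]
        z = (g - g.mean()) / g.std()
        assert np.allclose(act["TF1"], z)

    def test_repressor_negates(self, rng):
        mc = _toy_table(rng)
        act = regulon_activity(
            mc,
            [
                Regulon("TFp", (("G02", 1, 1.0),)),
                Regulon("TFn", (("G02", -1, 1.0),)),
            ],
        )
        assert np.allclose(act["TFp"], -act["TFn"])

    def test_absent_regulon_excluded_with_warning(self, rng):
        mc = _toy_table(rng)
        with pytest.warns(UserWarning, match="Ghost"):
            act = regulon_activity(
                mc,
                [
                    Regulon("Ghost", (("Nope", 1, 1.0),)),
                    Regulon("TF1", (("G03", 1, 1.0),)),
                ],
            )
        assert list(act.columns) == ["TF1"]

    def test_regulon_validation(self):
        with pytest.raises(ValidationError, match="no targets"):
            Regulon("T", ())
        with pytest.raises(ValidationError, match="mode"):
            Regulon("T", (("G", 2, 1.0),))
        with pytest.raises(ValidationError, match="weights"):
            Regulon("T", (("G", 1, 1.5),))

    def test_planted_tf_tracks_latent_factor(self):
        import nichescore as ns
        from nichescore.preprocess import lognormalize
        from nichescore.scoring import score_battery

        ds, truth = ns.generate_dataset(ns.preset("drivers", seed=4))
        ds = lognormalize(ds)
        scores = score_battery(ds, ns.default_gene_sets(), seed=4)
        mc = build_metacells(ds, scores=scores, resolution=10.0, seed=4)
        act = regulon_activity(mc, ns.default_regulons(seed=4))
        latent = (
            truth.cells["activity"]
            .reindex(mc.assignment.index)
            .groupby(mc.assignment.values)
            .mean()
        )
        r = np.corrcoef(act[truth.planted_tf], latent)[0, 1]
        assert r > 0.9


class TestScoreScoreCorrelation:
    def test_identical_activity_ranks_first(self, rng):
        mc = _toy_table(rng)
        act = pd.DataFrame(
            {
                "Mirror": mc.score_means["ECM"].to_numpy(),
                "Flat": np.full(len(mc.profiles), 2.0),
                "Noise": rng.normal(size=len(mc.profiles)),
            },
            index=mc.score_means.index,
        )
        out = score_score_correlation(mc, act, "ECM", top_n=3)
        assert out.iloc[0]["tf"] == "Mirror"
        assert out.iloc[0]["r"] == pytest.approx(1.0)
        flat_rank = out.set_index("tf").index.get_loc("Flat")
        assert out.set_index("tf").loc["Flat", "r"] == 0.0
        assert flat_rank > 0

    def test_planted_tf_in_top_10(self):
        import nichescore as ns
        from nichescore.preprocess import lognormalize
        from nichescore.scoring import score_battery

        ds, truth = ns.generate_dataset(ns.preset("drivers", seed=6))
        ds = lognormalize(ds)
        scores = score_battery(ds, ns.default_gene_sets(), seed=6)
        mc = build_metacells(ds, scores=scores, resolution=10.0, seed=6)
        act = regulon_activity(mc, ns.default_regulons(seed=6))
        out = score_score_correlation(mc, act, "ECM", top_n=10)
        assert truth.planted_tf in set(out["tf"])
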