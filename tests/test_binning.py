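import logging

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import cdist
from sklearn.metrics import adjusted_rand_score

from popomics.binning import (
    UNBINNED,
    CompositeGenomeBinner,
    assign_bins,
    embed,
    fit_gmm,
    fit_gmm_bic,
    iterate_binning,
    recruit_reads,
    split_by_coverage,
)
from popomics.errors import ConsistencyError, DegeneracyError, ParameterError


def _blobs(rng, centers, n_per=60, scale=0.5):
    pts = np.vstack([c + scale * rng.standard_normal((n_per, 2)) for c in centers])
    labels = np.repeat(np.arange(len(centers)), n_per)
    return pts, labels


def _toy_signatures(seed=0, n_per=45):
    """Two synthetic populations in 20-D signature-like space."""
    rng = np.random.default_rng(seed)
    a = rng.standard_normal(20)
    b = rng.standard_normal(20) + 2.0
    X = np.vstack([a + 0.3 * rng.standard_normal((n_per, 20)),
                   b + 0.3 * rng.standard_normal((n_per, 20))])
    return X, np.repeat([0, 1], n_per)


class TestEmbed:
    def test_deterministic_for_fixed_seed(self):
        X, _ = _toy_signatures()
        e1 = embed(X, perplexity=10, seed=4)
        e2 = embed(X, perplexity=10, seed=4)
        assert np.array_equal(e1, e2)

    def test_too_few_points_rejected(self):
        with pytest.raises(ParameterError):
            embed(np.random.default_rng(0).standard_normal((20, 5)), perplexity=10)

    def test_population_structure_survives_projection(self):
        # brute-force distance oracle on the 2-D map
        X, labels = _toy_signatures(seed=1)
        e = embed(X, perplexity=10, seed=0)
        d = cdist(e, e)
        same = labels[:, None] == labels[None, :]
        off = ~np.eye(len(labels), dtype=bool)
        assert d[~same].mean() > d[same & off].mean()


class TestFitGmm:
    def test_single_component_recovers_sample_mean(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((200, 2)) * 3 + [5, -2]
        m = fit_gmm(X, n_components=1)
        assert np.allclose(m.means[0], X.mean(axis=0), atol=1e-9)

    def test_well_separated_clusters_match_nearest_mean_oracle(self):
        rng = np.random.default_rng(1)
        centers = np.array([[0.0, 0.0], [20.0, 0.0]])   # 20 sigma apart
        X, _ = _blobs(rng, centers, n_per=100, scale=1.0)
        m = fit_gmm(X, init_means=centers)
        hard = m.responsibilities(X).argmax(axis=1)
        oracle = cdist(X, centers).argmin(axis=1)
        assert np.array_equal(hard, oracle)

    def test_log_likelihood_trace_monotone(self):
        rng = np.random.default_rng(2)
        X, _ = _blobs(rng, [[0, 0], [4, 4], [-4, 4]])
        m = fit_gmm(X, n_components=3, seed=0)
        trace = np.array(m.log_likelihood_trace)
        assert np.all(np.diff(trace) >= -1e-8)
        assert abs(m.weights.sum() - 1.0) < 1e-9

    def test_responsibilities_row_normalized(self):
        rng = np.random.default_rng(3)
        X, _ = _blobs(rng, [[0, 0], [6, 0]])
        m = fit_gmm(X, n_components=2, seed=0)
        assert np.allclose(m.responsibilities(X).sum(axis=1), 1.0)

    def test_matches_reference_em_implementation(self):
        # independent cross-check: sklearn's GaussianMixture on the same
        # well-separated data must produce the same partition
        from sklearn.mixture import GaussianMixture

        rng = np.random.default_rng(4)
        X, _ = _blobs(rng, [[0, 0], [8, 8], [-8, 8]], n_per=80)
        ours = fit_gmm(X, n_components=3, seed=0).responsibilities(X).argmax(axis=1)
        ref = GaussianMixture(3, random_state=0, n_init=3).fit_predict(X)
        assert adjusted_rand_score(ours, ref) == 1.0

    def test_more_components_than_points_errors(self):
        with pytest.raises(DegeneracyError):
            fit_gmm(np.zeros((2, 2)), n_components=5)

    def test_bic_scan_finds_true_component_count(self):
        rng = np.random.default_rng(5)
        X, _ = _blobs(rng, [[0, 0], [10, 0], [0, 10]], n_per=70)
        m = fit_gmm_bic(X, k_max=6, seed=0)
        assert m.n_components == 3


class TestAssignBins:
    def _model_points(self):
        rng = np.random.default_rng(6)
        centers = np.array([[0.0, 0.0], [15.0, 0.0]])
        X, _ = _blobs(rng, centers, n_per=80, scale=1.0)
        return fit_gmm(X, init_means=centers), X

    def test_point_at_component_mean_gets_high_posterior(self):
        m, X = self._model_points()
        df = assign_bins(m, m.means, ["at_mean_0", "at_mean_1"])
        assert (df["posterior"] > 0.99).all()
        assert df["cg_id"].tolist() == ["CG1", "CG2"]

    def test_zero_cutoff_leaves_nothing_unbinned(self):
        m, X = self._model_points()
        df = assign_bins(m, X, [f"c{i}" for i in range(len(X))], min_posterior=0.0)
        assert (df["cg_id"] != UNBINNED).all()

    def test_ambiguous_points_go_unbinned(self):
        m, X = self._model_points()
        midpoint = m.means.mean(axis=0, keepdims=True)
        df = assign_bins(m, midpoint, ["mid"], min_posterior=0.95)
        assert df["cg_id"].iloc[0] == UNBINNED


class TestRecruitReads:
    def test_single_bin_takes_all(self):
        a = pd.DataFrame({"contig_id": ["c1", "c2"], "cg_id": "CG1",
                          "posterior": 1.0})
        counts = pd.DataFrame({"contig_id": ["c1", "c2"], "count": [100, 200]})
        c_i, residual = recruit_reads(a, counts)
        assert c_i["CG1"] == 300 and residual == 0

    def test_per_bin_addition(self):
        a = pd.DataFrame({"contig_id": ["c1", "c2", "c3"],
                          "cg_id": ["CG1", "CG1", "CG2"], "posterior": 1.0})
        counts = pd.DataFrame({"contig_id": ["c1", "c2", "c3"],
                               "count": [100, 200, 300]})
        c_i, _ = recruit_reads(a, counts)
        assert c_i.to_dict() == {"CG1": 300, "CG2": 300}

    def test_conservation_on_random_assignments(self):
        rng = np.random.default_rng(7)
        ids = [f"c{i}" for i in range(200)]
        a = pd.DataFrame({
            "contig_id": ids,
            "cg_id": rng.choice(["CG1", "CG2", "CG3", UNBINNED], size=200),
            "posterior": 1.0,
        })
        counts = pd.DataFrame({"contig_id": ids,
                               "count": rng.integers(0, 1000, 200)})
        c_i, residual = recruit_reads(a, counts)
        assert c_i.sum() + residual == counts["count"].sum()

    def test_unknown_contig_is_a_consistency_error(self):
        a = pd.DataFrame({"contig_id": ["c1"], "cg_id": ["CG1"], "posterior": 1.0})
        counts = pd.DataFrame({"contig_id": ["c1", "mystery"], "count": [1, 2]})
        with pytest.raises(ConsistencyError):
            recruit_reads(a, counts)


class TestIterateBinning:
    def test_all_short_contigs_pass_through(self, caplog):
        seqs = {f"c{i}": "ACGT" * 100 for i in range(10)}   # 400 bp each
        a = pd.DataFrame({"contig_id": list(seqs), "cg_id": "CG1",
                          "posterior": 1.0})
        with caplog.at_level(logging.WARNING):
            out = iterate_binning(seqs, a, round2_min_length=1000, perplexity=5)
        assert out["cg_id"].eq("CG1").all()
        assert any("passed through" in r.message for r in caplog.records)

    def test_mixed_group_is_split_improving_ari(self):
        # two populations deliberately merged into one first-round group
        import popomics as pm

        spec = pm.two_population_community(seed=9, genome_length=200_000,
                                           total_metag_reads=10_000,
                                           total_metat_reads=10_000)
        b = pm.generate_community(spec)
        a = pd.DataFrame({"contig_id": b.contigs["contig_id"], "cg_id": "CG1",
                          "posterior": 1.0})
        out = iterate_binning(b.sequences, a, perplexity=8.0, seed=0)
        truth = b.contigs.set_index("contig_id")["pop_id"]
        before = adjusted_rand_score(truth.loc[a["contig_id"]], a["cg_id"])
        after = adjusted_rand_score(truth.loc[out["contig_id"]], out["cg_id"])
        assert after > before
        assert out["cg_id"].nunique() >= 2


class TestSplitByCoverage:
    def test_unimodal_depths_not_split(self):
        rng = np.random.default_rng(8)
        depths = rng.lognormal(np.log(20), 0.05, 200)
        out = split_by_coverage([f"c{i}" for i in range(200)], depths, cg_id="CG3")
        assert out["cg_id"].eq("CG3").all()

    def test_bimodal_depths_split_with_ordered_labels(self):
        rng = np.random.default_rng(9)
        low = rng.lognormal(np.log(5), 0.05, 100)
        high = rng.lognormal(np.log(50), 0.05, 100)
        ids = [f"c{i}" for i in range(200)]
        out = split_by_coverage(ids, np.concatenate([low, high]), cg_id="CG8")
        merged = out.assign(depth=np.concatenate([low, high]))
        means = merged.groupby("cg_id")["depth"].mean()
        assert set(means.index) == {"CG8a", "CG8b"}
        assert means["CG8a"] < means["CG8b"]
        truth = np.repeat(["low", "high"], 100)
        purity = (pd.crosstab(out["cg_id"], truth).max(axis=1).sum() / 200)
        assert purity >= 0.95

    def test_tiny_bin_passes_through(self, caplog):
        with caplog.at_level(logging.WARNING):
            out = split_by_coverage(["a", "b", "c"], np.array([1.0, 2.0, 3.0]))
        assert out["cg_id"].nunique() == 1

    def test_nonpositive_depths_rejected(self):
        with pytest.raises(ParameterError):
            split_by_coverage(["a", "b", "c", "d"], np.array([1.0, 0.0, 2.0, 3.0]))


class TestCompositeGenomeBinner:
    def test_estimator_contract_and_recovery(self):
        X, labels = _toy_signatures(seed=10, n_per=60)
        binner = CompositeGenomeBinner(n_components=2, perplexity=10,
                                       random_state=0)
        out = binner.fit_predict(X)
        assert binner.embedding_.shape == (120, 2)
        assert adjusted_rand_score(labels, out) == 1.0
        params = binner.get_params()
        assert params["n_components"] == 2
        clone = CompositeGenomeBinner(**params).fit(X)
        assert np.array_equal(clone.labels_, binner.labels_)

    def test_assignments_table(self):
        X, _ = _toy_signatures(seed=11, n_per=60)
        binner = CompositeGenomeBinner(n_components=2, perplexity=10,
                                       random_state=0).fit(X)
        df = binner.assignments([f"c{i}" for i in range(120)])
        assert set(df.columns) == {"contig_id", "cg_id", "posterior"}
        assert df["posterior"].between(0, 1).all()
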