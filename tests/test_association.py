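"""Expression-mechanics association: z-scores, correlation, PCA, fold changes."""

import numpy as np
import pandas as pd
import pytest

from nucrheo.association import (
    ProfileMatrix,
    chromatin_scores,
    combine_protein_levels,
    fold_change_frame,
    log2_fold_changes,
    pca_cluster,
    pearson_matrix,
    zscore,
)
from nucrheo.synthetic import simulate_profiles

CONDITIONS = ["WT", "TKO", "A-rescue", "B1-rescue", "AB1-rescue"]


def profile(rows: dict, classes: dict | None = None) -> ProfileMatrix:
    values = pd.DataFrame(rows, index=CONDITIONS[: len(next(iter(rows.values())))]).T
    cls = pd.Series(classes) if classes else None
    return ProfileMatrix(values=values, classes=cls)


class TestZScore:
    def test_arithmetic_sequence_standardizes_to_unit_steps(self):
        pm = profile({"f": [1.0, 2.0, 3.0]})
        z = zscore(pm)
        np.testing.assert_allclose(z.values.loc["f"], [-1.0, 0.0, 1.0])

    def test_constant_feature_dropped_with_warning(self, caplog):
        pm = profile({"flat": [2.0, 2.0, 2.0], "ok": [1.0, 2.0, 3.0]})
        with caplog.at_level("WARNING"):
            z = zscore(pm)
        assert "flat" not in z.features and "ok" in z.features
        assert "zero-variance" in caplog.text

    def test_output_rows_have_zero_mean_unit_sd(self):
        rng = np.random.default_rng(0)
        pm = profile({f"f{i}": rng.normal(size=5).tolist() for i in range(4)})
        z = zscore(pm)
        assert z.standardized
        np.testing.assert_allclose(z.values.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.values.std(axis=1, ddof=1), 1.0, atol=1e-12)


class TestPearson:
    def test_perfect_and_anti_correlation(self):
        a = profile({"x": [1.0, 2.0, 3.0]})
        b = profile({"same": [1.0, 2.0, 3.0], "flip": [3.0, 2.0, 1.0]})
        r = pearson_matrix(a, b)
        assert r.at["x", "same"] == pytest.approx(1.0)
        assert r.at["x", "flip"] == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        a = profile({"x": [1.0, 2.0, 3.0]})
        b = profile({"y": [1.0, 2.0, 4.0]})
        assert pearson_matrix(a, b).at["x", "y"] == pytest.approx(0.9820, abs=1e-4)

    def test_mismatched_conditions_named_in_error(self):
        a = profile({"x": [1.0, 2.0, 3.0]})
        bv = pd.DataFrame([[1.0, 2.0, 3.0]], index=["y"], columns=["WT", "TKO", "other"])
        with pytest.raises(ValueError, match="other"):
            pearson_matrix(a, ProfileMatrix(values=bv))

    def test_values_bounded_and_permutation_consistent(self):
        pm = simulate_profiles(seed=1)
        z = zscore(pm)
        r = pearson_matrix(z.subset("protein"), z.subset("mechanics"))
        assert (r.values <= 1).all() and (r.values >= -1).all()
        perm = ["TKO", "AB1-rescue", "WT", "B1-rescue", "A-rescue"]
        zp = ProfileMatrix(values=z.values[perm], classes=z.classes, standardized=True)
        rp = pearson_matrix(zp.subset("protein"), zp.subset("mechanics"))
        np.testing.assert_allclose(r.values, rp.values, atol=1e-12)

    def test_lamin_a_couples_positively_to_maxwell_stiffness(self):
        pm = simulate_profiles(seed=3)
        z = zscore(pm)
        r = pearson_matrix(z.subset("protein"), z.subset("mechanics"))
        assert r.at["lamin_A", "k_M"] > 0


class TestPCA:
    def test_duplicated_feature_collapses_to_one_component(self):
        x = [1.0, -1.0, 0.5, -0.5, 0.0]
        pm = profile({"a": x, "b": x})
        res = pca_cluster(zscore(pm))
        np.testing.assert_allclose(res.loadings["PC1"].iloc[0],
                                   res.loadings["PC1"].iloc[1], atol=1e-10)
        assert res.explained_variance_ratio[1] == pytest.approx(0.0, abs=1e-10)

    def test_anticorrelated_blocks_separate_by_loading_sign(self):
        x = [1.0, -1.0, 0.5, -0.5, 0.25]
        neg = [-v for v in x]
        pm = profile({"a1": x, "a2": x, "b1": neg, "b2": neg})
        res = pca_cluster(zscore(pm))
        signs = np.sign(res.loadings["PC1"])
        assert signs["a1"] == signs["a2"] != signs["b1"] == signs["b2"]

    def test_requires_standardized_profile(self):
        pm = profile({"a": [1.0, 2.0, 3.0], "b": [2.0, 1.0, 3.0]})
        with pytest.raises(ValueError, match="standardized"):
            pca_cluster(pm)

    def test_reconstruction_with_all_components(self):
        pm = zscore(simulate_profiles(seed=2))
        res = pca_cluster(pm, n_components=min(len(pm.features), len(pm.conditions)))
        X = pm.values.to_numpy(float).T
        approx = res.scores.to_numpy() @ res.loadings.to_numpy().T + X.mean(0)
        np.testing.assert_allclose(approx, X, atol=1e-10)

    def test_lamin_blocks_cocluster_in_loading_plane(self):
        res = pca_cluster(zscore(simulate_profiles(seed=0)))
        mech = ["k_M", "mu_M", "k_KV", "mu_KV"]
        assert set(res.nearest_features("lamin_A", mech)) == {"k_M", "mu_M"}
        assert set(res.nearest_features("lamin_B1", mech)) == {"k_KV", "mu_KV"}


class TestFoldChanges:
    table = pd.DataFrame(
        {"WT": [9.5, 1.0], "TKO": [2.3, 1.0]}, index=["mu_M", "unchanged"]
    )

    def test_equal_values_give_zero(self):
        recs = log2_fold_changes(self.table, [("WT", "TKO")])
        by_feature = {r.feature: r.log2_ratio for r in recs}
        assert by_feature["unchanged"] == pytest.approx(0.0)

    def test_fourfold_viscosity_decrease_in_knockout(self):
        recs = log2_fold_changes(self.table, [("TKO", "WT")])
        mu = {r.feature: r.log2_ratio for r in recs}["mu_M"]
        assert mu == pytest.approx(-2.046, abs=1e-3)

    def test_three_to_one_ratio(self):
        t = pd.DataFrame({"a": [3.0], "b": [1.0]}, index=["f"])
        recs = log2_fold_changes(t, [("a", "b")])
        assert recs[0].log2_ratio == pytest.approx(1.585, abs=1e-3)

    def test_antisymmetry(self):
        fwd = log2_fold_changes(self.table, [("WT", "TKO")])
        rev = log2_fold_changes(self.table, [("TKO", "WT")])
        for f, r in zip(fwd, rev):
            assert f.log2_ratio == pytest.approx(-r.log2_ratio)

    def test_nonpositive_value_skipped_with_warning(self, caplog):
        t = pd.DataFrame({"a": [0.0], "b": [1.0]}, index=["f"])
        with caplog.at_level("WARNING"):
            recs = log2_fold_changes(t, [("a", "b")])
        assert recs == [] and "nonpositive" in caplog.text

    def test_missing_condition_rejected(self):
        with pytest.raises(KeyError, match="nope"):
            log2_fold_changes(self.table, [("WT", "nope")])

    def test_frame_view(self):
        recs = log2_fold_changes(self.table, [("WT", "TKO")])
        df = fold_change_frame(recs)
        assert list(df.columns) == ["feature", "numerator", "denominator", "log2_ratio"]
        assert len(df) == 2


def score_table(levels: dict) -> pd.DataFrame:
    rows = []
    for cond, level in levels.items():
        for compartment in ("peripheral", "nucleoplasmic"):
            for nucleus in range(3):
                for evaluator in "ABC":
                    rows.append((cond, compartment, nucleus, evaluator, level))
    return pd.DataFrame(rows, columns=["condition", "compartment", "nucleus",
                                       "evaluator", "score"])


class TestChromatinScores:
    def test_equal_scores_give_zero_fold_change(self):
        means, recs = chromatin_scores(score_table({"WT": 2.0, "TKO": 2.0}),
                                       contrasts=[("WT", "TKO")])
        assert all(r.log2_ratio == pytest.approx(0.0) for r in recs)

    def test_doubled_scores_give_unit_log2(self):
        means, recs = chromatin_scores(score_table({"WT": 2.0, "TKO": 1.0}),
                                       contrasts=[("WT", "TKO")])
        assert all(r.log2_ratio == pytest.approx(1.0) for r in recs)

    def test_fourfold_condensation_contrast(self):
        # knockout at basal level, wild type fourfold higher -> log2 FC = 2
        means, recs = chromatin_scores(score_table({"WT": 4.0, "TKO": 1.0}),
                                       contrasts=[("WT", "TKO")])
        assert all(r.log2_ratio == pytest.approx(2.0) for r in recs)
        assert means.at["WT", "peripheral"] == pytest.approx(4.0)

    def test_evaluators_averaged_before_nuclei(self):
        df = score_table({"WT": 1.0})
        # one deviant evaluator on one nucleus moves the mean by its share
        df.loc[(df.evaluator == "A") & (df.nucleus == 0)
               & (df.compartment == "peripheral"), "score"] = 4.0
        means, _ = chromatin_scores(df)
        assert means.at["WT", "peripheral"] == pytest.approx(1.0 + 3.0 / 9.0)
        assert means.at["WT", "nucleoplasmic"] == pytest.approx(1.0)

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="evaluator"):
            chromatin_scores(pd.DataFrame({"condition": [], "score": []}))


class TestCombineProteinLevels:
    def tidy(self, rows):
        return pd.DataFrame(rows, columns=["lamin", "condition", "method", "level"])

    def test_single_method_passthrough(self):
        m = self.tidy([("lamin_A", "WT", "IF", 8.0), ("lamin_A", "TKO", "IF", 4.0)])
        out = combine_protein_levels(m)
        assert out.at["lamin_A", "WT"] == pytest.approx(1.0)
        assert out.at["lamin_A", "TKO"] == pytest.approx(0.5)

    def test_methods_agreeing_at_wild_type_level(self):
        m = self.tidy([("lamin_A", "WT", meth, s) for meth, s in
                       [("IF", 5.0), ("WB", 100.0), ("MS", 0.2)]]
                      + [("lamin_A", "A-rescue", meth, s) for meth, s in
                         [("IF", 5.0), ("WB", 100.0), ("MS", 0.2)]])
        out = combine_protein_levels(m)
        assert out.at["lamin_A", "A-rescue"] == pytest.approx(1.0)

    def test_half_rescue_consensus(self):
        m = self.tidy([("lamin_A", "WT", meth, 1.0) for meth in ("IF", "WB", "MS")]
                      + [("lamin_A", "A-rescue", meth, lvl) for meth, lvl in
                         [("IF", 0.4), ("WB", 0.5), ("MS", 0.6)]])
        out = combine_protein_levels(m)
        assert out.at["lamin_A", "A-rescue"] == pytest.approx(0.5)

    def test_partial_methods_averaged_with_log(self, caplog):
        m = self.tidy([("lamin_B1", "WT", "IF", 2.0), ("lamin_B1", "WT", "WB", 3.0),
                       ("lamin_B1", "TKO", "IF", 1.0)])
        with caplog.at_level("WARNING"):
            out = combine_protein_levels(m)
        assert out.at["lamin_B1", "TKO"] == pytest.approx(0.5)
        assert "subset of methods" in caplog.text

    def test_missing_anchor_rejected(self):
        m = self.tidy([("lamin_A", "TKO", "IF", 1.0)])
        with pytest.raises(ValueError, match="anchor"):
            combine_protein_levels(m)


class TestSignRecovery:
    def test_zero_noise_unit_slopes_give_perfect_correlation(self):
        pm = simulate_profiles(noise_sd=0.0, seed=0)
        z = zscore(pm)
        r = pearson_matrix(z.subset("protein"), z.subset("mechanics"))
        assert r.at["lamin_A", "k_M"] == pytest.approx(1.0)
        assert r.at["lamin_B1", "k_KV"] == pytest.approx(1.0)

    def test_negated_slopes_flip_correlation_sign(self):
        pm = simulate_profiles(noise_sd=0.0, slope_a=-1.0, seed=0)
        z = zscore(pm)
        r = pearson_matrix(z.subset("protein"), z.subset("mechanics"))
        assert r.at["lamin_A", "k_M"] == pytest.approx(-1.0)

    def test_sign_recovered_in_at_least_95_percent_of_seeded_sets(self):
        hits = 0
        for seed in range(50):
            z = zscore(simulate_profiles(seed=seed))
            r = pearson_matrix(z.subset("protein"), z.subset("mechanics"))
            hits += (r.at["lamin_A", "k_M"] > 0) and (r.at["lamin_A", "mu_M"] > 0)
        assert hits >= 48  # >= 95% of 50

    def test_coupled_correlation_exceeds_cross_correlation(self):
        r_own, r_cross = [], []
        for seed in range(50):
            z = zscore(simulate_profiles(seed=seed))
            r = pearson_matrix(z.subset("protein"), z.subset("mechanics"))
            r_own.append(r.at["lamin_A", "k_M"])
            r_cross.append(r.at["lamin_A", "k_KV"])
        assert np.mean(r_own) > np.mean(r_cross)
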