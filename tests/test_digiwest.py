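import numpy as np
import pandas as pd
import pytest

from epiwindow import (
    FractionMatrix,
    SimConfig,
    cluster_significant,
    normalize_to_actin,
    permutation_anova2,
    quantify_analyte,
    render_blot,
    scale_blot,
    simulate_fraction_matrix,
)
from epiwindow.simulate import default_bands


def toy_matrix(n_analytes=2, seed=0):
    fm, truth = simulate_fraction_matrix(SimConfig(seed=seed, n_analytes=n_analytes))
    return fm, truth


def balanced_design(n_per_cell=2):
    rows = []
    for t in ("serum", "2i"):
        for c in ("J1", "TKO", "3B3l"):
            for r in range(n_per_cell):
                rows.append((f"{c}_{t}_{r}", t, c))
    df = pd.DataFrame(rows, columns=["sample", "treatment", "celltype"]).set_index("sample")
    return df


class TestScaleBlot:
    def test_simple(self):
        fm, _ = toy_matrix()
        fm.intensities[0] = 0.0
        fm.intensities[0, 0, :3] = [0.0, 5.0, 10.0]
        out = scale_blot(fm, fm.analytes[0])
        np.testing.assert_allclose(out[0, :3], [0, 0.5, 1.0])

    def test_idempotent(self):
        fm, _ = toy_matrix()
        once = scale_blot(fm, "analyte000")
        fm.intensities[fm.analyte_index("analyte000")] = once
        np.testing.assert_allclose(scale_blot(fm, "analyte000"), once)

    def test_argmax_preserved_max_is_one(self):
        fm, _ = toy_matrix(seed=3)
        block = fm.intensities[fm.analyte_index("analyte001")]
        out = scale_blot(fm, "analyte001")
        assert out.max() == 1.0
        assert np.argmax(out) == np.argmax(block)

    def test_all_zero_errors(self):
        fm, _ = toy_matrix()
        fm.intensities[0] = 0.0
        with pytest.raises(ValueError):
            scale_blot(fm, fm.analytes[0])


class TestRenderBlot:
    def test_all_zero_is_white(self):
        img = render_blot(np.zeros((4, 96)), element_height=6)
        assert img.shape[0] == 96 * 6
        assert np.all(img == 0)

    def test_constant_image_unchanged_by_blur(self):
        img = render_blot(np.full((4, 96), 0.7), element_height=6)
        np.testing.assert_allclose(img, 0.7, atol=1e-9)

    def test_single_cell_mass_conserved(self):
        scaled = np.zeros((4, 96))
        scaled[2, 48] = 1.0
        img = render_blot(scaled, element_height=8, lane_width=8)
        assert abs(img.sum() - 8 * 8) / (8 * 8) < 0.01  # reflective padding
        # blurred peak stays centered on the painted cell
        r, c = np.unravel_index(np.argmax(img), img.shape)
        assert 48 * 8 <= r < 49 * 8 and 2 * 8 <= c < 3 * 8

    def test_minimum_element_height(self):
        with pytest.raises(ValueError):
            render_blot(np.zeros((2, 96)), element_height=1)


class TestQuantifyAnalyte:
    def test_single_fraction_band(self):
        fm, _ = toy_matrix()
        fm.intensities[0, :, :] = 0.0
        fm.intensities[0, 0, 41] = 7.0  # fraction 42 (1-based)
        vals = quantify_analyte(fm, {fm.analytes[0]: (42, 42)})
        assert vals.iloc[0, 0] == 7.0

    def test_full_window_is_row_sum(self):
        fm, _ = toy_matrix(seed=1)
        vals = quantify_analyte(fm, {"analyte000": (1, 96)})
        block = fm.intensities[fm.analyte_index("analyte000")]
        np.testing.assert_allclose(vals.loc["analyte000"].to_numpy(), block.sum(axis=1))

    def test_band_captures_planted_gaussian_mass(self):
        fm, truth = toy_matrix(seed=2)
        bands = default_bands(truth, n_sigma=3.0)
        for analyte in fm.analytes:
            full = quantify_analyte(fm, {analyte: (1, 96)}).loc[analyte]
            band = quantify_analyte(fm, {analyte: bands[analyte]}).loc[analyte]
            assert (band / full > 0.99).all()

    def test_empty_window_rejected(self):
        fm, _ = toy_matrix()
        with pytest.raises(ValueError):
            quantify_analyte(fm, {fm.analytes[0]: (0, 5)})


class TestNormalizeToActin:
    def test_equal_to_actin_gives_zero(self):
        values = pd.DataFrame({"s1": [4.0], "s2": [8.0]}, index=["x"])
        actin = pd.Series({"s1": 4.0, "s2": 8.0})
        out = normalize_to_actin(values, actin)
        np.testing.assert_allclose(out.to_numpy(), 0.0)

    def test_doubling_adds_one_log2(self):
        values = pd.DataFrame({"s1": [4.0], "s2": [8.0]}, index=["x"])
        actin = pd.Series({"s1": 2.0, "s2": 2.0})
        out = normalize_to_actin(values, actin)
        assert out.loc["x", "s2"] - out.loc["x", "s1"] == pytest.approx(1.0)

    def test_round_trip(self):
        rng = np.random.default_rng(5)
        values = pd.DataFrame(rng.uniform(1, 100, size=(4, 6)),
                              index=list("wxyz"), columns=[f"s{i}" for i in range(6)])
        actin = pd.Series(rng.uniform(1, 10, size=6), index=values.columns)
        out = normalize_to_actin(values, actin)
        back = (2.0 ** out) * actin
        np.testing.assert_allclose(back.to_numpy(), values.to_numpy())

    def test_zero_handled_by_pseudo_floor(self):
        values = pd.DataFrame({"s1": [0.0], "s2": [8.0]}, index=["x"])
        actin = pd.Series({"s1": 2.0, "s2": 2.0})
        out = normalize_to_actin(values, actin)
        assert out.loc["x", "s1"] == pytest.approx(np.log2(4.0 / 2.0))  # floor = 8/2

    def test_nonpositive_actin_errors(self):
        values = pd.DataFrame({"s1": [1.0]}, index=["x"])
        with pytest.raises(ValueError):
            normalize_to_actin(values, pd.Series({"s1": 0.0}))


class TestPermutationAnova:
    def test_constant_analyte_f_zero_p_one(self):
        design = balanced_design()
        values = pd.DataFrame([np.full(12, 3.0)], index=["const"], columns=design.index)
        res = permutation_anova2(values, design["treatment"], design["celltype"], 200, seed=0)
        assert res.loc["const", "F_A"] == 0.0
        assert res.loc["const", "p_A"] == 1.0

    def test_planted_shift_saturates_p(self):
        # only treatment-partition-recreating permutations (~2 in 1000) can
        # match a saturated F, so p lands within a few floor units of 1/1001
        design = balanced_design()
        rng = np.random.default_rng(1)
        base = rng.normal(0, 1, 12)
        shift = np.where(design["treatment"] == "2i", 10.0 * base.std(), 0.0)
        values = pd.DataFrame([base + shift], index=["hit"], columns=design.index)
        res = permutation_anova2(values, design["treatment"], design["celltype"], 1000, seed=2)
        assert res.loc["hit", "p_A"] <= 6 / 1001

    def test_seed_determinism(self):
        design = balanced_design()
        rng = np.random.default_rng(3)
        values = pd.DataFrame(rng.normal(size=(5, 12)), columns=design.index,
                              index=[f"a{i}" for i in range(5)])
        r1 = permutation_anova2(values, design["treatment"], design["celltype"], 300, seed=9)
        r2 = permutation_anova2(values, design["treatment"], design["celltype"], 300, seed=9)
        pd.testing.assert_frame_equal(r1, r2)

    def test_affine_invariance_of_p(self):
        design = balanced_design()
        rng = np.random.default_rng(4)
        values = pd.DataFrame(rng.normal(size=(3, 12)), columns=design.index,
                              index=list("abc"))
        r1 = permutation_anova2(values, design["treatment"], design["celltype"], 300, seed=5)
        r2 = permutation_anova2(values * 7.0 - 2.0, design["treatment"], design["celltype"], 300, seed=5)
        np.testing.assert_allclose(r1[["F_A", "F_B", "F_AB"]], r2[["F_A", "F_B", "F_AB"]], rtol=1e-9)
        pd.testing.assert_frame_equal(r1[["p_A", "p_B", "p_AB"]], r2[["p_A", "p_B", "p_AB"]])

    def test_f_matches_statsmodels_on_balanced_design(self):
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        design = balanced_design()
        rng = np.random.default_rng(6)
        y = rng.normal(size=12)
        values = pd.DataFrame([y], index=["a"], columns=design.index)
        res = permutation_anova2(values, design["treatment"], design["celltype"], 100, seed=0)
        df = pd.DataFrame({"y": y, "t": design["treatment"].to_numpy(),
                           "c": design["celltype"].to_numpy()})
        tab = sm.stats.anova_lm(ols("y ~ C(t) * C(c)", data=df).fit(), typ=2)
        assert res.loc["a", "F_A"] == pytest.approx(tab.loc["C(t)", "F"])
        assert res.loc["a", "F_B"] == pytest.approx(tab.loc["C(c)", "F"])
        assert res.loc["a", "F_AB"] == pytest.approx(tab.loc["C(t):C(c)", "F"])

    def test_empty_cell_errors(self):
        design = balanced_design().iloc[2:]  # removes both serum/J1 replicates
        values = pd.DataFrame(np.zeros((1, len(design))), index=["a"], columns=design.index)
        with pytest.raises(ValueError, match="cell"):
            permutation_anova2(values, design["treatment"], design["celltype"], 100, seed=0)

    def test_pure_factor_b_effect_leaves_p_a_uniform(self):
        """With only a celltype effect planted, the treatment p-values stay
        uniform (empirical CDF within the DKW band)."""
        design = balanced_design()
        rng = np.random.default_rng(7)
        n_analytes = 200
        cell_shift = design["celltype"].map({"J1": 0.0, "TKO": 2.0, "3B3l": -2.0}).to_numpy()
        values = pd.DataFrame(
            rng.normal(size=(n_analytes, 12)) + cell_shift,
            columns=design.index, index=[f"a{i}" for i in range(n_analytes)],
        )
        res = permutation_anova2(values, design["treatment"], design["celltype"], 1000, seed=8)
        p = np.sort(res["p_A"].to_numpy())
        ecdf = np.arange(1, n_analytes + 1) / n_analytes
        dkw = np.sqrt(np.log(2 / 0.01) / (2 * n_analytes))
        assert np.max(np.abs(ecdf - p)) < dkw + 0.05


class TestClusterSignificant:
    def p_frame(self, names, ps):
        return pd.DataFrame({"p_A": ps, "p_B": 1.0, "p_AB": 1.0}, index=names)

    def test_identical_analytes_merge_at_zero(self):
        values = pd.DataFrame([[1.0, 2, 3], [1.0, 2, 3]], index=["x", "y"],
                              columns=["s1", "s2", "s3"])
        order, Z = cluster_significant(values, self.p_frame(["x", "y"], [0.001, 0.001]))
        assert Z[0, 2] == 0.0
        assert set(order) == {"x", "y"}

    def test_first_merge_joins_identical_pair(self):
        values = pd.DataFrame([[0.0, 0], [0.0, 0], [10.0, 10]], index=["a", "b", "c"],
                              columns=["s1", "s2"])
        order, Z = cluster_significant(values, self.p_frame(["a", "b", "c"], [0.001] * 3))
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}  # a and b merge first

    def test_no_significant_warns(self):
        values = pd.DataFrame([[1.0, 2]], index=["a"], columns=["s1", "s2"])
        with pytest.warns(UserWarning):
            order, Z = cluster_significant(values, self.p_frame(["a"], [0.5]))
        assert order == [] and Z is None
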