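import numpy as np
import pandas as pd
import pytest

from anuraprop import rmstats
from anuraprop.rmstats import (RmDesign, bonferroni_pairwise,
                               inverse_transform, mauchly_test, rm_anova,
                               transform_response)


def tidy_from_wide(y, codes, levels, names=("distance", "substrate",
                                            "locality")):
    """Tidy long frame from a subjects × cells array (cell order = product
    of levels, slowest first)."""
    rows = []
    grids = np.meshgrid(*[np.arange(k) for k in levels], indexing="ij")
    cells = np.stack([g.ravel() for g in grids], axis=1)
    for s in range(y.shape[0]):
        for c in range(y.shape[1]):
            row = {"subject": f"s{s:03d}", "group": f"g{codes[s]}",
                   "excess_attenuation": y[s, c]}
            for name, lev in zip(names, cells[c]):
                row[name] = f"{name[0]}{lev}"
            rows.append(row)
    return pd.DataFrame(rows)


class TestTransform:
    def test_all_positive_shiftless_log(self):
        v = np.array([1.0, 2.0, 4.0])
        out, info = transform_response(v - np.min(v) + 1.0, "shifted_log")
        # min maps to log(1)=0; a pure log up to the recorded shift
        assert out[0] == pytest.approx(0.0)

    def test_monotone_and_invertible(self):
        v = np.array([-7.0, -1.0, 0.0, 2.5, 11.0])
        for method in ("shifted_log", "identity", "linear_log"):
            out, info = transform_response(v, method)
            assert np.all(np.diff(out) > 0)
            assert np.allclose(inverse_transform(out, info), v, atol=1e-12)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            transform_response([1.0, np.nan])


class TestMauchly:
    def test_two_level_factor_vacuous(self):
        data = np.random.default_rng(0).standard_normal((10, 2))
        assert mauchly_test(data) == (1.0, 1.0)

    def test_matches_pingouin(self):
        """Independent cross-check on a plain one-within-factor design."""
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        wide = rng.standard_normal((15, 4)) @ np.diag([1.0, 1.5, 0.7, 1.2])
        w, p = mauchly_test(wide)
        ref = pingouin.sphericity(pd.DataFrame(wide))
        assert w == pytest.approx(ref.W, abs=1e-6)
        assert p == pytest.approx(ref.pval, abs=1e-6)

    def test_null_p_roughly_uniform(self):
        """Under compound symmetry the Mauchly p-value is approximately
        uniform (KS check at moderate rep count)."""
        from scipy import stats
        rng = np.random.default_rng(8)
        ps = [mauchly_test(rng.standard_normal((25, 4)))[1]
              for _ in range(300)]
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_autocorrelated_data_detected(self):
        """Strong AR(1)-style covariance across 4 levels gives small W and
        rejection at n = 30."""
        rng = np.random.default_rng(9)
        k, rho = 4, 0.95
        cov = rho ** np.abs(np.subtract.outer(np.arange(k), np.arange(k)))
        cov *= np.linspace(0.2, 3.0, k)[:, None] * np.linspace(0.2, 3.0, k)
        data = rng.multivariate_normal(np.zeros(k), cov, size=30)
        w, p = mauchly_test(data)
        assert w < 0.5 and p < 0.05


class TestRmAnova:
    def test_tone_design_df_structure(self):
        """29 tone subjects in 5 categories × (4 distances, 2 substrates,
        7 localities) reproduce the printed df pattern."""
        rng = np.random.default_rng(0)
        y, codes = rmstats.simulate_null_wide(rmstats.tone_design_groups(),
                                              (4, 2, 7), rng)
        t = rmstats._rm_anova_wide(
            y, codes, (4, 2, 7), between_name="frequency",
            within_names=("distance", "substrate", "locality"))
        dfs = t.set_index("effect")[["df_num", "df_den"]]
        assert tuple(dfs.loc["frequency"]) == (4, 24)
        assert tuple(dfs.loc["distance"]) == (3, 72)
        assert tuple(dfs.loc["substrate"]) == (1, 24)
        assert tuple(dfs.loc["locality"]) == (6, 144)
        assert tuple(dfs.loc["locality * frequency"]) == (24, 144)
        assert tuple(dfs.loc["distance * locality"]) == (18, 432)
        assert tuple(dfs.loc["distance * frequency"]) == (12, 72)

    def test_call_design_df_structure(self):
        """13 individuals in 2 species groups give the printed call-design
        pattern (species 1,11; distance 3,33; locality 6,66)."""
        rng = np.random.default_rng(1)
        y, codes = rmstats.simulate_null_wide([7, 6], (4, 2, 7), rng)
        t = rmstats._rm_anova_wide(
            y, codes, (4, 2, 7), between_name="species",
            within_names=("distance", "substrate", "locality"))
        dfs = t.set_index("effect")[["df_num", "df_den"]]
        assert tuple(dfs.loc["species"]) == (1, 11)
        assert tuple(dfs.loc["distance"]) == (3, 33)
        assert tuple(dfs.loc["locality"]) == (6, 66)

    def test_location_invariance(self):
        rng = np.random.default_rng(2)
        y, codes = rmstats.simulate_null_wide([4, 5], (3, 2), rng)
        t0 = rmstats._rm_anova_wide(y, codes, (3, 2),
                                    within_names=("w1", "w2"))
        t1 = rmstats._rm_anova_wide(y + 100.0, codes, (3, 2),
                                    within_names=("w1", "w2"))
        assert np.allclose(t0["F"], t1["F"])

    def test_matches_pingouin_one_within(self):
        """Single-group, one-within-factor case agrees with pingouin's
        rm_anova (F and uncorrected p)."""
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        wide = rng.standard_normal((12, 4)) + np.array([0, 0.3, 0.6, 0.9])
        t = rmstats._rm_anova_wide(wide, np.zeros(12, dtype=int), (4,),
                                   within_names=("w1",))
        long = pd.DataFrame({
            "subject": np.repeat(np.arange(12), 4),
            "w1": np.tile(np.arange(4), 12),
            "y": wide.ravel()})
        ref = pingouin.rm_anova(data=long, dv="y", within="w1",
                                subject="subject", correction=True)
        row = t[t["effect"] == "w1"].iloc[0]
        assert row["F"] == pytest.approx(ref["F"].iloc[0], rel=1e-6)
        assert row["p_uncorrected"] == pytest.approx(
            ref["p_unc"].iloc[0], rel=1e-6)
        assert row["epsilon_hf"] == pytest.approx(
            pingouin.epsilon(long.pivot(index="subject", columns="w1",
                                        values="y"), correction="hf"),
            abs=1e-6)

    def test_tidy_interface_matches_wide(self):
        rng = np.random.default_rng(4)
        y, codes = rmstats.simulate_null_wide([3, 4], (3, 2), rng)
        tidy = tidy_from_wide(y, codes, (3, 2), names=("distance",
                                                       "substrate"))
        design = RmDesign(subject="subject", between="group",
                          within=("distance", "substrate"))
        t_tidy = rm_anova(tidy, design)
        t_wide = rmstats._rm_anova_wide(y, codes, (3, 2),
                                        between_name="group",
                                        within_names=("distance",
                                                      "substrate"))
        merged = t_tidy.merge(t_wide, on="effect", suffixes=("_t", "_w"))
        assert np.allclose(merged["F_t"], merged["F_w"])

    def test_missing_cell_rejected(self):
        rng = np.random.default_rng(5)
        y, codes = rmstats.simulate_null_wide([3, 3], (3, 2), rng)
        tidy = tidy_from_wide(y, codes, (3, 2), names=("distance",
                                                       "substrate"))
        tidy = tidy[~((tidy["subject"] == "s000") &
                      (tidy["distance"] == "d0") &
                      (tidy["substrate"] == "s0"))]
        design = RmDesign(subject="subject", between="group",
                          within=("distance", "substrate"))
        with pytest.raises(ValueError, match="missing cells|incomplete"):
            rm_anova(tidy, design)

    def test_epsilon_decreases_with_sphericity_violation(self):
        """HF epsilon is 1 under compound symmetry and falls monotonically
        along an AR(1) family of increasing correlation decay."""
        rng = np.random.default_rng(6)
        k, n = 6, 60
        lags = np.abs(np.subtract.outer(np.arange(k), np.arange(k)))
        covs = [0.4 + 0.6 * np.eye(k)]  # compound symmetry: spherical
        covs += [rho ** lags for rho in (0.7, 0.95)]  # growing AR(1) decay
        eps_vals = []
        for cov in covs:
            y = rng.multivariate_normal(np.zeros(k), cov, size=n)
            t = rmstats._rm_anova_wide(y, np.zeros(n, dtype=int), (k,),
                                       within_names=("w1",))
            eps_vals.append(t[t["effect"] == "w1"]["epsilon_hf"].iloc[0])
        assert eps_vals[0] == pytest.approx(1.0, abs=0.05)
        assert eps_vals[0] > eps_vals[1] > eps_vals[2]

    def test_gg_flag_never_exceeds_hf(self):
        """Greenhouse–Geisser (opt-in) is at most as large as the default
        Huynh–Feldt epsilon, hence at least as conservative."""
        rng = np.random.default_rng(10)
        k, n = 5, 20
        cov = 0.9 ** np.abs(np.subtract.outer(np.arange(k), np.arange(k)))
        y = rng.multivariate_normal(np.zeros(k), cov, size=n)
        hf = rmstats._rm_anova_wide(y, np.zeros(n, dtype=int), (k,),
                                    within_names=("w1",))
        gg = rmstats._rm_anova_wide(y, np.zeros(n, dtype=int), (k,),
                                    within_names=("w1",), epsilon="gg")
        assert gg.iloc[-1]["epsilon_hf"] <= hf.iloc[-1]["epsilon_hf"] + 1e-12

    def test_power_against_injected_distance_effect(self):
        """A 2 dB/level distance effect at unit cell noise is detected
        (HF-corrected p < 0.01) in nearly every replicate."""
        rng = np.random.default_rng(7)
        levels = (4, 2, 7)
        grids = np.meshgrid(*[np.arange(k) for k in levels], indexing="ij")
        effect = 2.0 * grids[0].ravel().astype(float)
        hits = 0
        reps = 40
        for _ in range(reps):
            y, codes = rmstats.simulate_null_wide(
                rmstats.tone_design_groups(), levels, rng, effect=effect)
            t = rmstats._rm_anova_wide(y, codes, levels)
            if t[t["effect"] == "w1"]["p_hf"].iloc[0] < 0.01:
                hits += 1
        assert hits >= int(0.9 * reps)


class TestBonferroni:
    @staticmethod
    def _data(k=7, n=10, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for s in range(n):
            for lev in range(k):
                rows.append({"subject": s, "locality": f"L{lev}",
                             "excess_attenuation": rng.standard_normal()})
        return pd.DataFrame(rows)

    def test_pair_count(self):
        out = bonferroni_pairwise(self._data(), "locality")
        assert len(out) == 21  # C(7,2)
        assert (out["n_comparisons"] == 21).all()

    def test_correction_multiplies_and_caps(self):
        out = bonferroni_pairwise(self._data(), "locality")
        uncapped = out[out["p_raw"] * 21 < 1.0]
        assert np.allclose(uncapped["p_bonferroni"],
                           uncapped["p_raw"] * 21)
        assert (out["p_bonferroni"] <= 1.0).all()

    def test_single_level_rejected(self):
        df = self._data()
        with pytest.raises(ValueError):
            bonferroni_pairwise(df[df["locality"] == "L0"], "locality")
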