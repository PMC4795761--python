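"""Interspecific OLS fitting, AIC and model selection."""

import math

import numpy as np
import pandas as pd
import pytest

import beeallometry as ba
from beeallometry.fit import ModelSpec, aic_of, candidate_specs


def _means_frame(families, it, y, part="proboscis"):
    col = f"mean_{part}_mm"
    return pd.DataFrame(
        {
            "species": [f"sp{i}" for i in range(len(it))],
            "family": families,
            "n_specimens": 1,
            "mean_it_mm": it,
            col: y,
        }
    )


class TestFitOLS:
    def test_noise_free_interpolation_is_exact(self):
        cfg = ba.study_config(seed=3)
        cfg0 = ba.SyntheticConfig(
            true_coeffs=cfg.true_coeffs,
            it_range_by_family=cfg.it_range_by_family,
            n_species_by_family=cfg.n_species_by_family,
            sigma_log=0.0,
            seed=3,
        )
        means = ba.generate_interspecific(cfg0)
        fit = ba.fit_ols(means, ModelSpec("proboscis", "family", True, False))
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)
        c = ba.extract_coefficients(fit)
        for fam in ba.FAMILIES:
            assert c.a_by_family[fam] == pytest.approx(
                cfg.true_coeffs["proboscis"].a_by_family[fam], abs=1e-10
            )
        assert c.b == pytest.approx(0.96, abs=1e-10)

    def test_four_point_normal_equations_oracle(self):
        # IT-only model; oracle: explicit 2x2 normal equations on ln data
        it = np.array([1.0, 2.0, 3.0, 5.0])
        y = np.array([1.5, 2.2, 4.1, 6.3])
        x, ly = np.log(it), np.log(y)
        n = len(x)
        sx, sy_, sxx, sxy = x.sum(), ly.sum(), (x * x).sum(), (x * ly).sum()
        det = n * sxx - sx * sx
        slope_oracle = (n * sxy - sx * sy_) / det
        intercept_oracle = (sy_ * sxx - sx * sxy) / det
        df = _means_frame(["Apidae"] * 4, it, y)
        fit = ba.fit_ols(df, ModelSpec("proboscis", "none", True, False))
        assert fit.coefficients["ln_it"] == pytest.approx(slope_oracle, rel=1e-12)
        assert fit.coefficients["intercept"] == pytest.approx(intercept_oracle, rel=1e-12)

    def test_against_statsmodels(self, study_means_frame):
        sm = pytest.importorskip("statsmodels.api")
        df = study_means_frame
        fit = ba.fit_ols(df, ModelSpec("glossa", "family", True, True))
        # independent route: patsy-free design via pandas dummies
        X = pd.get_dummies(df["family"]).astype(float)
        lx = np.log(df["mean_it_mm"])
        for fam in X.columns:
            X[f"x_{fam}"] = X[fam] * lx
        res = sm.OLS(np.log(df["mean_glossa_mm"]), X).fit()
        assert fit.rss == pytest.approx(res.ssr, rel=1e-10)
        assert fit.r2 == pytest.approx(res.rsquared, rel=1e-10)
        for fam in ba.FAMILIES:
            assert fit.coefficients[f"intercept[{fam}]"] == pytest.approx(
                res.params[fam], rel=1e-9
            )
            assert fit.coefficients[f"ln_it[{fam}]"] == pytest.approx(
                res.params[f"x_{fam}"], rel=1e-9
            )

    def test_singular_design_names_group(self):
        # one Apidae species cannot support a family-specific slope
        df = _means_frame(
            ["Apidae"] + ["Halictidae"] * 5,
            [2.0, 1.0, 1.2, 1.5, 1.8, 2.2],
            [4.0, 1.5, 1.7, 2.1, 2.4, 2.9],
        )
        with pytest.raises(ValueError, match="Apidae"):
            ba.fit_ols(df, ModelSpec("proboscis", "family", True, True))

    def test_nested_models_r2_monotone(self, study_means_frame):
        # adding terms never decreases R^2
        order = [
            ModelSpec("proboscis", "none", True, False),
            ModelSpec("proboscis", "family", True, False),
            ModelSpec("proboscis", "family", True, True),
        ]
        r2s = [ba.fit_ols(study_means_frame, s).r2 for s in order]
        assert r2s[0] <= r2s[1] <= r2s[2]
        # same nesting chain for tongue type
        tt = [
            ModelSpec("proboscis", "tongue_type", False, False),
            ModelSpec("proboscis", "tongue_type", True, False),
            ModelSpec("proboscis", "tongue_type", True, True),
        ]
        r2t = [ba.fit_ols(study_means_frame, s).r2 for s in tt]
        assert r2t[0] <= r2t[1] <= r2t[2]


class TestAIC:
    def test_delta_two_for_equal_rss(self):
        f1 = ba.OLSFit(ModelSpec("proboscis", "none", True, False),
                       {}, n=50, k=2, rss=3.0, tss=10.0, aic=0.0)
        f2 = ba.OLSFit(ModelSpec("proboscis", "family", True, False),
                       {}, n=50, k=3, rss=3.0, tss=10.0, aic=0.0)
        assert aic_of(f2) - aic_of(f1) == pytest.approx(2.0)

    def test_direct_arithmetic(self):
        # n=10, rss=10, k=2: AIC = 10 ln(2 pi) + 10 ln(1) + 10 + 6
        f = ba.OLSFit(ModelSpec("proboscis", "none", True, False),
                      {}, n=10, k=2, rss=10.0, tss=20.0, aic=0.0)
        assert aic_of(f) == pytest.approx(10 * math.log(2 * math.pi) + 16, abs=1e-10)
        assert aic_of(f) == pytest.approx(34.379, abs=1e-3)

    def test_zero_rss_returns_neg_inf_with_warning(self):
        f = ba.OLSFit(ModelSpec("proboscis", "none", True, False),
                      {}, n=10, k=2, rss=0.0, tss=20.0, aic=0.0)
        with pytest.warns(RuntimeWarning):
            assert aic_of(f) == -math.inf

    def test_additive_structure_preferred_when_true(self):
        # simulated Family+IT truth: the additive model should win the AIC
        # comparison against the interaction model in most replicates
        base = ba.study_config(seed=0)
        wins = 0
        reps = 100
        for rep in range(reps):
            cfg = ba.SyntheticConfig(
                true_coeffs=base.true_coeffs,
                it_range_by_family=base.it_range_by_family,
                n_species_by_family=base.n_species_by_family,
                sigma_log=0.1,
                seed=20_000 + rep,
            )
            means = ba.generate_interspecific(cfg)
            add = ba.fit_ols(means, ModelSpec("proboscis", "family", True, False))
            inter = ba.fit_ols(means, ModelSpec("proboscis", "family", True, True))
            wins += add.aic < inter.aic
        assert wins / reps > 0.7


class TestModelSelection:
    def test_seven_candidates_per_response(self):
        for response in ba.PARTS:
            specs = candidate_specs(response)
            assert len(specs) == 7
            assert len({s.label for s in specs}) == 7

    def test_interaction_requires_grouping_and_it(self):
        with pytest.raises(ValueError):
            ModelSpec("proboscis", "none", True, True)
        with pytest.raises(ValueError):
            ModelSpec("proboscis", "family", False, True)

    def test_noise_free_truth_ranks_first(self):
        cfg = ba.study_config(seed=5)
        cfg0 = ba.SyntheticConfig(
            true_coeffs=cfg.true_coeffs,
            it_range_by_family=cfg.it_range_by_family,
            n_species_by_family=cfg.n_species_by_family,
            sigma_log=0.0,
            seed=5,
        )
        means = ba.generate_interspecific(cfg0)
        ranked = ba.model_selection(means, "proboscis")
        # both family models interpolate exactly; the tie breaks to fewer k
        assert ranked.iloc[0]["model"] == "Family + IT"

    def test_ranked_ascending_by_aic(self, study_means_frame):
        ranked = ba.model_selection(study_means_frame, "glossa")
        aics = ranked["aic"].to_numpy()
        assert np.all(np.diff(aics) >= 0)
        assert len(ranked) == 7

    def test_unfittable_candidates_reported_not_fatal(self):
        # 2 species per family cannot support the 10-parameter interaction
        df = _means_frame(
            ["Apidae", "Halictidae", "Apidae", "Halictidae"],
            [1.0, 1.2, 2.0, 2.4],
            [2.0, 1.5, 4.0, 3.2],
        )
        ranked = ba.model_selection(df, "proboscis")
        assert len(ranked) == 7
        failed = ranked[ranked["error"] != ""]
        assert len(failed) >= 1
        ok = ranked[ranked["error"] == ""]
        assert len(ok) >= 3


class TestExtractCoefficients:
    def test_exp_of_zero_intercept_is_one(self):
        fit = ba.OLSFit(
            ModelSpec("proboscis", "family", True, False),
            {**{f"intercept[{f}]": 0.0 for f in ba.FAMILIES}, "ln_it": 1.0},
            n=10, k=6, rss=1.0, tss=2.0, aic=0.0,
        )
        c = ba.extract_coefficients(fit)
        assert all(v == pytest.approx(1.0) for v in c.a_by_family.values())

    def test_rejects_non_family_grouping(self, study_means_frame):
        fit = ba.fit_ols(study_means_frame, ModelSpec("proboscis", "tongue_type", True, False))
        with pytest.raises(ValueError, match="Family"):
            ba.extract_coefficients(fit)
        fit2 = ba.fit_ols(study_means_frame, ModelSpec("proboscis", "family", False, False))
        with pytest.raises(ValueError):
            ba.extract_coefficients(fit2)

    def test_serialization_round_trip_into_predictor(self, study_means_frame, tmp_path):
        fit = ba.fit_ols(study_means_frame, ModelSpec("prementum", "family", True, True))
        c = ba.extract_coefficients(fit)
        p = tmp_path / "fitted.json"
        ba.save_coefficients(c, p)
        loaded = ba.load_coefficients(p, part="prementum")
        y, _ = ba.predict_part_length(2.0, "Apidae", "prementum", loaded)
        a, b = c.ab("Apidae")
        assert y == pytest.approx(a * 2.0**b, rel=1e-12)
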