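"""Binomial-logit fitting, Type-II LR tests, elimination, frame building."""

import numpy as np
import pandas as pd
import pytest

from phenoverlap.errors import AliasingError, ContractError, EmptySelectionError
from phenoverlap.field_data import NestRecord
from phenoverlap.glm import (
    ModelFrame,
    backward_eliminate,
    build_frames,
    contains,
    design_matrix,
    deviance_explained_gain,
    fit_binomial_logit,
    type2_lr_anova,
)
from phenoverlap.phenology import occurrence_window, overlap_table
from phenoverlap.synthetic import simulate_glm_dataset

CATS = {
    "host": ("A_io", "A_urticae"),
    "region": ("north", "south"),
    "year": ("2017", "2018"),
    "instar_class": ("1-2", "3", "4", "5"),
}


def frame_from(df, level="larva"):
    cats = {k: v for k, v in CATS.items() if k in df.columns}
    return ModelFrame(df, level, cats)


class TestFit:
    def test_intercept_only_half_successes(self):
        df = pd.DataFrame({"successes": [10], "trials": [20]})
        fit = fit_binomial_logit(frame_from(df), [])
        assert fit.coef("Intercept") == pytest.approx(0.0, abs=1e-10)

    def test_two_group_closed_form(self):
        df = pd.DataFrame({"host": ["A_io", "A_urticae"],
                           "successes": [2, 3], "trials": [4, 4]})
        fit = fit_binomial_logit(frame_from(df), ["host"])
        assert fit.coef("Intercept") == pytest.approx(0.0, abs=1e-8)
        assert fit.coef("host[A_urticae]") == pytest.approx(np.log(3), abs=1e-8)

    def test_quadratic_curvature_sign_on_dome_data(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(-2, 2, 400)
        eta = 0.5 - 0.8 * x ** 2
        succ = rng.binomial(20, 1 / (1 + np.exp(-eta)))
        df = pd.DataFrame({"x": x, "successes": succ, "trials": 20})
        fit = fit_binomial_logit(frame_from(df), ["x", "x^2"])
        assert fit.coef("x^2") < 0

    def test_fitted_successes_match_observed_with_intercept(self):
        df = simulate_glm_dataset(300, rng=1)
        fit = fit_binomial_logit(frame_from(df), ["host", "region", "week_c"])
        X, _ = design_matrix(frame_from(df), ["host", "region", "week_c"])
        eta = X.to_numpy() @ fit.table["coef"].to_numpy()
        fitted = df["trials"].to_numpy() / (1 + np.exp(-eta))
        assert (0 < fitted).all() and (fitted < df["trials"].to_numpy()).all()
        assert fitted.sum() == pytest.approx(df["successes"].sum(), rel=1e-6)

    def test_rank_deficiency_names_aliased_columns(self):
        df = simulate_glm_dataset(100, rng=2)
        df["week_copy"] = df["week_c"]
        with pytest.raises(AliasingError, match="week_copy"):
            fit_binomial_logit(frame_from(df), ["week_c", "week_copy"])

    def test_empty_frame_rejected(self):
        df = pd.DataFrame({"successes": [], "trials": []})
        with pytest.raises(EmptySelectionError):
            fit_binomial_logit(frame_from(df), [])


class TestMarginality:
    def test_contains_relation(self):
        assert contains("host:region", "host")
        assert contains("week_c^2", "week_c")
        assert not contains("host", "host")
        assert not contains("host:region", "year")
        assert not contains("week_c", "week_c^2")


class TestTypeTwoAnova:
    def test_all_zero_covariate_has_zero_lr(self):
        df = simulate_glm_dataset(400, rng=4)
        df["null_cov"] = 0.0
        fit = fit_binomial_logit(frame_from(df), ["host", "null_cov"])
        table = type2_lr_anova(fit, frame_from(df)).set_index("term")
        assert table.loc["null_cov", "lr_chisq"] == 0.0
        assert table.loc["null_cov", "p"] == 1.0

    def test_uninformative_covariate_small_lr(self):
        df = simulate_glm_dataset(400, rng=4)
        df["shuffled"] = np.random.default_rng(0).permutation(df["week_c"].to_numpy())
        fit = fit_binomial_logit(frame_from(df), ["host", "shuffled"])
        table = type2_lr_anova(fit, frame_from(df)).set_index("term")
        assert table.loc["shuffled", "lr_chisq"] < 7.0
        assert table.loc["shuffled", "p"] > 0.01

    def test_instar_class_has_three_df(self):
        df = simulate_glm_dataset(400, rng=5)
        fit = fit_binomial_logit(frame_from(df), ["host", "instar_class"])
        table = type2_lr_anova(fit, frame_from(df))
        assert int(table.set_index("term").loc["instar_class", "df"]) == 3

    def test_lr_equals_independent_double_fit(self):
        df = simulate_glm_dataset(300, rng=6)
        terms = ["host", "region", "week_c"]
        fit = fit_binomial_logit(frame_from(df), terms)
        table = type2_lr_anova(fit, frame_from(df)).set_index("term")
        without = fit_binomial_logit(frame_from(df), ["host", "region"])
        expected = 2 * (fit.llf - without.llf)
        assert table.loc["week_c", "lr_chisq"] == pytest.approx(expected, abs=1e-6)

    def test_main_effect_tested_without_its_interaction(self):
        df = simulate_glm_dataset(300, rng=7)
        terms = ["host", "region", "host:region"]
        fit = fit_binomial_logit(frame_from(df), terms)
        table = type2_lr_anova(fit, frame_from(df)).set_index("term")
        # manual Type-II comparison for 'host': both models exclude host:region
        m2 = fit_binomial_logit(frame_from(df), ["host", "region"])
        m1 = fit_binomial_logit(frame_from(df), ["region"])
        assert table.loc["host", "lr_chisq"] == pytest.approx(
            2 * (m2.llf - m1.llf), abs=1e-6)


class TestBackwardElimination:
    def test_generating_term_retained_noise_terms_dropped(self):
        df = simulate_glm_dataset(800, rng=8, host_effect=1.2, noise_covariates=2)
        result = backward_eliminate(
            frame_from(df), ["host", "noise1", "noise2", "host:noise1"])
        assert "host" in result.terms
        assert "noise2" not in result.terms

    def test_every_term_significant_is_fixed_point(self):
        df = simulate_glm_dataset(2000, rng=9, host_effect=1.5, year_effect=-1.0,
                                  region_effect=1.0, region_year_interaction=2.0)
        terms = ["host", "region", "year", "region:year"]
        result = backward_eliminate(frame_from(df), terms)
        assert set(result.terms) == set(terms)

    def test_marginality_respected_along_logged_path(self):
        rng = np.random.default_rng(10)
        for seed in range(5):
            df = simulate_glm_dataset(200, rng=rng)
            terms = ["host", "region", "year", "host:region", "region:year", "week_c",
                     "week_c^2"]
            result = backward_eliminate(frame_from(df), terms)
            retained = set(terms)
            for step in result.path:
                if step["dropped"] is None:
                    continue
                dropped = step["dropped"]
                assert not any(contains(t, dropped) for t in retained - {dropped})
                retained.discard(dropped)


class TestDevianceGain:
    def test_identity_gain_is_zero(self):
        df = simulate_glm_dataset(200, rng=11)
        fit = fit_binomial_logit(frame_from(df), ["host"])
        assert deviance_explained_gain(fit, fit) == 0.0

    def test_informative_augmentation_gains(self):
        df = simulate_glm_dataset(500, rng=12, artificial_effect=0.05)
        base = fit_binomial_logit(frame_from(df), ["host"])
        aug = fit_binomial_logit(frame_from(df), ["host", "artificial_100"])
        gain = deviance_explained_gain(base, aug)
        assert gain > 0
        assert gain == pytest.approx(aug.pseudo_r2 - base.pseudo_r2)

    def test_non_nested_rejected(self):
        df = simulate_glm_dataset(200, rng=13)
        a = fit_binomial_logit(frame_from(df), ["host"])
        b = fit_binomial_logit(frame_from(df), ["region"])
        with pytest.raises(ContractError):
            deviance_explained_gain(a, b)


def nest(site, year, week, host="A_urticae", n_par=0, region="south", instar=3):
    return NestRecord(site_id=site, region=region, year=year, week=week, host=host,
                      nest_id=f"{site}-{year}-{week}-{host}-{n_par}-{instar}",
                      instar=instar, n_larvae=10, n_parasitized=n_par)


class TestBuildFrames:
    def make_inputs(self):
        records = [
            # site A: parasitoid present, window weeks 3-5
            nest("A", 2017, 3, n_par=2),
            nest("A", 2017, 4, n_par=0),
            nest("A", 2017, 5, host="A_io", n_par=1),
            nest("A", 2017, 8, n_par=0),     # outside window
            # site B: parasitoid never observed in 2017
            nest("B", 2017, 4, n_par=0),
            # a non-native host is excluded regardless
            nest("A", 2017, 4, host="A_levana", n_par=0),
        ]
        overlaps = overlap_table(records)
        windows = occurrence_window(records)
        return records, overlaps, windows

    def test_unoccupied_site_excluded_from_nest_frame(self):
        records, overlaps, windows = self.make_inputs()
        nest_frame, _ = build_frames(records, overlaps, windows)
        assert "B" not in set(nest_frame.df["site_id"])

    def test_zero_parasitized_nest_only_in_nest_frame(self):
        records, overlaps, windows = self.make_inputs()
        nest_frame, larva_frame = build_frames(records, overlaps, windows)
        in_window_zero = nest_frame.df[nest_frame.df["n_parasitized"] == 0]
        assert len(in_window_zero) > 0
        assert (larva_frame.df["n_parasitized"] > 0).all()

    def test_row_counts_match_hand_enumeration(self):
        records, overlaps, windows = self.make_inputs()
        nest_frame, larva_frame = build_frames(records, overlaps, windows)
        # qualifying: site A native-host nests in weeks 3-5 -> 3 nests
        assert len(nest_frame.df) == 3
        assert len(larva_frame.df) == 2

    def test_include_unoccupied_sites_adds_absences(self):
        records, overlaps, windows = self.make_inputs()
        nest_frame, _ = build_frames(records, overlaps, windows,
                                     include_unoccupied_sites=True)
        # site B never hosted the parasitoid; its in-window nests enter as
        # absences with overlap zero by definition
        b_rows = nest_frame.df[nest_frame.df["site_id"] == "B"]
        assert len(b_rows) == 1
        assert (b_rows["successes"] == 0).all()
        assert (b_rows["oph"] == 0.0).all()

    def test_empty_selection_raises(self):
        records = [nest("A", 2017, 3, n_par=0)]
        with pytest.raises(EmptySelectionError):
            build_frames(records, [], {})

    def test_centering_constants_recorded(self):
        records, overlaps, windows = self.make_inputs()
        nest_frame, _ = build_frames(records, overlaps, windows)
        assert nest_frame.df["week_c"].mean() == pytest.approx(0.0, abs=1e-9)
        assert "week" in nest_frame.centers and "oph" in nest_frame.centers

    def test_simulation_site_filter(self, sim_study):
        records = sim_study.records
        overlaps = overlap_table(records)
        windows = occurrence_window(records)
        nest_frame, _ = build_frames(records, overlaps, windows)
        occupied = {(r.site_id, r.year) for r in records if r.n_parasitized > 0}
        frame_pairs = set(zip(nest_frame.df["site_id"],
                              nest_frame.df["year"].astype(int)))
        assert frame_pairs <= occupied
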