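import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from phylofunc.association import (
    BoostedLinearAssociation,
    adjust_global_bh,
    adjust_within_factor,
    bh_qvalues,
    boost_select,
    fit_feature_model,
)
from phylofunc.config import RunConfig
from phylofunc.containers import ValidationError

from conftest import make_feature_table, make_metadata


def noise_metadata(n, p, seed, prefix="X"):
    rng = np.random.default_rng(seed)
    cols = {f"{prefix}{i}": rng.normal(size=n) for i in range(p)}
    return make_metadata(cols, {k: "continuous" for k in cols}), cols


class TestBoostSelect:
    def test_planted_covariate_selected_across_seeds(self):
        # response = 0.5*X0 + N(0, 0.05) with 9 independent noise covariates
        n = 200
        hits = 0
        for seed in range(20):
            meta, cols = noise_metadata(n, 10, seed)
            rng = np.random.default_rng(1000 + seed)
            y = 0.5 * cols["X0"] + rng.normal(0, 0.05, n)
            sel = boost_select(y, meta, RunConfig(seed=seed))
            hits += "X0" in sel.selected
        assert hits >= 19

    def test_degenerate_threshold_selects_nothing(self):
        meta, _ = noise_metadata(50, 3, seed=0)
        rng = np.random.default_rng(0)
        sel = boost_select(
            rng.normal(size=50), meta, RunConfig(boost_selection_fraction=1.0)
        )
        assert sel.selected == []

    def test_deterministic_given_seed(self):
        meta, cols = noise_metadata(60, 4, seed=2)
        y = cols["X1"] * 0.2
        a = boost_select(y, meta, RunConfig(seed=9))
        b = boost_select(y, meta, RunConfig(seed=9))
        pd.testing.assert_series_equal(a.fractions, b.fractions)
        assert a.selected == b.selected

    def test_fractions_are_valid_and_consistent_with_flag(self):
        meta, cols = noise_metadata(80, 5, seed=3)
        sel = boost_select(cols["X0"] * 0.3, meta, RunConfig(seed=3))
        assert ((sel.fractions >= 0) & (sel.fractions <= 1)).all()
        assert set(sel.selected) == set(
            sel.fractions.index[sel.fractions >= sel.threshold]
        )

    def test_agrees_with_sklearn_booster_on_planted_signal(self):
        """Independent cross-check: sklearn's gradient booster with the
        same hyperparameters attributes the bulk of its splits to the
        same planted covariate."""
        from sklearn.ensemble import GradientBoostingRegressor

        n = 200
        meta, cols = noise_metadata(n, 8, seed=4)
        rng = np.random.default_rng(4)
        y = 0.4 * cols["X2"] + rng.normal(0, 0.1, n)
        sel = boost_select(y, meta, RunConfig(seed=4))
        X = np.column_stack([cols[f"X{i}"] for i in range(8)])
        gb = GradientBoostingRegressor(
            n_estimators=1000, max_depth=1, learning_rate=0.01,
            subsample=0.5, random_state=4,
        ).fit(X, y)
        sk_counts = np.bincount(
            [t[0].tree_.feature[0] for t in gb.estimators_], minlength=8
        )
        assert sel.fractions.idxmax() == "X2"
        assert int(np.argmax(sk_counts)) == 2
        # both attribute a clear majority of splits to the signal
        assert sel.fractions["X2"] > 0.5 and sk_counts[2] / 1000 > 0.5

    def test_categorical_dummies_pooled_per_metadatum(self):
        rng = np.random.default_rng(5)
        n = 120
        group = rng.choice(["a", "b", "c"], n)
        meta = make_metadata(
            {"group": group, "noise": rng.normal(size=n)},
            {"group": "categorical", "noise": "continuous"},
        )
        y = (group == "b") * 0.5 + rng.normal(0, 0.05, n)
        sel = boost_select(y, meta, RunConfig(seed=5))
        assert sel.fractions.index.tolist() == ["group", "noise"]
        # the factor's dummies pool into one clearly-selected covariate
        assert "group" in sel.selected
        assert sel.fractions["group"] > 0.2

    def test_requires_metadata_and_enough_samples(self):
        meta, cols = noise_metadata(5, 2, seed=0)
        with pytest.raises(ValidationError, match="10 samples"):
            boost_select(np.zeros(5), meta, RunConfig())


class TestLinearModel:
    def test_noiseless_recovery(self):
        n = 50
        meta, cols = noise_metadata(n, 2, seed=1)
        y = 0.7 + 0.3 * cols["X0"]
        records = fit_feature_model(y, meta, ["X0"], feature="f")
        (rec,) = records
        assert rec["coefficient"] == pytest.approx(0.3, abs=1e-8)
        assert rec["p"] < 1e-12
        assert rec["n"] == n

    def test_binary_metadatum_equals_group_mean_difference(self):
        rng = np.random.default_rng(2)
        n = 40
        group = np.array(["yes"] * 15 + ["no"] * 25)
        y = rng.normal(size=n)
        meta = make_metadata({"flag": group}, {"flag": "categorical"})
        (rec,) = fit_feature_model(y, meta, ["flag"], feature="f")
        # reference = most frequent level ("no"); coefficient = mean(yes) - mean(no)
        assert rec["level"] == "yes" and rec["reference"] == "no"
        expected = y[group == "yes"].mean() - y[group == "no"].mean()
        assert rec["coefficient"] == pytest.approx(expected, abs=1e-12)

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(3)
        n = 400
        pvals = []
        for _ in range(200):
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            meta = make_metadata({"X0": x}, {"X0": "continuous"})
            pvals.append(fit_feature_model(y, meta, ["X0"])[0]["p"])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_aliased_column_dropped_with_warning(self, caplog):
        rng = np.random.default_rng(4)
        x = rng.normal(size=30)
        meta = make_metadata(
            {"X0": x, "X0copy": x.copy()}, {"X0": "continuous", "X0copy": "continuous"}
        )
        with caplog.at_level("WARNING"):
            records = fit_feature_model(x * 0.2, meta, ["X0", "X0copy"])
        assert len(records) == 1
        assert "aliased" in caplog.text

    def test_more_parameters_than_samples_raises(self):
        meta, cols = noise_metadata(4, 5, seed=0)
        with pytest.raises(ValidationError, match="parameters"):
            fit_feature_model(np.zeros(4), meta, [f"X{i}" for i in range(5)])

    def test_nothing_selected_raises(self):
        meta, _ = noise_metadata(20, 1, seed=0)
        with pytest.raises(ValidationError, match="nothing to fit"):
            fit_feature_model(np.zeros(20), meta, [])


class TestAdjustments:
    def records(self, ps, metadatum="m", levels=None):
        return [
            {"feature": "f", "metadatum": metadatum,
             "level": (levels[i] if levels else ""), "p": p}
            for i, p in enumerate(ps)
        ]

    def test_bonferroni_multiplies_by_level_count(self):
        recs = adjust_within_factor(self.records([0.02, 0.5, 0.9], levels="abc"))
        assert recs[0]["p_adj"] == pytest.approx(0.06)
        assert recs[1]["p_adj"] == 1.0  # 1.5 capped

    def test_continuous_single_record_unchanged(self):
        (rec,) = adjust_within_factor(self.records([0.04]))
        assert rec["p_adj"] == pytest.approx(0.04)

    def test_bh_step_up_example(self):
        assert bh_qvalues([0.01, 0.02, 0.03, 0.04]).tolist() == pytest.approx(
            [0.04, 0.04, 0.04, 0.04]
        )

    def test_bh_single_and_degenerate(self):
        assert bh_qvalues([0.2]).tolist() == [0.2]
        assert bh_qvalues([1.0, 1.0, 1.0]).tolist() == [1.0, 1.0, 1.0]

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=60))
    def test_bh_matches_statsmodels_and_is_monotone(self, pvals):
        from statsmodels.stats.multitest import multipletests

        q = bh_qvalues(pvals)
        _, q_sm, _, _ = multipletests(pvals, method="fdr_bh")
        assert np.allclose(q, q_sm, atol=1e-12)
        order = np.argsort(pvals, kind="mergesort")
        assert (np.diff(q[order]) >= -1e-12).all()
        assert (q >= np.asarray(pvals) - 1e-12).all()

    def test_global_bh_attaches_q(self):
        recs = adjust_within_factor(self.records([0.01, 0.5]))
        recs = adjust_global_bh(recs)
        assert all("q" in r and r["q"] >= r["p_adj"] - 1e-12 for r in recs)


class TestAssociateAll:
    def planted_dataset(self, seed, n=150, n_features=12, beta=0.4):
        from phylofunc.synth import (
            PlantedEffect,
            generate_communities,
            generate_metadata,
        )

        from phylofunc.qc import impute

        meta = generate_metadata(n, seed=seed)
        table, truth = generate_communities(
            meta, n_features,
            [PlantedEffect(f"T{n_features // 2:04d}", "disease", beta, "UC")],
            seed=seed,
        )
        table, meta, _ = impute(table, meta)
        return table, meta, truth

    def test_planted_feature_found_and_determinism(self):
        table, meta, truth = self.planted_dataset(seed=21)
        config = RunConfig(seed=21, boost_n_estimators=300)
        est1 = BoostedLinearAssociation(config=config).fit(table, meta)
        est2 = BoostedLinearAssociation(config=config).fit(table, meta)
        pd.testing.assert_frame_equal(est1.results_, est2.results_)
        planted = truth.effects[0].feature
        sub = est1.results_.query("feature == @planted and metadatum == 'disease'")
        assert (sub["q"] < 0.25).any()

    def test_summary_counts_match_results(self):
        table, meta, _ = self.planted_dataset(seed=22)
        config = RunConfig(seed=22, boost_n_estimators=200)
        est = BoostedLinearAssociation(config=config).fit(table, meta)
        row = est.summary_.iloc[0]
        sig = est.results_[est.results_["q"] < config.q_threshold]["feature"].nunique()
        assert row["n_significant"] == sig
        assert row["feature_kind"] == "taxon"

    def test_removing_unrelated_metadatum_keeps_planted_selection(self):
        table, meta, truth = self.planted_dataset(seed=23)
        config = RunConfig(seed=23, boost_n_estimators=300)
        planted = truth.effects[0].feature
        est_full = BoostedLinearAssociation(config=config).fit(table, meta)
        reduced = meta.subset([n for n in meta.names if n != "smoking"])
        est_red = BoostedLinearAssociation(config=config).fit(table, reduced)
        f_full = est_full.selections_.loc[planted, "disease"]
        f_red = est_red.selections_.loc[planted, "disease"]
        assert f_full >= config.boost_selection_fraction
        assert f_red >= config.boost_selection_fraction
        assert abs(f_full - f_red) < 0.2  # boosting stochasticity only

    def test_planted_coefficient_recovered_within_two_se(self):
        """The planted group shift on the latent arcsine scale is the
        model's own coefficient; nominal ~95% coverage of the 2-SE band
        must hold across replicates where disease is selected (with a
        3-SD binomial allowance for the Monte Carlo sample size)."""
        from phylofunc.synth import (
            PlantedEffect,
            generate_communities,
            generate_metadata,
        )
        from phylofunc.qc import impute

        beta = 0.25
        ok = 0
        total = 0
        for seed in range(100):
            meta = generate_metadata(120, seed=seed)
            table, truth = generate_communities(
                meta, 6, [PlantedEffect("T0002", "disease", beta, "UC")],
                seed=seed, noise_sd=0.05,
            )
            table, meta, _ = impute(table, meta)
            # latent arcsine-scale response: the generative model itself,
            # free of the [0, pi/2] truncation of realized abundances
            y = truth.arcsine_values["T0002"].to_numpy()
            config = RunConfig(seed=seed, boost_n_estimators=300)
            sel = boost_select(y, meta, config)
            if "disease" not in sel.selected:
                continue
            total += 1
            recs = fit_feature_model(y, meta, sel.selected, feature="T0002")
            cd = [r for r in recs if r["metadatum"] == "disease" and r["level"] == "UC"]
            if not cd:  # UC happens to be the reference level in this replicate
                total -= 1
                continue
            if abs(cd[0]["coefficient"] - beta) <= 2 * cd[0]["stderr"]:
                ok += 1
        assert total >= 50
        # target coverage 0.95, minus 3 binomial SD at the realized n
        slack = 3 * (0.95 * 0.05 / total) ** 0.5
        assert ok / total >= 0.95 - slack
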