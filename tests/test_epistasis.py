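import itertools

import numpy as np
import pandas as pd
import pytest

from galswitch.epistasis import (ClassMeanGrowthModel,
                                 MultiplicativeNullModel,
                                 blinded_parameter_count, class_key,
                                 design_accounting, downsample_cv,
                                 fit_class_model, multiplicative_expectation,
                                 predict_and_score, propagate_se,
                                 variance_explained)
from galswitch.synthetic import ADMISSIBLE_CLASSES, broaden_class


class TestMultiplicative:
    def test_identity_mutant(self):
        # one single equal to WT leaves the other single's rate unchanged
        res = multiplicative_expectation(0.12, 0.0, 0.20, 0.0, 0.20, 0.0)
        assert res["mu_pred"] == pytest.approx(0.12)

    def test_closed_form(self):
        res = multiplicative_expectation(0.12, 0.0, 0.15, 0.0, 0.20, 0.0)
        assert res["mu_pred"] == pytest.approx(0.09)

    def test_symmetry(self):
        a = multiplicative_expectation(0.12, 0.01, 0.15, 0.02, 0.20, 0.01,
                                       background=0.02)
        b = multiplicative_expectation(0.15, 0.02, 0.12, 0.01, 0.20, 0.01,
                                       background=0.02)
        assert a == b

    def test_background_subtraction_and_readdition(self):
        bg = 0.02
        res = multiplicative_expectation(0.12, 0.0, 0.20, 0.0, 0.20, 0.0,
                                         background=bg)
        expected = (0.12 - bg) * (0.20 - bg) / (0.20 - bg) + bg
        assert res["mu_pred"] == pytest.approx(expected)

    def test_wt_equal_background_flagged(self):
        res = multiplicative_expectation(0.1, 0.0, 0.1, 0.0, 0.02, 0.0,
                                         background=0.02)
        assert res["flagged"] and np.isnan(res["mu_pred"])


class TestSEPropagation:
    def test_error_free_limit_is_zero(self):
        assert propagate_se(0.09, 0.12, 0.0, 0.15, 0.0, 0.20, 0.0, 2) == 0.0
        assert propagate_se(0.09, 0.12, 0.0, 0.15, 0.0, 0.20, 0.0, 2,
                            mode="as_printed") == 0.0

    def test_as_printed_wt_term_vanishes_at_n1(self):
        # the (N-1) coefficient removes the WT term when N = 1
        with_wt = propagate_se(0.09, 0.12, 0.001, 0.15, 0.002, 0.20, 0.5, 1,
                               mode="as_printed")
        without = propagate_se(0.09, 0.12, 0.001, 0.15, 0.002, 0.20, 0.0, 1,
                               mode="as_printed")
        assert with_wt == pytest.approx(without)

    def test_corrected_matches_monte_carlo(self):
        """First-order propagation vs the SD of 1e5 draws of
        mu1*mu2/mu_wt under independent normal errors."""
        m1, s1, m2, s2, mw, sw = 0.12, 0.006, 0.15, 0.007, 0.20, 0.008
        rng = np.random.default_rng(0)
        n = 100000
        draws = (rng.normal(m1, s1, n) * rng.normal(m2, s2, n)
                 / rng.normal(mw, sw, n))
        mc_sd = draws.std()
        se = propagate_se(m1 * m2 / mw, m1, s1, m2, s2, mw, sw, 2)
        assert abs(se - mc_sd) / mc_sd <= 0.15

    def test_zero_denominator_undefined(self):
        assert np.isnan(propagate_se(0.1, 0.0, 0.01, 0.1, 0.01, 0.2,
                                     0.01, 2))


def _planted_doubles(sigma=0.02, seed=0, n_per_cell=40):
    """Doubles whose growth is pure class-combination structure + noise."""
    rng = np.random.default_rng(seed)
    pairs = [("GAL3", "GAL80"), ("GAL3", "GAL4"), ("GAL80", "GAL4")]
    rows = []
    key_means = {}
    for l1, l2 in pairs:
        for c1 in ADMISSIBLE_CLASSES[l1]:
            for c2 in ADMISSIBLE_CLASSES[l2]:
                key = class_key(l1, c1, l2, c2)
                key_means.setdefault(key, rng.uniform(0.02, 0.32))
                for i in range(n_per_cell):
                    j, k = i % 6, (i // 6) % 6  # cover the allele grid
                    rows.append(dict(
                        genotype_id=f"{l1}.{c1}.{i}+{l2}.{c2}.{i}",
                        locus1=l1, allele1=f"{l1}.{c1}.a{j}", class1=c1,
                        locus2=l2, allele2=f"{l2}.{c2}.a{k}", class2=c2,
                        mu=key_means[key] + rng.normal(0, sigma),
                        n_rep=2))
    return pd.DataFrame(rows), key_means


class TestClassMeanModel:
    def test_training_prediction_equals_group_means_oracle(self):
        doubles, _ = _planted_doubles()
        model = fit_class_model(doubles)
        # brute-force oracle: group means computed independently
        keys = [class_key(r["locus1"], r["class1"], r["locus2"],
                          r["class2"]) for _, r in doubles.iterrows()]
        oracle = {}
        for k, mu in zip(keys, doubles["mu"]):
            oracle.setdefault(k, []).append(mu)
        oracle = {k: np.mean(v) for k, v in oracle.items()}
        pred = model.predict(doubles)
        np.testing.assert_allclose(pred, [oracle[k] for k in keys],
                                   rtol=1e-12)

    def test_training_ve_equals_anova_between_share(self):
        """On training data the class-mean model's variance explained is
        exactly the between-group share of a one-way decomposition."""
        doubles, _ = _planted_doubles()
        model = fit_class_model(doubles)
        ve = predict_and_score(model, doubles).variance_explained
        keys = [class_key(r["locus1"], r["class1"], r["locus2"],
                          r["class2"]) for _, r in doubles.iterrows()]
        df = pd.DataFrame({"k": keys, "mu": doubles["mu"].to_numpy()})
        grand = df["mu"].mean()
        between = sum(len(g) * (g["mu"].mean() - grand) ** 2
                      for _, g in df.groupby("k"))
        total = ((df["mu"] - grand) ** 2).sum()
        assert ve == pytest.approx(between / total, abs=1e-12)

    def test_planted_variance_recovery(self):
        """VE ~ 1 - sigma^2/Var(mu) for planted class-mean structure."""
        sigma = 0.02
        doubles, _ = _planted_doubles(sigma=sigma, seed=3, n_per_cell=80)
        model = fit_class_model(doubles)
        ve = predict_and_score(model, doubles).variance_explained
        expected = 1.0 - sigma ** 2 / doubles["mu"].var(ddof=0)
        assert ve == pytest.approx(expected, abs=0.03)

    def test_uncovered_key_falls_back_to_grand_mean(self):
        doubles, _ = _planted_doubles(n_per_cell=5)
        train = doubles[doubles["class1"] != "Uninducible"]
        model = fit_class_model(train)
        test = doubles[doubles["class1"] == "Uninducible"]
        out = model.predict_df(test)
        assert (~out["covered"]).any()
        uncov = out[~out["covered"]]
        np.testing.assert_allclose(uncov["mu_pred"], model.grand_mean_)

    def test_locus_aware_key_coarsens_to_unique_blinded_key(self):
        """Surjection: every locus-aware key maps to exactly one
        locus-blinded key."""
        pairs = [("GAL3", "GAL80"), ("GAL3", "GAL4"), ("GAL80", "GAL4")]
        mapping = {}
        for l1, l2 in pairs:
            for c1 in ADMISSIBLE_CLASSES[l1]:
                for c2 in ADMISSIBLE_CLASSES[l2]:
                    aware = class_key(l1, c1, l2, c2, locus_aware=True)
                    blind = class_key(l1, c1, l2, c2, locus_aware=False)
                    assert mapping.setdefault(aware, blind) == blind

    def test_missing_class_rows_excluded(self):
        doubles, _ = _planted_doubles(n_per_cell=3)
        doubles.loc[doubles.index[:5], "class1"] = None
        model = fit_class_model(doubles)
        assert model.n_excluded_ == 5


class TestScoring:
    def test_perfect_predictions_score_one(self):
        obs = np.array([0.1, 0.2, 0.3])
        assert variance_explained(obs, obs) == 1.0

    def test_grand_mean_scores_zero(self):
        obs = np.array([0.1, 0.2, 0.3])
        assert variance_explained(obs, np.full(3, obs.mean())) == \
            pytest.approx(0.0, abs=1e-12)

    def test_empty_input_rejected(self):
        model = ClassMeanGrowthModel()
        with pytest.raises(ValueError):
            predict_and_score(model, pd.DataFrame(columns=["mu"]))


class TestPipelineCounts:
    def test_full_synthetic_parameter_counts(self, small_run):
        """On the full synthetic design the four model variants recover
        the combinatorial parameter counts: 23/14 locus-aware, 13/6
        blinded."""
        n = small_run["stages"]["predict"]["n_parameters"]
        assert n["classmean_intermediate5_locus_aware"] == 23
        assert n["classmean_broad3_locus_aware"] == 14
        assert n["classmean_intermediate5_blinded"] == 13
        assert n["classmean_broad3_blinded"] == 6

    def test_class_model_beats_multiplicative_on_class_driven_data(
            self, small_run):
        ve = small_run["stages"]["predict"]["variance_explained"]
        assert (ve["classmean_intermediate5_locus_aware"]
                > ve["multiplicative"])


class TestDownsampleCV:
    def test_full_k_equals_full_fit(self):
        doubles, _ = _planted_doubles(n_per_cell=36)
        model = fit_class_model(doubles)
        full_ve = predict_and_score(model, doubles).variance_explained
        cv = downsample_cv(doubles, k_alleles_per_class=6, iterations=10,
                           seed=0)
        assert cv["median"] == pytest.approx(full_ve)

    def test_deterministic_under_seed(self):
        doubles, _ = _planted_doubles(n_per_cell=12)
        a = downsample_cv(doubles, 1, iterations=20, seed=5)
        b = downsample_cv(doubles, 1, iterations=20, seed=5)
        assert a["median"] == b["median"]
        np.testing.assert_array_equal(a["scores"], b["scores"])

    def test_planted_structure_holds_up_at_k1(self):
        """With pure class-mean structure, one allele per class suffices:
        held-out VE stays close to the full fit."""
        doubles, _ = _planted_doubles(sigma=0.02, seed=7, n_per_cell=72)
        model = fit_class_model(doubles)
        full_ve = predict_and_score(model, doubles).variance_explained
        cv = downsample_cv(doubles, 1, iterations=200, seed=1)
        assert abs(cv["median"] - full_ve) <= 0.05

    def test_small_class_rejected_by_name(self):
        doubles, _ = _planted_doubles(n_per_cell=3)
        with pytest.raises(ValueError, match="class group"):
            downsample_cv(doubles, 10, iterations=2, seed=0)


class TestDesignAccounting:
    @pytest.mark.parametrize("scheme,possible,excluded,realizable", [
        ("intermediate5", 32, 9, 23),
        ("broad3", 18, 4, 14),
    ])
    def test_scheme_counts(self, scheme, possible, excluded, realizable):
        acc = design_accounting(scheme)
        assert acc == {"possible": possible, "excluded": excluded,
                       "realizable": realizable}

    def test_matches_independent_enumeration(self):
        """Brute-force loop with the constraint predicate as the oracle."""
        for scheme in ("intermediate5", "broad3"):
            if scheme == "intermediate5":
                sets = {l: ADMISSIBLE_CLASSES[l] for l in ADMISSIBLE_CLASSES}
            else:
                sets = {l: sorted({broaden_class(c)
                                   for c in ADMISSIBLE_CLASSES[l]})
                        for l in ADMISSIBLE_CLASSES}
            triples = list(itertools.product(sets["GAL3"], sets["GAL80"],
                                             sets["GAL4"]))
            unreachable = [
                (c3, c80, c4) for c3, c80, c4 in triples
                if c3 == "Uninducible" and c80 != "Inducible"
                and c4 != "Inducible"]
            acc = design_accounting(scheme)
            assert acc["possible"] == len(triples)
            assert acc["excluded"] == len(unreachable)
            assert acc["realizable"] == len(triples) - len(unreachable)

    def test_singleton_class_sets(self):
        sets = {"GAL3": ("Inducible",), "GAL80": ("Inducible",),
                "GAL4": ("Inducible",)}
        acc = design_accounting(class_sets=sets)
        assert acc == {"possible": 1, "excluded": 0, "realizable": 1}

    def test_empty_class_set_rejected(self):
        with pytest.raises(ValueError):
            design_accounting(class_sets={"GAL3": (), "GAL80": ("I",),
                                          "GAL4": ("I",)})

    def test_blinded_parameter_count_broad(self):
        assert blinded_parameter_count("broad3") == 6


class TestMultiplicativeModelEstimator:
    def test_fit_predict_roundtrip(self):
        singles = pd.DataFrame([
            dict(allele="WT", mu=0.30, se_mu=0.005, n_rep=4),
            dict(allele="A", mu=0.20, se_mu=0.004, n_rep=2),
            dict(allele="B", mu=0.25, se_mu=0.004, n_rep=2),
        ])
        doubles = pd.DataFrame([dict(genotype_id="A+B", allele1="A",
                                     allele2="B", n_rep=2)])
        est = MultiplicativeNullModel(background=0.02).fit(singles)
        out = est.predict_df(doubles)
        expected = (0.20 - 0.02) * (0.25 - 0.02) / (0.30 - 0.02) + 0.02
        assert out["mu_pred"].iloc[0] == pytest.approx(expected)
        assert out["se"].iloc[0] > 0

    def test_wt_required(self):
        singles = pd.DataFrame([dict(allele="A", mu=0.2, se_mu=0.01)])
        with pytest.raises(ValueError, match="WT"):
            MultiplicativeNullModel().fit(singles)
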