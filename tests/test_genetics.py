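import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from leafspec.errors import DegenerateDataError, InvalidParameterError
from leafspec.genetics import (
    PairCovariance,
    VarianceComponents,
    breeding_values,
    fit_pair_covariance,
    fit_univariate_reml,
    genetic_correlation,
    heritability,
    jackknife_se,
    phenotypic_correlation,
    realized_gain,
    select_families,
    summarize_genetics,
)
from leafspec.simulate import TraitParams, make_design, simulate_traits


def _vc(s2f, s2e, trait="t"):
    return VarianceComponents(trait, s2f, s2e, 50, 30.0, 0.0)


class TestREML:
    def test_matches_balanced_anova_oracle(self):
        design = make_design(25, 4, 3)
        tr = simulate_traits(design, TraitParams(), seed=50)
        y = tr["anth"].to_numpy()
        fam = tr["family_id"].to_numpy()
        rep = tr["replication_id"].to_numpy()
        vc = fit_univariate_reml(y, fam, rep)

        F, R, T = 25, 4, 3
        ybar = y.mean()
        fm = pd.Series(y).groupby(fam).mean()
        rm = pd.Series(y).groupby(rep).mean()
        ss_fam = R * T * ((fm - ybar) ** 2).sum()
        ss_rep = F * T * ((rm - ybar) ** 2).sum()
        ss_err = ((y - ybar) ** 2).sum() - ss_fam - ss_rep
        ms_fam = ss_fam / (F - 1)
        ms_err = ss_err / (len(y) - F - R + 1)
        assert vc.sigma2_f == pytest.approx(max(0.0, (ms_fam - ms_err) / (R * T)),
                                            abs=1e-4)
        assert vc.sigma2_e == pytest.approx(ms_err, abs=1e-4)

    def test_matches_statsmodels_mixedlm(self):
        smf = pytest.importorskip("statsmodels.formula.api")
        design = make_design(15, 3, 3)
        tr = simulate_traits(design, TraitParams(), seed=51)
        vc = fit_univariate_reml(tr["flav"], tr["family_id"], tr["replication_id"])
        df = tr.assign(rep=tr["replication_id"].astype(str))
        ref = smf.mixedlm("flav ~ C(rep)", df, groups=df["family_id"]).fit(reml=True)
        assert vc.sigma2_f == pytest.approx(float(ref.cov_re.iloc[0, 0]), abs=2e-3)
        assert vc.sigma2_e == pytest.approx(float(ref.scale), abs=2e-3)

    def test_null_family_signal_estimates_near_zero(self):
        design = make_design(40, 2, 10)
        tr = simulate_traits(design, TraitParams(cov_f=np.zeros((3, 3))), seed=52)
        vc = fit_univariate_reml(tr["anth"], tr["family_id"], tr["replication_id"])
        assert vc.sigma2_f < 0.05
        assert vc.sigma2_f >= 0.0  # floored, flagged when truncated

    def test_single_family_rejected(self):
        with pytest.raises(InvalidParameterError):
            fit_univariate_reml([1.0, 2.0, 3.0], [1, 1, 1], None)

    def test_unbalanced_data_accepted(self):
        design = make_design(10, 2, 4)
        tr = simulate_traits(design, TraitParams(), seed=53)
        sub = tr.iloc[: len(tr) - 17]
        vc = fit_univariate_reml(sub["nbi"], sub["family_id"], sub["replication_id"])
        assert vc.sigma2_e > 0


class TestPairCovariance:
    def test_self_covariance_equals_variance(self):
        design = make_design(20, 3, 4)
        tr = simulate_traits(design, TraitParams(), seed=54)
        vc = fit_univariate_reml(tr["anth"], tr["family_id"], tr["replication_id"])
        pc = fit_pair_covariance(tr["anth"], tr["anth"], tr["family_id"],
                                 tr["replication_id"])
        assert pc.cov_f == pytest.approx(vc.sigma2_f, abs=1e-6)
        assert pc.cov_e == pytest.approx(vc.sigma2_e, abs=1e-6)

    def test_independent_traits_have_null_family_covariance(self):
        params = TraitParams(cov_f=np.diag([0.3, 0.3, 0.3]),
                             cov_e=np.diag([0.7, 0.7, 0.7]))
        design = make_design(20, 1, 10)
        covs = []
        for s in range(200):
            tr = simulate_traits(design, params, seed=600 + s)
            pc = fit_pair_covariance(tr["anth"], tr["flav"], tr["family_id"])
            covs.append(pc.cov_f)
        covs = np.asarray(covs)
        se = covs.std(ddof=1) / np.sqrt(len(covs))
        assert abs(covs.mean()) <= 2 * se

    def test_length_mismatch_rejected(self):
        with pytest.raises(InvalidParameterError):
            fit_pair_covariance([1.0, 2.0], [1.0], [1, 2], None)


class TestFormulas:
    @pytest.mark.parametrize(
        "s2f,s2e,k,expected",
        [(1.0, 1.5, 2.5, 1.0), (0.0, 3.0, 2.5, 0.0), (0.2, 0.8, 2.5, 0.5)],
    )
    def test_heritability_arithmetic(self, s2f, s2e, k, expected):
        assert heritability(_vc(s2f, s2e), k) == pytest.approx(expected)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.floats(0.01, 100.0))
    def test_heritability_scale_invariant(self, c):
        # scaling y by c scales both components by c^2; h2 is unchanged
        h_raw = heritability(_vc(0.3, 0.7))
        h_scaled = heritability(_vc(0.3 * c**2, 0.7 * c**2))
        assert h_scaled == pytest.approx(h_raw, rel=1e-9)

    def test_genetic_correlation_examples(self):
        vc_i, vc_j = _vc(0.25, 0.5), _vc(0.64, 0.5)
        assert genetic_correlation(PairCovariance("i", "j", 0.3, 0.0),
                                   vc_i, vc_j) == pytest.approx(0.75)
        assert genetic_correlation(PairCovariance("i", "j", 0.0, 0.1),
                                   vc_i, vc_j) == 0.0
        # trait against itself must give exactly 1 (product-form denominator)
        assert genetic_correlation(PairCovariance("i", "i", 0.25, 0.5),
                                   vc_i, vc_i) == pytest.approx(1.0)

    def test_genetic_correlation_undefined_without_family_variance(self):
        with pytest.raises(DegenerateDataError):
            genetic_correlation(PairCovariance("i", "j", 0.0, 0.0),
                                _vc(0.0, 1.0), _vc(0.3, 0.7))

    def test_phenotypic_correlation_examples(self):
        vc = _vc(0.5, 0.5)
        assert phenotypic_correlation(PairCovariance("i", "j", 0.1, 0.1),
                                      vc, vc) == pytest.approx(0.2)
        assert phenotypic_correlation(PairCovariance("i", "j", 0.0, 0.0),
                                      vc, vc) == 0.0
        assert phenotypic_correlation(
            PairCovariance("i", "i", 0.5, 0.5), vc, vc
        ) == pytest.approx(1.0)


class TestJackknife:
    def _table(self, seed=55, F=12):
        design = make_design(F, 3, 3)
        return simulate_traits(design, TraitParams(), seed=seed)

    def test_constant_statistic_has_zero_se(self):
        assert jackknife_se(self._table(), lambda df: 42.0) == 0.0

    def test_se_nonnegative(self):
        se = jackknife_se(self._table(), ("h2", "anth"))
        assert se >= 0.0

    def test_jackknife_of_mean_matches_textbook_identity(self):
        tr = self._table()
        fam_means = tr.groupby("family_id")["anth"].mean()

        def stat(df):
            return df.groupby("family_id")["anth"].mean().mean()

        se = jackknife_se(tr, stat)
        expected = fam_means.std(ddof=1) / np.sqrt(len(fam_means))
        assert se == pytest.approx(expected, rel=1e-9)

    def test_too_few_families_rejected(self):
        design = make_design(2, 2, 3)
        tr = simulate_traits(design, TraitParams(), seed=56)
        with pytest.raises(InvalidParameterError):
            jackknife_se(tr, ("h2", "anth"))


class TestBreedingValues:
    def _data(self, seed=57):
        design = make_design(15, 3, 4)
        tr = simulate_traits(design, TraitParams(), seed=seed)
        vc = fit_univariate_reml(tr["anth"], tr["family_id"],
                                 tr["replication_id"], "anth")
        return tr, vc

    def test_zero_family_variance_gives_zero_bvs(self):
        tr, _ = self._data()
        bv = breeding_values(tr["anth"], tr["family_id"], _vc(0.0, 1.0))
        np.testing.assert_array_equal(bv["bv"], 0.0)

    def test_vanishing_residual_gives_raw_family_deviation(self):
        tr, _ = self._data()
        bv = breeding_values(tr["anth"], tr["family_id"], _vc(0.5, 1e-12))
        dev = (tr.groupby("family_id")["anth"].mean() - tr["anth"].mean())
        np.testing.assert_allclose(bv["bv"], dev.to_numpy(), rtol=1e-6)

    def test_shrinkage_bounds(self):
        tr, vc = self._data()
        bv = breeding_values(tr["anth"], tr["family_id"], vc)
        dev = (tr.groupby("family_id")["anth"].mean() - tr["anth"].mean())
        assert (np.abs(bv["bv"].to_numpy()) <= np.abs(dev.to_numpy()) + 1e-12).all()

    def test_bvs_sum_near_zero(self):
        tr, vc = self._data()
        bv = breeding_values(tr["anth"], tr["family_id"], vc)
        assert abs(bv["bv"].sum()) < 1e-8 * len(bv)


class TestGainAndSelection:
    def _bv(self):
        return pd.DataFrame(
            {"family_id": [1, 2, 3, 4], "bv_anth": [2.0, 1.0, -1.0, -2.0],
             "bv_flav": [1.0, -1.0, 1.0, -1.0]}
        )

    def test_select_all_gives_zero_gain(self):
        assert realized_gain(self._bv(), "anth", 1.0) == pytest.approx(0.0)

    def test_single_top_family(self):
        assert realized_gain(self._bv(), "anth", 0.25) == pytest.approx(2.0)

    def test_gain_nonincreasing_in_fraction(self):
        bv = self._bv()
        gains = [realized_gain(bv, "anth", f) for f in (0.25, 0.5, 0.75, 1.0)]
        assert all(b <= a + 1e-12 for a, b in zip(gains, gains[1:]))

    def test_invalid_fraction_rejected(self):
        with pytest.raises(InvalidParameterError):
            realized_gain(self._bv(), "anth", 0.0)

    def test_both_above_mean_selects_intersection(self):
        bv = pd.DataFrame(
            {"family_id": [1, 2, 3], "bv_anth": [1.0, 1.0, -1.0],
             "bv_flav": [1.0, -1.0, 1.0]}
        )
        assert select_families(bv, ["anth", "flav"]) == [1]

    def test_no_rules_selects_all(self):
        assert select_families(self._bv(), []) == [1, 2, 3, 4]

    def test_adding_rules_never_enlarges(self):
        bv = self._bv()
        one = set(select_families(bv, ["anth"]))
        two = set(select_families(bv, ["anth", "flav"]))
        assert two <= one


class TestPipelineRecovery:
    def test_heritability_from_predicted_traits_is_attenuated_not_inflated(self):
        """Spectra -> ensemble prediction -> REML recovers h2 with non-negative
        attenuation, on a reduced trial (50 families x 6 trees, half measured)."""
        from leafspec.evaluate import ensemble_predict, evaluate_pipeline
        from leafspec.simulate import (
            SpectraParams,
            simulate_spectra,
            subsample_measured,
        )

        design = make_design(50, 1, 6)
        h2_true, h2_pred = [], []
        for s in range(20):
            tr = simulate_traits(design, TraitParams(), seed=900 + s)
            spectra = simulate_spectra(tr, SpectraParams(), seed=1900 + s)
            measured = subsample_measured(design, 150, seed=2900 + s)
            midx = np.where(measured)[0]
            y = tr["anth"].to_numpy()
            dist = evaluate_pipeline(
                spectra.take(midx), y[midx], "raw", "none", n_rep=8,
                seed=3900 + s, max_ncomp=6,
            )
            pred, _ = ensemble_predict(dist.pipelines, spectra)
            combined = np.where(measured, y, pred)
            fam = tr["family_id"].to_numpy()
            h2_true.append(heritability(fit_univariate_reml(y, fam, None)))
            h2_pred.append(heritability(fit_univariate_reml(combined, fam, None)))
        mean_true, mean_pred = np.mean(h2_true), np.mean(h2_pred)
        # prediction noise can only dilute the family signal
        assert mean_pred <= mean_true + 0.03
        assert abs(mean_pred - 0.78) <= 0.15


class TestSummarizeGenetics:
    def test_summary_structure(self):
        design = make_design(10, 2, 4)
        tr = simulate_traits(design, TraitParams(), seed=58)
        s = summarize_genetics(tr, k=2.5, jackknife=False)
        assert set(s.heritability) == {"anth", "flav", "nbi"}
        assert len(s.breeding_values) == 10
        assert all(0.0 <= h <= 2.5 for h in s.heritability.values())
        d = s.to_dict()
        assert "anth__flav" in d["genetic_correlation"]
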