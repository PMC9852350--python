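import numpy as np
import pandas as pd
import pytest

from xenotraffic.expression import PresenceSet
from xenotraffic.io_formats import ExpressionMatrix, RunConfig, default_design
from xenotraffic.mobility import MobilityCall
from xenotraffic.stats import (
    abundance_contrast,
    hypergeometric_enrichment,
    orthogroup_loss,
    shared_missing_pct,
    source_dest_correlation,
)

from oracles import brute_force_spearman


def _fpkm_matrix(rng, n, cd_vals=None, hc_vals=None):
    design = default_design()
    values = rng.random((n, len(design))) + 0.5
    if cd_vals is not None:
        values[:, 0:3] = cd_vals[:, None]
    if hc_vals is not None:
        values[:, 3:6] = hc_vals[:, None]
    return ExpressionMatrix(
        unigene_ids=[f"u{i}" for i in range(n)],
        libraries=design,
        values=values,
        value_kind="fpkm",
    )


def _calls(n_mobile, n_non, direction="CD_to_HC"):
    calls = [MobilityCall(f"u{i}", "HA_exclusive", "A_only", direction)
             for i in range(n_mobile)]
    calls += [MobilityCall(f"u{i}", "non_candidate", "", "non_mobile")
              for i in range(n_mobile, n_mobile + n_non)]
    return calls


class TestAbundanceContrast:
    def test_tenfold_mobile_abundance_detected(self, run_config):
        """With mobile source abundance x10 the mobile median exceeds the
        non-mobile median in every one of 10 seeds."""
        for seed in range(10):
            rng = np.random.default_rng(seed)
            cd = np.concatenate([10 * rng.lognormal(1, 1, 100),
                                 rng.lognormal(1, 1, 100)])
            fpkm = _fpkm_matrix(rng, 200, cd_vals=cd)
            res = abundance_contrast(fpkm, _calls(100, 100), "CD", run_config)
            assert res.quantiles_mobile["median"] > res.quantiles_non_mobile["median"]
            assert res.p_value < 0.05

    def test_single_class_reports_missing_statistic(self, run_config):
        rng = np.random.default_rng(0)
        fpkm = _fpkm_matrix(rng, 10)
        res = abundance_contrast(fpkm, _calls(10, 0), "CD", run_config)
        assert res.statistic is None and res.p_value is None

    def test_null_type_one_error_calibrated(self, run_config):
        """Identical mobile/non-mobile distributions: rejection rate at
        nominal 0.05 stays in [0.02, 0.09] over 200 seeds."""
        rejections = 0
        n_seeds = 200
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            cd = rng.lognormal(1, 1, 200)
            fpkm = _fpkm_matrix(rng, 200, cd_vals=cd)
            res = abundance_contrast(fpkm, _calls(100, 100), "CD", run_config)
            rejections += res.p_value < 0.05
        assert 0.02 <= rejections / n_seeds <= 0.09


class TestSourceDestCorrelation:
    def test_exact_dilution_gives_rho_one(self, run_config):
        rng = np.random.default_rng(1)
        src = rng.lognormal(2, 1, 50)
        fpkm = _fpkm_matrix(rng, 50, cd_vals=src, hc_vals=0.1 * src)
        rho, r_log, n = source_dest_correlation(fpkm, _calls(50, 0),
                                                "CD_to_HC", run_config)
        assert rho == pytest.approx(1.0)
        # the log-scale Pearson is near-perfect but not exactly 1 because
        # of the additive pseudocount
        assert r_log > 0.999
        assert n == 50

    def test_independent_source_and_dest_uncorrelated(self, run_config):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            fpkm = _fpkm_matrix(rng, 500, cd_vals=rng.lognormal(1, 1, 500),
                                hc_vals=rng.lognormal(1, 1, 500))
            rho, _, _ = source_dest_correlation(fpkm, _calls(500, 0),
                                                "CD_to_HC", run_config)
            assert abs(rho) < 0.15

    def test_matches_brute_force_rank_correlation(self, run_config, rng):
        for _ in range(50):
            n = int(rng.integers(5, 30))
            src = rng.lognormal(1, 1, n)
            dst = rng.lognormal(1, 1, n)
            fpkm = _fpkm_matrix(rng, n, cd_vals=src, hc_vals=dst)
            rho, _, _ = source_dest_correlation(fpkm, _calls(n, 0),
                                                "CD_to_HC", run_config)
            assert rho == pytest.approx(brute_force_spearman(src, dst), abs=1e-9)

    def test_too_few_mobile_is_error(self, run_config):
        rng = np.random.default_rng(2)
        fpkm = _fpkm_matrix(rng, 5)
        with pytest.raises(ValueError, match=">= 3"):
            source_dest_correlation(fpkm, _calls(2, 3), "CD_to_HC", run_config)


class TestHypergeometricEnrichment:
    def test_exact_combinatorial_value(self, run_config):
        """N=20, K=5, n=10, k=5 -> p = C(5,5) C(15,5) / C(20,10)."""
        background = {f"g{i}" for i in range(20)}
        term = {f"g{i}" for i in range(5)}
        chosen = set(list(term) + [f"g{i}" for i in range(5, 10)])
        (res,) = hypergeometric_enrichment(chosen, background, {"t": term}, run_config)
        assert res.k_in_set == 5 and res.K_in_background == 5
        assert res.p_value == pytest.approx(3003 / 184756, rel=1e-12)

    def test_k_zero_gives_p_one(self, run_config):
        background = {f"g{i}" for i in range(20)}
        (res,) = hypergeometric_enrichment(
            {"g10"}, background, {"t": {"g0", "g1"}}, run_config)
        assert res.k_in_set == 0 and res.p_value == 1.0

    def test_bh_adjustment_hand_example(self, run_config):
        """BH on p = (0.01, 0.02, 0.03) gives adjusted (0.03, 0.03, 0.03)."""
        from statsmodels.stats.multitest import multipletests
        _, adj, _, _ = multipletests([0.01, 0.02, 0.03], method="fdr_bh")
        np.testing.assert_allclose(adj, [0.03, 0.03, 0.03])

    def test_set_not_subset_of_background_is_error(self, run_config):
        with pytest.raises(ValueError, match="subset"):
            hypergeometric_enrichment({"x"}, {"y"}, {"t": {"y"}}, run_config)

    def test_bh_is_monotone_in_raw_p(self, run_config, rng):
        background = {f"g{i}" for i in range(200)}
        annotation = {
            f"t{j}": set(rng.choice(sorted(background), size=30, replace=False))
            for j in range(15)
        }
        chosen = set(rng.choice(sorted(background), size=40, replace=False))
        results = hypergeometric_enrichment(chosen, background, annotation, run_config)
        by_p = sorted(results, key=lambda r: r.p_value)
        adj = [r.p_adjusted for r in by_p]
        assert adj == sorted(adj)

    def test_null_draws_are_superuniform(self, run_config, rng):
        """Sets drawn uniformly from the background reject at <= 0.07
        (raw p < 0.05) over 500 draws."""
        background = sorted(f"g{i}" for i in range(300))
        annotation = {
            f"t{j}": set(rng.choice(background, size=40, replace=False))
            for j in range(5)
        }
        n_tests = rejections = 0
        for _ in range(500):
            chosen = set(rng.choice(background, size=50, replace=False))
            for r in hypergeometric_enrichment(chosen, set(background),
                                               annotation, run_config):
                n_tests += 1
                rejections += r.p_value < 0.05
        assert rejections / n_tests <= 0.07


class TestOrthogroupLoss:
    ASTERIDS = [f"ast{i}" for i in range(5)]
    COMPS = ["par1", "par2"]

    def _matrix(self, rng, n=200):
        cols = ["focal", *self.ASTERIDS, *self.COMPS]
        data = rng.random((n, len(cols))) < 0.7
        return pd.DataFrame(data, columns=cols,
                            index=[f"OG{i:04d}" for i in range(n)])

    def test_complete_focal_has_zero_missing(self, rng):
        m = self._matrix(rng)
        m["focal"] = True
        rep = orthogroup_loss(m, "focal", self.ASTERIDS, self.COMPS)
        assert rep["n_missing_in_focal"] == 0

    def test_published_tally_percent(self):
        assert shared_missing_pct(926, 1720) == 53.84

    def test_matches_brute_force_on_random_matrices(self, rng):
        for _ in range(20):
            m = self._matrix(rng)
            rep = orthogroup_loss(m, "focal", self.ASTERIDS, self.COMPS)
            conserved = [og for og in m.index
                         if sum(m.at[og, a] for a in self.ASTERIDS) >= 3]
            missing = [og for og in conserved if not m.at[og, "focal"]]
            assert rep["n_conserved"] == len(conserved)
            assert rep["n_missing_in_focal"] == len(missing)
            for comp in self.COMPS:
                shared = [og for og in missing if not m.at[og, comp]]
                assert rep["shared_missing"][comp]["n_shared"] == len(shared)

    def test_tightening_rule_shrinks_conserved_set(self, rng):
        m = self._matrix(rng)
        r3 = orthogroup_loss(m, "focal", self.ASTERIDS, self.COMPS,
                             min_asterid_present=3)
        r4 = orthogroup_loss(m, "focal", self.ASTERIDS, self.COMPS,
                             min_asterid_present=4)
        assert r4["n_conserved"] <= r3["n_conserved"]

    def test_missing_species_is_error(self, rng):
        m = self._matrix(rng)
        with pytest.raises(ValueError, match="ghost"):
            orthogroup_loss(m, "ghost", self.ASTERIDS, self.COMPS)
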