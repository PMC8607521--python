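"""The z score, empirical-null locfdr estimation and SMD calling."""

import math

import numpy as np
import pytest
from scipy.stats import norm

from smdtools.mutmap import DomainMutationCount
from smdtools.smd import (
    SmdModel,
    SmdResult,
    call_smds,
    fit_empirical_null,
    heatmap_matrix,
    locfdr_values,
    relative_frequency,
    top_k,
    zscore,
)


def _count(fam="PF1", site="skin", count=15, length=150):
    return DomainMutationCount(fam, site, count, length, 3)


def _res(fam, locfdr, count=10, site="skin", significant=False):
    return SmdResult(fam, site, count, 100, 0.03, zscore(0.03), locfdr, significant)


class TestRelativeFrequency:
    def test_nt_and_aa_basis(self):
        c = _count(count=15, length=150)
        assert relative_frequency(c, basis="nt") == pytest.approx(15 / 450)
        assert relative_frequency(c, basis="aa") == pytest.approx(15 / 150)

    def test_zero_count_clamps_low_and_logs(self):
        log = []
        p = relative_frequency(_count(count=0, length=100), clamp_log=log)
        assert p == 1e-9
        assert len(log) == 1

    def test_count_exceeding_length_clamps_high(self):
        log = []
        p = relative_frequency(_count(count=1000, length=100), clamp_log=log)
        assert p == 1 - 1e-9
        assert len(log) == 1

# the count dataclass rejects zero length itself; build one directly to
# exercise the function's own guard
def test_relative_frequency_zero_length_error():
    bad = DomainMutationCount.__new__(DomainMutationCount)
    object.__setattr__(bad, "domain_family", "PF1")
    object.__setattr__(bad, "primary_site", "skin")
    object.__setattr__(bad, "accumulated_count", 0)
    object.__setattr__(bad, "cumulative_length_aa", 0)
    object.__setattr__(bad, "n_instances", 0)
    with pytest.raises(ValueError):
        relative_frequency(bad)


class TestZscore:
    @pytest.mark.parametrize("p,expected", [(0.5, 1.0), (0.8, 2.0), (0.2, 0.5)])
    def test_printed_values(self, p, expected):
        assert zscore(p) == pytest.approx(expected)

    def test_strictly_monotone_and_identity(self):
        ps = np.linspace(0.01, 0.99, 60)
        zs = [zscore(p) for p in ps]
        assert all(a < b for a, b in zip(zs, zs[1:]))
        for p, z in zip(ps, zs):
            assert z**2 * (1 - p) == pytest.approx(p)

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.2, 1.5])
    def test_domain_error(self, p):
        with pytest.raises(ValueError):
            zscore(p)


class TestEmpiricalNull:
    def test_standard_normal_recovered(self):
        rng = np.random.default_rng(123)
        fit = fit_empirical_null(rng.normal(0, 1, 5000))
        assert abs(fit.delta) < 0.1
        assert abs(fit.sigma - 1) < 0.1
        assert fit.pi0 > 0.9
        assert not fit.theoretical

    def test_shifted_null_center_recovered(self):
        rng = np.random.default_rng(123)
        fit = fit_empirical_null(rng.normal(0.5, 1, 5000))
        assert abs(fit.delta - 0.5) < 0.1

    def test_small_sample_falls_back_to_theoretical(self):
        rng = np.random.default_rng(1)
        with pytest.warns(UserWarning, match="theoretical"):
            fit = fit_empirical_null(rng.normal(0, 1, 100))
        assert (fit.delta, fit.sigma, fit.pi0) == (0.0, 1.0, 1.0)
        assert fit.theoretical

    def test_degenerate_sample_falls_back(self):
        with pytest.warns(UserWarning):
            fit = fit_empirical_null(np.ones(500))
        assert fit.theoretical


class TestLocfdr:
    def test_pure_null_calls_almost_nothing(self):
        rng = np.random.default_rng(9)
        z = rng.normal(0, 1, 5000)
        fit = fit_empirical_null(z)
        fdr = locfdr_values(z, fit)
        assert np.all((fdr >= 0) & (fdr <= 1))
        assert (fdr < 0.1).mean() <= 0.02

    def test_mixture_signal_receives_low_fdr(self):
        rng = np.random.default_rng(10)
        z0 = rng.normal(0, 1, 4750)
        z1 = rng.normal(4, 1, 250)
        fit = fit_empirical_null(np.concatenate([z0, z1]))
        # oracle: exact fdr from the known mixture densities
        def exact_fdr(z):
            f0 = norm.pdf(z)
            f = 0.95 * f0 + 0.05 * norm.pdf(z, 4, 1)
            return 0.95 * f0 / f
        fdr1 = locfdr_values(z1, fit)
        assert (fdr1 < 0.1).mean() >= 0.6
        clearly = z1 > 3.5  # where the oracle itself is well below threshold
        assert np.all(exact_fdr(z1[clearly]) < 0.1)
        assert (fdr1[clearly] < 0.1).mean() >= 0.9

    def test_mode_value_exceeds_signal_tail(self):
        rng = np.random.default_rng(11)
        z = np.concatenate([rng.normal(0, 1, 4800), rng.normal(4, 0.5, 200)])
        fit = fit_empirical_null(z)
        at_mode = locfdr_values([fit.delta], fit)[0]
        far_tail = locfdr_values([4.5], fit)[0]
        raw = float(fit.pi0 * fit.null_density(np.array([fit.delta]))[0]
                    / fit.marginal.density(np.array([fit.delta]))[0])
        assert at_mode == pytest.approx(min(raw, 1.0), rel=1e-6)
        assert at_mode >= far_tail

    def test_null_calibration_over_20_seeds(self):
        fracs = []
        for s in range(20):
            rng = np.random.default_rng(3000 + s)
            z = rng.normal(0, 1, 5000)
            fit = fit_empirical_null(z)
            fracs.append((locfdr_values(z, fit) < 0.1).mean())
        assert np.mean(fracs) < 0.02


class TestCalling:
    def test_strict_threshold_boundary(self):
        results = [_res("A", 0.05), _res("B", 0.1), _res("C", 0.2)]
        called = call_smds(results, 0.1)
        assert [r.domain_family for r in called] == ["A"]
        assert called[0].significant

    def test_empty_input(self):
        assert call_smds([]) == []

    def test_anti_monotone_in_threshold(self):
        results = [_res(f"F{i}", fdr) for i, fdr in
                   enumerate([0.01, 0.05, 0.09, 0.3, 0.7])]
        small = {r.domain_family for r in call_smds(results, 0.05)}
        large = {r.domain_family for r in call_smds(results, 0.1)}
        assert small <= large


class TestTopK:
    def test_fewer_results_than_k(self):
        results = [_res("B", 0.3), _res("A", 0.1), _res("C", 0.2)]
        ranked = top_k(results, 10)
        assert [r.domain_family for r in ranked] == ["A", "C", "B"]

    def test_tie_broken_by_higher_count_then_accession(self):
        results = [
            _res("B", 0.1, count=5),
            _res("A", 0.1, count=9),
            _res("D", 0.1, count=5),
            _res("C", 0.05, count=1),
        ]
        ranked = top_k(results, 3)
        assert [r.domain_family for r in ranked] == ["C", "A", "B"]

    def test_agrees_with_full_sort_oracle(self):
        rng = np.random.default_rng(8)
        results = [
            _res(f"PF{i:05d}", round(float(rng.uniform(0, 1)), 2),
                 count=int(rng.integers(0, 30)))
            for i in range(100)
        ]
        oracle = sorted(results, key=lambda r: (r.locfdr, -r.accumulated_count,
                                                r.domain_family))[:10]
        assert top_k(results, 10) == oracle


class TestHeatmap:
    def test_shared_smd_row_populated_in_both_sites(self):
        results = [
            _res("A", 0.02, site="skin", significant=True),
            _res("A", 0.04, site="lung", significant=True),
            _res("B", 0.5, site="skin"),
            _res("B", 0.6, site="lung"),
        ]
        mat = heatmap_matrix(results)
        assert list(mat.index) == ["A"]
        assert mat.loc["A", "skin"] == 0.02
        assert mat.loc["A", "lung"] == 0.04

    def test_site_without_smds_gets_sentinel_column(self):
        results = [
            _res("A", 0.02, site="skin", significant=True),
            _res("B", 0.9, site="eye"),
        ]
        mat = heatmap_matrix(results)
        assert mat.loc["A", "eye"] == 1.0


class TestModelResults:
    @staticmethod
    @pytest.fixture(scope="class")
    def fitted():
        rng = np.random.default_rng(21)
        counts = []
        lam = 0.02  # mutations per coding nt
        for site in ("skin", "lung"):
            for i in range(300):
                length = int(rng.integers(60, 200))
                planted = i < 5
                mu = lam * 3 * length * (8.0 if planted else 1.0)
                counts.append(DomainMutationCount(
                    f"PF{i:05d}", site, int(rng.poisson(mu)), length, 2))
        return SmdModel.from_counts(counts).fit(), counts

    def test_planted_families_called_per_site(self, fitted):
        results, _ = fitted
        planted = {f"PF{i:05d}" for i in range(5)}
        called = {(r.domain_family, r.primary_site) for r in results.significant()}
        hits = sum((fam, site) in called
                   for fam in planted for site in ("skin", "lung"))
        assert hits >= 8  # at least 80% of 10 planted (family, site) pairs

    def test_matrix_cells_equal_per_site_locfdr(self, fitted):
        results, _ = fitted
        mat = results.heatmap_matrix()
        for r in results.results:
            if r.domain_family in mat.index:
                assert mat.loc[r.domain_family, r.primary_site] == pytest.approx(
                    r.locfdr
                )

    def test_summary_lists_each_site(self, fitted):
        results, _ = fitted
        text = results.summary()
        assert "skin" in text and "lung" in text

    def test_frame_round_trips_counts(self, fitted):
        results, counts = fitted
        df = results.frame
        assert len(df) == len(counts)
        assert (df.locfdr.between(0, 1)).all()
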