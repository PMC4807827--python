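"""Change statistic, paired tests, redundancy regressions, Moran's I."""

import json
import subprocess

import numpy as np
import pytest
from scipy import stats as sps

import divnull as dn
from divnull.errors import InputError


class TestRelativeChange:
    @pytest.mark.parametrize(
        "wet,dry,expected",
        [(10, 10, 0.0), (8, 2, -0.75), (4, 5, 0.25), (7, 0, -1.0)],
    )
    def test_printed_formula(self, wet, dry, expected):
        assert dn.relative_change(wet, dry) == pytest.approx(expected)

    def test_wet_must_be_positive(self):
        with pytest.raises(InputError):
            dn.relative_change(0.0, 1.0)

    def test_strictly_increasing_in_dry(self, rng):
        wet = 6.0
        dry = np.sort(rng.uniform(0, 12, 30))
        vals = [dn.relative_change(wet, d) for d in dry]
        assert all(b > a for a, b in zip(vals, vals[1:]))


class TestPairedTest:
    def test_textbook_example(self):
        # differences {1,2,3}: mean 2, sd 1 -> t = 2*sqrt(3), df 2
        rep = dn.paired_test([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        assert rep.t == pytest.approx(2 * np.sqrt(3))
        assert rep.df == 2
        assert rep.mean_difference == pytest.approx(2.0)

    def test_zero_variance_is_error_not_nan(self):
        with pytest.raises(InputError, match="zero variance"):
            dn.paired_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_sign_flip_antisymmetry(self, rng):
        a = rng.normal(size=10)
        b = rng.normal(size=10)
        fwd = dn.paired_test(a, b)
        rev = dn.paired_test(b, a)
        assert fwd.t == pytest.approx(-rev.t)
        assert fwd.p == pytest.approx(rev.p)

    def test_matches_reference_implementation(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            n = int(rng.integers(3, 30))
            a = rng.normal(size=n)
            b = rng.normal(size=n)
            rep = dn.paired_test(a, b)
            ref = sps.ttest_rel(a, b)
            assert rep.t == pytest.approx(ref.statistic, abs=1e-10)
            assert rep.p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_welch_matches_reference(self, rng):
        a = rng.normal(size=12)
        b = rng.normal(loc=0.5, scale=2.0, size=9)
        rep = dn.welch_test(a, b)
        ref = sps.ttest_ind(a, b, equal_var=False)
        assert rep.t == pytest.approx(ref.statistic, abs=1e-12)
        assert rep.p == pytest.approx(ref.pvalue, abs=1e-12)


class TestRedundancyRegression:
    def test_linear_data_selects_linear(self):
        """A straight FD~SR line with small noise keeps the linear model."""
        rng = np.random.default_rng(1)
        sr = np.arange(2, 14, dtype=float)
        hits = 0
        for _ in range(200):
            y = 2.0 * sr + rng.normal(0, 0.05, sr.size)
            rep = dn.redundancy_regression(sr, y)
            hits += rep.selected == "linear"
        assert hits >= 190  # >= 95% of 200 runs

    def test_saturating_data_selects_negative_quadratic(self):
        rng = np.random.default_rng(2)
        sr = np.arange(2, 14, dtype=float)
        hits = 0
        for _ in range(200):
            y = 3.0 * sr - 0.12 * sr**2 + rng.normal(0, 0.05, sr.size)
            rep = dn.redundancy_regression(sr, y)
            hits += rep.selected == "quadratic" and rep.quadratic_coef < 0
            assert rep.redundancy == (
                rep.selected == "quadratic" and (rep.quadratic_coef or 0) < 0
            )
        assert hits >= 190

    def test_constant_sr_rejected(self):
        with pytest.raises(InputError, match="constant"):
            dn.redundancy_regression([3, 3, 3, 3], [1.0, 2.0, 3.0, 4.0])

    def test_two_distinct_sr_values_rank_deficient(self):
        with pytest.raises(InputError, match="rank deficient"):
            dn.redundancy_regression([2, 2, 5, 5], [1.0, 1.1, 2.0, 2.1])

    def test_aic_counts_error_variance_with_small_sample_correction(self):
        """AICc from the Gaussian likelihood, sigma^2 counted as a parameter."""
        rng = np.random.default_rng(3)
        sr = np.arange(2, 14, dtype=float)
        y = 1.5 * sr + rng.normal(0, 1.0, sr.size)
        rep = dn.redundancy_regression(sr, y)
        n = sr.size
        X = np.column_stack([np.ones(n), sr])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss = ((y - X @ beta) ** 2).sum()
        k = 3  # intercept, slope, sigma^2
        aic = n * np.log(2 * np.pi * rss / n) + n + 2 * k
        expect = aic + 2 * k * (k + 1) / (n - k - 1)
        assert rep.aic_reduced == pytest.approx(expect, abs=1e-8)


class TestMoransI:
    def coords(self, rng, n=12):
        return rng.uniform(0, 100, size=(n, 2))

    def test_permutation_null_mean(self):
        """Mean of I over value permutations approaches -1/(n-1)."""
        rng = np.random.default_rng(8)
        xy = self.coords(rng)
        base = rng.normal(size=12)
        obs = [
            dn.morans_i(rng.permutation(base), xy).observed for _ in range(1000)
        ]
        assert np.mean(obs) == pytest.approx(-1 / 11, abs=0.02)

    def test_spatial_gradient_detected(self):
        rng = np.random.default_rng(9)
        xy = self.coords(rng, 15)
        values = 0.05 * xy[:, 0] + rng.normal(0, 0.2, 15)
        rep = dn.morans_i(values, xy)
        assert rep.observed > rep.expected
        assert rep.p < 0.01

    def test_constant_values_rejected(self):
        rng = np.random.default_rng(10)
        with pytest.raises(InputError, match="constant"):
            dn.morans_i(np.ones(8), self.coords(rng, 8))

    def test_coincident_sites_rejected(self):
        xy = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0]])
        with pytest.raises(InputError, match="coincident"):
            dn.morans_i([1.0, 2.0, 3.0], xy)

    def test_matches_ape_reference(self, tmp_path):
        """Row-standardised variant reproduces the classical R implementation."""
        rng = np.random.default_rng(11)
        xy = self.coords(rng, 10)
        values = rng.normal(size=10)
        np.savetxt(tmp_path / "xy.csv", xy, delimiter=",")
        np.savetxt(tmp_path / "v.csv", values, delimiter=",")
        script = tmp_path / "moran.R"
        script.write_text(
            """
            suppressMessages(library(ape))
            xy <- as.matrix(read.csv(commandArgs(TRUE)[1], header=FALSE))
            v <- scan(commandArgs(TRUE)[2], quiet=TRUE)
            w <- 1/as.matrix(dist(xy)); diag(w) <- 0
            r <- Moran.I(v, w)
            cat(sprintf('{"observed": %.12f, "expected": %.12f, "sd": %.12f, "p": %.12f}',
                        r$observed, r$expected, r$sd, r$p.value))
            """
        )
        out = subprocess.run(
            ["Rscript", str(script), str(tmp_path / "xy.csv"), str(tmp_path / "v.csv")],
            capture_output=True,
            text=True,
            check=True,
        )
        ref = json.loads(out.stdout)
        rep = dn.morans_i(values, xy, row_standardise=True)
        assert rep.observed == pytest.approx(ref["observed"], abs=1e-8)
        assert rep.expected == pytest.approx(ref["expected"], abs=1e-12)
        assert rep.sd == pytest.approx(ref["sd"], abs=1e-8)
        assert rep.p == pytest.approx(ref["p"], abs=1e-8)


class TestSeasonSummary:
    def build_report(self, seed=0, replicates=120):
        ds = dn.simulate_dataset(dn.ScenarioConfig(), seed=seed)
        report, _ = dn.analyze(
            ds.occurrences,
            ds.traits,
            ds.tree,
            coords=ds.coordinates,
            replicates=replicates,
            seed=seed,
        )
        return report

    def test_report_schema_covers_all_sections(self):
        report = self.build_report()
        tests = set(report.global_tests["test"])
        assert "SR wet vs dry" in tests
        for stat in ("FD", "PD"):
            assert f"{stat} change: observed vs null" in tests
            assert f"{stat} wet: observed vs null" in tests
            assert f"{stat} dry: observed vs null" in tests
        assert set(report.regressions["season"]) == {"wet", "dry"}
        assert len(report.regressions) == 8  # 2 seasons x {FD,PD} x {obs,null}
        assert report.morans is not None and len(report.morans) == 9
        seasons = set(report.per_site["season"])
        assert seasons == {"wet", "dry", "change"}
        for col in ("FD_null_mean", "FD_ses", "PD_null_mean", "PD_ses"):
            assert col in report.per_site.columns

    def test_deterministic_given_seed(self, tmp_path):
        r1 = self.build_report(seed=5, replicates=60)
        r2 = self.build_report(seed=5, replicates=60)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        r1.to_csvs(d1)
        r2.to_csvs(d2)
        for name in ("per_site_diversity", "global_tests", "regressions", "morans_i"):
            assert (d1 / f"{name}.csv").read_bytes() == (
                d2 / f"{name}.csv"
            ).read_bytes()
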