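"""Inverse-normal percentile reconstruction: grid placement, moments,
coupling, and the SEM conversion."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import special

from cytoms.reconstruct import (
    ReconstructionConfig,
    SummaryStat,
    grid_sd_shrinkage,
    percentile_grid,
    reconstruct_cohort,
    sem_to_sd,
    zscore_percentile_values,
)
from cytoms.synthetic import summarize_cohort


def inv_norm_cdf_bisect(p: float, lo=-10.0, hi=10.0, tol=1e-12) -> float:
    """Independent numeric inversion of the standard normal CDF by
    bisection on scipy.special.ndtr (no use of norm.ppf)."""
    while hi - lo > tol:
        mid = (lo + hi) / 2
        if special.ndtr(mid) < p:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


class TestSemToSd:
    @pytest.mark.parametrize("sem,n,expected", [
        (0.5, 100, 5.0),
        (1.0, 1, 1.0),
        (0.0, 7, 0.0),
    ])
    def test_known_conversions(self, sem, n, expected):
        assert sem_to_sd(sem, n) == pytest.approx(expected)

    def test_large_n_against_high_precision(self):
        # 0.3 * sqrt(833) evaluated with integer-exact arithmetic
        import decimal
        d = decimal.Decimal(833).sqrt() * decimal.Decimal("0.3")
        assert sem_to_sd(0.3, 833) == pytest.approx(float(d), rel=1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            sem_to_sd(-0.1, 10)
        with pytest.raises(ValueError):
            sem_to_sd(0.5, 0)


class TestPercentileGrid:
    def test_single_value_is_median(self):
        assert zscore_percentile_values(0.0, 1.0, 1) == pytest.approx([0.0])

    def test_zero_sd_repeats_mean(self):
        vals = zscore_percentile_values(10.0, 0.0, 5)
        assert vals == pytest.approx([10.0] * 5)

    def test_included_mass_accounting(self):
        """CDF mass between the outermost grid bounds is exactly the
        configured included mass (bounds at the (1-mass)/2 quantiles)."""
        mass = 0.997
        lower_p = (1 - mass) / 2
        upper_p = 1 - lower_p
        assert (upper_p - lower_p) == pytest.approx(mass, abs=1e-12)
        grid = percentile_grid(1001, mass)
        assert grid[0] > lower_p and grid[-1] < upper_p

    def test_extremes_within_mass_bound(self):
        mass = 0.997
        bound = inv_norm_cdf_bisect((1 + mass) / 2)
        vals = zscore_percentile_values(0.0, 1.0, 5000)
        assert vals.min() > -bound and vals.max() < bound

    def test_boundary_percentile_matches_numeric_inversion(self):
        """The extreme reconstructed value equals the inverse CDF at the
        outermost midpoint percentile, cross-checked by bisection."""
        n, mass = 1001, 0.997
        p_last = (1 - mass) / 2 + (n - 0.5) / n * mass
        vals = zscore_percentile_values(0.0, 1.0, n)
        assert vals[-1] == pytest.approx(inv_norm_cdf_bisect(p_last), abs=1e-6)
        assert vals.mean() == pytest.approx(0.0, abs=1e-9)

    @settings(derandomize=True, max_examples=50)
    @given(mu=st.floats(-50, 50), sigma=st.floats(0, 20),
           n=st.integers(1, 300))
    def test_location_scale_equivariance(self, mu, sigma, n):
        base = zscore_percentile_values(0.0, 1.0, n)
        shifted = zscore_percentile_values(mu, sigma, n)
        assert np.allclose(shifted, mu + sigma * base, atol=1e-9)

    @settings(derandomize=True, max_examples=30)
    @given(n=st.integers(1, 400), sigma=st.floats(0.1, 10))
    def test_symmetry_and_monotonicity(self, n, sigma):
        vals = zscore_percentile_values(0.0, sigma, n)
        assert np.allclose(vals, -vals[::-1], atol=1e-9)  # antisymmetric
        assert (np.diff(vals) >= 0).all()                 # sorted ascending

    @pytest.mark.parametrize("n", [1, 2, 3, 10, 101, 1001])
    def test_mean_preservation(self, n):
        vals = zscore_percentile_values(5.0, 1.0, n)
        assert vals.mean() == pytest.approx(5.0, abs=1e-9)

    def test_sd_shrinkage_matches_brute_force_grid(self):
        """The SD of the reconstructed values is a deterministic constant
        below sigma; recompute it by brute force from first principles."""
        n, mass = 5000, 0.997
        lower = (1 - mass) / 2
        ps = [lower + (i - 0.5) / n * mass for i in range(1, n + 1)]
        zs = np.array([inv_norm_cdf_bisect(p, tol=1e-10) for p in ps[::50]])
        # brute-force grid SD on a subsample agrees with the implementation
        impl = zscore_percentile_values(0.0, 1.0, n)[::50]
        assert np.allclose(impl, zs, atol=1e-8)
        shrink = grid_sd_shrinkage(n, mass)
        assert 0.97 < shrink < 1.00
        assert np.std(zscore_percentile_values(0.0, 1.0, n)) == pytest.approx(
            shrink, abs=1e-12)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            ReconstructionConfig(included_mass=1.0)
        with pytest.raises(ValueError):
            ReconstructionConfig(coupling="copula")


def _stat(cyto, group, mean, sd, n, cohort="c", kind="SD"):
    return SummaryStat(cytokine_name=cyto, group=group, cohort_label=cohort,
                       mean=mean, dispersion=sd, dispersion_kind=kind, n=n)


class TestReconstructCohort:
    def test_zero_sd_gives_identical_records(self):
        stats = [_stat("IL2", "MS", 4.0, 0.0, 3),
                 _stat("IL4", "MS", 2.0, 0.0, 3),
                 _stat("IL2", "control", 3.0, 0.0, 3),
                 _stat("IL4", "control", 1.0, 0.0, 3)]
        table = reconstruct_cohort(stats)
        ms = table[table.status == "MS"]
        assert len(ms) == 3
        assert (ms["IL2"] == 4.0).all() and (ms["IL4"] == 2.0).all()

    def test_mean_preserved_per_group(self):
        stats = [_stat("IL2", "MS", 5.0, 1.0, 101),
                 _stat("IL2", "control", 3.0, 1.0, 50)]
        table = reconstruct_cohort(stats)
        assert table.loc[table.status == "MS", "IL2"].mean() == pytest.approx(
            5.0, abs=1e-9)
        assert len(table) == 151

    def test_sem_entries_converted_before_gridding(self):
        by_sd = reconstruct_cohort(
            [_stat("IL2", "MS", 5.0, 2.0, 100),
             _stat("IL2", "control", 3.0, 2.0, 100)])
        by_sem = reconstruct_cohort(
            [_stat("IL2", "MS", 5.0, 0.2, 100, kind="SEM"),
             _stat("IL2", "control", 3.0, 0.2, 100, kind="SEM")])
        assert np.allclose(np.sort(by_sd["IL2"]), np.sort(by_sem["IL2"]))

    def test_comonotone_coupling_sorts_all_cytokines_together(self):
        stats = [_stat("IL2", "MS", 5.0, 1.0, 20),
                 _stat("IL4", "MS", 2.0, 0.5, 20),
                 _stat("IL2", "control", 3.0, 1.0, 5),
                 _stat("IL4", "control", 1.0, 0.5, 5)]
        table = reconstruct_cohort(
            stats, ReconstructionConfig(coupling="comonotone"))
        ms = table[table.status == "MS"]
        assert (np.diff(ms["IL2"]) >= 0).all()
        assert (np.diff(ms["IL4"]) >= 0).all()

    def test_independent_coupling_breaks_comonotonicity(self):
        stats = [_stat("IL2", "MS", 5.0, 1.0, 200),
                 _stat("IL4", "MS", 2.0, 0.5, 200),
                 _stat("IL2", "control", 3.0, 1.0, 50),
                 _stat("IL4", "control", 1.0, 0.5, 50)]
        table = reconstruct_cohort(stats, ReconstructionConfig(seed=1))
        ms = table[table.status == "MS"]
        rho = np.corrcoef(ms["IL2"], ms["IL4"])[0, 1]
        assert abs(rho) < 0.3  # shuffled, not rank-coupled

    def test_round_trip_through_summaries(self):
        """summarize(reconstruct(stats)) recovers the input means exactly
        and SDs shrunk by the deterministic grid constant."""
        n = 400
        stats = [_stat("IL2", "MS", 8.0, 2.0, n),
                 _stat("IL2", "control", 5.0, 2.0, n)]
        table = reconstruct_cohort(stats)
        summ = summarize_cohort(table)
        ms = summ[(summ.group == "MS")].iloc[0]
        assert ms["mean"] == pytest.approx(8.0, abs=1e-9)
        # sample SD uses ddof=1; the grid constant is the ddof=0 figure
        expected_sd = 2.0 * grid_sd_shrinkage(n) * math.sqrt(n / (n - 1))
        assert ms["sd"] == pytest.approx(expected_sd, rel=1e-9)

    def test_mismatched_n_rejected(self):
        stats = [_stat("IL2", "MS", 5.0, 1.0, 10),
                 _stat("IL4", "MS", 2.0, 1.0, 12)]
        with pytest.raises(ValueError, match="disagree on n"):
            reconstruct_cohort(stats)

    def test_missing_cytokine_in_one_group_rejected(self):
        stats = [_stat("IL2", "MS", 5.0, 1.0, 10),
                 _stat("IL4", "MS", 2.0, 1.0, 10),
                 _stat("IL2", "control", 3.0, 1.0, 10)]
        with pytest.raises(ValueError, match="panels"):
            reconstruct_cohort(stats)

    def test_negative_values_kept_unless_clamped(self):
        stats = [_stat("IL2", "MS", 1.0, 2.0, 100),
                 _stat("IL2", "control", 1.0, 2.0, 100)]
        kept = reconstruct_cohort(stats)
        assert (kept["IL2"] < 0).any()
        clamped = reconstruct_cohort(
            stats, ReconstructionConfig(clamp_negative=True))
        assert (clamped["IL2"] >= 0).all()
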