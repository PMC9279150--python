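"""Temporal selection scan: regression oracle, genomic control,
neighbourhood filter vs brute force, region calling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import paleotempo as pt
from paleotempo.tempscan import (
    CHI2_1_MEDIAN,
    REASON_LOW_CALLS,
    REASON_LOW_MAF,
    REASON_MONOMORPHIC,
    REASON_NEIGHBOURHOOD,
    REASON_OK,
)

from conftest import make_dataset


def sites_frame(pos, p, chrom="chr1", reason=REASON_OK):
    df = pd.DataFrame({
        "chrom": chrom, "pos": pos, "p_gc": p,
        "reason": reason,
    })
    return df


class TestSiteRegression:
    def test_matches_closed_form_ols_oracle(self):
        # 6 samples, arbitrary dosages/ages; compare with scipy.linregress
        ages = np.array([0, 0, 10_000, 20_000, 35_000, 60_000], dtype=float)
        dosages = np.array([2, 1, 1, 0, 0, 0], dtype=np.int8)
        ds = make_dataset(dosages[None, :], ages=ages)
        out = pt.site_regression(ds, ages)
        lr = stats.linregress(dosages.astype(float), ages)
        assert out.loc[0, "beta"] == pytest.approx(lr.slope, rel=1e-12)
        assert out.loc[0, "p_raw"] == pytest.approx(lr.pvalue, rel=1e-9)
        assert out.loc[0, "chi2"] == pytest.approx(
            (lr.rvalue**2) * 4 / (1 - lr.rvalue**2), rel=1e-9
        )

    def test_orientation_swap_keeps_p(self):
        # regressing dosage on age gives the same two-sided P (t equal)
        ages = np.array([0, 5_000, 10_000, 25_000, 40_000, 70_000], dtype=float)
        dosages = np.array([2, 2, 1, 1, 0, 1], dtype=float)
        fwd = stats.linregress(dosages, ages)
        rev = stats.linregress(ages, dosages)
        assert fwd.pvalue == pytest.approx(rev.pvalue, rel=1e-12)

    def test_monomorphic_site_skipped_with_reason(self):
        ds = make_dataset(np.array([[1, 1, 1, 1]], dtype=np.int8),
                          ages=[0, 1000, 2000, 3000])
        out = pt.site_regression(ds)
        assert out.loc[0, "reason"] == REASON_MONOMORPHIC
        assert np.isnan(out.loc[0, "p_raw"])

    def test_identical_ages_rejected(self):
        ds = make_dataset(np.array([[0, 1, 2]], dtype=np.int8), ages=[5.0, 5.0, 5.0])
        with pytest.raises(ValueError, match="degenerate"):
            pt.site_regression(ds)

    def test_permutation_null_uniform_p(self):
        # dosages independent of age by construction -> raw P uniform
        rng = np.random.default_rng(8)
        n, S = 80, 4000
        ages = np.concatenate([np.zeros(40), rng.uniform(1000, 90_000, 40)])
        freqs = rng.uniform(0.1, 0.9, S)
        calls = rng.binomial(2, freqs[:, None], (S, n)).astype(np.int8)
        ds = make_dataset(calls, ages=ages)
        out = pt.site_regression(ds)
        pv = out["p_raw"].dropna().to_numpy()
        assert stats.kstest(pv, "uniform").pvalue > 0.01


class TestGenomicControl:
    def test_lambda_one_when_chi2_at_reference_median(self):
        df = pd.DataFrame({"chi2": np.full(200, CHI2_1_MEDIAN),
                           "reason": REASON_OK})
        gc, out = pt.genomic_control(df)
        assert gc.lam == pytest.approx(1.0)
        assert np.allclose(out["chi2_gc"], CHI2_1_MEDIAN)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(3)
        chi2 = rng.chisquare(1, 500)
        df = pd.DataFrame({"chi2": chi2, "reason": REASON_OK})
        gc1, out1 = pt.genomic_control(df)
        df2 = pd.DataFrame({"chi2": 2 * chi2, "reason": REASON_OK})
        gc2, out2 = pt.genomic_control(df2)
        assert gc2.lam == pytest.approx(2 * gc1.lam)
        assert np.allclose(out1["p_gc"], out2["p_gc"])

    def test_null_chi2_gives_lambda_one(self):
        rng = np.random.default_rng(4)
        lams = []
        for _ in range(20):
            df = pd.DataFrame({"chi2": rng.chisquare(1, 2000), "reason": REASON_OK})
            gc, _ = pt.genomic_control(df)
            lams.append(gc.lam)
        assert np.mean(lams) == pytest.approx(1.0, abs=0.05)

    def test_adjusted_p_uniform_for_true_chi2_null(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({"chi2": rng.chisquare(1, 5000), "reason": REASON_OK})
        _, out = pt.genomic_control(df)
        assert stats.kstest(out["p_gc"], "uniform").pvalue > 0.01

    def test_deflation_not_clipped_by_default(self):
        df = pd.DataFrame({"chi2": np.full(200, CHI2_1_MEDIAN / 2),
                           "reason": REASON_OK})
        gc, _ = pt.genomic_control(df)
        assert gc.lam == pytest.approx(0.5)
        gc_c, _ = pt.genomic_control(df, clip=True)
        assert gc_c.lam == 1.0

    def test_needs_enough_sites(self):
        df = pd.DataFrame({"chi2": np.ones(10), "reason": REASON_OK})
        with pytest.raises(ValueError, match=">= 100"):
            pt.genomic_control(df)


class TestScanFilters:
    def make_sites(self, n_anc, maf):
        return pd.DataFrame({
            "chrom": "chr1", "pos": [100], "n_ancient_calls": [n_anc],
            "maf_ancient": [maf], "reason": [REASON_OK],
        })

    def test_39_ancient_calls_removed(self):
        out = pt.scan_filters(self.make_sites(39, 0.3))
        assert out.loc[0, "reason"] == REASON_LOW_CALLS

    def test_low_maf_removed(self):
        out = pt.scan_filters(self.make_sites(50, 0.04))
        assert out.loc[0, "reason"] == REASON_LOW_MAF

    def test_boundary_values_inclusive(self):
        out = pt.scan_filters(self.make_sites(40, 0.05))
        assert out.loc[0, "reason"] == REASON_OK


def brute_force_neighbourhood(df, window_bp=50_000, min_neighbours=7, frac=0.9):
    """O(n^2) oracle for the neighbourhood filter (centered window)."""
    out = df.copy()
    reason = out["reason"].to_numpy(dtype=object).copy()
    ok = reason == REASON_OK
    logp = -np.log10(out["p_gc"].to_numpy())
    chrom = out["chrom"].to_numpy()
    pos = out["pos"].to_numpy()
    for i in range(len(out)):
        if not ok[i]:
            continue
        count = 0
        for j in range(len(out)):
            if j == i or not ok[j] or chrom[j] != chrom[i]:
                continue
            if abs(pos[j] - pos[i]) <= window_bp / 2 and logp[j] >= frac * logp[i]:
                count += 1
        if count < min_neighbours:
            reason[i] = REASON_NEIGHBOURHOOD
    out["reason"] = reason
    return out


class TestNeighbourhoodFilter:
    def test_seven_strong_neighbours_retained(self):
        pos = [10_000 + 1000 * k for k in range(8)]
        p = [1e-10] + [1e-9] * 7  # focal needs 9 >= 0.9*10: yes
        out = pt.neighbourhood_filter(sites_frame(pos, p))
        assert out.loc[0, "reason"] == REASON_OK

    def test_six_qualifying_neighbours_removed(self):
        pos = [10_000 + 1000 * k for k in range(7)]
        p = [1e-10] + [1e-9] * 6
        out = pt.neighbourhood_filter(sites_frame(pos, p))
        assert out.loc[0, "reason"] == REASON_NEIGHBOURHOOD

    def test_weak_neighbours_do_not_count(self):
        pos = [10_000 + 1000 * k for k in range(8)]
        p = [1e-10] + [1e-8] * 7  # 8 < 0.9*10 -> none qualify
        out = pt.neighbourhood_filter(sites_frame(pos, p))
        assert out.loc[0, "reason"] == REASON_NEIGHBOURHOOD

    def test_isolated_site_removed(self):
        out = pt.neighbourhood_filter(sites_frame([100], [1e-10]))
        assert out.loc[0, "reason"] == REASON_NEIGHBOURHOOD

    def test_matches_bruteforce_oracle_exactly(self):
        rng = np.random.default_rng(17)
        n = 3000
        chroms = np.repeat(["chr1", "chr2"], n // 2)
        pos = np.concatenate([
            np.sort(rng.choice(np.arange(1, 900_000), n // 2, replace=False)),
            np.sort(rng.choice(np.arange(1, 900_000), n // 2, replace=False)),
        ])
        p = 10 ** (-rng.uniform(0, 12, n))
        df = pd.DataFrame({"chrom": chroms, "pos": pos, "p_gc": p,
                           "reason": REASON_OK})
        df.loc[rng.choice(n, 200, replace=False), "reason"] = REASON_LOW_MAF
        fast = pt.neighbourhood_filter(df)
        slow = brute_force_neighbourhood(df)
        assert list(fast["reason"]) == list(slow["reason"])

    def test_candidate_restriction_gives_same_verdicts(self):
        rng = np.random.default_rng(18)
        n = 2000
        pos = np.sort(rng.choice(np.arange(1, 500_000), n, replace=False))
        p = 10 ** (-rng.uniform(0, 12, n))
        df = pd.DataFrame({"chrom": "chr1", "pos": pos, "p_gc": p,
                           "reason": REASON_OK})
        cand = p < 1e-8
        full = pt.neighbourhood_filter(df)
        part = pt.neighbourhood_filter(df, candidates=cand)
        assert list(full.loc[cand, "reason"]) == list(part.loc[cand, "reason"])


class TestCallRegions:
    def test_no_significant_sites(self):
        out = pt.call_regions(sites_frame([100, 200], [0.5, 0.2]))
        assert len(out) == 0

    def test_pair_kept_lone_site_dropped(self):
        df = pd.concat([
            sites_frame([100_000, 110_000], [1e-9, 1e-10], chrom="chr1"),
            sites_frame([500_000], [1e-12], chrom="chr2"),
        ], ignore_index=True)
        out = pt.call_regions(df)
        assert len(out) == 1
        assert out.loc[0, "chrom"] == "chr1"
        assert out.loc[0, "n_sites"] == 2
        assert out.loc[0, "lead_pos"] == 110_000

    def test_sites_beyond_merge_distance_both_dropped(self):
        df = sites_frame([100_000, 160_000], [1e-9, 1e-10])
        out = pt.call_regions(df, merge_bp=50_000)
        assert len(out) == 0

    def test_non_retained_sites_cannot_seed_regions(self):
        df = sites_frame([100_000, 110_000], [1e-9, 1e-10],
                         reason=REASON_NEIGHBOURHOOD)
        assert len(pt.call_regions(df)) == 0


class TestScanDeterminismAndOrder:
    def test_sample_order_invariance(self, panmictic_serial_sim):
        ds = pt.degrade_to_pseudohaploid(panmictic_serial_sim, seed=31)
        perm = np.random.default_rng(0).permutation(ds.n_samples)
        shuffled = pt.GenotypeDataset(
            ds.sites.copy(), ds.calls[:, perm],
            ds.samples.iloc[perm].reset_index(drop=True),
        )
        _, s1, r1 = pt.run_scan(ds)
        _, s2, r2 = pt.run_scan(shuffled)
        assert np.allclose(s1["p_raw"], s2["p_raw"], equal_nan=True)
        assert r1.equals(r2)

    def test_rerun_identical(self, panmictic_serial_sim):
        ds = pt.degrade_to_pseudohaploid(panmictic_serial_sim, seed=31)
        out1 = pt.run_scan(ds)
        out2 = pt.run_scan(ds)
        assert out1[1].equals(out2[1])
        assert out1[2].equals(out2[2])

    def test_sweep_error_for_calibration(self, panmictic_serial_sim):
        swept = pt.inject_sweep_cluster(
            panmictic_serial_sim, "chr1", int(2e6), n_sites=8, span_bp=40_000,
            seed=3,
        )
        with pytest.raises(ValueError, match="not a neutral calibration"):
            pt.calibrate_neutral(swept)
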