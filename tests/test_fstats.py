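"""f-statistics: direct evaluations, algebraic symmetries, oracle equality,
jackknife calibration."""

import numpy as np
import pandas as pd
import pytest

import paleotempo as pt
from paleotempo.fstats import (
    f3_self,
    group_freqs,
    heterozygous_site_mask,
    jackknife_from_blocks,
)

from conftest import make_dataset


def freqs_from_matrix(p, n=None):
    """FreqTable straight from a frequency matrix (groups g0, g1, ...)."""
    p = np.asarray(p, dtype=float)
    S, G = p.shape
    n = np.full((S, G), 10, dtype=np.int64) if n is None else np.asarray(n)
    sites = pd.DataFrame(
        {"chrom": "chr1", "pos": np.arange(1, S + 1), "ref": "A", "alt": "C",
         "is_transversion": True}
    )
    return pt.FreqTable(groups=[f"g{i}" for i in range(G)], p=p, n=n, sites=sites)


def one_block(S):
    return pt.BlockAssignment(
        site_block=np.zeros(S, dtype=int),
        blocks=pd.DataFrame({"chrom": ["chr1"], "start": [1], "end": [S]}),
    )


def blocks_of(site_block):
    site_block = np.asarray(site_block)
    nb = site_block.max() + 1
    return pt.BlockAssignment(
        site_block=site_block,
        blocks=pd.DataFrame({"chrom": "chr1", "start": np.arange(nb), "end": np.arange(nb)}),
    )


class TestGroupFreqs:
    def test_single_pseudohaploid_sample(self):
        ds = make_dataset([[2], [0], [-1]], ploidy_modes=["pseudohaploid"])
        ft = group_freqs(ds, {"g": ["s0"]})
        assert ft.p[0, 0] == 1.0 and ft.n[0, 0] == 1
        assert ft.p[1, 0] == 0.0
        assert np.isnan(ft.p[2, 0]) and ft.n[2, 0] == 0

    def test_two_diploids(self):
        ds = make_dataset([[1, 2]])
        ft = group_freqs(ds, {"g": ["s0", "s1"]})
        assert ft.p[0, 0] == pytest.approx(3 / 4)
        assert ft.n[0, 0] == 4

    def test_mixed_ploidy_allele_weights(self):
        ds = make_dataset([[1, 2]], ploidy_modes=["diploid", "pseudohaploid"])
        ft = group_freqs(ds, {"g": ["s0", "s1"]})
        # diploid 1/2 alleles alt + pseudohaploid 1 alt allele = 2/3
        assert ft.p[0, 0] == pytest.approx(2 / 3)
        assert ft.n[0, 0] == 3

    def test_empty_group_rejected(self):
        ds = make_dataset([[0]])
        with pytest.raises(ValueError, match="empty"):
            group_freqs(ds, {"g": []})


class TestF4:
    def test_direct_evaluation(self):
        ft = freqs_from_matrix(np.array([
            [1, 0, 1, 0],
            [1, 0, 1, 0],
            [1, 0, 0, 0],
        ]))
        r = pt.f4("g0", "g1", "g2", "g3", ft, one_block(3))
        assert r.estimate == pytest.approx(2 / 3)
        assert r.n_sites == 3

    def test_identical_cd_gives_zero(self):
        rng = np.random.default_rng(0)
        p = rng.random((50, 3))
        ft = freqs_from_matrix(np.column_stack([p, p[:, 2]]))
        r = pt.f4("g0", "g1", "g2", "g3", ft, one_block(50))
        assert r.estimate == 0.0

    def test_antisymmetry_and_pair_swap(self):
        rng = np.random.default_rng(1)
        ft = freqs_from_matrix(rng.random((100, 4)))
        b = blocks_of(np.repeat(np.arange(5), 20))
        r = pt.f4("g0", "g1", "g2", "g3", ft, b)
        r_ab = pt.f4("g1", "g0", "g2", "g3", ft, b)
        r_sw = pt.f4("g2", "g3", "g0", "g1", ft, b)
        assert r_ab.estimate == pytest.approx(-r.estimate, abs=1e-15)
        assert r_ab.se == pytest.approx(r.se)
        assert r_sw.estimate == pytest.approx(r.estimate, abs=1e-15)

    def test_additivity_in_third_slot(self):
        rng = np.random.default_rng(2)
        ft = freqs_from_matrix(rng.random((80, 5)))
        b = one_block(80)
        full = pt.f4("g0", "g1", "g2", "g3", ft, b).estimate
        part1 = pt.f4("g0", "g1", "g2", "g4", ft, b).estimate
        part2 = pt.f4("g0", "g1", "g4", "g3", ft, b).estimate
        assert full == pytest.approx(part1 + part2, abs=1e-12)

    def test_distinct_groups_required(self):
        ft = freqs_from_matrix(np.random.default_rng(0).random((5, 3)))
        with pytest.raises(ValueError, match="distinct"):
            pt.f4("g0", "g1", "g2", "g2", ft, one_block(5))

    def test_zero_usable_sites_is_error_not_zero(self):
        p = np.full((4, 4), np.nan)
        ft = freqs_from_matrix(p)
        with pytest.raises(ValueError, match="zero usable"):
            pt.f4("g0", "g1", "g2", "g3", ft, one_block(4))


class TestF3:
    def test_direct_evaluation(self):
        ft = freqs_from_matrix([[0.5, 0.0, 1.0]])
        r = pt.f3("g0", "g1", "g2", ft, one_block(1))
        assert r.estimate == pytest.approx(-0.25)

    def test_collapse_to_f2(self):
        rng = np.random.default_rng(3)
        ft = freqs_from_matrix(rng.random((60, 2)))
        b = blocks_of(np.repeat(np.arange(4), 15))
        assert f3_self("g0", "g1", ft, b).estimate == pytest.approx(
            pt.f2("g0", "g1", ft, b).estimate
        )

    def test_fixed_identical_groups_give_zero(self):
        ft = freqs_from_matrix(np.ones((10, 3)))
        r = pt.f3("g0", "g1", "g2", ft, one_block(10))
        assert r.estimate == 0.0

    def test_corrected_needs_two_alleles(self):
        ft = freqs_from_matrix([[0.5, 0.1, 0.9]], n=np.array([[1, 10, 10]]))
        with pytest.raises(ValueError, match="count >= 2"):
            pt.f3("g0", "g1", "g2", ft, one_block(1), corrected=True)

    def test_correction_value(self):
        # correction per site is pA(1-pA)/(nA-1)
        ft = freqs_from_matrix([[0.5, 0.0, 1.0]], n=np.array([[6, 10, 10]]))
        r_unc = pt.f3("g0", "g1", "g2", ft, one_block(1))
        r_cor = pt.f3("g0", "g1", "g2", ft, one_block(1), corrected=True)
        assert r_unc.estimate - r_cor.estimate == pytest.approx(0.25 / 5)


class TestOracleEquivalence:
    """Estimators must equal naive per-site brute force to 1e-12."""

    def test_f_statistics_match_bruteforce(self, panmictic_serial_sim):
        ds = pt.degrade_to_pseudohaploid(panmictic_serial_sim, seed=21)
        ds = ds.take_sites(np.arange(ds.n_sites) < 1000)
        blocks = pt.assign_blocks(ds, 1e6)
        ft = group_freqs(ds)
        g = ft.groups  # modern, anc15, anc45, anc75
        r4 = pt.f4(g[0], g[1], g[2], g[3], ft, blocks)
        r3 = pt.f3(g[0], g[1], g[2], ft, blocks)
        r2 = pt.f2(g[0], g[1], ft, blocks)

        # brute force straight from the dosage matrix
        def naive_freq(site, group):
            tot = alt = 0.0
            for j in range(ds.n_samples):
                if ds.samples.group[j] != group or ds.calls[site, j] == -1:
                    continue
                w = 2 if ds.samples.ploidy_mode[j] == "diploid" else 1
                tot += w
                alt += ds.calls[site, j] * w / 2
            return (alt / tot) if tot else np.nan

        acc4, acc3, acc2 = [], [], []
        for s in range(ds.n_sites):
            p = [naive_freq(s, x) for x in g]
            if not np.isnan(p[:4]).any():
                acc4.append((p[0] - p[1]) * (p[2] - p[3]))
            if not np.isnan(p[:3]).any():
                acc3.append((p[0] - p[1]) * (p[0] - p[2]))
            if not np.isnan(p[:2]).any():
                acc2.append((p[0] - p[1]) ** 2)
        assert r4.estimate == pytest.approx(np.mean(acc4), abs=1e-12)
        assert r3.estimate == pytest.approx(np.mean(acc3), abs=1e-12)
        assert r2.estimate == pytest.approx(np.mean(acc2), abs=1e-12)


class TestJackknife:
    def test_se_matches_replicate_sd(self):
        """Jackknife SE should approximate the SD of the estimate across
        independent simulation replicates (within ~20%, averaged)."""
        ests, ses = [], []
        for seed in range(60, 84):
            cfg = pt.SimConfig(
                n_chromosomes=4, chrom_length_bp=2e6, mu=1.25e-8, rec=1e-8,
                populations=[(n, 10_000) for n in ["A", "B", "AB", "O", "R"]],
                events=[pt.Split(600, ["A", "B"], "AB"),
                        pt.Split(3000, ["AB", "O"], "R")],
                sampling=[pt.SampleSpec("A", 0, 4), pt.SampleSpec("B", 0, 4),
                          pt.SampleSpec("O", 0, 4)],
                seed=seed,
            )
            sim = pt.simulate_dataset(cfg)
            blocks = pt.assign_blocks(sim.dataset, 0.5e6)
            ft = group_freqs(sim.dataset)
            r = pt.f3("O", "A", "B", ft, blocks)
            ests.append(r.estimate)
            ses.append(r.se)
        sd = np.std(ests, ddof=1)
        mean_se = np.mean(ses)
        assert abs(mean_se - sd) / sd < 0.35  # 24 replicates: SD itself noisy

    def test_unequal_block_weighting(self):
        # one fat block + tiny blocks: weighted jackknife downweights the
        # small ones; a constant statistic still has SE 0
        sums = np.array([50.0, 1.0, 1.0])
        counts = np.array([100, 2, 2])
        est, se, n, b = jackknife_from_blocks(sums, counts)
        assert est == pytest.approx(0.5)
        assert se == pytest.approx(0.0, abs=1e-12)


class TestOutgroupF3Matrix:
    def test_ascertainment_and_diagonal(self, outgroup_tree_sim):
        ds = outgroup_tree_sim.dataset
        blocks = pt.assign_blocks(ds, 1e6)
        ind = ds.samples.sample_id[ds.samples.group == "O"].iloc[0]
        grouping = {"A": list(ds.samples.sample_id[ds.samples.group == "A"]),
                    "B": list(ds.samples.sample_id[ds.samples.group == "B"]),
                    "O": [s for s in ds.samples.sample_id[ds.samples.group == "O"]
                          if s != ind]}
        mat = pt.outgroup_f3_matrix(
            ["A", "B"], "O", ds, blocks, ascertainment_individual=ind,
            grouping=grouping,
        )
        est = mat.map(lambda r: r.estimate)
        # on a clean tree, self-affinity exceeds cross-affinity
        assert est.loc["A", "A"] > est.loc["A", "B"]
        assert est.loc["B", "B"] > est.loc["A", "B"]
        assert est.loc["A", "B"] == est.loc["B", "A"]

    def test_homozygous_ascertainment_individual_rejected(self):
        ds = make_dataset([[0, 2], [2, 0]])
        with pytest.raises(ValueError, match="heterozygous nowhere"):
            heterozygous_site_mask(ds, "s0")
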