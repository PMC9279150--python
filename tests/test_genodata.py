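"""Data model, I/O round trips, pseudohaploid calling and filters."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import paleotempo as pt
from paleotempo.genodata import (
    MISSING,
    PileupSite,
    _excess_het_pvalues,
    read_metadata,
)

from conftest import make_dataset


@pytest.fixture
def small_dataset():
    rng = np.random.default_rng(3)
    calls = rng.integers(0, 3, size=(10, 4)).astype(np.int8)
    calls[calls == 1] = 0  # columns 2,3 pseudohaploid below
    calls[:, :2] = rng.integers(0, 3, size=(10, 2))
    calls[0, 0] = MISSING
    return make_dataset(
        calls, ploidy_modes=["diploid", "diploid", "pseudohaploid", "pseudohaploid"],
        ages=[0, 0, 30_000, 50_000],
    )


class TestDatasetInvariants:
    def test_pseudohaploid_cannot_hold_dosage_one(self, small_dataset):
        bad = small_dataset.calls.copy()
        bad[1, 3] = 1
        with pytest.raises(ValueError, match="dosage 1"):
            pt.GenotypeDataset(small_dataset.sites, bad, small_dataset.samples)

    def test_positions_strictly_increasing(self, small_dataset):
        sites = small_dataset.sites.copy()
        sites.loc[1, "pos"] = sites.loc[0, "pos"]
        with pytest.raises(ValueError, match="increasing"):
            pt.GenotypeDataset(sites, small_dataset.calls, small_dataset.samples)


class TestRoundTrips:
    @pytest.mark.parametrize("fmt", ["eigenstrat", "vcf"])
    def test_write_read_identity(self, small_dataset, tmp_path, fmt):
        prefix = str(tmp_path / "ds")
        pt.write_dataset(small_dataset, prefix, fmt=fmt)
        back = pt.read_dataset(prefix + (".vcf" if fmt == "vcf" else ""), fmt=fmt,
                               metadata_path=prefix + ".meta.tsv")
        assert back == small_dataset

    def test_eigenstrat_nine_is_missing(self, small_dataset, tmp_path):
        prefix = str(tmp_path / "ds")
        pt.write_dataset(small_dataset, prefix)
        geno_line_0 = open(prefix + ".geno").readline().strip()
        assert geno_line_0[0] == "9"  # we blanked site 0 sample 0
        back = pt.read_dataset(prefix)
        assert back.calls[0, 0] == MISSING

    def test_sample_missing_from_metadata_is_named(self, small_dataset, tmp_path):
        prefix = str(tmp_path / "ds")
        pt.write_dataset(small_dataset, prefix)
        meta = pd.read_csv(prefix + ".meta.tsv", sep="\t")
        meta = meta[meta.sample_id != "s2"]
        meta.to_csv(prefix + ".meta.tsv", sep="\t", index=False)
        with pytest.raises(ValueError, match="s2"):
            pt.read_dataset(prefix)

    def test_metadata_requires_all_columns(self, tmp_path):
        path = tmp_path / "meta.tsv"
        pd.DataFrame({"sample_id": ["a"], "group": ["g"]}).to_csv(
            path, sep="\t", index=False)
        with pytest.raises(ValueError, match="age_bp"):
            read_metadata(str(path))


class TestPseudohaploidCall:
    REF, ALT = "A", "C"

    def pileup(self, bases, bq=40, mq=40, rlen=60):
        return PileupSite("chr1", 100, [(b, bq, mq, rlen) for b in bases])

    def test_no_reads_pass_thresholds_gives_missing(self):
        assert pt.pseudohaploid_call(
            self.pileup("AAAA", bq=10), self.REF, self.ALT, rng=0) == MISSING
        assert pt.pseudohaploid_call(
            self.pileup("AAAA", mq=10), self.REF, self.ALT, rng=0) == MISSING
        assert pt.pseudohaploid_call(
            self.pileup("AAAA", rlen=30), self.REF, self.ALT, rng=0) == MISSING
        assert pt.pseudohaploid_call(
            PileupSite("chr1", 100, []), self.REF, self.ALT, rng=0) == MISSING

    def test_unanimous_alt_reads_give_dosage_two(self):
        assert pt.pseudohaploid_call(self.pileup("CCC"), self.REF, self.ALT, rng=0) == 2

    def test_third_allele_read_gives_missing(self):
        assert pt.pseudohaploid_call(self.pileup("G"), self.REF, self.ALT, rng=0) == MISSING

    def test_uniform_draw_matches_read_fraction(self):
        # 3 ref + 1 alt: alt should be drawn ~25% of the time
        rng = np.random.default_rng(11)
        n = 10_000
        hits = sum(
            pt.pseudohaploid_call(self.pileup("AAAC"), self.REF, self.ALT, rng=rng) == 2
            for _ in range(n)
        )
        lo, hi = stats.binom.interval(0.99, n, 0.25)
        assert lo <= hits <= hi


class TestFilters:
    def test_depth_masking_thresholds(self):
        calls = np.full((3, 2), 1, dtype=np.int8)
        ds = make_dataset(calls)
        depth = np.array([[3, 10], [4, 10], [10, 10]], dtype=float)
        out = pt.filter_sites(
            ds, depth=depth, sample_mean_depth=np.array([10.0, 6.0]),
            max_missing=2,
        )
        # site0 sample0: 3 < 10/3 -> masked; site1 sample0: 4 < 5 floor -> masked
        assert out.calls[0, 0] == MISSING
        assert out.calls[1, 0] == MISSING
        assert out.calls[2, 0] == 1
        # sample 1 at depth 10 vs mean 6: 10 <= 12 -> kept
        assert (out.calls[:, 1] == 1).all()

    def test_transversion_restriction(self):
        calls = np.zeros((2, 2), dtype=np.int8)
        ds = make_dataset(calls)
        ds.sites.loc[0, ["ref", "alt"]] = ["C", "T"]  # transition
        ds.sites.loc[0, "is_transversion"] = False
        ds.sites.loc[1, ["ref", "alt"]] = ["C", "G"]
        out = pt.filter_sites(ds, max_missing=2, transversions_only=True)
        assert list(out.sites["ref"]) == ["C"]
        assert list(out.sites["alt"]) == ["G"]

    def test_missingness_site_removal(self):
        calls = np.array([[0, MISSING, MISSING], [0, 0, MISSING]], dtype=np.int8)
        ds = make_dataset(calls)
        out = pt.filter_sites(ds, max_missing=2)
        assert out.n_sites == 1

    def test_indel_carriers_masked(self):
        calls = np.array([[0, 2], [0, 2]], dtype=np.int8)
        ds = make_dataset(calls)
        ds.sites.loc[0, "alt"] = "CTT"  # indel allele
        out = pt.filter_sites(ds, max_missing=99)
        assert out.calls[0, 1] == MISSING  # carrier masked
        assert out.calls[0, 0] == 0  # non-carrier kept
        assert out.calls[1, 1] == 2

    def test_excess_heterozygosity_removal(self):
        # 12 diploids all heterozygous: gross HW excess
        n = 12
        calls = np.vstack([
            np.full(n, 1, dtype=np.int8),
            np.array([0, 2] * (n // 2), dtype=np.int8),
        ])
        ds = make_dataset(calls)
        pv = _excess_het_pvalues(ds)
        # all-het probability under Levene's exact distribution, n=12/12
        # alleles: 0.0015 (checked against a permutation Monte Carlo)
        assert pv[0] == pytest.approx(0.0015147, rel=1e-3)
        assert pv[1] > 0.5
        out = pt.filter_sites(ds, exchet_p=0.01, max_missing=n)
        assert out.n_sites == 1

    def test_filters_idempotent(self, panmictic_serial_sim):
        ds = pt.degrade_to_pseudohaploid(panmictic_serial_sim, seed=8)
        once = pt.filter_sites(ds, max_missing=5)
        twice = pt.filter_sites(once, max_missing=5)
        assert once == twice


class TestBlocks:
    def test_25mb_chromosome_gives_three_blocks(self):
        calls = np.zeros((3, 1), dtype=np.int8)
        ds = make_dataset(calls, start=1, step=12_000_000)  # 1, 12e6+1, 24e6+1
        ba = pt.assign_blocks(ds, 10e6)
        assert ba.n_blocks == 3
        assert list(ba.site_block) == [0, 1, 2]
        assert (ba.blocks["end"] - ba.blocks["start"] + 1).max() <= 10e6

    def test_canfam_like_genome_gives_about_225_blocks(self):
        # 38 autosome lengths summing to ~2.2 Gb (canFam3.1-like scale)
        rng = np.random.default_rng(0)
        lengths = rng.uniform(25e6, 123e6, 38)
        lengths *= 2.2e9 / lengths.sum()
        chrom_lengths = {f"chr{i+1}": int(l) for i, l in enumerate(lengths)}
        calls = np.zeros((38, 1), dtype=np.int8)
        sites = pd.DataFrame(
            {
                "chrom": list(chrom_lengths),
                "pos": 1,
                "ref": "A",
                "alt": "C",
                "is_transversion": True,
            }
        )
        samples = pd.DataFrame(
            {
                "sample_id": ["s0"], "group": ["g"], "age_bp": [0.0],
                "is_ancient": [False], "coverage": [1.0],
                "ploidy_mode": ["diploid"],
            }
        )
        ds = pt.GenotypeDataset(sites, calls, samples)
        ba = pt.assign_blocks(ds, 10e6, chrom_lengths=chrom_lengths)
        assert 215 <= ba.n_blocks <= 240

    def test_empty_chromosome_contributes_no_blocks(self):
        calls = np.zeros((2, 1), dtype=np.int8)
        ds = make_dataset(calls)
        ba = pt.assign_blocks(ds, 10e6)
        assert set(ba.blocks["chrom"]) == {"chr1"}

    def test_blocks_cover_all_sites(self, panmictic_serial_sim):
        ds = panmictic_serial_sim.dataset
        ba = pt.assign_blocks(ds, 1e6)
        assert (ba.site_block >= 0).all()
        # block boundaries respect chromosome boundaries
        for chrom, grp in ds.sites.groupby("chrom"):
            blocks_here = set(ba.site_block[grp.index])
            assert (ba.blocks.loc[sorted(blocks_here), "chrom"] == chrom).all()
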