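"""Genotype data model, file I/O, pseudohaploid calling and dataset-level filters.

The central container is :class:`GenotypeDataset`: a sites x samples matrix of
allele-dosage calls (diploid 0/1/2, pseudohaploid 0/2, ``-1`` = missing) with a
site table and per-sample metadata. Ancient samples genotyped from low-coverage
data are represented as pseudohaploid: a single sequencing read is drawn at
random per site and its allele reported as a homozygous dosage (0 or 2), the
standard convention for ancient DNA.

File formats: EIGENSTRAT (geno/snp/ind triplet, ``9`` = missing) and VCFv4.2,
plus a tab-separated sample metadata table with columns
``sample_id  group  age_bp  is_ancient  coverage``.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

MISSING = -1

#: purine<->purine and pyrimidine<->pyrimidine pairs (transitions)
_TRANSITIONS = {frozenset(("A", "G")), frozenset(("C", "T"))}

SAMPLE_COLUMNS = ["sample_id", "group", "age_bp", "is_ancient", "coverage"]


def is_transversion(ref: str, alt: str) -> bool:
    """True if ref/alt is a purine<->pyrimidine change (damage-immune class)."""
    return frozenset((ref.upper(), alt.upper())) not in _TRANSITIONS


@dataclass
class GenotypeDataset:
    """Sites x samples dosage matrix with site and sample metadata.

    Attributes
    ----------
    sites:
        DataFrame with columns ``chrom, pos, ref, alt, is_transversion``;
        positions 1-based, strictly increasing within each chromosome.
    calls:
        int8 array of shape (n_sites, n_samples); values in {0, 1, 2, -1}.
        Pseudohaploid samples never hold dosage 1.
    samples:
        DataFrame with columns ``sample_id, group, age_bp, is_ancient,
        coverage, ploidy_mode`` (``ploidy_mode`` in {"diploid",
        "pseudohaploid"}).
    """

    sites: pd.DataFrame
    calls: np.ndarray
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.sites), len(self.samples)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.sites)} sites x {len(self.samples)} samples"
            )
        self.sites = self.sites.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)
        if "ploidy_mode" not in self.samples.columns:
            self.samples["ploidy_mode"] = np.where(
                self.samples["is_ancient"], "pseudohaploid", "diploid"
            )
        self.validate()

    # -- invariants ----------------------------------------------------
    def validate(self) -> None:
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("calls contain values outside {0,1,2,-1}")
        for chrom, grp in self.sites.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")
        ph = (self.samples["ploidy_mode"] == "pseudohaploid").to_numpy()
        if ph.any() and np.any(self.calls[:, ph] == 1):
            raise ValueError("pseudohaploid sample holds dosage 1")

    # -- convenience ---------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, sample_id: str) -> int:
        idx = np.flatnonzero((self.samples["sample_id"] == sample_id).to_numpy())
        if len(idx) == 0:
            raise KeyError(f"unknown sample {sample_id!r}")
        return int(idx[0])

    def take_sites(self, mask: np.ndarray) -> "GenotypeDataset":
        mask = np.asarray(mask)
        return GenotypeDataset(
            sites=self.sites.loc[mask].reset_index(drop=True),
            calls=self.calls[mask],
            samples=self.samples.copy(),
        )

    def copy(self) -> "GenotypeDataset":
        return GenotypeDataset(
            self.sites.copy(), self.calls.copy(), self.samples.copy()
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeDataset):
            return NotImplemented
        return (
            self.sites.equals(other.sites)
            and np.array_equal(self.calls, other.calls)
            and self.samples[SAMPLE_COLUMNS + ["ploidy_mode"]].equals(
                other.samples[SAMPLE_COLUMNS + ["ploidy_mode"]]
            )
        )


@dataclass
class PileupSite:
    """Reads stacked on one site: (base, base_quality, mapping_quality, read_length)."""

    chrom: str
    pos: int
    reads: list  # list of (base, base_quality, mapping_quality, read_length)

    def __post_init__(self) -> None:
        for base, bq, mq, _ in self.reads:
            if bq < 0 or mq < 0:
                raise ValueError("qualities must be >= 0")


@dataclass
class BlockAssignment:
    """Per-site genomic block index plus the block table (for jackknifing)."""

    site_block: np.ndarray  # int array, len n_sites
    blocks: pd.DataFrame  # columns chrom, start, end (1-based inclusive)

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)


# ---------------------------------------------------------------------------
# pseudohaploid calling
# ---------------------------------------------------------------------------

def pseudohaploid_call(
    pileup: PileupSite,
    ref: str,
    alt: str,
    *,
    min_len: int = 35,
    min_mq: int = 20,
    min_bq: int = 30,
    rng=None,
) -> int:
    """Call one pseudohaploid dosage from a pileup.

    Reads shorter than ``min_len`` or below the mapping/base-quality cutoffs
    are discarded; one retained read is chosen uniformly at random and its
    base compared with the dataset alleles. A base matching neither allele
    yields a missing call, as does an empty (post-filter) pileup.
    """
    rng = np.random.default_rng(rng)
    kept = [
        base
        for base, bq, mq, rlen in pileup.reads
        if rlen >= min_len and mq >= min_mq and bq >= min_bq
    ]
    if not kept:
        return MISSING
    base = kept[int(rng.integers(len(kept)))]
    if base == ref:
        return 0
    if base == alt:
        return 2
    return MISSING


# ---------------------------------------------------------------------------
# site / genotype filters
# ---------------------------------------------------------------------------

def _excess_het_pvalues(dataset: GenotypeDataset) -> np.ndarray:
    """One-sided exact test for heterozygote excess, per site.

    Only diploid samples inform the test (pseudohaploid calls carry no
    heterozygosity). The P-value is the probability, under Hardy-Weinberg
    conditional on the observed allele counts, of at least the observed
    number of heterozygotes (Levene's exact distribution).
    """
    dip = (dataset.samples["ploidy_mode"] == "diploid").to_numpy()
    calls = dataset.calls[:, dip]
    pvals = np.ones(dataset.n_sites)
    for i in range(dataset.n_sites):
        row = calls[i]
        row = row[row != MISSING]
        n = len(row)
        if n < 2:
            continue
        n_het = int(np.sum(row == 1))
        n_alt = int(row.sum())
        n_ref = 2 * n - n_alt
        n_minor = min(n_ref, n_alt)
        hets = np.arange(n_minor % 2, n_minor + 1, 2)
        # Levene (1949) exact probabilities of het counts given allele counts
        logp = (
            hets * np.log(2)
            + _lfact(n)
            - _lfact((n_minor - hets) // 2)
            - _lfact(hets)
            - _lfact((2 * n - n_minor - hets) // 2)
        )
        logp -= _lfact(2 * n) - _lfact(n_minor) - _lfact(2 * n - n_minor)
        prob = np.exp(logp - logp.max())
        prob /= prob.sum()
        pvals[i] = prob[hets >= n_het].sum()
    return pvals


def _lfact(x):
    from scipy.special import gammaln

    return gammaln(np.asarray(x, dtype=float) + 1.0)


def filter_sites(
    dataset: GenotypeDataset,
    *,
    exchet_p: float = 1e-6,
    depth: np.ndarray | None = None,
    sample_mean_depth: np.ndarray | None = None,
    indel_carrier: np.ndarray | None = None,
    third_allele: np.ndarray | None = None,
    max_missing: int = 130,
    transversions_only: bool = False,
) -> GenotypeDataset:
    """Dataset-level filters, applied in fixed order.

    1. remove sites with excess heterozygosity (exact test P < ``exchet_p``);
    2. mask genotypes of indel-allele carriers (boolean sites x samples mask);
    3. mask genotypes whose depth is below a third of, or above twice, the
       sample's genome-wide mean, or below 5 reads;
    4. mask genotypes carrying a third allele (boolean mask);
    5. remove sites where ``max_missing`` or more samples are missing;
    6. optionally restrict to transversion sites.
    """
    ds = dataset.copy()
    keep = _excess_het_pvalues(ds) >= exchet_p
    ds = ds.take_sites(keep)
    calls = ds.calls

    def _subset(mask):
        return mask[keep] if mask is not None and mask.shape[0] == len(keep) else mask

    indel_carrier = _subset(indel_carrier)
    third_allele = _subset(third_allele)
    depth = _subset(depth)

    if indel_carrier is None:
        # derive from the site table: any non-SNP allele marks its carriers
        is_indel = (
            ds.sites["ref"].str.len().gt(1) | ds.sites["alt"].str.len().gt(1)
        ).to_numpy()
        if is_indel.any():
            indel_carrier = is_indel[:, None] & (calls > 0)
    if indel_carrier is not None:
        calls[indel_carrier] = MISSING
    if depth is not None:
        if sample_mean_depth is None:
            raise ValueError("depth filtering requires sample_mean_depth")
        mean = np.asarray(sample_mean_depth, dtype=float)[None, :]
        bad = (depth < mean / 3.0) | (depth > 2.0 * mean) | (depth < 5)
        calls[bad] = MISSING
    if third_allele is not None:
        calls[third_allele] = MISSING

    n_missing = np.sum(calls == MISSING, axis=1)
    if max_missing >= ds.n_samples:
        import warnings

        warnings.warn("max_missing >= sample count; missingness filter is vacuous")
    ds = GenotypeDataset(ds.sites, calls, ds.samples)
    ds = ds.take_sites(n_missing < max_missing)
    if transversions_only:
        ds = ds.take_sites(ds.sites["is_transversion"].to_numpy())
    return ds


# ---------------------------------------------------------------------------
# jackknife blocks
# ---------------------------------------------------------------------------

def assign_blocks(
    dataset: GenotypeDataset,
    block_size_bp: float = 10e6,
    chrom_lengths: dict | None = None,
) -> BlockAssignment:
    """Cut each chromosome into consecutive ``block_size_bp`` windows.

    Trailing partial windows form their own block. When ``chrom_lengths`` is
    given, blocks tile the full chromosome (empty blocks included so the
    expected block count is reproduced for a given genome build); otherwise
    blocks cover only the observed site range.
    """
    block_size = int(block_size_bp)
    site_block = np.full(dataset.n_sites, -1, dtype=int)
    rows = []
    offset = 0
    chroms = list(dict.fromkeys(dataset.sites["chrom"]))
    if chrom_lengths is not None:
        for c in chrom_lengths:
            if c not in chroms:
                chroms.append(c)
    for chrom in chroms:
        mask = (dataset.sites["chrom"] == chrom).to_numpy()
        pos = dataset.sites.loc[mask, "pos"].to_numpy()
        if chrom_lengths is not None and chrom in chrom_lengths:
            length = int(chrom_lengths[chrom])
        elif mask.any():
            length = int(pos.max())
        else:
            continue
        n_blocks = max(1, int(np.ceil(length / block_size)))
        if mask.any():
            site_block[mask] = offset + (pos - 1) // block_size
        for b in range(n_blocks):
            rows.append(
                {
                    "chrom": chrom,
                    "start": b * block_size + 1,
                    "end": min((b + 1) * block_size, length),
                }
            )
        offset += n_blocks
    blocks = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return BlockAssignment(site_block=site_block, blocks=blocks)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_metadata(path: str) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = set(SAMPLE_COLUMNS) - set(meta.columns)
    if missing:
        raise ValueError(f"metadata file lacks columns: {sorted(missing)}")
    meta["is_ancient"] = meta["is_ancient"].astype(bool)
    return meta


def write_metadata(samples: pd.DataFrame, path: str) -> None:
    samples[SAMPLE_COLUMNS].to_csv(path, sep="\t", index=False)


def write_dataset(dataset: GenotypeDataset, prefix: str, fmt: str = "eigenstrat") -> None:
    """Write geno/snp/ind (EIGENSTRAT) or a .vcf, plus the metadata TSV."""
    if fmt == "eigenstrat":
        _write_eigenstrat(dataset, prefix)
    elif fmt == "vcf":
        _write_vcf(dataset, prefix + ".vcf")
    else:
        raise ValueError(f"unknown format {fmt!r}")
    write_metadata(dataset.samples, prefix + ".meta.tsv")


def read_dataset(prefix: str, fmt: str = "eigenstrat", metadata_path: str | None = None) -> GenotypeDataset:
    metadata_path = metadata_path or prefix + ".meta.tsv"
    meta = read_metadata(metadata_path)
    if fmt == "eigenstrat":
        ds = _read_eigenstrat(prefix, meta)
    elif fmt == "vcf":
        path = prefix if prefix.endswith(".vcf") else prefix + ".vcf"
        ds = _read_vcf(path, meta)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return ds


def _geno_char(dosage: int) -> str:
    # EIGENSTRAT counts REFERENCE alleles; we store ALT dosage.
    return "9" if dosage == MISSING else str(2 - dosage)


def _write_eigenstrat(dataset: GenotypeDataset, prefix: str) -> None:
    lut = np.empty(4, dtype="U1")
    lut[[0, 1, 2]] = ["2", "1", "0"]
    lut[3] = "9"
    idx = dataset.calls.copy()
    idx[idx == MISSING] = 3
    with open(prefix + ".geno", "w") as fh:
        for row in lut[idx]:
            fh.write("".join(row) + "\n")
    with open(prefix + ".snp", "w") as fh:
        for i, s in dataset.sites.iterrows():
            fh.write(
                f"rs{i + 1}\t{s.chrom}\t0.0\t{int(s.pos)}\t{s.ref}\t{s.alt}\n"
            )
    with open(prefix + ".ind", "w") as fh:
        for _, s in dataset.samples.iterrows():
            fh.write(f"{s.sample_id}\tU\t{s.group}\n")


def _read_eigenstrat(prefix: str, meta: pd.DataFrame) -> GenotypeDataset:
    ind = pd.read_csv(
        prefix + ".ind", sep=r"\s+", header=None, names=["sample_id", "sex", "group"],
        dtype=str,
    )
    snp = pd.read_csv(
        prefix + ".snp", sep=r"\s+", header=None,
        names=["snp_id", "chrom", "gpos", "pos", "ref", "alt"], dtype={"chrom": str},
    )
    rows = []
    with open(prefix + ".geno") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if len(line) != len(ind):
                raise ValueError(f"{prefix}.geno line {lineno}: expected {len(ind)} genotypes")
            try:
                rows.append([int(c) for c in line])
            except ValueError as e:
                raise ValueError(f"{prefix}.geno line {lineno}: {e}") from None
    ref_count = np.array(rows, dtype=np.int8)
    calls = np.where(ref_count == 9, MISSING, 2 - ref_count).astype(np.int8)
    sites = pd.DataFrame(
        {
            "chrom": snp["chrom"],
            "pos": snp["pos"].astype(int),
            "ref": snp["ref"],
            "alt": snp["alt"],
        }
    )
    sites["is_transversion"] = [
        is_transversion(r, a) for r, a in zip(sites["ref"], sites["alt"])
    ]
    samples = _align_meta(list(ind["sample_id"]), meta)
    return GenotypeDataset(sites, calls, samples)


def _align_meta(sample_ids: list, meta: pd.DataFrame) -> pd.DataFrame:
    meta = meta.set_index("sample_id")
    unknown = [s for s in sample_ids if s not in meta.index]
    if unknown:
        raise ValueError(f"samples missing from metadata: {unknown}")
    out = meta.loc[sample_ids].reset_index()
    out["ploidy_mode"] = np.where(out["is_ancient"], "pseudohaploid", "diploid")
    return out


def _write_vcf(dataset: GenotypeDataset, path: str) -> None:
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    ph_map = {0: "0", 2: "1", MISSING: "."}
    ph = (dataset.samples["ploidy_mode"] == "pseudohaploid").to_numpy()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in dict.fromkeys(dataset.sites["chrom"]):
            maxpos = dataset.sites.loc[dataset.sites["chrom"] == chrom, "pos"].max()
            fh.write(f"##contig=<ID={chrom},length={int(maxpos) + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(dataset.samples["sample_id"])
            + "\n"
        )
        for i, s in dataset.sites.iterrows():
            gts = [
                ph_map[c] if ph[j] else gt_map[c]
                for j, c in enumerate(dataset.calls[i])
            ]
            fh.write(
                f"{s.chrom}\t{int(s.pos)}\t.\t{s.ref}\t{s.alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def _read_vcf(path: str, meta: pd.DataFrame) -> GenotypeDataset:
    from cyvcf2 import VCF

    vcf = VCF(path)
    sample_ids = list(vcf.samples)
    rows, calls = [], []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValueError(
                f"multi-allelic record at {rec.CHROM}:{rec.POS}; decompose first"
            )
        alt = rec.ALT[0]
        a = rec.genotype.array()[:, :-1]  # allele indices; -1 missing, -2 ploidy padding
        ploidy = (a != -2).sum(axis=1)
        absent = (a == -1).any(axis=1) | (ploidy == 0)
        alt_count = ((a > 0) & (a != -2)).sum(axis=1)
        dos = np.where(ploidy == 1, 2 * alt_count, alt_count)
        dos = np.where(absent, MISSING, dos)
        rows.append(
            {
                "chrom": rec.CHROM,
                "pos": rec.POS,
                "ref": rec.REF,
                "alt": alt,
                "is_transversion": is_transversion(rec.REF, alt),
            }
        )
        calls.append(dos.astype(np.int8))
    sites = pd.DataFrame(rows)
    samples = _align_meta(sample_ids, meta)
    return GenotypeDataset(sites, np.array(calls, dtype=np.int8), samples)


def write_regions_bed(regions: pd.DataFrame, path: str) -> None:
    """Regions (1-based inclusive start/end) as 0-based half-open BED."""
    with open(path, "w") as fh:
        for _, r in regions.iterrows():
            fh.write(f"{r.chrom}\t{int(r.start) - 1}\t{int(r.end)}\n")
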