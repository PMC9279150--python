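"""Coalescent generation of time-stamped genotype datasets.

Emulates the study design of a 100,000-year wolf time series: ancient samples
are serially sampled lineages (ages in years BP converted to whole
generations), genotypes are diploid truths that can be degraded to
pseudohaploid calls with coverage-dependent missingness, and selective sweeps
are imposed as deterministic logistic allele-frequency trajectories at chosen
sites. All simulated sites are flagged as transversions so that downstream
transversion-only filters pass them (post-mortem damage is out of scope).

The backward-in-time engine is msprime (Hudson coalescent with recombination);
chromosomes are simulated independently, which is exact for unlinked
chromosomes and keeps large multi-chromosome genomes affordable.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

import msprime

from .genodata import MISSING, GenotypeDataset


class ConfigError(ValueError):
    """Raised for inconsistent simulation configurations."""


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------

@dataclass
class Split:
    time: float  # generations
    derived: list
    ancestral: str
    kind: str = "split"


@dataclass
class Pulse:
    """Admixture pulse: ``derived`` is created at ``time`` from ``ancestral``
    populations with the given ``fractions`` (summing to 1)."""

    time: float
    derived: str
    ancestral: list
    fractions: list
    kind: str = "pulse_admixture"


@dataclass
class MigrationChange:
    time: float
    rate: float
    populations: list | None = None  # None = all pairs
    kind: str = "migration_change"


@dataclass
class SampleSpec:
    population: str
    age_years: float
    n: int
    mean_coverage: float = 1.0
    group: str | None = None
    is_ancient: bool | None = None  # default: age_years > 0

    def resolved_group(self) -> str:
        return self.group if self.group is not None else self.population

    def resolved_ancient(self) -> bool:
        return self.is_ancient if self.is_ancient is not None else self.age_years > 0


@dataclass
class SweepSpec:
    """Deterministic logistic sweep at one site.

    ``t_start_years > t_end_years`` (BP convention: the sweep starts at the
    older date); the derived allele sits at frequency ``p0`` before
    ``t_start_years`` and follows p(dt) = p0 / (p0 + (1-p0) exp(-s dt))
    (dt in generations since onset) until ``t_end_years``, after which it is
    held at the terminal value.
    """

    chromosome: str
    position: int
    s: float
    t_start_years: float
    t_end_years: float
    p0: float

    def __post_init__(self) -> None:
        if self.s < 0:
            raise ConfigError("selection coefficient s must be >= 0")
        if not (0 < self.p0 < 1):
            raise ConfigError("p0 must lie in (0, 1)")
        if self.t_start_years <= self.t_end_years:
            raise ConfigError("t_start_years must be older (larger) than t_end_years")

    def frequency_at(self, age_years: float, gen_years: float) -> float:
        if age_years >= self.t_start_years:
            return self.p0
        dt_years = self.t_start_years - max(age_years, self.t_end_years)
        dt = dt_years / gen_years
        return self.p0 / (self.p0 + (1.0 - self.p0) * np.exp(-self.s * dt))


def sweep_duration_generations(p0: float, p1: float, s: float) -> float:
    """Generations for a logistic trajectory to move from p0 to p1 at rate s."""
    return np.log(p1 * (1 - p0) / (p0 * (1 - p1))) / s


@dataclass
class SimConfig:
    """Fully determines a synthetic dataset (given ``seed``)."""

    n_chromosomes: int = 20
    chrom_length_bp: float = 10e6
    mu: float = 0.4e-8
    rec: float = 1e-8
    gen_years: float = 3.0
    populations: list = field(default_factory=lambda: [("pop0", 50_000)])
    events: list = field(default_factory=list)
    migration: list = field(default_factory=list)  # (pop_a, pop_b, rate)
    sampling: list = field(default_factory=list)
    sweep: SweepSpec | None = None
    seed: int = 1

    def validate(self) -> None:
        if self.mu < 0 or self.rec < 0:
            raise ConfigError("rates must be >= 0")
        if not self.sampling or sum(s.n for s in self.sampling) == 0:
            raise ConfigError("no samples scheduled")
        for s in self.sampling:
            if s.age_years < 0:
                raise ConfigError("sample ages must be >= 0")
        names = [p for p, _ in self.populations]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate population names")
        for ev in self.events:
            if isinstance(ev, Pulse):
                if not np.isclose(sum(ev.fractions), 1.0):
                    raise ConfigError("pulse fractions must sum to 1")
                if any(not (0 <= f <= 1) for f in ev.fractions):
                    raise ConfigError("pulse fractions must lie in [0, 1]")


@dataclass
class SimDataset:
    """True diploid genotypes plus the truth record behind them."""

    dataset: GenotypeDataset
    config: SimConfig
    truth: dict

    @property
    def ages(self) -> np.ndarray:
        return self.dataset.samples["age_bp"].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# demography construction
# ---------------------------------------------------------------------------

def _build_demography(config: SimConfig) -> msprime.Demography:
    dem = msprime.Demography()
    for name, ne in config.populations:
        dem.add_population(name=name, initial_size=float(ne))
    for a, b, rate in config.migration:
        dem.set_symmetric_migration_rate([a, b], rate)
    for ev in sorted(config.events, key=lambda e: e.time):
        if isinstance(ev, Split):
            dem.add_population_split(
                time=ev.time, derived=list(ev.derived), ancestral=ev.ancestral
            )
        elif isinstance(ev, Pulse):
            dem.add_admixture(
                time=ev.time,
                derived=ev.derived,
                ancestral=list(ev.ancestral),
                proportions=list(ev.fractions),
            )
        elif isinstance(ev, MigrationChange):
            if ev.populations:
                for i, a in enumerate(ev.populations):
                    for b in ev.populations[i + 1:]:
                        dem.add_symmetric_migration_rate_change(
                            time=ev.time, populations=[a, b], rate=ev.rate
                        )
            else:
                dem.add_migration_rate_change(time=ev.time, rate=ev.rate)
        else:
            raise ConfigError(f"unknown event {ev!r}")
    dem.sort_events()
    return dem


_TRANSVERSION_PAIRS = [("A", "C"), ("A", "T"), ("C", "G"), ("G", "T")]


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def simulate_dataset(config: SimConfig) -> SimDataset:
    """Simulate the configured demography and sampling schedule.

    Returns biallelic variant sites with true diploid genotypes for every
    scheduled sample; positions are strictly increasing within chromosomes
    and the output is a deterministic function of ``config`` (incl. seed).
    """
    config.validate()
    try:
        dem = _build_demography(config)
        dem.validate()
    except Exception as e:  # msprime raises several exception types here
        raise ConfigError(str(e)) from e

    sample_sets = []
    meta_rows = []
    for spec in config.sampling:
        gens = int(round(spec.age_years / config.gen_years))
        sample_sets.append(
            msprime.SampleSet(spec.n, population=spec.population, time=gens, ploidy=2)
        )
        for k in range(spec.n):
            meta_rows.append(
                {
                    "sample_id": f"{spec.resolved_group()}_{spec.age_years:g}_{k}",
                    "group": spec.resolved_group(),
                    "age_bp": float(spec.age_years),
                    "is_ancient": spec.resolved_ancient(),
                    "coverage": float(spec.mean_coverage),
                }
            )
    samples = pd.DataFrame(meta_rows)
    if samples["sample_id"].duplicated().any():
        samples["sample_id"] = [
            f"{sid}_{i}" for i, sid in enumerate(samples["sample_id"])
        ]
    n_ind = len(samples)

    ss = np.random.SeedSequence(config.seed)
    chrom_seeds = ss.generate_state(2 * config.n_chromosomes + 1, dtype=np.uint64)
    allele_rng = np.random.default_rng(ss.spawn(1)[0])

    site_frames = []
    call_blocks = []
    for c in range(config.n_chromosomes):
        chrom = f"chr{c + 1}"
        anc_seed = int(chrom_seeds[2 * c] % (2**31 - 1)) + 1
        mut_seed = int(chrom_seeds[2 * c + 1] % (2**31 - 1)) + 1
        ts = msprime.sim_ancestry(
            samples=sample_sets,
            demography=dem,
            sequence_length=config.chrom_length_bp,
            recombination_rate=config.rec,
            random_seed=anc_seed,
        )
        if config.mu > 0:
            ts = msprime.sim_mutations(
                ts,
                rate=config.mu,
                random_seed=mut_seed,
                model=msprime.BinaryMutationModel(),
                discrete_genome=True,
            )
        if ts.num_sites == 0:
            continue
        G = ts.genotype_matrix()  # sites x haplotypes, 0/1
        dos = (G[:, 0::2] + G[:, 1::2]).astype(np.int8)
        pos = np.array([int(s.position) for s in ts.sites()])
        # keep segregating, biallelic (binary model guarantees <=2 alleles)
        seg = (dos.sum(axis=1) > 0) & (dos.sum(axis=1) < 2 * n_ind)
        # discrete genome: guard against duplicate integer positions
        uniq = np.concatenate([[True], np.diff(pos) > 0])
        keep = seg & uniq
        dos, pos = dos[keep], pos[keep]
        pairs = [
            _TRANSVERSION_PAIRS[i]
            for i in allele_rng.integers(0, len(_TRANSVERSION_PAIRS), len(pos))
        ]
        site_frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos + 1,  # 1-based
                    "ref": [p[0] for p in pairs],
                    "alt": [p[1] for p in pairs],
                    "is_transversion": True,
                }
            )
        )
        call_blocks.append(dos)

    if site_frames:
        sites = pd.concat(site_frames, ignore_index=True)
        calls = np.concatenate(call_blocks, axis=0)
    else:
        sites = pd.DataFrame(
            columns=["chrom", "pos", "ref", "alt", "is_transversion"]
        )
        calls = np.zeros((0, n_ind), dtype=np.int8)

    samples = samples.copy()
    samples["ploidy_mode"] = "diploid"  # truths are diploid; degrade later
    dataset = GenotypeDataset(sites, calls, samples)
    truth = {
        "populations": {p: ne for p, ne in config.populations},
        "admixture": [
            {
                "derived": ev.derived,
                "ancestral": list(ev.ancestral),
                "fractions": list(ev.fractions),
                "time": ev.time,
            }
            for ev in config.events
            if isinstance(ev, Pulse)
        ],
        "sweep": None,
        "genome_length_bp": config.n_chromosomes * config.chrom_length_bp,
    }
    return SimDataset(dataset=dataset, config=config, truth=truth)


# ---------------------------------------------------------------------------
# sweep injection
# ---------------------------------------------------------------------------

def _apply_sweep(sim: SimDataset, dataset: GenotypeDataset, spec: SweepSpec,
                 rng) -> None:
    ds = sim.dataset
    idx = np.flatnonzero(
        (ds.sites["chrom"] == spec.chromosome).to_numpy()
        & (ds.sites["pos"] == spec.position).to_numpy()
    )
    if len(idx) == 0:
        raise ConfigError(
            f"position {spec.chromosome}:{spec.position} not among simulated sites"
        )
    ages = ds.samples["age_bp"].to_numpy(dtype=float)
    if not (ages > spec.t_start_years).any() or not (ages < spec.t_end_years).any():
        raise ConfigError("need samples both older than t_start and younger than t_end")
    p = np.array([spec.frequency_at(a, sim.config.gen_years) for a in ages])
    dataset.calls[idx[0]] = rng.binomial(2, p).astype(np.int8)


def inject_sweep(sim: SimDataset, spec: SweepSpec, seed: int = 0) -> SimDataset:
    """Overwrite the genotypes at the selected site with the sweep trajectory.

    Each sample's diploid dosage is redrawn as Binomial(2, p(age)) where p
    follows the deterministic logistic trajectory of ``spec``. Only the
    selected site is rewritten (linked hitchhiking is emulated by injecting
    clusters of co-selected sites, see :func:`inject_sweep_cluster`).
    """
    rng = np.random.default_rng(seed)
    new = sim.dataset.copy()
    _apply_sweep(sim, new, spec, rng)
    truth = dict(sim.truth)
    swept = list(truth.get("sweep") or [])
    swept.append(
        {
            "chrom": spec.chromosome,
            "pos": int(spec.position),
            "s": spec.s,
            "t_start_years": spec.t_start_years,
            "t_end_years": spec.t_end_years,
            "p0": spec.p0,
        }
    )
    truth["sweep"] = swept
    return SimDataset(dataset=new, config=sim.config, truth=truth)


def inject_sweep_cluster(
    sim: SimDataset,
    chromosome: str,
    center_bp: int,
    *,
    n_sites: int = 10,
    span_bp: int = 24_000,
    s: float = 0.05,
    t_start_years: float = 40_000,
    t_end_years: float = 30_000,
    p0: float = 0.01,
    seed: int = 0,
) -> SimDataset:
    """Rewrite the ``n_sites`` existing sites nearest ``center_bp`` (within
    ``span_bp``) as co-selected copies of one swept haplotype.

    This emulates the site cluster left by a selective sweep without a
    forward simulator; the temporal scan detects the cluster, exercising the
    neighbourhood filter.
    """
    ds = sim.dataset
    on_chrom = (ds.sites["chrom"] == chromosome).to_numpy()
    pos = ds.sites["pos"].to_numpy()
    cand = np.flatnonzero(on_chrom & (np.abs(pos - center_bp) <= span_bp / 2))
    if len(cand) < n_sites:
        raise ConfigError(
            f"only {len(cand)} sites within {span_bp} bp of "
            f"{chromosome}:{center_bp}; need {n_sites}"
        )
    order = cand[np.argsort(np.abs(pos[cand] - center_bp))][:n_sites]
    rng = np.random.default_rng(seed)
    new = sim.dataset.copy()
    truth = dict(sim.truth)
    swept = list(truth.get("sweep") or [])
    for i in sorted(order):
        spec = SweepSpec(
            chromosome=chromosome,
            position=int(pos[i]),
            s=s,
            t_start_years=t_start_years,
            t_end_years=t_end_years,
            p0=p0,
        )
        _apply_sweep(sim, new, spec, rng)
        swept.append(
            {"chrom": chromosome, "pos": int(pos[i]), "s": s,
             "t_start_years": t_start_years, "t_end_years": t_end_years,
             "p0": p0}
        )
    truth["sweep"] = swept
    return SimDataset(dataset=new, config=sim.config, truth=truth)


# ---------------------------------------------------------------------------
# pseudohaploid degradation
# ---------------------------------------------------------------------------

def degrade_to_pseudohaploid(
    sim: SimDataset | GenotypeDataset,
    coverage: np.ndarray | dict | None = None,
    seed: int = 0,
) -> GenotypeDataset:
    """Degrade ancient samples to pseudohaploid calls with missingness.

    Each ancient sample's call becomes a single allele drawn from its true
    diploid genotype (dosage 0 or 2) and is set missing with probability
    exp(-coverage) — the Poisson zero-read class. Modern (non-ancient)
    samples keep their diploid calls. ``coverage`` defaults to the per-sample
    metadata coverage.
    """
    ds = sim.dataset if isinstance(sim, SimDataset) else sim
    rng = np.random.default_rng(seed)
    out = ds.copy()
    cov = out.samples["coverage"].to_numpy(dtype=float).copy()
    if coverage is not None:
        if isinstance(coverage, dict):
            for sid, c in coverage.items():
                cov[out.sample_index(sid)] = c
        else:
            cov = np.asarray(coverage, dtype=float)
    if np.any(cov < 0):
        raise ConfigError("coverages must be >= 0")
    ancient = out.samples["is_ancient"].to_numpy()
    anc = np.flatnonzero(ancient)
    if len(anc):
        sub = out.calls[:, anc]
        hap = sub.copy()
        hets = sub == 1
        hap[hets] = (2 * rng.integers(0, 2, int(hets.sum()))).astype(np.int8)
        miss = rng.random(sub.shape) < np.exp(-cov[anc])[None, :]
        hap[miss | (sub == MISSING)] = MISSING
        out.calls[:, anc] = hap
    out.samples.loc[ancient, "ploidy_mode"] = "pseudohaploid"
    out.validate()
    return out


# ---------------------------------------------------------------------------
# study-design default and summaries
# ---------------------------------------------------------------------------

def default_study_config(
    seed: int = 1,
    *,
    n_chromosomes: int = 20,
    chrom_length_bp: float = 10e6,
    n_ancient: int = 72,
    n_modern: int = 68,
    ne: float = 50_000,
    ancient_coverage: float = 1.0,
) -> SimConfig:
    """The neutral panmictic study design: ``n_ancient`` ancient samples with
    ages uniform on [1, 100] kyr BP plus ``n_modern`` modern samples, Ne as
    given, mu = 0.4e-8 / generation, 3-year generations."""
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xA6E5)))
    ages = np.sort(rng.uniform(1_000, 100_000, n_ancient))[::-1]
    sampling = [
        SampleSpec("pop0", float(a), 1, mean_coverage=ancient_coverage)
        for a in ages
    ]
    sampling.append(SampleSpec("pop0", 0.0, n_modern, mean_coverage=30.0))
    return SimConfig(
        n_chromosomes=n_chromosomes,
        chrom_length_bp=chrom_length_bp,
        populations=[("pop0", ne)],
        sampling=sampling,
        seed=seed,
    )


def dual_ancestry_design(
    alpha: float,
    seed: int = 1,
    *,
    n_chromosomes: int = 9,
    chrom_length_bp: float = 6e6,
    ne: float = 10_000,
    target_coverage: float = 2.0,
) -> SimConfig:
    """Two diverged source populations, an admixed target, and reference
    populations for admixture-weight recovery experiments.

    A "western" and an "eastern" clade split deep in the tree; the target is
    created by a single pulse drawing fraction ``alpha`` from the western
    true progenitor into an eastern background. Each true progenitor has a
    sampled sister population serving as its source proxy; two references
    per clade, a mid-depth reference and a deep outgroup give the right set
    the differential relatedness the weights are estimated from. The target
    is sampled as an ancient (pseudohaploidisable) population.

    Left = target + {SrcW, SrcE}; right = {Out, RefW1, RefW2, RefE1, RefE2,
    RefMid}. The truth record carries ``alpha``.
    """
    names = [
        "Target", "SrcW", "SrcE", "TrueW", "TrueE",
        "RefW1", "RefW2", "RefE1", "RefE2", "RefMid", "Out",
        "AncW", "AncW2", "AncW3", "AncE", "AncE2", "AncE3",
        "AncWE", "AncWE2", "Root",
    ]
    events = [
        Pulse(100, "Target", ["TrueW", "TrueE"], [alpha, 1 - alpha]),
        Split(250, ["TrueW", "SrcW"], "AncW"),
        Split(250, ["TrueE", "SrcE"], "AncE"),
        Split(500, ["AncW", "RefW1"], "AncW2"),
        Split(500, ["AncE", "RefE1"], "AncE2"),
        Split(800, ["AncW2", "RefW2"], "AncW3"),
        Split(800, ["AncE2", "RefE2"], "AncE3"),
        Split(1500, ["AncW3", "AncE3"], "AncWE"),
        Split(2000, ["AncWE", "RefMid"], "AncWE2"),
        Split(4000, ["AncWE2", "Out"], "Root"),
    ]
    sampling = [
        SampleSpec("Target", 0.0, 8, mean_coverage=target_coverage, is_ancient=True),
        SampleSpec("SrcW", 0.0, 6),
        SampleSpec("SrcE", 0.0, 6),
    ]
    for r in ["RefW1", "RefW2", "RefE1", "RefE2", "RefMid", "Out"]:
        sampling.append(SampleSpec(r, 0.0, 4))
    return SimConfig(
        n_chromosomes=n_chromosomes,
        chrom_length_bp=chrom_length_bp,
        mu=1.25e-8,
        rec=1e-8,
        populations=[(n, ne) for n in names],
        events=events,
        sampling=sampling,
        seed=seed,
    )


DUAL_ANCESTRY_LEFT = ("Target", "SrcW", "SrcE")
DUAL_ANCESTRY_RIGHT = ("Out", "RefW1", "RefW2", "RefE1", "RefE2", "RefMid")


def single_population_design(
    seed: int = 1,
    *,
    n_groups: int = 6,
    n_per_group: int = 5,
    n_chromosomes: int = 24,
    chrom_length_bp: float = 0.3e6,
    ne: float = 10_000,
) -> SimConfig:
    """One panmictic population sampled as several nominal groups — the null
    design for qpWave calibration (any group partition is one ancestry
    stream). Many short chromosomes give genuinely independent jackknife
    blocks (one per chromosome)."""
    sampling = [
        SampleSpec("pop0", 0.0, n_per_group, group=f"g{k}")
        for k in range(n_groups)
    ]
    return SimConfig(
        n_chromosomes=n_chromosomes,
        chrom_length_bp=chrom_length_bp,
        mu=1e-8,
        rec=1e-8,
        populations=[("pop0", ne)],
        sampling=sampling,
        seed=seed,
    )


def mean_pairwise_diversity(sim: SimDataset, sample_a: str, sample_b: str) -> float:
    """Per-bp probability that random alleles from the two samples differ.

    Averages, per site, p_a(1-p_b) + p_b(1-p_a) with p = dosage/2, then
    divides by total genome length (monomorphic sites count as zero).
    """
    ds = sim.dataset
    ia, ib = ds.sample_index(sample_a), ds.sample_index(sample_b)
    a = ds.calls[:, ia].astype(float)
    b = ds.calls[:, ib].astype(float)
    ok = (a != MISSING) & (b != MISSING)
    pa, pb = a[ok] / 2.0, b[ok] / 2.0
    diff = pa * (1 - pb) + pb * (1 - pa)
    return float(diff.sum() / sim.truth["genome_length_bp"])


def write_truth(sim: SimDataset, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(sim.truth, fh, indent=1, default=float)
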