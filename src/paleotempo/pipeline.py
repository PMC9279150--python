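"""Configuration-driven orchestration of the analysis stages.

A single YAML document drives a run: either a ``simulate`` block (coalescent
generation of a time-stamped dataset) or an ``input`` block (existing
genotypes + metadata), followed by any subset of the analysis stages. All
randomness derives from one root seed through named substreams, so a rerun
with the same configuration reproduces every output bit for bit; the run
manifest records parameters, seeds, output paths, content hashes and wall
times per stage.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import fstats, genodata, popsum, qpadm, simdata, structure, tempscan

KNOWN_KEYS = {"seed", "outdir", "stages", "simulate", "input", "filter",
              "fstats", "pca", "qpadm", "scan", "summaries", "block_size_bp"}
STAGES = ["simulate", "filter", "fstats", "pca", "qpadm", "scan", "summaries"]
_NEEDS_GENOTYPES = {"filter", "fstats", "pca", "qpadm", "scan", "summaries"}


def load_config(path: str) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def validate_config(config: dict) -> list:
    """Return a list of human-readable violations; empty iff runnable."""
    v = []
    unknown = set(config) - KNOWN_KEYS
    if unknown:
        v.append(f"unknown keys: {sorted(unknown)}")
    seed = config.get("seed", 0)
    if not isinstance(seed, int) or seed < 0:
        v.append("seed: must be a non-negative integer")
    stages = config.get("stages", [])
    if not stages:
        v.append("stages: at least one stage required")
    bad = [s for s in stages if s not in STAGES]
    if bad:
        v.append(f"stages: unknown stage(s) {bad}")
    has_geno = "simulate" in stages or "input" in config
    for s in stages:
        if s in _NEEDS_GENOTYPES and not has_geno:
            v.append(f"{s}: requires genotypes (simulate stage or input block)")
    if "scan" in stages and "input" in config:
        meta = config["input"].get("metadata")
        if meta is None:
            v.append("scan: input block lacks metadata (need age_bp per sample)")
        elif Path(meta).exists():
            try:
                genodata.read_metadata(meta)
            except ValueError as e:
                v.append(f"scan: metadata invalid ({e}); need age_bp")
    if "simulate" in stages:
        sim = config.get("simulate", {})
        if not sim.get("sampling"):
            v.append("simulate.sampling: at least one sampling entry required")
        for ev in sim.get("events", []):
            if ev.get("kind") == "pulse_admixture":
                fr = ev.get("fractions", [])
                if abs(sum(fr) - 1.0) > 1e-9:
                    v.append("simulate.events: pulse fractions must sum to 1")
    return v


def _sim_config_from_dict(block: dict, seed: int) -> simdata.SimConfig:
    events = []
    for ev in block.get("events", []):
        kind = ev.get("kind")
        if kind == "split":
            events.append(simdata.Split(ev["time"], ev["derived"], ev["ancestral"]))
        elif kind == "pulse_admixture":
            events.append(
                simdata.Pulse(ev["time"], ev["derived"], ev["ancestral"], ev["fractions"])
            )
        elif kind == "migration_change":
            events.append(
                simdata.MigrationChange(ev["time"], ev["rate"], ev.get("populations"))
            )
        else:
            raise simdata.ConfigError(f"unknown event kind {kind!r}")
    sampling = [
        simdata.SampleSpec(
            s["population"], float(s["age_years"]), int(s["n"]),
            mean_coverage=float(s.get("mean_coverage", 1.0)),
            group=s.get("group"), is_ancient=s.get("is_ancient"),
        )
        for s in block.get("sampling", [])
    ]
    return simdata.SimConfig(
        n_chromosomes=int(block.get("n_chromosomes", 5)),
        chrom_length_bp=float(block.get("chrom_length_bp", 5e6)),
        mu=float(block.get("mu", 0.4e-8)),
        rec=float(block.get("rec", 1e-8)),
        gen_years=float(block.get("gen_years", 3.0)),
        populations=[(p["name"], float(p["ne"])) for p in
                     block.get("populations", [{"name": "pop0", "ne": 50_000}])],
        events=events,
        migration=[tuple(m) for m in block.get("migration", [])],
        sampling=sampling,
        seed=seed,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run(config: dict, outdir: str | None = None) -> dict:
    """Execute the configured stages in dependency order.

    Returns the manifest (also written to ``manifest.json``). A stage
    failure marks the stage failed, skips downstream stages and is
    reflected in the manifest.
    """
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid config: " + "; ".join(violations))
    out = Path(outdir or config.get("outdir", "paleotempo_run"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    stages = [s for s in STAGES if s in config.get("stages", [])]
    manifest = {"seed": seed, "stages": {}, "outputs": {}}
    dataset = None
    failed = False

    def record(stage, status, t0, outputs=(), extra=None):
        manifest["stages"][stage] = {
            "status": status,
            "wall_s": round(time.time() - t0, 3),
            "outputs": [str(p) for p in outputs],
            **(extra or {}),
        }
        for p in outputs:
            manifest["outputs"][str(p)] = _sha256(Path(p))

    def stage_seed(stage):
        return int(
            np.random.SeedSequence((seed, STAGES.index(stage))).generate_state(1)[0]
            % 2**31
        )

    if "input" in config and "simulate" not in stages:
        blk = config["input"]
        dataset = genodata.read_dataset(
            blk["prefix"], blk.get("format", "eigenstrat"), blk.get("metadata")
        )

    for stage in stages:
        if failed:
            manifest["stages"][stage] = {"status": "skipped"}
            continue
        t0 = time.time()
        try:
            if stage == "simulate":
                cfg = _sim_config_from_dict(config.get("simulate", {}), stage_seed(stage))
                sim = simdata.simulate_dataset(cfg)
                dataset = simdata.degrade_to_pseudohaploid(sim, seed=stage_seed(stage) + 1)
                prefix = str(out / "simulated")
                genodata.write_dataset(dataset, prefix)
                simdata.write_truth(sim, prefix + ".truth.json")
                record(stage, "completed", t0,
                       [prefix + e for e in (".geno", ".snp", ".ind", ".meta.tsv", ".truth.json")],
                       {"n_sites": dataset.n_sites})
            elif stage == "filter":
                params = config.get("filter", {})
                dataset = genodata.filter_sites(
                    dataset,
                    exchet_p=float(params.get("exchet_p", 1e-6)),
                    max_missing=int(params.get("max_missing", 130)),
                    transversions_only=bool(params.get("transversions_only", False)),
                )
                prefix = str(out / "filtered")
                genodata.write_dataset(dataset, prefix)
                record(stage, "completed", t0,
                       [prefix + e for e in (".geno", ".snp", ".ind", ".meta.tsv")],
                       {"n_sites": dataset.n_sites})
            elif stage == "fstats":
                params = config.get("fstats", {})
                blocks = genodata.assign_blocks(
                    dataset, float(config.get("block_size_bp", 10e6)))
                freqs = fstats.group_freqs(dataset, params.get("grouping"))
                rows = []
                for spec in params.get("stats", []):
                    pops = spec["pops"]
                    if spec["stat"] == "f4":
                        r = fstats.f4(*pops, freqs, blocks)
                    elif spec["stat"] == "f3":
                        r = fstats.f3(*pops, freqs, blocks,
                                      corrected=spec.get("corrected", False))
                    else:
                        r = fstats.f2(*pops, freqs, blocks)
                    rows.append({
                        "stat": r.kind, **{f"pop{i+1}": p for i, p in enumerate(r.pops)},
                        "estimate": r.estimate, "se": r.se, "z": r.z,
                        "n_sites": r.n_sites, "n_blocks": r.n_blocks,
                    })
                path = out / "fstats.tsv"
                pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
                record(stage, "completed", t0, [path])
            elif stage == "pca":
                params = config.get("pca", {})
                blocks = genodata.assign_blocks(
                    dataset, float(config.get("block_size_bp", 10e6)))
                fit = params["fit"]
                project = params.get("project", [])
                outgroup = params["outgroup"]
                mat = fstats.outgroup_f3_matrix(
                    fit + project, outgroup, dataset, blocks,
                    ascertainment_individual=params.get("ascertain_het_in"),
                )
                dd = structure.f3_distance_matrix(fstats.estimates_matrix(mat))
                res = structure.pca_fit_project(
                    dd, fit, project, n_components=int(params.get("components", 2)),
                    seed=stage_seed(stage),
                )
                path = out / "pca_coords.tsv"
                res.coords.to_csv(path, sep="\t")
                record(stage, "completed", t0, [path])
            elif stage == "qpadm":
                params = config.get("qpadm", {})
                blocks = genodata.assign_blocks(
                    dataset, float(config.get("block_size_bp", 10e6)))
                freqs = fstats.group_freqs(dataset, params.get("grouping"))
                if "rotate" in params:
                    rep = qpadm.rotate_models(
                        params["target"], params["rotate"], freqs, blocks,
                        max_sources=int(params.get("max_sources", 3)),
                        p_threshold=float(params.get("p_threshold", 0.01)),
                    )
                    table = qpadm.report_table(rep)
                else:
                    m = qpadm.qpadm_fit(
                        params["target"], params["sources"], params["right"],
                        freqs, blocks,
                    )
                    table = qpadm.report_table(
                        qpadm.ModelSearchReport(m.target, (), [m], m))
                path = out / "qpadm_models.tsv"
                table.to_csv(path, sep="\t", index=False)
                record(stage, "completed", t0, [path])
            elif stage == "scan":
                params = config.get("scan", {})
                gc, sites, regions = tempscan.run_scan(
                    dataset,
                    alpha=float(params.get("alpha", 5e-8)),
                    min_ancient_calls=int(params.get("min_ancient_calls", 40)),
                    min_maf_ancient=float(params.get("min_maf_ancient", 0.05)),
                    window_bp=int(params.get("window_bp", 50_000)),
                    min_neighbours=int(params.get("min_neighbours", 7)),
                    frac=float(params.get("frac", 0.9)),
                    merge_bp=int(params.get("merge_bp", 50_000)),
                )
                sites_path = out / "scan_sites.tsv"
                regions_path = out / "scan_regions.tsv"
                bed_path = out / "scan_regions.bed"
                sites.to_csv(sites_path, sep="\t", index=False)
                regions.to_csv(regions_path, sep="\t", index=False)
                genodata.write_regions_bed(regions, str(bed_path))
                record(stage, "completed", t0, [sites_path, regions_path, bed_path],
                       {"lambda": gc.lam, "n_regions": len(regions)})
            elif stage == "summaries":
                params = config.get("summaries", {})
                outputs = []
                if "pools" in params:
                    blocks = genodata.assign_blocks(
                        dataset, float(config.get("block_size_bp", 10e6)))
                    res = popsum.pairwise_fst(
                        dataset, params["pools"], blocks,
                        max_age_gap=params.get("max_age_gap"),
                        seed=stage_seed(stage),
                    )
                    path = out / "fst.tsv"
                    pd.DataFrame([r.__dict__ for r in res]).to_csv(path, sep="\t", index=False)
                    outputs.append(path)
                if "sexing" in params:
                    cov = pd.read_csv(params["sexing"], sep="\t")
                    rep = popsum.sex_and_ratio(cov)
                    path = out / "sexing.tsv"
                    rep.per_sample.to_csv(path, sep="\t", index=False)
                    summary = out / "sexing_summary.json"
                    with open(summary, "w") as fh:
                        json.dump({
                            "n_male": rep.n_male, "n_assigned": rep.n_assigned,
                            "male_fraction": rep.male_fraction,
                            "ci": [rep.ci_low, rep.ci_high], "p": rep.p_binomial,
                        }, fh, indent=1)
                    outputs += [path, summary]
                record(stage, "completed", t0, outputs)
        except Exception as e:  # noqa: BLE001 - stage boundary
            record(stage, "failed", t0, extra={"error": str(e)})
            failed = True

    manifest["ok"] = not failed
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
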