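import numpy as np
import pandas as pd
import pytest

import paleotempo as pt


def make_dataset(calls, ploidy_modes=None, chrom="chr1", start=100, step=1000,
                 ages=None, groups=None):
    """Hand-build a small GenotypeDataset from a dosage matrix."""
    calls = np.asarray(calls, dtype=np.int8)
    S, N = calls.shape
    sites = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": start + step * np.arange(S),
            "ref": "A",
            "alt": "C",
            "is_transversion": True,
        }
    )
    ploidy_modes = ploidy_modes or ["diploid"] * N
    samples = pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(N)],
            "group": groups or [f"s{i}" for i in range(N)],
            "age_bp": ages if ages is not None else np.zeros(N),
            "is_ancient": [m == "pseudohaploid" for m in ploidy_modes],
            "coverage": 1.0,
            "ploidy_mode": ploidy_modes,
        }
    )
    return pt.GenotypeDataset(sites, calls, samples)


@pytest.fixture(scope="session")
def panmictic_serial_sim():
    """Panmictic Ne=10k population with ancient and modern samples,
    grouped into age strata; used across f-stat / summary-stat tests."""
    sampling = [
        pt.SampleSpec("pop0", 0.0, 10, group="modern"),
        pt.SampleSpec("pop0", 15_000, 4, group="anc15"),
        pt.SampleSpec("pop0", 45_000, 4, group="anc45"),
        pt.SampleSpec("pop0", 75_000, 4, group="anc75"),
    ]
    cfg = pt.SimConfig(
        n_chromosomes=4,
        chrom_length_bp=4e6,
        mu=1e-8,
        rec=1e-8,
        populations=[("pop0", 10_000)],
        sampling=sampling,
        seed=424,
    )
    return pt.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def outgroup_tree_sim():
    """Three-population tree (A,B) + outgroup O, no gene flow."""
    cfg = pt.SimConfig(
        n_chromosomes=4,
        chrom_length_bp=3e6,
        mu=1.25e-8,
        rec=1e-8,
        populations=[(n, 10_000) for n in ["A", "B", "AB", "O", "ROOT"]],
        events=[
            pt.Split(600, ["A", "B"], "AB"),
            pt.Split(3000, ["AB", "O"], "ROOT"),
        ],
        sampling=[
            pt.SampleSpec("A", 0.0, 6),
            pt.SampleSpec("B", 0.0, 6),
            pt.SampleSpec("O", 0.0, 6),
        ],
        seed=77,
    )
    return pt.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def neutral_scan_sim():
    """The neutral panmictic study design at ~200 Mb: Ne = 50,000,
    72 ancient samples (1-100 kyr BP) + 68 modern. Expensive; shared by the
    scan calibration and sweep-power tests."""
    cfg = pt.default_study_config(seed=2024, n_chromosomes=20, chrom_length_bp=10e6)
    return pt.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def neutral_scan_pseudohaploid(neutral_scan_sim):
    return pt.degrade_to_pseudohaploid(neutral_scan_sim, seed=2025)
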