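import numpy as np
import pandas as pd
import pytest

from methrda import (
    BetaMatrix,
    CpGAnnotation,
    CpGParameterSet,
    ScenarioConfig,
    default_cpg_parameters,
    encode_design,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def cpg_params():
    """Default synthetic chromosome-22-like parameter set (8432 CpGs)."""
    return default_cpg_parameters(seed=11)


@pytest.fixture(scope="session")
def small_params():
    """A small, fast parameter set (600 CpGs on a 4 Mb pseudo-chromosome)."""
    rng = np.random.default_rng(5)
    n = 600
    mu = np.clip(rng.beta(2, 2, size=n), 0.05, 0.95)
    nu = rng.uniform(60, 300, size=n)
    pos = np.sort(rng.choice(4_000_000, size=n, replace=False)) + 1
    return CpGParameterSet(a=mu * nu, b=(1 - mu) * nu, positions=pos,
                           chrom_length=4_000_000)


@pytest.fixture()
def strong_dataset(small_params):
    """A replicate with a strong injected DMR (d=0.3, 30% DMPs, n=40)."""
    cfg = ScenarioConfig(region_width=500_000, n_samples=40,
                         effect_d=0.3, dmp_fraction=0.30)
    return simulate_dataset(small_params, cfg, replicate_seed=101)


@pytest.fixture()
def null_dataset(small_params):
    """A signal-free replicate (d=0): groups identically distributed."""
    cfg = ScenarioConfig(region_width=500_000, n_samples=40,
                         effect_d=0.0, dmp_fraction=0.30)
    return simulate_dataset(small_params, cfg, replicate_seed=102)


def make_annotation(positions, chromosome="chr1", probe_prefix="cg"):
    ids = [f"{probe_prefix}{i:04d}" for i in range(len(positions))]
    return CpGAnnotation(
        pd.DataFrame(
            {"chromosome": chromosome, "position": positions},
            index=pd.Index(ids, name="probe_id"),
        )
    )


def binary_design(n, n1=None):
    """Centered one-column design for two balanced groups of n samples."""
    n1 = n // 2 if n1 is None else n1
    pheno = pd.DataFrame(
        {"group": ["A"] * n1 + ["B"] * (n - n1)},
        index=[f"s{i}" for i in range(n)],
    )
    return encode_design(pheno, ["group"])


def random_beta_matrix(rng, n_cpgs, n_samples):
    vals = rng.beta(2, 5, size=(n_cpgs, n_samples))
    return BetaMatrix(
        pd.DataFrame(
            vals,
            index=[f"cg{i:04d}" for i in range(n_cpgs)],
            columns=[f"s{j}" for j in range(n_samples)],
        )
    )
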