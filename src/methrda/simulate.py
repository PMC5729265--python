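"""Simulation of 450K-like methylation data with an injected large DMR.

Beta values are drawn per CpG from a Beta(a_j, b_j) distribution on a
pseudo-chromosome emulating chromosome-22 array density (8432 CpGs over
51 Mb).  A differentially methylated region (DMR) is injected by shifting
the Beta mean of a fraction of the region's CpGs by +/- ``effect_d`` in
one of two sample groups, preserving each CpG's precision (a + b).  The
benchmark grid crosses region width (500/300/100/50 kb), sample size
(10/40/100), mean-methylation difference (0.3/0.1/0.05) and DMP fraction
(30%/10%), with 200 replicate datasets per cell, and evaluates power on
the injected target and the false-positive rate on signal-free random
regions.

The per-CpG Beta parameters of the original reference cohort are not
published; :func:`default_cpg_parameters` draws a declared synthetic
stand-in with array-like bimodality (most CpGs strongly hypo- or
hyper-methylated), so absolute R2 levels under signal are properties of
this stand-in while null behaviour (R2 level, type-I error) is
baseline-free.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import (
    MIN_CPGS,
    BetaMatrix,
    CpGAnnotation,
    GenomicRegion,
    beta_to_m,
    encode_design,
    select_region,
)
from .exceptions import FormatError, InfeasibleError, ParameterError
from .rda import fit_rda, permutation_test
from .regional_null import sample_random_windows

logger = logging.getLogger(__name__)

DEFAULT_N_CPGS = 8432
DEFAULT_CHROM_LENGTH = 51_000_000
DEFAULT_CHROMOSOME = "chr22"

#: bounds for the shifted DMP mean; keeps Beta parameters well conditioned
MEAN_CLAMP = (0.02, 0.98)

DEFAULT_REGION_WIDTHS = (500_000, 300_000, 100_000, 50_000)
DEFAULT_SAMPLE_SIZES = (10, 40, 100)
DEFAULT_EFFECT_SIZES = (0.3, 0.1, 0.05)
DEFAULT_DMP_FRACTIONS = (0.30, 0.10)
DEFAULT_N_REPLICATES = 200


@dataclass
class ScenarioConfig:
    """One cell of the simulation grid."""

    region_width: int = 500_000
    n_samples: int = 40
    effect_d: float = 0.3
    dmp_fraction: float = 0.30
    n_replicates: int = DEFAULT_N_REPLICATES
    direction: str = "random"  # up | down | random

    def __post_init__(self) -> None:
        if not 0.0 <= self.effect_d < 1.0:
            raise ParameterError(f"effect_d must be in [0, 1), got {self.effect_d}")
        if not 0.0 < self.dmp_fraction <= 1.0:
            raise ParameterError(
                f"dmp_fraction must be in (0, 1], got {self.dmp_fraction}"
            )
        if self.n_samples < 4 or self.n_samples % 2:
            raise ParameterError(
                f"n_samples must be even and >= 4, got {self.n_samples}"
            )
        if self.direction not in ("up", "down", "random"):
            raise ParameterError(f"unknown shift direction {self.direction!r}")


@dataclass
class CpGParameterSet:
    """Per-CpG Beta(a, b) shape parameters on a pseudo-chromosome."""

    a: np.ndarray
    b: np.ndarray
    positions: np.ndarray  # 1-based bp, strictly increasing
    chromosome: str = DEFAULT_CHROMOSOME
    chrom_length: int = DEFAULT_CHROM_LENGTH

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        self.positions = np.asarray(self.positions, dtype=int)
        if not (len(self.a) == len(self.b) == len(self.positions)):
            raise FormatError("a, b and positions must have equal length")
        if (self.a <= 0).any() or (self.b <= 0).any():
            raise FormatError("Beta shape parameters must be positive")
        if (np.diff(self.positions) <= 0).any():
            raise FormatError("positions must be strictly increasing")

    @property
    def n_cpgs(self) -> int:
        return len(self.a)

    @property
    def mean(self) -> np.ndarray:
        return self.a / (self.a + self.b)

    @property
    def precision(self) -> np.ndarray:
        return self.a + self.b

    def annotation(self) -> CpGAnnotation:
        probe_ids = [f"cg{i:07d}" for i in range(self.n_cpgs)]
        return CpGAnnotation(
            pd.DataFrame(
                {"chromosome": self.chromosome, "position": self.positions},
                index=pd.Index(probe_ids, name="probe_id"),
            )
        )


def default_cpg_parameters(seed: int = 0) -> CpGParameterSet:
    """Synthetic array-like per-CpG Beta parameters (declared stand-in).

    Per-CpG means come from a three-component mixture emulating the
    bimodal marginal of 450K data: hypomethylated (mean ~ Beta(2, 18),
    weight 0.45), hypermethylated (mean ~ Beta(18, 2), weight 0.40) and
    intermediate (mean ~ Beta(5, 5), weight 0.15).  Precision nu = a + b
    is log-uniform in [50, 500].  Positions are uniform over a 51 Mb
    pseudo-chromosome, sorted and deduplicated.
    """
    rng = np.random.default_rng(seed)
    n = DEFAULT_N_CPGS
    component = rng.choice(3, size=n, p=[0.45, 0.40, 0.15])
    mu = np.empty(n)
    mu[component == 0] = rng.beta(2, 18, size=(component == 0).sum())
    mu[component == 1] = rng.beta(18, 2, size=(component == 1).sum())
    mu[component == 2] = rng.beta(5, 5, size=(component == 2).sum())
    lo, hi = MEAN_CLAMP
    mu = np.clip(mu, lo, hi)
    nu = np.exp(rng.uniform(np.log(50.0), np.log(500.0), size=n))
    positions = rng.choice(DEFAULT_CHROM_LENGTH, size=n, replace=False) + 1
    positions.sort()
    return CpGParameterSet(a=mu * nu, b=(1.0 - mu) * nu, positions=positions)


def fit_cpg_parameters(reference_betas: BetaMatrix) -> CpGParameterSet:
    """Method-of-moments Beta fit per CpG from a reference beta matrix.

    mu_hat is the sample mean, nu_hat = mu(1-mu)/var - 1 floored at 2
    (zero-variance CpGs hit the floor, with a warning), then
    a = mu*nu, b = (1-mu)*nu.  Positions are assigned by row order on the
    default pseudo-chromosome grid; use the returned set with your own
    annotation if real coordinates matter.
    """
    vals = reference_betas.values.to_numpy()
    if vals.shape[1] < 3:
        raise FormatError("need at least 3 samples per CpG to fit parameters")
    mu = vals.mean(axis=1)
    lo, hi = MEAN_CLAMP
    mu = np.clip(mu, lo, hi)
    var = vals.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        nu = mu * (1.0 - mu) / var - 1.0
    # round-off can leave a constant CpG with variance ~1e-33 instead of 0
    floored = ~np.isfinite(nu) | (nu < 2.0) | (var <= 1e-12)
    if floored.any():
        warnings.warn(
            f"{int(floored.sum())} CpG(s) with (near-)zero variance; "
            "precision floored at 2"
        )
    nu = np.where(floored, 2.0, nu)
    n = len(mu)
    step = DEFAULT_CHROM_LENGTH // (n + 1)
    positions = (np.arange(n) + 1) * max(step, 1)
    return CpGParameterSet(a=mu * nu, b=(1.0 - mu) * nu, positions=positions)


@dataclass
class SimulatedDataset:
    """One simulated replicate with its ground truth."""

    betas: BetaMatrix
    annotation: CpGAnnotation
    groups: pd.Series  # sample id -> "group1" / "group2"
    target_region: GenomicRegion
    dmp_indices: np.ndarray  # row indices into the beta matrix
    config: ScenarioConfig
    replicate_id: int = 0
    seed: int = 0

    @property
    def dmp_probe_ids(self) -> list[str]:
        return list(self.betas.values.index[self.dmp_indices])

    def phenotypes(self) -> pd.DataFrame:
        return pd.DataFrame({"group": self.groups})


def _shifted_mean(mu: float, d: float, direction: str, rng) -> float:
    lo, hi = MEAN_CLAMP
    if direction == "up":
        up = True
    elif direction == "down":
        up = False
    else:
        up = bool(rng.random() < 0.5)
        # feasibility vs the clamp: a mean that cannot shift down shifts up
        up_ok = mu + d <= hi
        down_ok = mu - d >= lo
        if up and not up_ok and down_ok:
            up = False
        elif not up and not down_ok and up_ok:
            up = True
    mu2 = mu + d if up else mu - d
    clamped = min(max(mu2, lo), hi)
    if clamped != mu2:
        logger.debug("shifted mean %.3f clamped to %.3f", mu2, clamped)
    return clamped


def simulate_dataset(
    params: CpGParameterSet,
    config: ScenarioConfig,
    replicate_seed: int = 0,
    *,
    min_cpgs: int = MIN_CPGS,
    max_placement_tries: int = 1000,
) -> SimulatedDataset:
    """Draw one dataset: background betas plus a DMR in group 2.

    The target region is placed uniformly at random among width-eligible
    placements (those containing at least ``min_cpgs`` CpGs).  Group 1
    draws Beta(a_j, b_j) everywhere; group 2 is identical except at the
    DMPs, whose mean is shifted by +/- ``effect_d`` (clamped to
    [0.02, 0.98]) with the precision preserved.  DMP positions are chosen
    uniformly without replacement within the region; the DMP count is
    round-half-up of ``dmp_fraction * k``.
    """
    rng = np.random.default_rng(replicate_seed)
    pos = params.positions
    width = config.region_width
    last_start = params.chrom_length - width + 1
    if last_start < 1:
        raise InfeasibleError("region width exceeds chromosome length")
    for _ in range(max_placement_tries):
        start = int(rng.integers(1, last_start + 1))
        region = GenomicRegion(params.chromosome, start, start + width - 1)
        in_region = np.flatnonzero((pos >= region.start) & (pos <= region.end))
        if len(in_region) >= min_cpgs:
            break
    else:
        raise InfeasibleError(
            f"no placement of a {width} bp region with >= {min_cpgs} CpGs found"
        )
    k = len(in_region)
    n_dmp = int(np.floor(config.dmp_fraction * k + 0.5))  # round half up
    n_dmp = max(min(n_dmp, k), 1)
    dmp = np.sort(rng.choice(in_region, size=n_dmp, replace=False))

    n = config.n_samples
    n1 = n // 2
    a, b = params.a, params.b
    betas = rng.beta(a[:, None], b[:, None], size=(params.n_cpgs, n))
    if config.effect_d > 0:
        nu = params.precision
        mu = params.mean
        for j in dmp:
            mu2 = _shifted_mean(float(mu[j]), config.effect_d, config.direction, rng)
            betas[j, n1:] = rng.beta(mu2 * nu[j], (1.0 - mu2) * nu[j], size=n - n1)

    ann = params.annotation()
    sample_ids = [f"s{i + 1:04d}" for i in range(n)]
    groups = pd.Series(
        ["group1"] * n1 + ["group2"] * (n - n1),
        index=pd.Index(sample_ids, name="sample_id"),
        name="group",
    )
    beta_df = pd.DataFrame(betas, index=ann.probe_ids, columns=sample_ids)
    return SimulatedDataset(
        betas=BetaMatrix(beta_df),
        annotation=ann,
        groups=groups,
        target_region=region,
        dmp_indices=dmp,
        config=config,
        seed=replicate_seed,
    )


def default_grid(
    region_widths=DEFAULT_REGION_WIDTHS,
    sample_sizes=DEFAULT_SAMPLE_SIZES,
    effect_sizes=DEFAULT_EFFECT_SIZES,
    dmp_fractions=DEFAULT_DMP_FRACTIONS,
    n_replicates: int = DEFAULT_N_REPLICATES,
) -> list[ScenarioConfig]:
    """The full benchmark grid (4 widths x 3 n x 3 effects x 2 fractions)."""
    return [
        ScenarioConfig(
            region_width=w,
            n_samples=n,
            effect_d=d,
            dmp_fraction=f,
            n_replicates=n_replicates,
        )
        for w in region_widths
        for n in sample_sizes
        for d in effect_sizes
        for f in dmp_fractions
    ]


def _seed_from(seq: np.random.SeedSequence) -> int:
    return int(seq.generate_state(1)[0] % (2**31))


def run_grid(
    params: CpGParameterSet,
    grid: list[ScenarioConfig],
    b_perm: int = 10_000,
    master_seed: int = 0,
) -> pd.DataFrame:
    """Run the benchmark: per replicate, test the target region and one
    signal-free random region of the same CpG count.

    Seeds are hierarchical (master -> scenario -> replicate -> stream), so
    any cell can be rerun independently and reproducibly.  Returns one row
    per test with columns: scenario identifiers, replicate, kind
    ("target"/"null"), k, r2, f_obs, p_value, seed.
    """
    rows: list[dict] = []
    scen_seqs = np.random.SeedSequence(master_seed).spawn(len(grid))
    for config, scen_seq in zip(grid, scen_seqs):
        rep_seqs = scen_seq.spawn(config.n_replicates)
        for rep, rep_seq in enumerate(rep_seqs):
            s_data, s_perm, s_win, s_perm2 = (
                _seed_from(s) for s in rep_seq.spawn(4)
            )
            ds = simulate_dataset(params, config, s_data)
            ds.replicate_id = rep
            m = beta_to_m(ds.betas)
            design = encode_design(ds.phenotypes(), ["group"])
            y, probes = select_region(m, ds.annotation, ds.target_region)
            res = permutation_test(y, design, b=b_perm, seed=s_perm)
            base = {
                "region_width": config.region_width,
                "n_samples": config.n_samples,
                "effect_d": config.effect_d,
                "dmp_fraction": config.dmp_fraction,
                "replicate": rep,
            }
            fit = fit_rda(y, design)
            rows.append(
                base
                | {
                    "kind": "target",
                    "k": len(probes),
                    "r2": fit.r2,
                    "f_obs": res.f_obs,
                    "p_value": res.p_value,
                    "seed": s_data,
                }
            )
            # signal-free region with the same CpG count, away from the target
            win = sample_random_windows(
                ds.annotation, len(probes), 1, exclude=ds.target_region, seed=s_win
            )[0]
            y_null = m.values.iloc[win]
            res_null = permutation_test(y_null, design, b=b_perm, seed=s_perm2)
            fit_null = fit_rda(y_null, design)
            rows.append(
                base
                | {
                    "kind": "null",
                    "k": len(win),
                    "r2": fit_null.r2,
                    "f_obs": res_null.f_obs,
                    "p_value": res_null.p_value,
                    "seed": s_data,
                }
            )
    return pd.DataFrame(rows)


SCENARIO_COLUMNS = ["region_width", "n_samples", "effect_d", "dmp_fraction"]


def evaluate(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-scenario power, type-I error on null regions, and R2 summaries."""
    if not 0.0 < alpha < 1.0:
        raise ParameterError(f"alpha must be in (0, 1), got {alpha}")
    out: list[dict] = []
    for key, group in results.groupby(SCENARIO_COLUMNS, sort=True):
        target = group[group["kind"] == "target"]
        null = group[group["kind"] == "null"]
        if target.empty and null.empty:
            warnings.warn(f"scenario {key}: no results, omitted")
            continue
        row = dict(zip(SCENARIO_COLUMNS, key))
        row["n_replicates"] = int(len(target))
        row["power"] = (
            float((target["p_value"] < alpha).mean()) if len(target) else np.nan
        )
        row["type_i_error"] = (
            float((null["p_value"] < alpha).mean()) if len(null) else np.nan
        )
        row["mean_r2_target"] = float(target["r2"].mean()) if len(target) else np.nan
        row["sd_r2_target"] = (
            float(target["r2"].std(ddof=1)) if len(target) > 1 else np.nan
        )
        row["mean_r2_null"] = float(null["r2"].mean()) if len(null) else np.nan
        row["sd_r2_null"] = float(null["r2"].std(ddof=1)) if len(null) > 1 else np.nan
        out.append(row)
    return pd.DataFrame(out)
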