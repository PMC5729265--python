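"""Empirical genome-wide null for a target region's R2.

Whether a region-design R2 of, say, 0.06 is remarkable depends on what
random stretches of the genome achieve with the same design.  This module
samples random *windows of the same CpG count* (runs of k consecutive
annotated probes on a single chromosome), fits the same RDA to each, and
reports the exceedance probability of the target region's R2 against that
empirical null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .data_model import (
    MIN_CPGS,
    CpGAnnotation,
    DesignMatrix,
    GenomicRegion,
    MValueMatrix,
    select_region,
)
from .exceptions import InfeasibleError, MethRdaError, ParameterError
from .rda import fit_rda

logger = logging.getLogger(__name__)


@dataclass
class RegionalNullResult:
    """Target R2 versus the random-region R2 null distribution."""

    r2_obs: float
    r2_null: np.ndarray
    p_value: float
    b: int
    window_cpg_count: int
    seed: int


def enumerate_windows(
    ann: CpGAnnotation,
    k: int,
    exclude: GenomicRegion | None = None,
) -> list[np.ndarray]:
    """All runs of k consecutive annotated CpGs, per chromosome.

    Windows never cross a chromosome boundary.  A window is rejected when
    any of its probes lies inside ``exclude``.
    """
    if k < 1:
        raise ParameterError(f"window CpG count must be >= 1, got {k}")
    tbl = ann.table
    positions_all = np.arange(len(tbl))
    windows: list[np.ndarray] = []
    for chrom in ann.chromosomes:
        rows = positions_all[(tbl["chromosome"] == chrom).to_numpy()]
        if len(rows) < k:
            continue
        if exclude is not None and exclude.chromosome == chrom:
            pos = tbl["position"].to_numpy()[rows]
            inside = (pos >= exclude.start) & (pos <= exclude.end)
        else:
            inside = np.zeros(len(rows), dtype=bool)
        for i in range(len(rows) - k + 1):
            if inside[i : i + k].any():
                continue
            windows.append(rows[i : i + k])
    return windows


def sample_random_windows(
    ann: CpGAnnotation,
    k: int,
    b: int,
    exclude: GenomicRegion | None = None,
    seed: int = 0,
) -> list[np.ndarray]:
    """Draw ``b`` windows of k consecutive CpGs uniformly at random.

    Sampling is without replacement while ``b`` does not exceed the number
    of eligible windows, and with replacement (logged) otherwise.  Returns
    integer row indices into the sorted annotation table.
    """
    if b < 1:
        raise ParameterError(f"number of windows must be >= 1, got {b}")
    windows = enumerate_windows(ann, k, exclude)
    if not windows:
        raise InfeasibleError(
            f"no eligible window of {k} consecutive CpGs outside the excluded region"
        )
    rng = np.random.default_rng(seed)
    if b > len(windows):
        logger.info(
            "requested %d windows but only %d eligible; sampling with replacement",
            b,
            len(windows),
        )
        chosen = rng.integers(0, len(windows), size=b)
    else:
        chosen = rng.choice(len(windows), size=b, replace=False)
    return [windows[i] for i in chosen]


def compute_rda_r2(
    m: MValueMatrix,
    ann: CpGAnnotation,
    x: DesignMatrix,
    target: GenomicRegion,
    b: int = 10_000,
    seed: int = 0,
    *,
    exclude_target: bool = True,
    min_cpgs: int = MIN_CPGS,
    scale: bool = False,
) -> RegionalNullResult:
    """Exceedance probability of the target region's R2 among random regions.

    Fits the RDA on the target region and on ``b`` random same-CpG-count
    windows (same design, same fit path), and returns
    ``p = (1 + #{R2_null >= R2_obs}) / (b + 1)``.
    """
    y_target, target_probes = select_region(m, ann, target, min_cpgs=min_cpgs)
    k = len(target_probes)
    r2_obs = fit_rda(y_target, x, scale=scale).r2

    ann_avail = ann.restrict(m.values.index)
    windows = sample_random_windows(
        ann_avail, k, b, exclude=target if exclude_target else None, seed=seed
    )
    values = m.values.to_numpy()
    # map sorted-annotation rows back to matrix rows
    row_of_probe = {p: i for i, p in enumerate(m.values.index)}
    ann_rows = np.array([row_of_probe[p] for p in ann_avail.table.index])
    r2_null = np.empty(len(windows))
    for i, win in enumerate(windows):
        try:
            r2_null[i] = fit_rda(values[ann_rows[win]], x, scale=scale).r2
        except MethRdaError as exc:
            probes = list(ann_avail.table.index[win])
            raise type(exc)(f"window {probes[0]}..{probes[-1]}: {exc}") from exc
    p_value = (1 + int(np.count_nonzero(r2_null >= r2_obs))) / (b + 1)
    return RegionalNullResult(
        r2_obs=float(r2_obs),
        r2_null=r2_null,
        p_value=p_value,
        b=b,
        window_cpg_count=k,
        seed=seed,
    )
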