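"""Readers and writers for the plain-text formats the tool consumes.

* Beta matrix: TSV (or CSV by extension), first column probe ID, header
  row of sample IDs.
* Annotation: TSV with columns probe_id / chromosome / position (1-based),
  or a 4-column BED (chrom, start, end, probe_id) interpreted 0-based
  half-open and converted on read.
* Phenotypes: TSV, first column sample ID, remaining columns variables.
* Results: a JSON summary plus TSVs for scores, loadings and null draws.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import BetaMatrix, CpGAnnotation
from .exceptions import FormatError
from .simulate import SimulatedDataset


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_beta_matrix(path) -> BetaMatrix:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"cannot read beta matrix {path}: {exc}") from exc
    return BetaMatrix(df)


def read_annotation(path) -> CpGAnnotation:
    path = Path(path)
    if path.suffix.lower() == ".bed":
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["chromosome", "start", "end", "probe_id"],
            usecols=[0, 1, 2, 3],
        )
        # BED is 0-based half-open; a single-base probe record [start, start+1)
        # maps to 1-based position start + 1
        df["position"] = df["start"].astype(int) + 1
        df = df.set_index("probe_id")[["chromosome", "position"]]
        return CpGAnnotation(df)
    df = pd.read_csv(path, sep=_sep_for(path))
    required = {"probe_id", "chromosome", "position"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"annotation {path} must have columns {sorted(required)} "
            "(or be a .bed file)"
        )
    return CpGAnnotation(df.set_index("probe_id")[["chromosome", "position"]])


def read_phenotypes(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if df.empty:
        raise FormatError(f"phenotype table {path} is empty")
    df.index = df.index.map(str)
    return df


def write_tsv(df: pd.DataFrame, path, index_label: str | None = None) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index_label=index_label)


def write_json(obj: dict, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, default=_default) + "\n")


def write_simulated_dataset(ds: SimulatedDataset, outdir) -> dict[str, Path]:
    """Write a simulated replicate as the tool's standard input files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "betas": outdir / "betas.tsv",
        "annotation": outdir / "annotation.tsv",
        "phenotypes": outdir / "phenotypes.tsv",
        "truth": outdir / "truth.tsv",
        "meta": outdir / "meta.json",
    }
    ds.betas.values.to_csv(paths["betas"], sep="\t", index_label="probe_id")
    ds.annotation.table.to_csv(paths["annotation"], sep="\t", index_label="probe_id")
    ds.phenotypes().to_csv(paths["phenotypes"], sep="\t", index_label="sample_id")
    pd.DataFrame({"probe_id": ds.dmp_probe_ids}).to_csv(
        paths["truth"], sep="\t", index=False
    )
    write_json(
        {
            "target_region": str(ds.target_region),
            "n_dmps": len(ds.dmp_indices),
            "config": {
                "region_width": ds.config.region_width,
                "n_samples": ds.config.n_samples,
                "effect_d": ds.config.effect_d,
                "dmp_fraction": ds.config.dmp_fraction,
                "direction": ds.config.direction,
            },
            "replicate_id": ds.replicate_id,
            "seed": ds.seed,
        },
        paths["meta"],
    )
    return paths
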