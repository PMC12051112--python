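"""File formats: long/wide methylation tables, model JSON, output headers.

All tabular IO is plain CSV; the fitted model is persisted as a single JSON
file.  Ages are decimal years everywhere; readers accept a ``months`` flag
that divides by 12 at load time.  Every file written by the tool carries a
leading comment line with the tool version and a hash of the run
configuration, and readers skip ``#`` comment lines.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .model import COLUMNS, MethylationSeriesSet, MultiMeanGP

__all__ = [
    "config_hash",
    "header_line",
    "read_long_table",
    "write_long_table",
    "read_wide_matrix",
    "save_model",
    "load_model",
]

logger = logging.getLogger(__name__)


def config_hash(config: dict | None) -> str:
    """Short stable hash of a run configuration."""
    payload = json.dumps(config or {}, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def header_line(config: dict | None = None) -> str:
    return f"# methylgp v{__version__} config={config_hash(config)}"


def _write_frame(frame: pd.DataFrame, path, config: dict | None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(header_line(config) + "\n")
        frame.to_csv(fh, index=False)


def _count_leading_comments(path) -> int:
    n = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                n += 1
            else:
                break
    return n


def read_long_table(path, months: bool = False) -> MethylationSeriesSet:
    """Read a long-format methylation CSV into a validated series set.

    Expected header: ``individual_id,cpg_id,age_years,beta``.  Validation
    failures report 1-based file line numbers.  ``months=True`` converts
    the age column from months to years.
    """
    offset = _count_leading_comments(path) + 2  # header + 1-based data rows
    frame = pd.read_csv(path, comment="#")
    missing = [c for c in COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if len(frame) == 0:
        raise ValueError(f"{path}: empty input, no methylation records")
    if months:
        frame["age_years"] = frame["age_years"].astype(float) / 12.0
    beta = frame["beta"].astype(float)
    bad = frame.index[~np.isfinite(beta) | (beta < 0) | (beta > 1)]
    if len(bad):
        lines = [int(i) + offset for i in bad[:10]]
        raise ValueError(f"{path}: beta outside [0, 1] at line(s) {lines}")
    age = frame["age_years"].astype(float)
    bad_t = frame.index[~np.isfinite(age) | (age < 0)]
    if len(bad_t):
        lines = [int(i) + offset for i in bad_t[:10]]
        raise ValueError(f"{path}: invalid age at line(s) {lines}")
    dup = frame.duplicated(subset=["individual_id", "cpg_id", "age_years"])
    if dup.any():
        lines = [int(i) + offset for i in frame.index[dup][:10]]
        raise ValueError(f"{path}: duplicate (individual, cpg, age) at line(s) {lines}")
    data = MethylationSeriesSet(frame, validate=False)
    logger.info("read %d records from %s", len(data), path)
    return data


def write_long_table(
    data: MethylationSeriesSet, path, config: dict | None = None
) -> None:
    _write_frame(data.frame, path, config)


def read_wide_matrix(matrix_path, metadata_path, months: bool = False) -> MethylationSeriesSet:
    """Read a wide beta matrix (CpG rows x sample columns) plus metadata.

    The matrix CSV has a ``cpg_id`` first column and one column per sample;
    the metadata CSV maps ``sample_id`` to ``individual_id`` and
    ``age_years``.  Cells marked NA (failed detection) are dropped with a
    logged count; a matrix column without a metadata row is an error.
    """
    matrix = pd.read_csv(matrix_path, comment="#")
    meta = pd.read_csv(metadata_path, comment="#")
    if "cpg_id" not in matrix.columns:
        raise ValueError(f"{matrix_path}: first column must be cpg_id")
    need = {"sample_id", "individual_id", "age_years"}
    if not need.issubset(meta.columns):
        raise ValueError(f"{metadata_path}: must have columns {sorted(need)}")
    meta = meta.set_index(meta["sample_id"].astype(str))
    samples = [c for c in matrix.columns if c != "cpg_id"]
    orphans = [s for s in samples if s not in meta.index]
    if orphans:
        raise ValueError(f"matrix columns without metadata: {orphans[:5]}")

    long = matrix.melt(id_vars="cpg_id", var_name="sample_id", value_name="beta")
    n_before = len(long)
    long = long.dropna(subset=["beta"])
    dropped = n_before - len(long)
    if dropped:
        logger.warning("dropped %d NA cells (failed detection)", dropped)
    long["individual_id"] = meta.loc[long["sample_id"], "individual_id"].to_numpy()
    long["age_years"] = meta.loc[long["sample_id"], "age_years"].to_numpy().astype(float)
    if months:
        long["age_years"] = long["age_years"] / 12.0
    return MethylationSeriesSet(
        long[["individual_id", "cpg_id", "age_years", "beta"]].reset_index(drop=True)
    )


def save_model(model: MultiMeanGP, path, config: dict | None = None) -> None:
    """Persist a fitted model (hyperparameters, grid, per-CpG posteriors)."""
    payload = model.to_payload()
    payload["tool_version"] = __version__
    payload["config_hash"] = config_hash(config)
    with open(path, "w") as fh:
        json.dump(payload, fh)
    logger.info("saved model with %d CpG posteriors to %s", len(model.mean_posteriors_), path)


def load_model(path) -> MultiMeanGP:
    with open(path) as fh:
        payload = json.load(fh)
    return MultiMeanGP.from_payload(payload)
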