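"""CSV schemas and table validation.

Two table layouts are understood, using the column vocabulary widespread
among ΔΔCq users (``housek0`` = housekeeping gene, control condition;
``target1`` = target gene, test condition, etc.):

estimate schema (one row per bulk sample)
    sample_id, n, housek0, target0, housek1, target1

calibrate schema (one row per Cq well)
    ratio, gene (target|housek), condition (0=control, 1=test),
    replicate, cq

The calibrate schema may omit arbitrary wells (the unpaired case);
the estimate schema requires complete quartets.
"""

from __future__ import annotations

import math
import warnings
from pathlib import Path
from typing import List, Tuple

import pandas as pd

from .calibration import KnownRatioObservation
from .model_core import CqQuartet

__all__ = [
    "read_cq_table",
    "write_estimate_table",
    "average_technical_replicates",
    "ESTIMATE_COLUMNS",
    "CALIBRATE_COLUMNS",
]

ESTIMATE_COLUMNS = ("sample_id", "n", "housek0", "target0", "housek1", "target1")
CALIBRATE_COLUMNS = ("ratio", "gene", "condition", "replicate", "cq")

_GENE_MAP = {"housek": "housekeeping", "target": "target"}
_COND_MAP = {0: "W", 1: "D"}


class CqTableError(ValueError):
    """A table failed validation; the message names the offending rows."""


def _require_columns(df: pd.DataFrame, columns, path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise CqTableError(f"{path}: missing required column(s) {missing}")


def _check_finite(df: pd.DataFrame, columns, path) -> None:
    for col in columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna() | ~vals.apply(math.isfinite)]
        if len(bad):
            rows = ", ".join(str(i + 2) for i in bad[:5])  # +2: header + 1-based
            raise CqTableError(
                f"{path}: column {col!r} has non-numeric or non-finite "
                f"values at file row(s) {rows}"
            )
        df[col] = vals


def read_cq_table(path, schema: str):
    """Read and validate a Cq table.

    Returns ``(records, dataframe)`` where records are typed:
    ``[(sample_id, CqQuartet, n), ...]`` for the estimate schema and
    ``[KnownRatioObservation, ...]`` for the calibrate schema.
    """
    path = Path(path)
    if not path.exists():
        raise CqTableError(f"{path}: file not found")
    df = pd.read_csv(path, float_precision="round_trip")
    if schema == "estimate":
        _require_columns(df, ESTIMATE_COLUMNS, path)
        _check_finite(df, ["n", "housek0", "target0", "housek1", "target1"], path)
        records = []
        for idx, row in df.iterrows():
            n = row["n"]
            if n != int(n) or n < 1:
                raise CqTableError(
                    f"{path}: pool size n must be a positive integer, got "
                    f"{n!r} at file row {idx + 2}"
                )
            quartet = CqQuartet(
                tau_HW=float(row["housek0"]),
                tau_TW=float(row["target0"]),
                tau_HD=float(row["housek1"]),
                tau_TD=float(row["target1"]),
            )
            records.append((row["sample_id"], quartet, int(n)))
        return records, df
    if schema == "calibrate":
        _require_columns(df, CALIBRATE_COLUMNS, path)
        df = df.dropna(subset=["cq"]).reset_index(drop=True)
        _check_finite(df, ["ratio", "cq"], path)
        records = []
        for idx, row in df.iterrows():
            gene = str(row["gene"]).strip()
            if gene not in _GENE_MAP:
                raise CqTableError(
                    f"{path}: gene must be 'target' or 'housek', got "
                    f"{gene!r} at file row {idx + 2}"
                )
            cond = int(row["condition"])
            if cond not in _COND_MAP:
                raise CqTableError(
                    f"{path}: condition must be 0 (control) or 1 (test), got "
                    f"{cond!r} at file row {idx + 2}"
                )
            records.append(
                KnownRatioObservation(
                    ratio=float(row["ratio"]),
                    gene=_GENE_MAP[gene],
                    condition=_COND_MAP[cond],
                    replicate=int(row["replicate"]),
                    cq=float(row["cq"]),
                )
            )
        return records, df
    raise ValueError(f"unknown schema {schema!r}")


def write_estimate_table(path, samples) -> None:
    """Write ``[(sample_id, CqQuartet, n), ...]`` in the estimate schema."""
    rows = [
        {
            "sample_id": sid,
            "n": n,
            "housek0": q.tau_HW,
            "target0": q.tau_TW,
            "housek1": q.tau_HD,
            "target1": q.tau_TD,
        }
        for sid, q, n in samples
    ]
    pd.DataFrame(rows, columns=list(ESTIMATE_COLUMNS)).to_csv(path, index=False)


def average_technical_replicates(df: pd.DataFrame) -> pd.DataFrame:
    """Collapse technical replicates by per-channel arithmetic mean.

    Rows sharing a ``sample_id`` are averaged channel-wise.  Averaging k
    replicates shrinks the effective Cq error, so a σc fitted from
    averaged data is the per-mean SD, not the per-well SD; this is
    harmless as long as every sample has the same replicate count, hence
    the warning when counts differ.
    """
    for col in ESTIMATE_COLUMNS:
        if col not in df.columns:
            raise CqTableError(f"missing required column {col!r}")
    counts = df.groupby("sample_id").size()
    if counts.nunique() > 1:
        warnings.warn(
            "unequal technical-replicate counts across samples: the fitted "
            "sigma_c will mix different effective error scales",
            stacklevel=2,
        )
    if df.groupby("sample_id")["n"].nunique().max() > 1:
        raise CqTableError("pool size n differs between replicates of a sample")
    out = (
        df.groupby("sample_id", sort=False)
        .agg(
            n=("n", "first"),
            housek0=("housek0", "mean"),
            target0=("target0", "mean"),
            housek1=("housek1", "mean"),
            target1=("target1", "mean"),
        )
        .reset_index()
    )
    return out
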