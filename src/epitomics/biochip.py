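"""Biochip data model and RLU/RLUmax % normalization.

The raw unit is the background-corrected relative light unit (RLU) of one
biochip spot. Each run carries dedicated tracer-only positions whose signal
(RLUmax, no competing sample) anchors the normalization: the reported feature
is ``100 * RLU / RLUmax`` per mAb, computed strictly within a run so that
run-level multiplicative effects (operator, lot, instrument drift) cancel.

Two layouts are supported:

- ``QP69``:  six racks of nine chips give 18 measurement positions, two of
  which are tracer-only; their RLUmax values are averaged per mAb before
  dividing the sample RLUs.
- ``QP300``: the same rack block gives only three positions, exactly one of
  which is tracer-only; samples are divided by that single RLUmax.

Replicate profiles are averaged per (sample, mAb, dilution) and then capped at
120 % -- the cap is applied after averaging, to the final analysis variable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MEASUREMENT_COLUMNS",
    "LAYOUTS",
    "BiochipRun",
    "NormalizedProfile",
    "NormalizationError",
    "normalize_qp69",
    "normalize_qp300",
    "normalize_run",
    "aggregate_replicates",
    "read_measurements",
    "write_measurements",
    "read_profile",
    "write_profile",
]

MEASUREMENT_COLUMNS = [
    "sample_id",
    "mab_id",
    "run_id",
    "rack",
    "position",
    "role",
    "operator",
    "lot",
    "dilution",
    "replicate",
    "rlu",
]

#: layout -> (total measurement positions per run, tracer-only positions per run)
LAYOUTS = {"QP69": (18, 2), "QP300": (3, 1)}

DEFAULT_CAP = 120.0


class NormalizationError(ValueError):
    """Raised when a run violates its layout's tracer structure."""


@dataclass
class BiochipRun:
    """A collection of raw measurement records with a declared chip layout."""

    layout_kind: str
    records: pd.DataFrame

    def __post_init__(self) -> None:
        if self.layout_kind not in LAYOUTS:
            raise ValueError(f"unknown layout {self.layout_kind!r}; expected one of {sorted(LAYOUTS)}")
        missing = [c for c in MEASUREMENT_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"measurement table missing columns: {missing}")
        if (self.records["rlu"] < 0).any():
            raise ValueError("negative RLU values are not permitted")

    @property
    def run_ids(self) -> list:
        return sorted(self.records["run_id"].unique())


@dataclass
class NormalizedProfile:
    """Long-format RLU/RLUmax % table: one row per (sample, mAb, dilution).

    ``values`` columns: sample_id, mab_id, dilution, value, n_replicates.
    Values are percentages in [0, cap] after aggregation (pre-aggregation
    profiles may exceed the cap; the cap is applied by
    :func:`aggregate_replicates`).
    """

    values: pd.DataFrame
    cap: float = DEFAULT_CAP
    flagged: list = field(default_factory=list)

    def matrix(self, dilution: float | None = None) -> pd.DataFrame:
        """Wide sample x mAb matrix, optionally restricted to one dilution."""
        df = self.values
        if dilution is not None:
            df = df[df["dilution"] == dilution]
        return df.pivot_table(index="sample_id", columns="mab_id", values="value", aggfunc="mean")


def _normalize(run: BiochipRun, expected_tracers: int, exact: bool) -> NormalizedProfile:
    rec = run.records
    out_rows = []
    flagged = []
    for run_id, grp in rec.groupby("run_id", sort=True):
        tracers = grp[grp["role"] == "tracer_only"]
        n_positions = tracers["position"].nunique()
        if n_positions < expected_tracers or (exact and n_positions != expected_tracers):
            raise NormalizationError(
                f"run {run_id!r}: found {n_positions} tracer-only position(s), "
                f"layout {run.layout_kind} requires {'exactly' if exact else 'at least'} {expected_tracers}"
            )
        # RLUmax per mAb: mean over the run's tracer-only positions
        rlumax = tracers.groupby("mab_id")["rlu"].mean()
        samples = grp[grp["role"] == "sample"]
        for mab_id, sgrp in samples.groupby("mab_id", sort=True):
            if mab_id not in rlumax.index or rlumax[mab_id] == 0:
                flagged.append((run_id, mab_id, "zero or missing RLUmax"))
                continue
            vals = 100.0 * sgrp["rlu"].to_numpy() / rlumax[mab_id]
            for (_, row), v in zip(sgrp.iterrows(), vals):
                out_rows.append(
                    (row["sample_id"], mab_id, row["dilution"], float(v), 1, run_id, row["replicate"])
                )
    values = pd.DataFrame(
        out_rows,
        columns=["sample_id", "mab_id", "dilution", "value", "n_replicates", "run_id", "replicate"],
    )
    return NormalizedProfile(values=values, flagged=flagged)


def normalize_qp69(run: BiochipRun) -> NormalizedProfile:
    """Normalize a QP69 run: average the two tracer RLUmax values, then divide."""
    if run.layout_kind != "QP69":
        raise NormalizationError(f"normalize_qp69 given a {run.layout_kind} run")
    return _normalize(run, expected_tracers=2, exact=False)


def normalize_qp300(run: BiochipRun) -> NormalizedProfile:
    """Normalize a QP300 run against its single tracer-only RLUmax."""
    if run.layout_kind != "QP300":
        raise NormalizationError(f"normalize_qp300 given a {run.layout_kind} run")
    return _normalize(run, expected_tracers=1, exact=True)


def normalize_run(run: BiochipRun) -> NormalizedProfile:
    return normalize_qp69(run) if run.layout_kind == "QP69" else normalize_qp300(run)


def aggregate_replicates(profile: NormalizedProfile, cap: float = DEFAULT_CAP) -> NormalizedProfile:
    """Mean over replicates per (sample, mAb, dilution), then cap at ``cap``.

    The cap is applied to the averaged value (the final analysis variable),
    and cells whose cap fired are recorded in ``flagged``.
    """
    df = profile.values
    agg = (
        df.groupby(["sample_id", "mab_id", "dilution"], dropna=False, sort=True)
        .agg(value=("value", "mean"), n_replicates=("n_replicates", "sum"))
        .reset_index()
    )
    capped = agg["value"] > cap
    flagged = list(profile.flagged) + [
        (row.sample_id, row.mab_id, "capped") for row in agg[capped].itertuples()
    ]
    agg.loc[capped, "value"] = cap
    return NormalizedProfile(values=agg, cap=cap, flagged=flagged)


# ---------------------------------------------------------------------------
# TSV I/O


def read_measurements(path, layout_kind: str | None = None) -> BiochipRun:
    """Read a measurements TSV into a :class:`BiochipRun`.

    When ``layout_kind`` is omitted it is inferred from the tracer structure
    (two tracer positions per run -> QP69, one -> QP300). Malformed rows and
    negative RLUs are rejected with their line number.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "mab_id": str, "run_id": str})
    if "sample_id" in df.columns:
        df["sample_id"] = df["sample_id"].fillna("")  # tracer-only rows carry no sample
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    bad_rlu = pd.to_numeric(df["rlu"], errors="coerce")
    for idx in df.index[bad_rlu.isna() | (bad_rlu < 0)]:
        # +2: header line plus 1-based indexing
        raise ValueError(f"{path}: invalid rlu {df.loc[idx, 'rlu']!r} at line {idx + 2}")
    df["rlu"] = bad_rlu
    if layout_kind is None:
        if len(df) == 0:
            raise ValueError(f"{path}: empty table; pass layout_kind explicitly")
        tracers = df[df["role"] == "tracer_only"]
        per_run = tracers.groupby("run_id")["position"].nunique()
        layout_kind = "QP69" if (len(per_run) and per_run.iloc[0] >= 2) else "QP300"
    return BiochipRun(layout_kind=layout_kind, records=df[MEASUREMENT_COLUMNS].copy())


def write_measurements(run: BiochipRun, path) -> None:
    run.records[MEASUREMENT_COLUMNS].to_csv(path, sep="\t", index=False)


def write_profile(profile: NormalizedProfile, path) -> None:
    cols = ["sample_id", "mab_id", "dilution", "value", "n_replicates"]
    profile.values[cols].to_csv(path, sep="\t", index=False)


def read_profile(path, cap: float = DEFAULT_CAP) -> NormalizedProfile:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "mab_id": str})
    return NormalizedProfile(values=df, cap=cap)
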