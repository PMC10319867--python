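"""Analytical QC: coefficient-of-variation decomposition and the <20% gate.

Assay qualification rests on plain CVs (sd/mean x 100), computed separately
for each replication dimension of the biochip experiment:

- ``intra_run``: CV of replicate spots within a run, averaged across runs
- ``inter_run``: CV of the per-run means across runs
- ``operator`` / ``lot``: CV of per-operator / per-lot means

A mAb qualifies when every component measured for it stays below the
threshold (default 20 %). Components backed by fewer than two observations
are reported missing, never zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["CVReport", "compute_cv", "cv_decompose", "cv_gate"]

COMPONENTS = ("intra_run", "inter_run", "operator", "lot")


@dataclass
class CVReport:
    """Long table: mab_id, dilution, component, cv_percent, n."""

    table: pd.DataFrame

    def component(self, name: str) -> pd.Series:
        df = self.table[self.table["component"] == name]
        return df.set_index("mab_id")["cv_percent"]


def compute_cv(values) -> float:
    """100 * sample sd (n-1 denominator) / mean; NaN if n < 2 or mean == 0."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        return float("nan")
    m = x.mean()
    if m == 0:
        return float("nan")
    return float(100.0 * x.std(ddof=1) / m)


def _within_group_cv(df: pd.DataFrame, group_col: str) -> tuple[float, int]:
    """Mean of within-group CVs over groups with >=2 values."""
    cvs = []
    n = 0
    for _, grp in df.groupby(group_col):
        if len(grp) >= 2:
            cv = compute_cv(grp["value"])
            if np.isfinite(cv):
                cvs.append(cv)
                n += len(grp)
    return (float(np.mean(cvs)) if cvs else float("nan")), n


def _between_group_cv(df: pd.DataFrame, group_col: str) -> tuple[float, int]:
    """CV of per-group means; missing unless >=2 groups."""
    means = df.groupby(group_col)["value"].mean()
    if len(means) < 2:
        return float("nan"), len(means)
    return compute_cv(means), len(means)


def cv_decompose(values: pd.DataFrame, components=COMPONENTS) -> CVReport:
    """Decompose replicate variability of a long value table.

    ``values`` needs columns mab_id, value, and (depending on the requested
    components) run_id, operator, lot; a ``dilution`` column is honoured as an
    extra stratum when present.
    """
    required = {"intra_run": "run_id", "inter_run": "run_id", "operator": "operator", "lot": "lot"}
    for comp in components:
        if comp not in required:
            raise ValueError(f"unknown CV component {comp!r}")
        if required[comp] not in values.columns:
            raise ValueError(f"component {comp!r} needs column {required[comp]!r}")
    strata = ["mab_id"] + (["dilution"] if "dilution" in values.columns else [])
    rows = []
    for keys, grp in values.groupby(strata, dropna=False, sort=True):
        keys = keys if isinstance(keys, tuple) else (keys,)
        dilution = keys[1] if len(keys) > 1 else np.nan
        for comp in components:
            if comp == "intra_run":
                cv, n = _within_group_cv(grp, "run_id")
            else:
                cv, n = _between_group_cv(grp, required[comp])
            rows.append((keys[0], dilution, comp, cv, n))
    return CVReport(pd.DataFrame(rows, columns=["mab_id", "dilution", "component", "cv_percent", "n"]))


def cv_gate(report: CVReport, threshold: float = 20.0) -> tuple[set, float]:
    """Qualify mAbs whose every available CV component is < threshold.

    Returns the passing mAb id set and the pass fraction over all mAbs in the
    report. mAbs with no finite component at all do not pass (unassessable).
    """
    df = report.table
    if len(df) == 0:
        raise ValueError("empty CV report")
    passing = set()
    all_mabs = set(df["mab_id"])
    for mab_id, grp in df.groupby("mab_id"):
        finite = grp["cv_percent"].dropna()
        if len(finite) and (finite < threshold).all():
            passing.add(mab_id)
    return passing, len(passing) / len(all_mabs)
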