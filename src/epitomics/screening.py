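"""Pooled-sample differential screening and correlation structure.

Pooled case and control plasma samples are each measured two or three times;
a mAb is selected for a contrast when its averaged case signal differs from
the control signal by more than 30 % of the control RLU/RLUmax %. Selections
across cancer types are partitioned into Venn regions (unique versus shared
epitopes), and the feature matrix's correlation structure is summarised with
pairwise-complete Pearson coefficients and Ward/Euclidean clustering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

__all__ = [
    "PoolProfile",
    "DifferentialSelection",
    "CorrelationSummary",
    "differential_mabs",
    "venn_partition",
    "correlation_summary",
    "cluster_profiles",
]


@dataclass
class PoolProfile:
    """Averaged pooled-sample profile: mab_id -> mean RLU/RLUmax %."""

    pool_id: str
    values: pd.Series
    n_repeats: int = 3

    def __post_init__(self) -> None:
        self.values = pd.Series(self.values, dtype=float)
        if self.n_repeats not in (2, 3):
            warnings.warn(
                f"pool {self.pool_id}: {self.n_repeats} repeats (expected 2 or 3)", stacklevel=2
            )

    @classmethod
    def from_repeats(cls, pool_id: str, repeats: pd.DataFrame) -> "PoolProfile":
        """Average a long table (mab_id, repeat, value) into one profile."""
        means = repeats.groupby("mab_id")["value"].mean()
        n = int(repeats.groupby("mab_id")["value"].size().mode().iloc[0])
        return cls(pool_id=pool_id, values=means, n_repeats=n)


@dataclass
class DifferentialSelection:
    contrast_id: str
    selected: set
    rel_diff: pd.Series           # signed (case - control) / control
    skipped: list = field(default_factory=list)  # mAbs with control == 0

    @property
    def up(self) -> set:
        return set(self.rel_diff[self.rel_diff > 0].index) & self.selected

    @property
    def down(self) -> set:
        return set(self.rel_diff[self.rel_diff < 0].index) & self.selected


def differential_mabs(
    control: PoolProfile,
    case: PoolProfile,
    rel_threshold: float = 0.30,
    contrast_id: str | None = None,
) -> DifferentialSelection:
    """Select mAbs with |case - control| strictly > rel_threshold x control.

    The rule is evaluated on the absolute difference (both directions count);
    the signed relative difference is kept so up/down subsets can be reported.
    mAbs with a zero control value cannot be screened and are skipped.
    """
    shared = control.values.index.intersection(case.values.index)
    if len(shared) == 0:
        raise ValueError(
            f"pools {control.pool_id!r} and {case.pool_id!r} share no mAb panel"
        )
    ctrl = control.values[shared]
    cs = case.values[shared]
    skipped = list(shared[ctrl == 0])
    ok = shared[ctrl != 0]
    rel = (cs[ok] - ctrl[ok]) / ctrl[ok]
    selected = set(rel[rel.abs() > rel_threshold].index)
    return DifferentialSelection(
        contrast_id=contrast_id or f"{case.pool_id}-vs-{control.pool_id}",
        selected=selected,
        rel_diff=rel,
        skipped=skipped,
    )


def venn_partition(selections: dict) -> dict:
    """Partition selected mAb sets into Venn regions.

    Returns ``regions`` (frozenset of contrast names -> member set),
    ``unique`` (members of exactly one contrast) and ``shared`` (members of
    two or more).
    """
    if len(selections) < 2:
        raise ValueError("need at least two contrasts")
    names = sorted(selections)
    universe = set().union(*selections.values())
    regions: dict[frozenset, set] = {}
    for item in universe:
        key = frozenset(n for n in names if item in selections[n])
        regions.setdefault(key, set()).add(item)
    unique = set().union(*(v for k, v in regions.items() if len(k) == 1)) if regions else set()
    shared = set().union(*(v for k, v in regions.items() if len(k) >= 2)) if regions else set()
    return {"regions": regions, "unique": unique, "shared": shared}


@dataclass
class CorrelationSummary:
    matrix: pd.DataFrame          # pairwise-complete Pearson r per mAb pair
    bin_edges: np.ndarray         # [-1, -0.9, ..., 1], bins closed on the right
    bin_fractions: np.ndarray     # fractions of off-diagonal pairs per bin
    high_fraction: float          # fraction of pairs with r in [0.8, 1.0]
    n_pairs: int
    dropped: list = field(default_factory=list)  # zero-variance columns


def correlation_summary(
    matrix: pd.DataFrame, min_samples: int = 3, listwise: bool = False
) -> CorrelationSummary:
    """Pearson correlation structure of a sample x mAb feature matrix.

    By default each pair uses its pairwise-complete rows; ``listwise=True``
    restricts to rows complete for every column first. The histogram uses
    0.1-wide bins over [-1, 1] closed on the right, so [0.8, 1.0] is the sum
    of the last two bins (and includes r = 1 from duplicated columns).
    """
    if matrix.shape[0] < min_samples or matrix.shape[1] < 2:
        raise ValueError("need >=3 samples and >=2 mAb columns")
    df = matrix.dropna(axis=0) if listwise else matrix
    variances = df.var(skipna=True)
    dropped = list(variances.index[(variances == 0) | variances.isna()])
    corr = df.drop(columns=dropped).corr(method="pearson", min_periods=2)
    vals = corr.to_numpy(dtype=float)
    iu = np.triu_indices(vals.shape[0], k=1)
    r = vals[iu]
    r = r[np.isfinite(r)]
    edges = np.round(np.arange(-1.0, 1.0 + 1e-9, 0.1), 10)
    # right-closed bins: (-1 excluded only for r == -1, which we clamp in)
    idx = np.clip(np.ceil((r - (-1.0)) / 0.1 - 1e-12).astype(int) - 1, 0, len(edges) - 2)
    counts = np.bincount(idx, minlength=len(edges) - 1)
    fractions = counts / r.size if r.size else np.zeros(len(edges) - 1)
    high = float(fractions[-2:].sum())
    return CorrelationSummary(
        matrix=corr,
        bin_edges=edges,
        bin_fractions=fractions,
        high_fraction=high,
        n_pairs=int(r.size),
        dropped=dropped,
    )


def cluster_profiles(matrix: pd.DataFrame, n_clusters: int = 2) -> dict:
    """Ward clustering on Euclidean distances of the rows.

    Rows are sorted by id before linkage so the result is independent of the
    input row order; missing cells are rejected (complete the matrix first).
    """
    df = matrix.sort_index()
    if df.isna().any().any():
        raise ValueError("matrix contains missing cells; complete or impute before clustering")
    Z = linkage(df.to_numpy(dtype=float), method="ward", metric="euclidean")
    flat = fcluster(Z, t=n_clusters, criterion="maxclust")
    labels = pd.Series(flat, index=df.index, name="cluster")
    return {"linkage": Z, "labels": labels, "ids": list(df.index)}
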