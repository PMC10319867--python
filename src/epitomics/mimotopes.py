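"""Mimotope peptide frequencies and the pairwise redundancy score RedXY.

Each mAb's epitope is fingerprinted by the 12-mer peptides ("mimotopes")
selected for it from a phage-display library; at least 12 clones are sequenced
per mAb, and a peptide's frequency within a mAb is its clone count divided by
the mAb's total clone count. The redundancy of two mAbs X and Y is

    RedXY = sum over peptides p common to X and Y of freqX(p) * freqY(p) * 100

i.e. 100 times the inner product of their peptide frequency vectors restricted
to shared peptides (exact string identity). RedXY is symmetric, bounded in
[0, 100], and obeys the Cauchy-Schwarz bound Red(X,Y)^2 <= Red(X,X)*Red(Y,Y);
the diagonal Red(X,X) is a Simpson-type concentration of X's own clone
distribution, reported but excluded from threshold summaries.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "AMINO_ACIDS",
    "MimotopeSet",
    "RedundancySummary",
    "peptide_frequencies",
    "redundancy",
    "redundancy_matrix",
    "summarize",
    "read_peptides",
    "write_peptides",
]

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

MIN_CLONES = 12  # "at least 12 phage clones" per mAb; fewer triggers a warning


@dataclass
class MimotopeSet:
    """One mAb's peptide -> clone count table."""

    mab_id: str
    peptides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {}
        for pep, count in self.peptides.items():
            pep = pep.upper()
            bad = set(pep) - AMINO_ACIDS
            if bad:
                raise ValueError(f"{self.mab_id}: non-amino-acid characters {sorted(bad)} in {pep!r}")
            if count < 1:
                raise ValueError(f"{self.mab_id}: non-positive clone count for {pep!r}")
            clean[pep] = clean.get(pep, 0) + int(count)
        self.peptides = clean
        if 0 < self.total_clones < MIN_CLONES:
            warnings.warn(f"{self.mab_id}: only {self.total_clones} clones (<{MIN_CLONES})", stacklevel=2)

    @property
    def total_clones(self) -> int:
        return sum(self.peptides.values())


def peptide_frequencies(s: MimotopeSet) -> dict:
    """Clone-count frequencies; they sum to 1 over the mAb's peptides."""
    total = s.total_clones
    if total == 0:
        raise ValueError(f"{s.mab_id}: empty mimotope set")
    return {p: c / total for p, c in s.peptides.items()}


def redundancy(x: MimotopeSet, y: MimotopeSet) -> float:
    """RedXY: 100 x inner product of frequency vectors over shared peptides."""
    fx = peptide_frequencies(x)
    fy = peptide_frequencies(y)
    return float(sum(fx[p] * fy[p] for p in fx.keys() & fy.keys()) * 100.0)


def redundancy_matrix(sets) -> pd.DataFrame:
    """Symmetric RedXY matrix over a library; diagonal is self-redundancy."""
    sets = list(sets)
    if len(sets) < 2:
        raise ValueError("need at least two mimotope sets")
    ids = [s.mab_id for s in sets]
    freqs = [peptide_frequencies(s) for s in sets]
    mat = np.zeros((len(sets), len(sets)))
    for i, fi in enumerate(freqs):
        for j in range(i, len(sets)):
            fj = freqs[j]
            red = sum(fi[p] * fj[p] for p in fi.keys() & fj.keys()) * 100.0
            mat[i, j] = mat[j, i] = red
    return pd.DataFrame(mat, index=ids, columns=ids)


@dataclass
class RedundancySummary:
    threshold: float
    n_mabs_over: int          # mAbs with at least one off-diagonal partner > threshold
    n_pairs_over: int         # unordered pairs > threshold
    max_value: float          # maximum off-diagonal RedXY
    max_pairs: list           # all unordered pairs attaining the maximum (to 1e-9)


def summarize(matrix: pd.DataFrame, threshold: float = 40.0) -> RedundancySummary:
    """Threshold summary over the off-diagonal part of a redundancy matrix."""
    ids = list(matrix.index)
    vals = matrix.to_numpy(dtype=float)
    off = vals.copy()
    np.fill_diagonal(off, -np.inf)
    over_mask = off > threshold
    n_mabs = int(np.sum(over_mask.any(axis=1)))
    iu = np.triu_indices(len(ids), k=1)
    pair_vals = vals[iu]
    n_pairs = int(np.sum(pair_vals > threshold))
    max_val = float(pair_vals.max()) if pair_vals.size else float("nan")
    max_pairs = [
        (ids[i], ids[j])
        for i, j in zip(*iu)
        if abs(vals[i, j] - max_val) < 1e-9
    ]
    return RedundancySummary(
        threshold=threshold,
        n_mabs_over=n_mabs,
        n_pairs_over=n_pairs,
        max_value=max_val,
        max_pairs=max_pairs,
    )


# ---------------------------------------------------------------------------
# I/O: TSV (mab_id, peptide, count) or FASTA with headers ">mabID|cloneN"


def read_peptides(path) -> list[MimotopeSet]:
    path = str(path)
    if path.endswith((".fa", ".fasta", ".faa")):
        counts: dict[str, Counter] = {}
        for rec in SeqIO.parse(path, "fasta"):
            mab_id = rec.id.split("|")[0]
            counts.setdefault(mab_id, Counter())[str(rec.seq).upper()] += 1
        return [MimotopeSet(mab_id=m, peptides=dict(c)) for m, c in sorted(counts.items())]
    df = pd.read_csv(path, sep="\t", dtype={"mab_id": str, "peptide": str})
    if "count" not in df.columns:
        df["count"] = 1
    sets = []
    for mab_id, grp in df.groupby("mab_id", sort=True):
        peptides: dict[str, int] = {}
        for pep, cnt in zip(grp["peptide"], grp["count"]):
            pep = str(pep).upper()
            peptides[pep] = peptides.get(pep, 0) + int(cnt)
        sets.append(MimotopeSet(mab_id=str(mab_id), peptides=peptides))
    return sets


def write_peptides(sets, path) -> None:
    rows = [
        (s.mab_id, pep, cnt)
        for s in sets
        for pep, cnt in sorted(s.peptides.items())
    ]
    pd.DataFrame(rows, columns=["mab_id", "peptide", "count"]).to_csv(path, sep="\t", index=False)
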