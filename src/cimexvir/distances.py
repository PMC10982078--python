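"""Pairwise p-distances and within/between-group mean-distance summaries.

The p-distance between two aligned nucleotide sequences is the proportion of
compared sites at which they differ, uncorrected for multiple substitutions.
Sites where either sequence carries a gap (``-``) or an ambiguous base (``N``)
are excluded pair by pair ("pairwise deletion").  Distances are stored as
fractions in [0, 1]; percent rendering (one decimal, half away from zero)
happens only at the reporting layer.

Group summaries average the pairwise distances within each clade and between
clades — e.g. an "Italy" clade versus a "rest of the world" clade versus a
tenuivirus outgroup.  The within-group mean of a singleton group is undefined
(reported as NaN), never zero.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "AlignedSet",
    "DistanceMatrix",
    "PDistance",
    "dedupe_within_sample",
    "p_distance",
    "distance_matrix",
    "group_mean_distances",
    "percent",
]

_EXCLUDED = {ord("-"), ord("N")}

POLICIES = ("pairwise_deletion", "complete_deletion")


@dataclass(frozen=True)
class AlignedSet:
    """An alignment: unique ids and equal-length rows over {A,C,G,T,N,-}."""

    ids: tuple
    rows: tuple

    def __post_init__(self):
        object.__setattr__(self, "ids", tuple(self.ids))
        object.__setattr__(self, "rows", tuple(r.upper() for r in self.rows))
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence IDs")
        if not self.rows or not self.rows[0]:
            raise ValueError("alignment must contain at least one non-empty row")
        width = len(self.rows[0])
        if any(len(r) != width for r in self.rows):
            raise ValueError("alignment rows have unequal lengths")
        bad = set("".join(self.rows)) - set("ACGTN-")
        if bad:
            raise ValueError(f"invalid alignment characters: {sorted(bad)}")

    @classmethod
    def from_fasta(cls, path) -> "AlignedSet":
        from Bio import SeqIO
        records = list(SeqIO.parse(str(path), "fasta"))
        return cls(tuple(r.id for r in records), tuple(str(r.seq) for r in records))

    def __len__(self):
        return len(self.ids)


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise p-distances with per-pair compared-site counts."""

    ids: tuple
    d: np.ndarray
    effective_sites: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=list(self.ids), columns=list(self.ids))


def dedupe_within_sample(records: list[tuple[str, str]]) -> list[tuple[str, str]]:
    """Drop exact duplicate sequences within each sample (first kept).

    Comparison is case-folded; identical sequences in *different* samples are
    retained (they are independent detections of the same virus).
    """
    seen: set[tuple[str, str]] = set()
    out = []
    for sample, seq in records:
        key = (sample, seq.upper())
        if key not in seen:
            seen.add(key)
            out.append((sample, seq))
    return out


def _site_arrays(a: str, b: str):
    if len(a) != len(b):
        raise ValueError("aligned rows must have equal length")
    av = np.frombuffer(a.upper().encode(), dtype=np.uint8)
    bv = np.frombuffer(b.upper().encode(), dtype=np.uint8)
    excluded = np.isin(av, list(_EXCLUDED)) | np.isin(bv, list(_EXCLUDED))
    return av, bv, ~excluded


def p_distance(a: str, b: str, policy: str = "pairwise_deletion") -> tuple[float, int]:
    """p-distance between two aligned rows; returns (distance, compared sites)."""
    if policy not in POLICIES:
        raise ValueError(f"unknown deletion policy {policy!r}")
    av, bv, included = _site_arrays(a, b)
    n = int(included.sum())
    if n == 0:
        raise ValueError("no comparable sites")
    mism = int(((av != bv) & included).sum())
    return mism / n, n


class PDistance(BaseEstimator, TransformerMixin):
    """Transformer computing the full pairwise p-distance matrix.

    Parameters
    ----------
    policy : {"pairwise_deletion", "complete_deletion"}
        Pairwise deletion excludes gap/N sites per pair; complete deletion
        first drops every column containing a gap or N in *any* row.

    Attributes (after fit)
    ----------------------
    ids_ : tuple of sequence IDs
    distances_ : (n, n) ndarray of fractions
    effective_sites_ : (n, n) ndarray of compared-site counts
    """

    def __init__(self, policy: str = "pairwise_deletion"):
        self.policy = policy

    def _coerce(self, X) -> AlignedSet:
        if isinstance(X, AlignedSet):
            return X
        if isinstance(X, dict):
            return AlignedSet(tuple(X), tuple(X.values()))
        X = list(X)
        if X and isinstance(X[0], (tuple, list)):
            return AlignedSet(tuple(i for i, _ in X), tuple(s for _, s in X))
        return AlignedSet(tuple(f"seq{i}" for i in range(len(X))), tuple(X))

    def fit(self, X, y=None):
        aln = self._coerce(X)
        if self.policy not in POLICIES:
            raise ValueError(f"unknown deletion policy {self.policy!r}")
        if len(aln) < 2:
            raise ValueError("need at least 2 sequences")
        mat = np.vstack([np.frombuffer(r.encode(), dtype=np.uint8) for r in aln.rows])
        keep = ~np.isin(mat, list(_EXCLUDED))
        if self.policy == "complete_deletion":
            cols = keep.all(axis=0)
            mat, keep = mat[:, cols], keep[:, cols]
        n = len(aln)
        d = np.zeros((n, n))
        eff = np.zeros((n, n), dtype=int)
        np.fill_diagonal(eff, keep.sum(axis=1))
        for i, j in itertools.combinations(range(n), 2):
            inc = keep[i] & keep[j]
            m = int(inc.sum())
            if m == 0:
                raise ValueError(f"no comparable sites for pair ({aln.ids[i]!r}, {aln.ids[j]!r})")
            dist = ((mat[i] != mat[j]) & inc).sum() / m
            d[i, j] = d[j, i] = dist
            eff[i, j] = eff[j, i] = m
        self.ids_ = aln.ids
        self.distances_ = d
        self.effective_sites_ = eff
        return self

    def transform(self, X) -> np.ndarray:
        return PDistance(self.policy).fit(X).distances_

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).distances_


def distance_matrix(aln: AlignedSet, policy: str = "pairwise_deletion") -> DistanceMatrix:
    """All-pairs p-distances; thin wrapper over PDistance."""
    est = PDistance(policy).fit(aln)
    return DistanceMatrix(est.ids_, est.distances_, est.effective_sites_)


def percent(x: float, decimals: int = 1) -> float:
    """Render a fraction as a percentage, rounding half away from zero."""
    scaled = x * 100 * 10 ** decimals
    return np.sign(scaled) * np.floor(abs(scaled) + 0.5) / 10 ** decimals


def group_mean_distances(D: DistanceMatrix | pd.DataFrame,
                         groups: dict[str, str]) -> pd.DataFrame:
    """Within- and between-group mean pairwise distances.

    Parameters
    ----------
    D : DistanceMatrix or square DataFrame of distances (fractions or percent —
        means are reported on the input scale).
    groups : mapping sequence ID -> group label; every ID must be labeled.

    Returns
    -------
    DataFrame with columns ``group_1``, ``group_2``, ``kind`` ("within" or
    "between"), ``mean_distance`` and ``n_pairs``.  A singleton group's
    within-group mean is NaN with ``n_pairs`` 0.
    """
    frame = D.to_frame() if isinstance(D, DistanceMatrix) else D
    ids = list(frame.index)
    unlabeled = [i for i in ids if i not in groups]
    if unlabeled:
        raise ValueError(f"unlabeled sequence IDs: {unlabeled}")
    labels = sorted({groups[i] for i in ids})
    members = {g: [i for i in ids if groups[i] == g] for g in labels}
    dmat = frame.to_numpy()
    pos = {i: k for k, i in enumerate(ids)}

    rows = []
    for g in labels:
        pairs = list(itertools.combinations(members[g], 2))
        mean = (float(np.mean([dmat[pos[a], pos[b]] for a, b in pairs]))
                if pairs else float("nan"))
        rows.append((g, g, "within", mean, len(pairs)))
    for g, h in itertools.combinations(labels, 2):
        vals = [dmat[pos[a], pos[b]] for a in members[g] for b in members[h]]
        rows.append((g, h, "between", float(np.mean(vals)), len(vals)))
    return pd.DataFrame(rows, columns=["group_1", "group_2", "kind",
                                       "mean_distance", "n_pairs"])
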