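"""Co-occurrence screening of candidate multipartite-virus genome segments.

RNA viruses with segmented genomes (e.g. bunya- and tenui-like viruses) are
assembled from metatranscriptomes as separate transcripts, and only the
RdRp-encoding segment can be recognised by homology with confidence.  The
remaining segments must be recovered by their pattern of presence across
samples: a genuine companion segment should appear in the samples that carry
the RdRp anchor, and rarely elsewhere.

Two statistics formalise this.  For a candidate transcript let ``S`` be the
set of samples in which it was detected and ``A`` the set of anchor-positive
samples (samples containing at least one RdRp-confirmed transcript of the
virus):

* ``V_co = |S ∩ A| / |A|`` — the fraction of anchor-positive samples that also
  contain the candidate (recall against the anchor).
* ``T_co = |S ∩ A| / |S|`` — the fraction of the candidate's occurrences that
  are anchor-positive (precision of the candidate; 1.0 means it is never seen
  without the anchor).

A transcript is called a candidate segment when ``V_co >= v_threshold``,
``T_co >= t_threshold`` and its longest open reading frame strictly exceeds
``min_orf_len`` nucleotides.  The default thresholds are 0.75, 0.5 and 500 nt.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "AnchorSet",
    "ScreenConfig",
    "CandidateScore",
    "CooccurrenceScreen",
    "anchor_positive_samples",
    "v_co",
    "t_co",
    "screen_candidates",
    "validate_presence_matrix",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnchorSet:
    """RdRp-confirmed transcripts anchoring one virus.

    A sample is anchor-positive if it contains *any* anchor transcript;
    partial and complete anchor sequences both count as present.
    """

    virus_id: str
    anchor_transcripts: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        object.__setattr__(self, "anchor_transcripts", frozenset(self.anchor_transcripts))
        if not self.anchor_transcripts:
            raise ValueError(f"AnchorSet for {self.virus_id!r} has no anchor transcripts")


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds of the candidate-segment screen.

    ``v_threshold`` and ``t_threshold`` are inclusive lower bounds; the ORF
    bound is exclusive (an ORF of exactly ``min_orf_len`` nt fails).
    """

    v_threshold: float = 0.75
    t_threshold: float = 0.5
    min_orf_len: int = 500

    def __post_init__(self):
        if not (0.0 <= self.v_threshold <= 1.0 and 0.0 <= self.t_threshold <= 1.0):
            raise ValueError("co-occurrence thresholds must lie in [0, 1]")
        if self.min_orf_len < 0:
            raise ValueError("min_orf_len must be >= 0")


@dataclass(frozen=True)
class CandidateScore:
    """Per-transcript screen result."""

    transcript_id: str
    v_co: float
    t_co: float
    max_orf_len: int
    passes: bool
    never_observed: bool = False


def validate_presence_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample x transcript presence/absence table.

    Index holds sample IDs, columns transcript(-cluster) IDs, cells 0/1 with
    no missing values.  Returns a boolean copy.
    """
    if not isinstance(matrix, pd.DataFrame):
        raise TypeError("presence matrix must be a pandas DataFrame")
    if matrix.index.has_duplicates:
        raise ValueError("duplicate sample IDs in presence matrix")
    if matrix.columns.has_duplicates:
        raise ValueError("duplicate transcript IDs in presence matrix")
    values = matrix.to_numpy()
    if values.size and not np.isin(values, [0, 1, True, False]).all():
        raise ValueError("presence matrix cells must be 0/1 with no missing values")
    return matrix.astype(bool)


def anchor_positive_samples(matrix: pd.DataFrame, anchors: AnchorSet) -> pd.Index:
    """Samples containing at least one anchor transcript of the virus."""
    matrix = validate_presence_matrix(matrix)
    missing = anchors.anchor_transcripts - set(matrix.columns)
    if missing:
        raise KeyError(f"anchor transcripts absent from matrix: {sorted(missing)}")
    mask = matrix[sorted(anchors.anchor_transcripts)].any(axis=1)
    return matrix.index[mask]


def _occurrence_sets(transcript: str, anchors: AnchorSet, matrix: pd.DataFrame):
    matrix = validate_presence_matrix(matrix)
    if transcript not in matrix.columns:
        raise KeyError(f"unknown transcript ID: {transcript!r}")
    a = set(anchor_positive_samples(matrix, anchors))
    s = set(matrix.index[matrix[transcript]])
    return s, a


def v_co(transcript: str, anchors: AnchorSet, matrix: pd.DataFrame) -> float:
    """Fraction of anchor-positive samples that contain *transcript*."""
    s, a = _occurrence_sets(transcript, anchors, matrix)
    if not a:
        raise ValueError("no anchor-positive samples")
    return len(s & a) / len(a)


def t_co(transcript: str, anchors: AnchorSet, matrix: pd.DataFrame) -> float:
    """Fraction of *transcript*'s occurrences that are anchor-positive."""
    s, a = _occurrence_sets(transcript, anchors, matrix)
    if not s:
        raise ValueError("undefined T_co: transcript never observed")
    return len(s & a) / len(s)


class CooccurrenceScreen(BaseEstimator):
    """Screen non-anchor transcripts for candidate virus segments.

    Parameters
    ----------
    v_threshold, t_threshold : float, default 0.75 / 0.5
        Inclusive lower bounds on V_co and T_co.
    min_orf_len : int, default 500
        Exclusive lower bound on the longest ORF, in nucleotides.

    Attributes
    ----------
    scores_ : pandas.DataFrame
        One row per non-anchor transcript with columns ``v_co``, ``t_co``,
        ``max_orf_len``, ``passes``, ``never_observed``, sorted by
        (v_co desc, t_co desc, transcript ID asc).
    candidates_ : list of CandidateScore
        The same rows as frozen records.
    anchor_samples_ : pandas.Index
        The anchor-positive sample set used as the reference.

    Notes
    -----
    Transcripts absent from every sample cannot have a T_co (the denominator
    is empty); they are reported with ``never_observed=True``, ``t_co=NaN``
    and ``passes=False`` rather than aborting the screen.  Transcripts missing
    from the ORF-length map are screened with length 0 and logged.
    """

    def __init__(self, v_threshold: float = 0.75, t_threshold: float = 0.5,
                 min_orf_len: int = 500):
        self.v_threshold = v_threshold
        self.t_threshold = t_threshold
        self.min_orf_len = min_orf_len

    def fit(self, X: pd.DataFrame, y=None, *, anchors: AnchorSet,
            orf_lengths: dict | None = None):
        config = ScreenConfig(self.v_threshold, self.t_threshold, self.min_orf_len)
        matrix = validate_presence_matrix(X)
        a_index = anchor_positive_samples(matrix, anchors)
        if len(a_index) == 0:
            raise ValueError("no anchor-positive samples")
        orf_lengths = dict(orf_lengths or {})

        candidates = [c for c in matrix.columns if c not in anchors.anchor_transcripts]
        missing_orfs = [c for c in candidates if c not in orf_lengths]
        if missing_orfs:
            logger.warning(
                "%d transcript(s) missing from the ORF-length map; screened with "
                "max ORF length 0: %s", len(missing_orfs), missing_orfs[:10])

        a_mask = matrix.index.isin(a_index)
        sub = matrix[candidates].to_numpy(dtype=bool) if candidates else np.empty((len(matrix), 0), bool)
        n_s = sub.sum(axis=0)                       # |S|
        n_sa = sub[a_mask].sum(axis=0)              # |S ∩ A|

        rows = []
        for j, tid in enumerate(candidates):
            vco = n_sa[j] / len(a_index)
            never = n_s[j] == 0
            tco = math.nan if never else n_sa[j] / n_s[j]
            max_orf = int(orf_lengths.get(tid, 0))
            passes = (not never
                      and vco >= config.v_threshold
                      and tco >= config.t_threshold
                      and max_orf > config.min_orf_len)
            rows.append(CandidateScore(tid, float(vco), float(tco), max_orf,
                                       bool(passes), bool(never)))
        # NaN t_co sorts last within equal v_co by treating it as -inf
        rows.sort(key=lambda c: (-c.v_co,
                                 -(c.t_co if not math.isnan(c.t_co) else -math.inf),
                                 c.transcript_id))
        self.candidates_ = rows
        self.scores_ = pd.DataFrame(
            [(c.transcript_id, c.v_co, c.t_co, c.max_orf_len, c.passes, c.never_observed)
             for c in rows],
            columns=["transcript_id", "v_co", "t_co", "max_orf_len", "passes",
                     "never_observed"],
        ).set_index("transcript_id")
        self.anchor_samples_ = a_index
        return self


def screen_candidates(matrix: pd.DataFrame, anchors: AnchorSet,
                      orf_lengths: dict | None = None,
                      config: ScreenConfig | None = None) -> list[CandidateScore]:
    """Run the candidate-segment screen; thin wrapper over CooccurrenceScreen."""
    config = config or ScreenConfig()
    est = CooccurrenceScreen(config.v_threshold, config.t_threshold, config.min_orf_len)
    est.fit(matrix, anchors=anchors, orf_lengths=orf_lengths)
    return est.candidates_
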