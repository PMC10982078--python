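"""Independent brute-force oracles used across the test suite.

These deliberately take different routes from the package implementation:
the ORF oracle works by translating whole frames with Biopython and splitting
the protein at stop symbols; the co-occurrence oracle counts sample sets
literally; the divergence oracle is the closed-form Jukes-Cantor-style
channel composition; the screen-pass oracle is exact enumeration over
binomial distributions.
"""

from __future__ import annotations

import itertools

import numpy as np
from Bio.Seq import Seq, reverse_complement
from scipy import stats


def oracle_orfs(seq: str, start_required: bool, min_len: int = 0):
    """Six-frame ORF set via frame translation and '*'-splitting.

    Returns a set of (frame, fwd_start, fwd_end, nt_seq) tuples.  Assumes an
    unambiguous A/C/G/T sequence.
    """
    seq = seq.upper()
    n = len(seq)
    out = set()
    for strand in (+1, -1):
        s = seq if strand > 0 else reverse_complement(seq)
        for off in range(3):
            ncod = (n - off) // 3
            sub = s[off:off + 3 * ncod]
            aa = str(Seq(sub).translate())
            codon_pos = 0
            for frag in aa.split("*"):
                begin = codon_pos
                if start_required:
                    m = frag.find("M")
                    begin = None if m < 0 else codon_pos + m
                if begin is not None:
                    length = (codon_pos + len(frag)) - begin
                    if length > 0 and 3 * length >= min_len:
                        b = off + 3 * begin
                        e = off + 3 * (codon_pos + len(frag))
                        nt = s[b:e]
                        fs, fe = (b, e) if strand > 0 else (n - e, n - b)
                        out.add((strand * (off + 1), fs, fe, nt))
                codon_pos += len(frag) + 1
    return out


def oracle_cooccurrence(matrix_rows, anchor_cols, transcript_col):
    """(V_co, T_co) by literal set counting.

    ``matrix_rows`` is a list of 0/1 row tuples; columns indexed by position.
    Returns (v, t) where either may be None when its denominator is empty.
    """
    a_set = {i for i, row in enumerate(matrix_rows)
             if any(row[c] for c in anchor_cols)}
    s_set = {i for i, row in enumerate(matrix_rows) if row[transcript_col]}
    v = None if not a_set else len(s_set & a_set) / len(a_set)
    t = None if not s_set else len(s_set & a_set) / len(s_set)
    return v, t


def jc_mismatch(branch_probs) -> float:
    """Expected mismatch fraction between sequence ends of a substitution path.

    Each branch substitutes a site with probability p, uniformly over the
    three alternative bases; such channels compose multiplicatively in the
    eigenvalue lambda = 1 - 4p/3, and the end-to-end mismatch probability is
    (3/4) * (1 - prod(lambda)).
    """
    lam = np.prod([1.0 - 4.0 * p / 3.0 for p in branch_probs])
    return 0.75 * (1.0 - lam)


def exact_screen_pass_probability(n_samples, prevalence, p_in, p_out,
                                  v_threshold=0.75, t_threshold=0.5):
    """P(a transcript passes the co-occurrence thresholds), by enumeration.

    The anchor-positive count a ~ Binomial(n, prevalence) conditioned on
    a >= 1; hits inside A are X ~ Binomial(a, p_in); hits outside are
    Y ~ Binomial(n - a, p_out).  The transcript passes when X/a >= v_threshold
    and X/(X+Y) >= t_threshold with X >= 1.  Returns (P(pass), P(both of two
    conditionally independent transcripts pass)).
    """
    pa = stats.binom.pmf(np.arange(n_samples + 1), n_samples, prevalence)
    single = 0.0
    both = 0.0
    for a in range(1, n_samples + 1):
        p_pass = 0.0
        for x in range(1, a + 1):
            if x / a < v_threshold:
                continue
            # X/(X+Y) >= t  <=>  Y <= X*(1-t)/t
            y_max = int(np.floor(x * (1 - t_threshold) / t_threshold))
            p_pass += (stats.binom.pmf(x, a, p_in)
                       * stats.binom.cdf(y_max, n_samples - a, p_out))
        single += pa[a] * p_pass
        both += pa[a] * p_pass ** 2
    norm = 1.0 - pa[0]
    return single / norm, both / norm


def naive_p_distance(a: str, b: str):
    """Per-site loop p-distance with pairwise deletion."""
    mism = comp = 0
    for x, y in zip(a.upper(), b.upper()):
        if x in "-N" or y in "-N":
            continue
        comp += 1
        mism += x != y
    return (mism / comp if comp else None), comp


def grand_mean_identity(dmat: np.ndarray, labels: list) -> tuple[float, float]:
    """(overall mean pairwise distance, reconstruction from group means)."""
    n = len(labels)
    pairs = list(itertools.combinations(range(n), 2))
    overall = np.mean([dmat[i, j] for i, j in pairs])
    groups = sorted(set(labels))
    idx = {g: [i for i, l in enumerate(labels) if l == g] for g in groups}
    total = 0.0
    count = 0
    for g in groups:
        for i, j in itertools.combinations(idx[g], 2):
            total += dmat[i, j]
            count += 1
    for g, h in itertools.combinations(groups, 2):
        for i in idx[g]:
            for j in idx[h]:
                total += dmat[i, j]
                count += 1
    return float(overall), total / count
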