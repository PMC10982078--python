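"""Synthetic inputs with the statistical structure the analyses assume.

The real study inputs are per-sample transcript catalogs from field-collected
bed bugs; this module generates stand-ins with known ground truth so that
every downstream stage (co-occurrence screen, ORF finder, p-distance
summaries, abundance regression) can be tested end to end without sequencing
data.

All randomness flows through ``numpy.random.default_rng`` (PCG64, a named and
stable generator); ``seed`` is a required argument of every stochastic
operation and identical seeds give byte-identical outputs.

Generative models
-----------------
* Presence/absence: each sample independently carries each virus with
  probability ``prevalence``.  The anchor (RdRp) segment is detected exactly
  in carrier samples; each non-anchor segment is detected in a carrier with
  probability ``fidelity`` and in a non-carrier with probability ``spillover``
  (conditionally independent across segments).  Background transcripts are
  detected independently at ``bg_rate``.
* Divergent families: a uniform-random root sequence; per-clade ancestors
  substituted per site at ``between_divergence``; clade members substituted
  from their ancestor at ``within_divergence``.  Substitutions are uniform
  over the three alternative bases, with no rate heterogeneity or indels —
  sufficient because the p-distance is the only downstream statistic.
* Abundance: y = intercept + slope*x + N(0, noise_sd), truncated at 0 because
  read percentages cannot be negative.
* ORF fixtures: start-to-stop ORFs of stated lengths implanted at stated
  frames, separated by A/T-only spacers that contain stop codons in all six
  frames, so no longer ORF spans an implanted one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .orf import OrfRecord, translate

__all__ = [
    "VirusSpec",
    "CladeScenario",
    "simulate_presence_matrix",
    "simulate_divergent_family",
    "simulate_abundance_table",
    "simulate_transcript_with_orfs",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class VirusSpec:
    """A multi-segment virus for presence-matrix simulation.

    ``prevalence`` is the probability a sample carries the virus; ``fidelity``
    the probability each non-anchor segment is detected in a carrier given the
    anchor is detected; ``spillover`` the probability a non-anchor segment is
    (spuriously) detected in a non-carrier.
    """

    virus_id: str
    n_segments: int
    anchor_segment_index: int = 0
    prevalence: float = 0.5
    fidelity: float = 0.9
    spillover: float = 0.0

    def __post_init__(self):
        if self.n_segments < 1:
            raise ValueError("n_segments must be >= 1")
        if not 0 <= self.anchor_segment_index < self.n_segments:
            raise ValueError("anchor_segment_index out of range")
        if not 0 < self.prevalence <= 1:
            raise ValueError("prevalence must lie in (0, 1]")
        if not 0 < self.fidelity <= 1:
            raise ValueError("fidelity must lie in (0, 1]")
        if not 0 <= self.spillover < 1:
            raise ValueError("spillover must lie in [0, 1)")


@dataclass(frozen=True)
class CladeScenario:
    """A two-or-more-clade sequence family for p-distance simulation."""

    n_per_clade: tuple = (5, 5)
    seq_len: int = 2000
    within_divergence: float | tuple = 0.03
    between_divergence: float = 0.2

    def __post_init__(self):
        object.__setattr__(self, "n_per_clade", tuple(int(n) for n in self.n_per_clade))
        if not self.n_per_clade or any(n < 1 for n in self.n_per_clade):
            raise ValueError("each clade must have at least one member")
        if self.seq_len <= 0:
            raise ValueError("seq_len must be positive")
        w = self.within_divergences()
        if any(not 0 <= x < 1 for x in (*w, self.between_divergence)):
            raise ValueError("divergences must lie in [0, 1)")

    def within_divergences(self) -> tuple:
        w = self.within_divergence
        if np.isscalar(w):
            return (float(w),) * len(self.n_per_clade)
        w = tuple(float(x) for x in w)
        if len(w) != len(self.n_per_clade):
            raise ValueError("within_divergence must be scalar or one value per clade")
        return w


def simulate_presence_matrix(n_samples: int, viruses: list[VirusSpec],
                             n_background: int = 0, bg_rate: float = 0.1,
                             seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a boolean sample x transcript presence matrix with truth labels.

    Returns ``(matrix, truth)``: the matrix has one column per virus segment
    (named ``<virus_id>_seg<k>``) plus ``n_background`` background columns;
    truth maps each column to its virus/segment role (``anchor``, ``segment``
    or ``background``).
    """
    if n_samples < 1:
        raise ValueError("empty design: n_samples must be >= 1")
    if not viruses and n_background == 0:
        raise ValueError("nothing to simulate: no viruses and no background")
    if not 0 <= bg_rate <= 1:
        raise ValueError("bg_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    samples = [f"sample{i:03d}" for i in range(n_samples)]
    columns, truth_rows = [], []
    data = {}
    for virus in viruses:
        carriers = rng.random(n_samples) < virus.prevalence
        for k in range(virus.n_segments):
            name = f"{virus.virus_id}_seg{k}"
            if k == virus.anchor_segment_index:
                col = carriers.copy()
                role = "anchor"
            else:
                det_in = rng.random(n_samples) < virus.fidelity
                det_out = rng.random(n_samples) < virus.spillover
                col = np.where(carriers, det_in, det_out)
                role = "segment"
            columns.append(name)
            data[name] = col.astype(np.int8)
            truth_rows.append((name, virus.virus_id, role, k))
    for b in range(n_background):
        name = f"bg{b:04d}"
        columns.append(name)
        data[name] = (rng.random(n_samples) < bg_rate).astype(np.int8)
        truth_rows.append((name, "background", "background", -1))
    matrix = pd.DataFrame(data, index=pd.Index(samples, name="sample"),
                          columns=columns)
    truth = pd.DataFrame(truth_rows, columns=["transcript_id", "virus_id",
                                              "role", "segment_index"])
    return matrix, truth


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each site with probability *rate*, uniform over the 3 others."""
    out = seq.copy()
    hits = np.flatnonzero(rng.random(seq.size) < rate)
    if hits.size:
        # shift by 1..3 in base space to guarantee a different base
        idx = np.searchsorted(_BASES, out[hits])
        out[hits] = _BASES[(idx + rng.integers(1, 4, hits.size)) % 4]
    return out


def simulate_divergent_family(scenario: CladeScenario,
                              seed: int = 0) -> tuple[list[tuple[str, str]], dict]:
    """Simulate equal-length sequences with clade structure.

    Returns ``(sequences, groups)`` where sequences is a list of
    ``(seq_id, sequence)`` and groups maps seq_id to its clade label
    (``cladeA``, ``cladeB``, ...).
    """
    rng = np.random.default_rng(seed)
    root = rng.choice(_BASES, size=scenario.seq_len)
    sequences, groups = [], {}
    withins = scenario.within_divergences()
    for c, (n_members, w) in enumerate(zip(scenario.n_per_clade, withins)):
        label = f"clade{chr(ord('A') + c)}"
        ancestor = _mutate(root, scenario.between_divergence, rng)
        for i in range(n_members):
            member = _mutate(ancestor, w, rng)
            sid = f"{label}_seq{i}"
            sequences.append((sid, member.tobytes().decode()))
            groups[sid] = label
    return sequences, groups


def simulate_abundance_table(n: int, slope: float, intercept: float,
                             noise_sd: float, x_values=None,
                             seed: int = 0) -> pd.DataFrame:
    """Simulate per-sample (pct_virus, pct_wolbachia) pairs on a known line.

    ``x_values`` fixes the predictor; by default Wolbachia percentages are
    drawn from a lognormal (median ~0.7%, long right tail) mimicking the
    skewed endosymbiont titres seen across field samples.  Responses are
    ``intercept + slope*x + N(0, noise_sd)`` truncated at 0 (percentages are
    nonnegative).
    """
    if n < 3:
        raise ValueError("degenerate regression design: need n >= 3")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    if x_values is None:
        x = rng.lognormal(mean=-0.35, sigma=1.0, size=n)
    else:
        x = np.asarray(list(x_values), dtype=float)
        if x.size != n:
            raise ValueError("x_values length must equal n")
        if (x < 0).any():
            raise ValueError("x values must be nonnegative")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor")
    y = intercept + slope * x + rng.normal(0.0, noise_sd, size=n)
    y = np.maximum(y, 0.0)
    return pd.DataFrame({
        "sample": [f"sample{i:03d}" for i in range(n)],
        "pct_virus": y,
        "pct_wolbachia": x,
    })


# A/T-only spacer unit: TAA (forward stop) at offsets 1,5,9 and TTA
# (reverse-strand stop) at offsets 0,4,8 cover all six frames within 12 nt,
# and an A/T alphabet can never form ATG or CAT.
_SPACER_UNIT = "TTAA"
_CG_CODONS = [a + b + c for a in "CG" for b in "CG" for c in "CG"]


def _spacer(length: int) -> str:
    return (_SPACER_UNIT * (length // 4 + 1))[:length]


def simulate_transcript_with_orfs(orf_lengths: list[int], frames: list[int],
                                  spacer_len: int = 30,
                                  seed: int = 0) -> tuple[str, list[OrfRecord]]:
    """Construct a transcript containing exactly the stated start-to-stop ORFs.

    Each ORF is ATG followed by codons over {C,G}^3 (stop- and start-free in
    every frame) and a TAA stop; minus-strand implants are reverse-complemented
    in place.  Spacers are TTAA repeats, padded so each implant lands on its
    stated frame while every block stays a codon multiple (the total length is
    then a multiple of 3, which keeps minus-strand frame labels well defined).
    The only ATG/CAT trinucleotides anywhere in the construct are the implant
    starts, so a start-to-stop scan returns exactly the implanted set.

    ``orf_lengths`` are nucleotide lengths excluding the stop codon, each >= 6
    and divisible by 3; ``frames`` in {+1,+2,+3,-1,-2,-3}.
    """
    if len(orf_lengths) != len(frames):
        raise ValueError("orf_lengths and frames must have equal length")
    if not orf_lengths:
        raise ValueError("nothing to simulate: no ORFs requested")
    for length in orf_lengths:
        if length < 6 or length % 3:
            raise ValueError(f"ORF length {length} must be >= 6 and divisible by 3")
    valid_frames = {1, 2, 3, -1, -2, -3}
    if any(f not in valid_frames for f in frames):
        raise ValueError("frames must be in {+1,+2,+3,-1,-2,-3}")
    if spacer_len < 0:
        raise ValueError("spacer_len must be >= 0")
    rng = np.random.default_rng(seed)
    # effective spacer: codon multiple, long enough for stops in all 6 frames
    eff = max(-(-spacer_len // 3) * 3, 12)

    from .orf import reverse_complement

    parts = [_spacer(eff)]
    pos = eff
    truth = []
    for length, frame in zip(orf_lengths, frames):
        body = "ATG" + "".join(rng.choice(_CG_CODONS) for _ in range(length // 3 - 1))
        block = body + "TAA"                     # ORF + its stop, len = length + 3
        if frame > 0:
            pad = (frame - 1) % 3
        else:
            pad = (3 - (-frame - 1)) % 3         # end ≡ -(|frame|-1) mod 3
        parts.append(_spacer(pad) if pad else "")
        start = pos + pad
        if frame > 0:
            orf_start, orf_end = start, start + length
            nt = body
        else:
            block = reverse_complement(block)
            orf_start, orf_end = start + 3, start + 3 + length
            nt = body
        parts.append(block)
        truth.append(OrfRecord("synthetic", frame, orf_start, orf_end,
                               nt, translate(nt)))
        tail = (3 - pad) % 3
        parts.append(_spacer(eff + tail))
        pos = start + length + 3 + eff + tail
    seq = "".join(parts)
    assert len(seq) == pos and len(seq) % 3 == 0
    return seq, truth
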