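"""Six-frame open-reading-frame extraction with getorf-style mode semantics.

An ORF is a stop-free codon run in one of the six reading frames.  Two run
definitions are supported, mirroring EMBOSS getorf's ``-find`` options:

* ``stop_to_stop`` — a maximal codon run between stop codons; the sequence
  ends act as virtual stops (``-find 0``/``-find 2``).  This is the pipeline
  default used for the >500 nt candidate-segment filter.
* ``start_to_stop`` — the run from the first ATG after the previous stop to
  the next stop (``-find 1``/``-find 3``).  Only ATG counts as a start.

The ``_nt``/``_aa`` suffixes of the mode names select getorf's output flavour
(nucleotide vs translation); records here always carry both sequences, so the
suffix does not change which ORFs are found.  ``min_len`` is measured in
nucleotides, excluding the stop codon.

Coordinates are 0-based half-open on the forward strand of the input.  Frames
are ``+1/+2/+3`` for reads starting at forward offsets 0/1/2 and ``-1/-2/-3``
for reads starting at offsets 0/1/2 of the reverse complement.  For
reverse-strand records ``nt_seq`` is the reverse complement of the
``[start, end)`` forward slice.  Codons containing ``N`` never match a start
or stop codon and translate to ``X``.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Data import CodonTable
from Bio.Seq import reverse_complement

__all__ = ["OrfRecord", "find_orfs", "translate", "MODES"]

MODES = ("stop_to_stop_nt", "start_to_stop_nt", "stop_to_stop_aa", "start_to_stop_aa",
         "stop_to_stop", "start_to_stop")

_STOPS = {"TAA", "TAG", "TGA"}
_VALID = set("ACGTN")


@dataclass(frozen=True)
class OrfRecord:
    seq_id: str
    frame: int
    start: int  # 0-based, forward strand
    end: int    # half-open, forward strand
    nt_seq: str
    aa_seq: str

    @property
    def length_nt(self) -> int:
        return self.end - self.start


def _codon_table(genetic_code: int) -> dict:
    table = CodonTable.unambiguous_dna_by_id[genetic_code]
    mapping = dict(table.forward_table)
    for stop in table.stop_codons:
        mapping[stop] = "*"
    return mapping


def translate(nt: str, genetic_code: int = 1) -> str:
    """Translate a nucleotide string; stops as ``*``, N-containing codons as ``X``.

    Raises ValueError if the length is not a multiple of 3.
    """
    nt = nt.upper()
    if len(nt) % 3:
        raise ValueError(f"sequence length {len(nt)} is not a multiple of 3")
    table = _codon_table(genetic_code)
    out = []
    for i in range(0, len(nt), 3):
        codon = nt[i:i + 3]
        out.append(table.get(codon, "X") if "N" not in codon else "X")
    return "".join(out)


def _check_alphabet(seq: str) -> str:
    seq = seq.upper()
    for pos, ch in enumerate(seq):
        if ch not in _VALID:
            raise ValueError(f"invalid nucleotide {ch!r} at position {pos}")
    return seq


def _scan_strand(seq: str, start_required: bool, min_len: int):
    """Yield (offset_in_strand, orf_start, orf_end_exclusive_of_stop) per frame."""
    n = len(seq)
    for offset in range(3):
        run_start = offset          # first codon after the previous stop
        atg = None                  # first ATG in the current run
        i = offset
        while i + 3 <= n:
            codon = seq[i:i + 3]
            is_stop = codon in _STOPS  # N-containing codons are never stops
            if start_required and atg is None and codon == "ATG":
                atg = i
            if is_stop:
                begin = atg if start_required else run_start
                if begin is not None and i > begin and (i - begin) >= min_len:
                    yield offset, begin, i
                run_start = i + 3
                atg = None
            i += 3
        # sequence end acts as a virtual stop
        begin = atg if start_required else run_start
        if begin is not None and i > begin and (i - begin) >= min_len:
            yield offset, begin, i


def find_orfs(seq: str, mode: str = "stop_to_stop_nt", min_len: int = 0,
              genetic_code: int = 1, seq_id: str = "") -> list[OrfRecord]:
    """Scan all six frames of *seq* for ORFs under the given mode.

    Returns records sorted by (start, frame).  ``min_len`` drops ORFs shorter
    than that many nucleotides (stop codon excluded).
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    if min_len < 0:
        raise ValueError("min_len must be >= 0")
    start_required = mode.startswith("start_to_stop")
    seq = _check_alphabet(seq)
    n = len(seq)
    records = []

    for offset, b, e in _scan_strand(seq, start_required, min_len):
        nt = seq[b:e]
        records.append(OrfRecord(seq_id, offset + 1, b, e, nt, translate(nt, genetic_code)))

    rc = reverse_complement(seq)
    for offset, b, e in _scan_strand(rc, start_required, min_len):
        nt = rc[b:e]
        records.append(OrfRecord(seq_id, -(offset + 1), n - e, n - b, nt,
                                 translate(nt, genetic_code)))

    records.sort(key=lambda r: (r.start, r.frame))
    return records
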