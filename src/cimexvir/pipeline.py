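"""Orchestration: annotation ingest, presence-matrix assembly, and reporting.

Ties the analysis stages together: tabular homology hits are filtered by
e-value, per-sample transcript catalogs become a presence/absence matrix with
RdRp anchor sets, and ``run_report`` executes screen → ORF filter →
(optional) distance summaries → (optional) abundance correlation, writing
TSV/JSON outputs plus a run log.

Upstream steps (read QC, assembly, 90%-identity clustering, homology search,
alignment, tree inference, read mapping) are assumed done; transcript IDs are
cluster IDs shared across samples.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cooccurrence import AnchorSet, ScreenConfig, screen_candidates
from .orf import find_orfs
from .distances import AlignedSet, distance_matrix, group_mean_distances, percent
from .abundance import correlate, format_result
from . import io as _io

__all__ = [
    "BLAST_COLUMNS", "RunConfig",
    "parse_blast_tab", "build_presence_matrix", "max_orf_lengths", "run_report",
]

logger = logging.getLogger(__name__)

# outfmt-6 tabular dialect
BLAST_COLUMNS = ("qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
                 "qstart", "qend", "sstart", "send", "evalue", "bitscore")
_NUMERIC = {"pident": float, "length": int, "mismatch": int, "gapopen": int,
            "qstart": int, "qend": int, "sstart": int, "send": int,
            "evalue": float, "bitscore": float}


def parse_blast_tab(path, evalue_cutoff: float = 1e-5) -> pd.DataFrame:
    """Parse a 12-column tabular hit file, dropping rows above the e-value cutoff.

    Extra trailing columns are tolerated and ignored; fewer than 12 columns or
    unparsable numeric fields raise with the offending line number.  The count
    of dropped rows is logged.
    """
    rows = []
    dropped = 0
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < len(BLAST_COLUMNS):
                raise ValueError(
                    f"{path}:{lineno}: expected >= {len(BLAST_COLUMNS)} "
                    f"tab-separated columns, got {len(fields)}")
            row = {}
            for name, value in zip(BLAST_COLUMNS, fields):
                conv = _NUMERIC.get(name, str)
                try:
                    row[name] = conv(value)
                except ValueError as exc:
                    raise ValueError(
                        f"{path}:{lineno}: cannot parse field {name!r} "
                        f"from {value!r}") from exc
            if row["evalue"] > evalue_cutoff:
                dropped += 1
                continue
            rows.append(row)
    logger.info("parse_blast_tab: dropped %d hit(s) above e-value %g",
                dropped, evalue_cutoff)
    table = pd.DataFrame(rows, columns=list(BLAST_COLUMNS))
    table.attrs["dropped_hits"] = dropped
    return table


def build_presence_matrix(catalogs: dict[str, set],
                          anchor_flags: pd.DataFrame | None = None
                          ) -> tuple[pd.DataFrame, dict[str, AnchorSet]]:
    """Assemble a presence matrix from per-sample transcript-cluster catalogs.

    ``anchor_flags`` (optional) has columns ``transcript_id``, ``virus_id``
    and boolean ``complete_rdrp``; clusters flagged complete become the
    anchors of their virus.  Raises if a flagged anchor is absent from every
    sample.
    """
    if not catalogs:
        raise ValueError("empty catalogs: no samples")
    samples = sorted(catalogs)
    transcripts = sorted(set().union(*(set(c) for c in catalogs.values())))
    if not transcripts:
        raise ValueError("empty catalogs: no transcripts in any sample")
    matrix = pd.DataFrame(
        [[int(t in catalogs[s]) for t in transcripts] for s in samples],
        index=pd.Index(samples, name="sample"), columns=transcripts, dtype="int8")

    anchors: dict[str, AnchorSet] = {}
    if anchor_flags is not None and len(anchor_flags):
        flagged = anchor_flags[anchor_flags["complete_rdrp"].astype(bool)]
        for virus, sub in flagged.groupby("virus_id", sort=True):
            ids = frozenset(sub["transcript_id"])
            missing = ids - set(transcripts)
            if missing:
                raise ValueError(
                    f"anchor cluster(s) absent from all samples: {sorted(missing)}")
            anchors[virus] = AnchorSet(virus, ids)
    return matrix, anchors


def max_orf_lengths(sequences: list[tuple[str, str]], mode: str = "stop_to_stop_nt",
                    genetic_code: int = 1) -> dict[str, int]:
    """Longest ORF (nt, stop excluded) per sequence under the given mode."""
    out = {}
    for sid, seq in sequences:
        orfs = find_orfs(seq, mode=mode, genetic_code=genetic_code, seq_id=sid)
        out[sid] = max((o.length_nt for o in orfs), default=0)
    return out


@dataclass
class RunConfig:
    """Paths and thresholds of a full pipeline run.

    The distance and abundance stages are optional: leave their paths unset
    to skip them (the run log records the omission).
    """

    matrix: str = ""
    anchors: str = ""
    fasta: str = ""              # transcript sequences for the ORF filter
    orf_lengths: str = ""        # alternative to fasta: precomputed lengths
    alignment: str = ""          # aligned FASTA for the distance stage
    groups: str = ""
    abundance: str = ""
    out_dir: str = "cimexvir_report"
    v_threshold: float = 0.75
    t_threshold: float = 0.5
    min_orf_len: int = 500
    orf_mode: str = "stop_to_stop_nt"
    distance_policy: str = "pairwise_deletion"
    drop_samples: tuple = field(default_factory=tuple)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as handle:
            raw = yaml.safe_load(handle) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "drop_samples" in raw and raw["drop_samples"] is not None:
            raw["drop_samples"] = tuple(raw["drop_samples"])
        return cls(**raw)


def run_report(config: RunConfig) -> dict:
    """Execute the configured stages and write the report bundle.

    Writes ``candidates.tsv`` (screen), optionally ``distance_matrix.tsv`` and
    ``group_distances.tsv``, optionally ``regression.json``, plus
    ``run_log.json``.  Returns the log dict.  Stage failures propagate with
    the stage name prefixed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": {"v_threshold": config.v_threshold,
                       "t_threshold": config.t_threshold,
                       "min_orf_len": config.min_orf_len},
        "stages": {},
    }

    def _stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        return wrap

    # --- co-occurrence screen -------------------------------------------
    if not config.matrix or not config.anchors:
        raise ValueError("run_report requires 'matrix' and 'anchors' inputs")

    def _screen():
        matrix = _io.read_presence_matrix(config.matrix)
        anchor_sets = _io.read_anchor_table(config.anchors)
        if config.orf_lengths:
            lengths = _io.read_orf_lengths(config.orf_lengths)
        elif config.fasta:
            lengths = max_orf_lengths(_io.read_fasta(config.fasta),
                                      mode=config.orf_mode)
        else:
            lengths = {}
            logger.warning("no FASTA or ORF-length table: ORF lengths default to 0")
        screen = ScreenConfig(config.v_threshold, config.t_threshold,
                              config.min_orf_len)
        frames = []
        for virus, anchors in sorted(anchor_sets.items()):
            scores = screen_candidates(matrix, anchors, lengths, screen)
            df = pd.DataFrame(
                [(virus, c.transcript_id, f"{c.v_co:.4f}", f"{c.t_co:.4f}",
                  c.max_orf_len, c.passes, c.never_observed) for c in scores],
                columns=["virus_id", "transcript_id", "v_co", "t_co",
                         "max_orf_len", "passes", "never_observed"])
            frames.append(df)
        result = pd.concat(frames, ignore_index=True)
        result.to_csv(out / "candidates.tsv", sep="\t", index=False)
        return {"viruses": len(anchor_sets), "candidates": int(len(result)),
                "passing": int(result["passes"].sum()),
                "missing_orf_lengths": int(
                    (~result["transcript_id"].isin(lengths)).sum())}

    log["stages"]["screen"] = _stage("screen")(_screen)

    # --- distance summaries (optional) ----------------------------------
    if config.alignment and config.groups:
        def _distances():
            aln = AlignedSet.from_fasta(config.alignment)
            D = distance_matrix(aln, config.distance_policy)
            _io.write_distance_matrix(D, out / "distance_matrix.tsv")
            groups = _io.read_groups(config.groups)
            summary = group_mean_distances(D, groups)
            summary = summary.assign(
                mean_pct=[percent(x) if pd.notna(x) else float("nan")
                          for x in summary["mean_distance"]])
            summary.to_csv(out / "group_distances.tsv", sep="\t", index=False)
            return {"sequences": len(aln), "groups": len(set(groups.values()))}

        log["stages"]["distances"] = _stage("distances")(_distances)
    else:
        log["stages"]["distances"] = "skipped: no alignment/groups supplied"

    # --- abundance regression (optional) --------------------------------
    if config.abundance:
        def _abundance():
            table = _io.read_abundance_table(config.abundance)
            res = correlate(table, tuple(config.drop_samples))
            report = format_result(res)
            with open(out / "regression.json", "w", encoding="utf-8") as fh:
                json.dump(report, fh, indent=2)
            return report

        log["stages"]["correlation"] = _stage("correlation")(_abundance)
    else:
        log["stages"]["correlation"] = "skipped: no abundance table supplied"

    with open(out / "run_log.json", "w", encoding="utf-8") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
    return log
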