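"""Readers and writers for the plain-text formats the pipeline touches.

All coordinates are 0-based half-open on the 3'UTR of a single transcript
(the BED "chromosome" is the transcript id). Sequences are RNA over
{A, C, G, U, N}; DNA input is transliterated on read. Genome-space mapping
is out of scope: interval inputs are consumed already projected onto
transcript coordinates, on the sense strand ('+' only).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("rbpmt")

RNA_ALPHABET = frozenset("ACGUN")

#: Flat config defaults; every threshold named in the pipeline lives here so a
#: single YAML document can override any of them.
DEFAULT_CONFIG: dict = {
    "min_utr_sites": 300,          # RBP retained only with >= this many 3'UTR intervals
    "expression_quantile": 0.5,    # RBPs / transcripts below this quantile dropped
    "flank": 50,                   # nt flank for bound-RBP counting
    "flank_wide": 100,             # wider flank for coverage analyses
    "local_au_window": 30,         # nt each side for local AU content
    "dms_window": 100,             # fragment window (nt)
    "dms_step": 10,                # fragment step (nt)
    "dms_pseudocount": 1.0,        # RPM pseudocount in log-ratio scores
    "balance_alpha": 0.05,         # indistinguishability threshold
    "balance_retries": 10,
    "cutoff_shrink": 0.8,          # multiplicative cutoff shrink on balance failure
    "stringent_score_quantile": 0.5,  # BED score quantile separating tiers
    "fold_len_cap": 300,           # max sequence length for the fold engine
    "derepression_quantile": 0.75,  # "highly de-repressed" threshold
    "ko_distance_cutoff": 100,     # d < cutoff = "short" stratum
}


class FormatError(ValueError):
    """Malformed input file (bad coordinates, duplicate ids, missing columns)."""


@dataclass
class Transcript:
    """A 3'UTR sequence with an (optional) expression level.

    The sequence is the coordinate frame for every interval referring to
    this transcript. Expression is in arbitrary TPM-like units and stays
    ``None`` until joined from an expression table.
    """

    id: str
    utr_seq: str
    expression: float | None = None

    def __post_init__(self) -> None:
        if len(self.utr_seq) < 1:
            raise FormatError(f"transcript {self.id}: empty sequence")
        bad = set(self.utr_seq) - RNA_ALPHABET
        if bad:
            raise FormatError(
                f"transcript {self.id}: invalid characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.utr_seq)


@dataclass
class IntervalRecord:
    """One BED6 line: a half-open interval on a transcript.

    ``name`` is parsed downstream as ``"<rbp_id>[:<tier>]"`` when present.
    """

    seq_id: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0:
            raise FormatError(f"negative start {self.start} on {self.seq_id}")
        if self.end <= self.start:
            raise FormatError(
                f"start >= end ({self.start} >= {self.end}) on {self.seq_id}"
            )
        if self.strand != "+":
            raise FormatError(
                f"strand {self.strand!r} rejected: 3'UTR-space intervals are sense-strand"
            )

    @property
    def rbp_id(self) -> str:
        return self.name.split(":", 1)[0]

    @property
    def tier(self) -> str | None:
        parts = self.name.split(":", 1)
        return parts[1] if len(parts) == 2 else None


def _to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def read_fasta(path: str | Path) -> list[Transcript]:
    """Read a FASTA of 3'UTRs (or miRNAs) into Transcript records.

    Sequences are upper-cased and T is transliterated to U. Duplicate ids and
    empty files are hard errors.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: empty FASTA")
    out: list[Transcript] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate id {rec.id}")
        seen.add(rec.id)
        out.append(Transcript(id=rec.id, utr_seq=_to_rna(str(rec.seq))))
    logger.info("read_fasta: %d records from %s", len(out), path)
    return out


def write_fasta(transcripts: Iterable[Transcript], path: str | Path) -> None:
    recs = [SeqRecord(Seq(t.utr_seq), id=t.id, description="") for t in transcripts]
    SeqIO.write(recs, str(path), "fasta")


def read_bed(path: str | Path, sequences: Sequence[Transcript] | None = None
             ) -> list[IntervalRecord]:
    """Read BED6 intervals; coordinates validated, never clamped.

    When ``sequences`` is given, interval ends are checked against the
    referenced sequence lengths.
    """
    lengths = {t.id: len(t) for t in sequences} if sequences is not None else None
    out: list[IntervalRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: fewer than 3 columns at line {lineno}")
            seq_id = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(
                    f"{path}: non-integer coordinate at line {lineno}"
                ) from exc
            if start < 0:
                raise FormatError(f"{path}: negative start at line {lineno}")
            if start >= end:
                raise FormatError(f"{path}: start >= end at line {lineno}")
            name = fields[3] if len(fields) > 3 else "."
            score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
            strand = fields[5] if len(fields) > 5 else "+"
            if lengths is not None:
                if seq_id not in lengths:
                    raise FormatError(f"{path}: unknown sequence {seq_id} at line {lineno}")
                if end > lengths[seq_id]:
                    raise FormatError(
                        f"{path}: end {end} beyond {seq_id} length {lengths[seq_id]}"
                        f" at line {lineno}"
                    )
            out.append(IntervalRecord(seq_id, start, end, name, score, strand))
    logger.info("read_bed: %d intervals from %s", len(out), path)
    return out


def write_bed(intervals: Iterable[IntervalRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.seq_id}\t{iv.start}\t{iv.end}\t{iv.name}\t{iv.score:g}\t{iv.strand}\n"
            )


def read_table(path: str | Path, required_columns: Sequence[str] = ()) -> pd.DataFrame:
    """Read a tab-separated table with a header row.

    Missing values ("NA", empty) become NaN and are never silently zeroed;
    rows with missing values are retained.
    """
    df = pd.read_csv(path, sep="\t", na_values=["NA", "NaN", ""])
    for col in required_columns:
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col}")
    logger.info("read_table: %d rows, %d cols from %s", len(df), df.shape[1], path)
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def load_config(path: str | Path | None = None) -> dict:
    """Load the flat YAML config, filling unspecified keys with defaults."""
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        unknown = set(user) - set(cfg)
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(user)
    return cfg


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
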