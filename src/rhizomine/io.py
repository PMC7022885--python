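"""Readers and writers for the tabular and sequence dialects the
pipeline consumes and emits.

Everything tabular is TSV (taxon names may contain commas); FASTA goes
through Biopython.  Count tables and result tables are written with a
provenance header (``# rhizomine <version>``, config hash, seed) so a
table can always be traced to the run that produced it; readers skip
``#`` comment lines.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .pseudoreads import MappedInterval, ReferenceSet
from .read_assignment import AlignmentHit

PathLike = Union[str, Path]

#: standard BLAST outfmt-6 column order, with subject taxid appended
BLAST_COLUMNS = (
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
    "staxid",
)


class ParseError(ValueError):
    """Malformed record, annotated with file and line number."""

    def __init__(self, path: PathLike, line_no: int, message: str):
        super().__init__(f"{path}:{line_no}: {message}")
        self.path = str(path)
        self.line_no = line_no


# -- FASTA ---------------------------------------------------------------


def read_fasta(path: PathLike) -> dict[str, str]:
    """Read FASTA into an ordered id -> sequence mapping."""
    records = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in records:
            raise ValueError(f"duplicate FASTA id {record.id!r} in {path}")
        records[record.id] = str(record.seq)
    return records


def write_fasta(sequences: Mapping[str, str] | Iterable[tuple[str, str]], path: PathLike) -> None:
    if isinstance(sequences, Mapping):
        items = sequences.items()
    else:
        items = sequences
    records = (
        SeqRecord(Seq(seq), id=name, description="") for name, seq in items
    )
    SeqIO.write(records, str(path), "fasta")


def read_reference_set(path: PathLike) -> ReferenceSet:
    return ReferenceSet(read_fasta(path))


# -- alignment hits ------------------------------------------------------


def read_alignment_tsv(
    path: PathLike,
    column_map: Optional[Mapping[str, int]] = None,
) -> list[AlignmentHit]:
    """Parse BLAST-tabular hits (12 standard columns + subject taxid).

    ``column_map`` overrides the 0-based column index of any field
    named in :data:`BLAST_COLUMNS`.  Subject coordinates arrive 1-based
    inclusive and possibly reversed (minus strand); they are converted
    to 0-based half-open plus an explicit strand.
    """
    columns = {name: i for i, name in enumerate(BLAST_COLUMNS)}
    if column_map:
        columns.update(column_map)
    hits = []
    with open(path) as handle:
        for line_no, line in enumerate(handle, start=1):
            line = line.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                sstart = int(fields[columns["sstart"]])
                send = int(fields[columns["send"]])
                strand = "+" if send >= sstart else "-"
                lo, hi = min(sstart, send), max(sstart, send)
                hits.append(
                    AlignmentHit(
                        read_id=fields[columns["qseqid"]],
                        subject_id=fields[columns["sseqid"]],
                        subject_taxid=int(fields[columns["staxid"]]),
                        percent_identity=float(fields[columns["pident"]]),
                        score=float(fields[columns["bitscore"]]),
                        subject_start=lo - 1,
                        subject_end=hi,
                        strand=strand,
                    )
                )
            except (IndexError, ValueError) as exc:
                raise ParseError(path, line_no, f"bad alignment record: {exc}") from exc
    return hits


def write_alignment_tsv(hits: Iterable[AlignmentHit], path: PathLike) -> None:
    """Write hits in the 13-column BLAST-tabular dialect read back by
    :func:`read_alignment_tsv`.  Unmodelled columns are filled neutrally."""
    with open(path, "w") as handle:
        for h in hits:
            if h.strand == "+":
                sstart, send = h.subject_start + 1, h.subject_end
            else:
                sstart, send = h.subject_end, h.subject_start + 1
            length = h.subject_end - h.subject_start
            handle.write(
                "\t".join(
                    str(v)
                    for v in (
                        h.read_id,
                        h.subject_id,
                        h.percent_identity,
                        length,
                        0,
                        0,
                        1,
                        length,
                        sstart,
                        send,
                        1e-5,
                        h.score,
                        h.subject_taxid,
                    )
                )
                + "\n"
            )


# -- BED intervals -------------------------------------------------------


def read_bed(path: PathLike) -> list[MappedInterval]:
    """Minimal BED reader: chrom, start, end[, name, score, strand]."""
    intervals = []
    with open(path) as handle:
        for line_no, line in enumerate(handle, start=1):
            line = line.rstrip("\r\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(path, line_no, "BED needs >= 3 columns")
            try:
                intervals.append(
                    MappedInterval(
                        ref_id=fields[0],
                        start=int(fields[1]),
                        end=int(fields[2]),
                        read_id=fields[3] if len(fields) > 3 else f"iv{line_no}",
                        strand=fields[5] if len(fields) > 5 else "+",
                    )
                )
            except ValueError as exc:
                raise ParseError(path, line_no, f"bad BED record: {exc}") from exc
    return intervals


# -- tables --------------------------------------------------------------


def provenance_header(
    config: Optional[Mapping] = None, seed: Optional[int] = None
) -> str:
    from . import __version__

    lines = [f"# rhizomine {__version__}"]
    if config is not None:
        digest = hashlib.sha256(
            json.dumps(dict(config), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]
        lines.append(f"# config_hash={digest}")
    if seed is not None:
        lines.append(f"# seed={seed}")
    return "\n".join(lines) + "\n"


def write_count_table(
    table: pd.DataFrame,
    path: PathLike,
    config: Optional[Mapping] = None,
    seed: Optional[int] = None,
    index_label: str = "feature",
) -> None:
    with open(path, "w") as handle:
        handle.write(provenance_header(config, seed))
        table.to_csv(handle, sep="\t", index_label=index_label, lineterminator="\n")


def read_count_table(path: PathLike) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if frame.index.duplicated().any():
        raise ValueError(f"duplicate feature ids in {path}")
    return frame


def read_metadata(path: PathLike) -> pd.DataFrame:
    """Sample sheet: first column is the sample id; expects at least
    ``genotype`` and ``soil`` columns for design-aware analyses."""
    meta = pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype=str)
    if meta.index.duplicated().any():
        raise ValueError(f"duplicate sample ids in {path}")
    return meta


def read_mapping_table(path: PathLike) -> dict[str, set[str]]:
    """Two-column mapping TSV (e.g. KO <-> COG); returns first-column
    key -> set of second-column values."""
    mapping: dict[str, set[str]] = {}
    with open(path) as handle:
        for line_no, line in enumerate(handle, start=1):
            line = line.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(path, line_no, "mapping rows need 2 columns")
            mapping.setdefault(fields[0], set()).add(fields[1])
    return mapping


def invert_mapping(mapping: Mapping[str, set[str]]) -> dict[str, set[str]]:
    inverted: dict[str, set[str]] = {}
    for key, values in mapping.items():
        for value in values:
            inverted.setdefault(value, set()).add(key)
    return inverted
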