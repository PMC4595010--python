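"""Sequence and table I/O, plus the packaged miRNA fixture tables.

All RNA sequences are normalised to a lowercase {a,c,g,u} alphabet at the
boundary (DNA input is accepted and transparently converted, t→u).  The
fixture bundle ships the curated set of 14 novel Homalodisca vitripennis
mature miRNAs together with their precursor sequences, host-transcript
origin annotations, dot-bracket precursor structures, and per-strand read
counts.
"""

from __future__ import annotations

import csv
import gzip
import io
from dataclasses import dataclass, fields
from importlib import resources
from pathlib import Path
from typing import Any, Iterable, Sequence

from Bio import SeqIO

from .errors import FixtureError, ParseError, StructureError

RNA_ALPHABET = frozenset("acgu")

#: typographic ellipsis glyphs that appear in printed dot-bracket strings;
#: each stands for three unpaired positions
_ELLIPSIS_GLYPHS = ("…",)


def normalize_residues(raw: str) -> str:
    """Lowercase and convert DNA to RNA (t→u); validate the alphabet."""
    residues = raw.strip().lower().replace("t", "u")
    if not residues:
        raise ParseError("empty sequence")
    bad = set(residues) - RNA_ALPHABET
    if bad:
        raise ParseError(f"non-RNA characters in sequence: {sorted(bad)}")
    return residues


@dataclass(frozen=True)
class RNASequence:
    """A named RNA sequence with lowercase {a,c,g,u} residues."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self):
        if not self.residues:
            raise ValueError("residues must be non-empty")
        bad = set(self.residues) - RNA_ALPHABET
        if bad:
            raise ValueError(f"invalid residues {sorted(bad)} in {self.id!r}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class OriginRecord:
    """Host-transcript origin of a miRNA: free-text description + coordinates.

    Coordinates are stored verbatim as printed in the source table; the
    0/1-based and open/closed convention of that table is unknown, so they
    are not used as ground truth for interval arithmetic.  The pipeline's
    own coordinates are 1-based fully-closed.
    """

    name: str
    description: str
    start: int
    end: int


@dataclass
class FixtureBundle:
    """The five cross-keyed fixture tables for the 14 novel miRNAs."""

    matures: list[RNASequence]
    precursors: list[RNASequence]
    origins: dict[str, OriginRecord]
    structures: dict[str, str]
    abundances: dict[str, tuple[int, int, int]]  # (total, mature, star)

    @property
    def names(self) -> list[str]:
        return [m.id for m in self.matures]

    def mature(self, name: str) -> RNASequence:
        for m in self.matures:
            if m.id == name:
                return m
        raise KeyError(name)

    def precursor(self, name: str) -> RNASequence:
        for p in self.precursors:
            if p.id == name:
                return p
        raise KeyError(name)


def _open_maybe_gzip(path: str | Path):
    path = Path(path)
    handle = open(path, "rb")
    magic = handle.read(2)
    handle.seek(0)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.GzipFile(fileobj=handle))
    return io.TextIOWrapper(handle)


def read_fasta(path: str | Path) -> list[RNASequence]:
    """Read a (possibly gzipped) FASTA file into normalised RNASequences.

    Raises ParseError naming the offending line for records with empty
    sequences or for content preceding the first header.
    """
    records: list[RNASequence] = []
    with _open_maybe_gzip(path) as handle:
        text = handle.read()
    # light syntactic pre-pass so errors carry a line number
    header_line = None
    seen_ids: set[str] = set()
    body_len = 0
    lineno = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith(">"):
            if header_line is not None and body_len == 0:
                raise ParseError("header with empty sequence", line=header_line)
            header_line, body_len = lineno, 0
        else:
            if header_line is None:
                raise ParseError("sequence data before first '>' header", line=lineno)
            body_len += len(stripped)
    if header_line is not None and body_len == 0:
        raise ParseError("header with empty sequence", line=header_line)

    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        if rec.id in seen_ids:
            raise ParseError(f"duplicate record id {rec.id!r}")
        seen_ids.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(RNASequence(rec.id, normalize_residues(str(rec.seq)), desc))
    return records


def write_fasta(records: Iterable[RNASequence], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as out:
        for rec in records:
            header = f">{rec.id}"
            if rec.description:
                header += f" {rec.description}"
            out.write(header + "\n")
            for i in range(0, len(rec.residues), width):
                out.write(rec.residues[i:i + width] + "\n")


def read_fastq(path: str | Path):
    """Read 4-line FASTQ records (optionally gzipped) into SmallRNAReads.

    Counts initialise to 1.  A quality string whose length differs from its
    sequence raises ParseError with the record's first line number.
    """
    from .reads import SmallRNARead  # local import to avoid a cycle

    reads: list[SmallRNARead] = []
    with _open_maybe_gzip(path) as handle:
        lines = handle.read().splitlines()
    stripped = [ln for ln in lines if ln.strip()]
    if len(stripped) % 4:
        raise ParseError("FASTQ record count is not a multiple of 4-line blocks")
    for i in range(0, len(stripped), 4):
        head, seq, plus, qual = stripped[i:i + 4]
        lineno = i + 1
        if not head.startswith("@"):
            raise ParseError("expected '@' header", line=lineno)
        if not plus.startswith("+"):
            raise ParseError("expected '+' separator", line=lineno + 2)
        if len(seq) != len(qual):
            raise ParseError(
                f"quality length {len(qual)} != sequence length {len(seq)}",
                line=lineno,
            )
        reads.append(
            SmallRNARead(id=head[1:].split()[0], residues=normalize_residues(seq),
                         count=1, quality=qual)
        )
    return reads


def write_fastq(reads, path: str | Path) -> None:
    with open(path, "w") as out:
        for r in reads:
            qual = getattr(r, "quality", None) or "I" * len(r.residues)
            out.write(f"@{r.id}\n{r.residues}\n+\n{qual}\n")


def normalize_structure(raw: str) -> str:
    """Expand typographic ellipses to '...' and validate balance.

    The printed structure strings use the single-character ellipsis glyph
    for runs of three unpaired positions.  Unbalanced parentheses raise
    StructureError naming the first offending position (1-based).
    """
    expanded = raw.strip()
    for glyph in _ELLIPSIS_GLYPHS:
        expanded = expanded.replace(glyph, "...")
    bad = set(expanded) - set("().")
    if bad:
        raise StructureError(f"illegal structure characters {sorted(bad)}")
    depth = 0
    for pos, ch in enumerate(expanded, start=1):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise StructureError("unmatched ')'", position=pos)
    if depth:
        raise StructureError("unmatched '('", position=len(expanded))
    return expanded


def _fixture_rows(basename: str) -> list[dict[str, str]]:
    ref = resources.files("sharpmir.data").joinpath(basename)
    with ref.open() as handle:
        return list(csv.DictReader(handle, delimiter="\t"))


def load_fixtures() -> FixtureBundle:
    """Load and cross-validate the packaged 14-miRNA fixture tables."""
    matures = [
        RNASequence(r["name"], normalize_residues(r["sequence"]))
        for r in _fixture_rows("matures.tsv")
    ]
    precursors = [
        RNASequence(r["name"], normalize_residues(r["sequence"]))
        for r in _fixture_rows("precursors.tsv")
    ]
    origins = {
        r["name"]: OriginRecord(r["name"], r["description"], int(r["start"]), int(r["end"]))
        for r in _fixture_rows("origins.tsv")
    }
    structures = {
        r["name"]: normalize_structure(r["structure"])
        for r in _fixture_rows("structures.tsv")
    }
    abundances = {
        r["name"]: (int(r["total"]), int(r["mature_reads"]), int(r["star_reads"]))
        for r in _fixture_rows("abundance.tsv")
    }

    names = [m.id for m in matures]
    if len(names) != len(set(names)):
        raise FixtureError("duplicate miRNA names in mature table")
    for label, keys in (
        ("precursors", [p.id for p in precursors]),
        ("origins", list(origins)),
        ("structures", list(structures)),
        ("abundances", list(abundances)),
    ):
        if set(keys) != set(names) or len(keys) != len(names):
            raise FixtureError(f"fixture table {label} does not key the same miRNA set")
    pre_by_name = {p.id: p for p in precursors}
    for m in matures:
        if m.residues not in pre_by_name[m.id].residues:
            raise FixtureError(f"mature {m.id} is not a substring of its precursor")
        if len(structures[m.id]) != len(pre_by_name[m.id].residues):
            raise FixtureError(f"structure length mismatch for {m.id}")
    for name, (total, mat, star) in abundances.items():
        if total != mat + star:
            raise FixtureError(f"abundance total mismatch for {name}")
    return FixtureBundle(matures, precursors, origins, structures, abundances)


def _record_to_dict(record: Any) -> dict[str, Any]:
    if isinstance(record, dict):
        return record
    return {f.name: getattr(record, f.name) for f in fields(record)}


def write_table(records: Sequence[Any], path: str | Path,
                columns: Sequence[str] | None = None) -> None:
    """Write homogeneous records (dataclasses or dicts) as headered TSV.

    Integer and string fields round-trip losslessly; counts are written as
    plain integers (no thousands separators).
    """
    rows = [_record_to_dict(r) for r in records]
    if columns is None:
        if not rows:
            raise ValueError("cannot infer columns from an empty record list")
        columns = list(rows[0])
    with open(path, "w", newline="") as out:
        writer = csv.DictWriter(out, fieldnames=list(columns), delimiter="\t",
                                lineterminator="\n")
        writer.writeheader()
        writer.writerows(rows)


def read_table(path: str | Path) -> list[dict[str, str]]:
    with open(path, newline="") as handle:
        return list(csv.DictReader(handle, delimiter="\t"))


def write_vienna(records: Iterable[tuple[str, str, str, float]],
                 path: str | Path) -> None:
    """Write (id, residues, dotbracket, energy) records as Vienna-style
    text: header line, sequence line, structure line with the energy in
    parentheses."""
    with open(path, "w") as out:
        for rec_id, residues, dotbracket, energy in records:
            out.write(f">{rec_id}\n{residues}\n{dotbracket} ({energy:.2f})\n")
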