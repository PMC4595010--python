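"""Small-RNA read processing: adapter trimming, length filtering, read
collapsing, rRNA/tRNA contaminant removal, and transcriptome mapping.

Mapping is an exact/mismatch-bounded direct scan over transcripts — at
desk scale (a few hundred transcripts, collapsed read sets in the
thousands) no index is needed, and the naive scan doubles as its own
specification.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .io_formats import RNASequence

_COMPLEMENT = str.maketrans("acgu", "ugca")


def reverse_complement(residues: str) -> str:
    return residues.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SmallRNARead:
    """A (possibly collapsed) small-RNA read."""

    id: str
    residues: str
    count: int = 1
    quality: str | None = None
    label: str | None = None  # ground-truth tag from the simulator, if any

    def __post_init__(self):
        if self.count < 1:
            raise ValueError("count must be >= 1")
        if not self.residues:
            raise ValueError("empty read")


@dataclass(frozen=True)
class MappingHit:
    """A placement of a read on a transcript (1-based 5' start)."""

    read_id: str
    transcript_id: str
    start: int
    strand: str  # "sense" | "antisense"
    mismatches: int
    read_length: int

    @property
    def end(self) -> int:
        return self.start + self.read_length - 1


@dataclass
class TrimResult:
    kept: list[SmallRNARead] = field(default_factory=list)
    rejected: list[SmallRNARead] = field(default_factory=list)


def trim_adapter_read(read: SmallRNARead, adapter: str, min_overlap: int = 6,
                      max_mismatch_rate: float = 0.1) -> SmallRNARead | None:
    """Trim the 3' adapter from one read; None if untrimmed or empty insert.

    Finds the longest removable tail: the earliest position at which a
    prefix of the adapter matches the read with overlap >= min_overlap and
    a per-overlap mismatch rate <= max_mismatch_rate.  Bases downstream of
    a fully matched adapter (sequencing past the ligation junction) are
    removed with it, so the rule reduces to the classic read-suffix /
    adapter-prefix overlap when the adapter runs off the 3' end.
    """
    adapter = adapter.strip().lower().replace("t", "u")
    if len(adapter) < min_overlap:
        raise ValueError("adapter shorter than min_overlap")
    seq = read.residues
    best_start = None
    for start in range(0, len(seq) - min_overlap + 1):
        olap = min(len(adapter), len(seq) - start)
        mism = sum(1 for a, b in zip(seq[start:start + olap], adapter) if a != b)
        if mism / olap <= max_mismatch_rate:
            best_start = start
            break
    if best_start is None or best_start == 0:
        return None
    return replace(read, residues=seq[:best_start],
                   quality=read.quality[:best_start] if read.quality else None)


def trim_adapters(reads: Iterable[SmallRNARead], adapter: str,
                  min_overlap: int = 6,
                  max_mismatch_rate: float = 0.1) -> TrimResult:
    result = TrimResult()
    for read in reads:
        trimmed = trim_adapter_read(read, adapter, min_overlap, max_mismatch_rate)
        (result.kept if trimmed is not None else result.rejected).append(
            trimmed if trimmed is not None else read)
    return result


def filter_by_length(reads: Iterable[SmallRNARead], min_len: int,
                     max_len: int) -> tuple[list[SmallRNARead], list[SmallRNARead]]:
    """Retain reads with min_len <= length <= max_len; returns (kept, removed)."""
    if min_len > max_len:
        raise ValueError("min_len > max_len")
    kept, removed = [], []
    for read in reads:
        (kept if min_len <= len(read.residues) <= max_len else removed).append(read)
    return kept, removed


def collapse_reads(reads: Iterable[SmallRNARead]) -> list[SmallRNARead]:
    """One record per distinct sequence; counts summed, smallest id kept.

    Output is ordered by descending count then sequence, so the collapsed
    set is deterministic regardless of input order.
    """
    groups: dict[str, list[SmallRNARead]] = defaultdict(list)
    for read in reads:
        groups[read.residues].append(read)
    collapsed = []
    for residues, members in groups.items():
        rep = min(m.id for m in members)
        label = next((m.label for m in members if m.label), None)
        collapsed.append(SmallRNARead(
            id=rep, residues=residues, count=sum(m.count for m in members),
            label=label))
    collapsed.sort(key=lambda r: (-r.count, r.residues))
    return collapsed


def _occurs_with_mismatches(needle: str, hay: str, max_mismatch: int) -> bool:
    if max_mismatch == 0:
        return needle in hay
    n, m = len(needle), len(hay)
    for start in range(m - n + 1):
        mism = 0
        for a, b in zip(needle, hay[start:start + n]):
            if a != b:
                mism += 1
                if mism > max_mismatch:
                    break
        if mism <= max_mismatch:
            return True
    return False


def filter_contaminants(reads: Iterable[SmallRNARead],
                        contaminants: Sequence[RNASequence],
                        max_mismatch: int = 0
                        ) -> tuple[list[SmallRNARead], list[SmallRNARead]]:
    """Remove reads occurring inside any contaminant (either strand).

    A read is removed iff it is a substring of a contaminant sequence or of
    its reverse complement with <= max_mismatch mismatches.
    """
    haystacks = [c.residues for c in contaminants]
    haystacks += [reverse_complement(h) for h in haystacks]
    kept, removed = [], []
    for read in reads:
        hit = any(_occurs_with_mismatches(read.residues, hay, max_mismatch)
                  for hay in haystacks)
        (removed if hit else kept).append(read)
    return kept, removed


def map_reads(reads: Iterable[SmallRNARead],
              transcriptome: Sequence[RNASequence],
              max_mismatch: int = 0) -> list[MappingHit]:
    """Report every sense and antisense placement of each read.

    Positions are 1-based on the sense strand of the transcript; an
    antisense hit at start s means the reverse complement of the read
    matches the transcript beginning at s.
    """
    hits: list[MappingHit] = []
    for transcript in transcriptome:
        hay = transcript.residues
        for read in reads:
            for strand, needle in (("sense", read.residues),
                                   ("antisense", reverse_complement(read.residues))):
                n = len(needle)
                if n > len(hay):
                    continue
                if max_mismatch == 0:
                    start = hay.find(needle)
                    while start != -1:
                        hits.append(MappingHit(read.id, transcript.id, start + 1,
                                               strand, 0, n))
                        start = hay.find(needle, start + 1)
                else:
                    for start in range(len(hay) - n + 1):
                        mism = 0
                        for a, b in zip(needle, hay[start:start + n]):
                            if a != b:
                                mism += 1
                                if mism > max_mismatch:
                                    break
                        if mism <= max_mismatch:
                            hits.append(MappingHit(read.id, transcript.id,
                                                   start + 1, strand, mism, n))
    hits.sort(key=lambda h: (h.transcript_id, h.start, h.read_id, h.strand))
    return hits
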