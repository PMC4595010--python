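"""Conservation calling, 5'-nucleotide bias, origin annotation, and
per-strand abundance quantification.

Conservation against a miRBase-style reference set is ungapped: the
shorter sequence slides along the longer with end offsets of up to 2 nt,
overhanging positions count as mismatches, and a query is conserved iff
its best reference is within the allowed mismatch count (2 by default, the
standard miRBase-comparison allowance).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from .hairpin import HairpinPrecursor
from .io_formats import RNASequence
from .reads import MappingHit, SmallRNARead
from .simulate import _min_mismatches


@dataclass
class ConservationCall:
    query: str
    best_reference: str | None
    mismatches: int | None
    status: str  # "conserved" | "novel"


@dataclass
class AbundanceRecord:
    name: str
    mature_reads: int
    star_reads: int

    @property
    def total(self) -> int:
        return self.mature_reads + self.star_reads


#: categories counted as transposable-element-derived in rollups
TRANSPOSABLE_SUPERSET = ("transposable_element", "tc3_transposable_element",
                        "retrotransposon")


@dataclass
class OriginCall:
    name: str
    category: str
    evidence: str

    @property
    def is_transposable(self) -> bool:
        return self.category in TRANSPOSABLE_SUPERSET


def classify_conservation(query: RNASequence,
                          references: Sequence[RNASequence],
                          max_mismatch: int = 2) -> ConservationCall:
    """Call a query conserved or novel against a mature reference set.

    The minimum mismatch count over all ungapped placements (end offsets
    <= 2 nt) is computed per reference; ties keep the first reference in
    input order.  An empty reference set yields a novel call with no best
    reference.
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    best_ref, best_mism = None, None
    for ref in references:
        mism = _min_mismatches(query.residues, ref.residues)
        if best_mism is None or mism < best_mism:
            best_ref, best_mism = ref.id, mism
    status = "conserved" if best_mism is not None and best_mism <= max_mismatch \
        else "novel"
    return ConservationCall(query.id, best_ref, best_mism, status)


def five_prime_summary(matures: Iterable[RNASequence]) -> dict[str, int]:
    """Tally of 5'-terminal nucleotides across {a,c,g,u}.

    The 5' nucleotide biases Argonaute loading (5' U favours AGO1, 5' A
    AGO2, 5' C AGO5), so the tally is the standard first summary of a
    novel miRNA set.
    """
    counts = Counter(m.residues[0] for m in matures)
    return {nt: counts.get(nt, 0) for nt in "acgu"}


def annotate_origin(name: str, transcript_description: str) -> OriginCall:
    """Keyword cascade over the host transcript description.

    Order is fixed (tc3 before retro before transposable) so the call is
    deterministic on descriptions that match several keywords.
    """
    text = transcript_description.strip()
    lowered = text.lower()
    if "tc3" in lowered:
        category = "tc3_transposable_element"
    elif "retro" in lowered:
        category = "retrotransposon"
    elif "transposable" in lowered:
        category = "transposable_element"
    elif not text or "uncharacterized" in lowered:
        category = "uncharacterized"
    else:
        category = "named_gene"
    return OriginCall(name, category, text)


def _within(hit_start: int, hit_end: int, span: tuple[int, int],
            tolerance: int) -> bool:
    lo, hi = span
    return hit_start >= lo - tolerance and hit_end <= hi + tolerance


def quantify(hits: Sequence[MappingHit], reads: Sequence[SmallRNARead],
             hairpins: Sequence[HairpinPrecursor], cutoff: int = 10,
             tolerance: int = 0) -> tuple[list[AbundanceRecord], int]:
    """Per-strand abundance from sense-strand mapping intervals.

    A read accrues to a miRNA's mature (resp. star) tally iff one of its
    sense hits lies within the mature (resp. star) arm interval on the
    host transcript, extended by `tolerance` nt at each end.  Each read is
    assigned at most once; mature wins overlap ties.  Records with total <
    cutoff are dropped.  Returns (records, unassigned_read_count).
    """
    counts = {r.id: r.count for r in reads}
    arm_index: dict[str, list[tuple[tuple[int, int], str, str]]] = {}
    for hp in hairpins:
        if hp.transcript_id is None or hp.transcript_span is None:
            continue
        t0 = hp.transcript_span[0]
        mspan = (t0 + hp.mature_span[0] - 1, t0 + hp.mature_span[1] - 1)
        arm_index.setdefault(hp.transcript_id, []).append((mspan, hp.name, "mature"))
        if hp.star_span is not None:
            sspan = (t0 + hp.star_span[0] - 1, t0 + hp.star_span[1] - 1)
            arm_index.setdefault(hp.transcript_id, []).append((sspan, hp.name, "star"))

    mature_tally: Counter[str] = Counter()
    star_tally: Counter[str] = Counter()
    hits_by_read: dict[str, list[MappingHit]] = {}
    for hit in hits:
        hits_by_read.setdefault(hit.read_id, []).append(hit)

    unassigned = 0
    for read_id, read_hits in hits_by_read.items():
        count = counts.get(read_id, 1)
        assignment = None
        for hit in read_hits:
            if hit.strand != "sense":
                continue
            for span, name, arm in arm_index.get(hit.transcript_id, []):
                if _within(hit.start, hit.end, span, tolerance):
                    cand = (0 if arm == "mature" else 1, name, arm)
                    if assignment is None or cand < assignment:
                        assignment = cand
        if assignment is None:
            unassigned += count
        elif assignment[2] == "mature":
            mature_tally[assignment[1]] += count
        else:
            star_tally[assignment[1]] += count

    records = []
    for hp in hairpins:
        rec = AbundanceRecord(hp.name, mature_tally.get(hp.name, 0),
                              star_tally.get(hp.name, 0))
        if rec.total >= cutoff:
            records.append(rec)
    records.sort(key=lambda r: r.name)
    return records, unassigned
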