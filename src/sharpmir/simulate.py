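"""Synthetic data generation: transcriptomes, reference miRNA sets,
rRNA/tRNA contaminant pools, and adapter-ligated FASTQ read pools.

The simulator emulates the statistical structure the analysis assumes: a
transcriptome in which each curated precursor is embedded at its annotated
start coordinate inside a host transcript, a miRBase-style reference set
with or without the novel matures, contaminant sequences free of any
mature 22-mer, and a read pool with exact per-arm counts, a ligated 3'
adapter, random background and contaminant-derived reads.  Every output is
byte-deterministic under a fixed seed.  Ground truth travels in the read
ids ("name|arm|serial"), so quantification recovery needs no side files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import SharpmirError, StarInferenceError
from .hairpin import HairpinPrecursor, SecondaryStructure, infer_star
from .io_formats import FixtureBundle, RNASequence
from .reads import SmallRNARead

#: Illumina TruSeq small-RNA 3' adapter (DNA, as ligated); the library kit
#: is named by the protocol, the sequence is the kit's published adapter.
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

DEFAULT_READ_LENGTH = 36

_ALPHABET = np.array(list("acgu"))


@dataclass
class SimulationSpec:
    """Parameters of one synthetic dataset."""

    seed: int = 0
    n_decoy_transcripts: int = 20
    decoy_length_range: tuple[int, int] = (300, 800)
    abundance_plan: dict[str, tuple[int, int]] = field(default_factory=dict)
    adapter: str = DEFAULT_ADAPTER
    background_reads: int = 1000
    contaminant_reads: int = 500
    read_length: int = DEFAULT_READ_LENGTH

    def __post_init__(self):
        if self.background_reads < 0 or self.contaminant_reads < 0:
            raise ValueError("read counts must be >= 0")
        for name, (mat, star) in self.abundance_plan.items():
            if mat < 0 or star < 0:
                raise ValueError(f"negative plan counts for {name}")


def _random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(_ALPHABET[rng.integers(0, 4, size=length)])


def build_transcriptome(fixtures: FixtureBundle,
                        spec: SimulationSpec) -> list[RNASequence]:
    """One host transcript per precursor plus precursor-free random decoys.

    Each precursor is embedded starting at its annotated start coordinate
    (1-based) with seeded random padding on both sides; the transcript
    description carries the origin text.  Decoys are redrawn until they
    contain none of the precursors.
    """
    rng = np.random.default_rng(spec.seed)
    transcripts: list[RNASequence] = []
    precursor_seqs = [p.residues for p in fixtures.precursors]
    for pre in fixtures.precursors:
        origin = fixtures.origins[pre.id]
        left = origin.start - 1
        right = max(0, origin.end - origin.start + 1 - len(pre.residues)) + 60
        residues = _random_rna(rng, left) + pre.residues + _random_rna(rng, right)
        transcripts.append(RNASequence(
            id=f"host_{pre.id}", residues=residues, description=origin.description))
    for k in range(spec.n_decoy_transcripts):
        lo, hi = spec.decoy_length_range
        while True:
            length = int(rng.integers(lo, hi + 1))
            residues = _random_rna(rng, length)
            if not any(p in residues for p in precursor_seqs):
                break
        transcripts.append(RNASequence(id=f"decoy_{k:04d}", residues=residues,
                                       description="random decoy"))
    return transcripts


def _min_mismatches(a: str, b: str, max_shift: int = 2) -> int:
    """Minimum mismatch count over ungapped placements with small end offsets;
    overhanging positions count as mismatches."""
    if len(a) > len(b):
        a, b = b, a
    best = len(a)
    for shift in range(-max_shift, len(b) - len(a) + max_shift + 1):
        mism = 0
        for i, ch in enumerate(a):
            j = i + shift
            if j < 0 or j >= len(b):
                mism += 1
            elif ch != b[j]:
                mism += 1
        best = min(best, mism)
    return best


def make_reference_set(fixtures: FixtureBundle, include_novel: bool,
                       n_conserved: int = 50, seed: int = 0) -> list[RNASequence]:
    """A miRBase-like mature reference FASTA.

    n_conserved random 21-23-nt entries, each at least 3 mismatches away
    from every curated novel mature (verified, redrawn otherwise), plus the
    14 novel matures themselves iff include_novel.
    """
    if n_conserved < 0:
        raise ValueError("n_conserved must be >= 0")
    rng = np.random.default_rng(seed)
    refs: list[RNASequence] = []
    matures = [m.residues for m in fixtures.matures]
    for k in range(n_conserved):
        while True:
            length = int(rng.integers(21, 24))
            candidate = _random_rna(rng, length)
            if all(_min_mismatches(candidate, m) >= 3 for m in matures):
                break
        refs.append(RNASequence(id=f"ref-miR-{k:04d}", residues=candidate,
                                description="synthetic conserved mature"))
    if include_novel:
        refs.extend(fixtures.matures)
    return refs


def make_contaminant_set(seed: int = 0, n: int = 30) -> list[RNASequence]:
    """n random 60-120-nt rRNA/tRNA-like sequences, free of curated matures."""
    from .io_formats import load_fixtures

    if n < 0:
        raise ValueError("n must be >= 0")
    matures = [m.residues for m in load_fixtures().matures]
    rng = np.random.default_rng(seed)
    out = []
    for k in range(n):
        while True:
            length = int(rng.integers(60, 121))
            residues = _random_rna(rng, length)
            if not any(m in residues for m in matures):
                break
        kind = "rRNA" if k % 2 == 0 else "tRNA"
        out.append(RNASequence(id=f"contam_{kind}_{k:04d}", residues=residues,
                               description=f"synthetic {kind} fragment"))
    return out


def fixture_hairpins(fixtures: FixtureBundle) -> list[HairpinPrecursor]:
    """HairpinPrecursors built from the curated precursor sequences and
    their published dot-bracket structures, with star spans inferred."""
    from .energy import evaluate_energy

    hairpins = []
    for mat in fixtures.matures:
        pre = fixtures.precursor(mat.id)
        db = fixtures.structures[mat.id]
        structure = SecondaryStructure.from_dotbracket(
            db, evaluate_energy(pre.residues, db))
        pos = pre.residues.find(mat.residues)
        hp = HairpinPrecursor(
            name=mat.id, residues=pre.residues, structure=structure,
            mature_span=(pos + 1, pos + len(mat.residues)),
            transcript_id=f"host_{mat.id}",
            transcript_span=(fixtures.origins[mat.id].start,
                             fixtures.origins[mat.id].start + len(pre.residues) - 1),
        )
        star, span = infer_star(hp)
        hp.star_span = span
        hairpins.append(hp)
    return hairpins


def _as_read(name: str, arm: str, serial: int, insert: str, adapter_rna: str,
             read_length: int) -> SmallRNARead:
    full = (insert + adapter_rna)[:read_length]
    if len(full) < read_length:
        full = full + "a" * (read_length - len(full))
    return SmallRNARead(id=f"{name}|{arm}|{serial:06d}", residues=full,
                        count=1, quality="I" * len(full), label=f"{name}|{arm}")


def simulate_reads(fixtures: FixtureBundle,
                   hairpins: list[HairpinPrecursor],
                   spec: SimulationSpec,
                   contaminants: list[RNASequence] | None = None
                   ) -> list[SmallRNARead]:
    """Emit the adapter-ligated read pool for an abundance plan.

    Per miRNA: exactly mature_count reads whose insert is the mature
    sequence and star_count reads whose insert is the inferred star
    sequence, plus background random reads and contaminant-derived reads.
    Order is shuffled deterministically by the spec seed.
    """
    rng = np.random.default_rng(spec.seed + 1)
    adapter_rna = spec.adapter.strip().lower().replace("t", "u")
    by_name = {h.name: h for h in hairpins}
    reads: list[SmallRNARead] = []
    for name, (mat_count, star_count) in spec.abundance_plan.items():
        hp = by_name.get(name)
        if hp is None:
            raise SharpmirError(f"abundance plan names unknown miRNA {name!r}")
        mature_seq = hp.mature_sequence
        for serial in range(mat_count):
            reads.append(_as_read(name, "mature", serial, mature_seq,
                                  adapter_rna, spec.read_length))
        if star_count:
            star_seq = hp.star_sequence
            if star_seq is None:
                raise StarInferenceError(
                    f"star reads requested for {name} but no star span is set")
            for serial in range(star_count):
                reads.append(_as_read(name, "star", serial, star_seq,
                                      adapter_rna, spec.read_length))
    for serial in range(spec.background_reads):
        insert = _random_rna(rng, int(rng.integers(18, 29)))
        reads.append(_as_read("background", "none", serial, insert,
                              adapter_rna, spec.read_length))
    if spec.contaminant_reads:
        if not contaminants:
            raise SharpmirError("contaminant reads requested without a contaminant set")
        for serial in range(spec.contaminant_reads):
            src = contaminants[int(rng.integers(0, len(contaminants)))]
            ins_len = int(rng.integers(20, 25))
            start = int(rng.integers(0, len(src.residues) - ins_len + 1))
            insert = src.residues[start:start + ins_len]
            reads.append(_as_read("contaminant", "none", serial, insert,
                                  adapter_rna, spec.read_length))
    order = rng.permutation(len(reads))
    return [reads[i] for i in order]
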