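"""End-to-end orchestration of the discovery pipeline.

Stage order follows the small-RNA analysis convention: adapter removal →
length filter → redundancy collapse → rRNA/tRNA filter → transcriptome
mapping → reference (miRBase-style) comparison → precursor location and
hairpin screening → annotation and per-strand quantification → optional
target scan.  Every stage reads and writes plain files under the output
directory, and the run report carries in/out counts per stage, so each
intermediate is inspectable and the whole run is byte-deterministic under
a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .annotate import (AbundanceRecord, annotate_origin, classify_conservation,
                       five_prime_summary, quantify)
from .config import PipelineConfig, validate_config
from .energy import EnergyModel
from .errors import ConfigError, StarInferenceError
from .hairpin import (HairpinPrecursor, evaluate_hairpin, fold_mfe, infer_star,
                      locate_precursor)
from .io_formats import (RNASequence, load_fixtures, read_fasta, read_fastq,
                         write_fasta, write_fastq, write_table, write_vienna)
from .reads import (SmallRNARead, collapse_reads, filter_by_length,
                    filter_contaminants, map_reads, trim_adapters)
from .simulate import (SimulationSpec, build_transcriptome, fixture_hairpins,
                       make_contaminant_set, make_reference_set, simulate_reads)
from .targets import predict_targets


@dataclass
class DiscoveredMiRNA:
    """A novel miRNA discovered from the read data."""

    name: str
    guide: str                       # most abundant arm sequence
    guide_count: int
    hairpin: HairpinPrecursor
    passenger: str | None = None     # second arm sequence observed in reads
    passenger_count: int = 0
    conservation_status: str = "novel"


@dataclass
class RunReport:
    seed: int
    stage_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    config: dict | None = None

    def record(self, stage: str, **counts: int) -> None:
        self.stage_counts[stage] = dict(counts)


def process_reads(raw: list[SmallRNARead], config: PipelineConfig,
                  contaminants: list[RNASequence],
                  report: RunReport) -> list[SmallRNARead]:
    """Trim, length-filter, collapse, and decontaminate a raw read pool."""
    trimmed = trim_adapters(raw, config.adapter, config.trim_min_overlap,
                            config.trim_max_mismatch_rate)
    report.record("trim", reads_in=sum(r.count for r in raw),
                  kept=sum(r.count for r in trimmed.kept),
                  rejected=sum(r.count for r in trimmed.rejected))
    sized, undersized = filter_by_length(trimmed.kept, config.min_len,
                                         config.max_len)
    report.record("length_filter", reads_in=sum(r.count for r in trimmed.kept),
                  kept=sum(r.count for r in sized),
                  removed=sum(r.count for r in undersized))
    collapsed = collapse_reads(sized)
    report.record("collapse", reads_in=sum(r.count for r in sized),
                  distinct=len(collapsed),
                  total=sum(r.count for r in collapsed))
    clean, contaminated = filter_contaminants(collapsed, contaminants,
                                              config.contaminant_max_mismatch)
    report.record("contaminant_filter",
                  reads_in=sum(r.count for r in collapsed),
                  kept=sum(r.count for r in clean),
                  removed=sum(r.count for r in contaminated))
    return clean


def discover_mirnas(clean: list[SmallRNARead], hits, transcriptome,
                    references: list[RNASequence], config: PipelineConfig,
                    report: RunReport) -> list[DiscoveredMiRNA]:
    """Locate precursors for abundant novel reads and screen the hairpins.

    Candidates are processed in descending abundance; the first read to
    seed an accepted hairpin at a locus becomes its guide, and any later
    candidate whose mapping interval falls inside that hairpin's window is
    recorded as the passenger strand rather than a separate discovery.
    """
    transcripts = {t.id: t for t in transcriptome}
    sense_hits: dict[str, list] = {}
    for hit in hits:
        if hit.strand == "sense":
            sense_hits.setdefault(hit.read_id, []).append(hit)
    candidates = [r for r in clean
                  if r.count >= config.abundance_cutoff and r.id in sense_hits]
    candidates.sort(key=lambda r: (-r.count, r.residues))

    model = EnergyModel()
    discovered: list[DiscoveredMiRNA] = []
    n_conserved = 0
    for read in candidates:
        call = classify_conservation(
            RNASequence(read.id, read.residues), references,
            config.conservation_max_mismatch)
        if call.status == "conserved":
            n_conserved += 1
            continue
        # passenger of an already-discovered hairpin?
        placed = False
        for hit in sense_hits[read.id]:
            for disc in discovered:
                hp = disc.hairpin
                if hp.transcript_id != hit.transcript_id or hp.transcript_span is None:
                    continue
                lo, hi = hp.transcript_span
                if hit.start >= lo and hit.end <= hi:
                    if disc.passenger is None:
                        disc.passenger = read.residues
                        disc.passenger_count = read.count
                    placed = True
                    break
            if placed:
                break
        if placed:
            continue
        # try to locate and screen a precursor at each mapped locus
        best: HairpinPrecursor | None = None
        for hit in sense_hits[read.id]:
            transcript = transcripts[hit.transcript_id]
            windows = locate_precursor(RNASequence(read.id, read.residues),
                                       transcript, config.flank)
            for window in windows:
                structure = fold_mfe(window.residues, model)
                verdict = evaluate_hairpin(window.residues, structure,
                                           window.mature_span, config.hairpin)
                if not verdict.passed:
                    continue
                hp = HairpinPrecursor(
                    name=read.id, residues=window.residues, structure=structure,
                    mature_span=window.mature_span,
                    transcript_id=transcript.id,
                    transcript_span=window.window_span)
                try:
                    _, span = infer_star(hp)
                    hp.star_span = span
                except StarInferenceError:
                    continue
                if best is None or structure.energy < best.structure.energy:
                    best = hp
        if best is not None:
            discovered.append(DiscoveredMiRNA(
                name=read.id, guide=read.residues, guide_count=read.count,
                hairpin=best))
    report.record("discover", candidates=len(candidates),
                  conserved=n_conserved, novel_discovered=len(discovered))
    return discovered


def run_pipeline(config: PipelineConfig,
                 simulation: SimulationSpec | None = None) -> RunReport:
    """Execute every stage under one config; artifacts land in output_dir.

    When `simulation` is given, the simulate stage writes the synthetic
    transcriptome, reference set, contaminants, and read pool first and
    the downstream stages consume those files; otherwise all input paths
    must exist.
    """
    errors = validate_config(config, check_paths=simulation is None)
    if errors:
        raise ConfigError("; ".join(errors))
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(seed=config.seed)

    if simulation is not None:
        fixtures = load_fixtures()
        transcriptome = build_transcriptome(fixtures, simulation)
        contaminants = make_contaminant_set(seed=simulation.seed)
        references = make_reference_set(fixtures, include_novel=False,
                                        seed=simulation.seed)
        hairpins = fixture_hairpins(fixtures)
        raw = simulate_reads(fixtures, hairpins, simulation, contaminants)
        write_fasta(transcriptome, outdir / "transcriptome.fasta")
        write_fasta(contaminants, outdir / "contaminants.fasta")
        write_fasta(references, outdir / "references.fasta")
        write_fastq(raw, outdir / "reads.fastq")
        report.record("simulate", reads=len(raw),
                      transcripts=len(transcriptome))
        config.reads_path = str(outdir / "reads.fastq")
        config.transcriptome_path = str(outdir / "transcriptome.fasta")
        config.reference_path = str(outdir / "references.fasta")
        config.contaminants_path = str(outdir / "contaminants.fasta")

    for name in ("reads_path", "transcriptome_path", "reference_path",
                 "contaminants_path"):
        if getattr(config, name) is None:
            raise ConfigError(f"{name} is required")

    raw = read_fastq(config.reads_path)
    transcriptome = read_fasta(config.transcriptome_path)
    references = read_fasta(config.reference_path)
    contaminants = read_fasta(config.contaminants_path)

    clean = process_reads(raw, config, contaminants, report)
    write_fasta([RNASequence(f"{r.id}_x{r.count}", r.residues) for r in clean],
                outdir / "collapsed.fasta")

    hits = map_reads(clean, transcriptome, config.mapping_max_mismatch)
    mapped_ids = {h.read_id for h in hits if h.strand == "sense"}
    report.record("map", distinct_in=len(clean), distinct_mapped=len(mapped_ids),
                  hits=len(hits))
    write_table([{"read": h.read_id, "transcript": h.transcript_id,
                  "start": h.start, "strand": h.strand,
                  "mismatches": h.mismatches} for h in hits],
                outdir / "hits.tsv",
                columns=["read", "transcript", "start", "strand", "mismatches"])

    discovered = discover_mirnas(clean, hits, transcriptome, references,
                                 config, report)

    descriptions = {t.id: t.description for t in transcriptome}
    origin_calls = [annotate_origin(d.name,
                                    descriptions.get(d.hairpin.transcript_id, ""))
                    for d in discovered]
    bias = five_prime_summary(
        [RNASequence(d.name, d.guide) for d in discovered])
    report.record("annotate",
                  transposable=sum(c.is_transposable for c in origin_calls),
                  **{f"five_prime_{nt}": n for nt, n in bias.items()})

    records, unassigned = quantify(hits, clean, [d.hairpin for d in discovered],
                                   config.abundance_cutoff, config.arm_tolerance)
    report.record("quantify", records=len(records),
                  assigned=sum(r.total for r in records), unassigned=unassigned)
    write_table([{"name": r.name, "total": r.total, "mature_reads": r.mature_reads,
                  "star_reads": r.star_reads} for r in records],
                outdir / "abundance.tsv",
                columns=["name", "total", "mature_reads", "star_reads"])
    write_table([{"name": d.name, "transcript": d.hairpin.transcript_id,
                  "window_start": d.hairpin.transcript_span[0],
                  "window_end": d.hairpin.transcript_span[1],
                  "pairs": d.hairpin.structure.n_pairs,
                  "energy": d.hairpin.structure.energy,
                  "guide": d.guide, "passenger": d.passenger or ""}
                 for d in discovered], outdir / "discovered.tsv",
                columns=["name", "transcript", "window_start", "window_end",
                         "pairs", "energy", "guide", "passenger"])

    write_vienna([(d.name, d.hairpin.residues, d.hairpin.structure.dotbracket,
                   d.hairpin.structure.energy) for d in discovered],
                 outdir / "discovered_structures.txt")

    if config.run_targets:
        sites = []
        for disc in discovered:
            sites.extend(predict_targets(
                RNASequence(disc.name, disc.guide), transcriptome,
                config.scoring))
        report.record("targets", accepted_sites=len(sites))
        write_table([{"miRNA": s.alignment.mirna_id,
                      "transcript": s.alignment.transcript_id,
                      "start": s.alignment.target_span[0],
                      "end": s.alignment.target_span[1],
                      "score": s.alignment.score, "energy": s.energy,
                      "accepted": s.accepted} for s in sites],
                    outdir / "target_sites.tsv",
                    columns=["miRNA", "transcript", "start", "end", "score",
                             "energy", "accepted"])

    report.config = {"preset": config.preset, "cutoff": config.abundance_cutoff,
                     "length_window": [config.min_len, config.max_len],
                     "arm_tolerance": config.arm_tolerance}
    with open(outdir / "run_report.json", "w") as out:
        json.dump({"seed": report.seed, "stages": report.stage_counts,
                   "config": report.config}, out, indent=2, sort_keys=True)
    return report


def recover_abundances(seed: int = 0,
                       plan: dict[str, tuple[int, int]] | None = None,
                       cutoff: int = 10,
                       background_reads: int = 1000,
                       contaminant_reads: int = 500
                       ) -> tuple[list[AbundanceRecord], RunReport]:
    """Simulate a read pool at a given per-arm plan and quantify it back.

    The default plan is the curated per-strand abundance table.  Arms are
    taken from the curated precursors/structures (exact-arm mode, zero
    assignment tolerance); the length window (12, 30) spans the full range
    of inferred star lengths so that no planned read is lost to the
    filter.  Returns the abundance records and the stage report.
    """
    fixtures = load_fixtures()
    if plan is None:
        plan = {name: (mat, star)
                for name, (_, mat, star) in fixtures.abundances.items()}
    sim = SimulationSpec(seed=seed, abundance_plan=plan,
                         background_reads=background_reads,
                         contaminant_reads=contaminant_reads)
    hairpins = fixture_hairpins(fixtures)
    contaminants = make_contaminant_set(seed=seed)
    raw = simulate_reads(fixtures, hairpins, sim, contaminants)
    transcriptome = build_transcriptome(fixtures, sim)

    config = PipelineConfig(min_len=12, max_len=30, arm_tolerance=0,
                            abundance_cutoff=cutoff, seed=seed)
    report = RunReport(seed=seed)
    clean = process_reads(raw, config, contaminants, report)
    hits = map_reads(clean, transcriptome, config.mapping_max_mismatch)
    records, unassigned = quantify(hits, clean, hairpins, cutoff,
                                   config.arm_tolerance)
    report.record("quantify", records=len(records),
                  assigned=sum(r.total for r in records), unassigned=unassigned)
    return records, report
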