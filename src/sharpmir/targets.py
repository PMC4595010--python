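"""miRanda-style miRNA:mRNA target scanning.

The scanner slides a window over each transcript, aligns the miRNA
(5'→3') against the reverse-complemented reading of the window with an
affine-gap duplex alignment, and screens candidate sites with the three
published rules — a perfect seed (miRNA positions 2–7, at most one G:U
wobble there), at most one gap in the duplex — plus the score (>= 145)
and hybridisation-energy (<= -10 kcal/mol) thresholds.  Per-position
weights are the canonical target-scanner defaults (match +5, G:U +1,
mismatch -3, gap -9/-4, 4x seed scaling over positions 1-8); the
thresholds are only meaningful relative to these weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .energy import EnergyModel
from .io_formats import RNASequence

_WC = {("a", "u"), ("u", "a"), ("g", "c"), ("c", "g")}
_GU = {("g", "u"), ("u", "g")}

NEG_INF = float("-inf")


@dataclass
class ScoringScheme:
    match: float = 5.0
    gu_wobble: float = 1.0
    mismatch: float = -3.0
    gap_open: float = -9.0
    gap_extend: float = -4.0
    seed_scale: float = 4.0
    scale_span: tuple[int, int] = (1, 8)   # miRNA positions receiving seed_scale
    min_score: float = 145.0
    max_energy: float = -10.0
    seed_span: tuple[int, int] = (2, 7)    # filtered seed region
    max_seed_gu: int = 1
    max_duplex_gaps: int = 1

    def __post_init__(self):
        if self.min_score <= 0:
            raise ValueError("min_score must be positive")


@dataclass
class AlignedColumn:
    kind: str                 # watson_crick | gu | mismatch | gap_miRNA | gap_target
    mirna_pos: int            # 1-based miRNA position associated with the column
    mirna_base: str | None
    target_base: str | None
    target_pos: int | None    # 1-based position on the transcript, sense strand


@dataclass
class DuplexAlignment:
    mirna_id: str
    transcript_id: str
    target_span: tuple[int, int]
    columns: list[AlignedColumn]
    score: float

    @property
    def n_gaps(self) -> int:
        return sum(c.kind in ("gap_miRNA", "gap_target") for c in self.columns)


@dataclass
class TargetSite:
    alignment: DuplexAlignment
    energy: float
    passes_seed: bool
    passes_score: bool
    passes_energy: bool
    seed_reasons: list[str] = field(default_factory=list)

    @property
    def accepted(self) -> bool:
        return self.passes_seed and self.passes_score and self.passes_energy


def _column_kind(m: str, t: str) -> str:
    if (m, t) in _WC:
        return "watson_crick"
    if (m, t) in _GU:
        return "gu"
    return "mismatch"


def _pair_score(kind: str, scheme: ScoringScheme) -> float:
    if kind == "watson_crick":
        return scheme.match
    if kind == "gu":
        return scheme.gu_wobble
    return scheme.mismatch


def align_duplex(mirna: RNASequence, window: str, scheme: ScoringScheme,
                 transcript_id: str = "", window_start: int = 1) -> DuplexAlignment:
    """Best duplex alignment of the miRNA against one target window.

    Global in the miRNA (every position consumed once, in order), local in
    the target (free leading/trailing target bases).  Column scores at
    miRNA positions inside scale_span are multiplied by seed_scale (gap
    penalties included, keyed to the column's associated miRNA position).
    Ties break towards the smallest target start, then fewest gaps.
    """
    mseq = mirna.residues
    rwin = window[::-1]  # miRNA 5'→3' pairs the window 3'→5'
    M, N = len(mseq), len(rwin)
    if N < M:
        raise ValueError("window shorter than miRNA")
    lo, hi = scheme.scale_span

    def scale(pos: int) -> float:
        return scheme.seed_scale if lo <= pos <= hi else 1.0

    # DP over states: P pair/mismatch column, Qm miRNA-vs-gap, Qt target-vs-gap
    P = [[NEG_INF] * (N + 1) for _ in range(M + 1)]
    Qm = [[NEG_INF] * (N + 1) for _ in range(M + 1)]
    Qt = [[NEG_INF] * (N + 1) for _ in range(M + 1)]
    start0 = [[0] * (N + 1) for _ in range(3)]  # unused placeholder

    for i in range(1, M + 1):
        for j in range(0, N + 1):
            # Qm: miRNA i aligned to a gap
            if j >= 0:
                cands = []
                if i == 1:
                    cands.append(scheme.gap_open * scale(1))
                if P[i - 1][j] > NEG_INF:
                    cands.append(P[i - 1][j] + scheme.gap_open * scale(i))
                if Qt[i - 1][j] > NEG_INF:
                    cands.append(Qt[i - 1][j] + scheme.gap_open * scale(i))
                if Qm[i - 1][j] > NEG_INF:
                    cands.append(Qm[i - 1][j] + scheme.gap_extend * scale(i))
                if cands:
                    Qm[i][j] = max(cands)
            if j == 0:
                continue
            # P: miRNA i paired with reversed-window j
            kind = _column_kind(mseq[i - 1], rwin[j - 1])
            col = _pair_score(kind, scheme) * scale(i)
            if i == 1:
                P[i][j] = col  # leading target bases are free
            else:
                best_prev = max(P[i - 1][j - 1], Qm[i - 1][j - 1], Qt[i - 1][j - 1])
                if best_prev > NEG_INF:
                    P[i][j] = best_prev + col
            # Qt: target j aligned to a gap (associated with miRNA pos i)
            cands = []
            if P[i][j - 1] > NEG_INF:
                cands.append(P[i][j - 1] + scheme.gap_open * scale(i))
            if Qm[i][j - 1] > NEG_INF:
                cands.append(Qm[i][j - 1] + scheme.gap_open * scale(i))
            if Qt[i][j - 1] > NEG_INF:
                cands.append(Qt[i][j - 1] + scheme.gap_extend * scale(i))
            if cands:
                Qt[i][j] = max(cands)

    # trailing target bases are free: take the best end state at i = M
    best = (NEG_INF, 0, "")
    for j in range(0, N + 1):
        for state, mat in (("P", P), ("Qm", Qm)):
            if mat[M][j] > best[0]:
                best = (mat[M][j], j, state)
    score, j, state = best
    if score == NEG_INF:
        raise ValueError("no valid alignment")

    # traceback
    EPS = 1e-9
    columns: list[AlignedColumn] = []
    i = M
    while i > 0:
        if state == "P":
            kind = _column_kind(mseq[i - 1], rwin[j - 1])
            col = _pair_score(kind, scheme) * scale(i)
            target_pos = window_start + (N - j)  # original sense coordinates
            columns.append(AlignedColumn(kind, i, mseq[i - 1], rwin[j - 1], target_pos))
            if i == 1:
                break
            prev = P[i][j] - col
            for st, mat in (("P", P), ("Qm", Qm), ("Qt", Qt)):
                if abs(mat[i - 1][j - 1] - prev) < EPS:
                    state, i, j = st, i - 1, j - 1
                    break
            else:
                raise AssertionError("duplex traceback failed (P)")
        elif state == "Qm":
            columns.append(AlignedColumn("gap_target", i, mseq[i - 1], None, None))
            if i == 1:
                break
            v = Qm[i][j]
            if abs((P[i - 1][j] + scheme.gap_open * scale(i)) - v) < EPS:
                state, i = "P", i - 1
            elif abs((Qt[i - 1][j] + scheme.gap_open * scale(i)) - v) < EPS:
                state, i = "Qt", i - 1
            elif abs((Qm[i - 1][j] + scheme.gap_extend * scale(i)) - v) < EPS:
                state, i = "Qm", i - 1
            else:
                raise AssertionError("duplex traceback failed (Qm)")
        else:  # Qt
            target_pos = window_start + (N - j)
            columns.append(AlignedColumn("gap_miRNA", i, None, rwin[j - 1], target_pos))
            v = Qt[i][j]
            if abs((P[i][j - 1] + scheme.gap_open * scale(i)) - v) < EPS:
                state, j = "P", j - 1
            elif abs((Qm[i][j - 1] + scheme.gap_open * scale(i)) - v) < EPS:
                state, j = "Qm", j - 1
            elif abs((Qt[i][j - 1] + scheme.gap_extend * scale(i)) - v) < EPS:
                state, j = "Qt", j - 1
            else:
                raise AssertionError("duplex traceback failed (Qt)")
    columns.reverse()
    tpos = [c.target_pos for c in columns if c.target_pos is not None]
    span = (min(tpos), max(tpos)) if tpos else (window_start, window_start)
    return DuplexAlignment(mirna.id, transcript_id, span, columns, score)


def rescore_columns(alignment: DuplexAlignment, scheme: ScoringScheme) -> float:
    """Independent column-wise rescoring of an emitted alignment."""
    lo, hi = scheme.scale_span
    total = 0.0
    prev_gap_kind = None
    for col in alignment.columns:
        s = scheme.seed_scale if lo <= col.mirna_pos <= hi else 1.0
        if col.kind in ("gap_miRNA", "gap_target"):
            pen = scheme.gap_extend if prev_gap_kind == col.kind else scheme.gap_open
            total += pen * s
            prev_gap_kind = col.kind
        else:
            total += _pair_score(col.kind, scheme) * s
            prev_gap_kind = None
    return total


def duplex_energy(alignment: DuplexAlignment,
                  model: EnergyModel | None = None) -> float:
    """Hybridisation energy: nearest-neighbor stacks over consecutive paired
    columns (G:U included) plus the duplex initiation penalty.  Gap and
    mismatch columns break stacking runs; no intramolecular terms."""
    model = model or EnergyModel()
    energy = model.duplex_init
    prev = None
    for col in alignment.columns:
        if col.kind in ("watson_crick", "gu"):
            pair = col.mirna_base + col.target_base
            if prev is not None:
                energy += model.stack(prev, pair)
            prev = pair
        else:
            prev = None
    return round(energy, 10)


def seed_filter(alignment: DuplexAlignment,
                scheme: ScoringScheme) -> tuple[bool, list[str]]:
    """Apply the three screening rules to an alignment.

    Pass iff the seed region (miRNA positions seed_span) has no mismatch
    and no gap columns and at most max_seed_gu G:U columns, and the whole
    duplex has at most max_duplex_gaps gap columns.
    """
    lo, hi = scheme.seed_span
    reasons = []
    seed_cols = [c for c in alignment.columns if lo <= c.mirna_pos <= hi]
    if any(c.kind == "mismatch" for c in seed_cols):
        reasons.append("seed_mismatch")
    if any(c.kind in ("gap_miRNA", "gap_target") for c in seed_cols):
        reasons.append("seed_gap")
    if sum(c.kind == "gu" for c in seed_cols) > scheme.max_seed_gu:
        reasons.append("seed_gu")
    if alignment.n_gaps > scheme.max_duplex_gaps:
        reasons.append("duplex_gaps")
    return (not reasons), reasons


def _evaluate_window(mirna: RNASequence, window: str, scheme: ScoringScheme,
                     transcript_id: str, window_start: int,
                     model: EnergyModel) -> TargetSite:
    alignment = align_duplex(mirna, window, scheme, transcript_id, window_start)
    energy = duplex_energy(alignment, model)
    ok_seed, reasons = seed_filter(alignment, scheme)
    return TargetSite(
        alignment=alignment, energy=energy,
        passes_seed=ok_seed,
        passes_score=alignment.score >= scheme.min_score,
        passes_energy=energy <= scheme.max_energy,
        seed_reasons=reasons,
    )


def predict_targets(mirna: RNASequence, transcriptome: Sequence[RNASequence],
                    scheme: ScoringScheme | None = None,
                    model: EnergyModel | None = None) -> list[TargetSite]:
    """Scan every transcript and return accepted target sites.

    Sliding window of width len(miRNA) + 8, step 1; overlapping accepted
    sites are merged keeping the single best-scoring one (ties: smallest
    start, fewest gaps).  Output order is deterministic: transcript id,
    then start.
    """
    scheme = scheme or ScoringScheme()
    model = model or EnergyModel()
    width = len(mirna.residues) + 8
    accepted: list[TargetSite] = []
    for transcript in transcriptome:
        seq = transcript.residues
        sites: list[TargetSite] = []
        if len(seq) < len(mirna.residues):
            continue
        w = min(width, len(seq))
        for start in range(0, len(seq) - w + 1):
            site = _evaluate_window(mirna, seq[start:start + w], scheme,
                                    transcript.id, start + 1, model)
            if site.accepted:
                sites.append(site)
        # merge overlapping sites, best score first
        sites.sort(key=lambda s: (-s.alignment.score, s.alignment.target_span[0],
                                  s.alignment.n_gaps))
        chosen: list[TargetSite] = []
        for site in sites:
            lo1, hi1 = site.alignment.target_span
            if all(hi1 < c.alignment.target_span[0] or lo1 > c.alignment.target_span[1]
                   for c in chosen):
                chosen.append(site)
        accepted.extend(chosen)
    accepted.sort(key=lambda s: (s.alignment.transcript_id,
                                 s.alignment.target_span[0]))
    return accepted
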