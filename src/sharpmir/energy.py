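"""Nearest-neighbor energy model shared by the folder and all evaluators.

The model is a simplified Turner-style nearest-neighbor scheme: Watson-Crick
and G:U wobble stack energies, loop-length penalties for hairpin, bulge and
internal loops (Jacobson-Stockmayer extrapolation beyond the tables), an
affine multiloop term, and a terminal-AU/GU helix-end penalty.  Dangling
ends and coaxial stacking are excluded.  One parameter file backs both the
minimum-free-energy folder and the structure evaluator, so DP results and
independent re-evaluation agree exactly by construction.
"""

from __future__ import annotations

import json
import math
from functools import lru_cache
from importlib import resources

from .errors import StructureError

CANONICAL_PAIRS = frozenset({"au", "ua", "gc", "cg", "gu", "ug"})
_WOBBLE_OR_AU = frozenset({"au", "ua", "gu", "ug"})

INF = float("inf")


@lru_cache(maxsize=None)
def load_params() -> dict:
    ref = resources.files("sharpmir.data").joinpath("nn_params.json")
    with ref.open() as handle:
        return json.load(handle)


class EnergyModel:
    """Loop-decomposition energies under the embedded parameter tables."""

    def __init__(self, params: dict | None = None):
        p = params or load_params()
        self.stacks = dict(p["stacks"])
        self.hairpin_table = {int(k): v for k, v in p["hairpin"].items()}
        self.bulge_table = {int(k): v for k, v in p["bulge"].items()}
        self.internal_table = {int(k): v for k, v in p["internal"].items()}
        self.asym = p["internal_asymmetry"]
        self.asym_max = p["internal_asymmetry_max"]
        self.ml_init = p["multiloop_init"]
        self.ml_branch = p["multiloop_branch"]
        self.ml_unpaired = p["multiloop_unpaired"]
        self.terminal_au = p["terminal_au"]
        self.duplex_init = p["duplex_init"]
        self.js = p["js_coef"]
        self.min_loop = p["min_loop"]
        self.max_interior = p["max_interior_loop"]

    # -- elementary terms ---------------------------------------------------
    def can_pair(self, a: str, b: str) -> bool:
        return a + b in CANONICAL_PAIRS

    def stack(self, p1: str, p2: str) -> float:
        return self.stacks[f"{p1}:{p2}"]

    def au_end(self, pair: str) -> float:
        return self.terminal_au if pair in _WOBBLE_OR_AU else 0.0

    def _extrapolate(self, table: dict[int, float], n: int) -> float:
        if n in table:
            return table[n]
        nmax = max(table)
        return table[nmax] + self.js * math.log(n / nmax)

    def hairpin(self, size: int) -> float:
        if size < self.min_loop:
            raise StructureError(f"hairpin loop of size {size} < {self.min_loop}")
        return self._extrapolate(self.hairpin_table, size)

    def bulge(self, size: int) -> float:
        return self._extrapolate(self.bulge_table, size)

    def internal(self, n1: int, n2: int) -> float:
        base = self._extrapolate(self.internal_table, n1 + n2)
        return base + min(self.asym * abs(n1 - n2), self.asym_max)

    def interior_energy(self, seq: str, i: int, j: int, k: int, l: int) -> float:
        """Energy of the interior loop (or stack) closed by 0-based pairs
        (i,j) outer and (k,l) inner."""
        p1 = seq[i] + seq[j]
        p2 = seq[k] + seq[l]
        n1, n2 = k - i - 1, j - l - 1
        if n1 == 0 and n2 == 0:
            return self.stack(p1, p2)
        if n1 + n2 == 1:
            # single-nucleotide bulge: helix stacking is preserved
            return self.bulge(1) + self.stack(p1, p2)
        if n1 == 0 or n2 == 0:
            return self.bulge(n1 + n2) + self.au_end(p1) + self.au_end(p2)
        return self.internal(n1, n2) + self.au_end(p1) + self.au_end(p2)

    def hairpin_energy(self, seq: str, i: int, j: int) -> float:
        return self.hairpin(j - i - 1) + self.au_end(seq[i] + seq[j])


def pair_table(dotbracket: str) -> list[int]:
    """0-based partner table; -1 for unpaired. Raises on imbalance."""
    pt = [-1] * len(dotbracket)
    stack: list[int] = []
    for pos, ch in enumerate(dotbracket):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise StructureError("unmatched ')'", position=pos + 1)
            i = stack.pop()
            pt[i], pt[pos] = pos, i
        elif ch != ".":
            raise StructureError(f"illegal character {ch!r}", position=pos + 1)
    if stack:
        raise StructureError("unmatched '('", position=stack[-1] + 1)
    return pt


def _children(pt: list[int], i: int, j: int) -> list[tuple[int, int]]:
    """Pairs directly enclosed by (i, j), exclusive."""
    out = []
    k = i + 1
    while k < j:
        if pt[k] > k:
            out.append((k, pt[k]))
            k = pt[k] + 1
        else:
            k += 1
    return out


def evaluate_energy(residues: str, dotbracket: str,
                    model: EnergyModel | None = None) -> float:
    """Free energy of `dotbracket` on `residues` by full loop decomposition.

    The open chain scores exactly 0.  Pairing two non-complementary bases
    raises StructureError.
    """
    model = model or EnergyModel()
    if len(residues) != len(dotbracket):
        raise StructureError(
            f"structure length {len(dotbracket)} != sequence length {len(residues)}")
    pt = pair_table(dotbracket)
    for i, j in enumerate(pt):
        if j > i and not model.can_pair(residues[i], residues[j]):
            raise StructureError(
                f"non-pairable bases {residues[i]}:{residues[j]}", position=i + 1)

    total = 0.0
    # exterior loop: terminal-AU penalty per top-level helix
    for i, j in _children(pt, -1, len(residues)):
        total += model.au_end(residues[i] + residues[j])
    stack_pairs = [(i, j) for i, j in enumerate(pt) if j > i]
    for i, j in stack_pairs:
        kids = _children(pt, i, j)
        if not kids:
            total += model.hairpin_energy(residues, i, j)
        elif len(kids) == 1:
            (k, l), = kids
            total += model.interior_energy(residues, i, j, k, l)
        else:
            unpaired = (j - i - 1) - sum(l - k + 1 for k, l in kids)
            total += (model.ml_init
                      + model.ml_branch * (len(kids) + 1)
                      + model.ml_unpaired * unpaired
                      + model.au_end(residues[i] + residues[j])
                      + sum(model.au_end(residues[k] + residues[l]) for k, l in kids))
    return round(total, 10)
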