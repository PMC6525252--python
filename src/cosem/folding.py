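"""5' mRNA secondary-structure features.

The expression score uses the minimum free energy and the hairpin count of
the predicted structure of the first 30 codons (90 nt).  The folding engine
is pluggable: when the ViennaRNA python bindings are importable they are the
default engine; otherwise a deterministic built-in engine based on weighted
base-pair maximization with a stacking bonus is used.  Both return a
dot-bracket structure plus an energy in kcal/mol.

Hairpin convention: a hairpin is an innermost base pair whose closing stem
(contiguous stacked pairs) is at least ``min_stem`` = 3 bp long.  The energy
model of the built-in engine is a documented heuristic, not a
nearest-neighbour parameter set; it exists so that structure-derived
features are always computable and deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol

__all__ = [
    "FoldingEngine",
    "ViennaEngine",
    "StackingNussinovEngine",
    "FoldingError",
    "default_engine",
    "count_hairpins",
    "pair_map",
]

MIN_LOOP = 3  # minimum unpaired nucleotides in a hairpin loop

# built-in engine constants (documented heuristic):
#   DP pairing weights favour GC over AU over GU wobble pairs,
#   energies are assigned per pair with a bonus per stacked pair.
PAIR_WEIGHT = {("G", "C"): 3, ("C", "G"): 3, ("A", "T"): 2, ("T", "A"): 2,
               ("G", "T"): 1, ("T", "G"): 1}
PAIR_ENERGY = {3: -2.0, 2: -1.0, 1: -0.5}  # kcal/mol by pairing weight
STACK_BONUS = -0.5  # kcal/mol per stacked adjacent pair


class FoldingError(RuntimeError):
    """A folding engine failed; the message names the engine."""


class FoldingEngine(Protocol):
    name: str

    def fold(self, seq: str) -> tuple[str, float]:
        """Return (dot-bracket structure, energy in kcal/mol) for a DNA/RNA
        sequence (T and U both accepted)."""
        ...


@dataclass
class ViennaEngine:
    """Thermodynamic MFE folding via the ViennaRNA python bindings."""

    name: str = "viennarna"

    def fold(self, seq: str) -> tuple[str, float]:
        try:
            import RNA  # pylint: disable=import-error
        except ImportError as exc:  # pragma: no cover - depends on env
            raise FoldingError("engine viennarna: python bindings not importable") from exc
        rna = seq.upper().replace("T", "U")
        try:
            structure, energy = RNA.fold(rna)
        except Exception as exc:  # pragma: no cover
            raise FoldingError(f"engine viennarna failed: {exc}") from exc
        return structure, float(energy)


class StackingNussinovEngine:
    """Deterministic fallback: weighted base-pair maximization with stacking.

    Dynamic programming maximizes the total pairing weight (GC=3, AU=2,
    GU=1, minimum loop 3 nt); the energy of the traceback structure is the
    sum of per-pair energies plus a stacking bonus for each pair whose
    enclosing pair is directly adjacent.
    """

    name = "stacking-nussinov"

    def fold(self, seq: str) -> tuple[str, float]:
        s = seq.upper().replace("U", "T")
        n = len(s)
        if n == 0:
            raise FoldingError("engine stacking-nussinov: empty sequence")
        w = [[0] * n for _ in range(n)]
        for span in range(MIN_LOOP + 1, n):
            for i in range(n - span):
                j = i + span
                best = w[i][j - 1]
                for k in range(i, j - MIN_LOOP):
                    pw = PAIR_WEIGHT.get((s[k], s[j]))
                    if pw:
                        left = w[i][k - 1] if k > i else 0
                        cand = left + w[k + 1][j - 1] + pw
                        if cand > best:
                            best = cand
                w[i][j] = best
        structure = ["."] * n
        stack = [(0, n - 1)]
        pairs: list[tuple[int, int]] = []
        while stack:
            i, j = stack.pop()
            if i >= j or w[i][j] == 0:
                continue
            if w[i][j] == w[i][j - 1]:
                stack.append((i, j - 1))
                continue
            for k in range(i, j - MIN_LOOP):
                pw = PAIR_WEIGHT.get((s[k], s[j]))
                if pw:
                    left = w[i][k - 1] if k > i else 0
                    if left + w[k + 1][j - 1] + pw == w[i][j]:
                        pairs.append((k, j))
                        structure[k] = "("
                        structure[j] = ")"
                        if k > i:
                            stack.append((i, k - 1))
                        stack.append((k + 1, j - 1))
                        break
        dot = "".join(structure)
        paired = dict(pairs)
        energy = 0.0
        for i, j in pairs:
            energy += PAIR_ENERGY[PAIR_WEIGHT[(s[i], s[j])]]
            if paired.get(i + 1) == j - 1:  # stacked inside (i, j)
                energy += STACK_BONUS
        return dot, energy


def default_engine() -> FoldingEngine:
    """ViennaRNA when importable, the built-in engine otherwise."""
    try:
        import RNA  # noqa: F401

        return ViennaEngine()
    except ImportError:
        return StackingNussinovEngine()


def pair_map(structure: str) -> dict[int, int]:
    """Map each '(' position to its ')' partner (both directions)."""
    stack: list[int] = []
    pm: dict[int, int] = {}
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket structure")
            j = stack.pop()
            pm[j] = i
            pm[i] = j
    if stack:
        raise ValueError("unbalanced dot-bracket structure")
    return pm


def count_hairpins(structure: str, min_stem: int = 3) -> int:
    """Count hairpin loops closed by a stem of >= ``min_stem`` stacked pairs.

    An innermost pair (i, j) (no pairs between i and j) closes a hairpin;
    the stem length is the number of contiguous stacked pairs
    (i-k, j+k) around it, including (i, j) itself.
    """
    pm = pair_map(structure)
    n = len(structure)
    count = 0
    for i in sorted(p for p in pm if p < pm[p]):
        j = pm[i]
        if any(k in pm for k in range(i + 1, j)):
            continue  # not innermost
        stem = 1
        a, b = i - 1, j + 1
        while a >= 0 and b < n and pm.get(a) == b:
            stem += 1
            a -= 1
            b += 1
        if stem >= min_stem:
            count += 1
    return count
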