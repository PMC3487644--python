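"""Strict consensus and ensemble fit indices.

The strict consensus of a set of trees over one leaf set contains exactly
the bipartitions shared by every tree.  The ensemble consistency index
CI = Σm/Σs and retention index RI = (Σg−Σs)/(Σg−Σm) summarize homoplasy
over the whole matrix (m, g are the per-character minimum and maximum
conceivable steps, s the realized steps on the tree).  Because the display
convention of parsimony programs varies, both the all-characters and the
informative-characters-only versions are always computed; which one is
intended for comparison against published values is the caller's choice.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable

from .fitch import max_steps, min_steps, tree_length
from .matrix import CharacterMatrix, CellKind
from .trees import PhyloTree, tree_from_bipartitions

__all__ = ["strict_consensus", "is_informative", "ensemble_indices",
           "IndexReport", "ConventionIndices", "round2"]


def strict_consensus(trees: Iterable[PhyloTree]) -> PhyloTree:
    """Tree containing exactly the bipartitions present in every input."""
    trees = list(trees)
    if not trees:
        raise ValueError("strict_consensus needs at least one tree")
    taxa = trees[0].taxa
    for t in trees[1:]:
        if t.taxa != taxa:
            raise ValueError("trees are over different leaf sets")
    common = frozenset.intersection(*(t.bipartitions() for t in trees))
    return tree_from_bipartitions(taxa, common)


def is_informative(matrix: CharacterMatrix, char_index: int) -> bool:
    """Parsimony-informativeness: at least two states each scored as the
    single state of at least two taxa (ambiguous cells count toward no
    state)."""
    tally: dict = {}
    for cell in matrix.column(char_index):
        if cell.kind is CellKind.OBSERVED:
            (s,) = cell.states
            tally[s] = tally.get(s, 0) + 1
    return sum(1 for c in tally.values() if c >= 2) >= 2


def round2(x: float) -> float:
    """Round half-up to 2 decimals (the convention used when comparing with
    values printed to two decimals)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConventionIndices:
    """Ensemble sums and ratios under one character-inclusion convention."""

    n_characters: int
    sum_steps: int
    sum_min: int
    sum_max: int
    CI: float | None
    RI: float | None

    @property
    def RC(self) -> float | None:
        if self.CI is None or self.RI is None:
            return None
        return self.CI * self.RI

    def to_dict(self) -> dict:
        return {
            "n_characters": self.n_characters,
            "sum_steps": self.sum_steps,
            "sum_min": self.sum_min,
            "sum_max": self.sum_max,
            "CI": self.CI,
            "RI": self.RI,
            "RC": self.RC,
        }


def _convention(steps, mins, maxs, keep) -> ConventionIndices:
    s = sum(steps[j] for j in keep)
    m = sum(mins[j] for j in keep)
    g = sum(maxs[j] for j in keep)
    ci = (m / s) if s > 0 else None
    ri = ((g - s) / (g - m)) if g > m else None
    return ConventionIndices(len(keep), s, m, g, ci, ri)


@dataclass(frozen=True)
class IndexReport:
    """Tree length with per-character and ensemble fit indices.

    ``per_character_ci``/``ri`` are None where undefined (s=0, or g=m).
    ``all_characters`` and ``informative_only`` are always both present;
    ``convention`` names the one the ensemble properties delegate to.
    """

    total_length: int
    per_character_steps: tuple
    per_character_min: tuple
    per_character_max: tuple
    per_character_ci: tuple
    per_character_ri: tuple
    informative: tuple
    all_characters: ConventionIndices
    informative_only: ConventionIndices
    convention: str = "all_characters"

    @property
    def _primary(self) -> ConventionIndices:
        return getattr(self, self.convention)

    @property
    def CI(self) -> float | None:
        return self._primary.CI

    @property
    def RI(self) -> float | None:
        return self._primary.RI

    @property
    def RC(self) -> float | None:
        return self._primary.RC

    def to_dict(self) -> dict:
        return {
            "total_length": self.total_length,
            "convention": self.convention,
            "all_characters": self.all_characters.to_dict(),
            "informative_only": self.informative_only.to_dict(),
            "per_character": [
                {"index": j, "steps": s, "min": m, "max": g,
                 "ci": self.per_character_ci[j], "ri": self.per_character_ri[j],
                 "informative": self.informative[j]}
                for j, (s, m, g) in enumerate(zip(self.per_character_steps,
                                                  self.per_character_min,
                                                  self.per_character_max))
            ],
        }

    def to_table(self) -> str:
        """Human-readable per-character table keyed by character index."""
        lines = ["char  steps  min  max     ci     ri  informative"]
        for j in range(len(self.per_character_steps)):
            ci = self.per_character_ci[j]
            ri = self.per_character_ri[j]
            lines.append(
                f"{j:4d}  {self.per_character_steps[j]:5d}  "
                f"{self.per_character_min[j]:3d}  {self.per_character_max[j]:3d}  "
                f"{'  -  ' if ci is None else f'{ci:5.2f}'}  "
                f"{'  -  ' if ri is None else f'{ri:5.2f}'}  "
                f"{'yes' if self.informative[j] else 'no'}")
        return "\n".join(lines)


def ensemble_indices(trees_or_tree, matrix: CharacterMatrix,
                     convention: str = "all_characters") -> IndexReport:
    """Compute the index report on a tree (or, given several equally long
    trees, on the canonically first — the ensemble ratios are identical
    across trees of equal length since Σs is their shared length)."""
    if convention not in ("all_characters", "informative_only"):
        raise ValueError(f"unknown convention {convention!r}")
    if isinstance(trees_or_tree, PhyloTree):
        tree = trees_or_tree
    else:
        trees = sorted(trees_or_tree, key=lambda t: t.to_newick())
        if not trees:
            raise ValueError("no trees given")
        tree = trees[0]
    score = tree_length(tree, matrix)
    steps = score.per_character_steps
    mins = score.per_character_min
    maxs = score.per_character_max
    k = matrix.n_characters
    info = tuple(is_informative(matrix, j) for j in range(k))
    ci = tuple((mins[j] / steps[j]) if steps[j] > 0 else None for j in range(k))
    ri = tuple(((maxs[j] - steps[j]) / (maxs[j] - mins[j]))
               if maxs[j] > mins[j] else None for j in range(k))
    return IndexReport(
        total_length=score.total_length,
        per_character_steps=steps,
        per_character_min=mins,
        per_character_max=maxs,
        per_character_ci=ci,
        per_character_ri=ri,
        informative=info,
        all_characters=_convention(steps, mins, maxs, range(k)),
        informative_only=_convention(steps, mins, maxs,
                                     [j for j in range(k) if info[j]]),
        convention=convention,
    )
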