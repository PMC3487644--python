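"""Discrete morphological character matrices.

A :class:`CharacterMatrix` is a rectangular grid of taxa x characters where
each cell holds a *set* of states together with a flag saying how that set
arose: a single observed state, an observed polymorphism, or a
missing/inapplicable entry.  Missing ("?") and inapplicable ("N"/"-") cells
are resolved to the character's full observed-state set — wildcard semantics,
the conventional treatment in parsimony programs — but the original kind is
preserved so reports can distinguish them.

Three text dialects are supported: NEXUS (CHARACTERS/DATA block, parsed with
Bio.Nexus), TNT ``xread``, and a plain tab-separated format (one taxon per
line, one token per character, no header).  ``parse -> write -> parse`` is an
identity on the cell grid for every dialect.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from io import StringIO
from typing import Iterable, Sequence

__all__ = [
    "CellKind",
    "Cell",
    "CharacterDef",
    "CharacterMatrix",
    "MatrixError",
    "MatrixParseError",
    "parse_matrix",
    "write_matrix",
    "load_reference_matrix",
    "REFERENCE_TAXA",
]


class MatrixError(ValueError):
    """Invalid matrix structure or content."""


class MatrixParseError(MatrixError):
    """Malformed matrix text; message names the offending row/column."""


class CellKind(str, Enum):
    OBSERVED = "observed"
    POLYMORPHIC = "polymorphic"
    MISSING = "missing"
    INAPPLICABLE = "inapplicable"


@dataclass(frozen=True)
class Cell:
    """One taxon x character entry.

    ``states`` is the set of states the cell may take during optimization.
    For missing/inapplicable cells this is the character's full
    observed-state set (wildcard); it may be empty only when the character
    has no observed state anywhere.
    """

    states: frozenset
    kind: CellKind

    @property
    def is_ambiguous(self) -> bool:
        return self.kind is not CellKind.OBSERVED

    @property
    def is_wildcard(self) -> bool:
        return self.kind in (CellKind.MISSING, CellKind.INAPPLICABLE)


@dataclass(frozen=True)
class CharacterDef:
    """An unordered, unit-weight character column.

    ``observed_states`` is derived from the matrix column (observed and
    polymorphic cells), not from any external state list.
    """

    index: int
    description: str = ""
    observed_states: frozenset = frozenset()
    ordered: bool = False  # Fitch (unordered) throughout
    weight: int = 1


class CharacterMatrix:
    """Taxa x characters grid of :class:`Cell` values.

    Construct with :meth:`from_tokens` or one of the parsers; rows are
    validated for rectangularity, duplicate taxa and state consistency.
    """

    def __init__(self, taxa: Sequence[str], characters: Sequence[CharacterDef],
                 cells: Sequence[Sequence[Cell]]):
        taxa = tuple(taxa)
        if len(set(taxa)) != len(taxa):
            dup = sorted({t for t in taxa if taxa.count(t) > 1})
            raise MatrixError(f"duplicate taxon labels: {dup}")
        if not taxa or not characters:
            raise MatrixError("matrix must have at least one taxon and one character")
        for t, row in zip(taxa, cells):
            if len(row) != len(characters):
                raise MatrixError(
                    f"taxon {t!r} has {len(row)} cells, expected {len(characters)}")
        self.taxa = taxa
        self.characters = tuple(characters)
        self._cells = [tuple(row) for row in cells]
        self._index = {t: i for i, t in enumerate(taxa)}
        for j, ch in enumerate(self.characters):
            for t, row in zip(taxa, self._cells):
                c = row[j]
                if c.kind in (CellKind.OBSERVED, CellKind.POLYMORPHIC) \
                        and not c.states <= ch.observed_states:
                    raise MatrixError(
                        f"cell ({t!r}, {j}) has states {sorted(c.states)} outside "
                        f"the character's observed states {sorted(ch.observed_states)}")

    # -- accessors ---------------------------------------------------------

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_characters(self) -> int:
        return len(self.characters)

    def taxon_index(self, taxon: str) -> int:
        try:
            return self._index[taxon]
        except KeyError:
            raise KeyError(f"taxon {taxon!r} not in matrix") from None

    def cell(self, taxon, char_index: int) -> Cell:
        i = self.taxon_index(taxon) if isinstance(taxon, str) else int(taxon)
        return self._cells[i][char_index]

    def row(self, taxon) -> tuple:
        i = self.taxon_index(taxon) if isinstance(taxon, str) else int(taxon)
        return self._cells[i]

    def column(self, char_index: int) -> tuple:
        return tuple(row[char_index] for row in self._cells)

    def state_sets(self, char_index: int) -> list:
        """Per-taxon optimization state sets (wildcards already resolved)."""
        return [row[char_index].states for row in self._cells]

    def __eq__(self, other) -> bool:
        if not isinstance(other, CharacterMatrix):
            return NotImplemented
        return (self.taxa == other.taxa
                and len(self.characters) == len(other.characters)
                and self._cells == other._cells)

    def __repr__(self) -> str:
        return f"<CharacterMatrix {self.n_taxa} taxa x {self.n_characters} characters>"

    # -- construction ------------------------------------------------------

    @classmethod
    def from_tokens(cls, taxa: Sequence[str], rows: Sequence[Sequence[tuple]],
                    descriptions: Sequence[str] | None = None) -> "CharacterMatrix":
        """Build from parsed tokens: each token is ``(kind, states)`` where
        ``states`` is an iterable of ints (ignored for wildcards)."""
        n_char = len(rows[0]) if rows else 0
        observed = [set() for _ in range(n_char)]
        for row in rows:
            for j, (kind, states) in enumerate(row):
                if kind in (CellKind.OBSERVED, CellKind.POLYMORPHIC):
                    observed[j].update(states)
        characters = [
            CharacterDef(index=j,
                         description=(descriptions[j] if descriptions else ""),
                         observed_states=frozenset(observed[j]))
            for j in range(n_char)
        ]
        cells = []
        for row in rows:
            r = []
            for j, (kind, states) in enumerate(row):
                if kind in (CellKind.MISSING, CellKind.INAPPLICABLE):
                    r.append(Cell(frozenset(observed[j]), kind))
                else:
                    r.append(Cell(frozenset(states), kind))
            cells.append(r)
        return cls(taxa, characters, cells)

    def census(self) -> dict:
        """Counts of ambiguous cells, for reporting."""
        counts = {k: 0 for k in CellKind}
        for row in self._cells:
            for c in row:
                counts[c.kind] += 1
        return {
            "n_taxa": self.n_taxa,
            "n_characters": self.n_characters,
            "observed": counts[CellKind.OBSERVED],
            "polymorphic": counts[CellKind.POLYMORPHIC],
            "missing": counts[CellKind.MISSING],
            "inapplicable": counts[CellKind.INAPPLICABLE],
        }


# ---------------------------------------------------------------------------
# dialect parsing / writing
# ---------------------------------------------------------------------------

_DIALECTS = ("NEXUS", "TNT", "TSV")


def _token_to_cell(tok: str, where: str) -> tuple:
    """TSV token -> (kind, states)."""
    if tok == "?":
        return (CellKind.MISSING, ())
    if tok in ("N", "-"):
        return (CellKind.INAPPLICABLE, ())
    if tok == "$":
        return (CellKind.POLYMORPHIC, (0, 1))
    if "&" in tok:
        try:
            states = tuple(sorted({int(s) for s in tok.split("&")}))
        except ValueError:
            raise MatrixParseError(f"bad token {tok!r} at {where}") from None
        if len(states) < 2:
            raise MatrixParseError(f"polymorphism token {tok!r} at {where} "
                                   "needs at least two distinct states")
        return (CellKind.POLYMORPHIC, states)
    if tok.isdigit() and len(tok) == 1:
        return (CellKind.OBSERVED, (int(tok),))
    raise MatrixParseError(f"unrecognized token {tok!r} at {where}")


def _parse_tsv(text: str) -> CharacterMatrix:
    taxa, rows = [], []
    for ln, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise MatrixParseError(f"line {ln}: expected taxon and cell tokens")
        taxon = parts[0].strip()
        toks = [p.strip() for p in parts[1:]]
        taxa.append(taxon)
        rows.append([_token_to_cell(t, f"({taxon!r}, column {j})")
                     for j, t in enumerate(toks)])
    if not rows:
        raise MatrixParseError("no data rows")
    width = len(rows[0])
    for taxon, row in zip(taxa, rows):
        if len(row) != width:
            raise MatrixParseError(
                f"ragged matrix: taxon {taxon!r} has {len(row)} cells, expected {width}")
    return CharacterMatrix.from_tokens(taxa, rows)


def _write_tsv(m: CharacterMatrix) -> str:
    out = []
    for i, t in enumerate(m.taxa):
        toks = []
        for c in m.row(i):
            if c.kind is CellKind.MISSING:
                toks.append("?")
            elif c.kind is CellKind.INAPPLICABLE:
                toks.append("N")
            elif c.kind is CellKind.POLYMORPHIC:
                toks.append("&".join(str(s) for s in sorted(c.states)))
            else:
                toks.append(str(next(iter(c.states))))
        out.append(t + "\t" + "\t".join(toks))
    return "\n".join(out) + "\n"


def _symbols(m: CharacterMatrix) -> str:
    states = sorted(set().union(*(ch.observed_states for ch in m.characters)) or {0})
    for s in states:
        if not 0 <= s <= 9:
            raise MatrixError(f"state {s} outside the single-digit dialect alphabet")
    return "".join(str(s) for s in states)


def _nexus_label(t: str) -> str:
    if re.fullmatch(r"[\w.]+", t):
        return t
    return "'" + t.replace("'", "''") + "'"


def _write_nexus(m: CharacterMatrix) -> str:
    sym = _symbols(m)
    lines = [
        "#NEXUS",
        "BEGIN DATA;",
        f"DIMENSIONS NTAX={m.n_taxa} NCHAR={m.n_characters};",
        f'FORMAT DATATYPE=STANDARD SYMBOLS="{sym}" MISSING=? GAP=-;',
        "MATRIX",
    ]
    width = max(len(_nexus_label(t)) for t in m.taxa) + 2
    for i, t in enumerate(m.taxa):
        toks = []
        for c in m.row(i):
            if c.kind is CellKind.MISSING:
                toks.append("?")
            elif c.kind is CellKind.INAPPLICABLE:
                toks.append("-")
            elif c.kind is CellKind.POLYMORPHIC:
                toks.append("(" + "".join(str(s) for s in sorted(c.states)) + ")")
            else:
                toks.append(str(next(iter(c.states))))
        lines.append(_nexus_label(t).ljust(width) + "".join(toks))
    lines += [";", "END;", ""]
    return "\n".join(lines)


def _parse_nexus(text: str) -> CharacterMatrix:
    from Bio.Nexus import Nexus

    try:
        nx = Nexus.Nexus(StringIO(text))
    except Exception as exc:  # Bio.Nexus raises plain Exception subclasses
        raise MatrixParseError(f"NEXUS parse failed: {exc}") from None
    if not nx.matrix:
        raise MatrixParseError("NEXUS text contains no character matrix")
    taxa = list(nx.taxlabels) if nx.taxlabels else list(nx.matrix)
    rows = []
    for t in taxa:
        try:
            seq = nx.matrix[t]
        except KeyError:
            raise MatrixParseError(f"taxon {t!r} declared but has no row") from None
        row = []
        for j, cellrec in enumerate(seq):
            d = cellrec["d"]
            where = f"({t!r}, column {j})"
            if cellrec["t"] == "multi" or len(d) > 1:
                try:
                    states = tuple(sorted({int(s) for s in d}))
                except ValueError:
                    raise MatrixParseError(f"bad symbols {d!r} at {where}") from None
                row.append((CellKind.POLYMORPHIC, states))
            else:
                s = d[0]
                if s == (nx.missing or "?"):
                    row.append((CellKind.MISSING, ()))
                elif s == (nx.gap or "-"):
                    row.append((CellKind.INAPPLICABLE, ()))
                elif s.isdigit():
                    row.append((CellKind.OBSERVED, (int(s),)))
                else:
                    raise MatrixParseError(f"unrecognized symbol {s!r} at {where}")
        rows.append(row)
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise MatrixParseError(f"ragged NEXUS matrix: row lengths {sorted(widths)}")
    return CharacterMatrix.from_tokens(taxa, rows)


def _tnt_label(t: str) -> str:
    return t.replace(" ", "_")


def _write_tnt(m: CharacterMatrix) -> str:
    _symbols(m)  # alphabet check
    lines = ["xread", f"{m.n_characters} {m.n_taxa}"]
    for i, t in enumerate(m.taxa):
        toks = []
        for c in m.row(i):
            if c.kind is CellKind.MISSING:
                toks.append("?")
            elif c.kind is CellKind.INAPPLICABLE:
                toks.append("-")
            elif c.kind is CellKind.POLYMORPHIC:
                toks.append("[" + "".join(str(s) for s in sorted(c.states)) + "]")
            else:
                toks.append(str(next(iter(c.states))))
        lines.append(_tnt_label(t) + " " + "".join(toks))
    lines += [";", ""]
    return "\n".join(lines)


_TNT_CELL = re.compile(r"\[([0-9]+)\]|([0-9?\-])")


def _parse_tnt(text: str) -> CharacterMatrix:
    body = text.strip()
    if not body.lower().startswith("xread"):
        raise MatrixParseError("TNT text must start with 'xread'")
    body = body[5:].strip()
    body = re.sub(r"^'[^']*'", "", body).strip()  # optional title comment
    m = re.match(r"(\d+)\s+(\d+)\s*(.*)$", body, flags=re.S)
    if not m:
        raise MatrixParseError("TNT header must give nchar and ntax")
    n_char, n_tax, rest = int(m.group(1)), int(m.group(2)), m.group(3)
    rest = rest.rstrip()
    if rest.endswith(";"):
        rest = rest[:-1]
    taxa, rows = [], []
    for ln, line in enumerate(rest.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        try:
            name, seq = line.split(None, 1)
        except ValueError:
            raise MatrixParseError(f"TNT row {ln}: expected name and states") from None
        taxon = name.replace("_", " ")
        row = []
        pos = 0
        for match in _TNT_CELL.finditer(seq.replace(" ", "")):
            where = f"({taxon!r}, column {len(row)})"
            if match.group(1) is not None:
                states = tuple(sorted({int(s) for s in match.group(1)}))
                if len(states) < 2:
                    raise MatrixParseError(
                        f"polymorphism with fewer than two states at {where}")
                row.append((CellKind.POLYMORPHIC, states))
            else:
                s = match.group(2)
                if s == "?":
                    row.append((CellKind.MISSING, ()))
                elif s == "-":
                    row.append((CellKind.INAPPLICABLE, ()))
                else:
                    row.append((CellKind.OBSERVED, (int(s),)))
            pos = match.end()
        if len(row) != n_char:
            raise MatrixParseError(
                f"taxon {taxon!r} has {len(row)} cells, expected {n_char}")
        taxa.append(taxon)
        rows.append(row)
    if len(taxa) != n_tax:
        raise MatrixParseError(f"TNT header declares {n_tax} taxa, found {len(taxa)}")
    return CharacterMatrix.from_tokens(taxa, rows)


def parse_matrix(text: str, dialect: str) -> CharacterMatrix:
    """Parse character-matrix text in the named dialect (NEXUS, TNT or TSV)."""
    d = dialect.upper()
    if d == "TSV":
        return _parse_tsv(text)
    if d == "NEXUS":
        return _parse_nexus(text)
    if d == "TNT":
        return _parse_tnt(text)
    raise ValueError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")


def write_matrix(matrix: CharacterMatrix, dialect: str) -> str:
    """Serialize a matrix in the named dialect; round-trips through
    :func:`parse_matrix` (TNT maps spaces in labels to underscores)."""
    d = dialect.upper()
    if d == "TSV":
        return _write_tsv(matrix)
    if d == "NEXUS":
        return _write_nexus(matrix)
    if d == "TNT":
        return _write_tnt(matrix)
    raise ValueError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")


# ---------------------------------------------------------------------------
# packaged reference dataset
# ---------------------------------------------------------------------------

# sha256 of the packaged transcription of the published 20-taxon x
# 38-character Stoiba / Mesomphaliini matrix; guards against silent edits.
_REFERENCE_SHA256 = "8fa01913270e5b64bfaa284dd36f35d0c25cd6850a72b9afced9a8c5ca2e429a"

REFERENCE_TAXA = (
    "Spaethiella sp.",
    "Physonota alutacea",
    "Asteriza flavicornis",
    "Chelymorpha sp.",
    "Phytodectoidea sp.",
    "Stolas sp.",
    "Stoiba angusticollis",
    "Stoiba bruneri",
    "Stoiba fascicollis",
    "Stoiba flavicollis",
    "Stoiba fuscicornis",
    "Stoiba indivisa",
    "Stoiba marginata",
    "Stoiba nigricans",
    "Stoiba swartzii",
    "Elytrogona bacca",
    "Elytrogona gemmata",
    "Elytrogona nigrodorsata",
    "Elytrogona quatuordecimmaculata",
    "Elytrogona bulla",
)


def load_reference_matrix() -> CharacterMatrix:
    """Load the packaged transcription of the published tortoise-beetle
    morphology matrix: 20 taxa (nine *Stoiba* species plus eleven outgroups)
    by 38 unordered characters, with one polymorphic cell and sparse
    missing/inapplicable entries."""
    data = resources.files("cladist.data")
    text = (data / "stoiba_matrix.tsv").read_text()
    digest = hashlib.sha256(text.encode()).hexdigest()
    if digest != _REFERENCE_SHA256:
        raise RuntimeError(
            "packaged reference matrix failed its integrity check "
            f"(sha256 {digest})")
    descs = {}
    for line in (data / "stoiba_characters.tsv").read_text().splitlines():
        idx, desc = line.split("\t", 1)
        descs[int(idx)] = desc
    m = _parse_tsv(text)
    characters = [
        CharacterDef(index=ch.index, description=descs.get(ch.index, ""),
                     observed_states=ch.observed_states)
        for ch in m.characters
    ]
    if m.taxa != REFERENCE_TAXA:
        raise RuntimeError("packaged reference matrix has unexpected taxon labels")
    return CharacterMatrix(m.taxa, characters, [m.row(i) for i in range(m.n_taxa)])
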