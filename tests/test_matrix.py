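"""Matrix representation, dialect round trips, and the packaged fixture."""

import string

import pytest
from hypothesis import given, settings, strategies as st

from cladist.matrix import (CellKind, CharacterMatrix, MatrixError,
                            MatrixParseError, load_reference_matrix,
                            parse_matrix, write_matrix)

from _oracles import make_matrix


class TestReferenceFixture:
    def test_dimensions(self, reference_matrix):
        assert reference_matrix.n_taxa == 20
        assert reference_matrix.n_characters == 38

    def test_every_character_unordered_unit_weight(self, reference_matrix):
        for ch in reference_matrix.characters:
            assert not ch.ordered
            assert ch.weight == 1
            assert ch.observed_states  # every column has an observed state

    def test_single_polymorphic_cell(self, reference_matrix):
        cells = [(t, j)
                 for t in reference_matrix.taxa
                 for j in range(38)
                 if reference_matrix.cell(t, j).kind is CellKind.POLYMORPHIC]
        assert cells == [("Stoiba flavicollis", 29)]
        assert reference_matrix.cell("Stoiba flavicollis", 29).states == {0, 1}

    def test_missing_and_inapplicable_coordinates(self, reference_matrix):
        missing = {(t, j)
                   for t in reference_matrix.taxa for j in range(38)
                   if reference_matrix.cell(t, j).kind is CellKind.MISSING}
        assert missing == {("Stolas sp.", 36), ("Stoiba indivisa", 33),
                           ("Stoiba indivisa", 34), ("Elytrogona bulla", 17)}
        inapplicable = {(t, j)
                        for t in reference_matrix.taxa for j in range(38)
                        if reference_matrix.cell(t, j).kind is CellKind.INAPPLICABLE}
        assert inapplicable == {("Spaethiella sp.", 5), ("Spaethiella sp.", 31),
                                ("Physonota alutacea", 31),
                                ("Asteriza flavicornis", 31)}

    def test_wildcard_cells_resolve_to_full_state_set(self, reference_matrix):
        cell = reference_matrix.cell("Elytrogona bulla", 17)
        assert cell.states == reference_matrix.characters[17].observed_states

    def test_three_state_character_example(self, reference_matrix):
        assert reference_matrix.characters[12].observed_states == {0, 1, 2}


class TestParsing:
    def test_minimal_tsv(self):
        m = parse_matrix("A\t0\nB\t1", "TSV")
        assert m.taxa == ("A", "B")
        assert m.cell("A", 0).kind is CellKind.OBSERVED
        assert m.cell("B", 0).states == {1}

    def test_dollar_token_is_01_polymorphism(self):
        m = parse_matrix("A\t$\nB\t0\nC\t1", "TSV")
        assert m.cell("A", 0).kind is CellKind.POLYMORPHIC
        assert m.cell("A", 0).states == {0, 1}

    def test_ragged_row_names_taxon(self):
        with pytest.raises(MatrixParseError, match="B"):
            parse_matrix("A\t0\t1\nB\t0", "TSV")

    def test_duplicate_taxa_rejected(self):
        with pytest.raises(MatrixError, match="duplicate"):
            parse_matrix("A\t0\nA\t1", "TSV")

    def test_bad_token_names_position(self):
        with pytest.raises(MatrixParseError, match="'x'"):
            parse_matrix("A\tx", "TSV")

    def test_empty_matrix_rejected(self):
        with pytest.raises(MatrixParseError):
            parse_matrix("", "TSV")
        with pytest.raises(MatrixError):
            CharacterMatrix([], [], [])

    def test_unknown_dialect(self):
        with pytest.raises(ValueError, match="dialect"):
            parse_matrix("A\t0", "PHYLIP")


class TestWriting:
    def test_nexus_polymorphism_token(self):
        m = make_matrix(["0 01", "1 1", "0 0"])
        assert "(01)" in write_matrix(m, "NEXUS")

    def test_tnt_brackets_and_header(self):
        m = make_matrix(["0 01", "1 1", "0 0"])
        text = write_matrix(m, "TNT")
        assert text.startswith("xread")
        assert "[01]" in text
        assert "2 3" in text  # nchar ntax

    def test_state_outside_alphabet_rejected(self):
        from cladist.matrix import CharacterDef, Cell
        ch = CharacterDef(index=0, observed_states=frozenset({0, 12}))
        cells = [[Cell(frozenset({0}), CellKind.OBSERVED)],
                 [Cell(frozenset({12}), CellKind.OBSERVED)]]
        m = CharacterMatrix(["A", "B"], [ch], cells)
        with pytest.raises(MatrixError, match="alphabet"):
            write_matrix(m, "NEXUS")


# -- round-trip property ----------------------------------------------------

_LABEL_ALPHA = string.ascii_letters + " ."


@st.composite
def matrices(draw):
    n_taxa = draw(st.integers(2, 5))
    n_char = draw(st.integers(1, 5))
    labels = draw(st.lists(
        st.text(_LABEL_ALPHA, min_size=1, max_size=10)
          .map(str.strip).filter(lambda s: s and not s.startswith("'")),
        min_size=n_taxa, max_size=n_taxa, unique=True))
    cell = st.one_of(
        st.integers(0, 2).map(lambda s: (CellKind.OBSERVED, (s,))),
        st.just((CellKind.MISSING, ())),
        st.just((CellKind.INAPPLICABLE, ())),
        st.lists(st.integers(0, 2), min_size=2, max_size=3, unique=True)
          .map(lambda ss: (CellKind.POLYMORPHIC, tuple(sorted(ss)))),
    )
    rows = draw(st.lists(
        st.lists(cell, min_size=n_char, max_size=n_char),
        min_size=n_taxa, max_size=n_taxa))
    return CharacterMatrix.from_tokens(labels, rows)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(matrices(), st.sampled_from(["TSV", "NEXUS", "TNT"]))
def test_round_trip_identity(matrix, dialect):
    """parse(write(M)) reproduces the cell grid, kinds included."""
    back = parse_matrix(write_matrix(matrix, dialect), dialect)
    assert back == matrix


def test_reference_round_trips_all_dialects(reference_matrix):
    for dialect in ("TSV", "NEXUS", "TNT"):
        back = parse_matrix(write_matrix(reference_matrix, dialect), dialect)
        assert back == reference_matrix


def test_reference_loader_is_idempotent():
    assert load_reference_matrix() == load_reference_matrix()
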