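import numpy as np
import pytest

from cladist.matrix import load_reference_matrix


@pytest.fixture(scope="session")
def reference_matrix():
    return load_reference_matrix()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_state_matrix(rng, n_taxa, n_char, n_states=3, p_wild=0.1,
                        p_poly=0.05):
    """Random small matrix with occasional ambiguity (shared test helper)."""
    from cladist.matrix import CellKind, CharacterMatrix

    rows = []
    for _ in range(n_taxa):
        row = []
        for _ in range(n_char):
            u = rng.random()
            if u < p_wild / 2:
                row.append((CellKind.MISSING, ()))
            elif u < p_wild:
                row.append((CellKind.INAPPLICABLE, ()))
            elif u < p_wild + p_poly:
                pair = rng.choice(n_states, size=2, replace=False)
                row.append((CellKind.POLYMORPHIC, tuple(sorted(int(x) for x in pair))))
            else:
                row.append((CellKind.OBSERVED, (int(rng.integers(n_states)),)))
        rows.append(row)
    taxa = [chr(ord("A") + i) for i in range(n_taxa)]
    return CharacterMatrix.from_tokens(taxa, rows)
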