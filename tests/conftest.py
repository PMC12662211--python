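import numpy as np
import pytest

from mitofounder.haplotree import ReferenceHaplogroupTree
from mitofounder.synthetic_data import synthetic_reference


@pytest.fixture(scope="session")
def reference():
    """Session-wide synthetic reference on the rCRS coordinate grid."""
    return synthetic_reference()


@pytest.fixture()
def toy_motif_tree(reference):
    """Three-level motif tree whose tokens are consistent with the reference
    sequence (from-allele = reference base at each position)."""

    def tok(pos, to):
        frm = reference.base(pos)
        alts = [b for b in "ACGT" if b != frm]
        return f"{frm}{pos}{to if to in alts else alts[0]}"

    def alt(pos):
        return tok(pos, "G")[-1]

    nodes = {
        "ROOT": (None, []),
        "A": ("ROOT", [tok(769, "G")]),
        "A1": ("A", [tok(1000, "G"), tok(2000, "G")]),
        "A2": ("A", [tok(1000, "G"), tok(3000, "G")]),
        "B": ("ROOT", [tok(5000, "G")]),
        "B1": ("B", [tok(6000, "G")]),
    }
    return ReferenceHaplogroupTree(nodes)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
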