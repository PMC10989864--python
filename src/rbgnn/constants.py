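"""Frozen atom-feature layout.

The layout is versioned so that saved model checkpoints can verify they
were trained against the same featurization.  Changing anything in this
file requires bumping FEATURE_LAYOUT_VERSION.

The blocks mirror the conventional "canonical" atom featurization used
throughout molecular machine learning: one-hot element type (with a
dedicated trailing "other" slot for elements outside the list), one-hot
heavy-atom degree, one-hot implicit valence, formal charge, number of
radical electrons, one-hot hybridization, an aromaticity flag and a
one-hot total hydrogen count.
"""

FEATURE_LAYOUT_VERSION = "canonical-v1"

# Element order is fixed; the final slot is the catch-all "other".
ATOM_TYPES = [
    "C", "N", "O", "S", "F", "Si", "P", "Cl", "Br", "Mg", "Na", "Ca",
    "Fe", "As", "Al", "I", "B", "V", "K", "Tl", "Yb", "Sb", "Sn", "Ag",
    "Pd", "Co", "Se", "Ti", "Zn", "H", "Li", "Ge", "Cu", "Au", "Ni",
    "Cd", "In", "Mn", "Zr", "Cr", "Pt", "Hg", "Pb",
]
N_ATOM_TYPES = len(ATOM_TYPES) + 1          # + "other" slot

DEGREES = list(range(11))                   # 0..10 heavy-atom neighbours
IMPLICIT_VALENCES = list(range(7))          # 0..6
HYBRIDIZATIONS = ["SP", "SP2", "SP3", "SP3D", "SP3D2"]
NUM_HS = list(range(5))                     # 0..4 total hydrogens

# Block widths, in order of concatenation.
BLOCK_SIZES = {
    "atom_type": N_ATOM_TYPES,
    "degree": len(DEGREES),
    "implicit_valence": len(IMPLICIT_VALENCES),
    "formal_charge": 1,
    "radical_electrons": 1,
    "hybridization": len(HYBRIDIZATIONS),
    "aromatic": 1,
    "num_hs": len(NUM_HS),
}

ATOM_FEATURE_DIM = sum(BLOCK_SIZES.values())


def block_slice(name: str) -> slice:
    """Return the column slice of a named feature block."""
    start = 0
    for key, width in BLOCK_SIZES.items():
        if key == name:
            return slice(start, start + width)
        start += width
    raise KeyError(name)
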