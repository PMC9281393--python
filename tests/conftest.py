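import numpy as np
import pandas as pd
import pytest

from ghbfit import make_training_suite

# Atom compositions for building small test topologies (PDB v3 naming).
_BACKBONE_5P = ["HO5'", "O5'", "C5'", "H5'", "H5''", "C4'", "H4'", "O4'", "C1'", "H1'",
                "C3'", "H3'", "O3'", "C2'", "H2'", "O2'", "HO2'"]
_BACKBONE = ["P", "OP1", "OP2"] + _BACKBONE_5P[1:]
_BASES = {
    "G": ["N9", "C8", "H8", "N7", "C5", "C6", "O6", "N1", "H1", "C2", "N2",
          "H21", "H22", "N3", "C4"],
    "C": ["N1", "C2", "O2", "N3", "C4", "N4", "H41", "H42", "C5", "H5", "C6", "H6"],
    "A": ["N9", "C8", "H8", "N7", "C5", "C6", "N6", "H61", "H62", "N1", "C2", "H2",
          "N3", "C4"],
    "U": ["N1", "C2", "O2", "N3", "H3", "C4", "O4", "C5", "H5", "C6", "H6"],
}


def rna_topology(sequence: str) -> pd.DataFrame:
    """Atom table for a single-stranded RNA with the given sequence."""
    rows = []
    for i, res in enumerate(sequence, start=1):
        backbone = _BACKBONE_5P if i == 1 else _BACKBONE
        for atom in backbone + _BASES[res]:
            rows.append({"residue_index": i, "residue_name": res, "atom_name": atom})
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def gc_dinucleotide():
    return rna_topology("GC")


@pytest.fixture(scope="session")
def small_suite():
    """Noisy three-system suite at desk scale (shared; treat as read-only)."""
    return make_training_suite(seed=11, n_frames=2000, noise_scale=1.0)


@pytest.fixture(scope="session")
def noise_free_suite():
    return make_training_suite(seed=5, n_frames=3000, noise_scale=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
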