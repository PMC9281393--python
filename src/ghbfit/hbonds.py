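"""Hydrogen-bond taxonomy, donor/acceptor classification and feature matrices.

The correction potential acts on hydrogen--acceptor distances through a
switching function, with one trainable strength per hydrogen-bond *type*.
A type is a (donor class, acceptor class) pair.  Two donor classes are
considered -- base -NH groups and the sugar 2'-OH -- and six acceptor
classes: base ring nitrogens, base carbonyl oxygens, nonbridging phosphate
oxygens, bridging phosphate oxygens, sugar O2' and sugar O4'.  That gives
12 types and therefore 12 trainable parameters.

The per-frame *feature* ``n_j(x)`` is the smooth count of formed bonds of
type ``j`` in frame ``x``: the sum over donor/acceptor pairs of that type of
a switching function of the hydrogen--acceptor distance, which is 1 at short
distance and 0 at long distance.  Internally the per-pair count lives in
[0, 1]; the equivalent -1..0 convention (identical up to an additive
constant) is used only at the PLUMED interface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ClassificationError, ConfigurationError, DimensionError, InputError

DONOR_CLASSES = ("NH", "O2H")
ACCEPTOR_CLASSES = ("baseN", "baseO", "nbO", "bO", "O2p", "O4p")
N_TYPES = len(DONOR_CLASSES) * len(ACCEPTOR_CLASSES)


@dataclass(frozen=True)
class HBondType:
    donor_class: str
    acceptor_class: str
    index: int

    @property
    def label(self) -> str:
        return f"{self.donor_class}..{self.acceptor_class}"


def type_index(donor_class: str, acceptor_class: str) -> int:
    """Bijection from (donor class, acceptor class) onto 0..11."""
    try:
        d = DONOR_CLASSES.index(donor_class)
        a = ACCEPTOR_CLASSES.index(acceptor_class)
    except ValueError as exc:
        raise ClassificationError(
            f"unknown donor/acceptor class ({donor_class!r}, {acceptor_class!r})"
        ) from exc
    return d * len(ACCEPTOR_CLASSES) + a


HBOND_TYPES: tuple[HBondType, ...] = tuple(
    HBondType(d, a, type_index(d, a)) for d in DONOR_CLASSES for a in ACCEPTOR_CLASSES
)

TYPE_LABELS: tuple[str, ...] = tuple(t.label for t in HBOND_TYPES)


# --- RNA atom classification (standard PDB v3 naming) ----------------------

# Base donor hydrogens (amino and imino groups).
_BASE_DONOR_H = {
    "A": ("H61", "H62"),
    "G": ("H1", "H21", "H22"),
    "C": ("H41", "H42"),
    "U": ("H3",),
}
_SUGAR_DONOR_H = "HO2'"

# Base acceptors per residue.
_BASE_ACCEPTORS = {
    "A": {"N1": "baseN", "N3": "baseN", "N7": "baseN"},
    "G": {"N3": "baseN", "N7": "baseN", "O6": "baseO"},
    "C": {"N3": "baseN", "O2": "baseO"},
    "U": {"O2": "baseO", "O4": "baseO"},
}
# Backbone/sugar acceptors common to all residues (O1P/O2P are legacy
# PDB v2 spellings of the nonbridging phosphate oxygens).
_COMMON_ACCEPTORS = {
    "OP1": "nbO",
    "OP2": "nbO",
    "OP3": "nbO",
    "O1P": "nbO",
    "O2P": "nbO",
    "O3P": "nbO",
    "O3'": "bO",
    "O5'": "bO",
    "O2'": "O2p",
    "O4'": "O4p",
}

# Atoms that are recognized but neither donate nor accept: carbons, CH
# hydrogens, protonated/amino nitrogens, phosphorus and sugar hydrogens.
_COMMON_IGNORED = {
    "P", "C1'", "C2'", "C3'", "C4'", "C5'",
    "H1'", "H2'", "H3'", "H4'", "H5'", "H5''",
    "HO5'", "HO3'", "HOP3",
}
_RES_IGNORED = {
    "A": {"N9", "C8", "H8", "C2", "H2", "C4", "C5", "C6", "N6"},
    "G": {"N9", "C8", "H8", "C2", "C4", "C5", "C6", "N1", "N2"},
    "C": {"N1", "C2", "C4", "C5", "C6", "H5", "H6", "N4"},
    "U": {"N1", "C2", "C4", "C5", "C6", "H5", "H6", "N3"},
}


@dataclass
class PairList:
    """Candidate donor-hydrogen / acceptor pairs with their type indices.

    Atom ids are 0-based indices into the topology table.  Intra-nucleotide
    pairs are excluded; entries are sorted by (hydrogen id, acceptor id).
    """

    hydrogen_ids: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    acceptor_ids: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    type_indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    hydrogen_residues: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    acceptor_residues: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    # names kept for readable PLUMED output
    hydrogen_names: list[str] = field(default_factory=list)
    acceptor_names: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.hydrogen_ids)


@dataclass(frozen=True)
class SwitchSpec:
    """Switching function on the hydrogen--acceptor distance (Angstrom).

    Per-pair smooth count is 1 for r <= r_low, 0 for r >= r_high and
    interpolates in between, either linearly or with a cubic smoothstep.
    """

    r_low: float = 2.0
    r_high: float = 3.0
    shape: str = "linear"

    def __post_init__(self):
        if not (0 < self.r_low < self.r_high):
            raise ConfigurationError(
                f"switching spec requires 0 < r_low < r_high, got ({self.r_low}, {self.r_high})"
            )
        if self.shape not in ("linear", "smoothstep"):
            raise ConfigurationError(f"unknown switching shape {self.shape!r}")


def topology_from_table(path) -> pd.DataFrame:
    """Read a plain-text atom table with columns residue_index, residue_name, atom_name."""
    top = pd.read_csv(path, sep="\t", comment="#")
    required = {"residue_index", "residue_name", "atom_name"}
    missing = required - set(top.columns)
    if missing:
        raise InputError(f"atom table {path} missing columns: {sorted(missing)}")
    return top.reset_index(drop=True)


def topology_from_pdb(path) -> pd.DataFrame:
    """Read an RNA topology from a PDB file (first model)."""
    from biotite.structure.io.pdb import PDBFile

    pdbfile = PDBFile.read(str(path))
    atoms = pdbfile.get_structure(model=1)
    return pd.DataFrame(
        {
            "residue_index": np.asarray(atoms.res_id, dtype=int),
            "residue_name": [str(r).strip() for r in atoms.res_name],
            "atom_name": [str(a).strip() for a in atoms.atom_name],
        }
    )


_RES_ALIASES = {"A": "A", "RA": "A", "A3": "A", "A5": "A", "AN": "A",
                "C": "C", "RC": "C", "C3": "C", "C5": "C", "CN": "C",
                "G": "G", "RG": "G", "G3": "G", "G5": "G", "GN": "G",
                "U": "U", "RU": "U", "U3": "U", "U5": "U", "UN": "U"}


def classify_pairs(topology: pd.DataFrame) -> PairList:
    """Enumerate donor-hydrogen / acceptor pairs and classify each into a type.

    Parameters
    ----------
    topology : DataFrame with columns residue_index, residue_name, atom_name.
        Standard RNA residues (A, C, G, U; AMBER-style aliases accepted)
        with PDB v3 atom naming.  Row order defines 0-based atom ids.

    Raises
    ------
    ClassificationError
        On an unknown residue or atom name, naming the offending atom.
    """
    res_idx = topology["residue_index"].to_numpy()
    if len(np.unique(res_idx)) < 2:
        warnings.warn("topology has fewer than 2 residues; no inter-nucleotide pairs exist")
        return PairList()

    donors: list[tuple[int, int, int, str]] = []  # (atom_id, res, donor_class_idx, name)
    acceptors: list[tuple[int, int, int, str]] = []  # (atom_id, res, acc_class_idx, name)

    for atom_id, row in enumerate(topology.itertuples(index=False)):
        rname = _RES_ALIASES.get(str(row.residue_name).strip())
        aname = str(row.atom_name).strip()
        if rname is None:
            raise ClassificationError(
                f"unknown residue name {row.residue_name!r} at atom {atom_id} ({aname})"
            )
        if aname == _SUGAR_DONOR_H:
            donors.append((atom_id, row.residue_index, 1, aname))
        elif aname in _BASE_DONOR_H[rname]:
            donors.append((atom_id, row.residue_index, 0, aname))
        elif aname in _BASE_ACCEPTORS[rname]:
            acc = _BASE_ACCEPTORS[rname][aname]
            acceptors.append((atom_id, row.residue_index, ACCEPTOR_CLASSES.index(acc), aname))
        elif aname in _COMMON_ACCEPTORS:
            acc = _COMMON_ACCEPTORS[aname]
            acceptors.append((atom_id, row.residue_index, ACCEPTOR_CLASSES.index(acc), aname))
        elif aname in _COMMON_IGNORED or aname in _RES_IGNORED[rname]:
            continue
        else:
            raise ClassificationError(
                f"unknown atom name {aname!r} in residue {row.residue_name!r} (atom id {atom_id})"
            )

    h_ids, a_ids, t_idx, h_res, a_res, h_names, a_names = [], [], [], [], [], [], []
    for h_id, h_r, d_cls, h_name in donors:
        for a_id, a_r, a_cls, a_name in acceptors:
            if h_r == a_r:  # covalently constrained, not a hydrogen bond of interest
                continue
            h_ids.append(h_id)
            a_ids.append(a_id)
            t_idx.append(d_cls * len(ACCEPTOR_CLASSES) + a_cls)
            h_res.append(h_r)
            a_res.append(a_r)
            h_names.append(h_name)
            a_names.append(a_name)

    order = np.lexsort((np.asarray(a_ids, dtype=int), np.asarray(h_ids, dtype=int)))
    return PairList(
        hydrogen_ids=np.asarray(h_ids, dtype=int)[order],
        acceptor_ids=np.asarray(a_ids, dtype=int)[order],
        type_indices=np.asarray(t_idx, dtype=int)[order],
        hydrogen_residues=np.asarray(h_res, dtype=int)[order],
        acceptor_residues=np.asarray(a_res, dtype=int)[order],
        hydrogen_names=[h_names[i] for i in order],
        acceptor_names=[a_names[i] for i in order],
    )


def pair_count(r, spec: SwitchSpec):
    """Per-pair smooth bond count n(r) in [0, 1]; 1 = fully formed."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise InputError("distances must be non-negative")
    u = np.clip((r - spec.r_low) / (spec.r_high - spec.r_low), 0.0, 1.0)
    if spec.shape == "smoothstep":
        u = u * u * (3.0 - 2.0 * u)
    return 1.0 - u


def switching_value(r, spec: SwitchSpec):
    """Switching function in [-1, 0]: -1 at short distance, 0 at long distance.

    This is the PLUMED-facing convention; it equals ``-pair_count(r, spec)``.
    """
    return -pair_count(r, spec)


def compute_features(distances, pairs: PairList, spec: SwitchSpec) -> np.ndarray:
    """Per-frame smooth counts of formed bonds, one column per type.

    Parameters
    ----------
    distances : (frames, n_pairs) array of hydrogen--acceptor distances (Angstrom),
        columns ordered as in ``pairs``.

    Returns
    -------
    (frames, 12) float array; entry (x, j) sums the per-pair count over all
    pairs of type j.
    """
    distances = np.asarray(distances, dtype=float)
    if distances.ndim != 2 or distances.shape[1] != len(pairs):
        raise DimensionError(
            f"distances has shape {distances.shape}, expected (frames, {len(pairs)})"
        )
    counts = pair_count(distances, spec)
    features = np.zeros((distances.shape[0], N_TYPES))
    np.add.at(features.T, pairs.type_indices, counts.T)
    return features


def correction_energy(features: np.ndarray, lam: np.ndarray, temperature: float | None = None):
    """Correction energy per frame, -k_B*T * sum_j lambda_j n_j(x).

    With ``temperature=None`` the unitless exponent f(x, lambda) is returned;
    otherwise the energy in kcal/mol at that temperature.  Positive lambda_j
    lowers the energy of frames where type-j bonds are formed, i.e. supports
    their formation.
    """
    from .units import kbt

    exponent = -np.asarray(features, dtype=float) @ np.asarray(lam, dtype=float)
    if temperature is None:
        return exponent
    return kbt(temperature) * exponent
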