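"""From an RNA topology to feature matrices and PLUMED bias files.

Classifies every donor-hydrogen/acceptor pair of a GCAU strand into the 12
hydrogen-bond types, evaluates switching functions on synthetic distances
to get per-frame smooth bond counts, and emits the PLUMED input with its
types and scaling tables.
"""

import numpy as np
import pandas as pd

from ghbfit import (
    ParamVector,
    SwitchSpec,
    TYPE_LABELS,
    classify_pairs,
    compute_features,
    write_plumed_input,
)

# atom table of a 4-mer; in practice use topology_from_pdb("file.pdb")
rows = []
backbone = ["P", "OP1", "OP2", "O5'", "C5'", "H5'", "H5''", "C4'", "H4'", "O4'",
            "C1'", "H1'", "C3'", "H3'", "O3'", "C2'", "H2'", "O2'", "HO2'"]
bases = {
    "G": ["N9", "C8", "H8", "N7", "C5", "C6", "O6", "N1", "H1", "C2", "N2",
          "H21", "H22", "N3", "C4"],
    "C": ["N1", "C2", "O2", "N3", "C4", "N4", "H41", "H42", "C5", "H5", "C6", "H6"],
    "A": ["N9", "C8", "H8", "N7", "C5", "C6", "N6", "H61", "H62", "N1", "C2", "H2",
          "N3", "C4"],
    "U": ["N1", "C2", "O2", "N3", "H3", "C4", "O4", "C5", "H5", "C6", "H6"],
}
for i, res in enumerate("GCAU", start=1):
    for atom in backbone + bases[res]:
        rows.append({"residue_index": i, "residue_name": res, "atom_name": atom})
topology = pd.DataFrame(rows)

pairs = classify_pairs(topology)
print(f"{len(pairs)} donor/acceptor pairs across {len(set(pairs.type_indices))} types")

# synthetic H..acceptor distances for 5 frames
rng = np.random.default_rng(1)
distances = rng.uniform(1.8, 4.5, size=(5, len(pairs)))
spec = SwitchSpec(r_low=2.0, r_high=3.0, shape="linear")
features = compute_features(distances, pairs, spec)
for j, label in enumerate(TYPE_LABELS):
    if features[:, j].any():
        print(f"  {label:12s} mean count {features[:, j].mean():.2f}")

params = ParamVector(np.linspace(-0.5, 0.5, 12))
paths = write_plumed_input(pairs, params, spec, "scratch/plumed_demo")
print("PLUMED files:", *(p.name for p in paths.values()))
# scalingParameters.dat holds kB*T*lambda per type in kcal/mol; the main
# input declares one switching function per pair and a COMBINE bias.
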