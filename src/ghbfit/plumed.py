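"""Bias-generation files in PLUMED input syntax.

Three text artifacts are written: the main input declaring one switching
function per donor/acceptor pair and a linear-combination bias, a types
table mapping each pair to its hydrogen-bond type, and a scaling table with
the per-type prefactors k_B*T*lambda in kcal/mol.  At this interface the
switching function follows the -1 (short distance) .. 0 (long distance)
convention, which differs from the internal [0, 1] count only by an
additive constant per pair.  Atom serials in the emitted files are 1-based,
as PLUMED expects.

All outputs are byte-stable across runs, and the scaling table round-trips
to 6 decimals through :func:`read_scaling_table`.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .errors import InputError
from .hbonds import HBOND_TYPES, N_TYPES, PairList, SwitchSpec
from .objective import ParamVector
from .units import DEFAULT_TEMPERATURE, kbt

MAIN_FILE = "plumed_ghbfix.dat"
TYPES_FILE = "typesTable.dat"
SCALING_FILE = "scalingParameters.dat"


def write_plumed_input(
    pairs: PairList,
    params: ParamVector,
    spec: SwitchSpec,
    directory,
    temperature: float = DEFAULT_TEMPERATURE,
) -> dict[str, Path]:
    """Write the main input, types table and scaling table; returns their paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    scale = kbt(temperature) * np.asarray(params.lam, dtype=float)

    scaling_path = directory / SCALING_FILE
    lines = [
        "# gHBfix scaling parameters: kB*T*lambda in kcal/mol "
        f"at T={temperature:.2f} K",
        "# columns: type_index donor_class acceptor_class scale_kcal_per_mol",
    ]
    for t in HBOND_TYPES:
        lines.append(f"{t.index} {t.donor_class} {t.acceptor_class} {scale[t.index]:.6f}")
    scaling_path.write_text("\n".join(lines) + "\n")

    types_path = directory / TYPES_FILE
    lines = [
        "# gHBfix pair table; atom serials are 1-based",
        "# columns: hydrogen_serial acceptor_serial type_index",
    ]
    for h, a, t in zip(pairs.hydrogen_ids, pairs.acceptor_ids, pairs.type_indices):
        lines.append(f"{h + 1} {a + 1} {t}")
    types_path.write_text("\n".join(lines) + "\n")

    main_path = directory / MAIN_FILE
    lines = [
        "# gHBfix bias: V = sum_pairs kB*T*lambda[type] * s(r_H..acceptor)",
        f"# switching: -1 for r <= {spec.r_low:g}, 0 for r >= {spec.r_high:g}, "
        f"{spec.shape} in between",
    ]
    labels = []
    coeffs = []
    for k, (h, a, t) in enumerate(
        zip(pairs.hydrogen_ids, pairs.acceptor_ids, pairs.type_indices)
    ):
        label = f"ghb{k}"
        labels.append(label)
        coeffs.append(f"{scale[t]:.6f}")
        lines.append(
            f"{label}: GHBFIX ATOMS={h + 1},{a + 1} TYPE={t} "
            f"SWITCH={{GHBFIX R_LOW={spec.r_low:g} R_HIGH={spec.r_high:g}}}"
        )
    if labels:
        lines.append(
            f"ghbsum: COMBINE ARG={','.join(labels)} "
            f"COEFFICIENTS={','.join(coeffs)} PERIODIC=NO"
        )
        lines.append("BIASVALUE ARG=ghbsum")
    main_path.write_text("\n".join(lines) + "\n")
    return {"main": main_path, "types": types_path, "scaling": scaling_path}


def read_scaling_table(path) -> np.ndarray:
    """Parse a scaling table back into the 12 per-type kcal/mol prefactors."""
    values = np.full(N_TYPES, np.nan)
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) != 4:
            raise InputError(f"malformed scaling-table line: {line!r}")
        idx = int(fields[0])
        if not 0 <= idx < N_TYPES:
            raise InputError(f"type index {idx} out of range in scaling table")
        values[idx] = float(fields[3])
    if np.isnan(values).any():
        missing = np.flatnonzero(np.isnan(values)).tolist()
        raise InputError(f"scaling table missing type indices {missing}")
    return values
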