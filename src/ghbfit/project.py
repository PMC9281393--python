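"""Project loading, validation and report generation.

A *project* is a directory with one YAML config naming the training
systems, plus per-system TSV files:

``<system>.frames.tsv``
    One row per frame (0-based, documented in the header): the 12 feature
    columns named by hydrogen-bond type label, an optional ``w0`` prior
    weight column (uniform if absent) and one column per observable with
    its per-frame forward-model input.
``<system>.observables.tsv``
    One row per observable: name, kind, group, exp_value, sigma, the name
    of its per-frame column in the frames table and optional Karplus
    coefficients.

Validation reports *every* problem found, not just the first.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ProjectError
from .fitting import CVCurve, FitResult, default_alpha_grid
from .hbonds import N_TYPES, TYPE_LABELS
from .objective import REG_KINDS, ParamVector, SystemEnsemble
from .observables import J_COUPLING, KINDS, Observable
from .units import DEFAULT_TEMPERATURE, kbt

CONFIG_NAME = "config.yaml"
_FLOAT = "%.10g"


@dataclass
class Project:
    systems: list[SystemEnsemble]
    params: ParamVector
    reg_kinds: list[str]
    alpha_grid: np.ndarray
    cv_strategy: str
    n_segments: int
    temperature: float
    config_path: Path
    config_hash: str = ""


def config_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def _load_system(name, frames_path, obs_path, omega, problems) -> SystemEnsemble | None:
    ok = True
    for p in (frames_path, obs_path):
        if not Path(p).is_file():
            problems.append(f"system {name!r}: missing file {p}")
            ok = False
    if not ok:
        return None
    frames = pd.read_csv(frames_path, sep="\t", comment="#")
    obs_table = pd.read_csv(obs_path, sep="\t", comment="#")
    missing = [c for c in TYPE_LABELS if c not in frames.columns]
    if missing:
        problems.append(f"system {name!r}: frames table missing feature columns {missing}")
        return None
    features = frames[list(TYPE_LABELS)].to_numpy(dtype=float)
    n = len(frames)
    prior = (
        frames["w0"].to_numpy(dtype=float) if "w0" in frames.columns else np.full(n, 1.0 / n)
    )
    observables = []
    for row_idx, row in obs_table.iterrows():
        label = f"system {name!r}, observables row {row_idx} ({row.get('name', '?')!r})"
        if row["kind"] not in KINDS:
            problems.append(f"{label}: unknown kind {row['kind']!r}")
            continue
        if not row["sigma"] > 0:
            problems.append(f"{label}: sigma must be > 0, got {row['sigma']}")
            continue
        col = row["frame_column"]
        if col not in frames.columns:
            problems.append(
                f"{label}: frame column {col!r} not found among {len(frames.columns)} "
                f"columns of {frames_path} ({n} frames)"
            )
            continue
        karplus = None
        if row["kind"] == J_COUPLING:
            try:
                karplus = (
                    float(row["karplus_A"]), float(row["karplus_B"]), float(row["karplus_C"])
                )
            except (KeyError, TypeError, ValueError):
                problems.append(f"{label}: J_COUPLING needs karplus_A/B/C")
                continue
            if any(np.isnan(karplus)):
                problems.append(f"{label}: J_COUPLING needs karplus_A/B/C")
                continue
        try:
            observables.append(
                Observable(
                    name=str(row["name"]), kind=str(row["kind"]),
                    per_frame_values=frames[col].to_numpy(dtype=float),
                    exp_value=float(row["exp_value"]), sigma=float(row["sigma"]),
                    group=str(row["group"]), karplus=karplus,
                )
            )
        except Exception as exc:  # collect, do not abort
            problems.append(f"{label}: {exc}")
    if not observables:
        problems.append(f"system {name!r}: no valid observables")
        return None
    try:
        return SystemEnsemble(
            name=name, features=features, prior=prior, observables=observables, omega=omega
        )
    except Exception as exc:
        problems.append(f"system {name!r}: {exc}")
        return None


def load_project(config_path) -> Project:
    """Load and fully validate a project; raises ProjectError listing all problems."""
    config_path = Path(config_path)
    if not config_path.is_file():
        raise ProjectError([f"config file {config_path} not found"])
    base = config_path.parent
    cfg = yaml.safe_load(config_path.read_text()) or {}
    problems: list[str] = []

    temperature = float(cfg.get("temperature", DEFAULT_TEMPERATURE))
    lam_max_kcal = float(cfg.get("lam_max_kcal", 1.0))
    lam_max = lam_max_kcal / kbt(temperature)
    lam0 = np.asarray(cfg.get("lam0", np.zeros(N_TYPES)), dtype=float)
    if lam0.shape != (N_TYPES,):
        problems.append(f"lam0 must have {N_TYPES} entries, got {lam0.shape}")
        lam0 = np.zeros(N_TYPES)

    reg_cfg = cfg.get("regularization", {}) or {}
    reg_kinds = list(reg_cfg.get("kinds", ["L2"]))
    for kind in reg_kinds:
        if kind not in REG_KINDS:
            problems.append(f"unknown regularization kind {kind!r}")
    alpha_grid = default_alpha_grid(
        n=int(reg_cfg.get("n_alphas", 25)),
        low=float(reg_cfg.get("alpha_min", 1e-4)),
        high=float(reg_cfg.get("alpha_max", 1e4)),
    )

    cv_cfg = cfg.get("cv", {}) or {}
    cv_strategy = str(cv_cfg.get("strategy", "SEGMENTS"))
    n_segments = int(cv_cfg.get("n_segments", 5))

    systems = []
    for entry in cfg.get("systems", []):
        name = str(entry.get("name", "?"))
        sys = _load_system(
            name,
            base / entry.get("frames", f"{name}.frames.tsv"),
            base / entry.get("observables", f"{name}.observables.tsv"),
            float(entry.get("omega", 1.0)),
            problems,
        )
        if sys is not None:
            systems.append(sys)
    if not cfg.get("systems"):
        problems.append("config names no systems")
    if problems:
        raise ProjectError(problems)

    params = ParamVector(lam=lam0.copy(), lam0=lam0, lam_max=lam_max)
    return Project(
        systems=systems,
        params=params,
        reg_kinds=reg_kinds,
        alpha_grid=alpha_grid,
        cv_strategy=cv_strategy,
        n_segments=n_segments,
        temperature=temperature,
        config_path=config_path,
        config_hash=config_digest(config_path),
    )


# --- reports ----------------------------------------------------------------


def _write_tsv(path: Path, header: list[str], rows) -> None:
    lines = ["\t".join(header)]
    for row in rows:
        lines.append(
            "\t".join(_FLOAT % v if isinstance(v, float) else str(v) for v in row)
        )
    path.write_text("\n".join(lines) + "\n")


def report(result, project: Project, outdir) -> dict[str, Path]:
    """Write parameter tables, chi^2 breakdowns, diagnostics and a JSON summary.

    Accepts a FitResult or a CVCurve; output ordering and float formatting
    are fixed, so identical inputs produce byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    if isinstance(result, FitResult):
        scale = kbt(project.temperature)
        paths["params"] = outdir / "parameters.tsv"
        _write_tsv(
            paths["params"],
            ["type_index", "type_label", "lambda", "lambda0", "kcal_per_mol"],
            [
                (j, TYPE_LABELS[j], float(result.params.lam[j]),
                 float(result.params.lam0[j]), float(scale * result.params.lam[j]))
                for j in range(N_TYPES)
            ],
        )
        paths["chi2"] = outdir / "per_system_chi2.tsv"
        _write_tsv(
            paths["chi2"],
            ["system", "chi2", "kish_inverse"],
            [
                (name, float(result.per_system_chi2[name]),
                 float(result.kish_per_system[name]))
                for name in sorted(result.per_system_chi2)
            ],
        )
        summary = {
            "cost_train": result.cost_train,
            "data_cost": result.data_cost,
            "reg_value": result.reg_value,
            "per_system_chi2": {k: result.per_system_chi2[k] for k in sorted(result.per_system_chi2)},
            "kish_per_system": {k: result.kish_per_system[k] for k in sorted(result.kish_per_system)},
            "converged": result.converged,
            "n_restarts_used": result.n_restarts_used,
            "seed": result.seed,
            "lambda": result.params.lam.tolist(),
            "lambda_kcal": (scale * result.params.lam).tolist(),
            "temperature": project.temperature,
        }
    elif isinstance(result, CVCurve):
        paths["curve"] = outdir / "cv_curve.tsv"
        _write_tsv(
            paths["curve"],
            ["alpha", "train_error", "val_error"],
            [
                (float(a), float(t), float(v))
                for a, t, v in zip(result.alphas, result.train_error, result.val_error)
            ],
        )
        paths["folds"] = outdir / "cv_folds.tsv"
        rows = []
        for ai, a in enumerate(result.alphas):
            for fi in range(result.fold_val_errors.shape[1]):
                rows.append(
                    (float(a), fi, float(result.fold_train_errors[ai, fi]),
                     float(result.fold_val_errors[ai, fi]))
                )
        _write_tsv(paths["folds"], ["alpha", "fold", "train_error", "val_error"], rows)
        paths["figure"] = outdir / "cv_curve.png"
        _plot_curve(result, paths["figure"])
        summary = {
            "reg_kind": result.reg_kind,
            "best_alpha": result.best_alpha,
            "best_val_error": result.best_val_error,
            "alphas": result.alphas.tolist(),
            "train_error": result.train_error.tolist(),
            "val_error": result.val_error.tolist(),
        }
    else:
        raise TypeError(f"cannot report a {type(result).__name__}")
    paths["summary"] = outdir / "summary.json"
    paths["summary"].write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return paths


def _plot_curve(curve: CVCurve, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(curve.alphas, curve.train_error, "o-", label="train")
    ax.plot(curve.alphas, curve.val_error, "s-", label="validation")
    ax.axvline(curve.best_alpha, color="k", ls="--", lw=0.8, label=f"best alpha={curve.best_alpha:g}")
    ax.set_xscale("log")
    ax.set_xlabel("regularization strength alpha")
    ax.set_ylabel("error")
    ax.set_title(f"{curve.reg_kind} cross-validation")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# --- synthetic project writer ----------------------------------------------


def write_synthetic_project(systems, truth, outdir) -> Path:
    """Write a complete project directory consumable by load_project unchanged."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for sys in systems:
        frames = pd.DataFrame(sys.features, columns=list(TYPE_LABELS))
        frames["w0"] = sys.prior
        obs_rows = []
        for obs in sys.observables:
            col = f"obs_{obs.name}"
            frames[col] = obs.per_frame_values
            karplus = obs.karplus or (np.nan, np.nan, np.nan)
            obs_rows.append(
                {
                    "name": obs.name, "kind": obs.kind, "group": obs.group,
                    "exp_value": obs.exp_value, "sigma": obs.sigma, "frame_column": col,
                    "karplus_A": karplus[0], "karplus_B": karplus[1], "karplus_C": karplus[2],
                }
            )
        frames_path = outdir / f"{sys.name}.frames.tsv"
        with open(frames_path, "w") as fh:
            fh.write("# one row per frame, frame indices 0-based\n")
            frames.to_csv(fh, sep="\t", index=False, float_format=_FLOAT)
        obs_path = outdir / f"{sys.name}.observables.tsv"
        pd.DataFrame(obs_rows).to_csv(obs_path, sep="\t", index=False, float_format=_FLOAT)
        entries.append(
            {
                "name": sys.name,
                "frames": frames_path.name,
                "observables": obs_path.name,
                "omega": float(sys.omega),
            }
        )
    cfg = {
        "temperature": DEFAULT_TEMPERATURE,
        "lam_max_kcal": 1.0,
        "lam0": [0.0] * N_TYPES,
        "cv": {"strategy": "SEGMENTS", "n_segments": 5},
        "regularization": {"kinds": ["L2"], "alpha_min": 1e-4, "alpha_max": 1e4, "n_alphas": 25},
        "systems": entries,
    }
    config_path = outdir / CONFIG_NAME
    config_path.write_text(yaml.safe_dump(cfg, sort_keys=False))
    lam_true = truth["lam_true"]
    _write_tsv(
        outdir / "lam_true.tsv",
        ["type_index", "type_label", "lambda_true"],
        [(j, TYPE_LABELS[j], float(lam_true[j])) for j in range(N_TYPES)],
    )
    return config_path
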