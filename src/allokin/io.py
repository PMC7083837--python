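"""Readers, writers and run configuration.

All tabular formats are UTF-8 comma-delimited text with a required header and
dot-decimal numbers; units are embedded in column names (conc_nM, time_min,
k_per_min, time_ns, angle_deg, distance_A).  Structures travel as multi-frame
PDB (MODEL/ENDMDL), read and written through biotite.
"""

from __future__ import annotations

import io as _io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .binding_models import TimeCourse
from .trajectory_synth import FrameEnsemble, StateSeries

__all__ = [
    "RunConfig",
    "read_timecourse_table",
    "write_timecourse_table",
    "read_rate_table",
    "write_rate_table",
    "read_saturation_table",
    "write_saturation_table",
    "read_dialysis_table",
    "write_dialysis_table",
    "read_series_table",
    "write_series_table",
    "read_multiframe_pdb",
    "write_multiframe_pdb",
    "write_manifest",
]

TIMECOURSE_COLUMNS = ["condition", "conc_nM", "time_min", "signal", "replicate"]
RATE_COLUMNS = ["condition", "conc_nM", "replicate", "k_per_min", "se_k", "b0", "r_squared"]
SATURATION_COLUMNS = ["substrate_nM", "velocity_fmol_min", "inhibitor_nM", "replicate"]
DIALYSIS_COLUMNS = ["time_min", "value", "animal_id", "condition"]


class SchemaError(ValueError):
    """A delimited-text table violates the declared schema."""


def _read_table(path, required: list[str], numeric: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep=",", encoding="utf-8")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")
    for col in numeric:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise SchemaError(
                f"{path}: non-numeric value {df.loc[row, col]!r} in column "
                f"{col!r}, row {row + 2} (decimal commas are not accepted; "
                "use dot-decimal)"
            )
        df[col] = coerced
    return df


def read_timecourse_table(path) -> list[TimeCourse]:
    """Read dissociation time courses from the canonical CSV schema."""
    df = _read_table(path, TIMECOURSE_COLUMNS, ["conc_nM", "time_min", "signal", "replicate"])
    out = []
    keys = ["condition", "conc_nM", "replicate"]
    for (cond, conc, rep), g in df.groupby(keys, sort=False):
        g = g.sort_values("time_min")
        out.append(
            TimeCourse(
                condition=str(cond),
                concentration=float(conc),
                replicate=int(rep),
                times=g["time_min"].to_numpy(),
                signals=g["signal"].to_numpy(),
            )
        )
    return out


def write_timecourse_table(timecourses, path) -> None:
    rows = []
    for tc in timecourses:
        for t, s in zip(tc.times, tc.signals):
            rows.append(
                {"condition": tc.condition, "conc_nM": tc.concentration,
                 "time_min": t, "signal": s, "replicate": tc.replicate}
            )
    pd.DataFrame(rows, columns=TIMECOURSE_COLUMNS).to_csv(path, index=False)


def read_rate_table(path) -> pd.DataFrame:
    return _read_table(path, RATE_COLUMNS, RATE_COLUMNS[1:])


def write_rate_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=RATE_COLUMNS)


def read_saturation_table(path) -> pd.DataFrame:
    return _read_table(path, SATURATION_COLUMNS, SATURATION_COLUMNS)


def write_saturation_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=SATURATION_COLUMNS)


def read_dialysis_table(path) -> pd.DataFrame:
    return _read_table(path, DIALYSIS_COLUMNS, ["time_min", "value"])


def write_dialysis_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=DIALYSIS_COLUMNS)


def read_series_table(path) -> pd.DataFrame:
    """Per-frame trajectory series: trajectory_id, frame, time_ns and one of
    angle_deg / distance_A / state."""
    df = _read_table(path, ["trajectory_id", "frame", "time_ns"], ["frame", "time_ns"])
    value_cols = [c for c in ("angle_deg", "distance_A", "state") if c in df.columns]
    if not value_cols:
        raise SchemaError(f"{path}: expected one of angle_deg/distance_A/state columns")
    return df


def write_series_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_multiframe_pdb(path, atom_selection=None) -> FrameEnsemble:
    """Read a MODEL/ENDMDL multi-frame PDB into a FrameEnsemble.

    ``atom_selection``, if given, is a sequence of atom names to keep (in
    file order).  Atom counts must be constant across models.
    """
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure(model=None)  # AtomArrayStack; errors on ragged models
    names = np.asarray(stack.atom_name)
    if atom_selection is not None:
        mask = np.isin(names, list(atom_selection))
        if not mask.any():
            raise ValueError(f"selection {list(atom_selection)} matches no atoms")
        stack = stack[:, mask]
        names = np.asarray(stack.atom_name)
    return FrameEnsemble(
        frames=np.asarray(stack.coord, dtype=float),
        atom_names=tuple(names.tolist()),
        residue_names=tuple(np.asarray(stack.res_name).tolist()),
        residue_ids=tuple(np.asarray(stack.res_id).tolist()),
    )


def write_multiframe_pdb(ensemble: FrameEnsemble, path) -> None:
    """Write a FrameEnsemble as a multi-frame PDB (one MODEL per frame)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n_frames, n_atoms, _ = ensemble.frames.shape
    arr = struc.AtomArray(n_atoms)
    arr.atom_name = np.asarray(ensemble.atom_names)
    arr.res_name = (
        np.asarray(ensemble.residue_names)
        if ensemble.residue_names is not None
        else np.full(n_atoms, "UNK")
    )
    arr.res_id = (
        np.asarray(ensemble.residue_ids)
        if ensemble.residue_ids is not None
        else np.ones(n_atoms, dtype=int)
    )
    arr.chain_id = np.full(n_atoms, "A")
    arr.element = np.asarray([n[0] for n in np.asarray(ensemble.atom_names)])
    stack = struc.stack([arr] * n_frames)
    stack.coord = np.asarray(ensemble.frames, dtype=float)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


# -- run configuration ---------------------------------------------------------

_KNOWN_KEYS = {
    "seed", "units", "dissociation", "potency", "competition", "uptake",
    "synergy", "microdialysis", "trajectory", "analysis", "inputs", "outputs",
}


@dataclass
class RunConfig:
    """Structured run configuration: one seed, per-stage parameter blocks.

    Unknown top-level keys are rejected so that typos fail loudly.
    """

    seed: int = 0
    units: dict = field(default_factory=lambda: {"concentration": "nM", "time": "min",
                                                 "trajectory_time": "ns"})
    stages: dict = field(default_factory=dict)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text(encoding="utf-8")
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise SchemaError(f"{path}: config must be a mapping")
        unknown = set(data) - _KNOWN_KEYS
        if unknown:
            raise SchemaError(f"{path}: unknown config key(s) {sorted(unknown)}")
        seed = int(data.pop("seed", 0))
        units = data.pop("units", None) or {"concentration": "nM", "time": "min",
                                            "trajectory_time": "ns"}
        return cls(seed=seed, units=units, stages=data)

    def stage(self, name: str, default: dict | None = None) -> dict:
        return dict(self.stages.get(name, default or {}))


def write_manifest(path, subcommand: str, config: RunConfig | None, parameters: dict) -> None:
    """Write the JSON run manifest: package version, seed, resolved parameters."""
    from . import __version__

    manifest = {
        "tool": "allokin",
        "version": __version__,
        "subcommand": subcommand,
        "seed": None if config is None else config.seed,
        "parameters": parameters,
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str), encoding="utf-8")
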