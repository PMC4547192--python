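"""Result serialization: IV-curve CSV, field dumps, run records.

All CSV files carry a documented fixed column set; floats are written in
shortest round-trip representation so a read-back reproduces the values
bit for bit.  Receptor patterns serialize as semicolon-joined indices
("1;5;8").  Run metadata (config hash, seed, solver diagnostics, output
manifest) goes to a JSON run record; timestamps live only there, so the
CSV outputs of identical (config, seed) runs are byte-identical.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .experiments import IVCurve
from .solver import BiasPoint, SolutionState
from .mesh import Mesh, MAT_NAMES

IV_COLUMNS = ["bias_V", "I_D_A_per_um", "V_source_V", "V_drain_V",
              "V_bulk_V", "V_ref_V", "swept_terminal", "pH", "pattern",
              "seed"]


def encode_pattern(pattern) -> str:
    return ";".join(str(int(i)) for i in pattern)


def decode_pattern(text) -> tuple[int, ...]:
    if text is None or text == "" or (isinstance(text, float)
                                      and np.isnan(text)):
        return ()
    return tuple(int(tok) for tok in str(text).split(";"))


def iv_to_frame(curve: IVCurve) -> pd.DataFrame:
    fb = curve.fixed_biases
    n = curve.bias_values.size
    return pd.DataFrame({
        "bias_V": curve.bias_values,
        "I_D_A_per_um": curve.I_D,
        "V_source_V": np.full(n, fb.V_source),
        "V_drain_V": np.full(n, fb.V_drain),
        "V_bulk_V": np.full(n, fb.V_bulk),
        "V_ref_V": np.full(n, fb.V_ref),
        "swept_terminal": [curve.swept_terminal] * n,
        "pH": np.full(n, curve.pH),
        "pattern": [encode_pattern(curve.receptor_pattern)] * n,
        "seed": [("" if curve.seed is None else curve.seed)] * n,
    })


def write_iv_csv(curve: IVCurve, path) -> None:
    """Write an IV curve; an empty curve produces a header-only file."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    try:
        iv_to_frame(curve).to_csv(path, index=False)
    except OSError as err:
        raise OSError(f"cannot write IV curve to {path}: {err}") from err


def read_iv_csv(path) -> IVCurve:
    """Read back a curve written by :func:`write_iv_csv`."""
    df = pd.read_csv(path)
    missing = [c for c in IV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing IV columns {missing}")
    if df.empty:
        return IVCurve("drain", np.array([]), np.array([]), BiasPoint(),
                       7.0)
    fb = BiasPoint(V_source=float(df["V_source_V"].iloc[0]),
                   V_drain=float(df["V_drain_V"].iloc[0]),
                   V_bulk=float(df["V_bulk_V"].iloc[0]),
                   V_ref=float(df["V_ref_V"].iloc[0]))
    seed = df["seed"].iloc[0]
    seed = None if pd.isna(seed) or seed == "" else int(seed)
    return IVCurve(swept_terminal=str(df["swept_terminal"].iloc[0]),
                   bias_values=df["bias_V"].to_numpy(),
                   I_D=df["I_D_A_per_um"].to_numpy(),
                   fixed_biases=fb, pH=float(df["pH"].iloc[0]),
                   receptor_pattern=decode_pattern(df["pattern"].iloc[0]),
                   seed=seed)


def write_fields_csv(state: SolutionState, mesh: Mesh, path) -> None:
    """Dump the full node solution: x_um, y_um, material, psi_V, n_cm3,
    p_cm3 -- one row per mesh node."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    X, Y = np.meshgrid(mesh.x, mesh.y)
    pd.DataFrame({
        "x_um": X.ravel(),
        "y_um": Y.ravel(),
        "material": [MAT_NAMES[m] for m in mesh.node_material.ravel()],
        "psi_V": state.psi.ravel(),
        "n_cm3": state.n.ravel(),
        "p_cm3": state.p.ravel(),
    }).to_csv(path, index=False)


@dataclass
class RunRecord:
    """Metadata for one CLI run (the only place timestamps appear)."""

    config_hash: str
    seed: int | None
    experiment: str
    started_utc: str = ""
    finished_utc: str = ""
    gummel_iterations: int = 0
    worst_residual_V: float = 0.0
    manifest: list = field(default_factory=list)

    def write(self, path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        for f in self.manifest:
            if not Path(f).exists():
                raise FileNotFoundError(f"manifest entry missing: {f}")
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)
            fh.write("\n")


def utc_now() -> str:
    return time.strftime("%Y-%m-%dT%H:%M:%SZ", time.gmtime())
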