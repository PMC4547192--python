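"""Experiment drivers: I-V sweeps, pH sensitivity, receptor-charge studies.

Each driver is a pure function of (device, operating conditions, seed):
it builds the mesh, runs the continuation/Gummel solver and returns plain
tables.  Drain current is reported as ``I_D = -I(drain contact)`` so that
a conventional n-channel device under positive V_DS gives positive I_D.

Operating points: the occupancy studies run at V_DS = 100 mV with
V_REF = 0 or 1 V; the single-receptor position scan and pattern
comparisons default to V_REF = 0.5 V, a sub-threshold point where the
channel current is orders of magnitude above the numerical noise floor of
the current extraction (~1e-15 A/um) while the device is still off.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from itertools import combinations

import numpy as np
import pandas as pd

from .device import DeviceSpec, set_receptor_states, DEFAULTS
from .electrolyte import ElectrolyteSpec
from .mesh import Mesh, MeshSpec, build_mesh
from .solver import (BiasPoint, DeviceProblem, NonConvergenceError,
                     SolutionState, SolverOptions, equilibrium_solve,
                     ramp_to_bias, bias_solve)

__all__ = [
    "IVCurve", "OccupancyStudyResult", "sweep_id_vds", "sweep_id_vref",
    "extract_threshold", "ph_sensitivity", "single_receptor_scan",
    "compare_patterns", "random_combinations", "modulation_ratio",
    "channel_profile", "solve_operating_point", "SCAN_OPERATING_POINT",
    "DEFAULT_I_CRIT",
]

#: default sub-threshold operating point for position/pattern studies
SCAN_OPERATING_POINT = BiasPoint(V_drain=0.1, V_ref=0.5)

#: constant-current threshold criterion, A/um (1e-7 A/um scaled by W/L)
DEFAULT_I_CRIT = 1.0e-7 * (DEFAULTS["width_normalization"]
                           / DEFAULTS["channel_length"])


class ExtractionError(ValueError):
    """Threshold (or similar) extraction failed on the given curve."""


@dataclass
class IVCurve:
    """One swept-terminal current table."""

    swept_terminal: str
    bias_values: np.ndarray       # V, strictly monotone
    I_D: np.ndarray               # A/um width, -I(drain)
    fixed_biases: BiasPoint
    pH: float
    receptor_pattern: tuple[int, ...] = ()
    seed: int | None = None

    def __post_init__(self) -> None:
        self.bias_values = np.asarray(self.bias_values, float)
        self.I_D = np.asarray(self.I_D, float)
        if self.bias_values.shape != self.I_D.shape:
            raise ValueError("bias and current arrays differ in length")
        d = np.diff(self.bias_values)
        if d.size and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("bias_values must be strictly monotone")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            f"V_{self.swept_terminal}_V": self.bias_values,
            "I_D_A_per_um": self.I_D,
        })


@dataclass
class OccupancyStudyResult:
    """Currents of randomly sampled occupancy patterns at fixed n_on."""

    n_on: int
    patterns: list
    I_D_at_operating_point: list
    operating_point: BiasPoint
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.patterns) != len(self.I_D_at_operating_point):
            raise ValueError("one current per pattern required")
        keys = {tuple(sorted(p)) for p in self.patterns}
        if len(keys) != len(self.patterns):
            raise ValueError("patterns must be distinct")


# ---------------------------------------------------------------------------
# solver plumbing
# ---------------------------------------------------------------------------

def _problem(device: DeviceSpec, mesh_spec: MeshSpec | None) -> DeviceProblem:
    mesh = build_mesh(device, mesh_spec)
    return DeviceProblem(mesh, device.materials())


def solve_operating_point(device: DeviceSpec, operating: BiasPoint,
                          options: SolverOptions | None = None,
                          mesh_spec: MeshSpec | None = None
                          ) -> tuple[SolutionState, DeviceProblem]:
    """Continuation solve from equilibrium to ``operating``; returns the
    state and the assembled problem (for profiles/cuts)."""
    prob = _problem(device, mesh_spec)
    state = ramp_to_bias(prob, operating, options)
    return state, prob


def _drain_current(state: SolutionState) -> float:
    return -state.terminal_currents["drain"]


def _sweep(device, swept, grid, fixed: BiasPoint, options, mesh_spec,
           pH=None) -> IVCurve:
    grid = np.asarray(grid, float)
    if grid.size and np.any(np.diff(grid) <= 0):
        raise ValueError("sweep grid must be strictly increasing")
    opts = options or SolverOptions()
    prob = _problem(device, mesh_spec)

    def bias_at(v):
        kw = {"V_source": fixed.V_source, "V_drain": fixed.V_drain,
              "V_bulk": fixed.V_bulk, "V_ref": fixed.V_ref}
        kw[f"V_{swept}"] = v
        return BiasPoint(**kw)

    currents = []
    state = None
    for v in grid:
        try:
            state = ramp_to_bias(prob, bias_at(v), opts, initial=state)
        except NonConvergenceError as err:
            raise NonConvergenceError(
                f"sweep failed at {swept} = {v:.4g} V", state=err.state,
                history=err.history) from err
        currents.append(_drain_current(state))
    return IVCurve(swept_terminal=swept, bias_values=grid,
                   I_D=np.asarray(currents), fixed_biases=fixed,
                   pH=pH if pH is not None else device.electrolyte.pH,
                   receptor_pattern=tuple(
                       b.index for b in device.receptors if b.charge != 0.0))


def sweep_id_vds(device: DeviceSpec, V_ref: float, vds_grid,
                 options: SolverOptions | None = None,
                 mesh_spec: MeshSpec | None = None) -> IVCurve:
    """Output characteristic I_D(V_DS) at fixed reference-electrode bias."""
    return _sweep(device, "drain", vds_grid, BiasPoint(V_ref=V_ref),
                  options, mesh_spec)


def sweep_id_vref(device: DeviceSpec, V_ds: float, vref_grid,
                  options: SolverOptions | None = None,
                  mesh_spec: MeshSpec | None = None) -> IVCurve:
    """Transfer characteristic I_D(V_REF) at fixed drain bias."""
    return _sweep(device, "ref", vref_grid, BiasPoint(V_drain=V_ds),
                  options, mesh_spec)


def extract_threshold(curve: IVCurve, I_crit: float = DEFAULT_I_CRIT) -> float:
    """Constant-current threshold: the swept bias where |I_D| crosses
    ``I_crit``, log-linearly interpolated between the bracketing samples.

    The first upward crossing (with the sweep direction) is used; a curve
    that never reaches ``I_crit`` raises :class:`ExtractionError`.
    """
    if I_crit <= 0:
        raise ExtractionError("I_crit must be positive")
    V = curve.bias_values
    I = np.abs(curve.I_D)
    for k in range(len(V) - 1):
        lo, hi = I[k], I[k + 1]
        if lo == I_crit:
            return float(V[k])
        if (lo - I_crit) * (hi - I_crit) < 0:
            f = ((math.log(I_crit) - math.log(lo))
                 / (math.log(hi) - math.log(lo)))
            return float(V[k] + f * (V[k + 1] - V[k]))
    if I.size and I[-1] == I_crit:
        return float(V[-1])
    raise ExtractionError(
        f"I_crit = {I_crit:.3e} A/um not crossed by the curve "
        f"(range {I.min():.3e} .. {I.max():.3e})")


def ph_sensitivity(device: DeviceSpec, ph_list, V_ds: float = 2.0,
                   I_crit: float = DEFAULT_I_CRIT,
                   vref_grid=None,
                   options: SolverOptions | None = None,
                   mesh_spec: MeshSpec | None = None,
                   return_details: bool = False):
    """Threshold-voltage pH sensitivity in mV/pH.

    For each pH the electrolyte-equivalent material is regenerated (NC and
    NV from the ionic-product/Avogadro mapping), the transfer curve is
    swept at ``V_ds`` and the constant-current threshold extracted; the
    least-squares slope of threshold vs pH is returned in mV per pH unit.
    The thermodynamic ceiling is the Nernst limit (kT/q) ln10 ~ 59.6 mV/pH
    at 300 K.
    """
    phs = [float(v) for v in ph_list]
    if len(set(phs)) < 2:
        raise ValueError("need at least two distinct pH values for a slope")
    if vref_grid is None:
        vref_grid = np.arange(0.0, 1.6000001, 0.05)
    thresholds = []
    for ph in phs:
        dev = replace(device, electrolyte=replace(device.electrolyte, pH=ph))
        curve = sweep_id_vref(dev, V_ds, vref_grid, options, mesh_spec)
        thresholds.append(extract_threshold(curve, I_crit))
    slope_v_per_ph = np.polyfit(phs, thresholds, 1)[0]
    slope = 1000.0 * float(slope_v_per_ph)
    if return_details:
        return slope, pd.DataFrame({"pH": phs, "V_T_V": thresholds})
    return slope


def single_receptor_scan(device: DeviceSpec, Q_T: float,
                         operating: BiasPoint = SCAN_OPERATING_POINT,
                         options: SolverOptions | None = None,
                         mesh_spec: MeshSpec | None = None) -> pd.DataFrame:
    """I_D with exactly one charged block, for each block position, plus
    the all-neutral baseline (block = 0)."""
    if not device.receptors:
        raise ValueError("device has no receptor blocks")
    rows = []
    for idx in [0] + [b.index for b in device.receptors]:
        pattern = [] if idx == 0 else [idx]
        dev = set_receptor_states(device, pattern, Q_T)
        state, _ = solve_operating_point(dev, operating, options, mesh_spec)
        x_c = math.nan if idx == 0 else next(
            b.x_center for b in device.receptors if b.index == idx)
        rows.append({"block": idx, "x_center_um": x_c,
                     "I_D_A_per_um": _drain_current(state)})
    return pd.DataFrame(rows)


def compare_patterns(device: DeviceSpec, patterns, Q_T: float,
                     operating: BiasPoint = SCAN_OPERATING_POINT,
                     options: SolverOptions | None = None,
                     mesh_spec: MeshSpec | None = None) -> pd.DataFrame:
    """I_D for each receptor occupancy pattern at one operating point."""
    rows = []
    for pat in patterns:
        dev = set_receptor_states(device, list(pat), Q_T)
        state, _ = solve_operating_point(dev, operating, options, mesh_spec)
        rows.append({"pattern": ";".join(str(i) for i in sorted(pat)),
                     "n_on": len(pat),
                     "I_D_A_per_um": _drain_current(state)})
    return pd.DataFrame(rows)


def sample_patterns(n_blocks: int, n_on: int, n_samples: int,
                    seed: int | None) -> list[tuple[int, ...]]:
    """Uniformly sample distinct occupancy patterns without replacement.

    Deterministic in ``seed`` (numpy PCG64 generator contract); returns
    all C(n_blocks, n_on) patterns when ``n_samples`` covers them.
    """
    if not 0 <= n_on <= n_blocks:
        raise ValueError(f"n_on must be in [0, {n_blocks}]")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    total = math.comb(n_blocks, n_on)
    rng = np.random.default_rng(seed)
    if total <= 200_000:
        allpats = list(combinations(range(1, n_blocks + 1), n_on))
        if n_samples >= total:
            return allpats
        idx = rng.choice(total, size=n_samples, replace=False)
        return [allpats[i] for i in sorted(idx)]
    seen: set[tuple[int, ...]] = set()
    while len(seen) < n_samples:
        pat = tuple(sorted(rng.choice(np.arange(1, n_blocks + 1),
                                      size=n_on, replace=False)))
        seen.add(pat)
    return sorted(seen)


def random_combinations(device: DeviceSpec, n_on: int, n_samples: int,
                        seed: int | None,
                        operating: BiasPoint = BiasPoint(V_drain=0.1),
                        Q_T: float | None = None,
                        options: SolverOptions | None = None,
                        mesh_spec: MeshSpec | None = None
                        ) -> OccupancyStudyResult:
    """Randomly sampled occupancy patterns with ``n_on`` bound receptors.

    Patterns are drawn uniformly without replacement among the
    C(N, n_on) combinations; the same seed reproduces the same patterns
    and currents.
    """
    if Q_T is None:
        Q_T = DEFAULTS["charge_sign"] * DEFAULTS["Q_T"]
    pats = sample_patterns(len(device.receptors), n_on, n_samples, seed)
    table = compare_patterns(device, pats, Q_T, operating, options, mesh_spec)
    return OccupancyStudyResult(
        n_on=n_on, patterns=pats,
        I_D_at_operating_point=list(table["I_D_A_per_um"]),
        operating_point=operating, seed=seed)


def modulation_ratio(results) -> float:
    """I_Dmax/I_Dmin between the all-receptors-on and all-neutral states.

    ``results`` is an iterable of :class:`OccupancyStudyResult` that must
    include the n_on = 0 and n_on = N cases (N inferred as the largest
    n_on present).
    """
    results = list(results)
    if not results:
        raise ValueError("empty result family")
    by_n = {r.n_on: r for r in results}
    n_max = max(by_n)
    if 0 not in by_n:
        raise ValueError("family must include the all-neutral (n_on=0) case")
    i_off = max(abs(v) for v in by_n[0].I_D_at_operating_point)
    i_on = max(abs(v) for v in by_n[n_max].I_D_at_operating_point)
    if i_off == 0.0:
        raise ZeroDivisionError("baseline current is zero; ratio undefined")
    return i_on / i_off


def channel_profile(state: SolutionState, mesh: Mesh,
                    depth: float = 0.002) -> pd.DataFrame:
    """Electron density along the channel at ``depth`` um below the
    Si/SiO2 interface (y = -depth), interpolated in log density."""
    y_target = -float(depth)
    sil = np.flatnonzero(np.any(mesh.node_material == 0, axis=1))
    y_si_min = mesh.y[sil].min() if sil.size else np.inf
    if not (y_si_min - 1e-9 <= y_target <= 0.0 + 1e-12) or depth <= 0:
        raise ValueError(f"depth {depth} um is outside the silicon body")
    j = int(np.clip(np.searchsorted(mesh.y, y_target) - 1, 0, mesh.ny - 2))
    t = (y_target - mesh.y[j]) / (mesh.y[j + 1] - mesh.y[j])
    t = float(np.clip(t, 0.0, 1.0))
    logn = ((1 - t) * np.log(np.maximum(state.n[j], 1e-300))
            + t * np.log(np.maximum(state.n[j + 1], 1e-300)))
    return pd.DataFrame({"x_um": mesh.x, "n_cm3": np.exp(logn)})
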