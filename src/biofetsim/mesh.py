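"""Tensor-product finite-volume mesh over a :class:`DeviceSpec`.

Mesh lines are forced onto every material boundary (region edges, receptor
block edges, contact span ends) so each cell holds exactly one material.
Node control volumes are the usual quarter-cell boxes; carrier-bearing
volumes are tracked per material so that interface nodes (e.g. on the
Si/SiO2 line) carry silicon carriers over the silicon fraction of their
box only.  Receptor charge is spread uniformly over the block volume and
then lumped onto nodes by quarter-cell area, which conserves the total
charge exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import UM_TO_CM
from .device import DeviceSpec, GeometryError, doping_at

CARRIER_NONE, CARRIER_SI, CARRIER_ELEC = 0, 1, 2
MAT_IDS = {"silicon": 0, "oxide": 1, "electrolyte": 2, "receptor_block": 3}
MAT_NAMES = {v: k for k, v in MAT_IDS.items()}


@dataclass(frozen=True)
class MeshSpec:
    """Target spacings (um) for the graded mesh; ``scale`` multiplies all
    of them, so ``scale=0.5`` refines every direction by 2x."""

    scale: float = 1.0
    dx_sd: float = 0.25
    dx_junction: float = 0.05
    dx_channel: float = 0.06
    dx_channel_max: float = 0.13
    dy_si_bulk: float = 0.32
    dy_si_mid: float = 0.08
    dy_si_surface: float = 0.001
    dy_oxide: float = 0.006
    dy_receptor: float = 0.013
    dy_elec_surface: float = 0.012
    dy_elec_max: float = 0.35
    growth: float = 1.45

    def __post_init__(self) -> None:
        if self.scale <= 0 or self.growth <= 1.0:
            raise GeometryError("mesh scale must be > 0 and growth > 1")


def graded_segment(a: float, b: float, ha: float, hb: float,
                   hmax: float, growth: float = 1.45) -> np.ndarray:
    """Node positions on [a, b] with geometric grading from both ends.

    Spacing starts at ``ha`` near ``a`` and ``hb`` near ``b``, grows by
    ``growth`` toward the interior, capped at ``hmax``.  Spacings are
    rescaled slightly so the segment is tiled exactly.
    """
    L = b - a
    if L <= 0:
        raise GeometryError(f"empty segment [{a}, {b}]")
    hl, hr = min(ha, hmax, L), min(hb, hmax, L)
    if L <= 1.5 * min(hl, hr):
        return np.array([a, b])
    left: list[float] = []
    right: list[float] = []
    used = 0.0
    while used + max(hl, hr) < L:
        if hl <= hr:
            left.append(hl)
            used += hl
            hl = min(hl * growth, hmax)
        else:
            right.append(hr)
            used += hr
            hr = min(hr * growth, hmax)
    rem = L - used
    spac = left + [rem] + right[::-1]
    # absorb a sliver remainder into its neighbours by rescaling
    if len(spac) > 2 and rem < 0.4 * min(hl, hr):
        spac = left + right[::-1]
        spac = [s * L / used for s in spac]
    pos = a + np.concatenate([[0.0], np.cumsum(spac)])
    pos[-1] = b
    return pos


def _merge_features(vals, tol=1e-9):
    out: list[float] = []
    for v in sorted(vals):
        if not out or v - out[-1] > tol:
            out.append(v)
    return out


@dataclass
class Mesh:
    """2D tensor mesh plus the per-node fields the solver consumes."""

    x: np.ndarray                 # um, sorted
    y: np.ndarray                 # um, sorted
    cell_mat: np.ndarray          # (ny-1, nx-1) material id per cell
    node_material: np.ndarray     # (ny, nx) dominant material id per node
    carrier_system: np.ndarray    # (ny, nx) CARRIER_* per node
    doping_net: np.ndarray        # (ny, nx) cm^-3, donors positive
    fixed_charge_density: np.ndarray  # (ny, nx) C/cm^3
    area_total: np.ndarray        # (ny, nx) control volume, cm^2
    area_mat: dict                # material id -> (ny, nx) quarter-area cm^2
    contacts: dict                # name -> bool (ny, nx)
    width_cm: float

    @property
    def nx(self) -> int:
        return self.x.size

    @property
    def ny(self) -> int:
        return self.y.size

    @property
    def n_nodes(self) -> int:
        return self.x.size * self.y.size

    @property
    def x_cm(self) -> np.ndarray:
        return self.x * UM_TO_CM

    @property
    def y_cm(self) -> np.ndarray:
        return self.y * UM_TO_CM

    def fixed_charge_integral(self) -> float:
        """Integral of the fixed charge density over the device, C/cm
        (i.e. total receptor charge divided by the out-of-plane width)."""
        a_rec = self.area_mat.get(MAT_IDS["receptor_block"])
        if a_rec is None:
            return 0.0
        return float(np.sum(self.fixed_charge_density * a_rec))

    def to_frame(self):
        """Node table (x_um, y_um, material, doping_cm3, fixed_charge_Ccm3)."""
        import pandas as pd
        X, Y = np.meshgrid(self.x, self.y)
        return pd.DataFrame({
            "x_um": X.ravel(), "y_um": Y.ravel(),
            "material": [MAT_NAMES[m] for m in self.node_material.ravel()],
            "doping_cm3": self.doping_net.ravel(),
            "fixed_charge_C_per_cm3": self.fixed_charge_density.ravel(),
        })


def _x_features(device: DeviceSpec, spec: MeshSpec):
    bx0, bx1, _, _ = device.bounding_box
    s = spec.scale
    feats = {bx0: spec.dx_sd * s, bx1: spec.dx_sd * s}

    def add(x, h):
        feats[x] = min(feats.get(x, np.inf), h)

    for r in device.regions:
        if r.overlay:  # implant windows: refine at the junction edge
            for xe in (r.rect[0], r.rect[1]):
                if bx0 < xe < bx1:
                    add(xe, spec.dx_junction * s)
    for b in device.receptors:
        add(b.x0, spec.dx_channel * s)
        add(b.x1, spec.dx_channel * s)
    for c in device.contacts:
        if c.side in ("top", "bottom"):
            for xe in c.span:
                if bx0 < xe < bx1:
                    add(xe, spec.dx_junction * s)
    return feats


def _y_features(device: DeviceSpec, spec: MeshSpec):
    _, _, by0, by1 = device.bounding_box
    sx0, sx1, sy0, sy1 = device.bounds_of("silicon")
    ox0, ox1, oy0, oy1 = device.bounds_of("oxide")
    s = spec.scale
    feats = {by0: spec.dy_si_bulk * s, by1: spec.dy_elec_max * s}

    def add(y, h):
        feats[y] = min(feats.get(y, np.inf), h)

    add(sy1, spec.dy_si_surface * s)        # Si/SiO2 interface
    add(oy1, spec.dy_elec_surface * s)      # oxide/electrolyte surface
    for r in device.regions:
        if r.overlay:                       # junction depth
            add(r.rect[2], spec.dy_si_mid * s)
    for b in device.receptors:
        add(oy1 + b.standoff, spec.dy_receptor * s)
        add(oy1 + b.standoff + b.thickness, spec.dy_receptor * s)
    for c in device.contacts:
        if c.side in ("left", "right"):
            for ye in c.span:
                if by0 < ye < by1:
                    add(ye, spec.dy_si_mid * s)
    return feats


def _grade_axis(feats: dict, hmax_fn, growth: float) -> np.ndarray:
    keys = _merge_features(feats)
    segs = []
    for a, b in zip(keys, keys[1:]):
        hmax = hmax_fn(0.5 * (a + b))
        seg = graded_segment(a, b, feats[a], feats[b], hmax, growth)
        segs.append(seg[:-1])
    segs.append(np.array([keys[-1]]))
    return np.concatenate(segs)


def build_mesh(device: DeviceSpec, refinement: MeshSpec | None = None) -> Mesh:
    """Build the finite-volume mesh for a device."""
    spec = refinement or MeshSpec()
    s = spec.scale
    bx0, bx1, by0, by1 = device.bounding_box
    _, _, _, oy1 = device.bounds_of("oxide")
    _, _, sy0, sy1 = device.bounds_of("silicon")

    if device.receptors:
        ch0 = min(b.x0 for b in device.receptors)
        ch1 = max(b.x1 for b in device.receptors)
    else:
        ovl = [r for r in device.regions if r.overlay]
        ch0 = min((r.rect[1] for r in ovl), default=bx0)
        ch1 = max((r.rect[0] for r in ovl), default=bx1)

    def hmax_x(xm):
        return (spec.dx_channel_max if ch0 <= xm <= ch1 else spec.dx_sd) * s

    def hmax_y(ym):
        if ym < sy1:
            return spec.dy_si_bulk * s
        if ym < oy1:
            return spec.dy_oxide * s
        return spec.dy_elec_max * s

    x = _grade_axis(_x_features(device, spec), hmax_x, spec.growth)
    y = _grade_axis(_y_features(device, spec), hmax_y, spec.growth)
    nx, ny = x.size, y.size
    if nx < 3 or ny < 3:
        raise GeometryError("mesh degenerate: fewer than 3 lines per axis")

    xc = 0.5 * (x[:-1] + x[1:])
    yc = 0.5 * (y[:-1] + y[1:])
    cell_mat = np.empty((ny - 1, nx - 1), dtype=np.int8)
    for j, ycj in enumerate(yc):
        for i, xci in enumerate(xc):
            cell_mat[j, i] = MAT_IDS[device.material_at(xci, ycj)]

    # quarter-cell areas (cm^2) per node, split by material
    dx_cm = np.diff(x) * UM_TO_CM
    dy_cm = np.diff(y) * UM_TO_CM
    cell_area = np.outer(dy_cm, dx_cm)
    area_mat = {m: np.zeros((ny, nx)) for m in MAT_IDS.values()}
    for m, arr in area_mat.items():
        q = 0.25 * cell_area * (cell_mat == m)
        arr[:-1, :-1] += q
        arr[:-1, 1:] += q
        arr[1:, :-1] += q
        arr[1:, 1:] += q
    area_total = sum(area_mat.values())

    # node material: silicon > electrolyte > receptor > oxide priority
    node_material = np.full((ny, nx), MAT_IDS["oxide"], dtype=np.int8)
    for m in (MAT_IDS["receptor_block"], MAT_IDS["electrolyte"],
              MAT_IDS["silicon"]):
        node_material[area_mat[m] > 0] = m

    carrier = np.full((ny, nx), CARRIER_NONE, dtype=np.int8)
    has_si = area_mat[MAT_IDS["silicon"]] > 0
    has_el = area_mat[MAT_IDS["electrolyte"]] > 0
    if np.any(has_si & has_el):
        raise GeometryError("silicon and electrolyte regions touch; an "
                            "insulator must separate the carrier systems")
    carrier[has_si] = CARRIER_SI
    carrier[has_el] = CARRIER_ELEC

    # net doping, evaluated at silicon nodes
    doping = np.zeros((ny, nx))
    sx0, sx1, _, _ = device.bounds_of("silicon")
    for j in range(ny):
        if y[j] > sy1 + 1e-12:
            continue
        for i in range(nx):
            if has_si[j, i]:
                doping[j, i] = doping_at(device,
                                         float(np.clip(x[i], sx0, sx1)),
                                         float(np.clip(y[j], sy0, sy1)))

    # receptor fixed charge: uniform volume density per block, lumped by
    # quarter-cell area so the integral is conserved exactly
    width_cm = device.width_normalization * UM_TO_CM
    rho_nodes = np.zeros((ny, nx))  # accumulated C/cm (area-weighted)
    for b in device.receptors:
        if b.charge == 0.0:
            continue
        yb0 = oy1 + b.standoff
        yb1 = yb0 + b.thickness
        vol_cm3 = (b.length * UM_TO_CM) * (b.thickness * UM_TO_CM) * width_cm
        rho = b.charge / vol_cm3     # C/cm^3
        in_x = (xc >= b.x0 - 1e-12) & (xc <= b.x1 + 1e-12)
        in_y = (yc >= yb0 - 1e-12) & (yc <= yb1 + 1e-12)
        cells = np.outer(in_y, in_x) & (cell_mat == MAT_IDS["receptor_block"])
        q = 0.25 * cell_area * cells * rho
        rho_nodes[:-1, :-1] += q
        rho_nodes[:-1, 1:] += q
        rho_nodes[1:, :-1] += q
        rho_nodes[1:, 1:] += q
    a_rec = area_mat[MAT_IDS["receptor_block"]]
    fixed_density = np.divide(rho_nodes, a_rec,
                              out=np.zeros_like(rho_nodes), where=a_rec > 0)

    contacts = {}
    for c in device.contacts:
        mask = np.zeros((ny, nx), dtype=bool)
        lo, hi = min(c.span), max(c.span)
        if c.side == "left":
            sel = (y >= lo - 1e-9) & (y <= hi + 1e-9)
            mask[sel, 0] = True
        elif c.side == "right":
            sel = (y >= lo - 1e-9) & (y <= hi + 1e-9)
            mask[sel, -1] = True
        elif c.side == "bottom":
            sel = (x >= lo - 1e-9) & (x <= hi + 1e-9)
            mask[0, sel] = True
        elif c.side == "top":
            sel = (x >= lo - 1e-9) & (x <= hi + 1e-9)
            mask[-1, sel] = True
        else:
            raise GeometryError(f"contact {c.name}: unknown side {c.side!r}")
        if not mask.any():
            raise GeometryError(f"contact {c.name} matches no boundary nodes")
        contacts[c.name] = mask

    return Mesh(x=x, y=y, cell_mat=cell_mat, node_material=node_material,
                carrier_system=carrier, doping_net=doping,
                fixed_charge_density=fixed_density, area_total=area_total,
                area_mat=area_mat, contacts=contacts, width_cm=width_cm)
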