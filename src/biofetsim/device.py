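"""ISFET/BioFET device description: regions, doping, contacts, receptors.

Coordinate convention: x runs laterally (source at low x), y vertically
with y = 0 at the Si/SiO2 interface and y > 0 pointing into the
electrolyte.  All geometry is in um; the mesh converts to cm.

The reference device is a planar ISFET: p-type substrate, n+ source/drain
implant windows with Gaussian tails, a thin gate oxide, and an electrolyte
column contacted on top by an ideal reference electrode.  The BioFET
variant adds a row of receptor blocks -- thin dielectric bricks sitting on
the oxide inside the electrolyte -- each of which carries a fixed charge
Q_T once its receptor has bound a target molecule and zero charge before.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from .constants import UM_TO_CM
from .electrolyte import ElectrolyteSpec, SemiconductorParams, build_electrolyte_material
from . import materials as mat

MATERIALS = ("silicon", "oxide", "electrolyte", "receptor_block")


class GeometryError(ValueError):
    """Inconsistent or degenerate device geometry."""


class PatternError(ValueError):
    """Invalid receptor occupancy pattern."""


@dataclass(frozen=True)
class Region:
    """An axis-aligned rectangular material region.

    ``overlay`` regions only contribute doping (implant windows) and do not
    participate in material tagging; base regions must not overlap.
    """

    name: str
    rect: tuple[float, float, float, float]  # (x0, x1, y0, y1) um
    material: str
    doping_type: str = "none"          # donor | acceptor | none
    doping_peak: float = 0.0           # cm^-3
    doping_profile: str = "uniform"    # uniform | gaussian
    profile_params: dict = field(default_factory=dict)  # sigma_x/sigma_y um
    overlay: bool = False

    def __post_init__(self) -> None:
        x0, x1, y0, y1 = self.rect
        if not (x0 < x1 and y0 < y1):
            raise GeometryError(f"region {self.name}: degenerate rect {self.rect}")
        if self.material not in MATERIALS:
            raise GeometryError(f"region {self.name}: unknown material "
                                f"{self.material!r}")
        if self.doping_type not in ("donor", "acceptor", "none"):
            raise GeometryError(f"region {self.name}: bad doping_type")

    def contains(self, x: float, y: float) -> bool:
        x0, x1, y0, y1 = self.rect
        return x0 <= x <= x1 and y0 <= y <= y1


@dataclass(frozen=True)
class ReceptorBlock:
    """One receptor site: a dielectric brick above the oxide.

    ``charge`` is the total fixed charge in C held by the block (0 when the
    receptor is unbound, +/-Q_T when a target is captured); it is spread
    uniformly over the block volume when the mesh is built.
    """

    index: int
    x_center: float
    length: float = 0.5
    thickness: float = 0.05
    standoff: float = 0.0
    charge: float = 0.0
    eps_r: float = 2.5

    @property
    def x0(self) -> float:
        return self.x_center - self.length / 2.0

    @property
    def x1(self) -> float:
        return self.x_center + self.length / 2.0


@dataclass(frozen=True)
class Contact:
    """A named Dirichlet boundary segment.

    ``side`` is one of left/right/bottom/top; ``span`` the coordinate
    interval (y for lateral sides, x for horizontal sides) in um.
    """

    name: str
    side: str
    span: tuple[float, float]


@dataclass(frozen=True)
class DeviceSpec:
    regions: tuple[Region, ...]
    receptors: tuple[ReceptorBlock, ...]
    contacts: tuple[Contact, ...]
    electrolyte: ElectrolyteSpec
    oxide_thickness: float = 0.025       # um
    width_normalization: float = 1.0     # um, out-of-plane width
    receptor_eps_r: float = 2.5

    def __post_init__(self) -> None:
        names = [c.name for c in self.contacts]
        if "reference" not in names:
            raise GeometryError("device needs a reference contact")
        # receptor blocks must not overlap and must sit inside the electrolyte
        blocks = sorted(self.receptors, key=lambda b: b.x_center)
        for a, b in zip(blocks, blocks[1:]):
            if b.x0 < a.x1 - 1e-12:
                raise GeometryError(
                    f"receptor blocks {a.index} and {b.index} overlap")
        if not blocks:
            return
        ex0, ex1, ey0, ey1 = self.bounds_of("electrolyte")
        for b in blocks:
            if b.x0 < ex0 - 1e-9 or b.x1 > ex1 + 1e-9:
                raise GeometryError(f"receptor block {b.index} outside the "
                                    "electrolyte laterally")
            if b.standoff < -1e-12 or ey0 + b.standoff + b.thickness > ey1:
                raise GeometryError(f"receptor block {b.index} outside the "
                                    "electrolyte vertically")

    # -- geometry helpers -------------------------------------------------
    def bounds_of(self, material: str) -> tuple[float, float, float, float]:
        rects = [r.rect for r in self.regions
                 if r.material == material and not r.overlay]
        if not rects:
            raise GeometryError(f"no region of material {material!r}")
        return (min(r[0] for r in rects), max(r[1] for r in rects),
                min(r[2] for r in rects), max(r[3] for r in rects))

    @property
    def bounding_box(self) -> tuple[float, float, float, float]:
        rects = [r.rect for r in self.regions if not r.overlay]
        return (min(r[0] for r in rects), max(r[1] for r in rects),
                min(r[2] for r in rects), max(r[3] for r in rects))

    def material_at(self, x: float, y: float) -> str:
        """Material at a point; receptor blocks shadow the electrolyte."""
        _, _, _, oy1 = self.bounds_of("oxide")
        for b in self.receptors:
            y0 = oy1 + b.standoff
            if b.x0 <= x <= b.x1 and y0 <= y <= y0 + b.thickness:
                return "receptor_block"
        for r in self.regions:
            if not r.overlay and r.contains(x, y):
                return r.material
        raise GeometryError(f"point ({x}, {y}) um outside the device")

    def materials(self) -> dict[str, SemiconductorParams]:
        """Material name -> solver parameter set for this device."""
        elec = build_electrolyte_material(self.electrolyte)
        return {
            "silicon": mat.silicon(T=self.electrolyte.T),
            "oxide": mat.oxide(T=self.electrolyte.T),
            "electrolyte": elec,
            "receptor_block": mat.receptor_dielectric(
                self.receptor_eps_r, T=self.electrolyte.T),
        }

    def total_receptor_charge(self) -> float:
        """Sum of the fixed charges on all blocks (C)."""
        return sum(b.charge for b in self.receptors)


# -- default reference device ---------------------------------------------

# Geometry calibration of the reference device (all um / cm^-3).  The
# ten 0.5-um receptor blocks define the segmented-gate layout; the rest
# are the package's planar-ISFET calibration choices and are configurable.
DEFAULTS = dict(
    channel_length=5.0,
    sd_window=1.0,          # source/drain implant window length
    substrate_depth=2.0,
    oxide_thickness=0.025,
    electrolyte_height=2.0,
    junction_depth=0.5,
    lateral_straggle=0.1,
    nd_peak=1.0e19,
    na_substrate=1.0e15,
    receptor_length=0.5,
    receptor_thickness=0.05,
    receptor_eps_r=2.5,
    width_normalization=1.0,
    Q_T=4.8e-16,            # |fixed charge| per bound receptor, C
    charge_sign=+1.0,       # + attracts channel electrons (turn-on)
)


def default_isfet_device(n_receptors: int = 10, pH: float = 7.0,
                         **overrides) -> DeviceSpec:
    """Build the reference ISFET/BioFET.

    ``n_receptors`` 0.5-um blocks tile the channel span (10 blocks exactly
    tile the 5 um channel); ``n_receptors = 0`` gives the plain ISFET.  All
    blocks start neutral.  ``overrides`` patch the DEFAULTS table.
    """
    if n_receptors < 0:
        raise GeometryError("n_receptors must be >= 0")
    g = dict(DEFAULTS)
    unknown = set(overrides) - set(g)
    if unknown:
        raise GeometryError(f"unknown geometry overrides: {sorted(unknown)}")
    g.update(overrides)

    L = g["channel_length"]
    w = g["sd_window"]
    x_total = L + 2 * w
    tox = g["oxide_thickness"]
    dsub = g["substrate_depth"]
    helec = g["electrolyte_height"]
    # vertical Gaussian sigma so the metallurgical junction sits at the
    # requested depth: N_D(yj) = N_A
    sig_y = g["junction_depth"] / math.sqrt(
        math.log(g["nd_peak"] / g["na_substrate"]))
    sig_x = g["lateral_straggle"]

    regions = (
        Region("substrate", (0.0, x_total, -dsub, 0.0), "silicon",
               "acceptor", g["na_substrate"], "uniform"),
        Region("gate_oxide", (0.0, x_total, 0.0, tox), "oxide"),
        Region("solution", (0.0, x_total, tox, tox + helec), "electrolyte"),
        Region("source_implant", (0.0, w, -g["junction_depth"], 0.0),
               "silicon", "donor", g["nd_peak"], "gaussian",
               {"sigma_x": sig_x, "sigma_y": sig_y,
                "window": (0.0, w)}, overlay=True),
        Region("drain_implant", (x_total - w, x_total,
                                 -g["junction_depth"], 0.0),
               "silicon", "donor", g["nd_peak"], "gaussian",
               {"sigma_x": sig_x, "sigma_y": sig_y,
                "window": (x_total - w, x_total)}, overlay=True),
    )
    lb = g["receptor_length"]
    blocks = tuple(
        ReceptorBlock(index=i + 1,
                      x_center=w + (i + 0.5) * lb,
                      length=lb,
                      thickness=g["receptor_thickness"],
                      standoff=0.0,
                      charge=0.0,
                      eps_r=g["receptor_eps_r"])
        for i in range(n_receptors))
    # source/drain contacts stop short of the metallurgical junction:
    # an ohmic boundary reaching into the space-charge region would pin
    # near-intrinsic densities there and act as a parasitic carrier sink
    d_contact = 0.7 * g["junction_depth"]
    contacts = (
        Contact("source", "left", (-d_contact, 0.0)),
        Contact("drain", "right", (-d_contact, 0.0)),
        Contact("bulk", "bottom", (0.0, x_total)),
        Contact("reference", "top", (0.0, x_total)),
    )
    return DeviceSpec(
        regions=regions,
        receptors=blocks,
        contacts=contacts,
        electrolyte=ElectrolyteSpec(pH=pH),
        oxide_thickness=tox,
        width_normalization=g["width_normalization"],
        receptor_eps_r=g["receptor_eps_r"],
    )


def set_receptor_states(device: DeviceSpec, pattern: list[int] | tuple[int, ...],
                        Q_T: float) -> DeviceSpec:
    """Return a copy of ``device`` with the listed blocks charged.

    ``pattern`` holds 1-based block indices (C1 at the source end); listed
    blocks get charge ``Q_T`` (signed), all others 0.  Pure function.
    """
    valid = {b.index for b in device.receptors}
    pat = list(pattern)
    if len(set(pat)) != len(pat):
        raise PatternError(f"duplicate indices in pattern {pat}")
    bad = set(pat) - valid
    if bad:
        raise PatternError(f"pattern indices {sorted(bad)} out of range "
                           f"(valid: {sorted(valid)})")
    on = set(pat)
    new_blocks = tuple(
        replace(b, charge=Q_T if b.index in on else 0.0)
        for b in device.receptors)
    return replace(device, receptors=new_blocks)


def doping_at(device: DeviceSpec, x: float, y: float) -> float:
    """Net doping (cm^-3, donors positive) at a point in the silicon.

    Implant windows decay as Gaussians vertically from the surface and
    laterally beyond the window edges (lateral out-diffusion), on top of
    the uniform substrate acceptor background.
    """
    x0, x1, y0, y1 = device.bounds_of("silicon")
    if not (x0 <= x <= x1 and y0 <= y <= y1):
        raise GeometryError(f"point ({x}, {y}) um outside the silicon")
    net = 0.0
    for r in device.regions:
        if r.material != "silicon" or r.doping_type == "none":
            continue
        if r.doping_profile == "uniform":
            val = r.doping_peak if r.contains(x, y) else 0.0
        else:
            wx0, wx1 = r.profile_params["window"]
            sig_x = r.profile_params["sigma_x"]
            sig_y = r.profile_params["sigma_y"]
            dx = 0.0 if wx0 <= x <= wx1 else min(abs(x - wx0), abs(x - wx1))
            dy = abs(y)   # implant from the y = 0 surface
            val = r.doping_peak * math.exp(-(dx / sig_x) ** 2
                                           - (dy / sig_y) ** 2)
        net += val if r.doping_type == "donor" else -val
    return net
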