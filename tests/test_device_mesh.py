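"""Device geometry, doping profiles, receptor bookkeeping and meshing."""

import math

import numpy as np
import pytest

from biofetsim.constants import UM_TO_CM
from biofetsim.device import (GeometryError, PatternError,
                              default_isfet_device, doping_at,
                              set_receptor_states)
from biofetsim.mesh import MeshSpec, build_mesh


class TestDefaultDevice:
    def test_blocks_tile_channel(self, device10):
        blocks = sorted(device10.receptors, key=lambda b: b.index)
        assert len(blocks) == 10
        assert blocks[0].x0 == pytest.approx(1.0)
        assert blocks[-1].x1 == pytest.approx(6.0)
        for a, b in zip(blocks, blocks[1:]):
            assert a.x1 == pytest.approx(b.x0)
        assert all(b.length == 0.5 for b in blocks)
        assert all(b.charge == 0.0 for b in blocks)

    def test_plain_isfet(self):
        dev = default_isfet_device(0, 7.0)
        assert dev.receptors == ()
        assert {c.name for c in dev.contacts} == {
            "source", "drain", "bulk", "reference"}

    def test_material_stack(self, device10):
        assert device10.material_at(3.5, -1.0) == "silicon"
        assert device10.material_at(3.5, 0.01) == "oxide"
        assert device10.material_at(3.5, 0.05) == "receptor_block"
        assert device10.material_at(3.5, 1.0) == "electrolyte"
        assert device10.material_at(0.5, 0.05) == "electrolyte"  # no block
        with pytest.raises(GeometryError):
            device10.material_at(100.0, 0.0)

    def test_unknown_override_rejected(self):
        with pytest.raises(GeometryError):
            default_isfet_device(10, 7.0, not_a_knob=1.0)


class TestReceptorStates:
    def test_assignment_and_purity(self, device10):
        q = -4.8e-16
        dev = set_receptor_states(device10, [1, 5, 8], q)
        charged = {b.index for b in dev.receptors if b.charge == q}
        assert charged == {1, 5, 8}
        assert all(b.charge == 0.0 for b in device10.receptors)  # pure

    def test_all_on_additivity(self, device10):
        q = 4.8e-16
        dev = set_receptor_states(device10, list(range(1, 11)), q)
        assert dev.total_receptor_charge() == pytest.approx(10 * q)

    def test_empty_pattern_resets(self, device10):
        dev = set_receptor_states(device10, [3], 1e-16)
        dev = set_receptor_states(dev, [], 1e-16)
        assert dev.total_receptor_charge() == 0.0

    def test_pattern_errors(self, device10):
        with pytest.raises(PatternError):
            set_receptor_states(device10, [1, 1], 1e-16)
        with pytest.raises(PatternError):
            set_receptor_states(device10, [0], 1e-16)
        with pytest.raises(PatternError):
            set_receptor_states(device10, [11], 1e-16)


class TestDoping:
    def test_substrate_background(self, device10):
        assert doping_at(device10, 3.5, -1.8) == pytest.approx(-1e15)

    def test_source_peak(self, device10):
        # donor peak minus the substrate acceptor background
        assert doping_at(device10, 0.5, 0.0) == pytest.approx(1e19 - 1e15,
                                                              rel=1e-9)

    def test_lateral_gaussian_decay(self, device10):
        # one straggle length beyond the window edge: factor exp(-1)
        edge, sigma = 1.0, 0.1
        inside = doping_at(device10, edge - 1e-9, 0.0)
        outside = doping_at(device10, edge + sigma, 0.0)
        donors_in = inside + 1e15
        donors_out = outside + 1e15
        assert donors_out / donors_in == pytest.approx(math.exp(-1), rel=1e-6)

    def test_metallurgical_junction_depth(self, device10):
        # net doping changes sign at the configured junction depth
        assert doping_at(device10, 0.5, -0.49) > 0
        assert doping_at(device10, 0.5, -0.51) < 0

    def test_outside_silicon(self, device10):
        with pytest.raises(GeometryError):
            doping_at(device10, 3.5, 1.0)


class TestMesh:
    def test_cells_have_single_material(self, problem10):
        mesh = problem10.mesh
        assert mesh.cell_mat.shape == (mesh.ny - 1, mesh.nx - 1)
        assert set(np.unique(mesh.cell_mat)) <= {0, 1, 2, 3}

    def test_control_volumes_tile_device(self, device10, problem10):
        mesh = problem10.mesh
        x0, x1, y0, y1 = device10.bounding_box
        area = (x1 - x0) * (y1 - y0) * UM_TO_CM ** 2
        assert mesh.area_total.sum() == pytest.approx(area, rel=1e-12)

    def test_carrier_systems_disjoint(self, problem10):
        # no node may carry both silicon and electrolyte carriers
        assert problem10.is_carrier.sum() > 0

    @pytest.mark.parametrize("pattern", [[1], [2, 5, 8], list(range(1, 11))])
    def test_fixed_charge_integral(self, device10, pattern):
        q = -4.8e-16
        dev = set_receptor_states(device10, pattern, q)
        mesh = build_mesh(dev)
        width_cm = dev.width_normalization * UM_TO_CM
        expected = len(pattern) * q / width_cm
        assert mesh.fixed_charge_integral() == pytest.approx(expected,
                                                             rel=1e-9)

    def test_refinement_preserves_charge_and_grows(self, device10):
        dev = set_receptor_states(device10, [2, 7], 4.8e-16)
        coarse = build_mesh(dev, MeshSpec())
        fine = build_mesh(dev, MeshSpec(scale=0.5))
        assert fine.n_nodes > 2 * coarse.n_nodes
        assert fine.fixed_charge_integral() == pytest.approx(
            coarse.fixed_charge_integral(), rel=1e-9)

    def test_contacts_resolved(self, problem10):
        for name, mask in problem10.mesh.contacts.items():
            assert mask.any(), name

    def test_node_table(self, problem10):
        df = problem10.mesh.to_frame()
        assert len(df) == problem10.mesh.n_nodes
        assert {"x_um", "y_um", "material", "doping_cm3",
                "fixed_charge_C_per_cm3"} <= set(df.columns)
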