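"""Synthetic morphologies: areas, tree structure, opsin distribution, SWC."""

import numpy as np
import pytest

from optoca1 import morphology as M
from optoca1.morphology import (Morphology, Section, align_somatodendritic_axis,
                                distribute_opsin, generate_interneuron,
                                generate_pyramidal, region_area)


def _cylinder_cell(length=100.0, diam=2.0, region="soma"):
    sec = Section(region, np.array([[0, 0, 0], [0, 0, length]], float),
                  np.array([diam, diam]))
    return Morphology([sec])


class TestAreas:
    def test_cylinder_lateral_area(self):
        m = _cylinder_cell(100.0, 2.0)
        assert region_area(m, "soma") == pytest.approx(np.pi * 2.0 * 100.0,
                                                       rel=1e-9)

    def test_partition_identities(self, small_pyr):
        a_basal = region_area(small_pyr, "basal")
        a_apic = region_area(small_pyr, "apic")
        assert region_area(small_pyr, "dend") == pytest.approx(
            a_basal + a_apic, rel=1e-12)
        assert region_area(small_pyr, "allsec") == pytest.approx(
            region_area(small_pyr, "dend") + region_area(small_pyr, "soma")
            + region_area(small_pyr, "axon"), rel=1e-12)

    def test_unknown_region(self, small_pyr):
        with pytest.raises(KeyError):
            region_area(small_pyr, "spine")


class TestPyramidalGenerator:
    def test_soma_area_in_reference_band(self):
        m = generate_pyramidal(seed=1)
        assert 400.0 <= region_area(m, "soma") <= 1400.0

    def test_region_areas_near_reference_ranges(self):
        m = generate_pyramidal(seed=1)
        # within +-50% of the reconstructed-cell bands
        assert 0.5 * 5930 <= region_area(m, "basal") <= 1.5 * 10671
        assert 0.5 * 13632 <= region_area(m, "apic") <= 1.5 * 14787
        assert 0.5 * 1051 <= region_area(m, "axon") <= 1.5 * 1641

    def test_apical_up_basal_down(self):
        seg = generate_pyramidal(seed=2).segments()
        assert seg.centroid[seg.region == "apic"][:, 2].mean() > 0
        assert seg.centroid[seg.region == "basal"][:, 2].mean() < 0

    def test_seed_determinism(self):
        a = generate_pyramidal(seed=3).segments()
        b = generate_pyramidal(seed=3).segments()
        assert np.array_equal(a.centroid, b.centroid)
        assert np.array_equal(a.area, b.area)

    def test_tree_is_topologically_ordered(self, small_pyr):
        parent = small_pyr.segments().parent
        assert parent[0] == -1
        assert np.all(parent[1:] < np.arange(1, len(parent)))
        assert np.sum(parent == -1) == 1  # single root

    def test_no_basal_branches_errors_informatively(self):
        m = generate_pyramidal(M.PyramidalParams(n_basal=0), seed=1)
        with pytest.raises(KeyError, match="basal"):
            region_area(m, "basal")


class TestInterneuronGenerator:
    def test_bistratified_axon_dominates(self):
        m = generate_interneuron("bistratified", seed=1)
        assert region_area(m, "axon") > region_area(m, "dend")
        assert 2.5e4 <= region_area(m, "axon") <= 1.1e5

    def test_basket_axon_smaller_than_bistratified(self):
        basket = generate_interneuron("basket", seed=1)
        bistrat = generate_interneuron("bistratified", seed=1)
        a_basket = region_area(basket, "axon")
        assert a_basket < region_area(bistrat, "axon")
        assert 2.5e4 * 0.5 <= a_basket <= 1.1e5
        # reconstructed basket cells carry axon and dendrite areas of the
        # same order (axon slightly larger)
        assert a_basket < 2.0 * region_area(basket, "dend")

    def test_no_basal_apic_split(self):
        m = generate_interneuron("basket", seed=1)
        assert m.regions == {"soma", "axon", "dend"}
        with pytest.raises(KeyError):
            region_area(m, "apic")

    def test_unknown_preset(self):
        with pytest.raises(ValueError):
            generate_interneuron("chandelier", seed=1)


class TestOpsinDistribution:
    def test_conductance_conservation(self, small_pyr):
        seg = small_pyr.segments()
        for region in ("soma", "basal", "dend", "allsec"):
            g = distribute_opsin(small_pyr, region, 2.5)
            total_us = np.sum(g * seg.area * 1e-8) * 1e6
            assert total_us == pytest.approx(2.5, rel=1e-9)

    def test_specific_conductance_from_reference_soma_area(self):
        # soma cylinder sized to 699.46 um^2: 1 uS spreads to ~0.143 S/cm^2
        diam = 15.0
        length = 699.46 / (np.pi * diam)
        m = _cylinder_cell(length, diam)
        g = distribute_opsin(m, "soma", 1.0)
        assert g.max() == pytest.approx(0.143, abs=0.001)

    def test_confinement_raises_local_density(self, small_pyr):
        g_soma = distribute_opsin(small_pyr, "soma", 1.0).max()
        g_all = distribute_opsin(small_pyr, "allsec", 1.0).max()
        assert g_soma > g_all

    def test_allsec_everywhere_nonzero(self, small_pyr):
        assert np.all(distribute_opsin(small_pyr, "allsec", 1.0) > 0)

    def test_invalid_inputs(self, small_pyr):
        with pytest.raises(ValueError):
            distribute_opsin(small_pyr, "soma", 0.0)
        with pytest.raises((KeyError, ValueError)):
            distribute_opsin(small_pyr, "spine", 1.0)


class TestAlignment:
    def test_removes_soma_offset(self, small_pyr):
        shifted = Morphology(
            [Section(s.region, s.points + np.array([10.0, 20.0, 30.0]),
                     s.diams.copy(), s.parent) for s in small_pyr.sections],
            max_seg_len=small_pyr.max_seg_len)
        aligned = align_somatodendritic_axis(shifted)
        seg = aligned.segments()
        soma_c = seg.centroid[seg.region == "soma"].mean(axis=0)
        assert np.allclose(soma_c, 0.0, atol=1e-9)

    def test_recovers_random_rotation(self, small_pyr, rng):
        # rotate by a random rotation; re-alignment must restore the
        # somato-dendritic axis onto z with apical mass up
        from scipy.spatial.transform import Rotation

        rot = Rotation.random(rng=rng).as_matrix()
        rotated = Morphology(
            [Section(s.region, s.points @ rot.T, s.diams.copy(), s.parent)
             for s in small_pyr.sections],
            max_seg_len=small_pyr.max_seg_len)
        aligned = align_somatodendritic_axis(rotated)
        seg = aligned.segments()
        non_axon = seg.centroid[seg.region != "axon"]
        centered = non_axon - non_axon.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        assert abs(vt[0] @ np.array([0.0, 0.0, 1.0])) > 0.999
        assert seg.centroid[seg.region == "apic"][:, 2].mean() > 0
        # areas are rotation invariant
        assert region_area(aligned, "allsec") == pytest.approx(
            region_area(small_pyr, "allsec"), rel=1e-9)

    def test_alignment_is_idempotent_up_to_roll(self, small_pyr):
        once = align_somatodendritic_axis(small_pyr)
        twice = align_somatodendritic_axis(once)
        z1 = once.segments().centroid[:, 2]
        z2 = twice.segments().centroid[:, 2]
        r1 = np.hypot(*once.segments().centroid[:, :2].T)
        r2 = np.hypot(*twice.segments().centroid[:, :2].T)
        assert np.allclose(z1, z2, atol=1e-6)
        assert np.allclose(r1, r2, atol=1e-6)

    def test_degenerate_geometry_rejected(self):
        m = _cylinder_cell(10.0, 10.0)
        with pytest.raises(ValueError):
            align_somatodendritic_axis(m)


class TestSWC:
    def test_roundtrip_preserves_areas(self, small_pyr, tmp_path):
        path = tmp_path / "cell.swc"
        M.write_swc(small_pyr, path)
        back = M.read_swc(path, max_seg_len=small_pyr.max_seg_len)
        for region in ("soma", "axon", "basal", "apic"):
            assert region_area(back, region) == pytest.approx(
                region_area(small_pyr, region), rel=0.05)

    def test_interneuron_import_collapses_dendrites(self, small_pyr,
                                                    tmp_path):
        path = tmp_path / "cell.swc"
        M.write_swc(small_pyr, path)
        back = M.read_swc(path, interneuron=True,
                          max_seg_len=small_pyr.max_seg_len)
        assert "basal" not in back.regions
        assert "apic" not in back.regions
        assert "dend" in back.regions


def test_section_validation():
    with pytest.raises(ValueError):
        Section("soma", np.zeros((2, 3)), np.array([1.0, -1.0]))
    with pytest.raises(ValueError):
        Section("elbow", np.zeros((2, 3)), np.array([1.0, 1.0]))
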