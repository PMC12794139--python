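"""H-bonds, stacking RDF, SASA/AP, CED, density profiles, Ramachandran,
Debye SAXS -- each checked against brute-force or closed-form oracles."""

import numpy as np
import pytest

from lipoforge.assembly import AssemblyModel, build_sheet
from lipoforge.lipopeptide import MoleculeGeometry
from lipoforge.analysis import (
    AnalysisError,
    HBondCriterion,
    aromatic_rdf,
    cohesive_energy_density,
    count_hbonds,
    debye_saxs,
    density_profile,
    first_rdf_peak,
    ramachandran_map,
    rdf_from_points,
    sasa_and_ap,
)


def point_molecule(xyz, element="C", name="X"):
    xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
    return MoleculeGeometry([name] * len(xyz), [element] * len(xyz),
                            np.ones(len(xyz), dtype=int), ["PLM"] * len(xyz),
                            xyz, [], None)


class TestHBonds:
    def test_single_molecule_has_none(self, kyk_monomer):
        per_mol, capable = count_hbonds(AssemblyModel([kyk_monomer]))
        assert per_mol == 0.0 and capable == 0.0

    def test_built_tape_exceeds_reference_density(self, kyk_bilayer_256):
        per_mol, capable = count_hbonds(kyk_bilayer_256)
        assert per_mol > 1.5
        assert capable >= per_mol

    def test_angle_filter_tightens_count(self, kyk_bilayer_64):
        loose = count_hbonds(kyk_bilayer_64,
                             HBondCriterion(max_angle=None))[0]
        tight = count_hbonds(kyk_bilayer_64,
                             HBondCriterion(max_angle=10.0))[0]
        assert tight <= loose

    def test_neighbor_search_equals_bruteforce(self, kyk_monomer):
        """O(N^2) oracle on a small sheet reproduces the tree-based count."""
        sheet = build_sheet(kyk_monomer, 3)
        per_mol, capable = count_hbonds(sheet)
        # brute force
        atoms = []
        for mi, m in enumerate(sheet.molecules):
            for i in range(m.n_atoms):
                atoms.append((mi, m.names[i], m.elements[i], m.coords[i]))
        donors = [(mi, xyz) for mi, nm, el, xyz in atoms if nm == "N"]
        hydro = [(mi, xyz) for mi, nm, el, xyz in atoms if el == "H"]
        accept = [(mi, xyz) for mi, nm, el, xyz in atoms
                  if nm in ("O", "O1", "OXT")]
        n_bonds = 0
        for mi, d in donors:
            hs = [h for mj, h in hydro if np.linalg.norm(h - d) < 1.25]
            for mj, a in accept:
                if mj == mi or np.linalg.norm(a - d) > 3.5:
                    continue
                for h in hs:
                    v1, v2 = h - d, a - d
                    cosang = v1 @ v2 / np.linalg.norm(v1) / np.linalg.norm(v2)
                    if np.degrees(np.arccos(np.clip(cosang, -1, 1))) <= 30.0:
                        n_bonds += 1
                        break
        assert per_mol == pytest.approx(n_bonds / 3, abs=1e-12)

    def test_invalid_criterion_rejected(self):
        with pytest.raises(AnalysisError):
            HBondCriterion(max_distance=-1.0)
        with pytest.raises(AnalysisError):
            HBondCriterion(max_angle=120.0)


class TestAromaticRDF:
    def test_tape_first_peak_near_strand_spacing(self, kyk_bilayer_256):
        r, g = aromatic_rdf(kyk_bilayer_256)
        assert first_rdf_peak(r, g) == pytest.approx(5.0, abs=0.5)

    def test_random_points_give_flat_rdf(self, rng):
        # r_max well below the box edge keeps finite-box shell clipping
        # small; g(r) should then be ~1 beyond the first bin
        pts = rng.uniform(0, 60, size=(600, 3))
        r, g = rdf_from_points(pts, 60.0**3, bin_width=1.5, r_max=7.5)
        assert np.all(np.abs(g[1:] - 1.0) < 0.35)

    def test_histogram_equals_bruteforce(self, rng):
        pts = rng.uniform(0, 25, size=(40, 3))
        r, g = rdf_from_points(pts, 25.0**3, bin_width=1.0, r_max=10.0)
        edges = np.arange(0, 10.0 + 1.0, 1.0)
        dist = [np.linalg.norm(pts[i] - pts[j])
                for i in range(40) for j in range(i + 1, 40)]
        hist, _ = np.histogram(dist, bins=edges)
        shell = 4 / 3 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
        expected = hist / (40 * 39 / 2 * shell / 25.0**3)
        assert np.allclose(g, expected)

    def test_1d_lattice_peaks_at_multiples(self):
        pts = np.array([[0.0, 0.0, 5.0 * k] for k in range(24)])
        r, g = rdf_from_points(pts, 20.0 * 20.0 * 120.0,
                               bin_width=0.5, r_max=18.0)
        peaks = [r[i] for i in range(1, len(g) - 1)
                 if g[i] > g[i - 1] and g[i] >= g[i + 1] and g[i] > 1]
        for k, peak in enumerate(peaks[:3], start=1):
            assert peak == pytest.approx(5.0 * k, abs=0.26)

    def test_no_aromatics_raises(self, rng):
        mol = point_molecule([[0, 0, 0]])
        with pytest.raises(AnalysisError):
            aromatic_rdf(AssemblyModel([mol]))


class TestSasaAP:
    def test_single_sphere_closed_form(self):
        import biotite.structure as struc

        arr = struc.AtomArray(1)
        arr.coord[0] = [0.0, 0.0, 0.0]
        arr.element[0] = "C"
        arr.atom_name[0] = "C"
        arr.res_id[0] = 1
        arr.res_name[0] = "PLM"
        arr.chain_id[0] = "A"
        res = sasa_and_ap(arr, point_number=2000)
        # biotite 'Single' vdW radius for carbon is 1.70 A
        assert res["sasa"][0] == pytest.approx(
            4 * np.pi * (1.70 + 1.4) ** 2, rel=0.01)
        assert res["ap"] is None

    def test_static_trajectory_ap_is_one(self, kyk_monomer):
        frame = AssemblyModel([kyk_monomer])
        res = sasa_and_ap([frame, frame, frame])
        assert res["ap"] == pytest.approx(1.0, abs=1e-12)

    def test_sasa_decreases_on_approach(self, kyk_monomer):
        far = AssemblyModel([kyk_monomer,
                             kyk_monomer.transformed(translation=[80, 0, 0])])
        near = AssemblyModel([kyk_monomer,
                              kyk_monomer.transformed(translation=[0, 4.8, 0])])
        s_far = sasa_and_ap(far)["sasa"][0]
        s_near = sasa_and_ap(near)["sasa"][0]
        assert s_near < s_far


class TestCED:
    def test_two_particles_at_lj_minimum(self):
        sigma, eps = 3.40, 0.36  # carbon defaults
        r_min = 2 ** (1 / 6) * sigma
        pair = AssemblyModel([point_molecule([[0, 0, 0]]),
                              point_molecule([[r_min, 0, 0]])])
        ced = cohesive_energy_density(pair, volume_nm3=1.0)
        assert ced == pytest.approx(-eps, rel=1e-9)

    def test_separated_molecules_tend_to_zero(self, kyk_monomer):
        near = AssemblyModel([kyk_monomer,
                              kyk_monomer.transformed(translation=[0, 4.8, 0])])
        ced_near = cohesive_energy_density(near, volume_nm3=10.0)
        far = AssemblyModel([kyk_monomer,
                             kyk_monomer.transformed(translation=[0, 48.0, 0])])
        ced_far = cohesive_energy_density(far, volume_nm3=10.0)
        assert ced_near < 0
        assert abs(ced_far) < 0.1 * abs(ced_near)

    def test_hbonded_sheet_is_cohesive(self, kyk_monomer):
        # a small beta-sheet ladder at build spacing is net attractive
        sheet = build_sheet(kyk_monomer, 4)
        assert cohesive_energy_density(sheet) < 0

    def test_single_atom_volume_undefined(self):
        with pytest.raises(AnalysisError):
            cohesive_energy_density(AssemblyModel([point_molecule([[0, 0, 0]])]))


class TestDensityProfile:
    def test_tail_maximum_at_center(self, kyk_bilayer_256):
        profiles = density_profile(kyk_bilayer_256, mode="axis", axis=0)
        centers, rho_tail = profiles["tail"]
        peak_r = centers[np.argmax(rho_tail)]
        assert abs(peak_r) < 5.0

    def test_profile_mirror_balance(self, kyk_bilayer_256):
        # leaflet symmetry: equal tail mass on the two sides of the peak
        profiles = density_profile(kyk_bilayer_256, mode="axis", axis=0,
                                   bin_width=2.0)
        centers, rho = profiles["tail"]
        mid = centers[np.argmax(rho)]
        left = rho[centers < mid].sum()
        right = rho[centers > mid].sum()
        assert abs(left - right) / (left + right) < 0.15

    def test_mass_conservation(self, kyk_bilayer_64):
        from lipoforge.analysis import _DENSITY_CONV, _atoms_of, _masses

        atoms = _atoms_of(kyk_bilayer_64)
        total_mass = _masses(atoms).sum()
        profiles = density_profile(kyk_bilayer_64, mode="axis", axis=0)
        centers, rho = profiles["tail"]
        bin_w = centers[1] - centers[0]
        others = atoms["coords"][:, [1, 2]]
        cross = np.prod(others.max(axis=0) - others.min(axis=0))
        integral = sum(p[1].sum() for p in profiles.values()) \
            * bin_w * cross / _DENSITY_CONV
        assert integral == pytest.approx(total_mass, rel=1e-6)

    def test_radial_mode_runs(self, wkk_fibril_64):
        profiles = density_profile(wkk_fibril_64, mode="radial")
        centers, rho_tail = profiles["tail"]
        # tail density should be concentrated well inside the peptide shell
        _, rho_k = profiles["K"]
        assert centers[np.argmax(rho_tail)] < centers[np.argmax(rho_k)]


class TestRamachandran:
    def test_built_assembly_in_beta_region(self, kyk_bilayer_64):
        phi_edges, psi_edges, neg_log = ramachandran_map(kyk_bilayer_64)
        finite = np.isfinite(neg_log)
        i, j = np.unravel_index(np.argmin(np.where(finite, neg_log, np.inf)),
                                neg_log.shape)
        phi_c = 0.5 * (phi_edges[i] + phi_edges[i + 1])
        psi_c = 0.5 * (psi_edges[j] + psi_edges[j + 1])
        assert phi_c < 0 and psi_c > 90

    def test_map_minimum_zero_and_normalized(self, kyk_bilayer_64):
        _, _, neg_log = ramachandran_map(kyk_bilayer_64)
        finite = neg_log[np.isfinite(neg_log)]
        assert finite.min() == pytest.approx(0.0, abs=1e-12)
        # probability mass sums to 1 up to the uniform offset:
        # sum exp(-(neg_log + offset)) = 1 for some offset >= 0
        mass = np.exp(-finite).sum()
        assert mass >= 1.0 - 1e-12


class TestDebye:
    def test_single_scatterer_monotone_f_squared(self, kyk_monomer):
        mol = point_molecule([[0.0, 0.0, 0.0]])
        q = np.linspace(0.01, 1.5, 60)
        prof = debye_saxs(AssemblyModel([mol]), q, displaced_solvent=False,
                          histogram_bin=None)
        from lipoforge.analysis import xray_form_factor

        assert np.allclose(prof.intensity, xray_form_factor("C", q) ** 2)
        assert np.all(np.diff(prof.intensity) <= 0)

    def test_two_point_closed_form_exact(self):
        d = 10.0
        toy = AssemblyModel([point_molecule([[0, 0, 0]]),
                             point_molecule([[d, 0, 0]])])
        q = np.linspace(0.01, 1.0, 50)
        prof = debye_saxs(toy, q, unit_scatterers=True, histogram_bin=None)
        expected = 2.0 * (1.0 + np.sin(q * d) / (q * d))
        assert np.max(np.abs(prof.intensity - expected)) < 1e-10

    def test_histogram_acceleration_close_to_exact(self, kyk_monomer):
        q = np.geomspace(0.02, 0.8, 40)
        one = AssemblyModel([kyk_monomer])
        exact = debye_saxs(one, q, histogram_bin=None)
        fast = debye_saxs(one, q, histogram_bin=0.05)
        assert np.allclose(fast.intensity, exact.intensity, rtol=0.02)

    def test_rigid_body_invariance(self, rng):
        pts = rng.uniform(0, 20, size=(30, 3))
        base = AssemblyModel([point_molecule(pts)])
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                        [np.sin(theta), np.cos(theta), 0], [0, 0, 1]])
        moved = AssemblyModel([point_molecule(pts @ rot.T + [5, -3, 2])])
        q = np.geomspace(0.02, 1.0, 30)
        a = debye_saxs(base, q, unit_scatterers=True, histogram_bin=None)
        b = debye_saxs(moved, q, unit_scatterers=True, histogram_bin=None)
        assert np.allclose(a.intensity, b.intensity, rtol=1e-9)

    def test_fibril_lowq_slope_near_minus_one(self, wkk_fibril_64):
        """A long fibril (periodic repeats of the built 64-mer along its
        axis, reduced to a per-molecule point cloud) scatters with the
        rod-like q^-1 low-q power law."""
        from lipoforge.saxs import lowq_exponent

        pts = []
        for m in wkk_fibril_64.molecules:
            for rid in (1, 2, 3, 4):
                for nm in ("CA", "C1", "C8", "C16"):
                    try:
                        pts.append(m.coords[m.index_of(rid, nm)])
                    except KeyError:
                        pass
        pts = np.array(pts)
        period = 8 * 4.8
        cloud = np.concatenate([pts + np.array([0.0, k * period, 0.0])
                                for k in range(12)])
        mol = point_molecule(cloud)
        q = np.geomspace(0.012, 0.06, 20)
        prof = debye_saxs(AssemblyModel([mol]), q, unit_scatterers=True,
                          histogram_bin=0.5)
        assert lowq_exponent(prof, (0.012, 0.035)) == pytest.approx(
            -1.0, abs=0.3)

    def test_empty_structure_rejected(self):
        with pytest.raises(AnalysisError):
            debye_saxs(AssemblyModel([]), np.array([0.01, 0.02]))
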