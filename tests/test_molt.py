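"""Mean-field theory: bead models, conformers, SCF invariants, charge
regulation and titration behavior."""

import numpy as np
import pytest

from lipoforge.molt import (
    BEAD_VOLUMES,
    Conditions,
    GeometrySpec,
    ModelParametrization,
    MoltError,
    apparent_pka,
    build_bead_model,
    cached_ensemble,
    epsilon,
    generate_conformers,
    solve_scf,
    volume_fraction_profiles,
)

PARAMS1 = ModelParametrization(model_id=1)
PARAMS2 = ModelParametrization(model_id=2)


@pytest.fixture(scope="module")
def wkk_ensemble():
    return cached_ensemble("C16-WKK", PARAMS1, 8000, 7)


class TestBeadModel:
    def test_c16_maps_to_four_tail_beads(self):
        bm = build_bead_model("C16-WKK", PARAMS1)
        assert sum(1 for b in bm.beads if b.species == "tail") == 4

    def test_side_chain_volumes_ordered(self):
        assert BEAD_VOLUMES["scY"] == 0.153
        assert BEAD_VOLUMES["scW"] == 0.186
        assert BEAD_VOLUMES["scY"] < BEAD_VOLUMES["scW"]

    def test_model1_type_assignments(self):
        bm = build_bead_model("C16-KWK", PARAMS1)
        types = {b.label: b.cg_type for b in bm.beads}
        assert types["bb1"] == "P5" and types["bb3"] == "P5"  # K backbones
        assert types["bb2"] == "Nda"                          # W backbone
        assert types["sc2"] == "C5"                           # W side chain
        assert types["sc1"] == "C3"                           # K side chain

    def test_model2_type_assignments(self):
        bm = build_bead_model("C16-KWK", PARAMS2)
        types = {b.label: b.cg_type for b in bm.beads}
        assert all(types[f"bb{i}"] == "Nda" for i in (1, 2, 3))
        assert types["sc1"] == "P1"

    def test_titratable_beads_have_pka(self):
        bm = build_bead_model("C16-KYK", PARAMS1)
        titr = [(b.species, b.titratable, b.pka)
                for b in bm.beads if b.titratable]
        assert ("scK", "base", 10.54) in titr
        assert ("scY", "acid", 10.5) in titr

    def test_epsilon_matrix_symmetric(self):
        types = ["P5", "P4", "P1", "Nda", "C5", "C3", "C1"]
        for a in types:
            for b in types:
                assert epsilon(a, b) == epsilon(b, a)


class TestConformers:
    def test_seeded_determinism(self):
        bm = build_bead_model("C16-WKK", PARAMS1)
        a = generate_conformers(bm, 500, seed=3)
        b = generate_conformers(bm, 500, seed=3)
        assert np.array_equal(a.positions, b.positions)
        c = generate_conformers(bm, 500, seed=4)
        assert not np.array_equal(a.positions, c.positions)

    def test_self_avoidance(self, wkk_ensemble):
        bm = wkk_ensemble.bead_model
        bonded = set()
        chain = bm.backbone
        for i, j in zip(chain[:-1], chain[1:]):
            bonded.add((min(i, j), max(i, j)))
        for bb, sc in bm.branches.items():
            bonded.add((min(bb, sc), max(bb, sc)))
        for k in range(0, wkk_ensemble.n_conf, 500):
            pos = wkk_ensemble.positions[k]
            for i in range(len(pos)):
                for j in range(i + 1, len(pos)):
                    if (i, j) in bonded:
                        continue
                    assert np.linalg.norm(pos[i] - pos[j]) >= 0.399

    def test_end_to_end_below_contour(self, wkk_ensemble):
        bm = wkk_ensemble.bead_model
        first, last = bm.backbone[0], bm.backbone[-1]
        e2e = np.linalg.norm(wkk_ensemble.positions[:, last]
                             - wkk_ensemble.positions[:, first], axis=1)
        contour = 0.5 * (len(bm.backbone) - 1)
        assert e2e.mean() < contour
        assert e2e.max() <= contour + 1e-9

    def test_junction_at_origin(self, wkk_ensemble):
        j = wkk_ensemble.bead_model.junction
        assert np.allclose(wkk_ensemble.positions[:, j], 0.0)


class TestSCF:
    def test_converged_residuals_small(self, wkk_ensemble):
        geo = GeometrySpec("cylindrical", n_layers=30)
        state = solve_scf(wkk_ensemble, geo, Conditions(ph=10.0),
                          PARAMS1, sigma=1.5)
        assert state.residuals["packing"] < 1e-6
        assert state.residuals["electroneutrality"] < 1e-6
        assert state.residuals["probability"] < 1e-12
        for s, f in state.protonation.items():
            assert np.all((f >= 0) & (f <= 1))

    def test_henderson_hasselbalch_at_zero_potential(self, wkk_ensemble):
        """With no field, the local equilibrium gives f = 1/2 at
        pH = pKa exactly."""
        from lipoforge.molt import _System

        geo = GeometrySpec("planar", n_layers=30)
        sys_ = _System(wkk_ensemble, geo, Conditions(ph=10.54), PARAMS1, 1.5)
        _xi, f = sys_.site_xi("base", 10.54, np.zeros(30))
        assert np.allclose(f, 0.5)
        _xi, f = sys_.site_xi("acid", 10.5, np.zeros(30))
        k10 = 10.0 ** (10.54 - 10.5)
        assert np.allclose(f, k10 / (1 + k10))

    def test_ideal_chain_limit(self):
        """Zero attraction, no titratable charge: the density profile is
        the unperturbed-ensemble density (fields vanish)."""
        from lipoforge.molt import _System

        params = ModelParametrization(model_id=1, contact_strength=0.0)
        ens = cached_ensemble("C16-WKK", params, 4000, 11)
        geo = GeometrySpec("planar", n_layers=40)
        cond = Conditions(ph=14.0)  # lysines fully neutral
        sigma = 0.01  # dilute: negligible packing interaction
        state = solve_scf(ens, geo, cond, params, sigma)
        sys_ = _System(ens, geo, cond, params, sigma)
        ideal, _p = sys_.chain_densities(np.zeros((sys_.ns, sys_.nl)))
        for s in state.phi:
            k = sys_.spi[s]
            assert np.allclose(state.phi[s], ideal[k],
                               atol=0.05 * max(ideal[k].max(), 1e-9))
        # closed-form limit: conformational term vanishes (uniform P)
        # and only the solvent-exchange term survives, computable from
        # the unperturbed ideal profile alone
        phi_w_ideal = 1.0 - ideal.sum(axis=0)
        f_expected = float(np.sum(
            sys_.vols / 0.030 * phi_w_ideal * np.log(phi_w_ideal))) / sys_.n_mol
        assert state.free_energy == pytest.approx(f_expected, abs=0.2)

    def test_charge_regulation_direction(self, wkk_ensemble):
        """Denser aggregates shift the lysine equilibrium toward neutral:
        mean protonation decreases with sigma at fixed pH."""
        geo = GeometrySpec("cylindrical", n_layers=30)
        cond = Conditions(ph=10.0)
        f_vals = []
        for sigma in (0.8, 1.5, 2.2):
            state = solve_scf(wkk_ensemble, geo, cond, PARAMS1, sigma)
            f_vals.append(state.mean_protonation("scK"))
        assert f_vals[0] >= f_vals[1] >= f_vals[2]

    def test_protonation_below_bulk_value(self, wkk_ensemble):
        geo = GeometrySpec("cylindrical", n_layers=30)
        ph = 10.0
        state = solve_scf(wkk_ensemble, geo, Conditions(ph=ph),
                          PARAMS1, sigma=1.8)
        bulk = 1.0 / (1.0 + 10.0 ** (ph - 10.54))
        assert state.mean_protonation("scK") < bulk

    def test_picard_free_energy_monotone(self):
        params = ModelParametrization(model_id=1, contact_strength=0.3)
        ens = cached_ensemble("C16-WKK", params, 4000, 11)
        geo = GeometrySpec("spherical", n_layers=30)
        state = solve_scf(ens, geo, Conditions(ph=12.0), params, sigma=1.0,
                          solver="picard", max_iter=4000, mixing=0.1,
                          tol=1e-5)
        trace = state.free_energy_trace
        assert len(trace) > 5
        assert np.all(np.diff(trace) <= 1e-9)

    def test_invalid_inputs_rejected(self, wkk_ensemble):
        geo = GeometrySpec("planar", n_layers=20)
        with pytest.raises(MoltError):
            solve_scf(wkk_ensemble, geo, Conditions(ph=7.0), PARAMS1, -1.0)
        with pytest.raises(MoltError):
            solve_scf(wkk_ensemble, geo,
                      Conditions(ph=7.0, ionic_strength=-0.1), PARAMS1, 1.0)

    def test_w_y_swap_symmetry(self):
        """With identical parametrization (same types and volumes), a W
        molecule and its Y-swapped analogue give identical results."""
        from dataclasses import replace as _r
        from lipoforge.molt import BeadModel, BeadSpec, _System

        params = ModelParametrization(model_id=1)
        bm_w = build_bead_model("C16-WKK", params)
        # rename W species to Y but keep W volumes/types: parametrization
        # equality implies identical physics
        beads_y = [BeadSpec(b.label, b.species.replace("W", "Y"), b.volume,
                            b.cg_type, b.titratable, b.pka)
                   for b in bm_w.beads]
        bm_y = BeadModel(beads_y, bm_w.backbone, bm_w.branches, bm_w.junction)
        ens_w = generate_conformers(bm_w, 3000, seed=5)
        ens_y = generate_conformers(bm_y, 3000, seed=5)
        geo = GeometrySpec("cylindrical", n_layers=30)
        st_w = solve_scf(ens_w, geo, Conditions(ph=11.0), params, 1.5)
        st_y = solve_scf(ens_y, geo, Conditions(ph=11.0), params, 1.5)
        assert st_w.free_energy == pytest.approx(st_y.free_energy, abs=1e-8)


class TestProfilesAndPka:
    def test_volume_fraction_table_shape(self, wkk_ensemble):
        geo = GeometrySpec("cylindrical", n_layers=30)
        state = solve_scf(wkk_ensemble, geo, Conditions(ph=12.0),
                          PARAMS1, 1.5)
        table = volume_fraction_profiles(state)
        assert "phi_tail" in table and "phi_water" in table
        assert len(table["r_nm"]) == 30

    def test_no_water_in_dense_core(self, wkk_ensemble):
        geo = GeometrySpec("cylindrical", n_layers=30)
        state = solve_scf(wkk_ensemble, geo, Conditions(ph=12.0),
                          PARAMS1, 2.0)
        core = state.phi_water[state.phi["tail"] > 0.5]
        assert core.size and np.all(core < 0.25)

    def test_dilute_apparent_pka_equals_bulk(self):
        params = ModelParametrization(model_id=1, contact_strength=0.0)
        result = apparent_pka("C16-WKK", "scK", params, morphology="lamella",
                              sigma=0.02, n_conf=3000)
        assert not result["censored"]
        assert result["pka"] == pytest.approx(10.54, abs=0.1)

    def test_aggregate_lowers_lysine_pka(self):
        result = apparent_pka("C16-WKK", "scK", PARAMS1,
                              morphology="lamella", sigma=1.8, n_conf=6000)
        assert not result["censored"]
        assert result["pka"] < 10.54

    def test_acid_shift_opposite_to_base(self):
        """In a cationic aggregate the tyrosine (acid) apparent pKa
        shifts down (deprotonation helped by positive potential) --
        opposite in sign convention to the base shift at equal density.
        At minimum the acid's charged fraction at its bulk pKa exceeds
        one half when psi > 0."""
        from lipoforge.molt import _System

        ens = cached_ensemble("C16-KYK", PARAMS1, 6000, 7)
        geo = GeometrySpec("cylindrical", n_layers=30)
        state = solve_scf(ens, geo, Conditions(ph=8.0), PARAMS1, 1.8)
        assert np.all(state.psi >= -1e-9)  # cationic aggregate
        sys_ = _System(ens, geo, Conditions(ph=10.5), PARAMS1, 1.8)
        _xi, f_acid = sys_.site_xi("acid", 10.5, state.psi)
        assert np.all(f_acid[state.psi > 1e-6] > 0.5)
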