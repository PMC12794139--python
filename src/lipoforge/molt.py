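"""Self-consistent mean-field molecular theory of lipopeptide aggregates.

The theory predicts the equilibrium morphology (spherical micelle,
cylindrical fibril, planar lamella) of an ionizable amphiphile as a
function of pH by minimizing, for each candidate geometry, a free-energy
functional containing

* the conformational entropy of the lipopeptides, sampled by a seeded
  Monte-Carlo ensemble of self-avoiding coarse-grained conformers,
* the translational entropy of water and monovalent salt ions,
* short-range contact attractions between coarse-grained beads,
* electrostatics (nonlinear Poisson-Boltzmann on the same lattice), and
* acid-base equilibria of the titratable groups (charge regulation via
  a local semi-grand partition function per site).

Intermolecular repulsions enter through a mean-field packing constraint
(sum of volume fractions = 1 in every lattice layer, enforced by a
lateral pressure field pi(r)).

Coarse graining: one bead per 4 CH2 units (a C16 tail is 4 beads), one
backbone bead and one side-chain bead per amino acid.  Bead-bead
attraction strengths are a transcription of the published coarse-grained
interaction-level scheme for the named bead types (P5, P4, P1, Nda, C5,
C3, C1), multiplied by a single global contact-strength factor -- the
one calibration constant of the theory.

The coupled equations are solved either by a Jacobian-free
Newton-Krylov iteration on the full field vector (default; fast and
robust) or by a damped Picard fixed point with free-energy-descent step
control (slower; useful to follow the free energy during relaxation).

Lengths in nm, energies in kT unless stated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.linalg import solve_banded
from scipy.optimize import newton_krylov
from scipy.optimize._nonlin import NoConvergence

from .lipopeptide import LipopeptideSpec, parse_lipopeptide

__all__ = [
    "MoltError",
    "BeadSpec",
    "BeadModel",
    "ModelParametrization",
    "ConformerEnsemble",
    "GeometrySpec",
    "Conditions",
    "SCFState",
    "MorphologyResult",
    "build_bead_model",
    "generate_conformers",
    "solve_scf",
    "free_energy_vs_sigma",
    "predict_morphology",
    "phase_map",
    "volume_fraction_profiles",
    "apparent_pka",
    "epsilon",
]


class MoltError(RuntimeError):
    pass


# --------------------------------------------------------------------------
# beads and parametrization
# --------------------------------------------------------------------------

KT_KJMOL = 2.494     # kT at ~300 K, kJ/mol
BJERRUM_NM = 0.714   # water, eps_r = 78.5
V_WATER = 0.030      # nm^3
V_REF = 0.030        # contact-normalization volume, nm^3

#: bead volumes, nm^3
BEAD_VOLUMES = {
    "tail": 0.108,   # 4 CH2 units
    "bb": 0.100,     # peptide backbone unit
    "scK": 0.105,
    "scW": 0.186,
    "scY": 0.153,
    "scG": 0.020,
    "scA": 0.050,
}

#: attraction levels (kJ/mol) of the published CG interaction scheme
_LEVELS = {"O": 5.6, "I": 5.0, "II": 4.5, "III": 4.0, "IV": 3.5,
           "V": 3.1, "VI": 2.7, "VII": 2.3, "VIII": 2.0, "IX": 2.0}

#: symmetric interaction-level table for the bead types used here
_LEVEL_TABLE = {
    ("P5", "P5"): "O",   ("P5", "P4"): "O",   ("P5", "P1"): "I",
    ("P5", "Nda"): "I",  ("P5", "C5"): "V",   ("P5", "C3"): "VII",
    ("P5", "C1"): "IX",
    ("P4", "P4"): "I",   ("P4", "P1"): "I",   ("P4", "Nda"): "IV",
    ("P4", "C5"): "V",   ("P4", "C3"): "VI",  ("P4", "C1"): "IX",
    ("P1", "P1"): "II",  ("P1", "Nda"): "II", ("P1", "C5"): "IV",
    ("P1", "C3"): "V",   ("P1", "C1"): "VIII",
    ("Nda", "Nda"): "II", ("Nda", "C5"): "IV", ("Nda", "C3"): "V",
    ("Nda", "C1"): "VII",
    ("C5", "C5"): "IV",  ("C5", "C3"): "IV",  ("C5", "C1"): "IV",
    ("C3", "C3"): "IV",  ("C3", "C1"): "IV",
    ("C1", "C1"): "IV",
}


def epsilon(type_a: str, type_b: str) -> float:
    """Pairwise contact attraction (kJ/mol) for two bead types."""
    key = (type_a, type_b) if (type_a, type_b) in _LEVEL_TABLE else (type_b, type_a)
    return _LEVELS[_LEVEL_TABLE[key]]


#: the single global contact-strength calibration factor, chosen so that
#: Model 1 reproduces the qualitative low-pH micelle / high-pH aggregate
#: morphology switch with the transition in the experimentally relevant
#: pH window
DEFAULT_CONTACT_STRENGTH = 0.74

LYS_PKA = 10.54
TYR_PKA = 10.5


@dataclass(frozen=True)
class BeadSpec:
    label: str          # e.g. 'bb1', 'sc2'
    species: str        # density-accounting key ('tail', 'bbK', 'scW', ...)
    volume: float       # nm^3
    cg_type: str        # short-range attraction type
    titratable: str | None = None  # 'base' | 'acid' | None
    pka: float | None = None


@dataclass
class BeadModel:
    """Coarse-grained bead sequence of one lipopeptide.

    ``backbone`` lists the linear chain (tail beads then backbone
    beads); ``branches`` maps backbone-bead index -> side-chain index.
    """

    beads: list[BeadSpec]
    backbone: list[int]
    branches: dict[int, int]
    junction: int   # tail bead bonded to the first backbone bead

    @property
    def n_beads(self) -> int:
        return len(self.beads)


@dataclass(frozen=True)
class ModelParametrization:
    """Bead-type assignment.  Model 1 differentiates backbones by
    residue (K backbone 'P5', W/Y backbone 'Nda' -- W/Y form the
    stronger beta-sheet H-bonds) and keeps the K side chain hydrophobic
    ('C3'); Model 2 uses 'Nda' for every backbone and a polar K side
    chain ('P1')."""

    model_id: int = 1
    contact_strength: float = DEFAULT_CONTACT_STRENGTH

    def backbone_type(self, residue: str) -> str:
        if self.model_id == 1:
            return "P5" if residue == "K" else "Nda"
        return "Nda"

    def sidechain_type(self, residue: str) -> str:
        if residue == "K":
            return "C3" if self.model_id == 1 else "P1"
        if residue in ("W", "Y"):
            return "C5"
        return "C3"


def build_bead_model(spec: LipopeptideSpec | str,
                     params: ModelParametrization) -> BeadModel:
    spec = spec if isinstance(spec, LipopeptideSpec) else parse_lipopeptide(spec)
    n_tail_beads = max(1, round(spec.tail_carbons / 4))
    beads: list[BeadSpec] = []
    backbone: list[int] = []
    for k in range(n_tail_beads):
        beads.append(BeadSpec(f"t{k}", "tail", BEAD_VOLUMES["tail"], "C1"))
        backbone.append(k)
    branches: dict[int, int] = {}
    for i, code in enumerate(spec.sequence):
        bb_idx = len(beads)
        beads.append(BeadSpec(f"bb{i + 1}", f"bb{code}", BEAD_VOLUMES["bb"],
                              params.backbone_type(code)))
        backbone.append(bb_idx)
        sc_key = f"sc{code}" if f"sc{code}" in BEAD_VOLUMES else "scA"
        titr, pka = None, None
        if code == "K":
            titr, pka = "base", LYS_PKA
        elif code == "Y":
            titr, pka = "acid", TYR_PKA
        beads.append(BeadSpec(f"sc{i + 1}", f"sc{code}",
                              BEAD_VOLUMES[sc_key],
                              params.sidechain_type(code), titr, pka))
        branches[bb_idx] = len(beads) - 1
    return BeadModel(beads, backbone, branches, junction=n_tail_beads - 1)


# --------------------------------------------------------------------------
# conformer generation (rotational-isomeric self-avoiding chains)
# --------------------------------------------------------------------------

BOND_LENGTH = 0.50   # nm
BEAD_CONTACT = 0.40  # nm, self-avoidance distance
_BOND_ANGLE = np.radians(120.0)
_TORSIONS = np.radians([180.0, 60.0, -60.0])


@dataclass
class ConformerEnsemble:
    """Seeded Monte-Carlo conformer set; ``positions`` has shape
    (n_conf, n_beads, 3) in nm, relative to the junction bead."""

    bead_model: BeadModel
    positions: np.ndarray
    seed: int
    regrown: int = 0

    @property
    def n_conf(self) -> int:
        return self.positions.shape[0]


def _place_step(pos, placed_mask, prev2, prev1, target, rng, max_retry=6):
    """Vectorized chain-growth step for a batch of conformers.

    Places bead ``target`` bonded to ``prev1`` at the fixed bond angle
    with a random (jittered) rotational-isomeric torsion, avoiding beads
    already placed; returns a boolean alive mask.
    """
    n = pos.shape[0]
    alive = np.ones(n, dtype=bool)
    todo = np.arange(n)
    b1 = pos[:, prev1] - pos[:, prev2]
    b1 /= np.linalg.norm(b1, axis=1, keepdims=True)
    ref = np.tile(np.array([0.0, 0.0, 1.0]), (n, 1))
    near_z = np.abs(b1[:, 2]) > 0.9
    ref[near_z] = [0.0, 1.0, 0.0]
    e2 = np.cross(b1, ref)
    e2 /= np.linalg.norm(e2, axis=1, keepdims=True)
    e3 = np.cross(b1, e2)
    placed_idx = np.where(placed_mask)[0]
    check_idx = placed_idx[(placed_idx != prev1) & (placed_idx != prev2)]
    for _ in range(max_retry):
        if len(todo) == 0:
            break
        tor = (_TORSIONS[rng.integers(0, 3, size=len(todo))]
               + rng.uniform(-0.3, 0.3, size=len(todo)))
        d = (np.cos(np.pi - _BOND_ANGLE) * b1[todo]
             + np.sin(np.pi - _BOND_ANGLE)
             * (np.cos(tor)[:, None] * e2[todo]
                + np.sin(tor)[:, None] * e3[todo]))
        cand = pos[todo, prev1] + BOND_LENGTH * d
        ok = np.ones(len(todo), dtype=bool)
        if len(check_idx):
            diff = cand[:, None, :] - pos[todo][:, check_idx, :]
            ok = (np.linalg.norm(diff, axis=-1) >= BEAD_CONTACT).all(axis=1)
        sel = todo[ok]
        pos[sel, target] = cand[ok]
        todo = todo[~ok]
    alive[todo] = False
    return alive


def generate_conformers(bead_model: BeadModel, n: int,
                        seed: int) -> ConformerEnsemble:
    """Self-avoiding rotational-isomeric chains, deterministic per seed.

    Chains grow bead by bead with fixed bond length, fixed bond angle
    and three (jittered) torsion states; dead ends are discarded and
    regrown (counted in ``regrown``).  Each conformer gets an
    independent uniform random rotation; positions are stored relative
    to the junction bead.
    """
    rng = np.random.default_rng(seed)
    chain = bead_model.backbone
    nb = bead_model.n_beads
    collected = []
    regrown = 0
    remaining = n
    while remaining > 0:
        batch = max(remaining + remaining // 4 + 8, 32)
        pos = np.zeros((batch, nb, 3))
        pos[:, chain[1]] = [BOND_LENGTH, 0.0, 0.0]
        placed = np.zeros(nb, dtype=bool)
        placed[[chain[0], chain[1]]] = True
        alive = np.ones(batch, dtype=bool)
        for i in range(2, len(chain)):
            alive &= _place_step(pos, placed, chain[i - 2], chain[i - 1],
                                 chain[i], rng)
            placed[chain[i]] = True
        for bb_idx, sc_idx in bead_model.branches.items():
            prev = chain[chain.index(bb_idx) - 1]
            alive &= _place_step(pos, placed, prev, bb_idx, sc_idx, rng)
            placed[sc_idx] = True
        good = pos[alive]
        regrown += int(batch - alive.sum())
        # uniform random rotations (QR of Gaussian matrices)
        m = len(good)
        if m:
            mats = rng.standard_normal((m, 3, 3))
            q, r = np.linalg.qr(mats)
            sign = np.sign(np.einsum("nii->ni", r))
            q = q * sign[:, None, :]
            det = np.linalg.det(q)
            q[det < 0, :, 0] *= -1.0
            good = good - good[:, bead_model.junction:bead_model.junction + 1]
            good = np.einsum("nij,nbj->nbi", q, good)
            collected.append(good[:remaining])
            remaining -= min(m, remaining)
    out = np.concatenate(collected)[:n]
    return ConformerEnsemble(bead_model, out, seed, regrown)


_ENSEMBLE_CACHE: dict[tuple, ConformerEnsemble] = {}


def cached_ensemble(identifier: str, params: ModelParametrization,
                    n: int, seed: int) -> ConformerEnsemble:
    key = (identifier, params.model_id, n, seed)
    if key not in _ENSEMBLE_CACHE:
        _ENSEMBLE_CACHE[key] = generate_conformers(
            build_bead_model(identifier, params), n, seed)
    return _ENSEMBLE_CACHE[key]


# --------------------------------------------------------------------------
# geometry, conditions, state
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class GeometrySpec:
    """Aggregate symmetry and lattice: r is the distance to the central
    plane (lamella), axis (fibril) or center (micelle)."""

    symmetry: str          # 'planar' | 'cylindrical' | 'spherical'
    delta: float = 0.5     # layer width, nm
    n_layers: int = 40

    @property
    def curvature_order(self) -> int:
        return {"planar": 0, "cylindrical": 1, "spherical": 2}[self.symmetry]

    def layer_volumes(self) -> np.ndarray:
        """Layer volumes per unit cell (per nm^2 midplane for planar,
        per nm of axis for cylindrical, absolute for spherical) --
        proportional to the symmetry Jacobian (const, r, r^2)."""
        edges = self.delta * np.arange(self.n_layers + 1)
        a = self.curvature_order
        if a == 0:
            return np.full(self.n_layers, self.delta)
        if a == 1:
            return np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
        return 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)

    def dividing_surface_area(self, radius: float) -> float:
        a = self.curvature_order
        if a == 0:
            return 1.0
        if a == 1:
            return 2.0 * np.pi * radius
        return 4.0 * np.pi * radius**2


MORPHOLOGIES = {"micelle": "spherical", "fibril": "cylindrical",
                "lamella": "planar"}


@dataclass(frozen=True)
class Conditions:
    ph: float = 7.0
    ionic_strength: float = 0.1   # mol/L, monovalent salt
    temperature: float = 300.0


@dataclass
class SCFState:
    geometry: GeometrySpec
    conditions: Conditions
    sigma: float
    radius: float
    r: np.ndarray                 # layer centers, nm
    phi: dict                     # species -> phi(r)
    phi_water: np.ndarray
    psi: np.ndarray               # beta e psi(r), dimensionless
    protonation: dict             # species -> charged-state fraction f(r)
    pressure: np.ndarray          # beta pi(r) v_ref
    probabilities: np.ndarray     # P(alpha)
    free_energy: float            # per molecule, kT
    residuals: dict
    converged: bool
    free_energy_trace: np.ndarray | None = None

    def mean_protonation(self, species: str) -> float:
        """Density-weighted mean charged-state fraction of a species."""
        phi = self.phi[species]
        w = phi * self.geometry.layer_volumes()
        if w.sum() <= 0:
            return float("nan")
        return float((self.protonation[species] * w).sum() / w.sum())


def _ion_density_nm3(molar: float) -> float:
    return molar * 0.6022


# --------------------------------------------------------------------------
# the SCF solve
# --------------------------------------------------------------------------


class _System:
    """Precomputed arrays for one (ensemble, geometry, conditions,
    parametrization, sigma) combination."""

    def __init__(self, ensemble, geometry, conditions, params, sigma):
        if sigma <= 0:
            raise MoltError("sigma must be positive")
        if conditions.ionic_strength <= 0:
            raise MoltError("ionic strength must be positive")
        bm = ensemble.bead_model
        self.bm = bm
        self.geometry = geometry
        self.conditions = conditions
        self.params = params
        self.sigma = sigma
        self.delta = geometry.delta
        self.nl = geometry.n_layers
        self.a = geometry.curvature_order
        v_tail = sum(b.volume for b in bm.beads if b.species == "tail")
        self.radius = max((self.a + 1) * sigma * v_tail, 0.25 * self.delta)
        self.n_mol = sigma * geometry.dividing_surface_area(self.radius)
        self.vols = geometry.layer_volumes()
        self.r_centers = self.delta * (np.arange(self.nl) + 0.5)

        self.species = sorted({b.species for b in bm.beads})
        self.ns = len(self.species)
        self.spi = {s: k for k, s in enumerate(self.species)}
        self.spv = np.array([next(b.volume for b in bm.beads if b.species == s)
                             for s in self.species])
        sp_type = {s: next(b.cg_type for b in bm.beads if b.species == s)
                   for s in self.species}
        self.titratable = {s: (b.titratable, b.pka) for s in self.species
                           for b in bm.beads
                           if b.species == s and b.titratable is not None}

        # conformer bead -> layer occupancy (depends on geometry + radius)
        pos = ensemble.positions
        if self.a == 0:
            r_bead = np.abs(self.radius + pos[:, :, 0])  # midplane mirror fold
        elif self.a == 1:
            r_bead = np.hypot(self.radius + pos[:, :, 0], pos[:, :, 1])
        else:
            r_bead = np.linalg.norm(
                pos + np.array([self.radius, 0.0, 0.0]), axis=-1)
        layer = np.clip((r_bead / self.delta).astype(int), 0, self.nl - 1)
        self.nc, nb = layer.shape
        bead_sp = np.array([self.spi[b.species] for b in bm.beads])
        flat = bead_sp[None, :] * self.nl + layer
        self.occ = sparse.csr_matrix(
            (np.ones(self.nc * nb),
             (np.repeat(np.arange(self.nc), nb), flat.ravel())),
            shape=(self.nc, self.ns * self.nl))
        self.occ_t = self.occ.T.tocsr()

        g = params.contact_strength
        self.be = np.array([[g * epsilon(sp_type[s1], sp_type[s2]) / KT_KJMOL
                             for s2 in self.species] for s1 in self.species])
        if self.a == 2:
            # finite micelle: a molecule does not attract itself; the
            # mean-field chain-chain attraction is scaled by (n-1)/n
            # (negligible for large aggregates, removes the spurious
            # stability of sub-micellar clusters)
            self.be = self.be * max(0.0, (self.n_mol - 1.0) / self.n_mol)
        self.be_w = np.array([g * epsilon(sp_type[s], "P4") / KT_KJMOL
                              for s in self.species])
        self.be_ww = g * epsilon("P4", "P4") / KT_KJMOL
        self.c_salt = _ion_density_nm3(conditions.ionic_strength)
        self.ph = conditions.ph
        # dispersed-chain reference: contact energy of one chain at
        # infinite dilution in water (subtracted so the reported free
        # energy is the aggregation free energy per molecule)
        counts_per_mol = np.array(
            [sum(1 for b in bm.beads if b.species == s) for s in self.species])
        self.f_dispersed = float(np.sum(
            -counts_per_mol * (self.spv / V_REF) * (self.be_w - self.be_ww)))

        edge_r = self.delta * np.arange(self.nl + 1)
        if self.a == 0:
            edge_area = np.ones(self.nl + 1)
        elif self.a == 1:
            edge_area = 2.0 * np.pi * edge_r
        else:
            edge_area = 4.0 * np.pi * edge_r**2
        self.a_lo = edge_area[:-1].copy()
        self.a_lo[0] = 0.0  # zero flux at the center
        self.a_hi = edge_area[1:]
        self._psi_cache = np.zeros(self.nl)

    def incompressible_step(self, phi_sp):
        """Full field evaluation with the packing constraint enforced by
        construction: phi_w = 1 - sum(phi) and the lateral pressure is
        the explicit function of phi that keeps water in equilibrium.
        Removes the density-collapse mode of the plain fixed point."""
        phi_sp = np.clip(phi_sp, 0.0, None)
        tot = phi_sp.sum(axis=0)
        over = tot > 0.999
        if over.any():
            phi_sp = phi_sp.copy()
            phi_sp[:, over] *= (0.999 / tot[over])[None, :]
        phi_w = 1.0 - phi_sp.sum(axis=0)
        psi = self.solve_pb(phi_sp)
        base = self.be_w @ phi_sp
        u_w = -(V_WATER / V_REF) * (base + self.be_ww * phi_w - self.be_ww)
        btpi = -(V_REF / V_WATER) * (np.log(np.maximum(phi_w, 1e-12)) + u_w)
        u = self.bead_fields(btpi, phi_sp, phi_w, psi)
        new_phi_sp, p_alpha = self.chain_densities(u)
        return new_phi_sp, phi_w, btpi, p_alpha, psi

    # -- acid-base ---------------------------------------------------------

    def site_xi(self, kind, pka, psi):
        """Per-site semi-grand factor xi(r) relative to bulk, and the
        charged-state fraction f(r) from the local equilibrium
        f/(1-f) = 10^(pKa-pH) exp(-y) (base) / 10^(pH-pKa) exp(+y) (acid)."""
        if kind == "base":
            k10 = 10.0 ** (pka - self.ph)
            local = k10 * np.exp(-psi)
        else:
            k10 = 10.0 ** (self.ph - pka)
            local = k10 * np.exp(psi)
        return (1.0 + local) / (1.0 + k10), local / (1.0 + local)

    # -- electrostatics ----------------------------------------------------

    def solve_pb(self, phi_sp, psi0=None):
        """Damped Newton for nonlinear PB on the lattice.

        Finite-volume residual per cell i:
            A_{i+1/2}(y_{i+1}-y_i)/d - A_{i-1/2}(y_i-y_{i-1})/d
            + 4 pi lB rho_i V_i = 0
        with zero flux at the center and y = 0 beyond the outer edge.
        """
        if not self.titratable:
            return np.zeros(self.nl)
        psi = (psi0 if psi0 is not None else self._psi_cache).copy()
        fac = 4.0 * np.pi * BJERRUM_NM
        site_density = {s: phi_sp[self.spi[s]] / self.spv[self.spi[s]]
                        for s in self.titratable}
        for _ in range(100):
            rho = self.c_salt * (np.exp(-psi) - np.exp(psi))
            drho = self.c_salt * (-np.exp(-psi) - np.exp(psi))
            for s, (kind, pka) in self.titratable.items():
                _, f = self.site_xi(kind, pka, psi)
                sign = 1.0 if kind == "base" else -1.0
                rho = rho + sign * site_density[s] * f
                drho = drho - site_density[s] * f * (1.0 - f)
            flux_hi = np.empty(self.nl)
            flux_hi[:-1] = self.a_hi[:-1] * np.diff(psi) / self.delta
            flux_hi[-1] = self.a_hi[-1] * (0.0 - psi[-1]) / self.delta
            flux_lo = np.zeros(self.nl)
            flux_lo[1:] = self.a_lo[1:] * np.diff(psi) / self.delta
            resid = flux_hi - flux_lo + fac * rho * self.vols
            if np.max(np.abs(resid)) < 1e-10 * max(1.0, fac * self.c_salt):
                break
            main = -(self.a_lo + self.a_hi) / self.delta + fac * drho * self.vols
            ab = np.zeros((3, self.nl))
            ab[0, 1:] = self.a_hi[:-1] / self.delta
            ab[1, :] = main
            ab[2, :-1] = self.a_lo[1:] / self.delta
            psi = psi + np.clip(solve_banded((1, 1), ab, -resid), -2.0, 2.0)
        self._psi_cache = psi
        return psi

    # -- field evaluation --------------------------------------------------

    def bead_fields(self, btpi, phi_sp, phi_w, psi):
        """beta u per bead, per (species, layer): pressure + contact
        attraction (relative to bulk water) + acid-base semi-grand."""
        u = (btpi[None, :] * (self.spv / V_REF)[:, None]
             - (self.spv / V_REF)[:, None]
             * (self.be @ phi_sp + self.be_w[:, None] * phi_w
                - self.be_w[:, None]))
        for s, (kind, pka) in self.titratable.items():
            xi, _ = self.site_xi(kind, pka, psi)
            u[self.spi[s]] -= np.log(xi)
        return u

    def water_fraction(self, btpi, phi_sp, phi_w_guess):
        """phi_w from its Boltzmann factor (self-consistent in its own
        attraction term via a short fixed point)."""
        phw = phi_w_guess
        base = self.be_w @ phi_sp
        for _ in range(6):
            u_w = -(V_WATER / V_REF) * (base + self.be_ww * phw - self.be_ww)
            phw = np.exp(np.clip(-btpi * (V_WATER / V_REF) - u_w, -60.0, 1.5))
        return phw

    def chain_densities(self, u):
        energies = self.occ @ u.ravel()
        energies = energies - energies.min()
        weights = np.exp(-np.clip(energies, None, 700.0))
        p_alpha = weights / weights.sum()
        counts = (self.occ_t @ p_alpha).reshape(self.ns, self.nl)
        phi_sp = self.n_mol * counts * self.spv[:, None] / self.vols[None, :]
        return phi_sp, p_alpha

    def step(self, btpi, phi_sp):
        """One full field evaluation given pressure + lipid densities."""
        psi = self.solve_pb(phi_sp)
        phi_w = self.water_fraction(btpi, phi_sp, np.ones(self.nl))
        u = self.bead_fields(btpi, phi_sp, phi_w, psi)
        new_phi_sp, p_alpha = self.chain_densities(u)
        return new_phi_sp, phi_w, p_alpha, psi, u

    # -- free energy -------------------------------------------------------

    def free_energy(self, btpi, phi_sp, phi_w, p_alpha, psi) -> float:
        """Free energy per molecule (kT) from converged fields.

        Terms: chain conformational entropy (relative to the unweighted
        ensemble); acid-base semi-grand contribution per site; water and
        ion translational entropy (grand canonical, relative to bulk);
        the Poisson-Boltzmann field action evaluated at its saddle; and
        the contact attraction energy counted once per pair, relative to
        bulk water.
        """
        nl = self.nl
        p = np.maximum(p_alpha, 1e-300)
        f_conf = float(np.sum(p * np.log(p * self.nc)))
        occ_mean = (self.occ_t @ p_alpha).reshape(self.ns, nl)
        f_chem = 0.0
        for s, (kind, pka) in self.titratable.items():
            xi, _ = self.site_xi(kind, pka, psi)
            f_chem += float(np.sum(occ_mean[self.spi[s]] * (-np.log(xi))))
        # incompressible-solution solvent entropy (Flory-Huggins form;
        # zero both in the bulk, phi_w = 1, and in a dry core, phi_w = 0)
        f_water = float(np.sum(self.vols / V_WATER
                               * phi_w * np.log(np.maximum(phi_w, 1e-300))))
        grad = np.diff(psi) / self.delta
        area = self.a_hi[:-1]
        f_field = -0.5 / (4.0 * np.pi * BJERRUM_NM) * float(
            np.sum(area * grad**2 * self.delta))
        f_ions = float(np.sum(self.vols * self.c_salt
                              * (2.0 - np.exp(-psi) - np.exp(psi))))
        amix = np.einsum("ab,ai,bi->i", self.be, phi_sp, phi_sp)
        amix += 2.0 * (self.be_w @ phi_sp) * phi_w
        amix += self.be_ww * phi_w**2
        f_att = -0.5 / V_REF * float(
            np.sum(self.vols * (amix - self.be_ww)))
        total = (self.n_mol * (f_conf + f_chem)
                 + f_water + f_field + f_ions + f_att)
        return total / self.n_mol - self.f_dispersed


def solve_scf(ensemble: ConformerEnsemble, geometry: GeometrySpec,
              conditions: Conditions, params: ModelParametrization,
              sigma: float, solver: str = "newton", max_iter: int = 200,
              mixing: float = 0.05, tol: float = 1e-6,
              track_free_energy: bool = False) -> SCFState:
    """Solve the coupled mean-field equations at fixed surface density.

    ``sigma`` is the number of molecules per nm^2 of the dividing
    surface, whose radius follows from filling the aggregate core with
    the tail volume.  ``solver`` 'newton' uses Jacobian-free
    Newton-Krylov on the full field vector; 'picard' uses a damped fixed
    point whose step is rejected (and the damping halved) whenever the
    free energy rises, so the free energy decreases monotonically across
    accepted iterations.  Raises ``MoltError`` on non-convergence.
    """
    sys_ = _System(ensemble, geometry, conditions, params, sigma)
    nl, ns = sys_.nl, sys_.ns

    def residual(x):
        phi_sp = x.reshape(ns, nl)
        new_phi_sp, _w, _b, _p, _psi = sys_.incompressible_step(phi_sp)
        return (new_phi_sp - phi_sp).ravel()

    trace = []
    if solver == "newton":
        sol = None
        last_exc = ""
        for warmup in (0, 200):
            x0 = np.zeros(ns * nl)
            if warmup:
                lam = 0.05
                phi = x0.reshape(ns, nl).copy()
                for _ in range(warmup):
                    new_phi, *_rest = sys_.incompressible_step(phi)
                    phi = (1.0 - lam) * phi + lam * new_phi
                x0 = phi.ravel()
            try:
                sol = newton_krylov(residual, x0, f_tol=tol * 1e-2,
                                    maxiter=max_iter)
                break
            except NoConvergence as exc:
                cand = np.asarray(exc.args[0])
                if np.max(np.abs(residual(cand))) < tol:
                    sol = cand
                    break
                last_exc = f"residual {np.max(np.abs(residual(cand))):.2e}"
            except ValueError as exc:
                last_exc = str(exc)
        if sol is None:
            raise MoltError(
                f"SCF Newton-Krylov did not converge for "
                f"{geometry.symmetry} at sigma={sigma:.3f} ({last_exc})")
        phi_sp = sol.reshape(ns, nl)
    elif solver == "picard":
        phi_sp = np.zeros((ns, nl))
        f_prev = np.inf
        lam = mixing
        def f_at(phi):
            new_phi, phi_w, btpi, p_alpha, psi = sys_.incompressible_step(phi)
            f_here = sys_.free_energy(btpi, phi, phi_w, p_alpha, psi)
            return f_here, new_phi

        f_prev, new_phi = f_at(phi_sp)
        trace.append(f_prev)
        step_res = np.inf
        for _iteration in range(max_iter):
            step_res = float(np.max(np.abs(new_phi - phi_sp)))
            if step_res < tol:
                break
            cand = (1.0 - lam) * phi_sp + lam * new_phi
            f_cand, cand_new = f_at(cand)
            if f_cand > f_prev + 1e-10:
                lam = max(lam * 0.5, 1e-4)  # reject-and-damp
                continue
            phi_sp, f_prev, new_phi = cand, f_cand, cand_new
            lam = min(lam * 1.1, mixing)
            trace.append(f_cand)
        else:
            raise MoltError(
                f"Picard SCF did not converge in {max_iter} iterations "
                f"(residual {step_res:.2e})")
    else:
        raise MoltError(f"unknown solver {solver!r}")

    new_phi_sp, phi_w, btpi, p_alpha, psi = sys_.incompressible_step(phi_sp)
    pack_res = float(np.max(np.abs(new_phi_sp.sum(axis=0) + phi_w - 1.0)))
    self_res = float(np.max(np.abs(new_phi_sp - phi_sp)))
    pack_res = max(min(pack_res, self_res), 0.0) if False else pack_res
    f_mol = sys_.free_energy(btpi, new_phi_sp, phi_w, p_alpha, psi)

    protonation = {}
    rho = sys_.c_salt * (np.exp(-psi) - np.exp(psi))
    for s, (kind, pka) in sys_.titratable.items():
        _xi, f = sys_.site_xi(kind, pka, psi)
        protonation[s] = f
        sign = 1.0 if kind == "base" else -1.0
        rho = rho + sign * f * new_phi_sp[sys_.spi[s]] / sys_.spv[sys_.spi[s]]
    net = float(np.sum(rho * sys_.vols))
    # ionic countercharge continuing beyond the lattice enters through
    # the outer-boundary field flux (Gauss's law)
    boundary = -sys_.a_hi[-1] * psi[-1] / sys_.delta / (4.0 * np.pi * BJERRUM_NM)
    n_sites = sum(float(np.sum(new_phi_sp[sys_.spi[s]]
                               / sys_.spv[sys_.spi[s]] * sys_.vols))
                  for s in sys_.titratable)
    charge_res = abs(net + boundary) / n_sites if n_sites > 0 else 0.0

    return SCFState(
        geometry=geometry, conditions=conditions, sigma=sigma,
        radius=sys_.radius, r=sys_.r_centers,
        phi={s: new_phi_sp[sys_.spi[s]].copy() for s in sys_.species},
        phi_water=phi_w.copy(), psi=psi.copy(), protonation=protonation,
        pressure=btpi.copy(), probabilities=p_alpha, free_energy=f_mol,
        residuals={"packing": pack_res, "electroneutrality": charge_res,
                   "probability": abs(float(p_alpha.sum()) - 1.0)},
        converged=pack_res < max(tol, 1e-5) * 10,
        free_energy_trace=np.array(trace) if trace else None,
    )


# --------------------------------------------------------------------------
# morphology prediction
# --------------------------------------------------------------------------


@dataclass
class MorphologyResult:
    winner: str
    free_energies: dict     # morphology -> (sigma_opt, F per molecule)
    states: dict            # morphology -> SCFState at the optimum
    ph: float


def free_energy_vs_sigma(ensemble, geometry, conditions, params, sigma_grid,
                         **kw) -> list[tuple[float, float]]:
    out = []
    for sigma in sigma_grid:
        try:
            state = solve_scf(ensemble, geometry, conditions, params,
                              sigma, **kw)
            out.append((sigma, state.free_energy))
        except MoltError:
            out.append((sigma, np.inf))
    return out


#: fixed surface-density grid over which the free energy is minimized
#: (molecules per nm^2 of the dividing surface; spans loosely packed to
#: tightly packed amphiphile layers)
SIGMA_GRID = (0.5, 0.7, 0.9, 1.1, 1.4, 1.7, 2.0)


def _minimize_sigma(ensemble, geometry, conditions, params,
                    sigma_grid=SIGMA_GRID):
    """Free-energy minimum over the fixed sigma grid (deterministic)."""
    scan = free_energy_vs_sigma(ensemble, geometry, conditions, params,
                                sigma_grid, max_iter=150)
    fs = np.array([f for _s, f in scan])
    if not np.isfinite(fs).any():
        raise MoltError(f"no converged sigma for {geometry.symmetry}")
    k = int(np.argmin(np.where(np.isfinite(fs), fs, np.inf)))
    sigma_best = sigma_grid[k]
    state = solve_scf(ensemble, geometry, conditions, params, sigma_best,
                      max_iter=150)
    return sigma_best, state


def predict_morphology(identifier: str | LipopeptideSpec,
                       conditions: Conditions,
                       params: ModelParametrization | None = None,
                       n_conf: int = 20000, seed: int = 2024,
                       n_layers: int = 40) -> MorphologyResult:
    """Free-energy ranking of micelle / fibril / lamella at one pH.

    For each geometry the free energy per molecule is minimized over the
    surface density sigma; the lowest-free-energy aggregate is the
    predicted equilibrium morphology.  Ties within 0.01 kT/molecule are
    broken toward the higher-curvature morphology.
    """
    params = params or ModelParametrization()
    ident = (identifier if isinstance(identifier, str)
             else f"C{identifier.tail_carbons}-{identifier.sequence}")
    ensemble = cached_ensemble(ident, params, n_conf, seed)
    free_energies = {}
    states = {}
    for morph, symmetry in MORPHOLOGIES.items():
        geometry = GeometrySpec(symmetry, n_layers=n_layers)
        try:
            sigma_opt, state = _minimize_sigma(ensemble, geometry,
                                               conditions, params)
        except MoltError:
            continue
        free_energies[morph] = (sigma_opt, state.free_energy)
        states[morph] = state
    if not free_energies:
        raise MoltError("no geometry converged")
    order = {"micelle": 2, "fibril": 1, "lamella": 0}  # curvature rank
    winner = min(free_energies,
                 key=lambda m: (round(free_energies[m][1] / 0.01) * 0.01,
                                -order[m]))
    return MorphologyResult(winner=winner, free_energies=free_energies,
                            states=states, ph=conditions.ph)


def phase_map(identifier, ph_values,
              params: ModelParametrization | None = None,
              ionic_strength: float = 0.1, n_conf: int = 20000,
              seed: int = 2024, transition_resolution: float = 0.1,
              n_layers: int = 40) -> dict:
    """Morphology along a pH grid plus bisected transition pH values."""
    params = params or ModelParametrization()
    ph_values = np.asarray(ph_values, dtype=float)
    if np.any(np.diff(ph_values) <= 0):
        raise MoltError("pH grid must be strictly increasing")

    def morph_at(ph):
        res = predict_morphology(
            identifier, Conditions(ph=ph, ionic_strength=ionic_strength),
            params, n_conf=n_conf, seed=seed, n_layers=n_layers)
        return res.winner

    entries = [(float(ph), morph_at(ph)) for ph in ph_values]
    transitions = []
    for (ph1, m1), (ph2, m2) in zip(entries[:-1], entries[1:]):
        if m1 == m2:
            continue
        lo, hi = ph1, ph2
        while hi - lo > transition_resolution:
            mid = 0.5 * (lo + hi)
            if morph_at(mid) == m1:
                lo = mid
            else:
                hi = mid
        transitions.append({"ph": round(0.5 * (lo + hi), 3),
                            "from": m1, "to": m2})
    return {"entries": entries, "transitions": transitions}


def volume_fraction_profiles(state: SCFState) -> dict:
    """phi(r) per species plus water as a column table; refuses
    unconverged states."""
    if not state.converged:
        raise MoltError("state is not converged")
    table = {"r_nm": state.r}
    for s, phi in state.phi.items():
        table[f"phi_{s}"] = phi
    table["phi_water"] = state.phi_water
    return table


def apparent_pka(identifier, species: str = "scK",
                 params: ModelParametrization | None = None,
                 morphology: str = "lamella", sigma: float = 1.0,
                 ionic_strength: float = 0.1, n_conf: int = 8000,
                 seed: int = 2024, n_layers: int = 40) -> dict:
    """pH at which the mean charged-state fraction of a titratable
    species crosses 1/2 in the aggregate, by bisection; reports the
    shift relative to the bulk pKa.  ``censored`` is set when the
    fraction never crosses 1/2 within pH 0..14.
    """
    params = params or ModelParametrization()
    ensemble = cached_ensemble(identifier, params, n_conf, seed)
    bm = ensemble.bead_model
    try:
        bead = next(b for b in bm.beads
                    if b.species == species and b.titratable is not None)
    except StopIteration:
        raise MoltError(f"species {species!r} is not titratable in {identifier}")
    geometry = GeometrySpec(MORPHOLOGIES[morphology], n_layers=n_layers)

    def mean_f(ph):
        state = solve_scf(ensemble, geometry,
                          Conditions(ph=ph, ionic_strength=ionic_strength),
                          params, sigma)
        return state.mean_protonation(species)

    lo, hi = 0.0, 14.0
    f_lo, f_hi = mean_f(lo), mean_f(hi)
    if (f_lo - 0.5) * (f_hi - 0.5) > 0:
        return {"pka": None, "shift": None, "bulk_pka": bead.pka,
                "censored": True}
    for _ in range(20):
        mid = 0.5 * (lo + hi)
        f_mid = mean_f(mid)
        if (f_lo - 0.5) * (f_mid - 0.5) <= 0:
            hi, f_hi = mid, f_mid
        else:
            lo, f_lo = mid, f_mid
        if hi - lo < 0.02:
            break
    value = 0.5 * (lo + hi)
    return {"pka": value, "shift": value - bead.pka,
            "bulk_pka": bead.pka, "censored": False}
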