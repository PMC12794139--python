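"""Per-structure metrics for built assemblies and external trajectories.

All operations take either an :class:`~lipoforge.assembly.AssemblyModel`
or a biotite ``AtomArray`` (``AtomArrayStack`` / list of assemblies for
trajectory operations).  Distances are Angstrom, energies kJ/mol,
densities g/cm^3 unless stated otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree, ConvexHull

from .lipopeptide import AROMATIC_RING_ATOMS, AVERAGE_MASS, measure_dihedral
from .assembly import AssemblyModel

__all__ = [
    "AnalysisError",
    "HBondCriterion",
    "AnalysisReport",
    "count_hbonds",
    "aromatic_rdf",
    "first_rdf_peak",
    "sasa_and_ap",
    "cohesive_energy_density",
    "density_profile",
    "ramachandran_map",
    "debye_saxs",
]


class AnalysisError(RuntimeError):
    pass


@dataclass(frozen=True)
class HBondCriterion:
    """Geometric hydrogen-bond definition.

    ``max_distance`` is the donor-acceptor heavy-atom cutoff (A);
    ``max_angle`` the H-donor-acceptor angle cutoff (deg), or ``None``
    for a distance-only test.
    """

    max_distance: float = 3.5
    max_angle: float | None = 30.0

    def __post_init__(self):
        if self.max_distance <= 0:
            raise AnalysisError("H-bond distance cutoff must be positive")
        if self.max_angle is not None and not (0.0 < self.max_angle <= 90.0):
            raise AnalysisError("H-bond angle cutoff must be in (0, 90] deg")


@dataclass
class AnalysisReport:
    """Bag of per-structure metrics filled by the individual operations."""

    hbonds_per_molecule: float | None = None
    hbond_capable_pairs: float | None = None
    rdf: tuple[np.ndarray, np.ndarray] | None = None
    sasa: np.ndarray | None = None
    aggregation_propensity: float | None = None
    dg_solv: float | None = None
    cohesive_energy_density: float | None = None
    density_profiles: dict = field(default_factory=dict)
    ramachandran: tuple | None = None


# --------------------------------------------------------------------------
# structure adapters
# --------------------------------------------------------------------------


def _atoms_of(structure) -> dict:
    """Flatten a structure to parallel arrays with molecule ids.

    AssemblyModel: molecule ids are molecule indices.  biotite
    AtomArray: a new molecule starts wherever the tail residue (name
    'PLM'/'AC*') recurs, falling back to one molecule per chain.
    """
    if isinstance(structure, AssemblyModel):
        if not structure.molecules:
            raise AnalysisError("empty structure")
        names, elements, res_names, res_ids, mol_ids, coords = [], [], [], [], [], []
        for i, mol in enumerate(structure.molecules):
            names.extend(mol.names)
            elements.extend(mol.elements)
            res_names.extend(mol.res_names)
            res_ids.extend(mol.res_ids.tolist())
            mol_ids.extend([i] * mol.n_atoms)
            coords.append(mol.coords)
        return {
            "names": np.array(names), "elements": np.array(elements),
            "res_names": np.array(res_names), "res_ids": np.array(res_ids),
            "mol_ids": np.array(mol_ids), "coords": np.concatenate(coords),
        }
    # biotite AtomArray
    arr = structure
    names = np.asarray(arr.atom_name)
    res_names = np.asarray(arr.res_name)
    tail_start = np.array([rn == "PLM" or rn.startswith("AC")
                           for rn in res_names])
    mol_ids = np.zeros(len(names), dtype=int)
    if tail_start.any():
        res_change = np.zeros(len(names), dtype=bool)
        res_change[1:] = (np.asarray(arr.res_id)[1:] != np.asarray(arr.res_id)[:-1])
        new_mol = tail_start & (res_change | (np.arange(len(names)) == 0))
        mol_ids = np.cumsum(new_mol) - 1
    else:
        chains = np.asarray(arr.chain_id)
        new_chain = np.ones(len(names), dtype=bool)
        new_chain[1:] = chains[1:] != chains[:-1]
        mol_ids = np.cumsum(new_chain) - 1
    return {
        "names": names, "elements": np.asarray(arr.element),
        "res_names": res_names, "res_ids": np.asarray(arr.res_id),
        "mol_ids": mol_ids, "coords": np.asarray(arr.coord),
    }


def _frames_of(trajectory) -> list[dict]:
    if isinstance(trajectory, (list, tuple)):
        return [_atoms_of(f) for f in trajectory]
    if isinstance(trajectory, AssemblyModel):
        return [_atoms_of(trajectory)]
    if hasattr(trajectory, "stack_depth"):  # AtomArrayStack
        return [_atoms_of(trajectory[i]) for i in range(trajectory.stack_depth())]
    return [_atoms_of(trajectory)]


def _masses(atoms: dict) -> np.ndarray:
    return np.array([AVERAGE_MASS.get(e.capitalize(), 0.0)
                     for e in atoms["elements"]])


# --------------------------------------------------------------------------
# hydrogen bonds
# --------------------------------------------------------------------------

_BACKBONE_ACCEPTORS = {"O", "O1", "OXT"}
_BACKBONE_DONOR_N = {"N"}


def count_hbonds(structure, criterion: HBondCriterion | None = None,
                 selection: str = "backbone",
                 intermolecular: bool = True) -> tuple[float, float]:
    """Hydrogen bonds and H-bond-capable pairs, per molecule.

    A bond requires donor-acceptor distance <= cutoff and (unless the
    criterion is distance-only) an H-donor-acceptor angle <= cutoff.
    The capable-pair count is the number of donor/acceptor heavy-atom
    pairs within the distance cutoff regardless of angle.  By default
    only intermolecular pairs are counted.

    ``selection`` 'backbone' restricts donors to amide N-H and acceptors
    to carbonyl/carboxyl O; 'all' admits every N/O.
    """
    criterion = criterion or HBondCriterion()
    atoms = _atoms_of(structure)
    xyz = atoms["coords"]
    names = atoms["names"]
    elements = atoms["elements"]
    mol_ids = atoms["mol_ids"]
    n_mol = int(mol_ids.max()) + 1 if len(mol_ids) else 0

    if selection == "backbone":
        donor_mask = np.isin(names, list(_BACKBONE_DONOR_N))
        acceptor_mask = np.isin(names, list(_BACKBONE_ACCEPTORS))
    elif selection == "all":
        donor_mask = np.isin(elements, ["N", "O"])
        acceptor_mask = np.isin(elements, ["N", "O"])
    else:
        raise AnalysisError(f"unknown selection {selection!r}")

    donors = np.where(donor_mask)[0]
    acceptors = np.where(acceptor_mask)[0]
    if len(donors) == 0 or len(acceptors) == 0:
        return 0.0, 0.0

    # attach hydrogens to donors (covalent H within 1.25 A)
    h_idx = np.where(elements == "H")[0]
    donor_h: dict[int, list[int]] = {}
    if len(h_idx):
        h_tree = cKDTree(xyz[h_idx])
        for d in donors:
            close = h_tree.query_ball_point(xyz[d], 1.25)
            if close:
                donor_h[d] = [int(h_idx[k]) for k in close]
    if criterion.max_angle is not None and not donor_h:
        raise AnalysisError(
            "no hydrogens found for the angle test; use a distance-only "
            "criterion (max_angle=None)")

    acc_tree = cKDTree(xyz[acceptors])
    n_bonds = 0
    n_capable = 0
    for d in donors:
        for k in acc_tree.query_ball_point(xyz[d], criterion.max_distance):
            a = int(acceptors[k])
            if a == d:
                continue
            if intermolecular and mol_ids[a] == mol_ids[d]:
                continue
            n_capable += 1
            if criterion.max_angle is None:
                n_bonds += 1
                continue
            ok = False
            for h in donor_h.get(d, ()):
                v1 = xyz[h] - xyz[d]
                v2 = xyz[a] - xyz[d]
                cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                if np.degrees(np.arccos(np.clip(cosang, -1, 1))) <= criterion.max_angle:
                    ok = True
                    break
            if ok:
                n_bonds += 1
    denom = max(n_mol, 1)
    return n_bonds / denom, n_capable / denom


# --------------------------------------------------------------------------
# aromatic-stacking RDF
# --------------------------------------------------------------------------


def aromatic_centroids(structure) -> np.ndarray:
    """Six-membered-ring centroids of Trp (benzene ring of the indole)
    and Tyr (phenol ring), one per aromatic residue."""
    atoms = _atoms_of(structure)
    xyz = atoms["coords"]
    centroids = []
    key = np.stack([atoms["mol_ids"], atoms["res_ids"]], axis=1)
    order = np.lexsort((atoms["res_ids"], atoms["mol_ids"]))
    # group atoms by (molecule, residue)
    groups: dict[tuple, list[int]] = {}
    for i in order:
        rn = atoms["res_names"][i]
        if rn in AROMATIC_RING_ATOMS:
            groups.setdefault((atoms["mol_ids"][i], atoms["res_ids"][i]), []).append(i)
    for (mi, ri), idx in sorted(groups.items()):
        ring_names = AROMATIC_RING_ATOMS[atoms["res_names"][idx[0]]]
        sel = [i for i in idx if atoms["names"][i] in ring_names]
        if len(sel) == 6:
            centroids.append(xyz[sel].mean(axis=0))
    if not centroids:
        raise AnalysisError("structure contains no aromatic (Trp/Tyr) residues")
    return np.array(centroids)


def aromatic_rdf(structure, bin_width: float = 0.5, r_max: float = 20.0
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Centroid-centroid radial distribution function g(r).

    Normalized against an ideal gas of the same centroid density in the
    rectangular analysis volume (bounding box of all atoms); returns
    (bin centers, g).
    """
    cent = aromatic_centroids(structure)
    atoms = _atoms_of(structure)
    box = atoms["coords"].max(axis=0) - atoms["coords"].min(axis=0)
    volume = float(np.prod(np.maximum(box, 1.0)))
    return rdf_from_points(cent, volume, bin_width, r_max)


def rdf_from_points(points: np.ndarray, volume: float,
                    bin_width: float = 0.5, r_max: float = 20.0
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Pair RDF of a point set in a given analysis volume (A^3)."""
    n = len(points)
    if n < 2:
        raise AnalysisError("need at least two points for an RDF")
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    tree = cKDTree(points)
    pairs = tree.query_pairs(r_max, output_type="ndarray")
    if len(pairs):
        dist = np.linalg.norm(points[pairs[:, 0]] - points[pairs[:, 1]], axis=1)
        hist, _ = np.histogram(dist, bins=edges)
    else:
        hist = np.zeros(len(centers))
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    ideal = n * (n - 1) / 2.0 * shell_vol / volume
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(ideal > 0, hist / ideal, 0.0)
    return centers, g


def first_rdf_peak(r: np.ndarray, g: np.ndarray,
                   min_height: float = 1.0) -> float:
    """Position of the first local maximum of g(r) above ``min_height``."""
    for i in range(1, len(g) - 1):
        if g[i] >= min_height and g[i] >= g[i - 1] and g[i] > g[i + 1]:
            return float(r[i])
    raise AnalysisError("no RDF peak found")


# --------------------------------------------------------------------------
# SASA and aggregation propensity
# --------------------------------------------------------------------------


def _to_atom_array(structure):
    import biotite.structure as struc

    if isinstance(structure, AssemblyModel):
        from .assembly import to_atom_array

        return to_atom_array(structure)
    return structure


def sasa_and_ap(trajectory, probe_radius: float = 1.4,
                point_number: int = 500, final_window: int = 1,
                vdw_radii="Single") -> dict:
    """Shrake-Rupley solvent-accessible surface area per frame, and the
    aggregation propensity AP = SASA(first frame) / SASA(final frames).

    The denominator averages the last ``final_window`` frames.  With a
    single frame the SASA is returned and AP is ``None``.  Units: A^2.
    """
    import biotite.structure as struc

    frames = trajectory if isinstance(trajectory, (list, tuple)) else None
    if frames is None:
        if hasattr(trajectory, "stack_depth"):
            frames = [trajectory[i] for i in range(trajectory.stack_depth())]
        else:
            frames = [trajectory]
    sasa = []
    for frame in frames:
        arr = _to_atom_array(frame)
        per_atom = struc.sasa(arr, probe_radius=probe_radius,
                              point_number=point_number,
                              vdw_radii=vdw_radii, ignore_ions=False)
        sasa.append(float(np.nansum(per_atom)))
    sasa = np.array(sasa)
    if len(sasa) < 2:
        return {"sasa": sasa, "ap": None}
    final = float(np.mean(sasa[-final_window:]))
    return {"sasa": sasa, "ap": float(sasa[0] / final)}


# --------------------------------------------------------------------------
# cohesive energy density
# --------------------------------------------------------------------------

#: generic per-element Lennard-Jones parameters (sigma A, epsilon kJ/mol)
LJ_PARAMS = {
    "C": (3.40, 0.36), "H": (2.50, 0.065), "N": (3.25, 0.71),
    "O": (2.96, 0.88), "S": (3.55, 1.05),
}
_COULOMB_K = 1389.35458  # kJ/mol * A / e^2


def cohesive_energy_density(structure, cutoff: float = 10.0,
                            charges: np.ndarray | None = None,
                            volume_nm3: float | None = None,
                            lj_params: dict | None = None) -> float:
    """Intermolecular nonbonded energy per aggregate volume, kJ/mol/nm^3.

    Energy is a Lennard-Jones sum (Lorentz-Berthelot mixing) over
    intermolecular pairs within ``cutoff`` A, plus Coulomb terms when
    ``charges`` (e units, per atom) are given.  The volume defaults to
    the convex hull of the heavy atoms, converted to nm^3.  Negative
    values mean cohesion.
    """
    lj = lj_params or LJ_PARAMS
    atoms = _atoms_of(structure)
    xyz = atoms["coords"]
    mol_ids = atoms["mol_ids"]
    elements = atoms["elements"]
    if volume_nm3 is None:
        heavy = elements != "H"
        pts = xyz[heavy]
        if len(pts) < 4:
            raise AnalysisError(
                "aggregate volume undefined (need >= 4 heavy atoms or an "
                "explicit volume_nm3)")
        volume_nm3 = ConvexHull(pts).volume / 1000.0
    sigma = np.array([lj.get(e, (3.4, 0.3))[0] for e in elements])
    eps = np.array([lj.get(e, (3.4, 0.3))[1] for e in elements])
    tree = cKDTree(xyz)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if len(pairs):
        pairs = pairs[mol_ids[pairs[:, 0]] != mol_ids[pairs[:, 1]]]
    energy = 0.0
    if len(pairs):
        d = np.linalg.norm(xyz[pairs[:, 0]] - xyz[pairs[:, 1]], axis=1)
        s = 0.5 * (sigma[pairs[:, 0]] + sigma[pairs[:, 1]])
        e = np.sqrt(eps[pairs[:, 0]] * eps[pairs[:, 1]])
        sr6 = (s / d) ** 6
        energy += float(np.sum(4.0 * e * (sr6**2 - sr6)))
        if charges is not None:
            q = np.asarray(charges)
            energy += float(np.sum(
                _COULOMB_K * q[pairs[:, 0]] * q[pairs[:, 1]] / d))
    return energy / volume_nm3


# --------------------------------------------------------------------------
# density profiles
# --------------------------------------------------------------------------

#: amu/A^3 -> g/cm^3
_DENSITY_CONV = 1.66053907


def default_species_groups(sequence: str | None = None):
    """Standard grouping: tail, per-residue-type peptide groups."""
    def tail(atoms, i):
        return atoms["res_names"][i] == "PLM" or atoms["res_names"][i].startswith("AC")

    groups = {"tail": tail}
    for rn, label in (("LYS", "K"), ("TRP", "W"), ("TYR", "Y"), ("GLY", "G"),
                      ("ALA", "A")):
        groups[label] = (lambda atoms, i, rn=rn: atoms["res_names"][i] == rn)
    return groups


def density_profile(structure, mode: str = "axis", axis: int = 0,
                    species_groups: dict | None = None,
                    bin_width: float = 1.0, r_max: float | None = None
                    ) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Mass density profiles per species group, in g/cm^3.

    mode 'axis': binned along Cartesian ``axis`` relative to the
    center of mass (bilayer normal).  mode 'radial': binned radially
    about the y axis (fibril).  Returns {group: (bin centers A, rho)}.
    Groups with no atoms yield zero profiles.
    """
    atoms = _atoms_of(structure)
    xyz = atoms["coords"]
    masses = _masses(atoms)
    groups = species_groups or default_species_groups()
    com = (xyz * masses[:, None]).sum(axis=0) / masses.sum()
    rel = xyz - com
    if mode == "axis":
        coord = rel[:, axis]
        span = (coord.min(), coord.max())
        edges = np.arange(span[0] - bin_width, span[1] + 2 * bin_width, bin_width)
        others = [k for k in range(3) if k != axis]
        cross = np.prod([rel[:, k].max() - rel[:, k].min() for k in others])
        bin_vol = np.full(len(edges) - 1, max(cross, 1e-9) * bin_width)
    elif mode == "radial":
        coord = np.hypot(rel[:, 0], rel[:, 2])
        r_hi = r_max if r_max is not None else float(coord.max()) + bin_width
        edges = np.arange(0.0, r_hi + bin_width, bin_width)
        height = rel[:, 1].max() - rel[:, 1].min()
        bin_vol = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2) * max(height, 1e-9)
    else:
        raise AnalysisError(f"unknown profile mode {mode!r}")
    centers = 0.5 * (edges[:-1] + edges[1:])
    out = {}
    for name, selector in groups.items():
        mask = np.array([bool(selector(atoms, i)) for i in range(len(xyz))])
        if not mask.any():
            out[name] = (centers, np.zeros(len(centers)))
            continue
        hist, _ = np.histogram(coord[mask], bins=edges, weights=masses[mask])
        out[name] = (centers, hist / bin_vol * _DENSITY_CONV)
    return out


# --------------------------------------------------------------------------
# Ramachandran free-energy map
# --------------------------------------------------------------------------


def ramachandran_map(trajectory, bins: int = 36
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """2D map of -ln P(phi, psi) over all residues and frames.

    phi of residue 1 uses the acyl carbonyl carbon as the preceding C
    (N-acylated convention).  Returns (phi_edges, psi_edges, neg_log_p);
    the map is offset so its minimum is 0 and P integrates to 1.
    """
    frames = trajectory if isinstance(trajectory, (list, tuple)) else [trajectory]
    phis, psis = [], []
    for frame in frames:
        if not isinstance(frame, AssemblyModel):
            raise AnalysisError(
                "ramachandran_map expects AssemblyModel frames (use the "
                "builder or group atoms into molecules first)")
        for mol in frame.molecules:
            n_res = len(mol.spec.sequence) if mol.spec else int(mol.res_ids.max()) - 1
            if n_res < 2:
                raise AnalysisError("need >= 2 residues for dihedrals")
            from .lipopeptide import backbone_dihedrals

            for phi, psi in backbone_dihedrals(mol):
                phis.append(phi)
                psis.append(psi)
    edges = np.linspace(-180.0, 180.0, bins + 1)
    hist, _, _ = np.histogram2d(phis, psis, bins=[edges, edges])
    p = hist / hist.sum()
    with np.errstate(divide="ignore"):
        neg_log = -np.log(p)
    neg_log -= neg_log[np.isfinite(neg_log)].min()
    return edges, edges, neg_log


# --------------------------------------------------------------------------
# Debye-equation SAXS
# --------------------------------------------------------------------------

#: Cromer-Mann coefficients (a1..a4, b1..b4, c) for X-ray form factors
CROMER_MANN = {
    "H": ([0.489918, 0.262003, 0.196767, 0.049879],
          [20.6593, 7.74039, 49.5519, 2.20159], 0.001305),
    "C": ([2.31000, 1.02000, 1.58860, 0.865000],
          [20.8439, 10.2075, 0.568700, 51.6512], 0.215600),
    "N": ([12.2126, 3.13220, 2.01250, 1.16630],
          [0.005700, 9.89330, 28.9975, 0.582600], -11.529),
    "O": ([3.04850, 2.28680, 1.54630, 0.867000],
          [13.2771, 5.70110, 0.323900, 32.9089], 0.250800),
    "S": ([6.90530, 5.20340, 1.43790, 1.58630],
          [1.46790, 22.2151, 0.253600, 56.1720], 0.866900),
}

#: displaced solvent volumes per element, A^3 (atomic group volumes)
DISPLACED_VOLUME = {"H": 5.15, "C": 16.44, "N": 2.49, "O": 9.13, "S": 19.86}
_WATER_EDENSITY = 0.334  # e / A^3


def xray_form_factor(element: str, q: np.ndarray) -> np.ndarray:
    """Cromer-Mann X-ray atomic form factor f(q), q in 1/A."""
    a, b, c = CROMER_MANN[element.capitalize()]
    s2 = (q / (4.0 * np.pi)) ** 2
    f = np.full_like(q, c, dtype=float)
    for ai, bi in zip(a, b):
        f += ai * np.exp(-bi * s2)
    return f


def excess_form_factor(element: str, q: np.ndarray) -> np.ndarray:
    """Atomic form factor minus the displaced-solvent Gaussian term."""
    v = DISPLACED_VOLUME[element.capitalize()]
    solvent = _WATER_EDENSITY * v * np.exp(-(v ** (2.0 / 3.0)) * q**2 / (4.0 * np.pi))
    return xray_form_factor(element, q) - solvent


def debye_saxs(structure, q_grid, displaced_solvent: bool = True,
               unit_scatterers: bool = False, background: float = 0.0,
               histogram_bin: float | None = 0.1):
    """Scattered intensity I(q) from atomic coordinates via the Debye sum

        I(q) = sum_ij f_i(q) f_j(q) sin(q r_ij) / (q r_ij).

    ``histogram_bin`` enables distance-histogram acceleration (pair
    distances binned per element pair); pass ``None`` for the exact
    double sum.  ``unit_scatterers`` replaces the form factors with 1
    (point scatterers).  Returns a :class:`~lipoforge.saxs.ScatteringProfile`.
    """
    from .saxs import ScatteringProfile

    q = np.asarray(q_grid, dtype=float)
    atoms = _atoms_of(structure)
    xyz = atoms["coords"]
    n = len(xyz)
    if n == 0:
        raise AnalysisError("empty structure")
    elements = np.array([e.capitalize() for e in atoms["elements"]])

    if unit_scatterers:
        kinds = np.zeros(n, dtype=int)
        factors = [np.ones_like(q)]
    else:
        uniq = sorted(set(elements))
        kinds = np.array([uniq.index(e) for e in elements])
        ff = excess_form_factor if displaced_solvent else xray_form_factor
        factors = [ff(e, q) for e in uniq]

    intensity = np.zeros_like(q)
    # self terms
    for k, f in enumerate(factors):
        intensity += np.sum(kinds == k) * f**2

    if histogram_bin is None:
        for i in range(n - 1):
            d = np.linalg.norm(xyz[i + 1:] - xyz[i], axis=1)
            for j_kind in range(len(factors)):
                mask = kinds[i + 1:] == j_kind
                if not mask.any():
                    continue
                qr = np.outer(q, d[mask])
                sinc = np.where(qr > 1e-12, np.sin(qr) / np.where(qr > 0, qr, 1.0), 1.0)
                intensity += 2.0 * factors[kinds[i]] * factors[j_kind] * sinc.sum(axis=1)
    else:
        from scipy.spatial.distance import cdist

        d_max = float(np.linalg.norm(xyz.max(axis=0) - xyz.min(axis=0))) + histogram_bin
        n_bins = int(d_max / histogram_bin) + 2
        centers = histogram_bin * (np.arange(n_bins) + 0.5)
        n_kind = len(factors)
        hists = np.zeros((n_kind, n_kind, n_bins))
        chunk = max(1, int(2e7) // max(n, 1))
        for start in range(0, n, chunk):
            stop = min(start + chunk, n)
            d = cdist(xyz[start:stop], xyz)
            idx = (d / histogram_bin).astype(np.int64)
            for a in range(n_kind):
                rows = kinds[start:stop] == a
                if not rows.any():
                    continue
                for b in range(n_kind):
                    cols = kinds == b
                    if not cols.any():
                        continue
                    h = np.bincount(idx[rows][:, cols].ravel(),
                                    minlength=n_bins)
                    hists[a, b] += h[:n_bins]
        # the full n x n histogram double counts pairs and includes self
        qr = np.outer(q, centers)
        sinc = np.where(qr > 1e-12, np.sin(qr) / np.where(qr > 0, qr, 1.0), 1.0)
        for a in range(n_kind):
            for b in range(n_kind):
                h = hists[a, b].copy()
                if a == b:
                    pass  # self distances fall in the r=0 bin, handled below
                if h.any():
                    if a == b:
                        h[0] -= np.sum(kinds == a)  # remove self pairs
                    intensity += factors[a] * factors[b] * (sinc @ h)
        # self terms were already added once above; the histogram loop
        # re-added the (i == j) zero-distance contributions via h[0]
    return ScatteringProfile(q=q, intensity=intensity + background,
                             sigma=None, provenance="computed")
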