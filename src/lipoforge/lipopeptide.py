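"""Lipopeptide identity, composition and single-molecule geometry.

A lipopeptide such as ``C16-KWK`` is a short peptide whose N-terminus is
acylated with a fatty-acid tail (here palmitoyl, sixteen carbons).  This
module parses such identifiers, computes exact molecular formulas and
masses, and constructs deterministic full-atom coordinates of a single
molecule in an idealized extended (beta-strand) conformation with an
all-trans alkyl tail -- the monomer from which hydrogen-bonded sheet
assemblies are grown.

Coordinates are in Angstrom throughout; masses in g/mol.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "LipopeptideError",
    "GeometryError",
    "TitratableGroup",
    "LipopeptideSpec",
    "MoleculeGeometry",
    "parse_lipopeptide",
    "format_lipopeptide",
    "composition",
    "molecular_mass",
    "build_extended_monomer",
    "measure_dihedral",
    "backbone_dihedrals",
]


class LipopeptideError(ValueError):
    """Malformed identifier or invalid molecular specification."""


class GeometryError(RuntimeError):
    """Requested geometry is sterically impossible or ill-defined."""


# --------------------------------------------------------------------------
# element masses and residue formulas
# --------------------------------------------------------------------------

MONOISOTOPIC_MASS = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
}

AVERAGE_MASS = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
}

#: residue (= amino acid minus water) formulas for the 20 canonical codes
RESIDUE_FORMULA = {
    "G": "C2H3NO", "A": "C3H5NO", "S": "C3H5NO2", "P": "C5H7NO",
    "V": "C5H9NO", "T": "C4H7NO2", "C": "C3H5NOS", "L": "C6H11NO",
    "I": "C6H11NO", "N": "C4H6N2O2", "D": "C4H5NO3", "Q": "C5H8N2O2",
    "K": "C6H12N2O", "E": "C5H7NO3", "M": "C5H9NOS", "H": "C6H7N3O",
    "F": "C9H9NO", "R": "C6H12N4O", "Y": "C9H9NO2", "W": "C11H10N2O",
}

THREE_LETTER = {
    "G": "GLY", "A": "ALA", "S": "SER", "P": "PRO", "V": "VAL",
    "T": "THR", "C": "CYS", "L": "LEU", "I": "ILE", "N": "ASN",
    "D": "ASP", "Q": "GLN", "K": "LYS", "E": "GLU", "M": "MET",
    "H": "HIS", "F": "PHE", "R": "ARG", "Y": "TYR", "W": "TRP",
}

#: bulk (isolated-group) pKa values used for titratable sites
LYS_PKA = 10.54
TYR_PKA = 10.5
CTERM_PKA = 3.6


def _parse_formula(formula: str) -> Counter:
    counts: Counter = Counter()
    for element, num in re.findall(r"([A-Z][a-z]?)(\d*)", formula):
        if element:
            counts[element] += int(num) if num else 1
    return counts


# --------------------------------------------------------------------------
# specification
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class TitratableGroup:
    """An acid/base site: ``site`` like 'LYS3:NZ', 'TYR2:OH' or 'CTERM'."""

    site: str
    pka: float
    kind: str  # 'acid' (charged when deprotonated) or 'base' (charged when protonated)


@dataclass(frozen=True)
class LipopeptideSpec:
    """Parsed identity of a lipopeptide (tail + peptide + termini)."""

    tail_carbons: int
    sequence: str
    c_terminus: str = "COOH"
    titratable_groups: tuple[TitratableGroup, ...] = ()

    def __post_init__(self):
        if self.tail_carbons < 2:
            raise LipopeptideError(
                f"tail must have >= 2 carbons, got {self.tail_carbons}"
            )
        if len(self.sequence) < 1:
            raise LipopeptideError("empty peptide sequence")
        for code in self.sequence:
            if code not in RESIDUE_FORMULA:
                raise LipopeptideError(f"unknown residue code {code!r}")
        if self.c_terminus not in ("COOH", "COO-", "amide"):
            raise LipopeptideError(f"unknown C-terminus {self.c_terminus!r}")
        valid_sites = {"CTERM"} | {
            f"{THREE_LETTER[c]}{i + 1}:{'NZ' if c == 'K' else 'OH'}"
            for i, c in enumerate(self.sequence)
            if c in ("K", "Y")
        }
        for group in self.titratable_groups:
            if group.site not in valid_sites:
                raise LipopeptideError(
                    f"titratable site {group.site!r} does not exist in "
                    f"C{self.tail_carbons}-{self.sequence}"
                )


def parse_lipopeptide(identifier: str, titratable_cterm: bool = False) -> LipopeptideSpec:
    """Parse an identifier of the form ``C16-KWK``.

    Titratable groups are auto-populated: every lysine epsilon-amine
    (base, pKa 10.54) and every tyrosine phenol (acid, pKa 10.5).  The
    C-terminus defaults to neutral COOH and is only listed as titratable
    when ``titratable_cterm`` is set.
    """
    match = re.fullmatch(r"C(\d+)-([A-Za-z]*)", identifier.strip())
    if not match:
        raise LipopeptideError(
            f"malformed lipopeptide identifier {identifier!r}: "
            "expected 'C<number>-<residues>'"
        )
    tail = int(match.group(1))
    sequence = match.group(2).upper()
    if not sequence:
        raise LipopeptideError(f"empty peptide sequence in {identifier!r}")
    groups = []
    for i, code in enumerate(sequence):
        if code == "K":
            groups.append(TitratableGroup(f"LYS{i + 1}:NZ", LYS_PKA, "base"))
        elif code == "Y":
            groups.append(TitratableGroup(f"TYR{i + 1}:OH", TYR_PKA, "acid"))
    if titratable_cterm:
        groups.append(TitratableGroup("CTERM", CTERM_PKA, "acid"))
    return LipopeptideSpec(tail, sequence, "COOH", tuple(groups))


def format_lipopeptide(spec: LipopeptideSpec) -> str:
    return f"C{spec.tail_carbons}-{spec.sequence}"


# --------------------------------------------------------------------------
# composition and mass
# --------------------------------------------------------------------------


def composition(spec: LipopeptideSpec) -> Counter:
    """Molecular formula of the neutral molecule as an element Counter.

    Peptide = sum of residue formulas + H2O; N-acylation adds the fatty
    acyl group C_nH_{2n-1}O in place of one N-terminal hydrogen, i.e. a
    net increment equal to the fatty acid minus water (C_nH_{2n-2}O).
    """
    counts: Counter = Counter()
    for code in spec.sequence:
        counts += _parse_formula(RESIDUE_FORMULA[code])
    counts += Counter({"H": 2, "O": 1})  # hydrolysis water
    n = spec.tail_carbons
    counts += Counter({"C": n, "H": 2 * n - 2, "O": 1})
    if spec.c_terminus == "amide":
        counts += Counter({"N": 1, "H": 1})
        counts -= Counter({"O": 1})
    elif spec.c_terminus == "COO-":
        counts -= Counter({"H": 1})
    return counts


def molecular_mass(spec: LipopeptideSpec, kind: str = "monoisotopic") -> float:
    """Neutral molecular mass in g/mol (monoisotopic by default)."""
    if kind not in ("monoisotopic", "average"):
        raise LipopeptideError(f"unknown mass kind {kind!r}")
    table = MONOISOTOPIC_MASS if kind == "monoisotopic" else AVERAGE_MASS
    return float(sum(table[el] * n for el, n in composition(spec).items()))


# --------------------------------------------------------------------------
# geometry container
# --------------------------------------------------------------------------


@dataclass
class MoleculeGeometry:
    """Full-atom coordinates, bonds and bookkeeping for one molecule.

    ``res_ids`` are 1-based: residue 1 is the acyl tail (PLM for C16),
    the amino acids follow as residues 2..n+1.
    """

    names: list[str]
    elements: list[str]
    res_ids: np.ndarray
    res_names: list[str]
    coords: np.ndarray
    bonds: list[tuple[int, int]]
    spec: LipopeptideSpec | None = None

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    def heavy_mask(self) -> np.ndarray:
        return np.array([el != "H" for el in self.elements])

    def index_of(self, res_id: int, name: str) -> int:
        for i in range(self.n_atoms):
            if self.res_ids[i] == res_id and self.names[i] == name:
                return i
        raise KeyError(f"no atom {name!r} in residue {res_id}")

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "MoleculeGeometry":
        xyz = self.coords
        if rotation is not None:
            xyz = xyz @ np.asarray(rotation).T
        if translation is not None:
            xyz = xyz + np.asarray(translation)
        return replace(self, coords=np.array(xyz), res_ids=self.res_ids.copy())


def measure_dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, IUPAC convention."""
    b0 = np.asarray(p0) - np.asarray(p1)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1u = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1u) * b1u
    w = b2 - np.dot(b2, b1u) * b1u
    x = np.dot(v, w)
    y = np.dot(np.cross(b1u, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def backbone_dihedrals(geom: MoleculeGeometry) -> list[tuple[float, float]]:
    """Per-amino-acid (phi, psi) in degrees.

    Under the N-acylated convention the acyl carbonyl carbon serves as
    the "previous C" for phi of residue 1.  psi of the last residue is
    measured to OXT (placed where the next amide nitrogen would sit).
    """
    n_res = len(geom.spec.sequence) if geom.spec else int(max(geom.res_ids)) - 1
    out = []
    xyz = geom.coords
    for i in range(1, n_res + 1):
        rid = i + 1  # residue ids offset by the tail residue
        n = xyz[geom.index_of(rid, "N")]
        ca = xyz[geom.index_of(rid, "CA")]
        c = xyz[geom.index_of(rid, "C")]
        if i == 1:
            c_prev = xyz[geom.index_of(1, "C1")]
        else:
            c_prev = xyz[geom.index_of(rid - 1, "C")]
        phi = measure_dihedral(c_prev, n, ca, c)
        if i < n_res:
            nxt = xyz[geom.index_of(rid + 1, "N")]
        else:
            try:
                nxt = xyz[geom.index_of(rid, "OXT")]
            except KeyError:
                nxt = xyz[geom.index_of(rid, "NT")]
        psi = measure_dihedral(n, ca, c, nxt)
        out.append((phi, psi))
    return out


# --------------------------------------------------------------------------
# internal-coordinate construction (NeRF)
# --------------------------------------------------------------------------

_B = {  # ideal bond lengths, Angstrom
    "C-C": 1.526, "C-H": 1.090, "C=O": 1.231, "C-N": 1.335, "N-CA": 1.458,
    "CA-C": 1.525, "N-H": 1.010, "C-Oh": 1.340, "O-H": 0.970, "C-Nz": 1.470,
    "CB-CG": 1.510, "Car-H": 1.080, "Car-O": 1.360,
}
_TET = 109.47
_SP3C = 111.6


def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
          bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom d bonded to c with angle(b,c,d) and dihedral(a,b,c,d)."""
    ang = np.radians(angle_deg)
    tor = np.radians(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(ang),
        bond * np.sin(ang) * np.cos(tor),
        bond * np.sin(ang) * np.sin(tor),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


class _Builder:
    def __init__(self):
        self.names: list[str] = []
        self.elements: list[str] = []
        self.res_ids: list[int] = []
        self.res_names: list[str] = []
        self.coords: list[np.ndarray] = []
        self.bonds: list[tuple[int, int]] = []

    def add(self, name, element, res_id, res_name, xyz, parent=None) -> int:
        idx = len(self.names)
        self.names.append(name)
        self.elements.append(element)
        self.res_ids.append(res_id)
        self.res_names.append(res_name)
        self.coords.append(np.asarray(xyz, dtype=float))
        if parent is not None:
            self.bonds.append((parent, idx))
        return idx

    def place(self, name, element, res_id, res_name,
              a, b, c, bond, angle, torsion, parent=None) -> int:
        xyz = _nerf(self.coords[a], self.coords[b], self.coords[c],
                    bond, angle, torsion)
        return self.add(name, element, res_id, res_name, xyz,
                        parent=c if parent is None else parent)

    def methylene_h(self, res_id, res_name, prefix, i_next, i_prev, i_atom,
                    bond=None, angle=_TET):
        """Two H on an sp3 atom, staggered about the next-chain-atom plane."""
        bond = _B["C-H"] if bond is None else bond
        for suffix, offs in (("A", 120.0), ("B", -120.0)):
            self.place(prefix + suffix, "H", res_id, res_name,
                       i_next, i_prev, i_atom, bond, angle, offs,
                       parent=i_atom)


# ---- rigid aromatic side-chain templates (planar, 2D) --------------------


def _tyr_ring_template() -> tuple[dict[str, np.ndarray], list[tuple[str, str]]]:
    """Phenol ring: CG at origin, CB->CG direction = +x (para axis)."""
    side = 1.390
    centroid = np.array([side, 0.0])
    names = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
    template = {}
    for i, name in enumerate(names):
        ang = np.radians(180.0 + 60.0 * i)
        template[name] = centroid + side * np.array([np.cos(ang), np.sin(ang)])
    for ring_atom, h_name in (("CD1", "HD1"), ("CE1", "HE1"),
                              ("CE2", "HE2"), ("CD2", "HD2")):
        u = template[ring_atom] - centroid
        u = u / np.linalg.norm(u)
        template[h_name] = template[ring_atom] + _B["Car-H"] * u
    template["OH"] = template["CZ"] + np.array([_B["Car-O"], 0.0])
    template["HH"] = template["OH"] + _B["O-H"] * np.array(
        [np.cos(np.radians(71.0)), np.sin(np.radians(71.0))])
    bonds = [("CG", "CD1"), ("CD1", "CE1"), ("CE1", "CZ"), ("CZ", "CE2"),
             ("CE2", "CD2"), ("CD2", "CG"), ("CZ", "OH"), ("OH", "HH"),
             ("CD1", "HD1"), ("CE1", "HE1"), ("CE2", "HE2"), ("CD2", "HD2")]
    return template, bonds


def _trp_ring_template() -> tuple[dict[str, np.ndarray], list[tuple[str, str]]]:
    """Indole: CG at origin, CB->CG direction = +x (bisects CD1/CD2).

    Regular pentagon (side 1.42) fused to a near-regular hexagon across
    the CD2-CE2 edge -- idealized geometry for a rigid single rotamer.
    """
    side5 = 1.42
    r5 = side5 / (2 * np.sin(np.pi / 5))
    centroid5 = np.array([r5, 0.0])
    template = {}
    for i, name in enumerate(["CG", "CD1", "NE1", "CE2", "CD2"]):
        ang = np.radians(180.0 + 72.0 * i)
        template[name] = centroid5 + r5 * np.array([np.cos(ang), np.sin(ang)])
    ce2, cd2 = template["CE2"], template["CD2"]
    mid = 0.5 * (ce2 + cd2)
    edge = np.linalg.norm(ce2 - cd2)
    normal = np.array([(ce2 - cd2)[1], -(ce2 - cd2)[0]]) / edge
    if np.dot(normal, mid - centroid5) < 0:
        normal = -normal
    r6 = 1.39
    centroid6 = mid + np.sqrt(r6**2 - (edge / 2) ** 2) * normal
    a0 = np.arctan2(*(ce2 - centroid6)[::-1])
    a1 = np.arctan2(*(cd2 - centroid6)[::-1])
    span = (a1 - a0) % (2 * np.pi)
    # walk from CE2 the long way around toward CZ2, CH2, CZ3, CE3
    if span > np.pi:
        step = span / 5.0
    else:
        step = -(2 * np.pi - span) / 5.0
    for k, name in enumerate(["CZ2", "CH2", "CZ3", "CE3"], start=1):
        ang = a0 + k * step
        template[name] = centroid6 + r6 * np.array([np.cos(ang), np.sin(ang)])
    for ring_atom, h_name, center in (
        ("CD1", "HD1", centroid5), ("NE1", "HE1", centroid5),
        ("CZ2", "HZ2", centroid6), ("CH2", "HH2", centroid6),
        ("CZ3", "HZ3", centroid6), ("CE3", "HE3", centroid6),
    ):
        u = template[ring_atom] - center
        u = u / np.linalg.norm(u)
        length = 1.01 if ring_atom == "NE1" else _B["Car-H"]
        template[h_name] = template[ring_atom] + length * u
    bonds = [("CG", "CD1"), ("CD1", "NE1"), ("NE1", "CE2"), ("CE2", "CD2"),
             ("CD2", "CG"), ("CE2", "CZ2"), ("CZ2", "CH2"), ("CH2", "CZ3"),
             ("CZ3", "CE3"), ("CE3", "CD2"), ("CD1", "HD1"), ("NE1", "HE1"),
             ("CZ2", "HZ2"), ("CH2", "HH2"), ("CZ3", "HZ3"), ("CE3", "HE3")]
    return template, bonds


_TYR_TEMPLATE, _TYR_BONDS = _tyr_ring_template()
_TRP_TEMPLATE, _TRP_BONDS = _trp_ring_template()

#: six-membered-ring heavy atoms used for aromatic centroids downstream
AROMATIC_RING_ATOMS = {
    "TYR": ("CG", "CD1", "CE1", "CZ", "CE2", "CD2"),
    "TRP": ("CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3"),
}


def _attach_ring(builder: _Builder, template, ring_bonds,
                 res_id: int, res_name: str,
                 i_ca: int, i_cg: int, i_cb: int, chi2: float) -> None:
    """Map a planar template onto the already-placed CB-CG bond.

    The template +x axis maps to the CB->CG direction; the ring-plane
    roll about that axis is set by ``chi2`` measured from the plane
    containing CA.
    """
    ca, cb, cg = builder.coords[i_ca], builder.coords[i_cb], builder.coords[i_cg]
    ex = cg - cb
    ex = ex / np.linalg.norm(ex)
    ref = ca - cb
    ey0 = ref - np.dot(ref, ex) * ex
    ey0 = ey0 / np.linalg.norm(ey0)
    ez0 = np.cross(ex, ey0)
    chi = np.radians(chi2)
    ey = np.cos(chi) * ey0 + np.sin(chi) * ez0
    index_map: dict[str, int] = {"CG": i_cg}
    for name, xy in template.items():
        if name == "CG":
            continue
        xyz = cg + xy[0] * ex + xy[1] * ey
        element = name[0] if name[0] in ("N", "O", "H") else "C"
        index_map[name] = builder.add(name, element, res_id, res_name, xyz)
    for a, b in ring_bonds:
        builder.bonds.append((index_map[a], index_map[b]))


# ---- clash screening ------------------------------------------------------


def _bond_graph_exclusions(n_atoms: int, bonds, max_sep: int = 2) -> set:
    adjacency: dict[int, set[int]] = {i: set() for i in range(n_atoms)}
    for a, b in bonds:
        adjacency[a].add(b)
        adjacency[b].add(a)
    excluded = set()
    for a in range(n_atoms):
        frontier = {a}
        seen = {a}
        for _ in range(max_sep):
            frontier = {c for b in frontier for c in adjacency[b]} - seen
            seen |= frontier
            for b in frontier:
                excluded.add((min(a, b), max(a, b)))
    return excluded


def _check_internal_clashes(geom: MoleculeGeometry, cutoff: float = 1.5) -> None:
    heavy = np.where(geom.heavy_mask())[0]
    excluded = _bond_graph_exclusions(geom.n_atoms, geom.bonds)
    xyz = geom.coords[heavy]
    diff = xyz[:, None, :] - xyz[None, :, :]
    dist = np.sqrt((diff**2).sum(-1))
    n = len(heavy)
    ii, jj = np.where((dist < cutoff) & ~np.eye(n, dtype=bool))
    for i, j in zip(ii, jj):
        if i >= j:
            continue
        gi, gj = int(heavy[i]), int(heavy[j])
        if (min(gi, gj), max(gi, gj)) not in excluded:
            raise GeometryError(
                f"steric clash within monomer: {geom.names[gi]}(res {geom.res_ids[gi]}) "
                f"vs {geom.names[gj]}(res {geom.res_ids[gj]}) at {dist[i, j]:.2f} A"
            )


# ---- the monomer builder --------------------------------------------------


def build_extended_monomer(spec: LipopeptideSpec, phi: float = -139.0,
                           psi: float = 135.0, chi2: float = 140.0,
                           check_clashes: bool = True) -> MoleculeGeometry:
    """Construct one lipopeptide in an idealized extended conformation.

    The alkyl tail is all-trans; every amino acid carries the same
    (phi, psi) backbone dihedrals (defaults in the parallel-beta region);
    side chains use a single fixed extended rotamer (chi1 = 180, ring
    roll ``chi2``).  The output is deterministic and canonically
    oriented: backbone axis along +x with the tail toward -x, first
    backbone carbonyl C=O in the +y half-plane, acyl carbonyl carbon at
    the origin.
    """
    if not (-180.0 < phi <= 180.0) or not (-180.0 < psi <= 180.0):
        raise GeometryError(f"phi/psi must lie in (-180, 180], got {phi}, {psi}")
    builder = _Builder()
    n_tail = spec.tail_carbons
    tail_name = "PLM" if n_tail == 16 else f"AC{n_tail}"

    # --- all-trans tail, built from the terminal methyl (C{n}) down to C1
    chain: list[int] = []  # indices ordered C{n} .. C1
    for k in range(n_tail, 0, -1):
        name = f"C{k}"
        if not chain:
            idx = builder.add(name, "C", 1, tail_name, [0.0, 0.0, 0.0])
        elif len(chain) == 1:
            idx = builder.add(name, "C", 1, tail_name, [1.526, 0.0, 0.0],
                              parent=chain[-1])
        elif len(chain) == 2:
            # third atom: any in-plane position with the ideal angle
            ang = np.radians(180.0 - _SP3C)
            base = builder.coords[chain[-1]]
            idx = builder.add(name, "C", 1, tail_name,
                              base + 1.526 * np.array([np.cos(ang), np.sin(ang), 0.0]),
                              parent=chain[-1])
        else:
            idx = builder.place(name, "C", 1, tail_name,
                                chain[-3], chain[-2], chain[-1],
                                _B["C-C"], _SP3C, 180.0)
        chain.append(idx)
    i_c1, i_c2, i_c3 = chain[-1], chain[-2], chain[-3]

    # amide N of residue 1 continues the chain; acyl O completes sp2 C1
    first_rname = THREE_LETTER[spec.sequence[0]]
    i_n1 = builder.place("N", "N", 2, first_rname,
                         i_c3, i_c2, i_c1, _B["C-N"], 115.0, 180.0)
    builder.place("O1", "O", 1, tail_name,
                  i_c3, i_c2, i_c1, _B["C=O"], 121.0, 0.0)

    # tail hydrogens
    for pos, c in enumerate(chain):
        k = n_tail - pos
        if k == 1:
            continue  # carbonyl carbon, no H
        if pos == 0:
            for suffix, tors in (("A", 60.0), ("B", 180.0), ("C", -60.0)):
                builder.place(f"H{k}{suffix}", "H", 1, tail_name,
                              chain[2], chain[1], c, _B["C-H"], _TET, tors)
        else:
            i_next = chain[pos + 1] if pos + 1 < len(chain) else i_n1
            builder.methylene_h(1, tail_name, f"H{k}", i_next, chain[pos - 1], c)

    # --- peptide backbone: ...C(i-1), N(i), CA(i), C(i)... via NeRF
    res_data = []
    n_res = len(spec.sequence)
    prev = {"N": i_c2, "CA": i_c2, "C": i_c1}  # acyl group stands in for residue 0
    prev_prev_for_r1 = i_c3
    i_n = i_n1
    for r in range(n_res):
        rid = r + 2
        code = spec.sequence[r]
        rname = THREE_LETTER[code]
        if r > 0:
            i_n = builder.place("N", "N", rid, rname,
                                prev["N"], prev["CA"], prev["C"],
                                _B["C-N"], 116.2, psi)
        a_omega = prev_prev_for_r1 if r == 0 else prev["CA"]
        i_ca = builder.place("CA", "C", rid, rname,
                             a_omega, prev["C"], i_n, _B["N-CA"], 121.7, 180.0)
        builder.place("H", "H", rid, rname,
                      a_omega, prev["C"], i_n, _B["N-H"], 119.0, 0.0)
        i_c = builder.place("C", "C", rid, rname,
                            prev["C"], i_n, i_ca, _B["CA-C"], 111.0, phi)
        builder.place("HA", "H", rid, rname,
                      prev["C"], i_n, i_ca, _B["C-H"], 108.0, phi + 118.0)
        i_o = builder.place("O", "O", rid, rname,
                            i_n, i_ca, i_c, _B["C=O"], 120.8, psi + 180.0)
        res_data.append({"N": i_n, "CA": i_ca, "C": i_c, "O": i_o,
                         "rid": rid, "rname": rname, "code": code})
        if code != "G":
            i_cb = builder.place("CB", "C", rid, rname,
                                 prev["C"], i_n, i_ca,
                                 1.530, 110.1, phi - 122.0)
            _build_side_chain(builder, code, rid, rname, i_n, i_ca, i_cb, chi2)
        else:
            builder.place("HA2", "H", rid, rname, prev["C"], i_n, i_ca,
                          _B["C-H"], 108.0, phi - 122.0)
        prev_prev_for_r1 = None
        prev = {"N": i_n, "CA": i_ca, "C": i_c}

    # --- C-terminus
    last = res_data[-1]
    if spec.c_terminus in ("COOH", "COO-"):
        i_oxt = builder.place("OXT", "O", last["rid"], last["rname"],
                              last["N"], last["CA"], last["C"],
                              _B["C-Oh"], 117.0, psi)
        if spec.c_terminus == "COOH":
            builder.place("HXT", "H", last["rid"], last["rname"],
                          last["CA"], last["C"], i_oxt,
                          _B["O-H"], 110.0, 180.0)
    else:  # amide
        i_nt = builder.place("NT", "N", last["rid"], last["rname"],
                             last["N"], last["CA"], last["C"],
                             _B["C-N"], 116.2, psi)
        builder.place("HT1", "H", last["rid"], last["rname"],
                      last["CA"], last["C"], i_nt, _B["N-H"], 119.0, 0.0)
        builder.place("HT2", "H", last["rid"], last["rname"],
                      last["CA"], last["C"], i_nt, _B["N-H"], 119.0, 180.0)

    geom = MoleculeGeometry(
        names=builder.names,
        elements=builder.elements,
        res_ids=np.array(builder.res_ids, dtype=int),
        res_names=builder.res_names,
        coords=np.array(builder.coords),
        bonds=builder.bonds,
        spec=spec,
    )
    _canonical_orientation(geom, res_data)
    if check_clashes:
        _check_internal_clashes(geom)
    return geom


def _build_side_chain(builder: _Builder, code: str, rid: int, rname: str,
                      i_n: int, i_ca: int, i_cb: int, chi2: float) -> None:
    if code == "A":
        for suffix, tors in (("1", 60.0), ("2", 180.0), ("3", -60.0)):
            builder.place(f"HB{suffix}", "H", rid, rname,
                          i_n, i_ca, i_cb, _B["C-H"], _TET, tors)
        return
    if code == "K":
        prev3 = [i_n, i_ca, i_cb]
        placed = {"CB": i_cb}
        for name, element, bond in (("CG", "C", 1.526), ("CD", "C", 1.526),
                                    ("CE", "C", 1.526), ("NZ", "N", _B["C-Nz"])):
            idx = builder.place(name, element, rid, rname,
                                prev3[-3], prev3[-2], prev3[-1],
                                bond, _SP3C, 180.0)
            placed[name] = idx
            prev3.append(idx)
        for atom, nxt, prv in (("CB", "CG", None), ("CG", "CD", "CB"),
                               ("CD", "CE", "CG"), ("CE", "NZ", "CD")):
            i_prev = i_ca if prv is None else placed[prv]
            builder.methylene_h(rid, rname, "H" + atom[1:],
                                placed[nxt], i_prev, placed[atom])
        # neutral -NH2 reference state
        for label, tors in (("HZ1", 60.0), ("HZ2", -60.0)):
            builder.place(label, "H", rid, rname,
                          placed["CD"], placed["CE"], placed["NZ"],
                          _B["N-H"], _TET, tors)
        return
    if code in ("Y", "W"):
        i_cg = builder.place("CG", "C", rid, rname,
                             i_n, i_ca, i_cb, _B["CB-CG"], 114.0, 180.0)
        template, ring_bonds = ((_TYR_TEMPLATE, _TYR_BONDS) if code == "Y"
                                else (_TRP_TEMPLATE, _TRP_BONDS))
        _attach_ring(builder, template, ring_bonds, rid, rname,
                     i_ca, i_cg, i_cb, chi2)
        builder.methylene_h(rid, rname, "HB", i_cg, i_ca, i_cb)
        return
    raise GeometryError(
        f"no side-chain rotamer template for residue {code!r}; "
        "supported: G, A, K, W, Y")


def _canonical_orientation(geom: MoleculeGeometry, res_data) -> None:
    """Rotate/translate in place: backbone axis -> +x, first backbone
    C=O -> +y half-plane, acyl carbonyl carbon -> origin."""
    xyz = geom.coords
    axis = xyz[res_data[-1]["C"]] - xyz[res_data[0]["N"]]
    axis = axis / np.linalg.norm(axis)
    x = np.array([1.0, 0.0, 0.0])
    v = np.cross(axis, x)
    s = np.linalg.norm(v)
    c = np.dot(axis, x)
    if s < 1e-12:
        rot = np.eye(3) if c > 0 else np.diag([-1.0, -1.0, 1.0])
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        rot = np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)
    xyz = xyz @ rot.T
    co = xyz[res_data[0]["O"]] - xyz[res_data[0]["C"]]
    roll = np.arctan2(co[2], co[1])
    cr, sr = np.cos(-roll), np.sin(-roll)
    roll_rot = np.array([[1, 0, 0], [0, cr, -sr], [0, sr, cr]])
    xyz = xyz @ roll_rot.T
    xyz = xyz - xyz[geom.index_of(1, "C1")]
    geom.coords[:] = xyz
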