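"""Hierarchical construction of beta-sheet lipopeptide assemblies.

Implements the dimer -> 32-mer parallel beta-sheet -> interdigitated
bilayer 256-mer nanotape construction, and the alternative radial
(fibril) arrangement of sheets about a cylinder axis, with deterministic
clash avoidance and PDB/GRO export.

Geometric conventions (from the canonical monomer orientation):

* x -- strand axis; the alkyl tail points toward -x, the peptide toward +x
* y -- hydrogen-bond direction; sheets grow by translation along +y and
  the fibril long axis / nanotape long axis is y
* z -- sheet-stacking direction

Coordinates are Angstrom in memory; GRO output is converted to nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .lipopeptide import (
    LipopeptideSpec,
    MoleculeGeometry,
    build_extended_monomer,
    parse_lipopeptide,
)

__all__ = [
    "BuildError",
    "SheetParameters",
    "AssemblyModel",
    "build_sheet",
    "build_bilayer",
    "build_fibril",
    "build_assembly",
    "relax_clashes",
    "check_clashes",
    "write_structure",
    "read_structure",
    "to_atom_array",
]


class BuildError(RuntimeError):
    """Assembly construction failed (irreparable steric clash etc.)."""


@dataclass
class SheetParameters:
    """Geometric parameters of the sheet/bilayer/fibril construction.

    All lengths in Angstrom, angles in degrees.
    """

    strand_spacing: float = 4.8            # beta-sheet inter-strand repeat
    sheet_stagger: float = 2.4             # lateral y-shift between stacked sheets
    bilayer_interdigitation_offset: float = 6.0  # tail-tail overlap depth
    stack_spacing: float = 10.0            # sheet-to-sheet distance along z
    fibril_slot_count: int = 8             # sheets per disk cross-section
    fibril_twist: float = 0.0              # degrees of twist per disk (untwisted start)
    tail_tilt: float = 45.0                # tangential tail tilt in fibrils
    fibril_junction_radius: float = 15.0   # radius of the tail/peptide junction
    clash_cutoff: float = 2.0              # min allowed inter-molecular heavy-atom distance

    def __post_init__(self):
        if not (4.2 <= self.strand_spacing <= 5.5):
            raise BuildError(
                f"strand_spacing {self.strand_spacing} outside the "
                "physical beta-sheet range [4.2, 5.5] A")
        if self.fibril_slot_count < 3:
            raise BuildError("fibril_slot_count must be >= 3")


@dataclass
class AssemblyModel:
    """A multi-molecule assembly: rigid copies of a monomer plus tags.

    ``tags`` holds one dict per molecule with topology bookkeeping
    (sheet index, leaflet, angular slot).
    """

    molecules: list[MoleculeGeometry]
    tags: list[dict] = field(default_factory=list)
    morphology: str = "sheet"

    def __post_init__(self):
        if not self.tags:
            self.tags = [{} for _ in self.molecules]

    @property
    def molecule_count(self) -> int:
        return len(self.molecules)

    @property
    def n_atoms(self) -> int:
        return sum(m.n_atoms for m in self.molecules)

    def all_coords(self) -> np.ndarray:
        return np.concatenate([m.coords for m in self.molecules])

    def heavy_coords_and_molecule_ids(self) -> tuple[np.ndarray, np.ndarray]:
        coords, mol_ids = [], []
        for i, mol in enumerate(self.molecules):
            mask = mol.heavy_mask()
            coords.append(mol.coords[mask])
            mol_ids.append(np.full(mask.sum(), i))
        return np.concatenate(coords), np.concatenate(mol_ids)

    def bounding_box(self) -> np.ndarray:
        """(2, 3) array of min/max coordinates in Angstrom."""
        xyz = self.all_coords()
        return np.stack([xyz.min(axis=0), xyz.max(axis=0)])

    def translated(self, shift) -> "AssemblyModel":
        return AssemblyModel(
            [m.transformed(translation=shift) for m in self.molecules],
            [dict(t) for t in self.tags], self.morphology)


# --------------------------------------------------------------------------
# clash detection
# --------------------------------------------------------------------------


def check_clashes(assembly: AssemblyModel, cutoff: float | None = None
                  ) -> tuple[float, tuple[int, int]]:
    """Minimum inter-molecular heavy-atom distance and the molecule pair.

    If ``cutoff`` is given, only pairs below it are searched (fast path);
    returns (inf, (-1, -1)) when no pair is closer than the cutoff.
    """
    xyz, mol_ids = assembly.heavy_coords_and_molecule_ids()
    tree = cKDTree(xyz)
    search = cutoff if cutoff is not None else 6.0
    pairs = tree.query_pairs(search, output_type="ndarray")
    if len(pairs) == 0:
        return float("inf"), (-1, -1)
    inter = mol_ids[pairs[:, 0]] != mol_ids[pairs[:, 1]]
    pairs = pairs[inter]
    if len(pairs) == 0:
        return float("inf"), (-1, -1)
    dist = np.linalg.norm(xyz[pairs[:, 0]] - xyz[pairs[:, 1]], axis=1)
    k = int(np.argmin(dist))
    return float(dist[k]), (int(mol_ids[pairs[k, 0]]), int(mol_ids[pairs[k, 1]]))


def _require_clash_free(assembly: AssemblyModel, cutoff: float, what: str) -> None:
    dmin, (i, j) = check_clashes(assembly, cutoff)
    if dmin < cutoff:
        raise BuildError(
            f"{what}: molecules {i} and {j} clash at {dmin:.2f} A "
            f"(cutoff {cutoff:.2f} A)")


# --------------------------------------------------------------------------
# sheet -> bilayer -> tape / fibril
# --------------------------------------------------------------------------


def build_sheet(monomer: MoleculeGeometry, n: int,
                params: SheetParameters | None = None) -> AssemblyModel:
    """Parallel beta-sheet: ``n`` copies translated along the H-bond axis.

    Every copy has identical orientation (parallel registry); adjacent
    strands sit ``strand_spacing`` apart along y, which reproduces the
    backbone N-H...O=C ladder of the canonically oriented monomer.
    """
    params = params or SheetParameters()
    if n < 2:
        raise BuildError("a sheet needs at least 2 strands")
    molecules = [
        monomer.transformed(translation=[0.0, k * params.strand_spacing, 0.0])
        for k in range(n)
    ]
    tags = [{"sheet": 0, "strand": k} for k in range(n)]
    assembly = AssemblyModel(molecules, tags, morphology="sheet")
    _require_clash_free(assembly, params.clash_cutoff, "sheet build")
    return assembly


def _rotation_y(angle_deg: float) -> np.ndarray:
    a = np.radians(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def _offset_scan(base: AssemblyModel, new_block: AssemblyModel,
                 cutoff: float, max_y: float = 2.4, max_z: float = 6.0,
                 step_y: float = 0.4, step_z: float = 0.5) -> AssemblyModel:
    """Shift ``new_block`` laterally (y, z) until it clears ``base``.

    Deterministic grid scan preferring the smallest displacement (|dz|
    first, then |dy|); the y step is a fraction of the strand period so
    half-period staggers are reachable exactly."""
    def ladder(limit, step):
        out = [0.0]
        k = step
        while k <= limit + 1e-9:
            out.extend([k, -k])
            k += step
        return out

    base_xyz, _ = base.heavy_coords_and_molecule_ids()
    tree = cKDTree(base_xyz)
    for dz in ladder(max_z, step_z):
        for dy in ladder(max_y, step_y):
            shifted = new_block.translated([0.0, dy, dz])
            xyz, _ = shifted.heavy_coords_and_molecule_ids()
            d, _idx = tree.query(xyz, k=1)
            if d.min() >= cutoff:
                return shifted
    raise BuildError(
        "could not remove inter-block clash by lateral offsets of up to "
        f"+/-{max_y} A (y) and +/-{max_z} A (z)")


def _merge(a: AssemblyModel, b: AssemblyModel, morphology: str) -> AssemblyModel:
    return AssemblyModel(a.molecules + b.molecules, a.tags + b.tags, morphology)


def _tail_extent(monomer: MoleculeGeometry) -> float:
    """Length of the tail region along -x in the canonical frame."""
    tail_mask = monomer.res_ids == 1
    return float(-monomer.coords[tail_mask, 0].min())


def build_bilayer(sheet: AssemblyModel,
                  params: SheetParameters | None = None,
                  auto_relax: bool = True) -> AssemblyModel:
    """Interdigitated bilayer tape: mirror-leaflet + two stacking doublings.

    The input sheet (tails toward -x) is duplicated by a 180 deg rotation
    about the H-bond axis, placed tail-to-tail with the configured
    interdigitation overlap and a half-period stagger, then the 2n-mer is
    doubled twice along the stacking axis z -- giving 8x the input
    molecule count with peptides facing solvent on both faces.
    """
    params = params or SheetParameters()
    monomer = sheet.molecules[0]
    tail_len = _tail_extent(monomer)
    rot = _rotation_y(180.0)
    shift_x = -2.0 * tail_len + params.bilayer_interdigitation_offset
    leaflet2 = AssemblyModel(
        [m.transformed(rotation=rot,
                       translation=[shift_x, params.sheet_stagger, 0.0])
         for m in sheet.molecules],
        [dict(t, leaflet=1) for t in sheet.tags], "bilayer")
    leaflet1 = AssemblyModel(sheet.molecules,
                             [dict(t, leaflet=0) for t in sheet.tags],
                             "bilayer")
    leaflet2 = _offset_scan(leaflet1, leaflet2, params.clash_cutoff)
    bilayer = _merge(leaflet1, leaflet2, "bilayer")

    # two successive doublings along the stacking axis, staggered to
    # avoid clashes of terminal peptide groups
    block = bilayer
    for doubling in range(2):
        n_sheets = 2**doubling
        shift = [0.0, params.sheet_stagger,
                 params.stack_spacing * n_sheets]
        copy = AssemblyModel(
            [m.transformed(translation=shift) for m in block.molecules],
            [dict(t, sheet=t.get("sheet", 0) + n_sheets) for t in block.tags],
            "bilayer")
        try:
            copy = _offset_scan(block, copy, params.clash_cutoff)
        except BuildError:
            if not auto_relax:
                raise
            # fall through: keep the best stagger, relax the residue below
            copy = copy.translated([0.0, 0.0, 0.5])
        block = _merge(block, copy, "bilayer")
    dmin, _ = check_clashes(block, params.clash_cutoff)
    if dmin < params.clash_cutoff and auto_relax:
        # lateral moves only: keeps leaflet interdigitation and thickness
        block, diag = relax_clashes(block, max_iter=1500,
                                    cutoff=params.clash_cutoff, step=0.1,
                                    move_axes=(1, 2))
    # center the tape at the origin
    center = block.bounding_box().mean(axis=0)
    block = block.translated(-center)
    _require_clash_free(block, params.clash_cutoff, "bilayer build")
    return block


def _kinked_monomers(sheet: AssemblyModel, tilt: float, r_j: float
                     ) -> list[MoleculeGeometry]:
    """Tilt each molecule's tail tangentially about the H-bond axis at
    the acyl junction and move the junction to radius ``r_j``.

    ``tilt`` is measured from the inward radial direction, referenced to
    the actual tail-tip direction so the result does not depend on the
    monomer's intrinsic roll."""
    out = []
    rot_sense = None
    for mol in sheet.molecules:
        i_c1 = mol.index_of(1, "C1")
        i_tip = mol.index_of(1, f"C{mol.spec.tail_carbons}")
        pivot = mol.coords[i_c1]
        d = mol.coords[i_tip] - pivot
        theta0 = np.degrees(np.arctan2(d[2], -d[0]))
        rot_tail = _rotation_y(tilt - theta0)
        xyz = mol.coords.copy()
        tail_mask = (mol.res_ids == 1) & (np.arange(mol.n_atoms) != i_c1)
        xyz[tail_mask] = (xyz[tail_mask] - pivot) @ rot_tail.T + pivot
        xyz[:, 0] += r_j - pivot[0]
        out.append(MoleculeGeometry(mol.names, mol.elements,
                                    mol.res_ids.copy(), mol.res_names,
                                    xyz, mol.bonds, mol.spec))
    return out


def build_fibril(sheet: AssemblyModel,
                 params: SheetParameters | None = None,
                 auto_relax: bool = True) -> AssemblyModel:
    """Cylindrical fibril: sheets at angular slots about the y axis.

    Tails point inward, peptides outward.  Because a fully extended C16
    tail is longer than the observed fibril core radius, tails are tilted
    tangentially (pinwheel-fashion) by ``tail_tilt`` at the acyl
    junction; the tilt sense alternates between neighbouring slots and
    odd slots are axially staggered by half a strand spacing, which
    interleaves the tails in the core.  Residual shallow tail-tail
    contacts are removed by deterministic rigid-body relaxation.
    """
    params = params or SheetParameters()
    slots = params.fibril_slot_count
    r_j = params.fibril_junction_radius

    molecules, tags = [], []
    for slot in range(slots):
        tilt = params.tail_tilt if slot % 2 == 0 else -params.tail_tilt
        kinked = _kinked_monomers(sheet, tilt, r_j)
        angle = 360.0 * slot / slots + params.fibril_twist * slot
        rot = _rotation_y(angle)
        stagger = params.sheet_stagger * (slot % 2)
        for mol, tag in zip(kinked, sheet.tags):
            molecules.append(mol.transformed(rotation=rot,
                                             translation=[0.0, stagger, 0.0]))
            tags.append(dict(tag, slot=slot))
    fibril = AssemblyModel(molecules, tags, morphology="fibril")
    dmin, _pair = check_clashes(fibril, params.clash_cutoff)
    if dmin < params.clash_cutoff and auto_relax:
        fibril, diag = relax_clashes(fibril, max_iter=1500,
                                     cutoff=params.clash_cutoff, step=0.1)
        dmin = diag["min_distance"]
    if dmin < params.clash_cutoff:
        _dmin, (i, j) = check_clashes(fibril, params.clash_cutoff)
        raise BuildError(
            f"fibril build: molecules {i} and {j} clash at {dmin:.2f} A; "
            f"try fewer than {slots} slots or a larger junction radius")
    return fibril


def build_assembly(identifier_or_spec, morphology: str, n: int = 256,
                   params: SheetParameters | None = None,
                   phi: float = -139.0, psi: float = 135.0) -> AssemblyModel:
    """One-call pipeline: monomer -> sheet -> requested morphology.

    ``n`` is the total molecule count; for 'bilayer' it must be 8x a
    sheet size, for 'fibril' slots x sheet size.
    """
    params = params or SheetParameters()
    spec = (identifier_or_spec if isinstance(identifier_or_spec, LipopeptideSpec)
            else parse_lipopeptide(identifier_or_spec))
    monomer = build_extended_monomer(spec, phi=phi, psi=psi)
    if morphology == "sheet":
        return build_sheet(monomer, n, params)
    if morphology == "bilayer":
        if n % 8:
            raise BuildError("bilayer molecule count must be divisible by 8")
        sheet = build_sheet(monomer, n // 8, params)
        return build_bilayer(sheet, params)
    if morphology == "fibril":
        slots = params.fibril_slot_count
        if n % slots:
            raise BuildError(
                f"fibril molecule count must be divisible by {slots} slots")
        sheet = build_sheet(monomer, n // slots, params)
        return build_fibril(sheet, params)
    raise BuildError(f"unknown morphology {morphology!r}")


# --------------------------------------------------------------------------
# rigid-body clash relaxation
# --------------------------------------------------------------------------


def relax_clashes(assembly: AssemblyModel, max_iter: int = 500,
                  cutoff: float = 2.0, step: float = 0.2,
                  move_axes: tuple[int, ...] = (0, 1, 2)) -> tuple[AssemblyModel, dict]:
    """Soft-sphere steepest descent on rigid molecule translations.

    Molecules are moved (internal geometry kept rigid) down the gradient
    of sum((cutoff - d)^2) over inter-molecular heavy-atom pairs with
    d < cutoff, until no pair remains below the cutoff or ``max_iter``.
    The step size is halved whenever 40 iterations pass without progress
    (damps the oscillation of symmetric contacts).  ``move_axes`` can
    restrict the rigid translations to a subset of Cartesian axes (used
    to preserve a bilayer's thickness while relieving lateral contacts).
    Returns the relaxed assembly and a diagnostics dict with keys
    'converged', 'iterations', 'min_distance'.
    """
    axis_mask = np.zeros(3)
    axis_mask[list(move_axes)] = 1.0
    molecules = [m.transformed() for m in assembly.molecules]
    n_mol = len(molecules)
    heavy_masks = [m.heavy_mask() for m in molecules]
    diag = {"converged": True, "iterations": 0, "min_distance": float("inf")}
    best_dmin = -np.inf
    stall = 0
    for iteration in range(max_iter):
        coords = np.concatenate([m.coords[hm] for m, hm in zip(molecules, heavy_masks)])
        mol_ids = np.concatenate([np.full(hm.sum(), i)
                                  for i, hm in enumerate(heavy_masks)])
        tree = cKDTree(coords)
        pairs = tree.query_pairs(cutoff, output_type="ndarray")
        if len(pairs):
            pairs = pairs[mol_ids[pairs[:, 0]] != mol_ids[pairs[:, 1]]]
        if len(pairs) == 0:
            diag["iterations"] = iteration
            dmin, _ = check_clashes(AssemblyModel(molecules), cutoff=None)
            diag["min_distance"] = dmin
            return AssemblyModel(molecules, [dict(t) for t in assembly.tags],
                                 assembly.morphology), diag
        delta = coords[pairs[:, 0]] - coords[pairs[:, 1]]
        dist = np.maximum(np.linalg.norm(delta, axis=1), 1e-6)
        dmin_now = float(dist.min())
        if dmin_now > best_dmin + 1e-4:
            best_dmin = dmin_now
            stall = 0
        else:
            stall += 1
            if stall >= 40:
                step *= 0.5
                stall = 0
        grad = np.zeros((n_mol, 3))
        # force magnitude (cutoff - d) along the pair axis, equal and opposite
        f = ((cutoff - dist) / dist)[:, None] * delta * axis_mask
        np.add.at(grad, mol_ids[pairs[:, 0]], f)
        np.add.at(grad, mol_ids[pairs[:, 1]], -f)
        norms = np.linalg.norm(grad, axis=1, keepdims=True)
        moving = norms[:, 0] > 0
        moves = np.zeros_like(grad)
        moves[moving] = step * grad[moving] / norms[moving]
        for i in np.where(moving)[0]:
            molecules[i] = molecules[i].transformed(translation=moves[i])
    dmin, _ = check_clashes(AssemblyModel(molecules), cutoff=None)
    diag.update(converged=False, iterations=max_iter, min_distance=dmin)
    return AssemblyModel(molecules, [dict(t) for t in assembly.tags],
                         assembly.morphology), diag


# --------------------------------------------------------------------------
# structure I/O (biotite-backed)
# --------------------------------------------------------------------------


def to_atom_array(assembly: AssemblyModel):
    """Flatten an assembly into a biotite AtomArray (coordinates in A).

    Chain identifiers cycle A..Z per molecule; residue ids run globally so
    that every (chain, residue) pair is unique within a 26-molecule block.
    """
    import biotite.structure as struc

    n = assembly.n_atoms
    arr = struc.AtomArray(n)
    pos = 0
    chain_letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    res_offset = 0
    for mol_index, mol in enumerate(assembly.molecules):
        k = mol.n_atoms
        sl = slice(pos, pos + k)
        arr.coord[sl] = mol.coords
        arr.atom_name[sl] = mol.names
        arr.element[sl] = mol.elements
        arr.res_id[sl] = mol.res_ids + res_offset
        arr.res_name[sl] = mol.res_names
        arr.chain_id[sl] = chain_letters[mol_index % 26]
        arr.hetero[sl] = False
        pos += k
        res_offset += int(mol.res_ids.max())
    return arr


def write_structure(assembly: AssemblyModel, path: str, fmt: str = "PDB",
                    box_nm: tuple[float, float, float] | None = None) -> None:
    """Write PDB (CRYST1 + ATOM records) or GRO (nm) via biotite.

    The assembly is centered in the box.  Raises ``BuildError`` when the
    assembly does not fit, listing the extent per axis.
    """
    if assembly.molecule_count == 0:
        raise BuildError("cannot write an empty assembly")
    arr = to_atom_array(assembly)
    if box_nm is not None:
        box = np.asarray(box_nm, dtype=float) * 10.0  # Angstrom
        extent = assembly.bounding_box()
        span = extent[1] - extent[0]
        # align the assembly's principal extents with the box dimensions
        # (longest along longest), preserving chirality
        axis_order = np.argsort(-span)
        box_order = np.argsort(-box)
        perm = np.zeros((3, 3))
        for k in range(3):
            perm[box_order[k], axis_order[k]] = 1.0
        if np.linalg.det(perm) < 0:
            perm[box_order[2], :] *= -1.0
        arr.coord = arr.coord @ perm.T
        extent = np.stack([arr.coord.min(axis=0), arr.coord.max(axis=0)])
        span = extent[1] - extent[0]
        if np.any(span > box):
            over = ", ".join(
                f"{'xyz'[k]}: {span[k] / 10.0:.2f} nm > {box[k] / 10.0:.2f} nm"
                for k in range(3) if span[k] > box[k])
            raise BuildError(f"assembly exceeds the box ({over})")
        center = extent.mean(axis=0)
        arr.coord += box / 2.0 - center
        arr.box = np.diag(box)
    fmt = fmt.upper()
    if fmt == "PDB":
        from biotite.structure.io.pdb import PDBFile

        f = PDBFile()
        f.set_structure(arr)
        f.write(path)
    elif fmt == "GRO":
        from biotite.structure.io.gro import GROFile

        f = GROFile()
        f.set_structure(arr)
        f.write(path)
    else:
        raise BuildError(f"unknown structure format {fmt!r}")


def read_structure(path: str):
    """Read a PDB/GRO structure (or multi-model PDB trajectory).

    Returns a biotite AtomArray, or an AtomArrayStack for multi-model
    files; suffix decides the parser.
    """
    lower = str(path).lower()
    if lower.endswith(".gro"):
        from biotite.structure.io.gro import GROFile

        return GROFile.read(path).get_structure(model=1)
    from biotite.structure.io.pdb import PDBFile

    f = PDBFile.read(path)
    stack = f.get_structure()
    if stack.stack_depth() == 1:
        return stack[0]
    return stack
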