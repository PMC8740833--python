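"""Interface identification, surface burial, rigid displacement and pose metrics.

The interface of a two-partner complex is the set of residues with any
heavy-atom pair across partners closer than a cutoff (10 Å by default).
Everything here is geometric: no energies, no hydrogens.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import Atom, ComplexStructure, Residue, StructureError

log = logging.getLogger(__name__)

#: Van-der-Waals radii (Å) for heavy elements, used by the SASA calculation.
VDW_RADII = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80, "SE": 1.90,
}
DEFAULT_VDW = 1.70

#: Residues counted as nonpolar or aromatic by the database composition filter.
NONPOLAR_AROMATIC = {"ALA", "VAL", "LEU", "ILE", "MET", "PRO", "CYS",
                     "PHE", "TRP", "TYR"}


@dataclass
class InterfaceDefinition:
    cutoff: float
    residues_a: list[Residue] = field(default_factory=list)
    residues_b: list[Residue] = field(default_factory=list)

    @property
    def is_empty(self) -> bool:
        return not (self.residues_a or self.residues_b)


@dataclass
class Placement:
    translation: np.ndarray  # (3,) Å
    match_count: int
    mean_match_rmsd: float | None


def _heavy_atom_table(residues: list[Residue]) -> tuple[np.ndarray, list[int]]:
    """Coordinates of all heavy atoms plus a parallel residue-index column."""
    coords, owner = [], []
    for i, res in enumerate(residues):
        for a in res.heavy_atoms():
            coords.append(a.coords)
            owner.append(i)
    return (np.array(coords) if coords else np.empty((0, 3))), owner


def identify_interface(cs: ComplexStructure, cutoff: float = 10.0) -> InterfaceDefinition:
    """Residues of each partner with any heavy atom strictly within `cutoff`
    of a heavy atom of the other partner.

    Uses a k-d tree; the result is identical to the all-pairs scan.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    ra, rb = cs.partner_a.residues, cs.partner_b.residues
    xa, own_a = _heavy_atom_table(ra)
    xb, own_b = _heavy_atom_table(rb)
    if len(xa) == 0 or len(xb) == 0:
        return InterfaceDefinition(cutoff)
    tree_b = cKDTree(xb)
    hits_a: set[int] = set()
    hits_b: set[int] = set()
    for ia, neighbours in enumerate(tree_b.query_ball_point(xa, cutoff)):
        for ib in neighbours:
            if np.linalg.norm(xa[ia] - xb[ib]) < cutoff:  # strict <
                hits_a.add(own_a[ia])
                hits_b.add(own_b[ib])
    return InterfaceDefinition(
        cutoff,
        residues_a=[ra[i] for i in sorted(hits_a)],
        residues_b=[rb[i] for i in sorted(hits_b)],
    )


def segment_com(segment: list[Residue]) -> np.ndarray:
    """Unweighted mean of the segment's Cα coordinates."""
    cas = []
    for res in segment:
        ca = res.atom("CA")
        if ca is None:
            raise StructureError(f"incomplete backbone: {res.res_name} {res.key} lacks CA")
        cas.append(ca.coords)
    return np.mean(cas, axis=0)


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral point set on the unit sphere."""
    i = np.arange(n)
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(1.0 - z * z)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def sasa(atoms_or_structure, probe: float = 1.4, n_points: int = 960) -> np.ndarray:
    """Shrake–Rupley solvent-accessible surface area, per heavy atom (Å²).

    Each atom's sphere of radius ``r_vdw + probe`` is sampled with a
    deterministic golden-spiral point set; a point is accessible if it lies
    strictly outside every neighbouring atom's expanded sphere.  Exactly
    coincident equal-radius atoms are counted once (the duplicates report
    zero area), so the degenerate fully-overlapping pair sums to one sphere.

    Accepts a ComplexStructure, a PartnerGroup, a residue list, or an atom
    list; returns per-atom areas in the heavy-atom traversal order (sums to
    the molecule total).
    """
    atoms = _as_heavy_atoms(atoms_or_structure)
    n = len(atoms)
    if n == 0:
        return np.empty(0)
    coords = np.array([a.coords for a in atoms])
    radii = np.array([VDW_RADII.get(a.element.upper(), DEFAULT_VDW) + probe for a in atoms])
    areas = np.zeros(n)
    seen: dict[tuple, int] = {}
    keep = []
    for i in range(n):
        key = (round(coords[i, 0], 6), round(coords[i, 1], 6),
               round(coords[i, 2], 6), round(radii[i], 6))
        if key not in seen:
            seen[key] = i
            keep.append(i)
    coords_u, radii_u = coords[keep], radii[keep]
    unit = _sphere_points(n_points)
    tree = cKDTree(coords_u)
    max_r = radii_u.max()
    for k, i in enumerate(keep):
        pts = coords_u[k] + radii_u[k] * unit
        neigh = [j for j in tree.query_ball_point(coords_u[k], radii_u[k] + max_r)
                 if j != k]
        buried = np.zeros(n_points, dtype=bool)
        for j in neigh:
            d2 = np.sum((pts - coords_u[j]) ** 2, axis=1)
            buried |= d2 < radii_u[j] ** 2
        areas[i] = (1.0 - buried.mean()) * 4.0 * math.pi * radii_u[k] ** 2
    return areas


def _as_heavy_atoms(obj) -> list[Atom]:
    if isinstance(obj, ComplexStructure):
        residues = obj.all_residues()
    elif hasattr(obj, "residues"):
        residues = obj.residues
    elif obj and isinstance(obj[0], Residue):
        residues = obj
    else:
        return list(obj)
    return [a for r in residues for a in r.heavy_atoms()]


def buried_area(cs: ComplexStructure, probe: float = 1.4, n_points: int = 960,
                halved: bool = True) -> float:
    """Solvent-accessible area buried on complex formation.

    ``(SASA(A) + SASA(B) − SASA(AB)) / 2`` by default; ``halved=False`` gives
    the unhalved two-body sum.
    """
    a = sasa(cs.partner_a, probe, n_points).sum()
    b = sasa(cs.partner_b, probe, n_points).sum()
    ab = sasa(cs, probe, n_points).sum()
    total = a + b - ab
    return total / 2.0 if halved else total


def _interface_atom_coms(cs: ComplexStructure, cutoff: float = 10.0) -> tuple[np.ndarray, np.ndarray]:
    """Mass-unweighted COM of each partner's interface heavy atoms
    (atoms within `cutoff` of the other partner)."""
    xa, _ = _heavy_atom_table(cs.partner_a.residues)
    xb, _ = _heavy_atom_table(cs.partner_b.residues)
    if len(xa) == 0 or len(xb) == 0:
        raise StructureError("displacement axis undefined: a partner has no atoms")
    ta, tb = cKDTree(xa), cKDTree(xb)
    near_a = sorted({i for i, js in enumerate(ta.query_ball_tree(tb, cutoff)) if js})
    near_b = sorted({j for js in ta.query_ball_tree(tb, cutoff) for j in js})
    if not near_a or not near_b:
        raise StructureError("displacement axis undefined: empty interface")
    return xa[near_a].mean(axis=0), xb[np.array(near_b)].mean(axis=0)


def interface_axis(cs: ComplexStructure, cutoff: float = 10.0) -> np.ndarray:
    """Unit vector from the COM of partner A's interface atoms to the COM of
    partner B's interface atoms (heavy atoms within `cutoff` of the other
    partner, mass-unweighted)."""
    com_a, com_b = _interface_atom_coms(cs, cutoff)
    axis = com_b - com_a
    norm = np.linalg.norm(axis)
    if norm < 1e-9:
        raise StructureError("displacement axis undefined: coincident interface COMs")
    return axis / norm


def displace_partner(cs: ComplexStructure, distance: float,
                     interface_cutoff: float = 10.0,
                     axis: np.ndarray | None = None) -> ComplexStructure:
    """Rigidly translate partner B along the interface centre-of-mass axis.

    Positive distance separates the partners; ``distance == 0`` returns an
    identical copy.  By default the axis is recomputed from the pose given
    (see :func:`interface_axis`); a displacement *series* is defined along
    the line fixed by its reference pose, so pass that pose's axis explicitly
    (or displace the reference each time) — interface membership changes as
    the partners separate, which would otherwise bend the line.
    """
    out = cs.copy()
    if distance == 0.0:
        return out
    if axis is None:
        axis = interface_axis(cs, interface_cutoff)
    else:
        axis = np.asarray(axis, float)
        axis = axis / np.linalg.norm(axis)
    shift = axis * distance
    for res in out.partner_b.residues:
        for a in res.atoms:
            a.coords = a.coords + shift
    return out


def translate_partner(cs: ComplexStructure, shift) -> ComplexStructure:
    """Rigidly translate partner B by an arbitrary vector (helper for scans)."""
    out = cs.copy()
    shift = np.asarray(shift, dtype=float)
    for res in out.partner_b.residues:
        for a in res.atoms:
            a.coords = a.coords + shift
    return out


def _ideal_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """CB at the ideal tetrahedral position for an L-amino acid (1.53 Å)."""
    u_n = (n - ca) / np.linalg.norm(n - ca)
    u_c = (c - ca) / np.linalg.norm(c - ca)
    bisector = u_n + u_c
    bisector /= np.linalg.norm(bisector)
    perp = np.cross(u_n, u_c)
    perp /= np.linalg.norm(perp)
    # N-CA-CB ≈ C-CA-CB ≈ 110.4° with the L chirality
    half = math.acos(float(np.dot(u_n, u_c))) / 2.0
    alpha = -math.cos(math.radians(110.4)) / math.cos(half)
    alpha = min(alpha, 1.0)
    beta = math.sqrt(max(0.0, 1.0 - alpha * alpha))
    direction = -alpha * bisector + beta * perp
    return ca + 1.53 * direction / np.linalg.norm(direction)


def strip_side_chains(cs: ComplexStructure, region: InterfaceDefinition | None = None,
                      mutate_gly: bool = False) -> ComplexStructure:
    """Replace side chains by alanine (poly-Ala interface).

    Selected residues keep only N, CA, C, O, CB and are renamed ALA; a missing
    CB is synthesised at the ideal tetrahedral position.  Glycine is left
    untouched unless ``mutate_gly``.  ``region=None`` strips everything.
    """
    out = cs.copy()
    selected: set[tuple] | None = None
    if region is not None:
        selected = {r.key for r in region.residues_a} | {r.key for r in region.residues_b}
    for res in out.all_residues():
        if selected is not None and res.key not in selected:
            continue
        if res.res_name == "GLY" and not mutate_gly:
            continue
        keep = {a.name: a for a in res.atoms if a.name in ("N", "CA", "C", "O", "CB")}
        if not all(k in keep for k in ("N", "CA", "C")):
            continue  # cannot rebuild on a broken backbone
        if "CB" not in keep:
            cb = _ideal_cb(keep["N"].coords, keep["CA"].coords, keep["C"].coords)
            keep["CB"] = Atom("CB", "C", cb)
        res.res_name = "ALA"
        res.atoms = [keep[k] for k in ("N", "CA", "C", "O", "CB") if k in keep]
    return out


def scan_placement(cs: ComplexStructure, db, step: float = 1.0, radius: float = 3.0,
                   params=None) -> list[Placement]:
    """Translational placement scan of partner B on a full cubic grid.

    Every integer-step translation with each component in [-radius, +radius]
    (origin included) is evaluated by running the matcher; placements are
    returned sorted by match count (desc), mean match RMSD (asc, None last)
    and lexicographic translation.  Deterministic.
    """
    from .matching import MatchParams, match_interface

    params = params or MatchParams()
    k = int(round(radius / step))
    offsets = [np.array(t) * step
               for t in itertools.product(range(-k, k + 1), repeat=3)]
    placements = []
    for off in offsets:
        pose = translate_partner(cs, off)
        matches = match_interface(pose, db, params)
        mean_rmsd = float(np.mean([m.rmsd for m in matches])) if matches else None
        placements.append(Placement(off, len(matches), mean_rmsd))
    placements.sort(key=lambda p: (
        -p.match_count,
        p.mean_match_rmsd if p.mean_match_rmsd is not None else float("inf"),
        tuple(p.translation),
    ))
    return placements


def _paired_heavy_coords(ref_residues: list[Residue], model_index: dict) -> tuple[np.ndarray, np.ndarray]:
    ref_pts, mod_pts = [], []
    for res in ref_residues:
        mres = model_index.get(res.key)
        if mres is None:
            raise StructureError(f"residue inventory mismatch: {res.key} missing from model")
        for a in res.heavy_atoms():
            ma = mres.atom(a.name)
            if ma is None:
                raise StructureError(f"atom inventory mismatch: {res.key} {a.name}")
            ref_pts.append(a.coords)
            mod_pts.append(ma.coords)
    return np.array(ref_pts), np.array(mod_pts)


def _model_index(model: ComplexStructure) -> dict:
    return {r.key: r for r in model.all_residues()}


def irmsd(reference: ComplexStructure, model: ComplexStructure, cutoff: float = 10.0) -> float:
    """Interface RMSD: heavy-atom RMSD over the residues of the *reference*
    interface, after best superposition of exactly those atoms."""
    from .matching import kabsch

    iface = identify_interface(reference, cutoff)
    residues = iface.residues_a + iface.residues_b
    if not residues:
        raise StructureError("reference has an empty interface")
    ref, mod = _paired_heavy_coords(residues, _model_index(model))
    _, _, rms = kabsch(mod, ref)
    return rms


def lrmsd(reference: ComplexStructure, model: ComplexStructure) -> float:
    """Ligand RMSD: superpose the model's partner A (receptor) onto the
    reference's, then report partner B heavy-atom RMSD without refitting."""
    from .matching import kabsch

    idx = _model_index(model)
    ref_a, mod_a = _paired_heavy_coords(reference.partner_a.residues, idx)
    rot, trans, _ = kabsch(mod_a, ref_a)
    ref_b, mod_b = _paired_heavy_coords(reference.partner_b.residues, idx)
    mod_b_fit = mod_b @ rot.T + trans
    return float(np.sqrt(np.mean(np.sum((mod_b_fit - ref_b) ** 2, axis=1))))
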