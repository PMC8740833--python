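"""Synthetic complex generator: ideal helix pairs with known ground truth.

Every other module is testable without downloads: the generator builds ideal
α-helices (NeRF backbone construction at canonical φ/ψ, side chains taken
from ideal residue templates), pairs them into two-partner complexes, and
records what the pipeline should find (planted motifs, chain breaks, known
clashes, displacement series).  Output is deterministic under a fixed seed.

Side chains carry a single idealized conformer (the chemical-component
ideal coordinates); that is sufficient here because the method transplants
side-chain conformations rather than refining them.
"""

from __future__ import annotations

import json
import math
import random
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import biotite.structure.info as struc_info

from .interface_geometry import displace_partner
from .matching import kabsch
from .motif_db import (InteractionMotif, MotifDatabase, MotifResidue,
                       build_database_from_complexes, distance_vector)
from .structure_io import Atom, ComplexStructure, PartnerGroup, Residue, write_complex

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}

# Ideal backbone geometry (Å / degrees) for the NeRF build
BOND_N_CA, BOND_CA_C, BOND_C_N, BOND_C_O = 1.458, 1.525, 1.329, 1.231
ANG_N_CA_C, ANG_CA_C_N, ANG_C_N_CA, ANG_CA_C_O = 111.2, 116.2, 121.7, 120.8
HELIX_PHI, HELIX_PSI, OMEGA = -57.8, -47.0, 180.0

#: Alphabet used for random fixture sequences — hydrophobic-rich so motifs
#: pass the database composition filter, with polar residues mixed in.
FIXTURE_ALPHABET = "LLVVIAAFMSTQK"


def _place_atom(a, b, c, bond, angle_deg, dihedral_deg):
    """NeRF internal-coordinate atom placement (d bonded to c)."""
    theta = math.radians(angle_deg)
    chi = math.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([-bond * math.cos(theta),
                        bond * math.sin(theta) * math.cos(chi),
                        bond * math.sin(theta) * math.sin(chi)])
    return c + np.column_stack([bc, m, n]) @ d_local


def _helix_backbone(n_res: int) -> list[dict[str, np.ndarray]]:
    """Ideal α-helix backbone (N, CA, C, O per residue) in a local frame."""
    res: list[dict[str, np.ndarray]] = []
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([BOND_N_CA, 0.0, 0.0])
    theta = math.radians(ANG_N_CA_C)
    c0 = ca0 + BOND_CA_C * np.array([-math.cos(theta), math.sin(theta), 0.0])
    res.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, n_res):
        prev = res[-1]
        n = _place_atom(prev["N"], prev["CA"], prev["C"], BOND_C_N, ANG_CA_C_N, HELIX_PSI)
        ca = _place_atom(prev["CA"], prev["C"], n, BOND_N_CA, ANG_C_N_CA, OMEGA)
        c = _place_atom(prev["C"], n, ca, BOND_CA_C, ANG_N_CA_C, HELIX_PHI)
        prev["O"] = _place_atom(n, prev["CA"], prev["C"], BOND_C_O, ANG_CA_C_O, 180.0)
        res.append({"N": n, "CA": ca, "C": c})
    last = res[-1]
    last["O"] = _place_atom(last["N"], last["CA"], last["C"], BOND_C_O, ANG_CA_C_O,
                            HELIX_PSI + 180.0)
    return res


_TEMPLATE_CACHE: dict[str, tuple[np.ndarray, list[tuple[str, str]], np.ndarray]] = {}


def _residue_template(res_name: str):
    """Ideal-geometry heavy-atom template: (backbone N/CA/C frame,
    [(side-chain atom name, element)], side-chain coords)."""
    if res_name not in _TEMPLATE_CACHE:
        arr = struc_info.residue(res_name)
        arr = arr[arr.element != "H"]
        names = list(arr.atom_name)
        frame = np.array([arr.coord[names.index(n)] for n in ("N", "CA", "C")])
        side = [(n, e, c) for n, e, c in zip(arr.atom_name, arr.element, arr.coord)
                if n not in ("N", "CA", "C", "O", "OXT")]
        _TEMPLATE_CACHE[res_name] = (
            frame,
            [(n, e) for n, e, _ in side],
            np.array([c for _, _, c in side]) if side else np.empty((0, 3)),
        )
    return _TEMPLATE_CACHE[res_name]


def make_ideal_helix(n_res: int, sequence: str, axis=(0, 0, 1.0), origin=(0, 0, 0),
                     chain_id: str = "A", start_seq: int = 1, roll_deg: float = 0.0
                     ) -> PartnerGroup:
    """Build an ideal α-helix with full heavy-atom side chains.

    The canonical backbone (φ = −57.8°, ψ = −47°) gives consecutive Cα–Cα
    distances of ~3.8 Å; side chains are grafted from ideal residue
    templates via the local N/CA/C frame.  The helix is oriented along
    `axis` with its Cα centroid at `origin`.
    """
    if n_res < 4:
        raise ValueError("helix needs at least 4 residues")
    if len(sequence) != n_res:
        raise ValueError("sequence length must equal n_res")
    for ch in sequence:
        if ch not in ONE_TO_THREE:
            raise ValueError(f"invalid sequence letter {ch!r}")
    backbone = _helix_backbone(n_res)

    # orient: principal axis of the CA trace -> requested axis
    cas = np.array([r["CA"] for r in backbone])
    centred = cas - cas.mean(axis=0)
    helix_axis = np.linalg.svd(centred)[2][0]
    if np.dot(helix_axis, cas[-1] - cas[0]) < 0:
        helix_axis = -helix_axis
    target_axis = np.asarray(axis, float)
    target_axis /= np.linalg.norm(target_axis)
    rot = _rotation_between(helix_axis, target_axis)
    if roll_deg:
        rot = _axis_rotation(target_axis, math.radians(roll_deg)) @ rot
    shift = np.asarray(origin, float)

    def xf(p):
        return rot @ (p - cas.mean(axis=0)) + shift

    residues = []
    for i, (letter, bb) in enumerate(zip(sequence, backbone)):
        res_name = ONE_TO_THREE[letter]
        atoms = [Atom(n, n[0], xf(bb[n])) for n in ("N", "CA", "C", "O")]
        frame, side_names, side_coords = _residue_template(res_name)
        if len(side_names):
            bb_frame = np.array([xf(bb[n]) for n in ("N", "CA", "C")])
            r, t, _ = kabsch(frame, bb_frame)
            placed = side_coords @ r.T + t
            for (name, elem), coord in zip(side_names, placed):
                atoms.append(Atom(name, elem, coord))
        residues.append(Residue(res_name, chain_id, start_seq + i, "", atoms))
    return PartnerGroup(f"{chain_id}-side", {chain_id}, residues)


def _rotation_between(u, v) -> np.ndarray:
    """Minimal proper rotation taking unit vector u onto unit vector v."""
    c = float(np.dot(u, v))
    if c > 1 - 1e-12:
        return np.eye(3)
    if c < -1 + 1e-12:
        # pick any perpendicular axis for the 180° flip
        perp = np.cross(u, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(u, [0.0, 1.0, 0.0])
        return _axis_rotation(perp / np.linalg.norm(perp), math.pi)
    axis = np.cross(u, v)
    s = np.linalg.norm(axis)
    axis /= s
    return _axis_rotation(axis, math.atan2(s, c))


def _axis_rotation(axis, angle) -> np.ndarray:
    axis = np.asarray(axis, float)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + math.sin(angle) * k + (1 - math.cos(angle)) * (k @ k)


@dataclass
class FixtureSpec:
    kind: str = "helix_pair"     # helix_pair | planted_motif | chain_break |
                                 # clash_pair | displacement_series
    n_res: int = 12
    distance: float = 9.0        # inter-axial helix distance (Å)
    antiparallel: bool = True
    roll_a: float = 0.0
    roll_b: float = 0.0
    tilt_b: float = 0.0          # crossing angle: helix B axis tilted about y (deg)
    jitter: float = 0.15         # per-coordinate Gaussian noise σ (Å); emulates
                                 # the structural heterogeneity of real complexes
                                 # and breaks the exact screw symmetry of ideal
                                 # helices (0 = strictly ideal geometry)
    seq_a: str | None = None
    seq_b: str | None = None
    seed: int = 0
    complex_id: str = "fixture"
    extras: dict = field(default_factory=dict)


def _random_sequence(n: int, rng: random.Random) -> str:
    return "".join(rng.choice(FIXTURE_ALPHABET) for _ in range(n))


def make_complex_fixture(spec: FixtureSpec) -> tuple[ComplexStructure, dict]:
    """Build a synthetic two-helix complex plus ground-truth annotation.

    Kinds: ``helix_pair`` (two antiparallel helices at the requested
    inter-axial distance), ``planted_motif`` (records the central 4+4 window
    as the native motif), ``chain_break`` (partner A carries a >4.5 Å Cα gap
    after residue 4), ``clash_pair`` (helices close enough for sub-2.5 Å
    side-chain contacts), ``displacement_series`` (base pose; displaced
    poses via :func:`displaced_series`).
    """
    rng = random.Random(spec.seed)
    n = spec.n_res
    seq_a = spec.seq_a or _random_sequence(n, rng)
    seq_b = spec.seq_b or _random_sequence(n, rng)
    distance = spec.distance if spec.kind != "clash_pair" else spec.extras.get("distance", 5.0)
    axis_b = np.array([0.0, 0.0, -1.0 if spec.antiparallel else 1.0])
    if spec.tilt_b:
        axis_b = _axis_rotation((0, 1.0, 0), math.radians(spec.tilt_b)) @ axis_b
    helix_a = make_ideal_helix(n, seq_a, axis=(0, 0, 1.0), origin=(0, 0, 0),
                               chain_id="A", roll_deg=spec.roll_a)
    helix_b = make_ideal_helix(n, seq_b, axis=axis_b, origin=(distance, 0, 0),
                               chain_id="B", roll_deg=spec.roll_b)
    if spec.jitter > 0:
        noise_rng = np.random.default_rng(spec.seed + 10_007)
        for group in (helix_a, helix_b):
            for res in group.residues:
                for a in res.atoms:
                    a.coords = a.coords + noise_rng.normal(scale=spec.jitter, size=3)
    truth: dict = {"kind": spec.kind, "seq_a": seq_a, "seq_b": seq_b,
                   "distance": distance, "n_res": n, "jitter": spec.jitter}

    if spec.kind == "chain_break":
        gap = spec.extras.get("gap_after", 4)
        shift = np.array([0.0, 0.0, spec.extras.get("gap_shift", 4.0)])
        for res in helix_a.residues[gap:]:
            for a in res.atoms:
                a.coords = a.coords + shift
        truth["gap_after"] = gap

    cs = ComplexStructure(spec.complex_id, helix_a, helix_b)

    if spec.kind == "planted_motif":
        mid = (n - 4) // 2
        truth["native_window_a"] = [r.key for r in helix_a.residues[mid:mid + 4]]
        truth["native_window_b"] = [r.key for r in helix_b.residues[mid:mid + 4]]
    return cs, truth


def displaced_series(cs: ComplexStructure, distances=(0, 1, 2, 3, 4)
                     ) -> list[tuple[float, ComplexStructure]]:
    """Poses with partner B moved along the reference pose's interface-COM
    axis (Å steps); all poses lie on the same line."""
    from .interface_geometry import interface_axis
    axis = interface_axis(cs)
    return [(float(d), displace_partner(cs, float(d), axis=axis)) for d in distances]


def default_fixture_specs(seed: int = 7) -> list[FixtureSpec]:
    """The bundled fixture corpus: five helix pairs with distinct packing
    geometries (inter-axial distance, crossing angle, parallel vs
    antiparallel, helical phase) so each complex's motifs survive redundancy
    reduction as its own representatives."""
    return [
        FixtureSpec(n_res=12, distance=8.0, seed=seed, complex_id="fix0"),
        FixtureSpec(n_res=12, distance=9.5, roll_b=60.0, seed=seed + 1,
                    complex_id="fix1"),
        FixtureSpec(n_res=12, distance=8.5, antiparallel=False, roll_a=30.0,
                    seed=seed + 2, complex_id="fix2"),
        FixtureSpec(n_res=14, distance=9.2, roll_b=150.0, seed=seed + 3,
                    complex_id="fix3"),
        FixtureSpec(n_res=12, distance=9.0, tilt_b=35.0, seed=seed + 4,
                    complex_id="fix4"),
    ]


def make_fixture_database(specs: list[FixtureSpec] | None = None, *,
                          seed: int = 7, com_cutoff: float = 11.0,
                          min_nonpolar: int = 3, reduce_cutoff: float = 1.0,
                          min_interface_area: float = 0.0,
                          min_partner_residues: int = 0
                          ) -> tuple[MotifDatabase, list[tuple[ComplexStructure, dict]]]:
    """Build a motif database over generated fixtures.

    Inclusion filters default to off: the synthetic helices are deliberately
    much smaller than the database-corpus inclusion thresholds.  Returns the
    database and the generated (complex, ground truth) list for assertions.
    """
    specs = specs if specs is not None else default_fixture_specs(seed)
    generated = [make_complex_fixture(s) for s in specs]
    db = build_database_from_complexes(
        [cs for cs, _ in generated],
        com_cutoff=com_cutoff, min_nonpolar=min_nonpolar,
        reduce_cutoff=reduce_cutoff, min_interface_area=min_interface_area,
        min_partner_residues=min_partner_residues)
    return db, generated


def make_random_motifs(n: int, seed: int = 0, spread: float = 8.0) -> list[InteractionMotif]:
    """Synthetic motif entries for scale tests: two 4-residue Cα traces with
    ~3.8 Å virtual bonds, random relative placement, CA-only residues."""
    rng = np.random.default_rng(seed)
    motifs = []
    for k in range(n):
        segs = []
        for s in range(2):
            start = rng.normal(scale=spread, size=3) if s else np.zeros(3)
            pts = [start]
            for _ in range(3):
                step = rng.normal(size=3)
                step *= 3.8 / np.linalg.norm(step)
                pts.append(pts[-1] + step)
            segs.append(np.array(pts))
        ca = np.vstack(segs)
        seg_res = []
        for s in range(2):
            seg_res.append([
                MotifResidue("ALA", "AB"[s], i + 1, "", ["CA"], ["C"],
                             ca[4 * s + i:4 * s + i + 1].copy())
                for i in range(4)])
        motifs.append(InteractionMotif(
            source_id=f"synth{k}", seg_a=seg_res[0], seg_b=seg_res[1],
            ca_coords=ca, dist_vector=distance_vector(ca),
            com_distance=float(np.linalg.norm(ca[:4].mean(0) - ca[4:].mean(0)))))
    return motifs


def write_fixture_corpus(out_dir, specs: list[FixtureSpec] | None = None,
                         seed: int = 7) -> Path:
    """Write fixture PDBs, a build manifest and ground-truth JSON sidecars.

    Returns the manifest path (TSV: file, partner A chains, partner B chains).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    specs = specs if specs is not None else default_fixture_specs(seed)
    lines = []
    for spec in specs:
        cs, truth = make_complex_fixture(spec)
        name = f"{spec.complex_id}.pdb"
        write_complex(cs, out_dir / name)
        with open(out_dir / f"{spec.complex_id}.truth.json", "w") as fh:
            json.dump({k: _jsonable(v) for k, v in truth.items()}, fh, indent=1)
        lines.append(f"{name}\tA\tB")
    manifest = out_dir / "manifest.tsv"
    manifest.write_text("\n".join(lines) + "\n")
    return manifest


def _jsonable(v):
    if isinstance(v, (list, tuple)):
        return [_jsonable(x) for x in v]
    return v
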