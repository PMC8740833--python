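"""Interaction-motif extraction, filtering, redundancy reduction and storage.

An interaction motif is a pair of four-residue, chain-contiguous segments —
one per binding partner — whose Cα centres of mass lie within a cutoff
(11 Å when building the database, 10 Å on the target side).  A motif is
characterised by its 28 internal Cα–Cα distances (all pairs of the 8 Cα
atoms, segment A residues 1–4 then segment B residues 1–4); this distance
vector is rotation-, translation- and reflection-invariant and drives the
fast matching prefilter.  Full heavy-atom coordinates are kept alongside for
side-chain grafting.
"""

from __future__ import annotations

import gzip
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .interface_geometry import NONPOLAR_AROMATIC, buried_area, segment_com
from .structure_io import Atom, ComplexStructure, Residue, parse_complex

log = logging.getLogger(__name__)

DB_MAGIC = "MOTIFMATCH-DB"
DB_VERSION = 1

#: Index pairs (i < j) of the 8 ordered Cα atoms, fixed storage order.
PAIR_INDICES = [(i, j) for i in range(8) for j in range(i + 1, 8)]

#: Permutation of the 28-vector that corresponds to swapping segment A and B
#: (atom i -> (i + 4) mod 8, within-segment order preserved).
_swap_atom = [(i + 4) % 8 for i in range(8)]
_pair_pos = {p: k for k, p in enumerate(PAIR_INDICES)}
SWAP_PERMUTATION = np.array([
    _pair_pos[tuple(sorted((_swap_atom[i], _swap_atom[j])))] for i, j in PAIR_INDICES
])


@dataclass
class MotifResidue:
    """Identity + heavy-atom coordinates of one motif residue (graft source)."""
    res_name: str
    chain_id: str
    res_seq: int
    icode: str
    atom_names: list[str]
    atom_elements: list[str]
    atom_coords: np.ndarray  # (n, 3)

    @classmethod
    def from_residue(cls, res: Residue) -> "MotifResidue":
        heavy = res.heavy_atoms()
        return cls(res.res_name, res.chain_id, res.res_seq, res.icode,
                   [a.name for a in heavy], [a.element for a in heavy],
                   np.array([a.coords for a in heavy]))

    def to_residue(self) -> Residue:
        return Residue(self.res_name, self.chain_id, self.res_seq, self.icode,
                       [Atom(n, e, c) for n, e, c in
                        zip(self.atom_names, self.atom_elements, self.atom_coords)])

    @property
    def key(self):
        return (self.chain_id, self.res_seq, self.icode)


@dataclass
class InteractionMotif:
    source_id: str
    seg_a: list[MotifResidue]  # 4 residues, N→C
    seg_b: list[MotifResidue]
    ca_coords: np.ndarray      # (8, 3): seg_a 1–4 then seg_b 1–4
    dist_vector: np.ndarray    # (28,)
    com_distance: float

    @property
    def residue_names(self) -> list[str]:
        return [r.res_name for r in self.seg_a + self.seg_b]

    def identity_key(self) -> tuple:
        return (self.source_id,
                tuple(r.key for r in self.seg_a),
                tuple(r.key for r in self.seg_b))

    def segments(self, swapped: bool = False) -> tuple[list[MotifResidue], list[MotifResidue]]:
        return (self.seg_b, self.seg_a) if swapped else (self.seg_a, self.seg_b)

    def ca_matrix(self, swapped: bool = False) -> np.ndarray:
        if not swapped:
            return self.ca_coords
        return np.vstack([self.ca_coords[4:], self.ca_coords[:4]])


@dataclass
class MotifDatabase:
    motifs: list[InteractionMotif] = field(default_factory=list)
    build_params: dict = field(default_factory=dict)
    version: int = DB_VERSION
    _matrix: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __len__(self):
        return len(self.motifs)

    def distance_matrix(self) -> np.ndarray:
        """(n, 28) stack of all stored distance vectors (cached)."""
        if self._matrix is None or len(self._matrix) != len(self.motifs):
            self._matrix = (np.vstack([m.dist_vector for m in self.motifs])
                            if self.motifs else np.empty((0, 28)))
        return self._matrix


def distance_vector(ca_coords: np.ndarray) -> np.ndarray:
    """All 28 pairwise Cα distances of an 8-point motif, fixed (i<j) order."""
    ca = np.asarray(ca_coords, dtype=float)
    if ca.shape != (8, 3):
        raise ValueError(f"expected (8, 3) Cα matrix, got {ca.shape}")
    diffs = ca[:, None, :] - ca[None, :, :]
    dmat = np.sqrt(np.sum(diffs ** 2, axis=-1))
    return np.array([dmat[i, j] for i, j in PAIR_INDICES])


def drmsd(v1: np.ndarray, v2: np.ndarray) -> float:
    """Root-mean-square difference of two internal-distance vectors (Å)."""
    v1, v2 = np.asarray(v1, float), np.asarray(v2, float)
    if v1.shape != v2.shape:
        raise ValueError(f"length mismatch: {v1.shape} vs {v2.shape}")
    return float(np.sqrt(np.mean((v1 - v2) ** 2)))


def _make_motif(source_id: str, win_a: list[Residue], win_b: list[Residue],
                com_dist: float) -> InteractionMotif:
    ca = np.array([r.atom("CA").coords for r in win_a + win_b])
    return InteractionMotif(
        source_id=source_id,
        seg_a=[MotifResidue.from_residue(r) for r in win_a],
        seg_b=[MotifResidue.from_residue(r) for r in win_b],
        ca_coords=ca,
        dist_vector=distance_vector(ca),
        com_distance=com_dist,
    )


def extract_motifs(cs: ComplexStructure, com_cutoff: float = 11.0) -> list[InteractionMotif]:
    """Enumerate all 4+4 contiguous-window pairs with segment Cα-COM distance
    strictly below `com_cutoff` (stride-1 windows, one motif per kept pair)."""
    if com_cutoff <= 0:
        raise ValueError("com_cutoff must be positive")
    wins_a = cs.partner_a.contiguous_windows(4)
    wins_b = cs.partner_b.contiguous_windows(4)
    if not wins_a or not wins_b:
        log.warning("%s: a partner has no contiguous 4-residue window", cs.id)
        return []
    coms_a = np.array([segment_com(w) for w in wins_a])
    coms_b = np.array([segment_com(w) for w in wins_b])
    dists = np.linalg.norm(coms_a[:, None, :] - coms_b[None, :, :], axis=-1)
    motifs = []
    for i in range(len(wins_a)):
        for j in range(len(wins_b)):
            if dists[i, j] < com_cutoff:
                motifs.append(_make_motif(cs.id, wins_a[i], wins_b[j], float(dists[i, j])))
    return motifs


def composition_filter(motif: InteractionMotif, min_nonpolar: int = 3) -> bool:
    """True iff at least `min_nonpolar` of the motif's 8 residues are
    nonpolar or aromatic (ALA VAL LEU ILE MET PRO CYS PHE TRP TYR)."""
    count = sum(1 for name in motif.residue_names if name in NONPOLAR_AROMATIC)
    return count >= min_nonpolar


def reduce_database(motifs: list[InteractionMotif], drmsd_cutoff: float = 1.0) -> list[InteractionMotif]:
    """Greedy redundancy reduction, deterministic in input order.

    A motif is kept iff its dRMSD to every previously kept motif exceeds
    `drmsd_cutoff`.  Idempotent; output preserves input order.
    """
    kept: list[InteractionMotif] = []
    kept_vecs: list[np.ndarray] = []
    mat: np.ndarray | None = None
    for m in motifs:
        if kept:
            if mat is None or len(mat) != len(kept_vecs):
                mat = np.vstack(kept_vecs)
            d = np.sqrt(np.mean((mat - m.dist_vector) ** 2, axis=1))
            if not np.all(d > drmsd_cutoff):
                continue
        kept.append(m)
        kept_vecs.append(m.dist_vector)
        mat = None
    return kept


def read_manifest(path) -> list[tuple[str, list[str], list[str]]]:
    """TSV manifest: ``file<TAB>partner_a_chains<TAB>partner_b_chains``,
    chains comma-separated; '#' lines ignored."""
    entries = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fname, a, b = line.split("\t")
        entries.append((fname, a.split(","), b.split(",")))
    return entries


def build_database_from_complexes(complexes: list[ComplexStructure],
                                  com_cutoff: float = 11.0,
                                  min_interface_area: float = 1000.0,
                                  min_partner_residues: int = 40,
                                  min_nonpolar: int = 3, reduce_cutoff: float = 1.0,
                                  sasa_points: int = 240,
                                  area_halved: bool = True) -> MotifDatabase:
    """Build a motif database from parsed complexes.

    Per complex: skip if the buried interface area is below
    `min_interface_area` (Å², 0 disables) or either partner has fewer than
    `min_partner_residues` residues (0 disables); otherwise extract motifs
    at `com_cutoff`.  Pooled motifs then pass the nonpolar-composition
    filter and greedy dRMSD redundancy reduction.  Every stage count is
    recorded in ``build_params`` so the bookkeeping is reproducible on any
    corpus.
    """
    pooled: list[InteractionMotif] = []
    counts = {"complexes": 0, "skipped_small_partner": 0, "skipped_small_interface": 0,
              "included": 0, "extracted": 0}
    corpus_listing = []
    for cs in complexes:
        counts["complexes"] += 1
        if min_partner_residues > 0 and (
                len(cs.partner_a.residues) < min_partner_residues
                or len(cs.partner_b.residues) < min_partner_residues):
            log.info("skipping %s: partner <%d residues", cs.id, min_partner_residues)
            counts["skipped_small_partner"] += 1
            continue
        if min_interface_area > 0 and buried_area(
                cs, n_points=sasa_points, halved=area_halved) < min_interface_area:
            log.info("skipping %s: interface <%g Å²", cs.id, min_interface_area)
            counts["skipped_small_interface"] += 1
            continue
        motifs = extract_motifs(cs, com_cutoff)
        counts["included"] += 1
        counts["extracted"] += len(motifs)
        pooled.extend(motifs)
        corpus_listing.append(cs.id)
    filtered = [m for m in pooled if composition_filter(m, min_nonpolar)]
    counts["after_composition_filter"] = len(filtered)
    reduced = reduce_database(filtered, reduce_cutoff)
    counts["after_reduction"] = len(reduced)
    log.info("database build: %s", counts)
    return MotifDatabase(
        motifs=reduced,
        build_params={
            "com_cutoff": com_cutoff,
            "min_interface_area": min_interface_area,
            "min_partner_residues": min_partner_residues,
            "min_nonpolar": min_nonpolar,
            "reduce_cutoff": reduce_cutoff,
            "corpus": corpus_listing,
            "counts": counts,
        },
    )


def build_database(corpus_dir, manifest, com_cutoff: float = 11.0,
                   min_interface_area: float = 1000.0, min_partner_residues: int = 40,
                   min_nonpolar: int = 3, reduce_cutoff: float = 1.0,
                   sasa_points: int = 240, area_halved: bool = True) -> MotifDatabase:
    """Build a motif database from a directory of complex PDB files.

    The manifest (TSV path or pre-parsed list) names the partner chain
    groups per file.  Unreadable files are logged and skipped, never fatal
    for the batch.  See :func:`build_database_from_complexes` for the
    filtering pipeline.
    """
    corpus_dir = Path(corpus_dir)
    entries = read_manifest(manifest) if not isinstance(manifest, list) else manifest
    complexes = []
    unreadable = 0
    for fname, chains_a, chains_b in entries:
        try:
            complexes.append(parse_complex(corpus_dir / fname, chains_a, chains_b,
                                           complex_id=Path(fname).stem))
        except Exception as exc:  # never fatal for the batch
            log.warning("skipping %s: %s", fname, exc)
            unreadable += 1
    db = build_database_from_complexes(
        complexes, com_cutoff=com_cutoff, min_interface_area=min_interface_area,
        min_partner_residues=min_partner_residues, min_nonpolar=min_nonpolar,
        reduce_cutoff=reduce_cutoff, sasa_points=sasa_points,
        area_halved=area_halved)
    db.build_params["counts"]["skipped_unreadable"] = unreadable
    return db


def _motif_to_dict(m: InteractionMotif) -> dict:
    def seg(residues):
        return [{
            "res_name": r.res_name, "chain_id": r.chain_id,
            "res_seq": r.res_seq, "icode": r.icode,
            "atom_names": r.atom_names, "atom_elements": r.atom_elements,
            "atom_coords": r.atom_coords.tolist(),
        } for r in residues]
    return {
        "source_id": m.source_id,
        "seg_a": seg(m.seg_a), "seg_b": seg(m.seg_b),
        "ca_coords": m.ca_coords.tolist(),
        "com_distance": m.com_distance,
    }


def _motif_from_dict(d: dict) -> InteractionMotif:
    def seg(items):
        return [MotifResidue(x["res_name"], x["chain_id"], x["res_seq"], x["icode"],
                             list(x["atom_names"]), list(x["atom_elements"]),
                             np.array(x["atom_coords"])) for x in items]
    ca = np.array(d["ca_coords"])
    return InteractionMotif(d["source_id"], seg(d["seg_a"]), seg(d["seg_b"]),
                            ca, distance_vector(ca), d["com_distance"])


def save_database(db: MotifDatabase, path) -> None:
    """Write the database as (optionally gzip-compressed) JSON with a magic
    header and format version; '.gz' suffix selects compression."""
    payload = {
        "magic": DB_MAGIC,
        "version": DB_VERSION,
        "build_params": db.build_params,
        "motifs": [_motif_to_dict(m) for m in db.motifs],
    }
    data = json.dumps(payload).encode()
    path = Path(path)
    if path.suffix == ".gz":
        with gzip.open(path, "wb") as fh:
            fh.write(data)
    else:
        path.write_bytes(data)


def load_database(path) -> MotifDatabase:
    path = Path(path)
    raw = gzip.open(path, "rb").read() if path.suffix == ".gz" else path.read_bytes()
    try:
        payload = json.loads(raw)
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise ValueError(f"{path}: not a valid motif database (corrupt or truncated): {exc}")
    if not isinstance(payload, dict) or payload.get("magic") != DB_MAGIC:
        raise ValueError(f"{path}: not a motif database file (missing magic header)")
    if payload.get("version") != DB_VERSION:
        raise ValueError(f"{path}: database version {payload.get('version')} "
                         f"not supported (expected {DB_VERSION})")
    return MotifDatabase(
        motifs=[_motif_from_dict(d) for d in payload["motifs"]],
        build_params=payload.get("build_params", {}),
        version=payload["version"],
    )
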