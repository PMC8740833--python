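"""Coordinate model for two-partner protein complexes and PDB I/O.

The tool operates on a *complex* of two partner groups, each a set of chains.
Only the 20 standard amino acids are retained (selenomethionine is mapped to
methionine); waters, ligands and hydrogens are dropped on parsing.  Alternate
locations are resolved to the highest-occupancy conformer.

PDB reading and writing is delegated to :mod:`gemmi`; this module owns the
in-memory model the rest of the pipeline works with.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import gemmi
import numpy as np

log = logging.getLogger(__name__)

#: Three-letter codes retained on parsing.
STANDARD_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

#: Non-standard residue names mapped onto a standard parent.
RESIDUE_ALIASES = {"MSE": "MET"}

BACKBONE_ATOMS = ("N", "CA", "C")

#: Maximum Cα(i)–Cα(i+1) distance for two residues to count as consecutive.
#: Author numbering is not trusted across crystallographic chain breaks.
CONTIGUITY_CA_CA = 4.5


class StructureError(ValueError):
    """Raised for malformed or inconsistent structure input."""


@dataclass
class Atom:
    name: str
    element: str
    coords: np.ndarray  # (3,) Å
    occupancy: float = 1.0
    b_factor: float = 0.0

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise StructureError(f"atom {self.name!r}: coords must be a finite 3-vector")
        if not self.name:
            raise StructureError("atom name must be non-empty")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


@dataclass
class Residue:
    res_name: str
    chain_id: str
    res_seq: int
    icode: str = ""
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int, str]:
        """(chain, number, insertion code) — unique within a complex."""
        return (self.chain_id, self.res_seq, self.icode)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def has_backbone(self) -> bool:
        return all(self.atom(n) is not None for n in BACKBONE_ATOMS)

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def side_chain_atoms(self) -> list[Atom]:
        """Heavy atoms beyond the N/CA/C/O backbone (CB included)."""
        return [a for a in self.heavy_atoms()
                if a.name not in ("N", "CA", "C", "O", "OXT")]


@dataclass
class PartnerGroup:
    label: str
    chain_ids: set[str]
    residues: list[Residue]

    def __post_init__(self):
        if not self.residues:
            raise StructureError(f"empty partner {self.label!r}")
        bad = {r.chain_id for r in self.residues} - set(self.chain_ids)
        if bad:
            raise StructureError(f"partner {self.label!r}: residues from undeclared chains {bad}")

    def heavy_coords(self) -> np.ndarray:
        """(n, 3) stack of all heavy-atom coordinates."""
        pts = [a.coords for r in self.residues for a in r.heavy_atoms()]
        return np.array(pts) if pts else np.empty((0, 3))

    def contiguous_windows(self, size: int = 4) -> list[list[Residue]]:
        """All stride-1 windows of `size` chain-contiguous residues.

        Contiguity = same chain and consecutive Cα–Cα distance below
        :data:`CONTIGUITY_CA_CA`; residues lacking a full N/CA/C backbone
        break contiguity.
        """
        windows = []
        run: list[Residue] = []
        for res in self.residues:
            ca = res.atom("CA")
            if not res.has_backbone or ca is None:
                run = []
                continue
            if run:
                prev_ca = run[-1].atom("CA")
                same = run[-1].chain_id == res.chain_id
                if not (same and np.linalg.norm(ca.coords - prev_ca.coords) < CONTIGUITY_CA_CA):
                    run = []
            run.append(res)
            if len(run) >= size:
                windows.append(run[-size:])
        return windows


@dataclass
class ComplexStructure:
    id: str
    partner_a: PartnerGroup
    partner_b: PartnerGroup

    def __post_init__(self):
        if self.partner_a.chain_ids & self.partner_b.chain_ids:
            raise StructureError("partners share chain ids")

    def partners(self) -> tuple[PartnerGroup, PartnerGroup]:
        return self.partner_a, self.partner_b

    def all_residues(self) -> list[Residue]:
        return list(self.partner_a.residues) + list(self.partner_b.residues)

    def copy(self) -> "ComplexStructure":
        return copy.deepcopy(self)


def _resolve_altlocs(raw_atoms: list[tuple[str, str, np.ndarray, float, float, str]]) -> list[Atom]:
    """Keep one atom per name: highest occupancy, ties broken toward altloc 'A'."""
    best: dict[str, tuple[float, int, Atom]] = {}
    for name, element, pos, occ, b, altloc in raw_atoms:
        # rank: occupancy first, then altloc 'A' (or blank) preferred
        pref = 1 if altloc in ("", "A") else 0
        atom = Atom(name, element, pos, occ, b)
        cur = best.get(name)
        if cur is None or (occ, pref) > (cur[0], cur[1]):
            best[name] = (occ, pref, atom)
    return [v[2] for v in best.values()]


def _convert_chain(chain: gemmi.Chain) -> list[Residue]:
    residues = []
    for gres in chain:
        name = RESIDUE_ALIASES.get(gres.name, gres.name)
        if name not in STANDARD_RESIDUES:
            continue
        raw = []
        for at in gres:
            if at.element.is_hydrogen:
                continue
            raw.append((at.name, at.element.name,
                        np.array([at.pos.x, at.pos.y, at.pos.z]),
                        at.occ, at.b_iso, at.altloc))
        if not raw:
            continue
        residues.append(Residue(
            res_name=name,
            chain_id=chain.name,
            res_seq=gres.seqid.num,
            icode=gres.seqid.icode.strip(),
            atoms=_resolve_altlocs(raw),
        ))
    return residues


def parse_complex(path, partner_a_chains: list[str], partner_b_chains: list[str],
                  complex_id: str | None = None) -> ComplexStructure:
    """Parse a PDB file into a two-partner complex.

    Parameters
    ----------
    path
        PDB file with ATOM/HETATM records.
    partner_a_chains, partner_b_chains
        Disjoint, non-empty chain-id lists defining the two partner groups.
    """
    a_set, b_set = set(partner_a_chains), set(partner_b_chains)
    if not a_set or not b_set:
        raise StructureError("both partner chain lists must be non-empty")
    if a_set & b_set:
        raise StructureError(f"partner chain lists overlap: {a_set & b_set}")

    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise StructureError(f"{path}: no models")
    model = st[0]
    chains = {ch.name: ch for ch in model}
    for cid in a_set | b_set:
        if cid not in chains:
            raise StructureError(f"chain not found: {cid!r} (file has {sorted(chains)})")

    def build(label: str, ids: list[str]) -> PartnerGroup:
        residues: list[Residue] = []
        for cid in ids:  # caller-given order
            residues.extend(_convert_chain(chains[cid]))
        if not residues:
            raise StructureError(f"empty partner: no standard residues in chains {ids}")
        return PartnerGroup(label, set(ids), residues)

    return ComplexStructure(
        id=complex_id or st.name or str(path),
        partner_a=build("A-side", list(partner_a_chains)),
        partner_b=build("B-side", list(partner_b_chains)),
    )


def write_complex(cs: ComplexStructure, path, remarks: list[str] | None = None) -> None:
    """Write the complex as fixed-width PDB ATOM records.

    Round-trips through :func:`parse_complex` to 3 decimals (PDB precision).
    Residues with no atoms are skipped with a warning.
    """
    st = gemmi.Structure()
    st.name = cs.id
    model = gemmi.Model("1")
    for group in cs.partners():
        by_chain: dict[str, gemmi.Chain] = {}
        for res in group.residues:
            if not res.atoms:
                log.warning("skipping empty residue %s %s", res.res_name, res.key)
                continue
            ch = by_chain.get(res.chain_id)
            if ch is None:
                ch = gemmi.Chain(res.chain_id)
                by_chain[res.chain_id] = ch
            gres = gemmi.Residue()
            gres.name = res.res_name
            gres.seqid = gemmi.SeqId(res.res_seq, res.icode or " ")
            for a in res.atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(*a.coords)
                ga.occ = a.occupancy
                ga.b_iso = a.b_factor
                gres.add_atom(ga)
            ch.add_residue(gres)
        for ch in by_chain.values():
            model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))
    if remarks:
        with open(path) as fh:
            body = fh.read()
        header = "".join(f"REMARK 999 {text}\n" for text in remarks)
        with open(path, "w") as fh:
            fh.write(header + body)


def backbone_coords(segment: list[Residue], atom_set=("CA",)) -> np.ndarray:
    """Stack the requested backbone atoms of a residue segment.

    Returns an ``(len(segment) * len(atom_set), 3)`` matrix in residue order,
    atoms in the given order within each residue.
    """
    rows = []
    for res in segment:
        for name in atom_set:
            at = res.atom(name)
            if at is None:
                raise StructureError(
                    f"incomplete backbone: residue {res.res_name} {res.key} lacks {name}")
            rows.append(at.coords)
    return np.array(rows)
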