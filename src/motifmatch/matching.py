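"""Motif matching: dRMSD prefilter, Kabsch superposition, match selection.

A target motif matches a database motif when (1) their internal Cα–Cα
distance vectors agree to within a dRMSD threshold and (2) the optimal
*proper* rigid superposition of the 8 Cα atoms has RMSD below a second
threshold.  The distance stage is reflection-blind and cheap (it vectorises
over the whole database); the superposition stage restores chirality
sensitivity and is only run on prefilter survivors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .motif_db import (InteractionMotif, MotifDatabase, SWAP_PERMUTATION,
                       extract_motifs)
from .structure_io import ComplexStructure

log = logging.getLogger(__name__)


class DegenerateSuperposition(ValueError):
    pass


@dataclass
class MatchParams:
    com_cutoff: float = 10.0     # target-side segment-COM cutoff (Å)
    drmsd_cutoff: float = 1.0    # distance-vector prefilter (Å)
    rmsd_cutoff: float = 1.0     # superposition acceptance (Å)
    allow_partner_swap: bool = True

    def __post_init__(self):
        if min(self.com_cutoff, self.drmsd_cutoff, self.rmsd_cutoff) <= 0:
            raise ValueError("all cutoffs must be positive")


@dataclass
class Match:
    target_motif: InteractionMotif
    db_motif: InteractionMotif
    db_index: int
    drmsd: float
    rotation: np.ndarray     # (3,3) proper rotation, db -> target
    translation: np.ndarray  # (3,)
    rmsd: float
    swapped: bool = False
    target_index: int = 0

    def transform(self, coords: np.ndarray) -> np.ndarray:
        """Map db-frame coordinates into the target frame."""
        return coords @ self.rotation.T + self.translation


def kabsch(moving: np.ndarray, fixed: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of `moving` onto `fixed`.

    Returns ``(rotation, translation, rmsd)`` with ``det(rotation) = +1``
    (reflections forbidden); ``moving @ R.T + t`` best fits ``fixed`` over
    proper rigid motions, and `rmsd` is that minimum.

    Raises :class:`DegenerateSuperposition` for fewer than 3 points or a
    collinear point set.
    """
    moving = np.asarray(moving, float)
    fixed = np.asarray(fixed, float)
    if moving.shape != fixed.shape or moving.ndim != 2 or moving.shape[1] != 3:
        raise ValueError("point sets must both be (N, 3)")
    n = len(moving)
    if n < 3:
        raise DegenerateSuperposition(f"degenerate superposition: {n} points")
    mc, fc = moving.mean(axis=0), fixed.mean(axis=0)
    p, q = moving - mc, fixed - fc
    h = p.T @ q
    u, s, vt = np.linalg.svd(h)
    if np.linalg.matrix_rank(p, tol=1e-8) < 2:
        raise DegenerateSuperposition("degenerate superposition: collinear points")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    trans = fc - rot @ mc
    fitted = moving @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - fixed) ** 2, axis=1))))
    return rot, trans, rmsd


def match_interface(target: ComplexStructure, db: MotifDatabase,
                    params: MatchParams | None = None) -> list[Match]:
    """Match every target interface motif against the full database.

    Pipeline: extract target motifs at ``params.com_cutoff``; prefilter each
    target/db pair by dRMSD (direct orientation and, if enabled, with the db
    segments swapped); run Kabsch on the 8 Cα atoms of survivors (db onto
    target) and keep matches with RMSD ≤ ``rmsd_cutoff``.  Output is sorted
    by (target motif, rmsd, source id, db index, swapped) — fully
    deterministic.
    """
    params = params or MatchParams()
    if len(db) == 0:
        log.info("empty database: no matches possible")
        return []
    target_motifs = extract_motifs(target, params.com_cutoff)
    if not target_motifs:
        log.info("no interface segments under COM cutoff %.1f Å", params.com_cutoff)
        return []
    dbmat = db.distance_matrix()            # (n_db, 28)
    orientations = [(False, dbmat)]
    if params.allow_partner_swap:
        orientations.append((True, dbmat[:, SWAP_PERMUTATION]))
    matches: list[Match] = []
    for ti, tm in enumerate(target_motifs):
        v = tm.dist_vector
        for swapped, mat in orientations:
            dr = np.sqrt(np.mean((mat - v) ** 2, axis=1))
            for di in np.nonzero(dr <= params.drmsd_cutoff)[0]:
                dm = db.motifs[int(di)]
                try:
                    rot, trans, rmsd = kabsch(dm.ca_matrix(swapped), tm.ca_coords)
                except DegenerateSuperposition:
                    continue
                if rmsd <= params.rmsd_cutoff:
                    matches.append(Match(tm, dm, int(di), float(dr[di]),
                                         rot, trans, rmsd, swapped, ti))
    if not matches:
        log.info("no database hits for %d target motifs", len(target_motifs))
    matches.sort(key=lambda m: (m.target_index, m.rmsd, m.db_motif.source_id,
                                m.db_index, m.swapped))
    return matches


@dataclass
class SelfRecoveryReport:
    n_matches: int
    n_positions: int
    accepted_changes: int
    vacuous: bool
    non_native: list[tuple] = field(default_factory=list)


def self_recovery_check(target: ComplexStructure, db: MotifDatabase,
                        strict_rmsd: float = 0.25,
                        params: MatchParams | None = None) -> tuple[bool, SelfRecoveryReport]:
    """At a strict RMSD threshold, matching a complex against a database that
    contains its own motifs must reproduce the native interface sequence.

    Runs the matcher with ``rmsd_cutoff = strict_rmsd`` followed by the
    redesign selection; returns True iff every accepted substitution equals
    the native residue (zero matches is vacuously true but flagged).
    """
    from .redesign import redesign_interface

    base = params or MatchParams()
    strict = MatchParams(base.com_cutoff, base.drmsd_cutoff, strict_rmsd,
                         base.allow_partner_swap)
    matches = match_interface(target, db, strict)
    _, report = redesign_interface(target, matches)
    non_native = [(t.target_position, t.native_res, t.chosen)
                  for t in report.tallies
                  if t.chosen is not None and t.chosen != t.native_res]
    rep = SelfRecoveryReport(
        n_matches=len(matches),
        n_positions=len(report.tallies),
        accepted_changes=report.accepted_count,
        vacuous=(len(matches) == 0),
        non_native=non_native,
    )
    return (len(non_native) == 0), rep
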