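import copy
import json

import numpy as np
import pytest

from motifmatch import (Atom, MatchParams, Residue, clash_check,
                        graft_side_chain, match_interface, redesign_interface,
                        tally_positions, write_redesign_outputs)
from motifmatch.fixtures import FixtureSpec, make_complex_fixture, make_fixture_database
from motifmatch.matching import Match
from motifmatch.motif_db import MotifResidue, extract_motifs
from motifmatch.redesign import (STATUS_ACCEPTED, STATUS_ALL_CLASH,
                                 STATUS_CONFIRMED)


def _fake_match(target_motif, db_motif, rmsd, db_index=0, swapped=False):
    return Match(target_motif=target_motif, db_motif=db_motif, db_index=db_index,
                 drmsd=rmsd, rotation=np.eye(3), translation=np.zeros(3),
                 rmsd=rmsd, swapped=swapped)


@pytest.fixture(scope="module")
def matched_fixture():
    spec = FixtureSpec(seed=31, complex_id="rd", distance=8.5)
    cs, _ = make_complex_fixture(spec)
    db, _ = make_fixture_database([spec, FixtureSpec(seed=32, complex_id="rd2",
                                                     distance=8.5, roll_b=20.0)])
    matches = match_interface(cs, db, MatchParams())
    assert matches
    return cs, db, matches


class TestTally:
    def test_unanimous_candidate(self, matched_fixture):
        cs, db, matches = matched_fixture
        one = [m for m in matches if not m.swapped][:3]
        # force all three matches to be the same motif -> unanimous counts
        tallies = tally_positions([one[0]] * 3)
        for t in tallies:
            assert sum(t.candidates.values()) == 3
            assert len(t.candidates) == 1

    def test_counts_sum_to_coverage(self, matched_fixture):
        cs, db, matches = matched_fixture
        tallies = tally_positions(matches)
        coverage = {}
        for m in matches:
            for r in m.target_motif.seg_a + m.target_motif.seg_b:
                coverage[r.key] = coverage.get(r.key, 0) + 1
        assert {t.target_position for t in tallies} == set(coverage)
        for t in tallies:
            assert sum(t.candidates.values()) == coverage[t.target_position]

    def test_tie_broken_by_mean_rmsd(self, matched_fixture):
        cs, db, matches = matched_fixture
        base = matches[0]
        good = copy.deepcopy(base)
        bad = copy.deepcopy(base)
        good.rmsd, bad.rmsd = 0.3, 0.6
        for r in bad.db_motif.seg_a + bad.db_motif.seg_b:
            r.res_name = "TRP"
        for r in good.db_motif.seg_a + good.db_motif.seg_b:
            r.res_name = "LEU"
        tallies = tally_positions([good, bad])
        for t in tallies:
            assert t.candidates == {"LEU": 1, "TRP": 1}
            assert t.ranked[0] == "LEU"  # equal counts, lower mean rmsd wins


class TestGraft:
    def test_identity_graft(self, matched_fixture):
        cs, _, _ = matched_fixture
        res = cs.partner_a.residues[3]
        grafted = graft_side_chain(res, MotifResidue.from_residue(res))
        assert grafted.res_name == res.res_name
        assert [a.name for a in grafted.atoms] == \
               [a.name for a in res.heavy_atoms()]
        for a1, a2 in zip(grafted.atoms, res.heavy_atoms()):
            np.testing.assert_allclose(a1.coords, a2.coords, atol=1e-6)

    def test_internal_geometry_preserved_across_frames(self, matched_fixture):
        from motifmatch.fixtures import _axis_rotation
        cs, _, _ = matched_fixture
        source = next(r for r in cs.partner_a.residues if r.res_name == "LEU")
        # target backbone: rotated/translated copy of the source backbone
        rot = _axis_rotation(np.array([0.2, 0.8, 0.56]) / np.linalg.norm([0.2, 0.8, 0.56]), 1.3)
        target = Residue("ALA", "B", 99, "", [
            Atom(a.name, a.element, rot @ a.coords + np.array([4.0, -7.0, 2.0]))
            for a in source.atoms if a.name in ("N", "CA", "C", "O", "CB")])
        grafted = graft_side_chain(target, MotifResidue.from_residue(source))
        assert grafted.res_name == "LEU"

        def geom(res):
            ca, cb, cg = (res.atom(n).coords for n in ("CA", "CB", "CG"))
            d = np.linalg.norm(cb - ca)
            v1, v2 = ca - cb, cg - cb
            ang = np.degrees(np.arccos(np.dot(v1, v2)
                                       / np.linalg.norm(v1) / np.linalg.norm(v2)))
            return d, ang

        d_src, ang_src = geom(source)
        d_out, ang_out = geom(grafted)
        assert d_out == pytest.approx(d_src, abs=1e-3)
        assert ang_out == pytest.approx(ang_src, abs=0.1)

    def test_gly_graft_is_backbone_rename(self, matched_fixture):
        cs, _, _ = matched_fixture
        target = cs.partner_a.residues[2]
        gly = MotifResidue("GLY", "X", 1, "", ["N", "CA", "C", "O"],
                           ["N", "C", "C", "O"],
                           np.array([[0, 0, 0], [1.46, 0, 0], [2.0, 1.4, 0],
                                     [1.3, 2.4, 0.0]]))
        grafted = graft_side_chain(target, gly)
        assert grafted.res_name == "GLY"
        assert {a.name for a in grafted.atoms} == {"N", "CA", "C", "O"}
        for name in ("N", "CA", "C", "O"):
            np.testing.assert_allclose(grafted.atom(name).coords,
                                       target.atom(name).coords)


class TestClashCheck:
    def _probe(self, cs, xyz):
        """Single-CB candidate placed at xyz on a fresh residue."""
        ca = np.asarray(xyz) + np.array([1.5, 0, 0])
        return Residue("ALA", "A", 999, "", [
            Atom("N", "N", ca + [1.0, 1.0, 0]), Atom("CA", "C", ca),
            Atom("C", "C", ca + [1.0, -1.0, 0]),
            Atom("CB", "C", np.asarray(xyz, dtype=float))])

    def test_distance_conventions(self, matched_fixture):
        cs, _, _ = matched_fixture
        anchor = cs.partner_b.residues[5].atom("CA").coords
        far = self._probe(cs, anchor + [0, 0, 30.0])
        assert clash_check(far, cs)[0] is False
        near = self._probe(cs, anchor + [1.0, 0, 0])
        clash, pairs = clash_check(near, cs)
        assert clash and pairs

    def test_boundary_exactly_at_cutoff_is_no_clash(self):
        # isolated two-residue complex with a known exact 2.5 Å contact
        from motifmatch import ComplexStructure, PartnerGroup
        res_b = Residue("ALA", "B", 1, "", [
            Atom("N", "N", np.array([20.0, 1.0, 0.0])),
            Atom("CA", "C", np.array([20.0, 0.0, 0.0])),
            Atom("C", "C", np.array([21.0, -1.0, 0.0]))])
        res_a = Residue("ALA", "A", 1, "", [
            Atom("N", "N", np.array([0.0, 1.0, 0.0])),
            Atom("CA", "C", np.array([0.0, 0.0, 0.0])),
            Atom("C", "C", np.array([1.0, -1.0, 0.0])),
            Atom("CB", "C", np.array([17.5, 0.0, 0.0]))])  # exactly 2.5 from B's CA
        cs = ComplexStructure("b", PartnerGroup("A-side", {"A"}, [res_a]),
                              PartnerGroup("B-side", {"B"}, [res_b]))
        assert clash_check(res_a, cs, min_dist=2.5)[0] is False
        res_a.atom("CB").coords[0] = 17.51  # 2.49 Å -> clash
        assert clash_check(res_a, cs, min_dist=2.5)[0] is True


class TestRedesign:
    def test_empty_matches_leave_structure_identical(self, matched_fixture):
        cs, _, _ = matched_fixture
        out, report = redesign_interface(cs, [])
        assert report.tallies == [] and report.accepted_count == 0
        for r1, r2 in zip(cs.all_residues(), out.all_residues()):
            assert r1.res_name == r2.res_name
            for a1, a2 in zip(r1.atoms, r2.atoms):
                assert np.array_equal(a1.coords, a2.coords)

    def test_backbone_bit_identical_after_redesign(self, matched_fixture):
        cs, _, matches = matched_fixture
        out, report = redesign_interface(cs, matches)
        assert report.accepted_count > 0  # something actually changed
        idx = {r.key: r for r in out.all_residues()}
        for r in cs.all_residues():
            for name in ("N", "CA", "C", "O"):
                a1, a2 = r.atom(name), idx[r.key].atom(name)
                if a1 is not None:
                    assert np.array_equal(a1.coords, a2.coords)

    def test_no_clash_in_final_structure(self, matched_fixture):
        cs, _, matches = matched_fixture
        out, report = redesign_interface(cs, matches)
        changed = {t.target_position for t in report.tallies
                   if t.status == STATUS_ACCEPTED}
        idx = {r.key: r for r in out.all_residues()}
        for key in changed:
            clash, pairs = clash_check(idx[key], out, min_dist=2.5)
            assert not clash, pairs

    def test_stricter_threshold_never_increases_changes(self, matched_fixture):
        cs, db, _ = matched_fixture
        loose = match_interface(cs, db, MatchParams(rmsd_cutoff=1.0))
        strict = match_interface(cs, db, MatchParams(rmsd_cutoff=0.25))
        _, rep_loose = redesign_interface(cs, loose)
        _, rep_strict = redesign_interface(cs, strict)
        assert rep_strict.accepted_count <= rep_loose.accepted_count

    def test_clash_falls_through_to_next_candidate(self, matched_fixture):
        cs, _, matches = matched_fixture
        # craft one target position with two candidates: bulky TRP from a
        # better match placed right on top of the partner (forced clash), and
        # a small ALA fallback from a worse match
        base = next(m for m in matches if not m.swapped)
        tgt = base.target_motif
        bully = copy.deepcopy(base)
        bully.rmsd = 0.05
        fallback = copy.deepcopy(base)
        fallback.rmsd = 0.9
        # identify the nearest partner-B atom to the first seg_a position
        tkey = tgt.seg_a[0].key
        target_res = next(r for r in cs.all_residues() if r.key == tkey)
        foreign = min((a for r in cs.partner_b.residues for a in r.heavy_atoms()),
                      key=lambda a: np.linalg.norm(a.coords - target_res.atom("CA").coords))
        # bully contributes a fake side chain exactly at the foreign atom
        src = bully.db_motif.seg_a[0] if not bully.swapped else bully.db_motif.seg_b[0]
        src.res_name = "TRP"
        n, ca, c = (target_res.atom(x).coords for x in ("N", "CA", "C"))
        src.atom_names = ["N", "CA", "C", "CB"]
        src.atom_elements = ["N", "C", "C", "C"]
        src.atom_coords = np.vstack([n, ca, c, foreign.coords])  # CB on the clash site
        fb_src = fallback.db_motif.seg_a[0]
        fb_src = MotifResidue("ALA", fb_src.chain_id, fb_src.res_seq, fb_src.icode,
                              ["N", "CA", "C", "CB"], ["N", "C", "C", "C"],
                              np.vstack([n, ca, c, ca + (ca - foreign.coords)
                                         / np.linalg.norm(ca - foreign.coords) * 1.53]))
        fallback.db_motif = copy.deepcopy(fallback.db_motif)
        fallback.db_motif.seg_a[0] = fb_src
        out, report = redesign_interface(cs, [bully, fallback])
        tally = next(t for t in report.tallies if t.target_position == tkey)
        assert tally.ranked[0] == "TRP"
        assert any("clash" in reason for cand, reason in tally.rejection_log
                   if cand == "TRP")
        assert tally.chosen != "TRP"

    def test_self_recovery_confirms_native_everywhere(self):
        spec = FixtureSpec(seed=33, complex_id="sr2", distance=8.5)
        cs, _ = make_complex_fixture(spec)
        db, _ = make_fixture_database([spec])
        matches = match_interface(cs, db, MatchParams(rmsd_cutoff=0.25))
        out, report = redesign_interface(cs, matches)
        assert report.accepted_count == 0
        assert all(t.status == STATUS_CONFIRMED for t in report.tallies)


class TestOutputs:
    def test_report_files_consistent_with_structure(self, matched_fixture, tmp_path):
        from motifmatch import parse_complex
        cs, _, matches = matched_fixture
        out, report = redesign_interface(cs, matches)
        pdb = tmp_path / "redesigned.pdb"
        write_redesign_outputs(out, report, pdb, tmp_path / "report")
        text = pdb.read_text()
        assert "NOT ENERGY MINIMIZED" in text
        tsv = (tmp_path / "report.tsv").read_text().splitlines()
        assert tsv[0].split("\t") == ["chain", "res_seq", "native", "chosen",
                                      "count", "status"]
        accepted_rows = [l for l in tsv[1:] if l.endswith(STATUS_ACCEPTED)]
        assert len(accepted_rows) == report.accepted_count
        payload = json.loads((tmp_path / "report.json").read_text())
        assert payload["accepted_count"] == report.accepted_count
        reread = parse_complex(pdb, ["A"], ["B"])
        names = {r.key: r.res_name for r in reread.all_residues()}
        for t in report.tallies:
            if t.status == STATUS_ACCEPTED:
                assert names[t.target_position] == t.chosen
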