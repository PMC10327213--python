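"""Segment identification, occupancy harmonization, relabeling, culling."""

import numpy as np
import pytest

from multiconf.assembly import (
    Segment,
    clash_energy,
    cull_low_occupancy,
    equalize_segment_conformers,
    identify_segments,
    optimize_segment,
    relabel,
    segment_only,
    write_occupancy_restraints,
)
from multiconf.structure import Atom, Conformer, Residue, Structure


def residue_with(seqnum, occupancies, name="SER", chain="A", spread=2.0):
    """Residue at an isolated location with one conformer per occupancy."""
    base = np.array([seqnum * 10.0, 0.0, 0.0])
    confs = []
    for i, occ in enumerate(occupancies):
        atoms = [Atom(n, base + np.array([j * 1.4, i * spread, 0]), 15.0, occ)
                 for j, n in enumerate(("N", "CA", "C", "O", "CB"))]
        altloc = "" if len(occupancies) == 1 else "ABCDE"[i]
        confs.append(Conformer(altloc, atoms, occ))
    return Residue(chain, seqnum, "", name, confs)


class TestIdentifySegments:
    def test_all_single_conformer_gives_no_segments(self):
        model = Structure([residue_with(i, [1.0]) for i in range(1, 6)])
        assert identify_segments(model) == []

    def test_contiguous_multiconformer_run(self):
        residues = [residue_with(i, [1.0]) for i in range(1, 5)]
        residues += [residue_with(i, [0.6, 0.4]) for i in range(5, 8)]
        residues += [residue_with(i, [1.0]) for i in range(8, 11)]
        model = Structure(residues)
        segs = identify_segments(model)
        assert len(segs) == 1
        assert [model.residues[i].seqnum for i in segs[0].residue_indices] == \
            [5, 6, 7]

    def test_chain_break_terminates_segment(self):
        residues = [residue_with(1, [0.6, 0.4]), residue_with(2, [0.6, 0.4]),
                    residue_with(9, [0.6, 0.4])]
        model = Structure(residues)
        assert len(identify_segments(model)) == 2

    def test_segments_and_singles_partition_model(self):
        rng = np.random.default_rng(4)
        residues = [residue_with(i, [0.5, 0.5] if rng.random() < 0.4 else [1.0])
                    for i in range(1, 20)]
        model = Structure(residues)
        covered = [i for s in identify_segments(model)
                   for i in s.residue_indices]
        multi = [i for i, r in enumerate(model.residues)
                 if len(r.conformers) > 1]
        assert sorted(covered) == multi


class TestOptimizeSegment:
    def test_truth_pairing_recovered(self):
        """Density from consistent A-with-A pairing is best explained by
        fragments that pair the ground-truth conformers."""
        from multiconf.bench import make_p1_grid
        from multiconf.density import ScatteringMode, density_on_grid

        res1 = residue_with(1, [0.6, 0.4], spread=3.0)
        res2 = residue_with(2, [0.6, 0.4], spread=3.0)
        truth = Structure([res1.copy(), res2.copy()])
        mode = ScatteringMode("em")
        grid = make_p1_grid(truth, 0.4)
        density_on_grid([c for r in truth.residues for c in r.conformers],
                        grid, mode, 1.2)
        model = Structure([res1.copy(), res2.copy()])
        # disturb occupancies; optimization should restore the 0.6/0.4 split
        for r in model.residues:
            r.conformers[0].set_occupancy(0.5)
            r.conformers[1].set_occupancy(0.5)
        seg = identify_segments(model)[0]
        optimize_segment(model, seg, grid, mode, 1.2)
        for r in model.residues:
            occs = sorted(c.occupancy for c in r.conformers)
            assert occs[-1] == pytest.approx(0.6, abs=0.1)
        # neighbors share occupancies after harmonization
        o1 = sorted(c.occupancy for c in model.residues[0].conformers)
        o2 = sorted(c.occupancy for c in model.residues[1].conformers)
        np.testing.assert_allclose(o1, o2, atol=0.05)

    def test_single_residue_segment_unchanged(self):
        model = Structure([residue_with(1, [0.7, 0.3])])
        seg = Segment([0])
        optimize_segment(model, seg, None, None, 1.0)
        assert [c.occupancy for c in model.residues[0].conformers] == \
            [0.7, 0.3]


def clashing_pair_model():
    """Two residues whose B conformers overlap but cross-pairing does not."""
    r1 = residue_with(1, [0.5, 0.5], spread=4.0)
    r2 = residue_with(1, [0.5, 0.5], spread=4.0, chain="A")
    r2.seqnum = 2
    # place residue 2's B conformer on top of residue 1's B conformer
    for a1, a2 in zip(r1.conformers[1].atoms, r2.conformers[1].atoms):
        a2.pos = a1.pos + np.array([0.4, 0.0, 0.0])
    # move residue 2's A conformer far away
    for a in r2.conformers[0].atoms:
        a.pos = a.pos + np.array([0.0, 20.0, 0.0])
    return Structure([r1, r2])


class TestRelabel:
    def test_no_contacts_labels_unchanged(self):
        model = Structure([residue_with(i, [0.6, 0.4]) for i in (1, 5)])
        out = relabel(model, seed=0)
        for res in out.residues:
            assert [c.altloc for c in res.conformers] == ["A", "B"]

    def test_swap_resolves_same_altloc_clash(self):
        model = clashing_pair_model()
        assert clash_energy(model) > 0
        out = relabel(model, seed=0)
        assert clash_energy(out) == pytest.approx(0.0, abs=1e-12)

    def test_energy_never_increases(self):
        model = clashing_pair_model()
        before = clash_energy(model)
        for seed in range(5):
            assert clash_energy(relabel(model, seed=seed)) <= before + 1e-12

    def test_reproducible_for_fixed_seed(self):
        model = clashing_pair_model()
        a = relabel(model, seed=3)
        b = relabel(model, seed=3)
        for ra, rb in zip(a.residues, b.residues):
            assert [c.altloc for c in ra.conformers] == \
                [c.altloc for c in rb.conformers]


class TestSegmentOnly:
    def test_duplication_example(self):
        r1 = residue_with(1, [0.3, 0.3, 0.2, 0.2])
        r2 = residue_with(2, [0.6, 0.4])
        model = Structure([r1, r2])
        seg = identify_segments(model)[0]
        equalize_segment_conformers(model, seg)
        assert len(model.residues[1].conformers) == 4
        assert [c.altloc for c in model.residues[1].conformers] == \
            ["A", "B", "C", "D"]

    def test_duplication_preserves_occupancy_totals(self):
        r1 = residue_with(1, [0.3, 0.3, 0.2, 0.2])
        r2 = residue_with(2, [0.6, 0.4])
        model = Structure([r1, r2])
        equalize_segment_conformers(model, identify_segments(model)[0])
        assert model.residues[1].total_occupancy() == pytest.approx(1.0,
                                                                    abs=1e-6)

    def test_uniform_segment_counts_unchanged(self):
        model = Structure([residue_with(1, [0.6, 0.4]),
                           residue_with(2, [0.5, 0.5])])
        equalize_segment_conformers(model, identify_segments(model)[0])
        assert all(len(r.conformers) == 2 for r in model.residues)

    def test_occupancy_sums_restored_to_one(self):
        model = Structure([residue_with(1, [0.5, 0.2]),
                           residue_with(2, [0.4, 0.3])])
        out = segment_only(model)
        for res in out.residues:
            assert res.total_occupancy() == pytest.approx(1.0, abs=1e-6)


class TestCullLowOccupancy:
    def test_low_occupancy_conformer_removed(self):
        model = Structure([residue_with(1, [0.95, 0.05])])
        out = cull_low_occupancy(model)
        res = out.residues[0]
        assert len(res.conformers) == 1
        assert res.conformers[0].occupancy == 1.0
        assert res.conformers[0].altloc == ""

    def test_healthy_pair_unchanged(self):
        model = Structure([residue_with(1, [0.6, 0.4])])
        out = cull_low_occupancy(model)
        assert [c.occupancy for c in out.residues[0].conformers] == [0.6, 0.4]

    def test_renormalization_arithmetic(self):
        model = Structure([residue_with(1, [0.50, 0.42, 0.08])])
        out = cull_low_occupancy(model)
        occs = [c.occupancy for c in out.residues[0].conformers]
        np.testing.assert_allclose(occs, [0.50 / 0.92, 0.42 / 0.92],
                                   atol=1e-6)

    def test_all_below_cutoff_keeps_best(self):
        model = Structure([residue_with(1, [0.06, 0.04])])
        out = cull_low_occupancy(model)
        res = out.residues[0]
        assert len(res.conformers) == 1
        assert res.conformers[0].occupancy == 1.0

    def test_idempotent(self):
        model = Structure([residue_with(1, [0.50, 0.42, 0.08]),
                           residue_with(2, [0.95, 0.05])])
        once = cull_low_occupancy(model)
        twice = cull_low_occupancy(once)
        for r1, r2 in zip(once.residues, twice.residues):
            assert [c.occupancy for c in r1.conformers] == \
                [c.occupancy for c in r2.conformers]


class TestOccupancyRestraints:
    def test_no_segments_writes_header_only(self, tmp_path):
        model = Structure([residue_with(1, [1.0])])
        path = tmp_path / "restraints.txt"
        write_occupancy_restraints(model, path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 1 and lines[0].startswith("#")

    def test_two_residue_segment_two_groups(self, tmp_path):
        model = Structure([residue_with(1, [0.6, 0.4]),
                           residue_with(2, [0.6, 0.4])])
        path = tmp_path / "restraints.txt"
        write_occupancy_restraints(model, path)
        text = path.read_text()
        assert text.count("group {") == 2
        assert "resseq 1:2 and altloc A" in text
        assert "resseq 1:2 and altloc B" in text

    def test_groups_cover_all_segment_altlocs(self, tmp_path):
        model = Structure([residue_with(1, [0.4, 0.3, 0.3]),
                           residue_with(2, [0.4, 0.3, 0.3])])
        path = tmp_path / "restraints.txt"
        write_occupancy_restraints(model, path)
        text = path.read_text()
        for alt in "ABC":
            assert f"altloc {alt}" in text
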