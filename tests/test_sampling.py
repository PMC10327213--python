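"""Candidate enumeration contracts and pruning."""

import numpy as np
import pytest

from multiconf.sampling import (
    CandidateSet,
    MissingBackboneError,
    SamplingParams,
    has_internal_clash,
    prune,
    sample_aromatic_angle,
    sample_backbone,
    sample_bfactors,
    sample_chi,
    _excluded_pairs,
)
from multiconf.structure import (
    RotamerLibrary,
    conformer_rmsd,
    get_chi,
)

def residue_of(structure, name):
    return next(r for r in structure.residues if r.name == name)


def as_candidates(residue):
    conf = residue.conformers[0]
    return CandidateSet(residue.id, residue.name, "backbone", [conf.copy()],
                        conf.copy())


class TestBackboneSampling:
    def test_isotropic_count_and_input_included(self, toy_peptide):
        res = residue_of(toy_peptide, "VAL")
        cs = sample_backbone(res)
        assert len(cs.conformers) == 9
        rms = [conformer_rmsd(c, res.conformers[0]) for c in cs.conformers]
        assert min(rms) == pytest.approx(0.0, abs=1e-12)

    def test_anisotropic_count(self, toy_peptide):
        res = residue_of(toy_peptide, "VAL").copy()
        res.conformers[0].atom("CB").aniso = np.diag([0.4, 0.25, 0.15])
        cs = sample_backbone(res)
        assert len(cs.conformers) == 81

    def test_anisotropic_candidates_distinct(self, toy_peptide):
        res = residue_of(toy_peptide, "VAL").copy()
        res.conformers[0].atom("CB").aniso = np.diag([0.4, 0.25, 0.15])
        cs = sample_backbone(res)
        assert len(prune(cs).conformers) == 81

    def test_max_displacement_bound(self, toy_peptide):
        res = residue_of(toy_peptide, "SER")
        cs = sample_backbone(res)
        for c in cs.conformers:
            per_atom = np.linalg.norm(
                c.coords() - res.conformers[0].coords(), axis=1)
            assert np.all(per_atom <= np.sqrt(3) * 0.3 + 1e-9)

    def test_gly_uses_pseudo_cb_direction(self):
        from multiconf.peptide import build_peptide

        gly = build_peptide(["GLY"]).residues[0]
        cs = sample_backbone(gly)
        assert len(cs.conformers) == 9

    def test_missing_backbone_signals_skip(self, toy_peptide):
        res = residue_of(toy_peptide, "SER").copy()
        res.conformers[0].atoms = [a for a in res.conformers[0].atoms
                                   if a.name != "O"]
        with pytest.raises(MissingBackboneError):
            sample_backbone(res)


class TestAromaticSampling:
    def test_five_per_backbone_conformer(self, toy_peptide):
        res = residue_of(toy_peptide, "TYR")
        cs = sample_aromatic_angle(sample_backbone(res))
        assert len(cs.conformers) == 45

    def test_angle_offsets_realized(self, toy_peptide):
        res = residue_of(toy_peptide, "TYR")
        cs = sample_aromatic_angle(as_candidates(res))

        def angle(conf):
            ca, cb, cg = (conf.atom(n).pos for n in ("CA", "CB", "CG"))
            v1, v2 = ca - cb, cg - cb
            return np.degrees(np.arccos(
                v1 @ v2 / np.linalg.norm(v1) / np.linalg.norm(v2)))

        base = angle(res.conformers[0])
        got = sorted(angle(c) - base for c in cs.conformers)
        np.testing.assert_allclose(got, [-7.5, -3.75, 0, 3.75, 7.5], atol=1e-6)

    def test_non_aromatic_passthrough(self, toy_peptide):
        res = residue_of(toy_peptide, "LEU")
        cs = as_candidates(res)
        assert sample_aromatic_angle(cs) is cs

    def test_zero_offset_candidate_matches_parent(self, toy_peptide):
        res = residue_of(toy_peptide, "TYR")
        cs = sample_aromatic_angle(as_candidates(res))
        rms = [conformer_rmsd(c, res.conformers[0]) for c in cs.conformers]
        assert min(rms) == pytest.approx(0.0, abs=1e-9)


class TestChiSampling:
    def test_ser_count_three_means(self, toy_peptide):
        from multiconf.structure import set_chi

        res = residue_of(toy_peptide, "SER").copy()
        # input chi placed on a library mean, so exactly 3 means x 9 offsets
        res.conformers[0] = set_chi(res.conformers[0], "SER", 1, -65.0)
        cs = sample_chi(as_candidates(res), 1)
        assert len(cs.conformers) == 27

    def test_input_chi_off_rotamer_adds_shifted_means(self, toy_peptide):
        from multiconf.structure import set_chi

        res = residue_of(toy_peptide, "SER").copy()
        res.conformers[0] = set_chi(res.conformers[0], "SER", 1, -20.0)
        cs = sample_chi(as_candidates(res), 1)
        # 3 library means + 3 deviation-shifted means (one of which is the
        # input chi itself), 9 offsets each
        assert len(cs.conformers) == 54
        chis = {round(get_chi(c, "SER", 1)) for c in cs.conformers}
        assert -20 in chis  # input conformation reachable

    def test_proline_pucker_count(self):
        from multiconf.peptide import build_peptide

        pro = build_peptide(["ALA", "PRO", "ALA"]).residues[1]
        cs = sample_chi(as_candidates(pro), 1)
        assert len(cs.conformers) == 18

    def test_proline_ring_bonds_preserved(self):
        from multiconf.peptide import build_peptide

        pro = build_peptide(["ALA", "PRO", "ALA"]).residues[1]
        conf = pro.conformers[0]
        d_bg = np.linalg.norm(conf.atom("CB").pos - conf.atom("CG").pos)
        d_gd = np.linalg.norm(conf.atom("CG").pos - conf.atom("CD").pos)
        for c in sample_chi(as_candidates(pro), 1).conformers:
            assert np.linalg.norm(c.atom("CB").pos - c.atom("CG").pos) == \
                pytest.approx(d_bg, abs=1e-9)
            assert np.linalg.norm(c.atom("CG").pos - c.atom("CD").pos) == \
                pytest.approx(d_gd, abs=1e-9)

    def test_chi_equals_mean_plus_offset(self, toy_peptide):
        res = residue_of(toy_peptide, "SER")
        lib = RotamerLibrary()
        params = SamplingParams()
        cs = sample_chi(as_candidates(res), 1, lib, params)
        expected = [m + o for m in lib.chi_means("SER", 1)
                    for o in params.chi_offsets()]
        got = [get_chi(c, "SER", 1) for c in cs.conformers]
        for g, e in zip(got, expected):
            assert abs((g - e + 180) % 360 - 180) < 1e-6

    def test_out_of_range_chi_rejected(self, toy_peptide):
        res = residue_of(toy_peptide, "SER")
        with pytest.raises(ValueError):
            sample_chi(as_candidates(res), 2)


class TestPrune:
    def test_duplicates_collapse_to_one(self, toy_peptide):
        res = residue_of(toy_peptide, "SER")
        conf = res.conformers[0]
        cs = CandidateSet(res.id, "SER", "chi_1",
                          [conf.copy() for _ in range(5)], conf.copy())
        assert len(prune(cs).conformers) == 1

    def test_pair_below_threshold_loses_one(self, toy_peptide):
        res = residue_of(toy_peptide, "SER")
        a = res.conformers[0].copy()
        b = a.copy()
        for atom in b.atoms:
            atom.pos = atom.pos + 0.005 / np.sqrt(3)  # all-atom RMSD 0.005
        cs = CandidateSet(res.id, "SER", "chi_1", [a, b], a.copy())
        assert len(prune(cs).conformers) == 1

    def test_matches_greedy_pairwise_oracle(self, toy_peptide):
        res = residue_of(toy_peptide, "LEU")
        cs = sample_chi(as_candidates(res), 1)
        params = SamplingParams()
        excluded = _excluded_pairs(cs.reference, "LEU")
        kept = []
        for conf in cs.conformers:  # independent O(n^2) reference filter
            if has_internal_clash(conf, excluded, params.clash_scale):
                continue
            if any(conformer_rmsd(conf, k) < params.redundancy_rmsd
                   for k in kept):
                continue
            kept.append(conf)
        got = prune(cs, params).conformers
        assert len(got) == len(kept)
        for a, b in zip(got, kept):
            np.testing.assert_array_equal(a.coords(), b.coords())

    def test_idempotent(self, toy_peptide):
        res = residue_of(toy_peptide, "LEU")
        once = prune(sample_chi(as_candidates(res), 1))
        twice = prune(once)
        assert len(once.conformers) == len(twice.conformers)

    def test_clashing_conformer_removed(self, toy_peptide):
        res = residue_of(toy_peptide, "SER").copy()
        bad = res.conformers[0].copy()
        bad.atom("OG").pos = bad.atom("N").pos + np.array([0.5, 0, 0])
        cs = CandidateSet(res.id, "SER", "chi_1",
                          [res.conformers[0].copy(), bad],
                          res.conformers[0].copy())
        assert len(prune(cs).conformers) == 1


class TestBfactorSampling:
    def test_six_multipliers_per_conformer(self, toy_peptide):
        res = residue_of(toy_peptide, "SER")
        cs = as_candidates(res)
        cs.conformers = [cs.conformers[0].copy() for _ in range(5)]
        out = sample_bfactors(cs)
        assert len(out.conformers) == 30

    def test_multiplier_set_and_unscaled_absent(self, toy_peptide):
        res = residue_of(toy_peptide, "SER")
        out = sample_bfactors(as_candidates(res))
        b0 = res.conformers[0].atoms[0].b
        mults = sorted(c.atoms[0].b / b0 for c in out.conformers)
        np.testing.assert_allclose(mults, [0.5, 0.7, 0.9, 1.1, 1.3, 1.5])
        assert 1.0 not in mults

    def test_coordinates_unchanged(self, toy_peptide):
        res = residue_of(toy_peptide, "SER")
        out = sample_bfactors(as_candidates(res))
        for c in out.conformers:
            np.testing.assert_array_equal(c.coords(),
                                          res.conformers[0].coords())


class TestDeterminism:
    def test_identical_inputs_identical_candidate_lists(self, toy_peptide):
        res = residue_of(toy_peptide, "LEU")
        a = sample_chi(sample_backbone(res), 1)
        b = sample_chi(sample_backbone(res), 1)
        assert len(a.conformers) == len(b.conformers)
        for ca, cb in zip(a.conformers, b.conformers):
            np.testing.assert_array_equal(ca.coords(), cb.coords())

    def test_step_must_divide_extent(self):
        with pytest.raises(ValueError):
            SamplingParams(chi_step=7.0, chi_extent=24.0)
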