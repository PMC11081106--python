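"""Geometry primitives and the four observable back-calculators.

Expected values come from independent oracles: component-wise brute-force
arithmetic for distances and power means, closed-form trigonometry for the
Karplus curve, and the torsion list the synthetic builder was given.
"""

import math
from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from idpcalc.calc import (
    DEFAULT_KARPLUS, KarplusCoefficients, backcalc_jc, backcalc_noe,
    backcalc_pre, backcalc_smfret, compute_phi, dihedral, euclidean_distance,
    fret_efficiency, karplus, noe_average,
)
from idpcalc.errors import UndefinedTorsionError
from idpcalc.templates import JcRecord, NoePair, PrePair, SmfretPair
from idpcalc.synthetic import TorsionSpec, build_peptide

from conftest import make_conformer, random_rigid_transform, transform_conformer

finite = st.floats(min_value=-1e3, max_value=1e3, allow_nan=False)


class TestDistance:
    def test_3_4_5_triangle(self):
        assert euclidean_distance((0, 0, 0), (3, 4, 0)) == 5.0

    def test_identity(self):
        p = (1.3, -2.7, 9.9)
        assert euclidean_distance(p, p) == 0.0

    @settings(max_examples=100, deadline=None)
    @given(st.tuples(finite, finite, finite), st.tuples(finite, finite, finite))
    def test_matches_componentwise_oracle_and_symmetry(self, p, q):
        dx, dy, dz = (a - b for a, b in zip(p, q))
        oracle = math.sqrt(dx * dx + dy * dy + dz * dz)
        assert euclidean_distance(p, q) == pytest.approx(oracle, abs=1e-12)
        assert euclidean_distance(q, p) == euclidean_distance(p, q)


class TestDihedral:
    def test_trans_is_pi(self):
        # planar zig-zag, end points on opposite sides of the central bond
        assert dihedral((1, 1, 0), (1, 0, 0), (0, 0, 0), (-1, -1, 0)) == pytest.approx(math.pi)

    def test_cis_is_zero(self):
        assert dihedral((1, 1, 0), (1, 0, 0), (0, 0, 0), (-1, 1, 0)) == pytest.approx(0.0)

    def test_mirror_negates(self):
        pts = [(0.2, 1.1, 0.4), (1.5, 0.1, -0.3), (2.2, 1.4, 0.8), (3.6, 1.0, 0.1)]
        mirrored = [(x, y, -z) for x, y, z in pts]
        a = dihedral(*pts)
        assert dihedral(*mirrored) == pytest.approx(-a, abs=1e-12)

    def test_collinear_raises(self):
        with pytest.raises(UndefinedTorsionError):
            dihedral((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0))

    def test_range_half_open(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            pts = rng.normal(size=(4, 3)) * 3
            try:
                a = dihedral(*pts)
            except UndefinedTorsionError:
                continue
            assert -math.pi < a <= math.pi


class TestPhi:
    def test_builder_round_trip(self, pentapeptide):
        spec, conf = pentapeptide
        for resseq in range(2, 6):
            assert compute_phi(conf, resseq) == pytest.approx(spec.phi[resseq - 1], abs=1e-6)

    def test_first_residue_undefined(self, pentapeptide):
        _, conf = pentapeptide
        with pytest.raises(UndefinedTorsionError):
            compute_phi(conf, 1)

    def test_rotation_invariance(self, pentapeptide):
        spec, conf = pentapeptide
        rot, trans = random_rigid_transform(np.random.default_rng(3))
        moved = transform_conformer(conf, rot, trans)
        for resseq in range(2, 6):
            assert compute_phi(moved, resseq) == pytest.approx(
                compute_phi(conf, resseq), abs=1e-9)


class TestPre:
    def test_fixture_pair_5A(self, dumbbell):
        assert backcalc_pre(dumbbell, [PrePair(2, "H", 14, "H")]) == [5.0]

    def test_degenerate_template_same_atom(self, dumbbell):
        assert backcalc_pre(dumbbell, [PrePair(2, "H", 2, "CA")]) == [1.0]

    def test_20_pair_template_matches_bruteforce(self, ensemble_dir):
        _, ens = ensemble_dir
        conf = ens.conformers[0]
        rng = np.random.default_rng(17)
        atoms = conf.atoms
        pairs, oracle = [], []
        while len(pairs) < 20:
            a, b = rng.choice(len(atoms), size=2, replace=False)
            a, b = atoms[a], atoms[b]
            if (a.resseq, a.name) == (b.resseq, b.name):
                continue
            pairs.append(PrePair(a.resseq, a.name, b.resseq, b.name))
            oracle.append(math.sqrt(sum((u - v) ** 2 for u, v in zip(a.coord, b.coord))))
        assert backcalc_pre(conf, pairs) == pytest.approx(oracle, abs=1e-12)


class TestNoe:
    def test_single_combination_reduces_to_pre(self, dumbbell):
        pair = NoePair(2, "H", (), 14, "H", ())
        for mode in ("r6", "rminus6"):
            assert backcalc_noe(dumbbell, [pair], averaging=mode) == [5.0]

    def test_equal_distances_average_to_themselves(self):
        assert noe_average([3.2, 3.2, 3.2], "r6") == pytest.approx(3.2)
        assert noe_average([3.2, 3.2, 3.2], "rminus6") == pytest.approx(3.2)

    def test_worked_two_combination_value(self):
        # combinations at 1 A and 2 A: ((1 + 64)/2)^(1/6)
        oracle = ((1.0 ** 6 + 2.0 ** 6) / 2.0) ** (1.0 / 6.0)
        conf = make_conformer([
            (2, "ALA", "H", (0.0, 0.0, 0.0)),
            (5, "ALA", "HB1", (1.0, 0.0, 0.0)),
            (5, "ALA", "HB2", (2.0, 0.0, 0.0)),
        ])
        pair = NoePair(2, "H", (), 5, "HB1", ("HB2",))
        (value,) = backcalc_noe(conf, [pair], averaging="r6")
        assert value == pytest.approx(oracle, abs=1e-12)
        assert value == pytest.approx(1.7864, abs=1e-4)

    def test_empty_alts_equals_pre_elementwise(self, ensemble_dir):
        _, ens = ensemble_dir
        conf = ens.conformers[3]
        residues = [r for r in conf.residue_numbers() if (r, "H") in conf.index]
        noe_pairs = [NoePair(r1, "H", (), r2, "H", ())
                     for r1, r2 in zip(residues[:-1], residues[1:])]
        pre_pairs = [PrePair(p.res1, p.atom1, p.res2, p.atom2) for p in noe_pairs]
        assert backcalc_noe(conf, noe_pairs) == pytest.approx(
            backcalc_pre(conf, pre_pairs), abs=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(min_value=0.5, max_value=20), min_size=2, max_size=8),
           st.randoms(use_true_random=False))
    def test_bounds_and_permutation_invariance(self, dists, rnd):
        for mode in ("r6", "rminus6"):
            value = noe_average(dists, mode)
            assert min(dists) - 1e-9 <= value <= max(dists) + 1e-9
            shuffled = list(dists)
            rnd.shuffle(shuffled)
            assert noe_average(shuffled, mode) == pytest.approx(value, rel=1e-12)

    def test_pseudoatom_expansion_contributes_all_members(self):
        conf = make_conformer([
            (2, "ALA", "H", (0.0, 0.0, 0.0)),
            (5, "ALA", "HB1", (1.0, 0.0, 0.0)),
            (5, "ALA", "HB2", (2.0, 0.0, 0.0)),
            (5, "ALA", "HB3", (3.0, 0.0, 0.0)),
        ])
        pair = NoePair(2, "H", (), 5, "HB", ())
        oracle = ((1.0 + 2 ** 6 + 3 ** 6) / 3.0) ** (1.0 / 6.0)
        assert backcalc_noe(conf, [pair]) == pytest.approx([oracle], abs=1e-12)


class TestKarplus:
    def test_phi_pi_third_gives_sum(self):
        k = DEFAULT_KARPLUS
        assert karplus(math.pi / 3, k) == pytest.approx(k.A + k.B + k.C, abs=1e-12)

    def test_phi_offset_quarter_turn_gives_c(self):
        k = DEFAULT_KARPLUS
        assert karplus(math.pi / 3 + math.pi / 2, k) == pytest.approx(k.C, abs=1e-12)

    def test_worked_minus60_value(self):
        # cos(-2pi/3) = -1/2: 6.51/4 - 1.76*(-1/2) + 1.60
        assert karplus(-math.pi / 3) == pytest.approx(4.1075, abs=1e-12)

    def test_curve_within_quadratic_bounds_on_grid(self):
        k = DEFAULT_KARPLUS
        phis = np.linspace(-math.pi, math.pi, 3600)
        values = np.array([karplus(p, k) for p in phis])
        # brute-force extremes of A c^2 + B c + C over c in [-1, 1]
        c_grid = np.linspace(-1, 1, 200001)
        quad = k.A * c_grid ** 2 + k.B * c_grid + k.C
        assert values.min() >= quad.min() - 1e-9
        assert values.max() <= quad.max() + 1e-9

    def test_jc_on_builder_torsions(self, pentapeptide):
        spec, conf = pentapeptide
        records = [JcRecord(r) for r in range(2, 6)]
        values = backcalc_jc(conf, records)
        oracle = [karplus(spec.phi[r - 1]) for r in range(2, 6)]
        assert values == pytest.approx(oracle, abs=1e-5)

    def test_custom_coefficients(self, pentapeptide):
        _, conf = pentapeptide
        k = KarplusCoefficients(7.09, -1.42, 1.55)
        (value,) = backcalc_jc(conf, [JcRecord(2)], k=k)
        phi = compute_phi(conf, 2)
        c = math.cos(phi - math.pi / 3)
        assert value == pytest.approx(7.09 * c * c - 1.42 * c + 1.55, abs=1e-12)


class TestSmfret:
    def test_half_efficiency_when_corrected_distance_equals_scale(self):
        n, s = 10, 40.0
        d = s * n / (n + 7)  # makes D' == S
        assert fret_efficiency(d, n, s) == pytest.approx(0.5, abs=1e-12)

    def test_contact_limit_is_one(self):
        assert fret_efficiency(1e-9, 10, 40.0) == pytest.approx(1.0)

    def test_worked_value_d30_n50_s54(self):
        d_corr = 30.0 * 57.0 / 50.0
        oracle = 1.0 / (1.0 + (d_corr / 54.0) ** 6)
        assert fret_efficiency(30.0, 50, 54.0) == pytest.approx(oracle, abs=1e-12)
        assert oracle == pytest.approx(0.9394, abs=1e-4)

    def test_strictly_decreasing_in_distance(self):
        grid = np.linspace(1.0, 120.0, 400)
        values = [fret_efficiency(d, 25, 54.0) for d in grid]
        assert all(a > b for a, b in zip(values, values[1:]))
        assert all(0.0 < v <= 1.0 for v in values)

    def test_backcalc_uses_ca_atoms(self):
        conf = make_conformer([
            (6, "ALA", "CA", (0.0, 0.0, 0.0)),
            (6, "ALA", "H", (99.0, 0.0, 0.0)),  # decoy: must not be used
            (56, "GLY", "CA", (30.0, 0.0, 0.0)),
        ])
        (value,) = backcalc_smfret(conf, [SmfretPair(6, 56, 54.0)])
        assert value == pytest.approx(fret_efficiency(30.0, 50, 54.0), abs=1e-12)


class TestRigidMotionInvariance:
    def test_all_four_calculators(self, ensemble_dir):
        _, ens = ensemble_dir
        conf = ens.conformers[0]
        residues = conf.residue_numbers()
        pre_pairs = [PrePair(2, "H", 8, "H"), PrePair(3, "HA", 10, "CA")]
        noe_pairs = [NoePair(2, "H", ("HA",), 9, "H", ())]
        jc_records = [JcRecord(r) for r in residues[1:6]]
        fret_pairs = [SmfretPair(residues[0], residues[-1], 54.0)]

        rng = np.random.default_rng(23)
        for _ in range(5):
            rot, trans = random_rigid_transform(rng)
            moved = transform_conformer(conf, rot, trans)
            for fn, arg in [(backcalc_pre, pre_pairs), (backcalc_noe, noe_pairs),
                            (backcalc_jc, jc_records), (backcalc_smfret, fret_pairs)]:
                assert fn(moved, arg) == pytest.approx(fn(conf, arg), abs=1e-9)


def test_missing_atom_null_policy_vs_fail(dumbbell):
    pairs = [PrePair(2, "H", 14, "H"), PrePair(2, "H", 14, "HZ9")]
    from idpcalc.errors import MissingAtomError
    with pytest.raises(MissingAtomError):
        backcalc_pre(dumbbell, pairs, missing="fail")
    assert backcalc_pre(dumbbell, pairs, missing="null") == [5.0, None]
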