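import math

import numpy as np
import pytest

from trefoilkit.errors import UnderdeterminedError
from trefoilkit.simulate import SimulationConfig, evolve_family
from trefoilkit.structure_io import Residue, StructureRecord
from trefoilkit.superpose import (
    align_structures,
    kabsch,
    reference_msa,
    superpose_shared_residues,
)


def quaternion_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Independent closed-form superposition rmsd (Horn's quaternion method)."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    m = a.T @ b
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    k = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    lam = np.linalg.eigvalsh(k)[-1]
    sq = ((a ** 2).sum() + (b ** 2).sum() - 2.0 * lam) / len(a)
    return math.sqrt(max(sq, 0.0))


def rigid_motion(points, angle, axis, translation):
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    c, s = math.cos(angle), math.sin(angle)
    x, y, z = axis
    rot = np.array(
        [
            [c + x * x * (1 - c), x * y * (1 - c) - z * s, x * z * (1 - c) + y * s],
            [y * x * (1 - c) + z * s, c + y * y * (1 - c), y * z * (1 - c) - x * s],
            [z * x * (1 - c) - y * s, z * y * (1 - c) + x * s, c + z * z * (1 - c)],
        ]
    )
    return points @ rot.T + np.asarray(translation, float)


def as_structure(name, coords):
    return StructureRecord(
        name,
        tuple(
            Residue(i + 1, "A", tuple(float(v) for v in xyz))
            for i, xyz in enumerate(coords)
        ),
    )


class TestKabsch:
    def test_identical_points_zero_rmsd_identity_rotation(self):
        pts = np.random.default_rng(0).normal(size=(10, 3))
        sup = kabsch(pts, pts)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(sup.rotation, np.eye(3), atol=1e-10)

    def test_recovers_rigid_motion(self):
        pts = np.random.default_rng(1).normal(size=(12, 3)) * 5
        moved = rigid_motion(pts, math.pi / 2, (0, 0, 1), (5, 0, 0))
        sup = kabsch(pts, moved)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(sup.transform(pts), moved, atol=1e-9)

    def test_matches_quaternion_oracle_on_noisy_sets(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            a = rng.normal(size=(10, 3)) * 4
            b = a + rng.normal(scale=0.5, size=(10, 3))
            assert kabsch(a, b).rmsd == pytest.approx(quaternion_rmsd(a, b), abs=1e-8)

    def test_invariant_under_joint_rigid_motion(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(15, 3)) * 4
        b = a + rng.normal(scale=0.8, size=(15, 3))
        base = kabsch(a, b).rmsd
        for k in range(5):
            am = rigid_motion(a, 0.3 + k, (1, 2, k + 1), (k, -k, 2))
            bm = rigid_motion(b, 1.1 * k, (k + 1, 1, 0), (-k, 3, k))
            assert kabsch(am, bm).rmsd == pytest.approx(base, abs=1e-8)

    def test_optimal_among_random_rotations(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=(10, 3)) * 3
        b = a + rng.normal(scale=0.4, size=(10, 3))
        best = kabsch(a, b).rmsd
        ac = a - a.mean(axis=0)
        bc = b - b.mean(axis=0)
        for _ in range(100):
            angle = rng.uniform(0, 2 * math.pi)
            axis = rng.normal(size=3)
            trial = rigid_motion(ac, angle, axis, (0, 0, 0))
            trial_rmsd = math.sqrt(((trial - bc) ** 2).sum() / len(a))
            assert best <= trial_rmsd + 1e-12

    def test_rotation_is_proper_and_orthonormal(self):
        rng = np.random.default_rng(11)
        a = rng.normal(size=(8, 3))
        b = rng.normal(size=(8, 3))
        sup = kabsch(a, b)
        np.testing.assert_allclose(sup.rotation @ sup.rotation.T, np.eye(3), atol=1e-8)
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-8)

    def test_too_few_points_raises(self):
        with pytest.raises(UnderdeterminedError):
            kabsch(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_input_flagged_degenerate(self):
        a = np.array([[float(i), 0.0, 0.0] for i in range(5)])
        sup = kabsch(a, a)
        assert sup.degenerate
        assert sup.rmsd == pytest.approx(0.0, abs=1e-12)


class TestAlignStructures:
    def test_rigid_copy_gives_identity_correspondence(self, template):
        moved = rigid_motion(template.coords, 0.9, (1, 1, 0), (4, -3, 7))
        copy = as_structure("copy", moved)
        sup = align_structures(template, copy)
        assert sup.correspondence == tuple((i, i) for i in range(len(template)))
        assert sup.rmsd == pytest.approx(0.0, abs=1e-9)
        assert sup.converged

    def test_family_member_coverage_high_at_low_divergence(self, template):
        structs, _, _ = evolve_family(
            template, SimulationConfig(seed=17, n_taxa=8, structure_noise_scale=0.5)
        )
        for s in structs:
            sup = align_structures(s, template)
            assert sup.aligned_length / len(template) > 0.8

    def test_unrelated_random_walks_align_poorly(self):
        def walk(seed, n=150):
            rng = np.random.default_rng(seed)
            pts = [np.zeros(3)]
            d = np.array([1.0, 0.0, 0.0])
            for _ in range(n - 1):
                d = d + rng.normal(scale=0.8, size=3)
                d /= np.linalg.norm(d)
                pts.append(pts[-1] + 3.8 * d)
            return as_structure(f"w{seed}", np.array(pts))

        poor = 0
        for s in range(20):
            sup = align_structures(walk(1000 + 2 * s), walk(1001 + 2 * s))
            if sup.aligned_length / 150 < 0.5:
                poor += 1
        assert poor >= 18

    def test_correspondence_strictly_monotone(self, template, small_family):
        structs, _, _ = small_family
        sup = align_structures(structs[3], template)
        pairs = sup.correspondence
        assert all(a2 > a1 and b2 > b1 for (a1, b1), (a2, b2) in zip(pairs, pairs[1:]))

    def test_rmsd_symmetric_between_directions(self, template, small_family):
        structs, _, _ = small_family
        a, b = structs[1], structs[2]
        assert abs(align_structures(a, b).rmsd - align_structures(b, a).rmsd) < 0.1

    def test_short_chains_rejected(self, template):
        stub = as_structure("stub", template.coords[:5])
        with pytest.raises(UnderdeterminedError):
            align_structures(stub, template)


class TestReferenceMsa:
    def test_identical_inputs_give_gapfree_msa(self, template):
        copies = [
            as_structure(f"c{i}", template.coords.copy()) for i in range(4)
        ]
        msa, report = reference_msa(copies, "c0")
        assert msa.width == len(template)
        assert all("-" not in row for row in msa.rows)
        assert not report.excluded

    def test_width_equals_reference_length_and_order_kept(self, small_family):
        structs, _, _ = small_family
        ref = structs[0].id
        msa, report = reference_msa(structs, ref)
        assert msa.width == len(structs[0])
        kept_order = [s.id for s in structs if s.id in msa.taxa]
        assert list(msa.taxa) == kept_order

    def test_recovers_planted_gap_rate(self, template):
        structs, _, _ = evolve_family(
            template,
            SimulationConfig(seed=9, n_taxa=24, structure_noise_scale=0.3),
        )
        msa, _ = reference_msa(structs, structs[0].id)
        arr = msa.to_array()
        mean_gap = float((arr == "-").mean())
        assert mean_gap == pytest.approx(0.05, abs=0.05)

    def test_missing_reference_rejected(self, small_family):
        structs, _, _ = small_family
        with pytest.raises(UnderdeterminedError):
            reference_msa(structs, "no-such-id")


def test_shared_residue_superposition_uses_numbering(template, small_family):
    structs, _, _ = small_family
    sup = superpose_shared_residues(structs[0], template)
    nums = {r.number for r in structs[0].residues}
    assert sup.aligned_length == len(nums)
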