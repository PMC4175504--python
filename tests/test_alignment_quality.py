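"""Equivalence counts, Kabsch superposition and consensus fitting."""

import numpy as np
import pytest

from domdiff.alignment_quality import (consensus_superpose,
                                       initial_equivalences,
                                       kabsch_superpose, pairwise_rmsds,
                                       quality_report, sst_equivalences)
from domdiff.model import DomainMember, ScopClass, Superfamily
from domdiff.synthetic import (build_terminal_alignment,
                               generate_coordinates, generate_superfamily)
from domdiff.classification import Label


# ---------------------------------------------------------------------------
# equivalences

def test_initial_equivalences_counts_gapless_columns():
    aln = {"a": "ACDEF", "b": "ACDEF", "c": "ACDEF"}
    assert initial_equivalences(aln) == 5
    aln["b"] = "AC-EF"
    assert initial_equivalences(aln) == 4
    aln["c"] = "-----"
    assert initial_equivalences(aln) == 0


def test_initial_equivalences_empty_alignment_errors():
    with pytest.raises(ValueError):
        initial_equivalences({})


def test_sst_equivalences_unanimous_states():
    aln = {"a": "AAAA", "b": "AAAA"}
    ss = {"a": "HHHH", "b": "HHHH"}
    assert sst_equivalences(aln, ss) == 4
    ss["b"] = "HHEH"
    assert sst_equivalences(aln, ss) == 3  # one column H vs E excluded


def test_sst_equivalences_counted_fixture():
    # 40 gapless columns, the first 25 state-unanimous, the rest split H/E
    aln = {"a": "A" * 40, "b": "A" * 40, "c": "A" * 40}
    ss = {"a": "H" * 40, "b": "H" * 40, "c": "H" * 25 + "E" * 15}
    assert initial_equivalences(aln) == 40
    assert sst_equivalences(aln, ss) == 25


def test_sst_missing_member_errors():
    with pytest.raises(ValueError, match="missing"):
        sst_equivalences({"a": "AA", "b": "AA"}, {"a": "HH"})


def test_sst_not_above_initial_on_gapped_rows():
    aln = {"a": "AC-DEF", "b": "ACQDEF"}
    ss = {"a": "HHHHH", "b": "HHHHHH"}
    n_init = initial_equivalences(aln)
    n_sst = sst_equivalences(aln, ss)
    assert 0 <= n_sst <= n_init <= 6


# ---------------------------------------------------------------------------
# Kabsch

def _random_rotation(rng):
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def test_kabsch_identical_sets():
    pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.0]])
    sup = kabsch_superpose(pts, pts)
    assert sup.rmsd == pytest.approx(0.0, abs=1e-12)
    np.testing.assert_allclose(sup.rotation, np.eye(3), atol=1e-12)


def test_kabsch_recovers_rigid_motion():
    rng = np.random.default_rng(0)
    x = rng.normal(size=(10, 3))
    R = _random_rotation(rng)
    y = x @ R.T + np.array([1.0, -2.0, 3.0])
    sup = kabsch_superpose(x, y)
    assert sup.rmsd == pytest.approx(0.0, abs=1e-9)
    np.testing.assert_allclose(sup.apply(y), x, atol=1e-9)
    assert np.linalg.det(sup.rotation) == pytest.approx(1.0)


def test_kabsch_rotation_always_proper():
    # mirrored target must not be fit by a reflection
    rng = np.random.default_rng(1)
    x = rng.normal(size=(6, 3))
    y = x.copy()
    y[:, 0] = -y[:, 0]
    sup = kabsch_superpose(x, y)
    assert np.linalg.det(sup.rotation) == pytest.approx(1.0)
    assert sup.rmsd > 0.1


def test_kabsch_requires_three_points():
    with pytest.raises(ValueError):
        kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


def test_kabsch_invariant_to_common_rigid_motion():
    rng = np.random.default_rng(2)
    x = rng.normal(size=(8, 3))
    y = x + rng.normal(scale=0.3, size=x.shape)
    base = kabsch_superpose(x, y).rmsd
    for seed in range(5):
        r2 = np.random.default_rng(seed)
        R = _random_rotation(r2)
        t = r2.normal(size=3)
        moved = kabsch_superpose(x @ R.T + t, y @ R.T + t).rmsd
        assert moved == pytest.approx(base, abs=1e-9)


def test_kabsch_no_worse_than_unfitted():
    rng = np.random.default_rng(3)
    x = rng.normal(size=(12, 3))
    y = x + rng.normal(scale=0.5, size=x.shape)
    raw = float(np.sqrt(np.mean(np.sum((y - x) ** 2, axis=1))))
    assert kabsch_superpose(x, y).rmsd <= raw + 1e-12


def test_kabsch_matches_numeric_rotation_search():
    """5-point noisy toy: the SVD answer equals a numeric minimisation over
    rotation parameters (coarse Euler-angle grid refined by simplex)."""
    from scipy.optimize import minimize
    from scipy.spatial.transform import Rotation

    rng = np.random.default_rng(4)
    x = rng.normal(size=(5, 3))
    y = x + rng.normal(scale=0.4, size=x.shape)
    got = kabsch_superpose(x, y).rmsd

    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)

    def objective(angles):
        R = Rotation.from_euler("zyx", angles).as_matrix()
        return np.sqrt(np.mean(np.sum((yc @ R.T - xc) ** 2, axis=1)))

    best = np.inf
    grid = np.linspace(-np.pi, np.pi, 7)
    for a in grid:
        for b in grid:
            for c in grid:
                res = minimize(objective, [a, b, c], method="Nelder-Mead",
                               options={"xatol": 1e-10, "fatol": 1e-12})
                best = min(best, res.fun)
    assert got == pytest.approx(best, abs=1e-6)


def test_kabsch_matches_scipy_align_vectors():
    from scipy.spatial.transform import Rotation

    rng = np.random.default_rng(5)
    x = rng.normal(size=(9, 3))
    y = x + rng.normal(scale=0.2, size=x.shape)
    got = kabsch_superpose(x, y)
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    rot, rssd = Rotation.align_vectors(xc, yc)
    np.testing.assert_allclose(got.rotation, rot.as_matrix(), atol=1e-8)
    assert got.rmsd == pytest.approx(rssd / np.sqrt(len(x)), abs=1e-8)


# ---------------------------------------------------------------------------
# consensus superposition

def _coord_members(n, length, sigma, seed):
    rng = np.random.default_rng(seed)
    template = generate_coordinates(length, 0.0, rng)
    members = {}
    for i in range(n):
        noise = rng.normal(scale=sigma, size=template.shape) if sigma else 0.0
        members[f"m{i}"] = template + noise
    aln = {mid: "A" * length for mid in members}
    return members, aln


def test_consensus_identical_traces_zero():
    members, aln = _coord_members(3, 30, 0.0, 0)
    per_member, consensus = consensus_superpose(members, aln)
    assert consensus == pytest.approx(0.0, abs=1e-9)
    assert all(v == pytest.approx(0.0, abs=1e-9) for v in per_member.values())


def test_consensus_objective_monotone_nonincreasing():
    for seed in range(4):
        members, aln = _coord_members(4, 25, 0.8, seed)
        _, _, history = consensus_superpose(members, aln,
                                            return_history=True)
        assert all(b <= a + 1e-8 for a, b in zip(history, history[1:]))


def test_consensus_rmsd_grows_with_noise():
    levels = []
    for sigma in (0.1, 0.5, 1.0, 2.0):
        values = []
        for seed in range(5):
            members, aln = _coord_members(4, 40, sigma, seed)
            _, consensus = consensus_superpose(members, aln)
            values.append(consensus)
        levels.append(np.mean(values))
    assert levels == sorted(levels)


def test_consensus_needs_enough_columns():
    members, _ = _coord_members(2, 10, 0.0, 0)
    aln = {mid: "AA--------" for mid in members}
    trimmed = {mid: coords[:2] for mid, coords in members.items()}
    with pytest.raises(ValueError):
        consensus_superpose(trimmed, aln)


# ---------------------------------------------------------------------------
# quality report

def test_quality_report_without_coordinates():
    rng = np.random.default_rng(6)
    sf = generate_superfamily(Label.RIGID, 4, 60, rng, with_ss=True)
    qm = quality_report(sf)
    assert qm.mean_pairwise_rmsd is None and qm.consensus_rmsd is None
    assert qm.n_members_with_coords == 0
    assert 0 <= qm.n_sst_equivalences <= qm.n_initial_equivalences
    assert qm.n_initial_equivalences <= sf.alignment_length


def test_quality_report_identical_members_zero_rmsd():
    length = 30
    rng = np.random.default_rng(7)
    seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), length))
    coords = generate_coordinates(length, 0.0, rng)
    members = [DomainMember(f"{i}aaa_A", f"{i}aaa", "A", "1", ScopClass.A,
                            seq, ss_string="H" * length,
                            ca_trace=coords.copy()) for i in range(1, 4)]
    sf = Superfamily("1", "identical", ScopClass.A, members,
                     build_terminal_alignment(members))
    qm = quality_report(sf)
    assert qm.mean_pairwise_rmsd == pytest.approx(0.0, abs=1e-9)
    assert qm.consensus_rmsd == pytest.approx(0.0, abs=1e-9)
    assert qm.n_sst_equivalences == qm.n_initial_equivalences == length


def test_rigid_superfamily_has_larger_core_fraction_than_deviant():
    rng = np.random.default_rng(8)
    rigid = generate_superfamily(Label.RIGID, 5, 100, rng)
    deviant = generate_superfamily(Label.DEVIANT, 5, 100, rng)

    def core_fraction(sf):
        return (initial_equivalences(sf.alignment)
                / np.mean([m.length for m in sf.members]))

    assert core_fraction(rigid) >= core_fraction(deviant)
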