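"""Generator guarantees: identity targets, forced-margin labels,
determinism, and truth-record consistency."""

import numpy as np
import pytest

from domdiff.align import global_align_identity
from domdiff.classification import DEFAULT_CONFIG, Label, classify_improved
from domdiff.length_variation import superfamily_profile
from domdiff.synthetic import (GenerationError, GeneratorSpec,
                               cascade_fixture, generate_coordinates,
                               generate_superfamily, generate_version_pair,
                               mutate_to_identity, split_fixture)
from domdiff.alignment_quality import kabsch_superpose
from domdiff.version_diff import Fate, assign_member_fates


def test_mutate_identity_full_target_is_identity(rng):
    seq = "ACDEFGHIKLMNPQRSTVWY" * 3
    assert mutate_to_identity(seq, 100.0, rng) == seq


def test_mutate_identity_zero_target_hits_floor(rng):
    # full substitution cannot erase identity: gapped realignment of two
    # random same-length 100-mers recovers ~11-15% spurious matches, so a
    # 0% target (tolerance 5) is unreachable and must say so
    seq = "".join(np.random.default_rng(0).choice(
        list("ACDEFGHIKLMNPQRSTVWY"), 100))
    with pytest.raises(GenerationError, match="floor"):
        mutate_to_identity(seq, 0.0, rng)


def test_mutate_identity_low_target_within_tolerance(rng):
    seq = "".join(np.random.default_rng(0).choice(
        list("ACDEFGHIKLMNPQRSTVWY"), 100))
    mutant = mutate_to_identity(seq, 15.0, rng)
    assert len(mutant) == len(seq)
    assert 10.0 <= global_align_identity(seq, mutant)[0] <= 20.0


def test_mutate_identity_band_30_on_200mer():
    base_rng = np.random.default_rng(1)
    seq = "".join(base_rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 200))
    for seed in range(20):
        rng = np.random.default_rng(seed)
        mutant = mutate_to_identity(seq, 30.0, rng)
        ident = global_align_identity(seq, mutant)[0]
        assert 25.0 <= ident <= 35.0, (seed, ident)


@pytest.mark.parametrize("label,n,mean", [
    (Label.RIGID, 5, 150),
    (Label.RIGID, 4, 60),
    (Label.DEVIANT, 12, 200),
    (Label.DEVIANT, 4, 80),
    (Label.NORMAL, 4, 100),
    (Label.NORMAL, 7, 90),
])
def test_generate_superfamily_label_roundtrip(label, n, mean, rng):
    sf = generate_superfamily(label, n, mean, rng)
    got = classify_improved(superfamily_profile(sf), DEFAULT_CONFIG)
    assert got.label == label
    if label == Label.DEVIANT and n >= 10:
        values = superfamily_profile(sf).per_member_variation.values()
        assert sum(1 for v in values if abs(v) > 30) >= 9


def test_generate_superfamily_infeasible(rng):
    with pytest.raises(GenerationError):
        generate_superfamily(Label.DEVIANT, 3, 20, rng)  # mean too small
    with pytest.raises(GenerationError):
        generate_superfamily(Label.RIGID, 2, 100, rng)


def test_generated_superfamilies_respect_identity_cap(rng):
    from domdiff.model import DatabaseVersion

    sf = generate_superfamily(Label.DEVIANT, 6, 90, rng)
    DatabaseVersion("v", {sf.code: sf}).validate(redundancy_check=True)


def test_coordinates_deterministic_and_rigid(rng):
    a = generate_coordinates(25, 0.0, np.random.default_rng(0))
    b = generate_coordinates(25, 0.0, np.random.default_rng(99))
    np.testing.assert_array_equal(a, b)  # noiseless curve ignores the rng
    assert kabsch_superpose(a, b).rmsd == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(ValueError):
        generate_coordinates(30, -1.0, rng)


def test_coordinate_noise_matches_expected_magnitude():
    # per-residue displacement is isotropic N(0, sigma^2 I): RMSD to the
    # noiseless curve concentrates near sigma * sqrt(3); superposition can
    # only shave a little off
    sigma = 1.0
    rmsds = []
    for seed in range(50):
        rng = np.random.default_rng(seed)
        clean = generate_coordinates(60, 0.0, rng)
        noisy = generate_coordinates(60, sigma, np.random.default_rng(seed + 1))
        rmsds.append(kabsch_superpose(clean, noisy).rmsd)
    mean_rmsd = float(np.mean(rmsds))
    assert 0.85 * sigma * np.sqrt(3) * 0.9 <= mean_rmsd <= sigma * np.sqrt(3) * 1.1


def test_version_pair_deterministic():
    spec = GeneratorSpec(seed=77)
    a1, a2, ta = generate_version_pair(spec)
    b1, b2, tb = generate_version_pair(spec)
    assert ta.to_dict() == tb.to_dict()
    for va, vb in ((a1, b1), (a2, b2)):
        assert sorted(va.member_ids()) == sorted(vb.member_ids())
        for code in va.superfamilies:
            assert va.superfamilies[code].alignment == \
                vb.superfamilies[code].alignment


def test_version_pair_split_plan_recovered():
    from domdiff.version_diff import detect_splits_merges, EventKind

    spec = GeneratorSpec(seed=31)
    spec.n_superfamilies = {Label.RIGID: 2}
    spec.superfamily_sizes = [12, 4]
    spec.split_plans = [("900001", 4)]
    v1, v2, truth = generate_version_pair(spec)
    events = detect_splits_merges(v1, v2)
    assert len(events) == 1
    assert events[0].kind == EventKind.SPLIT
    assert events[0].old_codes == ["900001"]
    assert len(events[0].new_codes) == 4
    assert events[0].to_dict() == truth.events[0].to_dict()


def test_version_pair_merge_plan_recovered():
    from domdiff.version_diff import detect_splits_merges, EventKind

    spec = GeneratorSpec(seed=32)
    spec.n_superfamilies = {Label.RIGID: 3}
    spec.superfamily_sizes = [4, 4, 5]
    spec.merge_plans = [(["900001", "900002"], "52402")]
    v1, v2, truth = generate_version_pair(spec)
    events = detect_splits_merges(v1, v2)
    merges = [e for e in events if e.kind == EventKind.MERGE]
    assert len(merges) == 1
    assert merges[0].old_codes == ["900001", "900002"]
    assert merges[0].new_codes == ["52402"]


def test_contradictory_fate_plan_rejected():
    spec = GeneratorSpec(seed=1)
    spec.fate_counts = {Fate.RETAINED: 1}  # cannot cover all members
    with pytest.raises(GenerationError):
        generate_version_pair(spec)


def test_split_fixture_member_conservation():
    for scenario in ("viral_4way", "ovomucoid_2way", "etfp_merge"):
        v1, v2 = split_fixture(scenario)
        assert v1.member_ids() == v2.member_ids()


def test_cascade_fixture_deterministic_and_seed_stable():
    a1, a2 = cascade_fixture(seed=5)
    b1, b2 = cascade_fixture(seed=5)
    assert sorted(a1.member_ids()) == sorted(b1.member_ids())
    assert sorted(a2.member_ids()) == sorted(b2.member_ids())
    assert a2.outliers == b2.outliers


def test_truth_fates_recovered_with_coords_and_ss():
    spec = GeneratorSpec(seed=55, with_ss=True, with_coords=True,
                         coord_noise_sigma=0.3)
    spec.n_superfamilies = {Label.RIGID: 2}
    spec.superfamily_sizes = [5, 5]
    spec.fate_counts = {Fate.RETAINED: 6, Fate.OUTLIER: 1,
                        Fate.RESCUED_BY_SEARCH: 1,
                        Fate.RESCUED_BY_IDENTITY: 1, Fate.UNACCOUNTED: 1}
    v1, v2, truth = generate_version_pair(spec)
    fates = {f.member_id: f.fate for f in assign_member_fates(v1, v2)}
    for mid, want in truth.fates.items():
        assert fates[mid] == want
    for sf in list(v1.superfamilies.values()) + list(v2.superfamilies.values()):
        for m in sf.members:
            assert m.ss_string is not None and len(m.ss_string) == m.length
            assert m.ca_trace is not None and m.ca_trace.shape == (m.length, 3)
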