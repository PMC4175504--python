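"""Version diffing: aligner correctness, mapping, splits/merges,
supersession and member fates."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from domdiff.align import global_align, global_align_identity, percent_identity
from domdiff.model import DatabaseVersion, ScopClass, Superfamily
from domdiff.synthetic import (GeneratorSpec, build_terminal_alignment,
                               generate_version_pair, mutate_to_identity,
                               split_fixture)
from domdiff.version_diff import (EventKind, Fate, accounting_cascade,
                                  assign_member_fates, detect_splits_merges,
                                  detect_supersession, map_superfamilies)

from conftest import make_superfamily


# ---------------------------------------------------------------------------
# alignment oracles

def enumerate_alignments(a, b):
    """Every global alignment of a and b as gapped row pairs."""
    if not a and not b:
        yield ("", "")
        return
    if a and b:
        for ra, rb in enumerate_alignments(a[:-1], b[:-1]):
            yield (ra + a[-1], rb + b[-1])
    if a:
        for ra, rb in enumerate_alignments(a[:-1], b):
            yield (ra + a[-1], rb + "-")
    if b:
        for ra, rb in enumerate_alignments(a, b[:-1]):
            yield (ra + "-", rb + b[-1])


def score_alignment(ra, rb, match=1, mismatch=-1, gap=-2):
    s = 0
    for x, y in zip(ra, rb):
        if x == "-" or y == "-":
            s += gap
        elif x == y:
            s += match
        else:
            s += mismatch
    return s


def test_identity_trivial_values():
    assert global_align_identity("PEPTIDE", "PEPTIDE")[0] == 100.0
    assert global_align_identity("AAAA", "CCCC")[0] == 0.0


def test_identity_matches_enumeration_oracle_example():
    a, b = "ACGTA", "ACTA"
    best = max(score_alignment(ra, rb)
               for ra, rb in enumerate_alignments(a, b))
    optimal_ids = {percent_identity(ra, rb)
                   for ra, rb in enumerate_alignments(a, b)
                   if score_alignment(ra, rb) == best}
    score, ra, rb = global_align(a, b)
    assert score == best
    assert global_align_identity(a, b)[0] in optimal_ids


def test_empty_sequence_rejected():
    with pytest.raises(ValueError):
        global_align("", "ACD")


@settings(max_examples=150, deadline=None, derandomize=True)
@given(st.text(alphabet="ACG", min_size=1, max_size=5),
       st.text(alphabet="ACG", min_size=1, max_size=5))
def test_aligner_score_optimal_and_identity_coherent(a, b):
    best = max(score_alignment(ra, rb)
               for ra, rb in enumerate_alignments(a, b))
    optimal_ids = {percent_identity(ra, rb)
                   for ra, rb in enumerate_alignments(a, b)
                   if score_alignment(ra, rb) == best}
    score, ra, rb = global_align(a, b)
    assert score == best
    assert score_alignment(ra, rb) == best
    assert global_align_identity(a, b)[0] in optimal_ids


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.text(alphabet="ACDEFG", min_size=1, max_size=12),
       st.text(alphabet="ACDEFG", min_size=1, max_size=12))
def test_identity_symmetric(a, b):
    assert global_align_identity(a, b)[0] == \
        pytest.approx(global_align_identity(b, a)[0])


def test_score_matches_biopython_reference():
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    rng = np.random.default_rng(5)
    aas = list("ACDEFGHIKLMNPQRSTVWY")
    for _ in range(40):
        a = "".join(rng.choice(aas, rng.integers(3, 30)))
        b = "".join(rng.choice(aas, rng.integers(3, 30)))
        assert global_align(a, b)[0] == pytest.approx(aligner.score(a, b))


# ---------------------------------------------------------------------------
# superfamily mapping and split/merge events

def _stub_version(label, codes):
    return DatabaseVersion(label, {c: Superfamily(c, c, ScopClass.A)
                                   for c in codes})


def test_map_superfamilies_partitions():
    v1 = _stub_version("v1", [str(i) for i in range(397)])
    v2 = _stub_version("v2", [str(i) for i in range(377)]
                       + [f"n{i}" for i in range(259)])
    mapping = map_superfamilies(v1, v2)
    assert (len(mapping.common), len(mapping.absent_from_new),
            len(mapping.new_in_new)) == (377, 20, 259)
    union = mapping.common | mapping.absent_from_new | mapping.new_in_new
    assert union == set(v1.superfamilies) | set(v2.superfamilies)


def test_map_identical_and_disjoint():
    v = _stub_version("v", ["1", "2"])
    m = map_superfamilies(v, v)
    assert m.common == {"1", "2"} and not m.absent_from_new
    m2 = map_superfamilies(_stub_version("a", ["1"]),
                           _stub_version("b", ["2"]))
    assert not m2.common


def test_split_fixture_viral_four_way():
    v1, v2 = split_fixture("viral_4way")
    events = detect_splits_merges(v1, v2)
    assert len(events) == 1
    ev = events[0]
    assert ev.kind == EventKind.SPLIT
    assert ev.old_codes == ["49611"]
    assert ev.new_codes == ["88633", "88645", "88648", "88650"]


def test_split_fixture_ovomucoid_two_way():
    v1, v2 = split_fixture("ovomucoid_2way")
    events = detect_splits_merges(v1, v2)
    assert len(events) == 1
    assert events[0].kind == EventKind.SPLIT
    assert events[0].old_codes == ["57467"]
    assert events[0].new_codes == ["100895", "100897"]


def test_split_fixture_etfp_merge():
    v1, v2 = split_fixture("etfp_merge")
    events = detect_splits_merges(v1, v2)
    assert len(events) == 1
    assert events[0].kind == EventKind.MERGE
    assert events[0].old_codes == ["52402", "52431"]
    assert events[0].new_codes == ["52402"]


def test_no_events_on_identical_versions():
    v1, _, _ = generate_version_pair(GeneratorSpec(seed=9))
    assert detect_splits_merges(v1, v1) == []


def test_split_merge_symmetric_under_swap():
    for scenario in ("viral_4way", "etfp_merge"):
        v1, v2 = split_fixture(scenario)
        fwd = detect_splits_merges(v1, v2)
        rev = detect_splits_merges(v2, v1)
        assert len(fwd) == len(rev) == 1
        assert {fwd[0].kind, rev[0].kind} == {EventKind.SPLIT, EventKind.MERGE}
        assert fwd[0].old_codes == rev[0].new_codes
        assert fwd[0].new_codes == rev[0].old_codes


# ---------------------------------------------------------------------------
# supersession and fates

def test_supersession_cases():
    sf = make_superfamily([50, 50, 50], seed=3)
    original = sf.members[0]
    same_seq_new_pdb = sf.members[1]
    same_seq_new_pdb.sequence = original.sequence
    assert detect_supersession(original, [same_seq_new_pdb]) is same_seq_new_pdb
    # same pdb code is retention, not supersession
    clone = sf.members[2]
    clone.sequence = original.sequence
    clone.pdb_code = original.pdb_code
    assert detect_supersession(original, [clone]) is None


def test_supersession_requires_full_identity():
    rng = np.random.default_rng(0)
    sf = make_superfamily([60], seed=4)
    original = sf.members[0]
    near = make_superfamily([60], code=sf.code, seed=5).members[0]
    near.sequence = mutate_to_identity(original.sequence, 95.0, rng,
                                       tolerance=3.0)
    assert near.sequence != original.sequence
    assert detect_supersession(original, [near]) is None


def test_all_retained_when_versions_equal():
    v1, _, _ = generate_version_pair(GeneratorSpec(seed=2))
    fates = assign_member_fates(v1, v1)
    assert {f.fate for f in fates} == {Fate.RETAINED}


def test_dropped_member_without_homolog_unaccounted():
    sf1 = make_superfamily([50, 50, 50, 50], seed=6)
    v1 = DatabaseVersion("v1", {sf1.code: sf1})
    kept = sf1.members[:3]
    sf2 = Superfamily(sf1.code, sf1.name, sf1.scop_class, list(kept),
                      build_terminal_alignment(kept))
    v2 = DatabaseVersion("v2", {sf2.code: sf2})
    fates = {f.member_id: f for f in assign_member_fates(v1, v2)}
    dropped = sf1.members[3].member_id
    assert fates[dropped].fate == Fate.UNACCOUNTED


def test_identity_rescue_boundary():
    rng = np.random.default_rng(8)
    sf1 = make_superfamily([60, 60, 60, 60], seed=7)
    v1 = DatabaseVersion("v1", {sf1.code: sf1})
    dropped = sf1.members[3]
    kept = sf1.members[:3]
    homolog = None
    for _ in range(50):  # land strictly inside (30, 40)
        cand = mutate_to_identity(dropped.sequence, 35.0, rng, tolerance=2.0)
        ident = global_align_identity(dropped.sequence, cand)[0]
        if 30.0 < ident < 40.0 and all(
                global_align_identity(cand, k.sequence)[0] < 40.0
                for k in kept):
            homolog = cand
            break
    assert homolog is not None
    from domdiff.model import DomainMember
    hm = DomainMember("9zzz_A", "9zzz", "A", sf1.code, sf1.scop_class, homolog)
    ms = kept + [hm]
    sf2 = Superfamily(sf1.code, sf1.name, sf1.scop_class, ms,
                      build_terminal_alignment(ms))
    v2 = DatabaseVersion("v2", {sf2.code: sf2})
    fates = {f.member_id: f for f in assign_member_fates(v1, v2)}
    assert fates[dropped.member_id].fate == Fate.RESCUED_BY_IDENTITY


def test_member_of_vanished_superfamily_unaccounted():
    sf1 = make_superfamily([50, 50, 50], seed=9)
    v1 = DatabaseVersion("v1", {sf1.code: sf1})
    v2 = DatabaseVersion("v2", {})
    fates = assign_member_fates(v1, v2)
    assert all(f.fate == Fate.UNACCOUNTED for f in fates)
    assert all("superfamily absent" in f.evidence for f in fates)


# ---------------------------------------------------------------------------
# fate partition and cascade telescoping

def _mixed_pair(seed):
    spec = GeneratorSpec(
        n_superfamilies={},
        fate_counts=None, seed=seed)
    from domdiff.classification import Label
    spec.n_superfamilies = {Label.RIGID: 2, Label.NORMAL: 1}
    spec.superfamily_sizes = [6, 5, 5]
    spec.fate_counts = {Fate.RETAINED: 7, Fate.SUPERSEDED: 1,
                        Fate.OUTLIER: 2, Fate.RESCUED_BY_SEARCH: 2,
                        Fate.RESCUED_BY_IDENTITY: 2, Fate.UNACCOUNTED: 2}
    return generate_version_pair(spec)


def test_fate_partition_and_truth_recovery():
    for seed in (0, 1, 2):
        v1, v2, truth = _mixed_pair(seed)
        fates = assign_member_fates(v1, v2)
        by_id = {f.member_id: f.fate for f in fates}
        v1_ids = v1.member_ids()
        assert sum(1 for f in fates if f.fate != Fate.NEW) == len(v1_ids)
        for mid, want in truth.fates.items():
            assert by_id[mid] == want, (seed, mid)
        for mid in truth.new_members:
            assert by_id[mid] == Fate.NEW


def test_cascade_telescoping_identities():
    for seed in (3, 4):
        v1, v2, _ = _mixed_pair(seed)
        rep = accounting_cascade(v1, v2)
        assert rep.n_missing == rep.n_v1_total - rep.n_retained
        assert rep.n_queries == rep.n_missing - rep.n_outlier
        assert rep.n_search_missing == rep.n_queries - rep.n_search_hits
        assert rep.n_unaccounted == rep.n_search_missing - rep.n_identity_rescued
        # independent recount from the fate list
        tally = {}
        for f in rep.per_member:
            tally[f.fate] = tally.get(f.fate, 0) + 1
        assert rep.n_retained == tally.get(Fate.RETAINED, 0)
        assert rep.n_outlier == tally.get(Fate.OUTLIER, 0)
        assert rep.n_search_hits == (tally.get(Fate.RESCUED_BY_SEARCH, 0)
                                     + tally.get(Fate.SUPERSEDED, 0))
        assert rep.n_identity_rescued == tally.get(Fate.RESCUED_BY_IDENTITY, 0)
        assert rep.n_unaccounted == tally.get(Fate.UNACCOUNTED, 0)


def test_all_retained_cascade_is_flat():
    v1, v2, _ = generate_version_pair(GeneratorSpec(seed=11))
    rep = accounting_cascade(v1, v2)
    assert rep.n_missing == 0
    assert rep.n_queries == rep.n_search_missing == rep.n_unaccounted == 0
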