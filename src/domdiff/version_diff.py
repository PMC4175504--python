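"""Diffing two database versions.

Superfamilies are mapped by code; splits and merges are read off the
bipartite member-overlap graph between the versions' superfamilies; each
old-version member receives exactly one fate, decided by a fixed rule
cascade mirroring the curation workflow:

1. retained        — same member id present in the new version;
2. superseded      — replaced by a better structure of the same protein
                     (100% sequence identity, same length, new PDB code);
3. outlier         — listed as structurally unalignable in the new version;
4. rescued_by_search   — a sequence search against the new version of its
                         superfamily finds a hit at >= 40% identity (the
                         in-repo stand-in for BLAST/HMM searches);
5. rescued_by_identity — a forcible-alignment identity > 30% to some new
                         member of its superfamily places it there;
6. unaccounted     — none of the above.

Members present only in the new version are "new".  The accounting cascade
rolls the fates up into the stage counts used to audit an update: of the
members not carried over, how many were outliers, how many were recovered
by search, how many by identity placement, and how many remain missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

from .align import global_align_identity
from .model import DatabaseVersion, DomainMember

DEFAULT_SEARCH_IDENTITY_CUTOFF = 40.0     # rescue rule 4: search-hit stand-in
DEFAULT_PLACEMENT_IDENTITY_CUTOFF = 30.0  # rescue rule 5: identity placement


@dataclass
class SuperfamilyMapping:
    """Partition of the union of superfamily codes across two versions."""

    common: set[str]
    absent_from_new: set[str]
    new_in_new: set[str]

    def to_dict(self) -> dict:
        return {
            "common": sorted(self.common),
            "absent_from_new": sorted(self.absent_from_new),
            "new_in_new": sorted(self.new_in_new),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SuperfamilyMapping":
        return cls(common=set(d["common"]),
                   absent_from_new=set(d["absent_from_new"]),
                   new_in_new=set(d["new_in_new"]))


class EventKind(str, Enum):
    SPLIT = "split"
    MERGE = "merge"


@dataclass
class SplitMergeEvent:
    kind: EventKind
    old_codes: list[str]
    new_codes: list[str]
    shared_member_counts: dict[tuple[str, str], int]  # (old, new) -> n shared

    def to_dict(self) -> dict:
        return {
            "kind": self.kind.value,
            "old_codes": list(self.old_codes),
            "new_codes": list(self.new_codes),
            "shared_member_counts": [
                [o, n, c] for (o, n), c in sorted(self.shared_member_counts.items())
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SplitMergeEvent":
        return cls(
            kind=EventKind(d["kind"]),
            old_codes=list(d["old_codes"]),
            new_codes=list(d["new_codes"]),
            shared_member_counts={(o, n): c
                                  for o, n, c in d["shared_member_counts"]},
        )


class Fate(str, Enum):
    RETAINED = "retained"
    SUPERSEDED = "superseded"
    OUTLIER = "outlier"
    RESCUED_BY_SEARCH = "rescued_by_search"
    RESCUED_BY_IDENTITY = "rescued_by_identity"
    UNACCOUNTED = "unaccounted"
    NEW = "new"


@dataclass
class MemberFate:
    member_id: str
    fate: Fate
    evidence: str = ""

    def to_dict(self) -> dict:
        return {"member_id": self.member_id, "fate": self.fate.value,
                "evidence": self.evidence}

    @classmethod
    def from_dict(cls, d: dict) -> "MemberFate":
        return cls(member_id=d["member_id"], fate=Fate(d["fate"]),
                   evidence=d.get("evidence", ""))


@dataclass
class AccountingReport:
    """Stage-wise counts of the missing-member accounting cascade.

    Telescoping identities hold by construction:
    ``n_missing = n_v1_total - n_retained``;
    ``n_queries = n_missing - n_outlier``;
    ``n_search_missing = n_queries - n_search_hits``;
    ``n_unaccounted = n_search_missing - n_identity_rescued``.
    """

    n_v1_total: int
    n_retained: int
    n_missing: int
    n_outlier: int
    n_queries: int
    n_search_hits: int
    n_search_missing: int
    n_identity_rescued: int
    n_unaccounted: int
    per_member: list[MemberFate] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_v1_total": self.n_v1_total,
            "n_retained": self.n_retained,
            "n_missing": self.n_missing,
            "n_outlier": self.n_outlier,
            "n_queries": self.n_queries,
            "n_search_hits": self.n_search_hits,
            "n_search_missing": self.n_search_missing,
            "n_identity_rescued": self.n_identity_rescued,
            "n_unaccounted": self.n_unaccounted,
            "per_member": [f.to_dict() for f in self.per_member],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AccountingReport":
        d = dict(d)
        d["per_member"] = [MemberFate.from_dict(f) for f in d["per_member"]]
        return cls(**d)


def map_superfamilies(v1: DatabaseVersion, v2: DatabaseVersion) -> SuperfamilyMapping:
    """Partition superfamily codes into common / dropped / newly introduced."""
    c1, c2 = set(v1.superfamilies), set(v2.superfamilies)
    return SuperfamilyMapping(common=c1 & c2, absent_from_new=c1 - c2,
                              new_in_new=c2 - c1)


def detect_splits_merges(v1: DatabaseVersion, v2: DatabaseVersion,
                         min_shared: int = 1) -> list[SplitMergeEvent]:
    """Splits and merges from the bipartite member-overlap graph.

    Member identity across versions is by member id.  An old superfamily
    whose members land in >= 2 new superfamilies (each overlap of at least
    ``min_shared`` members) is a split; the symmetric pattern is a merge.
    An old code linked only to the same code is neither.  Events are sorted
    by first old code.
    """
    ids1 = {code: set(sf.member_ids) for code, sf in v1.superfamilies.items()}
    ids2 = {code: set(sf.member_ids) for code, sf in v2.superfamilies.items()}
    overlap: dict[tuple[str, str], int] = {}
    for c1, m1 in ids1.items():
        for c2, m2 in ids2.items():
            shared = len(m1 & m2)
            if shared >= min_shared:
                overlap[(c1, c2)] = shared

    events: list[SplitMergeEvent] = []
    for c1 in sorted(ids1):
        partners = sorted(c2 for (o, c2) in overlap if o == c1)
        if len(partners) >= 2:
            events.append(SplitMergeEvent(
                kind=EventKind.SPLIT, old_codes=[c1], new_codes=partners,
                shared_member_counts={(c1, p): overlap[(c1, p)]
                                      for p in partners}))
    for c2 in sorted(ids2):
        partners = sorted(o for (o, n) in overlap if n == c2)
        if len(partners) >= 2:
            events.append(SplitMergeEvent(
                kind=EventKind.MERGE, old_codes=partners, new_codes=[c2],
                shared_member_counts={(p, c2): overlap[(p, c2)]
                                      for p in partners}))
    events.sort(key=lambda e: (e.old_codes[0], e.kind.value))
    return events


def detect_supersession(member: DomainMember,
                        candidates: list[DomainMember]) -> Optional[DomainMember]:
    """A candidate with 100% sequence identity, equal length and a different
    PDB code supersedes ``member`` (better-resolution redeposit of the same
    protein).  Candidates are scanned in sorted member-id order."""
    for cand in sorted(candidates, key=lambda c: c.member_id):
        if cand.pdb_code == member.pdb_code:
            continue
        if cand.length != member.length:
            continue
        if cand.sequence == member.sequence:
            return cand
        ident, _, _ = global_align_identity(member.sequence, cand.sequence)
        if ident == 100.0:
            return cand
    return None


def assign_member_fates(
    v1: DatabaseVersion,
    v2: DatabaseVersion,
    search_identity_cutoff: float = DEFAULT_SEARCH_IDENTITY_CUTOFF,
    placement_identity_cutoff: float = DEFAULT_PLACEMENT_IDENTITY_CUTOFF,
) -> list[MemberFate]:
    """One fate per old member (first matching rule wins) plus ``new`` for
    members present only in the new version."""
    v2_ids = v2.member_ids()
    v1_ids = v1.member_ids()
    fates: list[MemberFate] = []
    for member in v1.iter_members():
        fates.append(_fate_of(member, v2, v2_ids,
                              search_identity_cutoff,
                              placement_identity_cutoff))
    for member in v2.iter_members():
        if member.member_id not in v1_ids:
            fates.append(MemberFate(member.member_id, Fate.NEW))
    return fates


def _fate_of(member: DomainMember, v2: DatabaseVersion, v2_ids: set[str],
             search_cutoff: float, placement_cutoff: float) -> MemberFate:
    mid = member.member_id
    if mid in v2_ids:  # rule 1
        return MemberFate(mid, Fate.RETAINED, "same id in new version")

    sf2 = v2.superfamilies.get(member.superfamily_code)
    candidates = sf2.members if sf2 is not None else []

    if candidates:  # rule 2
        winner = detect_supersession(member, candidates)
        if winner is not None:
            return MemberFate(mid, Fate.SUPERSEDED,
                              f"superseded by {winner.member_id}")

    if mid in v2.outliers:  # rule 3
        return MemberFate(mid, Fate.OUTLIER, "listed as outlier")

    if sf2 is None:  # rules 4-5 need the superfamily in the new version
        return MemberFate(mid, Fate.UNACCOUNTED, "superfamily absent")

    best_id = -1.0
    best_cand = None
    for cand in sorted(candidates, key=lambda c: c.member_id):
        ident, _, _ = global_align_identity(member.sequence, cand.sequence)
        if ident > best_id:
            best_id = ident
            best_cand = cand
    if best_cand is not None and best_id >= search_cutoff:  # rule 4
        return MemberFate(mid, Fate.RESCUED_BY_SEARCH,
                          f"hit {best_cand.member_id} at {best_id:.1f}%")
    if best_cand is not None and best_id > placement_cutoff:  # rule 5
        return MemberFate(mid, Fate.RESCUED_BY_IDENTITY,
                          f"placed by {best_cand.member_id} at {best_id:.1f}%")
    return MemberFate(mid, Fate.UNACCOUNTED,
                      f"best identity {best_id:.1f}%" if best_cand is not None
                      else "no candidates")


def accounting_cascade(
    v1_subset: DatabaseVersion,
    v2: DatabaseVersion,
    search_identity_cutoff: float = DEFAULT_SEARCH_IDENTITY_CUTOFF,
    placement_identity_cutoff: float = DEFAULT_PLACEMENT_IDENTITY_CUTOFF,
) -> AccountingReport:
    """Stage-wise accounting of the members of ``v1_subset`` against ``v2``.

    ``v1_subset`` is the superfamily set under audit (e.g. the length-deviant
    superfamilies of the old version).  Superseded members count as search
    hits in the stage totals: a 100%-identity replacement is the strongest
    possible search hit, and keeping it inside ``n_search_hits`` preserves
    the telescoping identities against the per-member fate list.
    """
    fates = [f for f in assign_member_fates(
        v1_subset, v2,
        search_identity_cutoff=search_identity_cutoff,
        placement_identity_cutoff=placement_identity_cutoff)
        if f.fate != Fate.NEW]
    tally = {fate: 0 for fate in Fate}
    for f in fates:
        tally[f.fate] += 1
    n_total = len(fates)
    n_retained = tally[Fate.RETAINED]
    n_missing = n_total - n_retained
    n_outlier = tally[Fate.OUTLIER]
    n_queries = n_missing - n_outlier
    n_search_hits = tally[Fate.RESCUED_BY_SEARCH] + tally[Fate.SUPERSEDED]
    n_search_missing = n_queries - n_search_hits
    n_identity_rescued = tally[Fate.RESCUED_BY_IDENTITY]
    n_unaccounted = n_search_missing - n_identity_rescued
    return AccountingReport(
        n_v1_total=n_total, n_retained=n_retained, n_missing=n_missing,
        n_outlier=n_outlier, n_queries=n_queries,
        n_search_hits=n_search_hits, n_search_missing=n_search_missing,
        n_identity_rescued=n_identity_rescued, n_unaccounted=n_unaccounted,
        per_member=fates)
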