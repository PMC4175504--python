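"""Synthetic database-version generator.

The test substrate for the whole pipeline: paired database versions with
known ground truth.  Generated data emulate the entry rules of a curated
superfamily alignment database — at least three members per superfamily,
under 40% mutual sequence identity — and realise a controlled plan of

* per-superfamily length-variation labels (deviant / rigid / normal), with
  forced margins (rigid members within ~5% of the mean, deviant members at
  ~45%, normal members in the 12-25% band) so label recovery is exact
  rather than probabilistic;
* per-member fates across the version pair (retained, superseded, outlier,
  rescued-by-search, rescued-by-identity, unaccounted, new), realised with
  sequence-identity bands that trigger the intended fate rule unambiguously
  (bands are verified with the pipeline's own aligner and resampled when
  the background identity of unrelated sequences breaks them by chance);
* superfamily splits and merges by code reassignment.

Length differences are realised as C-terminal extensions over a common
aligned core, the simplest alignment-consistent indel model.  Sequences are
uniform over the 20 standard amino acids; coordinates are an idealised
helical curve plus isotropic Gaussian noise.  None of this mimics real
evolutionary sequence or structure processes — it provides exact,
controllable ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .align import global_align_identity, percent_identity
from .classification import DEFAULT_CONFIG, ClassificationConfig, Label
from .model import AMINO_ACIDS, DatabaseVersion, DomainMember, ScopClass, Superfamily
from .version_diff import EventKind, Fate, SplitMergeEvent

# fate -> (lo, hi) target band of percent identity between a dropped old
# member and its planted replacement in the new version; chosen to clear the
# 40% search-hit and 30% identity-placement rules with margin on both sides
DEFAULT_IDENTITY_TARGETS: dict[Fate, tuple[float, float]] = {
    Fate.RESCUED_BY_SEARCH: (45.0, 60.0),
    Fate.RESCUED_BY_IDENTITY: (33.0, 37.0),
}
SEARCH_CUTOFF = 40.0     # fate rule 4 threshold the bands must respect
PLACEMENT_CUTOFF = 30.0  # fate rule 5 threshold

_SS_PATTERN = "HHHHHHEEEEECCCC"  # repeating helix/strand/coil motif


class GenerationError(RuntimeError):
    """The requested synthetic scenario is infeasible or failed to converge."""


@dataclass
class GeneratorSpec:
    """Plan for one synthetic version pair."""

    n_superfamilies: dict[Label, int] = field(
        default_factory=lambda: {Label.DEVIANT: 2, Label.RIGID: 2,
                                 Label.NORMAL: 2})
    members_per_superfamily: tuple[int, int] = (4, 8)   # inclusive range
    superfamily_sizes: Optional[list[int]] = None       # exact sizes override
    mean_length: tuple[int, int] = (60, 120)            # residues
    fate_counts: Optional[dict[Fate, int]] = None       # None -> all retained
    split_plans: list[tuple[str, int]] = field(default_factory=list)
    merge_plans: list[tuple[list[str], str]] = field(default_factory=list)
    identity_targets: dict[Fate, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_IDENTITY_TARGETS))
    coord_noise_sigma: float = 0.0
    with_coords: bool = False
    with_ss: bool = False
    enforce_identity_cap: bool = True   # <40% mutual identity within superfamily
    band_safe_ratio: float = 1.45       # max length ratio for identity-banded fates
    seed: int = 0


@dataclass
class TruthRecord:
    """Ground truth emitted alongside a generated version pair."""

    labels: dict[str, Label]            # v1 superfamily code -> true label
    fates: dict[str, Fate]              # v1 member id -> true fate
    new_members: set[str]               # v2-only member ids (incl. superseding
    #                                     redeposits and planted homologs)
    events: list[SplitMergeEvent]

    def to_dict(self) -> dict:
        return {
            "labels": {c: l.value for c, l in sorted(self.labels.items())},
            "fates": {m: f.value for m, f in sorted(self.fates.items())},
            "new_members": sorted(self.new_members),
            "events": [e.to_dict() for e in self.events],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TruthRecord":
        return cls(
            labels={c: Label(l) for c, l in d["labels"].items()},
            fates={m: Fate(f) for m, f in d["fates"].items()},
            new_members=set(d["new_members"]),
            events=[SplitMergeEvent.from_dict(e) for e in d["events"]],
        )


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def mutate_to_identity(seq: str, target_identity: float,
                       rng: np.random.Generator,
                       tolerance: float = 5.0,
                       max_rounds: int = 60) -> str:
    """Substitution-only mutant whose measured global-alignment identity to
    ``seq`` is within ``tolerance`` points of ``target_identity``.

    The substitution count is adjusted against the *measured* identity —
    gapped alignments of highly diverged pairs recover spurious matches, so
    measurement, not arithmetic, decides.  Raises :class:`GenerationError`
    if the target is unreachable at this length.
    """
    if not 0 <= target_identity <= 100:
        raise ValueError(f"target identity {target_identity} out of [0, 100]")
    if target_identity == 100.0:
        return seq
    L = len(seq)
    k = int(round(L * (1.0 - target_identity / 100.0)))
    floor_hit = 0
    for _ in range(max_rounds):
        k = min(max(k, 0), L)
        mutant = _substitute(seq, k, rng)
        ident, _, _ = global_align_identity(seq, mutant)
        if abs(ident - target_identity) <= tolerance:
            return mutant
        step = max(1, int(abs(ident - target_identity) / 100.0 * L / 2))
        if ident > target_identity:
            if k == L:
                floor_hit += 1
                if floor_hit >= 5:
                    raise GenerationError(
                        f"cannot reach identity {target_identity}% at length "
                        f"{L}: floor is {ident:.1f}%")
            k += step
        else:
            if k == 0:
                raise GenerationError(
                    f"cannot reach identity {target_identity}% at length {L}")
            k -= step
    raise GenerationError(
        f"identity target {target_identity}% did not converge at length {L}")


def _substitute(seq: str, k: int, rng: np.random.Generator) -> str:
    positions = rng.choice(len(seq), size=k, replace=False)
    chars = list(seq)
    for pos in positions:
        others = [a for a in AMINO_ACIDS if a != chars[pos]]
        chars[pos] = others[int(rng.integers(len(others)))]
    return "".join(chars)


# ---------------------------------------------------------------------------
# superfamily generation

def _length_deviations(label: Label, n: int, config: ClassificationConfig,
                       rng: np.random.Generator) -> list[float]:
    """Fractional deviations from the mean, summing to ~0, with forced
    margins for the requested label."""
    if label == Label.RIGID:
        devs = []
        for _ in range(n // 2):
            u = rng.uniform(0.01, 0.03)
            devs += [u, -u]
        if n % 2:
            devs.append(0.0)
        return devs
    if label == Label.DEVIANT:
        if n >= config.sparse_max_members:
            k = math.ceil(config.majority_fraction * n)
        else:
            k = config.sparse_deviant_min
        if k >= n:
            raise GenerationError(
                f"deviant superfamily with n={n} needs {k} deviant members "
                f"plus at least one at the mean")
        devs = []
        for _ in range(k // 2):
            devs += [0.45, -0.45]
        rest = [0.0] * (n - k)
        if k % 2:
            devs.append(0.45)
            rest = [-0.45 / len(rest)] * len(rest)
        return devs + rest
    # normal: every member inside the 12-25% band, zero-sum, and with the
    # total length span kept under ~1.45x so identity-banded fates can still
    # be planted in the superfamily (see _assign_fate_tokens).  Odd counts
    # need a (+2a, -a, -a) triple whose top member already spans 1.24/0.88,
    # so the remaining pairs stay at the narrow end of the band.
    devs = []
    m = n
    if n % 2:
        devs += [0.24, -0.12, -0.12]
        m = n - 3
        lo_u, hi_u = 0.12, 0.125
    else:
        lo_u, hi_u = 0.13, 0.17
    for _ in range(m // 2):
        u = rng.uniform(lo_u, hi_u)
        devs += [u, -u]
    return devs


def _fresh_pdb_code(rng: np.random.Generator, used: set[str]) -> str:
    # synthetic 4-char codes (digit + three letters), unique per generation
    for _ in range(10000):
        code = (str(int(rng.integers(1, 10)))
                + "".join(rng.choice(list("abcdefghijklmnopqrstuvwxyz"),
                                     size=3)))
        if code not in used:
            used.add(code)
            return code
    raise GenerationError("pdb-code space exhausted")


def generate_coordinates(length: int, noise_sigma: float,
                         rng: np.random.Generator) -> np.ndarray:
    """Idealised alpha-helical C-alpha trace: 1.5 A rise and 100 degrees of
    turn per residue on a 2.3 A radius, plus isotropic Gaussian noise."""
    if length < 3:
        raise ValueError("trace needs length >= 3")
    if noise_sigma < 0:
        raise ValueError("noise sigma must be non-negative")
    t = np.arange(length, dtype=float)
    theta = np.deg2rad(100.0) * t
    coords = np.stack([2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * t],
                      axis=1)
    if noise_sigma > 0:
        coords = coords + rng.normal(0.0, noise_sigma, size=coords.shape)
    return coords


def _ss_string(length: int) -> str:
    reps = -(-length // len(_SS_PATTERN))
    return (_SS_PATTERN * reps)[:length]


def build_terminal_alignment(members: list[DomainMember]) -> dict[str, str]:
    """Gapped rows over a shared N-terminal core: every sequence written in
    full, padded with C-terminal gaps to the longest member."""
    if not members:
        return {}
    width = max(m.length for m in members)
    return {m.member_id: m.sequence + "-" * (width - m.length)
            for m in members}


def generate_superfamily(
    label: Label,
    n_members: int,
    mean_length: int,
    rng: np.random.Generator,
    code: str = "900000",
    scop_class: ScopClass = ScopClass.AB,
    config: ClassificationConfig = DEFAULT_CONFIG,
    with_coords: bool = False,
    with_ss: bool = False,
    coord_noise_sigma: float = 0.0,
    enforce_identity_cap: bool = True,
    identity_cap: float = 40.0,
    _used_codes: Optional[set[str]] = None,
) -> Superfamily:
    """A superfamily whose improved-scheme classification is ``label``.

    Lengths are the rounded mean plus forced-margin deviations; the result
    is re-classified as a hard post-condition.  Member sequences are mutually
    unrelated; with ``enforce_identity_cap`` any chance pair at or above the
    cap (40%, the database entry rule) is resampled.
    """
    if n_members < 3:
        raise GenerationError("superfamilies need >= 3 members")
    if mean_length < 40:
        raise GenerationError(
            "mean length < 40 leaves no margin for forced-label rounding")
    used = _used_codes if _used_codes is not None else set()
    devs = _length_deviations(label, n_members, config, rng)
    lengths = [max(3, int(round(mean_length * (1 + d)))) for d in devs]

    members: list[DomainMember] = []
    for L in lengths:
        pdb = _fresh_pdb_code(rng, used)
        seq = random_sequence(L, rng)
        if enforce_identity_cap:
            # the entry rule lives on the database's structure-based
            # alignment; rows here are terminally padded, so row identity is
            # a positional comparison over the shorter member
            for _ in range(50):
                if all(percent_identity(seq, m.sequence) < identity_cap
                       for m in members):
                    break
                seq = random_sequence(L, rng)
            else:
                raise GenerationError(
                    f"could not satisfy <{identity_cap}% identity in {code}")
        members.append(DomainMember(
            member_id=f"{pdb}_A", pdb_code=pdb, chain="A",
            superfamily_code=code, scop_class=scop_class, sequence=seq,
            ss_string=_ss_string(L) if with_ss else None,
            ca_trace=generate_coordinates(L, coord_noise_sigma, rng)
            if with_coords else None,
        ))
    sf = Superfamily(code=code, name=f"synthetic-{label.value}-{code}",
                     scop_class=scop_class, members=members,
                     alignment=build_terminal_alignment(members))

    from .classification import classify_improved
    from .length_variation import superfamily_profile
    got = classify_improved(superfamily_profile(sf), config).label
    if got != label:
        raise GenerationError(
            f"forced-margin generation produced {got.value}, wanted "
            f"{label.value} (n={n_members}, mean={mean_length})")
    return sf


# ---------------------------------------------------------------------------
# version pairs

def generate_version_pair(
    spec: GeneratorSpec,
) -> tuple[DatabaseVersion, DatabaseVersion, TruthRecord]:
    """Generate ``(v1, v2, truth)`` realising the spec's label and fate plan.

    ``spec.fate_counts`` must sum to the number of v1 members outside
    split/merge superfamilies (an optional ``Fate.NEW`` entry adds that many
    extra v2-only members); split/merge superfamilies retain all members
    under reassigned codes.  Members planted to be rescued sit in verified
    identity bands; fate recovery by the diff rules is exact when the
    identity cap is enforced (the cap guarantees that fixed old-version
    sequences can never fake a search hit).
    """
    rng = np.random.default_rng(spec.seed)
    config = DEFAULT_CONFIG
    used_codes: set[str] = set()

    # --- v1 -----------------------------------------------------------
    v1 = DatabaseVersion(label="v1")
    truth = TruthRecord(labels={}, fates={}, new_members=set(), events=[])
    code_counter = 900001
    plan_codes = {old for old, _ in spec.split_plans}
    for old_codes, _ in spec.merge_plans:
        plan_codes |= set(old_codes)
    plan_labels = [label for label in (Label.DEVIANT, Label.RIGID, Label.NORMAL)
                   for _ in range(spec.n_superfamilies.get(label, 0))]
    if spec.superfamily_sizes is not None and \
            len(spec.superfamily_sizes) != len(plan_labels):
        raise GenerationError("superfamily_sizes length != superfamily count")
    for i, label in enumerate(plan_labels):
        n = spec.superfamily_sizes[i] if spec.superfamily_sizes is not None \
            else int(rng.integers(spec.members_per_superfamily[0],
                                  spec.members_per_superfamily[1] + 1))
        mean = int(rng.integers(spec.mean_length[0],
                                spec.mean_length[1] + 1))
        code = str(code_counter)
        code_counter += 1
        sf = generate_superfamily(
            label, n, mean, rng, code=code, config=config,
            with_coords=spec.with_coords, with_ss=spec.with_ss,
            coord_noise_sigma=spec.coord_noise_sigma,
            enforce_identity_cap=spec.enforce_identity_cap,
            _used_codes=used_codes)
        v1.superfamilies[code] = sf
        truth.labels[code] = label
    missing_plan = plan_codes - set(v1.superfamilies)
    if missing_plan:
        raise GenerationError(
            f"split/merge plans name unknown codes {sorted(missing_plan)}")

    # --- fate plan ----------------------------------------------------
    free_by_sf = {code: list(v1.superfamilies[code].members)
                  for code in sorted(v1.superfamilies) if code not in plan_codes}
    free_members = [m for ms in free_by_sf.values() for m in ms]
    n_free = len(free_members)
    fate_counts = dict(spec.fate_counts) if spec.fate_counts else \
        {Fate.RETAINED: n_free}
    n_new_extra = fate_counts.pop(Fate.NEW, 0)
    if any(v < 0 for v in fate_counts.values()):
        raise GenerationError("negative fate counts")
    if sum(fate_counts.values()) != n_free:
        raise GenerationError(
            f"fate counts sum to {sum(fate_counts.values())}, but the plan "
            f"covers {n_free} members outside split/merge superfamilies")

    assignment = _assign_fate_tokens(free_by_sf, fate_counts, rng,
                                     spec.band_safe_ratio)
    truth.fates.update({m.member_id: assignment[m.member_id]
                        for m in free_members})

    # --- v2: splits and merges ----------------------------------------
    v2 = DatabaseVersion(label="v2")
    for old, n_desc in sorted(spec.split_plans):
        sf = v1.superfamilies[old]
        if sf.n_members < 3 * n_desc:
            raise GenerationError(
                f"split of {old} into {n_desc} needs >= {3 * n_desc} members")
        new_codes = [f"{old}{chr(ord('a') + i)}" for i in range(n_desc)]
        groups = np.array_split(np.arange(sf.n_members), n_desc)
        counts = {}
        for nc, idxs in zip(new_codes, groups):
            ms = [_clone(sf.members[i], superfamily_code=nc) for i in idxs]
            v2.superfamilies[nc] = Superfamily(
                code=nc, name=nc, scop_class=sf.scop_class, members=ms,
                alignment=build_terminal_alignment(ms))
            counts[(old, nc)] = len(idxs)
        for m in sf.members:
            truth.fates[m.member_id] = Fate.RETAINED
        truth.events.append(SplitMergeEvent(
            kind=EventKind.SPLIT, old_codes=[old], new_codes=new_codes,
            shared_member_counts=counts))
    for old_codes, new_code in spec.merge_plans:
        pooled: list[DomainMember] = []
        counts = {}
        for oc in sorted(old_codes):
            sf = v1.superfamilies[oc]
            pooled += [_clone(m, superfamily_code=new_code) for m in sf.members]
            counts[(oc, new_code)] = sf.n_members
            for m in sf.members:
                truth.fates[m.member_id] = Fate.RETAINED
        v2.superfamilies[new_code] = Superfamily(
            code=new_code, name=new_code,
            scop_class=v1.superfamilies[sorted(old_codes)[0]].scop_class,
            members=pooled, alignment=build_terminal_alignment(pooled))
        truth.events.append(SplitMergeEvent(
            kind=EventKind.MERGE, old_codes=sorted(old_codes),
            new_codes=[new_code], shared_member_counts=counts))

    # --- v2: fate realisation -----------------------------------------
    planted: dict[str, str] = {}  # homolog member_id -> source v1 member_id
    for code in sorted(free_by_sf):
        _realise_superfamily_v2(v1.superfamilies[code], assignment, v2,
                                spec, rng, truth, planted, used_codes)
    codes2 = sorted(free_by_sf)
    for i in range(n_new_extra):
        sf2 = v2.superfamilies[codes2[i % len(codes2)]]
        _add_new_member(sf2, rng, truth, spec, used_codes)

    _verify_identity_bands(v1, v2, truth, spec, rng, planted)
    return v1, v2, truth


CONSTRAINED_FATES = {Fate.RESCUED_BY_SEARCH, Fate.RESCUED_BY_IDENTITY,
                     Fate.UNACCOUNTED}
PRODUCING_FATES = {Fate.RETAINED, Fate.SUPERSEDED, Fate.RESCUED_BY_SEARCH,
                   Fate.RESCUED_BY_IDENTITY}


def _assign_fate_tokens(free_by_sf: dict[str, list[DomainMember]],
                        fate_counts: dict[Fate, int],
                        rng: np.random.Generator,
                        band_safe_ratio: float) -> dict[str, Fate]:
    """Distribute fate tokens over members.

    Identity-banded fates (search/identity rescue, unaccounted) only work
    where the fate rules' pairwise realignment identity separates cleanly
    from background, which fails between members of very different lengths:
    realigning a short against a long random sequence routinely scores above
    the 30-40% thresholds.  Such tokens are therefore confined to
    superfamilies whose member lengths span at most ``band_safe_ratio``
    (length-rigid and length-normal superfamilies qualify; length-deviant
    ones, spanning ~1.8x and above, do not).
    Each superfamily's first three members get a v2-producing fate first, so
    new-version superfamilies stay viable without filler where possible.
    """
    safe = {code: (max(m.length for m in ms) / min(m.length for m in ms)
                   <= band_safe_ratio)
            for code, ms in free_by_sf.items()}
    tokens: list[Fate] = []
    for fate in (Fate.RETAINED, Fate.SUPERSEDED, Fate.RESCUED_BY_SEARCH,
                 Fate.RESCUED_BY_IDENTITY, Fate.OUTLIER, Fate.UNACCOUNTED):
        tokens += [fate] * fate_counts.get(fate, 0)
    assignment: dict[str, Fate] = {}
    for code in sorted(free_by_sf):
        for m in free_by_sf[code][:3]:
            for i, tok in enumerate(tokens):
                if tok in PRODUCING_FATES and \
                        (safe[code] or tok not in CONSTRAINED_FATES):
                    assignment[m.member_id] = tokens.pop(i)
                    break
    unassigned = [m for code in sorted(free_by_sf)
                  for m in free_by_sf[code] if m.member_id not in assignment]
    constrained = [t for t in tokens if t in CONSTRAINED_FATES]
    unconstrained = [t for t in tokens if t not in CONSTRAINED_FATES]
    safe_pool = [m for m in unassigned if safe[m.superfamily_code]]
    if len(constrained) > len(safe_pool):
        raise GenerationError(
            f"{len(constrained)} identity-banded fates requested but only "
            f"{len(safe_pool)} members sit in length-homogeneous "
            f"superfamilies (length span <= {band_safe_ratio}x)")
    safe_pool = [safe_pool[i] for i in rng.permutation(len(safe_pool))]
    for m, tok in zip(safe_pool, constrained):
        assignment[m.member_id] = tok
    rest = [m for m in unassigned if m.member_id not in assignment]
    unconstrained = [unconstrained[i]
                     for i in rng.permutation(len(unconstrained))]
    for m, tok in zip(rest, unconstrained):
        assignment[m.member_id] = tok
    return assignment


def _clone(member: DomainMember, superfamily_code: Optional[str] = None,
           pdb_code: Optional[str] = None,
           member_id: Optional[str] = None) -> DomainMember:
    return DomainMember(
        member_id=member_id or member.member_id,
        pdb_code=pdb_code or member.pdb_code,
        chain=member.chain,
        superfamily_code=superfamily_code or member.superfamily_code,
        scop_class=member.scop_class,
        sequence=member.sequence,
        ss_string=member.ss_string,
        ca_trace=None if member.ca_trace is None else member.ca_trace.copy(),
        resolution=member.resolution,
    )


def _make_member(sequence: str, sf_code: str, scop_class: ScopClass,
                 spec: GeneratorSpec, rng: np.random.Generator,
                 used_codes: set[str]) -> DomainMember:
    pdb = _fresh_pdb_code(rng, used_codes)
    L = len(sequence)
    return DomainMember(
        member_id=f"{pdb}_A", pdb_code=pdb, chain="A",
        superfamily_code=sf_code, scop_class=scop_class, sequence=sequence,
        ss_string=_ss_string(L) if spec.with_ss else None,
        ca_trace=generate_coordinates(L, spec.coord_noise_sigma, rng)
        if spec.with_coords else None)


def _add_new_member(sf2: Superfamily, rng: np.random.Generator,
                    truth: TruthRecord, spec: GeneratorSpec,
                    used_codes: set[str]) -> DomainMember:
    L = (int(np.mean([m.length for m in sf2.members])) if sf2.members
         else int(rng.integers(spec.mean_length[0], spec.mean_length[1] + 1)))
    m = _make_member(random_sequence(max(10, L), rng), sf2.code,
                     sf2.scop_class, spec, rng, used_codes)
    sf2.members.append(m)
    sf2.alignment = build_terminal_alignment(sf2.members)
    truth.new_members.add(m.member_id)
    return m


def _realise_superfamily_v2(sf1: Superfamily, assignment: dict[str, Fate],
                            v2: DatabaseVersion, spec: GeneratorSpec,
                            rng: np.random.Generator, truth: TruthRecord,
                            planted: dict[str, str],
                            used_codes: set[str]) -> None:
    members2: list[DomainMember] = []
    for m in sf1.members:
        fate = assignment[m.member_id]
        if fate == Fate.RETAINED:
            members2.append(_clone(m))
        elif fate == Fate.SUPERSEDED:
            pdb = _fresh_pdb_code(rng, used_codes)
            redeposit = _clone(m, pdb_code=pdb, member_id=f"{pdb}_A")
            members2.append(redeposit)
            truth.new_members.add(redeposit.member_id)
        elif fate == Fate.OUTLIER:
            v2.outliers.add(m.member_id)
        elif fate in (Fate.RESCUED_BY_SEARCH, Fate.RESCUED_BY_IDENTITY):
            lo, hi = spec.identity_targets[fate]
            target = float(rng.uniform(lo, hi))
            homolog = _make_member(
                mutate_to_identity(m.sequence, target, rng, tolerance=2.0),
                sf1.code, m.scop_class, spec, rng, used_codes)
            members2.append(homolog)
            truth.new_members.add(homolog.member_id)
            planted[homolog.member_id] = m.member_id
        elif fate == Fate.UNACCOUNTED:
            pass  # dropped without trace
        else:
            raise GenerationError(f"unexpected planned fate {fate}")
    sf2 = Superfamily(code=sf1.code, name=sf1.name,
                      scop_class=sf1.scop_class, members=members2,
                      alignment={})
    v2.superfamilies[sf1.code] = sf2
    while sf2.n_members < 3:
        _add_new_member(sf2, rng, truth, spec, used_codes)
    sf2.alignment = build_terminal_alignment(sf2.members)


def _verify_identity_bands(v1: DatabaseVersion, v2: DatabaseVersion,
                           truth: TruthRecord, spec: GeneratorSpec,
                           rng: np.random.Generator,
                           planted: dict[str, str],
                           max_rounds: int = 60) -> None:
    """Fixpoint pass per superfamily: resample sequences until every planned
    fate triggers exactly its intended diff rule.

    Unaccounted members must sit at or below the placement cutoff against
    every candidate; identity-rescued members' best candidate must stay
    inside (30, 40); search-rescued members need a candidate at or above 40.
    Offending candidates that are themselves planted (homologs, filler
    members) are regenerated; offending fixed members cannot occur when the
    identity cap is enforced, and exhaustion raises.
    """
    v1_seq = {m.member_id: m for m in v1.iter_members()}
    homolog_of = {src: hom for hom, src in planted.items()}
    for code in sorted(v1.superfamilies):
        if code not in v2.superfamilies:
            continue
        sf1 = v1.superfamilies[code]
        sf2 = v2.superfamilies[code]
        for _ in range(max_rounds):
            violation = _find_violation(sf1, sf2, truth, spec)
            if violation is None:
                break
            member, kind, offender = violation
            if kind == "unaccounted_too_close":
                # the dropped member itself is free to resample
                member.sequence = random_sequence(member.length, rng)
                sf1.alignment = build_terminal_alignment(sf1.members)
            elif offender is not None and offender.member_id in planted:
                src = v1_seq[planted[offender.member_id]]
                fate = truth.fates[src.member_id]
                lo, hi = spec.identity_targets[fate]
                offender.sequence = mutate_to_identity(
                    src.sequence, float(rng.uniform(lo, hi)), rng,
                    tolerance=2.0)
                _refresh(offender, spec, rng)
                sf2.alignment = build_terminal_alignment(sf2.members)
            elif offender is not None and offender.member_id in truth.new_members \
                    and offender.sequence not in {m.sequence for m in sf1.members}:
                offender.sequence = random_sequence(offender.length, rng)
                _refresh(offender, spec, rng)
                sf2.alignment = build_terminal_alignment(sf2.members)
            elif member.member_id in homolog_of:
                # the offending candidate is a fixed member (retained or a
                # superseding redeposit of one): give the dropped source
                # member itself a fresh sequence and replant its homolog
                member.sequence = random_sequence(member.length, rng)
                _refresh(member, spec, rng)
                sf1.alignment = build_terminal_alignment(sf1.members)
                hom = sf2.member(homolog_of[member.member_id])
                lo, hi = spec.identity_targets[truth.fates[member.member_id]]
                hom.sequence = mutate_to_identity(
                    member.sequence, float(rng.uniform(lo, hi)), rng,
                    tolerance=2.0)
                _refresh(hom, spec, rng)
                sf2.alignment = build_terminal_alignment(sf2.members)
            else:
                raise GenerationError(
                    f"unresolvable identity-band violation in {code}: "
                    f"{kind} for {member.member_id}")
        else:
            raise GenerationError(
                f"identity bands did not converge in superfamily {code}")


def _refresh(member: DomainMember, spec: GeneratorSpec,
             rng: np.random.Generator) -> None:
    if spec.with_ss:
        member.ss_string = _ss_string(member.length)
    if spec.with_coords:
        member.ca_trace = generate_coordinates(
            member.length, spec.coord_noise_sigma, rng)


def _find_violation(sf1: Superfamily, sf2: Superfamily, truth: TruthRecord,
                    spec: GeneratorSpec):
    """First band violation in this superfamily, or None."""
    for m in sf1.members:
        fate = truth.fates.get(m.member_id)
        if fate not in (Fate.UNACCOUNTED, Fate.RESCUED_BY_IDENTITY,
                        Fate.RESCUED_BY_SEARCH):
            continue
        best_c, best_i = None, -1.0
        for c in sf2.members:
            ident = global_align_identity(m.sequence, c.sequence)[0]
            if ident > best_i:
                best_c, best_i = c, ident
        if fate == Fate.UNACCOUNTED and best_i > PLACEMENT_CUTOFF:
            return m, "unaccounted_too_close", best_c
        if fate == Fate.RESCUED_BY_IDENTITY and not \
                (PLACEMENT_CUTOFF < best_i < SEARCH_CUTOFF):
            return m, "identity_band", best_c
        if fate == Fate.RESCUED_BY_SEARCH and best_i < SEARCH_CUTOFF:
            return m, "search_band", best_c
    return None


# ---------------------------------------------------------------------------
# named fixtures

def cascade_fixture(seed: int = 0) -> tuple[DatabaseVersion, DatabaseVersion]:
    """Deterministic version pair realising the printed accounting-cascade
    composition over 64 superfamilies: 809 old members, of which 333 are
    retained, 162 filtered as outliers, 201 recovered as search hits, 80
    placed back by identity and 33 left unaccounted.

    The stage counts are construction invariants: any seed reproduces them.
    Superfamilies are length-homogeneous (rigid) so that every planted
    rescue band separates cleanly from the realignment identity background;
    the stage arithmetic is independent of the length-variation labels.
    """
    # 64 superfamilies holding 809 members: 41 of 13 members, 23 of 12
    spec = GeneratorSpec(
        n_superfamilies={Label.RIGID: 64},
        superfamily_sizes=[13] * 41 + [12] * 23,
        mean_length=(48, 64),
        fate_counts={Fate.RETAINED: 333, Fate.OUTLIER: 162,
                     Fate.RESCUED_BY_SEARCH: 201,
                     Fate.RESCUED_BY_IDENTITY: 80, Fate.UNACCOUNTED: 33},
        seed=seed,
    )
    v1, v2, _ = generate_version_pair(spec)
    return v1, v2


SPLIT_SCENARIOS = ("viral_4way", "ovomucoid_2way", "etfp_merge")


def split_fixture(scenario: str, seed: int = 0,
                  ) -> tuple[DatabaseVersion, DatabaseVersion]:
    """Minimal version pairs realising the documented split/merge case
    studies, labelled with their SCOP superfamily codes:

    * ``viral_4way`` — viral coat and capsid proteins (49611) split into
      88633, 88645, 88648 and 88650;
    * ``ovomucoid_2way`` — ovomucoid/PC-1-like inhibitors (57467) split
      into 100895 and 100897;
    * ``etfp_merge`` — ETFP adenine-nucleotide-binding (52431) merged into
      adenine-nucleotide alpha-hydrolase-like (52402).
    """
    rng = np.random.default_rng(seed)
    used: set[str] = set()

    def make(code: str, n: int, cls: ScopClass = ScopClass.B) -> Superfamily:
        return generate_superfamily(
            Label.NORMAL, n, 80, rng, code=code, scop_class=cls,
            enforce_identity_cap=False, _used_codes=used)

    if scenario == "viral_4way":
        old = make("49611", 12)
        v1 = DatabaseVersion(label="v1", superfamilies={"49611": old})
        v2 = DatabaseVersion(label="v2")
        new_codes = ["88633", "88645", "88648", "88650"]
        groups = np.array_split(np.arange(old.n_members), 4)
        for nc, idxs in zip(new_codes, groups):
            ms = [_clone(old.members[i], superfamily_code=nc) for i in idxs]
            v2.superfamilies[nc] = Superfamily(
                code=nc, name=nc, scop_class=old.scop_class, members=ms,
                alignment=build_terminal_alignment(ms))
        return v1, v2
    if scenario == "ovomucoid_2way":
        old = make("57467", 6)
        v1 = DatabaseVersion(label="v1", superfamilies={"57467": old})
        v2 = DatabaseVersion(label="v2")
        for nc, idxs in zip(["100895", "100897"],
                            np.array_split(np.arange(old.n_members), 2)):
            ms = [_clone(old.members[i], superfamily_code=nc) for i in idxs]
            v2.superfamilies[nc] = Superfamily(
                code=nc, name=nc, scop_class=old.scop_class, members=ms,
                alignment=build_terminal_alignment(ms))
        return v1, v2
    if scenario == "etfp_merge":
        etfp = make("52431", 3, ScopClass.AB)
        hydrolase = make("52402", 3, ScopClass.AB)
        v1 = DatabaseVersion(label="v1", superfamilies={
            "52431": etfp, "52402": hydrolase})
        pooled = [_clone(m, superfamily_code="52402")
                  for m in etfp.members + hydrolase.members]
        v2 = DatabaseVersion(label="v2", superfamilies={
            "52402": Superfamily(code="52402", name="52402",
                                 scop_class=ScopClass.AB, members=pooled,
                                 alignment=build_terminal_alignment(pooled))})
        return v1, v2
    raise ValueError(f"unknown scenario {scenario!r}; "
                     f"choose from {SPLIT_SCENARIOS}")
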