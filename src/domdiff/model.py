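"""Core data model: domain members, superfamilies, database versions.

The unit of analysis is the SCOP-style protein domain superfamily: a set of
domains with similar tertiary structure but low mutual sequence identity,
distributed together with a gapped structure-based multiple sequence
alignment.  A database version is a labelled collection of superfamilies
keyed by superfamily code (SCOP sunid), plus a list of members flagged as
structural-alignment outliers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

GAP = "-"

SS_STATES = frozenset("HEC")


class ScopClass(str, Enum):
    """The four major SCOP structural classes."""

    A = "a"        # all-alpha
    B = "b"        # all-beta
    AB = "a/b"     # alternating alpha/beta
    A_PLUS_B = "a+b"

    @classmethod
    def parse(cls, text: str) -> "ScopClass":
        try:
            return cls(text.strip())
        except ValueError:
            raise ValidationError(f"unknown SCOP class label: {text!r}") from None


class ValidationError(ValueError):
    """A record violates a model invariant."""


class FormatError(ValueError):
    """An input file does not conform to its expected on-disk format."""


@dataclass
class DomainMember:
    """One protein domain entry.

    ``member_id`` follows the convention lowercase PDB code + ``_`` + chain,
    with an optional opaque region suffix (e.g. ``"1jce_A"``).
    """

    member_id: str
    pdb_code: str
    chain: str
    superfamily_code: str
    scop_class: ScopClass
    sequence: str
    ss_string: Optional[str] = None
    ca_trace: Optional[np.ndarray] = None  # (length, 3) Cartesian, Angstrom
    resolution: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"{self.member_id}: empty sequence")
        bad = set(self.sequence) - _AA_SET
        if bad:
            raise ValidationError(
                f"{self.member_id}: non-amino-acid characters {sorted(bad)!r}"
            )
        if isinstance(self.scop_class, str):
            self.scop_class = ScopClass.parse(self.scop_class)
        if self.ss_string is not None:
            if len(self.ss_string) != self.length:
                raise ValidationError(
                    f"{self.member_id}: ss_string length {len(self.ss_string)} "
                    f"!= sequence length {self.length}"
                )
            bad_ss = set(self.ss_string) - SS_STATES
            if bad_ss:
                raise ValidationError(
                    f"{self.member_id}: secondary-structure states outside "
                    f"H/E/C: {sorted(bad_ss)!r}"
                )
        if self.ca_trace is not None:
            self.ca_trace = np.asarray(self.ca_trace, dtype=float)
            if self.ca_trace.shape != (self.length, 3):
                raise ValidationError(
                    f"{self.member_id}: ca_trace shape {self.ca_trace.shape} "
                    f"!= ({self.length}, 3)"
                )

    @property
    def length(self) -> int:
        """Domain length in residues."""
        return len(self.sequence)


def degap(aligned: str) -> str:
    """Remove gap characters from an aligned string."""
    return aligned.replace(GAP, "")


@dataclass
class Superfamily:
    """A coded set of domain members plus their gapped multiple alignment.

    Invariants (checked by :meth:`validate`): all aligned strings share one
    length; de-gapping a member's aligned string reproduces its sequence;
    in database mode the superfamily has at least three members.
    """

    code: str
    name: str
    scop_class: ScopClass
    members: list[DomainMember] = field(default_factory=list)
    alignment: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if isinstance(self.scop_class, str):
            self.scop_class = ScopClass.parse(self.scop_class)

    @property
    def member_ids(self) -> list[str]:
        return [m.member_id for m in self.members]

    @property
    def n_members(self) -> int:
        return len(self.members)

    def member(self, member_id: str) -> DomainMember:
        for m in self.members:
            if m.member_id == member_id:
                return m
        raise KeyError(member_id)

    @property
    def alignment_length(self) -> int:
        if not self.alignment:
            return 0
        return len(next(iter(self.alignment.values())))

    def validate(self, min_members: int = 3) -> None:
        if self.n_members < min_members:
            raise ValidationError(
                f"superfamily {self.code}: {self.n_members} members "
                f"(minimum {min_members})"
            )
        ids = self.member_ids
        if len(set(ids)) != len(ids):
            raise ValidationError(f"superfamily {self.code}: duplicate member ids")
        if self.alignment:
            lengths = {len(s) for s in self.alignment.values()}
            if len(lengths) > 1:
                raise ValidationError(
                    f"superfamily {self.code}: ragged alignment lengths {lengths}"
                )
            for m in self.members:
                if m.member_id not in self.alignment:
                    raise ValidationError(
                        f"superfamily {self.code}: member {m.member_id} "
                        "missing from alignment"
                    )
                if degap(self.alignment[m.member_id]) != m.sequence:
                    raise ValidationError(
                        f"superfamily {self.code}: de-gapped alignment row of "
                        f"{m.member_id} does not match its sequence"
                    )


@dataclass
class DatabaseVersion:
    """A labelled database release: superfamilies keyed by code, plus the
    set of member ids excluded from alignments as structural outliers."""

    label: str
    superfamilies: dict[str, Superfamily] = field(default_factory=dict)
    outliers: set[str] = field(default_factory=set)

    @property
    def n_superfamilies(self) -> int:
        return len(self.superfamilies)

    @property
    def n_members(self) -> int:
        return sum(sf.n_members for sf in self.superfamilies.values())

    def iter_members(self):
        for code in sorted(self.superfamilies):
            for m in self.superfamilies[code].members:
                yield m

    def member_ids(self) -> set[str]:
        return {m.member_id for m in self.iter_members()}

    def superfamily_of(self, member_id: str) -> Optional[str]:
        for code, sf in self.superfamilies.items():
            if member_id in sf.member_ids:
                return code
        return None

    def validate(self, min_members: int = 3, redundancy_check: bool = False,
                 identity_cutoff: float = 40.0) -> None:
        """Check version-level invariants.

        With ``redundancy_check`` the <40% mutual-identity entry rule is
        enforced within every superfamily (quadratic in member count; off by
        default).
        """
        seen: set[str] = set()
        for sf in self.superfamilies.values():
            sf.validate(min_members=min_members)
            for mid in sf.member_ids:
                if mid in seen:
                    raise ValidationError(f"duplicate member id across version: {mid}")
                seen.add(mid)
        for out in self.outliers:
            if out in seen:
                raise ValidationError(
                    f"outlier {out} also present in an alignment"
                )
        if redundancy_check:
            # the entry rule is defined on the database's own structure-based
            # alignment: positional identity between aligned rows, not a
            # pairwise realignment (which inflates identity for members of
            # very different lengths)
            from .align import global_align_identity, percent_identity

            for sf in self.superfamilies.values():
                ms = sf.members
                for i in range(len(ms)):
                    for j in range(i + 1, len(ms)):
                        a, b = ms[i], ms[j]
                        if sf.alignment:
                            ident = percent_identity(
                                sf.alignment[a.member_id],
                                sf.alignment[b.member_id])
                        else:
                            ident, _, _ = global_align_identity(
                                a.sequence, b.sequence)
                        if ident >= identity_cutoff:
                            raise ValidationError(
                                f"superfamily {sf.code}: members "
                                f"{a.member_id}/{b.member_id} at "
                                f"{ident:.1f}% identity (cutoff "
                                f"{identity_cutoff}%)"
                            )
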