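"""Shared fixtures: hand-built superfamilies and version pairs."""

from __future__ import annotations

import numpy as np
import pytest

from domdiff.model import DatabaseVersion, DomainMember, ScopClass, Superfamily
from domdiff.length_variation import LengthStats
from domdiff.synthetic import build_terminal_alignment, random_sequence


def make_superfamily(lengths, code="53067", scop_class=ScopClass.AB,
                     seed=0, name=None) -> Superfamily:
    """Superfamily with prescribed member lengths and random sequences."""
    rng = np.random.default_rng(seed)
    members = []
    for i, L in enumerate(lengths):
        pdb = f"{i + 1}xx{chr(ord('a') + i % 26)}"
        members.append(DomainMember(
            member_id=f"{pdb}_A", pdb_code=pdb, chain="A",
            superfamily_code=code, scop_class=scop_class,
            sequence=random_sequence(L, rng)))
    return Superfamily(code=code, name=name or f"sf-{code}",
                       scop_class=scop_class, members=members,
                       alignment=build_terminal_alignment(members))


def make_profile(variations, code="53067", mean_length=100.0) -> LengthStats:
    """LengthStats straight from per-member variation percentages."""
    per = {f"m{i}_A": float(v) for i, v in enumerate(variations)}
    values = np.array(list(per.values()))
    return LengthStats(
        superfamily_code=code, mean_length=mean_length,
        per_member_variation=per,
        sd_variation=float(np.std(values)),
        max_abs_variation=float(np.max(np.abs(values))),
        n_members=len(per))


def single_sf_version(sf, label="v1") -> DatabaseVersion:
    return DatabaseVersion(label=label, superfamilies={sf.code: sf})


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def trio_superfamily():
    """Three members, lengths 90/100/110."""
    return make_superfamily([90, 100, 110])
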