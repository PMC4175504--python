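"""Superfamily classification by extent of length variation.

Two schemes label each superfamily as length-deviant, length-rigid or
length-normal:

* the original scheme — a superfamily is deviant when at least 75% of its
  members vary by more than 30% from the mean domain length, rigid when at
  least 75% vary by less than 10%, otherwise normal;
* the improved scheme — densely populated superfamilies keep the 75%
  majority rule, while sparsely populated ones (fewer than 10 members) use
  the relaxed "more-than-one" strategy: at least ``sparse_deviant_min``
  deviant members make the whole superfamily deviant, and otherwise the
  larger of the deviant and rigid member counts wins, ties going to a
  configured fallback label (normal by default, flagged ``tie_broken``
  where a curator would have intervened by hand).

Thresholds compare |variation|; the signed values remain available on the
:class:`~domdiff.length_variation.LengthStats` profile for reporting.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum

from .length_variation import LengthStats, superfamily_profile
from .model import DatabaseVersion


class Label(str, Enum):
    DEVIANT = "deviant"
    RIGID = "rigid"
    NORMAL = "normal"


class Scheme(str, Enum):
    OLD = "old"
    IMPROVED = "improved"


@dataclass
class ClassificationConfig:
    deviant_cutoff: float = 30.0      # |variation| above this is a deviant member
    rigid_cutoff: float = 10.0        # |variation| below this is a rigid member
    majority_fraction: float = 0.75   # dense-branch majority
    sparse_max_members: int = 10      # sparse iff n_members < this
    sparse_deviant_min: int = 2       # "more-than-one" deviant-member trigger
    tie_label: Label = Label.NORMAL   # sparse-branch tie fallback

    def __post_init__(self) -> None:
        if not 0 < self.rigid_cutoff < self.deviant_cutoff:
            raise ValueError("need 0 < rigid_cutoff < deviant_cutoff")
        if not 0 < self.majority_fraction <= 1:
            raise ValueError("majority_fraction must be in (0, 1]")


DEFAULT_CONFIG = ClassificationConfig()


@dataclass
class ClassificationResult:
    superfamily_code: str
    label: Label
    scheme: Scheme
    fraction_deviant_members: float
    fraction_rigid_members: float
    n_members: int
    tie_broken: bool = False

    def to_dict(self) -> dict:
        return {
            "superfamily_code": self.superfamily_code,
            "label": self.label.value,
            "scheme": self.scheme.value,
            "fraction_deviant_members": self.fraction_deviant_members,
            "fraction_rigid_members": self.fraction_rigid_members,
            "n_members": self.n_members,
            "tie_broken": self.tie_broken,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ClassificationResult":
        d = dict(d)
        d["label"] = Label(d["label"])
        d["scheme"] = Scheme(d["scheme"])
        return cls(**d)


def _member_counts(profile: LengthStats,
                   config: ClassificationConfig) -> tuple[int, int]:
    values = profile.per_member_variation.values()
    n_dev = sum(1 for v in values if abs(v) > config.deviant_cutoff)
    n_rig = sum(1 for v in values if abs(v) < config.rigid_cutoff)
    return n_dev, n_rig


def classify_old(profile: LengthStats,
                 config: ClassificationConfig = DEFAULT_CONFIG) -> ClassificationResult:
    """75% majority rule regardless of superfamily size."""
    n = profile.n_members
    n_dev, n_rig = _member_counts(profile, config)
    if n_dev / n >= config.majority_fraction:
        label = Label.DEVIANT
    elif n_rig / n >= config.majority_fraction:
        label = Label.RIGID
    else:
        label = Label.NORMAL
    return ClassificationResult(
        superfamily_code=profile.superfamily_code,
        label=label, scheme=Scheme.OLD,
        fraction_deviant_members=n_dev / n,
        fraction_rigid_members=n_rig / n,
        n_members=n,
    )


def classify_improved(profile: LengthStats,
                      config: ClassificationConfig = DEFAULT_CONFIG) -> ClassificationResult:
    """Size-aware scheme: dense superfamilies use the 75% majority rule,
    sparse ones the relaxed more-than-one / member-majority rule."""
    n = profile.n_members
    n_dev, n_rig = _member_counts(profile, config)
    tie_broken = False
    if n >= config.sparse_max_members:  # dense branch
        if n_dev / n >= config.majority_fraction:
            label = Label.DEVIANT
        elif n_rig / n >= config.majority_fraction:
            label = Label.RIGID
        else:
            label = Label.NORMAL
    else:  # sparse branch
        if n_dev >= config.sparse_deviant_min:
            label = Label.DEVIANT
        elif n_dev > n_rig:
            label = Label.DEVIANT
        elif n_rig > n_dev:
            label = Label.RIGID
        else:
            label = config.tie_label
            tie_broken = True
    return ClassificationResult(
        superfamily_code=profile.superfamily_code,
        label=label, scheme=Scheme.IMPROVED,
        fraction_deviant_members=n_dev / n,
        fraction_rigid_members=n_rig / n,
        n_members=n, tie_broken=tie_broken,
    )


def classify_database(
    db: DatabaseVersion,
    scheme: Scheme = Scheme.IMPROVED,
    config: ClassificationConfig = DEFAULT_CONFIG,
) -> tuple[list[ClassificationResult], Counter]:
    """Classify every superfamily; returns results (sorted by code) and the
    label tally.  Counts always partition the superfamily set."""
    classify = classify_improved if scheme == Scheme.IMPROVED else classify_old
    results = [classify(superfamily_profile(db.superfamilies[code]), config)
               for code in sorted(db.superfamilies)]
    counts = Counter(r.label for r in results)
    return results, counts
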