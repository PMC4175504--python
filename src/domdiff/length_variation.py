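"""Domain-length variation statistics.

The central quantity is the extent of length variation of a member relative
to its superfamily:

    variation% = 100 * (domain_length - mean_length) / mean_length

where mean_length is the arithmetic mean of member lengths in the
superfamily.  Signed per-member variations, their population standard
deviation, and the maximum absolute variation summarise a superfamily;
binned distributions (5%-wide half-open bins with an open-ended >45% tail)
summarise a database version, overall or per SCOP structural class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Union

import numpy as np

from .model import DatabaseVersion, ScopClass, Superfamily, ValidationError


@dataclass
class LengthStats:
    """Per-superfamily length-variation profile."""

    superfamily_code: str
    mean_length: float
    per_member_variation: dict[str, float]  # member_id -> signed percent
    sd_variation: float                     # population SD of the signed %
    max_abs_variation: float
    n_members: int

    def to_dict(self) -> dict:
        return {
            "superfamily_code": self.superfamily_code,
            "mean_length": self.mean_length,
            "per_member_variation": dict(sorted(self.per_member_variation.items())),
            "sd_variation": self.sd_variation,
            "max_abs_variation": self.max_abs_variation,
            "n_members": self.n_members,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LengthStats":
        return cls(**d)


@dataclass
class VariationHistogram:
    """Half-open percentage bins [lo, hi), terminal open bin [overflow_min, inf)."""

    bin_width: float = 5.0
    counts: dict[tuple[float, float], int] = field(default_factory=dict)
    overflow_min: float = 45.0

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def add(self, value: float) -> None:
        if value >= self.overflow_min:
            key = (self.overflow_min, float("inf"))
        else:
            lo = np.floor(value / self.bin_width) * self.bin_width
            key = (float(lo), float(lo + self.bin_width))
        self.counts[key] = self.counts.get(key, 0) + 1

    def sorted_bins(self) -> list[tuple[float, float, int]]:
        return [(lo, hi, c) for (lo, hi), c in sorted(self.counts.items())]

    def to_dict(self) -> dict:
        return {
            "bin_width": self.bin_width,
            "overflow_min": (self.overflow_min
                             if np.isfinite(self.overflow_min) else None),
            "bins": [[lo, hi if np.isfinite(hi) else None, c]
                     for lo, hi, c in self.sorted_bins()],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VariationHistogram":
        counts = {
            (float(lo), float("inf") if hi is None else float(hi)): int(c)
            for lo, hi, c in d["bins"]
        }
        overflow = d["overflow_min"]
        return cls(bin_width=d["bin_width"], counts=counts,
                   overflow_min=float("inf") if overflow is None else overflow)


def mean_domain_length(superfamily: Superfamily) -> float:
    """Arithmetic mean of member lengths (residues)."""
    if superfamily.n_members == 0:
        raise ValueError(f"superfamily {superfamily.code}: no members")
    return float(np.mean([m.length for m in superfamily.members]))


def variation_percent(domain_length: int, mean_length: float) -> float:
    """Signed percent deviation of one domain's length from the mean."""
    if mean_length <= 0:
        raise ValueError(f"mean length must be positive, got {mean_length}")
    return 100.0 * (domain_length - mean_length) / mean_length


def superfamily_profile(superfamily: Superfamily) -> LengthStats:
    """Mean length, signed per-member variations, their population SD and
    the maximum absolute variation."""
    mean = mean_domain_length(superfamily)
    var = {m.member_id: variation_percent(m.length, mean)
           for m in superfamily.members}
    values = np.array(list(var.values()))
    return LengthStats(
        superfamily_code=superfamily.code,
        mean_length=mean,
        per_member_variation=var,
        sd_variation=float(np.std(values)),  # population SD: ddof=0
        max_abs_variation=float(np.max(np.abs(values))),
        n_members=len(var),
    )


SUPERFAMILY_STATISTICS = ("max_abs", "mean_abs", "sd")


def bin_variations(
    stats: Union[LengthStats, Iterable[LengthStats]],
    by: Literal["member", "superfamily"] = "member",
    use_absolute: bool = True,
    bin_width: float = 5.0,
    overflow_min: float = 45.0,
    superfamily_statistic: str = "max_abs",
) -> VariationHistogram:
    """Bin length variations per member or per superfamily.

    ``by="member"`` bins every member's variation; ``by="superfamily"`` bins
    one value per superfamily — by default its maximum absolute variation
    (``superfamily_statistic`` may instead be ``"mean_abs"`` or ``"sd"``).
    With ``use_absolute`` (default) magnitudes are binned, matching the
    non-negative bins of the published distributions; signed binning keeps
    negative bins and an open tail on both sides.
    """
    if isinstance(stats, LengthStats):
        stats = [stats]
    hist = VariationHistogram(bin_width=bin_width, overflow_min=overflow_min)
    for st in stats:
        if by == "member":
            values = list(st.per_member_variation.values())
        elif by == "superfamily":
            if superfamily_statistic == "max_abs":
                values = [st.max_abs_variation]
            elif superfamily_statistic == "mean_abs":
                values = [float(np.mean(np.abs(
                    list(st.per_member_variation.values()))))]
            elif superfamily_statistic == "sd":
                values = [st.sd_variation]
            else:
                raise ValueError(
                    f"unknown superfamily statistic {superfamily_statistic!r}")
        else:
            raise ValueError(f"unknown binning mode {by!r}")
        for v in values:
            hist.add(abs(v) if use_absolute else v)
    return hist


def class_distribution(db: DatabaseVersion, **bin_kwargs) -> dict[ScopClass, VariationHistogram]:
    """Per-SCOP-class histograms of member length variations.

    Classes with no members are absent from the map (not zero-filled).
    Raises :class:`ValidationError` on an unknown class label.
    """
    use_absolute = bin_kwargs.pop("use_absolute", True)
    hists: dict[ScopClass, VariationHistogram] = {}
    for code in sorted(db.superfamilies):
        sf = db.superfamilies[code]
        profile = superfamily_profile(sf)
        for m in sf.members:
            if not isinstance(m.scop_class, ScopClass):
                raise ValidationError(
                    f"{m.member_id}: unknown class label {m.scop_class!r}")
            v = profile.per_member_variation[m.member_id]
            hist = hists.setdefault(
                m.scop_class, VariationHistogram(**bin_kwargs))
            hist.add(abs(v) if use_absolute else v)
    return hists
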