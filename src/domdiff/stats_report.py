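"""Version-level summaries and cross-version comparisons.

Summaries tabulate every superfamily (member count, mean domain length,
spread of length variation, labels under both classification schemes);
comparisons histogram the per-superfamily member counts and variation
spreads of two versions side by side and test the shift of each metric with
Welch's unequal-variance two-sided t-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .classification import (ClassificationConfig, DEFAULT_CONFIG,
                             classify_improved, classify_old)
from .length_variation import (VariationHistogram, bin_variations,
                               superfamily_profile)
from .model import DatabaseVersion


@dataclass
class VersionSummary:
    label: str
    n_superfamilies: int
    n_members: int
    per_superfamily: pd.DataFrame  # code, n_members, mean_length, sd_variation,
    #                                max_abs_variation, label_old, label_improved


@dataclass
class TestResult:
    t: float
    df: float
    p: float

    def to_dict(self) -> dict:
        return {"t": self.t, "df": self.df, "p": self.p}


@dataclass
class ComparisonReport:
    labels: tuple[str, str]
    membership_histograms: dict[str, VariationHistogram]
    variation_histograms: dict[str, VariationHistogram]
    sd_histograms: dict[str, VariationHistogram]
    tests: dict[str, TestResult] = field(default_factory=dict)
    omitted: dict[str, str] = field(default_factory=dict)  # metric -> reason


def welch_t_test(sample_a, sample_b) -> TestResult:
    """Welch's two-sample t-test (unequal variances), two-sided.

    The degrees of freedom follow Welch-Satterthwaite.  Two constant,
    identical samples have no resolvable difference scale and raise.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    if np.var(a) == 0 and np.var(b) == 0:
        raise ValueError("both samples have zero variance")
    res = sps.ttest_ind(a, b, equal_var=False)
    t = float(res.statistic)
    p = float(res.pvalue)
    df = float(res.df)
    if a.mean() == b.mean():  # exact null: identical means
        t, p = 0.0, 1.0
    return TestResult(t=t, df=df, p=p)


def summarize_version(
    db: DatabaseVersion,
    config: ClassificationConfig = DEFAULT_CONFIG,
) -> VersionSummary:
    """One table row per superfamily, with totals and both labels."""
    rows = []
    for code in sorted(db.superfamilies):
        sf = db.superfamilies[code]
        profile = superfamily_profile(sf)
        rows.append({
            "code": code,
            "n_members": sf.n_members,
            "mean_length": profile.mean_length,
            "sd_variation": profile.sd_variation,
            "max_abs_variation": profile.max_abs_variation,
            "label_old": classify_old(profile, config).label.value,
            "label_improved": classify_improved(profile, config).label.value,
        })
    table = pd.DataFrame(rows, columns=[
        "code", "n_members", "mean_length", "sd_variation",
        "max_abs_variation", "label_old", "label_improved"])
    return VersionSummary(
        label=db.label,
        n_superfamilies=db.n_superfamilies,
        n_members=int(table["n_members"].sum()) if len(table) else 0,
        per_superfamily=table,
    )


def _membership_histogram(summary: VersionSummary,
                          bin_width: float = 5.0) -> VariationHistogram:
    """Superfamily counts binned by member count (bins of 5 members)."""
    hist = VariationHistogram(bin_width=bin_width, overflow_min=float("inf"))
    for n in summary.per_superfamily["n_members"]:
        hist.add(float(n))
    return hist


def compare_versions(
    dbA: DatabaseVersion,
    dbB: DatabaseVersion,
    config: ClassificationConfig = DEFAULT_CONFIG,
    rmsds_a: Optional[list[float]] = None,
    rmsds_b: Optional[list[float]] = None,
) -> ComparisonReport:
    """Histograms plus Welch tests on per-superfamily member counts, mean
    domain lengths and (when supplied) alignment RMSDs.

    Metrics with insufficient or degenerate data are omitted with a reason
    rather than raising.
    """
    sa = summarize_version(dbA, config)
    sb = summarize_version(dbB, config)
    profiles = {
        dbA.label: [superfamily_profile(sf)
                    for sf in dbA.superfamilies.values()],
        dbB.label: [superfamily_profile(sf)
                    for sf in dbB.superfamilies.values()],
    }
    report = ComparisonReport(
        labels=(dbA.label, dbB.label),
        membership_histograms={dbA.label: _membership_histogram(sa),
                               dbB.label: _membership_histogram(sb)},
        variation_histograms={lbl: bin_variations(ps, by="member")
                              for lbl, ps in profiles.items()},
        sd_histograms={lbl: bin_variations(ps, by="superfamily",
                                           superfamily_statistic="sd")
                       for lbl, ps in profiles.items()},
    )
    metrics = {
        "member_count": (sa.per_superfamily["n_members"].tolist(),
                         sb.per_superfamily["n_members"].tolist()),
        "mean_length": (sa.per_superfamily["mean_length"].tolist(),
                        sb.per_superfamily["mean_length"].tolist()),
    }
    if rmsds_a is not None or rmsds_b is not None:
        metrics["rmsd"] = (list(rmsds_a or []), list(rmsds_b or []))
    else:
        report.omitted["rmsd"] = "omitted: no coordinates"
    for name, (xs, ys) in metrics.items():
        try:
            report.tests[name] = welch_t_test(xs, ys)
        except ValueError as exc:
            report.omitted[name] = f"omitted: {exc}"
    return report
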