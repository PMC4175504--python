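#!/usr/bin/env python
"""Database-level comparison of the two synthetic versions.

Per-superfamily member-count, variation and spread histograms side by
side, plus Welch t-tests on member counts and mean domain lengths —
the whole-database summary view of the update.  Writes
results/comparison.json.
"""

from pathlib import Path

from domdiff.io import read_version_dir, write_json_report
from domdiff.stats_report import compare_versions, summarize_version

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    v1 = read_version_dir(ROOT / "synthetic" / "v1")
    v2 = read_version_dir(ROOT / "synthetic" / "v2")
    for db in (v1, v2):
        s = summarize_version(db)
        print(f"{s.label}: {s.n_superfamilies} superfamilies, "
              f"{s.n_members} members, median superfamily size "
              f"{s.per_superfamily['n_members'].median():.0f}")
    report = compare_versions(v1, v2)
    for name, res in report.tests.items():
        print(f"  {name}: t={res.t:+.3f} df={res.df:.1f} p={res.p:.4f}")
    for name, reason in report.omitted.items():
        print(f"  {name}: {reason}")
    payload = {
        "labels": list(report.labels),
        "tests": {k: v.to_dict() for k, v in report.tests.items()},
        "omitted": report.omitted,
        "membership_histograms": {k: v.to_dict() for k, v in
                                  report.membership_histograms.items()},
        "variation_histograms": {k: v.to_dict() for k, v in
                                 report.variation_histograms.items()},
        "sd_histograms": {k: v.to_dict() for k, v in
                          report.sd_histograms.items()},
    }
    write_json_report(payload, ROOT / "comparison.json")
    print(f"wrote {ROOT / 'comparison.json'}")


if __name__ == "__main__":
    main()
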