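#!/usr/bin/env python
"""Generate the synthetic study database: two versions of a superfamily
alignment database with known ground truth.

The pair emulates one update cycle of a curated structure-alignment
database: superfamilies of all three length-variation characters, a mix of
member fates (retention, supersession by better structures, outlier
filtering, search- and identity-rescue, loss), one superfamily split and
one merge.  Everything downstream (02-07) reads the directories written
here; truth.json records what was planted so recovery can be audited.
"""

from pathlib import Path

from domdiff.classification import Label
from domdiff.io import write_json_report, write_version_dir
from domdiff.synthetic import GeneratorSpec, generate_version_pair
from domdiff.version_diff import Fate

OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic"
SEED = 20130

# 5 deviant, 12 rigid, 5 normal superfamilies; the first rigid superfamily
# (900006) splits in two, the next two (900007, 900008) merge into 910000
SIZES = ([6, 5, 7, 4, 12]            # deviant
         + [8, 6, 6] + [6] * 9      # rigid (first three carry split/merge)
         + [6, 5, 4, 6, 5])         # normal

# members outside the split/merge superfamilies: 114; fates echo the
# roughly 45/20/20/7/5 retained/outlier/search/identity/lost mix of a
# real update audit, plus 30 brand-new members
FATES = {Fate.RETAINED: 52, Fate.SUPERSEDED: 4, Fate.OUTLIER: 22,
         Fate.RESCUED_BY_SEARCH: 22, Fate.RESCUED_BY_IDENTITY: 8,
         Fate.UNACCOUNTED: 6, Fate.NEW: 30}


def main() -> None:
    spec = GeneratorSpec(
        n_superfamilies={Label.DEVIANT: 5, Label.RIGID: 12, Label.NORMAL: 5},
        superfamily_sizes=SIZES,
        mean_length=(60, 140),
        fate_counts=FATES,
        split_plans=[("900006", 2)],
        merge_plans=[(["900007", "900008"], "910000")],
        with_ss=True,
        seed=SEED,
    )
    v1, v2, truth = generate_version_pair(spec)
    v1.label, v2.label = "synthetic-2004", "synthetic-2008"
    write_version_dir(v1, OUT / "v1")
    write_version_dir(v2, OUT / "v2")
    write_json_report(truth, OUT / "truth.json")
    print(f"wrote {OUT}")
    print(f"  v1: {v1.n_superfamilies} superfamilies, {v1.n_members} members")
    print(f"  v2: {v2.n_superfamilies} superfamilies, {v2.n_members} members "
          f"({len(v2.outliers)} outliers listed)")
    print(f"  planted events: {[e.kind.value for e in truth.events]}")


if __name__ == "__main__":
    main()
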