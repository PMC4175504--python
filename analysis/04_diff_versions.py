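#!/usr/bin/env python
"""Diff the two synthetic versions: superfamily mapping, split/merge
events, and one fate per old member.

Recovery is audited against the generator's truth record — every planted
fate and event should be found by the diff rules alone (no access to the
truth during inference).  Writes fates.tsv and events.json under
results/diff/.
"""

import json
from pathlib import Path

from domdiff.io import read_version_dir, write_json_report
from domdiff.version_diff import (assign_member_fates, detect_splits_merges,
                                  map_superfamilies)

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "diff"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    v1 = read_version_dir(ROOT / "synthetic" / "v1")
    v2 = read_version_dir(ROOT / "synthetic" / "v2")
    truth = json.loads((ROOT / "synthetic" / "truth.json").read_text())

    mapping = map_superfamilies(v1, v2)
    print(f"superfamilies: {len(mapping.common)} common, "
          f"{len(mapping.absent_from_new)} absent from new, "
          f"{len(mapping.new_in_new)} newly introduced")

    events = detect_splits_merges(v1, v2)
    for e in events:
        print(f"  {e.kind.value}: {e.old_codes} -> {e.new_codes}")
    planted = [(e["kind"], e["old_codes"], e["new_codes"])
               for e in truth["events"]]
    found = [(e.kind.value, e.old_codes, e.new_codes) for e in events]
    print(f"planted events recovered: "
          f"{sum(p in found for p in planted)}/{len(planted)}")

    fates = assign_member_fates(v1, v2)
    lines = ["member_id\tfate\tevidence"]
    lines += [f"{f.member_id}\t{f.fate.value}\t{f.evidence}" for f in fates]
    (OUT / "fates.tsv").write_text("\n".join(lines) + "\n")
    write_json_report({"mapping": mapping, "events": events},
                      OUT / "events.json")

    by_id = {f.member_id: f.fate.value for f in fates}
    hits = sum(by_id[mid] == want for mid, want in truth["fates"].items())
    print(f"member fates recovered: {hits}/{len(truth['fates'])}")
    tally = {}
    for f in fates:
        tally[f.fate.value] = tally.get(f.fate.value, 0) + 1
    print(f"fate tally: {dict(sorted(tally.items()))}")


if __name__ == "__main__":
    main()
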