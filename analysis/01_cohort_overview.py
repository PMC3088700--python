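#!/usr/bin/env python
"""Cohort overview: load the bundled specimen table and count what each
sequencing method detected.

The table holds 25 mutation/specimen rows (24 physical specimens from
22 patients; one relapse specimen carries two mutations and appears
twice).  Massively parallel sequencing is the reference: it calls 18
mutation rows, against which dideoxy sequencing finds 12 and
pyrosequencing 16.
"""

import json
from pathlib import Path

from mutbench import load_table1, mutated_specimens, responders

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cohort = load_table1()
    counts = {
        method: len(mutated_specimens(cohort, method))
        for method in ("dideoxy", "pyro", "parallel")
    }
    summary = {
        "n_rows": cohort.n_rows,
        "n_specimens": cohort.n_specimens,
        "n_patients": cohort.n_patients,
        "mutations_detected": counts,
        "partial_responders": sorted(responders(cohort)),
    }
    print(f"cohort: {cohort.n_rows} rows, {cohort.n_specimens} specimens, "
          f"{cohort.n_patients} patients")
    for method, n in counts.items():
        print(f"  {method:8s} called {n} mutation rows")
    print(f"  {len(summary['partial_responders'])} patients with confirmed PR")
    OUT.mkdir(exist_ok=True)
    (OUT / "cohort_overview.json").write_text(
        json.dumps(summary, indent=2) + "\n"
    )
    print(f"wrote {OUT / 'cohort_overview.json'}")


if __name__ == "__main__":
    main()
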