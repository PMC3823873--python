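"""Species discovery: can the methods tell new taxa from new forms?

References are restricted to the specimens already known at the historic
baseline; queries are the later discoveries (new taxa, new forms of
existing species, and one new member of a known complex).  The NJ-based
and distance-to-exemplar approaches are assessed against both reference
schemes and across thresholds.
"""

import argparse
from pathlib import Path

import pandas as pd

import barcodegap as bg
from barcodegap.evaluate import discovery_assessment

DATA = Path("results/data")
OUT = Path("results/discovery")

THRESHOLDS = (0.02, 0.04, 0.06, 0.08, 0.10)


def main() -> None:
    argparse.ArgumentParser().parse_args()
    OUT.mkdir(parents=True, exist_ok=True)

    sset = bg.read_fasta(DATA / "skink_current.fasta")
    maps = bg.read_metadata(DATA / "skink_current.tsv", ["current", "historic"])
    sset = bg.merge_dataset(sset, maps)
    m = bg.build_matrix(sset)

    rows = []
    for scheme in ("historic", "current"):
        nj = discovery_assessment(sset, m, scheme, "nj")
        rows.append(nj.to_row() | {"ref_scheme": scheme})
        print(
            f"NJ, {scheme} references: {nj.success_pct():.0f}% of "
            f"{nj.n} discovery queries handled correctly {nj.counts}"
        )
        for t in THRESHOLDS:
            tab = discovery_assessment(sset, m, scheme, "exemplar", t)
            rows.append(tab.to_row() | {"ref_scheme": scheme})
            print(
                f"exemplar t={100 * t:.0f}%, {scheme} refs: "
                f"{tab.success_pct():.0f}% success {tab.counts}"
            )
    pd.DataFrame(rows).to_csv(OUT / "discovery.tsv", sep="\t", index=False)
    print(f"\nwrote {OUT / 'discovery.tsv'}")


if __name__ == "__main__":
    main()
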