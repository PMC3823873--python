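"""Barcoding-gap analyses on the simulated skink-like world.

Reads the datasets written by 01_simulate_datasets.py, computes the
intra/inter distance overlap (total and 90%) under both taxonomies, the
per-species local-gap table, candidate thresholds (10x rule and the
barcode-gap partitioner) and the between-taxonomy ANOVA on species-level
mean intraspecific distances.  Writes tables to results/gap/ and the two
diagnostic figures (overlap histogram, max-intra vs nearest-neighbour
scatter) to results/gap/figures/.
"""

import argparse
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

import barcodegap as bg
from barcodegap.gap import status_counts, write_local_gap_table, write_overlap_table

DATA = Path("results/data")
OUT = Path("results/gap")


def load(name):
    sset = bg.read_fasta(DATA / f"{name}.fasta")
    maps = bg.read_metadata(DATA / f"{name}.tsv", ["current", "historic"])
    return bg.merge_dataset(sset, maps)


def overlap_histogram(pools, title, path):
    fig, ax = plt.subplots(figsize=(6, 4))
    bins = np.linspace(0, 0.25, 51)
    ax.hist([100 * d for d in pools.intra_pooled], bins=100 * bins,
            alpha=0.6, label="intraspecific", density=True)
    ax.hist([100 * d for d in pools.inter_pooled], bins=100 * bins,
            alpha=0.6, label="interspecific", density=True)
    ax.set_xlabel("K2P distance (%)")
    ax.set_ylabel("density")
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def local_gap_scatter(records, title, path):
    fig, ax = plt.subplots(figsize=(5, 5))
    xs = [100 * r.max_intra for r in records]
    ys = [100 * r.nn for r in records]
    ax.scatter(xs, ys, s=18)
    lim = max(xs + ys) * 1.05
    ax.plot([0, lim], [0, lim], "k--", lw=1)
    ax.set_xlabel("max intraspecific K2P distance (%)")
    ax.set_ylabel("nearest-neighbour distance (%)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def main() -> None:
    argparse.ArgumentParser().parse_args()
    OUT.mkdir(parents=True, exist_ok=True)
    figs = OUT / "figures"
    figs.mkdir(exist_ok=True)

    sset = load("skink_current")
    m = bg.build_matrix(sset)
    his = sset.taxonomies["historic"]
    m77 = m.submatrix([i for i in m.ids if i in his.label_of])

    pools = {
        "historic": bg.pool_distances(m77, his),
        "current": bg.pool_distances(m, sset.taxonomies["current"]),
    }
    overlaps = {}
    for scheme, p in pools.items():
        for trim, tag in ((0.0, "total"), (0.05, "90pct")):
            r = bg.overlap_report(p, trim)
            overlaps[f"{scheme}_{tag}"] = r
            print(
                f"{scheme} {tag} overlap: width {100 * r.width:.2f}%, "
                f"{r.pct_observations:.1f}% of observations inside"
            )
        print(f"{scheme} 10x-mean-intra threshold: {100 * bg.threshold_10x(p):.1f}%")
    write_overlap_table(overlaps, OUT / "overlap.tsv")

    for scheme, p in pools.items():
        recs = bg.local_gap_table(p)
        write_local_gap_table(recs, OUT / f"local_gap_{scheme}.tsv")
        counts = status_counts(recs)
        n = len(recs)
        absent = counts["absent_below"] + counts["absent_on_line"]
        print(
            f"{scheme}: local gap absent for {absent}/{n} species "
            f"({counts['absent_below']} below the line, "
            f"{counts['absent_on_line']} on it)"
        )
        local_gap_scatter(
            recs, f"local barcoding gap ({scheme})",
            figs / f"local_gap_{scheme}.png",
        )
        overlap_histogram(
            p, f"distance overlap ({scheme})", figs / f"overlap_{scheme}.png"
        )

    res = bg.abgd_partition(m)
    if res.consensus_threshold:
        lo, hi = res.consensus_threshold
        print(
            f"barcode-gap partitioner (current scheme): modal "
            f"{res.modal_n_groups} groups, consensus threshold "
            f"{100 * lo:.2f}-{100 * hi:.2f}%"
        )
    else:
        print("barcode-gap partitioner: no qualifying gap at any prior")
    pd.DataFrame(
        [
            {
                "prior_pct": 100 * r.prior,
                "threshold_pct": 100 * r.threshold if r.threshold else None,
                "n_groups": r.n_groups,
            }
            for r in res.per_prior
        ]
    ).to_csv(OUT / "abgd_per_prior.tsv", sep="\t", index=False)

    a = list(pools["historic"].species_mean_intra().values())
    b = list(pools["current"].species_mean_intra().values())
    an = bg.anova_intraspecific(a, b)
    print(
        f"species-level mean intraspecific distance, historic "
        f"({np.mean(a) * 100:.2f}%) vs current ({np.mean(b) * 100:.2f}%): "
        f"F({an.df1},{an.df2}) = {an.F:.2f}, P = {an.p:.4f}"
    )
    pd.DataFrame([an.__dict__]).to_csv(OUT / "anova.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
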