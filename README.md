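# barcodegap

Retrospective evaluation of COI DNA barcoding for specimen identification
and species discovery, with a synthetic radiation simulator.

DNA barcoding assigns specimens to species from a short mitochondrial
marker (usually ~650 bp of COI) on the premise of a *barcoding gap*:
intraspecific divergence below, interspecific divergence above.  In
recently radiated groups — island skinks being a classic case — that
premise fails: species complexes go unrecognised, sister species sit
within intraspecific distance of each other, and hybridisation moves
whole mitochondria across species boundaries.  `barcodegap` is for
systematists and method developers who want to *measure* what each
standard identification method would get right under those conditions,
by scoring a historic (morphology-only) taxonomy against the current
integrated one.

The package provides:

* **Distances** — Kimura 2-parameter distances with pairwise deletion,
  `d = -½ ln(1−2P−Q) − ¼ ln(1−2Q)` with transition/transversion
  proportions `P`, `Q`; saturated pairs are errors, never clamped.
* **Gap analytics** — total and 90% intra/inter overlap, per-species
  local gaps (max intraspecific vs nearest-neighbour distance), the
  10×-mean-intraspecific threshold, a simplified automatic barcode-gap
  partitioner over a prior grid, and a between-taxonomy ANOVA on
  species-level mean intraspecific distances.
* **Trees** — deterministic neighbour joining (Saitou–Nei, lexicographic
  tie rule), site-resampling bootstrap, newick export.
* **Identification** — five leave-one-out methods: best match, best close
  match, all species barcodes, distance to species exemplar, and NJ
  tree-based identification with clade criteria.
* **Evaluation** — two-taxonomy scoring (success / correctly flagged new /
  correctly flagged known complex / incorrectly flagged / misidentified /
  ambiguous), threshold sweeps at 2–10%, and a species-discovery
  assessment against baseline-restricted reference libraries.
* **Simulator** — a two-parameter substitution process over a species
  tree with star genealogies, lumped complexes, merged labels, new
  taxa/forms and mtDNA capture, shipped as three named presets
  (`gapped`, `skink1977`, `skink_current`).

## Worked example

The numbered scripts under `analysis/` run the whole study on the
simulated skink-like world (seed 1):

```sh
python analysis/01_simulate_datasets.py   # writes results/data/*.fasta + .tsv
python analysis/02_barcoding_gap.py
python analysis/03_build_trees.py
python analysis/04_identification_sweep.py
python analysis/05_species_discovery.py
```

`02_barcoding_gap.py` prints, among other lines:

```
historic total overlap: width 17.07%, 96.2% of observations inside
current total overlap: width 6.51%, 14.7% of observations inside
historic 10x-mean-intra threshold: 20.6%
historic: local gap absent for 12/23 species (12 below the line, 0 on it)
current: local gap absent for 5/26 species (5 below the line, 0 on it)
barcode-gap partitioner (current scheme): modal 21 groups, consensus threshold 3.48-3.48%
```

Under the historic labels the intra- and inter-specific distance
distributions overlap almost completely (96% of observations inside the
overlap range) — there is no global barcoding gap, because lumped
complexes put 16%-divergent lineages under one name while the radiation
keeps distinct species ~1% apart.  Resolving the complexes (current
scheme) shrinks the overlap to 15% of observations but cannot remove it:
recent speciation and hybridisation remain.  The 10× rule yields an
absurd 20.6% threshold; the gap partitioner settles near 3.5%.

`04_identification_sweep.py` then shows the central contrast: against the
historic scheme, best match "succeeds" for 98% of specimens despite the
unrecognised complexes (the closest-match fallacy), while the
neighbourhood-purity method (all species barcodes) succeeds for only
16–40% — it is the method that actually detects the taxonomic problems.
`05_species_discovery.py` shows the NJ tree classifying 100% of the 18
post-baseline discovery queries correctly, while the exemplar method's
accuracy swings from 100% to 44% with the threshold chosen.

## Layout

```
src/barcodegap/     io, distances, gap, njtree, identify, evaluate, simulate
analysis/           numbered narrative drivers writing results/
tests/              pytest suite (unit, hypothesis properties, end-to-end)
scripts/acceptance.py
docs/methods.md     model, conventions, design choices, limitations
```
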