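"""Retrospective scoring, threshold sweeps and species-discovery assessment.

Identification outcomes are produced against an *evaluated* taxonomy (for
instance a historic, morphology-only scheme) and then scored against a
*truth* taxonomy (the current, integrated one).  A query flagged as
distinct (no match, or an ambiguous placement marked as a candidate new
species) is:

* ``correctly_flagged_new`` when its truth species has no reference in the
  evaluated dataset and is not part of a recorded species complex;
* ``correctly_flagged_known_complex`` when its truth species belongs to
  the expansion of a lumped (since split) label of the evaluated scheme;
* ``incorrectly_flagged`` when its truth species does have a reference.

Counts are primary; percentages are always recomputed from counts.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .distances import DistanceMatrix
from .identify import IdentificationResult, run_method
from .io import SequenceSet, TaxonomyMap
from .njtree import neighbor_joining

CATEGORIES = (
    "success",
    "correctly_flagged_new",
    "correctly_flagged_known_complex",
    "incorrectly_flagged",
    "misidentified_or_not_flagged",
    "ambiguous",
    "no_match",
)

DISCOVERY_CATEGORIES = (
    "correctly_grouped_existing",
    "correctly_flagged_new",
    "correctly_flagged_part_of_complex",
    "incorrectly_flagged_new",
    "incorrectly_lumped",
)


class EvaluationError(ValueError):
    pass


@dataclass
class SummaryTable:
    method: str
    threshold: Optional[float]
    counts: dict[str, int] = field(default_factory=lambda: {c: 0 for c in CATEGORIES})

    @property
    def n(self) -> int:
        return sum(self.counts.values())

    def percentages(self) -> dict[str, float]:
        n = self.n
        return {c: (100.0 * k / n if n else 0.0) for c, k in self.counts.items()}

    def pct(self, category: str) -> float:
        return self.percentages()[category]

    def to_row(self) -> dict:
        row: dict = {"method": self.method, "threshold_pct": (
            100 * self.threshold if self.threshold is not None else None
        ), "n": self.n}
        pcts = self.percentages()
        for c in CATEGORIES:
            row[c] = self.counts[c]
            row[f"{c}_pct"] = round(pcts[c], 4)
        return row


def _is_flagged(res: IdentificationResult) -> bool:
    if res.outcome == "no_match":
        return True
    return res.outcome == "ambiguous" and bool(res.evidence.get("candidate_new"))


def score_against_truth(
    results: Sequence[IdentificationResult],
    eval_tax: TaxonomyMap,
    truth_tax: TaxonomyMap,
    ref_ids: Sequence[str],
    method: str = "",
    threshold: Optional[float] = None,
) -> SummaryTable:
    """Score identification results against the truth taxonomy.

    ``ref_ids`` are the specimens that served as references (exemplars for
    the exemplar and NJ methods, the full library for matching methods):
    a flagged query is only *correctly* flagged if its truth species had no
    reference available.
    """
    ref_truth = {
        truth_tax.label_of[r] for r in ref_ids if r in truth_tax.label_of
    }
    complex_union: set[str] = set()
    for members in eval_tax.complex_map.values():
        complex_union |= members

    table = SummaryTable(method=method, threshold=threshold)
    for res in results:
        q = res.query_id
        if q not in truth_tax.label_of:
            raise EvaluationError(f"query {q!r} missing from truth taxonomy")
        t_lab = truth_tax.label_of[q]
        if _is_flagged(res):
            if t_lab in ref_truth:
                cat = "incorrectly_flagged"
            elif t_lab in complex_union:
                cat = "correctly_flagged_known_complex"
            else:
                cat = "correctly_flagged_new"
        elif res.outcome == "success":
            cat = "success"
        elif res.outcome == "misidentified":
            cat = "misidentified_or_not_flagged"
        else:
            cat = "ambiguous"
        table.counts[cat] += 1
    return table


DEFAULT_THRESHOLDS = (0.02, 0.04, 0.06, 0.08, 0.10)


def threshold_sweep(
    sset: SequenceSet,
    m: DistanceMatrix,
    eval_scheme: str,
    truth_scheme: str,
    methods: Sequence[str] = ("nj", "exemplar", "best_match", "best_close_match",
                              "all_species_barcodes"),
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> list[SummaryTable]:
    """One summary per method x threshold (NJ and Best Match ignore thresholds)."""
    eval_tax = sset.taxonomies[eval_scheme]
    truth_tax = sset.taxonomies[truth_scheme]
    labelled = [s for s in m.ids if s in eval_tax.label_of]
    sub = m.submatrix(labelled) if len(labelled) != len(m) else m

    tree = neighbor_joining(sub) if "nj" in methods else None
    out: list[SummaryTable] = []
    for method in methods:
        if method in ("nj", "best_match"):
            results = run_method(sub, eval_tax, method, tree=tree)
            refs = (
                sorted(eval_tax.exemplar_ids()) if method == "nj" else labelled
            )
            out.append(
                score_against_truth(results, eval_tax, truth_tax, refs, method)
            )
            continue
        refs = (
            sorted(e for e in eval_tax.exemplar_ids() if e in sub._index)
            if method == "exemplar"
            else labelled
        )
        for t in thresholds:
            results = run_method(sub, eval_tax, method, t=t)
            out.append(
                score_against_truth(
                    results, eval_tax, truth_tax, refs, method, threshold=t
                )
            )
    return out


def sweep_to_dataframe(tables: Sequence[SummaryTable]) -> pd.DataFrame:
    return pd.DataFrame([t.to_row() for t in tables])


# ---------------------------------------------------------------------------
# species discovery
# ---------------------------------------------------------------------------

@dataclass
class DiscoveryTable:
    method: str
    threshold: Optional[float]
    counts: dict[str, int] = field(
        default_factory=lambda: {c: 0 for c in DISCOVERY_CATEGORIES}
    )
    per_query: dict[str, str] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return sum(self.counts.values())

    def success_pct(self) -> float:
        ok = (
            self.counts["correctly_grouped_existing"]
            + self.counts["correctly_flagged_new"]
            + self.counts["correctly_flagged_part_of_complex"]
        )
        return 100.0 * ok / self.n if self.n else 0.0

    def to_row(self) -> dict:
        row: dict = {
            "method": self.method,
            "threshold_pct": 100 * self.threshold if self.threshold is not None else None,
            "n": self.n,
            "success_pct": round(self.success_pct(), 4),
        }
        row.update(self.counts)
        return row


def _restricted_eval_map(
    sset: SequenceSet,
    ref_scheme: str,
    ref_ids: list[str],
    query_ids: list[str],
) -> TaxonomyMap:
    """Reference-scheme labels on the references, plus each query's expected
    label (the label its conspecific references bear, if any)."""
    ref_tax = sset.taxonomies[ref_scheme]
    truth = sset.taxonomies["current"]
    tax = TaxonomyMap(scheme_name=f"{ref_scheme}_restricted")
    for r in ref_ids:
        tax.label_of[r] = ref_tax.label_of[r]
    for sp, ex in ref_tax.exemplar_of.items():
        if ex in tax.label_of:
            tax.exemplar_of[sp] = ex
    label_by_truth: dict[str, str] = {}
    for r in ref_ids:
        label_by_truth.setdefault(truth.label_of[r], ref_tax.label_of[r])
    for q in query_ids:
        expected = label_by_truth.get(truth.label_of[q])
        if expected is not None:
            tax.label_of[q] = expected
    tax.complex_map = dict(ref_tax.complex_map)
    return tax


def discovery_assessment(
    sset: SequenceSet,
    m: DistanceMatrix,
    ref_scheme: str,
    method: str,
    t: Optional[float] = None,
) -> DiscoveryTable:
    """Can the method tell new taxa from new forms of existing species?

    References are the specimens already known at the baseline
    (``known_historic`` and labelled under ``ref_scheme``); queries are the
    later discoveries.  A flagged query whose truth species belongs to a
    complex recorded in the reference scheme counts as
    ``correctly_flagged_part_of_complex``.
    """
    if method not in ("nj", "exemplar"):
        raise EvaluationError("discovery assessment supports 'nj' and 'exemplar'")
    truth = sset.taxonomies["current"]
    ref_tax = sset.taxonomies[ref_scheme]
    ref_ids = [
        s for s in m.ids
        if truth.status(s) == "known_historic" and s in ref_tax.label_of
    ]
    query_ids = [
        s for s in m.ids
        if truth.status(s) in ("new_taxon", "new_form_of_existing")
    ]
    if not query_ids:
        raise EvaluationError("no queries with a new discovery status")
    eval_map = _restricted_eval_map(sset, ref_scheme, ref_ids, query_ids)
    sub = m.submatrix(ref_ids + query_ids)

    if method == "nj":
        tree = neighbor_joining(sub)
        exemplars = set(eval_map.exemplar_of.values())
        all_results = run_method(sub, eval_map, "nj", tree=tree)
        results = {r.query_id: r for r in all_results if r.query_id in set(query_ids)}
    else:
        if t is None:
            raise EvaluationError("exemplar discovery needs a threshold")
        res_list = run_method(sub, eval_map, "exemplar", t=t, query_ids=query_ids)
        results = {r.query_id: r for r in res_list}

    complex_union: set[str] = set()
    for members in eval_map.complex_map.values():
        complex_union |= members

    table = DiscoveryTable(method=method, threshold=t)
    for q in query_ids:
        res = results[q]
        status = truth.status(q)
        grouped = res.outcome in ("success", "misidentified")
        if grouped:
            cat = (
                "correctly_grouped_existing"
                if status == "new_form_of_existing"
                else "incorrectly_lumped"
            )
        else:
            if status == "new_form_of_existing":
                cat = "incorrectly_flagged_new"
            elif truth.label_of[q] in complex_union:
                cat = "correctly_flagged_part_of_complex"
            else:
                cat = "correctly_flagged_new"
        table.counts[cat] += 1
        table.per_query[q] = cat
    return table


# ---------------------------------------------------------------------------
# pipeline driver
# ---------------------------------------------------------------------------

def write_manifest(outdir: Path, config_repr: str, seed: int) -> None:
    import numpy, scipy, Bio, dendropy  # noqa: PLC0415

    manifest = {
        "barcodegap": __version__,
        "seed": seed,
        "config_sha1": hashlib.sha1(config_repr.encode()).hexdigest(),
        "python": platform.python_version(),
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "biopython": Bio.__version__,
        "dendropy": dendropy.__version__,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def results_to_dataframe(results: Sequence[IdentificationResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "query_id": r.query_id,
                "method": r.method,
                "threshold_pct": 100 * r.threshold if r.threshold is not None else None,
                "assigned": r.assigned,
                "outcome": r.outcome,
                "nearest_id": ";".join(r.evidence.get("nearest_ids", [])),
                "nearest_distance": r.evidence.get("nearest_distance"),
            }
        )
    return pd.DataFrame(rows)
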