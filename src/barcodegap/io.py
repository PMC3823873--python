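"""Sequence and specimen-metadata I/O.

A barcoding dataset is an aligned set of COI sequences plus one or more
taxonomy schemes (e.g. a historic, morphology-only classification and the
current integrated one).  Metadata live in a sidecar TSV keyed by
``specimen_id`` rather than in FASTA headers: two taxonomies plus exemplar
and discovery flags do not fit a header cleanly.

Reading-frame QC (:func:`validate_coding`) screens for premature stop
codons under the vertebrate mitochondrial code, the standard sanity check
that a COI amplicon is not a nuclear pseudogene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger(__name__)

#: IUPAC nucleotide codes plus the gap character.
IUPAC_NT = set("ACGTRYSWKMBDHVN-")

#: Discovery statuses a specimen can carry.
DISCOVERY_STATUSES = ("known_historic", "new_taxon", "new_form_of_existing")


class DatasetError(ValueError):
    """Raised for malformed sequence or metadata input."""


@dataclass
class SequenceRecord:
    """One aligned specimen sequence."""

    specimen_id: str
    sequence: str
    locality: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.specimen_id:
            raise DatasetError("specimen_id must be non-empty")
        if not self.sequence:
            raise DatasetError(f"empty sequence for {self.specimen_id!r}")
        bad = set(self.sequence.upper()) - IUPAC_NT
        if bad:
            raise DatasetError(
                f"non-IUPAC characters {sorted(bad)} in {self.specimen_id!r}"
            )


@dataclass
class TaxonomyMap:
    """Specimen labels under one taxonomy scheme.

    ``complex_map`` records lumping between schemes: a historic label that
    spans several current (truth) species.  ``discovery_status_of`` defaults
    to ``known_historic`` for unlisted specimens.
    """

    scheme_name: str
    label_of: dict[str, str] = field(default_factory=dict)
    exemplar_of: dict[str, str] = field(default_factory=dict)
    complex_map: dict[str, frozenset[str]] = field(default_factory=dict)
    discovery_status_of: dict[str, str] = field(default_factory=dict)

    def species(self) -> set[str]:
        return set(self.label_of.values())

    def specimens_of(self, label: str) -> list[str]:
        return [s for s, lab in self.label_of.items() if lab == label]

    def status(self, specimen_id: str) -> str:
        return self.discovery_status_of.get(specimen_id, "known_historic")

    def exemplar_ids(self) -> set[str]:
        return set(self.exemplar_of.values())

    def validate(self) -> None:
        for sp, ex in self.exemplar_of.items():
            if ex not in self.label_of:
                raise DatasetError(
                    f"scheme {self.scheme_name!r}: exemplar {ex!r} for species "
                    f"{sp!r} is not a labelled specimen"
                )
        for h, members in self.complex_map.items():
            if not members:
                raise DatasetError(
                    f"scheme {self.scheme_name!r}: empty complex for {h!r}"
                )
        for s, st in self.discovery_status_of.items():
            if st not in DISCOVERY_STATUSES:
                raise DatasetError(f"unknown discovery status {st!r} for {s!r}")


@dataclass
class SequenceSet:
    """Aligned records plus any number of named taxonomy schemes."""

    records: list[SequenceRecord]
    aligned_length: int = 0
    taxonomies: dict[str, TaxonomyMap] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.records and not self.aligned_length:
            self.aligned_length = len(self.records[0].sequence)

    @property
    def ids(self) -> list[str]:
        return [r.specimen_id for r in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def get(self, specimen_id: str) -> SequenceRecord:
        for r in self.records:
            if r.specimen_id == specimen_id:
                return r
        raise KeyError(specimen_id)

    def subset(self, keep: Iterable[str]) -> "SequenceSet":
        """Restrict to the given specimen ids (taxonomies filtered along)."""
        keep = set(keep)
        recs = [r for r in self.records if r.specimen_id in keep]
        taxes = {}
        for name, tax in self.taxonomies.items():
            taxes[name] = TaxonomyMap(
                scheme_name=tax.scheme_name,
                label_of={s: l for s, l in tax.label_of.items() if s in keep},
                exemplar_of={
                    sp: ex for sp, ex in tax.exemplar_of.items() if ex in keep
                },
                complex_map=dict(tax.complex_map),
                discovery_status_of={
                    s: st
                    for s, st in tax.discovery_status_of.items()
                    if s in keep
                },
            )
        return SequenceSet(recs, self.aligned_length, taxes)

    def check_aligned(self) -> None:
        lengths = {len(r.sequence) for r in self.records}
        if len(lengths) > 1:
            raise DatasetError(f"unequal aligned lengths: {sorted(lengths)}")


def read_fasta(path: str | Path) -> SequenceSet:
    """Read a FASTA file into a :class:`SequenceSet` (records only).

    Ids are the header token before the first whitespace.  Duplicate ids and
    empty files are errors.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise DatasetError(f"duplicate specimen id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, str(rec.seq)))
    if not records:
        raise DatasetError(f"no FASTA records in {path}")
    return SequenceSet(records)


def write_fasta(sset: SequenceSet, path: str | Path) -> None:
    recs = [
        _BioSeqRecord(Seq(r.sequence), id=r.specimen_id, description="")
        for r in sset.records
    ]
    SeqIO.write(recs, str(path), "fasta")


def read_metadata(
    path: str | Path, scheme_names: Iterable[str]
) -> dict[str, TaxonomyMap]:
    """Read the sidecar metadata TSV into one :class:`TaxonomyMap` per scheme.

    Expected columns: ``specimen_id``, one label column per scheme, and
    optionally ``<scheme>_exemplar`` (truthy marker), ``discovery_status``
    and ``locality``.  A specimen with an empty label in a scheme is simply
    absent from that scheme (excluded from its analyses).
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if "specimen_id" not in df.columns:
        raise DatasetError("metadata TSV lacks a specimen_id column")
    maps: dict[str, TaxonomyMap] = {}
    for scheme in scheme_names:
        if scheme not in df.columns:
            raise DatasetError(f"metadata TSV lacks column {scheme!r}")
        tax = TaxonomyMap(scheme_name=scheme)
        ex_col = f"{scheme}_exemplar"
        for _, row in df.iterrows():
            sid = row["specimen_id"]
            label = row[scheme].strip()
            if not label:
                continue
            tax.label_of[sid] = label
            if ex_col in df.columns and row[ex_col].strip():
                if label in tax.exemplar_of:
                    raise DatasetError(
                        f"two exemplars marked for species {label!r} in "
                        f"scheme {scheme!r}: {tax.exemplar_of[label]!r} and {sid!r}"
                    )
                tax.exemplar_of[label] = sid
            if "discovery_status" in df.columns and row["discovery_status"].strip():
                tax.discovery_status_of[sid] = row["discovery_status"].strip()
        tax.validate()
        n_missing = len(df) - len(tax.label_of)
        if n_missing:
            logger.info(
                "scheme %s: %d specimens have no label and are excluded",
                scheme,
                n_missing,
            )
        maps[scheme] = tax

    # lumping between schemes: a label of one scheme spanning >=2 labels of
    # another is a species complex; members missing from the lumped scheme
    # (e.g. a newly discovered complex member) come from `part_of_complex`
    for scheme, tax in maps.items():
        spans: dict[str, set[str]] = {}
        for other, otax in maps.items():
            if other == scheme:
                continue
            for sid, lab in tax.label_of.items():
                olab = otax.label_of.get(sid)
                if olab is not None:
                    spans.setdefault(lab, set()).add(olab)
        tax.complex_map = {
            h: frozenset(mem) for h, mem in spans.items() if len(mem) >= 2
        }
    if "part_of_complex" in df.columns:
        for _, row in df.iterrows():
            h = row["part_of_complex"].strip()
            if not h:
                continue
            for scheme, tax in maps.items():
                if h not in set(tax.label_of.values()):
                    continue
                for other, otax in maps.items():
                    if other == scheme:
                        continue
                    olab = otax.label_of.get(row["specimen_id"])
                    if olab is not None:
                        tax.complex_map[h] = (
                            tax.complex_map.get(h, frozenset()) | {olab}
                        )
    return maps


def write_metadata(sset: SequenceSet, path: str | Path) -> None:
    """Write taxonomies back to the sidecar TSV dialect of :func:`read_metadata`.

    Lumping is mostly implicit in the paired label columns; a
    ``part_of_complex`` column records complex members that carry no label
    in the lumped scheme (they would otherwise be unrecoverable on read).
    """
    complex_of: dict[str, str] = {}
    for tax in sset.taxonomies.values():
        for h, members in tax.complex_map.items():
            for r in sset.records:
                if r.specimen_id in tax.label_of:
                    continue
                for other in sset.taxonomies.values():
                    if other is tax:
                        continue
                    if other.label_of.get(r.specimen_id) in members:
                        complex_of[r.specimen_id] = h
    rows = []
    for r in sset.records:
        row: dict[str, str] = {"specimen_id": r.specimen_id}
        for name, tax in sset.taxonomies.items():
            row[name] = tax.label_of.get(r.specimen_id, "")
            row[f"{name}_exemplar"] = (
                "x" if r.specimen_id in tax.exemplar_ids() else ""
            )
            st = tax.discovery_status_of.get(r.specimen_id)
            if st:
                row["discovery_status"] = st
        row.setdefault("discovery_status", "")
        row["part_of_complex"] = complex_of.get(r.specimen_id, "")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def merge_dataset(
    sset: SequenceSet, taxonomies: Mapping[str, TaxonomyMap]
) -> SequenceSet:
    """Attach taxonomies to a sequence set, validating cross-references.

    Every specimen referenced by any scheme must exist among the records.
    """
    known = set(sset.ids)
    for name, tax in taxonomies.items():
        tax.validate()
        ghosts = set(tax.label_of) - known
        if ghosts:
            raise DatasetError(
                f"scheme {name!r} labels unknown specimens: {sorted(ghosts)[:5]}"
            )
        absent = known - set(tax.label_of)
        if absent:
            logger.info(
                "scheme %s: %d specimens unlabelled, excluded from that "
                "scheme's analyses",
                name,
                len(absent),
            )
    return SequenceSet(sset.records, sset.aligned_length, dict(taxonomies))


def validate_coding(
    record: SequenceRecord,
    genetic_code: int = 2,
    frame: int | str = "auto",
) -> dict:
    """Screen a sequence for premature stop codons.

    Gaps are removed before translation.  With ``frame="auto"`` all three
    forward frames are translated and the frame with the fewest internal
    stops is chosen (ties go to the lowest frame).  The default genetic code
    is vertebrate mitochondrial (NCBI table 2).

    Returns ``{"frame": 1|2|3, "has_internal_stop": bool, "n_stops": int}``.
    """
    seq = record.sequence.upper().replace("-", "")
    if len(seq) < 3:
        raise DatasetError(
            f"{record.specimen_id!r}: sequence shorter than one codon"
        )

    def stops_in_frame(f: int) -> int:
        sub = seq[f:]
        sub = sub[: len(sub) - len(sub) % 3]
        if not sub:
            return 0
        aa = str(Seq(sub).translate(table=genetic_code))
        # a stop at the very end of the amplicon is not "internal"
        return aa[:-1].count("*")

    if frame == "auto":
        counts = {f: stops_in_frame(f) for f in (0, 1, 2) if len(seq) - f >= 3}
        best = min(counts, key=lambda f: (counts[f], f))
    else:
        best = int(frame) - 1
        if best not in (0, 1, 2):
            raise DatasetError(f"frame must be 1..3, got {frame!r}")
        counts = {best: stops_in_frame(best)}
    n = counts[best]
    return {"frame": best + 1, "has_internal_stop": n > 0, "n_stops": n}
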