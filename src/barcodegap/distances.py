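"""Kimura 2-parameter distances with pairwise deletion.

The K2P model corrects observed divergence using separate transition (P)
and transversion (Q) proportions::

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

Sites where either sequence has a gap or an ambiguity code are dropped for
that pair only (pairwise deletion, the convention of MEGA's distance
tables).  Transitions are A<->G and C<->T; every other mismatch is a
transversion; comparison is case-insensitive.  A pair whose observed
divergence puts the logs outside their domain is saturated and aborts
rather than being clamped: silently capped distances corrupt overlap
statistics downstream.

Distances are kept in substitutions/site throughout; multiply by 100 only
at reporting boundaries.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import SequenceRecord, SequenceSet

# byte -> code lookup: A=0, C=1, G=2, T=3, everything else 255 (non-comparable)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _CODE[ord(_c)] = _i
    _CODE[ord(_c.lower())] = _i


class DistanceError(ValueError):
    """No comparable sites, or a saturated pair."""


@dataclass(frozen=True)
class K2PResult:
    d: float
    P: float
    Q: float
    n_sites: int


def encode(sequence: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes (255 = gap/ambiguity)."""
    return _CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


def _k2p_from_codes(x: np.ndarray, y: np.ndarray, ida: str, idb: str) -> K2PResult:
    ok = (x < 4) & (y < 4)
    n = int(ok.sum())
    if n == 0:
        raise DistanceError(f"no comparable sites between {ida!r} and {idb!r}")
    xs, ys = x[ok], y[ok]
    diff = xs != ys
    # with codes A0 C1 G2 T3, a mismatch is a transition iff x^y == 2
    ts = int((diff & ((xs ^ ys) == 2)).sum())
    tv = int(diff.sum()) - ts
    P = ts / n
    Q = tv / n
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise DistanceError(
            f"saturated pair {ida!r} / {idb!r} (P={P:.3f}, Q={Q:.3f})"
        )
    d = -0.5 * math.log(w1) - 0.25 * math.log(w2)
    return K2PResult(d=d, P=P, Q=Q, n_sites=n)


def k2p(a: SequenceRecord, b: SequenceRecord) -> K2PResult:
    """K2P distance between two aligned records (pairwise deletion)."""
    if len(a.sequence) != len(b.sequence):
        raise DistanceError(
            f"unequal aligned lengths for {a.specimen_id!r} ({len(a.sequence)}) "
            f"and {b.specimen_id!r} ({len(b.sequence)})"
        )
    return _k2p_from_codes(
        encode(a.sequence), encode(b.sequence), a.specimen_id, b.specimen_id
    )


class DistanceMatrix:
    """Symmetric K2P distance matrix with per-pair comparable-site counts."""

    def __init__(self, ids: list[str], d: np.ndarray, n_sites: np.ndarray):
        self.ids = list(ids)
        self.d = np.asarray(d, dtype=float)
        self.n_sites = np.asarray(n_sites, dtype=int)
        self._index = {sid: i for i, sid in enumerate(self.ids)}
        n = len(self.ids)
        if self.d.shape != (n, n) or self.n_sites.shape != (n, n):
            raise ValueError("matrix shape does not match id count")
        if not np.allclose(self.d, self.d.T) or np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")

    def __len__(self) -> int:
        return len(self.ids)

    def index(self, specimen_id: str) -> int:
        return self._index[specimen_id]

    def distance(self, a: str, b: str) -> float:
        return float(self.d[self._index[a], self._index[b]])

    def row(self, specimen_id: str) -> np.ndarray:
        return self.d[self._index[specimen_id]]

    def submatrix(self, keep: list[str]) -> "DistanceMatrix":
        idx = [self._index[s] for s in keep]
        return DistanceMatrix(
            list(keep), self.d[np.ix_(idx, idx)], self.n_sites[np.ix_(idx, idx)]
        )

    def condensed(self) -> np.ndarray:
        """Upper-triangle distances in pair order (i<j)."""
        iu = np.triu_indices(len(self.ids), k=1)
        return self.d[iu]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.ids, columns=self.ids)

    def write_square_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t")

    def write_lower_csv(self, path: str | Path) -> None:
        """MEGA-like lower-triangular CSV."""
        with open(path, "w") as fh:
            fh.write("," + ",".join(self.ids) + "\n")
            for i, sid in enumerate(self.ids):
                cells = [f"{self.d[i, j]:.8f}" for j in range(i)]
                fh.write(sid + "," + ",".join(cells) + "\n")


def matrix_from_codes(ids: list[str], codes: np.ndarray) -> DistanceMatrix:
    """All-pairs K2P matrix from an (n, L) uint8 code array.

    Used for bootstrap replicates where columns are resampled without
    re-encoding the alignment.
    """
    n, _ = codes.shape
    d = np.zeros((n, n))
    ns = np.zeros((n, n), dtype=int)
    for i in range(n):
        ns[i, i] = int((codes[i] < 4).sum())
    for i, j in itertools.combinations(range(n), 2):
        res = _k2p_from_codes(codes[i], codes[j], ids[i], ids[j])
        d[i, j] = d[j, i] = res.d
        ns[i, j] = ns[j, i] = res.n_sites
    return DistanceMatrix(ids, d, ns)


def build_matrix(sset: SequenceSet) -> DistanceMatrix:
    """All-pairs K2P matrix for an aligned set (>=2 records required)."""
    if len(sset) < 2:
        raise DistanceError("need at least 2 records for a distance matrix")
    sset.check_aligned()
    codes = [encode(r.sequence) for r in sset.records]
    n = len(codes)
    d = np.zeros((n, n))
    ns = np.zeros((n, n), dtype=int)
    for i in range(n):
        ns[i, i] = int((codes[i] < 4).sum())
    for i, j in itertools.combinations(range(n), 2):
        res = _k2p_from_codes(
            codes[i], codes[j], sset.records[i].specimen_id,
            sset.records[j].specimen_id,
        )
        d[i, j] = d[j, i] = res.d
        ns[i, j] = ns[j, i] = res.n_sites
    return DistanceMatrix(sset.ids, d, ns)
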