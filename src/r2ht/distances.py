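"""Uncorrected p-distances with pairwise deletion.

The divergence statistic throughout the pipeline is the uncorrected
p-distance: the proportion of differing sites among the alignment
columns comparable for a pair of records.  Columns holding a gap (``-``)
or missing symbol (``N`` for nucleotide, ``X`` for amino acid) in either
row, or lying outside either record's coverage interval, are excluded
pair-by-pair (pairwise deletion).  This keeps partial copies — e.g. a
5'-only fragment — comparable to full-length elements on their shared
columns.

Standard errors use the binomial approximation ``sqrt(d(1-d)/n)``; a
site-bootstrap alternative is available for non-analytic error bars.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GAP = "-"
MISSING = {"nt": "N", "aa": "X"}


class NotComputable(Exception):
    """A pair with zero comparable sites (or a degenerate partner)."""


@dataclass
class DistanceMatrix:
    """Symmetric p-distance matrix with per-pair site counts and SEs.

    ``not_computed`` holds unordered label pairs whose distance is not
    defined in this mode (amino-acid comparisons against a degenerate
    element, or zero comparable sites).  Entries of ``d`` for such pairs
    are NaN.  ``n_sites`` may be 0 where unknown (e.g. a matrix read
    from a published table).
    """

    labels: list[str]
    d: np.ndarray
    n_sites: np.ndarray
    se: np.ndarray
    mode: str = "nt"
    not_computed: set[frozenset] = field(default_factory=set)

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate labels in distance matrix")
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    def get(self, a: str, b: str) -> float:
        return float(self.d[self._index[a], self._index[b]])

    def get_se(self, a: str, b: str) -> float:
        return float(self.se[self._index[a], self._index[b]])

    def is_computed(self, a: str, b: str) -> bool:
        return frozenset((a, b)) not in self.not_computed

    def pairs(self):
        """Yield (label_a, label_b, d, n_sites, se) for computed pairs."""
        for i, j in itertools.combinations(range(len(self.labels)), 2):
            a, b = self.labels[i], self.labels[j]
            if frozenset((a, b)) in self.not_computed:
                continue
            yield a, b, float(self.d[i, j]), int(self.n_sites[i, j]), \
                float(self.se[i, j])

    def submatrix(self, labels: list[str]) -> "DistanceMatrix":
        idx = [self._index[lab] for lab in labels]
        return DistanceMatrix(
            labels=list(labels),
            d=self.d[np.ix_(idx, idx)].copy(),
            n_sites=self.n_sites[np.ix_(idx, idx)].copy(),
            se=self.se[np.ix_(idx, idx)].copy(),
            mode=self.mode,
            not_computed={
                p for p in self.not_computed if p <= set(labels)
            },
        )

    def to_tidy(self) -> pd.DataFrame:
        rows = []
        for i, j in itertools.combinations(range(len(self.labels)), 2):
            a, b = self.labels[i], self.labels[j]
            nc = frozenset((a, b)) in self.not_computed
            rows.append({
                "a": a, "b": b, "mode": self.mode,
                "d": np.nan if nc else self.d[i, j],
                "n_sites": 0 if nc else int(self.n_sites[i, j]),
                "se": np.nan if nc else self.se[i, j],
                "computed": not nc,
            })
        return pd.DataFrame(rows)


def _mask(row: str, mode: str, coverage: tuple[int, int] | None) -> \
        np.ndarray:
    """Boolean mask of columns usable for this record."""
    arr = np.frombuffer(row.upper().encode(), dtype="S1")
    ok = (arr != GAP.encode()) & (arr != MISSING[mode].encode())
    if coverage is not None:
        lo, hi = coverage
        idx = np.arange(1, len(row) + 1)
        ok &= (idx >= lo) & (idx <= hi)
    return ok


def p_distance(
    row_a: str,
    row_b: str,
    mode: str = "nt",
    coverage_a: tuple[int, int] | None = None,
    coverage_b: tuple[int, int] | None = None,
) -> tuple[float, int]:
    """Uncorrected p-distance of two aligned rows.

    Returns ``(d, n_sites)`` where ``d = mismatches / compared_sites``
    under pairwise deletion.  Raises :class:`NotComputable` when no
    column is comparable (deliberately distinct from a distance of 0).
    """
    if len(row_a) != len(row_b):
        raise ValueError("aligned rows differ in length")
    a = np.frombuffer(row_a.upper().encode(), dtype="S1")
    b = np.frombuffer(row_b.upper().encode(), dtype="S1")
    ok = _mask(row_a, mode, coverage_a) & _mask(row_b, mode, coverage_b)
    n = int(ok.sum())
    if n == 0:
        raise NotComputable("zero comparable sites")
    mism = int((a[ok] != b[ok]).sum())
    return mism / n, n


def p_distance_se(d: float, n_sites: int) -> float:
    """Analytic (binomial) standard error of a p-distance."""
    if n_sites <= 0:
        raise ValueError("n_sites must be positive")
    return float(np.sqrt(d * (1.0 - d) / n_sites))


def bootstrap_se(
    row_a: str,
    row_b: str,
    mode: str = "nt",
    n_reps: int = 500,
    seed: int = 0,
    coverage_a: tuple[int, int] | None = None,
    coverage_b: tuple[int, int] | None = None,
) -> float:
    """Site-resampling bootstrap SE of the pairwise p-distance."""
    a = np.frombuffer(row_a.upper().encode(), dtype="S1")
    b = np.frombuffer(row_b.upper().encode(), dtype="S1")
    ok = _mask(row_a, mode, coverage_a) & _mask(row_b, mode, coverage_b)
    diff = (a[ok] != b[ok]).astype(float)
    if diff.size == 0:
        raise NotComputable("zero comparable sites")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, diff.size, size=(n_reps, diff.size))
    return float(diff[idx].mean(axis=1).std(ddof=1))


def build_matrix(
    records: dict[str, str],
    mode: str = "nt",
    coverage: dict[str, tuple[int, int]] | None = None,
    degenerate: set[str] | None = None,
) -> DistanceMatrix:
    """All-pairs p-distance matrix from aligned records.

    ``records`` maps label -> aligned row (equal lengths).  ``coverage``
    optionally restricts a record to its covered alignment columns
    (1-based inclusive), as for fragments.  In amino-acid mode, pairs
    involving a ``degenerate`` record (no meaningful conceptual
    translation) are marked not-computed, as are pairs with zero
    comparable sites in any mode.
    """
    labels = list(records)
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate labels")
    coverage = coverage or {}
    degenerate = degenerate or set()
    k = len(labels)
    d = np.zeros((k, k))
    n = np.zeros((k, k), dtype=int)
    se = np.zeros((k, k))
    nc: set[frozenset] = set()
    for i, j in itertools.combinations(range(k), 2):
        a, b = labels[i], labels[j]
        if mode == "aa" and (a in degenerate or b in degenerate):
            nc.add(frozenset((a, b)))
            d[i, j] = d[j, i] = np.nan
            continue
        try:
            dij, nij = p_distance(
                records[a], records[b], mode,
                coverage.get(a), coverage.get(b),
            )
        except NotComputable:
            nc.add(frozenset((a, b)))
            d[i, j] = d[j, i] = np.nan
            continue
        d[i, j] = d[j, i] = dij
        n[i, j] = n[j, i] = nij
        se[i, j] = se[j, i] = p_distance_se(dij, nij)
    return DistanceMatrix(labels, d, n, se, mode, nc)
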