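"""Distances between encoded sequences.

Two matrix distances between ``m x 5`` factor matrices:

* the *positional* distance — per-position Euclidean norms between matrix
  rows, summed over positions (the package default for tree building), and
* the *Frobenius* distance — a single square root over the total sum of
  squared entry differences, equivalently ``sqrt(tr((X-Y)^T (X-Y)))``.

The positional distance dominates the Frobenius distance (a sum of norms
versus the norm of the concatenation), with equality exactly when at most
one position differs.  For single-property waves the analogue is the
*sum-difference*: the L1 distance between the two numeric strings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .alignment import FactorMatrix, PropertyWave
from .exceptions import DimensionError, PropseqError

METRICS = ("positional", "frobenius", "sum_difference")


@dataclass
class DistanceMatrix:
    """Symmetric labelled distance matrix, the input to tree building."""

    taxa: tuple
    d: np.ndarray
    metric_name: str = "distance"
    #: free-form extras (e.g. clamp reports from statistic transforms)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.taxa = tuple(self.taxa)
        d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if d.shape != (n, n):
            raise DimensionError(f"distance matrix shape {d.shape} does not match {n} taxa")
        if not np.all(np.isfinite(d)):
            raise PropseqError("distance matrix has non-finite entries")
        if not np.allclose(d, d.T):
            raise PropseqError("distance matrix is not symmetric")
        if np.any(np.diag(d) != 0):
            raise PropseqError("distance matrix diagonal must be zero")
        if np.any(d < 0):
            raise PropseqError("distance matrix has negative entries")
        self.d = d

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def value(self, a: str, b: str) -> float:
        return float(self.d[self.taxa.index(a), self.taxa.index(b)])

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=list(self.taxa), columns=list(self.taxa))

    # -- interchange -------------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        """Square TSV with taxon header row and column."""
        self.as_frame().rename_axis("taxon").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path, metric_name: str = "distance") -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(tuple(df.index.astype(str)), df.to_numpy(dtype=float), metric_name)

    def to_phylip(self, path: str | Path) -> None:
        """PHYLIP square-matrix dialect (count line, then label + row)."""
        with open(path, "w") as fh:
            fh.write(f"{self.n_taxa}\n")
            for t, row in zip(self.taxa, self.d):
                fh.write(t + "  " + "  ".join(f"{v:.6f}" for v in row) + "\n")

    @classmethod
    def from_phylip(cls, path: str | Path, metric_name: str = "distance") -> "DistanceMatrix":
        with open(path) as fh:
            lines = [ln.split() for ln in fh if ln.strip()]
        n = int(lines[0][0])
        taxa = tuple(ln[0] for ln in lines[1 : n + 1])
        d = np.array([[float(v) for v in ln[1 : n + 1]] for ln in lines[1 : n + 1]])
        return cls(taxa, d, metric_name)


# --------------------------------------------------------------------------
# Elementary distances
# --------------------------------------------------------------------------

def position_distance(a, b) -> float:
    """Euclidean norm between two 5-vectors of state-space coordinates."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != (5,) or b.shape != (5,):
        raise DimensionError(f"expected 5-vectors, got shapes {a.shape} and {b.shape}")
    return float(np.linalg.norm(a - b))


def _mat(x) -> np.ndarray:
    return x.x if isinstance(x, FactorMatrix) else np.asarray(x, dtype=float)


def _wave(x) -> np.ndarray:
    return x.values if isinstance(x, PropertyWave) else np.asarray(x, dtype=float)


def matrix_distance_positional(X, Y) -> float:
    """Sum over positions of per-position Euclidean norms between matrix rows."""
    X, Y = _mat(X), _mat(Y)
    if X.shape != Y.shape:
        raise DimensionError(f"shape mismatch {X.shape} vs {Y.shape}")
    return float(np.linalg.norm(X - Y, axis=1).sum())


def frobenius_distance(X, Y) -> float:
    """Square root of the total sum of squared entry differences.

    Computed elementwise; identical (to rounding) to the trace form
    ``sqrt(tr((X-Y)^T (X-Y)))``.
    """
    X, Y = _mat(X), _mat(Y)
    if X.shape != Y.shape:
        raise DimensionError(f"shape mismatch {X.shape} vs {Y.shape}")
    return float(np.sqrt(((X - Y) ** 2).sum()))


def frobenius_distance_trace(X, Y) -> float:
    """Trace-form Frobenius distance, kept as an explicit cross-check."""
    X, Y = _mat(X), _mat(Y)
    if X.shape != Y.shape:
        raise DimensionError(f"shape mismatch {X.shape} vs {Y.shape}")
    D = X - Y
    return float(np.sqrt(np.trace(D.T @ D)))


def sum_difference(x, y) -> float:
    """L1 distance between two property waves (sum of |x_j - y_j|)."""
    x, y = _wave(x), _wave(y)
    if x.shape != y.shape:
        raise DimensionError(f"length mismatch {x.shape} vs {y.shape}")
    return float(np.abs(x - y).sum())


_METRIC_FNS = {
    "positional": matrix_distance_positional,
    "frobenius": frobenius_distance,
    "sum_difference": sum_difference,
}


def pairwise_distances(items, metric: str = "positional") -> DistanceMatrix:
    """All-pairs distance matrix over factor matrices or property waves.

    Parameters
    ----------
    items : list of FactorMatrix (metrics "positional"/"frobenius") or
        PropertyWave (metric "sum_difference"); labels are taken from the
        items' ``taxon`` fields.
    """
    if metric not in _METRIC_FNS:
        raise PropseqError(f"unknown metric {metric!r}; choose from {METRICS}")
    items = list(items)
    if len(items) < 2:
        raise DimensionError("need at least 2 items for a pairwise distance matrix")
    fn = _METRIC_FNS[metric]
    taxa = tuple(it.taxon for it in items)
    n = len(items)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = fn(items[i], items[j])
    return DistanceMatrix(taxa, d, metric)
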