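"""Whole-protein similarity statistics between property waves.

Three scalar similarity readouts compare two taxa's numeric strings:

* lag-0 normalized cross-covariance (the Pearson-type "autocorrelation"
  statistic, +1 perfect synchrony, -1 exact mirror image, 0 no linear
  relation);
* average mutual information AMI = H(X) + H(Y) - H(X,Y) from empirical
  frequency tables (nats by default);
* the box-counting estimate of the fractal dimension of the paired scatter
  (near 1 for identical waves, approaching 2 for independent ones).

Statistics can be averaged across properties and inverted (1/stat) into
distances for tree building.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .distances import DistanceMatrix
from .exceptions import DegenerateInputError, DimensionError, PropseqError

_LN2 = float(np.log(2.0))


@dataclass
class PairStatTable:
    """Symmetric table of a pairwise statistic over all taxa (diagonal = self)."""

    taxa: tuple
    stat_name: str
    values: np.ndarray

    def __post_init__(self):
        self.taxa = tuple(self.taxa)
        v = np.asarray(self.values, dtype=float)
        n = len(self.taxa)
        if v.shape != (n, n):
            raise DimensionError(f"stat table shape {v.shape} does not match {n} taxa")
        if not np.all(np.isfinite(v)):
            raise PropseqError("stat table has non-finite entries")
        if not np.allclose(v, v.T):
            raise PropseqError("stat table is not symmetric")
        self.values = v

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.taxa), columns=list(self.taxa))

    def to_tsv(self, path: str | Path) -> None:
        self.as_frame().rename_axis("taxon").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path, stat_name: str = "stat") -> "PairStatTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(tuple(df.index.astype(str)), stat_name, df.to_numpy(dtype=float))

    def to_long_csv(self, path: str | Path) -> None:
        """Long format (taxon_i, taxon_j, stat, value) for heatmap-style plotting."""
        rows = [
            (self.taxa[i], self.taxa[j], self.stat_name, self.values[i, j])
            for i in range(len(self.taxa))
            for j in range(len(self.taxa))
        ]
        pd.DataFrame(rows, columns=["taxon_i", "taxon_j", "stat", "value"]).to_csv(
            path, index=False
        )


def _wave(x) -> np.ndarray:
    return np.asarray(getattr(x, "values", x), dtype=float)


# --------------------------------------------------------------------------
# Correlation
# --------------------------------------------------------------------------

def autocorrelation(x, y, lag: int = 0) -> float:
    """Normalized cross-covariance between two waves at the given lag.

    At lag 0 this is the Pearson coefficient: cov(x,y)/(sd(x) sd(y)),
    in [-1, 1].  The algebraically exact endpoints (+1 for proportional
    waves, -1 for mirrored ones, 0 for exactly zero covariance) are returned
    exactly rather than up to rounding.

    Raises
    ------
    DegenerateInputError
        if either (lagged) wave has zero variance.
    """
    x, y = _wave(x), _wave(y)
    if x.shape != y.shape:
        raise DimensionError(f"length mismatch {x.shape} vs {y.shape}")
    m = len(x)
    if lag < 0 or lag >= m - 1:
        raise DimensionError(f"lag {lag} out of range for length {m}")
    if lag:
        x, y = x[: m - lag], y[lag:]
    if len(x) < 2:
        raise DimensionError("need at least 2 overlapping positions")
    xc = x - x.mean()
    yc = y - y.mean()
    dxx = float(xc @ xc)
    dyy = float(yc @ yc)
    if dxx == 0.0 or dyy == 0.0:
        raise DegenerateInputError("zero variance wave: correlation undefined")
    num = float(xc @ yc)
    if num == 0.0:
        return 0.0
    if num * num == dxx * dyy:  # exact |r| = 1 (identical / mirrored up to affine maps)
        return float(np.copysign(1.0, num))
    r = num / (np.sqrt(dxx) * np.sqrt(dyy))
    return float(min(1.0, max(-1.0, r)))


# --------------------------------------------------------------------------
# Entropy and mutual information
# --------------------------------------------------------------------------

def shannon_entropy(counts, unit: str = "nats") -> float:
    """Plug-in Shannon entropy of a count vector (-sum p log p over nonzero cells)."""
    counts = np.asarray(counts, dtype=float).ravel()
    if np.any(counts < 0):
        raise PropseqError("negative counts")
    total = counts.sum()
    if total <= 0:
        raise DegenerateInputError("empty distribution: all counts zero")
    p = counts[counts > 0] / total
    h = float(-(p * np.log(p)).sum())
    return h / _LN2 if unit == "bits" else h


def _discretize(x: np.ndarray, y: np.ndarray, mode: str, bins: int | None):
    """Map paired values to integer codes for contingency counting."""
    if mode == "categorical":
        return np.unique(x, return_inverse=True)[1], np.unique(y, return_inverse=True)[1]
    if mode == "equal_width_bins":
        b = bins if bins is not None else int(np.clip(np.ceil(np.sqrt(len(x))), 2, 20))
        if b < 2:
            raise PropseqError("need at least 2 bins")

        def code(v):
            lo, hi = v.min(), v.max()
            if hi == lo:
                return np.zeros(len(v), dtype=int)
            return np.minimum((b * (v - lo) / (hi - lo)).astype(int), b - 1)

        return code(x), code(y)
    raise PropseqError(f"unknown discretization mode {mode!r}")


def average_mutual_information(x, y, mode: str = "categorical",
                               bins: int | None = None, unit: str = "nats") -> float:
    """AMI = H(X) + H(Y) - H(X,Y) from empirical frequency tables.

    Property waves take at most 21 distinct values (20 residues plus the gap
    zero), so the default treats values as categories; ``equal_width_bins``
    handles genuinely continuous inputs (default bin count ``ceil(sqrt(m))``
    clamped to [2, 20]).  The tiny negative rounding residue of the plug-in
    estimator is clipped at zero.
    """
    x, y = _wave(x), _wave(y)
    if x.shape != y.shape:
        raise DimensionError(f"length mismatch {x.shape} vs {y.shape}")
    cx, cy = _discretize(x, y, mode, bins)
    joint = np.zeros((cx.max() + 1, cy.max() + 1))
    np.add.at(joint, (cx, cy), 1.0)
    hx = shannon_entropy(joint.sum(axis=1), unit)
    hy = shannon_entropy(joint.sum(axis=0), unit)
    hxy = shannon_entropy(joint, unit)
    return max(0.0, hx + hy - hxy)


# --------------------------------------------------------------------------
# Box-counting dimension
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BoxCountConfig:
    """Grid settings for the box-counting estimator.

    ``offsets > 1`` slides the grid origin over a uniform lattice of the box
    side and keeps the minimum occupied-box count per scale — a pattern-search
    style remedy for the quantization error of an arbitrary grid position.
    ``fit_range`` optionally restricts the log-log slope fit to a (start,
    stop) subrange of scale indices (0-based, stop exclusive).
    """

    n_scales: int = 6
    offsets: int = 1
    fit_range: tuple | None = None

    def __post_init__(self):
        if self.n_scales < 3:
            raise PropseqError("n_scales must be >= 3")
        if self.offsets < 1:
            raise PropseqError("offsets must be >= 1")


@dataclass(frozen=True)
class BoxCountResult:
    dimension: float
    scales: np.ndarray        # box subdivision exponents g = 1..n_scales
    counts: np.ndarray        # occupied boxes N_g (min over offsets)
    degenerate: bool = False

    def __float__(self) -> float:
        return self.dimension


def box_counts(x, y, cfg: BoxCountConfig = BoxCountConfig()) -> BoxCountResult:
    """Occupied-box counts of the (x_j, y_j) scatter at dyadic scales.

    The scatter is covered by the bounding square (side = larger coordinate
    range); at subdivision g the boxes have side ``side / 2**g``.
    """
    x, y = _wave(x), _wave(y)
    if x.shape != y.shape:
        raise DimensionError(f"length mismatch {x.shape} vs {y.shape}")
    m = len(x)
    if m < 8:
        raise DimensionError(f"need at least 8 points, got {m}")
    x0, y0 = x.min(), y.min()
    side = max(x.max() - x0, y.max() - y0)
    gs = np.arange(1, cfg.n_scales + 1)
    if side == 0.0:  # both waves constant: a single occupied box at every scale
        return BoxCountResult(0.0, gs, np.ones(cfg.n_scales), degenerate=True)
    counts = np.empty(cfg.n_scales)
    for i, g in enumerate(gs):
        b = side / 2**g
        best = np.inf
        for o in range(cfg.offsets):
            shift = o * b / cfg.offsets
            ix = np.floor((x - x0 + shift) / b).astype(np.int64)
            iy = np.floor((y - y0 + shift) / b).astype(np.int64)
            n_occ = len(np.unique(ix * (2 ** (g + 1) + 2) + iy))
            best = min(best, n_occ)
        counts[i] = best
    return BoxCountResult(np.nan, gs, counts)


def box_counting_dimension(x, y, cfg: BoxCountConfig = BoxCountConfig()) -> float:
    """Least-squares slope of ln N_g against ln 2^g — the box-counting dimension.

    Near 1 for identical waves (diagonal scatter), approaching 2 for
    independent ones.  Returns 0 for a both-constant scatter (single box at
    every scale; flagged degenerate in :func:`box_counts`).
    """
    res = box_counts(x, y, cfg)
    if res.degenerate:
        return 0.0
    sel = slice(*cfg.fit_range) if cfg.fit_range else slice(None)
    lx = res.scales[sel] * _LN2  # ln 2^g
    ly = np.log(res.counts[sel])
    if len(lx) < 2:
        raise PropseqError("fit_range leaves fewer than 2 scales")
    slope = np.polyfit(lx, ly, 1)[0]
    return float(slope)


# --------------------------------------------------------------------------
# Whole-table operations
# --------------------------------------------------------------------------

def pairwise_stat(waves, stat: str = "autocorrelation", **kwargs) -> PairStatTable:
    """Apply a pairwise statistic over all wave pairs (diagonal = self-statistic)."""
    fns = {
        "autocorrelation": autocorrelation,
        "ami": average_mutual_information,
        "box_counting": lambda a, b: box_counting_dimension(
            a, b, kwargs.get("cfg", BoxCountConfig())
        ),
    }
    if stat not in fns:
        raise PropseqError(f"unknown statistic {stat!r}")
    fn = fns[stat]
    if stat != "box_counting":
        fn_kwargs = kwargs
    else:
        fn_kwargs = {}
    waves = list(waves)
    n = len(waves)
    taxa = tuple(w.taxon for w in waves)
    v = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            v[i, j] = v[j, i] = fn(waves[i], waves[j], **fn_kwargs)
    return PairStatTable(taxa, stat, v)


def combine_over_properties(stats) -> PairStatTable:
    """Elementwise mean of per-property statistic tables (same taxa required)."""
    stats = list(stats)
    if not stats:
        raise PropseqError("no tables to combine")
    taxa = stats[0].taxa
    for s in stats[1:]:
        if s.taxa != taxa:
            raise PropseqError("taxa mismatch between statistic tables")
    mean = np.mean([s.values for s in stats], axis=0)
    return PairStatTable(taxa, f"mean_{stats[0].stat_name}", mean)


#: Floor applied to non-positive statistics before inversion so that trees
#: remain constructible; clamped cells are reported, not silently absorbed.
INVERSE_EPS = 1e-9


def stat_to_distance(stat: PairStatTable, transform: str = "inverse") -> DistanceMatrix:
    """Turn a similarity statistic into a distance matrix (d = 1/stat off-diagonal).

    Non-positive statistics are clamped to ``INVERSE_EPS``; the affected
    (taxon_i, taxon_j) pairs are listed in ``result.meta["clamped"]``.
    """
    if transform != "inverse":
        raise PropseqError(f"unknown transform {transform!r}")
    n = len(stat.taxa)
    d = np.zeros((n, n))
    clamped = []
    for i in range(n):
        for j in range(i + 1, n):
            v = stat.values[i, j]
            if v < INVERSE_EPS:
                clamped.append((stat.taxa[i], stat.taxa[j]))
                v = INVERSE_EPS
            d[i, j] = d[j, i] = 1.0 / v
    return DistanceMatrix(
        stat.taxa, d, f"inv_{stat.stat_name}", meta={"clamped": clamped}
    )
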