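"""Regional mutability summaries.

Localizes mutable versus conserved stretches of a protein family:

* per-residue distance profiles of each taxon's factor matrix against a
  reference — either the hypothetical "average amino acid" (the residue
  centroid in the 5-dimensional state space) or a designated parent taxon's
  matrix (the natural mode for variant series such as viral lineages);
* a positions x taxa heatmap table of those profiles, optionally with
  average-linkage hierarchical orderings of rows and/or columns (values are
  never altered by the ordering);
* per-position mean/sd profiles of property waves across species — large
  scatter flags evolutionarily unstable regions;
* weighted edge-list export of a factor matrix (position nodes vs factor-axis
  nodes) for graph tooling.

With the normalized factor table the average-amino-acid reference is the
zero vector, so gap rows score ~0 there — a documented artifact of the
zero-vector gap encoding.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .alignment import FactorMatrix
from .distances import DistanceMatrix
from .exceptions import DimensionError, PropseqError
from .phylo import upgma
from .tables import FactorTable, average_amino_acid


def residue_profile(X: FactorMatrix | np.ndarray, reference) -> np.ndarray:
    """Per-position Euclidean distance of a factor matrix to a reference.

    ``reference`` is either a 5-vector (every position scored against it) or
    an equally long matrix (positionwise comparison, e.g. a parent sequence).
    """
    x = X.x if isinstance(X, FactorMatrix) else np.asarray(X, dtype=float)
    ref = reference.x if isinstance(reference, FactorMatrix) else np.asarray(
        reference, dtype=float
    )
    if ref.ndim == 1:
        if ref.shape != (5,):
            raise DimensionError(f"vector reference must be a 5-vector, got {ref.shape}")
        diff = x - ref[None, :]
    else:
        if ref.shape != x.shape:
            raise DimensionError(f"matrix reference shape {ref.shape} != {x.shape}")
        diff = x - ref
    return np.linalg.norm(diff, axis=1)


@dataclass
class HeatmapTable:
    """Positions x taxa table of per-residue reference distances.

    ``row_order``/``col_order`` are permutations (indices into positions and
    taxa) from hierarchical clustering; the cell values themselves are never
    reordered in storage.
    """

    taxa: tuple
    positions: np.ndarray
    values: np.ndarray  # shape (m, n_taxa)
    row_order: np.ndarray
    col_order: np.ndarray
    meta: dict = field(default_factory=dict)

    def as_frame(self, ordered: bool = False) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.positions, columns=list(self.taxa))
        df.index.name = "position"
        if ordered:
            df = df.iloc[self.row_order, self.col_order]
        return df

    def to_csv(self, path: str | Path, ordered: bool = False) -> None:
        self.as_frame(ordered).to_csv(path)

    def orders_to_json(self, path: str | Path) -> None:
        payload = {
            "row_order": [int(i) for i in self.row_order],
            "col_order": [int(i) for i in self.col_order],
            "taxa": list(self.taxa),
            **self.meta,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _cluster_order(mat: np.ndarray, labels) -> np.ndarray:
    """Leaf order of an average-linkage (UPGMA) dendrogram over the rows of mat."""
    n = mat.shape[0]
    if n < 2:
        return np.arange(n)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = float(np.linalg.norm(mat[i] - mat[j]))
    dm = DistanceMatrix(tuple(labels), d, "euclidean")
    tree = upgma(dm)
    index = {l: i for i, l in enumerate(labels)}
    return np.array([index[name] for name in tree.leaf_names])


def heatmap_table(matrices, reference_mode: str = "average_aa",
                  parent: str | None = None, table: FactorTable | None = None,
                  cluster: str = "none") -> HeatmapTable:
    """Assemble the per-residue reference-distance heatmap over a family.

    Parameters
    ----------
    matrices : list of FactorMatrix (one per taxon, equal row counts).
    reference_mode : "average_aa" (residue-centroid 5-vector of ``table``)
        or "parent" (positionwise distance to the ``parent`` taxon's matrix).
    cluster : {"none", "rows", "cols", "both"} — average-linkage orderings.
    """
    from .tables import factor_table as _default_table

    matrices = list(matrices)
    if not matrices:
        raise PropseqError("no matrices")
    m = matrices[0].length
    for X in matrices:
        if X.length != m:
            raise DimensionError("factor matrices have unequal row counts")
    taxa = tuple(X.taxon for X in matrices)
    if reference_mode == "average_aa":
        reference = average_amino_acid(table if table is not None else _default_table())
    elif reference_mode == "parent":
        if parent is None or parent not in taxa:
            raise PropseqError(f"unknown parent taxon {parent!r}")
        reference = matrices[taxa.index(parent)]
    else:
        raise PropseqError(f"unknown reference mode {reference_mode!r}")
    values = np.column_stack([residue_profile(X, reference) for X in matrices])
    positions = np.arange(1, m + 1)
    row_order = np.arange(m)
    col_order = np.arange(len(taxa))
    if cluster not in ("none", "rows", "cols", "both"):
        raise PropseqError(f"unknown cluster mode {cluster!r}")
    # zero-padded position labels keep the tie rule's lexicographic order natural
    if cluster in ("rows", "both"):
        row_order = _cluster_order(values, [f"pos{j:06d}" for j in positions])
    if cluster in ("cols", "both"):
        col_order = _cluster_order(values.T, list(taxa))
    return HeatmapTable(
        taxa, positions, values, row_order, col_order,
        meta={"reference_mode": reference_mode, "parent": parent, "cluster": cluster},
    )


def position_profile(waves) -> pd.DataFrame:
    """Per-position mean and sample sd of property waves across species.

    Positions with large sd mark evolutionarily unstable regions.
    """
    waves = list(waves)
    if len(waves) < 2:
        raise DimensionError("need at least 2 waves")
    m = len(waves[0].values)
    for w in waves:
        if len(w.values) != m:
            raise DimensionError("waves have unequal lengths")
    arr = np.stack([w.values for w in waves])
    return pd.DataFrame(
        {
            "position": np.arange(1, m + 1),
            "mean": arr.mean(axis=0),
            "sd": arr.std(axis=0, ddof=1),
        }
    )


def adjacency_edges(X: FactorMatrix) -> pd.DataFrame:
    """Weighted bipartite edge list of a factor matrix.

    One edge per (position j, factor axis k) with weight ``x[j, k]``; node
    labels ``pos:j`` (1-based) and ``factor:k`` (E1..E5), j-major order.
    Consumable by any graph tool as a standard 3-column weighted edge list.
    """
    m = X.length
    records = [
        (f"pos:{j + 1}", f"factor:E{k + 1}", X.x[j, k])
        for j in range(m)
        for k in range(5)
    ]
    return pd.DataFrame(records, columns=["node_a", "node_b", "weight"])


def write_edge_tsv(edges: pd.DataFrame, path: str | Path) -> None:
    edges.to_csv(path, sep="\t", index=False, header=False)
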