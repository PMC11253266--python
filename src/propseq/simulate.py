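"""Synthetic protein families with known history.

Generates random rooted ultrametric trees and evolves aligned amino-acid
families along them, so that every downstream stage (encoding, distances,
statistics, tree building) can be exercised against a known ground truth
without any sequence downloads.

The process is deliberately simple machinery, not an empirical substitution
model: per-site Poisson substitutions whose replacement choice can be biased
toward physicochemically similar residues (a temperature parameter over
factor-space distances, emulating selective pressure), and shared indel
events applied on the tree so homology is preserved and the rows come out
aligned without re-alignment.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .alignment import Alignment
from .exceptions import ConfigError
from .phylo import Dendrogram, Node, to_newick
from .tables import AA_LETTERS, factor_table


@dataclass(frozen=True)
class EvolutionConfig:
    """Study conditions for a simulated family.

    Defaults describe a moderate benchmark family: 8 taxa, 300 positions,
    and a substitution rate of 0.15 per site per unit branch length — with a
    unit-height tree this yields on the order of 15 substitutions per branch,
    enough signal for distance methods without saturating.  ``tau`` biases
    replacements toward factor-space neighbours of the original residue
    (0 = uniform over the other 19).  Gap blocks arrive as Poisson events per
    branch with geometric lengths and are inherited by the whole subtree.
    """

    n_taxa: int = 8
    sequence_length: int = 300
    substitution_rate: float = 0.15
    tau: float = 0.0
    gap_block_rate: float = 0.0
    mean_gap_length: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.n_taxa < 2:
            raise ConfigError("n_taxa must be >= 2")
        if self.sequence_length < 1:
            raise ConfigError("sequence_length must be >= 1")
        if self.substitution_rate < 0 or self.gap_block_rate < 0 or self.tau < 0:
            raise ConfigError("rates and tau must be >= 0")
        if self.mean_gap_length < 1:
            raise ConfigError("mean_gap_length must be >= 1")


def random_tree(n_taxa: int, seed: int = 0) -> Dendrogram:
    """Random rooted ultrametric tree with unit root height.

    Clusters merge in random pairs; successive merge heights grow by
    increments drawn as 0.5 + U(0,1) and are rescaled so the root sits at
    height 1 — consecutive merge levels therefore never come closer than a
    third of the largest spacing, keeping branch lengths well separated.
    """
    if n_taxa < 2:
        raise ConfigError("n_taxa must be >= 2")
    rng = np.random.default_rng(seed)
    increments = 0.5 + rng.random(n_taxa - 1)
    heights = np.cumsum(increments)
    heights /= heights[-1]
    clusters = [Node(0.0, name=f"t{i + 1}") for i in range(n_taxa)]
    for h in heights:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        a, b = clusters[i], clusters[j]
        left, right = (a, b) if min(a.leaf_names()) <= min(b.leaf_names()) else (b, a)
        merged = Node(float(h), children=(left, right))
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    return Dendrogram(clusters[0])


def _substitution_weights(tau: float) -> np.ndarray:
    """20x20 replacement weights: exp(-factor distance / tau), zero diagonal."""
    coords = factor_table().matrix()
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    if tau == 0:
        w = np.ones((20, 20))
    else:
        w = np.exp(-d / tau)
    np.fill_diagonal(w, 0.0)
    return w / w.sum(axis=1, keepdims=True)


def evolve_alignment(tree: Dendrogram, cfg: EvolutionConfig) -> Alignment:
    """Simulate an aligned family along a tree.

    The root sequence is uniform over the 20 residues; on each branch every
    (non-deleted) site substitutes with probability ``1 - exp(-rate * bl)``,
    and gap-block deletion events (Poisson per branch, geometric lengths)
    mask runs of positions for the entire descendant subtree.  Output rows
    share length ``sequence_length``.
    """
    rng = np.random.default_rng(cfg.seed)
    m = cfg.sequence_length
    weights = _substitution_weights(cfg.tau)
    letters = np.array(list(AA_LETTERS))
    root_seq = rng.integers(0, 20, size=m)
    rows: dict = {}

    def descend(node: Node, seq: np.ndarray, gap_mask: np.ndarray, parent_h: float):
        bl = parent_h - node.height
        seq = seq.copy()
        gap_mask = gap_mask.copy()
        if bl > 0:
            p_sub = 1.0 - np.exp(-cfg.substitution_rate * bl)
            hit = (rng.random(m) < p_sub) & ~gap_mask
            for j in np.nonzero(hit)[0]:
                seq[j] = rng.choice(20, p=weights[seq[j]])
            n_events = rng.poisson(cfg.gap_block_rate * bl)
            for _ in range(n_events):
                start = rng.integers(0, m)
                length = rng.geometric(1.0 / cfg.mean_gap_length)
                gap_mask[start : start + length] = True
        if node.is_leaf:
            chars = letters[seq].copy()
            chars[gap_mask] = "-"
            rows[node.name] = "".join(chars)
        else:
            for child in node.children:
                descend(child, seq, gap_mask, node.height)

    root = tree.root
    descend(root, root_seq, np.zeros(m, dtype=bool), root.height)
    taxa = tuple(tree.leaf_names)
    return Alignment(taxa, tuple(rows[t] for t in taxa))


def simulate_family(cfg: EvolutionConfig) -> tuple[Dendrogram, Alignment]:
    """Convenience wrapper: random tree (same seed) plus evolved alignment."""
    tree = random_tree(cfg.n_taxa, cfg.seed)
    return tree, evolve_alignment(tree, cfg)


def write_fixture(directory: str | Path, cfg: EvolutionConfig) -> dict:
    """Write an aligned FASTA, ground-truth Newick, and a JSON manifest.

    Returns the manifest (paths and configuration)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tree, aln = simulate_family(cfg)
    fasta = directory / "alignment.fasta"
    newick = directory / "true_tree.nwk"
    manifest_path = directory / "manifest.json"
    aln.to_fasta(fasta)
    newick.write_text(to_newick(tree) + "\n")
    manifest = {
        "alignment": fasta.name,
        "true_tree": newick.name,
        "config": asdict(cfg),
    }
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest
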