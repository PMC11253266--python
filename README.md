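# propseq

Quantitative protein phylogenetics from physicochemical property encodings.

Classical distance-based phylogenetics scores aligned protein sequences by
letter match/mismatch, discarding everything chemistry knows about the
residues. `propseq` instead re-expresses each aligned sequence numerically
and analyzes the numbers:

* **Property waves** — each residue replaced by one measured physicochemical
  value (side-chain volume, isoelectric point, octanol partition free
  energy), gaps by 0, giving equal-length numeric strings per taxon.
* **Factor matrices** — each residue replaced by its 5-vector of coordinates
  in the standard five-factor amino-acid state space (axes normalized to
  mean 0 / sd 1 over the 20 residues), giving an *m* × 5 matrix per taxon
  with all-zero rows at gaps.

From these encodings the package computes, for *n* taxa with *m* aligned
positions (x<sub>ijk</sub> = descriptor *k* of position *j* in taxon *i*):

* **Positional matrix distance** (the default tree input):
  d(i,i′) = Σ<sub>j</sub> √(Σ<sub>k</sub> (x<sub>ijk</sub> − x<sub>i′jk</sub>)²)
  — and the **Frobenius distance**
  √(Σ<sub>j</sub>Σ<sub>k</sub> (x<sub>ijk</sub> − x<sub>i′jk</sub>)²) =
  √tr((X−X′)ᵀ(X−X′)). The positional form always dominates the Frobenius
  form, with equality exactly when at most one position differs.
* **Similarity statistics** between property waves: the lag-0 normalized
  cross-covariance (Pearson-type, +1 synchrony / −1 mirror image / 0 none),
  average mutual information AMI = H(X) + H(Y) − H(X,Y) from empirical
  frequency tables, and the box-counting fractal dimension of the paired
  scatter (≈1 for identical waves, →2 for independent ones), all averageable
  across properties and invertible (1/stat) into tree distances.
* **Rooted dendrograms**: UPGMA/WPGMA on any distance matrix, the stepwise
  sum-difference procedure on raw waves (merge closest strings, replace by
  their positionwise mean, repeat), and the analogous stepwise scheme on
  inverted statistics; Newick output, monophyly and leaf-ranking checks.
* **Bivariate Morlet wavelet analysis** of two waves — cross power,
  coherence (bounded [0,1]), phase difference, scale-averaged power, cone of
  influence, white-noise surrogate significance — localizing scales and
  positions where two proteins' property profiles co-vary.
* **Regional mutability**: per-residue distance profiles against a reference
  (the hypothetical "average amino acid" centroid or a parent sequence),
  clustered heatmap tables, per-position mean/sd profiles across species,
  and weighted edge-list export of factor matrices.
* **Simulation**: random ultrametric trees and alignments evolved along
  them, so every stage is testable against a known ground truth.

## Worked example

```python
import propseq as ps

# a simulated 5-taxon family, 120 aligned positions, known true tree
tree, aln = ps.simulate_family(ps.EvolutionConfig(n_taxa=5, sequence_length=120, seed=1))

mats = ps.factor_matrices(aln, ps.factor_table())
dm = ps.pairwise_distances(mats, metric="positional")
print(dm.as_frame().round(1))
est = ps.upgma(dm)
print(ps.to_newick(est, precision=4))
print("topology recovered:", est.clades() == tree.clades())
```

prints

```
      t1     t2    t4     t3    t5
t1   0.0   15.2  46.0   96.3  75.6
t2  15.2    0.0  56.8  107.1  86.4
t4  46.0   56.8   0.0   80.4  64.7
t3  96.3  107.1  80.4    0.0  55.5
t5  75.6   86.4  64.7   55.5   0.0
(((t1:7.618,t2:7.618):18.1,t4:25.71):16.82,(t3:27.74,t5:27.74):14.79);
topology recovered: True
```

The matrix entries are positional distances in normalized factor units
summed over 120 positions: t1 and t2 are each other's closest relatives
(15.2) and merge first at height 7.6; the dendrogram groups {t1,t2,t4} and
{t3,t5} exactly as in the simulated history. The same alignment viewed
through one property gives the correlation statistic per pair,

```python
waves = ps.property_waves(aln, ps.default_property_tables()["volume"])
print(ps.pairwise_stat(waves, "autocorrelation").as_frame().round(3))
```

```
       t1     t2     t4     t3     t5
t1  1.000  0.978  0.816  0.695  0.705
t2  0.978  1.000  0.818  0.697  0.707
t4  0.816  0.818  1.000  0.764  0.778
t3  0.695  0.697  0.764  1.000  0.832
t5  0.705  0.707  0.778  0.832  1.000
```

— the self-diagonal is exactly 1, and the closest pair (t1,t2) again stands
out at 0.978. `ps.stat_merge_tree` turns 1/these values into a dendrogram.

The same workflow is scriptable from the shell:

```
propseq simulate --seed 1 --n-taxa 5 --length 120 --out-dir sim
propseq pipeline --input sim/alignment.fasta --out-dir run   # distances.tsv, tree.nwk
propseq wavelet  --input sim/alignment.fasta --taxon-x t1 --taxon-y t2 --property volume
propseq heatmap  --input sim/alignment.fasta --cluster both
```

Every subcommand writes a JSON manifest of its parameters (including seeds)
next to its outputs.

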