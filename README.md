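# mitonet

Anchored gene co-expression network inference with PCIT.

`mitonet` reconstructs a co-expression network centred on a predefined
*anchor* gene set — the motivating use case is the mRNA encoding the
mitochondrial proteome in a large multi-tissue RNA-seq atlas — and provides
the downstream analyses such a network supports: topology statistics
(degree, sub-networks, radiality), overlay of differential-expression fold
changes from independent experiments, and a transcription-factor-augmented
network with a TF-relevance filter.  It is aimed at systems biologists who
want a reproducible, scriptable version of this workflow instead of a chain
of one-off scripts and GUI plugins.

## Method

Edges are decided by the **partial correlation and information theory
(PCIT)** algorithm.  Given the product-moment correlation matrix *r* over
all gene pairs, every unordered trio (x, y, z) is examined.  The first-order
partial correlations, e.g.

```
r_xy·z = (r_xy − r_xz·r_yz) / √((1 − r_xz²)(1 − r_yz²))
```

measure the association of two genes after removing the third's linear
effect.  The trio's data-driven tolerance is the mean ratio

```
ε = ⅓ (|r_xy·z / r_xy| + |r_xz·y / r_xz| + |r_yz·x / r_yz|)
```

and the pair (x, y) is *eliminated* within the trio when

```
|r_xy| ≤ ε·|r_xz|   and   |r_xy| ≤ ε·|r_yz| ,
```

i.e. when its direct correlation is explainable through z.  A pair is
significant iff **no** trio eliminates it.  Significant pairs with
|r| ≥ 0.7 (the default cutoff) become weighted, undirected edges.  Because
no scale-free topology is imposed, a heavy-tailed degree distribution in
the result is an empirical finding, not an artefact of the method.

On top of the network, the package computes per-node degree, connected
components (sub-networks), neighbourhoods, and **radiality** — a
closeness-like centrality normalised per component,
`Rad(v) = (Δ + 1 − mean distance from v) / Δ` with Δ the component
diameter — plus:

- **anchor selection**: (distinct ortholog-map targets ∪ organelle-encoded
  genes) ∩ expressed genes, with stage counts;
- **CPM filter**: keep genes with ≥ 1 CPM in at least half the samples;
- **DE overlay**: attach per-contrast log2 fold changes and
  up/down/unaffected classes to nodes, and query genes consistently up- or
  downregulated across *all* contrasts;
- **TF network**: add a TF list to the anchors, rerun PCIT, then drop every
  TF with strictly more connections to other TFs than to anchor genes, and
  rank the survivors by degree and radiality.

A seeded synthetic-data generator with planted block-correlation modules,
a quasi-isolated cluster (the mtDNA-like sub-network analog), planted
low-expression genes and planted consistently-signed DE genes gives every
stage a recoverable ground truth.

## Worked example

Generate a synthetic dataset (five 20-gene modules at ρ = 0.85, a 28-gene
isolated cluster, 40 background genes, 20 TFs, 200 samples) and run the
full pipeline:

```bash
mitonet simulate --out-dir demo/data --seed 1
cat > demo/config.yaml <<EOF
expression_path: demo/data/expression.tsv
orthologs_path: demo/data/orthologs.tsv
organelle_path: demo/data/organelle_genes.txt
catalog_path: demo/data/catalog.tsv
tf_path: demo/data/tf_genes.txt
overlay_path: demo/data/overlay.tsv
counts_path: demo/data/counts.tsv
output_dir: demo/out
seed: 1
EOF
mitonet run --config demo/config.yaml
```

The run logs (stderr):

```
mitonet INFO expression: 188 genes x 200 samples
mitonet INFO anchor selection: mapped=100 union=128 present=128
mitonet INFO pcit: 128 genes, 2023/8128 significant pairs, 1328 edges at |r|>=0.70
mitonet INFO topology: 128 nodes, 6 components
mitonet INFO overlay: 2 consistent up, 7 down
mitonet INFO tf network: 5 retained, 0 excluded
```

Reading the numbers: 100 ortholog-mapped genes plus 28 organelle-encoded
genes give 128 anchors, all present in the expression matrix.  PCIT keeps
2023 of the 8128 candidate pairs and the |r| ≥ 0.7 cutoff leaves 1328
edges — exactly the 950 within-module pairs plus the 378 isolated-cluster
pairs (`report.json` records `within_module_recall: 1.0`).  The network
splits into 6 components: the five planted modules and the isolated
28-gene cluster, which separates from everything else just as an
organelle-genome sub-network would.  The overlay finds the 9 genes planted
with a consistent sign across all six contrasts (2 up, 7 down), and all 5
TFs that reached the network are retained by the TF filter (they sit
inside anchor modules, so anchor connections dominate).  `demo/out/`
contains the edge list, SIF and GraphML exports, the topology table, the
overlay-annotated network and a `report.json` echoing config and stage
counts; rerunning the command reproduces every file byte-for-byte.

Each stage is also available separately (`mitonet select-genes`, `pcit`,
`topology`, `overlay`, `tf-network`) and as library functions
(`mitonet.pcit_significance`, `mitonet.radiality`, ...).

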