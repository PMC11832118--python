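# Methods

## The model

`mitonet` treats co-expression network reconstruction as a three-stage
decision: (1) estimate all pairwise product-moment correlations of an
FPKM-like genes × samples matrix; (2) decide pairwise *significance* with
the PCIT trio-elimination rule; (3) threshold surviving pairs on
correlation magnitude.  The rationale for PCIT over a plain correlation
cutoff is that a strong r_xy may be entirely mediated by a third gene z;
comparing each direct correlation against the trio's first-order partial
correlations removes such redundant edges without any distributional
p-value machinery, and without forcing a scale-free topology on the
result.

For every unordered trio (x, y, z):

- partial correlations
  `r_xy·z = (r_xy − r_xz r_yz) / √((1 − r_xz²)(1 − r_yz²))` (cyclically for
  the other two pairs);
- tolerance `ε = ⅓ Σ |partial/direct|` over the three pairs;
- pair (x, y) is eliminated in this trio iff `|r_xy| ≤ ε|r_xz|` **and**
  `|r_xy| ≤ ε|r_yz|`.

A pair is significant iff no trio eliminates it (with only two genes no
trio exists and the pair is vacuously significant).  Elimination by *any*
trio is what produces PCIT's characteristic sparsity (a few percent edge
density on real atlases).

## Numerical conventions

These choices pin down behaviour on degenerate inputs and make the fast
kernel bit-reproducible against the brute-force oracle:

- **Zero-direct-correlation guard.** A ratio whose direct correlation has
  magnitude < 1e−12 contributes 0 to ε (the ratio is otherwise undefined
  for orthogonal pairs); non-degenerate trios are unaffected.
- **Vacuous-tolerance guard.** A trio with ε = 0 eliminates nothing.
  Without this, an all-zero correlation matrix would eliminate every pair
  through the inclusive ≤ comparison, which inverts the rule's intent —
  a zero tolerance carries no evidence of mediation.
- **ε term ordering.** The three ratio terms are sorted numerically before
  the `(a + b) + c` summation.  Floating-point addition is commutative but
  not associative, so without sorting the same trio could yield ε values
  differing in the last ulp depending on which pair is being tested or how
  genes are ordered.  Sorting makes ε a symmetric function of the trio,
  hence the mask exactly permutation-equivariant.
- **Canonical gene order.** Both implementations sort gene ids before trio
  enumeration and map the mask back, so results are input-order
  independent.
- **Exact comparisons.** All elimination comparisons are exact on doubles;
  the compiled kernel (numba, no fastmath) and the pure-Python oracle
  execute the same expression sequence and agree bit-for-bit — the test
  suite asserts mask equality on 100 random instances.
- **Collinearity.** Off-diagonal |r| = 1 is rejected (the partial
  correlation denominator vanishes); callers must deduplicate perfectly
  collinear genes.  Correlation estimates are symmetrised
  (`(R + Rᵀ)/2`) because BLAS matrix products are not exactly symmetric,
  then clipped to [−1, 1] with the diagonal pinned to 1.
- **Threshold.** `|r| ≥ cutoff` is inclusive by default (a strict mode is
  exposed); for continuous data the two differ only on a measure-zero set.
  Default cutoff 0.7.

The kernel enumerates all C(n,3) trios in O(n³/6); at 1139 genes
(≈ 2.5 × 10⁸ trios) it completes in under 10 s on one CPU, which is the
atlas-scale regime the acceptance script times.

## Topology statistics

The network is an undirected weighted `networkx` graph whose node set is
exactly the set of edge endpoints — anchor genes that retain no edge do
not appear, which is why a real network can have far fewer nodes than the
anchor list.  Degree, degree histogram, connected components (largest
first, ties broken on the lexicographically first member) and sorted
neighbourhoods are standard.

**Radiality** is computed per component: for node v in component C with
hop-count diameter Δ ≥ 1,
`Rad(v) = (Δ + 1 − mean_{w≠v} d(v, w)) / Δ ∈ [0, 1]`, reaching 1 iff v is
adjacent to every other node of C.  Published radiality rankings for
networks of this kind report values in [0, 1] on this convention, but no
closed formula usually accompanies them; the within-component,
diameter-normalised form is adopted here and validated against closed
forms (star centre 1.0, star-on-5 leaf 0.625, complete graph 1.0) and a
brute-force Floyd–Warshall oracle.  Cross-component distances are treated
as undefined rather than infinite, and singleton components have no
radiality (NaN).  Edge weights never enter the distances.

Hand-drawn module boundaries from force-directed layouts are deliberately
out of scope: the package reports components, neighbourhoods and attribute
queries, not a re-derivation of visually delineated modules.

## Anchor selection, overlay, TF filter

- Anchor set = (distinct ortholog-map **target** ids ∪ organelle-encoded
  list) ∩ expressed genes.  Many-to-one ortholog mappings collapse to
  distinct targets (the count semantics of "genes", not "mappings");
  matching is exact and case-sensitive.  An empty intersection raises an
  error carrying the stage counts, since it almost always signals an
  id-namespace mismatch.
- CPM filter: keep genes with CPM ≥ 1 in at least half the samples;
  "at least half" uses the ceiling rule for odd n.  Library sizes default
  to column sums but can be supplied.
- Node classification is dual-mode because published overlays rarely state
  whether "unaffected" meant a failed significance test or a small fold
  change: with a DE flag, the flag gates the sign; without one, a
  configurable |log2fc| floor (default 0) does.  Missing (gene, contrast)
  values classify as unaffected, never error — every node gets a colour.
- Cross-contrast consistency: a gene is consistent iff its class equals
  the queried direction in *every* contrast; genes missing any contrast
  are excluded.  Up- and down-consistent sets are disjoint by
  construction.
- TF filter: a TF-only node is removed iff it has strictly more TF-only
  neighbours than anchor neighbours, counts evaluated simultaneously on
  the unfiltered graph (single pass).  Genes that are both TF and anchor
  count as anchors on the neighbour side and are exempt from removal —
  the filter targets *additional* TFs, not anchor genes that happen to be
  TFs.  Ties retain ("more than" is strict).  A sequential re-evaluating
  variant would keep the second member of a mutually dependent TF pair;
  the single-pass semantics is symmetric and order-independent, and the
  test suite pins it with exactly that example.

## Synthetic data

The generator emulates the statistical regime of a large multi-tissue
expression atlas, not its biology:

- **Expression.** Multivariate normal in log space, exponentiated.
  Modules are compound-symmetric blocks (constant within-module ρ, zero
  across blocks) — the simplest positive-definite planted structure with
  one recall/precision knob.  The isolated cluster (default 28 genes,
  ρ = 0.9) has zero correlation to everything else, giving
  `connected_components` a planted ground truth analogous to an
  organelle-genome sub-network.  Log-space location 3.0 and scale 0.5:
  exponentiation of a lognormal attenuates a planted correlation ρ to
  (e^{ρs²} − 1)/(e^{s²} − 1), which at s = 0.5 is a < 2 % loss, so the
  planted ρ remains interpretable on the FPKM-like scale where the
  pipeline correlates.  Negative-correlation blocks are not simulated
  (thresholding on real atlas data retains positive edges only).
- **Defaults as study conditions.** Five 20-gene modules at ρ = 0.85,
  40 background genes, 200 samples — the planted-recovery regime the test
  suite asserts (recall ≥ 0.90, cross-module false edges ≤ 1 %); six
  contrasts; 20 standalone TFs plus one TF planted inside each module
  (a gene that is both TF and anchor, exercising the "both" label).  The
  atlas-scale feasibility check uses 1139 genes × 723 samples.
- **Counts.** Per-gene Poisson rates around a lognormal depth with
  heterogeneous (0.5–2×) library scales; a designated subset of background
  genes (default 5) is planted at ~0.05 expected counts per sample, far
  below 1 CPM, so the CPM filter's casualties are known exactly.
- **Overlay.** A seeded fraction (default 5 %) of genes gets one sign
  across all contrasts with magnitudes 0.25–2 (mostly sub-2-fold, the
  regime where network overlay beats gene-by-gene testing); the rest draw
  independent N(0, 1) values.  In the default flag mode, planted genes are
  DE in every contrast and background genes only where |log2fc| > 1.5, so
  the consistency query recovers the planted sets exactly.  In sign-only
  mode (no flag) a background gene is chance-consistent with probability
  2·0.5^k over k contrasts — the analytic rate the generator tests pin.
- **Determinism.** One `numpy` Generator per output family, seeded from
  `(stream, seed)`, so expression, counts and overlay are independent but
  each is bit-reproducible.

What passing these tests does **not** show: real atlases have tissue
hierarchies, batch effects, heteroscedastic noise, overlapping modules and
negative correlations; recovery rates on the generator are upper bounds,
and the planted defaults are a calibration regime, not a claim about
biological effect sizes.

## Known limitations

- PCIT conditions on single genes only (first-order partials); mediation
  through gene *sets* is invisible to it.
- The significance decision is tolerance-based, not probabilistic: no
  error rates are attached to edges.
- Radiality rankings from other tools can differ if those tools normalise
  across, rather than within, components, or treat disconnected pairs as
  finite-distance.
- The DE model producing the overlay table is out of scope by design; the
  package consumes (gene, contrast, log2fc[, is_de]) tables as given.
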