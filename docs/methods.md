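# Methods

## The scoring model

A pathway collection is a set of `M` pathways `P = {p_1, …, p_M}` over a
gene universe. Each pathway is an undirected graph of node boxes; a box
holds one gene (`single`), a set of interchangeable homologs
(`homolog_group`), or the subunits of a protein complex (`complex`). A
mined gene set `T` is scored against pathway `p` as

    score(T, p) = Σ_j Weight(node_j, p) · Score(T, node_j)

with three orthogonal components.

**Gene weight.** `w(g) = log(M / df(g))`, where `df(g)` is the number of
pathways whose gene union contains `g`. `df ≥ 1` for every indexed gene,
so no smoothing term is needed; `w = 0` iff the gene is in every pathway.
The log base (default: natural) rescales all weights by one constant, so
every ranking the package produces is base-invariant. Mined genes outside
the collection carry weight 0 and drop out of every node intersection
("skip-unknown"); this is deliberate — text-mined sets routinely contain
genes the pathway database does not know.

**Node score.** With aggregation on, `single` and `homolog_group` boxes
score `max{ w(g) : g ∈ box ∩ T }` (interchangeable genes are a single
piece of evidence; hitting three homologs is no stronger than hitting the
most specific one), and `complex` boxes score
`(|box ∩ T| / |box|) · Σ_{g ∈ box ∩ T} w(g)` — the completeness
coefficient discounts partially covered complexes, whose subunits only
function together. With aggregation off, every box contributes the plain
sum of its mined members' weights. The coefficient uses the
*intersection* `box ∩ T`: a union with `T` would be unbounded and could
not express completeness.

**Node weight.** For every unordered pair of distinct nodes `(r, s)` in
the same connected component, an intermediate node `j ∉ {r, s}` earns one
count if it lies on *at least one* shortest `r–s` path. The credit is
binary per pair (not split over path multiplicity as in Brandes
betweenness), endpoints earn nothing for their own pairs, and
disconnected pairs contribute nothing. The integer counts are normalized
per pathway by a softmax (max-subtraction for numerical stability), giving
strictly positive node weights that sum to one.

The seven named variants toggle these components:

| variant                  | node weight | node score | gene weight |
|--------------------------|-------------|------------|-------------|
| IPF_gene                 | 1           | plain sum  | log(M/df)   |
| IPF_node                 | 1           | aggregated | 1           |
| IPF_shortpath            | softmax     | plain sum  | 1           |
| IPF_shortpath_gene       | softmax     | plain sum  | log(M/df)   |
| IPF_shortpath_node       | softmax     | aggregated | 1           |
| IPF_gene_node            | 1           | aggregated | log(M/df)   |
| IPF_gene_node_shortpath  | softmax     | aggregated | log(M/df)   |

The baseline is the one-sided hypergeometric tail
`P(X ≥ x)` with universe `N` (union of all collection genes), pathway
size `K`, sample size `k = |T ∩ background|` and overlap
`x = |T ∩ p|` — the standard urn model, evaluated through
`scipy.stats.hypergeom.sf`.

**Ranking and evaluation.** IPF scores rank descending, p-values
ascending; ties break by pathway id so rankings are reproducible. Against
a key-pathway list the package computes `CumPer(i) = |key ∩ top-i| / |key|`
(recall-at-i; the curve reaches 1 once all key pathways are retrieved)
and its area `AUC = (1/M) Σ_i CumPer(i)` by the rectangle rule at unit
rank spacing. Recall-at-i was chosen as the default denominator because
it makes AUC comparable across metrics and collections; precision-at-i
(`/i`) is available via `mode="precision"`.

## Co-occurrence mining

The PubTator plain format is parsed tolerantly: out-of-range annotation
offsets are dropped with a warning, mention/span mismatches are kept with
a warning, gene annotations without a normalized id are dropped.
`ABSTRACT` pairing links every pair of distinct normalized gene ids in a
document; `SENTENCE` pairing restricts to mentions in one sentence, using
a deterministic punctuation-based splitter (terminal punctuation +
whitespace + capital/digit, with a fixed abbreviation guard list).
Determinism was preferred over linguistic perfection: the splitter's
occasional over- or under-segmentation only moves pairs between the
SENTENCE and ABSTRACT windows, never outside them, so sentence pairs are
a subset of abstract pairs on every corpus. Two or more genes in a window
form pairs (a pair plainly needs only two genes). Stricter syntactic or
event-based extractors are out of scope; their pair files plug in through
`read_pair_tsv`.

## The synthetic study generator

`SimConfig` defines the conditions of one simulated enrichment study; the
defaults are one fixed, documented choice of what a small literature-
mining study looks like:

| parameter | default | meaning |
|---|---|---|
| `n_pathways` | 50 | collection size M |
| `universe_size` | 1500 | gene namespace; larger than the union of pathway genes, so mined noise includes database-unknown genes |
| `genes_per_pathway` | 12–30 | uniform per pathway |
| `node_kind_mix` | 0.40/0.35/0.25 | single / homolog group / complex; KEGG maps routinely collapse families and complexes into one box |
| `group_size_range` | 2–5 | genes per multi-gene box |
| `edge_density` | 0.2 | extra-edge probability on top of a random spanning tree (graphs stay connected, so shortest-path weights are never degenerate) |
| `housekeeping_fraction` | 0.04 | share of the universe forming the promiscuous pool |
| `housekeeping_share` | 0.05 | fraction of each pathway's genes drawn from that pool; all other pathway genes are specific to exactly one pathway |
| `coverage` | 0.6 | fraction of the planted pathway's genes mined |
| `noise_genes` | 3 | extra mined genes |
| `noise_promiscuity_bias` | 0.25 | probability a noise gene is drawn from the promiscuous (df ≥ 2) genes |

One integer seed drives named substreams (`SeedSequence(seed,
spawn_key=(m,))` for pathway `m`), so a fixed config always regenerates
identical data and adding pathways never perturbs earlier ones. Noise is
drawn from the universe minus the genes already sampled; at coverage 0
the mined set is therefore exactly independent of which pathway carries
the "planted" label, which makes the no-signal null (planted rank uniform
over 1..M) hold by construction.

The *literature-noise* regime used in the metric-comparison study and in
`scripts/acceptance.py` concentrates the promiscuity: a pool of 2% of the
universe supplies 30% of each pathway's genes, coverage drops to 0.2 and
12 noise genes are drawn with bias 0.85 toward promiscuous genes. This
was designed from the urn model before running it: distractor pathways
then see overlap fluctuations comparable to the planted pathway's true
overlap (~Poisson(2) vs ~4), which is precisely where overlap counting
(the p-value) gets distracted while frequency-aware weighting does not.

What the generator does **not** emulate: real KEGG topology (hub spokes,
compound-mediated links), gene-family correlation between pathways,
corpus-level mention statistics. Passing tests therefore show internal
consistency and the direction of the metric comparison under the stated
noise model, not performance on real literature.

## Numerical choices

* Softmax with max-subtraction; counts are raw integers, no temperature.
* Hypergeometric tail via `sf(x−1)`, clamped into [0, 1].
* Ties in rankings break lexicographically by pathway id.
* Empty mined sets are legal everywhere and score 0 (p-value 1).
* Duplicate edges collapse; self-relations are dropped with a warning.
* Shortest-path counts use dense all-pairs distance matrices
  (`scipy.sparse.csgraph`); pathway graphs are small, so the O(n³)
  tensor check is cheap and exact.

## Known limitations

* **The softmax node weight is effectively an argmax.** Shortest-path
  counts grow with the square of the component size, and `exp` of integer
  gaps ≥ ~5 leaves >99% of the weight on the single highest-count node.
  `IPF_shortpath` therefore behaves like "was the hub box hit, and how
  many of its genes": in planted-recovery simulations at coverage 0.6 it
  recovers the planted pathway in only ~87% of runs (versus 100% for
  `IPF_node`), failing precisely when the planted hub's genes are all
  missed — the planted score then collapses below that of any pathway
  with a single lucky noise hit. Large mined sets saturate hub boxes and
  mask the effect, which is why the behaviour only surfaces at moderate
  coverage. A tempered or rank-based normalization would smooth it, but
  the untempered softmax over raw counts is the model implemented.
* Gene identifiers are compared as exact strings after whitespace trim;
  no symbol/accession mapping is attempted.
* KGML interpretation is restricted to `gene` entries, `group` entries
  and `relation` edges; whether KEGG groups coincide exactly with
  protein-complex boxes is an interpretation.
* The miner's sentence splitter is rule-based; abbreviation coverage is
  a fixed list, not a learned model.
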