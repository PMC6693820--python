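# Methods

## Model overview

`viratax` computes a distance between viral genomes in two layers and
combines them with a single physical rule.

**Gene layer.** A genome is a bag of genes (annotated coding sequences).
For a pair of genes the package estimates mutual information from a
translated local alignment: the raw Smith-Waterman score $S$ of the best
of the 36 frame-pair alignments is converted to a bit score
$S' = (\lambda S - \ln K)/\ln 2$ (Karlin-Altschul), and $I \equiv S'$.
The bit score is the log2 size of a database in which an equally good
match would arise once by chance, which is why it is usable as a shared
information measure; any proportionality constant between bit score and
mutual information only rescales the gene layer as a whole and is absorbed
later by the k-mer rescaling step. A gene's entropy is its self-alignment
bit score, and the gene-pair dissimilarity is the variation of information
$D = H_a + H_b - 2I$, which is a metric on random variables. Dissimilarities
of all matched gene pairs between two genomes combine in parallel,
$D_{eq} = (\sum_i 1/D_i)^{-1}$: one shared gene sets the distance, extra
shared genes only decrease it, and unmatched gene pairs are open circuits
that contribute nothing. A genome pair with no matches at all gets an
infinite-distance sentinel.

**K-mer layer.** Every genome also gets a composition profile: for each of
the 256 4-mers, a binary flag saying whether its frequency in the genome
strictly exceeds its pooled frequency across the whole corpus (ties count
as under-represented; the rule must be fixed because ties are common in
small fixtures even though they are measure-zero in real data). 4-mers are
counted in every sliding-window position on the given strand, windows
containing N excluded; there is no reverse-complement canonicalization.
Treating the flag vector as a binary random variable over the 256 types,
the mutual information between two genomes is the four-term sum
$I = \sum_{a,b\in\{\mathrm{over},\mathrm{under}\}} p(a,b)\log_2\frac{p(a,b)}{p(a)p(b)}$
and the distance is again the variation of information, which for binary
variables lies in $[0, 2]$ bits and is finite for every pair.

Cell probabilities are fractions of the 256 k-mer *types* (uniform weight
per type). A token-weighted variant, in which each type is weighted by its
pooled corpus frequency, is implemented behind `weighting="token"`; the two
conventions disagree and the type-fraction definition is the default.

**Combination.** Finite gene distances reach thousands of bits while the
k-mer VI is bounded by 2, so the k-mer matrix is first rescaled by
$s = \max D_{gene}^{finite} / \max D_{kmer}$ (maxima over off-diagonal
entries, no outlier trimming) and then added as one more parallel
resistor: $D = (1/D_{gene} + 1/(s\,D_{kmer}))^{-1}$, with $D = s\,D_{kmer}$
where the gene layer is an open circuit. The diagonal is fixed at zero by
convention rather than computed.

**Embedding and clustering.** The combined matrix is noisy and can violate
the triangle inequality, so clustering is done on an embedding rather than
on the matrix: classical (Torgerson) MDS into 50 dimensions — negative
eigenvalues of the double-centered matrix are clipped to zero and counted,
the standard remedy for non-metric input — followed by Barnes-Hut t-SNE to
3 dimensions (perplexity 30, θ = 0.5), restarted 20 times with the
lowest-KL run kept. t-SNE preserves neighbor probabilities rather than
global distances, which both suits the local reliability of the alignment
signal and motivates a density-based clusterer; OPTICS is run on the 3-D
coordinates. Dendrograms over clusters use average linkage on the matrix
of mean inter-cluster Euclidean distances in the 3-D space; branch length
is a confidence score for a cluster's distinctness, not an evolutionary
time. Sub-structure inside one cluster is explored by re-running the same
clustering on that cluster's members (`subcluster`), with no special-case
code. A 2-D PCA projection of the 3-D embedding is available for plotting
only.

**Placement of new genomes.** A frozen reference model stores the corpus
baseline, each non-noise reference genome's flag vector, and its cluster.
A new genome is flagged against the *frozen* baseline (additions would not
change it measurably), its k-mer VI to every reference genome is computed,
and the cluster with the largest size-weighted count among the k = 30
nearest references wins. The default weight $w(s) = 1/s$ is the simplest
rule that keeps clusters smaller than $k/2$ reachable at all; the weight
function is pluggable. The winner's share of the total weighted count is
reported as a confidence, and an optional threshold leaves low-confidence
genomes unassigned.

## Parameter defaults

| parameter | default | units | why |
|---|---|---|---|
| substitution matrix / gaps | BLOSUM62, open 11, extend 1 | score units | standard gapped protein-search scoring |
| λ, K | 0.267, 0.041 | nats per score unit, — | standard gapped Karlin-Altschul constants for that scoring |
| `min_bitscore` | 35 | bits | expect-value logic: chance alignments in an all-vs-all six-frame search over ~1e5 residues per side stay below one expected hit only above ~33 bits; a lower floor floods the parallel sum with chance matches between unrelated genomes (see below) |
| `epsilon` (VI clamp) | 1e-6 | bits | heuristic searches can report $I > (H_a+H_b)/2$; the clamp keeps $1/D$ finite while staying far below any real gene VI, preserving ordering |
| k-mer length `k` | 4 | nt | 256 types are cheap to count and short enough to be populated by short genomes |
| MDS dims | 50 | — | standard t-SNE preprocessing dimensionality |
| perplexity / θ / restarts | 30 / 0.5 / 20 | — | Barnes-Hut t-SNE operating point; perplexity auto-reduces to ⌊(n−1)/3⌋ with a warning when n ≤ 3·perplexity |
| OPTICS `min_samples` | 5 | genomes | smallest neighborhood that defines density for family-sized clusters |
| extraction | reachability cut at largest gap | — | see below |
| k-NN `k` | 30 | neighbors | large enough for a stable plurality; must not exceed the reference size (tests and the acceptance run use k = 7 against 30-genome references) |

The `min_bitscore` floor deserves emphasis: it is the analogue of a search
tool's e-value cutoff. With an exact all-vs-all aligner there is no
reporting heuristic to discard chance hits, and a 20-bit floor admits
thousands of them in even a desk-scale corpus; each is a huge-VI resistor,
but many huge resistors in parallel still produce a deceptively moderate
distance between genuinely unrelated genomes. At 35 bits the expected
number of chance matches over the whole search is below one, restoring the
regime in which most genome pairs have no gene-layer signal at all and the
k-mer layer does the bridging. The floor should be raised logarithmically
with corpus size.

**Cluster extraction.** Steepness-based (ξ) extraction from the
reachability plot proved erratic on small samples: on clean, widely
separated Gaussian blobs it splits clusters and labels large fractions of
points noise. The default is therefore a single cut of the reachability
plot, placed in the middle of the largest gap between sorted finite
reachability values — the cut level whose cluster count is stable over the
widest range of thresholds. ξ extraction and fixed-threshold cuts remain
available (`method="xi"`, `method="cut"` with explicit `eps`).

## Synthetic data

The generator produces corpora with known family structure so every stage
is testable without downloads. Each family has one ancestor: 4–6 genes of
60–120 codons (no in-frame stops), separated by 20–50 nt intergenic
spacers, drawn with a family-specific GC content (evenly spaced over
[0.35, 0.65] by default); roughly 30% of genes sit on the minus strand.
Each of the 10 descendants per family applies i.i.d. per-site substitution
(default 5%), whole-gene loss (10%), and gene gain (10%; novel random
genes by default, or same-family copies with `gene_transfer=True`, which
creates the chimeric regime where no one member need share a gene with
every other). Defaults produce within-family translated-alignment matches
and no between-family ones, with family separation in the k-mer layer
driven by GC content — the same two-layer signal structure the distance
model assumes in real data.

What the generator does *not* emulate: indels and recombination (the
alignment layer is exercised only through substitutions), codon usage and
amino-acid composition biases beyond GC content, overlapping or spliced
genes, segmented genomes, and realistic genome lengths (simulated genomes
are 1–3 kb). Passing tests therefore demonstrate the machinery's
correctness and the recoverability of a clean family signal at small
scale, not performance on real RefSeq-scale diversity, where divergence
depths, family sizes, and compositional signals are far less uniform.

A subtlety of the flag representation worth knowing: variation of
information measures statistical *dependence*, not agreement. In a corpus
composed of exactly two balanced, compositionally opposite families, each
family's flags are close to the complement of the other's relative to the
pooled baseline; anti-correlated binary variables share high mutual
information, so the two families can look *close* in the k-mer metric.
With three or more families (or any realistically diverse corpus) the
pooled baseline is not the mirror axis of any one pair and the effect
vanishes; k-mer-based tests and study corpora here use ≥ 3 families.

## Numerical choices

- Gene-pair scores are deduplicated to one score per unordered gene pair
  (the maximum over orderings and alternative alignments) before entering
  the parallel sum, to avoid double-counting overlapping alignments.
- The gene entropy is exempt from the `min_bitscore` floor — it is a
  definition, not a reported match — and, being a max over all 36 frame
  pairs, can exceed the coding frame's diagonal score when an alternate
  reading frame is unusually self-similar.
- Ambiguity codes other than N are mapped to N on load; 4-mer windows and
  translated codons containing N are handled as missing (excluded or X).
- The MDS eigenvalue clip tolerance is relative (1e-9 of the largest
  eigenvalue); clipped counts are logged, as is the per-run count of
  clamped gene VIs.
- t-SNE restart r uses `random_state = seed + r` with a single worker, so
  runs are bit-reproducible for a fixed seed; the restart with the lowest
  final KL divergence is returned.
- k-NN neighbor selection breaks distance ties by reference order, and
  plurality ties go to the lower cluster id (logged); assignments are
  independent of query order.
- GenBank coordinates are converted to 0-based half-open on read;
  minus-strand CDS sequences are stored reverse-complemented (coding
  orientation). Multi-segment records are separate genomes unless
  `merge_segments` concatenates records sharing an organism name.
- Degenerate inputs have defined behavior: genomes shorter than 4 nt are
  an error for the k-mer layer; genes shorter than one codon are no-match;
  an all-sentinel gene matrix is an error at the rescaling step with a
  pointer to k-mer-only use; a corpus with fewer than 3 genomes cannot be
  embedded.

## Problem sizes

The test suite and the acceptance script run the full pipeline on
3-family corpora of 30 reference genomes (~150 genes, ~1–3 kb genomes)
with 6 held-out genomes, the k-mer bound checks on 50 genomes, and the
aligner-vs-oracle comparison on 20 random short genes; a full pipeline run
at this size takes well under a minute on one CPU. These sizes were chosen
so that every stage, including the exact all-pairs aligner, runs
comfortably on a laptop; the tabular backend exists precisely so that
larger corpora can bring their own search results.

## Known limitations

- The internal aligner is exact DP over all 36 frame pairs of all gene
  pairs: quadratic in corpus size and in gene length. It is a desk-scale
  tool; full-scale runs should use an external translated search and the
  tabular backend.
- Whether multiple distinct alignments between one gene pair should sum
  (rather than max) in the parallel rule is a modeling choice; summing
  would double-count overlapping regions, so the maximum is used.
- Homologous repeats (one gene matching several genes in the partner
  genome) all enter the parallel sum, which may overweight repeat-rich
  genomes.
- t-SNE is trustworthy only up to 3 output dimensions, and the embedding
  sacrifices fine within-family precision for a consistent global picture;
  for closely related genomes the raw distance matrix (or whole-genome
  alignment) is the better instrument.
- Cluster count and membership depend on the extraction parameters; the
  largest-gap cut is robust for well-separated embeddings but, like any
  density method, has no guarantee on overlapping clusters.
- The k-mer layer uses single-strand counts; strand-asymmetric composition
  therefore affects it, which is intended but worth knowing when mixing
  annotation conventions.
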