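# Methods

## Problem setting

Distance-based alignment-free phylogeny estimates a tree from per-species
k-mer count vectors. The approach inherits a blind spot: when a contiguous
region is missing from one species (incomplete assembly, large deletion), all
k-mers of that region are absent from it at once. Distance measures read this
as extra divergence concentrated on the affected species, although the
homologous sequence that *is* present may be nearly identical. The package's
central component classifies each absent k-mer as "absent because of a missing
region" or "absent because of substitutions/small indels", using only k-mer
tables, and removes the former before distances are computed.

## Canonical counting

Counts are kept per species as sparse maps from canonical k-mer to count. The
canonical form is the lexicographic minimum of a k-mer and its reverse
complement, so both strands share one entry. Windows containing any non-ACGT
character (N or other IUPAC ambiguity codes) are skipped entirely, matching
common k-mer-counter behaviour; multiple records with the same species id are
treated as contigs — counts pool, windows never span a record boundary. A
dense 4^K vector is never formed: every distance is evaluated over the union
of stored keys, which is identical because absent-in-both terms vanish in all
three measures.

## Entropy-based selection of K

For candidate lengths K in a configurable range (default 6–18 at desk scale),
each distinct canonical k-mer contributes the binary Shannon entropy of its
presence fraction p across the n species, and H̄(K) is the average over the m
distinct k-mers. Two conventions the formula leaves open are fixed as: log
base 2 (each term then lies in [0,1]) and averaging by m (making profiles
comparable across K, where m varies by orders of magnitude). The selected K is
the argmax, ties broken toward smaller K (cheaper tables). The profile is
computed on unfiltered tables: selection precedes filtering in the pipeline
order.

Mechanics of the profile shape: while 4^K is small relative to sequence
length, every k-mer occurs in every species by saturation and H̄ ≈ 0; once K
is large enough that windows are mostly unique, H̄ is a mixture of
shared-by-subsets k-mers (entropy up to 1 bit) and private ones (entropy
H(1/n)); as K grows further the private fraction dominates and H̄ decays
toward H(1/n). The interior maximum sits where a typical window has
accumulated on the order of one difference between related species. The
entropy demonstration dataset (5 species, pendant branch length 0.1, 10 kb)
was chosen so the default 6–18 range brackets that regime: at K = 6 all 4096
canonical 6-mers occur in every species, and at K = 18 a window is co-retained
between two species with probability ≈ 0.9^18 ≈ 0.15.

## The missing-region filter

Parameters, with defaults:

* **K** — k-mer length used for phylogeny (fixed, or entropy-selected).
* **k** — substring length, default `max(K − ⌊K/5⌋, 7)`. Substrings about 20%
  shorter than K discriminate well; below 7 bases chance occurrences elsewhere
  in the sequence mask true missing regions, hence the floor.
* **Th** — threshold ratio (total substrings / missing substrings), default 2.
  A candidate k-mer is discarded iff, for at least one species in which it is
  absent, strictly more than m/Th of its m = K − k + 1 substrings are absent
  from that species' full length-k table. Ties (exactly m/2 at Th = 2) are
  kept. Raising Th lowers the cutoff, so the discarded set grows monotonically.

Design choices where the procedure was genuinely open:

* **Global discard scope.** A k-mer flagged in any species is removed from
  every species' table, so all pairwise distances use one consistent
  vocabulary; per-pair filtering would make distances incomparable.
* **Whole-table substring lookup.** Substring presence is tested against the
  species' complete substring table, not near any locus — the method stays
  alignment-free. This is also the mechanism behind its operating
  characteristics (below).
* **Canonicalisation throughout** covers reverse complements on both the K and
  the k level.

### Operating characteristics

The filter's two error rates are governed by the chance "rescue" probability
that an absent substring re-occurs elsewhere in the species, roughly
`1 − exp(−2·L/4^k)` for sequence length L. When 4^k ≫ L (e.g. k = 13 vs 20 kb)
there is no rescue: sensitivity to true missing regions approaches 100%, but a
k-mer absent because of a *centrally located* substitution also has all m
substrings absent — its discard signature is identical — so specificity is
low; only substitutions near the k-mer's ends (fewer than m covering
substrings) are kept. Geometrically, at K = 16, k = 13 (m = 4) at least 3 of 4
substrings cover positions 2–13 of 16, so most substitution-absent k-mers are
discarded along with the missing ones. When 4^k is comparable to L (e.g.
k = 8 vs 16–20 kb) rescue protects substitution k-mers (high specificity) but
also hides genuinely missing substrings (lower sensitivity). There is no
setting of (k, Th) that makes both error rates small on i.i.d. sequence at
these scales; on real genomes, composition bias and repeats shift the
trade-off. Users should read the filter as "high recall for missing k-mers,
at the price of thinning ordinary divergent k-mers", which is acceptable
because the retained vocabulary is consistent across species (see next
section).

### Alignment-based ground truth

When a trusted multiple sequence alignment exists, k-mers can be labelled
instead of simulated: each occurrence's K ungapped positions are mapped to
alignment columns, and a (k-mer, species) pair is labelled missing when the
species has strictly more than K/3 gap characters in those columns for some
occurrence. Sensitivity is the fraction of labelled-missing candidates
discarded; specificity the fraction of other candidates kept (a k-mer counts
as missing if labelled for at least one species).

## Distances and tree estimation

All three measures operate on the (filtered) sparse tables. The Mahalanobis
σᵢ is the population (divide-by-N) standard deviation of k-mer i's counts
across all dataset species with absent = 0; σᵢ = 0 terms contribute 0 (all
counts equal, so the numerator is 0 too). The fractional common k-mer count
distance divides Σ min(qᵢ, sᵢ) by `min(n, m) − K + 1`, the window count of the
shorter sequence; ε (default 1e-10, natural log) only guards log(0), and after
filtering the *original* sequence lengths are used in the denominator —
lengths are properties of the sequences, not of the retained vocabulary.

Neighbor Joining is the classic Saitou–Nei agglomeration: join the pair
minimising Q(i,j) = (r−2)d(i,j) − Rᵢ − Rⱼ, assign branch lengths by the
standard formulas, reduce the matrix. Ties on Q are broken toward the
lexicographically smallest pair of subtree labels (smallest contained leaf),
and negative branch lengths are clamped to 0; both choices make runs exactly
reproducible. On additive matrices from binary trees with positive edges the
implementation recovers topology and path lengths to 1e-9 (tested).

Robinson–Foulds distances are computed on unrooted trees as the symmetric
difference of non-trivial bipartition sets; a rooted mode comparing clade sets
is available because published RF values for very small taxon sets are
sometimes only explicable under rooted comparison.

## The simulator

`simulate` emulates the study setting: an i.i.d. root sequence at configurable
GC, per-branch substitution probability equal to the branch length with
uniform replacement among the other three bases, optional small indels
(Poisson events scaled by branch length, geometric lengths, mean 3), and
planted deletions — per species, contiguous intervals of configured length at
uniformly random non-overlapping positions, recorded as ground truth in that
species' pre-deletion coordinates. Default root length 20 kb; the planted
deletion grid used in the study scripts is 200, 500, 1000, 2000 bp. A fixed
seed yields byte-identical outputs.

What the generator does *not* emulate: compositional bias, repeats and
segmental duplications, rearrangements, rate heterogeneity across sites and
lineages. Consequently the filter's measured error rates here are the
idealised ones derived above; passing tests demonstrate the algorithm's
mechanics and its effect on tree estimates under clean relatedness, not its
exact performance on real genomes, where repeats raise rescue rates and
composition bias changes chance-occurrence probabilities.

Study problem sizes were chosen at desk scale: 5–7 species of 20 kb for the
filter and tree experiments (a mitochondrial-genome-like scale at which every
stage is exact, with no approximations) and 10 kb for the entropy profile.
The 7-species tree uses pendant branches 0.03, internal branches 0.008 —
internal edges carry ~160 expected substitutions over 20 kb, a resolvable but
not trivial signal.

A further property observed in these experiments and worth stating: the
fractional common k-mer count distance is intrinsically robust to
*independently placed* per-species deletions, because a deletion removes
roughly the same number of shared k-mers from every pair involving that
species — an additive pendant-branch shift that Neighbor Joining tolerates.
Topological damage from missing regions appears when internal branches are
short relative to the deletion noise; filtering then trades that noise against
a thinner retained vocabulary.

## Numerical and degenerate-input conventions

* 0·log 0 := 0 in the entropy; presence fractions validated to [0, 1].
* Identical sequences give zero matrices; NJ still returns a tree (degenerate
  star-like resolution via the tie-break order).
* Sequences shorter than K contribute no windows; a species whose length is
  below K makes the fractional denominator invalid and is rejected with an
  error.
* Duplicate species ids, ragged alignments, non-IUPAC characters and malformed
  Newick are rejected at the I/O boundary with messages naming the offender.
* All randomness flows from a single integer seed through
  `numpy.random.default_rng`; derived seeds stay below 2^31.

## Known limitations

* The filter classifies k-mers only; it does not localise missing regions to
  coordinates.
* Specificity against substitution-absent k-mers is intrinsically limited in
  the no-rescue regime (see operating characteristics); distantly related
  species push every k-mer toward candidacy and lose vocabulary under
  filtering.
* Counting is exact and in-memory; the package targets desk-scale sequences
  (up to a few Mb), not terabase collections.
* The entropy criterion assumes ≥ 2 species and is computed before filtering;
  a circular selected-K-after-filtering variant is not provided.
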