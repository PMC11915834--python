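# Methods

This note records the models, conventions, and numerical choices behind
`vespscope`, and what the synthetic-data tests do and do not establish.

## Occurrence profiles and ESP filters

Occurrence is strictly presence/absence: a Pfam family is "present" in a
genome if it has at least one domain hit there, regardless of copy number.
Hits are trusted as pre-thresholded (the upstream search is expected to run
with the Pfam noise cutoff), so no e-value filtering happens here. Per-group
prevalence is the exact ratio `count / group_total`, with the five groups
bacteria, archaea, Asgard archaea, eukaryotes, and nucleocytoviruses; Asgard
archaea are kept distinct by default because their ESP repertoire is the
interesting intermediate, but `compute_prevalence(..., merge_asgard=True)`
pools them into the archaea.

All filter rules are strict inequalities, following the "greater than"
wording they encode: ESP ⇔ eukaryote prevalence > 0.95; vESP ⇔ ESP and ≥ 1
viral genome; phylogenetically selected ⇔ ESP and > 10 viral genomes
(implemented as ≥ 11). All thresholds are arguments.

Per-viral-order percentages default to denominators counted from the
metadata table, so synthetic and subset analyses stay internally consistent;
the Giant Virus Database order totals (1,001 Imitervirales, 146
Pimascovirales, 120 Algavirales, 43 Chitovirales, 38 Pandoravirales, 32
Asfuvirales) are available as the constant `GVDB_ORDER_TOTALS` for
percentages against the full database.

## SOM clustering and cluster categories

Profiles are clustered in the five-dimensional prevalence space (not on raw
per-genome vectors): the question is *where* a family occurs, and group
prevalences are the sufficient summary.

The SOM is a batch implementation chosen for determinism: each epoch assigns
every profile to its best-matching unit (minimum Euclidean distance) and then
sets every codebook vector to the Gaussian-neighborhood-weighted mean of all
profiles. The neighborhood radius decays linearly from `max(rows, cols)/2`
to 0.5 over the epochs (default 50), after which one zero-radius Lloyd step
moves each occupied node to the plain mean of its assigned profiles,
sharpening quantization after the smoothed phase. The codebook is
initialized by sampling data points with the run's seed. Training internally
sorts profiles lexicographically, which makes the fit — including floating
point summation order — exactly invariant to the order profiles arrive in.
The default grid is the smallest square with at least `5·√N` nodes, capped
at 10×10 (a standard SOM sizing heuristic).

Clusters are obtained by k-means on the codebook (the usual second stage of
the kohonen workflow), not by treating each node as a cluster. Both the
elbow scan and the final k-means run on the *occupied* codebook vectors,
weighted by how many profiles map to each node: unoccupied interpolation
nodes carry no data mass, and including them would let empty regions of the
grid distort the within-cluster sum of squares. The number of clusters is
the k (in 2..10) maximizing the second forward difference of the WCSS curve,
ties to the smaller k; a curve with no positive curvature falls back to
`k_min`. Each k is fit best-of-20 restarts: with only ~5 restarts the k = 2
fit occasionally lands in a worse local optimum, which perturbs the
curvature estimate at small k.

A cluster's biological category is called from its mean prevalence vector
with two thresholds, `high = 0.5` and `low = 0.25`: eukaryote-high plus
bacteria and an archaeal lineage above `low` is *pan-cellular*;
eukaryote-high with all cellular groups below `low` is *true vESP*;
eukaryote-high with an archaeal lineage but not bacteria above `low` is
*archaea-vESP*; anything else is *other*.

## Tree certainty

Internode certainty uses the original two-split form: only the single most
prevalent split conflicting with the reference branch enters, not all
conflicting splits. With counts normalized to frequencies `p`,
`IC = 1 + Σ p·log2 p`, negated when the rival is the more frequent split, so
IC(f, 0) = 1, IC(f, f) = 0, and IC(a, b) = −IC(b, a). Tree certainty is the
sum over the reference tree's internal branches, and the *relative* TC
divides by `n_tips − 3` — the screened quantity, since its natural range for
concordant data is [0, 1]; the raw TC is also reported. A branch that never
appears in any replicate and has no conflicting split is assigned IC = 0 and
flagged rather than aborting the computation. The statistic is purely
topological; branch lengths and any support labels in the input Newick are
ignored. The reliability screen keeps trees with relative TC strictly
greater than 0.5 (configurable).

## Rooting, ultrametricization, and clade depth

Gene trees of eukaryotic/viral families rarely have outgroups, so the root
is estimated by **midpoint rooting**: the root is the midpoint of the
longest tip-to-tip path. Ties between equally long paths are broken by the
lexicographically smallest endpoint-label pair, making the rooting
reproducible; re-rooting an already midpoint-rooted tree leaves the root in
place.

**Ultrametricization** uses mean path length smoothing: bottom-up, each
node's age is the mean root-to-tip path length over its descendant tips
(computed as the tip-count-weighted mean of child age + child branch); a
child age exceeding its parent's is clamped to the parent age, giving a
zero-length branch. The method is deterministic, rate-free, and exactly
idempotent on ultrametric input. It is *not* a molecular-clock dating
method: depths are relative positions, never absolute times.

A **viral clade** is a maximal node whose descendant tips are all
virus-tagged; the clades partition the viral tips. Depth is measured at the
**attachment node** — the parent of the clade's stem edge, where the viral
lineage diverges from its non-viral sister — not at the clade's crown MRCA:
the quantity of interest is when the lineage split from cellular relatives,
and this convention makes the basal case exactly 0. Depth is the distance
from the root to the attachment node divided by tree height, hence invariant
to uniform branch scaling. Tips are tagged from a metadata table when
provided, else from label prefixes (`virus_…`, `euk_…`, …).

Terminal branches longer than `k` (default 10) times the median terminal
branch are reported as rogue-taxon candidates; flagging is advisory and
nothing is removed automatically.

## Synthetic data: what it emulates, and what it does not

Occurrence matrices are group-structured Bernoulli samples: each synthetic
family follows one of six planted archetypes (per-group presence
probabilities), with presence flipped at rate 0.05 to emulate annotation
noise, and group sizes defaulting to a realistic compilation (230 bacteria,
97 archaea, 182 Asgards, 127 eukaryotes, 343 viruses). The six archetypes —
two per category — are placed approximately equidistantly (pairwise
separations 1.0–1.5 in prevalence space, large against the ≤ 0.05 binomial
noise of a per-family prevalence) by maximin search inside the
category-semantics constraints. This placement is deliberate: it makes the
planted structure a clean six-cluster problem with no coarser super-cluster
level, which is the regime in which a curvature-based elbow is a meaningful
estimator of k. Real occurrence data need not be so obliging — families
form continua, cluster sizes are uneven, and hierarchical structure is
common — so recovery on these fixtures validates the machinery, not the
claim that any real dataset contains exactly six clusters.

Host trees are pure-birth (Yule) trees rescaled to height 1 — adequate for
depth-recovery testing, though real gene trees have rate variation the
generator does not model. Viral clades are grafted by inserting an
attachment node at exactly `depth × height` below the root on a uniformly
chosen edge spanning that height, with an ultrametric viral subtree reaching
the present, so the tree stays ultrametric and the planted depth is exact;
grafting adds tips rather than relabeling them, preserving the host
topology. Bootstrap sets mix the reference topology (probability =
concordance) with neighbors a configurable number of nearest-neighbor
interchanges away; branch lengths are resampled exponentially. NNI edges
hanging off a degree-2 root are excluded since a swap across them does not
change the unrooted topology. Toy alignments construct parsimony-informative
columns explicitly (two residues, each in ≥ 2 sequences) so the expected
count is exact by construction.

All generators draw from a single `numpy` Generator per call, seeded
explicitly; no global state, hashing, or iteration-order dependence enters.

## Alignment statistics

A column is parsimony-informative when at least two distinct residues each
occur in at least two sequences; gaps (`-`, `.`) and the ambiguity code `X`
carry no state, and the same characters are excluded from the denominator of
percent identity (the phyKIT-compatible convention). The viral-vs-eukaryote
identity range takes, for each viral row, its best identity against any
eukaryote row in the multiple alignment as provided (trimmed upstream), and
reports the min and max of those best hits; viral rows with no comparable
column are excluded rather than scored 0.

## Problem sizes and tolerances

The test suite runs at desk scale: planted-archetype recovery uses 480
families × 979 genomes over 20 seeds; depth recovery uses 100 20-tip trees
with depths drawn U(0.05, 0.95) and a ±0.05 tolerance (midpoint rooting can
shift the root slightly when the planted clade perturbs the tree diameter);
tree-certainty oracle checks use 200 random instances of ≤ 8 tips against an
exhaustive bipartition-counting reimplementation; midpoint rooting is checked
against a brute-force all-edge search on 200 trees of ≤ 12 tips. Ultrametric
equality is asserted to 1e-9 relative tolerance, depth scale-invariance to
1e-12.

## Known limitations

- Midpoint rooting misplaces the root when rate variation is strong; depth
  scores inherit that error, especially for small viral clades.
- Mean-path-length smoothing is a crude clock; depths from different trees
  are comparable only as rough relative ages.
- The elbow heuristic needs a genuine curvature signal; on data without
  clear cluster structure it falls back to the smallest k scanned.
- IC here is the two-split variant; all-conflict variants (TCA/ICA) and
  quartet concordance factors are out of scope.
- The domtblout parser reads the hit table dialect only; it does not
  re-threshold hits.
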