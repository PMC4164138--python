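# Methods

This note records the model, the knobs that matter, the numerical choices,
and what the synthetic data can and cannot tell you about real annotation
corpora.

## The census model

The unit of analysis is the terminal molecular-function GO term: a
non-obsolete `molecular_function` term with no incoming `is_a` edge from
another non-obsolete MF term. Only `is_a` edges define leafness — they are
the ontology's backbone, and the other relationship types (`part_of`,
`regulates`) express composition rather than specialization. Annotations to
obsolete or non-terminal terms are dropped, never propagated up or down the
DAG: the analysis deliberately samples the most specific annotations, and
propagation would blur exactly the signal (lineage-restricted
specialization) the method is after.

Organisms pass a three-rule screen, applied in order so each exclusion has
one auditable reason: (1) non-type strains (species-level deduplication),
(2) parasitic or facultative-parasitic lifestyle, (3) terminal-MF coverage
below 50%. The threshold is inclusive (coverage = 0.50 is retained): a
"threshold" naturally reads as the lowest admissible value. Coverage counts
distinct proteins annotated to *terminal MF* terms over the proteome size;
counting any-GO annotations instead would be a defensible variant, and the
choice is isolated in `annotations.coverage` for sensitivity analysis.

Abundance g_ab is the number of annotation records of term b in genome a.
Records, not proteins: a protein annotated twice to a term contributes two,
because duplicate records are how the GAF layer expresses redundant
encoding, which the persistence metrics (flexibility, robustness) need.

## HGT screening

The enrichment test's sampling frame is annotation records. With N records
in the census, n of them carried by proteins on the horizontally-transferred
lists, a term with K records of which k are HTP-borne is scored by the
upper-tail hypergeometric probability P(X ≥ k), X ~ Hyp(N, K, n)
(`scipy.stats.hypergeom.sf`). Enrichment only — depletion is not evidence
of transfer. P-values are Benjamini–Hochberg corrected across all census
terms and a term is flagged when the adjusted p falls below α = 0.05 (both
the correction method and α are arguments). Flagged terms are removed from
every genome: the exclusion is a property of the character, not of one
genome's copy.

## Encoding

States are round(ln(g_ab + 1) / ln(g_max + 1) × 31) with g_max the single
matrix-wide maximum of the post-exclusion census, written with the 32-letter
alphabet 0–9, A–V. Three numerical choices are load-bearing:

* **Rounding is half-up** (x.5 → x+1), implemented as floor(x + 0.5).
  Banker's rounding would silently shift every boundary state.
* **g_max is matrix-wide**, so identical (g, g_max) pairs encode identically
  regardless of which genome they sit in; encoding follows term exclusion in
  the pipeline order.
* The transform is monotone, so the cell(s) holding g_max always reach state
  31 — but cells *near* the maximum can also round to 31 (e.g. g = 99 with
  g_max = 100), and small states can be unreachable for moderate g_max
  (state 1 requires g_max ≳ 7.6 × 10⁹ before some integer abundance lands in
  its rounding window). `encoding.state_alphabet` computes the reachable
  set exactly from the rounding boundaries.

## Parsimony inference

Characters are **ordered (Wagner)** by default, cost |i − j|: the min/max
ancestral-state rooting polarity presupposes that states form an ordered
abundance scale. The unordered (Fitch) model is available for sensitivity
checks and is verified against an independent Fitch implementation in the
tests.

Scoring is the Sankoff dynamic program with integer costs throughout (tree
lengths are exact integers; no floating point enters scoring). Two
implementation details keep desk-scale search fast without changing any
result: identical character columns are collapsed once and re-expanded
through weights, and the min-plus product against the cost matrix uses O(k)
cumulative-min scans (exact for the |i − j| cost; two-term closed form for
unordered) instead of the dense k × k broadcast. Candidate rearrangements
are scored through directed edge "messages" (the cost profile of each side
of every edge), making each NNI/SPR/stepwise-insertion evaluation a
constant number of array operations; hill-climbing accepts only strict
improvements, so the procedure terminates.

The search schedule default is 10 random-addition starts (greedy stepwise
insertion in a seeded random taxon order), steepest-descent NNI to a local
optimum, then first-improvement SPR sweeps until neither move class helps.
Bootstrap replicates use 2 starts and NNI only. All schedule knobs are
exposed; all distinct topologies at the best length found are returned,
ordered by a canonical (sorted-bipartition) key so ties are deterministic
and surfaced rather than silently resolved.

**Lundberg rooting** attaches a hypothetical ancestor — every character at
state 31/V (ToF) or 0 (ToL) — to each branch in turn and roots on the
branch minimizing total length; ties are broken by canonical branch order
and flagged. The rooted tree keeps only the original tips.

**Bootstrap support** resamples characters with replacement (multinomial
reweighting of the collapsed columns), reruns the reduced search, and counts
a clade of the reference rooted tree whenever the replicate's best unrooted
tree contains the corresponding bipartition — given the root, clade and
bipartition determine each other.

**Fit indices** are ensemble values over non-invariant characters:
CI = Σm/Σs, RI = (Σg − Σs)/(Σg − Σm), RC = CI·RI, with m the per-character
minimum (state range for ordered costs), s the observed steps and g the
star-tree (maximum) steps.

## Evolutionary metrics

*Node distance.* Raw distance counts internal nodes strictly between a tip
and the root. The default normalization divides by the **maximum** raw
distance, so the most derived tip sits exactly at nd = 1 and basal tips at
0; dividing by the taxon count (the literal alternative,
`normalization="taxon_count"`) cannot reach 1 and is provided behind a flag.
Only a root-adjacent tip is guaranteed nd = 0; a root with two internal
children has no zero-nd tip, which the extreme-ancestor rooting makes rare
in practice.

*Distribution index* f is presence-based (g_ab > 0), globally and per
superkingdom; the global f is the genome-count-weighted mean of the three
kingdom values.

*Venn groups* concatenate, in fixed A,B,E order, the kingdoms with at least
one carrier. *Group appearance order* sorts groups by minimum nd after
removing Tukey 1.5×IQR outliers (quartiles by linear interpolation): an
early outlier — typically a laterally acquired term — should not set its
group's appearance time. Both the outlier-free and raw orders are reported.

*Persistence*: economy = distinct terms, flexibility = Σ g_ab, robustness =
flexibility/economy (undefined and flagged for empty genomes).

## Synthetic data

The generator emulates the statistical structure of a proteome-wide GOA
corpus, not its content: a seeded DAG ontology (multi-parent terms
included); a fixed pectinate species tree with the Archaea-like clade
branching first; an ancestral leaf repertoire at the root (default 30 of
150 terms); one clade-level reduction event on the A stem (each ancestral
term lost with probability 0.4); lineage-specific innovations for the
remaining leaves split 10/30/60% across A/B/E (each confined to a nested
clade of its kingdom), mirroring Eukarya-heavy late innovation; abundances
1 + Poisson(1.5) per present term, giving the right-skewed copy numbers the
log transform expects; and a handful of lateral transfers between akaryote
tips carried at a fixed high copy number (8) in donor and recipient — an
amplified, mobile-element-like signature that the enrichment screen is
meant to catch — with the recipient's carrier proteins written to its
HGT-DB-style list. Parasite and low-coverage labels are assigned by
deterministic quota (exact counts, seeded placement), so filter tests are
exact rather than stochastic.

Ground truth records the species tree, the pre-transfer Venn group of every
observed term, the transferred terms, the reduction event and the quota
assignments. Everything is deterministic given the seed, and the emitted
OBO/GAF/TSV files round-trip through the parsers.

What the generator does **not** emulate: annotation noise and evidence-code
heterogeneity, within-clade gradual loss, endosymbiotic transfer into
Eukarya, correlated term co-occurrence, or realistic ontology topology.
Passing recovery tests therefore show the pipeline's inferences are correct
when its assumptions hold — not that those assumptions hold for any given
real corpus.

## Problem sizes

The shipped tests and the acceptance script run at desk scale, chosen so
the whole suite completes in well under a minute of search time: default
corpora of 24 genomes × 150 ontology terms (≈ 60 terminal), exhaustive
search oracles at ≤ 7 taxa (945 topologies), and bootstraps of 30–100
replicates on 8–15 taxa. The same code paths scale to corpus-size matrices
(hundreds of taxa); only the search schedule needs widening.

## Known limitations

* The heuristic search carries no optimality guarantee beyond the ≤ 7-taxon
  oracle equivalence; pectinate-biased data can need more starts.
* Equally parsimonious trees are reported, but downstream metrics use the
  canonical best tree; a strict-consensus nd is not implemented.
* The hypergeometric screen assumes exchangeable annotation records; strong
  within-genome correlation of HTP annotations would inflate significance.
* Tree lengths and supports depend on the census composition, so absolute
  values from different corpora are not comparable — only the derived,
  normalized statistics (nd, f, groups) are.
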