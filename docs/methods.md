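# Methods

## Metrics

**PSD.** For ungapped sequences *x*, *y* an optimal global alignment is
computed by Needleman–Wunsch dynamic programming with linear gap costs
(default match = 1, mismatch = −1, gap = −2 per gap column; all three
are user-settable because upstream clustering tools do not publish their
internal parameters). Traceback is deterministic with tie-break
diagonal ≻ up ≻ left, so identical inputs always produce the identical
alignment. PSD is the fraction of disagreeing columns. Under the default
`GAPS_COUNT` policy a gap column is a disagreeing site — the reading we
take of "percentage of sites that disagree in the pairwise alignment";
`GAPS_EXCLUDED` drops gap columns from numerator and denominator, since
identity definitions vary across tools. Terminal gaps are treated like
internal gaps (the inputs are same-region amplicons; semi-global
alignment is out of scope). Columns containing `N` never count under
either policy: an ambiguous base carries no evidence about substitution.

**MSD.** For two rows of one shared MSA, the induced pairwise alignment
is the column-wise restriction to that pair. A column is *countable*
when both rows are non-gap and neither is `N`; MSD = disagreeing /
countable. Columns gapped in exactly one row are excluded rather than
counted as mismatches — the stricter reading of "non-gapped sites", and
the one that makes MSD a proper p-distance; the mismatch-counting
variant is available behind `one_gapped_is_mismatch` for sensitivity
analysis. Pairs with zero countable columns (possible for fragmentary
reads with disjoint footprints in a reference-based MSA) are dropped
from aggregates with a logged warning instead of failing the OTU.

**BLD.** The patristic distance between two leaves: the sum of branch
lengths on the unique connecting path. Trees are treated as unrooted —
patristic distance is root-invariant and the rooting of ML-estimator
output is arbitrary. `bld_rep_vs_all` computes all
representative-to-member distances in one breadth-first traversal of
the tree's undirected edge structure (linear in tree size); per-pair
`bld` is equivalent. Zero-length branches are legal (ML estimators emit
them); negative lengths are rejected. Leaves outside the OTU (reference
taxa retained in the alignment) are ignored with a logged count.

**Jukes–Cantor correction.** `jc_correct(p) = −(3/4)·ln(1 − 4p/3)`,
defined for p ∈ [0, 0.75); p ≥ 0.75 raises a saturation error rather
than returning infinity. Its inverse `expected_p_distance(d) =
(3/4)(1 − e^(−4d/3))` is used both for simulator validation and to
predict the size of p-distance underestimation. More elaborate
corrections (log-det, GTR distances) are out of scope.

## Audit statistics

Exceedance is strict (> threshold, default 0.03), matching the ">3%
dissimilar" convention; the divergence *stratum* used in the
concordance analysis is inclusive (mean MSD ≥ threshold), matching the
"0.03 or greater" convention. The OTU size filter keeps clusters with
representative + members ≥ `min_otu_size` (default 100, the
conventional cutoff for per-OTU phylogenetic analysis; the boundary is
inclusive). Dataset means of MSD and BLD are pooled over per-read
records (headline), and means of per-OTU means are also reported since
both conventions exist; the BLD/MSD ratio uses the pooled means.
Pearson correlations (per read and per OTU mean) use the sample
correlation; with fewer than two complete pairs or zero variance the
correlation is reported absent, never coerced to 0. Taxon grouping
assigns each OTU the taxon of its *representative's* lineage at the
requested rank (the representative defines the OTU's annotation);
unassigned representatives group under `UNASSIGNED`. Histograms use
half-open bins [k·w, (k+1)·w) with a value exactly on an edge assigned
to the right bin (an epsilon of 1e-9·w absorbs float division error).

## Concordance classification

Lineages are 7-rank (kingdom…species) with the assigned ranks forming a
prefix. A member is CONFLICTING against its representative if any rank
assigned in both differs; otherwise UNDER if its assigned depth is
shallower, OVER if deeper, else CONCORDANT. A conflict takes precedence
over a depth difference when both occur (e.g., member conflicting at
phylum but also less deeply classified): the conflict is the stronger
discordance, and the definition's "or" list does not order the cases.
This makes the four classes exhaustive and mutually exclusive, with
UNDER/OVER swapping under argument exchange and the other two classes
symmetric.

## Synthetic data generator

The generator emulates size-filtered 16S OTU collections: each OTU is a
cluster of `members_per_otu + 1` sequences with one designated
representative, a known true tree, a true (error-free) alignment, and
per-member lineages with known concordance classes.

* **Trees.** Yule (pure-birth) topologies: starting from a cherry, a
  uniformly random current leaf is split until the leaf count is
  reached; every edge gets an i.i.d. Exponential(1) length. Each tree is
  then rescaled exactly so the *mean* path length from the designated
  representative leaf to the other leaves equals `target_depth`
  (substitutions/site). With two leaves the single path equals
  `target_depth` exactly. The default depth 0.05 straddles the 0.03
  audit threshold.
* **Sequences.** The root sequence is drawn from the model's base
  frequencies; each branch applies exact transition probabilities — JC
  in closed form, or GTR+Γ with the rate matrix normalized to one
  expected substitution per site and four equal-probability discrete
  Gamma categories (quantile midpoints, renormalized to mean one; a
  site keeps its category across the whole tree). JC is the default
  because the closed-form p-distance expectation makes the simulator
  independently checkable; GTR+Γ mirrors the common `GTRGAMMA` setting
  of ML tree estimation. With the default `indel_rate = 0` the true
  alignment is the gap-free site matrix, so MSD is measured against a
  perfect MSA. A deletion-only indel model (per-site deletion
  probability 1 − e^(−rate·t) per branch, deletions inherited by all
  descendants) exercises gap handling without requiring an aligner.
* **Lineages.** A small synthetic taxonomy assigns each OTU a
  genus-depth base lineage (species unassigned, as is typical of
  classifier output). Each member is independently discordant with
  probability `p_discordant`; discordant members alternate between a
  sibling-genus swap (CONFLICTING) and a one-rank truncation (UNDER).
  The constructed class of every member is recorded as ground truth.
* **Seeding.** One master seed drives a generator that derives per-OTU
  seeds (and per-OTU tree/evolution sub-seeds), so datasets are
  bit-reproducible and individual OTUs regenerable.

What the generator does **not** emulate: sequencing error, chimeras,
PCR artifacts, insertion events, alignment-estimation error (the MSA is
true by construction), tree-estimation error (audits here score against
the true tree), or realistic taxonomies. Passing tests therefore
demonstrate correctness of the metrics and aggregation on known-truth
inputs — not robustness to upstream alignment or tree estimation error
on real amplicon data, where MSD and BLD additionally absorb those
errors.

## Numerical choices and problem sizes

* NW alignment is exact O(mn) dynamic programming; scores are floats
  and tie-breaks are deterministic, so outputs are reproducible across
  runs and platforms.
* Tree distance comparisons in tests use 1e-9 (Newick round-trip) and
  1e-12 (ground-truth path sums) tolerances; summation order differences
  leave ~1e-16 residues.
* The acceptance checks run at deliberately modest sizes chosen so each
  statistical assertion has a wide margin: 200 random MSAs (≤ 10 rows ×
  ≤ 100 columns) for the MSD oracle; 100 random trees (≤ 64 leaves,
  with re-rooting) for the BLD oracle; all sequence pairs of length ≤ 6
  over {A, C} for alignment optimality; 100 replicates at L = 10,000
  for JC consistency (the mean observed p-distance must sit within 3
  binomial standard errors of the closed form, and the corrected mean
  within 5% of the true distance); 5 replicates of 8 OTUs × 15 members
  at depth 0.1, L = 5,000 for the underestimation direction — at that
  depth the expected gap d − E[p(d)] (≈ 0.0075) exceeds five standard
  deviations of the replicate noise, which is inflated by the members'
  shared path segments near the representative, so "mean BLD ≥ mean MSD
  in every replicate" is assertable literally; and 10 compact
  (depth 0.01) + 10 divergent (depth 0.08) OTUs of 20 members at
  L = 5,000 for end-to-end flag recovery, where the compact maximum
  observed MSD (≲ 0.026) and divergent means (≳ 0.069) are separated
  from the 0.03 threshold by wide margins.

## Known limitations

* PSD reproduces the *definition* of pairwise-alignment dissimilarity,
  not any particular tool's identity value: heuristic clustering
  aligners use unpublished internal scoring, so exact agreement with
  their reported identities is a non-goal.
* Linear gap costs only; affine penalties and banded/heuristic
  alignment are out of scope.
* The OTU map dialect is QIIME classic TSV; BIOM is unsupported.
* Single-tree Newick files only; branch support values are ignored.
* The deletion-only indel model cannot create insertions, so simulated
  alignments never contain columns that are gaps in the representative
  but residues elsewhere in more than the deletion pattern implies.
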