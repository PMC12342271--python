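# Methods

This note records the statistical model behind each pipeline stage, the
parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic generators do and do not emulate.

## Cohort model

A mutation is identified by `GENE:protein_change` (exact level, e.g.
`KRAS:G12D`). Collapsing to residue position (`KRAS:G12`) is an explicit
transformation used only by the metastasis stage, where hotspot positions
are the natural marker unit; it is never applied implicitly. Duplicate
(sample, mutation) observations collapse silently into one presence bit.
Each `sample_id` is treated as an independent tumor; patient-level
deduplication is out of scope and should be done upstream if needed.

Filters, in order: records with VAF ≤ 0.125 are dropped (strict
inequality — "greater than" is read literally); hypermutated samples
(mutation count above a configurable cutoff, default 500) are removed
entirely; mutations recurring in fewer than 3 of the remaining samples
are dropped. Because recurrence is always counted among non-hypermutated
samples, the result is independent of the order in which the filters are
interleaved (property-tested). The hypermutation cutoff is a stand-in
default — the canonical rule is cohort-specific — and is recorded in the
run provenance.

## Pair mining

Every unordered cross-gene pair of retained mutations is tested; n_total
is always taken from the matrix, never hard-coded. The Fisher test is
two-sided (sum of hypergeometric outcomes at fixed margins with
probability ≤ observed, using the conventional 1+1e-7 relative gate),
implemented via log-gamma arithmetic so that ~10^5 tables per cohort run
in seconds; it matches both `scipy.stats.fisher_exact` and a brute-force
enumeration oracle to ≤ 1e-12 in the test suite. Odds ratios follow
ad/bc with zero-cell conventions: +inf when bc = 0 < ad, 0 when ad = 0 <
bc, NaN when both vanish.

BH adjustment is applied across all tested pairs (via statsmodels).
Classification: significant means q < 0.3; co-existing additionally
requires OR > 1 and a ≥ 3 joint carriers; excluded requires OR < 1 with
no joint-carrier floor (a = 0 pairs are deliberately tested and
reportable). The "observed in at least three tumor samples" condition is
read as a joint-occurrence requirement on the co-existing class only,
since excluded pairs with a = 0 are explicitly retained; both thresholds
are configurable. OR exactly 1 is labelled neutral — the two reported
classes are defined by the direction of deviation, and ties belong to
neither.

The test suite's choice of a two-sided test (rather than one-sided per
direction) matches reporting both classes from a single test and is the
convention the q < 0.3 threshold was applied to.

## Annotation

Pathway sharing is decided by gene-set intersection, never by pathway
name matching. Pairs where either gene is absent from every set are
flagged unannotated and excluded from the shared/not-shared tallies (the
three statuses partition the pair list). Tissue fractions support two
denominators — all tumors in the tissue, or tumors carrying either
constituent — the either-carrier fraction always dominating. The
pathway×tissue bubble table counts, per pathway, the union of
double-mutant tumors over pairs with at least one constituent gene in the
pathway; rows with fewer than 80 double-mutant tumors or under a 10% rate
are filtered ("less than" cutoffs, so boundary rows stay).

Synthetic-lethality enrichment projects mutation pairs to deduplicated
unordered gene pairs and tests each class against the rest in a 2×2
Fisher. The universe is the set of gene pairs appearing in any tested
pair result — the only choice reproducible from pipeline outputs alone.
Generic gene-set enrichment is a hypergeometric upper tail over a GMT
collection with BH; the background defaults to the union of set members
and is configurable.

## Subnetworks

Seed genes come from co-existing pairs whose tissue double-mutant
fraction strictly exceeds a tissue-specific threshold (fractions in
[0, 1]; e.g. 0.005 for a "0.5%" rule). Seed weights are all 1, normalized
internally to a restart distribution.

Personalized PageRank is an explicit sparse power iteration
x ← α(xP + (dangling mass)·p) + (1−α)p with dangling nodes redistributing
to the personalization vector; it stops at an L1 change below 1e-10 or
after 100 iterations. The iteration cap is the published setting; the
tolerance is ours. At α = 0.85 the cap binds before the tolerance
(0.85^100 ≈ 9e-8), so oracles in the tests replicate the same iteration
policy rather than the exact fixed point. Scores are nonnegative and sum
to 1 (±1e-9, asserted).

"Edges with score greater than the threshold" is implemented as a node
score threshold with induced edges — propagation yields node scores, and
the robustness analysis speaks of genes exceeding a score. The two
published thresholds (0.001 for subnetwork extraction, 0.002 in the
randomization analysis) are one parameter with per-analysis defaults.

Degree-preserving randomization attempts `swap_multiplier × |E|` two-edge
exchanges (a,b),(c,d) → (a,d),(c,b), rejecting self-loops and duplicate
edges; the budget counts attempted, not accepted, swaps (logged). In- and
out-degree sequences are preserved exactly. Enrichment robustness reports,
for each pathway enriched (BH q < 0.05) in the original subnetwork, the
percentage of randomized replicates in which it is also enriched.

## Metastasis mining

FP-growth is implemented from scratch (conditional pattern bases on a
prefix tree) because no frequent-itemset library is available in the
target environment; it is verified against an independent Apriori-style
levelwise oracle on databases with ≤ 15 items. Supports are exact;
output order is deterministic (support descending, then lexicographic).
Association rules A ⇒ C use confidence = support(A∪C)/support(A).

Support thresholds are plain configuration with no default coupling — the
sensible value depends strongly on cohort size (7e-5 at ~6×10^4 tumors
corresponds to a count of ~5; at n = 2000 it degenerates to a count of 1
and the search explodes, so small cohorts need an explicit, larger
value).

The marker tree roots at a null node; a chain A–B–C exists only if every
prefix rule ({A} ⇒ B, {A,B} ⇒ C) meets the confidence threshold. Within a
chain, items are ordered by marginal support (ancestral = more frequent,
ties lexicographic), which also makes the construction acyclic; rules are
consumed highest-confidence first. Pruning removes root-attached branches
whose subtree contains only direct pairs (depth ≤ 2), matching the stated
exclusion of pairs connected only to the null root — a planted triplet
survives as a depth-3 path, a lone pair prunes to an empty tree.

Pair statistics in a restricted cohort reuse the same Fisher machinery;
chi-square uses the 2×2 continuity correction (the default of the
standard implementation), configurable off, and is emitted missing for
degenerate margins. Volcano classification applies |log10 OR| > 0.75 and
−log10 p > 1.65 as stated; note 10^−1.65 ≈ 0.022, not 0.05 — the stated
1.65 is implemented, the equivalence claim is not. Zero/infinite ORs get
a Haldane 0.5 continuity-corrected stand-in, flagged. Pairs with fewer
than three joint occurrences are flagged out of volcano/bubble outputs.

## Transcriptome

Group 1 is tumors carrying an anchor mutation plus a partner-gene
mutation that together form a reported significant co-existing pair;
group 2 is tumors carrying exactly one side, or both sides without a
reported pair. Mann–Whitney is used exactly as stated (despite comparing
distributions rather than means): two-sided, scipy's automatic
exact/asymptotic switch with tie correction. BH runs across all tested
genes, not only those passing the fold-change cut (the order of
operations was open; testing everything is the conservative reading that
keeps q-values interpretable). log2FC is log2 of the mean-TPM ratio —
the printed formula omits the log operator, but the |log2FC| > 0.5
threshold fixes the intended semantics. A pseudocount (default 0.01) is
added to both means only when either is zero, perturbing no other gene.
z-scores use the population (divide-by-n) SD across the union of both
groups — unstated in the source, recorded in output metadata; zero-
variance genes are dropped.

## Synthetic generators

Every generator is a pure function of (config, seed); one integer seed
drives independent substreams per component, and identical seeds give
byte-identical files.

*Cohorts.* Background mutations are independent Bernoulli columns with
marginals drawn from a configurable range (default 0.02–0.15 — the upper
range of recurrent hotspot frequencies, chosen so recurrence filters pass
at n ≈ 2000). Planted pairs are drawn from the exact OR-parameterized 2×2
joint: p11 solves p11·p00 = θ·p10·p01 inside the Fréchet bounds (Plackett
construction, rationalized quadratic root for numerical stability near
θ = 1), so the planted θ is directly comparable to the pipeline's ad/bc
estimator — the reason this construction was chosen over latent-Gaussian
dichotomization. Metastatic markers are itemsets carried jointly: the
metastatic carrier rate is enrichment × base rate, with the primary rate
renormalized down so the cohort-wide marginal stays at the base rate; the
expected propensity then equals the enrichment factor exactly (requires
enrichment × metastatic fraction < 1). VAFs are drawn uniform on
(0.15, 0.6): generated cohorts emulate calls that already passed VAF QC,
so the loader's VAF filter is a pass-through on synthetic data (that
filter is exercised by hand-written fixtures instead).

*Networks.* Directed scale-free graphs (preferential attachment),
simplified to simple digraphs and patched to weak connectivity; pathway
gene sets grow from random centers through graph neighborhoods so
membership correlates with topology, as in curated databases.

*Expression.* TPM = 2^x with x normal in log2 space (default mean 5,
SD 0.5); planted genes shift the group-1 mean by the stated log2 effect.

What the generators do **not** emulate: mutational signatures and
trinucleotide context, copy-number events, patient-level structure,
inter-gene correlation beyond the planted pairs, pathway-coherent
mutation placement, and heavy-tailed TPM dispersion. A green recovery
test therefore establishes that the estimators recover the planted
parameters under the stated sampling model — not that real cohorts
satisfy that model.

## Numerical conventions

- Fisher two-sided gate: pmf ≤ observed × (1+1e-7); p clipped to 1.
- PageRank: L1 tolerance 1e-10, cap 100 iterations, scores renormalized
  to sum 1 after clipping negatives at 0 (float dust only).
- BH q-values clipped to [0, 1]; inputs outside [0, 1] are errors.
- Tie-breaks everywhere are lexicographic on rendered keys, making every
  output deterministic for a fixed input.
- Degenerate inputs favour explicit signals: empty groups, all-hypermutated
  cohorts, zero seeds, and σ = 0 genes raise or flag rather than silently
  producing numbers.

## Known limitations

- Gene-level set methods for mutual exclusivity (MEMo/MEGSA-style module
  search) are intentionally out of scope; mining is mutation-level.
- The pipeline treats samples as exchangeable across tissues during pair
  mining; large cohorts can dominate pan-cancer signals (the tissue
  tables downstream are the mitigation, not a mixed model).
- The optional candidate-pruning speed path mentioned in early design
  was not implemented: the vectorized Fisher made exhaustive testing fast
  enough that a bit-equivalence obligation was not worth carrying.
- `min_support` has no safe universal default; see above.
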