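# Methods

## The analysis model

A PAX experiment yields, per bait strip and replicate, a list of MS-identified
proteins with spectral counts. The pipeline treats these as a proteins ×
(bait, replicate) count matrix and asks two questions: *which proteins
associate selectively with one bait*, and *which associated proteins are
plausible direct binders given the bait's sequence*.

**Normalization.** Spectral counts are a relative-abundance proxy whose
scale varies between runs. Stage one rescales each sample column to the
average total spectral count over all samples ("quantitative values");
stage two expresses each count as a percentage of the total spectra in its
sample; stage three averages over each bait's replicates. Percent-of-total
is a ratio within a column, so any per-column rescaling — including stage
one — cancels in it: `percent_of_total ∘ quantitative_values ≡
percent_of_total` on raw counts. This collapse identity is property-tested
and makes the downstream analysis insensitive to the exact first-pass
normalization, which matters because first-pass "quantitative values" are
usually produced inside closed-source viewers whose algorithm can only be
approximated.

**Clustering.** Profiles are compared with the uncentered Pearson
correlation — the correlation about zero, equivalently the cosine of the
angle between profiles. For bait-association profiles this is the right
notion: two proteins that load on the same bait point in the same direction
from the origin regardless of their absolute abundance, and the statistic
is invariant to positive per-protein scaling. Distance is 1 − r;
agglomerative clustering uses average linkage (unweighted mean pairwise
distance), with single and complete linkage available. Linkage updates use
the Lance–Williams recurrence; ties on the minimum distance are broken
toward the pair containing the lowest leaf indices, so merge sequences are
fully deterministic and regression-testable. The test suite checks the
merge sequence against a brute-force oracle that recomputes linkage from
cluster member sets at every step, and merge heights against SciPy's
average-linkage implementation.

**Single-bait selection.** A protein is a single-bait interactor when its
replicate-mean signal exceeds a threshold τ for exactly one bait column
(the control counts as a column). τ defaults to 0: any reproducible mean
signal counts as association, the strictest reading, and is configurable.
`bait_pure_clusters` then returns the maximal dendrogram subtrees whose
leaves all share one bait assignment — a principled reconstruction of
cluster-boundary marking that is usually done by eye on the heat map.

**Domain filtering.** Consensus motifs in the bait predict the domain
classes of legitimate direct binders (PxxP→SH3, NPF→EH, PPxxF→EVH1 class
II, PPLP→WW, (F/L)PPPP→EVH1 class I; the registry is TSV-overridable).
Proteins with any control-peptide association are eliminated first; the
remainder are called for a bait iff they have signal there and carry an
expected domain. This keeps biologically sensible multi-bait binders (an
SH3+EH protein legitimately hits a PxxP bait and an NPF bait) that the
single-bait rule must discard. The final call set is the union of both
evidence streams keyed by (bait, protein).

**Motif scanning.** Patterns are matched at every start position;
overlapping and nested matches are all reported, since poly-proline runs
genuinely contain many PxxP registers and domain expectation only needs
presence. The crosslinker placeholder `@` matches no pattern position —
substituting a motif residue destroys the motif, which is also what the
motif-overlap annotation on array spots encodes.

**Array design.** When the spot budget k is below the bait length L,
substitution positions follow the even-spread rule
p_i = 1 + round((i−1)(L−1)/(k−1)) (round half away from zero, dedupe,
backfill with the smallest unused positions). The rule is deterministic,
covers both termini, and an explicit position list can override it — some
published arrays instead substitute a contiguous prefix, and the selection
rule is genuinely a free design choice. The crosslinker is represented
internally by `@` (every single-letter amino-acid code is taken or
ambiguous) and exported as the display token `[Bpa]`, which round-trips
losslessly. Membranes fill row-major (column fastest), the conventional
SPOT synthesis order.

**FDR.** Both target-decoy conventions are offered — decoys/targets
(default) and 2·decoys/(targets+decoys) for concatenated databases —
because published FDR figures rarely state their formula.

**Hi3 quantitation.** Protein quantity is the mean MS response of the top
three (or both, when only two exist) most intense peptides; single-peptide
proteins are flagged low-evidence. Absolute amounts come from the ratio to
a spike-in calibrant of known concentration (default 50 fmol/µg); the
calibrant self-quantifies exactly by construction.

## Synthetic experiments

The generator emulates the statistical structure the analysis assumes, at
the reference study conditions: 4 motif-bearing baits plus a motif-free
control, 3–8 specific interactors per bait, 13 sticky background proteins
(the observed number of highly abundant control-peptide binders), 2
multi-bait proteins, 5 domain-only decoys, and n = 2 replicates.

Counts are Poisson with rate λ = abundance × binding strength, making
lysate abundance (log-uniform over 3 orders of magnitude, the dynamic
range of a label-free lysate survey) and interaction strength separable.
Specific interactors draw strength 10^U(0.7, 1.5) so that genuine
interactions are detectable but span weak to strong; sticky proteins pair
high abundance 10^U(2, 3) with low per-strip stickiness 10^U(−1, −0.3),
reproducing the observation that non-specific binders are dominated by
highly abundant proteins. A 10% per-replicate dropout models stochastic
data-dependent acquisition — the reason duplicate runs are needed. A
quarter of the sticky proteins carry an SH3 domain, so control elimination
(not annotation gaps) is what removes them; domain-only decoys carry
expected domains but produce no records, probing that the filter requires
observation. Peptide responses for Hi3 are log-normal about true abundance
with σ = 0.25 (fixed in the config; σ = 0 recovers abundances exactly).
The target-decoy simulator scores correct matches N(8, 1) (targets only)
and random matches U(0, 10) split evenly between database halves, sized so
the decoys/targets estimate at threshold 5 equals the requested FDR in
expectation.

What the generator does *not* emulate: real protein identities and homology
structure, run-to-run retention or intensity drift, shared-peptide
inference ambiguity, or crosslinking chemistry. Passing recovery tests
therefore demonstrates that the pipeline's logic is sound under its own
assumptions, not that those assumptions hold for any particular lysate.

## Problem sizes and numerical choices

Tests and the acceptance script run 20-seed batches of the default-size
simulation (~30–40 proteins, 10 samples each), 200-trial oracle comparisons
on ≤10-leaf clustering instances, and 1000-peptide motif-scanner oracle
sweeps; the whole suite completes in a few seconds. Percent-of-total
columns are asserted to sum to 100 within 1e−9; correlation values are
clipped into [−1, 1] against floating-point overshoot; all-zero profiles
are an error (their direction is undefined) with the offending protein
named. Ranking ties break lexicographically by accession. All simulation
randomness flows through one `numpy` Generator per config, so outputs are
byte-identical under a fixed seed.

## Known limitations

- The headline counts of a real screen (proteins identified, interactions
  called) depend on the lysate and MS setup; the package reports computed
  totals only and both the per-bait tally and the distinct-pair count,
  since "possible interactions" can be tallied either way.
- Average linkage is a choice; the merge order under single/complete
  linkage can differ, and cluster-boundary extraction assumes the bait
  assignment is correct.
- The curated domain fixture for the worked-example prey proteins is an
  illustration set, not a database snapshot; real analyses should supply a
  Pfam/InterPro export.
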