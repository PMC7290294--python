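# Methods

`omegascan` diagnoses loss of function in a protein-coding marker gene from
two independent molecular signatures: (1) inactivating mutations visible in a
codon alignment — frameshift indels, premature stop codons, start-codon loss —
and (2) relaxation of purifying selection, detected as an elevated
nonsynonymous/synonymous rate ratio ω = dN/dS on designated foreground
branches of a species tree. This note documents the models, the numerical
choices, and what the synthetic-data tests do and do not demonstrate.

## Inactivating-mutation scanning

**Reference frame.** A sequence is scanned against the reading frame of a
designated set of intact reference taxa. The frame is made deterministic by a
majority-rule consensus over the reference rows (gap counts as a state; ties
break toward a base over a gap, then alphabetically). Reference codon *k*
occupies the *k*-th triplet of consensus non-gap columns from the frame
anchor. All reported coordinates are 1-based alignment columns.

**Frameshifts.** Focal-vs-consensus indels are collected into runs; runs
separated by at most 2 matching columns are merged before the test, so
co-located insertions that sum to a multiple of 3 (a compensated insertion
that restores the frame) are correctly not called. A merged run whose net
length is not a multiple of 3 is one frameshift event — an insertion if the
focal taxon has bases where the references gap, a deletion otherwise.

**Premature stops** are called in the reference frame only: a stop triplet at
any reference codon before the final one. Because alignment columns absorb
indels, reference-frame translation is well defined even downstream of a
frameshift; stops that would only exist in a shifted frame are deliberately
not called (the frameshift itself is the event), which avoids double counting.

**Start-codon events.** A mutated initiator codon is rescued if an in-frame
ATG lies within a window (default 100 nt) of the start; otherwise it is a
start loss. If the window instead contains an out-of-frame ATG, the event is
reported as a putative start+stop displacement — a pattern seen in real
pseudogenes where both ORF boundaries have slid — and flagged as such, since
the displaced stop cannot be verified from the alignment alone.

**Status and branch placement.** Any frameshift, premature stop, or start
loss makes a sequence a pseudogene; a start+stop displacement alone yields a
pseudogene call flagged "putative". Events identical in (kind, column,
length) are merged across taxa and placed on the stem edge of the smallest
clade containing exactly their carriers — a Dollo-style single-origin
assignment. Carriers that do not form a clade are split into maximal
sub-clades by a deterministic preorder traversal, each sub-clade receiving an
independent event.

## Alignment cleaning

Before any model fit the alignment is reduced to a stop-free codon matrix:
(i) minority insertion runs whose inserted length is not a multiple of 3
(frameshift insertions) are removed column-wise; (ii) minority in-frame
insertion runs (lineage-specific insertions) are removed likewise — "minority"
defaults to carried by fewer than 10% of the active taxa, configurable; (iii)
any codon site where an active taxon carries an in-frame stop is deleted for
all taxa, keeping every taxon on a single site set. Pseudogene sequences are
retained in the fits after cleaning; relaxation is then measurable on their
branches rather than assumed. Cleaning is idempotent. Residual Ns and gaps
inside a codon are treated as missing data in the likelihood.

## Codon substitution model

The substitution process is the Goldman–Yang codon model on the 61 sense
codons of the standard code (stop states excluded). For codons *i*, *j*
differing at exactly one position,

    q_ij = pi_j * kappa^[transition] * omega^[nonsynonymous],

zero for multi-position changes, diagonal set so rows sum to zero, and the
matrix rescaled so that −Σ_i pi_i q_ii = 1, making branch lengths expected
substitutions per codon. The construction is time-reversible (detailed
balance pi_i q_ij = pi_j q_ji), so P(t) = exp(Qt) is computed through a
symmetric eigendecomposition in the π-weighted inner product and reused
across branch lengths; rows are clamped at zero and renormalized to absorb
rounding.

Equilibrium frequencies come in the four schemes conventional for this model
family, with free-parameter counts used by AIC:

| scheme | definition | free params |
|--------|------------|-------------|
| CF0 | equal, 1/61 | 0 |
| CF1 | product of pooled nucleotide frequencies (F1x4) | 3 |
| CF2 | product of position-specific nucleotide frequencies (F3x4) | 9 |
| CF3 | empirical codon proportions (F61) | 60 |

CF3 uses a pseudocount of 1/61 on unobserved sense codons so the chain stays
irreducible; the 60 parameters are counted for AIC but not optimized —
empirical proportions are the maximum-likelihood estimate to the accuracy
that matters here, and optimizing 60 frequencies numerically is gratuitous.

## Likelihood and model fitting

Log-likelihoods use Felsenstein pruning over codon sites with unique-pattern
compression, per-pattern rescaling against underflow, and all-ones partials
for missing states. Trees may be rooted arbitrarily; time reversibility makes
the likelihood root-invariant, which the tests verify.

Model families:

* **one-ratio** — a single ω for all branches (the null);
* **branch** — one ω per branch category; categories label foreground
  lineages (several foreground categories are supported, e.g. separating an
  inactivated species from its intact sister species);
* **free-ratio** — an independent ω per branch, used as an exploratory
  screen; branches with reported ω above 0.8 (configurable) are flagged;
* **branch-site model A** — four site classes with proportions
  (p0, p1, p2a, p2b), p2a/p2b splitting 1−p0−p1 proportionally to p0:p1;
  class 0 has ω0 ≤ 1 everywhere, class 1 has ω = 1, classes 2a/2b have ω2 on
  the (single) foreground category. The alternative bounds ω2 ≥ 1; the null
  fixes ω2 = 1, one fewer free parameter.

Optimization is bounded L-BFGS-B on log-transformed parameters (ω ∈ [1e-4,
999], κ ∈ [1e-2, 100], branch lengths ∈ [1e-7, 50]; mixture proportions
through unconstrained stick weights), with jittered multi-restarts (default
3) and the best restart kept. Branch lengths are re-estimated under every
model by default; a fixed-branch-length mode is provided for speed and for
simulation studies where true lengths are known. κ is shared across
categories. Free parameters counted for AIC = κ + ω parameters + frequency
parameters + branch lengths when estimated; every non-root edge is counted
(2n−2 on a rooted binary tree rather than the unrooted 2n−3 — the constant
cancels in every nested comparison and same-tree AIC ranking).

**The ω = 999 sentinel.** When a category has no inferred synonymous change,
the likelihood is flat in ω above some point and the MLE is effectively
unbounded. After each fit, any ω estimate above 50 is pushed to the upper
bound if doing so changes lnL by less than 1e-3; such estimates are reported
as 999, the conventional sentinel for dS = 0 on that category. A finite
interior optimum (likelihood not flat) is never modified.

**Tests.** Nested models are compared by the likelihood-ratio statistic
2Δlnl against a χ² upper tail with df equal to the free-parameter difference
(df = number of extra ω categories for branch models). For the branch-site
test, χ²(1) is the default reference (conservative at the ω2 = 1 boundary);
the 50:50 mixture of χ²(0) and χ²(1) is available by flag. Frequency schemes
are selected by AIC of one-ratio fits on the intact-sequence set, ties
breaking toward fewer parameters.

## Synthetic data

The simulator draws root codons from π and evolves them branch-by-branch by
sampling from P(t) per site (site-independent transition-matrix sampling, not
an event-resolved Gillespie simulation — sufficient for likelihood-level
testing). Defaults emulate a conserved single-copy marker gene: background
ω = 0.4, relaxed foreground ω near 1, κ = 2, 324 codons (a 972-bp ORF), the
first codon pinned to ATG.

Inactivation events are injected after substitution, so the selection signal
(ω) and the disruption signal (events) are independently controllable —
mirroring the two diagnostic criteria. Injections carry an exact truth table
(kind, final alignment column, expected stem branch). Nonsense injections
write a stop into all descendants of a branch; frameshift injections
insert/delete runs with gap padding elsewhere; start-codon injections mutate
the initiator, and — to keep the truth table exact — remove chance ATG
trinucleotides from the rescue window of carrier rows (junction-aware across
indels, replacing one base with C, which can create neither a stop nor an
ATG) while protecting injected stops and the deliberately displaced start.
Co-located indel injections whose net length is a multiple of 3 are recorded
as compensated: no truth event, and the scanner finds none.

What the simulations do **not** emulate: alignment error, assembly artifacts
(N runs), rate variation among sites or lineages beyond the branch-ω map,
indel evolution outside injected events, selection on codon usage, and
sequencing error. Round-trip and recovery results on synthetic data
demonstrate internal consistency of scanner, simulator, and estimator — not
robustness to those real-data failure modes, which is why the pipeline keeps
the mutation table and the ω tests as two separate lines of evidence.

## Numerical and design notes

* Likelihood exactness is tested against brute-force enumeration over
  internal-node states on small trees (agreement ~1e-14, asserted at 1e-8).
* A site pattern receiving zero likelihood (possible only with zero branch
  lengths and conflicting states) raises an explicit numerical error naming
  the pattern.
* Empirical calibration at the shipped study conditions (12 taxa × 300
  codons, background ω 0.4 / foreground ω 1.2, 20 replicates; 10 taxa × 200
  codons, 200 null replicates): mean foreground ω̂ within ±0.15 of truth,
  LRT power 1.0, and two-ratio type-I error ≈ 7% at nominal 5% — close to
  but above nominal, as expected for moderate-length alignments. These sizes
  were chosen as representative of single-exon marker-gene analyses while
  keeping the full calibration reproducible in minutes; `scripts/acceptance.py`
  recomputes all of them.
* Simulated stationarity checks over the 61-state space need long sequences:
  multinomial noise alone gives an expected total-variation distance of
  ≈0.039·sqrt(1e4/n), so the 0.01-TV assertion simulates 5×10⁵ codons.
* The pipeline derives per-clade fit seeds from the run seed, records input
  SHA-256 digests in the manifest, and is bit-reproducible given the same
  config and seed.

## Known limitations

* The scanner's single-frame design will not call a premature stop that
  exists only in a frame shifted by an upstream indel of the same sequence;
  the upstream frameshift is the reported event.
* The start+stop-displacement call is heuristic (displaced out-of-frame ATG
  near the start) and always flagged putative.
* Free-ratio fits optimize all branch ω's jointly; above ~200 branches this
  is slow and a warning is logged.
* Branch lengths on the two root-adjacent edges of a rooted binary tree are
  only jointly identified; their sum is what the likelihood constrains.
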