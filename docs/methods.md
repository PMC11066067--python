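# Methods

## Dated trees and time slices

The species tree is rooted, binary, and ultrametric, with node ages in Ga
(larger = older); all leaves sit at age 0 with unique labels, and every
branch `parent -> child` has strictly positive duration.  Newick input may
carry ages either as ultrametric branch lengths (accumulated from the
leaves, with a relative ultrametricity tolerance of 1e-6) or as
`[&age=x]` node comments; the writer emits both so either convention
round-trips.  Polytomies are rejected: the reconciliation recurrence
assumes binary species nodes.

Distinct internal-node ages partition `[0, root age]` into time slices;
a branch is a member of every slice its interval covers, so two branches
co-occur in a slice exactly when their intervals overlap there.  Slices
are the contemporaneity structure for transfers: strict interval overlap
is required; lineages that merely touch at a boundary are not considered
contemporaneous.

Ages map to named geological intervals via a bundled table (Precambrian
eras plus Phanerozoic eras, Hadean bounded at 4.6 Ga).  A boundary age
belongs to the younger interval (ties toward the present): 3.2 Ga is
Mesoarchean, not Paleoarchean.  Age uncertainty is not modelled: the tree
carries point ages only, so credible intervals on node dates do not
propagate into event dates.

## The reconciliation engine

Events and default costs: transfer τ=3, duplication δ=2, loss λ=1,
speciation σ=0.  Costs are non-negative reals; integer-valued schemes are
compared exactly, float schemes at a 1e-9 tolerance.  The engine minimises
total cost = σ·S + δ·D + τ·T + λ·L over dated histories; origination is
free.

The dynamic program runs over DP levels young to old.  Levels 1..T are the
time slices; one zero-width stem level above the root holds a conceptual
stem branch so a gene can originate above the species root and speciate at
the root node (or duplicate there before speciating).  State value
`IN(u, x, t)` is the minimal cost of embedding gene clade `u` given
presence on branch `x` at the top of level `t`.  Within a level: descent
to the bottom boundary (free), duplication (δ, both sub-clades stay on
`x`), transfer (τ, one sub-clade stays, the other is received by any other
branch alive in the level, or the dead state), and transfer-loss
(τ+λ, the whole clade jumps).  At a bottom boundary where `x` ends in an
internal node: speciation (σ, sub-clades to the two descendant branches in
either assignment) or speciation-loss (λ, the clade continues into one
descendant).  At time 0 a singleton clade terminates, for free, exactly on
the species leaf its genome names.  The transfer minimisation uses the
best/second-best receiver trick, so each level costs O(branches) per clade
and split rather than O(branches²).

**The dead channel.** Unsampled or extinct diversity is modelled as one
extra state per level: free to persist, τ to enter (a reception), τ to
leave, duplication permitted at δ, no speciations, and no observed leaf
may terminate there.  One state (rather than one per hypothetical extinct
branch) is the minimal construction that lets transfers route through
unsampled lineages.  In synthetic truth the dead channel is never
*required* — the simulator transfers only between sampled branches — so it
is exercised as an option, not a necessity.

**Transfer-loss budget convention.** A transfer-loss is one transfer plus
one loss: it contributes τ+λ to the cost, one reception and one loss
record to the event list, and consumes two units of the brute-force
oracle's non-speciation event budget.

**Backtracking and ties.** One optimum is returned, deterministically:
among co-optimal moves the preference is speciation < speciation-loss <
duplication < transfer < transfer-loss, then the lower canonical species
branch index (a preorder index that depends only on topology, ages and
labels), then the younger slice.  Co-optima are not enumerated, and no
claim is made that the returned optimum matches any particular external
tool's representative (e.g. a symmetric-median selection among co-optima).

**Amalgamation.** With a conditional-clade table as input, the DP ranges
over the observed clades and observed splits only, as an unweighted set;
clade frequencies are carried for reporting but do not weight the
parsimony objective.  Because every sampled tree's splits are a subset of
the amalgamated split set, the amalgamated optimum can never exceed the
best single-tree optimum.  Unrooted gene trees are handled by trying every
rooting and keeping the cheapest (ties by canonical branch key).

**Oracles.** Two independent routes certify the DP.  (1) A brute-force
enumerator walks every dated history with at most 4 non-speciation events
on instances with ≤4 gene and ≤4 species leaves, with no memoisation and
its own alive/boundary computation.  (2) With transfers priced out
(τ=1e9), the optimum must equal the classical duplication-loss cost from
the LCA mapping closed form.  Both are exercised in the test suite and the
acceptance script.

## Event dating

Speciations are dated at the age of the node where they occur.
Duplications, losses and transfer receptions are dated at the midpoint of
their species branch — the event is only localised to a branch, so the
midpoint is the natural summary; an optional slice-midpoint mode (off by
default) dates them at the midpoint of the branch segment within the
event's DP slice instead.  Transfers yield exactly one dated record (the
reception); departures are internal bookkeeping.  Events on the stem are
dated at the root age.  Dead-lineage events have no date on the sampled
tree and are tallied separately in the log.  The first appearance of a
family is the maximum event date; losses count toward it by default (a
loss implies prior presence), with a gains-only switch.  All first
appearances are lower bounds: presence in extinct lineages cannot be
excluded.

## Homolog screen

Internal-node bit scores are the arithmetic mean over *descendant leaves*,
not over immediate children: the leaf mean is independent of how the
internal topology is resolved, whereas a children-mean depends on it.  The
retained family is the leaf set of the MRCA of the query sequences
together with every leaf at or above the bit-score threshold; per-family
thresholds default to the profile's trusted cutoff, falling back to the
minimum query score (conservative) when no cutoff is supplied.  The
e-value prefilter (0.1) is assumed applied upstream at search time and is
documented, not enforced.  Presence matrices are binary (presence, not
copy number); copy numbers are available separately but unused downstream.
Any manual curation of clade boundaries that a human might apply in a tree
viewer is outside the model.

## Regressions

Both regression forms fit ordinary least squares against the *raw*
phosphate concentration: linear (`abundance ~ phosphate`) and log-linear
(`log(abundance + pseudocount) ~ phosphate`), the latter being the
package's interpretation of an "exponential" fit.  The default pseudocount
is half the smallest non-zero abundance in the table.  Slope p-values are
two-sided t-tests; residual degrees of freedom are `n_used − 2`, where
samples with missing phosphate are dropped and counted.  (Survey analyses
sometimes report fewer residual degrees of freedom than `n − 2` — e.g. 129
from 139 samples — which simple OLS cannot produce; missing covariates are
the plausible cause, and this package reports the arithmetic df of the
samples it actually used.)  A constant response returns slope 0 with
p = 1.  Log-linear predictions invert the transform and are floored at 0.
The threshold drop-off statistic is the ratio of median abundance below vs
at-or-above a phosphate threshold, `inf` when the denominator median is 0.

## The simulator

`simulate_dated_tree` draws internal ages as uniform order statistics on
(0, root age) — a conditioned birth-process shape rescaled to a fixed root
age — and coalesces random lineage pairs young to old.  Defaults reflect
the study conditions the pipeline is meant for: 20-tip trees with a 4-Ga
root for reconciliation tests, DTL rates spanning {0, 0.1, 0.3} events per
lineage per Ga, 139-sample abundance tables with phosphate uniform on
0–3.29 μM, a generating slope of −0.79 (a realistic strong negative
coefficient on this scale), intercept 5 and Gaussian noise sd 1 (chosen so
the zero floor is hit in well under 1 % of samples and slope recovery is
unbiased to well within a standard error).

Gene families evolve forward from an origination point (default: the
root, where the family immediately speciates) with exponential waiting
times; transfers pick a uniformly random *other* branch alive at the exact
event time.  Extinct subtrees are pruned; surviving copies become leaves
labelled `g<k>_<genome>`.  The true history retains events with surviving
descendants and exact dates; its `parsimony_cost` prices the
reconciliation induced by the pruning (one-sided speciation →
speciation-loss; one-sided duplication → free pass-through; transfer with
extinct donor side → transfer-loss), which is a feasible reconciliation of
the emitted gene tree and hence an upper bound on the DP optimum — the
central end-to-end property.

What the simulator does *not* emulate: sequence evolution (no alignments
or substitution models — fixtures start at the tree/score level), extinct
species-tree lineages (so transfers to truly unsampled diversity never
occur in truth, only as a reconciliation option), rate heterogeneity
across branches, and correlated gene-tree error (posterior uncertainty is
emulated by Poisson-many random NNI moves per sampled tree, which need not
match any MCMC's correlation structure).  Passing tests therefore certify
the algorithms' contracts under the model's own assumptions, not the
field realism of any particular empirical dataset.

## Problem sizes and numerical choices

The acceptance measurements use 50 oracle instances (≤4 leaves), 50
duplication-loss instances (≤6 species tips), 200 grid families on 20-tip
trees, 25 monotonicity families (12 tips), 30 dating families (15 tips),
20 amalgamated samples of 50 trees on 8-tip trees, 100 scored trees, 2000
null and 500 alternative regression replicates — sizes at which every
property is exercised thousands of times while the whole script completes
in well under a minute on one core.  Ages are compared at 1e-9 Ga;
ultrametricity at 1e-6 relative; DP cost ties at 1e-9 (backtracking
matches values at 1e-7 to absorb accumulated float error in long event
chains).  All randomness flows from one seed, fanned out to components by
fixed offsets modulo 2³¹−1.

## Known limitations

* Point ages only; no propagation of node-age uncertainty.
* One deterministic optimum; co-optimal histories are not enumerated or
  summarised.
* Amalgamation is unweighted; clade frequencies do not bias the optimum.
* The dead channel is a single pooled state, not a model of explicit
  extinct branches.
* Strict-overlap contemporaneity; boundary-touching transfers disallowed.
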