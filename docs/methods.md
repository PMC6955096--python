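# Methods

## The rate-decay model

Apparent substitution rates of viruses decay with the timescale over which
they are measured: recent divergences accumulate change quickly, ancient
ones appear to have evolved slowly, because saturation, purifying
selection, and model misspecification all bias long-branch estimates
downward. The time-dependent rate phenomenon (TDRP) model absorbs this
decay into a power law between the amount of inferred change below a node
and the node's age,

    t = α · s^β ,   α, β > 0 ,

with *s* the average node-to-tip distance in substitutions per site and
*t* in millions of years (myr). β < 1 corresponds to the usual pattern
(deep nodes carry less change per unit time than the shallow calibrations
would predict); β = 1 is a strict clock with rate 1/α. The model is fitted
on the log–log scale, where it is simple linear regression: the slope
estimates β and the intercept log α. Natural logarithms are used
throughout; the choice of base changes neither α, β nor any goodness-of-fit
statistic. Goodness of fit is reported as the adjusted R² of the log–log
regression, 1 − (1 − R²)(n − 1)/(n − 2); it is undefined (NaN) for two-point
fits. An alternative natural-scale R² was considered and rejected: the fit
itself is performed in log space, so the log-scale statistic is the one
that describes it.

### Assumptions

- Calibration ages are known without error. Host node ages are treated as
  fixed constants, identical across posterior samples; only *s* varies per
  sample. Propagating host-date uncertainty would require host posterior
  age distributions, which the input chronogram format does not carry.
- One power law holds across the whole *s* range used, including
  extrapolation beyond the deepest calibration. Extrapolation is permitted
  (dating deep nodes is the point) but flagged with a warning when a query
  *s* falls outside the calibration range.
- Paths leading to endogenous copies (ERVs) are excluded from every
  node-to-tip average, because after germline integration a viral sequence
  evolves at the slow neutral host rate and would mix two rate regimes into
  one distance.

## Co-speciation calibration

A virus internal node is accepted as a co-speciation event when the host
taxa induced by its child clades (virus tips mapped through the
association table, duplicate hosts collapsed) form exactly the same
partition as the child clades of some internal node of the host
chronogram. This is strict set equality, not subset containment or
event-cost reconciliation: a looser criterion would let nodes adjacent to a
host switch donate wrong calibration ages. Multifurcations match only
multifurcations with the identical partition. Detection is filtered on
Bayesian posterior clade support (default threshold 0.75; a missing
support fails the threshold rather than counting as zero), and two manual
override channels exist because topology alone can mislead: events can be
excluded by id (divergences known from outside evidence to be
cross-species transmissions despite matching topology) and forced events
can be appended by virus tip set + host node (divergences known from
outside temporal evidence to be co-speciations despite ambiguous
topology), optionally with an explicit time override.

Events are persisted as virus tip sets, not node pointers, so the same
event can be located in every posterior sample as the MRCA of its tip set.
The MRCA is well-defined even when the tip set is non-monophyletic in a
given sample; the fraction of samples in which it is monophyletic is
reported per event and per query so users can filter. Samples in which a
calibration node retains no non-ERV descendant drop that point; samples
with fewer than two usable points (or no two distinct *s* values) are
skipped and counted, never imputed.

## Posterior summarisation

Per posterior sample the pipeline computes each calibration *s*, fits the
power law, and predicts *t* for each query *s*. Across samples it reports
the sample median and the 95% highest-posterior-density (HPD) interval for
α, β, adjusted R², every calibration *s*, and every query *s* and *t*. The
HPD is the shortest contiguous window of the sorted samples containing
⌈0.95·n⌉ values, ties broken toward the lower start index — deterministic,
and exact for the sample sizes involved (thousands of trees); no density
smoothing is applied.

The posterior bookkeeping helper `retained_sample_count` encodes the usual
MCMC arithmetic: a chain of N steps sampled every k-th yields ⌊N/k⌋
samples, of which the first 25% (floored) are discarded as burn-in — e.g.
10,000,000 steps sampled every 1,000th leave 7,500 retained samples, hence
7,500 fitted models.

## Consensus and annotation conventions

- **Consensus:** per column only unambiguous bases (A/C/G/T) are counted;
  N and ambiguity codes are ignored. The majority base is emitted; a count
  tie among k bases emits the IUPAC code for exactly that base set. A
  column is emitted only when bases are at least as many as gaps — a
  base-vs-gap tie resolves to the base (a consensus position exists);
  gap-majority columns are dropped. The exact gap rule is the one open
  convention here; emitting on ties keeps the consensus as long as the
  aligned element, which is what annotation needs.
- **Identity:** mean pairwise identity compares, per row pair, only
  columns where both rows carry an unambiguous base; the mean over all
  unordered pairs is returned as a percentage. A switch
  (`count_gap_mismatches`) instead counts base-vs-gap columns as compared
  mismatches, since published identity figures rarely state their gap
  convention.
- **Coordinates:** contig coordinate tokens follow the annotation-table
  dialect — optional thousands separators, leading `c` for the complement
  strand, `<`/`>` for truncated (partial) ends, trailing `(start)`/`(end)`
  contig-boundary notes. All spans are 1-based and fully closed on either
  strand, so length = |start − end| + 1. The feature-table validator
  recomputes every non-partial length and flags disagreements with the
  printed value; it never corrects them, because a printed/computed
  mismatch in a published table is a finding, not a typo to silently fix
  (published stork/sea-snake ERV tables contain exactly such rows).

## The synthetic co-phylogeny generator

The generator produces datasets with the statistical structure the
analysis assumes, with this causal chain:

1. **Host chronogram** — pure-birth (Yule) topology with exponential
   waiting times, a final holding time after the last split (so the
   youngest internal node has strictly positive age), rescaled to a root
   age of `root_age` myr. Pure birth rather than birth–death: tree shape
   is not an inference target, and extinct host lineages would carry no
   virus data anyway.
2. **Virus chronogram** — a mirror copy of the host tree (every internal
   node a true co-speciation event with t = host age). Each host switch
   prunes a random virus tip and regrafts it at the midpoint of a randomly
   chosen contemporaneous branch; losses prune tips independently. The
   truth list of surviving co-speciation events is recomputed from scratch
   by exact split-and-age matching, so it is correct under any
   switch/loss pattern.
3. **Substitution lengths** — inverting the power law, s(a) =
   (a/α)^(1/β); each branch gets s(parent age) − s(child age) times a
   multiplicative lognormal factor (log-scale sd `noise_sd`).
   Multiplicative noise keeps lengths non-negative and mirrors standard
   rate-variation conventions. At zero noise every node-to-tip path
   telescopes exactly to s(node age).
4. **ERV tips** — a fraction of tips is flagged endogenous and their
   terminal branch scaled by `erv_rate_scale` over the endogenized
   fraction of its duration (default: the whole branch), emulating the
   slow post-integration regime.
5. **Posterior ensemble** — branch lengths re-jittered by iid lognormal
   factors (sd `jitter_sd`), supports drawn uniformly from
   `support_low..support_high`; topology is fixed across samples.

All randomness flows from the single config seed; identical configs give
byte-identical output files.

### Defaults and what they emulate

| parameter | default | rationale |
| --- | --- | --- |
| alpha, beta | 4.0, 0.6 | a sublinear rate decay of the magnitude seen in deep retrovirus calibrations; β well inside (0, 1) |
| n_hosts | 13 | 12 internal calibratable nodes, the size of the richest real calibration set |
| root_age | 100 myr | the eutherian-radiation depth over which virus–mammal co-divergence is established |
| switch_count / loss_prob | 1 / 0.0 | broadly co-diverging with occasional host switches |
| erv_fraction / erv_rate_scale | 0.3 / 0.5 | a substantial minority of tips endogenous, evolving at roughly half the exogenous pace |
| noise_sd / jitter_sd | 0.05 / 0.05 | moderate branch-level rate noise; the ensemble jitter equals the generating noise, the parametric-bootstrap choice that makes the posterior spread commensurate with the data noise |
| ensemble_size | 100 | enough for stable 95% HPD endpoints at test scale |
| support_low..high | 0.9..1.0 | well-supported clades, as expected for genuine co-speciation nodes |

### What the generator does not emulate

Topology variation across posterior samples (only branch lengths jitter),
sequence-level evolution (no alignments are generated), host-tree dating
error, within-branch rate autocorrelation, and incomplete lineage sorting.
Passing tests therefore demonstrate that the estimator chain is correct
under its own model — power-law signal, multiplicative noise, fixed
topology — not that real posterior ensembles satisfy those conditions.
In particular the HPD-coverage checks (95% intervals covering a held-out
node's true age in 90–100% of replicates, verified by the test suite over
100 replicates at noise sd 0.05 with 12 calibration events and
100-sample ensembles) are a statement about this generative model.

## Numerical choices and degenerate inputs

- OLS via `scipy.stats.linregress` on the log-transformed points; any
  point with s ≤ 0 or t ≤ 0 is rejected at construction (log undefined),
  and a fit with all-equal s values raises a singular-fit error.
- Trees are used exactly as read and treated as rooted; re-rooting on an
  outgroup is available but never invoked implicitly. Branch lengths of
  exactly 0 are legal in phylogenies (posterior near-polytomies) but not
  in chronograms (parent age must strictly exceed child age).
- Chronogram ultrametricity tolerance defaults to 10⁻⁶ × root age; the
  worst tip pair is named in the error.
- Median is the standard sample median (mean of the two middle order
  statistics for even n).
- Newick output uses 17 significant digits, so write∘read round-trips
  branch lengths to well below the 10⁻⁹ tolerance the tests assert.

## Problem sizes used by the test suite

Simulation-based tests use 8–20 host tips with ensembles of 5–100 samples;
the replicated coverage check runs 100 independent datasets of 14 hosts
with 100-sample ensembles; oracle-equivalence checks use 100 random
instances per operation. These sizes give stable summaries while keeping
the default suite fast.

## Known limitations

- Host calibration ages enter as point values; their uncertainty is not
  propagated (it would add to, not subtract from, the reported HPD widths).
- A single power law is assumed per protein/data set; rate-decay regimes
  that differ between clades are not modelled.
- Event detection operates on one summary tree; per-sample re-detection
  under topology variation is not implemented (events are re-located by
  MRCA instead, with the monophyly fraction reported).
- The ERV terminal-branch slowdown model is a simple per-tip scaling; it
  does not model the integration time as an inferred quantity.
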