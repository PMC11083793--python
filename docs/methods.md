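# Methods

## Model

`armnma` fits arm-based hierarchical consistency models. For a binary
outcome, arm *k* of study *i* with events `r_ik` out of `n_ik` has

    r_ik ~ Binomial(n_ik, p_ik),   log p_ik = mu_i + delta_ik,

with `delta` fixed at 0 on each study's baseline arm (the arm whose
treatment comes first in the dataset's treatment ordering — the reference,
when the study includes it). The log link means the basic parameters
`d_1..d_{K-1}` (reference contrast identically 0) are log risk ratios and a
fitted probability must satisfy `mu + delta <= 0`; the sampler enforces this
by rejection (log-posterior `-inf`), which also handles zero-event arms
natively — no continuity corrections enter the likelihood. For continuous
outcomes the likelihood is `ybar_ik ~ Normal(mu_i + delta_ik, sd_ik /
sqrt(n_ik))` and `d` are mean differences.

Trial contrasts are exchangeable around the consistency means. Multi-arm
trials use the conditional construction of the exchangeable multivariate
normal: the *k*-th non-baseline contrast given the earlier ones is normal
with mean `d(t1->tk) + (1/(k-1)) * sum_{j<k} (delta_ij - d(t1->tj))` and
variance `tau^2 * k / (2(k-1))`; a two-arm trial reduces to
`delta ~ Normal(d, tau^2)`. Consistency (`d(a->b) + d(b->c) = d(a->c)`)
holds exactly by construction.

## Priors and their rationale

| parameter | prior | default | why |
|---|---|---|---|
| basic contrast `d` | Normal(0, scale²) | scale 0.4 (log-RR) | skeptical prior shrinking relative effects toward "no difference"; 0.4 read as the SD, the conventional meaning of "scale" for such priors |
| heterogeneity `tau` | Half-Normal(0, 0.5) | 0.5 | informative half-normal on the between-study SD |
| baseline `mu_i` | Normal(0, 10²) | 10 | weakly informative on a log-risk / arm-mean scale; the source analysis does not state a baseline prior, so this choice is deliberately diffuse and its influence is covered by the sensitivity machinery |

For continuous outcomes a raw 0.4 SD would be absurdly tight in units such
as operative minutes or milliliters of blood loss; by default the effect
scale is multiplied by the pooled within-arm SD of the outcome
(`rescale_continuous_effect=False` restores the raw value). Prior scales may
be set to `inf` for flat priors in reduction tests.

## Sampler

Component-wise adaptive random-walk Metropolis within Gibbs. Blocks that are
conditionally independent across studies (`mu`; the `delta` of single-
contrast studies) are proposed and accepted as vectors, which keeps one sweep
at a handful of small numpy operations; multi-arm `delta`, the `d`, optional
design offsets `omega`, and `tau` are updated as scalars. `tau` moves on the
log scale with the Jacobian correction, respecting the half-normal (or
uniform) support. Proposal scales adapt every `adapt_interval` (50)
iterations toward a 0.44 per-scalar acceptance rate during burn-in only, so
the retained chain has the correct stationary distribution.

Defaults mirror the analysis reproduced here: 300,000 retained-phase
iterations after 30,000 burn-in. The source does not state thinning or chain
count; we default to thin 10 (memory) and 3 chains with over-dispersed
initial values (drawn from the priors, with binary baselines shifted into
the feasible region), and treat the iteration counts as per-chain. Runs are
bit-reproducible given the seed: chain *c* uses the PCG64 stream spawned
from `SeedSequence([seed, c])`. Convergence is summarized per scalar with
split-R-hat and ESS (arviz), flagging R-hat > 1.01 or ESS < 400.

The analysis drivers and test-suite fits use reduced lengths (roughly
1,200–120,000 iterations depending on the check); each reported check
verifies its own Monte-Carlo error is small enough for the comparison made.

## Synthesis

League tables summarize all ordered pairs from the same pooled draws
(per-draw differences of basic contrasts), so direct and indirect cells are
automatically coherent. CrIs are equal-tailed 2.5/97.5 percentiles computed
on the contrast (log) scale and then transformed; consequently WMD tables
are antisymmetric and RR interval bounds exactly reciprocal across the
diagonal, while the reported RR mean is the posterior mean of the
exponentiated draws. Significance means the 95% CrI excludes the null (1 for
RR, 0 for WMD); equal-tailed rather than HPD intervals because only "95%
credible intervals" is specified.

Ranking sorts the (direction-adjusted) contrasts per draw; for `harm`
outcomes rank 1 is the lowest contrast. SUCRA is computed as
`(K - mean rank)/(K - 1)`, which makes the across-treatment SUCRA average
exactly 0.5. I² converts each `tau` draw via
`100 tau^2 / (tau^2 + s^2)` with `s^2` the Higgins–Thompson typical sampling
variance (inverse-variance weights from per-study contrast-variance
estimates; a 0.5 continuity correction only when a cell is 0 or n; multi-arm
studies contribute the mean of their baseline-vs-other contrast variances).
The posterior *median* I² is reported — the summary used in the reproduced
league tables is unstated, and the median is robust to the long right tail
of `tau`. Categories: ≤25 low, ≥75 high, 50–75 moderate; the published
banding leaves 25–50 undefined, so such values are labeled `intermediate`
rather than silently assigned.

## Diagnostics

Arm-level residual deviance uses the saturated form
`2[r log(r/rhat) + (n-r) log((n-r)/(n-rhat))]` with `rhat = n exp(mu+delta)`
(continuous: squared standardized residuals). Leverage is posterior-mean
deviance minus deviance at the posterior-mean *fitted values* (plug-in on
the arm level, the standard pD definition); leverages sum to pD and
`DIC = Dbar + pD`. A well-specified fit has total `Dbar` near the number of
data points.

The design-by-treatment check adds a scalar offset `omega` per
loop-closing design (a design whose treatments are already connected by the
designs scanned before it; determined by union-find over the design graph).
`omega` gets the same skeptical prior as the basic contrasts. When no design
closes a loop — as in the hub-plus-one-edge geometry of the motivating
network, where every comparison is informed by exactly one design — the
check returns a structural note instead of fitting anything: inconsistency
is not statistically identifiable there, and reporting "no inconsistency"
would be vacuous. When identifiable, each `omega`'s 95% CrI and the DIC
difference between the two models are reported; the packaged verdict rule
("no significant inconsistency" iff every CrI contains 0 and the
inconsistency model does not improve DIC by more than 3) is a pragmatic
default, and both ingredients are exposed so users can apply their own.

Prior sensitivity refits the full model under alternative heterogeneity
priors (defaults: half-normal scales 0.25 and 1.0, uniform(0, 2)) with the
same seed, and tabulates the maximum absolute shift of each contrast's
posterior mean against the base fit; the base prior is its own row with
shift exactly 0.

## Synthetic data

The generator draws networks from the same hierarchical model: per-study
baseline risks from a beta hyper-distribution (binary) or baselines from a
normal (continuous), trial contrasts from the multi-arm conditional normal,
then binomial counts or normal means (observed SDs get the chi-square
sampling noise of an SD estimate). The binary feasibility constraint
`risk * exp(delta) <= 1` is enforced by rejection with a bounded budget
(default 1000), and failure names the offending design.

`trial_network_truth()` encodes the study conditions of the motivating
network: the exact ten-trial geometry and arm sizes (20–520 per arm; hub
reference plus one laparoscopic-vs-robotic trial), null contrasts (the
reproduced analysis found no significant differences on the primary
outcomes), `tau = 0.1` (low heterogeneity, consistent with the published
I² categories), and baseline-risk hyper-distributions matched to the
published per-group crude rates (e.g. mean ~1.2% for anastomotic leak, ~6%
for severe complications). What the generator does *not* emulate: risk of
bias, covariate-driven effect modification (transitivity violations),
missing outcome reporting, or correlated multi-outcome data — so passing
recovery and coverage checks demonstrates correctness of the estimation
machinery under the assumed model, not robustness to those real-data
features. Published per-group rate ranges are used as a plausibility band
for simulated crude rates; groups observed in a single trial print a
degenerate "range" and are excluded from that comparison.

## Numerical choices and edge cases

- Binary support: `mu + delta > 0` gives log-posterior `-inf` (rejection);
  `mu + delta = 0` with `events < total` likewise has zero likelihood.
- `0 log 0 = 0` throughout the deviance computations.
- Quantiles use numpy's linear interpolation; reciprocity/antisymmetry of
  league-table bounds holds to floating-point round-off.
- Degenerate inputs: empty tables, duplicate (study, treatment) rows,
  `events > total`, non-positive SDs and single-arm studies are rejected at
  load time with the offending row named; disconnected networks are
  *reported* by `connectivity_report` but refused by the sampler and the
  pipeline runner.
- Single-study datasets: `tau` is not estimable; I² is omitted with a
  warning.
- Non-finite posterior at initialization (after 50 attempts) raises with
  advice to change seed/inits.

## Problem sizes

The analysis drivers fit 10-trial networks with 60,000 iterations after
10,000 burn-in over 3 chains; the replicated calibration study uses 200
replicates of a 20-study network at 2,000 iterations after 700 burn-in on a
single chain per replicate — sizes chosen so each check's Monte-Carlo error
is comfortably below the tolerance it asserts.

## Known limitations

- Contrast-based (summary-level) likelihoods, logit-link odds-ratio models
  and covariate meta-regression are out of scope.
- Median/range continuous summaries are not converted to mean ± SD; inputs
  must already be mean ± SD.
- The design-by-treatment implementation uses one scalar offset per
  loop-closing design, not the full per-comparison interaction vector; for
  two-arm designs (the dominant case here) the two coincide.
- Random-walk MCMC mixes slowly on very sparse networks; the convergence
  report should be consulted before trusting short runs.
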