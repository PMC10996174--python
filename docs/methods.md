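# Methods

## Model and procedure

The pipeline converts a genes × samples expression matrix, a sample metadata
table (reference vs. case cohort, progression stage, optional survival
follow-up) and an undirected interaction network into:

1. **Density profiles.** For every network gene and cohort, a Gaussian KDE
   with plug-in bandwidth h = (4σ⁵/3N)^(1/5) is evaluated *only at the
   cohort's own sample points* (self-kernel included) and renormalised to a
   strictly positive probability vector summing to one. σ is the sample
   standard deviation (N−1 denominator by default; `ddof` is configurable).
2. **Local edge scores.** For edge ⟨i,j⟩ and case sample k, the directed
   score combines gene i's full reference vector with gene j's scalar case
   probability at sample k: Σ p_r log p_r − log p_c. The edge score is the
   arithmetic mean of the two directions. Scores may be negative; natural
   logarithms throughout (a different base would only rescale every score by
   a constant).
3. **Per-sample aggregation.** Each case sample's score is the mean of its
   M = max(1, ⌊f·E⌋) largest edge values (f = 0.05 by default over E network
   edges); ties at the cutoff are broken by canonical lexicographic edge
   order so the selected set is deterministic.
4. **Stage signal and critical-stage test.** H(t) is the mean per-sample
   score at stage t. Each interior stage is tested two-sided (one-sample
   t-test, delegated to scipy) against the scalar mean of its two
   neighbouring stage signals and flagged critical when p < α (0.05) *and*
   H(t) exceeds the reference; the earliest flagged stage is reported. The
   first and last stages are not tested: the first is the natural baseline
   and the last is after-transition territory. An alternative reference —
   the mean of all other stages — is available (`reference="others"`). No
   multiple-testing correction is applied across stages; all per-stage
   p-values are reported.
5. **Edge biomarkers.** Patients are split at 5 years of follow-up: long
   survivors lived past the cut (censored or not), short survivors died at
   or before it, and patients censored at or before the cut are excluded as
   uninformative. An edge present in a sample's top-f set defines per-sample
   "high ERE"; prevalence strictly above 80% in the long (short) group calls
   a positive (negative) biomarker, and an edge above the threshold in both
   groups is reported with both prevalences but no direction. Per-edge
   patient stratification for survival curves splits at the median edge
   score (ties to the low group); Kaplan–Meier/log-rank analysis is
   delegated to lifelines.

## Case-cohort scope

The case probability p_c can be fitted from the **pooled case cohort**
(default, `case_scope="all"`) or from **each stage's own samples**
(`case_scope="per-stage"`). The pooled scope is the default for a structural
reason: the plug-in bandwidth is proportional to the cohort's standard
deviation, which makes the normalised probability vector at the cohort's own
points exactly scale-invariant. Under per-stage fitting a stage whose genes
merely fluctuate more strongly — the signature of an impending transition —
is therefore *indistinguishable* from a quiet stage; only shape changes
survive. Under the pooled scope the same stage's samples are outliers of the
whole case distribution, their p_c drops, and the −log p_c term raises the
stage signal. Per-stage fitting remains available for sensitivity analysis
and for settings where stages differ in location/shape rather than scale.

## Synthetic data generator

`simulate_cohorts` emulates a staged case-control expression study on a toy
network (default: a 16-gene ring plus 8 seeded random chords, 24 edges).
Reference samples (default 50) and non-critical pre-transition stages draw
every gene i.i.d. N(10, 1) — a log-intensity-like scale; translation
invariance of the score makes the baseline mean irrelevant. At the
programmed interior critical stage (default the third of five, 30 samples
per stage) a four-gene module has its dispersion inflated by κ (default 4).
Stages after the critical one shift the module genes by +2 to mimic the
settled after-transition state; under the pooled scope these samples form
their own high-density cluster and do not raise the signal. Setting κ = 1
and the shift to 0 yields an exact null. `excited_fraction < 1` switches to
a flickering variant (only a seeded fraction of critical-stage samples is
inflated), the shape-mixture mechanism that remains detectable under
per-stage fitting.

`simulate_survival` attaches prognostic ground truth: a minority of case
patients (25 long- plus 25 short-survivors by default; the rest are censored
before the 5-year cut, as in real cohorts) and, in 95% of each informative
group, far-outlier perturbations (uniform 10–30 noise-sd units, random sign)
of the endpoint genes of the planted positive/negative edge. Keeping the
informative groups a minority is essential, not cosmetic: the KDE
probability ratio between the dense baseline cluster and the perturbed band
depends on the ratio of their point counts (the band width cancels against
the bandwidth), so planted outliers must stay sparse in the pooled density.

What the generator does **not** emulate: correlated gene-gene noise,
heavy-tailed or platform-specific measurement error, batch effects, missing
values, stage-size imbalance, or genuinely dynamical (ODE/SDE) transitions.
Passing tests on this generator therefore demonstrate correctness of the
statistics and recoverability of dispersion-driven signals, not performance
on real tumour cohorts.

## Numerical choices

- Probabilities are clipped at 1e−300 before logs; clip events are counted
  and logged (they do not occur at the default study sizes).
- Degenerate genes (zero variance in any cohort used) are excluded with
  their incident edges, with a warning; a stage with fewer than two case
  samples is an error.
- Top-set ties and the membership matrix use one shared selection routine,
  so per-sample aggregation and biomarker membership can never disagree.
- The "over 80%" prevalence comparison is strict: exactly 80% is no call.
- All file outputs print floats with 12 significant digits; write→read round
  trips are lossless at that precision, and reruns with one seed are
  byte-identical.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| `top_fraction` | 0.05 | fraction of edges in each sample's high-ERE set |
| `alpha` | 0.05 | significance level of the stage test |
| `case_scope` | `all` | cohort used to fit case densities |
| `ddof` | 1 | denominator of the bandwidth's σ |
| `cut_years` | 5 | survival split |
| `prevalence_threshold` | 0.8 | strict biomarker prevalence cut |
| `dispersion_factor` κ | 4 | module dispersion inflation at the critical stage |
| `samples_per_stage` | 30 | case cohort size per stage |
| `n_reference` | 50 | reference cohort size |

Simulation sizes were chosen as a realistic small cohort study that keeps
100-replicate power runs in seconds; all are configurable.

## Known limitations

- The directed score is not a standard KL divergence — its second argument
  is a scalar probability, not a distribution — and is implemented exactly
  as defined; it has no non-negativity guarantee.
- The stage test treats the neighbour reference as a fixed constant, so
  between-stage sampling variability is not propagated; with few samples
  per stage the test is mildly anti-conservative (the null any-flag rate at
  defaults is ~9–12% across three tested stages at α = 0.05).
- Gene identifiers are matched exactly and case-sensitively; probe-to-gene
  collapsing is by arithmetic mean only.
- Survival handling of patients censored before the cut (exclusion) and the
  median high/low split for per-edge stratification are pragmatic choices;
  both are configurable at the API level where alternatives exist.
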