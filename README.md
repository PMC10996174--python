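# edgeentropy

Edge-based relative entropy (ERE) scoring of gene-expression cohorts on an
interaction network: per-edge, per-sample entropy scores, detection of the
critical (pre-transition) stage in staged or time-course data, and calling of
positive/negative prognostic edge biomarkers.

## The problem

Complex diseases often progress through three coarse states: a relatively
stable before-transition state, a *critical* (pre-transition) state in which a
small group of molecules — a dynamic network biomarker (DNB) module — starts
to fluctuate collectively, and an after-transition state from which recovery
is hard. Mean expression changes little until the transition has happened, so
node-level statistics signal the tipping point late or not at all. Shifting
attention from genes to gene *pairs* on an interaction network captures the
collective fluctuation earlier.

## The statistic

For gene *g<sub>i</sub>* with reference expression values
*x<sub>i1</sub>…x<sub>im</sub>* and case values *y<sub>i1</sub>…y<sub>in</sub>*,
a Gaussian kernel density estimate with the plug-in bandwidth

> h = (4σ⁵ / 3N)^(1/5)

is evaluated at the cohort's own sample points and renormalised, giving
probability vectors P<sub>r</sub> (reference) and P<sub>c</sub> (case). For an
interaction ⟨i, j⟩ and case sample *k*, the directed local score is

> H<sub>⟨j,i⟩</sub>(**x**<sub>j</sub>, y<sub>ik</sub>) = Σ<sub>m</sub> p<sub>r</sub>(x<sub>jm</sub>) · log [ p<sub>r</sub>(x<sub>jm</sub>) / p<sub>c</sub>(y<sub>ik</sub>) ]

and the local ERE of the edge is the symmetrised average
H<sup>k</sup>(i,j) = ½ [H<sub>⟨i,j⟩</sub> + H<sub>⟨j,i⟩</sub>]. Each sample is
summarised by H<sup>k</sup>, the mean over its top-5% edge set S (|S| = M),
and each stage by H(t), the mean of H<sup>k</sup> over the N(t) samples at
stage t. An interior stage is called critical when its samples' H<sup>k</sup>
values are significantly different from the mean of the two neighbouring
stage signals (one-sample t-test) *and* H(t) exceeds that reference. An edge
that sits in the top-ERE set of over 80% of long-survival (> 5 years)
patients is a positive edge biomarker; over 80% of short-survival patients,
a negative one.

## Worked example

```python
from edgeentropy import EdgeEntropyModel, EdgeKey
from edgeentropy.simulate import SimulationConfig, simulate_cohorts, simulate_survival

ds = simulate_cohorts(SimulationConfig(seed=1))           # 16 genes, 5 stages
recs = simulate_survival(ds, [EdgeKey("G05", "G06")],     # planted prognostic
                         [EdgeKey("G07", "G08")], seed=1) # edges
res = EdgeEntropyModel.from_synthetic(ds).fit()
print(res.summary())
```

```
Edge-based relative entropy — stage signal report
==========================================================
network genes: 16     edges: 24     reference N: 50
case scope: all        top fraction: 0.05  alpha: 0.05
----------------------------------------------------------
stage       N(t)      H(t)  ref mean   p-value  critical
S1            30    3.0143        --        --
S2            30    2.5788    3.1509     0.015
S3            30    3.2875    2.4615     2e-05       yes
S4            30    2.3442    2.9078    0.0098
S5            30    2.5280        --        --
----------------------------------------------------------
critical stage: S3
```

Stage S3 is the generator's programmed critical stage: its dispersion-inflated
module drives the stage signal H(t) up to 3.29 against a neighbour reference
of 2.46 (p = 2e-05). S2 and S4 also reach small p-values but sit *below*
their references — a significant decrease is not an early-warning signal, so
they are not flagged. Biomarker calling on the attached survival labels

```python
for c in res.call_biomarkers(records=recs):
    print(c.edge, c.call, c.prevalence_long, c.prevalence_short)
# G05--G06 positive 0.92 0.0
# G07--G08 negative 0.0  0.92
```

recovers both planted edges: `G05--G06` is a top-ERE edge in 92% of
long-survival patients (positive biomarker), `G07--G08` in 92% of
short-survival patients (negative biomarker).

The same pipeline is available from the shell:

```sh
edgeentropy --seed 1 simulate --outdir sim
edgeentropy --seed 1 run      sim/expression.tsv sim/metadata.tsv sim/network.tsv --outdir run
edgeentropy --seed 1 detect   sim/expression.tsv sim/metadata.tsv sim/network.tsv --outdir det
edgeentropy --seed 1 biomarkers sim/expression.tsv sim/metadata.tsv sim/network.tsv --outdir bio
```

All inputs and outputs are plain tab-separated text; see `docs/methods.md`
for file formats, model assumptions and parameter guidance.

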