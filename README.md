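# greytox

Grey-relational aggregation of multi-receptor ecotoxicity panels and
rule-based screening of low-toxicity derivative molecules.

## The problem

Phthalate diester plasticizers (PAEs) leach from plastics into water and
are acutely toxic to organisms across trophic levels — green algae,
daphnids, mysid shrimp and fish. A compound's hazard is therefore a
*joint* property over several receptors, but QSAR and pharmacophore
modelling traditionally regress against a single endpoint. `greytox`
implements the aggregation-and-screening workflow that bridges the two:
it collapses a compound × receptor matrix of acute EC50/LC50 values into
one comprehensive characterization value per compound using grey
relational analysis, then screens candidate derivative molecules for
toxicity remission with simple, auditable change-rate rules, and
evaluates the survivors' quantum-chemical, persistence, docking and
metabolic properties.

It is written for environmental chemists and cheminformaticians who have
per-receptor toxicity predictions (from ECOSAR-class tools) and
derivative activity estimates (from pharmacophore models) and need the
aggregation, screening and validation arithmetic between them to be
reproducible.

## The statistic

Let $x_i(k)$ be the toxicity of compound $k$ to receptor $i$ (mg/L) and
let the reference sequence be the constant acute-toxicity classification
boundary $x_0 = 1.0$ mg/L. With absolute differences
$\Delta_i(k) = |x_0 - x_i(k)|$, the grey interconnect coefficient is

$$\xi_i(k) = \frac{\Delta_{\min} + \rho\,\Delta_{\max}}
                  {\Delta_i(k) + \rho\,\Delta_{\max}},\qquad \rho = 0.5,$$

and the grey interconnect degree of compound $k$ is the weighted
horizontal mean $y_k = \sum_i w_i\,\xi_i(k)$ (uniform $w_i = 1/n$ by
default). Degrees lie in $(0, 1]$: higher means the compound's profile
sits closer to the 1 mg/L boundary, i.e. *lower* comprehensive toxicity.
Two conventions for the extremes $\Delta_{\min}, \Delta_{\max}$ are
supported — per-comparison-sequence (default, reproduces the published
worked example) and global double extremes (the textbook form); see
`docs/methods.md` for why both exist.

Downstream, everything is one formula — the change rate
$(new - old)/old \times 100$ — applied with stage-specific rules: a
strict >10% increase of the comprehensive characterization value
(stage 1), strictly negative per-receptor pEC50/pLC50 changes (stage 2),
a <5% total-energy increase, a 48 h air half-life persistence bound, and
docking/metabolite/barrier comparisons.

## Worked example

The published 14-phthalate × 4-receptor panel ships with the package:

```python
>>> import greytox as gt
>>> panel = gt.load_acute_toxicity_panel()
>>> result = gt.run_gra(panel)
>>> print(result.degrees.values.round(4).to_string())
compound
DEHP    0.7920
DIDP    0.7897
DNOP    0.7915
DPP     0.9356
DCHP    0.8447
DUP     0.7895
BCHP    1.0000
BDP     0.7974
BMPP    0.8285
BOP     0.8204
DINP    0.7900
DIPP    0.9852
DNDP    0.7896
HEHP    0.7980
```

BCHP's difference profile attains the column minimum for every receptor,
so its degree is exactly 1 — the least comprehensively toxic of the 14;
DUP (degree 0.7895) is the most. The derivative screen then reproduces
the published funnel — 16 of 22 monosubstituted DINP/DEHP derivatives
clear the >10% activity-increase screen, and 13 of those reduce
predicted toxicity on all four receptors:

```python
>>> s1 = gt.screen_activity_increase(gt.load_derivative_records())
>>> len(s1.passed)
16
>>> parents, derivatives, parent_of = gt.load_derivative_ptox()
>>> s2 = gt.screen_multireceptor_reduction(parents, derivatives, parent_of)
>>> len(s2.passed)
13
>>> print(s2.to_frame().round(2).loc[["DEHP-Br", "DEHP-F"]].to_string())
          green_algae  daphnid  mysid   fish  all_reduced  proportionality
compound
DEHP-Br         -3.75    -8.80  -5.57  -7.30         True             2.35
DEHP-F         -14.49   -18.08 -13.53 -15.05         True             1.34
```

The proportionality column is max|rate|/min|rate| across receptors — a
value near 1 means the decline is close to 1:1:1:1 over the four
receptors.

The grey-relational core is also a scikit-learn transformer
(`gt.GreyRelationalTransform`) with `fit`/`transform`/`get_params`, so
it composes with sklearn pipelines; `fit` learns the difference extremes
of a training panel and `transform` scores held-out compounds against
them.

The same stages are available from the shell:

```sh
greytox gra src/greytox/data/pae_acute_toxicity.csv --out-dir out/
greytox screen --activity src/greytox/data/pae_derivative_activity.csv \
               --ptox src/greytox/data/pae_derivative_ptox.csv --out-dir out/
greytox simulate --seed 7 --out-dir sim/
```

Every command writes a `manifest.json` with input digests and the config
snapshot, so runs are verifiable and idempotent.

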