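# evsynth — efficient value synthesis and range-adapting loss aversion

`evsynth` is a research pipeline for studying how *loss aversion adapts
to the range of gains and losses people face*, under the hypothesis that
orbitofrontal value signals are **synthesized** — constructed from
attribute inputs by neurons with bounded firing ranges — rather than
received and relayed.  It is aimed at computational
decision-neuroscientists who want to simulate the mechanism, fit it to
choice data, and compare its predicted representational geometry with
multivariate neural patterns.

## The model

A two-layer network turns a 50/50 gamble (win G / lose L) into value:

    x(i,j) = f(u(i); θ(i,j))            attribute sublayers (gain, loss)
    v(k)   = Σᵢⱼ C(i,j,k) x(i,j)        integration inputs
    z(k)   = f(v(k); φ(k))              integration outputs
    V      = Σₖ w(k) z(k)               linear population readout

with f a logistic sigmoid — units saturate, so inputs that land in a
unit's flat tails are not discriminable.  Minimizing the ensuing
information loss with a *local* gradient step, smoothed over trials,
yields an anti-Hebbian self-organized plasticity rule

    ΔC_t(i,j,k) = α(1−β) ΔC_{t−1}(i,j,k) + αβ (1/σ_z(k)) (1 − 2 z_t(k)) x_t(i,j)

(α = 0 or β = 0 gives a *static* network).  Because the rule adapts to
the spanned ranges of the attributes, not of value, it predicts: neural
encoding strength of each attribute falls as that attribute's range
grows; behavioral loss aversion λ = log(w_L/w_G) follows the ratio of
gain to loss ranges; and fitted plastic networks should generalize
across range contexts where static ones cannot.

The package implements the network and rule (`core`, `plasticity`, with
a JIT fast path in `engine`), Monte-Carlo range-adaptation experiments
(`simulation`), model-free behavioral analyses (`behavior`), MAP fitting
of plastic/static variants to choice series with counterfactual
cross-context prediction (`fitting`), representational similarity
machinery with confound corrections (`rsa`), and a synthetic two-group
study generator emulating the narrow-gain ($5–20) vs wide-gain ($10–40)
gamble designs, including a BIDS-like events-TSV reader (`synth`).

## Worked example

The numbered scripts under `analysis/` run the full study on synthetic
data and write tables to `results/`.  For example, the behavioral
analysis of a simulated two-group cohort (20 subjects per group of
range-adapting network agents):

```bash
$ python analysis/03_behavior_groups.py
        balanced_accuracy  gambling_rate  gambling_rate_common  loss_aversion  lam_first_quarter  lam_last_quarter
group
narrow             84.534          0.517                 0.548         -0.308             -0.082            -0.195
wide               83.678          0.502                 0.262          0.548              0.211             0.838

common-EV-range gambling rate, narrow - wide: 28.6 pp (F=103.8, dof=38, p=2e-12)
end-of-session loss aversion, group difference: F=42.4, dof=38, p=1.1e-07
```

Reading this: choices are fit by a within-subject logistic regression
p(accept) = s(w₀ + w_G·G − w_L·L) at ~84% balanced accuracy.  Both
groups gamble on about half their trials overall, but *within the EV
range common to both designs* the wide-gain group gambles 28.6
percentage points less — the context effect of range adaptation, since
these subjects face better gambles on average.  Windowed loss-aversion
estimates show the wide group drifting from near-neutral (0.21) to
strongly loss-averse (0.84) over the session while the narrow group
stays near zero: loss aversion here is *acquired* from the gain-range
context, exactly what the plasticity rule predicts.

`01_range_adaptation_curves.py` reproduces apparent value range
adaptation (EV-binned unit response curves with condition-invariant
endpoints, span CV 0.02), `02_range_grid_sweep.py` the range-grid maps
(gain-encoding vs gain range Spearman −1.0, loss-aversion ratio within
0.02 of 1 on the symmetric diagonal), `04_fit_counterfactual.py` the
plastic-vs-static counterfactual comparison, and
`05_rsa_model_vs_patterns.py` the model-vs-pattern RSA (mean RDM
correlation 0.85 at SNR 1, group t(19) = 76).

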