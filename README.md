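# wpbribbon

Inference about the lateral organization of the Golgi ribbon from the size
distribution of Weibel-Palade bodies (WPBs).

WPBs are the rod-shaped secretory granules of endothelial cells. Their Von
Willebrand Factor (VWF) cargo is molded into "quanta" by individual Golgi
mini-stacks (median quantum length l = 0.576 μm in HUVECs), and quanta
occupying *adjacent* mini-stacks are co-packaged into one granule at the
trans-Golgi network. A WPB of length n·l therefore reports a run of n
occupied, laterally linked mini-stacks — which makes the WPB size
distribution a quantitative readout of how mini-stacks are connected.
This package implements that inference chain for quantitative cell
biologists: quantization of measured organelle lengths, closed-form size
distributions under competing ribbon architectures, Kolmogorov–Smirnov (KS)
grid fitting, a stochastic simulator of mini-stack linking/unlinking, and
synthetic-data generators with ground-truth manifests.

## Models

With p the probability that a mini-stack holds a VWF quantum:

- **Linear array** (one effectively infinite ribbon):
  `P(N=n) = p^(n-1)(1-p)` — geometric; the 2Q proportion never exceeds
  0.25 (at p = 0.5).
- **Occupancy mixtures** across cells: `P(N=n) = Σ_k w_k p_k^(n-1)(1-p_k)`;
  uniform p on [0,1] gives `P(N=n) = 1/(n(n+1))`.
- **Mini-ribbon collection** (independent segments of L mini-stacks): run
  combinatorics on a finite Bernoulli lattice; expected runs
  `E[k] = p^k(1-p)[(L-k-1)(1-p)+2]` for k < L, `E[L] = p^L`. The 2Q
  proportion peaks at 0.268 for L = 3 and stays below 0.3 for L = 4.
- **Free dimers plus ribbon**: a fraction q of mini-stacks circulates as
  stable pairs; three-branch closed form with denominator `(1-p) + qp/2`.
- **1Q instability**: 1Q-WPBs are selectively depleted (e.g. basal
  exocytosis); their steady-state abundance is scaled by
  `α = β'/β ≤ 1`, and `α = p·f1 / [(1-p)(1-f1)]` inverts the model from
  the observed 1Q frequency f1.
- **Breathing ribbon**: mini-stack monomers and stable dimers continuously
  link (rate r, size-independent) and unlink (d1 for weak bonds, d2 < d1
  for dimer bonds), capped at pieces of five mini-stacks; exact Gillespie
  simulation plus mechanically generated mean-field ODEs, with (d1, d2)
  fit to observed Golgi fragment-length frequencies by KS grid search.

Fitting follows the two-step scheme the 1Q-instability model allows: p is
identified from the n ≥ 2 conditional tail (which stays geometric whatever
α is), then α is fixed algebraically from the 1Q frequency. Multi-condition
series (e.g. VWF knockdown titrations) share a single α taken as the
WPB-count-weighted mean of the per-condition inversions.

## Worked example

Draw 100,000 synthetic WPBs from the instability model at the reference
parameters, quantize them, and fit the model back:

```python
import numpy as np
from wpbribbon import (SyntheticSpec, sample_wpb_lengths, quantize_lengths,
                       empirical_distribution, fit_instability)

spec = SyntheticSpec(family="instability",
                     params={"p": 0.5692, "alpha": 0.2610},
                     n_wpbs=100_000, seed=1)
table, truth = sample_wpb_lengths(spec)
observed = empirical_distribution(quantize_lengths(table, spec.l_um))
fit = fit_instability(observed)
print("observed class frequencies (1Q..5Q):",
      np.round(observed.mass[:5], 4).tolist())
print("fitted p     =", round(fit.params["p"], 4))
print("fitted alpha =", round(fit.params["alpha"], 4))
print("KS distance  =", round(fit.ks_distance, 5))
```

prints

```
observed class frequencies (1Q..5Q): [0.165, 0.3603, 0.2053, 0.1154, 0.0669]
fitted p     = 0.5685
fitted alpha = 0.2604
KS distance  = 0.00052
```

The mode at 2Q with a depleted 1Q class is the signature the instability
model explains; the fit recovers the generating parameters to within
sampling error (p to 0.0007, α to 0.0006 here), and the KS distance of
5×10⁻⁴ says the fitted distribution is statistically indistinguishable
from the observed one at this sample size.

The same steps are available from the shell:

```sh
wpbribbon synth wpb --model instability --p 0.5692 --alpha 0.2610 \
    --n 100000 --seed 1 --out synth.tsv --manifest truth.json
wpbribbon quantize --input synth.tsv --quantum 0.576 --out quant.tsv
wpbribbon dist --input quant.tsv --out dist.tsv
wpbribbon fit --input dist.tsv --out fit.json
```

and `wpbribbon simulate-ribbon` / `fit-ribbon` drive the stochastic
linking/unlinking simulator.

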