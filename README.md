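# insideout

Directed-hierarchy analysis of multichannel amplitude-envelope timeseries:
time-reversal irreversibility, incoming–outgoing asymmetry, recurrence-
network dynamics, and the inference machinery to compare experimental
conditions — with a synthetic-cohort generator of known directional
asymmetry so every stage can be validated end to end.

## Who this is for

Researchers with epoched regional envelope recordings (the motivating
setting: source-localized MEG amplitude envelopes, 90 regions, 2-s epochs
at 200 Hz, a participant × drug × condition design) who want to quantify
how *directed* the coupling between channels is, and whether an
intervention changes it. Undirected functional connectivity is blind to
direction by construction; the metrics here are built from the asymmetry
of lagged correlations and vanish exactly when the dynamics are
time-reversible.

## The statistics at the core

For demeaned envelopes $x_i(t)$ and a lag $\tau$ (samples), the forward
lagged correlation matrix is

$$C^f_{ij}(\tau) = \frac{\sum_{t=1}^{n-\tau} x_i(t)\,x_j(t+\tau)}
{\sqrt{\sum_t x_i(t)^2 \sum_t x_j(t)^2}},$$

and the time-reversed matrix $C^r$ equals $(C^f)^\top$ exactly (reversing
both series and lagging one is the same as lagging the other forward).
The **irreversibility matrix** is

$$R(\tau) = \left(C^f(\tau) - C^r(\tau)\right)^{\circ 2},$$

elementwise squared, symmetric, zero for any time-reversible process.
The scalar irreversibility $r(\tau)$ is the mean of the upper-triangle
entries surviving a 95th-percentile threshold, averaged over epochs.

Per region, the squared forward row (outgoing components) and reversed
row (incoming) are concatenated, thresholded, surviving outgoing entries
negated, and averaged: the **incoming–outgoing asymmetry** $A_{\text{region}}$.
Its mean across regions is the **hierarchical coherence** $H_c$ and its
standard deviation the **hierarchical inhomogeneity** $H_i$.

Around these sit: three lag-selection schemes (curve integration,
orthogonal contrast, counter-balanced cross-validation), sign-flip and
cluster-based permutation tests, repeated-measures ANOVA contracts,
sliding-window metric timeseries embedded into recurrence networks (delay
from the first mutual-information minimum, dimension from false nearest
neighbours, threshold from the smallest distance connecting the graph),
coherent phase-randomization surrogates, random-forest comparisons of
metric families, and variogram-matched spatial null models for brain-map
correlations. See `docs/methods.md` for definitions and design choices.

## Worked example

Simulate a cohort of 16 participants whose directed coupling asymmetry is
reduced by 80% under a "drug" session, then test whether irreversibility
detects the manipulation:

```python
import numpy as np
from insideout import CohortSpec, StudyDesign, make_cohort, dataset_irrev
from insideout.stats import paired_permutation

spec = CohortSpec(n_subjects=16, n_regions=6, epochs_per_dataset=20,
                  epoch_length_s=1.0, drug_effect=0.8,
                  kappa_mean=0.6, kappa_sd=0.1, spectral_radius=0.8, seed=0)
design = StudyDesign(tuple(f"s{i:02d}" for i in range(16)),
                     condition_levels=("Open", "Closed"))
datasets, design = make_cohort(spec, design)

r = {key: dataset_irrev(env, tau=2, percentile=95.0).r
     for key, env in datasets.items()}
control = np.array([np.mean([r[(p, "control", c)] for c in design.condition_levels])
                    for p in design.participant_ids])
drug = np.array([np.mean([r[(p, "drug", c)] for c in design.condition_levels])
                 for p in design.participant_ids])
p = paired_permutation(control, drug, n_perm=2000, seed=1, alternative="greater")
print(f"mean r (control) = {control.mean():.4f}")
print(f"mean r (drug)    = {drug.mean():.4f}")
print(f"one-sided permutation p (drug < control) = {p:.4f}")
```

Output:

```
mean r (control) = 0.0553
mean r (drug)    = 0.0507
one-sided permutation p (drug < control) = 0.0035
```

The control sessions are measurably less time-reversible than the drug
sessions (higher `r`), and the paired sign-flip permutation test rejects
the null of no difference: the pipeline recovers the simulated reduction
in directed-coupling asymmetry. Note that `r` is not zero under the drug —
a finite sample of a reversible process always yields a positive
thresholded mean — which is why all inference is comparative.

The same analysis runs from the shell:

```bash
insideout simulate --n-subjects 4 --n-regions 8 --epochs 20 --seed 7 --out data/
insideout run-all --data-dir data/ --out results/
```

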