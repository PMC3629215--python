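# neodemic

Joint male/female genetic analysis of the European Neolithic transition:
Bayesian drift–admixture inference on haplogroup frequencies, and serial
coalescent simulation of ancient + modern mitochondrial DNA with ABC
model choice.

## The scientific problem

Did farming spread across Neolithic Europe with people (demic diffusion)
or as an idea passed between resident hunter-gatherer populations
(cultural diffusion)?  Two kinds of genetic evidence bear on this, and
this package implements a statistical pipeline for both:

1. **Admixture track.**  Each modern European population is modelled as
   an admixed population H formed from a Palaeolithic hunter-gatherer
   parent P₁ (contribution p₁) and a Neolithic farmer parent P₂
   (contribution 1 − p₁).  After admixture the three populations drift
   independently for scaled times tᵢ = T/Nᵢ.  A full-likelihood MCMC
   infers (p₁, t₁, t₂, t_h) from haplogroup counts, marginalising the
   sample's coalescent founder states exactly.  Posteriors for many
   populations are then regressed against great-circle distance from the
   Near East, propagating uncertainty by resampling — a declining
   Neolithic contribution with distance is the demic-diffusion
   signature.
2. **Ancient-DNA track.**  A serial coalescent simulator generates
   HVS-I-like sequence panels for ancient hunter-gatherers, early
   farmers and modern samples under three demographies of Central
   Europe: Total Panmixia (TP), Split (S) and Split with Differential
   Growth (SDG).  Approximate Bayesian computation on the three pairwise
   F_ST statistics (HG–farmer, HG–modern, farmer–modern) selects among
   the models (multinomial logistic regression and neural-network
   adjustments), estimates SDG parameters, and maps the probability
   P_S>O of matching an observed F_ST over a grid of
   (N_UP, N_N) population sizes.

The real published datasets analysed by this approach are not bundled;
`neodemic.synth` generates statistically analogous inputs with known
ground truth, which is how the pipeline is tested end to end.

## Worked example: admixture inference

```python
import numpy as np
from neodemic.synth import simulate_admixture_counts
from neodemic.admixture import run_admixture_mcmc, posterior_mode_hpd

table, truth = simulate_admixture_counts(
    p1=0.3, t1=0.05, t2=0.05, th=0.05, seed=7)
post = run_admixture_mcmc(table, seed=1, n_iter=20000, burn_in=5000, thin=10)
mode, (lo, hi) = posterior_mode_hpd(post["p1"], level=0.9)
print(f"true p1      : {truth['p1']:.2f}")
print(f"posterior    : mode {mode:.2f}, 90% HPD [{lo:.2f}, {hi:.2f}]")
print(f"drift t_h    : posterior median {np.median(post['th']):.3f} (truth 0.05)")
```

prints

```
true p1      : 0.30
posterior    : mode 0.65, 90% HPD [0.29, 1.00]
drift t_h    : posterior median 0.103 (truth 0.05)
```

The 90% interval covers the truth but is wide — the expected behaviour
for a single locus: with drift t = 0.05 the sample descends from only
≈ 2/t = 40 founder lineages, so any one population's estimate is noisy
and the geographic signal emerges only jointly across populations
(`neodemic.geo.posterior_regression`).

## Worked example: ancient DNA under differential growth

```python
from neodemic.coalescent import ModelParams
from neodemic.synth import simulate_study_panel
from neodemic.sumstats import sumstat_vector

params = ModelParams(N_UP=200, N_N=50_000, phi=0.9)
panel, truth = simulate_study_panel("SDG", params, seed=42)
s = sumstat_vector(panel)
print(f"panel: {panel.n} sequences of length {panel.length}")
print(f"F_ST  HG-farmer     : {s.fst_hg_farmer:.3f}")
print(f"F_ST  HG-modern     : {s.fst_hg_modern:.3f}")
print(f"F_ST  farmer-modern : {s.fst_farmer_modern:.3f}")
```

prints

```
panel: 145 sequences of length 360
F_ST  HG-farmer     : 0.861
F_ST  HG-modern     : 0.806
F_ST  farmer-modern : -0.011
```

A small, isolated hunter-gatherer deme (N_UP = 200, deme-1 share
1 − φ = 0.1) produces the pattern that motivates the SDG model: extreme
differentiation between hunter-gatherers and everyone else, with
farmers and moderns essentially undifferentiated.  Under panmixia (TP)
at the same sizes, all three values would sit near zero — the contrast
the ABC model choice and the exceedance grids quantify.

A thin CLI mirrors the library: `neodemic admix-mcmc`, `geo-trend`,
`simulate`, `abc-choose`, `abc-estimate`, `abc-validate`, `pso-grid`,
`synth` (see `neodemic --help`).

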