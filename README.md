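# manowave

Spectral decomposition and Bayesian functional mixed-effects analysis of
spatiotemporal quasiperiodic pressure recordings, built for high-resolution
colonic manometry: multichannel catheter recordings of colonic pressure
waves, where the scientific questions are *which frequencies carry power*,
*which way and how fast activity propagates*, and *how groups and
interventions (e.g. a meal) differ*.

Manual identification of propagating motor patterns in such recordings is
slow and laboratory-dependent. `manowave` replaces it with an automated
pipeline:

1. **Preprocess** — running-median baseline removal; exclusion of
   synchronous pressure increases (rises spanning *all* channels at once,
   typically strain/cough artifacts); clamp to 1 mmHg and log-transform.
2. **Spectra** — synchrosqueezed continuous wavelet transform per channel
   (analytic Morlet, FFT convolution), giving the log global wavelet
   power spectrum over 1/16–16 cycles/min (cpm); and cross-wavelet
   transforms of adjacent sensor pairs, giving a frequency x
   phase-difference power histogram whose phase axis encodes propagation
   direction and velocity, u = d·2πf/φ.
3. **Model** — each recording period contributes one response function
   y_i(x) (log power over frequency, or frequency x phase), modeled as a
   latent Gaussian-process function-on-scalar mixed model

       y_i(x) ~ GP(η_i(x), ω_i(x)ω_i(x')(k_σ(x,x') + σ_ε²))
       η_i = X_i β + Z_i b + o,      log ω_i = W_i γ

   with squared-exponential kernels in log frequency (times a periodic
   phase kernel in 2D, Kronecker-factorized), fixed effects for
   group/region/meal, correlated per-subject random effect functions, and
   a scale model for heteroscedasticity. Inference is adaptive HMC
   (an in-package No-U-Turn sampler over a purpose-built reverse-mode
   autodiff), non-centered throughout, with R-hat/ESS diagnostics.
4. **Refine & contrast** — posterior functions are refined to a fine grid
   by GP prediction (y* = Σ(x*,x)Σ(x,x)⁻¹y; 33→129 frequency bins at
   factor 4, 17→97 and 18→108 in 2D at factor 6), and condition
   comparisons are reported as power ratios with pointwise 95% credible
   envelopes — a region is significant where the envelope excludes
   ratio 1.

## Worked example

Simulate a small two-group study in which a meal raises 3 cpm power
equally in both groups, fit the 1D model, and test the contrasts:

```python
import numpy as np, pandas as pd
from manowave import (FrequencyGrid, ModelSpec, TrueEffects,
                      build_design_matrices, fit_hmc, simulate_responses,
                      meal_effect, meal_by_group_interaction)

obs = pd.DataFrame([
    {"subject": f"s{i}", "group": "healthy" if i < 5 else "patient",
     "meal": m, "nchan": 24}
    for i in range(10) for m in ("preprandial", "postprandial")])
dm = build_design_matrices(obs, "group*meal + (1|subject)", "1")

fg = FrequencyGrid.from_band(n=9)                       # 1/16-16 cpm
bump = np.exp(-0.5 * ((np.log(fg.centers) - np.log(3/60)) / 0.4) ** 2)
beta = np.vstack([np.zeros(9), np.zeros(9), bump, np.zeros(9)])
truth = TrueEffects(beta=beta, gamma=np.zeros((1, 9)),
                    sigma_b=np.array([[0.0625]]), tau_sigma=0.3,
                    lambda_sigma=0.25, sigma_eps=0.1)
Y = simulate_responses(dm.X, dm.Z, dm.W, fg.centers, truth, seed=42)

post = fit_hmc(ModelSpec(fgrid=fg), dm, Y, chains=4, warmup=250,
               iters=250, seed=1, max_treedepth=7)
me = meal_effect(post, group="healthy")
ia = meal_by_group_interaction(post)
print("draws:", post.n_draws, "max R-hat: %.3f" % post.diagnostics["rhat_max"])
print("meal-effect ratio at 3 cpm: %.2f  [%.2f, %.2f]" % (
    np.exp(me.median[5]), *np.exp(me.band[:, 5])))
print("meal effect significant bins:", np.flatnonzero(me.significant).tolist())
print("interaction significant bins:", np.flatnonzero(ia.significant).tolist())
```

prints (about ten minutes on one core):

```
draws: 1000 max R-hat: 1.046
meal-effect ratio at 3 cpm: 2.03  [1.51, 2.68]
meal effect significant bins: [4, 5, 6]
interaction significant bins: []
```

The injected meal effect peaks between grid bins 5 (2 cpm) and 6 (4 cpm);
its true ratio at bin 5 is e^0.60 ≈ 1.8, inside the reported credible
band, and the band excludes ratio 1 exactly in the bins around the bump.
The group x meal interaction, which is truly null here, is (correctly)
nowhere significant.

The same workflow runs from the shell on file-based artifacts:

```
manowave simulate --seed 7 --out rec.h5
manowave preprocess --in rec.h5 --out pre.h5
manowave spectra --in pre.h5 --nfreq 33 --out spec.h5
manowave fit --responses spec.h5 ... --seed 1 --out fit.h5
manowave refine --fit fit.h5 --factor 4 --out fine.h5
manowave contrast --fit fit.h5 --which meal_effect:healthy --out c.h5
manowave run --config demo.json --seed 7 --outdir out/   # whole pipeline
```

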