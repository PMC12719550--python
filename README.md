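# spectmcvar

Conventional versus hybrid Monte-Carlo SPECT reconstruction for
Lu-177-like quantitative imaging: a desk-scale, fully synthetic pipeline
for studying the **bias** and **variability** of region-of-interest (ROI)
activity estimates used in radiopharmaceutical dosimetry.

Quantitative SPECT after Lu-177 therapy has two error sources that matter
for dose estimates: systematic bias from imperfect scatter correction and
finite resolution, and statistical variability from the low count levels
of a clinical scan. The conventional pipeline reconstructs the photopeak
window with an analytic (scatter-free) system model and subtracts a
triple-energy-window (TEW) scatter estimate built from two flanking
windows; because that estimate comes from photons scattered through large
angles, it is spatially blurred, under-corrects hot regions, and injects
extra noise. The hybrid Monte-Carlo pipeline instead embeds scatter in the
forward projection itself — a Monte-Carlo simulation of the current image
estimate — while keeping the analytic back projection, removing both the
TEW bias and the TEW noise.

## The model

Ordered-subset EM with a pluggable forward operator:

    f^(k+1) = f^(k) * H^T( g / (H f^(k) + a) ) / (H^T 1)

with `a = (g_up/w_up + g_low/w_low) * w_peak/2` (conventional + TEW) or
`a = 0` with a Monte-Carlo `Hf` (hybrid). Accuracy is summarized by
background-calibrated recovery coefficients

    RC = (C_roi / C_bkg) / (A_roi / A_bkg) * 100%

and precision by the percent variability `sigma` of ROI counts across
repeated noise realizations, the paired difference
`Delta = sigma_conv - sigma_mc`, and the speed-up factor
`SF = (sigma_conv / sigma_mc)^2` — the relative scan time conventional
reconstruction would need to match the hybrid pipeline's precision — each
with a delta-method uncertainty that uses the covariance of the paired
series. RC-versus-radius curves are fit with a Gaussian-blurred-sphere
model `RC(R; S, w)` whose scale `S` isolates scatter-correction bias from
resolution loss `w`.

Everything is synthetic and self-contained: digital phantoms (hot-sphere
water cylinder; NEMA-IQ-like body), an attenuated rotation projector with
distance-dependent PSF and exact adjoint, and a simplified Monte-Carlo
photon transport engine (Klein-Nishina scattering, Woodcock tracking,
next-event estimation, triple-energy-window binning) that doubles as data
generator and hybrid forward operator. See `docs/methods.md` for the
model details and deliberate simplifications.

## Worked example

Reconstruct a simulated hot-sphere cylinder three ways and compare the
72 mm sphere recovery coefficient:

```python
from spectmcvar.experiments import ExperimentConfig, run_bias_experiment

table, ctx = run_bias_experiment(ExperimentConfig(master_seed=1))
final = table[(table.iteration == 10) & (table.roi == "sphere_72mm")]
print(final[["mode", "rc_percent"]].to_string(index=False))
```

prints (about eight minutes on one CPU):

```
                  mode  rc_percent
          conventional  109.574627
conventional_noscatter  103.115130
             hybrid_mc  103.502557
```

Read: with TEW scatter correction the 72 mm sphere is overestimated by
~10% — a pure scatter-correction artifact, since the same reconstruction
on scatter-free data (`conventional_noscatter`) and the hybrid-MC
reconstruction of the full data both land near 100%. The common ~3 pp
offset from exactly 100% is a convergence/discretization residual of the
fixed 10-iteration protocol, not scatter (see `docs/methods.md`).

The same machinery is scriptable from the shell:

```
spectmcvar experiment bias --seed 1 --out results/
spectmcvar experiment variance --seed 1 --out results/
spectmcvar simulate --phantom nema --seed 1 --out data/
spectmcvar reconstruct --mode hybrid-mc --data data/ --out recon/
```

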