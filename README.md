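# dropletkd

Quantitative analysis of DNA membrane-recruitment assays in water-in-oil
droplets: from confocal cross-sections of droplets whose periphery is
functionalized with a cholesterol-tagged ssDNA handle, it extracts apparent
dissociation constants for the binding of a fluorescently labelled,
pH-switchable tsDNA motif, plus the pH and kinetic switching parameters of
the system.  It is aimed at experimenters running droplet/vesicle
recruitment assays and at anyone validating such analyses on synthetic data
with known ground truth.

## The model

Binding sites are confined to a thin reaction layer of apparent thickness
ε at the droplet surface (radius r₀).  At steady state the
peripheral-to-inner per-area fluorescence intensity ratio of the recruited
species obeys

    I_peri / I_in = 1 + S_tot / (T_eq + K_D),

where S_tot is the layer-referenced site concentration, K_D = k_off/k_on
the apparent dissociation constant, and the free concentration T_eq follows
from mass action plus conservation of the recruited species per droplet
(T_tot = T_eq + g·C_eq, g = 3ε/r₀):

    T_eq = ½ [ −(g·S_tot + K_D − T_tot) + √((g·S_tot + K_D − T_tot)² + 4·T_tot·K_D) ].

Inverting the measured ratio yields K_D per droplet, with first-order error
propagation from the measured I_peri, I_in, r₀ and ε.  Around this core the
package provides:

* `quantify` — the image-analysis macro: droplet detection/selection
  (40–50 µm, no touching neighbours), inner-disk mean (r ≤ 0.5 r₀),
  peripheral radial-line maxima (20 lines every 18°), rim-thickness
  estimation from the radial profile;
* `fitting` — base-10 sigmoid fits I = I_min + (I_max−I_min)/(1+10^(±α(x−x_turn)))
  for pH titrations and detachment time courses (decay time t_d = 1/α);
* `rd` — a conservative finite-volume reaction–diffusion simulator in the
  sphere, the independent oracle for the closed-form steady state;
* `bootstrap` — autocorrelation-aware bootstrap confidence bands for
  binned densities of trajectory observables (e.g. radius of gyration);
* `synth` — generators for all of the above with known ground truth.

See `docs/methods.md` for assumptions, parameter defaults and numerical
choices.

## Worked example

Simulate a droplet field at known K_D, quantify it, and invert:

```sh
dropletkd simulate-droplets --kd 0.5 --n-droplets 6 --seed 4 --outdir run
dropletkd quantify run/droplets.tiff --outdir run
dropletkd estimate-kd run/droplets_quantified.csv --outdir run
```

which prints

```
wrote run/droplets.tiff and truth.csv
wrote run/droplets_quantified.csv (6 droplets, 6 selected)
wrote run/kd_estimates.csv
```

and `run/kd_estimates.csv` contains one row per droplet with its measured
ratio and apparent K_D; at these settings the median K_D is 0.50 µM,
matching the generator's ground truth.  The same workflow from Python:

```python
from dropletkd import (SyntheticGroundTruth, make_droplet_image,
                       quantify_image, estimate_kd_table)

gt = SyntheticGroundTruth(kd_um=0.5, seed=4)
image, truth = make_droplet_image(gt, n_droplets=6)
table = quantify_image(image).query("selected").rename(
    columns={"sd_in": "sd_I_in", "sd_peri": "sd_I_peri"})
table[["S_tot_uM", "T_tot_uM"]] = gt.s_bulk_um, gt.t_tot_um
print(estimate_kd_table(table, concentration_reference="bulk")
      [["droplet_id", "ratio", "K_D_uM", "sigma_K_D_uM"]])
```

The numbered scripts under `analysis/` run the full study on synthetic
data: `01` renders droplet fields at K_D ∈ {0.1, 0.5, 2, 10} µM, `02`
quantifies them and recovers each K_D (median error ≤ 2% under the default
noise model), `03`/`04` fit the pH titrations (turning points 5.80 and
6.05, separated by 2.5σ for the printed estimates) and the detachment
kinetics (turning time 33.5 s, decay time 3.45 s for the unmodified
handle), `05` validates the equilibrium formula against the
reaction–diffusion simulator (relative error ~1e-11), and `06` computes an
autocorrelation-aware density band for a gyration-radius-like trajectory.
Each writes its tables under `results/`.

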