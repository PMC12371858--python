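# tvfmap

Renal **tubular volume fraction (TVF) cartography** from multi-echo
T2-weighted MRI, with the full simulation machinery needed to validate it.

## The problem

In the kidney, an MRI voxel contains two kinds of water with very
different transverse relaxation: parenchyma and blood (short T2, roughly
10–40 ms at high field) and tubular fluid (long T2, around 150 ms for rat
urine).  A multi-echo spin-echo (MESE / CPMG) T2 decay can therefore be
decomposed as

```
I(t) = A1 · exp(−t / T2_long) + A2 · exp(−t / T2_short)
```

and the **tubular volume fraction** is the long-component share of the
total weight:

```
TVF = 100 · A1 / (A1 + A2)   [%]
```

Short-TE-range protocols (maximum TE ≈ 83 ms) cannot stably estimate
`T2_long`, so it is *fixed* (default 150 ms) while `T2_short` stays inside
hard bounds (default 10–40 ms) and the weights stay nonnegative.  Fixing
the long T2 buys stability and sensitivity to physiological change at the
price of a bias in absolute TVF whenever the true long T2 deviates from
the fixed value — this toolkit quantifies exactly that trade-off.

## What the package provides

| module | contents |
|---|---|
| `tvfmap.protocols` | `MESEProtocol` / `MGEProtocol`, presets `long_te` (42 × 6.96 ms), `short_te` (13 × 6.4 ms), `mge` (10 × 2.1 ms) |
| `tvfmap.epg` | extended-phase-graph (EPG) simulation of CPMG echo trains with imperfect refocusing pulses, multi-compartment composition, SNR-calibrated Gaussian noise |
| `tvfmap.fitting` | `BiExponentialTVF` and `MonoExponentialDecay` scikit-learn-style estimators, vectorized batch fitters, `t2prime` (1/T2\* = 1/T2 + 1/T2′) |
| `tvfmap.spectrum` | free (unregularized) NNLS T2 spectra over a log-spaced grid, peak segmentation for compartment counting |
| `tvfmap.simulation` | the fixed-long-T2 error study: fitted-TVF bias, SD, and MAE of relative TVF changes over a grid of true TVFs and true long T2s |
| `tvfmap.cartography` | voxel-wise TVF / T2 / T2\* / T2′ maps, ROI medians per renal layer, intervention time-course summaries |
| `tvfmap.phantom` | synthetic layered kidney images, tube-phantom-style mixtures, programmable intervention series |
| `tvfmap.io`, `tvfmap.cli` | NIfTI-1 + JSON-sidecar I/O, CSV tables, `tvfmap` command-line interface |

## Worked example

Quantify how fixing `T2_long = 150 ms` distorts TVF when the true value is
100, 150 or 200 ms (200 trials, 9-fit averaging per trial, SNR 100,
13-echo train with 170° refocusing):

```python
from tvfmap import SimulationConfig, run_table2

cfg = SimulationConfig(tvf_levels_percent=(15.0, 20.0, 25.0),
                       n_trials=200, rng_seed=7)
res = run_table2(cfg)
cols = ["t2_long_true_ms", "tvf_true_percent", "mean_fitted_tvf_percent",
        "sd_fitted_tvf_percent", "mae_relative_change_percent"]
print(res.table[cols].round(2).to_string(index=False))
```

```
 t2_long_true_ms  tvf_true_percent  mean_fitted_tvf_percent  sd_fitted_tvf_percent  mae_relative_change_percent
           100.0              15.0                     9.47                   0.30                          NaN
           100.0              20.0                    12.69                   0.34                         4.50
           100.0              25.0                    15.97                   0.40                         3.49
           150.0              15.0                    14.65                   0.32                          NaN
           150.0              20.0                    19.63                   0.33                         2.98
           150.0              25.0                    24.67                   0.34                         2.26
           200.0              15.0                    17.75                   0.28                          NaN
           200.0              20.0                    23.86                   0.32                         2.25
           200.0              25.0                    29.86                   0.27                         1.61
```

Reading: when the fit's fixed 150 ms is *correct* (middle block) the mean
fitted TVF tracks the truth to well under 1 pp.  When the true long T2 is
200 ms the absolute TVF is overestimated (23.9 % at a true 20 %), and when
it is 100 ms it is underestimated (12.7 %) — yet the **relative changes**
between levels stay close to their ground truth (e.g. 34.4 % fitted versus
33.3 % true), with single-digit MAE.  That is the core argument for
tracking physiological change via relative TVF even under an imperfect
long-T2 fixation.

The same study runs from the shell:

```sh
tvfmap simulate-table2 --seed 7 --n-trials 200 --out table2.csv
```

End-to-end on images — generate a noisy layered kidney phantom, map TVF
voxel-wise, and summarize per layer:

```python
from tvfmap import PhantomSpec, generate_layered_image, map_voxelwise, roi_median

spec = PhantomSpec(shape=(64, 64), snr=100.0, rng_seed=0)
image, labels, truth = generate_layered_image(spec)
tvf = map_voxelwise(image, "biexp_tvf")["tvf"]
for layer, median in roi_median(tvf, labels).items():
    print(f"{layer:>14s}: fitted median TVF = {median:5.1f} %")
```

```
        cortex: fitted median TVF =  29.8 %
 outer_medulla: fitted median TVF =  42.6 %
 inner_medulla: fitted median TVF =  76.2 %
```

against programmed layer truths of 29.8 / 42.6 / 76.4 %.

## Command-line interface

```
tvfmap simulate-table2 --config cfg.json --seed 0 --out table2.csv
tvfmap fit-maps --model tvf --in stack.nii.gz --protocol short_te --out maps/
tvfmap spectrum --in decay.csv --out spec
tvfmap phantom --spec spec.json --seed 0 --out phantom/
tvfmap t2prime --t2-ms 50 --t2star-ms 10
```

Exit codes: 0 success, 2 validation error, 3 fit-failure threshold
exceeded.  See `docs/methods.md` for the model assumptions, numerical
choices and known limitations.
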