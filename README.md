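# dermoct

Quantitative analysis of optical coherence tomography (OCT) scans of
layered skin, built around the changes lymphedema produces in the rat
hind-limb model: thickening of the stratum corneum, thinning of the viable
epidermis, and stronger light attenuation in the dermis. The package is
aimed at researchers working with spectral-domain OCT of small-animal or
human skin who want a reproducible path from raw B-scan volumes to layer
thicknesses, dermal extinction coefficients, profile-similarity scores and
a subject-wise classification accuracy — plus a speckled layered-skin
phantom generator so the whole chain can be exercised and validated
without any measured data.

## What it computes

Each analyzed profile is an **averaged A-scan**: the lateral mean of the
usable columns of one B-scan after per-column surface alignment. On such a
profile:

* **Layer landmarks.** The first intensity maximum lies in the stratum
  corneum, the first local minimum after it marks the stratum-corneum /
  viable-epidermis boundary, and the second maximum marks the start of the
  dermis. Index differences times the axial pitch (divided by the tissue
  refractive index *n* = 1.4 for physical depth) give the two layer
  thicknesses.
* **Dermal extinction.** Over a configured depth window the signal is fit
  with

  ```
  I(z) = I0 · exp(−μ z) + B
  ```

  where *z* is depth from the detected surface (cm), *μ* the extinction
  coefficient (cm⁻¹), *I0* the entry intensity and *B* an additive noise
  floor. Default windows: 80–180 µm (papillary dermis) and 180–400 µm
  (reticular dermis).
* **Curve proximity factor (CPF).** For two non-negative profiles X, Y on
  a common grid,

  ```
  S = 1 − Σ|Xᵢ − Yᵢ| / (½ Σ(Xᵢ + Yᵢ))
  ```

  S = 1 for identical curves, −1 for disjoint support; equivalently
  S = 1 − 2·BrayCurtis(X, Y).
* **Group statistics.** Median/quartile summaries and two-sided
  Mann–Whitney tests (exact for small samples), with the usual
  `*` (p < 0.05) / `**` (p < 0.01) star convention, plus a truncated-cone
  limb-volume helper from five circumference measurements.
* **Classification.** Air-removed, median-filtered, max-normalized
  profiles truncated to 400 µm and resampled to 200 bins feed an RBF-kernel
  SVM; accuracy is evaluated on three repeats of a subject-disjoint 80/20
  split so scans of one animal never straddle train and test.

## Worked example

Simulate a 16-subject two-group cohort, analyze it, and classify it:

```
python -c "
from dermoct import PipelineConfig, two_group_cohort_spec
PipelineConfig(cohort=two_group_cohort_spec(n_subjects=8, scans_per_subject=4,
               columns_per_scan=100, n_samples=600)).to_yaml('demo.yaml')"
dermoct simulate --config demo.yaml --seed 1 --out demo_out
dermoct analyze  demo_out --out demo_res
dermoct classify demo_out --seed 2 --out demo_res
dermoct report   demo_res
```

which prints (abridged):

```
== thickness_summary.csv ==
     group            layer  n  median_um   q1_um   q3_um
   healthy  stratum_corneum 32     15.675 14.8500 16.5000
lymphedema  stratum_corneum 32     21.450 19.8000 21.8625
   healthy viable_epidermis 32     33.825 33.0000 36.3000
lymphedema viable_epidermis 32     24.750 24.3375 28.4625

== extinction_summary.csv ==
     group window_um  n   mu_mean     mu_sd  n_flagged  p_vs_reference stars
   healthy    80-180 32 74.911577 11.820637          0             NaN   NaN
lymphedema    80-180 32 48.059136  6.347873          0    7.153131e-12    **

== cpf_summary.csv ==
     group reference  n_pairs  cpf_mean   cpf_sd  p_vs_within_reference stars
lymphedema   healthy     1024  0.783548 0.094438          1.100399e-103    **

== accuracy_summary.csv ==
 accuracy_mean_pct  accuracy_sd_pct  n_repeats  flagged_repeats
         88.888889        19.245009          3                0
```

Reading the output: the lymphedema group shows the expected thicker
stratum corneum (21.5 vs 15.7 µm median, physical depth at *n* = 1.4),
thinner viable epidermis (24.8 vs 33.8 µm), and lower dermal extinction
(48 vs 75 cm⁻¹ in the 80–180 µm window) — both contrasts doubly starred —
and the SVM separates the groups at ~89% mean accuracy over the three
subject-wise splits. CPF here compares lymphedema profiles against
healthy ones; the star marks that these cross-group pairs are
significantly less similar than healthy-vs-healthy pairs.

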