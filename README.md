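# scalemorph

Geometric morphometrics of teleost fish scales for species, body-area and
rearing-group discrimination.

A single dermal scale carries enough shape information to tell many teleost
species apart — useful in fisheries inspection, forensics, diet studies and
archaeology, where molecular identification is too slow or too expensive.
`scalemorph` implements the two standard geometric-morphometric routes over
binary scale silhouettes and compares them head-to-head:

* **Landmark route (LM):** 5 fixed landmarks at the margin junctions plus 80
  semilandmarks equidistant along each margin (40 on the variable anterior
  margin, 10 on each of the other four), generalized Procrustes
  superimposition, PCA, and PERMANOVA. The scheme is focus-free, so it also
  works on regenerated scales common in farmed fish.
* **Outline route (OL):** sub-pixel boundary tracing, equidistant
  resampling, centering and unit-centroid-size scaling, elliptic Fourier
  descriptors truncated at 99% cumulative harmonic power, PCA, and
  PERMANOVA.

For a configuration with points p₁…p_k and centroid p̄, centroid size is
CS = √Σᵢ‖pᵢ − p̄‖². Elliptic Fourier harmonic n contributes coefficients
(aₙ, bₙ, cₙ, dₙ) of cos/sin(2πnt/T) in x(t) and y(t), with harmonic power
(aₙ²+bₙ²+cₙ²+dₙ²)/2. PERMANOVA reports Anderson's pseudo-F and
R² = SS_between/SS_total from Euclidean distances, with whole-label
permutation p-values (exact enumeration when there are ≤ 10 000
arrangements) and Bonferroni adjustment across pairs.

A synthetic scale generator provides the five anterior-margin shape
families of the study system (smooth, striated, waved, dentate, plus a
small smooth-scaled family) with ground-truth landmarks, controlled noise
and group effect sizes, so the entire system — including the PNG/TPS/CSV
I/O path — is testable without the original images. See
`docs/methods.md` for the full model description.

## Worked example

```python
import scalemorph as sm
from scalemorph.pipeline import analyze_lm, analyze_ol, study_from_synthetic

templates = sm.species_templates()
ds = sm.generate_dataset(templates, {g: 12 for g in templates},
                         noise_sd=0.015, seed=42)
study = study_from_synthetic(ds)

lm = analyze_lm(study, n_permutations=999, seed=0)
print(lm.aligned.summary())
print(lm.allometry.summary())
print(lm.pairwise_table().head(4).to_string(index=False))
```

prints

```
Generalized Procrustes alignment
  shapes:          60
  points/shape:    85 (5 fixed)
  slide mode:      none
  iterations:      3 (converged)
  centroid size:   mean 12.63, range [5.291, 19.48]
  mean residual:   0.06185
Shape-on-size regression: R^2 = 0.5466, permutation p = 0.001 (999 permutations)
                         pair     R2  pseudo_F  p_raw  p_adjusted signif
dentate_sp vs smooth_small_sp 0.7977   86.7628  0.001        0.01      *
      dentate_sp vs smooth_sp 0.6734   45.3704  0.001        0.01      *
    dentate_sp vs striated_sp 0.2685    8.0770  0.001        0.01      *
       dentate_sp vs waved_sp 0.4925   21.3531  0.001        0.01      *
```

Every configuration carries the full 85 points; all superimpositions
converged in 3 iterations; each species pair separates with R² between
0.27 and 0.80 and the smallest attainable Bonferroni-adjusted p at 999
permutations (10 × 0.001 = 0.01). The allometry R² here is inflated by
pooling species of very different sizes — within one species group it
drops to ~0.01 (see the acceptance outputs). The outline route on the same
data keeps 3 harmonics at the 99% power criterion and flags the same 10
pairs:

```python
ol = analyze_ol(study, n_permutations=999, seed=0)
print(ol.n_harmonics)          # 3
print(ol.pairwise_table().head(1).to_string(index=False))
#                          pair     R2  pseudo_F  p_raw  p_adjusted signif
# dentate_sp vs smooth_small_sp 0.8427  117.8447  0.001        0.01      *
```

## Command line

```sh
scalemorph simulate --out data/ --seed 1            # 5-species synthetic study
scalemorph both --masks data/masks --tps data/landmarks.tps \
    --metadata data/metadata.csv --out run/ --seed 1
scalemorph report run/
```

`simulate` writes PNG silhouettes, a TPS landmark file and CSV metadata;
`lm` / `ol` / `both` run the pipelines and write CSV tables (pairwise
PERMANOVA with significance stars, PCA scores, aligned coordinates, size
tests) plus JSON reports with full provenance (seed, config hash, version);
`report` summarizes a finished run. All options can also come from a YAML
config (`--config`), with flags taking precedence.

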