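# hjorth2d

Texture parametrization of microscopy images with a 2D extension of
Hjorth's descriptors, plus the rank-based statistics needed to decide
whether named groups of images differ in texture.

## Who this is for

Melissopalynology — identifying the botanical origin of honey from the
pollen it carries — is accurate but slow and laboratory-bound. A cheap
pre-screen is to photograph pollen grains under an optical microscope and
ask whether simple whole-image texture numbers already separate candidate
taxa (e.g. *Brassica napus*, *Helianthus*, *Phacelia*). `hjorth2d`
implements that pre-screen: it turns each grayscale pollen image into
three scalar descriptors and then tests, nonparametrically, whether the
descriptor distributions differ between groups.

## The descriptors

Bo Hjorth's 1970 EEG parameters, applied to an image `I` and the
magnitudes of its first and second derivatives
`I' = sqrt((∂I/∂x)² + (∂I/∂y)²)` and `I'' = sqrt((∂²I/∂x²)² + (∂²I/∂y²)²)`:

| descriptor | definition | reads as |
|---|---|---|
| Activity   | `σ²(I)` | signal power (variance) |
| Mobility   | `σ(I′) / σ(I)` | dominant spatial frequency |
| Complexity | `(σ(I″)/σ(I′)) / (σ(I′)/σ(I))` | bandwidth / shape change |

All standard deviations are population (1/N) moments over every pixel.
Activity also equals the total spectral power of the mean-removed image
(Parseval's theorem), which the package exposes as a numerical
cross-check (`spectral_total_power`).

Each image is prepared as: RGB → grayscale (BT.601 weights) → min–max
normalization to [0, 1] → 3×3 unit-sum box smoothing → derivative
magnitudes by central differences.

## The statistics

Per descriptor: Shapiro–Wilk normality per group and Levene's
variance-homogeneity test (with the full SS/df/MS ANOVA decomposition);
the Kruskal–Wallis rank ANOVA `H` referred to χ²(k−1), with an exact
permutation option for tiny samples; and Dunn's pairwise z-tests on rank
means, Bonferroni-adjusted over the k(k−1)/2 comparisons,

```
z_ij = |R̄_i − R̄_j| / sqrt( N(N+1)/12 · (1/n_i + 1/n_j) ).
```

## Worked example

The original pollen micrographs are not public, so the package ships a
seeded synthetic generator whose groups differ in spatial-frequency
content (Gaussian random fields with power-law spectra `S(ω) ∝ |ω|^−β`,
β = 0/1/2), at the same 18/8/9 group sizes as the three-taxa study design:

```bash
cat > cohort.yaml <<'YAML'
shape: [256, 256]
groups:
  - {label: brassica,   n: 18, texture: {spectral_exponent: 0}}
  - {label: helianthus, n: 8,  texture: {spectral_exponent: 1}}
  - {label: phacelia,   n: 9,  texture: {spectral_exponent: 2}}
YAML
hjorth2d generate-cohort --config cohort.yaml --out images --seed 42
hjorth2d extract images --manifest images/manifest.csv --out descriptors.csv
hjorth2d stats descriptors.csv --out-dir stats
hjorth2d classify descriptors.csv --out confusion.json
```

`descriptors.csv` holds one row per image:

```
image_id,group,activity,mobility,complexity
brassica_000,brassica,0.0015159219126599463,0.38373572961059044,5.254293876764645
brassica_001,brassica,0.0017439969691110063,0.38027744397734453,5.334359391941867
```

and `stats/report.md` contains, per descriptor, the rank table and tests;
for Activity at seed 42:

```
| group      | n  | rank sum | rank average |
| brassica   | 18 | 171      | 9.500        |
| helianthus | 8  | 180      | 22.500       |
| phacelia   | 9  | 279      | 31.000       |

H = 28.414, df = 2, p = 6.75953e-07
```

so the three texture groups separate decisively (p « 0.01 for all three
descriptors), the Levene decomposition reports df = 2 and df* = 32 for
this 18/8/9 design, and `classify` prints `LOO accuracy 1.000 over 35
images` (an exploratory nearest-centroid check, not the scientific
output). The same operations are available as a library:

```python
from hjorth2d import TextureSpec, make_cohort, batch_descriptors, compare_groups

images, manifest = make_cohort(
    [("fine", TextureSpec(spectral_exponent=0.0), 18),
     ("mid", TextureSpec(spectral_exponent=1.0), 8),
     ("coarse", TextureSpec(spectral_exponent=2.0), 9)],
    master_seed=42,
)
report = compare_groups(batch_descriptors(images).table)
print(report["descriptors"]["mobility"]["kruskal_wallis"]["H"])
```

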