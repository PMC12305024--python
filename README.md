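# lightniche

A tested pipeline linking rainforest light microhabitats to mimicry-ring
membership and visual-system evolution in a butterfly community:

- **`visual_model`** — irradiance spectra to receptor quantum catches
  (Govardovskii A1 templates at λmax 340/435/545 nm), achromatic photon catch,
  and Michelson relative-catch contrasts over 310–670 nm.
- **`canopy`** — canopy openness (%) from 180° hemispherical photographs:
  blue-channel extraction, Otsu thresholding inside the fisheye circle, a
  7 zenith-ring × 8 azimuth-segment gap-fraction grid over 0–70°, and
  solid-angle-weighted aggregation.
- **`morphometrics`** — forewing area, aspect ratio (moment-equivalent
  ellipse) and wing loading from dorsal silhouettes.
- **`axes`** — species-mean aggregation and the correlation-matrix PCA that
  builds the two ecological axes (EC1 "light environment", EC2 "flight-related
  wing morphology"; eigenvalue ≥ 1 retained), plus the visual-trait PCA.
- **`phylo_stats`** — Pagel's-λ phylogenetic correlation, PGLS, Gaussian mixed
  models with crossed/phylogenetic random intercepts (ML/REML), AICc
  comparison, and SMA slope/elevation/shift tests.
- **`evo_models`** — equal-rates Mk fitting, stochastic character mapping,
  BM1/BMM/OU1/OUM/EB likelihoods and ML fits, and AICc densities of the
  multipeak models across an ensemble of sampled regime maps.
- **`synthetic_data`** — fully deterministic ground-truth communities: Yule
  trees, regime paintings, traits under BM/OU/EB, gap/shade irradiance
  archetypes, fisheye images with known sky fraction, elliptical wing
  silhouettes, and individual-level record tables.

## CLI

One entry point with per-stage subcommands:

```sh
lightniche simulate --seed 7 --out community/            # ground-truth fixture
lightniche spectra  --in community/spectra --out catches.csv
lightniche canopy   --in community/fisheye --out openness.csv
lightniche wings    --in community/wings --meta community/wings/meta.csv --out wings.csv
lightniche axes     --records community/records.csv --out-prefix ec
lightniche pgls     --tree community/tree.nwk --data community/truth.csv --response latent_light
lightniche sma      --data data.csv --x log_x --y log_y --group cluster
lightniche evofit   --tree community/tree.nwk --data species_scores.csv \
                    --trait PC1 --regimes mimetic_cluster --nmaps 500 --seed 42
```

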