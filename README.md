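# canopycomm

Analysis of how an animal community — butterflies in the motivating system —
responds to a grassland → savanna → forest gradient of canopy cover: from
raw line-transect observations, through distance-sampling density
estimation, to community statistics, ordinations, permutation inference,
and canopy-response peak regressions.

Midwest oak savannas and woodlands persist at a small fraction of their
historic extent, and restoration usually means choosing a target tree
density. The question this toolkit addresses is *where along the canopy
gradient do desirable community outcomes peak* — species richness, total
abundance, and the abundance of imperiled species — so that a manager can
ask whether one canopy condition serves all three.

## What it computes

* **Densities from counts.** Raw transect counts under-represent hard-to-see
  species. A half-normal detection function g(x) = exp(−x²/2σ²) is fit to
  perpendicular detection distances (pooling sparse species with congeners /
  confamilials), giving each species an effective strip width
  ESW = ∫g(x)dx and a density D = 10⁴·n/(2·L·ESW) per hectare per survey.
  Records identified only to family are apportioned to species in proportion
  to same-site, same-day identified counts.
* **Community metrics.** Per-survey richness and total density; the
  conservation value index CVI = Σ_{r_s>2} r_s·D_s with r_s the reversed
  NatureServe rank (1 secure … 5 critically imperiled); ACE asymptotic
  richness; individual- and site-based species accumulation curves with
  z-tests at common effort.
* **Composition.** One-dimensional principal-curve ordination scores;
  indicator species values (IndVal = 100·specificity·fidelity) with
  permutation tests; predictive co-correspondence analysis with
  leave-one-out cross-validated fit.
* **Inference.** PERMANOVA (Bray–Curtis / quantitative Sørensen) with
  pairwise contrasts, Kruskal–Wallis + Dunn, Spearman correlation,
  Benjamini–Hochberg correction.
* **Gradient peaks.** Cubic vs Gaussian-peak regressions (AICc selection) of
  each response against canopy cover, and a rank-averaged composite of
  richness, density, and CVI per site.
* **Synthetic data.** A generator with Gaussian canopy niches, phenology,
  half-normal detectability, and partial identification — with analytic
  ground truth (`true_peaks`) so every estimator can be tested for recovery.

## Worked example

Simulate the default study design (25 sites × 21 survey rounds, 60 species,
8% family-level records) and run the full chain — apportionment, detection
fits, densities, per-site metrics, peak regressions:

```python
import json, pandas as pd
from canopycomm import community, detection, gradient, synthetic_data as synth

data = synth.simulate_dataset(synth.default_config(1))
traits = data.species_traits
ranks = pd.Series([community.reversed_rank(r) for r in traits["natureserve_rank"]],
                  index=traits["species_code"])
out = gradient.report(data.observations, data.sites, traits, ranks,
                      surveys=data.ground_truth[detection.META_COLUMNS])
print(json.dumps(out["peaks"], indent=2))
```

prints

```json
{
  "richness_peak_canopy": 39.15361276576581,
  "density_peak_canopy": 27.984844574145058,
  "cvi_peak_canopy": 54.55191580227491,
  "composite_peak_canopy": 41.289046911441616
}
```

— the canopy cover (%) at which each fitted response curve peaks. For this
simulated community the generator's analytic truth
(`synth.true_peaks(synth.default_config(1))`) puts the density peak at 28.8%
and the CVI peak at 54.3% canopy, so the pipeline recovers both to within a
point; conservation value peaks at mid-gradient because the imperiled
species' niches center there, while total abundance peaks in more open
conditions.

The same steps are available from the shell:

```sh
canopycomm simulate --seed 1 --outdir run/
canopycomm densities --observations run/observations.csv --sites run/sites.csv \
    --species run/species.csv --out run/densities.csv
canopycomm report --observations run/observations.csv --sites run/sites.csv \
    --species run/species.csv
```

plus `metrics`, `ordinate`, `indval`, `coca`, `permanova`, `kwdunn`, and
`peaks` subcommands.

A replica of the published 61-species summary table (densities, counts,
habitat of maximum indicator value, effective strip widths) ships with the
package: `canopycomm.load_table2_fixture()`.

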