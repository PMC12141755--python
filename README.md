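# photobackcast

Backcasting breeding-songbird occurrence nearly a century into the past by
uniting land cover change measured in repeat oblique photographs with
multi-scale species distribution models (SDMs).

Mountain protected areas hold some of the oldest systematic photographic
records of any ecosystem: survey photographs from the 1920s-1950s that can be
re-taken from the same stations today. Classified into land cover categories
and aligned pixel-to-pixel, such pairs measure a century of landscape change
— typically conifer in-filling of subalpine meadows and wetlands. This
package turns that change into an estimate of how the breeding-bird
community's occurrence probabilities shifted over the same century, for
ecologists who have (a) classified photo pairs and (b) contemporary
point-count surveys or an already-fitted coefficient table.

## The model

Detection counts $y_i \in \{0,\dots,k\}$ out of $k$ sampling units per site
(here $k = 9$) are modelled per species as

$$y_i \sim \mathrm{Binomial}(k, P_i), \qquad
\operatorname{logit} P_i = \beta_0 + \sum_j \beta_j x_{ij},$$

where $x_{ij}$ is the **percent** cover of land cover category $j$ within a
buffer of radius $r$ around site $i$. The characteristic scale of selection
$r$ is chosen per species by refitting over radii 250-4500 m in 250-m steps
(collinearity screened at VIF < 3, terms reduced by bidirectional stepwise
AIC) and keeping the radius with minimum AIC. Detectability is summarised by
the probability of false absence $\mathrm{PFA} = (1-p)^k$.

The backcast applies a species' fitted model to the historical and modern
composition of each aligned photo pair through the inverse logit,

$$P = \frac{e^{\beta_0 + \sum_j \beta_j x_j}}{1 + e^{\beta_0 + \sum_j \beta_j x_j}},$$

and tests $P_\text{mod} - P_\text{hist}$ across pairs with a paired Wilcoxon
signed-rank test plus a bootstrap CI (species classified increased /
declined / no substantial change by whether the CI excludes 0). Coefficient
uncertainty is propagated by re-running the backcast with every coefficient
shifted to $\beta - \mathrm{SE}$ and $\beta + \mathrm{SE}$; landscape and
community change are summarised by Shannon diversity
$H = -\sum p_i \ln p_i$.

A first-class synthetic-data module generates landscapes, surveys and photo
pairs with known ground truth, so the whole pipeline is testable offline;
the coefficient table printed for the Willmore Wilderness songbird study
(15 species) is bundled and loadable via
`photobackcast.load_species_models()`.

## Worked example

The numbered scripts under `analysis/` run the full synthetic study; each is
a thin driver over the library:

```bash
python analysis/01_simulate_world.py --seed 1 --outdir results/run
python analysis/02_align_photos.py   --seed 1 --outdir results/run
python analysis/03_landcover_change.py --seed 1 --outdir results/run
python analysis/04_fit_sdms.py       --seed 1 --outdir results/run
python analysis/05_backcast_occurrence.py --seed 1 --outdir results/run
```

Stage 03 prints, for the engineered herbaceous/wetland → conifer in-filling
scenario:

```
substantial cover changes (>1 point):
  herbaceous            18.0% ->   9.0% (p = 0.00049, CI [-9.0, -8.8])
  wetland                8.0% ->   6.4% (p = 0.00049, CI [-1.7, -1.6])
  coniferous forest     45.1% ->  55.6% (p = 0.00049, CI [+10.4, +10.7])
landscape Shannon H: 1.70 -> 1.55 (p = 0.00049)
```

— conifer gains what meadows and wetlands lose, and landscape diversity
falls. Stage 05 then backcasts the fitted models over those same pairs:

```
conifer specialist   P 0.122 -> 0.154 (increased; p = 0.00049; direction-consistent)
forest generalist    P 0.151 -> 0.181 (increased; p = 0.00049; direction-consistent)
meadow specialist    P 0.242 -> 0.137 (declined; p = 0.00049; direction-consistent)
shrub nester         P 0.167 -> 0.167 (no substantial change; p = 0.9; direction-consistent)
```

Forest-associated species rise, the meadow specialist falls, and the species
whose habitat did not change is correctly left unclassified — matching the
generator's ground truth. The same stages are available as a console script
(`photobackcast simulate|align|account|fit|backcast|report -c config.yaml`),
which writes a manifest (config hash, seed, output checksums) for
reproducibility.

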