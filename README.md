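# coatmorph

Analysis pipeline for **feral cat (*Felis catus*) coat morphology from
camera-trap surveys**, built around the Tasmanian state-wide monitoring
design: hundreds of unlured trail cameras, each image labelled with a coat
pattern, colour and white-patch flag, and (where markings allow) an
individual identity.

The package answers two questions ecologists ask of such data:

1. **Spatial** — does the environment shape which coat type dominates a
   site? Each retained camera site gets a *modal coat type* (the category
   with the most identified individuals; ties broken by event count), and a
   multinomial logistic regression relates it to elevation, topographic
   roughness, isothermality, FPAR, distance to nearest town and vegetation
   class, with solid black cats as the reference level.
2. **Temporal** — are some coat types more nocturnally active under a dark
   moon? Camera-nights are classified by lunar luminosity (full > 80%
   illuminated, new < 20%, intermediate nights excluded) and a second
   multinomial model relates the coat type captured each night (reference:
   cat absence) to rainfall, solar exposure, minimum temperature, moon class
   and a moon × solar interaction. Activity is summarised by the PDE index
   (proportion of dates with events) with site-bootstrap standard errors.

## The models

For observation $i$ with covariates $x_i$ and outcome category $k \in
\{1,\dots,K\}$, the multinomial logit (fitted from first principles by
Newton–Raphson) is

$$\Pr(y_i = k) = \frac{\exp(\beta_k^\top x_i)}{1 + \sum_{l \ne \text{ref}} \exp(\beta_l^\top x_i)},
\qquad \beta_{\text{ref}} \equiv 0,$$

with odds ratios $\mathrm{OR} = e^{\beta}$ and two-sided Wald intervals
$\exp(\beta \pm z_{\alpha} \, \mathrm{se}(\beta))$ (default level 97.5%,
$z \approx 2.2414$). Solid black cats carry no identifying markings, so
their abundance uses the ratio estimator

$$\widehat{N}_{\text{black}} = \frac{\text{black images}}{\text{identifiable images} / \text{identified individuals}},$$

and activity is $\mathrm{PDE} = 100 \times \text{capture nights} /
\text{operating nights}$. Moonlight follows a mean-synodic-month cosine
model, $f(t) = \tfrac{1}{2}(1 - \cos 2\pi a(t)/P)$ with age $a(t)$ since a
reference new moon and $P = 29.530588$ d (an exact ephemeris table can be
substituted).

A seeded synthetic-survey generator (`coatmorph.simulate`) produces
complete surveys — site covariates, softmax coat assignment with known
coefficients, nightly detections whose rates differ by moon phase, image
bursts, unknown-identity noise, weather — so every stage is testable
against ground truth.

## Worked example

```python
import coatmorph as cm

# Black-cat abundance from the published survey tallies:
# 24,075 images minus 9,706 black and 1,388 unknown = 12,981 identifiable,
# across 674 identified individuals
est = cm.estimate_black(12_981, 674, 9_706)
print(f"images per identified cat: {est.images_per_cat:.2f}")
print(f"estimated solid-black cats: {est.estimated_black:.1f} (~{est.estimated_black_rounded})")

# A synthetic survey, end to end
survey = cm.simulate_survey(cm.SimConfig(n_sites=300, n_nights=365, seed=42))
det = cm.read_detections(survey.detections)
events = cm.group_events(det)
print(f"{len(det)} images -> {len(events)} events at {det['site_id'].nunique()} sites")

summaries = cm.site_summaries(events, det)
X, y = cm.build_spatial_model(summaries, survey.sites)
fit = cm.fit_multinomial(X, y, reference="solid_black")
table = cm.wald_intervals(fit, level=0.975)
row = table[(table.category == "tortoiseshell") & (table.predictor == "elevation")].iloc[0]
print(f"tortoiseshell ~ elevation: OR {row.odds_ratio:.2f} "
      f"(97.5% CI {row.lower:.2f}-{row.upper:.2f}), significant: {row.significant}")
```

prints

```
images per identified cat: 19.26
estimated solid-black cats: 504.0 (~504)
12794 images -> 4953 events at 300 sites
tortoiseshell ~ elevation: OR 2.00 (97.5% CI 1.02-3.91), significant: True
```

19.26 images per identified cat converts 9,706 unmarked black-cat images
into roughly 504 individuals; the synthetic survey was generated with a
positive tortoiseshell–elevation coefficient, and the fitted odds ratio
recovers it (high-elevation sites are about twice as likely to be
tortoiseshell-dominant per standard deviation of elevation).

## Command line

```bash
coatmorph simulate --config sim.yaml --out survey/
coatmorph run-spatial  --detections survey/detections.csv --deployments survey/deployments.csv \
                       --sites survey/sites.csv --out out/spatial
coatmorph run-temporal --detections survey/detections.csv --deployments survey/deployments.csv \
                       --weather survey/weather.csv --seed 1 --out out/temporal
coatmorph moon classify --from 2019-01-01 --to 2019-12-31
```

Every run writes a `manifest.json` with input checksums, per-stage row
accounting (each dropped row is attributed to a documented exclusion) and
seeds. Exit codes: 0 ok, 2 schema error, 3 convergence failure.

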