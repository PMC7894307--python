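# beetlescape

Do bark beetle outbreaks amplify or dampen *future* bark beetle
disturbance?  Outbreaks of the European spruce bark beetle
(*Ips typographus*) kill mature Norway spruce, and a warming climate
accelerates beetle development, improves winter survival and weakens tree
defence — an amplifying pathway.  But outbreaks also consume their own
host base and push the forest toward more diverse, less
spruce-dominated, more fragmented conditions — a potentially dampening,
self-regulating pathway.  `beetlescape` is a desk-scale pipeline for
quantifying the balance between the two, aimed at forest-disturbance
ecologists and modellers who want a fast, fully seeded, testable
sandbox for disturbance-feedback analysis.

The package provides:

- a **cohort-based forest landscape simulator** on a 100-m grid
  (growth, mortality, regeneration/succession, storm damage) with an
  annual beetle cycle: voltinism = floor(degree-days / 557), logistic
  winter survival, exponential dispersal, colonization against a defence
  `D = d0 · host_BA · drought_index`, and kill seeding next year's
  pressure — so outbreaks propagate until hosts are depleted;
- **eight diversity indicators** per 50-yr snapshot: within-stand Shannon
  entropy of 4-m height and 4-cm dbh classes (AlpHei, AlpDbh), canopy
  cover (CanCov), rumple index (RumInd), multiplicative among-stand
  diversity β = γ/ᾱ on the effective-number scale (BetHei, BetDbh),
  spruce share of basal area (ProSpr) and the 8-neighbour host
  aggregation index (AggInd);
- a **factorial experiment**: four climate scenarios (baseline BC,
  +2.0 °C MC, +4.5 °C HC, +4.5 °C/+10% precipitation HWC) × disturbed /
  undisturbed × replicates, with common random numbers within each pair;
- a **counterfactual feedback estimator**: a random forest trained on
  disturbed runs (response: beetle-killed volume per 50-yr window;
  predictors: the eight indicators at window start + window climate) is
  used to predict the response twice — with factual covariates, and with
  the indicator covariates swapped to the matched undisturbed run's
  values.  The percent difference of the summed predictions is the
  disturbance-mediated feedback (negative = dampening), decomposable into
  composition-only {ProSpr, AggInd} and structure-only swaps, and
  validated against closed-form truth on a synthetic benchmark.

See `docs/methods.md` for the model equations, default parameters and
their rationale, and known limitations.

## Worked example

```python
import beetlescape as bl
from beetlescape.config import make_config

cfg = make_config("desk", overrides={
    "landscape": {"rows": 20, "cols": 20},
    "experiment": {"horizon_yr": 100, "indicator_step_yr": 50,
                   "replicates": 3, "climates": ["BC", "HC"], "base_seed": 1},
})
exp = bl.run_experiment(cfg)

res = bl.cumulative_contrast(exp, "HC", "BC")
print(f"HC vs BC cumulative beetle kill: {res['percent']:+.1f}% "
      f"[{res['ci_lo']:.1f}, {res['ci_hi']:.1f}]")

run = exp.get("HC", True, 0)   # hot scenario, disturbed, replicate 0
for iv in (run.indicators[0], run.indicators[-1]):
    print(f"year {iv.year:3d}: ProSpr={iv.ProSpr:.1f}%  "
          f"AggInd={iv.AggInd:.1f}%  AlpHei={iv.AlpHei:.2f}")

ema = bl.ema_series(run.annual_kill)
print(f"peak 10-yr EMA of beetle kill: {ema.max():.2f} m3/ha/yr "
      f"(observed 1990-2010 reference: {bl.OBSERVED_EMA_REFERENCE_M3_HA_YR})")
```

prints

```
HC vs BC cumulative beetle kill: +37.6% [26.3, 60.3]
year   0: ProSpr=61.9%  AggInd=99.8%  AlpHei=1.04
year 100: ProSpr=28.2%  AggInd=13.8%  AlpHei=0.99
peak 10-yr EMA of beetle kill: 7.28 m3/ha/yr (observed 1990-2010 reference: 10.73)
```

Even on this miniature 400-ha landscape over one century, the hot
scenario kills ~38% more growing stock than baseline, the outbreak wave
dismantles the contiguous host layer (AggInd 100% → 14%) and halves the
spruce share, and peak activity approaches the reference level of the
historically observed outbreaks.  The full feedback analysis
(`build_training_table` → `fit_surrogate` → `decompose_feedback`) needs
the complete factorial experiment; see below.

A command-line interface wraps the same pipeline:

```sh
beetlescape run --preset desk --out results/desk
beetlescape feedback --out results/desk
beetlescape pca --out results/desk
beetlescape fixtures --out /tmp/fx     # miniature bundle for tests/docs
```

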