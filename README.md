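# agtarget

Spatial targeting of voluntary agricultural greenhouse-gas mitigation
programs at the county level: where is a dollar spent on incentivizing
cover-cropping or tillage reduction most likely to buy *additional* carbon
sequestration?

The package is aimed at agri-environmental economists and program analysts.
It couples a threshold model of conservation-practice diffusion — which
makes the additionality problem explicit — with an empirical forecasting
pipeline (honest regression forests on county census, weather, soil and
program-obligation data) and a bivariate cost-efficiency classification of
counties. Because the real data sources are portal downloads, the package
ships a synthetic-data generator that emulates their statistical structure,
so every stage is runnable and testable end to end.

## The model

Producer $i$ in county $c$ adopts a conservation practice in period $t$
when the net return is positive:

$$r^c_{i,t} = r^c_i + L_t > 0, \qquad r^c_i \sim N(\mu_c, \sigma^2),$$

where $r^c_i$ is a time-invariant individual component and $L_t$ a common
time-varying component (prices, practice effectiveness, adoption costs).
The county adoption share in period $t$ is $\Phi((\mu_c + L_t)/\sigma)$,
and sweeping $L_t$ upward traces the classic S-shaped diffusion curve.

A payment-for-practice program paying incentive $P$ for adoption during a
window shifts the final-period return by $P$. Enrollees decompose into
**additional** adopters (adopt only because of $P$) and **non-additional**
adopters (would have adopted anyway, but are paid too, since the
administrator cannot observe counterfactual returns). With per-enrollee
sequestration $s$, fixed cost $F$, and $n_e$ enrollees of which $n_a$ are
additional:

- cost per credit $AC_{cred} = (P\,n_e + F)/(s\,n_e)$ — lowest where
  adoption is fast;
- cost per additional ton $AC_{addseq} = (P\,n_e + F)/(s\,n_a)$ — lowest
  where adoption is *slow*, because fewer non-additional enrollees dilute
  the spend;
- credit quality $= s\,n_a/(P\,n_e + F)$, additional tons per dollar of
  credits sold at average cost.

The empirical pipeline uses the county-level *rate of change* in practice
acreage as the observable proxy for where a county sits on its diffusion
curve. It forecasts $\ln(y_{i,t}/y_{i,t-5})$ (log ratio of practice acres
across census waves) with an honest regression forest — per tree, disjoint
subsample halves choose splits and estimate leaf means — after an
iterative variable-selection pass, validates it with an out-of-bag
calibration test, and crosses the predicted-rate interval (negative /
low-positive / high-positive) with the county's sequestration tercile into
a 9-class map table, from `neg|T1` ("inefficient") to `high_pos|T3`
("cost-effective").

## Worked example

```bash
python examples/01_worked_example.py      # or: agtarget worked-example
```

prints, for the two-county illustration (county A: $\mu=-2/3$; county B:
$\mu=-2$; $\sigma=1$; $L=(0,\tfrac23,\tfrac43)$; $P=\$0.25$; $F=\$50$;
1000 producers; shares rounded to whole percents):

```
        enrollee_count  additional_count  total_cost  credits  ac_per_enrollee  ac_per_additional_ton  quality
A^low            320.0              70.0       130.0    320.0           0.4062                 1.8571   0.5385
A^high           320.0              70.0       130.0    640.0           0.4062                 0.9286   1.0769
B^low            250.0              90.0       112.5    250.0           0.4500                 1.2500   0.8000
B^high           250.0              90.0       112.5    500.0           0.4500                 0.6250   1.6000
B^mid            250.0              90.0       112.5    375.0           0.4500                 0.8333   1.2000
```

County A enrolls 32% of producers but only 7 points of that is additional:
credits are cheap ($0.41 each) yet an additional ton costs $1.86. County B
enrolls fewer (costlier credits at $0.45) but an additional ton is only
$1.25, and its credit quality is 0.80 tons per dollar versus 0.54 in A.
The other examples walk through county rankings, the synthetic panel
generator, the honest-forest forecast with its calibration test, and the
full config-driven pipeline (`examples/02`–`05`).

## Layout

- `src/agtarget/diffusion.py` — threshold adoption model, program
  outcomes, cost metrics, agent-based simulation
- `src/agtarget/synthdata.py` — synthetic county panels (census waves,
  daily weather, soils, obligations, sequestration scenarios) plus a
  held-out future wave
- `src/agtarget/features.py` — practice shares, cropland decile filter,
  degree-bin temperature exposure, seasonal precipitation, 20-yr normals,
  5-yr deviations, per-acre obligation measures, design-matrix assembly
- `src/agtarget/forest.py` — honest regression forest, OOB bookkeeping,
  split-frequency importance, iterative selection, calibration test
- `src/agtarget/targeting.py` — sequestration-scenario averaging,
  terciles, rate intervals, 9-class bivariate classification
- `src/agtarget/pipeline.py`, `cli.py` — YAML config, stage orchestration,
  thin command-line driver (`agtarget simulate|features|train|predict|classify|run|worked-example`)

See `docs/methods.md` for modelling assumptions, parameter conventions and
limitations.
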