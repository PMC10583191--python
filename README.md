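# phenoseason

Season length of perennial herbs, derived from shoot-size trajectories.

Perennial herbs in seasonal climates differ enormously in how long their
above-ground shoots are active — from spring geophytes that wither in
early summer to near-evergreen species.  `phenoseason` implements a
complete, tested pipeline that turns repeated morphometric measurements
of individual shoots (upper width, lower width and vegetative length,
recorded biweekly through one season) into species-level phenology and
then asks what explains the interspecific differences:

1. **Plant size.**  The three dimensions are combined into a
   conical-frustum volume V = πL/12 · (w_u² + w_u·w_l + w_l²) and the
   cube root `size = V^(1/3)` is the working variable.  A cubic
   smoothing spline (roughness chosen by generalized cross-validation)
   splits each shoot's trajectory into growing and declining parts at its
   maximum.
2. **Spring growth.**  All shoots of a species are fitted together with a
   nonlinear mixed-effects logistic curve
   `x(t) = A + (K − A) / (1 + e^(−b(t−a)))` with shoot-level random
   effects on the final size K (always) and optionally on one further
   parameter; the random-effect structure is chosen by AIC.  The fit
   yields the date of peak growth *a*, the standardized growth rate *b*
   (equal to 4d/K where d is the growth rate at the inflection), and the
   **season start**, the day the curve reaches 25 % of final size
   (closed form: a − ln 3 / b).
3. **Senescence.**  Each shoot's declining part is smoothed with a cubic
   spline at the conventional `spar = 0.5` penalty; the per-shoot curves
   are normalized and averaged into a species profile, from which come
   the senescence date (first 50 % crossing), pace
   (1 / days from the last 95 % to the first 5 % value), shape
   (log C/D, the late-to-early duration ratio) and the **season end**
   (first 25 % crossing).  Species that never drop below 25 % overwinter
   and get a season length of 365 d.
4. **Inference.**  Effects of functional traits (height, lateral spread,
   SLA, LDMC) and niche indicator values (moisture, light, reaction,
   nutrients, temperature, disturbance) on the phenological responses are
   estimated by exhaustive all-subsets OLS with AICc ranking, Akaike
   weights, and conditional model averaging inside a Δ < 3 window; plus
   PCA with passive projection of season length and standardized major
   axis regression.
5. **Structural equation model.**  A piecewise (locally estimated) SEM
   over the layered DAG niche → traits → phenology → season length, with
   directed-separation tests, Fisher's C = −2Σln p (χ², 2k df), and an
   iterative refinement loop that adds missing edges or correlated errors
   and prunes edges by AIC.

Because real garden campaigns rarely ship raw shoot measurements, the
package includes a first-class synthetic-data generator
(`phenoseason.synthetic_data`) that emulates the measurement protocol
with known ground truth — a logistic growth phase joined to a
Richards-type decline whose fraction crossings have closed forms — so
every stage has an analytic parameter-recovery surface.

## Worked example

```python
from phenoseason import synthetic_data as synth, trajectory, growth, senescence

cfg = synth.GenerationConfig(n_species=2, rng_seed=3)       # 7 shoots, biweekly, 5 % noise
measurements, covariates, truth = synth.simulate_dataset(cfg)

series = trajectory.measurements_to_series(measurements)     # split shoot trajectories
sp1 = [s for s in series if s.species_id == "sp1"]

fit = growth.LogisticGrowthModel.from_series(sp1).fit()      # mixed-effects logistic
print(fit.summary())

sen = senescence.species_senescence(sp1)                     # averaged decline profile
print(f"senescence date {sen.sen_date:.1f}, season end {sen.season_end:.1f}")
```

prints

```
Logistic growth fit: species sp1
  A mode: zero   random effects: K
  loglik -21.421   n_params 5   AIC 52.84
  parameter  estimate
          A  0
          K  19.06
          a  116.81
          b  0.14292
      sigma  0.23899
     tau_K  4.1939
  peak day 116.81   log b -1.9455   season start 109.12
senescence date 223.5, season end 243.7
```

The generating truth for this species was a = 117.3, b = 0.137,
K = 19.75: the inflection day is recovered within half a day and the
final size within 4 %, with the K-only random-effect structure correctly
selected (the generator draws shoot-level K_i around K_true).  The
senescence date and season end correspond to the 50 % and 25 % crossings
of the species' decline curve; season length is season end − season
start (here ≈ 135 d, an early-senescing species).

The same pipeline runs from a shell:

```bash
phenoseason all -c config.yaml      # simulate → extract → analyze → sem
```

writing `measurements.csv`, `pheno_records.csv`, `effects_*.csv`,
`pca.csv`, `sem_paths.csv` and a JSON run manifest into the configured
output directory.

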