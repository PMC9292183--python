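# tigrisim

Agent-based simulation of life-history evolution in fluctuating
environments, parameterised for the tide-pool copepod *Tigriopus
californicus*, plus the variance statistics needed to compare trait
variation between disturbance regimes.  It is aimed at evolutionary
ecologists studying how the *periodicity* of environmental disturbance —
fast tidal washes every few days versus slow cycles spanning a
generation — shapes the distribution of life-history strategies in a
population with overlapping generations.

## The model

Each individual carries a continuous developmental state `s ∈ [0, 3]`
(0 = newborn, `[0,1)` = juvenile, `[1,3)` = reproductive adult, 3 = death
of age) and two heritable traits: maturation rate μ (state units/day) and
fecundity f (offspring/day), linked by the trade-off

```
f = 1 / (4 μ)        so μ ∈ [0.02, 0.04]  ↔  f ∈ [6.25, 12.50]
```

Per day, each individual grows by μ; adults produce `Poisson(f)` newborns
whose traits are parental copies plus a small Gaussian error (SD = 1% of
the founding trait means).  Mortality has four channels: juvenile hazard
at Poisson rate `5μ`, adult hazard at rate `0.001·f`, density-dependent
removal of `N·0.001·(1 + N/250000)` random individuals per day, and
disturbance events that remove a random 30% of juveniles.  Disturbances
recur either deterministically every `period` days (3 = Fast, 14 = Slow)
or at uniformly random days with the event count matched to the
deterministic analogue.

Populations start at n = 5000 (25:1 juveniles:adults) and run for 150
days (~5–6 generations); ensembles of realisations track the
intrapopulation variances σμ² and σf² through time.  Ensembles are
compared with Welch's t-tests on log-transformed per-realisation
variances, and replicate-structured measurement tables (real or
synthetic) with a Monte Carlo permutation test whose null distribution is
resampled from variances of groups of 30 measurements pooled across all
treatments ("universal PDF", 50,000 permutations).

## Worked example

`examples/03_regime_variance_comparison.py` runs 10 desk-scale
realisations (500 founders) per deterministic regime and tests the
headline contrast:

```
Fast: 7/10 populations survive, mean endpoint var(mu) = 3.66e-06
Slow: 10/10 populations survive, mean endpoint var(mu) = 2.89e-05
Welch on log variances (Slow vs Fast): t = 5.06, df = 6.0, p = 0.0023
t > 0 with small p: Slow maintains significantly more variation.
```

Slow cycles leave roughly an order of magnitude more maturation-rate
variance standing at day 150 than Fast cycles, which purge variation
quickly (and often drive the population extinct: frequent disturbance
keeps juvenile recruitment below replacement).  The other examples cover
schedule construction, single-run transients, the permutation test, and
converting simulator endpoints into the lab measurement format.

The same machinery is scriptable from the shell:

```sh
tigrisim simulate --regime det --period 3 --seed 1 --out traj.csv
tigrisim ensemble --regime stoch --period 14 --n 100 --master-seed 1 --out-dir runs/
tigrisim synth --out campaign.csv --seed 1
tigrisim stats perm --a fast.csv --b slow.csv --trait f --seed 1
```

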