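# dyadseq

Statistical models for paired categorical behavior sequences from dyads
observed by interval sampling.

## The problem

Many observational studies of two-person systems (couples, parent–child
pairs, patient–therapist dyads) code behavior by **interval sampling**: the
observation period is split into T short intervals and, for each interval,
the occurrence (1) or non-occurrence (0) of one behavior per partner is
recorded — for example one partner's *stress communication* (SC) and the
other partner's *dyadic coping* (DC). The atomic data unit is therefore a
pair of aligned binary streams per dyad, and a study is a sample of such
pairs (typically on the order of 64 dyads × 48 intervals).

The two streams can be joined into a single sequence over four joint states
(*none / A-only / B-only / both*, called **state expansion**), which makes
the dyad a single categorical time series. `dyadseq` implements the major
analysis strategies for such data under one roof:

| Module | Question | Method |
|---|---|---|
| `seqdata` | What do the data look like? | State expansion, per-interval state distributions, entropy, transition counts |
| `logit_apim` | Does each partner's behavior depend on both partners' previous behavior? | Per-dyad saturated effect-coded logit on the 4×2 state-transition table, aggregated across dyads with t-tests (actor–partner interdependence model, APIM) |
| `mlm_apim` | Same question, with partial pooling | Multilevel logistic model with dyad-level random effects (Laplace marginal maximum likelihood) |
| `markov` | What are the dynamics of the joint state? | Basic, hidden, and mixture Markov models with EM fitting and BIC comparison |
| `om_cluster` | Are there subgroups of dyads with similar trajectories? | Optimal-matching distances (transition-rate substitution costs), Ward clustering, silhouette-based cluster-number selection |
| `design_power` | How long and how large should the study be? | Zero/low-frequency cell simulators for the transition table, exact noncentral-t and Fisher-z sample-size calculators |
| `simulate` | Ground-truth data for testing and design | Seeded generators for every model family above |

## Worked example

```python
import numpy as np
import dyadseq as dq

# A ground-truth first-order Markov process over the four joint states
# (NONE, A_ONLY, B_ONLY, BOTH) with strong persistence in BOTH:
truth = dq.MarkovModel(
    initial=[0.02, 0.03, 0.03, 0.92],
    transition=[[0.78, 0.06, 0.06, 0.10],
                [0.19, 0.33, 0.08, 0.40],
                [0.32, 0.05, 0.31, 0.32],
                [0.05, 0.08, 0.06, 0.81]],
)
data = dq.simulate_markov(truth, dq.SimulationSpec(n_dyads=64, t=48, seed=7),
                          label_a="SC", label_b="DC")

# 1. Descriptives: per-interval joint-state distribution and entropy
print(dq.describe(data).to_frame().head(3).round(3).to_string(index=False))
```

```
 interval  n_observed  p_NONE  p_A_ONLY  p_B_ONLY  p_BOTH  entropy
        1          64   0.031     0.062     0.016   0.891    0.324
        2          64   0.078     0.125     0.016   0.781    0.517
        3          64   0.109     0.203     0.047   0.641    0.717
```

```python
# 2. Aggregated logit APIM: does partner B's behavior at t depend on both
#    partners' behavior at t-1?
agg = dq.aggregate_logit(data, target="B")
print(agg.to_frame().round(3).to_string(index=False))
```

```
parameter  mean    sd      t  df     p  odds_ratio
       b0 0.242 0.548  3.532  63 0.001       1.274
  b_actor 0.876 0.372 18.832  63 0.000       2.402
b_partner 0.643 0.430 11.974  63 0.000       1.903
    b_ixn 0.011 0.378  0.229  63 0.820       1.011
```

```python
# 3. Basic Markov model and conditional actor/partner effects
model = dq.fit_markov(data.state_sequences())
eff = dq.conditional_effects(model)
print(np.round(model.transition, 2))
print(f"actor effect for A: {eff.actor_a_given_b_absent:.2f} (B absent), "
      f"{eff.actor_a_given_b_present:.2f} (B present)")
```

```
[[0.76 0.07 0.06 0.11]
 [0.19 0.34 0.07 0.4 ]
 [0.29 0.05 0.33 0.33]
 [0.05 0.08 0.05 0.81]]
actor effect for A: 0.74 (B absent), 0.90 (B present)
```

```python
# 4. Multilevel logistic APIM: choose the random-effect structure by BIC
rec = dq.build_long(data)
best, table = dq.select_random_structure(rec, candidates=[(), ("intercept",)])
print(table.round(1).to_string(index=False))
```

```
random_spec  loglik  n_free_params    bic  converged error
     (none) -2650.2              8 5333.6       True
  intercept -2642.9              9 5323.2       True
```

```python
# 5. Optimal-matching clustering with silhouette-based k selection
solution = dq.silhouette_select(dq.distance_matrix(data))
print(f"chosen k = {solution.chosen_k}, "
      f"mean silhouette = {solution.silhouette_mean[solution.chosen_k]:.3f}, "
      f"reasonable structure: {solution.reasonable_structure}")

# 6. Study planning: sample size for a one-sample t-test on aggregated betas
print(dq.sample_size_t(dq.PowerQuery(effect=0.5)))
```

```
chosen k = 2, mean silhouette = 0.220, reasonable structure: False
{'n_total': 34}
```

(The simulated single-group data correctly show no reasonable cluster
structure, and a medium effect of d = 0.5 needs 34 dyads at 80% power.)

## Command-line interface

Every analysis is also available as a `dyadseq` subcommand operating on
wide-format CSV/TSV files (one row per dyad, columns `a_1..a_T`, `b_1..b_T`,
terminal blanks = dropout):

```bash
dyadseq describe  --input data.csv --out results/
dyadseq logit     --input data.csv --target B --constant 0.5 --out logit.json
dyadseq mlm       --input data.csv --random intercept,ae,pe --out mlm.json
dyadseq markov    --input data.csv --out markov.json
dyadseq hmm       --input data.csv --k 2 --mask mask.yaml --out hmm.json
dyadseq mixture   --input data.csv --k 2 --out mixture.json
dyadseq cluster   --input data.csv --out cluster/
dyadseq simulate  --model markov --params params.yaml --n 64 --t 48 --out sim.csv
dyadseq design estfreq --probs probs.yaml --t 48
dyadseq design esttime --probs probs.yaml --tolerance 0.5
dyadseq power t --d 0.2
dyadseq power correlation --r 0.3
```

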