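# foragekit

Sequential choice modelling of human visual foraging.

In a foraging task a participant clears a display of ~40 selectable targets
of two classes, one tap or click at a time. `foragekit` treats each trial
as **sampling without replacement**: at every step each remaining item `i`
gets a weight

```
w_i = g(b_class·t_i + b_stick·m_i) · exp(−σ_d·d_i) · exp(−σ_θ·θ_i),
p_i = w_i / Σ_j w_j
```

where `t_i` flags class A, `m_i` flags a class repeat, `d_i` is the
distance from the last selection, `θ_i` the normalized change of heading,
and `g` the logistic function. The four biases — class salience (`pA`),
stick/switch (`pS`), proximity (`bP`) and direction momentum (`bM`) — are
estimated per participant by maximum likelihood, and the fitted model is
evaluated *target by target*: can it predict which item is picked next?
Where the first pick lands is modelled separately with per-participant beta
distributions or a shared two-component beta mixture (top-left-corner mode
vs. diffuse central mode, with a per-participant corner weight λ).

The package is for researchers in visual cognition and foraging behaviour
who want to fit these biases to trial data, simulate foragers with known
parameters, and quantify prediction accuracy and calibration against the
10.9% uniform chance baseline of a 40-target trial.

## Worked example

```python
import numpy as np
from foragekit import (
    ForagingParams, SimulationScenario, simulate_dataset,
    fit_foraging_params, step_through_dataset, participant_accuracy,
    chance_baseline,
)
from foragekit.simulate import ParamPopulation

# simulate 6 participants x 10 trials of 40 targets with known biases
scenario = SimulationScenario(
    n_participants=6, trials_per_participant=10, n_per_class=20,
    populations={"feature": ParamPopulation(
        mean=ForagingParams(0.5, 1.0, 5.0, 0.5),
        sd=ForagingParams(0.2, 0.3, 1.0, 0.2))},
    seed=42,
)
dataset, truth, _ = simulate_dataset(scenario)

# refit one participant from their trials alone
pairs = dataset.pairs_by_participant()["p001"]
fit = fit_foraging_params(pairs, seed=0)
print({k: round(v, 2) for k, v in fit.params.to_dict().items()})
print({k: round(v, 2) for k, v in fit.standard_errors.items()})

# step through every trial with the fitted biases
records = step_through_dataset(dataset, {p: fit.params for p in dataset.participants})
print(round(float(participant_accuracy(records).mean()), 3),
      "vs chance", round(chance_baseline(40), 3))
```

prints

```
{'b_class': 1.27, 'b_stick': 0.46, 'sigma_d': 4.51, 'sigma_theta': 0.36}
{'b_class': 0.71, 'b_stick': 0.46, 'sigma_d': 0.29, 'sigma_theta': 0.22}
0.293 vs chance 0.109
```

— participant `p001`'s generating biases were (b_class 0.68, b_stick 0.99,
σ_d 4.82, σ_θ 0.36), so every estimate from these 10 trials lands within
about one standard error of its true value, and the fitted model predicts
the next target ~2.7× better than uniform guessing.

The same pipeline is available from the shell:

```sh
forage simulate --participants 6 --trials 10 --seed 42 --out data.csv
forage fit      --data data.csv --seed 0 --out fits.json
forage evaluate --data data.csv --params fits.json --out summary.json
forage fit-initial --data data.csv --model mixture --out mixture.json
forage split    --data data.csv --fraction 0.5 --seed 1 \
                --train-out train.csv --test-out test.csv
```

See `docs/methods.md` for the model, the fitting procedures, what the
synthetic-data generator does and does not emulate, and numerical choices.

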