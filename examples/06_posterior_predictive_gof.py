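"""Item-level goodness of fit by posterior-predictive simulation.

Conditional on the filtered state trajectory, simulate many measurement
series and score each item's mean squared error against the observed data
(on the integer category scale for ordinal items). Lower MSE = the item is
better explained by the fitted state process; the SD quantifies simulation
noise in the index.
"""

from ordssm import (
    SimCondition, make_condition_dataset, posterior_predictive_item_mse, preset_desk, fit,
)

cond = SimCondition(T=150, items_per_state=3, J=7, AR=0.7, CR=0.25,
                    thresholds="offset", replicate_seed=21)
traj, y, model = make_condition_dataset(cond)

res = fit(y, model, preset_desk(seed=21, estimate_measurement=False))
from ordssm.mif2 import model_at
fitted_model = model_at(res.averaged_estimate, model)

mean_mse, sd_mse = posterior_predictive_item_mse(
    y, fitted_model, res.A, n_sims=200, seed=5,
    filtered_states=res.final_filter.filtered_means,
)
for it, m, s in zip(model.items, mean_mse, sd_mse):
    print(f"item {it.item_id}: MSE {m:.3f} (SD {s:.3f})")
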