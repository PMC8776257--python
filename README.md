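# btspsim

Simulation and analysis of **bidirectional behavioral-timescale synaptic
plasticity (BTSP)** in hippocampal place cells: the weight-dependent
learning rule driven by eligibility traces and plateau-evoked
instructive signals, the CA3→CA1 place-field voltage-ramp model, a
bounded stochastic parameter-fitting procedure, and a goal-directed CA1
network in which feedback inhibition gates stochastic plateau emission.

The package is for computational neuroscientists who want a tested,
seeded, fully synthetic implementation of this model family: every
input the pipeline consumes (run trajectories, induction protocols,
"recorded" cells with known ground truth, calibration targets) is
generated by code, so all stages run without downloads.

## The model

Each synapse `i` carries an eligibility trace driven by presynaptic
firing, and all synapses share an instructive signal driven by dendritic
plateau potentials; both decay exponentially over seconds:

    τ_ET dET_i/dt = −ET_i + λ_ET R_i          τ_IS dIS/dt = −IS + λ_IS P

Their overlap drives saturable potentiation and depression through
sigmoidal gains `q±` in a two-state kinetic scheme of finite synaptic
resources:

    dW_i/dt = (W_max − W_i) k⁺ q⁺(ET_i·IS) − W_i k⁻ q⁻(ET_i·IS)

so low-weight synapses potentiate, high-weight synapses depress, and
each pairing timing has a stable equilibrium weight
`W_eq = W_max k⁺ΔQ⁺ / (k⁺ΔQ⁺ + k⁻ΔQ⁻)`.  The subthreshold voltage ramp
of a CA1 cell is a weighted sum of 200 spatially tuned CA3 inputs on a
185 cm circular track, binned into 100 spatial bins.  See
`docs/methods.md` for the full account, parameter tables, and known
limitations.

## Worked example

```python
import numpy as np
from btspsim import (InductionProtocol, make_input_population,
                     make_synthetic_cell, make_trajectory)
from btspsim.network import network_rule_params
from btspsim.ramp import calibrate_scaling

pop = make_input_population()            # 200 inputs, 6σ = 90 cm, 40 Hz
c, sigma_w = calibrate_scaling(pop)      # 6 mV / 108 cm reference field
cell = make_synthetic_cell(
    network_rule_params(), pop, None,
    InductionProtocol(plateau_position=120.0),
    make_trajectory(n_laps=3), c=c, sigma_w=sigma_w)
print(round(cell.final_ramp.amplitude, 2),
      round(cell.final_ramp.peak_position, 1))
```

prints `8.02 108.2`: three laps with one 300 ms plateau per lap at
120 cm turn a silent cell into a place cell with an 8 mV ramp peaking
just before the plateau site — the asymmetric, predictively shifted
field that BTSP produces.

The numbered scripts under `analysis/` run the full study pipeline and
write their tables to `results/`:

| script | what it does |
|---|---|
| `01_calibrate_ramp_model.py`   | voltage scale of the linear ramp model (prints `amplitude 6.000 mV, width 108.00 cm`) |
| `02_single_spike_heatmaps.py`  | ΔW over (delay × initial weight) for the rule and its variants |
| `03_calibrate_network_rule.py` | stochastic search calibrating the 9 rule parameters to the synthetic target ramps |
| `04_fit_synthetic_cells.py`    | parameter-recovery experiment on synthetic recordings |
| `05_network_session.py`        | 25-lap goal-directed session of the 500-neuron network, place-field census |
| `06_delta_vm_analysis.py`      | ΔVm quantifications: time base, half-width vs speed, asymmetry, GP surface |

For example `python analysis/05_network_session.py` reports, per seed,
the plateau counts per lap falling from ~28 toward ~2 as feedback
inhibition rises, the number of neurons that acquired place fields
during novel exploration, the goal over-representation index (>1) after
the goal phase, and the position of the population-activity peak
relative to the goal.

A thin CLI mirrors the main entry points
(`btsp rule-heatmap`, `btsp calibrate`, `btsp network`).

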