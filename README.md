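# rlsm — reinforced liquid state machines

`rlsm` implements a reinforced liquid state machine (RLSM): a deep
reservoir-computing architecture for event-based classification in which
two spiking reservoirs ("liquids") are joined by a winner-takes-all (WTA)
layer whose input synapses learn with reward-modulated spike-timing-
dependent plasticity (R-STDP). It is aimed at researchers in
computational neuroscience and neuromorphic computing who want to study
how global reward signals can steer local, biologically plausible
learning in spiking networks — without backpropagation.

## The model

Spiking input (e.g. the Spiking Heidelberg Digits, or the built-in
synthetic spoken-digit stand-in) drives a 135-neuron leaky
integrate-and-fire (LIF) reservoir,

```
tau_m dV/dt = -(V - V_rest) + R_m I(t),
```

wired on a 15x3x3 grid with distance-dependent connection probability
`P(d) = C_xy exp(-(d/lambda)^2)` and an 80/20 excitatory/inhibitory
split. The reservoir projects all-to-all onto the excitatory neurons of
a WTA layer (lateral inhibition keeps its activity sparse), which in
turn drives a second reservoir read out by multinomial logistic
regression — the only conventionally trained component.

The reservoir->WTA weights learn with a three-factor rule:

* presynaptic trace: `dx_pre/dt = -x_pre/tau_pre + sum_f delta(t - t_f)`
* local update on a postsynaptic spike:
  `dw_local = eta (x_pre - x_tar) (w_max w)^mu`
* synaptic scaling: each winner's afferent sum is renormalized to `alpha`
* eligibility trace: `de/dt = -e/tau_trace + dw_local`
* global reward, once per sample: `dw_feedback = r * e_trace`

Three reward modes are compared. `none` is the unsupervised baseline.
`forgiving` reinforces (`dw = k e_trace`) only when the readout's
prediction matches the label. `strict` additionally shrinks all plastic
weights by `-gamma w` (with `gamma << eta`) on a miss, letting the layer
forget wiring that backed wrong answers.

Training follows a two-phase protocol: the first half of the (shuffled)
training samples run unsupervised and fit the readout as a rough
estimator; the second half runs with per-sample reward updates driven by
that frozen readout. Accuracy distributions over seeds are compared
between modes with the Mann-Whitney U test.

## Worked example

```python
import numpy as np
from rlsm import SyntheticSpec, default_config, run_batch

spec = SyntheticSpec(n_classes=3)           # 3 classes, 70 channels, 300 ms
cfg = default_config(synthetic=spec, seeds=tuple(range(6)))
batch = run_batch(cfg, modes=["none", "forgiving", "strict"])
for mode, s in batch.summary["modes"].items():
    print(f"{mode:10s} mean accuracy {s['mean_accuracy']:.3f}")
```

prints (about a minute per mode on one CPU):

```
none       mean accuracy 0.633
forgiving  mean accuracy 0.689
strict     mean accuracy 0.689
```

Both feedback modes beat the unsupervised baseline on the synthetic
task; `strict` tracks `forgiving` closely because `gamma` is deliberately
tiny relative to the reinforcement. The same comparison runs from the
shell:

```
rlsm run --feedback none --feedback forgiving --seeds 0..19 --out results/
```

which writes `results.tsv` (one row per run), per-run confusion
matrices, and `summary.json` with per-mode statistics and pairwise
Mann-Whitney p-values. `rlsm data synth` / `rlsm data downsample`
generate and downsample datasets in the SHD HDF5 layout; training on the
real SHD files works via `--data shd:train.h5:test.h5` (700 channels are
reduced to 70 by keeping every 10th).

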