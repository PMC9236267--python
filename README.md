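# stdplocus

Single-neuron simulations of **where** long-term spike-timing-dependent
plasticity (STDP) is expressed: presynaptically — as changes in vesicle
release probability and hence in short-term synaptic dynamics — or
postsynaptically, as changes in quantal amplitude.

Most learning models express plasticity as a bare weight change, which
implicitly assumes purely postsynaptic expression. This package separates
the synaptic weight into a presynaptic factor `P` (baseline release
probability) and a postsynaptic factor `q` (quantal amplitude), `W = P·q`,
and lets the same STDP rule write its changes into `P`, into `q`, or into
both, so that the functional consequences of the locus of expression can be
compared under matched total weight changes. It is aimed at computational
neuroscientists studying synaptic plasticity and learning.

## Model

One postsynaptic point neuron — conductance-based leaky integrate-and-fire
(LIF) or adaptive exponential integrate-and-fire (AdEx) — receives `n`
excitatory Poisson inputs. Transmission at each synapse is one of:

* pure weight: conductance increment `P·q·q_max`;
* stochastic release over `N = 5` independent sites,
  `k ~ Binomial(N, P)`, increment `(k/N)·q·q_max`;
* Tsodyks–Markram short-term plasticity (τ_D = 200 ms, τ_F = 50 ms):
  per-spike release probability `p = p_v·r` fluctuating around the
  baseline `P`, a mostly depressing synapse.

Long-term plasticity is either the additive pair rule

    F(Δt) = c_pot · exp(Δt/τ)    Δt < 0   (pre before post)
            c_dep · exp(−Δt/τ)   Δt ≥ 0

with τ = 20 ms, c_pot = 0.005, c_dep = −0.00525, whose raw increment `d` is
expressed at a configurable locus with matched total weight change
(`Δq = d`, `ΔP = d`, or the shared root of `(P+Δ)(q+Δ) − Pq = P·d`), or a
biologically tuned rule with separate pre- and postsynaptic components
(traces `x⁺, y⁺, y⁻`; presynaptic LTP/LTD at pre spikes, postsynaptic LTP
with heterosynaptic scaling at post spikes) whose constants were fitted to
neocortical layer-5 pyramidal connections.

Two learning paradigms are built in: **latency** (repeated volleys of
delayed input bursts; learning shortens the postsynaptic first-spike
latency) and **correlation** (continuous stimulation with a correlated
input subgroup that is selectively potentiated), plus a pre-vs-post
**competition** scenario under a fixed summed weight and a **frequency
scan** that scores how well correlated inputs can be read off the learned
weights.

## Worked example

```python
from stdplocus import preset_config, run_latency_experiment

cfg = preset_config("latency", "reduced", mechanism="stochastic",
                    locus="both", n_trials=100)
res = run_latency_experiment(cfg, seed=1)
m = res.metrics
print(f"mean latency, first 10 trials: {m.latency[:10].mean():6.1f} ms")
print(f"mean latency, last 10 trials:  {m.latency[-10:].mean():6.1f} ms")
print(f"response duration, trial 1 -> trial 100: "
      f"{m.duration.iloc[0]:.1f} -> {m.duration.iloc[-1]:.1f} ms")
print(f"final mean weight, early inputs: {m.mean_W_early.iloc[-1]:.3f}")
print(f"final mean weight, late inputs:  {m.mean_W_late.iloc[-1]:.3f}")
```

prints

```
mean latency, first 10 trials:  -10.5 ms
mean latency, last 10 trials:   -14.2 ms
response duration, trial 1 -> trial 100: 47.7 -> 31.8 ms
final mean weight, early inputs: 0.309
final mean weight, late inputs:  0.001
```

Latency is measured relative to the mean of the input delay distribution:
over 100 trials the response starts ~4 ms earlier and sharpens (shorter
burst), because inputs that fire early in the volley are potentiated while
late inputs are depressed toward the weight floor — the classic
latency-reduction outcome of additive STDP.

The same scenarios are available from the shell:

```
stdplocus latency --seed 1 --out results/latency --preset reduced
stdplocus correlation --config my_config.yaml --out results/corr
```

Each run writes `metrics.csv`, `weights.csv`, `post_spikes.csv`,
`config_used.yaml` and a `manifest.json` sufficient to reproduce it.

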