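# smkin

Analysis and simulation toolkit for real-time single-molecule fluorescence
measurements of transcription initiation: how long does RNA polymerase
(RNAP) take to unwind promoter DNA after binding, and when does its mobile
"clamp" lock shut around the unwound DNA?

The package is aimed at single-molecule TIRF practitioners. It implements,
as a tested and reusable pipeline, the two read-outs used to answer those
questions:

* **smUIFE** (single-molecule unwinding-induced fluorescence enhancement):
  a Cy3 probe in the promoter reports local DNA unwinding as a roughly
  two-fold intensity step (~200 → ~450 photon counts/frame).
* **ALEX smFRET**: a donor/acceptor pair across the RNAP active-centre
  cleft reports the clamp conformation through the apparent FRET efficiency
  `E* = I_DA / (I_DD + I_DA)`, stepping from ~0.40 (closed clamp) to ~0.48
  (locked clamp).

## The model

After binding, a molecule traverses *m* sequential, exponentially
distributed sub-steps before the signal transition. With the default
*m* = 2 (lifetimes t₁, t₂), the waiting time from binding to the
transition has the peaked density

```
f(x) = (exp(-x/t1) - exp(-x/t2)) / (t1 - t2),   mean = t1 + t2
```

The pipeline recovers this by: trajectory curation (brightness, multiple
binding events, blinking, multi-step photobleaching filters) → global
maximum-likelihood Gaussian-emission HMM idealization (3 states for
intensity traces on I_Cy3\* = I_Cy3/1000; 2 states for E\* traces) →
trajectory-shape classification (Class I: no transition; Class II:
low → high transition; Class III: starts high; Class IV: transient
open-clamp excursions, FRET only) → Class-II dwell extraction → least-
squares fit of the binned dwell histogram to `y = A (e^(−x/t1) − e^(−x/t2))`,
reporting the total t₁ + t₂ (an unbinned maximum-likelihood fit is computed
as a cross-check). Individual sub-step lifetimes are weakly identified;
only the total is treated as reliable.

A synthetic-data module generates ground-truth-labelled UIFE/ALEX
trajectories (and optional TIRF movie stacks) with this kinetic structure,
and a localization module (spot detection, 2-D Gaussian fitting,
background-corrected trace extraction, ALEX de-interleaving) closes the
loop from movies back to traces.

## Worked example

```python
from smkin.pipeline import RunConfig, run_scenario

report = run_scenario(RunConfig("lacCONS_plus2", seed=1, n_traces=300))
print(round(report["t_total_s"], 2))          # 7.17
print(report["class_fractions"])              # {'I': 0.0033..., 'II': 0.9966...}
print([round(s["mean"], 1) for s in report["state_summary"]])
                                              # [0.1, 200.0, 449.7]
print(round(report["enhancement_ratio"], 2))  # 2.25
```

This simulates 300 Class-II trajectories for the consensus-promoter
scenario (sub-steps 3.0 s + 4.5 s, levels 200/450 counts, 50 ms frames,
Gaussian noise sd 25 counts), runs the full pipeline, and recovers a total
pre-unwinding time of 7.17 s against the generator's 7.5 s, intensity-state
means of 200.0 and 449.7 counts (2.25-fold enhancement), with nearly all
trajectories correctly classified Class II (a few are censored by
photobleaching and fall into Class I).

The same pipeline is exposed as a CLI:

```
smkin run --scenario fret_lacCONS --n-traces 300 --seed 1 --out out/fret
smkin simulate --scenario gc_plus2 --n-traces 100 --seed 2 --out out/sim
smkin compare out/a/report.json out/b/report.json
```

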