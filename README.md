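# hexawalk

A decentralized, reactive controller for six-legged (stick-insect-like)
walking, implemented as a tested kinematic simulator with analysis tools.

## The problem

How do insects coordinate 18 leg joints into stable walking — forward and
backward, over steps, after losing legs — without any central pattern
generator?  The model implemented here answers: they largely don't
coordinate them centrally at all.  Each leg runs its own controller with
two procedures, *swing* (lift and reposition the leg) and *stance* (carry
and propel the body), selected by a small recurrent network of
*motivation units* (low-pass, piecewise-linear neurons under
winner-take-all coupling).  Legs influence each other only through

* **coordination rules 1–5**: local signals between neighbouring legs
  that shift the receiver's lift-off threshold (the posterior extreme
  position, PEP; rules 1–3), transmit the sender's foothold as the swing
  target (the anterior extreme position, AEP; rule 4), and share load
  (rule 5); and
* **the mechanics**: all legs on the ground are coupled through the body
  and the substrate — the "loop through the world".

The wave, tetrapod and tripod "gaits" — really a continuum parameterised
by walking velocity — emerge from these local interactions, as do
recovery from disturbances, tolerance of amputations, and backward
walking.  The package is aimed at researchers in computational
neuroethology and bio-inspired robotics who want a reproducible,
scriptable implementation of this architecture.

Key quantities, in the field's notation: a leg cycles between its AEP
(touchdown) and PEP (lift-off), a step of 0.3 m by default; rule 2 is
active 270 ms after the sender's touchdown for 50 ms; rule 1's delay and
rule 3's position threshold are decreasing functions of velocity; during
stance the α (protraction/retraction) and γ (flexion/extension) joints
run under positive velocity feedback while β (levation/depression) holds
body clearance.

## Worked example

```python
import hexawalk as hw
from hexawalk.gait_analysis import (
    podogram_from_trace, stance_count_profile, classify_gait,
    extract_step_events, delay31_vs_period,
)

trace = hw.simulate(hw.default_config(v_commanded=0.25, duration=30.0, seed=1))
podo = podogram_from_trace(trace)
counts, min_stance = stance_count_profile(podo)
df, summary = delay31_vs_period(extract_step_events(trace))
print(f"distance {trace.body_x[-1]:.2f} m, min stance {min_stance}, "
      f"gait {classify_gait(podo)}")
print(f"delay 3-1 {summary['delay_mean']:.2f} +/- {summary['delay_sd']:.2f} s "
      f"at period {summary['period_mean']:.2f} s")
```

prints

```
distance 7.50 m, min stance 4, gait tetrapod
delay 3-1 1.20 +/- 0.31 s at period 1.84 s
```

i.e. at 0.25 m/s the walker covers the commanded distance in a tetrapod
pattern (at least four legs always grounded), and a hind leg's swing is
followed by the ipsilateral front leg's swing after a delay of about
1.2 s — the roughly velocity-independent delay whose interplay with the
varying step period produces the gait continuum.  The same can be run
from the shell:

```bash
hexawalk simulate --velocity 0.25 --duration 30 --seed 1 --out-dir run_out --plot
hexawalk scenario gait_sweep --out-dir sweep_out
```

which writes a per-tick trace, step events, a plain-text podogram, the
coordination-shift log, summary metrics and a reproducibility manifest
(plus figures with `--plot`).

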