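# escapekin

Escape-response kinematics of desert rodents under simulated predator
attack.

Bipedal kangaroo rats (*Dipodomys*) evade single-strike predators such as
rattlesnakes and owls far better than most sympatric quadrupedal rodents,
and rapid vertical leaping is the prime suspect. `escapekin` is a tested,
reusable pipeline for the field experiment that probes this: a spring-loaded
strike simulator fires a cork at an animal at snake-strike speed while a
high-speed camera records its escape, and each trial yields either a jump
(scored by displacement and hang time) or a scramble. The package covers
the full analysis chain for six species — three kangaroo rats (DIME, DIDE,
DISP), the desert pocket mouse (CHPE), the white-throated woodrat (NEAL)
and the California ground squirrel (OTBE) — and includes a synthetic trial
generator with the statistical structure of the field data, so everything
runs end to end with no external data.

## The model

A jump is treated as level-ground projectile motion. From the horizontal
displacement *d* (m) and airborne time *t* (s):

```
v_h = d / t                 v_v = g t / 2          (g = 9.8 m s^-2)
speed = sqrt(v_h^2 + v_v^2)
angle = atan(v_v / v_h) * 180 / pi
height = v_v^2 / (2 g)
```

Performance metrics are size-corrected by regressing log(metric) on
log(body mass) over the pooled species and keeping the residuals
("overall performance"). Species are then compared with:

* a one-factor **PERMANOVA** (pseudo-F on Euclidean distances of the
  unit-standardized residuals, 999 label permutations, p = (#{F\* >= F}+1)/(n+1));
* **one-way linear models** with **Tukey HSD** pairwise tests
  (Tukey–Kramer SE for unequal n) and a compact letter display for raw
  reaction and take-off times;
* a **logistic regression** of jump probability on reaction time and a
  jump-vs-scramble take-off comparison within species that show both modes.

Censoring rules mirror the field protocol: trials where the animal was hit
by the cork, reacted before the cork moved, or the video was unusable are
excluded from timing analyses; scrambles, off-screen landings and poor
video are excluded from performance analyses.

## Worked example

```
python examples/03_full_analysis.py
```

simulates 50 trials per species from the packaged field-estimated profiles
and runs the full analysis. Output:

```
overall jump performance (size-corrected, ['CHPE', 'DIDE', 'DIME', 'DISP']): pseudo-F_3,126 = 1.49, p = 0.177
  -> no strong multivariate separation among the jumping species

reaction_time: F_5,246 = 18.2, p = 2.3e-15; Tukey letters {'CHPE': 'b', 'DIDE': 'c', 'DIME': 'bc', 'DISP': 'b', 'NEAL': 'c', 'OTBE': 'a'}
takeoff_time: F_5,246 = 24.3, p = 7.2e-20; Tukey letters {'CHPE': 'c', 'DIDE': 'bc', 'DIME': 'b', 'DISP': 'b', 'NEAL': 'a', 'OTBE': 'a'}

DIME take-off by mode: jump 85 ms vs scramble 136 ms (F_1,40 = 10.5, p = 0.002)
DIME jump probability vs reaction time: odds ratio 0.99/ms, p = 0.80
```

Reading: after size correction the four jumping species are statistically
indistinguishable in multivariate jump performance, but species differ
strongly in reaction and take-off time — the diurnal ground squirrel (OTBE)
reacts slowest and, with the woodrat (NEAL), takes longest to leave the
attack path; letters shared between species mean no significant pairwise
difference. Within Merriam's kangaroo rat, jumping clears the strike path
roughly 50 ms faster than scrambling, while reaction time does not predict
which mode an animal chooses.

A thin CLI wraps the same calls:

```
escapekin simulate --n 50 --seed 1 --out trials.csv
escapekin analyze trials.csv --out report.json
escapekin summarize trials.csv
```

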