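# betaclock

A simulator for the pancreatic β-cell circadian clock coupled to glucose
and insulin, built to study what happens when the two zeitgebers that
entrain a peripheral clock — the feeding schedule and the light-entrained
SCN cue — are put in conflict, as in daytime-restricted feeding of
nocturnal rodents.

## The model

Thirteen ordinary differential equations: nine clock components (mRNA and
protein for *Bmal1*, *Per*, *Cry*, *Rev-Erb* plus the PER–CRY complex),
blood glucose, insulin, and the mRNA/protein of a generic clock-controlled
exocytosis factor (EXO); two further equations turn the feeding window
into a smooth food-intake signal.  The clock is a standard
transcriptional–translational feedback network (CLOCK–BMAL1 activates
*Per*/*Cry*/*Rev-Erb*/*Exo*; PER–CRY inhibits CLOCK–BMAL1 action; REV-ERB
represses *Bmal1*), entrained through two inputs:

* glucose activates *Per* transcription (food-entrainable arm),
* an SCN-driven neural cue, peaking in the light phase and never moving
  with food, activates *Rev-Erb* transcription (light-entrainable arm).

Insulin obeys a coincidence rule,

    d[Ins]/dt = k_i · f_glu(G) · f_exo(EXO) − d_i · [Ins]

so secretion is high only when glucose *and* the clock-driven exocytosis
capacity are high simultaneously.  Inverting the feeding schedule while
the SCN cue stays put produces the signature phenotype: *Per* phase-shifts
by nearly 12 h with the food, the rest of the clock shifts only ~8 h, the
two secretion gates de-align, and the model develops hypoinsulinemia,
hyperglycemia and a loss of the pre-meal anticipatory insulin rise.

See `docs/methods.md` for equations, parameter meanings, the calibration
procedure and known limitations.

## Worked example

```
betaclock report --out out/
```

prints the nighttime-feeding (NF) vs daytime-feeding (DF) comparison for
the shipped reference parameters:

```json
{
  "entrained": true,
  "insulin_peak_ratio": 0.62,
  "glucose_mean_ratio": 1.08,
  "coincidence_NF": 0.69,
  "coincidence_DF": 0.59,
  "anticipation_NF": 0.078,
  "anticipation_DF": -0.027,
  "rupture_NF": true,
  "rupture_DF": false
}
```

Reading this: under DF the insulin peak drops to 62% of its NF value while
mean glucose rises by 8% (the modelled metabolic syndrome); the
coincidence index — the normalized overlap of the glucose and exocytosis
gates over the day — degrades from 0.69 to 0.59; and the slope-rupture
detector finds a pre-meal anticipatory insulin rise under NF
(normalized pre-slope 0.078) but not under DF (−0.027, a falling
profile).

The same quantities are available programmatically:

```python
from betaclock import reference_params
from betaclock.experiments import inversion_experiment, cneur_scan

summary = inversion_experiment(reference_params())
table = cneur_scan(reference_params())   # phase shifts vs SCN strength
```

Other entry points: `betaclock simulate` (trajectory export),
`betaclock experiment --name {inversion,cneur-scan,small-shift,sensitivity,
architectures,adaptation}`, `betaclock synth` (seeded pseudo-experimental
time courses) and `betaclock fit` (Hooke & Jeeves calibration against a
tidy time-course CSV).

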