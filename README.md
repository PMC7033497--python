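# emgid

Surface electromyography (sEMG) as a biometric trait: when a person performs a
hand gesture, the recorded muscle-activity spectrum carries both *who* is
contracting (physiology) and *which* gesture they chose (a changeable secret
code). `emgid` implements and evaluates a gesture-based biometric system in
both of its operating modes:

- **verification** — a one-to-one claim check ("is this really subject *j*
  performing their code gesture *i*?"), scored by DET curves, equal error rate
  (EER) and area under the DET curve (AUC) under three attack scenarios
  (code secret / code leaked / true user with the wrong gesture);
- **identification** — a one-to-many search over all enrolled subjects,
  scored by rank-*k* rates and the cumulative match characteristic (CMC)
  curve.

It is aimed at biometrics and myoelectric-control researchers who want a
tested, deterministic reference pipeline. Because multi-subject sEMG
recordings are rarely shareable, the package ships a synthetic multi-subject
generator with controllable between-subject separability, so every stage is
testable end to end without access data.

## Method

Each 8-channel recording (1024 Hz, band-limited 10–500 Hz, 5-s steady
contractions, 7 repetitions per gesture) is cut into 200-ms windows every
50 ms. Per window and channel, the feature is the log mean DFT magnitude in
each of six equal-width frequency segments spanning the passband:

$$\mathrm{DFT}_i = \ln\Big[\tfrac{1}{N_i}\sum_{j=1}^{N_i} |X(f_{i,j})|\Big],\qquad i = 1,\dots,6,$$

concatenated over channels into a 48-dimensional feature vector **p**. Each
enrolled (subject, gesture) class is summarized by its training centroid
$\mu$ and a shrinkage-regularized covariance $\Sigma$, and a probe is scored
by half its squared Mahalanobis distance

$$\mathrm{Score}(p) = \tfrac{1}{2}(p-\mu)^\top \Sigma^{-1} (p-\mu)$$

(lower = more similar). In verification, per-window threshold decisions are
postprocessed by a trailing majority vote over m ∈ {1, 5, 9, 13} points; in
identification, the distances themselves are averaged over m points before
ranking subjects. Everything is evaluated with sevenfold
leave-one-repetition-out cross-validation, and summaries report median,
quartiles and mean.

## Worked example

```python
from emgid import PopulationConfig, generate_dataset, run_full_experiment

cfg = PopulationConfig(n_subjects=4, n_gestures=4, seed=11)
res = run_full_experiment(generate_dataset(cfg))

ver = res.verification
for scen in ("normal", "leaked", "self"):
    sel = ver[ver.scenario == scen]
    print(f"{scen:>6}: EER {100*sel[sel.m==1].eer.mean():5.2f}% (m=1) -> "
          f"{100*sel[sel.m==13].eer.mean():5.2f}% (m=13)")
ident = res.identification
print(f"rank-1: {100*ident[ident.m==1].rank1.mean():5.2f}% (m=1) -> "
      f"{100*ident[ident.m==13].rank1.mean():5.2f}% (m=13)")
```

prints

```
normal: EER  4.32% (m=1) ->  2.06% (m=13)
leaked: EER 10.78% (m=1) ->  5.54% (m=13)
  self: EER  0.14% (m=1) ->  0.00% (m=13)
rank-1: 95.54% (m=1) -> 98.76% (m=13)
```

Imposters who know the gesture code (leaked) are harder to reject than
imposters guessing gestures (normal); majority voting over 13 samples —
0.8 s of signal per decision — roughly halves the error rates; and
closed-set identification approaches perfect rank-1. `res` also carries the
full per-(gesture, subject, fold, scenario, m) record tables, summary
statistics, CMC curves and fold provenance; `run_full_experiment(...,
out_dir=...)` writes them as CSV plus a JSON run manifest.

The same pipeline is scriptable from the shell:

```sh
emgid simulate --subjects 4 --gestures 4 --seed 11 --out ds/
emgid evaluate --dataset ds/ --out run/
```

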