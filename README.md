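# groomacc

Quantifying social grooming (and the rest of an activity budget) in
collar-tagged animals from tri-axial acceleration.

Allo-grooming is the backbone of primate social life, but measuring who
grooms, for how long, and when has traditionally required a human observer
following one animal at a time. `groomacc` implements the full
accelerometer alternative for a terrestrial primate wearing a 40 Hz collar
logger:

1. **Feature extraction** — 16 per-second variables from the raw surge /
   sway / heave trace: smoothed static (postural) acceleration, pitch and
   roll, VeDBA and smoothed VeDBA, per-axis partial dynamic body
   acceleration, and the two largest spectral peaks per axis. The spectral
   peaks matter because giving grooming is nearly motionless *except* for a
   low-amplitude rhythmic arm movement on the surge axis — a signature that
   energy-based features alone cannot separate from resting or being
   groomed.
2. **Classification** — a 500-tree random forest over six mutually
   exclusive behaviours (resting, giving grooming, receiving grooming,
   foraging, walking, running), trained on a stratified 70/30 split with
   explicit per-tree majority voting.
3. **Activity budgets** — continuous predictions rolled up into seconds,
   proportions and independent-event counts per clock window (24 h,
   07:00–17:00 day, night), with undefined epochs reported as
   "unclassified".
4. **Validation against focal observation** — a simulated human focal
   protocol (minute-by-minute scans plus continuously timed grooming
   bouts) and Spearman / Wilcoxon comparison of focal versus
   collar-derived behaviour rates.

Field recordings with video-verified labels are not redistributable, so the
package ships a calibrated synthetic generator (semi-Markov behaviour
sequences plus per-behaviour acceleration models) that reproduces the
statistical structure of the real calibration problem; every stage of the
pipeline is exercised and tested offline against it. See
[docs/methods.md](docs/methods.md) for the model, conventions and
limitations.

## Worked example (Python)

Simulate a two-hour labelled deployment, extract features, and fit the
classifier:

```python
import groomacc as g

configs = g.default_behaviour_configs()
weights = g.balanced_transition_weights(configs)     # ~equal time per behaviour
T = g.transition_matrix_from_weights(weights)
labels = g.generate_behaviour_sequence(configs, 7200, seed=1, transition=T)
trace = g.synthesize_acceleration(labels, configs, seed=2)
features = g.epoch_features(trace, labels=labels)

model = g.BehaviourClassifier.from_dataframe(features)
results = model.fit(n_trees=200, train_fraction=0.7, seed=3)
print(results.summary())
```

Output:

```
Behaviour classifier (random forest)
==============================
                              
------------------------------
                  trees    200
        training epochs   5037
      validation epochs   2160
achieved train fraction 0.7000
        macro precision  0.992
           macro recall  0.992
------------------------------
===================================
    behaviour      precision recall
-----------------------------------
          foraging     0.997  1.000
   giving_grooming     0.995  0.985
receiving_grooming     0.994  0.975
           resting     0.963  0.991
           running     1.000  1.000
           walking     1.000  1.000
-----------------------------------
============================
top features Gini importance
----------------------------
      VeDBAs          0.1673
       PSD2X          0.0973
       VeDBA          0.0934
       PSD1X          0.0881
       PDBAz          0.0799
----------------------------
```

Smoothed VeDBA separates the active behaviours; the surge-axis spectral
peaks (PSD1X, PSD2X) are what pick giving grooming out of the three
near-stationary ones. The `results` object also exposes the confusion
matrix (`results.confusion_matrix`), per-behaviour precision/recall
(`results.precision_recall`), the split report
(`results.split.cell_fractions`) and a tree-count stability curve
(`results.stability_curve()`).

A published validation confusion matrix ships as a fixture for worked
examples without simulation:

```python
from groomacc.io import reference_confusion_matrix
from groomacc.model import precision_recall
print((100 * precision_recall(reference_confusion_matrix())).round(1))
```

## Command line

The `groomacc` command mirrors the pipeline stages. A single-individual
walkthrough:

```sh
$ groomacc simulate --duration 3600 --seed 5 --individual F01 --out-dir data
wrote 3600 s of synthetic data to data
$ groomacc featurize data/accel.csv --labels data/labels.csv --individual F01 \
      --out data/features.csv
wrote 3600 epochs to data/features.csv
$ groomacc train data/features.csv --n-trees 100 --seed 9 --out-dir out
...
        macro precision  0.995
           macro recall  0.992
...
$ groomacc budget out/classifier.pkl data/features.csv --out-dir out
wrote budgets for 1 individual(s) to out
$ head -8 out/budget.csv
individual_id,window,behaviour,seconds,proportion
F01,24h,foraging,781,0.2173066221480245
F01,24h,giving_grooming,1363,0.379243183082916
F01,24h,receiving_grooming,299,0.08319421257651642
F01,24h,resting,864,0.24040066777963273
F01,24h,running,39,0.010851419031719533
F01,24h,walking,248,0.06900389538119088
F01,24h,unclassified,6,
```

Method comparison needs several individuals with focal follows. Simulate
six, budget them together, pool the focal files, and compare:

```sh
for i in 1 2 3 4 5 6; do
  groomacc simulate --duration 21600 --seed $((i * 10)) --n-follows 6 \
      --individual B0$i --out-dir data/B0$i
  groomacc featurize data/B0$i/accel.csv --individual B0$i \
      --out data/B0$i/features.csv
done
groomacc budget out/classifier.pkl data/B0*/features.csv --out-dir group
{ head -1 data/B01/focals.csv; tail -q -n +2 data/B0*/focals.csv; } > group/focals.csv
groomacc compare --budget group/budget.csv --focals group/focals.csv \
    --out group/comparison.csv
```

```
            behaviour  spearman_rho  spearman_p  wilcoxon_statistic  wilcoxon_z  wilcoxon_p  n
0            foraging      0.371429    0.497222                 4.0   -1.362770    0.172955  6
1     giving_grooming      0.828571    0.058333                10.0    0.104828    0.916512  6
2  receiving_grooming      0.485714    0.355556                 0.0    2.201398    0.027708  6
3             resting      0.771429    0.102778                 0.0   -2.201398    0.027708  6
4             running      0.085714    0.919444                 7.0    0.733799    0.463071  6
5             walking      0.771429    0.102778                10.0   -0.104828    0.916512  6
```

(Spearman p-values here are exact permutation values; rare behaviours such
as running correlate poorly because minute-interval scans barely sample
them — one of the motivations for collar-based budgets in the first
place.)

## Layout

- `src/groomacc/` — library (`synthetic`, `features`, `model`, `budgets`,
  `focal`, `io`, `cli`), plus shipped fixtures in `src/groomacc/data/`
  (calibrated ethogram YAML and the reference confusion matrix).
- `docs/methods.md` — models, conventions, calibration and limitations.
- `tests/` — pytest suite; `tests/test_acceptance.py` tracks the
  acceptance criteria end to end.
- `scripts/acceptance.py` — standalone acceptance metrics:
  `python scripts/acceptance.py --seed 1 --out results/acceptance.json`.
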