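# hrvfatigue

Driver fatigue detection from **2-minute ECG segments** using heart-rate-variability
(HRV) features, with explicit handling of sex differences.

Long monotonous driving shifts cardiac autonomic balance: as a driver becomes
drowsy, parasympathetic influence grows, the mean RR interval lengthens and
beat-to-beat variability rises. Standard short-term HRV analysis uses 5-minute
windows, which delays any fatigue alarm; this package implements the analysis
of the minimum acceptable window — 2 minutes — end to end:

1. **Cohort simulation** (`hrvfatigue.synthetic`) — RR-interval series for a
   configurable cohort (default 9 male + 9 female subjects, 60-minute drives)
   with an alert→fatigued changepoint per subject, ~0.1 Hz (LF) and ~0.25 Hz
   (HF) autonomic modulation, optional template-QRS ECG waveforms, and a
   simulated panel of 5 per-minute expert raters with a configurable error
   rate.
2. **Signal ingestion** (`hrvfatigue.ingest`) — plain-text ECG/RR readers, a
   Pan–Tompkins-style R-peak detector (band-pass 5–15 Hz → derivative →
   squaring → 150 ms integration → adaptive thresholds, 200 ms refractory),
   and optional median-filter artifact correction.
3. **Windowing and labeling** (`hrvfatigue.windows`) — overlapping 2-minute
   windows (60 min → 59 windows at 50 % overlap); a window is *alert* /
   *fatigued* when ≥ 3 of 5 raters agree in **both** minutes (`fatigued` and
   `very fatigued` votes pooled), otherwise *discordant* and excluded.
4. **HRV features** (`hrvfatigue.features`) — the 20-feature battery per
   segment: MRR, DRR (SDNN), MHR, DRMS (RMSSD), NNN15, pNN15; Welch band
   powers PLF/PHF (absolute and normalised units), LF/HF ratio, total power;
   Poincaré SD1/SD2 and their ratio; approximate and sample entropy; DFA
   α1/α2; Grassberger–Procaccia correlation dimension D2.
5. **Group statistics** (`hrvfatigue.stats`) — mean/SD/quartiles per state
   and a hand-implemented Mann–Whitney U test (midranks, tie-corrected
   normal approximation with continuity correction, exact enumeration for
   n1+n2 ≤ 12), pooled and per sex, with direction-of-change arrows (↑/↓/NS).
6. **Classification** (`hrvfatigue.classify`) — a from-scratch CART (Gini
   impurity, midpoint thresholds, deterministic tie-breaking, no pruning),
   stratified 8:2 train/test split, confusion-count metrics
   (SEN/SPE/PPV/ACC with *fatigued* positive), and an exhaustive search over
   all C(20,2)=190, C(20,3)=1140 and C(20,4)=4845 feature subsets ranked by
   test accuracy.

## Worked example

```python
from hrvfatigue import (CohortConfig, generate_cohort, compare_states,
                        exhaustive_subset_search)
from hrvfatigue.pipeline import features_from_recordings

cohort = CohortConfig(n_male=3, n_female=3, duration_s=1200.0,
                      fatigue_onset_s=600.0, rater_error_rate=0.0, seed=11)
features, segments = features_from_recordings(generate_cohort(cohort),
                                              duration_s=1200.0)
print(segments.groupby("label").size().to_dict())

table = compare_states(features, group="all", alpha=0.01).set_index("feature")
print(table.loc[["MRR", "DRR", "MHR"], ["p", "arrow"]])

best = exhaustive_subset_search(features, k=2, seed=11)[0]
print(best.feature_subset, f"ACC {best.metrics.acc:.1f}%")
```

prints

```
{'alert': 54, 'discordant': 6, 'fatigued': 54}
                     p arrow
feature
MRR      3.380515e-19     ↑
DRR      2.320970e-18     ↑
MHR      3.380515e-19     ↓
('MRR', 'DRR') ACC 100.0%
```

Each subject contributes 19 overlapping 2-minute windows; the window
straddling the minute-10 changepoint is discordant and dropped. Fatigue
lengthens the mean RR interval (MRR ↑), raises variability (DRR ↑) and lowers
heart rate (MHR ↓), and a two-feature decision tree separates the simulated
states perfectly — the synthetic cohort has no between-subject baseline
variation, so classification is easier than on real drivers (see
`docs/methods.md`).

The same pipeline is available from the shell:

```bash
hrv-fatigue run-all --seed 1 --out runs/demo
hrv-fatigue simulate --seed 1 --out runs/cohort     # RR + vote files only
hrv-fatigue compare  --features runs/demo/features.tsv --group female
```

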