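# phasetrack

Label-free quantification of single-cell motility from phase-contrast
time-lapse microscopy, and motility-based discrimination of two cell
populations (e.g. an invasive cancer line vs. a non-malignant fibroblast
line).

Phase-contrast imaging renders spread adherent cells as a low-contrast body
surrounded by a bright halo, so no fluorescent label — and no phototoxicity
over tens of hours of 1-min-interval acquisition — is needed. `phasetrack`
turns such a stack into per-cell trajectories and motility statistics:

1. **Segmentation** — Sobel gradient magnitude, fixed-threshold
   binarization, octagonal dilation (r = 3 px), hole filling, two diamond
   erosions (r = 5 px), then convex-hull smoothing of each connected
   component. The centroid and major axis are measured on the filled hull.
2. **Tracking** — each cell found in the first frame is followed with a
   moving square region of interest sized from its previous major axis;
   the window is re-segmented every frame. Zero or ≥ 2 detected centroids
   (cell loss, division, cell–cell contact) stop the track, keeping only
   the points collected before the event. Tracks longer than 1 h are
   analysed.
3. **Motility parameters** — ten per-cell statistics: mean migration
   speed; frequency of turns below 90°/60°/30°; migration distance between
   turns below those thresholds; sum of turn angles; quiescent time; total
   migration length. The turn angle at point *i* is the angle
   θᵢ ∈ [0°, 180°] between consecutive displacement vectors **r**ᵢ and
   **r**ᵢ₊₁; a zero displacement over one interval forces θ = 0 and is
   excluded from turn counts. Time-extensive parameters are normalized to
   a 30 h window.
4. **Discrimination** — Pearson correlation matrices and Welch tests per
   group, then two-class LDA/QDA with the nearest-class Mahalanobis rule
   d²ᵢ(x) = (x − x̄ᵢ)ᵀ Sᵢ⁻¹ (x − x̄ᵢ) (pooled S for LDA), sensitivity /
   specificity / accuracy under stratified 10-fold cross-validation, and
   an exhaustive ranking of all 45 parameter pairs.
5. **Synthetic data** — a persistent-random-walk generator (wrapped-normal
   heading kernel, two-state Markov or constant speed) with a
   phase-contrast-like scene renderer, providing ground truth for every
   stage without microscopy data.

## Worked example

Simulate, track and profile a small scene from the shell:

```sh
phasetrack simulate --preset cancerlike --n 4 --duration 90 --seed 11 --out-prefix demo
# wrote demo.tif (91 frames, 4 cells)
phasetrack track --input demo.tif --edge-threshold 60 --out demo.tracks.csv
# 4 tracks seeded; stops by reason: {'end_of_stack': 4}; 4 pass the >1 h filter
phasetrack motility --tracks demo.tracks.csv --label HT-like --out demo.features.csv
# wrote demo.features.csv (4 cells)
```

The features CSV holds one row per cell; e.g. the first simulated cell
moved at 0.0150 µm/s with 380 turns below 30° per 30 h and spent 45.6 % of
the track below its own mean speed.

In Python, fit a discriminant model to two simulated populations
(two-speed-mode bursty vs. homogeneous slow) on the pair that couples turn
frequency to cumulative polarity change:

```python
from phasetrack import (cancer_like_spec, fibroblast_like_spec,
                        simulate_population, DiscriminantAnalysis)

table = simulate_population(cancer_like_spec(n_cells=50, seed=1),
                            fibroblast_like_spec(n_cells=50, seed=2))
res = DiscriminantAnalysis(table, ["freq_turns_below_30", "sum_turn_angles_deg"],
                           kind="qda").fit()
print(res.summary())
```

```
QDA discriminant analysis
==============================================
parameters : freq_turns_below_30, sum_turn_angles_deg
n positive : 50    n negative : 50
mean (pos) : [   514.     113296.4094]
mean (neg) : [ 1521.6    29391.9465]
...
resubstitution  sens 100.0%  spec 100.0%  acc 100.0%
10-fold CV      sens 100.0%  spec 100.0%  acc 100.0%
```

The strongly separated presets are classified perfectly; sensitivity is
the fraction of cancer-like cells recovered, specificity the fraction of
fibroblast-like cells, accuracy the overall rate. `res.decision_boundary`
samples the d₁² = d₂² discrimination curve for plotting, and
`phasetrack discriminate` ranks all 45 parameter pairs by cross-validated
accuracy from the command line.

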