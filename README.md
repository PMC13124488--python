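# isletca

Analysis of pancreatic-islet Ca²⁺ imaging at single-cell resolution: from
per-ROI GCaMP fluorescence traces to islet-level Ca²⁺-dynamics metrics,
binarised-coactivity networks, and functional beta-cell subpopulations
(first-responders, highly connected "hub" cells, and leader cells).

## Who this is for

Labs recording glucose-stimulated Ca²⁺ activity in intact islets with a
genetically encoded indicator (GCaMP6-class) under the standard ramp
protocol — 3 mM glucose baseline, a step to 11 mM, a step to 25 mM, and a
terminal KCl depolarisation — who have already extracted per-ROI traces
(e.g. ImageJ "Multi Measure") and want a reproducible, scriptable path from
those CSVs to quantitative dynamics and subpopulation calls. A seeded
synthetic-islet generator with planted ground truth makes every stage of
the pipeline testable without imaging data.

## The method

**Signal conditioning.** Traces are smoothed with a centred moving average
(3–15 frames) and expressed as fold change `(F − F_min)/F_min` against the
minimum recorded at 3 mM glucose. Because the Ca²⁺ baseline often fails to
return to its pre-stimulus level, oscillation analysis detrends each
section with an *adaptive baseline*: signal valleys are detected, valleys
too close to their peak (<12.5 s) or with a relative drop
`(Peak − Valley)/Peak < 0.30` are discarded, and the survivors are
connected by straight lines. Fold change is then re-expressed against that
baseline.

**Global metrics.** Area under the fold-change curve per phase (plain sum
and trapezoid rule), first-phase activation time (FP-T₂₀ — first crossing
of the 0.2 fold-change threshold after the 11 mM step), amplitude and
width, and second-phase wave statistics. A Ca²⁺ wave is a deflection
exceeding 0.2 fold change sustained for ≥2 s; frequency is the wave count
divided by the window length (15 waves / 1,200 s = 0.75 waves/min).

**Coactivity network.** Each cell's detrended fold change is binarised
(active iff > 0.2); for each pair the coactivity coefficient is

```
C_ij = T_ij / sqrt(T_i · T_j)
```

with `T_ij` the co-active time and `T_i`, `T_j` the individual active
times, so 1 = perfect coordination, 0.5 = coordinated half the time,
0 = none. Pairs are tested against a circular-rotation surrogate
(10,000 shuffles by default; vectorised via circular cross-correlation, so
this takes seconds, not hours): a pair is significantly linked when the
observed `C_ij` exceeds the surrogate mean by more than two standard
deviations. Islet connectivity `C_islet` is the mean off-diagonal
coactivity, binned into low (≤0.5), medium (≤0.75) and high (>0.75).

**Subpopulations.** Cells unresponsive to KCl are excluded. The 10% of
cells with the fastest first-phase activation (FR-T₂₀, on min-max
normalised traces) are *first-responders*. *Hubs* are either the cells
with ≥80% of their significant connections at C ≥ 0.8, or the top 10% by
significant-connection count. *Leaders* have a mean per-wave activation
latency (SCSP-T₂₀, measured inside valley-to-valley wave windows) at or
below the 10th percentile.

## Worked example

`python examples/subpopulations.py` simulates a 50-cell islet with 5
planted first-responders, 5 leaders, 5 all-wave participants and 3
KCl-dead cells, runs the full pipeline, and prints:

```
included cells: 47 / 50 (KCl-dead excluded: [47, 48, 49])
first-responders   called [0, 1, 2, 3, 4]  planted [0, 1, 2, 3, 4]  recall 1.00
leaders            called [5, 6, 7, 8, 9]  planted [5, 6, 7, 8, 9]  recall 1.00
hubs (criterion)   called [5, 6, 7, 9, 10, 11, 12, 13, 14, 17]  planted [10, 11, 12, 13, 14]  recall 1.00
islet connectivity C_islet = 0.795 (high)
```

All three planted subpopulations are recovered; leaders also appear among
the hubs because they, too, participate in every wave. `C_islet ≈ 0.8`
classifies the islet as highly coordinated, as expected for a healthy
simulated islet. The other examples print the global dynamics
(`global_dynamics.py`: 29/29 waves detected, 1.318 waves/min over the
22-min 25 mM window) and the adaptive-baseline rescue on a drifting
recording (`adaptive_baseline_drift.py`: 15/29 waves with a fixed section
baseline vs 29/29 with the adaptive one).

## Command line

```
isletca simulate --preset clean --seed 7 --out sim/
isletca analyze --traces sim/traces.csv --timeline sim/timeline.json \
    --centroids sim/centroids.csv --out results/ --seed 7
isletca report --results results/
```

`analyze` writes `global_metrics.json`, `waves.csv`,
`coactivity_matrix.csv`, `significance_mask.csv`, `cell_labels.csv`,
`edges.csv` and the resolved configuration; outputs are byte-identical
across reruns of the same config and seed.

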