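# taphomark

Quantitative analysis of bone-surface modifications for zooarchaeology and
taphonomy: cut-mark cross-section morphometrics from micro-topographic
profiles, Vickers surface micro-hardness comparison across bone classes, and
blind-test inter-analyst scoring with its full nonparametric statistics
battery — plus a synthetic-data generator so every stage of the pipeline runs
and is testable with no external data.

## Who this is for

Zooarchaeologists comparing butchery marks on aquatic (catfish, reptile) vs
terrestrial (bovid) bone, and anyone evaluating how reliably analysts locate
and diagnose surface modifications. Marks on aquatic bone are smaller and
more variable in cross-section than their terrestrial counterparts — aquatic
bone surfaces are measurably harder — and that difference degrades both
detection and inter-analyst agreement, especially under a hand lens.

## The measurements

A mark transect is an ordered (x, z) profile in micrometers crossing a single
groove. After fitting the unmodified surface as a reference line and
segmenting the groove (base, two shoulders), the package computes per
transect:

| measure | definition |
|---|---|
| 1a | breadth B / depth D (optionally normalized by the geometric mean of B, D and the two shoulder heights) |
| 1b | B × D (µm², cross-sectional size proxy) |
| 2 | B / B25, where B25 is the groove width at 25% of the depth above the base |
| 3 | higher wall height / lower wall height (≥ 1) |
| 4 | depth of the hypothetical apex where straight-line wall fits intersect, ÷ D (1.0 for an ideal V) |

and per mark (three transects), measures 5–7: the coefficients of variation
(sample sd / mean) of measures 2–4 along the mark.

Hardness uses the simplified Vickers form Hv = F/D² (load F in kgf, mean
indentation diagonal D in mm); the conventional 1.8544·F/D² variant is also
exposed. Blind-test scoring distinguishes *locating* (is a mark present in
the designated zone?) from *diagnosing* (which actor/effector made it?), and
pairs of analysts are compared by *two-way correspondence*: the percentage of
jointly answered specimens on which both give the same correct response.

The statistics kernel pins down the exact small-sample conventions the
blind-test analyses require: Mann-Whitney with midrank ties, min(U₁,U₂)
reporting, tie-corrected variance and continuity correction; Wilcoxon
signed-rank with zero differences dropped, tie correction, no continuity
correction; Kendall's tau-b; one-way ANOVA with Tukey HSD; Shapiro-Wilk;
correlation-matrix PCA.

## Worked example

```python
from taphomark import GrooveSpec, simulate_groove_profile, measure_profile, mann_whitney
from taphomark.io import table3_values

# simulate one noisy U-sectioned groove and measure it back
prof, truth = simulate_groove_profile(
    GrooveSpec(form="U", breadth=120, depth=45, shoulder_asymmetry=1.3,
               noise_sd=0.9, n_samples=512, seed=7))
m = measure_profile(prof)
print(f"breadth {m.breadth:.1f} um (true {truth.breadth:.1f}), "
      f"depth {m.depth:.1f} um (true {truth.depth:.1f})")
print(f"measure 1a (B/D) {m.measure1a:.2f}   measure 2 (B/B25) {m.measure2:.2f}   "
      f"measure 3 (wall asymmetry) {m.measure3:.2f}   measure 4 (apex ratio) {m.measure4:.2f}")

# instrument effect on locating correspondence, from the packaged blind-test table
res = mann_whitney(table3_values("locating", "included", "hand_lens"),
                   table3_values("locating", "included", "microscope"))
print(f"U = {res.statistic}, z = {res.z:.3f}, p = {res.p:.4f}")
```

prints

```
breadth 125.1 um (true 120.0), depth 47.7 um (true 45.0)
measure 1a (B/D) 2.63   measure 2 (B/B25) 1.89   measure 3 (wall asymmetry) 1.28   measure 4 (apex ratio) 1.50
U = 12.0, z = -1.921, p = 0.0547
```

The measured breadth/depth land within a few percent of the generating truth
at this noise level; the groove's U section shows in the low measure 2 (walls
bow outward, so the width at 25% depth is close to the surface breadth) and
the apex ratio well above 1. The Mann-Whitney result says hand-lens analyst
pairs agree less often than microscope pairs on whether a mark is present
(U = 12 on 10 vs 6 pairwise correspondence percentages, two-sided p ≈ 0.055).

A full pipeline is available from the shell:

```bash
taphomark all --seed 7 --out runs/demo     # simulate -> measure -> score -> hardness -> stats -> report
taphomark report --out runs/tables-only    # fixture-based statistics reproduction alone
```

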