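# Methods

This note documents the analysis conventions the package implements, the
choices made where a convention was genuinely open, what the synthetic-data
generator does and does not emulate, and the problem sizes used by the test
suite.

## Preprocessing

**Rolling-percentile baseline.** The baseline for frame *i* is the 30th
percentile of the trace values in a 300 s window centered on *i*.
Percentiles use linear interpolation between order statistics (NumPy's
default); windows shrink at the recording edges rather than padding, so no
data are fabricated at the start of multi-hour recordings. Both choices are
fixed so outputs are bit-reproducible, and the implementation is tested for
exact agreement with a naive per-frame re-computation.

**ΔF/F** is (F − F_b)/F_b, unitless (1.0 = 100%). The baseline must be
strictly positive; a non-positive baseline is an error naming the frame.

**Drift QC.** Median raw fluorescence is computed in consecutive 5-min
bins; a cell is discarded when max/min − 1 exceeds 2.0 (a >200% swing),
which catches both physical drift and the sustained fluorescence rise of
Ca²⁺ dysregulation. "More than 200% drift" admits a second reading —
deviation of any bin from the *first* bin — which is available as
`drift_reference_first_bin=True`; the max/min ratio is the default because
it is symmetric in time and robust to a noisy first bin.

## Responder detection

A (cell, event) pair is a responder when peak ΔF/F over the half-open
window [onset, onset + 5 s) exceeds **both** 1.25 and 6× the sample SD of
ΔF/F over [onset − 30 s, onset). Ligand events use a 120 s window to match
the 2-min bath application and the variable onset of GPCR cascades.
Frames inside any earlier event's response window are masked out of the
noise-SD estimate (grid mapping runs at 15 s spacing, so pre-event windows
routinely overlap the previous site's transient); if masking leaves fewer
than 3 frames the full window is used. The SD uses ddof = 1.

Family-level assignment: brush and airpuff require hits on ≥ 2 of 3
applications; thermal ramps and static filament presentations count a
single hit, because those trials probe different ramp parameters or
different skin sites and are not replicates of one another.

**Threshold calibration.** The (amplitude, σ-multiple) grid is swept
against an annotated set; each point is scored by sensitivity +
1.25 × specificity, deliberately favoring specificity (false positives are
the costlier error in responder counting). Ties break toward higher
specificity, then a higher amplitude threshold. The reported AUC is the
Mann–Whitney AUC of the peak-amplitude score, cross-checked in the tests
against concordant-pair counting. When annotations are generated under the
default thresholds, the sweep returns (1.25, 6) exactly.

**Capsaicin responders.** Mean ΔF/F over [injection + 30 s,
injection + 150 s) must exceed 1.5× the mean over [injection − 150 s,
injection − 30 s); the 30 s on each side is the imaging blind spot around
needle placement. The placement of the two 2-min windows immediately
adjacent to the blind interval is a documented choice (the convention does
not pin them down); both the window length and the blind interval are
configurable. A pre-window mean at or below 10⁻⁶ cannot anchor a ratio and
the call is flagged indeterminate rather than negative.

## Vector tuning and receptive fields

The three compared modalities sit 120° apart: heat/brush +90°,
mechanical/LT +210°, cold/HT +330° (counter-clockwise from +x). Amplitudes
are the maximum response across the family's trials, normalized per cell by
the mean of the three — a per-cell normalization, so tuning is invariant to
uniform scaling of a cell's responsiveness. Cells with no responses across
the compared modalities carry no tuning information and are excluded.
Angle standardization maps angles to signed degrees-from-axis in
(−180°, 180°] by modular equivalence (+1° and −359° are the same
direction). The per-modality preference score is (X_i − X_avg)/X_max,
bounded above by 2/3 for three modalities.

Receptive-field size is the mean responsive-site count over grid passes
(0–16); area is count × 3.75 mm² (16 sites tile 225 mm²). The injection
locus is inferred by comparing the mediolateral distribution of capsaicin
responders with the distributions of HT-driven cells at each grid column
using the first Wasserstein distance — chosen over KS or energy distance
for its robustness at the small n (≥ 5 responders) this estimate must work
with; fewer responders, or a best-vs-second-best margin below 10%, yields a
low-confidence flag.

## CICADA profiling and clustering

Profiles of ligand-responsive cells are normalized (X − X_min)/X_max —
implemented literally, so the maximum is below 1 whenever X_min > 0; the
conventional (X − X_min)/(X_max − X_min) form is available behind
`minmax_normalization` for sensitivity analysis. Non-responsive cells are
divided by their mean ligand response instead, keeping sub-threshold
structure in a comparable range without amplifying noise. Clustering is
K-means (Euclidean, 25 restarts, seeded, best inertia kept) with k = 7 by
default; because no selection rule fixes that k, `select_k` scores a
candidate range by silhouette and warns when even the best silhouette is
low. Normalized amplitudes enter K-means without further rescaling
(they already share a 0–1 scale). Labels are renumbered Ex1…Exk by
ascending median depth so Ex1 is the most superficial population; the
ordering is stable for fixed data and depths.

## Depth assignment

The structural volume is 3-D median filtered (size 3), contrast-equalized
with CLAHE applied to the volume using a kernel spanning the full z extent
(clip limit 0.01, 32-px XY tiles) — per-slice CLAHE would stretch the
noise-only slices above the tissue to mid-gray and erase the very rise the
surface fit depends on — then averaged into 10×10×1 columns. Per column,
the plateau is the mean of the deepest quartile of slices and the surface
is the first z where the profile exceeds half the plateau, refined by
linear interpolation between bracketing slices ("asymptotic increase"
operationalized as half-plateau crossing; a 4-parameter logistic fit is
available as `method="logistic"`). Columns whose plateau-to-background
contrast falls below 0.05 (normalized scale) are marked missing. ROI depth
is plane z (offsets 0/14/28 µm for the three planes) minus the local
surface z; negative depths are kept but flagged. Functional-to-structural
registration is assumed done upstream. Laminar report bins
(`lamina_boundaries_um`, default 20/40 µm) are labelled conventions, not
measured boundaries.

## The synthetic-data generator

The generator produces what the downstream stages assume about real
recordings, with every injected response recorded for recovery tests.

- **Kernel.** Difference of exponentials, rise 0.2 s / decay 1.5 s
  (GCaMP6s-like at 1 Hz sampling); ligand responses use rise 8 s / decay
  40 s to mimic second-messenger kinetics. The kernel is normalized on the
  frame grid so a frame-aligned event of amplitude A has a *discrete* peak
  of exactly A — at 1 Hz the continuous peak falls between samples, and
  without this convention amplitude-recovery tests would chase a sampling
  artifact. Protocol onsets land on integer seconds.
- **Raw F** = baseline_F × (1 + ΔF/F_true) × bleach(t), with Gaussian
  noise (SD 0.05 ΔF/F) and multiplicative exponential bleach (10%/h), so
  the rolling baseline has realistic work to do.
- **Ongoing activity** is a gamma-renewal train of small transients
  (0.25 Hz, lognormal amplitude mean 0.2 ΔF/F, interval shape 10 — the
  quasi-regular ongoing discharge of tonically driven dorsal-horn cells).
  The 150%-of-pre capsaicin rule presupposes nonzero, estimable ongoing
  activity: the low duty cycle keeps the rolling 30th percentile at the
  noise floor, and the regularity keeps 2-min activity averages tight
  enough that a planted 2× rate increase is detectable. Capsaicin-direct
  cells double their event rate for 5 min after the injection.
- **Receptive fields** are discs in grid coordinates; static stimulation
  drives the cell only at sites inside the disc. `rf_expansion` multiplies
  the disc *area* (radius × √factor), so the planted factor equals the
  expected fold-change in responsive-site count — verified numerically for
  compact RFs (radius ≈ 0.9 sites, centers away from the grid edge), where
  a planted factor of 4 yields a mean measured fold of ≈ 4. `lt_gain`
  multiplies static-LT amplitudes in the post block only.
- **Somatotopy**: a cell's mediolateral ROI position tracks its RF column
  (SD 30 px), giving the locus-inference test a true gradient.
- **Population.** Seven archetypes loosely patterned on depth-ordered
  excitatory populations (principal ligands NKB/SP, SP, GRP/NMB, CCK,
  taltirelin, Oxo, OXT; depths 8–48 µm; one rare type at 5%), with ~25% of
  cells ligand-responsive and the rest unlabeled, and per-archetype
  capsaicin-direct probabilities (0.44 in the most superficial archetype
  vs 0.08 elsewhere). Amplitudes carry 10% lognormal jitter. Several
  archetypes deliberately sit *below* the 1.25 responder threshold
  pre-injection (static-LT ≈ 0.9) so that planted LT gains convert
  non-responders into responders, the signature the sensitization report
  must detect.
- **Structural volumes**: low plateau above the surface, sigmoidal rise of
  width 1 µm at it, speckled Gaussian cell bodies below (kept ≥ 4 radii
  under the surface so speckle cannot masquerade as the surface), plus
  Gaussian noise; the true surface map is returned exactly.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: movement and z-drift (QC is tested only against
synthetic drift/bleach), neuropil contamination, indicator nonlinearity and
saturation, inhibition or network correlations between cells, trial-to-trial
adaptation, thermal-ramp kinetics (thermal events are impulses like the
rest), and real annotator behavior (annotations are truth plus independent
label flips).

## Problem sizes and tolerances

The suite runs the full measurement path on: 40 cells × 128 grid events
(detection sensitivity ≥ 0.90 / specificity ≥ 0.95 on suprathreshold
2.0 ΔF/F responses; RF recovery within one site), 200 mixed-archetype
cells through the complete protocol (LT-gain recovery: Δ% LT responders in
the target archetype only; tuning shift toward the LT axis), 200
compact-RF cells (4× area expansion recovered within ±25%), 500 cells for
the capsaicin classifier (sensitivity ≥ 0.9, false-positive rate ≤ 0.05 at
a planted 2× effect), 300 cells in 3 ligand archetypes (K-means ARI
≥ 0.95), and 64×64×40 structural volumes (surface mean |error| ≤ 1 z-step).
Oracle-equivalence checks (rolling percentile, AUC) are exact to 1e-12.
These sizes are the package's benchmark conditions; effects reported from
real experiments at other scales inherit only the *correctness* guarantees,
not the specific error rates.

## Known limitations

- The responder rule is threshold-based; graded sub-threshold modulation
  (e.g. amplitude changes without threshold crossings) appears only through
  the tuning vectors, not the responder counts.
- The capsaicin rule compares only two fixed 2-min windows; slow or delayed
  sensitization outside them is invisible.
- Depth assignment assumes the structural and functional volumes are
  already registered (identity transform).
- `select_k` uses the silhouette criterion only; it is a diagnostic, not a
  substitute for biological validation of cluster count.
- Statistical testing of the reported deltas (mixed models, FDR) is out of
  scope by design: the pipeline exports tidy tables for external stats
  packages.
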