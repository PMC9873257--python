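# Methods

This note documents the quantitative procedures the package implements, the
assumptions behind them, the choices made where the underlying protocols are
silent, and what the synthetic generators do and do not emulate.

## Behavioral quantification

**Kinematic windows.** Trajectories are per-fly, per-frame series (position,
forward velocity in mm/s, angular velocity in deg/s) at 30 frames/s, produced
by an upstream tracker. Velocities are binned by arithmetic mean over 10-frame
(0.33 s) windows; a trailing partial bin is dropped, so `bin_kinematics` with
bin size 1 is the identity. Onset responses average velocity over the first
1 s of light and subtract a baseline averaged over the 4 s preceding onset;
offset responses average forward velocity over the 5 s after light offset
against the same pre-onset baseline. All windows are exposed as arguments with
these values as defaults. Flies are averaged within a trial and statistics
operate on trial-level values: one trial, one data point. Lost-track frames
(NaN) are excluded from window means; a window more than 50% missing raises a
quality error rather than silently returning a biased mean.

**Quadrant assignment.** The circular arena is partitioned into four
quadrants by the coordinate axes. A fly exactly on a boundary axis is assigned
to the adjacent quadrant with the lower index; the boundary set has measure
zero, so the preference index is insensitive to this rule.

**Preference index.** PI per 1 s bin is
(# flies in the stimulated quadrants − # flies outside) / total tracked flies,
so PI ∈ [−1, 1] and is antisymmetric under swapping a quadrant mask with its
complement. Occupancy within a bin samples the bin-midpoint frame by default;
a majority-frame rule is available. The final PI averages the last five 1 s
bins of a light epoch. Learned preference requires exactly two test epochs
with complementary CS+ quadrant sets and returns the mean of the two final
PIs; for any fly whose occupancy is time-invariant and odor-independent the
two finals cancel exactly, which is the point of counterbalancing.

## Feeding microstructure

Interactions (capacitance-detected food contacts) are sips; consecutive sips
separated by at most the intra-burst gap share a burst, and bursts separated
by at most the inter-bout gap share a bout. The default thresholds (0.5 s and
2 s) are package defaults chosen to sit between the three timescales of
typical sip trains; they are not measured values and should be tuned to the
sensor. Interactions shorter than 30 ms are discarded as sensor noise.
Segmentation sorts by onset first, so it is idempotent and order-independent,
and raising either threshold can only merge clusters (counts are monotone
non-increasing). Bout intervals include their internal gaps, so bout duration
sums exceed sip duration sums; the invariant maintained instead is interval
nesting (sip ⊆ burst ⊆ bout). Closed-loop light epochs are
(contact start, +1.5 s), merged when overlapping and truncated at session
end. Cumulative feeding curves are sampled on a 1 s grid; a sip straddling
the summary horizon is truncated at the horizon. The PER suppression index
`1 − with/without` returns NaN when the without-stimulus response is zero
(the index is undefined there; some conditions genuinely produce zero PER).

## Calcium responses

ΔF/F uses the mean of the 20 frames preceding stimulus delivery as baseline
B: ΔF/F = (F − B)/B, making the series gain-invariant and zero-mean over the
baseline window by construction. Peak extraction applies a 3-frame centered
moving average to suppress single-frame noise before taking maxima: the ON
amplitude is the smoothed maximum over the 5 s stimulus window, and the OFF
amplitude is the smoothed post-offset maximum (5 s search window) minus the
raw ΔF/F value at offset, floored at zero. Referencing the offset value keeps
a sustained ON plateau from registering as an OFF transient; the floor keeps
a decaying plateau from producing a negative OFF amplitude. Habituation
profiles normalize per-trial amplitudes to trial 1 and report the
final-to-first ratio per component; a component with zero first-trial
amplitude has an undefined profile (NaN). Both trial-level and fly-averaged
use is supported — the operations take whatever trace set the caller passes.

## Effect classification

The screen compares an experimental driver line against a driver-only and an
effector-only control at three light intensities, per behavior:

1. **Gate.** A one-way ANOVA across all genotype × intensity cells of the
   behavior asks whether there is an effect at any intensity (α = 0.05). If
   every value is identical the gate reports F = 0, p = 1 (degenerate-variance
   convention). The factor structure is configurable; the default is a single
   ANOVA over all cells of that behavior.
2. **Effect size.** Per intensity, the experimental mean is compared with each
   control mean; the smaller difference in magnitude is the effect, signed by
   the shared direction. If the two comparisons disagree in sign, the controls
   straddle the experimental group and no consistent effect exists: the effect
   is 0.
3. **Classification.** The maximal effect over intensities is normalized by
   the reference line's maximal effect (the line labeling the entire
   bitter-sensing population, computed the same way against its controls).
   Classes: strong ≥ 0.8, moderate ≥ 0.4, weak below 0.4 with a passing gate,
   none when the gate fails. Normalization makes the call invariant to common
   rescaling of all measurements. A zero reference effect leaves the call
   undefined (NaN) rather than inventing a denominator.

Dunnett's many-to-one test provides per-control adjusted p-values with
family-wise error control. The experimental group is shared across the two
comparisons, so it is passed as the test's common reference group; with a
single control the procedure reduces to an unadjusted two-sample t-test. The
adjusted p is computed by randomized integration of the multivariate t
distribution, so a fixed internal random state keeps results reproducible.
Null simulation (three groups of 8, normal, 10,000 replicates) confirms both
the gate and the family-wise procedure reject at 0.05 ± 0.01.

## Connectome tracing

The traced graph is directed and weighted by synapse count, pre-aggregated to
one edge per ordered cell pair. Layer admission uses the per-edge rule: a
cell joins the next layer if it receives at least `edge_min` (default 3)
synapses from at least one source cell. A member's reported total sums only
its qualifying (≥ `edge_min`) edges from the source set; sub-threshold edges
can be included via `include_subthreshold_in_total` — the published totals do
not state which convention they use, and the default (exclude) reproduces
them. Source cells re-admitted by lateral or feedback edges are retained and
flagged. Top targets are selected either by population input
(total ≥ k, default 20, after excluding the seed cells) or as the n
largest totals with ties broken by ascending cell ID for determinism.

Motif matrices aggregate qualifying edges (default ≥ 5 synapses) between
seed-subtype groups, counting either edges or summed synapses — the published
figure is ambiguous between the two, so both modes exist. Region-projection
fractions count members whose output regions include a region, under an
ipsilateral-only or either-hemisphere rule; "(C)" suffixes in region lists
mark contralateral projections. The region catalog defaults to the
abbreviation sets of the two packaged table legends (plus AL, which appears
in the printed rows without a legend entry); unknown tokens either extend the
catalog with a warning or are rejected, per configuration. Path search
enumerates simple paths (no revisits — the reported hop counts imply this)
with at most `max_intermediates` intermediate cells and all edges above
threshold, ranked by bottleneck weight then total weight. Every operation is
checked against brute-force enumeration on random graphs of up to 50 nodes.

The two packaged tables were transcribed from the published top-3N and
top-4N summaries; checksum tests guard against transcription drift. The
percent-input column requires each cell's total input synapse count and is
reported as unavailable when that count is absent, never estimated.

## Synthetic generators

Each generator plants known effects and records them in a `GroundTruth`
record; identical seed and parameters give bitwise-identical output.

* **Arena walks** emulate stimulus-locked kinematics: speed boost
  (+4 mm/s on a 6 mm/s baseline) and turn boost (+60 deg/s) while light is
  on, and probabilistic freezing after offset (probability 0.75, duration
  30 s, frozen speed drawn from |N(0, 0.1·baseline)| since the original
  reports report freezing qualitatively; the 30 s default reflects
  suppression persisting on the order of a minute). Positions follow a
  heading random walk with a signed drift (default −0.5 mm/s) toward/away
  from the nearest lit-quadrant centroid, which yields lit-quadrant occupancy
  below 0.5 under aversive drift. Not emulated: body posture, collisions,
  wall-following, identity swaps.
* **Feeding sessions** draw sip durations and inter-event intervals from
  exponentials at three nested timescales (defaults 0.2 s / 1 s / 60 s),
  truncated so generated gaps respect the segmentation thresholds — this is
  what makes planted counts exactly recoverable on noise-free streams, and it
  means the generator cannot test threshold misspecification. Suppression is
  modeled by retaining each post-first sip on the stimulated channel with
  probability equal to the suppression factor (the first, light-triggering
  contact always occurs); the default factor 0.1 mirrors the near-complete
  suppression the assay produces.
* **Calcium trials** superimpose a sustained ON plateau and a short-latency
  OFF transient (2-frame latency, 3-frame peak plateau, exponential decay,
  τ = 2 s) on a constant baseline with Gaussian noise (2% of baseline);
  per-trial amplitudes decay geometrically (ON factor 0.6, OFF factor 0.9,
  matching ON habituating more strongly than OFF). The plateau construction
  makes planted amplitudes exact fixed points of the smoothed-peak metric on
  noise-free traces. Not emulated: motion artifacts, bleaching, indicator
  nonlinearity.
* **Circuit graphs** plant a 21-cell seed population in three subtypes
  (6 + 5 + 10), 32 third-layer and 30 fourth-layer cells with supra-threshold
  input edges, a hierarchical seed-subtype motif (≥5-synapse edges), feedback
  edges from a fraction of fourth-layer cells back to seeds, and
  sub-threshold (weight < 3) decoy edges that must not change any membership.

Recovery tolerances in the tests are 10% relative for continuous planted
effects over 100 simulated trials and exact for set-valued structure on
noise-free graphs. Problem sizes (100 trials, 10,000 null replicates,
200 oracle graphs of ≤ 50 nodes) were chosen so the full suite exercises
every recovery path at useful statistical resolution while remaining quick to
run; passing them demonstrates internal consistency of the estimators on data
matching the generators' assumptions, not robustness to the artifacts real
recordings contain.

## Known limitations

* The segmentation thresholds and the calcium peak windows are package
  defaults, not measured constants; conclusions sensitive to them should
  sweep the configuration.
* The ANOVA gate assumes homoscedastic normal cells; heavily skewed behaviors
  should be transformed upstream.
* Path search is exhaustive over simple paths and is intended for bounded
  depths (2–3 intermediates) on circuit-scale graphs, not whole-brain search.
* The hemibrain-scale populations (hundreds of third-layer cells) require the
  external connectome volume; the packaged tables cover only the published
  top populations.
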