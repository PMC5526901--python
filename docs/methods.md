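# Methods

## Problem setting

A stained PBMC sample yields 10^5–10^6 events with scatter channels
(FSC-A, FSC-H, SSC-A) and fluorescence channels (viability stain, CD3 or
a dump/lineage-exclusion mix, CD8, one or two peptide–MHC multimer
conjugates). The quantity of interest is the frequency of multimer-binding
CD8+ T cells, reported as a percentage of live single lymphocytes
(primary denominator) or of CD8+ T cells. Target populations range from
several percent down to ~0.0001%, i.e. a handful of events, so both the
gating chain and the detection rule matter.

## DAG prefiltering

Each gate step is a 2D projection plus a rectangle in analysis-scale
units. The density on the projection is a `bins`×`bins` (default 128)
histogram over the observed range padded 1% per side, smoothed with a
Gaussian of σ = 2 bin widths, and normalized to unit mass. Iso-density
contours are traced by marching squares at levels max·i/32
(i = 1..31); open contours (touching the grid border) are discarded. Among
closed contours whose vertices all lie inside the rectangle, the one with
the largest enclosed (shoelace) area is the gate; ties go to the lower
level. Events are tested by the even-odd rule with an inclusive boundary
(a tolerance of 10⁻⁶ of the polygon extent). If no contour qualifies the
rectangle itself is the gate and a warning is logged. Steps apply
sequentially, so output events are always a subset of the input and the
procedure is fully deterministic.

Numerical behavior worth knowing: with 32 levels, the lowest closed
contour around a roughly Gaussian population sits near 2.6–2.8σ and holds
≈97–98% of its mass per step; the default three-step sequence retains
≈94% of the true live single lymphocytes at >99% purity on the synthetic
samples. Because the scatter/viability channels are independent of the
marker channels in the generator (and to good approximation in real
lymphocytes), this sub-unity retention cancels in the frequency ratio and
does not bias the reported percentages. Contours traced near the density
peak are resolution-limited: the radius error of an iso-contour scales
like (level noise)/|∇density|, so innermost contours wobble even for
perfectly circular truth — gates should (and by the area rule do) come
from the outer contour family.

Scatter channels are gated on the raw linear scale; fluorescence channels
are arcsinh-transformed (default cofactor 150) first. The default
rectangles are sized for the synthetic generator's intensity scale and
are ordinary config values for real data.

## Grid-density clustering and templates

Clustering channels (default: every marker role present — CD3, dump, CD8,
multimer channels; not scatter, not viability) are min–max scaled to
[0, 1] and binned on a 16-per-axis grid. Bins holding at least
`min_density` events (default `max(5, n // 100_000)`) are dense. Each
dense bin points to its best Chebyshev-adjacent bin under the
lexicographic key (occupancy, −flat index); following the pointers to
their fixed points partitions the dense region into local density modes.
We use mode-seeking rather than plain connected components because at a
threshold low enough to keep a ~100-event population dense, the abundant
populations connect through their saddle bins into a single component; a
single seed for the whole bulk then corrupts the nearest-centroid
assignment, and the rare-population seed gets dragged into the CD8+
cluster by the refinement step. Splitting at saddles keeps one seed per
population; where populations do not touch, the two rules coincide.

Each mode's events define a seed centroid; all events (dense-region or
not) are assigned to the nearest seed (Euclidean in scaled space, ties to
the lowest index), centroids are re-estimated once from that assignment,
and a final nearest-centroid pass fixes the model, which makes stored
counts exactly reproducible by re-assignment. The cluster count is capped
(default 100, keeping the largest modes). The fitted model freezes its
normalization scale, so a template built on a subsampled multi-sample
consensus (default 250,000 events per sample) assigns any sample's events
in a well-defined metric. Extra clusters from noise modes are harmless by
construction: the annotation rule selects clusters by centroid levels, and
a spurious mode inherits the levels of the region it sits in.

The `min_density` default is a calibration against two failure modes: too
low, and stray background bins seed meaningless clusters; too high, and a
0.01% population (~80–100 events among ~8×10^5 prefiltered at 10^6
acquired) never reaches the threshold in any bin. `max(5, n // 100_000)`
keeps such populations dense (their modal bin holds ~15–50 events for the
default separation) while the gap between the multimer+ and multimer−
clusters stays empty for any plausible lognormal tail.

## Annotation and quantification

For each clustering channel the observed event range (the model's frozen
scale) is split into four equal-width intervals; a cluster's level on a
marker is the interval of its centroid: 1 = negative, 2 = low,
3 = positive, 4 = high. The multimer+ call selects clusters with
multimer > 2 and CD8 > 1, plus CD3 > 1 when CD3 was clustered and
dump = 1 when a dump channel was clustered. The rule targets a single
configured multimer channel (default the PE conjugate): in two-multimer
panels the conjugates can carry different specificities, so requiring
both would conflate populations. The same cutoffs apply to every sample
— no per-sample tuning — which is the point of the design and also its
known weakness: a fixed equal-width rule can misfire on samples whose
intensity layout deviates from the bulk, and the evaluation layer is able
to exhibit that.

Frequencies: 100 × (events in selected clusters) / (prefiltered events)
for the lymphocyte denominator; when ground-truth labels are present the
CD8 denominator is the label-true CD8+ count **within the prefiltered
sample**, so numerator and denominator refer to the same event set (using
the whole-sample CD8 count would understate the frequency by the
prefilter retention, ~6%). A population is `detected` when it holds at
least `threshold_events` events (default 10 ≈ 0.001% of 10^6 live single
lymphocytes); replicates are combined as the arithmetic mean, with a
single run passing through unchanged.

## Synthetic samples

`simulate_donor` draws population sizes multinomially (fractions below)
and channel intensities lognormally, parameterized by arithmetic mean and
CV per (population, channel). Default composition: 6% debris, 4%
doublets, 6% dead, 84% live single lymphocytes, of which 30% non-T, 45%
CD3+CD8−, 25% CD8+; the multimer+ fraction is specified either as % of
live single lymphocytes or as % of CD8+ cells. Doublets draw a
singlet-like FSC-H and double FSC-A (±5% noise); singlets sit at
FSC-H ≈ 0.95 FSC-A (±3%), which is what makes the singlet gate
meaningful. Per-lab variation enters as multiplicative per-channel gain
shifts and a global CV multiplier (`noisy_lab_profile` draws lognormal
gains with σ = 0.25 and spread 1.4).

All channel locations and spreads are choices of this generator — the
default layout gives a clearly separated multimer+ population over low
background, as in a clean high-avidity staining — and are not measured
values from any dataset. The bundled donor presets encode the published
response sizes used as recovery targets: proficiency donors at
1.13 / 0.09 / 5.33 / 0.04% multimer+ of CD8 (≈0.28 / 0.022 / 1.33 /
0.01% of live single lymphocytes with the default 25% CD8 compartment),
and the spike-in donors at 1.7% (fivefold series, 7 steps) and 0.87%
(twofold series, 9 steps plus a pure-negative sample). Default sample
size is 2×10^5 events; rare-population checks use 10^6, where 0.001%
corresponds to the canonical 10 events.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: spillover/compensation artifacts, acquisition
drift, non-lognormal autofluorescence tails, doublets of unequal cells,
staining-quality variation within a population, and the full antibody/
instrument heterogeneity of a 28-lab panel (only first-order gain/spread
effects are modeled). Recovery results on synthetic data are a
correctness check of the chain, not a validation on clinical samples.

## Evaluation statistics

CV is the sample SD (n−1) over the mean, ×100. The CV-equality test is
the asymptotic Feltz–Miller statistic: with mᵢ = nᵢ−1, cᵢ the group CVs
and c̄ = Σmᵢcᵢ/Σmᵢ, D = Σmᵢ(cᵢ−c̄)²/(c̄²(0.5+c̄²)) ~ χ²(k−1) under the
null; its type-I error at n = 28 per group is calibrated by Monte Carlo
in the test suite (0.05 ± 0.02 over 2,000 null replicates). Paired t and
Pearson r/R² delegate to scipy with a log10 pre-transform option
(frequencies spanning decades are closer to normal on the log scale).
The limit-of-detection report orders dilution steps by decreasing
theoretical frequency f₀·d^−(k−1) and reports the smallest theoretical
frequency detected in *all* replicates.

## Problem sizes and scaled-down checks

The test suite runs everything at desk scale: recovery checks use 2×10^5
events per sample (10^6 for the rare-population preset), the consensus
check uses the full 12 × 250,000 = 3×10^6 events, panel-correlation
checks use 4–8 simulated samples of 2.5–6×10^4 events, and the
false-positive control runs 100 seeds at the default 2×10^5 events. The
multi-laboratory CV comparison is correspondingly a scaled-down, single-
panel check rather than a hundred-panel replication.

## Known limitations

- The 1–4 categorization from equal-width range splits is sensitive to a
  single extreme event stretching the channel range; robust quantiles
  would be more stable but would change the fixed-cutoff semantics.
- The detection flag, not the frequency, is what protects against false
  positives on negative samples: small noise modes in the multimer tail
  occasionally pass the level rule with < 10 events.
- Cross-sample templates assume the per-lab intensity scales are already
  comparable (harmonized channels, same staining); templates should not
  be shared across labs with different conjugates.
- DAG rectangles are scale-specific configuration: on data with other
  intensity ranges they must be adapted, exactly like manual pregating
  coordinates.
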