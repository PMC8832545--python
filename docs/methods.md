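# Methods

`pvcircuit` re-implements, as a reusable pipeline, the analysis conventions of
channelrhodopsin-assisted circuit mapping in the spinal dorsal horn:
intrinsic-excitability analysis of parvalbumin interneurons (PVINs),
classification of optically evoked postsynaptic currents (oPSCs) as mono- or
polysynaptic, sequential-blocker pharmacology, SWC-based morphometry of the
excitatory (ePVIN) and inhibitory (iPVIN) subtypes, and transcript-count cell
typing. Because the underlying recordings and images are not deposited, every
stage is exercised against a synthetic-data generator with known ground truth;
this note records the models, the defaults, and what the synthetic conditions
do and do not establish about real recordings.

## Synthetic recordings

**Current-clamp step sweeps.** The subthreshold response is a single-compartment
RC charge toward `rmp + I·R_in`, capped at spike threshold (default −45 mV);
membrane time constant is `R_in·C_m` (default 400 MΩ × 25 pF = 10 ms). Spikes
are placed phenomenologically by discharge phenotype and rendered as a fast
linear rise (threshold to +25 mV in 0.5 ms, ≈140 V/s) with exponential
repolarisation, so the derivative-threshold detector sees a realistic
dV/dt profile. Placement rules: tonic firing (TF) — regular discharge spanning
≥90% of the step with the last spike in the final 10%; initial bursting (IB) —
≥2 spikes confined to the first 20%; delayed firing (DF) — first spike between
45% and 60% of the step; single spiking (SS) — one spike near onset; rapidly
adapting (RA) — an onset burst of ≥3 spikes plus a bi-exponential depolarising
hump (20 mV amplitude, 3 ms rise / 25 ms decay) whose rise stays below the
spike dV/dt criterion. Additive Gaussian noise defaults to 0.3 mV (0 for
exact-oracle tests). The generator's `rheobase_pa` is the ground truth for
rheobase-recovery tests.

**Photostimulation trials (voltage clamp).** Each connection contributes, per
trial, a Bernoulli(reliability) event whose onset is
`pulse + 1.3 ms recruitment delay + N(latency_mean, latency_sd)` truncated at
zero, rendered as an inward bi-exponential current (rise 1.2 ms, decay 4.5 ms —
the measured miniature-EPSC kinetics) with log-normal amplitude around the
drug-scaled mean. ChR2-expressing cells additionally carry an inward
photocurrent that activates within the 1 ms pulse and deactivates slowly
(τ = 150 ms), giving the near-plateau that baseline re-zeroing assumes. Drug
conditions scale each transmitter component (GABA_A ← bicuculline, glycine ←
strychnine, AMPA ← CNQX) to a configurable residual fraction (default 0); TTX
removes all events, and 4-AP in TTX reinstates direct terminal release —
monosynaptic inputs and PAD-driven (primary-afferent-depolarisation) events
only. Recording noise defaults to 3 pA.

**mEPSC trains.** Homogeneous Poisson event times at the baseline rate for one
epoch and `rate × capsaicin_factor` for a second epoch of equal length, with
epoch-independent log-normal amplitudes. Default conditions follow the reported
regime (4.28 Hz baseline, 15.4 pA, factor 10.33/4.28 for capsaicin-sensitive
cells).

**What the generator does not emulate:** dendritic filtering and space-clamp
error, seal/access drift within a recording, correlated (1/f) noise,
photocurrent desensitisation across trains, stimulus artefacts, and
use-dependent synaptic depression. Passing recovery tests therefore shows the
estimators are unbiased under idealised noise, not that they are robust to
every recording pathology.

## Electrophysiology analysis

**Spike detection** follows the derivative-threshold convention (dV/dt >
15 V/s) on a 3-point smoothed trace with central differences; an excursion
only counts as a spike if its peak exceeds the threshold-crossing voltage by
20 mV, which rejects fast-but-small deflections. Threshold time is the first
suprathreshold dV/dt sample; on noise-free synthetic sweeps detection is exact
to within ~0.12 ms of the generator annotation at 10 kHz.

**Passive properties** invert the series-resistance / parallel-RC model of the
response to a −5 mV, 10 ms step: `R_s = V/I_peak`, `R_s + R_in = V/I_ss`, and
`C_m = τ/(R_s‖R_in)` with τ from a log-linear fit of the transient. In the
noise-free limit this is an exact inverse of the closed-form generator
(relative error < 1e-6). Note the steady-state current gives the *total*
resistance; the input resistance is reported net of R_s.

**Discharge classification** applies the placement rules above as decision
rules, in the priority order SS > RA > IB > DF > TF, on the first
suprathreshold sweep with confirmation on the next (disagreements defer to the
highest-amplitude sweep and are flagged low-confidence). The RA hump metric is
the spike-masked mean voltage of the first 50 ms of the step minus the
spike-masked steady state; the 3 mV criterion and all fractions are
configurable. The classifying thresholds are package decisions — the published
criteria live in earlier literature and are not restated in full anywhere we
could pin them to.

**Quality control** rejects recordings with RMP ≥ −50 mV (strictly more
negative passes), series resistance ≥ 30 MΩ, or any monitored passive value
drifting more than 30% relative to its starting value.

## oPSC analysis

Events are detected per trial as the first post-pulse deviation of the
smoothed current beyond max(amplitude floor, 4 × pre-pulse SD) in the stated
polarity, traced back to the 5%-of-peak crossing; the search window is 100 ms.
Trial statistics follow the 10-trial conventions: mean latency and jitter (SD
of latency) over responding trials, reliability as the responder fraction, and
amplitude as the peak of the trial-averaged trace. When a photocurrent is
present the average is first re-zeroed at the synaptic onset. Two caveats are
deliberate: (1) with latency jitter, averaging flattens the peak, so the
average-trace amplitude falls below the mean per-trial amplitude — a property
test asserts this direction; (2) re-zeroing at the mean onset of a jittered
response subtracts part of the early synaptic rise, so the exact-recovery test
uses a jitter-free connection.

**Mono/poly classification:** monosynaptic requires mean latency ≤ 7.0 ms
(1.3 ms recruitment + ~2 ms conduction/synaptic + 3.7 ms slack), jitter
< 1.0 ms, and reliability ≥ 0.8; any detected response failing a criterion is
polysynaptic; reliability below 0.2 (2/10 trials) is "none". The cutoffs are
package decisions placed between the two reported latency–jitter regimes
(≈4.3/0.5 ms vs ≈17/4.3 ms) with margin; all are configurable and each rule's
outcome is recorded in a criteria trace.

**Pharmacology:** the oPSC index is the drug/pre-drug amplitude ratio (1 = no
effect, 0 = complete block), floored at zero. Sequential indices are converted
to transmitter fractions on the original amplitude scale
(`fraction_k = cum_before − cum_before × index_k`); an index above 1.05 is
flagged as disinhibition ("unmasked") and excluded from the arithmetic rather
than clamped, so unmasking remains visible in reports. Dominance is
glutamatergic when the AMPA fraction exceeds 0.8 with both inhibitory
fractions below 0.1, otherwise the larger of the GABA/glycine fractions
(within 0.1 of each other → "mixed"). TTX/4-AP confirmation requires TTX to
reduce the amplitude below 20% of baseline and TTX+4-AP to restore at least
50%.

**Capsaicin assay:** a cell is a responder when the post-drug mEPSC frequency
strictly exceeds mean + 3 SD of the baseline-epoch frequencies. The assay
splits the baseline into five bins by default: a 3-sample SD is unstable
enough that the 3-SD rule fires on Poisson fluctuation alone in a few percent
of unchanged cells, while five bins keep the false-positive rate well under
5%. The mEPSC detector (median/MAD threshold crossing with a 2 ms merge gap)
undercounts by roughly 5–8% at 10 Hz because near-coincident events merge;
both epochs are affected, so frequency ratios are less biased than the rates
themselves.

## Morphometry

Features: sphere-model soma volume/surface from the soma-node radius; total
and per-axis projected dendritic lengths as edge sums; rostrocaudal (RC) and
dorsoventral (DV) spreads as coordinate extents; 3-D convex hull volume
(degenerate point sets are flagged and report 0); 2-D box-counting fractal
dimension on the RC–DV projection over six dyadic box sizes on densely
resampled edges; mean tortuosity as the path/chord ratio over
inter-branch-point segments; cylinder-model dendritic surface and volume;
branch counts and maximum branch order. Sixteen features ship implemented; the
registry is extensible rather than padded to the fifty parameters commercial
reconstruction software exports, most of which are not individually named in
any source we can pin to. The published "tortuosity" group values (≈42 vs ≈21)
cannot be a mean path/chord ratio, so no recovery target is attached to that
feature.

Clustering is two-cluster K-means with k-means++ seeding on z-scored features
(raw µm³-scale features would otherwise dominate the Euclidean metric;
whether the original analysis standardised is unstated). Constant columns are
dropped with a warning, and clusters are relabelled so cluster 1 holds the
smaller-soma centroid, matching the published contingency-table orientation.
Group comparisons run a Shapiro screen per sample (α = 0.05) and choose an
unpaired t test or Mann–Whitney accordingly.

**Morphology generator.** Per cell, targets (soma volume, total length, RC
spread, DV spread) are drawn log-normally around the class means (CV 0.25);
the RC-projected length is drawn as a ratio of that cell's total length so the
ratio stays feasible. Stems grow as 5 µm steps whose RC component is a fixed
fraction of step length (making the RC-projected length essentially exact, to
~1% lost at turns), zigzagging inside per-side bounds so coordinate extents
equal the sampled spreads; the two principal stems are unbranched so their
path depth guarantees the extents, and remaining stems branch with a per-step
probability. Class means follow the reported group statistics (iPVIN:
841.8 µm³ soma, 2054 µm total, 1603 µm RC length, 433.4 µm RC spread; ePVIN:
444.3 / 943 / 696 / 236.2). DV spreads are not reported numerically; the
defaults (150 µm iPVIN, 110 µm ePVIN) were chosen once as anatomically
plausible for laminae IIi–III cells and kept.

## Cell typing and laminae

A cell is positive for a gene at strictly more than 4 transcripts; excitatory
vs inhibitory identity follows Slc17a6 vs GAD1 with explicit "ambiguous"
(double-positive) and "neither" classes, reported rather than merged. Summary
proportions are computed per animal; the SEM convention is SD/√n over the
per-animal percentages. All printed percentages use half-up rounding at the
reported precision, centralised in one reporting function. Laminar boundaries:
the I/IIo border sits 20 µm below the dorsal white matter; IIo/IIi is the
dorsal edge of the PV plexus; IIi repeats the IIo extent and III the extent of
both combined; assignment uses half-open [lower, upper) intervals with depth
increasing ventrally.

The synthetic transcript panel draws cell classes from a mixture (default
52.7% excitatory), gives expressed genes a floor of 5 transcripts plus a
gamma-Poisson count (so a truly expressing cell is never called negative), and
non-expressing genes a Poisson(0.3) background (negative except ~1 in 60,000).
CCK co-expression defaults to 74.5% of excitatory cells.

## Problem sizes and numerical choices

The test suite and the acceptance script use: 100 morphologies per class for
group-mean recovery, a 34 + 30 cohort for clustering (10 seeds), 500 synthetic
connections and 500 synthetic cells for the classifier suites, 1000 trials for
jitter consistency, and 90 s epochs for the capsaicin assay — sizes at which
Monte-Carlo error sits well inside the stated tolerances. All generators take
explicit integer seeds and use a single `numpy.random.default_rng` stream per
call; ties in event ordering follow generation order. Degenerate inputs
(zero-amplitude steps, empty sweep lists, saturated traces, unlabeled cells,
zero-denominator animals) raise or warn explicitly rather than propagating
NaNs.

## Known limitations

Spike detection assumes somatic spikes with conventional kinetics; no
phase-plane or sag analysis is provided. The passive-property fit assumes a
single well-separated transient. The oPSC detector returns at most one event
per trial within the search window; barrages under disinhibition are outside
its scope. The fractal dimension depends on projection and box grid and is
only translation invariant up to box-edge rounding. The morphology generator
produces statistically matched, not biologically detailed, arbors (no spines,
no diameter taper, no lamination of branch angles).
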