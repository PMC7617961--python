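# Methods

`tonicpag` implements the quantitative analysis chain for studying tonically
active GABAergic (VGAT+) neurons of the dorsal periaqueductal gray (dPAG)
and their relation to instinctive escape: in vitro spike and synaptic
metrics, in vivo calcium-trace analysis, behavioural escape metrics, and the
synthetic-data generators that make every stage testable without raw
recordings. This note documents the models, the parameters that matter, the
numerical choices, and the limits of what the synthetic fixtures can show.

## Spike-train statistics

Firing rate is spike count over an explicit half-open analysis window
divided by its length; half-open counting makes rates additive over
adjacent windows. The coefficient of variation is the SD of inter-spike
intervals over the mean ISI. The SD is the population SD by default: the
analysis convention is unstated in the field's common usage and either is
defensible; `sample_sd=True` switches to the n−1 normalisation, and the
default is what the tests freeze.

CV2 is the local variability statistic

    CV2 = mean_i  2 |Δt_{i+1} − Δt_i| / (Δt_{i+1} + Δt_i)

over consecutive ISI pairs, with no edge padding. It is 0 for perfectly
regular firing, 1 in expectation for exponential (Poisson) ISIs, bounded by
2, and invariant to uniform time rescaling. Both calibration points are
verified: an ensemble of 100 Poisson trains (600 s × 5 Hz) gives mean CV2 =
1.00 ± 0.03, and a regular train gives exactly 0 (asserted on a 4 Hz grid,
whose 0.25 s ISI is exactly representable in binary floating point; a 5 Hz
grid leaves last-ulp ISI jitter and CV2 ~1e−14).

Passive properties: input resistance is Ohm's law on the steady-state
deflection of a hyperpolarising test pulse (mV/pA = GΩ·10⁻³, reported in
MΩ); the membrane time constant is a least-squares fit of
`y = y0 + A·exp(−(x − x0)/τ)` to the pulse decay, with flat segments
rejected as degenerate rather than fit.

## IPSC detection and quantification

Spontaneous IPSCs are detected on the baseline-subtracted current trace.
The baseline is a rolling median (1 s window, evaluated on a coarse grid
and interpolated — exact dense medians change nothing at synaptic
timescales). The noise SD is estimated robustly as 1.4826 × MAD of the
residual, and the default amplitude threshold is 4 × that value. Before
peak-finding the residual is boxcar-smoothed over 1 ms. Candidate events
must satisfy both an amplitude and a *prominence* criterion of one
threshold: a peak has to rise by a full threshold above the minimum
separating it from its neighbours. Height alone over-counts (noise riding
on a decay tail forms spurious local maxima) while the prominence rule
keeps genuinely overlapping events that carry their own rise. A 5 ms
refractory interval is enforced. Event onset is the last crossing of 10% of
the peak amplitude before the peak; per-event charge is the trapezoidal
integral over 50 ms from onset (pA·s = pC). On synthetic traces (6.5 Hz
events, amplitudes ≥5× noise SD) detection recall is ≥0.95 with a
false-positive rate ≤0.05 at 5 ms matching tolerance; residual misses are
event pairs closer than the refractory interval.

Derived quantities: peak conductance G = |I/V_hold| (valid with a
high-chloride internal solution, where E_Cl ≈ 0 mV and the driving force
equals the holding potential); unitary charge from the mean event waveform;
average charge rate = unitary charge × event frequency (a per-cell product
— the cohort mean of per-cell products is not the product of cohort means);
paired-pulse ratio = mean second-pulse peak / mean first-pulse peak, means
across sweeps taken before the ratio. Evoked responses average a minimum of
5 sweeps aligned on the first pulse; amplitude is the extremum of the
average in a post-pulse window (peak-of-average by default; an
average-of-peaks flag exists because the convention is ambiguous), and
latency is the onset-fraction (20%) crossing of the averaged trace. Drug
effects on event frequency are the post/baseline frequency ratio with a
2 min pre-onset baseline and preset wash-in windows (CNO: minutes 7–8
after onset; SR-95531: minutes 5–7).

## Calcium-trace preprocessing

The canonical order is flatfield → mask extraction → resample → dF/F and
z-score. Flatfield correction subtracts a zero-centred, Gaussian-blurred
time-mean image from every frame; blur sigma defaults to 1/8 of the frame
width, and the blur uses nearest-edge extension because reflect/mirror
boundary modes flatten the field at the frame border and leave ~10%
residual on a linear illumination gradient (nearest leaves ~5%). The
movie mean is unchanged by construction. Spatial downsampling is a block
mean (e.g. 630×630 → 126×126 with a 5×5 block). Trace extraction subtracts
a per-frame rolling-ball background (morphological grayscale opening with a
disk footprint, radius 10 px) and averages over the mask pixels. Traces are
linearly interpolated to 30 Hz to match behaviour tracking.

dF/F uses F0 = 10th percentile of the session trace by default (the
convention is not universal; pre-window mean and a user callable are
selectable, and the choice is logged by the pipeline). A neuron is "active"
when its session z-score exceeds 1.96 anywhere (strict inequality,
including at exactly 1.96). Calcium transients are local maxima of the
Savitzky-Golay-smoothed z-trace (2 s window rounded to an odd sample
count, polynomial order 2, reflect padding) with prominence ≥ 0.3 Z. The
low-pass filter is a hard FFT cutoff, default 2 Hz — below it the
escape-timescale signal survives, above it acquisition-rate artifacts are
removed; the same filter must be applied to every trace of a session.

## Locomotion modulation index

The baseline period (before the first threat stimulus) is split into 1 s
bins of continuous locomotion (speed > 1.5 cm/s) or stationary behaviour,
outside the shelter only; partial-second remainders of a state run are
dropped. For each neuron, LMI = (R_L − R_s)/(R_L + R_s) on bin-mean dF/F0.
|LMI| = 0.2 corresponds exactly to a 50% change in F/F0 between states.

Significance uses a reduced-sample bootstrap: consecutive 1 s bins are
correlated, so each replicate draws only a fraction 1 − R of the bins per
state (with replacement; ceil on the count so small-n neurons never draw
zero), where R is the lag-1 Pearson correlation between consecutive bin
values. R is computed per dataset by default, over consecutive-in-time
bins regardless of state changes (a stricter same-run option is not
needed for the fixtures and was not implemented); a pinned R (e.g. the
replication value 0.57, giving the 43% sample) is available. The fraction
is clamped to [0.1, 1.0] so pathological R estimates cannot empty or
overfill the replicate. A neuron is significantly modulated when the 95%
percentile CI of replicate LMIs excludes 0 *and* |LMI| > 0.2. On
unmodulated synthetic neurons the CI-only criterion flags ≈5% and the
magnitude gate brings this to ≈0.

## Escape behaviour

A successful escape is the full annotated sequence — stimulus-reaction
(startle), shelter-directed turn, run start, shelter entry — with entry at
most 6 s after stimulus end (closed bound; 7.5 s for head-mounted
imaging sessions) and an uninterrupted run. "Uninterrupted" was a manual
judgement in the original scoring; here it is operationalised as run speed
never below 5 cm/s for longer than 0.5 s before entry, both configurable.
Escape probability is per-animal; condition summaries average over
animals. Peak escape speed is the speed maximum from run initiation to
shelter entry. Termination distance is normalized along the arena's long
axis: 0 at the shelter entrance, 1 at the far end, negative past the
entrance. Path length sums Euclidean steps of the (2-D where available)
track from run start to escape stop.

## Escape responsiveness and time warping

Traces are baselined per trial by subtracting the mean of the 500 ms
before stimulus onset. A neuron is escape-active when, for any of the six
events (stimulus, reaction, turn, run, shelter entry, escape stop), the
distribution over trials of local slopes (least-squares over a 660 ms
window from event onset) differs from the distribution of baseline slopes
(the 660 ms immediately preceding stimulus onset, one sample per trial) by
two-tailed two-sample t-test, Bonferroni-corrected across the events
actually tested. Event windows that do not fit inside a trace are skipped
and the correction factor reduced accordingly. Degenerate zero-variance
comparisons (identically flat traces) yield p = 1. Type-I error on
pure-noise neurons is ≈5% (checked with a binomial band at 150–300
simulated neurons).

Motion artifacts (sharp symmetrical troughs from cable contact) are
repaired by cubic-spline interpolation across ±500 ms around annotated
trough times, anchored on the flanking data; troughs are inputs, matching
the original by-inspection identification.

The warp template is built from complete escape trials: per event, the
median time relative to stimulus onset; a 2 s tail after escape stop; a
uniform 30 Hz grid. Warping is piecewise linear: each trial event time maps
to its template time, intermediate times interpolate linearly, and times
before the first/after the last anchor extend with identity slope. The
warped trace is the input linearly interpolated at the mapped times — so
values at event anchors are preserved, the map is monotone, and warping an
already-aligned trace is the identity on the grid (checked to 1e−9).

Fail trials carry no post-reaction events and cannot be anchored; they are
sampled with the identity warp anchored at stimulus onset (template-time
sampling), which is the "same period" comparison used for escape vs fail
means. The summary statistic is the mean z between the reaction and
escape-stop template anchors.

## Clustering and spatial statistics

Mean warped responses (escape trials only) are low-pass filtered,
ternarized (y < −0.2 Z → −1, y > 0.2 Z → +1, else 0; strict boundaries),
embedded by mean-centred PCA, and clustered with K-means (k-means++, 50
initialisations, fixed seed) on the first 3 component scores. k is chosen
by the highest mean silhouette over k = 2..8; inertia is reported per k
for an elbow view but silhouette is authoritative. K-means labels are
arbitrary, so they are mapped to stable identities by each cluster's mean
response between the reaction and escape-stop anchors, most positive
first: cluster 1 is ramp-like (activity building to escape termination),
cluster 2 dip-like (transient decrease at escape onset). A `clusterable`
flag marks results whose best silhouette falls below 0.2; note that a
split *single* isotropic blob still scores ≈0.27–0.40 by the nature of the
silhouette statistic, so the flag catches only strong degeneracy
(identical rows are reported as a single cluster).

Extremum timing takes the argmax (cluster 1) or argmin (cluster 2) of each
neuron's mean warped trace relative to escape end, ties to the earliest.
Timing distributions are compared with event anchors by one-sample t-tests
(cluster 1) or sign tests (cluster 2), Holm-Bonferroni corrected.

Spatial overlap: convex hulls over each cluster's mask centroids in the
field of view (full-pixel hulls optional), Jaccard = hull intersection
area / union area; collinear point sets fall back to a bounding box and
are flagged. The permutation test shuffles cluster labels (default 1000
permutations) and reports a two-sided p on |J − null mean| with the +1
correction; under random labels the p-values are uniform (verified by KS
test).

## Synthetic data: what it emulates, and what it does not

All generators take an explicit seed, use one local `numpy` Generator, and
are bit-reproducible.

**Spike trains** — regular grids, Poisson, or gamma-renewal ISIs (shape 1 =
Poisson; larger shapes emulate the regular tonic phenotype).

**IPSC traces** — Poisson event trains with difference-of-exponentials
kinetics (defaults 0.8 ms rise, 8 ms decay — chosen for realism and
analytic integrability), Gaussian amplitude scatter around −45 pA,
Gaussian baseline noise, 10 kHz sampling, and drug epochs that rescale the
event rate (thinning algorithm), with the ground-truth event list
returned.

**Imaging sessions** — each neuron carries a motif drive convolved with a
slow-indicator kernel (difference of exponentials, unit area; defaults
0.2 s rise, 1.8 s decay, GCaMP6s-like) plus white noise in z units
(default 0.5 Z). Motifs: *ramp* — linear drive from stimulus onset to
escape stop (drive amplitude 3, giving a post-kernel peak ≈ +1.3 Z);
*dip* — negative pulse from the reaction toward the run onset (drive 6,
trough ≈ −0.9 Z); *unmodulated* — no drive. These response scales mirror
the magnitudes the analysis is designed to resolve. Because the kernel is
causal, the fluorescence extremum necessarily lags the drive extremum by
about the kernel rise time; construction-level timing checks therefore use
a near-instantaneous rise (a free fixture parameter), while analysis-level
checks (clustering, k-selection) run at the default slow kernel. Trials
have jittered event sequences (reaction ≈ 0.35 s after stimulus, entry
≈ 2.1 s, stop ≈ 2.4 s); fail trials stop after the reaction and carry no
motif drive. Speed/position are piecewise trapezoids consistent with the
events (baseline locomotion bouts at 8 cm/s shuttling outside the shelter,
triangular escape-run profiles covering the threat-to-shelter distance) —
sufficient for threshold-based segmentation and classification, not a
model of real kinematics. Masks are non-overlapping 3×3 pixel squares at
random positions in a 126×126 FOV, with no spatial organisation: the
spatial-overlap test should and does return null results on them.

What passing tests do *not* show about real data: the generators contain
no sensor nonlinearity, photobleaching, motion artifacts (except when
explicitly injected), neuropil contamination, correlated noise across
neurons, or behavioural variability beyond event-time jitter. Results on
synthetic sessions validate the *computations*, not biological claims.

**Default problem sizes.** The test suite and the acceptance script run at:
100 × 600 s Poisson trains for CV2; 60–120 s IPSC traces (≈400–800
events); 120-neuron two-motif cohorts over 20 seeds for k-selection;
150–300 noise neurons for type-I rates; 50 repeats for tau recovery.
These sizes put Monte-Carlo error comfortably below every asserted
tolerance while keeping runs desk-scale.

## Pipeline

`tonicpag.pipeline.run` executes simulate → invitro → calcium →
locomotion → behavior → response → cluster → report on a validated config
(unknown keys rejected). Every analysis constant defaults to the values
above and is echoed, with library versions and a config hash, into
`manifest.json`. Outputs are deterministic per seed; re-running a config
reproduces byte-identical tables. The `tonicpag` console script exposes
the stages as subcommands.

## Known limitations

- The IPSC detector's parameters (threshold multiple, onset fraction,
  refractory, smoothing) are documented defaults, not a reproduction of
  any specific published threshold algorithm.
- The exact dF/F baseline convention and FFT cutoff of the original
  analysis are unreported; the defaults here are stated choices.
- The escape "uninterrupted run" criterion replaces manual scoring with a
  speed-based rule.
- Warping assumes the template's event order in every trial; trials with
  reordered events are rejected, not repaired.
- The silhouette floor cannot flag a compact single cluster as
  unclusterable (see above); interpreting a k = 2 result still requires
  looking at the silhouette values themselves.
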