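# tonicpag

Analysis toolkit for studying **tonically active GABAergic (VGAT+) neurons
of the dorsal periaqueductal gray (dPAG)** and their role in instinctive
escape behaviour. The dPAG computes escape initiation and vigour through
its excitatory neurons; local GABAergic neurons fire regularly without
synaptic drive, supply sustained phasic inhibition, and modulate their
activity around escape — transiently dipping at escape onset and ramping
to a peak at escape termination. `tonicpag` implements the full
quantitative chain needed to measure these phenomena, for
electrophysiologists and systems neuroscientists working with slice
recordings, miniscope calcium imaging, and threat-assay behaviour.

## What it computes

**In vitro** — firing rate in explicit analysis windows; ISI coefficient of
variation; the local regularity statistic

    CV2 = mean_i 2|Δt_{i+1} − Δt_i| / (Δt_{i+1} + Δt_i)

(0 = perfectly regular, 1 = Poisson); input resistance and membrane τ from
test pulses; f-I curves; threshold-based IPSC detection with peak
conductance *G = I/V_hold*, unitary charge (50 ms integral from onset),
charge-transfer rate, paired-pulse ratio, evoked latency, and normalized
drug effects (CNO / SR-95531 wash-in presets).

**In vivo calcium** — flatfield correction, rolling-ball mask extraction,
30 Hz resampling, ΔF/F and z-scoring, the z > 1.96 activity criterion,
Savitzky-Golay transient detection (prominence 0.3 Z), FFT low-pass; the
locomotion modulation index **LMI = (R_L − R_s)/(R_L + R_s)** with its
reduced-sample bootstrap significance test (resampling a fraction 1 − R of
the 1 s bins to respect their serial correlation R); slope-based
escape-responsiveness testing (660 ms windows at each behavioural event vs
baseline, Bonferroni-corrected t-tests); piecewise-linear **time warping**
of each trial onto the median behavioural-event template; ternarize → PCA →
K-means clustering with silhouette k-selection; extremum-timing statistics
(Holm-Bonferroni); and a convex-hull Jaccard permutation test for spatial
cluster segregation.

**Behaviour** — escape/fail classification (full event sequence,
uninterrupted run, 6 s deadline or 7.5 s under head-mounted imaging),
per-animal escape probability, peak escape speed, normalized termination
distance, escape path length.

**Synthetic data** — seeded generators with ground truth for every stage:
regular/Poisson/gamma spike trains, IPSC traces with
difference-of-exponentials kinetics and drug epochs, imaging sessions with
ramp/dip/unmodulated response motifs convolved with a slow-indicator
kernel, locomotion bouts, and small movies. See `docs/methods.md` for the
model details and their limits.

## Worked example

Simulate a two-motif cohort (72 ramp + 48 dip neurons, noise 0.5 Z), warp
each neuron's trials to the median event template, and cluster the mean
responses:

```python
import numpy as np
from tonicpag import synth, calcium, clustering, escape_response as er

session = synth.gen_session(synth.SessionSpec(n_ramp=72, n_dip=48, n_unmod=0, seed=1))
escapes = [t for t in session.trials if t.outcome == "escape"]
template = er.build_template(
    [{k: v - t.stimulus_onset for k, v in t.events.items()} for t in escapes]
)
means, window_means = [], []
for i in range(session.n_neurons):
    trials = [
        (er.baseline_subtract(session.traces[i], session.frame_rate, t.stimulus_onset),
         t.events, t.outcome)
        for t in session.trials
    ]
    resp = er.mean_response(trials, session.frame_rate, template)
    means.append(resp.mean_escape)
    window_means.append(resp.window_mean_escape)

filtered = np.vstack([calcium.lowpass_fft(m, template.grid_rate) for m in means])
scores, evr = clustering.embed_pca(clustering.ternarize(filtered))
result = clustering.cluster_k(scores, window_means=np.array(window_means), seed=1)
print(f"chosen k = {result.chosen_k}, silhouette = {result.silhouette_by_k[result.chosen_k]:.2f}")
print(f"first 3 PCs explain {100 * evr.sum():.0f}% of variance")
print(f"cluster sizes = {np.bincount(result.labels)[1:]}")
```

prints

```
chosen k = 2, silhouette = 0.90
first 3 PCs explain 94% of variance
cluster sizes = [72 48]
```

— the silhouette criterion selects two clusters, the ramp-like group is
labelled cluster 1 and the dip-like group cluster 2 (identities assigned
by the sign of the mean response between the reaction and escape-stop
anchors, so labels are stable across seeds), and the recovered membership
matches the generator's ground truth. The cluster-1 mean trace peaks
within ~0.2 s of escape termination — the lag of the slow indicator
kernel.

The in vitro half works the same way:

```python
from tonicpag import spiketrain, synaptic

train = synth.gen_spike_train(
    synth.SpikeTrainSpec("gamma", rate=4.7, duration=240, gamma_shape=20, seed=1))
stats = spiketrain.isi_stats(train)
# firing rate = 4.70 Hz, CV = 0.23, CV2 = 0.25  -> regular tonic firing

rec, truth = synth.gen_ipsc_trace(synth.IpscTraceSpec(event_rate=6.5, duration=60, seed=2))
events = synaptic.detect_events(rec)
summary = synaptic.summarize(events, rec)
# IPSC frequency = 6.37 Hz, peak conductance = 0.69 nS, unitary charge = 0.61 pC
```

An end-to-end demo (simulation → all analysis stages → manifest) is one
command:

```bash
tonicpag all --seed 1 --out demo_run
```

## Layout

```
src/tonicpag/
  synth.py            seeded generators with ground truth
  spiketrain.py       rates, CV, CV2, passive properties
  synaptic.py         IPSC detection and quantification
  calcium.py          fluorescence preprocessing
  locomotion.py       state segmentation, LMI bootstrap
  behavior.py         escape classification and metrics
  escape_response.py  slope tests, artifact repair, time warping
  clustering.py       ternarize/PCA/K-means, timing, spatial overlap
  pipeline.py, cli.py orchestration and console entry point
docs/methods.md       models, parameters, numerical choices, limitations
tests/                pytest suite (unit, property, end-to-end)
```
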