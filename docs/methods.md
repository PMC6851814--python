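# Methods

`rhythmkit` treats a vocalization recording as a *point process*: an
ordered series of event onset times (call onsets, syllable centers,
amplitude-envelope peaks) on a finite observation window. Four
complementary analyses are provided, each with the synthetic ground-truth
generators needed to validate it.

## Event model

Times are stored in seconds and snapped to a quantization grid
(`resolution`, default 1 ms, i.e. a 1-kHz annotation rate) on ingest.
Two events that coincide after quantization are rejected rather than
merged — for annotated data a tie is an annotation error the user should
see. The elementary statistic is the inter-event interval (IEI). The
default convention is onset-to-onset; offset-to-onset (silent gap) is
available when per-event durations exist, and overlapping calls produce
non-positive gaps that are retained with a flag but excluded from any
log-domain analysis, where they are undefined.

## Synthetic generators

The generators define the toolkit's reference conditions:

| generator | defaults | what it emulates |
|---|---|---|
| isochronous | period 0.2 s, 10 s, 1-kHz grid, optional Gaussian position jitter (σ = 0.005 s in the reference condition) | metronomic calling |
| Poisson | λ = 12 events/s, 10 s | memoryless random calling |
| hierarchical | triplets of double pulses; gaps 0.05 / 0.20 / 0.60 s, gap jitter σ = 0.005 s | three nested interval scales |
| durational Markov | K = 3 categories at 0.4 / 0.7 / 1.3 s, 10% SD, row-stochastic transition matrix | category-structured sequences |
| speech-like | log10 IEI ~ Normal(log10 0.218, σ*) with σ* solved so P(0.19 ≤ IEI ≤ 0.25) = 0.5 | syllable-center timing of read speech |

Design choices worth knowing:

* **Jitter placement.** Position jitter for the isochronous series (each
  pulse deviates independently from its grid slot — the natural model for
  a vocalizer tracking an internal beat) but *gap* jitter for the
  hierarchical series (keeps the three interval scales separated instead
  of letting position noise mix adjacent gaps). Both are configurable.
* **Hierarchical gap values** 0.05/0.20/0.60 s were chosen once so a 10-s
  series shows three well-separated log-IEI peaks; nothing else depends
  on them.
* **Quantization after jitter**, matching a 1-kHz sampling of the
  jittered signal. The Poisson generator merges the rare tick collisions
  this produces (≈ 0.7% of events at λ·T = 1200 on a 10⁵-tick grid); the
  induced one-tick dead time is negligible for every statistic computed
  here.
* **Speech-like calibration** is exact in closed form (Gaussian quantile
  equation solved by Brent's method), not tuned: the median and the
  central 50% band fully determine the two lognormal parameters. It
  emulates only the *marginal* IEI distribution of read speech — no
  serial correlation, pauses, or phrase structure — so agreement on
  distribution-level statistics says nothing about higher-order temporal
  structure in real speech.
* All generators take a single integer seed and are bit-reproducible.

## Allan factor

For adjacent, non-overlapping windows of length `T` anchored at the start
of the observation window (trailing partial window discarded), with
counts `N_i` over `M` windows,

    A(T) = mean_i (N_{i+1} − N_i)² / (2 · mean_i N_i),   i = 1..M−1

using all M−1 adjacent pairs. `A(T) = 1` for a homogeneous Poisson
process at every `T`; `A(T) = 0` for a noise-free periodic series with
windows commensurate with the period; growth of `A(T)` with `T` measures
nested clustering. Window membership is decided by index with a
half-resolution guard so an event quantized onto a window edge belongs to
the window it opens — this keeps the periodic-series zero exact in
floating point.

AF functions use a geometric timescale ladder (dyadic by default; bounds
default to `4·resolution` and `span/4`, keeping ≥ 4 windows at the
coarsest scale; scales with < 2 windows are dropped). The shape summary
is an ordinary least-squares quadratic fit of log10 A(T) on log10 T:
the linear coefficient measures the degree of hierarchical structure, the
quadratic its change across scales. `A(T) = 0` is floored at 1e-6 before
the log; undefined values (no events) are excluded, never imputed.

**Sampling caveat:** at the coarsest scales only a handful of windows
exist and A(T) has large variance (relative SE ≈ √(2/(M−1))). Shape
coefficients from a single short series are therefore noisy; flatness
tests for Poisson data aggregate the AF function over seed replicates
before fitting. Note also that a *deterministically tiled* hierarchical
series is globally periodic, so its A(T) collapses at timescales above
the motif; persistent AF growth requires randomness at the cluster level
(e.g. Poisson cluster centers), which is how the clustering tests are
built.

## Log-IEI distributions and sKL divergence

Distributions are histograms of log10(IEI) on a grid shared by every
series being compared (default 30 uniform bins spanning the pooled log10
range plus half a bin of padding; a series whose intervals are all
identical gets a 0.1-dex window with the value at a bin center). A
pseudo-count of 0.5 per bin (Jeffreys-style) keeps every bin positive so
Kullback–Leibler terms are finite. Mode counting uses peak prominence
(default 5% of the maximum bin probability) on the zero-padded
probability vector, so boundary bins can be modes.

The divergence is the *sum* of the two directed KL divergences, in nats:

    sKL(p, q) = Σ p_i ln(p_i/q_i) + Σ q_i ln(q_i/p_i)

zero iff the smoothed histograms are identical. Because the histogram
discards interval order, any reordering of the IEIs leaves all distances
unchanged — the method is insensitive to higher-order temporal structure
by construction. When two narrow distributions stop overlapping, sKL
saturates at a smoothing-determined ceiling; monotone growth with
parameter separation is only meaningful while the histograms overlap.

Distance matrices are embedded in 2-D by metric MDS: SMACOF stress
minimization (scikit-learn), initialized from the classical Torgerson
scaling solution so the result is deterministic; 300 iterations,
convergence tolerance 1e-9. Reported stress is normalized Kruskal
stress-1, which is scale-free and < 1e-3 for perfectly Euclidean inputs.
Only inter-point distances are interpretable; the axes are arbitrary.

## Durational categories and transitions

Durations (or intervals) are modeled as a Gaussian mixture in log10
space; the number of categories `k` is chosen by minimum BIC over
`k = 1..k_max` (ties toward smaller `k`; three k-means initializations
per fit, variance floor 1e-6 against degenerate components). Centroids
are reported back in seconds (`10^mean`) and sorted ascending so fitted
models are comparable. Transition matrices are raw maximum-likelihood
bigram frequencies (no smoothing by default); rows never observed are
left all-zero and flagged rather than imputed.

With centroid separation ≥ 3 SD in log space and n ≥ 500, `k` recovery
is essentially perfect; the binomial SE of a transition entry is
√(p(1−p)/n_row), about 0.012 at n = 5000 over three categories — recovery
accuracy claims should be read against that floor.

## Isochrony

Grid fitting maximizes vector strength
`R(f) = |mean_k exp(2πi f t_k)|` over a geometric tempo grid (1% spacing
between `f_min` and `f_max`), then refines the best candidates by bounded
scalar optimization within one grid step — necessary because the R(f)
peak of an n-beat series is only ~1/span Hz wide. Near-ties break toward
the lower tempo to avoid harmonic doubling; competitive harmonics are
reported. The phase is the circular mean angle mapped to `[0, 1/f)`.

For Gaussian position jitter with SD σ, `R = exp(−2π²f²σ²)` in
expectation (≈ 0.988 at f = 5 Hz, σ = 5 ms). The interpretable companion
score is the fraction of onsets within a tolerance of the nearest beat;
a tolerance ≥ half the period saturates at 1 and triggers a warning.
Significance is assessed with interval-shuffled surrogates (default 200):
re-running the same tempo search on each surrogate gives a null
distribution of peak R and an add-one empirical p-value.

## Envelope events

Envelope extraction is the magnitude of the analytic (Hilbert) signal,
low-pass filtered with a zero-lag (forward-backward) 4th-order
Butterworth at 32 Hz and decimated to 200 Hz; peak events are local
maxima with prominence ≥ 10% of the envelope maximum (per-recording
normalization), greedily thinned to a 20-ms minimum separation keeping
the higher peak. These defaults capture syllable-rate bursts and suppress
pitch-rate ripple; all are exposed on the CLI. This path is intended for
clean recordings — for low-SNR wildlife audio, hand annotation read via
the CSV/TextGrid readers is the supported route.

## Problem sizes

The bundled tests and the demonstration run at desk scale: 10-s series
(≈ 50–120 events) for distribution-level results, 100-s series for
Allan-factor statistics, n = 5000 intervals for transition recovery, 20
seed replicates for stochastic claims, 18 × 300 intervals for the
emulated speech corpus. These sizes make every stochastic assertion
comfortably stable under its stated tolerance.

## Known limitations

* Single-signaler series only; no turn-taking attribution.
* Log-IEI/sKL comparisons ignore interval order entirely.
* The speech-like generator is a marginal-distribution stand-in, not a
  corpus; conclusions about real speech require real annotations
  (supply them via `--speech-dir`).
* Isochrony fitting assumes a constant tempo over the window; it is not
  a beat tracker for tempo-varying signals.
* BIC-selected mixtures operationalize "multimodality" pragmatically; no
  formal multimodality test (e.g. dip test) is included.
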