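# rhythmkit

Rhythm analysis of vocalization event series, for bioacousticians and
computational ethologists who have (or can extract) the *times* of vocal
events — call onsets, syllable centers, amplitude-envelope peaks — and
want to quantify their temporal structure and compare it across
recordings, individuals, or species.

Given an event series `t_1 < t_2 < … < t_n` on an observation window, the
toolkit computes:

* **Allan-factor functions** — clustering of event counts in adjacent
  windows of length T, `A(T) = E[(N_{i+1} − N_i)²] / (2 E[N_i])`,
  evaluated over a geometric ladder of timescales. `A(T) = 1` at every T
  for a homogeneous Poisson process; growth of A(T) with T indicates
  hierarchical nesting of event clusters. The log-log shape is summarized
  by a quadratic fit (linear coefficient = degree of hierarchy, quadratic
  = its change across scales).
* **Log-IEI distributions and sKL divergence** — the distribution of
  log10 inter-event intervals on a shared bin grid, compared with the
  symmetric Kullback–Leibler divergence
  `sKL(p,q) = KL(p‖q) + KL(q‖p)` (nats), assembled into distance
  matrices and embedded in 2-D with metric MDS.
* **Durational categories and transitions** — BIC-selected Gaussian
  mixtures on log durations (each mode ≈ one category prototype) and
  row-stochastic transition matrices `P(next category | current)`.
* **Isochrony** — the best-fitting metronomic grid (tempo + phase) by
  vector strength `R(f) = |n⁻¹ Σ_k exp(2πi f t_k)|`, the fraction of
  onsets within tolerance of the nearest beat, and a surrogate-based
  significance test.
* **Synthetic generators** — isochronous, Poisson, hierarchical
  (triplets of double pulses), durational-Markov, and speech-like pulse
  trains with known ground truth, used to validate every stage.

Audio in, events out: WAV recordings can be reduced to envelope peak
events (`rhythmkit events`), or annotations can be read from onset CSVs
and Praat TextGrids.

## Worked example

```python
import rhythmkit as rk

# a 10-s pulse train, one pulse every 0.2 s, 5-ms Gaussian jitter, 1-kHz grid
iso = rk.gen_isochronous(rk.IsochronousSpec(period=0.2, duration=10.0,
                                            jitter_sd=0.005, seed=1))
fit = rk.fit_isochronous_grid(iso, f_min=1.0, f_max=20.0)
print(f"tempo {fit.tempo:.3f} Hz, vector strength {fit.vector_strength:.3f}")
print(f"aligned fraction (tol 10 ms): {rk.beat_alignment_fraction(iso, fit, 0.01):.2f}")

report = rk.run_demo(seed=1)
print(f"{len(report.distributions)} distributions, "
      f"{report.distance_matrix.n_unique} unique sKL distances")
print(f"mode counts: iso={report.mode_counts['iso']}, "
      f"hier={report.mode_counts['hier']}, rand={report.mode_counts['rand']}")
print(f"within-speech mean sKL {report.within_speech_mean:.3f} "
      f"vs min speech-to-synthetic {report.speech_to_synthetic_min:.3f}")
```

prints

```
tempo 5.001 Hz, vector strength 0.990
aligned fraction (tol 10 ms): 0.94
21 distributions, 210 unique sKL distances
mode counts: iso=1, hier=3, rand=9
within-speech mean sKL 0.109 vs min speech-to-synthetic 2.050
```

The fitted tempo recovers the 5-Hz pulse rate; vector strength 0.990
matches the Gaussian-jitter expectation `exp(−2π²f²σ²) ≈ 0.988`, and 94%
of pulses land within ±2σ of their beat. The demo compares 21 series —
jittered isochronous, hierarchical, Poisson, and 18 speech-like series
emulating syllable-center annotations — giving 21·20/2 = 210 pairwise
divergences. The isochronous series shows a single log-IEI mode (at
0.2 s), the hierarchical series exactly three (its three gap scales), the
Poisson series a broad multi-bump spread around 1/λ; and the speech-like
group is far more similar internally (mean sKL 0.109) than to any
synthetic series (min 2.050), which is what the MDS map shows as a tight
speech cluster away from three isolated points.

## Command line

Every analysis is also a subcommand:
`simulate`, `events`, `af`, `ieidist`, `compare`, `categories`,
`isochrony`, `demo` — e.g.

```sh
rhythmkit simulate --kind iso --jitter-sd 0.005 --seed 1 --csv iso.csv
rhythmkit af iso.csv --json af.json
rhythmkit isochrony iso.csv --fmin 1 --fmax 20 --json fit.json
rhythmkit demo --seed 1 --out demo_out/
```

All commands are deterministic given `--seed`; JSON reports log their
parameters. `rhythmkit demo --speech-dir DIR` replaces the emulated
speech series with real syllable-onset CSVs.

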