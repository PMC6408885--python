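# feedercalls

Wintering tits (great, blue and marsh tits) call at food sources, and those
calls recruit other foragers. Field work on this system combines two data
streams: RFID-equipped feeders that log every visit of a PIT-tagged bird with
a timestamp, and audio annotation of the calls given at the feeder. The
observed pattern — birds give fewer calls per feeder visit in the afternoon
than in the morning, even though afternoon groups are larger — is consistent
with an economic account of recruitment calling: the anti-predator benefit of
one extra recruit scales as 1/N − 1/(N+1) = 1/(N(N+1)), so it collapses as
group size N grows, while competition and the conspicuousness cost of calling
keep rising.

`feedercalls` re-implements that entire analysis chain as a tested, reusable
pipeline, exercisable end-to-end on seeded synthetic data (the original field
data are not deposited):

* **`feedercalls.synthetic`** — generators for (a) multi-site feeder
  *discovery trials* with diurnal structure: right-skewed first-visit times
  (median 27 min after sunrise), a tent-shaped visit intensity peaking near
  13:00, and per-visit Poisson call counts whose log-rate declines linearly
  over the day; and (b) balanced *playback experiments* (every site gets
  playback and silent control, morning and afternoon, in random order 1–4)
  with Gamma latencies and Poisson unique-visitor counts under multiplicative
  condition effects and Gaussian site intercepts. Stimulus schedules (four
  calls per species, 10-min program presented at 0 and +60 min) are generated
  too.
* **`feedercalls.aggregation`** — hourly binning (calls, visits, distinct
  tagged individuals, calls-per-visit), across-site profiles, and the three
  playback response measures: latency to discovery censored at 60 min,
  unique birds within 2 min of discovery, unique birds over the first hour.
* **`feedercalls.permutation`** — the headline test: observed afternoon−morning
  difference in calls-per-visit against a null built by shuffling hour labels
  *within each trial* (restricted permutation), with a two-sided add-one
  p-value, a literal one-sided count, and the central 95% null range.
* **`feedercalls.glmm`** — random-intercept GLMMs fitted by the package's own
  approximate maximum likelihood (adaptive Gauss–Hermite quadrature over the
  site intercept; Laplace as the 1-node case): Gamma log-link for latency,
  Poisson log-link for counts, Wald z tests, and the rule that drops a
  non-significant time-of-day × treatment interaction.
* **`feedercalls.economics`** — the cost–benefit model of recruitment calling:
  net benefit = w_b · P(heard) · 1/(N(N+1)) − w_c · (1−s)·N/(N+1) − w_p ·
  conspicuousness cost, with CALL/NO_CALL decisions and ALONE / SMALL_GROUP /
  LARGE_GROUP regimes over group size.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic data
and write their tables under `results/`:

```sh
python analysis/01_simulate_discovery.py
python analysis/02_diurnal_permutation.py
python analysis/03_simulate_playback.py
python analysis/04_fit_playback_models.py
python analysis/05_recruitment_economics.py
```

Step 02 prints (seeds fixed in the scripts):

```
observed PM-AM calls/visit difference: -0.219
two-sided p_rand: 9.999e-05 (one-sided, observed direction: 9.999e-05)
95% range of randomised differences: [-0.112, +0.104]
```

i.e. the simulated birds give ~0.22 fewer calls per visit in the afternoon,
far outside the null range produced by within-trial shuffling — the morning
excess is real structure, not an artefact of which hours happened to be
sampled. Step 04 then fits the playback models; the pooled treatment row
(playback versus silent control) reads

```
           response  coefficient    se      z   p
            latency       -1.190 0.183 -6.492 0.0
initial_recruitment        0.600 0.086  7.009 0.0
        total_birds        0.577 0.068  8.425 0.0
```

playback cuts discovery latency to roughly exp(−1.19) ≈ 0.3 of the control
value and raises both recruit counts by ~80% (exp(0.6)), at any time of day.
Step 05 scans the economic model: at the default calibration (local
population 50) the net benefit of calling falls monotonically with group
size, a lone bird clearly calls, and the first NO_CALL occurs at N = 6.

The same stages are available as CLI subcommands over project CSV schemas
(`feedercalls simulate-discovery | simulate-playback | aggregate | permtest |
fit-playback | econ-scan`, each with `--seed`/`--out`; run with `--help` for
the documented config keys).

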