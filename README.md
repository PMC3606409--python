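# stepgls

Step detection for single-molecule real-time trajectories embedded in
**correlated (colored) noise**, using generalized least squares (GLS).

Optical-tweezers recordings of molecular motors — e.g. helicase unwinding
traces at 2.5 kHz — are piecewise-constant signals (dwells separated by
abrupt steps) buried in noise that is *autocorrelated in time*: the noise
at one sample depends on the previous few samples. Most step-detection
algorithms assume Gaussian white noise; on colored noise that assumption
produces severe over- or under-counting of steps. `stepgls` instead:

1. characterizes the noise with the autocorrelation (ACF) and partial
   autocorrelation (PACF) functions and fits an AR(p) model (the PACF of an
   AR(p) process cuts off after lag p);
2. proposes candidate step locations with a multi-window quantile-contrast
   statistic **η** ∈ [0, 1] — the mean squared difference of the quartiles
   on either side of each point, normalized by the squared window range —
   scanned over window half-widths 10–1000 so no pre-filtering or
   decimation of high-bandwidth data is needed;
3. fits the step regression
   `y_t = β₀ + Σⱼ βⱼ I(t ≥ tⱼ) + ε_t`
   by GLS, whitening both response and design with the Cochrane–Orcutt
   filter `1 − a₁B − … − a_pB^p` so the transformed errors are i.i.d.;
4. chooses the number of steps by backward elimination — repeatedly drop
   the step with the weakest Student-t p-value — keeping the fit with the
   lowest BIC (`−2ℓ + p ln n`) along the path.

The package also ships the simulation study used to validate the method: a
canonical 33-step "unwinding" fixture with six transient dwells (18–84 ms)
and AR(7) noise with coefficients 0.222, 0.072, 0.035, 0.015, 0.016,
0.003, 0.013, plus an evaluation harness (false positives, missed steps,
dwell-normalized location deviations, per-step detection efficiency).

## Worked example

```python
import stepgls as sg

spec = sg.unwinding_fixture()                    # 33-step fixture, 2.5 kHz
trace, truth = sg.render_trace(spec, sg.ar7_noise(0.30), seed=7)
fit = sg.detect_steps(trace, sg.RunConfig())
report = sg.match_steps(truth, fit.model)
print(fit.model.k, fit.noise.order, len(report.false_positives))
```

Output for this seed:

```
n samples: 97035
detected steps: 33 | true: 33
AR order used for whitening: 7
BIC: 35054.9
false positives: 0 | missed: 0
median |deviation|: 0.02%
first three steps:
  index   3180  size +1.012  se 0.051  p 9.22e-89
  index   3257  size +0.980  se 0.050  p 3.84e-84
  index   8628  size +1.032  se 0.014  p 0.00e+00
```

The detector found all 33 steps with no false positives, identified the
AR(7) noise from the fit residuals, and located steps to within a small
fraction of their adjacent dwells (`size` is the estimated step height in
step units, `se` its GLS standard error). Running the same traces with
`RunConfig(assume_iid=True)` — i.e. pretending the noise is white —
systematically inflates the step count (checked in the test suite), which
is the failure mode the method exists to avoid.

## Command line

```sh
stepgls simulate --out-prefix sim --noise ar7 --seed 1   # trace + truth
stepgls detect sim_trace.tsv --out-prefix fit            # step table + report
stepgls evaluate sim_truth.tsv fit_steps.tsv --trace sim_trace.tsv \
        --out-prefix ev                                  # match report
stepgls diagnose sim_trace.tsv --out-prefix diag         # ACF/PACF, AR order
stepgls replicate --n-reps 20 --seed 1 --out study.tsv   # simulation study
```

Traces are plain TSV (time, value — or one column plus `--rate`); results
are TSV step tables and JSON run reports. `detect --assume-iid` reproduces
the white-noise variant.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch: the two worked deviation-normalization examples;
the AR order identified from a fresh 200,000-sample simulation of the
AR(7) noise; and a 20-replicate run of the simulation study (mean detected
step count, median false-positive and missed-step counts, and the minimum
detection fraction over the six transient steps). Takes ≈7 minutes on one
CPU; all randomness derives from `--seed`.
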