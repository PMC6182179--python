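# srnafb

Modelling and analysis of synthetic **sRNA-based negative-feedback gene
circuits** in *E. coli*: a TetR--sfGFP autorepressor whose effective
feedback strength is tuned by an externally-inducible, translation-
inhibiting small RNA, and a closed-loop circuit in which the output
activator drives an sRNA that silences its own mRNA.

The package is for systems/synthetic biologists who want to simulate,
fit and stress-test these circuits end to end: deterministic ODE models,
exact stochastic simulation and extrinsic-variability sampling for noise
prediction, flow-cytometry summary statistics, least-squares parameter
identification from dose-response data, and a synthetic single-cell data
generator so every pipeline stage is testable from known ground truth.

## The models

All three circuits share mass-action kinetics with Hill-regulated
transcription (time in minutes, species in molecules per cell):

**Autorepressor** — mRNA `m`, protein `p`, aTc input `u1`:

    dm/dt = a0 + a1 / (1 + (R/K_R)^n_R) − δm m ,   R = p / (1 + (u1/θ1)^n1)
    dp/dt = κ m − δp p

**sRNA-tuned autorepressor** — adds inducible sRNA `s` (l-rhamnose `u2`)
and the translationally silent, co-degraded duplex `c`:

    dm/dt = ( as above ) − k s m
    ds/dt = b0 + b1 u2ⁿ²/(θ2ⁿ²+u2ⁿ²) − δs s − k s m
    dc/dt = k s m − δc c

**Closed-loop sRNA circuit** — the output is an activator that (with
`u2`) induces the sRNA silencing its own mRNA; its promoter is
constitutive or m-toluic-acid-inducible (`u3`).

Key statistics: the steady-state output `p*`, the response time **T90**
(first crossing of 90% of steady state), disturbance attenuation under a
multiplicative input modulation `u(t) = u0·u*(t)`, and the output
coefficient of variation **CoV = √(exp σ² − 1)** (σ² the log-variance of
per-cell fluorescence), decomposed into intrinsic (Gillespie simulation)
and extrinsic (parameter-variation) contributions combined in
quadrature. The one number calibrated against experiment is the sRNA
strength `b1`, set so saturating sRNA induction silences the tuned
autorepressor output by **92%**.

See `docs/methods.md` for the full model description, parameter
rationale and numerical choices.

## Worked example

`examples/` contains one short script per capability. Running
`python examples/04_fit_pipeline.py` generates a synthetic flow
experiment (8 rhamnose levels × 3 replicates × 10⁴ gated cells with
extrinsic and measurement noise), summarizes it into replicate geometric
means, fits the four-state model and prints:

```
generated 8 conditions x 3 replicates x 10000 cells
fit rss = 2.471e-05, converged = True
  a1      true          2  fitted      1.997  rel. error 0.13%
  b1      true        192  fitted      192.8  rel. error 0.40%
  n2      true          2  fitted      2.001  rel. error 0.06%
  theta2  true     0.0002  fitted  0.0001995  rel. error 0.27%
fitted-model knockdown at saturating u2: 92.04%  (ground truth: 92.00%)
```

i.e. the four free parameters of the sRNA channel are recovered to
within half a percent, and the fitted model reproduces the calibrated
92% knockdown. `examples/02_response_times.py` shows the dynamic
signatures (aTc-tuning couples output to response time, the sRNA dial
does not, closed-loop feedback cuts T90 from ~120 to ~10 min), and
`examples/03_noise_decomposition.py` the flat, extrinsic-dominated noise
profile.

## Command line

Each stage is also a `srnafb` subcommand driven by a YAML config:

```bash
srnafb generate --config run.yaml --seed 1 --out out/   # synthetic assay
srnafb summarize ...   srnafb fit ...   srnafb dose-response ...
srnafb step-response ...   srnafb noise ...   srnafb disturb ...
```

Every run writes a manifest (config echo, seed, version) before results;
identical config and seed give byte-identical artifacts.

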