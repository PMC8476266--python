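# crpen — penalized subdistribution hazards regression for competing risks

`crpen` selects covariates that drive the **cumulative incidence** of a
specific event type in right-censored competing-risks data — the
setting of, e.g., genomic studies where progression from the disease of
interest competes with death from other causes and the number of
candidate features far exceeds the sample size.

Rather than modeling cause-specific hazards, the package works directly
on the subdistribution scale. With `F1(t | z) = P(T <= t, cause = 1 | z)`
and `A(t | z) = -log(1 - F1(t | z))`, it fits the semiparametric
transformation family

    A(t | z) = g( exp(β'z) · A0(t) ),

where `A0` is an unspecified baseline and `g` a known increasing link:
the identity gives the Fine–Gray proportional subdistribution hazards
model, `g(x) = log(1 + x)` the proportional-odds subdistribution model,
with the full Box–Cox and logarithmic families available. Estimation
is by **weighted nonparametric maximum likelihood**: subjects who fail
from competing causes stay in the pseudo-risk set with inverse
probability of censoring weights built from the product-limit estimator
of the censoring distribution, and the baseline's jump sizes at the
observed event times are profiled out by a self-consistency update.

Sparsity comes from six penalties — adaptive LASSO, adaptive elastic
net, SCAD, MCP, and the ridge-augmented SCAD-L2 / MCP-L2 (whose L2 term
induces a grouping effect among highly correlated covariates) — solved
by a full-gradient ascent with Newton–Raphson switching and tuned by
BIC over a warm-started λ path. A simulation module generates the
matching synthetic designs (AR(1) and grouped-correlation covariates,
subdistribution-mixture and proportional-odds event times, uniform
censoring), and an evaluation harness measures selection sensitivity
(TPR) and false positive rate (FPR) over replicates.

See `docs/methods.md` for the model, algorithm and design choices.

## Worked example

Simulate a dataset with five informative covariates among 50, fit an
MCP-penalized path with BIC selection, and inspect the result:

```bash
crpen simulate --design table1 --n 300 --d 50 --k 0.8 --seed 7 --out demo.csv
crpen fit --data demo.csv --penalty mcp --outdir demo_fit
```

The first command prints

```json
{"written": "demo.csv", "n": 300, "d": 50, "censoring_rate": 0.3233333333333333}
```

and writes `demo.csv` (schema `time,status,cause,z1..z50`) plus
`demo.truth.json` recording the generating truth — here the informative
columns are z1–z5 with coefficients `(0.5, 0.5, -0.5, 0.5, -0.5)`.
The second prints

```json
{"outdir": "demo_fit", "selected": 6}
```

and writes `coefficients.csv`, `baseline.csv` (jump sizes and the
cumulative subdistribution baseline), `path.csv` (λ grid, model size,
BIC and log-likelihood per step) and `report.json`, which for this run
shows

```
"selected_support": ["z1", "z2", "z3", "z4", "z5", "z32"],
"model_size": 6
```

— the full generating support, plus one false positive. The selected
coefficients (`coefficients.csv`) are `0.43, 0.53, -0.38, 0.56, -0.69`
for z1–z5 — sign-correct and close to the generating ±0.5, the gap
being penalized-estimate shrinkage — and `-0.03` for the spurious z32.

The same pipeline is available from Python:

```python
from crpen import PenaltySpec, fit_path, make_design, simulate_dataset

data = simulate_dataset(make_design("table1", n=300, d=50, k=0.8, seed=7))
path = fit_path(data.sample, data.design.link, PenaltySpec("mcp"))
print(path.selected_support)   # -> [ 0  1  2  3  4 31]
```

Replicated selection experiments (the layout of the simulation result
tables) run through `crpen evaluate`:

```bash
crpen evaluate --design table4 --methods mcp,mcp_l2 --n 200 --d 500 \
    --k 0.5 --reps 25 --seed 1 --out grouped.csv
```

which writes per-method means and standard deviations of model size,
TPR and FPR, and a per-variable selection-frequency table.

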