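# crckinetics

Kinetic modelling of DNA-repair-protein recruitment and removal at laser
micro-irradiated DNA damage sites in living cells.

After a focused UV pulse inflicts complex DNA lesions in a cell nucleus,
fluorescently tagged repair proteins accumulate at the damage site over
seconds to tens of minutes, dwell there, and (for most proteins) dissociate
again.  Time-lapse imaging yields, for each protein, a curve of mean
damage-site intensity ± SD across 8–21 cells.  `crckinetics` quantifies such
curves with the **consecutive reactions chain (CRC) model**: recruitment is an
irreversible chain of first-order reactions

```
X₀ --k₁--> X₁ --k₂--> … --k_{n−1}--> X_{n−1}
```

whose terminal member is the bound, observed species, I(t) = A·X_{n−1}(t).
Proteins that detach carry a final dissociation reaction with rate constant
k_n which becomes active only after a detachment delay τ.  Measured curves are
often sums of several such chains — multiphase recruitment, "removable" plus
"non-removable" fractions — optionally plus a residual photobleaching deficit
B(t) = −A_b·e^(−k_b t).

The package provides, in the statsmodels idiom (a `CRCModel` estimator whose
`fit()`/`fit_select()` return a `CRCResults` object):

- exact (Bateman-type sum-of-exponentials) and stiff-ODE evaluation of chain
  models, cross-checked against each other;
- multistart weighted nonlinear least-squares fitting with log/softplus
  parameter transforms (rates and amplitudes stay positive);
- minimal chain-length selection: n is increased until the fit quality stops
  improving (AICc by default);
- composite decomposition (phases, non-removable fractions, bleach) and
  fit-and-subtract bleach correction;
- derived scalars — recruitment/removal halftimes, peak time, plateau
  fraction — plus temporal ranking and treated-vs-untreated comparison
  (parameter ratios, halftime deltas, recruitment-order shifts);
- a synthetic-data generator emulating the acquisition design (per-cell
  amplitude spread, detector noise, acquisition photobleaching and its
  compensation) and a deterministic benchmark-fixture suite;
- CSV/XLSX curve tables, JSON model specs, and a `crckinetics` command-line
  tool (`simulate`, `fit`, `select`, `halftime`, `compare`, `bleach-correct`,
  `fixtures`).

## Worked example

Simulate a 12-cell experiment from a known three-reaction model
(k = 0.05, 0.02, 0.005 s⁻¹, τ = 100 s, A = 1000) with 5% noise, then recover
the model without telling the fitter the chain length:

```python
import crckinetics as ck

truth = ck.CompositeModel.single(
    ck.CRCParameters(rates=(0.05, 0.02, 0.005), detachment_delay=100.0,
                     amplitude=1000.0, has_removal=True))
design = ck.SimulationDesign(n_cells=12, sampling_interval=2.0, duration=600.0,
                             noise_sd_fraction=0.05, cell_scale_sd=0.2, seed=42)
curve = ck.simulate_curve(truth, design)

model = ck.CRCModel(curve, options=ck.FitOptions(seed=42))
res = model.fit_select(removal=True)
print(res.summary())
```

```
CRC model fit
================================================================
protein: synthetic    treatment: none
observations: 301    free parameters: 5
weighted SSE: 37338.5    reduced chi^2: 126.144
converged: True    seed: 42
selected chain length n = 3
----------------------------------------------------------------
parameter               estimate         std err
c0.k1                  0.0189497       0.0006609
c0.k2                   0.054447        0.002882
c0.k3                 0.00504221       4.778e-05
c0.tau                       100           1.254
c0.A                     1068.42           10.01
baseline                       0         (fixed)
----------------------------------------------------------------
n            criterion             sse
2              1796.54          113755
3              1463.31         37338.5
4              1462.97           37038
```

The selector tries n = 2, 3, 4 and keeps n = 3: the AICc improvement from
3 to 4 (0.34) is below the acceptance threshold of 2.0.  Recruitment rates
within a chain are exchangeable (the curve is invariant under permuting
k₁…k_{n−1}), so the fitted pair {0.019, 0.054} matches the generating pair
{0.02, 0.05} as a set; the dissociation rate k₃ ≈ 0.005 s⁻¹ and the delay
τ = 100 s are recovered directly.  The derived scalars:

```python
s = ck.summarize(res.model)
```

```
recruitment halftime: 44.4 s     (truth: 44.7 s)
removal halftime:     301.0 s    (truth: 299.9 s)
peak time:            104.8 s
plateau fraction:     0.000
```

The same pipeline from the shell:

```sh
crckinetics --seed 42 fixtures --outdir fixtures/
crckinetics --seed 42 select --curve fixtures/delayed_removal.curve.csv \
            --removal --out selected.json
crckinetics halftime --model selected.json
```

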