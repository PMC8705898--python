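# topeq

Extended pharmaceutical equivalence analysis for topical semisolid products.

Demonstrating that two semisolid products (or two batches of the same
product) are equivalent involves far more than assay: regulators ask for the
same **microstructure** (droplet size, crystalline structure, rheology), the
same **in vitro release** through a synthetic membrane (IVRT) and, for complex
formulations, the same **in vitro permeation** through excised human skin
(IVPT). `topeq` implements that full analysis chain for Franz-diffusion-cell,
rheometer, droplet-size and powder-diffraction data, together with a
synthetic-study generator so every stage can be exercised and validated
without laboratory data. It is aimed at formulation scientists and
biostatisticians running batch-comparison or generic-development studies.

## The statistics at the core

Each comparison places a 90% confidence interval for a test/reference ratio
inside an acceptance range. From per-arm summaries (X̄, s², n):

- difference CI: (X̄ₜ − X̄ᵣ) ± t₁₋α/2,df · √(s²ₜ/nₜ + s²ᵣ/nᵣ), Welch–Satterthwaite df
  (pooled df available);
- ratio CI: X̄ₜ/X̄ᵣ ± t₁₋α/2,df · √(s²ₜ/nₜ + s²ᵣ/nᵣ) / X̄ᵣ — the difference CI
  shifted by the reference mean and divided by it;
- log-scale ratio CI (IVPT): the difference CI applied to log-transformed
  per-donor means and exponentiated, i.e. a CI for the ratio of geometric
  means.

Acceptance ranges (closed, on the ratio scale): **90–110%** for
physicochemical/microstructure parameters, **90–111%** for IVRT release
parameters, **80–125%** for IVPT permeation parameters. A verdict is `within`,
`outside` or `straddles`; a discriminatory (negative) control must fall
entirely `outside`.

Upstream of the statistics:

- **kinetics**: sampling-replacement correction
  Qₙ = (Cₙ·V_receptor + Σ_{i&lt;n} Cᵢ·V_sample)/A for periodic receptor draws;
- **ivrt**: Higuchi fits (Q vs √t slope K, Q6h) plus the four-part method
  validation (linearity across strengths, intermediate precision CV%,
  discriminatory power, robustness ANOVA);
- **ivpt**: TEER integrity gate (> 2000 Ω), steady-state flux and lag time,
  replicate → donor geometric means, mass balance;
- **rheology**: η at 300 s⁻¹, relative thixotropic loop area
  RTLA = 100·S_thix/S_asc, oscillatory yield stress, G\* and phase angle δ in
  the linear viscoelastic region;
- **microstructure**: droplet statistics with an Anderson–Darling normality
  check, diffraction peak detection over an amorphous hump, type I/II pattern
  classification (±0.2° 2θ) and Bragg spacings d = λ/(2 sin θ).

## Worked example

Release equivalence of two batches from their summary statistics
(Q6h means 57.27 vs 56.69 µg/cm², SDs 4.08 vs 8.88, n = 12 each):

```bash
topeq equivalence --test-mean 57.27 --test-sd 4.08 --test-n 12 \
                  --ref-mean 56.69 --ref-sd 8.88 --ref-n 12 \
                  --range ivrt_90_111
```

prints

```json
{
  "ci": {
    "alpha": 0.1,
    "df": 15.446126592572234,
    "kind": "ratio",
    "lower": 0.9231592205986627,
    "point": 1.0102310813194568,
    "range": "ivrt_90_111",
    "range_limits": [0.9, 1.11],
    "status": "within",
    "upper": 1.097302942040251
  },
  "ratio_percent": 101.02,
  ...
}
```

The batches release at essentially the same rate (ratio 101.02%) and the
whole 90% CI (0.923–1.097) sits inside 90–111%, so the release parameters are
equivalent. A full synthetic study runs end to end the same way:

```bash
topeq simulate --scenario examples/scenario_pilot.yaml --out study/
topeq ivrt-equivalence --test study/ivrt_batch1.csv --ref study/ivrt_batch2.csv
```

which fits Higuchi kinetics to each simulated Franz cell and reports, for
this scenario, K and Q6h ratios near 104% with `within` verdicts —
consistent with the generating release constants (28.7 vs
28.1 µg·h^-1/2·cm⁻²). The other subcommands (`ivpt-equivalence`,
`ivrt-validate`, `rheology`, `microstructure`) consume the matching CSVs in
`study/`.

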