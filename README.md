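# invivokin

Inference of **in vivo enzyme kinetics from steady-state metabolomics**, built
around a concrete biological puzzle: in *E. coli* strains carrying
destabilizing mutations in dihydrofolate reductase (DHFR), the pool of dTMP
drops to 10–50% of wild type, yet the next metabolite down the pyrimidine
pathway, dTDP (made from dTMP by thymidylate kinase, Tmk), drops to 1–20% — a
disproportionate collapse that the enzyme's ordinary in vitro
Michaelis–Menten behaviour cannot produce.

## The model

At steady state the flux producing an intermediate equals the flux consuming
it. For two consecutive enzymes obeying Hill kinetics with coefficients *m*
(upstream) and *n* (downstream),

    E10·k2·S1^m/(K*M1 + S1^m) = E20·k4·S2^n/(K*M2 + S2^n)

which rearranges to

    S2 = ( A·S1^m / (B + C·S1^m) )^(1/n),
    A = k2·K*M2·E10,  B = k4·K*M1·E20,  C = k4·E20 − k2·E10.

Consequences the package computes and tests:

* **MM chain (m = n = 1, C ≥ 0):** S2 is hyperbolic in S1 and a substrate
  fold-drop *f* can never depress the product pool below *f* — a 10-fold dTMP
  drop can never explain a 100-fold dTDP drop.
* **Hill chain (m = 2.5, n = 1):** in the low-substrate lag the product ratio
  approaches *f*^2.5 ≈ 0.003 for *f* = 0.1 — "1% or less", matching the
  observation.
* **Cooperative scatter iff m > n:** the apparent cooperativity of a
  steady-state S2-vs-S1 scatter at low S1 is exactly *m/n*.
* **Where the cooperativity comes from:** under diffusion limitation (e.g.
  substrate channeling in a metabolon) the rate "constant" decays as
  k0·t^(−h), which converts a bimolecular step into effective order
  α = 2 + h/(1−h) and an enzyme's rate law into an apparent Hill form —
  cooperativity without allostery.

The fitting machinery reproduces the paper-style statistics: unweighted
multi-start nonlinear least squares for Michaelis–Menten, 3-parameter Hill
and 4-parameter log-logistic (apparent K_I) models, initial rates from the
first 20 s of kinetic traces, and the extra sum-of-squares F-test for the
nested MM-vs-Hill comparison. A seeded synthetic-metabolomics generator
stands in for the original LC-MS deposit, with the same design (strains ×
conditions × 2/4/6/8 h × replicates, lognormal noise, detection-limit
censoring).

## Worked example

```bash
invivokin simulate --seed 1 --out table.csv
invivokin infer table.csv --out report.json
```

prints (seed 1):

```
unsupplemented Hill exponent 2.34; supplemented 0.875; min mutant ratio 0.004562
```

i.e. the in vivo Tmk activity curve assembled from metabolite pairs produced
*by the cell itself* is strongly cooperative (Hill exponent ≈ 2.5 truth), the
curve from externally supplied dTMP is hyperbolic (exponent ≈ 1), and under
the fitted cooperative curve a 10-fold dTMP drop drives dTDP to ~0.5% of
wild type — below the observed 1%, which no MM-form curve can reach. The same stages are available as numbered drivers under
`analysis/` (simulation, in vitro assay fits, in vivo Hill fits, the
mutant-ratio scan, the (m, n) cooperativity grid, and fractal effective
orders), each writing tables under `results/`.

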