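# cfbaudit

Tools for auditing the **concordance statistic for benefit** (*cfb*), a
rank-based discrimination metric for treatment-benefit predictors, together
with a Gini-type **Concentration of Benefit** alternative.

## The problem

Precision medicine asks not "who is at risk?" but "who benefits from
treatment?". With a binary treatment T and binary outcome Y, the individual
treatment benefit is the ternary contrast of potential outcomes
B = Y⁽¹⁾ − Y⁽⁰⁾ ∈ {−1, 0, +1} (harm / no effect / benefit). A benefit
predictor h(X) maps baseline covariates to a predicted benefit H = h(X); the
best possible predictor is the conditional mean h\*(x) = E[B | X = x].

The *cfb* extends the familiar c-statistic to this setting. For two random
patients,

    cfb = Pr(H₁ > H₂ | B₁ > B₂) + ½ Pr(H₁ = H₂ | B₁ > B₂),

i.e. concordant pairs score 1, prediction ties ½, discordant pairs 0, and
pairs tied on benefit are ignored. A benefit-independent predictor scores 0.5.

This package provides the machinery to show, by exact computation on discrete
populations, that *cfb* has structural defects as a scoring rule:

1. **Improperness** — populations exist where the *true* predictor h\* scores
   *below* 0.5, i.e. below random guessing. The package enumerates all such
   two-stratum populations on a probability-simplex grid, extends them to a
   continuous covariate X ~ Beta(ε, ε), and screens which of them can arise
   from conditionally independent counterfactual outcomes.
2. **Sensitivity to the counterfactual correlation ρ** — in a linear-Gaussian
   potential-outcomes model, cfb\* = ½ + arcsin(sd(H\*)/sd(B))/π depends on
   the correlation between the two arms' noise terms, a quantity no observable
   data can identify.
3. **Sensitivity to the matched-pair definition** — with only observed trial
   data, B is replaced by the outcome difference within a matched
   treated/control pair. Matching on the covariate X versus on the prediction
   H = h(X) gives different *cfb* values whenever h is not bijective, and the
   pair-sampling scheme can distort the covariate distribution.

The Concentration of Benefit, C_b = E|H₁ − H₂| / (2 E[H]) (the Gini
coefficient of the predicted-benefit distribution), is provided as a
dispersion-based alternative that needs neither matching nor counterfactual
assumptions.

## Worked example

The two-stratum "breast cancer surgery" population has Pr(X=1) = 0.5 and
benefit triples (0.25, 0.01, 0.74) for X = 0 and (0.14, 0.18, 0.68) for X = 1:

```python
from cfbaudit import (WORKED_EXAMPLE_POPULATION, cfb_from_table,
                      expected_benefit, pair_table, true_predictor)

pop = WORKED_EXAMPLE_POPULATION
h = true_predictor(pop)
print([h(0), h(1)])                  # [0.49, 0.54]
print(expected_benefit(pop))         # 0.515
table = pair_table(pop, h)
print(table.to_frame())
res = cfb_from_table(table)
print(round(res.value, 7))           # 0.4908655
```

The pair-relation table printed above is

```
          B1<B2    B1=B2     B1>B2
H1<H2  0.055450  0.13500  0.059550
H1=H2  0.109425  0.28115  0.109425
H1>H2  0.059550  0.13500  0.055450
```

so cfb\* = (0.05545 + ½·0.109425)/0.224425 = **0.4908655 < 0.5**: the best
possible predictor loses to a coin flip, so *cfb* is not a proper scoring
rule. The same commands are available from the shell:

```sh
cfbaudit worked-example --out results/worked_example
cfbaudit improper-search --step 0.01 --out results/improper_search
cfbaudit rho-curve --out results/rho_curve
cfbaudit matching-sweep --n-combos 10000 --seed 0 --out results/matching_sweep
cfbaudit feasibility-screen --step 0.05 --out results/feasibility
```

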