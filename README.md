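# anchorlink

Anchor-item IRT test equating and Monte-Carlo parameter-recovery
simulation.

`anchorlink` simulates dichotomous item responses under 2PL/3PL logistic
models, calibrates each test form by marginal maximum likelihood (EM with
fixed standard-normal quadrature, EAP ability scoring), links forms
through shared anchor items with five equating methods — mean-sigma (MS),
mean-mean (MM), mean-geometric-mean (MGM), Haebara/item response function
(IRF), and Stocking-Lord/test response function (TRF) — composes links
into chains for indirect equating, and scores parameter recovery
(Pearson r, bias, RMSE, MAE, SEE) of discriminations, difficulties and
abilities against the generating values across a factorial design of
test-set size × anchor proportion × sample size × guessing probability.

## Layout

| module | contents |
|---|---|
| `anchorlink.irt_core` | parameter containers, item characteristic curves, item-bank and response simulation |
| `anchorlink.calibration` | MML-EM fitting of 2PL/3PL, EAP scoring, quadrature grid |
| `anchorlink.equating` | the five linking methods, linear transforms, chain composition |
| `anchorlink.recovery` | recovery indices, 2.5 % quantile trimming, factor-level summaries |
| `anchorlink.study` | design grid, end-to-end iteration runner, convergence statistics |
| `anchorlink.cli_io` | CSV/JSON formats, YAML config loading, CLI |

## CLI

```sh
# simulate a (sub)grid of scenarios and write long-format records
anchorlink run-study --config study.yaml --seed 1 --out results/

# trim and average the records into factor-level tables
anchorlink summarize --records results/records.csv --out summary.csv

# link one item-parameter table onto another's scale
anchorlink equate --method mm --source form1.csv --target form2.csv \
    --out-transformed form1_on_form2.csv

# chained (indirect) equating through intermediate forms
anchorlink equate --method irf --source form1.csv --target form2.csv \
    --chain form3.csv

# emit the worked-example anchor tables used in tests/docs
anchorlink make-fixtures --out fixtures/
```

A study config is YAML with any subset of
`tss_levels, aip_levels, n_levels, c_levels, iterations, master_seed,
models, methods, calibration, anchor_a`; omitted keys fall back to the
full default design (4 × 5 × 5 × 4 = 400 scenarios, 1000 iterations).

## Library example

```python
from anchorlink import (
    generate_item_bank, generate_abilities, simulate_responses,
    fit_irt, AnchorPairs, compute_coefficients, transform_item,
)

bank = generate_item_bank(tss=40, n_anchor=6, c=0.125, rng_seed=1)
fits = {}
for form, (mu, sd) in zip((1, 2), ((-0.5, 0.8), (0.0, 1.0))):
    sample = generate_abilities(500, mu, sd, form_index=form, rng_seed=form)
    responses = simulate_responses(sample, bank.form_items(form), rng_seed=10 + form)
    fits[form] = fit_irt(responses, model="3PL")

pairs = AnchorPairs.from_estimates(
    fits[1].estimates_by_id(), fits[2].estimates_by_id(),
    [it.item_id for it in bank.anchors("link12")],
)
coef = compute_coefficients("TRF", pairs, source_form=1, target_form=2)
on_form2_scale = [transform_item(it, coef) for it in fits[1].item_estimates]
```

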