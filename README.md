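# xorseq

Design, simulation and analysis tools for **unbalanced exclusive-or (XOR)
sequence-learning experiments** — serial reaction-time tasks in which
participants touch three successive stimuli on a 3×3 grid and the response
times between stimuli track what has been learned about the sequence
statistics.

## The problem

A triplet sequence *X–Y–Z* carries two kinds of statistical structure:

* the **frequency** of the sequence, *f(XYZ)* — how often it occurs;
* **transitional probabilities (TPs)** — the first-order
  *p(Y|X)* and *p(Z|Y)*, and the second-order *p(Z|X,Y)*.

These dissociate. In the canonical unbalanced XOR design used here, four
triplets {ABC, AEF, DBF, DEC} are shown with frequencies .40/.25/.25/.10:

| sequence | frequency | p(2nd\|1st) | p(3rd\|2nd) | p(3rd\|1st,2nd) |
|----------|-----------|-------------|-------------|------------------|
| ABC      | .40       | .62         | .62         | 1                |
| AEF      | .25       | .38         | .71         | 1                |
| DBF      | .25       | .71         | .38         | 1                |
| DEC      | .10       | .29         | .29         | 1                |

The third item is perfectly predicted by the *combination* of the first two
(second-order TP = 1, the XOR property) but by neither alone, and the pair
with the highest first-order TP (D→B, .71) is *not* the most frequent pair
(A→B, .40). A learner driven by prediction should therefore order its
response times by TP, not by frequency — and lose its third-item advantage
in a **switch phase** where the third items are permuted across triplets
({ABF, AEC, DBC, DEF}), preserving every adjacent pair while invalidating
every learned triplet.

`xorseq` provides, as importable modules and a CLI:

* **design calculus** — first-order / second-order / non-adjacent TPs on
  weighted sequence inventories, XOR validation, switch-design construction;
* **scheduling** — the 224-trial training phase with full coverage of all 72
  ordered grid transitions, exhaustive *yoking* of items to grid positions
  so the eight design transitions have near-equal movement times, and the
  blocked learning + switch schedule (10 × 40 trials with exact
  largest-remainder allocation: 16/10/10/4 per block);
* **a synthetic cohort generator** — participants who incrementally track
  TPs with a pseudocount estimator and respond faster to predictable
  stimuli, standing in for human data;
* **preprocessing** — the [150, 850] ms outlier window (or ±k·SD) and
  wide-to-long reshaping with TP/frequency covariates;
* **statistics** — trial-level linear mixed models with participant random
  intercepts (via `statsmodels`), the full battery of planned contrasts,
  learning-curve aggregation/plots, and AIC comparison of the candidate
  TT2 learning-curve models.

## Worked example

```python
from xorseq import (xor_design, tp_table, build_switch, simulate_cohort,
                    reshape_long, filter_rts, run_planned_contrasts,
                    compare_models_aic)

design = xor_design()
print(tp_table(design))
#   sequence  frequency  tp_1_2  tp_2_3  second_order_tp
# 0      ABC       0.40    0.62    0.62              1.0
# 1      AEF       0.25    0.38    0.71              1.0
# 2      DBF       0.25    0.71    0.38              1.0
# 3      DEC       0.10    0.29    0.29              1.0

print(build_switch(design).labels)
# ('ABF', 'AEC', 'DBC', 'DEF')

cohort = simulate_cohort(design, n_participants=20, master_seed=12)
kept, report = filter_rts(reshape_long(cohort, design))
print(f"removed {100 * report.fraction_removed:.1f}% of rows")
# removed 0.3% of rows

learn = kept[(kept.phase == "learning") & (kept.transition == "TT1")]
print(learn[learn.block == 10].groupby("seq").rt.mean().round(0).to_dict())
# {'ABC': 367.0, 'AEF': 440.0, 'DBF': 353.0, 'DEC': 458.0}
```

Block-10 TT1 means order by first-order TP (DBF .71 fastest, DEC .29
slowest), not by frequency (ABC is the most frequent sequence but not the
fastest). The mixed-model contrasts and the AIC comparison make that formal:

```python
results = {r.label: r for r in run_planned_contrasts(kept)}
t = results["tp_vs_freq_tt1"].primary        # block x TP interaction, DBF vs ABC
print(f"F({t.num_df},{t.den_df}) = {t.fvalue:.1f}, p = {t.pvalue:.2g}")
# F(1,5196) = 54.1, p = 2.2e-13

print(compare_models_aic(kept).ranking)
# ['block*frequency*tp', 'block*tp', 'block*frequency']
```

The same pipeline runs from the shell:

```bash
xorseq design                      # TP table + XOR validation
xorseq pipeline --participants 20 --seed 12 --out-dir scratch/run
```

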