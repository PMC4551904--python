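# rax2

Nonparametric large-scale association testing for poly(A)-site ("tag")
usage changes between two conditions, from replicated 3'-end sequencing
count tables.

For every tag of a multi-tag transcription unit the package builds the
replicate series of 2x2 tables (tag vs rest-of-gene x condition) and derives
two statistics: a **treatment chi-square** (Pearson chi-square of the table
of replicate means) and a **null chi-square** estimated purely from
within-condition replicate variation.  Both statistic vectors are ranked and
compared position by position; scanning a grid of thresholds on the
rank-matched difference yields declared tag sets and a nonparametric FDR
estimate per threshold.  Downstream utilities classify declared multi-tag
genes into forward/backward switch and positive/negative accordance
patterns, and compute symmetric fold changes.

## Layout

| module            | contents |
|-------------------|----------|
| `rax2.io`         | count/design CSV I/O, median-of-ratios library normalization, per-gene 90%-coverage tag filter, single-tag-gene filter |
| `rax2.core`       | 2x2 series construction, treatment/null chi-squares, ranking, threshold scan, FDR curve, declaration |
| `rax2.simulate`   | negative-binomial null table simulator with injected association effects and true-vs-estimated FDR calibration |
| `rax2.baselines`  | mean-table Pearson and Fisher tests, CMH over replicate strata, Benjamini-Hochberg adjustment |
| `rax2.patterns`   | switch/accordance classification and fold changes |
| `rax2.cli`        | `rax2 run / simulate / baselines / classify` |

## CLI

```bash
# full pipeline: normalize -> filter -> ranked chi-squares -> declare -> patterns
rax2 run --counts counts.csv --design design.csv --out-dir out/ --alpha 0.05

# simulate a benchmark table with known effect tags and evaluate calibration
rax2 simulate --tags 5000 --replicates 3 --effect-fraction 0.1 \
    --seed 1 --out-dir sim/ --evaluate

# reference tests and BH adjustment
rax2 baselines --counts counts.csv --design design.csv \
    --methods pearson,fisher,cmh --out pvalues.csv

# pattern classification for an external declared-tag list
rax2 classify --counts counts.csv --design design.csv \
    --declared declared.txt --out patterns.csv
```

Count CSV dialect: header `tagid,geneid,name,strand,pos,annotation` followed
by one column per library; the design CSV maps `library_id,condition,replicate`
with condition `rest`/`stim` (or `1`/`2`) and an equal number of replicates
per condition.  All commands are deterministic given their options and
`--seed`; outputs carry the seed in a `#` header comment.

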