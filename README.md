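# cbqpcr — Common Base Method analysis of qPCR data

`cbqpcr` analyses relative gene expression from quantitative PCR the way the
statistics want it done: **entirely in log scale, for as long as possible**.

Each well of a qPCR plate yields two numbers — the quantification cycle
`Cq` and the amplification efficiency `E` (fold-amplification per cycle,
at most 2). Since the starting template quantity is proportional to
`E^(−Cq)`, wells with different efficiencies live on different exponential
scales. The common-base trick rewrites `E^Cq = 10^(log10(E)·Cq)` and works
with the *efficiency-weighted Cq value*

```
Cq(w) = log10(E) · Cq
```

which puts every well on one shared log10 scale. From there everything is
ordinary linear statistics:

- technical replicates are averaged arithmetically:
  `Cq(w)_{r,t,g} = (1/n) Σ_i log10(E_i)·Cq_i`;
- the gene of interest (GOI) is normalized against any number of reference
  genes by subtracting the arithmetic mean of their weighted values
  (equivalent to dividing by their geometric mean, without ever computing
  one): `ΔCq(w) = Cq(w)_GOI − mean_j Cq(w)_REF_j`;
- two conditions are compared through
  `ΔΔCq(w) = ΔCq(w)_A − ΔCq(w)_B` — a difference of group means (unpaired
  design) or a mean of within-pair differences (paired design);
- t-tests (Welch by default), randomized-complete-block ANOVA (plates or
  individuals as blocks) and Bonferroni post-hoc contrasts run on the
  ΔCq(w) values, where lognormal expression is approximately normal;
- only at the very end is the **relative expression ratio** recovered,
  `R = 10^(−ΔΔCq(w))`, together with an asymmetric confidence interval
  obtained by back-transforming the log-scale t-interval.

With a single reference gene and constant efficiencies this reduces
exactly to the classical efficiency-corrected fold-change formula, and to
`2^(−ΔΔCq)` when `E = 2`; the test suite verifies both equivalences to
1 part in 10¹².

The package also ships a deliberately *wrong* analysis
(`cbqpcr demo-misuse`): t-testing per-pair ratios directly on the ratio
scale, which can simultaneously reject "A vs B" and fail to reject
"B vs A" on the same data. The log-scale method is immune — swapping the
groups negates the estimate and inverts the ratio while leaving the
p-value untouched.

## Worked example

The bundled example data (`cbqpcr.datasets`) contain the normalized
ΔCq(w) values of four biological replicates measured in two conditions:

```python
from cbqpcr import datasets, inference

delta = datasets.unpaired_delta_cq()
result = inference.analyze_pair(
    delta, "A", "B", inference.DesignSpec(mode="paired")
)
print(result.ratio, result.ratio_ci)
```

or, from the shell, writing `demo.csv`/`demo.txt`:

```
$ cbqpcr analyze --input delta.csv --level delta --design paired --out demo
paired analysis (log base 10)
  estimate (log scale)     -0.5462
  SE (log scale)           0.1569
  t = -3.48 on df = 3, two-tailed p = 0.040
  95% CI (log scale)      (-1.0456, -0.0469)
  expression ratio         3.52
  95% CI (ratio scale)    (1.11, 11.1)
  n pairs                  4
```

Reading: the gene of interest is expressed about 3.5× higher in condition
A than in condition B (normalized to the reference genes), significantly
different from ratio 1 at the 5% level; the 95% interval for the true
fold-change runs from 1.11 to 11.1 and is asymmetric about 3.52 because it
was built in log scale and back-transformed.

Per-well tables go in as long-format CSV (one well per row, columns
`replicate, sample_type, gene, role, plate, well, efficiency, cq`;
instrument-specific headers are handled with `--schema`). Three-condition
studies use `--design anova` with `--block plate` or `--block replicate`,
producing the ANOVA table plus pairwise post-hoc ratios with CIs.
`cbqpcr simulate` generates synthetic plates with known ground truth from
a lognormal variance-components model (biological, plate, technical), used
by the test suite to verify type-I error, confidence-interval coverage and
the power gained by plate blocking.

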