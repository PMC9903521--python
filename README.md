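# panretain

Population-based comparative gene retention analysis for pangenome panels of
species with differing ploidy.

When a gene duplicates, the most likely fate of the new copy is loss; copies
caught mid-way to fixation are present in some individuals of a population
and absent in others. `panretain` measures this directly from pangenome
presence/absence data: for every hierarchical orthologous group (HOG) it
computes the **gene retention rate**

> GRR = 100 × (lines carrying the gene) / (lines in the panel)

in each species panel, then asks how retention varies with gene dosage. The
motivating system is the Triticeae: a diploid barley panel (20 lines), a
tetraploid wild emmer panel (20 lines) and a hexaploid bread wheat panel
(15–16 lines), where a duplicated vitamin-E biosynthesis gene is retained in
65%, 40% and 12.5% of lines respectively — retention falling as the number
of redundant homologous copies rises (gene dosage constraint).

On top of the core statistic the package provides:

- a **dosage-pattern filter** keeping HOGs with strictly decreasing GRR
  along a ploidy-ordered species list (GRR_barley > GRR_emmer > GRR_wheat);
- **R_bw categorisation** (R_bw = GRR_barley/GRR_wheat; ≥ 1.2 barley
  preferential, 0.9 < R_bw < 1.1 neutral, ≤ 0.8 wheat preferential);
- **family-size correlation**: Pearson r between parent-orthogroup size
  (number of member HOGs) and mean GRR — negative under dosage constraint;
- a **duplication-type classifier** (singleton / dispersed / proximal /
  tandem / WGD-segmental) from homology hits, gene ranks and a collinear
  block detector;
- pairwise **Ka/Ks by NG86 counting** (site fractions, pathway-averaged
  differences, Jukes–Cantor correction) with codon back-translation;
- **codon selection tests**: GY94/F1X4 likelihood on labeled trees, branch
  models (one ω per branch group), branch-site Model A and its ω2 = 1 null,
  naive-empirical-Bayes site posteriors, chi-square LRTs;
- **hypergeometric GO enrichment** with BH-FDR, −log10 p enrichment scores
  and term-overlap network edges;
- seeded **synthetic-pangenome generators** with ground truth for every
  stage, so the whole pipeline is testable without external genome data.

## Worked example

```python
import numpy as np
import panretain as pr

# retention of one gene across the three published panels
barley = np.array([True] * 13 + [False] * 7)   # 13 of 20 lines
emmer  = np.array([True] * 8  + [False] * 12)  # 8 of 20
wheat  = np.array([True] * 2  + [False] * 14)  # 2 of 16
rates = [pr.grr(p) for p in (barley, emmer, wheat)]
print(rates)                        # [65.0, 40.0, 12.5]

# retention against homologous copy number (1, 2, 3)
print(round(pr.pearson([1, 2, 3], rates), 4))   # -0.9996

# branch test: two-ratio vs one-ratio model from log-likelihoods
res = pr.lrt(-8204.98, -8199.87, df=1)
print(round(res.stat, 2), round(res.p_value, 4))  # 10.22 0.0014
```

The retention rates fall steeply with ploidy (the dosage-constraint
signature), their correlation with copy number is almost perfectly negative,
and the likelihood-ratio test shows a two-ratio branch model (separate ω for
the duplicated lineage) fits significantly better than a single shared ω —
the duplicate evolves under relaxed constraint.

End-to-end on synthetic data:

```bash
panretain simulate --preset dosage --seed 7 --out study/
panretain run-study --config study/config.yaml --out report/
```

`report/report.json` then contains the retention summary, the pattern gene
set, R_bw category counts, and per-category GO enrichment, with a
provenance block (config hash, seed, version).

## Layout

```
src/panretain/
  io.py          readers/writers: HOG tables, PAV matrices, GFF3, FASTA,
                 Newick with #k branch labels, missingness-based PAV calls
  retention.py   GRR, pattern filter, R_bw, family-size correlation
  dupclass.py    hit filtering, collinear blocks, duplication classifier
  kaks.py        back-translation, NG86, relative Ka/Ks, binning, t-tests
  codonmodel.py  GY94/F1X4 rate matrices, pruning likelihood, branch and
                 branch-site fits, LRTs
  enrichment.py  hypergeometric tests, BH-FDR, term-overlap edges
  simulate.py    seeded generators with ground truth
  pipeline.py    config validation and the end-to-end study
  cli.py         `panretain` subcommands
```

See `docs/methods.md` for the models, conventions and limitations.
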