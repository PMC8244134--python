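# refstab

Reference-gene stability validation for RT-qPCR and RNA-seq.

Comparative gene expression studies normalize target-gene mRNA levels to
*reference* ("housekeeping") genes assumed to be stably expressed across the
experimental groups. When a reference gene's own expression depends on the
condition — for example, when most housekeeping genes are expressed more
strongly in adult blood than in neonatal cord blood — every normalized fold
change inherits that bias, and true developmental differences can be
abolished or inverted. `refstab` implements the standard validation toolkit
for choosing reference genes and detecting such systematic bias:

* **BestKeeper** — descriptive stability on the cycle-threshold (ct) scale:
  per-gene SD of ct, and Pearson correlation (r, r²) of each gene with the
  BestKeeper index (per-sample geometric mean of all candidates' ct values).
  Genes with SD > 1 cycle (>2-fold template variation) are demoted below all
  others; the rest are ranked by descending r².
* **NormFinder** — model-based stability: per-sample centering decomposes each
  gene's log-scale expression into intergroup bias *d*<sub>ig</sub> and
  intragroup variance γ²<sub>ig</sub>; the stability value is
  ρ<sub>i</sub> = (1/G) Σ<sub>g</sub> ( |d̃<sub>ig</sub>| +
  √(γ²<sub>ig</sub>/n<sub>g</sub>) ), with d̃ the noise-shrunk intergroup
  estimate. A greedy search assembles a multi-gene normalization factor whose
  opposite-sign biases cancel.
* **GeNorm** — pairwise stability: M<sub>j</sub> = mean over partners k of
  SD(log₂ q<sub>j</sub>/q<sub>k</sub>), iterative elimination of the
  highest-M gene, and the pairwise-variation series
  V<sub>n,n+1</sub> = SD(log₂ NF<sub>n</sub>/NF<sub>n+1</sub>) to decide how
  many genes a normalization factor needs (V < 0.15 ⇒ n genes suffice).
* **Consensus workflow** — run all three over configurable group subsets,
  aggregate by mean rank, vet the proposed normalization factor against the
  best single gene (accepted only if strictly more stable), guard GeNorm's top
  pair against co-regulated gene-family members, and attach per-gene
  intergroup bias flags (one-way ANOVA on log₂ expression).
* **RNA-seq screen** — upper-quartile normalize a count matrix, filter genes
  by mean log₂(UQ) > 5, SD log₂(UQ) < 1, and no sample deviating ≥ 2 from the
  gene mean, then rank candidates by coefficient of variation; two datasets
  can be screened independently and their intersection re-screened combined.
* **Synthetic cohorts** — ct and negative-binomial count generators with known
  ground truth (shared per-sample loading effects, group-level shifts,
  per-gene noise, planted screen-passing genes), so the entire pipeline is
  testable without cohort data.

Expression is quantified by the 2^−Δct convention (100% PCR efficiency):
q<sub>ij</sub> = 2^(ct<sub>min,i</sub> − ct<sub>ij</sub>), and a normalization
factor is the per-sample geometric mean of the chosen genes' q values.

## Worked example

```python
from refstab import ReferenceGeneStability

model = ReferenceGeneStability.simulate(
    "paper-like", seed=7,
    family_map={"RPLP0": "ribosomal", "RPL13": "ribosomal"},
)
results = model.fit()
print(results.summary())
```

```
Step: preterm+fullterm (groups: preterm, fullterm)
------------------------------------------------------------------------
       bestkeeper  normfinder  genorm  mean_rank     M   rho  sd_ct    bias
PPIB        2.000       1.000   1.000      1.333 0.366 0.069  0.504  stable
RPLP0       1.000       2.000   4.000      2.333 0.385 0.085  0.581  stable
B2M         3.000       3.000   3.000      3.000 0.374 0.092  0.592  stable
ACTB        5.000       4.000   1.000      3.333 0.366 0.100  0.508  stable
GAPDH       6.000       5.000   5.000      5.333 0.446 0.101  0.499  stable
GUSB        4.000       7.000   7.000      6.000 0.476 0.113  0.644  stable
HPRT        7.000       6.000   6.000      6.333 0.472 0.104  0.517  stable
RPL13       8.000       8.000   8.000      8.000 0.502 0.118  0.436  stable
NF candidate PPIB/RPLP0/B2M/ACTB/GAPDH/HPRT/GUSB/RPL13: stability 0.035 vs best single PPIB 0.069 -> accept
GeNorm V: V2=0.109, V3=0.081, V4=0.076, V5=0.067, V6=0.055, V7=0.052; recommended NF size n=2

Step: preterm+fullterm+adult (groups: preterm, fullterm, adult)
------------------------------------------------------------------------
       bestkeeper  normfinder  genorm  mean_rank     M   rho  sd_ct    bias
ACTB        3.000       2.000   1.000      2.000 0.363 0.094  0.686  biased
GAPDH       4.000       1.000   4.000      3.000 0.416 0.089  0.663  biased
B2M         1.000       7.000   1.000      3.000 0.363 0.118  0.770  biased
PPIB        2.000       4.000   7.000      4.333 0.458 0.096  0.790  biased
HPRT        7.000       3.000   6.000      5.333 0.450 0.095  0.650  biased
GUSB        6.000       5.000   5.000      5.333 0.442 0.102  0.717  biased
RPLP0       5.000       8.000   3.000      5.333 0.412 0.134  0.648  biased
RPL13       8.000       6.000   8.000      7.333 0.496 0.116  0.620  biased
NF candidate GAPDH/ACTB/HPRT/GUSB/PPIB/RPL13: stability 0.041 vs best single GAPDH 0.089 -> accept
GeNorm V: V2=0.123, V3=0.087, V4=0.073, V5=0.061, V6=0.052, V7=0.051; recommended NF size n=2
```

Reading the output: within the neonatal groups (top step) every candidate is
flagged `stable` — the simulated gestational-age differences are small — and
PPIB leads the mean-rank consensus. Once the adult group enters (bottom
step), every gene carries the simulated age trend and is flagged `biased`
(each gene's mean expression differs between groups even though the *ranking*
algorithms, which only see relative behavior, still find a usable ordering).
The NF lines compare the greedy NormFinder gene set's stability value with
the best single gene's (lower is better; here 0.041 vs 0.089 → accept), and
the V series says two genes suffice for the normalization factor
(V₂ < 0.15).

The same analyses are available from the shell:

```bash
refstab simulate ct --scenario paper-like --seed 7 --out demo/
refstab validate --ct demo/ct.csv --design demo/design.tsv
refstab genorm --ct demo/ct.csv --design demo/design.tsv --exclude RPLP0
refstab screen --counts A.tsv --design designA.tsv --pseudocount 1
```

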