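# surrogene

Per-sample detection of **surrogate oncogenes** — genes whose immediate
protein–protein interaction (PPI) neighborhoods carry significantly more
somatic alterations than expected by chance — plus the downstream analyses
that make the calls useful: drug-sensitivity classification, molecular
subtype association, and survival-tree stratification.

Cancer genomes carry long tails of rare mutations that frequency-based
driver detection cannot see. The idea here is that such mutations often
cluster around a well-connected oncogene in the interactome: the oncogene
then acts as a *surrogate* summarizing a mutated subnetwork, even when it
is not altered itself. The package is aimed at cancer genomics analysts
working with cohort-level mutation (MAF) and copy-number (GISTIC) calls on
a symbol-level PPI network.

## The statistic

For a gene *g* with degree *k* in a network of *N* genes, and a sample with
*M* distinct altered genes of which *x* are neighbors of *g*, the null
places *M* distinct alterations uniformly on the network:

p = P(X ≥ x), X ~ Hypergeometric(N, k, M)

`mode="perm"` estimates p by genuine Monte-Carlo permutation (the
proportion of random placements reaching *x* or more neighbor hits, null
counts cached per (k, M)); `mode="exact"` (default) evaluates the
hypergeometric tail directly. The gene's own alteration never counts
toward *x*. A call is significant at p < α (default 0.05, no
multiple-testing adjustment by default).

Surrogate genes are drawn from a seed oncogene list expanded over the
network: every gene with ≥ 2 interactions into the seed set joins it.

## Worked example

Simulate a cohort with planted neighborhood enrichment and run the full
pipeline:

```sh
surrogene simulate --n-nodes 500 --n-samples 40 --background 0.02 \
    --targets 5 --enrichment 8 --exposed-fraction 0.5 --seed 42 --out fix/
surrogene run --network fix/edges.tsv --maf fix/muts.maf --gistic fix/cn.tsv \
    --seeds fix/seeds.txt --gi50 fix/gi50.csv --subtypes fix/subtypes.csv \
    --clinical fix/clinical.csv --seed 42 --out out/
```

`out/calls.csv` holds one row per (sample, gene) test; significant rows
look like:

```
sample,gene,k,M,x_obs,p_value,significant,self_altered
S001,G0006,66,31,11,0.000923,True,False
S002,G0004,63,43,13,0.001066,True,False
```

Sample S001 has M = 31 altered genes; 11 of the 66 neighbors of G0006 are
altered, which random placement of 31 alterations on 500 genes rarely
achieves (p ≈ 9 × 10⁻⁴) — G0006 is a surrogate oncogene in this sample,
itself unaltered. On this cohort the pipeline reports a mean of 2.9
significant surrogates per sample (40 samples, 61 surrogate-set genes).
`out/matrix.csv` codes each (sample, gene) state 0–3 (none /
surrogate only / altered only / both) and feeds the downstream commands
(`predict-drug`, `associate-subtype`, `survival`); `out/manifest.json`
records seed, parameters and input checksums for reproducibility.

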