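# plnet — phenotypic-linkage networks

Groupwise functional analysis of gene variants — "do the genes hit by de
novo mutations in this disorder work together?" — needs two ingredients: a
functional gene network whose edge weights can be trusted, and a null model
that does not mistake ascertainment bias for biology. `plnet` provides
both, for bioinformaticians analysing exome-study gene sets:

* **Benchmark-calibrated networks.** Heterogeneous evidence (co-expression,
  protein–protein interactions by assay, annotation-vocabulary similarity,
  pre-scored lists) is evaluated against a phenotype-annotation benchmark:
  pairs are binned by raw score and each bin's median semantic similarity
  of phenotype annotations (Resnik over disjunct common ancestors, with
  IC(a) = −log p(a)) is computed. Sources whose strongest links do not show
  phenotypically similar genes are excluded; the rest are rescored onto the
  phenotype-similarity scale by a linear fit to the binned medians and
  integrated with a rank-down-weighted evidence sum,
  WS = L₀ + Σᵢ Lᵢ/(D·i) with D = 5.
* **Bias-aware clustering tests.** The clustering statistic of a gene set
  is the sum of link weights among its genes, compared with random sets.
  Genes implicated by de novo variants are biased toward long coding
  sequences, and long genes tend to interconnect, so uniform nulls
  overstate significance. The CDS-matched null draws, for every study
  gene, one random gene from its 100 nearest neighbours in longest-CDS
  length; degree-matched and uniform nulls are also provided.

A synthetic-data module generates ontologies, annotations, evidence,
CDS lengths, networks and study sets with the assumed statistical
structure, so the entire pipeline is testable without any downloads.

## Worked example

Everything is available both as a library (`import plnet`) and through the
`plnet` command. A self-contained demonstration on generated data:

```
$ plnet fixtures demo --seed 1
fixture workspace written to demo (seed=1)

$ plnet derive-links --kind scored --pairs demo/scored_pairs.tsv \
        --source evidence --out links.tsv
wrote links.tsv (8883 pairs)

$ plnet evaluate --links links.tsv --benchmark-obo demo/ontology.obo \
        --benchmark-annotations demo/annotations.tsv --bin-size 200 \
        --bins-out bins.tsv --report-out report.tsv
evidence: rho=0.963 p=6.91e-26 -> included

$ plnet rescore --links links.tsv --benchmark-obo demo/ontology.obo \
        --benchmark-annotations demo/annotations.tsv --bin-size 200 \
        --out rescored.tsv
wrote rescored.tsv (8020 pairs, slope=0.4821)

$ plnet integrate --links rescored.tsv --out network.tsv
wrote network.tsv: 150 genes, 8020 links

$ plnet cluster-test --network network.tsv --genes demo/study_genes.txt \
        --null cds --lengths demo/lengths.tsv --n-rand 9999 --k 50 \
        --seed 7 --out result.tsv
Gene-set connectivity permutation test
--------------------------------------
genes in set         : 12
null model           : cds (9999 randomizations)
sum of link weights  : 22.8281
null median          : 10.4001
fold change vs null  : 2.195
empirical p-value    : 0.0001
```

Reading the output: the evidence source's strongest links do connect
phenotypically similar genes (rank correlation 0.963 across the binned
medians), so it is included and mapped onto the benchmark scale (fitted
slope 0.4821). The 12-gene study set — drawn from a planted functional
module — carries a within-set link-weight sum of 22.8, 2.2-fold the median
of 9,999 CDS-length-matched random sets, and none of those null sets
reaches it (empirical p = 1/10,000). With several evidence files, pass
`--links` repeatedly to `integrate`; `derive-links` also builds sources
from expression matrices (`--kind coexpression`), interaction tables
(`ppi-direct`, `ppi-indirect`) and annotation vocabularies
(`annotation`).

Defaults follow the reference procedure: bins of 1,000 pairs, D = 5,
candidate lists of 100 length-matched genes, 100,000 randomizations (both
reduced above for a quick demo). Every output file carries an audit header
(version, config hash, seed) and identical seeds give byte-identical
outputs.

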