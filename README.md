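# ribostruct

In vivo RNA structure, translation efficiency and riboSNitch analysis for
homoeologous gene pairs in an allopolyploid transcriptome.

Allopolyploid plants such as tetraploid wheat carry two parental subgenomes
(A and B) whose gene copies — homoeologs — diverge by a few percent of
point substitutions. `ribostruct` is a pipeline for asking, on such a
transcriptome, how mRNA secondary structure shapes translation and how it
differs between subgenomes:

- **SHAPE reactivity** — convert ±reagent RT-stop count tables
  (Structure-seq style) into normalized per-nucleotide reactivities
  (background subtraction, 2–8 % normalization, replicate merging with QC).
- **SHAPE-directed folding** — a McCaskill-style partition function over a
  pair-additive energy model with Deigan pseudo-energies
  `ΔG(i) = m·ln(reactivity+1) + b`, giving per-nucleotide base-pairing
  probabilities (BPP), MFE structures, PPV between in vivo and in silico
  folds, and reactivity/reference-structure agreement rates.
- **Translation efficiency** — TE = polysome abundance / mRNA abundance per
  replicate; CAI and tAI as geometric means `(Π r_i)^(1/n)`, `(Π w_k)^(1/n)`;
  covariate correlations; differential TE between homoeologs (t test on
  log2 TEs + Benjamini–Hochberg); metagene reactivity profiles and the
  3-nt periodicity score.
- **Subgenome asymmetry** — per-pair Wilcoxon BPP comparisons, asymmetry
  fractions, and the coupling of |ΔBPP| with |Δlog2 TE| globally, per genic
  region and per functional group.
- **riboSNitches** — homoeolog alignment (affine-gap global), SNV/indel
  extraction, eSDC = (1−r)·√L, and riboSNitch calls: SNVs around which both
  BPP and reactivity differ significantly from the pair's own noise
  baseline, with effect-size floors.
- **Population genetics** — allele frequencies from VCF genotypes,
  F_ST = σ²_π/(π̄(1−π̄)) across subpopulations, conservation ratios
  c(major)/c(total), and riboSNitch vs non-riboSNitch contrasts.
- **Synthetic data** — generators for every input (diverged homoeolog
  pairs, probing counts, negative-binomial expression, population
  genotypes, structure-flipping SNV fixtures) with recorded ground truth,
  so each stage has a parameter-recovery test.

## Worked example

Run the full pipeline on the built-in synthetic fixture (12 homoeolog
pairs, ~150-nt transcripts, all defaults; the seed is required):

```bash
cat > run.yaml <<EOF
seed: 1
EOF
ribostruct run --config run.yaml --outdir results/
```

which prints (and writes to `results/report.txt` / `results/summary.json`):

```
ribostruct pipeline report (config e6c1582513d8, seed 1)

homoeolog pairs with TE: 12
significant TE asymmetry: 25.0%
BPP asymmetry: A higher 16.7%, B higher 16.7%, NSD 66.7% (n=12)
SNVs: 81 (tested 81)
riboSNitches: 5 (ratio 6.17% of tested)
mean PPV (in vivo vs in silico): 0.570
mean F_ST riboSNitch: 0.6766; non-riboSNitch: 0.0172
|dBPP| vs |dTE| Pearson r = 0.052 (p = 0.874, n = 12)
```

Reading this: 3 of the 12 simulated pairs differ significantly in TE after
BH correction; 4 pairs differ significantly in average BPP between the A and
B copies; of 81 SNVs between the subgenomes, 5 disrupt local structure
enough (in both BPP and reactivity) to be called riboSNitches; and the
riboSNitch sites — which the population simulator gives divergent allele
frequencies across the three subpopulations — show far higher fixation
indices (0.68) than the near-fixed non-riboSNitch sites (0.02). Stage
outputs (`react.tsv`, `bpp_invivo.tsv`, `snv.tsv`, `fst.tsv`, …) are TSVs
whose first line records the package version and config hash; rerunning
with the same config is byte-identical.

Individual stages are available as subcommands (`simulate`, `reactivity`,
`fold`, `te`, `asymmetry`, `ribosnitch`, `popgen`, `report`) and as library
functions (`ribostruct.partition_function`, `ribostruct.cai`,
`ribostruct.fst`, …).

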