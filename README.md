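# hybridpanel

A reusable, tested implementation of a reduced ancestry-informative SNP-panel
workflow for detecting wolf–dog hybrids: marker panel selection, replicate
consensus genotyping and QC for non-invasive samples, pedigree-based hybrid
class simulation, Bayesian hybrid-category classification with extended
backcross classes, admixture-based ancestry assignment with Evanno model
selection, and accuracy evaluation.  A calibrated synthetic-data generator
emulates the allele-frequency structure of a 93-SNP wolf/dog panel (per-locus
Weir–Cockerham F_ST within [0.40, 0.88] averaging 0.70, 18 wolf-fixed loci,
rare wolf minor alleles elsewhere, opposite major alleles in the two species),
so the whole pipeline is exercisable without any external dataset.

## Layout

| module | contents |
| --- | --- |
| `hybridpanel.genotype_core` | genotype matrix model, tabular / PLINK PED-MAP / VCF readers and writers, replicate consensus, success-rate filtering, concordance QC |
| `hybridpanel.synthetic_data` | calibrated allele-frequency model generator, Hardy–Weinberg population sampling, non-invasive degradation (missingness, allelic dropout, false alleles) |
| `hybridpanel.panel_selection` | MAF filter, greedy LD pruning (composite r²), proximity exclusion against BED/VCF annotation, top-N F_ST ranking with audit trail |
| `hybridpanel.hybrid_sim` | pedigree-based simulation of W, D, F1, F2 and backcross classes; expected gene-copy origin profiles |
| `hybridpanel.hybrid_classify` | Gibbs sampler over genotype-frequency classes (10 categories incl. BC2/BC3 both ways), Jeffreys/uniform prior combinations, z-option clamping, ≥0.5 assignment and >0.7 hybrid-sum decisions |
| `hybridpanel.admixture_model` | K-population admixture Gibbs sampler (independent or correlated allele frequencies), multi-run label alignment, Evanno ΔK, relatedness-based subsampling |
| `hybridpanel.popgen_stats` | Weir–Cockerham F_ST (per-locus and ratio-of-sums multilocus, permutation p-values), dosage PCA with smartpca-style normalisation |
| `hybridpanel.workflow_eval` | pipeline orchestration with per-stage seed derivation, accuracy tables, q-distribution summaries, CLI |

## CLI

Every stage is exposed as a subcommand:

```bash
hybridpanel simulate-data --seed 1 --out-dir data/
hybridpanel degrade data/wolves.tsv --seed 1 --out reps.tsv
hybridpanel consensus reps.tsv --out consensus.tsv
hybridpanel qc data/wolves.tsv consensus.tsv
hybridpanel select-panel combined.tsv --annotation sites.bed --out-panel panel.tsv
hybridpanel simulate-hybrids data/wolves.tsv data/dogs.tsv --hybrid-class F1 --n 100 --seed 2 --out f1.tsv
hybridpanel classify all.tsv --all-priors --known-groups wolf=W,dog=D --out posteriors.tsv
hybridpanel admixture all.tsv --k 2 --runs 5 --out q.tsv --out-lnp lnp.tsv
hybridpanel evanno lnp.tsv --out evanno.tsv
hybridpanel fst all.tsv --groups wolf,dog --permutations 1000 --out fst.tsv
hybridpanel pca all.tsv --out pca.tsv
hybridpanel run-all --seed 1 --out-dir pipeline_out/   # full workflow
```

`run-all` accepts a YAML config (`--config`); see
`hybridpanel.workflow_eval.PipelineConfig` for the knobs.

## File formats

* **tabular** — header `id  group  sample_type  <locus ids…>`, one row per
  sample, two-character genotypes, `--` missing.
* **PLINK PED/MAP** — space-delimited, `0 0` missing; family id carries the
  group label.
* **VCF v4.2** — GT-only, `./.` missing; sample group/type kept in
  `##SAMPLE` header lines.
* **panel TSV** — `id  chromosome  position  allele1  allele2`.
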