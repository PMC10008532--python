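# spikeline

Analysis of 16S rRNA amplicon experiments that use an **in-situ mock
community (MC) spike-in** as a positive control. A defined pair of marine
bacteria — *Imtechella halotolerans* (gram-negative, 6.0×10⁷ 16S gene
copies per manufacturer dose) and *Allobacillus halotolerans*
(gram-positive, 1.4×10⁸ copies per dose) — is added to each sample before
DNA extraction. After sequencing and denoising, the spike's sequence
variants (SVs) carry three kinds of information:

1. **Process QC** — the spike read fraction per library and the
   gram-negative : gram-positive read ratio (expected 0.43 from the dosed
   copy numbers; an excess indicates under-extraction of gram-positive
   cells).
2. **Absolute abundance** — the total 16S gene copy number of library *j*
   is estimated from the reference taxon's read share:

   `GCN_j = (N_total_reads_j / ih_reads_j) × dose_copies_j`

   and sample-SV counts are rescaled to that absolute scale:

   `norm_ij = (SV_ij / counts_j) × GCN_j × (1 − ih_reads_j / counts_j)`

3. **Outlier detection** — libraries whose log₂ GCN deviates more than a
   fold threshold from their replicate-group median point to extraction
   failures or pipetting errors.

The package is aimed at microbiome researchers who already have denoised
SV tables (TSV or BIOM 1.0 JSON) and want spike-aware QC, absolute
quantification, dose guidance for new sample types (keeping the expected
spike share inside the recommended 1–10% band), and the standard
diversity stack: CLR normalisation, rarefaction, Hill-number alpha
diversity, Bray–Curtis / Euclidean distances, PCoA, sequential-term
PERMANOVA with permutation p-values, and Wilcoxon rank-sum comparisons.

A synthetic-experiment generator (`spikeline.simulate`) emulates the
spike-in design — log-normal communities, per-dose MC copy input,
gram-dependent extraction bias, multinomial read sampling, low-frequency
secondary MC variants — and returns the ground truth, so every stage is
testable without sequencing data. The bundled default MC reference
sequences are synthetic stand-ins (see `spikeline/synthetic_references.py`);
supply the published reference FASTA when analysing real data.

## Worked example

```python
import warnings
import spikeline as sp
from spikeline import detect, quantify

cfg = sp.study_design_config(seed=42, replicates=2, depth=30_000,
                             gram_pos_efficiency=0.336)
exp = sp.simulate_experiment(cfg)
assignment = detect.assign_mc_svs(exp.sequences, cfg.references, exp.table)
qc = detect.qc_metrics(exp.table, assignment, cfg.references)
print(f"mean Ih:Ah read ratio = {qc.ratio_mean:.2f} "
      f"(expected copy ratio {qc.expected_ratio:.2f})")
gcn = quantify.estimate_gcn(exp.table, assignment, exp.metadata, cfg.references)
print(gcn.table.head(4).to_string(index=False))
```

prints

```
mean Ih:Ah read ratio = 1.44 (expected copy ratio 0.43)
     sample_id  ih_reads  total_reads  dose_copies          gcn  log2_gcn    flag
BP1_HBM_nMC_r1         0        30000          0.0          NaN       NaN no-dose
BP1_HBM_nMC_r2         0        30000          0.0          NaN       NaN no-dose
BP1_HBM_LMC_r1         7        30000     750000.0 3.214286e+09 31.581851
BP1_HBM_LMC_r2        10        30000     750000.0 2.250000e+09 31.067278
```

The simulated gram-positive extraction efficiency of 0.336 inflates the
observed read ratio above the 0.43 copy ratio, as a real extraction bias
would. Undosed (`nMC`) libraries are correctly reported as not estimable;
the two low-dose libraries recover the true ≈2.15×10⁹ copies of a 50 mg
sample from only a handful of spike reads, which is why low-dose
estimates are noisy and the dose recommendation targets a 1–10% spike
read share.

The same pipeline is available from the shell:

```sh
spikeline simulate --seed 1 --out sim/
spikeline report --config config.yaml --seed 1 --out results/
```

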