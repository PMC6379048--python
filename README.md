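# ptrseq

Across human tissues, protein levels track mRNA levels only loosely: two
genes with the same mRNA abundance can differ a hundred-fold in protein.
The per-gene, per-tissue **protein-to-mRNA ratio (PTR)**,
`y_ij = log10(protein_ij / mRNA_ij)`, summarises everything that happens
after transcription — translation initiation, elongation, termination and
protein turnover — and a surprising amount of it is encoded in the mRNA
and protein sequence itself.

`ptrseq` implements the full analysis chain that quantifies those sequence
determinants:

1. **Expression preprocessing** — exonic read densities corrected by
   intronic (pre-mRNA) signal, median-of-ratios size factors, a
   10 reads/kb detection cutoff, replicate medians, log10 iBAQ protein
   intensities with per-tissue median alignment, and the resulting PTR
   matrix (`ptrseq.expression`).
2. **A ~204-column sequence design matrix** — codon and amino-acid log2
   frequencies, codon-pair principal components, start (Kozak) and stop
   codon context encodings, upstream-AUG/uORF flags, UTR motif site
   counts, region lengths and GC, RNA folding-energy windows around the
   start codon, PEST regions, isoelectric point, N-terminal
   hydrophobicity and linear protein motifs
   (`ptrseq.sequence_features`, `ptrseq.protein_features`,
   `ptrseq.folding`).
3. **The interpretable model** — per-tissue OLS
   `y_ij = b_j0 + x_i' b_j + e_ij` and the shared-coefficient variant
   `y_ij = b_j0 + x_i' b + e_ij`; the **PTR adaptation index** of a codon
   is `PTR-AI = 10^beta`, the PTR fold-change per doubling of that
   codon's frequency; 10-fold cross-validated explained variance,
   per-feature-group variance decomposition, Frisch–Waugh corrected
   effects, positional scans, BH FDR and LASSO candidate selection
   (`ptrseq.ptr_model`).
4. **De-novo k-mer motif discovery** — for every 3–8-mer in a region, a
   linear mixed model `y = Wa + x_k b_k + u + e` with
   `u ~ N(0, s2_g K)` and kinship `K = ZZ'/p` built from all
   standardized k-mer counts, so each k-mer is tested while controlling
   for all others; REML variance estimation, Wald scans over the median
   PTR and tissue-centered contexts, overlap assembly of significant
   k-mers, motif conservation tests against 10-nt flanks and 1-mismatch
   logo counts (`ptrseq.motif_discovery`).
5. **Auxiliary comparisons** — codon decoding-time aggregation across
   ribosome-profiling datasets and half-life effect regressions that the
   codon effects can be correlated against (`ptrseq.aux_metrics`).
6. **A synthetic-data generator with planted ground truth** — every
   stage above has a parameter-recovery test without any external
   download (`ptrseq.synthetic_data`).

## Worked example

```python
import numpy as np, pandas as pd
from ptrseq import expression, ptr_model, sequence_features, synthetic_data as sd

# simulate 1,500 genes x 4 tissues with planted codon and motif effects
cfg = sd.SimulationConfig(n_genes=1500, n_tissues=4, seed=3)
data = sd.simulate_dataset(cfg)

# counts + iBAQ -> PTR matrix
res = expression.run_expression(
    data.exonic, data.intronic, data.ibaq, data.sample_sheet,
    data.truth.exon_len, data.truth.intron_len)

# codon design -> shared-coefficient fit -> PTR-AI
X = pd.DataFrame([sequence_features.codon_log2_freq(r.cds) for r in data.transcripts],
                 index=[r.transcript_id for r in data.transcripts])
fit = ptr_model.fit_shared_model(res.ptr, X.loc[res.ptr.index])
ai = ptr_model.ptr_ai(shared_fit=fit).global_effects

from scipy.stats import spearmanr
rho = spearmanr(np.log10(ai), data.truth.codon_effects).statistic
print(f"codons: {len(ai)}, PTR-AI range {ai.min():.2f}-{ai.max():.2f}, "
      f"Spearman vs truth {rho:.3f}")
```

prints (machine-generated output of this exact snippet):

```
codons: 61, PTR-AI range 0.75-1.28, Spearman vs truth 0.997
```

i.e. the 61 fitted codon indices span roughly a 0.75–1.28-fold PTR change
per codon-frequency doubling and rank-correlate at 0.997 with the planted
per-doubling effects, despite the PTR matrix having passed through count
noise, censoring and median alignment.

A command-line interface mirrors the library
(`ptrseq simulate | expression | features | fit | scan-motifs | conserve | metrics`);
run `ptrseq --help` for the flags and `run.log` conventions.

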