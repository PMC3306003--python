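# exonscan

Detection of protein-coding regions (exons) in DNA sequences from their
period-3 statistical signature, using impulse-train cross-correlation
and discrete-wavelet denoising.

Coding DNA is read in triplets, and non-uniform codon usage makes the
same nucleotide recur at the same codon position — a statistical
periodicity of 3 that introns lack. `exonscan` turns this into a
per-base score:

1. **Indicator (Voss) mapping** — the sequence becomes four binary
   channels I_A, I_T, I_C, I_G, with I_X[n] = 1 iff base n is X.
2. **FIR bandpass** — each channel passes through a linear-phase,
   order-8 Hamming-window bandpass centred on ω = 2π/3 rad/sample, the
   spectral line of period-3 structure.
3. **Impulse-train cross-correlation** — each filtered channel B_X is
   correlated with a period-3 impulse train of length L = 270
   (N_δ = 90 impulses): c_X[j] = Σ_k B_X[j + 3k]. A periodic component
   adds coherently over the 90 impulses while zero-mean noise averages
   out with variance ∝ 1/N_δ. The per-base energy is
   M[j] = c_A² + c_T² + c_C² + c_G².
4. **Wavelet denoising** — one level of discrete wavelet decomposition
   (discrete Meyer, "dmey") splits M into approximation and detail;
   the detail band is discarded and the track rebuilt from the
   approximation alone.

On top of the score track the package provides threshold training
(T = (sd_e·mean_i + sd_i·mean_e)/(sd_e + sd_i) from labelled exon and
intron scores), interval calling, and the standard nucleotide-level
evaluation suite — sensitivity Sn = TP/(TP+FN), specificity
Sp = TP/(TP+FP), approximate correlation AC = 2·(ACP − ½), ROC/AUC and
FP-at-sensitivity — plus the classic sliding-window DFT spectral-content
detector as a baseline and a synthetic-genome generator (codon-biased
exons, i.i.d. introns) so everything is testable without downloads.

## Worked example

`examples/03_evaluate_vs_dft.py` generates ten 10 kb synthetic genomes,
scores them with both methods and evaluates at the nucleotide level:

```
cross-correlation + DWT: AUC = 0.9566
  at Sn >= 20%: FP =     54 bases, Sp = 0.976, AC = 0.542
  at Sn >= 40%: FP =     67 bases, Sp = 0.985, AC = 0.657
  at Sn >= 60%: FP =    491 bases, Sp = 0.932, AC = 0.739

sliding-DFT baseline: AUC = 0.9389
  at Sn >= 20%: FP =     54 bases, Sp = 0.976, AC = 0.542
  at Sn >= 40%: FP =    257 bases, Sp = 0.946, AC = 0.636
  at Sn >= 60%: FP =    831 bases, Sp = 0.890, AC = 0.716
```

AUC is the probability a random exon base outscores a random intron
base; FP-at-sensitivity counts intron bases miscalled when a fixed
fraction of exon bases must be recovered. The correlation pipeline
ranks better and makes fewer false calls at matched sensitivity. The
other example scripts demonstrate exon calling with a trained threshold
(`01`), the 1/N_δ noise-suppression law (`02`) and the method's
insensitivity to the train length L where the DFT baseline degrades
(`04`).

The same pipeline is scriptable from the shell:

```bash
exonscan simulate --fasta-out g.fa --bed-out g.bed
exonscan scan g.fa --out g.bedgraph                  # per-base score track
exonscan train-threshold g.fa g.bed --out model.json # fit T from labels
exonscan evaluate g.fa g.bed --json-out report.json  # AUC, FP-at-Sn, ...
```

`scan` accepts `--method dft` (baseline track), `--no-dwt` (skip
denoising), `--window-length`, `--filter-order`, `--center-freq`,
`--wavelet`, `--dwt-levels` and `--threshold`/`--calls-out` for BED
output of called exons.

## Evaluating on real annotated sequences

Nothing in the pipeline is synthetic-specific: give `evaluate` any
FASTA plus exon truth intervals in BED or GFF3 (e.g. a GenBank gene
converted with your tool of choice) and the same report is produced.
Multi-sequence datasets are pooled at the nucleotide level into a
single confusion table per threshold.

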