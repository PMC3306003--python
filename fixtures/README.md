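# Test fixture genomes (synthetic)

Three single-sequence synthetic genomes (10 kb each) with codon-biased
exons and uniform i.i.d. introns, generated by `exonscan.synth` with the
default `SyntheticSpec` at seeds 1, 2 and 3:

```python
from exonscan.synth import SyntheticSpec, generate_genome
from exonscan.seqio import write_fasta, write_annotations

for seed in (1, 2, 3):
    seqs, anns = generate_genome(SyntheticSpec(n_sequences=1, sequence_length=10000, seed=seed))
    seqs[0].id = anns[0].sequence_id = f"genome{seed}"
    write_fasta(seqs, f"genome{seed}.fa")
    write_annotations(anns, f"genome{seed}.bed")
```

Each `.fa` / `.bed` pair is a sequence plus its true exon intervals.
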