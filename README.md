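# seqnls

Nuclear localization signal (NLS) prediction from protein sequence by
gapped sequential-pattern mining and linear-motif scoring.

The package:

1. **mines** enriched word-list patterns (ordered dipeptide lists matched
   with inter-word gaps of at most 2 residues) from a positive corpus of NLS
   peptides against a negative corpus of length-40 non-NLS peptides, scoring
   each word-list by a log2 enrichment ratio;
2. **scans** query proteins with the mined patterns plus the bipartite
   consensus `(K/R)(K/R)X10(K/R)3/5` (whose enrichment is treated as
   infinitely large, so it survives every cutoff);
3. **scores** each candidate segment by combining the normalized enrichment
   (linear ramp from 1.0 to E_K = 1.62, clamped to [0, 1]) with a
   linear-motif probability S_L from an RBF-kernel SVM over the segment's
   median predicted disorder: `final = 0.8·Norm(E_S) + 0.2·β·S_L` with
   β = 0.6 for pattern matches (β = 1 for bipartite matches);
4. **masks** predictions by inverse relative local conservation (IRLC): a
   prediction is dropped when any residue within 5 positions of its
   boundaries is more conserved than the prediction's interior mean by more
   than 1.7 whole-sequence standard deviations (conservation comes from a
   PSI-BLAST ASCII PSSM or a plain-text track);
5. **evaluates** predictions with overlap-hit precision/recall/F1 and the
   amino-acid performance coefficient (aPC), plus Mann–Whitney ROC/AUC
   helpers; and
6. **simulates** fully synthetic, seeded benchmarks (planted word-lists and
   bipartite motifs, disorder elevated inside motifs, motifs more conserved
   than their flanks) so everything is testable offline.

## Command line

All stages are subcommands of `seqnls`:

```sh
# generate a synthetic benchmark
seqnls simulate --seed 1 --outdir bench/

# mine patterns: TSV of word-lists with supports and enrichment
seqnls mine --pos bench/train_pos.fasta --neg bench/train_neg.fasta \
    --min-support 3 --max-set-size 4 --es-threshold 1.0 --out patterns.tsv

# sequence-based predictor (enrichment cutoff only)
seqnls predict --patterns patterns.tsv --fasta bench/queries.fasta \
    --mode sequence_based --es-cutoff 1.62 --out pred_sb.tsv

# integrated predictor (disorder model + final-score cutoff + IRLC masking)
seqnls train --annotations bench/annotations.tsv --fasta bench/queries.fasta \
    --disorder bench/disorder.tsv --seed 0 --out model.bin
seqnls predict --patterns patterns.tsv --fasta bench/queries.fasta \
    --mode integrated --model model.bin --disorder bench/disorder.tsv \
    --conservation bench/conservation.tsv --final-cutoff 0.85 --out pred_int.tsv

# metrics
seqnls evaluate --predictions pred_int.tsv --annotations bench/annotations.tsv \
    --out report.tsv
```

Lower-level stages (`scan`, `score`, `mask`, `sweep`) are also exposed; see
`seqnls <cmd> --help`.

File conventions: FASTA for sequences; tab-separated tables for annotations
(`seq_id  start  end`, 1-based inclusive), per-residue score tracks
(`seq_id  position  score`), patterns, and predictions; PSI-BLAST
`-out_ascii_pssm` files for conservation. All coordinates are 1-based
inclusive on disk and 0-based half-open in memory.

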