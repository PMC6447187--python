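# dstile

Design tools for RNA-interference triggers, plus the companion qPCR
analysis. `dstile` tiles a target cDNA into 19-nt fragments, screens every
fragment against a transcriptome for potential off-target silencing
matches (aligned length > 17 nt, identity > 90%, gaps < 3), maps accepted
hits back onto the target, and selects the amplicon window with the least
off-target load for dsRNA synthesis (T7-promoter-tagged primers). The
knockdown side computes 2^-ddCt relative expression against a reference
gene and calibrator group, amplification efficiencies from standard-curve
slopes, and normality-gated two-group tests (Shapiro-Wilk, then unpaired
t-test or Mann-Whitney U).

Everything is testable offline: a synthetic-data module generates
transcriptomes with planted (optionally mutated) homology blocks and
replicate Cq tables with known knockdown fractions.

## Library overview

| module | what it does |
|---|---|
| `dstile.seq_io` | FASTA and BLAST-tabular (outfmt 6) I/O, JSON/TSV reports; all internal coordinates 0-based half-open |
| `dstile.offtarget` | k-mer tiling, seed-and-extend approximate matcher, acceptance rule, homolog-candidate filter (e < 1e-5, identity > 20%, coverage > 50%) |
| `dstile.amplicon` | per-fragment risk profile, exhaustive minimum-load window selection, T7 template construction |
| `dstile.quant` | standard curves (E = 10^(-1/slope)), 2^-ddCt with optional efficiency correction, group comparison |
| `dstile.simulate` | seeded synthetic transcriptomes, planted off-target blocks with truth records, simulated Cq tables |

The built-in matcher is complete by construction: with the automatically
derived seed length, any alignment passing the acceptance rule contains an
exact seed word (pigeonhole over the bounded error budget), and every
anchored window is searched exhaustively. The test suite checks exact
accepted-hit-set equality against a brute-force aligner on 100 seeded
planted-block instances.

## CLI

```bash
# design: pick the least-risky amplicon window
dstile design --target relish.fa --transcriptome transcripts.fa \
    --length 564 --out design.json --risk-tsv risk.tsv \
    --fwd-primer ACGT... --rev-primer TGCA...

# scan only (TSV of accepted off-target hits; optionally emit the
# fragment queries for an external BLASTn run)
dstile scan --target relish.fa --transcriptome transcripts.fa \
    --out hits.tsv --queries-out fragments.fa

# use precomputed BLAST outfmt-6 hits instead of the built-in matcher
# (query ids must end in _<fragment start>, as written by --queries-out)
dstile design --target relish.fa --transcriptome transcripts.fa \
    --length 564 --hits blast.tsv --out design.json

# relative expression: 2^-ddCt of a gene in one group vs a calibrator
dstile ddct --cq cq.csv --gene Prolixicin --ref Tubulin \
    --group dsRelish_Gneg --calibrator dsANT_Gneg

# synthetic fixtures
dstile simulate transcriptome --n 10 --seed 1 --out db.fa \
    --plant-target relish.fa --block-len 40 --truth-out truth.json
dstile simulate cq --group kd=0.12 --sigma 0.2 --seed 1 --out cq.csv
```

Every subcommand takes `--config file.yaml` (keys mirror the flags; flags
override) and embeds the resolved parameters in its report, so identical
inputs and seed produce byte-identical outputs.

Cq tables are delimited text with header `sample,group,gene,replicate,cq`;
standard-curve files have `gene,log10_amount,cq`.

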