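# pentaplex

Toolkit for detecting and characterizing **mixed-motif tandem-repeat
expansions** — adjacent expansions of several different repeat motifs at one
locus (e.g. pentanucleotide structures such as
`(TTTTA)exp-(TTTCA)exp-(TTTTA)exp-(TTGTA)exp`).

Three workflows:

1. **Short-read screen** — classify read pairs in which both mates are
   (nearly) pure repeat (> 125 bp of repeat per read by default) and every
   target motif reaches ≥ 50 bp summed across the pair; flag samples with at
   least 3 such pairs. This is a mapping-free screen for evidence of complex
   expansions in WGS/WES FASTQ data.
2. **Long-read decomposition** — extract targeted long reads over a locus
   (e.g. `chr5:10356339-10356411`), quantify per-motif repeat content, drop
   wild-type alleles (total repeat < 800 bp), exclude strand-biased basecall
   miscall artifacts (TTCCA-dominated reverse-strand reads), segment each
   read into ordered motif blocks, and summarize consensus structure,
   copy-number distributions and waterfall rows/plots.
3. **Simulation** — diploid alleles built from ordered motif blocks (with
   optional per-read mosaicism of one block), Illumina-like 151 bp read
   pairs, and noisy long-read amplicons with optional strand-biased TTCCA
   corruption. Every read carries ground-truth provenance, so both pipelines
   are testable end to end without patient data.

Motif identity is strand- and phase-free throughout: a motif, its rotations,
and the rotations of its reverse complement share one canonical key, while
the familiar display spelling (TTTCA, not a canonical rotation) is used for
reporting.

## Test

```sh
python -m pytest -q tests/
```

The suite includes unit tests per module, property tests (hypothesis),
brute-force oracle comparisons, and `tests/test_acceptance.py` with one test
per acceptance criterion.

## CLI

```sh
# simulate a diploid carrier and screen it
pentaplex simulate --config "(TTTTA)100-(TTTCA)100" --mode short \
    --coverage 30 --seed 7 --out sim/
pentaplex screen --motifs TTTTA,TTTCA --min-read-bp 125 --min-motif-bp 50 \
    --min-pairs 3 --r1 sim/reads_1.fastq --r2 sim/reads_2.fastq \
    --out sample.tsv --pairs-out pairs.tsv

# simulate and decompose a complex long-read locus
pentaplex simulate --config "(TTTTA)100-(TTTCA)100-(TTTTA)100-(TTGTA)700" \
    --mode long --coverage 50 --sub-rate 0.02 --ins-rate 0.01 --del-rate 0.01 \
    --seed 7 --out lr/
pentaplex decompose --region chr5:10356339-10356411 \
    --motifs TTTTA,TTTCA,TTGTA,TTCCA --min-total-bp 800 \
    --fastq lr/reads.fastq --reads-tsv lr/alignments.tsv --out-prefix locus

# per-read repeat content only
pentaplex scan --motifs TTTTA,TTTCA,TTGTA --fastq reads.fastq --out scan.tsv
```

Cohort mode: `pentaplex screen --manifest manifest.tsv` with columns
`sample_id`, `r1`, `r2`. All tabular outputs start with `#`-prefixed
provenance comments (version, config hash); results are deterministic given
`--seed`.

## Package layout

| module | contents |
| --- | --- |
| `pentaplex.repeat_model` | motif algebra (canonical keys), region and `(MOTIF)N-…` configuration parsing |
| `pentaplex.read_scan` | maximal exact tandem-run finding and per-read repeat profiles |
| `pentaplex.mixstr_screen` | pair classification, sample flagging, cohort screening |
| `pentaplex.longread_decompose` | region extraction, motif counting, wild-type/artifact filters, block segmentation, consensus, waterfall |
| `pentaplex.simulate` | allele models, short-read pair and long-read amplicon simulators with truth tables |
| `pentaplex.cli` | `pentaplex` command-line interface |
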