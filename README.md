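# virosift

Strand-specific small-RNA size-signature analysis for virome discovery on
assembled contigs. Given contigs and small-RNA-to-contig alignments, the
pipeline

1. applies contig QC (strict >500 nt length filter, greedy redundancy collapse
   at 95% identity over 90% of the shorter sequence, ORF functional-status
   tallies),
2. builds a 42-cell read-size profile per contig (sizes 15–35 nt on the
   positive then negative strand), keeps contigs with ≥100 in-range reads, and
   z-score-normalizes the frequency vectors,
3. clusters the z-profiles by UPGMA on correlation distance (1 − r) and labels
   each cluster with a signature — siRNA-like (21 nt, both strands),
   siRNA/piRNA mixed, or strand-biased piRNA-like (23–29 nt band) —
4. recruits unclassified contigs into virus clusters when their profile
   correlates ≥0.9 (inclusive) with a classified virus contig from the same
   sample pool, and runs the host-contig reconstruction control that measures
   how non-specific each signature class is,
5. computes supporting statistics: log2 RPKM abundance matrices, species
   composition with the ≥100-read / ≥1% frequency filter, and a
   continuity-corrected 2×2 chi-squared test on library-size-normalized
   counts.

A seeded synthetic-data generator (`virosift.synthetic`) emulates siRNA,
piRNA and degradation read populations so the whole pipeline is testable
offline, with ground truth.

## CLI

Every stage is a subcommand; `run` chains them from a JSON config.

```sh
# generate a synthetic fixture with ground truth
virosift simulate --n-per-class 20 --classes sirna,pirna,degradation \
    --seed 1 --outdir fixture/

# run the full pipeline
cat > config.json <<'EOF'
{"contigs": "fixture/contigs.fasta",
 "alignments": "fixture/alignments.tsv",
 "metadata": "fixture/truth.tsv",
 "outdir": "out", "k": 3}
EOF
virosift run --config config.json
```

Other subcommands: `map` (brute-force read mapper for fixtures), `qc`,
`profile`, `cluster`, `recruit`, `control`, `abundance`, `species`,
`pirna-test`. All thresholds (min length, min reads, correlation threshold,
k, identity/coverage, z-enrichment, strand-bias) are flags with the defaults
above. Outputs are plain TSV/JSON/Newick plus a `manifest.json` with seeds,
thresholds and output hashes; reruns with the same config are byte-identical.

## Layout

| module | contents |
| --- | --- |
| `virosift.synthetic` | signature models, contig/read simulator, fixture writer |
| `virosift.seqio` | FASTA/FASTQ/SAM/TSV readers and writers, brute-force mapper |
| `virosift.qc` | length filter, redundancy collapse, ORF summary |
| `virosift.profiles` | size/strand profiles, read-count gate, z-scores |
| `virosift.clustering` | correlation matrices, UPGMA, cluster cut, signature rules |
| `virosift.recruit` | recruitment and reconstruction control |
| `virosift.abundance` | log2 RPKM matrix, species composition filter |
| `virosift.stats` | normalized-count 2×2 chi-squared tests |
| `virosift.pipeline` / `virosift.cli` | orchestration, config, manifest, CLI |

Tests in `tests/` include independent brute-force oracles (`tests/_oracles.py`)
for the chi-squared formula, average-linkage heights and the alignment DP, and
`tests/test_acceptance.py` holds the acceptance criteria.
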