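# clipmeta

Background-aware metagene profiling of CLIP-seq signals around transcript
features.

CLIP-seq (cross-linking and immunoprecipitation followed by sequencing) maps
where an RNA-binding protein (RBP) touches the transcriptome, and *where* an
RBP binds relative to features like splice sites, branchpoints or
polyadenylation sites is often the best clue to its function. Two things make
naive metagene plots of CLIP data misleading: raw coverage mostly tracks the
expression level of the substrate rather than binding, and scaling features
to a common length destroys the near-nucleotide resolution that
crosslink-induced read truncations (CITs) and mutations (CIMs) provide.

`clipmeta` addresses both. It works on the unspliced pre-mRNA span of each
transcript (so intronic features are first-class), extracts a per-nucleotide
diagnostic signal (read coverage, CITs or CIMs) for the immunoprecipitated
(IP) library and a size-matched input (SMInput) background library, and
normalizes them per transcript via **relative information**: with
pseudocounted per-nucleotide densities `p` (IP) and `q` (SMInput) over a
transcript of length L,

```
RI_i = p_i · log2(p_i / q_i)        i = 1 … L   (bits)
```

the contribution of nucleotide `i` to the Kullback–Leibler divergence
D(p‖q) = Σ RI_i ≥ 0. Expression-driven background cancels because both
libraries are reduced to densities per transcript. RI values are then
collected in **fixed-length windows** (no length scaling) anchored on feature
boundaries — annotated ones (5′/3′ splice sites, TSS, TES, UTR/CDS
boundaries) or user-supplied BED features such as branchpoints — giving an
RBP map (sites × relative position) and its mean/median metagene profile.

It is intended for anyone analysing eCLIP-style data with a paired
background library, or any assay whose signal and background come as
BAM/BigWig tracks.

## Worked example

The package ships a deterministic simulator that plants crosslink sites at
known offsets, so the whole pipeline can be exercised without downloads.
Here we plant 10-fold IP enrichment 30 nt upstream of every 3′ splice site
and ask the pipeline to find it:

```bash
clipmeta simulate --seed 7 --n-transcripts 20 --read-depth 100 --out-dir fx
clipmeta extract  --bam fx/IP.bam      --gtf fx/annotation.gtf \
                  --signal truncation --library IP      --out ip.tsv.gz
clipmeta extract  --bam fx/SMInput.bam --gtf fx/annotation.gtf \
                  --signal truncation --library SMInput --out smi.tsv.gz
clipmeta normalize --ip ip.tsv.gz --sminput smi.tsv.gz --out ri.tsv.gz
clipmeta metagene --ri ri.tsv.gz --gtf fx/annotation.gtf \
                  --feature three_prime_ss --stat mean --out-prefix mg
```

which prints

```
wrote 20 transcript tracks to ip.tsv.gz
wrote 20 transcript tracks to smi.tsv.gz
wrote RI for 20 transcripts (0 excluded) to ri.tsv.gz
wrote 40-row RBP map to mg.matrix.tsv and profile to mg.profile.tsv
```

`mg.profile.tsv` holds the mean RI per relative position (0 = the first
exonic base after the intron) with the number of unmasked windows per
column:

```
 position   central  n
      -32 -0.000041 40
      -31 -0.000138 40
      -30  0.518588 40
      -29 -0.000376 40
```

The profile peaks at −30 with mean RI ≈ 0.52 bits — exactly the planted
offset — while every other position stays within sampling noise of zero
(|RI| < 0.001 bits). The 40 rows are the 20 transcripts × 2 introns each.
`clipmeta metagene --feature branchpoint --bed fx/branchpoints.bed` windows
the same RI archive around the simulated branchpoints instead, and
`--plot profile.png` renders any profile as a line plot with the anchor
marked at position 0.

The same `extract` command accepts `--bigwig-plus/--bigwig-minus` instead of
`--bam` for pre-computed strand-specific coverage tracks, and
`export_track` in the library writes any per-transcript signal back out as
genome-orientation WIG/BigWig.

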