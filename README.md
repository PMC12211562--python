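# kiquant

Classification and quantification of CRISPR knock-in repair outcomes
from long-read (PacBio HiFi) amplicon sequencing, with UMI-based
deduplication of linear-amplification libraries.

## What it does, and for whom

Inserting an epitope tag (or any short exogenous sequence) at a CRISPR
cut site produces a zoo of repair products: unmodified alleles, small
and kilobase-scale indels, precise knock-ins with seamless junctions,
knock-ins carrying junction indels, and tandem multi-copy insertions.
Short-read sequencing cannot see most of these - a tagged amplicon is
longer than the read, and long deletions or multi-copy inserts bias or
escape detection entirely. `kiquant` is for genome-editing labs (e.g.
zebrafish knock-in work) who sequence >=2 kb target amplicons on HiFi
and want per-molecule outcome calls plus honest rate estimates.

Each original template molecule is tagged during linear amplification
with an 8-bp unique molecular identifier (UMI), so PCR "jackpot"
over-amplification can be corrected by collapsing reads per UMI before
counting. For a sample with class counts $n_c$ over $N$ counted
molecules the package reports

- **indel rate** $= n_{\mathrm{indel}}/N$ — no tag, but indels at the
  target site;
- **total KI rate** $= (n_{\mathrm{precise}} + n_{5'} + n_{3'} +
  n_{\mathrm{both}} + n_{\mathrm{multi}})/N$ — any tag insertion;
- **precise KI rate** $= n_{\mathrm{precise}}/N$ — single tag, indel-free
  junctions across both homology arms,

plus indel size spectra and founder-screen percentages
(`round(100 * precise founders / screened P0)`).

Classification per molecule: Smith–Waterman detection of tag copies
(iterative best-hit masking, both strands), then semi-global affine
alignment to the expected precise or unmodified reference, left-shift
normalized indel calling, windowed junction scoring, optional
SNP/PAM-edit readout and control-based natural-indel filtering. A
ground-truthed HiFi library simulator (outcome mixtures, jackpot
duplication, per-base error model) validates every stage end to end.
See `docs/methods.md` for the full model and parameter rationale.

## Worked example

Simulate a 500-molecule library at the packaged default target (2,000 bp
amplicon, 90 bp Avitag-Myc insert at position 1,000, 50 bp arms) and run
the pipeline:

```bash
kiquant simulate --config src/kiquant/data/default_target.yaml \
    --n 500 --seed 7 --out-dir out/sim
kiquant run-all --config src/kiquant/data/default_target.yaml \
    --fastq out/sim/reads.fastq --out-dir out/run
```

The simulator reports `wrote 965 reads for 500 molecules` (PCR
duplication, mean 2x) and the pipeline prints one line per
demultiplexed sample:

```
emb1	n=536	indel=0.3284	total_ki=0.3563	precise_ki=0.1549
```

536 UMI groups were counted from 500 molecules (a sequencing error
inside a UMI creates an occasional extra singleton group): 32.8% of
counted molecules carry a target-site indel without a tag, 35.6% carry
some tag insertion, and 15.5% are precise seamless knock-ins — close to
the simulator's true mixture (30% indel + 2% large deletion, 33% tagged,
15% precise). `out/run/` contains `rates.tsv`, per-read `classes.tsv`,
`indel_spectrum.tsv`, a stage-by-stage `drop_ledger.tsv` and
`run_summary.json`. Founder arithmetic is available directly:

```bash
$ kiquant founder --total 30 --precise 7
23%
```

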