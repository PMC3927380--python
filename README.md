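# motifsampler

Gibbs site-sampler motif discovery for nucleotide sequence sets, with
position-weight-matrix (PWM) scoring and positional (S1D/S2D) analysis.

Short ungapped sequence motifs — transcription-factor binding sites,
splice/branch-point signals, other genetic switches — recur across
co-regulated genes but are too degenerate to find by exact matching. Given a
multi-FASTA of *n* sequences, this package finds one fixed-width motif
occurrence per sequence (the OOPS model) by Monte Carlo search, the approach
used to characterize a 6-mer motif (consensus `CUGGAA`) across the 34 gene
sequences of *E. coli* NC101 contig 1. It is aimed at computational
biologists who want that style of analysis as a reproducible, scriptable
pipeline with a planted-motif benchmark generator built in.

## Model

Sequences are handled in the RNA alphabet (A, C, G, U; DNA input is
transcribed on load). For an alignment assigning one width-*L* window per
sequence:

- site-specific counts: c_ij = number of windows with nucleotide *i* at
  position *j*;
- site-specific frequencies with a background pseudocount (one total
  pseudo-observation): p_ij = (c_ij + p_i) / (n + 1), where p_i is the
  pooled background frequency;
- weight matrix: PWM_ij = ln(p_ij / p′_i), where p′_i is by default the
  background recomputed after excluding the n·L nucleotides inside the
  motif windows (a flag restores the full background; the log base is
  configurable);
- motif score: PWMS = Σ_j PWM at the motif's residues (log form), or
  exp(PWMS) (odds form, the convention of the reference tables);
- global alignment score: F = Σ over sequences of the log-PWMS of their
  windows — the sampler's objective.

The Gibbs site sampler iteratively leaves one sequence out, builds the PWM
from the other n−1 windows, and resamples the left-out start from the
categorical distribution proportional to exp(window score), with periodic
coordinated phase-shift moves and multiple random restarts. The motif site
splits each sequence into an upstream segment of length S1D = start − 1 and
a downstream segment of length S2D = length − start − width + 1, summarized
as mean ± SEM.

## Worked example

Generate the default synthetic benchmark — 34 sequences, ~31.5 kb total,
background (A 0.2419, C 0.2532, G 0.2818, U 0.2231), one planted `CUGGAA`
per sequence with 8% per-position substitution noise — and run the sampler:

```python
import motifsampler as ms
from motifsampler.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(synthetic=ms.SyntheticSpec(seed=7), out_dir="demo")
bundle = run_pipeline(cfg)
print(round(bundle.F, 4))
print(bundle.motifs.head(5).to_string(index=False))
```

prints

```
243.0979
SeqName  Motif  Start  PWMS_log        PWMS
synth_1 CUGGAA    799  7.825930 2504.713260
synth_2 CUGGAA    440  7.825930 2504.713260
synth_3 CUGGAA    288  7.825930 2504.713260
synth_4 CUGGAA    562  7.825930 2504.713260
synth_5 CGGGAA    296  5.008066  149.615036
```

F = 243.0979 is the total log-odds of the best alignment found; each row
gives the motif window the sampler selected, its 1-based start, and its
PWMS in log and odds form — the exact consensus scores an odds ratio of
~2505 here, noisy variants much less. The sampler recovered the planted
consensus in 25 of 34 sequences and close one- or two-substitution variants
in the rest. `demo/` additionally contains the background frequency table,
site counts/frequencies, the PWM, the S1D/S2D scatter table and summary,
and a JSON manifest of the run.

The same pipeline runs from a shell:

```sh
motifsampler synth --out data/            # FASTA + ground truth
motifsampler run --in data/synthetic.fasta --width 6 --seed 1 --out reports/
motifsampler score --in data/synthetic.fasta \
    --alignment data/ground_truth.tsv --out truth_reports/
```

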