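# Methods

## The model

The package implements one-occurrence-per-sequence (OOPS) motif discovery:
every input sequence is assumed to contain exactly one instance of an
ungapped motif of fixed width L (default 6 nt). An alignment is therefore a
vector of n 1-based start positions. Alignments are scored by total
log-odds:

    F(A) = Σ_k Σ_j ln( p_{s_kj, j} / p′_{s_kj} )

where s_kj is the nucleotide of sequence k at motif position j,
p_ij = (c_ij + p_i) / (n + 1) is the pseudocount-smoothed site frequency
(c_ij the count of nucleotide i at position j over the aligned windows, p_i
the pooled background frequency; one total pseudo-observation distributed
as the background), and p′_i is the denominator background. All matrices
use the fixed row order A, C, G, U, and sequences are held in the RNA
alphabet (T → U on load).

Two denominator conventions are supported:

- **excluded background** (default): p′ is recomputed from the pooled
  counts after removing the n·L nucleotides inside the motif windows. This
  is the convention that reproduces the bundled reference PWM to within
  2×10⁻³ (in fact to ~5×10⁻⁶).
- **full background**: the textbook log-odds form, via
  `exclude_motif_background=False`.

The log base defaults to e: the reference PWM entries match natural
logarithms (e.g. ln(0.97866/0.25373) ≈ 1.3499 against the printed 1.34992,
where base 2 would give ≈ 1.948), and the reference PWMS values equal
exp(Σ weights). Reports therefore carry both the log-form PWMS and the
odds form exp(PWMS); the odds form is what the reference tables print. The
log base is a parameter for users who want bit-scaled matrices.

## The sampler

`run_sampler` is the classic leave-one-out site sampler. Per step, the
count matrix of the other n−1 windows defines a weight matrix (same
pseudocount rule with n−1 observations; denominator = pooled background
minus those n−1 windows); each candidate start x of the left-out sequence
gets weight exp(Σ_j W[s_{x+j}, j]) and the new start is drawn from the
normalized categorical distribution. A sweep visits all sequences in input
order (a shuffled order is available). Every `phase_shift_period` sweeps
(default 5) a coordinated shift of all starts by δ ∈ [−3, 3] is proposed
and accepted only on strict improvement of F, so ties keep the current
registration.

Numerical detail: inside the sampler (and only there) both the pseudocount
vector and the excluded-background denominator are smoothed with a light
uniform prior (half a count per nucleotide on the background). Without
this, tiny test instances — where the motif windows can consume every copy
of a nucleotide, or the input lacks a nucleotide entirely — produce
log(0)/log(∞) objectives. On realistic inputs the effect is O(1/total
length): on the 31.5 kb scale it moves F by ~3×10⁻⁴ nats. The final
reported matrices are rebuilt from the best alignment with the exact
excluded background.

Search control: default 20 restarts, each capped at 500 sweeps and stopped
after 40 sweeps without improvement of the restart's best F. These defaults
were sized on the default benchmark: a single restart nucleates the planted
motif with probability ≈ 0.25, so 20 restarts give ≈ 99.5% success while a
run stays in the seconds range. Restart r uses seed `seed + r`; runs are
bit-reproducible under a fixed seed. Best-so-far F per sweep is recorded as
a monotone trajectory. `exhaustive_oracle` enumerates all start
combinations (capped at 10⁶) for independent verification on toy instances;
ties break to the lexicographically smallest start vector.

## Synthetic benchmark

`SyntheticSpec` defaults emulate the reference dataset: 34 sequences,
lengths uniform on 927 ± 400 nt (total ≈ 31.5 kb), i.i.d. background with
composition (A 0.2419, C 0.2532, G 0.2818, U 0.2231), one planted `CUGGAA`
per sequence at a uniform position. Each planted residue is independently
substituted with probability 0.08 (uniform over the three alternatives);
that rate matches the divergence of the reference motif assignments, which
carry 16 mismatches to the consensus over 34×6 positions. The spread of 400
reflects that the reference start positions reach 765, implying lengths of
many hundreds of nucleotides.

Chance background copies of the *exact* consensus are redrawn so the
planted site is the unique exact occurrence per sequence. A ~31.5 kb
i.i.d. background otherwise contains several exact copies of any given
6-mer, making "which occurrence is the plant" unanswerable: a sampler that
lands on a chance copy attains the identical F. Removal keeps recovery
measurable; it does not make the search easier, since the decoys it removes
are exactly as strong as the plant.

What the generator does not emulate: genic structure, codon bias, local
composition heterogeneity of a real contig, and motif variants beyond
independent per-position substitution. Passing the planted-recovery tests
therefore demonstrates correct search and scoring under an i.i.d.
background, not performance on real genomic sequence.

## Positional analysis

With 1-based starts, S1D = start − 1 and S2D = length − start − width + 1,
so S1D + width + S2D tiles each sequence exactly. Summaries report the
mean, the sample (n−1) standard deviation, and the standard error of the
mean; the "±" values in the reference summary are SEMs under this
definition (their S1D mean/SEM of 270.61/37.17 are reproduced from the
reference starts; the S2D mean follows algebraically from the total length,
independent of how individual lengths are distributed).

## Reference fixtures

The published worked-example tables ship as TSVs
(`src/motifsampler/data/`): background counts, site counts, site
frequencies, final PWM, and the 34 per-gene motif assignments. Two
site-frequency entries were printed without decimal separators ("095091",
"020691") and are stored as 0.95091 and 0.20691; negative PWM entries use a
leading minus rather than the source's trailing-minus typography. Values
are otherwise verbatim, including two rows whose printed PWMS reads
2009.2159 instead of 2009.2156. Residual discrepancies of order 10⁻⁵–10⁻³
between recomputed and printed PWM entries are absorbed by the stated
tolerances and are attributed to rounding internal to the original
software.

## Degenerate inputs and errors

Zero-length records, duplicate ids, empty FASTA files and residues outside
{A,C,G,T,U} are rejected with named errors (a permissive reader drops
records containing IUPAC ambiguity codes with a warning — the matrices
assume a strict 4-letter alphabet). Alignments are validated against their
sequence set on every entry point; sequences shorter than the motif width
are reported by id. `excluded_background` refuses compositions that would
go negative, and a sequence that is entirely motif (n = 1, L = length)
leaves an empty background, which is an error.

## Report precision

Frequencies print at 4 decimals (site frequencies at 5), PWM entries at 5,
PWMS and F at 4 — the precisions of the reference tables. Pipeline runs
with a fixed seed are byte-identical, and `score_only` on a pipeline's best
alignment reproduces its tables exactly.
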