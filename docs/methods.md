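# Methods

## The selection model

The simulator stands in for the wet selection step of a Bind-n-Seq
experiment.  Candidate binding regions are i.i.d. uniform 21-mers.  For a
read `s`, let `b(s)` be its best window log-odds score (bits, both
strands) against the planted motif and `b_max` the motif's maximum
attainable score.  The read survives selection with probability
`min(1, p_spec + p_ns)` where

    p_spec = P / (P + K_half · exp(λ · (b_max − b(s)))) · exp(−w_spec · S)
    p_ns   = α · P / (P + K_half) · exp(−w_ns · S) + ε

with `P` the protein concentration (nM) and `S` the wash salt (mM).  The
first factor of `p_spec` is Hill-coefficient-1 occupancy whose effective
dissociation constant grows exponentially with the score deficit — the
standard PWM-energy correspondence, with `λ` converting bits to binding
free-energy units.  The wash is a single exponential survival per pathway
rather than a kinetic model of the six 10-minute washes of the bench
protocol: one interpretable parameter per phenomenon.  Nonspecific
retention shares the protein-occupancy form (scaled by `α`), decays faster
in salt (`w_ns > w_spec`), and sits on a salt-independent carryover floor
`ε` (fragments that elute regardless of washing).

Defaults, chosen from the closed-form behaviour of these expressions
before any simulation was run:

| parameter | default | units | why |
|---|---|---|---|
| `λ` (energy_scale) | ln 2 ≈ 0.693 | 1/bit | one bit of log-odds = one factor of two in affinity |
| `K_half` | 50 | nM | half-saturation at the assay's moderate protein concentration |
| `α` (nonspecific_floor) | 0.2 | – | nonspecific pathway visible but an order below saturated specific binding |
| `w_spec` | 0.01 | 1/mM | specific complexes survive a 100 mM wash at ~37% |
| `w_ns` | 0.03 | 1/mM | nonspecific complexes wash off ~3× faster |
| `ε` (carryover) | 0.001 | – | 0.1% of any pool survives regardless |
| consensus weight | 0.6 | – | planted PWM column probability: specific but not razor-sharp |
| region length | 21 | bp | library design |
| barcodes | ten 3-mers ACA…ATC | – | the published condition table |

With these defaults the closed form predicts (and simulation confirms)
planted-motif 10-mer fold enrichments of ~12 at the moderate condition
(50 nM / 50 mM), inside the 5–25× band the assay produces, and a
*non-monotone* protein response at 100 mM salt (~19 / 27 / 18 at
5 / 50 / 350 nM): at high protein, weak partial sites and the nonspecific
pathway grow linearly while consensus occupancy saturates, so relative
enrichment falls.  This mirrors the assay's observation that moderate
protein gives the best enrichment.  One known limitation: because the
carryover floor `ε` is salt-independent, enrichment along the *salt* axis
keeps rising from 50 to 100 mM under the defaults instead of peaking at
50 mM; no test depends on the salt axis beyond low-salt < moderate-salt.

A related subtlety: with the nonspecific pathway off (`α = ε = 0`),
raising protein *lowers* the consensus k-mer's measured fold enrichment
even though every read's retention probability rises — the retained pool
is renormalized and partial matches saturate later than perfect sites.
The monotone quantity is retention (occupancy) itself, which is what the
corresponding test asserts.

## Enrichment

Fold enrichment is the ratio of a k-mer's window frequency in a selected
pool to its frequency in a background pool, or to `strands · 4^-k` under
the uniform model (the default when no background pool is supplied).
Counting is both-strand: each window contributes a count to its forward
k-mer and its reverse complement, because the selection acts on
double-stranded probes — a reverse-complement palindrome therefore counts
twice per window, and a consensus and its reverse complement always have
identical counts.  k-mers absent from an empirical background are floored
at half a count; k-mers with fewer than 5 selected counts are suppressed
(divide-noise singletons).  A motif's enrichment score is the maximum fold
enrichment among k-mers within Hamming distance 1 of its consensus or the
consensus's reverse complement.

## ZOOPS EM

Each sequence contains at most one motif site.  With prior γ for "has a
site" (uniform over `2m` offset×strand positions), PWM `p` and background
`q`, the E-step posterior for a site at `(j, σ)` is proportional to
`γ/(2m) · Π p/q` over the window, and `1−γ` for no site.  The M-step
re-estimates the PWM from posterior-weighted site counts plus a 0.1
pseudocount per cell, and γ as the mean posterior site mass.  Iteration
stops when the largest absolute change in the probability matrix falls
below 1e-4 (or at 100 iterations); the observed-data log-likelihood is
non-decreasing and asserted so in tests.  γ₀ = 0.5.

Two identifiability notes.  (1) On signal-free data the EM drifts the
motif toward the background, at which point the likelihood is flat in γ
and γ settles at an arbitrary value; the quantity that *does* collapse is
the fitted motif's information content (< 0.5 bits/column on noise vs ~2
on planted data), and discovery's enrichment ranking stays below 2-fold.
(2) The match-back refinement rounds (threshold: best window score ≥
`min + 0.8 · (max − min)` of the attainable score range) deliberately
sharpen the PWM relative to the planted one; parameter recovery (mean
per-column total-variation distance < 0.1, measured ~0.01–0.03) holds for
the EM fit itself under strong selection (500 nM, no nonspecific pathway).

Discovery runs widths {6, 8, 10} by default (configurable within 6–30),
EM on a seeded random cluster of 10,000 reads, 5 seeds per width from the
top enriched k-mers (column probability 0.7 on the seed base), 3
match-back rounds, reverse-complement deduplication at Hamming distance
≤ 1 keeping the lexicographically smaller consensus, top 5 returned.

## Exact scan p-values

Log-odds matrices use a background-weighted pseudocount,
`p' = (p + c·q)/(1 + c)` with `c = 0.1`, keeping scores finite.  Scores
are discretized onto an integer grid (1000 bins over the attainable range
by default, scores rounded down) and the null distribution of the window
score under the background is computed by convolving the per-column score
distributions — scanning sums the same integerized columns, so scanned
scores and null tail probabilities share one grid and the p-value is
exact on it.  Rounding down makes the realized threshold p-value at a
requested cutoff slightly conservative (≤ the request); on the default
grid the gap is ≲10% of p at p = 1e-4 and shrinks with a finer grid, so
the calibration test (match rate on 10⁷ uniform windows within 3 binomial
SD of the requested p) uses 4000 bins.  For a consensus-like PWM whose
columns take only two values the score distribution is supported on ~w
points and no grid can make the realized cutoff match an arbitrary p;
calibration is therefore checked with a Dirichlet-sampled PWM, which is
also the shape EM-fitted motifs have.  A width-6 motif cannot reach
p < 1e-4 under a uniform background at all (its best score has
p = 4⁻⁶ ≈ 2.4e-4); scans for the 6-bp palindrome use a cutoff of 3e-4,
which admits exactly the consensus word and rejects all 1-mismatch words.

P-values are per window and per strand; no correction across windows is
applied, and a sequence counts once in fraction-of-sequences statistics
even when a palindrome matches the same window on both strands.

## Motif comparison

Best ungapped alignment over all offsets with ≥ 4 overlapping columns and
both orientations; column similarity is the Pearson correlation of
probability 4-vectors (constant columns get correlation 0), alignment
score the mean over the overlap.  Significance comes from a seeded
permutation null — the target's columns are independently shuffled, the
best alignment recomputed, and `p = (1 + #{perm ≥ obs}) / (n_perm + 1)` —
rather than an analytic null; `E = p · #targets`.  Forward orientation
wins exact ties, so a reverse-complement-palindromic query reports
"forward" deterministically.

## Peak annotation

Peaks are represented by their midpoint (floor of (start+end)/2).  The
nearest TSS is chosen by absolute distance, ties broken by lower TSS
coordinate then gene id; distances are strand-adjusted so negative always
means upstream.  Region classes partition peaks with priority promoter
(−1000..+100 bp of the TSS) > TTS region (−100..+1000 bp of the
termination site) > exon > intron > intergenic, evaluated at the midpoint
against the nearest gene only.  The proximity test uses |distance| ≤
1.5 kb; density histograms clamp distances at ±50 kb into boundary bins.
The chi-squared test on the 2×2 motif × proximity table is Pearson's
without continuity correction (df = 1); tables with an empty margin are
returned with a degeneracy flag instead of a p-value.  Whether "within
1.5 kb" should use midpoint, summit, or nearest edge is underdetermined
for the original analysis; midpoint is used throughout.

## The synthetic genome

A uniform-random single-contig genome with non-overlapping gene models
(one gene per fixed-width slot; 2–6 exons), peaks of 200 bp placed so that
motif-free peaks are TSS-proximal with probability `proximal_bias` and
motif-bearing peaks with probability `1 − proximal_bias`; each
motif-bearing peak carries exactly one planted consensus instance at a
recorded offset and strand, and motif-free peaks are rejection-sampled
until they contain no exact consensus instance on either strand.  The
emitted truth table (planted status, offset, strand, true signed TSS
distance) is exactly recoverable by string search over the emitted peak
sequences.  Chance 1-mismatch windows are *not* removed — at the default
scale they occur in ~1% of peaks, matching what a p < 1e-4 scan of real
peaks would also pick up.

## What the simulations do and do not show

The generator reproduces the features the analysis depends on: PWM-energy-
dependent retention, a protein/salt-dependent nonspecific floor, barcoded
fixed-length reads, and a motif whose genomic instances avoid promoters.
It omits sequencing error (reads are emitted at constant Q40, matching a
platform-filtered library), PCR amplification bias, position effects
within the randomized region, protein cooperativity (Hill coefficient is
1), and real genomic base composition (the background is uniform, so
empirical-background and uniform-model enrichment coincide in tests in a
way they would not on biased genomes).  Passing tests therefore
demonstrate the correctness of the computations and the qualitative
behaviour of the workflow under its stated model, not quantitative
agreement with any particular wet experiment.

## Problem sizes

Simulation-backed checks use 100,000 retained reads per condition (the
scale of one sequenced BnS sample) for discovery, enrichment magnitude and
the protein titration; 20,000–30,000 reads for secondary behavioural
tests; 10⁷ windows for scan calibration; and 300–400 peaks over a ~1.2 Mb
genome with 30 genes for the positional analysis.
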