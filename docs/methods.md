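# Methods

## Scope and model

`primertile` designs a minimal-cost set of PCR primers that tiles a set
of target gene sequences with amplicons, allowing primers to be reused
at multiple binding loci and to carry W/S ambiguity positions over
known SNPs. The objective is the total nucleotide count of the
*distinct* primers in a design; coverage (target base pairs inside
amplicons, primer footprints included) is measured and reported but
never optimized — when candidate loci are sparse, the sampler will
trade coverage away for cost, and that behaviour is intentional and
documented below.

## Melting temperature

Tm = 64.9 + 41·(nGC − 16.4)/N, with nGC counting G, C and S positions.
A composition-based formula is a modelling requirement, not merely a
convenience: the whole degeneracy scheme rests on A↔T and G↔C
substitutions being Tm-neutral, which holds for any composition formula
and fails for nearest-neighbour stacking models. The constant set
(64.9/41/16.4) is a conventional long-oligo parameterization and lives
in one place (`thermo.py`) so it can be swapped. Rounding to integer
target temperatures uses half-up rounding, so Tm classes are
deterministic and monotone in GC count.

Two consequences of this lattice matter in practice. First, an integer
temperature t has candidates only if some (length N, count nGC) pair
satisfies round(Tm(N, nGC)) = t; with the default length range there is
no such pair for t = 65, and classes near the top of a 50–70 sweep
reduce to one or two (N, nGC) combinations. Sweep statistics therefore
exclude temperatures whose candidate pool is empty, and the sweep
experiment below extends primer lengths to 30 so the high classes stay
populated. Second, because absolute Tm values depend on the constant
set, only trends across temperatures are meaningful, not the absolute
temperatures themselves.

## Candidate preparation

1. **Enumeration** — every substring of every consensus sequence, both
   strands, lengths `primer_len_min..primer_len_max` (default 18–27),
   whose rounded Tm equals the target; footprints containing N are
   excluded; duplicates are merged with unioned binding-site lists.
   SNP columns from the exceptions sequence force W ({A,T}) or S
   ({C,G}) inside any overlapping footprint (counting toward the
   degeneracy budget); columns with non-Tm-neutral variant sets
   disqualify the footprint.
2. **Screening** — primers that can hairpin (two reverse-complementary
   segments ≥ 4 nt separated by a loop ≥ 3 nt, any expansion), primers
   that self-dimer (3′-terminal 5-mer reverse-complementary to any of
   their own windows, or a ≥ 8 nt self reverse-complement match), and
   primers whose exact-match count over the background exceeds
   `max_redundancy` (default 10, guarding against low-complexity
   regions) are removed. The background search is an exact substring
   scan over both strands behind a narrow interface; a heavyweight
   external aligner is unnecessary at the target scale and could be
   substituted there.
   Cross-primer dimer compatibility is enforced between the forward and
   reverse primers of every amplicon at construction time and in
   `validate_design`. It is deliberately *not* enforced pairwise across
   the whole candidate pool: with thousands of candidates the 5-mer and
   8-mer spaces saturate, and a pool-wide pairwise rule at these
   thresholds would discard essentially every candidate.
3. **Degenerate generalization** — every way of replacing up to
   `max_degeneracy` (default 3, i.e. ≤ 2³ pool members) A/T positions by
   W and G/C positions by S is considered; a degenerate primer is
   retained only when at least two distinct concrete candidates match
   its expansions, with sites merged. Because two candidates can share a
   degenerate generalization only if their full W/S projections are
   identical, generation runs per projection bucket, which is exactly
   equivalent to brute-force generate-and-test over the pool (a property
   the tests verify against a naive oracle).

Primer preference everywhere is the weight order: higher redundancy
first, then lower degeneracy, then lexicographic sequence for
determinism.

## Optimization

A design proposal tiles each gene outward from a random seed position:
amplicon sizes are drawn uniformly from `[amplicon_min, amplicon_max]`
(defaults 50–250 bp), the forward locus is the most-reusable start
within `max_gap` of the current boundary, and the reverse locus the
most-reusable feasible end nearest the drawn size. If no amplicon can
open at a chosen start the tiler skips past it (up to 10 skips), and a
seed falling in a dead stretch falls back to tiling from the gene
start, so genes are covered whenever any feasible amplicon exists.
Consecutive amplicons overlap by `initial_overlap` bp of deliberate
slack; `prob_remove_redundant` sets the per-iteration probability of
deleting an amplicon that has become nested inside a neighbour.
Measured on the synthetic sets here, overlap slack buys more amplicons
and more total primer-use nucleotides, while the distinct-primer cost
can actually dip because overlapping amplicons share primers.

Three proposal generators — full re-seed, single-gene re-seed, and
single-locus reposition (which may move a locus to a different
position *and* a different primer) — are drawn with probability 0.8
for the generator matching the current third of the iteration budget
and 0.1 for each other (all three reachable at any time; weights are a
design choice, set once). Acceptance is Metropolis: downhill always,
uphill with min(1, e^(−δS·H)), H ≥ 0 the heating input (default 0.2);
δS = 0 accepts. An alternative `acceptance_mode = "fraction"` accepts a
fixed fraction H of uphill proposals, for users who read the heating
input as an acceptance quota rather than a Boltzmann exponent; the
Boltzmann mode is primary. The chain returns the lowest-cost design
ever visited plus a per-iteration trace. Early stopping (off by
default) activates when `early_proportion` > 0: after the early phase,
the chain halts once the best cost has improved by no more than
`cost_tolerance` over a sliding window of `early_proportion ·
n_iterations` iterations. With `save_interim` set, the best design is
checkpointed to a TSV every 1000 iterations; resuming from a checkpoint
is not implemented.

A known consequence of optimizing cost alone: wherever candidates are
sparse (high Tm classes, GC-poor regions), single-gene re-seeds that
drop coverage also drop cost and are always accepted, so the chain
ratchets toward sparser designs and the best-ever cost tracks coverage
downward. On temperature sweeps this caps the raw-cost rise at the top
of the range even though cost per covered base keeps rising.

## Synthetic data

The generator emulates the pipeline's intended inputs with known ground
truth: i.i.d. bases at a requested GC content, optionally with periodic
GC-rich blocks (emulating the compositional heterogeneity — GC-rich
exonic islands in an AT-leaning matrix — that lets real genes host
priming sites across a wide Tm range); planted shared 20-mer motifs
whose GC count is tuned to a requested integer Tm, placed at a
requested multiplicity without overlap and verified by exhaustive scan;
per-column SNPs (80% Tm-neutral {A,T}/{C,G}, 20% non-neutral to
exercise the rejection path), never inside planted footprints so motif
instances stay exact repeats; and a background of the genes plus a
decoy sequence. It does not emulate repeat families, codon structure,
or indels, so passing tests demonstrate algorithmic correctness and
qualitative trends, not performance on any particular genome.

## Experiment sizes (package choices)

* Convergence: 30 genes × 450 bp at GC 0.5 with 12 motifs × 3 loci,
  Tm 60, 10 chains × 5000 iterations.
* Temperature sweep: 10 genes × 700 bp, matrix GC 0.42 with GC-0.72
  blocks (period 120, width 55), planted reuse families 8×4 @Tm 52,
  4×8 @Tm 50, 4×8 @Tm 51; primer lengths 18–30; 400 iterations per Tm
  over 50–70. Empty Tm classes are excluded from trend statistics.
  Expected behaviour: coverage decreases significantly in Tm; the
  cost–Tm rank correlation is non-negative (cost rises through the
  well-populated classes and flattens where the lattice starves);
  reuse is markedly richer at Tm 50 than Tm 70.
* Oracle comparison: one 120 bp gene with six hand-placed candidate
  20-mers (forward and reverse footprints kept ≥ 8 bp apart, since an
  overlap of 8+ bp is a reverse-complement duplex by construction);
  exhaustive enumeration over all non-nested amplicon selections gives
  the max-coverage-then-min-cost optimum.
* Acceptance-rule calibration: 10⁵ draws per (δS, H) cell on
  {1,5,10} × {0.1,0.2,1}.

## Numerical and design choices

* Coordinates are 0-based, half-open; a −strand site is stored by the
  plus-strand start of its reverse-complement match.
* Consensus construction breaks majority ties alphabetically; variant
  sets must be pre-aligned, ungapped, equal length (no indel handling).
* Coverage counts primer footprints as covered; an amplicon must be at
  least as long as its two footprints combined.
* A primer serving as forward in one amplicon and reverse in another is
  one distinct primer for cost.
* `max_gap` is the largest tolerated uncovered gap between adjacent
  amplicons; larger gaps are reported as warnings by `validate_design`,
  not errors. Nested amplicons without a reused primer are likewise
  warnings: with `prob_remove_redundant = 0` (the default) nested pairs
  are a legal chain state.
* Degenerate-expansion matches are counted as distinct loci, not summed
  per expansion at one locus (two distinct exact sequences cannot match
  the same stranded locus).
* Reporting rounds cost per covered base and percentages to two
  decimals; the standard error of a mean is the sample standard
  deviation over √n.

## Limitations

No mismatch-tolerant binding-site search, no thermodynamic (ΔG) duplex
or salt-corrected Tm models, no multiplex-tube partitioning, no
alignment of variant sets, and no coverage-constrained optimization.
Absolute costs and coverages on synthetic fixtures are properties of
those fixtures; only the comparative and calibration results are
transferable claims.
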