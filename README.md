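# primertile

Cost-optimized design of reusable, optionally degenerate PCR primers
that tile a set of target genes with amplicons.

## The problem

Deep resequencing and high-throughput genotyping projects need hundreds
of primer pairs, and oligo synthesis is a real line item. Two things
cut the bill: **reuse** — one primer that binds at several conserved
loci closes several amplicons but is synthesized once — and
**degeneracy** — a primer pool with ambiguity positions anneals across
known SNPs instead of failing at them. Choosing a minimal set of
reusable, degenerate primers that still tiles every target is a variant
of the Multiple Degenerate Primer Selection Problem, whose exact forms
are NP-complete, so `primertile` searches the design space
stochastically.

## The model

For a design *D* containing *k* distinct primers of lengths *l₁ … l_k*,
the objective is the **cost**

&nbsp;&nbsp;&nbsp;&nbsp;cost(D) = Σᵢ lᵢ  (nucleotides; a reused primer is paid once),

alongside the **coverage** (base pairs of target inside the design's
amplicons) and their ratio, the **cost per covered base**. Candidate
primers are every substring of the targets (both strands, lengths
18–27 by default) whose melting temperature

&nbsp;&nbsp;&nbsp;&nbsp;Tm = 64.9 + 41·(nGC − 16.4)/N

rounds to the current target temperature. Degeneracy is restricted to
the IUPAC codes **W** (A/T) and **S** (G/C) because those substitutions
leave a composition-based Tm exactly unchanged — every expansion of a
W/S pool anneals at the same temperature. SNPs supplied as an
"exceptions" sequence force W or S at Tm-neutral variant columns and
disqualify footprints over non-neutral ones. Candidates are screened
for hairpins, self-dimers, and excessive redundancy against a genomic
background (exact-match search, capped at 10 occurrences), then
generalized into degenerate primers (≤ 3 W/S positions) wherever that
merges the binding sites of two or more concrete candidates.

Optimization is Metropolis–Hastings over amplicon tilings: three greedy
proposal generators (global re-seeding, per-gene re-seeding, single
primer repositioning) are scheduled by iteration third, downhill moves
are always accepted, and uphill moves with probability
exp(−δS·H) where δS is the cost increase and H the heating parameter
(default 0.2). Only cost is optimized; coverage is reported alongside.

## Worked example

Generate a synthetic six-gene set with eight reusable 20-mer motifs
planted at three loci each, then design primers for Tm 59–61:

```bash
primertile synth --genes 6 --length 600 --gc 0.5 --shared 8 --mult 3 \
    --motif-tm 60 --snp-rate 0.01 --seed 1 -o demo
cat > demo.cfg <<'CFG'
background_path = demo.background.fasta
consensus_path = demo.consensus.fasta
exceptions_path = demo.exceptions.fasta
Minumum melting temperature (centigrade)	59
Maximum melting temperature (centigrade)	61
Number of optimisations	2000
output_path = demo_results.out
CFG
primertile run --config demo.cfg --seed 7
```

prints

```
Tm 59: cost 573 nt, coverage 2151 bp (59.75%), 27 distinct primers
Tm 60: cost 614 nt, coverage 2290 bp (63.61%), 29 distinct primers
Tm 61: cost 627 nt, coverage 1972 bp (54.78%), 26 distinct primers
wrote demo_results.out
```

Each line is one temperature's optimized design: the total nucleotides
across its distinct primers (what you would synthesize), the target
base pairs its amplicons span, and the distinct-primer count (at Tm 59
the design makes 32 primer uses with only 27 distinct primers — the
planted shared sites are being reused). `demo_results.out` holds the
full per-Tm primer tables with degenerate primers flagged `*`, reuse
levels, and binding loci.

The same pipeline is available as a library:

```python
import primertile as pt

genes = pt.read_fasta("demo.consensus.fasta")
cfg = pt.ConfigParams(tm_min=60, tm_max=60, n_iterations=2000, rng_seed=7)
cands = pt.prepare_candidates(genes, 60, cfg, pt.read_fasta("demo.background.fasta"))
best, trace = pt.run_optimization(genes, cands, cfg)
print(pt.design_cost(best), pt.design_coverage(best))
print(pt.redundancy_histogram(best).histogram)
```

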