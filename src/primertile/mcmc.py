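"""Metropolis-Hastings optimization of primer-design cost.

A design proposal is a per-gene amplicon tiling assembled greedily from
the prepared candidate pool.  Three proposal generators operate at
decreasing granularity:

1. global re-seeding — every gene re-tiled from a fresh random seed
   position (genes visited in random order);
2. per-gene refinement — one uniformly chosen gene re-tiled, the rest
   kept;
3. repositioning — one primer locus of one amplicon moved to a random
   alternative binding site that keeps the amplicon within its length
   bounds.

The methods are scheduled stochastically by iteration third (the
third-appropriate method gets probability 0.8, the others 0.1 each, so
all three stay reachable at any time).  Proposals are accepted by the
Metropolis rule: always when cost decreases, otherwise with probability
exp(-deltaS * H) where H is the heating parameter.  Only cost is
optimized; coverage is reported alongside but never drives acceptance.
"""

from __future__ import annotations

import math
from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .candidates import (
    BindingSite,
    CandidatePrimer,
    check_dimer,
    prepare_candidates,
    primer_weight,
)
from .config import ConfigParams
from .design import (
    Amplicon,
    Design,
    ReuseProfile,
    design_cost,
    design_cost_no_reuse,
    design_coverage,
    percentage_coverage,
    redundancy_histogram,
)
from .seqio import GeneSequence


@dataclass
class McmcTrace:
    """Per-iteration record of the chain."""

    iteration: int
    method: int
    current_cost: int
    proposal_cost: int
    delta: int
    accepted: bool
    best_cost: int
    coverage: int


# ---------------------------------------------------------------------------
# candidate index


class CandidateIndex:
    """Per-gene position indexes over the candidate pool.

    For every gene, forward candidates are grouped by plus-strand start
    and reverse candidates by footprint end; each locus list is sorted
    by primer weight so the preferred (most reusable, least degenerate)
    primer at a locus is O(1)."""

    def __init__(
        self,
        genes: Sequence[GeneSequence],
        candidates: Sequence[CandidatePrimer],
        cfg: ConfigParams,
    ):
        self.genes = {g.gene_id: g for g in genes}
        self.cfg = cfg
        self._fwd: dict[str, dict[int, list[CandidatePrimer]]] = {
            g.gene_id: {} for g in genes
        }
        self._rev: dict[str, dict[int, list[CandidatePrimer]]] = {
            g.gene_id: {} for g in genes
        }
        for p in candidates:
            for site in p.sites:
                if site.gene_id not in self.genes:
                    continue
                if site.strand == "+":
                    self._fwd[site.gene_id].setdefault(site.start, []).append(p)
                else:
                    end = site.start + p.length
                    self._rev[site.gene_id].setdefault(end, []).append(p)
        for table in (self._fwd, self._rev):
            for buckets in table.values():
                for plist in buckets.values():
                    plist.sort(key=primer_weight)
        self._fwd_starts = {g: sorted(b) for g, b in self._fwd.items()}
        self._rev_ends = {g: sorted(b) for g, b in self._rev.items()}

    def fwd_starts(self, gene_id: str) -> list[int]:
        return self._fwd_starts[gene_id]

    def rev_ends(self, gene_id: str) -> list[int]:
        return self._rev_ends[gene_id]

    def fwd_at(self, gene_id: str, start: int) -> list[CandidatePrimer]:
        return self._fwd[gene_id].get(start, [])

    def rev_at(self, gene_id: str, end: int) -> list[CandidatePrimer]:
        return self._rev[gene_id].get(end, [])


# ---------------------------------------------------------------------------
# greedy amplicon placement


_MAX_ENDS_TRIED = 12
_MAX_PRIMERS_PER_LOCUS = 4
_MAX_START_ATTEMPTS = 10


def _locus_rank(plist: list[CandidatePrimer]) -> tuple[int, int]:
    best = plist[0]
    return (-best.redundancy, best.n_degenerate)


def _pick_pair(
    idx: CandidateIndex,
    gene_id: str,
    start: int,
    end: int,
    used_pairs: set[tuple[str, str]],
) -> tuple[CandidatePrimer, CandidatePrimer] | None:
    """Highest-weight compatible (fwd, rev) pair at a fixed interval."""
    for f in idx.fwd_at(gene_id, start)[:_MAX_PRIMERS_PER_LOCUS]:
        for r in idx.rev_at(gene_id, end)[:_MAX_PRIMERS_PER_LOCUS]:
            if f.seq == r.seq:
                continue
            if end - start < f.length + r.length:
                continue
            if (f.seq, r.seq) in used_pairs:
                continue
            if check_dimer(f.seq, r.seq):
                continue
            return f, r
    return None


def _place_right(
    idx: CandidateIndex,
    gene: GeneSequence,
    boundary: int,
    rng: np.random.Generator,
    used_pairs: set[tuple[str, str]],
) -> Amplicon | None:
    """Place one amplicon whose start is at or after ``boundary``."""
    cfg = idx.cfg
    starts = idx.fwd_starts(gene.gene_id)
    probe = boundary
    for _attempt in range(_MAX_START_ATTEMPTS):
        lo = bisect_left(starts, probe)
        if lo >= len(starts):
            return None
        hi = bisect_right(starts, probe + cfg.max_gap, lo=lo)
        window = starts[lo:hi] or [starts[lo]]
        # prefer the start hosting the most reusable primer; ties -> leftmost
        s = min(window, key=lambda x: (_locus_rank(idx.fwd_at(gene.gene_id, x)), x))
        size = int(rng.integers(cfg.amplicon_min, cfg.amplicon_max + 1))
        desired = s + size
        ends = idx.rev_ends(gene.gene_id)
        e_lo = bisect_left(ends, s + cfg.amplicon_min)
        e_hi = bisect_right(ends, min(s + cfg.amplicon_max, gene.length))
        feasible = ends[e_lo:e_hi]
        ranked = sorted(
            feasible,
            key=lambda e: (_locus_rank(idx.rev_at(gene.gene_id, e)), abs(e - desired), e),
        )
        for e in ranked[:_MAX_ENDS_TRIED]:
            pair = _pick_pair(idx, gene.gene_id, s, e, used_pairs)
            if pair is not None:
                f, r = pair
                return Amplicon(gene.gene_id, f, r, s, e)
        # no amplicon can open at this start: skip past it and retry
        probe = s + 1
    return None


def _place_left(
    idx: CandidateIndex,
    gene: GeneSequence,
    boundary: int,
    rng: np.random.Generator,
    used_pairs: set[tuple[str, str]],
) -> Amplicon | None:
    """Place one amplicon whose end is at or before ``boundary``."""
    cfg = idx.cfg
    ends = idx.rev_ends(gene.gene_id)
    starts = idx.fwd_starts(gene.gene_id)
    probe = boundary
    for _attempt in range(_MAX_START_ATTEMPTS):
        hi = bisect_right(ends, probe)
        if hi == 0:
            return None
        lo = bisect_left(ends, probe - cfg.max_gap, hi=hi)
        window = ends[lo:hi] or [ends[hi - 1]]
        e = min(window, key=lambda x: (_locus_rank(idx.rev_at(gene.gene_id, x)), -x))
        size = int(rng.integers(cfg.amplicon_min, cfg.amplicon_max + 1))
        desired = e - size
        s_lo = bisect_left(starts, max(0, e - cfg.amplicon_max))
        s_hi = bisect_right(starts, e - cfg.amplicon_min)
        feasible = starts[s_lo:s_hi]
        ranked = sorted(
            feasible,
            key=lambda s: (_locus_rank(idx.fwd_at(gene.gene_id, s)), abs(s - desired), s),
        )
        for s in ranked[:_MAX_ENDS_TRIED]:
            pair = _pick_pair(idx, gene.gene_id, s, e, used_pairs)
            if pair is not None:
                f, r = pair
                return Amplicon(gene.gene_id, f, r, s, e)
        probe = e - 1
    return None


def _tile_gene(
    idx: CandidateIndex,
    gene: GeneSequence,
    seed_pos: int,
    rng: np.random.Generator,
    used_pairs: set[tuple[str, str]],
) -> list[Amplicon]:
    """Tile one gene with amplicons outward from a seed position:
    rightward to the gene end, then leftward from the first amplicon.
    Consecutive amplicons overlap by ``initial_overlap`` bp of slack."""
    cfg = idx.cfg
    max_amps = gene.length // cfg.amplicon_min + 2
    amps: list[Amplicon] = []
    boundary = seed_pos
    while len(amps) < max_amps:
        amp = _place_right(idx, gene, boundary, rng, used_pairs)
        if amp is None:
            break
        amps.append(amp)
        used_pairs.add(amp.pair)
        boundary = max(amp.end - cfg.initial_overlap, amp.start + 1)
    left_boundary = amps[0].start + cfg.initial_overlap if amps else seed_pos
    left: list[Amplicon] = []
    while len(amps) + len(left) < max_amps:
        amp = _place_left(idx, gene, left_boundary, rng, used_pairs)
        if amp is None:
            break
        left.append(amp)
        used_pairs.add(amp.pair)
        left_boundary = min(amp.start + cfg.initial_overlap, amp.end - 1)
    amps.extend(left)
    if not amps and seed_pos > 0:
        # the seed fell in a stretch with no reachable loci in either
        # direction; the gene must still be covered, so tile from 0
        boundary = 0
        while len(amps) < max_amps:
            amp = _place_right(idx, gene, boundary, rng, used_pairs)
            if amp is None:
                break
            amps.append(amp)
            used_pairs.add(amp.pair)
            boundary = max(amp.end - cfg.initial_overlap, amp.start + 1)
    amps.sort(key=lambda a: (a.start, a.end))
    return amps


def _prune_nonreusable(design: Design, idx: CandidateIndex) -> Design:
    """Swap single-use primers for same-locus alternatives that are
    already used elsewhere in the design (lowers distinct-primer cost)."""
    uses = design.primer_uses()
    new = Design()
    pairs = set(design.pairs())
    for gid, amps in design.amplicons.items():
        new_amps = []
        for a in amps:
            f, r = a.fwd, a.rev
            if uses[f.seq] == 1:
                for alt in idx.fwd_at(gid, a.start):
                    if (
                        alt.seq != f.seq
                        and uses.get(alt.seq, 0) >= 1
                        and alt.seq != r.seq
                        and (alt.seq, r.seq) not in pairs
                        and a.length >= alt.length + r.length
                        and not check_dimer(alt.seq, r.seq)
                    ):
                        pairs.discard(a.pair)
                        uses[f.seq] -= 1
                        uses[alt.seq] = uses.get(alt.seq, 0) + 1
                        f = alt
                        pairs.add((f.seq, r.seq))
                        break
            if uses[r.seq] == 1:
                for alt in idx.rev_at(gid, a.end):
                    if (
                        alt.seq != r.seq
                        and uses.get(alt.seq, 0) >= 1
                        and alt.seq != f.seq
                        and (f.seq, alt.seq) not in pairs
                        and a.length >= f.length + alt.length
                        and not check_dimer(f.seq, alt.seq)
                    ):
                        pairs.discard((f.seq, r.seq))
                        uses[r.seq] -= 1
                        uses[alt.seq] = uses.get(alt.seq, 0) + 1
                        r = alt
                        pairs.add((f.seq, r.seq))
                        break
            new_amps.append(Amplicon(gid, f, r, a.start, a.end))
        new.amplicons[gid] = new_amps
    return new


# ---------------------------------------------------------------------------
# proposal generators


def build_initial_design(
    genes: Sequence[GeneSequence],
    candidates: Sequence[CandidatePrimer] | CandidateIndex,
    cfg: ConfigParams,
    rng: np.random.Generator,
) -> Design:
    """Greedy seeded tiling of all genes in random order; the highest
    weight available primer is taken at each locus."""
    idx = (
        candidates
        if isinstance(candidates, CandidateIndex)
        else CandidateIndex(genes, candidates, cfg)
    )
    design = Design()
    used_pairs: set[tuple[str, str]] = set()
    order = list(idx.genes.values())
    perm = rng.permutation(len(order))
    for i in perm:
        gene = order[i]
        seed_pos = int(rng.integers(0, gene.length))
        design.amplicons[gene.gene_id] = _tile_gene(idx, gene, seed_pos, rng, used_pairs)
    # keep deterministic gene order in the design mapping
    design.amplicons = {g.gene_id: design.amplicons[g.gene_id] for g in idx.genes.values()}
    if cfg.remove_nonreusable:
        design = _prune_nonreusable(design, idx)
    return design


def propose_method1_global(
    design: Design, idx: CandidateIndex, cfg: ConfigParams, rng: np.random.Generator
) -> Design:
    """A fresh global re-seeding producing a complete alternative design."""
    return build_initial_design(list(idx.genes.values()), idx, cfg, rng)


def propose_method2_gene(
    design: Design, idx: CandidateIndex, cfg: ConfigParams, rng: np.random.Generator
) -> Design:
    """Re-seed one uniformly chosen gene; all other genes unchanged."""
    gene_ids = list(design.amplicons)
    if not gene_ids:
        return design.copy()
    gid = gene_ids[int(rng.integers(0, len(gene_ids)))]
    new = design.copy()
    used_pairs = {
        a.pair for g, amps in new.amplicons.items() if g != gid for a in amps
    }
    gene = idx.genes[gid]
    seed_pos = int(rng.integers(0, gene.length))
    new.amplicons[gid] = _tile_gene(idx, gene, seed_pos, rng, used_pairs)
    return new


def _method3_alternatives(
    design: Design, idx: CandidateIndex, gid: str, i: int, side: str
) -> list[tuple[int, CandidatePrimer]]:
    """All alternative (position, primer) choices for one end of one
    amplicon that keep the amplicon inside its length bounds and the
    design valid."""
    cfg = idx.cfg
    amp = design.amplicons[gid][i]
    pairs = set(design.pairs())
    pairs.discard(amp.pair)
    gene_len = idx.genes[gid].length
    alts: list[tuple[int, CandidatePrimer]] = []
    if side == "fwd":
        lo = max(0, amp.end - cfg.amplicon_max)
        hi = amp.end - cfg.amplicon_min
        starts = idx.fwd_starts(gid)
        for s in starts[bisect_left(starts, lo) : bisect_right(starts, hi)]:
            for f in idx.fwd_at(gid, s):
                if (s, f.seq) == (amp.start, amp.fwd.seq):
                    continue
                if f.seq == amp.rev.seq:
                    continue
                if amp.end - s < f.length + amp.rev.length:
                    continue
                if (f.seq, amp.rev.seq) in pairs:
                    continue
                if check_dimer(f.seq, amp.rev.seq):
                    continue
                alts.append((s, f))
    else:
        lo = amp.start + cfg.amplicon_min
        hi = min(gene_len, amp.start + cfg.amplicon_max)
        ends = idx.rev_ends(gid)
        for e in ends[bisect_left(ends, lo) : bisect_right(ends, hi)]:
            for r in idx.rev_at(gid, e):
                if (e, r.seq) == (amp.end, amp.rev.seq):
                    continue
                if r.seq == amp.fwd.seq:
                    continue
                if e - amp.start < amp.fwd.length + r.length:
                    continue
                if (amp.fwd.seq, r.seq) in pairs:
                    continue
                if check_dimer(amp.fwd.seq, r.seq):
                    continue
                alts.append((e, r))
    return alts


def propose_method3_reposition(
    design: Design, idx: CandidateIndex, cfg: ConfigParams, rng: np.random.Generator
) -> Design:
    """Move one uniformly chosen primer locus to a random alternative
    binding site; the unchanged design when no alternative exists."""
    flat = [
        (gid, i)
        for gid, amps in design.amplicons.items()
        for i in range(len(amps))
    ]
    if not flat:
        return design.copy()
    gid, i = flat[int(rng.integers(0, len(flat)))]
    side = "fwd" if rng.random() < 0.5 else "rev"
    alts = _method3_alternatives(design, idx, gid, i, side)
    if not alts:
        return design.copy()
    pos, primer = alts[int(rng.integers(0, len(alts)))]
    amp = design.amplicons[gid][i]
    if side == "fwd":
        new_amp = Amplicon(gid, primer, amp.rev, pos, amp.end)
    else:
        new_amp = Amplicon(gid, amp.fwd, primer, amp.start, pos)
    new = design.copy()
    amps = list(new.amplicons[gid])
    amps[i] = new_amp
    amps.sort(key=lambda a: (a.start, a.end))
    new.amplicons[gid] = amps
    return new


# ---------------------------------------------------------------------------
# scheduling / acceptance


def choose_method(iteration: int, cfg: ConfigParams, rng: np.random.Generator) -> int:
    """Stochastic method schedule: uniform thirds weighting.

    When ``weight_greedy`` is on, the method matching the current
    iteration third is drawn with probability 0.8 and the other two with
    0.1 each; off means uniform 1/3."""
    if not cfg.weight_greedy:
        return int(rng.integers(1, 4))
    third = min(2, (3 * iteration) // max(1, cfg.n_iterations))
    probs = [0.1, 0.1, 0.1]
    probs[third] = 0.8
    u = rng.random()
    if u < probs[0]:
        return 1
    if u < probs[0] + probs[1]:
        return 2
    return 3


def metropolis_accept(
    current_cost: float,
    proposal_cost: float,
    heating: float,
    rng: np.random.Generator,
    mode: str = "boltzmann",
) -> bool:
    """Metropolis rule on the cost difference deltaS = C' - C.

    Downhill (deltaS < 0) always accepts.  In the default "boltzmann"
    mode uphill proposals are accepted with probability
    min(1, exp(-deltaS * H)); the alternative "fraction" mode accepts a
    fixed fraction H of uphill proposals."""
    delta = proposal_cost - current_cost
    if delta < 0:
        return True
    if mode == "fraction":
        if delta == 0:
            return True
        return bool(rng.random() < heating)
    p = math.exp(-delta * heating)
    return bool(rng.random() < p)


def remove_nested_pairs(
    design: Design, prob_remove_redundant: float, rng: np.random.Generator
) -> Design:
    """Delete each amplicon lying entirely inside a neighbour
    independently with probability ``prob_remove_redundant``."""
    if prob_remove_redundant <= 0:
        return design
    new = Design()
    for gid, amps in design.amplicons.items():
        keep = []
        for i, a in enumerate(amps):
            nested = any(
                j != i
                and b.start <= a.start
                and a.end <= b.end
                and (b.start, b.end) != (a.start, a.end)
                for j, b in enumerate(amps)
            )
            if nested and rng.random() < prob_remove_redundant:
                continue
            keep.append(a)
        new.amplicons[gid] = keep
    return new


# ---------------------------------------------------------------------------
# the chain


def write_checkpoint(design: Design, path: str | Path) -> None:
    """Serialize a design as a TSV of amplicons (gene, start, end,
    forward primer, reverse primer)."""
    with open(path, "w") as fh:
        fh.write("gene_id\tstart\tend\tfwd_seq\trev_seq\n")
        for amp in design.all_amplicons():
            fh.write(
                f"{amp.gene_id}\t{amp.start}\t{amp.end}\t{amp.fwd.seq}\t{amp.rev.seq}\n"
            )


def run_optimization(
    genes: Sequence[GeneSequence],
    candidates: Sequence[CandidatePrimer],
    cfg: ConfigParams,
    rng: np.random.Generator | None = None,
    count_reuse_once: bool = True,
    keep_trace: bool = True,
) -> tuple[Design, list[McmcTrace]]:
    """Run the full Metropolis-Hastings chain for one prepared candidate
    pool; returns the best-cost design ever seen and the iteration trace.

    ``count_reuse_once=False`` switches the objective to the no-reuse
    cost (every primer use paid separately) for comparison experiments.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed)
    cost_fn: Callable[[Design], int] = (
        design_cost if count_reuse_once else design_cost_no_reuse
    )
    idx = CandidateIndex(genes, candidates, cfg)
    current = build_initial_design(genes, idx, cfg, rng)
    current_cost = cost_fn(current)
    best = current.copy()
    best_cost = current_cost
    trace: list[McmcTrace] = []
    window = int(round(cfg.n_iterations * cfg.early_proportion))
    best_history: list[int] = []
    proposers = {
        1: propose_method1_global,
        2: propose_method2_gene,
        3: propose_method3_reposition,
    }
    for it in range(cfg.n_iterations):
        method = choose_method(it, cfg, rng)
        proposal = proposers[method](current, idx, cfg, rng)
        proposal_cost = cost_fn(proposal)
        pre_cost = current_cost
        accepted = metropolis_accept(
            current_cost, proposal_cost, cfg.heating, rng, cfg.acceptance_mode
        )
        if accepted:
            current = proposal
            current_cost = proposal_cost
        if cfg.prob_remove_redundant > 0:
            trimmed = remove_nested_pairs(current, cfg.prob_remove_redundant, rng)
            if trimmed is not current:
                current = trimmed
                current_cost = cost_fn(current)
        if current_cost < best_cost:
            best_cost = current_cost
            best = current.copy()
        if keep_trace:
            trace.append(
                McmcTrace(
                    iteration=it,
                    method=method,
                    current_cost=pre_cost,
                    proposal_cost=proposal_cost,
                    delta=proposal_cost - pre_cost,
                    accepted=accepted,
                    best_cost=best_cost,
                    coverage=design_coverage(current),
                )
            )
        if cfg.save_interim and (it + 1) % 1000 == 0:
            write_checkpoint(best, str(cfg.output_path) + ".checkpoint.tsv")
        best_history.append(best_cost)
        if window > 0 and it + 1 > window:
            if best_history[it - window] - best_cost <= cfg.cost_tolerance:
                break
    return best, trace


# ---------------------------------------------------------------------------
# exhaustive oracle (test-scale instances only)


def _feasible_amplicons(
    genes: Sequence[GeneSequence],
    candidates: Sequence[CandidatePrimer],
    cfg: ConfigParams,
) -> list[Amplicon]:
    idx = CandidateIndex(genes, candidates, cfg)
    amps = []
    for gene in genes:
        gid = gene.gene_id
        for s in idx.fwd_starts(gid):
            for e in idx.rev_ends(gid):
                if not (cfg.amplicon_min <= e - s <= cfg.amplicon_max):
                    continue
                if e > gene.length:
                    continue
                for f in idx.fwd_at(gid, s):
                    for r in idx.rev_at(gid, e):
                        if f.seq == r.seq:
                            continue
                        if e - s < f.length + r.length:
                            continue
                        if check_dimer(f.seq, r.seq):
                            continue
                        amps.append(Amplicon(gid, f, r, s, e))
    return amps


def oracle_optimal_cost(
    genes: Sequence[GeneSequence],
    candidates: Sequence[CandidatePrimer],
    cfg: ConfigParams,
    space_limit: int = 10**6,
) -> int:
    """Exhaustive enumeration of all valid non-nested amplicon
    selections; among those attaining maximal coverage, the minimum
    distinct-primer cost.  Refuses instances whose selection space
    exceeds ``space_limit``."""
    amps = _feasible_amplicons(genes, candidates, cfg)
    n = len(amps)
    if 2**n > space_limit:
        raise ValueError(
            f"oracle refuses: {n} feasible amplicons -> 2^{n} selections "
            f"exceeds the {space_limit} limit"
        )
    best_cov = -1
    best_cost = 0

    def compatible(a: Amplicon, chosen: list[Amplicon]) -> bool:
        for b in chosen:
            if a.pair == b.pair:
                return False
            if a.gene_id != b.gene_id:
                continue
            if (
                (b.start <= a.start and a.end <= b.end)
                or (a.start <= b.start and b.end <= a.end)
            ):
                return False
        return True

    def recurse(i: int, chosen: list[Amplicon]) -> None:
        nonlocal best_cov, best_cost
        if i == n:
            d = Design()
            for a in chosen:
                d.amplicons.setdefault(a.gene_id, []).append(a)
            cov = design_coverage(d)
            cost = design_cost(d)
            if cov > best_cov or (cov == best_cov and cost < best_cost):
                best_cov, best_cost = cov, cost
            return
        recurse(i + 1, chosen)
        if compatible(amps[i], chosen):
            chosen.append(amps[i])
            recurse(i + 1, chosen)
            chosen.pop()

    recurse(0, [])
    return best_cost


# ---------------------------------------------------------------------------
# Tm sweep


@dataclass
class TmResult:
    """Preparation + optimization outcome at one target Tm."""

    tm: int
    n_candidates: int
    design: Design
    cost: int
    coverage: int
    pct_coverage: float
    profile: ReuseProfile
    trace: list[McmcTrace] | None = None


def run_tm_sweep(
    genes: Sequence[GeneSequence],
    cfg: ConfigParams,
    background: Sequence[GeneSequence] | None = None,
    keep_traces: bool = False,
) -> list[TmResult]:
    """Prepare candidates and run the optimizer at every integer Tm in
    [tm_min, tm_max]; per-Tm chains are seeded from (rng_seed, tm)."""
    total_len = sum(g.length for g in genes)
    results = []
    for tm in range(cfg.tm_min, cfg.tm_max + 1):
        cands = prepare_candidates(genes, tm, cfg, background)
        rng = np.random.default_rng([cfg.rng_seed, tm])
        best, trace = run_optimization(
            genes, cands, cfg, rng=rng, keep_trace=keep_traces
        )
        cost = design_cost(best)
        cov = design_coverage(best)
        results.append(
            TmResult(
                tm=tm,
                n_candidates=len(cands),
                design=best,
                cost=cost,
                coverage=cov,
                pct_coverage=percentage_coverage(cov, total_len) if total_len else 0.0,
                profile=redundancy_histogram(best),
                trace=trace if keep_traces else None,
            )
        )
    return results
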