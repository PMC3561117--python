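"""Primer preparation: enumeration, screening, degeneracy, weighting.

The three preparation stages run before any optimization:

1. every substring of every target consensus (both strands) whose length
   is within the configured primer length range and whose rounded Tm
   equals the current target Tm is enumerated, subject to SNP
   constraints from the exceptions sequence;
2. hairpin-prone and self-dimerizing primers are removed, and each
   survivor's redundancy (distinct binding loci over the target set) and
   background occurrence count are assessed — primers more frequent than
   ``max_redundancy`` are discarded as likely low-complexity;
3. W/S degenerate generalizations are generated up to ``max_degeneracy``
   degenerate positions, retained only when at least two distinct
   already-enumerated primers match their expansions (these are the
   primers whose redundancy degeneracy actually buys).

Cross-primer dimer compatibility is enforced where it is physically
meaningful, between the forward and reverse primers of each amplicon,
at design-construction time (see the mcmc module) and in
``validate_design``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

from .config import ConfigParams
from .seqio import GeneSequence
from .thermo import round_half_up, tm_from_counts

_COMPLEMENT = str.maketrans("ACGTWSN", "TGCAWSN")

#: degenerate code -> concrete alternatives
DEGENERATE_BASES = {"W": "AT", "S": "GC"}
#: per-symbol base sets over the primer alphabet
_BASE_SETS = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"), "W": frozenset("AT"), "S": frozenset("GC"),
}
#: fully degenerate projection: A/T/W -> W, G/C/S -> S
_MASK = str.maketrans("ATWGCS", "WWWSSS")

DIMER_THREE_PRIME_K = 5
DIMER_MIN_DUPLEX = 8
HAIRPIN_MIN_STEM = 4
HAIRPIN_MIN_LOOP = 3


def revcomp(seq: str) -> str:
    """Reverse complement over the A/C/G/T/W/S/N alphabet (W and S are
    self-complementary)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class BindingSite:
    """One exact binding locus of a primer on a target gene.

    ``start`` is the 0-based plus-strand start of the footprint; a '-'
    strand site means the primer equals the reverse complement of the
    gene subsequence at [start, start + len)."""

    gene_id: str
    start: int
    strand: str


@dataclass
class CandidatePrimer:
    """A concrete or W/S-degenerate primer with its target-set loci."""

    seq: str
    tm: float
    n_degenerate: int
    sites: list[BindingSite] = field(default_factory=list)
    passed_filters: bool = True

    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def redundancy(self) -> int:
        return len(self.sites)


def primer_weight(p: CandidatePrimer):
    """Total-order sort key: higher redundancy first, then lower
    degeneracy, then lexicographic sequence (determinism)."""
    return (-p.redundancy, p.n_degenerate, p.seq)


def expand_degenerate(seq: str) -> set[str]:
    """All concrete expansions of a W/S degenerate oligo
    (cardinality 2**n_degenerate)."""
    pools = [DEGENERATE_BASES.get(b, b) for b in seq]
    return {"".join(p) for p in itertools.product(*pools)}


# ---------------------------------------------------------------------------
# dimer / hairpin screening


@lru_cache(maxsize=1 << 16)
def _dimer_concrete(p: str, q: str) -> bool:
    if revcomp(p[-DIMER_THREE_PRIME_K:]) in q:
        return True
    if revcomp(q[-DIMER_THREE_PRIME_K:]) in p:
        return True
    rcq = revcomp(q)
    k = DIMER_MIN_DUPLEX
    for i in range(len(p) - k + 1):
        if p[i : i + k] in rcq:
            return True
    return False


@lru_cache(maxsize=1 << 15)
def check_dimer(p: str, q: str) -> bool:
    """True when two primers can form a cross-dimer: the 3'-terminal
    5-mer of either is reverse-complementary to a window of the other,
    or the pair shares a contiguous reverse-complement match of >= 8 bp.
    Degenerate primers dimerize when any pair of expansions does."""
    for pe in expand_degenerate(p):
        for qe in expand_degenerate(q):
            if _dimer_concrete(pe, qe):
                return True
    return False


@lru_cache(maxsize=1 << 16)
def check_hairpin(p: str) -> bool:
    """True when a concrete oligo can fold back on itself: two disjoint
    reverse-complementary segments of length >= 4 separated by a loop of
    >= 3 bases."""
    stem, loop = HAIRPIN_MIN_STEM, HAIRPIN_MIN_LOOP
    for i in range(len(p) - 2 * stem - loop + 1):
        if p.find(revcomp(p[i : i + stem]), i + stem + loop) != -1:
            return True
    return False


def _hairpin_any(seq: str) -> bool:
    return any(check_hairpin(e) for e in expand_degenerate(seq))


# ---------------------------------------------------------------------------
# background specificity


def _count_occurrences(hay: str, needle: str) -> int:
    n = 0
    pos = hay.find(needle)
    while pos != -1:
        n += 1
        pos = hay.find(needle, pos + 1)
    return n


class BackgroundIndex:
    """Exact-match occurrence counting over a background sequence set.

    Stands in for an external alignment search: background sets here are
    desk-scale, and the screening contract only needs exact counts on
    both strands.  The class isolates the search so an external aligner
    could be substituted."""

    def __init__(self, genes: Sequence[GeneSequence]):
        self._text = "#".join(g.consensus for g in genes)
        self._rc_text = revcomp(self._text)

    def count(self, seq: str) -> int:
        total = 0
        for e in expand_degenerate(seq):
            total += _count_occurrences(self._text, e)
            total += _count_occurrences(self._rc_text, e)
        return total


def count_background_occurrences(
    p: CandidatePrimer | str, background: Sequence[GeneSequence] | BackgroundIndex
) -> int:
    """Number of exact matches of any expansion of a primer on either
    strand of the background set (distinct loci)."""
    seq = p if isinstance(p, str) else p.seq
    index = background if isinstance(background, BackgroundIndex) else BackgroundIndex(background)
    return index.count(seq)


def find_exact_sites(seq: str, genes: Sequence[GeneSequence]) -> list[BindingSite]:
    """All exact binding loci of a (possibly degenerate) primer over both
    strands of a gene set, as plus-strand-anchored BindingSites."""
    sites = []
    L = len(seq)
    for g in genes:
        for e in expand_degenerate(seq):
            pos = g.consensus.find(e)
            while pos != -1:
                sites.append(BindingSite(g.gene_id, pos, "+"))
                pos = g.consensus.find(e, pos + 1)
            rc = revcomp(e)
            pos = g.consensus.find(rc)
            while pos != -1:
                sites.append(BindingSite(g.gene_id, pos, "-"))
                pos = g.consensus.find(rc, pos + 1)
    return sorted(set(sites), key=lambda s: (s.gene_id, s.start, s.strand))


# ---------------------------------------------------------------------------
# SNP constraints


def snp_status(gene: GeneSequence) -> list[int]:
    """Per-column SNP status: 0 = unconstrained, 1 = forced W, 2 = forced
    S, 3 = primer footprints forbidden (N, or non-Tm-neutral SNP set)."""
    n = gene.length
    status = [0] * n
    for i, c in enumerate(gene.consensus):
        if c == "N":
            status[i] = 3
    if gene.exceptions is None:
        return status
    from .seqio import IUPAC_SETS

    for i, (c, e) in enumerate(zip(gene.consensus, gene.exceptions)):
        if status[i] == 3 or e == c:
            continue
        bases = IUPAC_SETS[e]
        if bases == frozenset("AT"):
            status[i] = 1
        elif bases == frozenset("GC"):
            status[i] = 2
        elif len(bases) > 1:
            status[i] = 3
    return status


def apply_snp_constraints(
    seq: str, gene: GeneSequence, start: int, strand: str
) -> tuple[bool, str, int]:
    """Adjust a primer footprint for the gene's collated SNPs.

    Columns whose exception set is {A,T} force a W at that primer
    position, {C,G} forces an S; any other multi-base set (not
    Tm-neutral) invalidates the candidate at this site.  Returns
    (valid, adjusted sequence, number of forced degenerate positions).
    """
    status = snp_status(gene)
    L = len(seq)
    plus = list(gene.consensus[start : start + L])
    forced = 0
    for off in range(L):
        st = status[start + off]
        if st == 3:
            return False, seq, 0
        if st == 1:
            plus[off] = "W"
            forced += 1
        elif st == 2:
            plus[off] = "S"
            forced += 1
    adjusted = "".join(plus)
    if strand == "-":
        adjusted = revcomp(adjusted)
    return True, adjusted, forced


# ---------------------------------------------------------------------------
# enumeration


def enumerate_candidates(
    genes: Sequence[GeneSequence], tm_target: int, cfg: ConfigParams
) -> list[CandidatePrimer]:
    """Stage 1: all substrings of all consensus sequences (both strands)
    with length in the primer range, rounded Tm equal to ``tm_target``,
    no N in the footprint, and SNP constraints satisfied; de-duplicated
    by sequence with merged binding-site lists."""
    by_seq: dict[str, CandidatePrimer] = {}

    def register(seq: str, tm: float, n_deg: int, site: BindingSite) -> None:
        p = by_seq.get(seq)
        if p is None:
            by_seq[seq] = CandidatePrimer(seq, tm, n_deg, [site])
        elif site not in p.sites:
            p.sites.append(site)

    for gene in genes:
        n = gene.length
        status = snp_status(gene)
        # prefix sums: strong-base count, forbidden count, forced count
        gc = [0] * (n + 1)
        bad = [0] * (n + 1)
        forced = [0] * (n + 1)
        for i, c in enumerate(gene.consensus):
            gc[i + 1] = gc[i] + (1 if c in "GCS" else 0)
            bad[i + 1] = bad[i] + (1 if status[i] == 3 else 0)
            forced[i + 1] = forced[i] + (1 if status[i] in (1, 2) else 0)
        for L in range(cfg.primer_len_min, cfg.primer_len_max + 1):
            for s in range(0, n - L + 1):
                if bad[s + L] - bad[s] > 0:
                    continue
                n_deg = forced[s + L] - forced[s]
                if n_deg > cfg.max_degeneracy:
                    continue
                n_gc = gc[s + L] - gc[s]
                tm = tm_from_counts(n_gc, L)
                if round_half_up(tm) != tm_target:
                    continue
                plus = list(gene.consensus[s : s + L])
                for off in range(L):
                    st = status[s + off]
                    if st == 1:
                        plus[off] = "W"
                    elif st == 2:
                        plus[off] = "S"
                plus_seq = "".join(plus)
                register(plus_seq, tm, n_deg, BindingSite(gene.gene_id, s, "+"))
                register(revcomp(plus_seq), tm, n_deg, BindingSite(gene.gene_id, s, "-"))
    out = list(by_seq.values())
    out.sort(key=primer_weight)
    return out


# ---------------------------------------------------------------------------
# degenerate generalization


def _mask(seq: str) -> str:
    return seq.translate(_MASK)


def _subsumes(degen: str, concrete: str) -> bool:
    """True when every expansion of ``concrete`` is an expansion of
    ``degen`` (position-wise base-set containment)."""
    return all(_BASE_SETS[d] >= _BASE_SETS[c] for d, c in zip(degen, concrete))


def generate_degenerates(
    candidates: Sequence[CandidatePrimer], cfg: ConfigParams
) -> list[CandidatePrimer]:
    """Stage 3: exhaustively generalize candidates with W/S positions up
    to ``max_degeneracy``; keep a degenerate primer only when >= 2
    distinct candidates match its expansions, with sites merged.

    Only candidates sharing the same fully W/S-masked projection can be
    generalized onto each other, so generation runs per mask bucket;
    this is exactly equivalent to brute-force generate-and-test over the
    whole pool.  Output is the input merged with the retained
    degenerates, de-duplicated by sequence."""
    by_seq: dict[str, CandidatePrimer] = {}
    for p in candidates:
        q = by_seq.get(p.seq)
        if q is None:
            by_seq[p.seq] = CandidatePrimer(
                p.seq, p.tm, p.n_degenerate, list(p.sites), p.passed_filters
            )
        else:
            for s in p.sites:
                if s not in q.sites:
                    q.sites.append(s)

    buckets: dict[str, list[CandidatePrimer]] = {}
    for p in by_seq.values():
        buckets.setdefault(_mask(p.seq), []).append(p)

    for members in buckets.values():
        if len(members) < 2:
            continue
        seen: set[str] = set()
        for m in members:
            free = [i for i, b in enumerate(m.seq) if b in "ACGT"]
            budget = cfg.max_degeneracy - m.n_degenerate
            for k in range(1, budget + 1):
                for combo in itertools.combinations(free, k):
                    chars = list(m.seq)
                    for i in combo:
                        chars[i] = "W" if chars[i] in "AT" else "S"
                    d = "".join(chars)
                    if d in seen:
                        continue
                    seen.add(d)
                    matched = [mm for mm in members if _subsumes(d, mm.seq)]
                    if len(matched) < 2:
                        continue
                    sites: list[BindingSite] = []
                    for mm in matched:
                        for s in mm.sites:
                            if s not in sites:
                                sites.append(s)
                    if len(sites) > cfg.max_redundancy:
                        continue
                    n_deg = sum(1 for b in d if b in "WS")
                    tm = matched[0].tm
                    existing = by_seq.get(d)
                    if existing is None:
                        by_seq[d] = CandidatePrimer(d, tm, n_deg, sites)
                    else:
                        for s in sites:
                            if s not in existing.sites:
                                existing.sites.append(s)
    out = list(by_seq.values())
    out.sort(key=primer_weight)
    return out


# ---------------------------------------------------------------------------
# full preparation pipeline


def screen_candidates(
    candidates: Iterable[CandidatePrimer],
    cfg: ConfigParams,
    background: BackgroundIndex | Sequence[GeneSequence] | None = None,
) -> list[CandidatePrimer]:
    """Stage 2: drop hairpin-prone, self-dimerizing, and over-redundant
    primers (target-set redundancy or background occurrence count above
    ``max_redundancy``)."""
    index: BackgroundIndex | None
    if background is None or isinstance(background, BackgroundIndex):
        index = background
    else:
        index = BackgroundIndex(background)
    kept = []
    for p in candidates:
        if p.redundancy > cfg.max_redundancy:
            p.passed_filters = False
            continue
        if _hairpin_any(p.seq) or check_dimer(p.seq, p.seq):
            p.passed_filters = False
            continue
        if index is not None and index.count(p.seq) > cfg.max_redundancy:
            p.passed_filters = False
            continue
        kept.append(p)
    return kept


def prepare_candidates(
    genes: Sequence[GeneSequence],
    tm_target: int,
    cfg: ConfigParams,
    background: BackgroundIndex | Sequence[GeneSequence] | None = None,
) -> list[CandidatePrimer]:
    """Run all three preparation stages for one target Tm and return the
    weight-sorted candidate list."""
    cands = enumerate_candidates(genes, tm_target, cfg)
    cands = screen_candidates(cands, cfg, background)
    cands = generate_degenerates(cands, cfg)
    cands = screen_candidates(cands, cfg, background)
    cands.sort(key=primer_weight)
    return cands
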