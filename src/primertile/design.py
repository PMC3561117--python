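"""Design state (per-gene amplicon tilings) and evaluation metrics.

The optimization objective is the design cost: the total nucleotide
count over the DISTINCT primers in the design — a primer reused at m
loci is paid for once.  Coverage is the number of target base pairs
falling inside the design's amplicons (primer footprints included),
and cost per covered base = cost / coverage is the headline summary
statistic.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

from .candidates import BindingSite, CandidatePrimer, check_dimer
from .config import ConfigParams
from .seqio import GeneSequence


@dataclass(frozen=True, eq=False)
class Amplicon:
    """A forward/reverse primer pair spanning [start, end) on one gene,
    primer footprints included."""

    gene_id: str
    fwd: CandidatePrimer
    rev: CandidatePrimer
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def pair(self) -> tuple[str, str]:
        return (self.fwd.seq, self.rev.seq)


@dataclass
class Design:
    """The full per-gene amplicon arrangement whose cost is optimized."""

    amplicons: dict[str, list[Amplicon]] = field(default_factory=dict)

    def all_amplicons(self) -> Iterator[Amplicon]:
        for amps in self.amplicons.values():
            yield from amps

    def n_amplicons(self) -> int:
        return sum(len(a) for a in self.amplicons.values())

    def copy(self) -> "Design":
        return Design({g: list(a) for g, a in self.amplicons.items()})

    def primer_uses(self) -> Counter:
        """Multiset of primer sequence uses (forward and reverse count
        separately; the same primer in two amplicons counts twice)."""
        uses: Counter = Counter()
        for amp in self.all_amplicons():
            uses[amp.fwd.seq] += 1
            uses[amp.rev.seq] += 1
        return uses

    def distinct_primers(self) -> dict[str, CandidatePrimer]:
        out: dict[str, CandidatePrimer] = {}
        for amp in self.all_amplicons():
            out.setdefault(amp.fwd.seq, amp.fwd)
            out.setdefault(amp.rev.seq, amp.rev)
        return out

    def pairs(self) -> list[tuple[str, str]]:
        return [amp.pair for amp in self.all_amplicons()]


def design_cost(d: Design) -> int:
    """Total nucleotides over distinct primer sequences (the optimization
    objective; reuse is paid once)."""
    return sum(len(s) for s in d.distinct_primers())


def design_cost_no_reuse(d: Design) -> int:
    """Cost when every primer use is paid separately (the no-reuse
    comparison arm)."""
    return sum(len(s) * n for s, n in d.primer_uses().items())


def design_coverage(d: Design) -> int:
    """Size of the union of amplicon intervals, summed over genes."""
    total = 0
    for amps in d.amplicons.values():
        intervals = sorted((a.start, a.end) for a in amps)
        cur_s: int | None = None
        cur_e = 0
        for s, e in intervals:
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                total += cur_e - cur_s
                cur_s, cur_e = s, e
        if cur_s is not None:
            total += cur_e - cur_s
    return total


def cost_per_covered_base(cost: float, coverage: float) -> float:
    """cost / coverage, rounded to 2 decimals (as reported)."""
    if coverage <= 0:
        raise ValueError("cost per covered base is undefined at zero coverage")
    return round(cost / coverage, 2)


def percentage_coverage(coverage: float, total_length: float) -> float:
    """100 * coverage / total target length, rounded to 2 decimals."""
    if total_length <= 0:
        raise ValueError("total target length must be positive")
    return round(100.0 * coverage / total_length, 2)


def percent_reduction(no_reuse: float, with_reuse: float) -> float:
    """Percent reduction in primer count from reuse:
    100 * (no_reuse - with_reuse) / no_reuse."""
    if no_reuse <= 0:
        return 0.0
    return 100.0 * (no_reuse - with_reuse) / no_reuse


@dataclass
class ReuseProfile:
    """Redundancy histogram of a design: reuse level -> number of
    distinct primers used at that level."""

    histogram: dict[int, int]

    @property
    def distinct(self) -> int:
        return sum(self.histogram.values())

    @property
    def uses(self) -> int:
        """Equivalent no-reuse primer count (sum of level * count)."""
        return sum(level * n for level, n in self.histogram.items())

    @property
    def reduction_percent(self) -> float:
        return percent_reduction(self.uses, self.distinct)

    def n_reused(self, min_level: int = 2) -> int:
        return sum(n for level, n in self.histogram.items() if level >= min_level)


def redundancy_histogram(d: Design) -> ReuseProfile:
    """Reuse level of each distinct primer = number of amplicon uses in
    the design (forward and reverse uses both count)."""
    uses = d.primer_uses()
    hist: dict[int, int] = {}
    for n in uses.values():
        hist[n] = hist.get(n, 0) + 1
    return ReuseProfile(dict(sorted(hist.items())))


# ---------------------------------------------------------------------------
# validation


@dataclass(frozen=True)
class Violation:
    code: str
    severity: str  # "error" | "warning"
    gene_id: str
    message: str


def _has_site(p: CandidatePrimer, gene_id: str, start: int, strand: str) -> bool:
    return BindingSite(gene_id, start, strand) in p.sites


def validate_design(
    d: Design, genes: Sequence[GeneSequence], cfg: ConfigParams
) -> list[Violation]:
    """Check all amplicon and design invariants; returns violations
    (severity "error") and advisory findings (severity "warning"),
    never raises.

    Warnings cover uncovered gaps larger than ``max_gap`` between
    adjacent amplicons and amplicons fully nested inside a neighbour
    without contributing a reused primer — legal states (nested pairs
    arise by repositioning and are only stochastically removed) that a
    finished design ideally avoids."""
    out: list[Violation] = []
    gene_len = {g.gene_id: g.length for g in genes}
    uses = d.primer_uses()
    seen_pairs: set[tuple[str, str]] = set()

    for gid, amps in d.amplicons.items():
        if gid not in gene_len:
            out.append(Violation("unknown_gene", "error", gid, "gene not in target set"))
            continue
        n = gene_len[gid]
        ordered = sorted(amps, key=lambda a: (a.start, a.end))
        for a in ordered:
            if not (cfg.amplicon_min <= a.length <= cfg.amplicon_max):
                out.append(Violation(
                    "amplicon_length", "error", gid,
                    f"amplicon [{a.start},{a.end}) length {a.length} outside "
                    f"[{cfg.amplicon_min},{cfg.amplicon_max}]"))
            if a.start < 0 or a.end > n:
                out.append(Violation(
                    "amplicon_bounds", "error", gid,
                    f"amplicon [{a.start},{a.end}) outside gene [0,{n})"))
            if a.length < a.fwd.length + a.rev.length:
                out.append(Violation(
                    "footprint_overlap", "error", gid,
                    f"amplicon [{a.start},{a.end}) shorter than its primer footprints"))
            if a.fwd.seq == a.rev.seq:
                out.append(Violation(
                    "identical_pair", "error", gid,
                    f"amplicon [{a.start},{a.end}) uses one primer as both ends"))
            if not _has_site(a.fwd, gid, a.start, "+"):
                out.append(Violation(
                    "fwd_site", "error", gid,
                    f"forward primer lacks a + site at {a.start}"))
            if not _has_site(a.rev, gid, a.end - a.rev.length, "-"):
                out.append(Violation(
                    "rev_site", "error", gid,
                    f"reverse primer lacks a - site ending at {a.end}"))
            if check_dimer(a.fwd.seq, a.rev.seq):
                out.append(Violation(
                    "pair_dimer", "error", gid,
                    f"amplicon [{a.start},{a.end}) primer pair can dimerize"))
            if a.pair in seen_pairs:
                out.append(Violation(
                    "duplicate_pair", "error", gid,
                    f"primer pair {a.pair} used by more than one amplicon"))
            seen_pairs.add(a.pair)
        for prev, cur in zip(ordered, ordered[1:]):
            gap = cur.start - prev.end
            if gap > cfg.max_gap:
                out.append(Violation(
                    "gap", "warning", gid,
                    f"uncovered gap of {gap} bp between amplicons at {prev.end}"))
        for i, a in enumerate(ordered):
            for j, b in enumerate(ordered):
                if i == j:
                    continue
                if b.start <= a.start and a.end <= b.end and (a.start, a.end) != (b.start, b.end):
                    if uses[a.fwd.seq] <= 1 and uses[a.rev.seq] <= 1:
                        out.append(Violation(
                            "nested_amplicon", "warning", gid,
                            f"amplicon [{a.start},{a.end}) nested in "
                            f"[{b.start},{b.end}) without reused primers"))
                    break
    return out


def design_ok(violations: Iterable[Violation]) -> bool:
    return not any(v.severity == "error" for v in violations)
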