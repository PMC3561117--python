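"""Human-readable output file and cross-run summary statistics.

The primary output is a single text file with one block per target Tm:
a weighted primer table (degenerate primers flagged), then the covered
bases, the final cost in nucleotides, and the cost per covered base.
The layout is stable and machine-parseable (see :func:`read_output`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from .config import ConfigParams
from .design import percent_reduction
from .mcmc import TmResult
from .candidates import primer_weight


def write_output(
    results: Sequence[TmResult], cfg: ConfigParams, path: str | Path | None = None
) -> Path:
    """Write the per-Tm result blocks; deterministic ordering (primers
    by weight, loci by gene/position)."""
    if not results:
        raise ValueError("no Tm results to write")
    path = Path(path if path is not None else cfg.output_path)
    with open(path, "w") as fh:
        fh.write("# reusable degenerate primer design results\n")
        fh.write(f"# seed: {cfg.rng_seed}\n")
        fh.write(f"# iterations: {cfg.n_iterations}\n")
        for res in results:
            fh.write(f"== Tm {res.tm} ==\n")
            primers = sorted(res.design.distinct_primers().values(), key=primer_weight)
            uses = res.design.primer_uses()
            fh.write(f"primers: {len(primers)} distinct ({sum(uses.values())} uses)\n")
            fh.write("sequence\tlength\tdegeneracy\treuse\tloci\n")
            for p in primers:
                loci = ";".join(
                    f"{s.gene_id}:{s.strand}{s.start}"
                    for s in sorted(p.sites, key=lambda s: (s.gene_id, s.start, s.strand))
                )
                flag = "*" if p.n_degenerate > 0 else ""
                fh.write(
                    f"{p.seq}{flag}\t{p.length}\t{p.n_degenerate}\t{uses[p.seq]}\t{loci}\n"
                )
            fh.write(f"covered bases: {res.coverage}\n")
            fh.write(f"final cost (nucleotides): {res.cost}\n")
            cpb = res.cost / res.coverage if res.coverage else float("nan")
            fh.write(f"cost per covered base: {cpb:.2f}\n")
    return path


def read_output(path: str | Path) -> dict[int, dict[str, float]]:
    """Parse an output file back into per-Tm metrics (round-trip of the
    cost, coverage, and primer-count lines)."""
    out: dict[int, dict[str, float]] = {}
    tm = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("== Tm "):
                tm = int(line.split()[2])
                out[tm] = {}
            elif tm is not None and line.startswith("primers: "):
                out[tm]["n_primers"] = int(line.split()[1])
            elif tm is not None and line.startswith("covered bases: "):
                out[tm]["coverage"] = int(line.split(": ")[1])
            elif tm is not None and line.startswith("final cost (nucleotides): "):
                out[tm]["cost"] = int(line.split(": ")[1])
            elif tm is not None and line.startswith("cost per covered base: "):
                out[tm]["cost_per_covered_base"] = float(line.split(": ")[1])
    return out


# ---------------------------------------------------------------------------
# summaries across repeated runs


def _mean(xs: Sequence[float]) -> float:
    return sum(xs) / len(xs)


def _stderr(xs: Sequence[float]) -> float:
    """Standard error of the mean: sample standard deviation / sqrt(n)."""
    n = len(xs)
    if n < 2:
        return 0.0
    m = _mean(xs)
    var = sum((x - m) ** 2 for x in xs) / (n - 1)
    return math.sqrt(var) / math.sqrt(n)


@dataclass
class RunSummary:
    """Across-run summary: mean/SE of cost per covered base and the
    redundancy-level table with its reuse arithmetic."""

    n_runs: int
    mean_cost_per_covered_base: float
    se_cost_per_covered_base: float
    level_means: dict[int, float]
    level_ses: dict[int, float]
    with_reuse_total: float
    no_reuse_total: float
    reduction_percent: float


def reuse_totals(level_means: Mapping[int, float]) -> tuple[float, float, float]:
    """From per-reuse-level mean primer counts: the equivalent no-reuse
    primer total (sum of level * count), the with-reuse total (sum of
    counts), and the percent reduction."""
    no_reuse = sum(level * n for level, n in level_means.items())
    with_reuse = sum(level_means.values())
    return no_reuse, with_reuse, percent_reduction(no_reuse, with_reuse)


def summarize_runs(
    runs: Sequence[tuple[float, float, Mapping[int, int]]],
) -> RunSummary:
    """Summarize repeated (cost, coverage, reuse histogram) runs."""
    if len(runs) < 2:
        raise ValueError("need at least two runs to summarize")
    cpbs = [cost / cov for cost, cov, _ in runs]
    levels = sorted({lvl for _, _, hist in runs for lvl in hist})
    level_counts = {lvl: [float(hist.get(lvl, 0)) for _, _, hist in runs] for lvl in levels}
    level_means = {lvl: _mean(cs) for lvl, cs in level_counts.items()}
    level_ses = {lvl: _stderr(cs) for lvl, cs in level_counts.items()}
    no_reuse, with_reuse, reduction = reuse_totals(level_means)
    return RunSummary(
        n_runs=len(runs),
        mean_cost_per_covered_base=_mean(cpbs),
        se_cost_per_covered_base=_stderr(cpbs),
        level_means=level_means,
        level_ses=level_ses,
        with_reuse_total=with_reuse,
        no_reuse_total=no_reuse,
        reduction_percent=reduction,
    )
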