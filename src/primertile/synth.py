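"""Synthetic fixture generator with known ground truth.

Emulates the kind of input the pipeline targets — a modest set of gene
consensus sequences with a genomic background — while planting features
whose locations are known exactly: reusable priming sites (a shared
20-mer appearing at several loci across genes, with a GC count tuned so
its rounded Tm equals a caller-chosen target) and per-column SNPs
written into an exceptions sequence (80% Tm-neutral {A,T}/{C,G} sets,
20% non-neutral sets to exercise the rejection path of the SNP
constraints).  Everything is reproducible from the seed.

What it does NOT emulate: repeat families, isochore-scale GC structure,
codon bias, or indel variation — synthetic bases are i.i.d. at the
requested GC content outside the planted motifs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .candidates import check_dimer, check_hairpin, find_exact_sites, revcomp
from .seqio import IUPAC_CODES, GeneSequence
from .thermo import TM_GC_OFFSET, TM_INTERCEPT, TM_SLOPE, round_half_up, tm_from_counts


@dataclass
class SyntheticTruth:
    """Ground truth of a generated fixture."""

    planted_motifs: list[tuple[str, list[tuple[str, int, str]]]]
    snp_positions: dict[str, list[tuple[int, frozenset]]]
    gc_target: float
    seed: int


@dataclass
class SyntheticGeneSet:
    consensus: list[GeneSequence]
    exceptions: list[GeneSequence]
    background: list[GeneSequence]
    truth: SyntheticTruth


def _random_bases(
    rng: np.random.Generator,
    n: int,
    gc: float,
    island_period: int = 0,
    island_width: int = 0,
    island_gc: float = 0.8,
) -> list[str]:
    """i.i.d. bases at the requested GC, optionally with periodic GC-rich
    islands (positions k*period .. k*period+width drawn at island_gc) to
    emulate the compositional heterogeneity of real genes."""
    p = np.full(n, gc)
    if island_period > 0 and island_width > 0:
        pos = np.arange(n)
        p[(pos % island_period) < island_width] = island_gc
    strong = rng.random(n) < p
    pick = rng.random(n) < 0.5
    out = []
    for st, pk in zip(strong, pick):
        if st:
            out.append("G" if pk else "C")
        else:
            out.append("A" if pk else "T")
    return out


def _motif_for_tm(
    rng: np.random.Generator, tm_target: int, length: int, existing: set[str]
) -> str:
    """A random motif whose rounded Tm equals the target and which
    survives hairpin/self-dimer screening.

    Not every (length, Tm) pair is attainable on the integer-GC lattice
    of the composition formula, so nearby lengths are searched when the
    requested one has no feasible GC count."""
    n_gc = None
    for delta in (0, -1, 1, -2, 2):
        cand_len = length + delta
        if cand_len < 15:
            continue
        n = round_half_up(
            (tm_target - TM_INTERCEPT) * cand_len / TM_SLOPE + TM_GC_OFFSET
        )
        n = max(0, min(cand_len, n))
        if round_half_up(tm_from_counts(n, cand_len)) == tm_target:
            n_gc, length = n, cand_len
            break
    if n_gc is None:
        raise ValueError(
            f"no GC count near length {length} gives a motif rounding to Tm {tm_target}"
        )
    for _ in range(2000):
        chars = ["G" if r < 0.5 else "C" for r in rng.random(n_gc)]
        chars += ["A" if r < 0.5 else "T" for r in rng.random(length - n_gc)]
        perm = rng.permutation(length)
        motif = "".join(chars[i] for i in perm)
        if motif in existing or revcomp(motif) in existing:
            continue
        if check_hairpin(motif) or check_dimer(motif, motif):
            continue
        return motif
    raise RuntimeError("could not generate a clean planted motif")


def generate_gene_set(
    n_genes: int,
    length: int,
    gc_target: float = 0.5,
    n_shared_sites: int = 0,
    site_multiplicity: int = 1,
    snp_rate: float = 0.0,
    seed: int = 0,
    motif_tm: int = 60,
    motif_length: int = 20,
    decoy_fraction: float = 0.5,
    neutral_snp_fraction: float = 0.8,
    island_period: int = 0,
    island_width: int = 0,
    island_gc: float = 0.8,
    planted_families: list[tuple[int, int, int]] | None = None,
) -> SyntheticGeneSet:
    """Generate consensus/exceptions/background gene sets with planted
    reusable priming sites and injected SNPs.

    Each of ``n_shared_sites`` distinct motifs is planted at
    ``site_multiplicity`` non-overlapping loci spread across genes; the
    background holds the genes plus a decoy sequence of
    ``decoy_fraction`` times the total gene length.  SNP columns avoid
    planted footprints so motif instances stay exact repeats.

    ``planted_families`` generalizes the scalar triple: a list of
    (n_motifs, multiplicity, target Tm) families planted together, e.g.
    a few highly reused low-Tm motifs alongside many moderately reused
    ones (real gene families show such a reuse spectrum).
    """
    rng = np.random.default_rng(seed)
    if planted_families is None:
        planted_families = (
            [(n_shared_sites, site_multiplicity, motif_tm)] if n_shared_sites else []
        )
    n_slots = sum(n * m for n, m, _ in planted_families)
    if n_slots * motif_length > n_genes * length // 2:
        raise ValueError("planted sites do not plausibly fit the gene set")

    for attempt in range(20):
        genes_chars = [
            _random_bases(rng, length, gc_target, island_period, island_width, island_gc)
            for _ in range(n_genes)
        ]
        reserved: dict[int, list[tuple[int, int]]] = {i: [] for i in range(n_genes)}
        motifs: list[str] = []
        placements: list[list[tuple[str, int, str]]] = []
        existing: set[str] = set()
        ok = True
        family_specs = [
            (mult, fam_tm)
            for n_motifs, mult, fam_tm in planted_families
            for _ in range(n_motifs)
        ]
        for fam_mult, fam_tm in family_specs:
            motif = _motif_for_tm(rng, fam_tm, motif_length, existing)
            existing.add(motif)
            motifs.append(motif)
            locs: list[tuple[str, int, str]] = []
            mlen = len(motif)
            for _ in range(fam_mult):
                placed = False
                for _try in range(200):
                    gi = int(rng.integers(0, n_genes))
                    pos = int(rng.integers(0, length - mlen + 1))
                    if any(
                        pos < e + 1 and s < pos + mlen + 1
                        for s, e in reserved[gi]
                    ):
                        continue
                    reserved[gi].append((pos, pos + mlen))
                    genes_chars[gi][pos : pos + mlen] = list(motif)
                    locs.append((f"g{gi + 1}", pos, "+"))
                    placed = True
                    break
                if not placed:
                    raise ValueError("cannot place planted sites without overlap")
            placements.append(locs)

        consensus = [
            GeneSequence(f"g{i + 1}", "".join(chars))
            for i, chars in enumerate(genes_chars)
        ]
        # verify each planted motif occurs at exactly its listed loci
        for motif, locs in zip(motifs, placements):
            found = find_exact_sites(motif, consensus)
            if len(found) != len(locs):
                ok = False
                break
        if ok:
            break
    else:
        raise RuntimeError("could not build a collision-free fixture")

    # SNP injection (outside planted footprints)
    snp_positions: dict[str, list[tuple[int, frozenset]]] = {}
    exceptions: list[GeneSequence] = []
    if snp_rate > 0:
        neutral_partner = {"A": "T", "T": "A", "C": "G", "G": "C"}
        other_class = {"A": "CG", "T": "CG", "C": "AT", "G": "AT"}
        for gi, gene in enumerate(consensus):
            codes = list(gene.consensus)
            snps: list[tuple[int, frozenset]] = []
            hit = rng.random(gene.length) < snp_rate
            neutral = rng.random(gene.length) < neutral_snp_fraction
            alt_pick = rng.random(gene.length) < 0.5
            for pos in range(gene.length):
                if not hit[pos]:
                    continue
                if any(s <= pos < e for s, e in reserved[gi]):
                    continue
                base = gene.consensus[pos]
                if neutral[pos]:
                    pair = frozenset((base, neutral_partner[base]))
                else:
                    alt = other_class[base][int(alt_pick[pos])]
                    pair = frozenset((base, alt))
                codes[pos] = IUPAC_CODES[pair]
                snps.append((pos, pair))
            snp_positions[gene.gene_id] = snps
            exceptions.append(GeneSequence(gene.gene_id, gene.consensus, "".join(codes)))
    else:
        exceptions = [GeneSequence(g.gene_id, g.consensus, g.consensus) for g in consensus]
        snp_positions = {g.gene_id: [] for g in consensus}

    decoy_len = int(n_genes * length * decoy_fraction)
    background = [GeneSequence(g.gene_id, g.consensus) for g in consensus]
    if decoy_len > 0:
        background.append(
            GeneSequence("decoy", "".join(_random_bases(
                rng, decoy_len, gc_target, island_period, island_width, island_gc)))
        )

    truth = SyntheticTruth(
        planted_motifs=list(zip(motifs, placements)),
        snp_positions=snp_positions,
        gc_target=gc_target,
        seed=seed,
    )
    return SyntheticGeneSet(consensus, exceptions, background, truth)


def write_gene_set(gs: SyntheticGeneSet, prefix: str) -> dict[str, str]:
    """Write the three FASTA files plus a ground-truth TSV; returns the
    paths written."""
    from .seqio import write_fasta

    paths = {
        "consensus": f"{prefix}.consensus.fasta",
        "exceptions": f"{prefix}.exceptions.fasta",
        "background": f"{prefix}.background.fasta",
        "truth": f"{prefix}.truth.tsv",
    }
    write_fasta(gs.consensus, paths["consensus"])
    write_fasta(gs.exceptions, paths["exceptions"], use_exceptions=True)
    write_fasta(gs.background, paths["background"])
    with open(paths["truth"], "w") as fh:
        fh.write("kind\tname\tgene_id\tposition\tdetail\n")
        for motif, locs in gs.truth.planted_motifs:
            for gid, pos, strand in locs:
                fh.write(f"motif\t{motif}\t{gid}\t{pos}\t{strand}\n")
        for gid, snps in gs.truth.snp_positions.items():
            for pos, bases in snps:
                fh.write(
                    f"snp\t{'/'.join(sorted(bases))}\t{gid}\t{pos}\t"
                    f"{'neutral' if bases in (frozenset('AT'), frozenset('CG')) else 'non-neutral'}\n"
                )
    return paths
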