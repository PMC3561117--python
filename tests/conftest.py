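"""Shared fixtures: deterministic hand-built instances and hypothesis setup."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from primertile import CandidatePrimer, BindingSite, ConfigParams, GeneSequence
from primertile.candidates import check_dimer, check_hairpin, revcomp

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def _clean_oracle_gene(seed0: int = 0) -> tuple[GeneSequence, list[CandidatePrimer]]:
    """A 120 bp gene with a hand-placed candidate set (3 forward starts,
    3 reverse ends, all 20-mers) whose primers are mutually dimer-free
    and hairpin-free, found by deterministic seed search.

    The locus layout keeps every forward footprint at least 8 bp clear
    of every reverse footprint, since footprints overlapping by >= 8 bp
    are reverse-complement matches by construction and would always
    trip the dimer screen."""
    starts = [0, 40, 80]
    ends = [38, 78, 120]
    for seed in range(seed0, seed0 + 2000):
        rng = np.random.default_rng(seed)
        gene_str = "".join(rng.choice(list("ACGT"), size=120))
        fwd_seqs = [gene_str[s : s + 20] for s in starts]
        rev_seqs = [revcomp(gene_str[e - 20 : e]) for e in ends]
        all_seqs = fwd_seqs + rev_seqs
        if len(set(all_seqs)) != len(starts) + len(ends):
            continue
        if any(check_hairpin(s) for s in all_seqs):
            continue
        if any(
            check_dimer(p, q) for i, p in enumerate(all_seqs) for q in all_seqs[i:]
        ):
            continue
        gene = GeneSequence("oracle_gene", gene_str)
        cands = []
        for s, seq in zip(starts, fwd_seqs):
            cands.append(
                CandidatePrimer(seq, 0.0, 0, [BindingSite("oracle_gene", s, "+")])
            )
        for e, seq in zip(ends, rev_seqs):
            cands.append(
                CandidatePrimer(seq, 0.0, 0, [BindingSite("oracle_gene", e - 20, "-")])
            )
        return gene, cands
    raise RuntimeError("no clean oracle gene found")


@pytest.fixture(scope="session")
def oracle_instance():
    """(genes, candidates, cfg) for exhaustive-oracle comparisons: one
    120 bp gene, 6 candidate 20-mers, amplicons 50-250 bp."""
    gene, cands = _clean_oracle_gene()
    cfg = ConfigParams(n_iterations=5000, tm_min=60, tm_max=60)
    return [gene], cands, cfg


@pytest.fixture(scope="session")
def small_fixture():
    """A small synthetic gene set with planted shared sites (multiplicity
    3) and its prepared Tm-60 candidate pool."""
    import primertile as pt

    gs = pt.generate_gene_set(
        n_genes=6, length=500, gc_target=0.5, n_shared_sites=8,
        site_multiplicity=3, snp_rate=0.0, seed=7, motif_tm=60,
    )
    cfg = pt.ConfigParams(tm_min=60, tm_max=60, n_iterations=800)
    cands = pt.prepare_candidates(gs.consensus, 60, cfg, gs.background)
    return gs, cfg, cands
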