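"""Primer preparation: enumeration, screening, degeneracy, weighting.

Brute-force oracles here are deliberately naive re-derivations (window
pair scans, generate-and-test) kept independent of the implementation.
"""

import itertools

import numpy as np
import pytest

from primertile import (
    BindingSite,
    CandidatePrimer,
    ConfigParams,
    GeneSequence,
    apply_snp_constraints,
    check_dimer,
    check_hairpin,
    count_background_occurrences,
    enumerate_candidates,
    expand_degenerate,
    generate_degenerates,
    primer_weight,
)
from primertile.candidates import revcomp, screen_candidates
from primertile.thermo import rounded_tm


# ---------------------------------------------------------------------------
# expansion


def test_expansion_cardinality_examples():
    assert expand_degenerate("AWSG") == {"AAGG", "AACG", "ATGG", "ATCG"}
    assert expand_degenerate("ACGT") == {"ACGT"}
    three = "ACGTACGTACGTACGTAWSW"
    assert len(expand_degenerate(three)) == 2**3


@pytest.mark.parametrize("w", [0, 1, 2, 3])
def test_expansion_cardinality_power_law(w):
    seq = "W" * w + "A" * (20 - w)
    assert len(expand_degenerate(seq)) == 2**w


# ---------------------------------------------------------------------------
# dimer / hairpin vs brute-force window oracles


def _oracle_dimer(p: str, q: str) -> bool:
    n, m = len(p), len(q)
    if any(p[-5:] == revcomp(q[j : j + 5]) for j in range(m - 4)):
        return True
    if any(q[-5:] == revcomp(p[i : i + 5]) for i in range(n - 4)):
        return True
    return any(
        p[i : i + k] == revcomp(q[j : j + k])
        for k in range(8, min(n, m) + 1)
        for i in range(n - k + 1)
        for j in range(m - k + 1)
    )


def _oracle_hairpin(p: str) -> bool:
    n = len(p)
    return any(
        p[j : j + k] == revcomp(p[i : i + k])
        for k in range(4, n)
        for i in range(n - k + 1)
        for j in range(i + k + 3, n - k + 1)
    )


def test_dimer_examples():
    p = "AAAAAAAAAAAAAAAGGGGG"
    assert check_dimer(p, revcomp(p))
    assert not check_dimer("A" * 20, "C" * 20)


def test_hairpin_examples():
    stem_loop = "GGGGAAATTTCCCCAGAT"  # GGGG ... CCCC with a 6-base loop
    assert check_hairpin(stem_loop)
    assert not check_hairpin("A" * 18)


def test_dimer_matches_window_oracle():
    rng = np.random.default_rng(42)
    bases = np.array(list("ACGT"))
    for _ in range(200):
        p = "".join(rng.choice(bases, size=int(rng.integers(18, 28))))
        q = "".join(rng.choice(bases, size=int(rng.integers(18, 28))))
        assert check_dimer(p, q) == _oracle_dimer(p, q), (p, q)


def test_hairpin_matches_segment_pair_oracle():
    rng = np.random.default_rng(43)
    bases = np.array(list("ACGT"))
    for _ in range(300):
        p = "".join(rng.choice(bases, size=int(rng.integers(18, 28))))
        assert check_hairpin(p) == _oracle_hairpin(p), p


def test_degenerate_dimer_any_expansion():
    p = "AAAAAAAAAAAAAAAGGGGG"
    q = revcomp(p)
    # make one end degenerate; some expansion still duplexes
    q_deg = "W" + q[1:]
    assert check_dimer(p, q_deg)


# ---------------------------------------------------------------------------
# enumeration vs brute force


def _oracle_enumerate(genes, tm_target, cfg):
    """Naive substring scan over both strands (no SNP handling)."""
    out = {}
    for g in genes:
        for L in range(cfg.primer_len_min, cfg.primer_len_max + 1):
            for s in range(g.length - L + 1):
                sub = g.consensus[s : s + L]
                if "N" in sub:
                    continue
                if rounded_tm(sub) != tm_target:
                    continue
                out.setdefault(sub, set()).add((g.gene_id, s, "+"))
                out.setdefault(revcomp(sub), set()).add((g.gene_id, s, "-"))
    return out


def test_enumeration_matches_brute_force():
    rng = np.random.default_rng(11)
    genes = [
        GeneSequence(f"g{i}", "".join(rng.choice(list("ACGT"), size=120)))
        for i in range(3)
    ]
    cfg = ConfigParams(primer_len_min=18, primer_len_max=21)
    for tm in (50, 55, 60):
        got = {
            p.seq: {(s.gene_id, s.start, s.strand) for s in p.sites}
            for p in enumerate_candidates(genes, tm, cfg)
        }
        assert got == _oracle_enumerate(genes, tm, cfg)


def test_enumeration_empty_gene_list():
    assert enumerate_candidates([], 60, ConfigParams()) == []


def test_planted_repeat_merges_sites():
    rng = np.random.default_rng(3)
    motif = "ATGCATTTGACGTAGGCTCA"  # 20-mer, 9 GC -> Tm 49.73 -> 50
    assert rounded_tm(motif) == 50
    chunks = []
    for i in range(3):
        filler = "".join(rng.choice(list("ACGT"), size=60))
        chunks.append(filler + motif)
    gene = GeneSequence("g1", "".join(chunks))
    cfg = ConfigParams()
    cands = enumerate_candidates([gene], 50, cfg)
    by_seq = {p.seq: p for p in cands}
    assert motif in by_seq
    assert by_seq[motif].redundancy == 3


def test_n_blocks_primer_footprints():
    gene = GeneSequence("g1", "A" * 30 + "N" + "A" * 30)
    cands = enumerate_candidates([gene], 38, ConfigParams())  # Tm of poly-A 20-mers
    for p in cands:
        for site in p.sites:
            assert not ("N" in gene.consensus[site.start : site.start + p.length])


# ---------------------------------------------------------------------------
# background screening


def test_background_counts_and_discard():
    rng = np.random.default_rng(5)
    primer = "ATGCATTTGACGTAGGCTAA"
    filler = lambda n: "".join(rng.choice(list("ACGT"), size=n))
    bg_seq = "".join(filler(30) + primer for _ in range(11)) + filler(30)
    background = [GeneSequence("bg", bg_seq)]
    assert count_background_occurrences(primer, background) == 11
    assert count_background_occurrences(filler(20), background) == 0
    cfg = ConfigParams()
    cand = CandidatePrimer(primer, 0.0, 0, [BindingSite("g1", 0, "+")])
    kept = screen_candidates([cand], cfg, background)
    assert kept == [] and cand.passed_filters is False


def test_degenerate_background_counts_sum_expansions():
    a = "ATGCATTTGACGTAGGCTAA"
    b = "TTGCATTTGACGTAGGCTAA"  # differs at position 0 (A/T)
    background = [GeneSequence("bg", a + "CC" + b + "CC" + a)]
    deg = "W" + a[1:]
    assert count_background_occurrences(deg, background) == 3


# ---------------------------------------------------------------------------
# degenerate generalization


def _oracle_generate(cands, cfg):
    """Generate-and-test every W/S generalization of every candidate."""
    def subsume(d, c):
        sets = {"A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
                "W": {"A", "T", "W"}, "S": {"G", "C", "S"}}
        return all(cb in sets[db] for db, cb in zip(d, c))

    seqs = [p.seq for p in cands]
    retained = {}
    for p in cands:
        free = [i for i, b in enumerate(p.seq) if b in "ACGT"]
        for k in range(1, cfg.max_degeneracy - p.n_degenerate + 1):
            for combo in itertools.combinations(free, k):
                chars = list(p.seq)
                for i in combo:
                    chars[i] = "W" if chars[i] in "AT" else "S"
                d = "".join(chars)
                matched = [s for s in seqs if subsume(d, s)]
                if len(matched) >= 2:
                    retained[d] = set(matched)
    return retained


def test_degenerate_hand_case():
    a = "AAGTACGTACGTACGTAC"
    b = "ATGTACGTACGTACGTAC"  # one A/T difference at position 1
    cands = [
        CandidatePrimer(a, 0.0, 0, [BindingSite("g1", 0, "+")]),
        CandidatePrimer(b, 0.0, 0, [BindingSite("g2", 5, "+")]),
    ]
    out = generate_degenerates(cands, ConfigParams())
    by_seq = {p.seq: p for p in out}
    d = "AWGTACGTACGTACGTAC"
    assert d in by_seq
    assert {(s.gene_id, s.start) for s in by_seq[d].sites} == {("g1", 0), ("g2", 5)}
    assert by_seq[d].n_degenerate == 1


def test_degenerate_zero_budget_identity():
    a = CandidatePrimer("AAGTACGTACGTACGTAC", 0.0, 0, [BindingSite("g1", 0, "+")])
    b = CandidatePrimer("ATGTACGTACGTACGTAC", 0.0, 0, [BindingSite("g2", 0, "+")])
    cfg = ConfigParams(max_degeneracy=0)
    out = generate_degenerates([a, b], cfg)
    assert sorted(p.seq for p in out) == sorted([a.seq, b.seq])


def test_degenerate_generation_matches_brute_force():
    """Retained degenerate set equals generate-and-test over the pool."""
    rng = np.random.default_rng(17)
    base = "".join(rng.choice(list("ACGT"), size=18))
    pool = {base}
    # random W/S-compatible variants of the base plus unrelated primers
    while len(pool) < 6:
        chars = list(base)
        for i in rng.choice(18, size=int(rng.integers(1, 4)), replace=False):
            chars[i] = {"A": "T", "T": "A", "C": "G", "G": "C"}[chars[i]]
        pool.add("".join(chars))
    for _ in range(3):
        pool.add("".join(rng.choice(list("ACGT"), size=18)))
    cands = [
        CandidatePrimer(s, 0.0, 0, [BindingSite(f"g{i}", 0, "+")])
        for i, s in enumerate(sorted(pool))
    ]
    cfg = ConfigParams()
    got = {p.seq for p in generate_degenerates(cands, cfg) if p.n_degenerate > 0}
    assert got == set(_oracle_generate(cands, cfg))


def test_all_expansions_of_degenerate_share_tm(small_fixture):
    from primertile import melting_temperature

    _, _, cands = small_fixture
    for p in cands:
        if p.n_degenerate:
            tms = {melting_temperature(e) for e in expand_degenerate(p.seq)}
            assert len(tms) == 1


def test_retained_redundancy_matches_site_scan(small_fixture):
    """Candidate redundancy equals a brute-force scan of expansion
    matches over both strands of the target set."""
    from primertile import find_exact_sites

    gs, _, cands = small_fixture
    rng = np.random.default_rng(0)
    subset = [cands[int(i)] for i in rng.integers(0, len(cands), size=40)]
    for p in subset:
        assert p.redundancy == len(find_exact_sites(p.seq, gs.consensus))


# ---------------------------------------------------------------------------
# SNP constraints


def test_snp_neutral_forces_degenerate_code():
    gene = GeneSequence("g", "ATGCATTTGACGTAGGCTAA", "WTGCATTTGACGTAGGCTAA")
    ok, adjusted, forced = apply_snp_constraints(
        gene.consensus, gene, 0, "+"
    )
    assert ok and adjusted.startswith("W") and forced == 1


def test_snp_non_neutral_invalidates():
    gene = GeneSequence("g", "ATGCATTTGACGTAGGCTAA", "RTGCATTTGACGTAGGCTAA")
    ok, _, _ = apply_snp_constraints(gene.consensus, gene, 0, "+")
    assert not ok


def test_no_exceptions_leaves_primer_unchanged():
    gene = GeneSequence("g", "ATGCATTTGACGTAGGCTAA")
    ok, adjusted, forced = apply_snp_constraints(gene.consensus, gene, 0, "+")
    assert ok and adjusted == gene.consensus and forced == 0


def test_enumeration_respects_snp_constraints():
    seq = "ATGCATTTGACGTAGGCTAAATGCATTTGACGTAGGCTAA"
    exc = list(seq)
    exc[5] = "W"   # Tm-neutral SNP over the T at column 5
    exc[20] = "R"  # non-neutral {A,G} SNP over the A at column 20
    gene = GeneSequence("g", seq, "".join(exc))
    cfg = ConfigParams(primer_len_min=18, primer_len_max=20)
    found = []
    for tm in range(40, 70):
        found.extend(enumerate_candidates([gene], tm, cfg))
    for p in found:
        for site in p.sites:
            footprint = range(site.start, site.start + p.length)
            assert 20 not in footprint  # non-neutral column excluded
            if 5 in footprint and site.strand == "+":
                assert p.seq[5 - site.start] == "W"


# ---------------------------------------------------------------------------
# weighting


def test_weight_ordering():
    hi = CandidatePrimer("C" * 20, 0.0, 1,
                         [BindingSite("g", i, "+") for i in range(3)])
    lo = CandidatePrimer("A" * 20, 0.0, 0,
                         [BindingSite("g", i, "+") for i in range(2)])
    assert primer_weight(hi) < primer_weight(lo)


def test_weight_tie_break_lexicographic():
    a = CandidatePrimer("AAAAAAAAAAAAAAAAAAAA", 0.0, 0, [BindingSite("g", 0, "+")])
    b = CandidatePrimer("CAAAAAAAAAAAAAAAAAAA", 0.0, 0, [BindingSite("g", 1, "+")])
    assert primer_weight(a) < primer_weight(b)


def test_weight_sort_is_total_and_idempotent():
    rng = np.random.default_rng(2)
    cands = [
        CandidatePrimer(
            "".join(rng.choice(list("ACGT"), size=20)),
            0.0,
            int(rng.integers(0, 3)),
            [BindingSite("g", int(i), "+") for i in range(int(rng.integers(1, 5)))],
        )
        for _ in range(50)
    ]
    once = sorted(cands, key=primer_weight)
    twice = sorted(once, key=primer_weight)
    assert [p.seq for p in once] == [p.seq for p in twice]
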