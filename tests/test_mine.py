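"""Exon miner: seeded search vs exhaustive Smith-Waterman, significance
gates, splice-boundary refinement and iterative paralog recovery."""

import numpy as np
import pytest

from famscan.mine import (
    Contig,
    ExonHit,
    MiningParams,
    iterative_mine,
    refine_exon_boundaries,
    seeded_local_search,
)
from famscan.pipeline import EXPECTED_EXON_LENGTHS
from famscan.simulate import FamilySpec, generate_truth, mutate_sequence, random_dna, revcomp

RNG = np.random.default_rng(1234)


def sw_oracle(target: str, query: str):
    """Brute-force local alignment (Gotoh affine) over the whole target.

    Independent of the package's seeded path: plain dynamic programming,
    match +2 / mismatch -3 / gap 5+2L, returns (score, target interval).
    """
    m, n = len(target), len(query)
    NEG = -1e18
    M = np.zeros((m + 1, n + 1))
    X = np.full((m + 1, n + 1), NEG)
    Y = np.full((m + 1, n + 1), NEG)
    best, best_pos = 0.0, (0, 0)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            sub = 2 if target[i - 1] == query[j - 1] and target[i - 1] != "N" else -3
            M[i, j] = max(0.0, M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + sub
            X[i, j] = max(M[i - 1, j] - 7, X[i - 1, j] - 2)
            Y[i, j] = max(M[i, j - 1] - 7, Y[i, j - 1] - 2)
            if M[i, j] > best:
                best, best_pos = M[i, j], (i, j)
    # walk back along M to find the start row (score path end only needed)
    return best, best_pos


def test_exact_substring_query_hits_with_full_identity():
    contig = random_dna(RNG, 3000)
    query = contig[1000:1300]
    hits = seeded_local_search({"c": contig}, {"N__q": query})
    assert len(hits) == 1
    h = hits[0]
    assert h.interval == (1000, 1300)
    assert h.identity == 1.0
    assert h.query_cover == 1.0
    assert h.strand == "+"
    assert h.evalue < 1e-10


def test_seeded_search_matches_smith_waterman_oracle():
    """On a small contig the seeded hit equals the exhaustive local DP."""
    rng = np.random.default_rng(7)
    contig = random_dna(rng, 1500)
    exon = random_dna(rng, 240)
    planted = contig[:700] + exon + contig[700:]
    query = mutate_sequence(rng, exon, 0.15, keep_orf=False)
    hits = seeded_local_search({"c": planted}, {"N__q": query})
    assert len(hits) == 1
    oracle_score, (end_t, _) = sw_oracle(planted, query)
    assert hits[0].score == pytest.approx(oracle_score)
    assert hits[0].interval[1] == end_t
    # truth overlap >= 90%
    s, e = hits[0].interval
    inter = min(e, 700 + 240) - max(s, 700)
    assert inter / 240 >= 0.9


def test_query_cover_gate_discards_partial_alignments():
    rng = np.random.default_rng(8)
    contig = random_dna(rng, 4000)
    fragment = contig[2000:2100]
    # query whose alignable part covers only ~33%
    query = fragment + random_dna(rng, 200)
    hits = seeded_local_search({"c": contig}, {"N__q": query})
    assert hits == []
    hits = seeded_local_search(
        {"c": contig}, {"N__q": query}, MiningParams(min_cover=0.2)
    )
    assert len(hits) == 1


def test_gene_free_contigs_produce_no_calls():
    rng = np.random.default_rng(9)
    contigs = {f"c{i}": random_dna(rng, 20000) for i in range(3)}
    queries = {"N__q": random_dna(rng, 321)}
    assert seeded_local_search(contigs, queries) == []


def test_empty_contig_set_is_empty_result_not_error():
    assert seeded_local_search({}, {"N__q": "ACGT" * 30}) == []


def test_contig_validation():
    with pytest.raises(ValueError):
        Contig("c", "")
    with pytest.raises(ValueError):
        Contig("c", "ACGU")


def test_strand_symmetry(small_truth, small_calls):
    """Reverse-complementing every contig flips strands and mirrors
    coordinates but preserves the call set."""
    rc_contigs = {k: revcomp(v) for k, v in small_truth.contigs.items()}
    rc_calls = iterative_mine(
        rc_contigs,
        small_truth.ancestors.seed_queries,
        EXPECTED_EXON_LENGTHS,
        MiningParams(),
    )
    lengths = {k: len(v) for k, v in small_truth.contigs.items()}
    fwd = {
        (c.contig_id, c.refined_interval, c.strand, c.sequence)
        for c in small_calls
    }
    mirrored = {
        (
            c.contig_id,
            (
                lengths[c.contig_id] - c.refined_interval[1],
                lengths[c.contig_id] - c.refined_interval[0],
            ),
            "+" if c.strand == "-" else "-",
            c.sequence,
        )
        for c in rc_calls
    }
    assert fwd == mirrored


class TestRefinement:
    def _planted_hit(self, truth, gene, exon):
        return ExonHit(
            query_id=f"{exon.domain}__q",
            contig_id=gene.contig_id,
            interval=(exon.start + 4, exon.end - 5),  # deliberately sloppy ends
            strand=gene.strand,
            score=400.0,
            evalue=1e-30,
            query_cover=1.0,
            identity=0.95,
            query_span=(4, len(exon.seq) - 5),
            query_len=len(exon.seq),
        )

    def test_planted_exon_round_trip(self, small_truth):
        g = next(gene for gene in small_truth.genes if not gene.donor_mutated_junctions)
        e = g.n_exon
        call = refine_exon_boundaries(
            self._planted_hit(small_truth, g, e),
            small_truth.contigs[g.contig_id],
            expected_length=len(e.seq),
        )
        assert call.refined_interval == (e.start, e.end)
        assert call.acceptor_ok and call.donor_ok and call.length_ok
        assert call.sequence == e.seq

    def test_mutated_donor_flagged(self):
        # a family of receptor genes that all carry a mutated donor site
        truth = generate_truth(
            FamilySpec(
                n_genes=6, psg_fraction=0.0, donor_mutated_fraction=1.0,
                contig_count=2, seed=31,
            )
        )
        flagged = 0
        for g in truth.genes:
            assert g.donor_mutated_junctions
            for j in g.donor_mutated_junctions:
                e = g.exons[j]
                call = refine_exon_boundaries(
                    self._planted_hit(truth, g, e),
                    truth.contigs[g.contig_id],
                    expected_length=len(e.seq),
                )
                assert not call.donor_ok
                flagged += 1
        assert flagged >= 6

    def test_contig_edge_truncation_is_partial_call(self):
        rng = np.random.default_rng(11)
        exon = random_dna(rng, 120)
        # exon runs off the contig end: no donor side at all
        contig = random_dna(rng, 500) + "AG" + exon[:70]
        hit = ExonHit(
            "N__q", "c", (502, 572), "+", 140.0, 1e-12, 0.58, 1.0, (0, 70), 120
        )
        call = refine_exon_boundaries(hit, contig, expected_length=120)
        assert not call.length_ok
        assert not call.donor_ok

    def test_n_in_exon_flagged_not_dropped(self):
        rng = np.random.default_rng(12)
        exon = random_dna(rng, 90)
        exon = exon[:40] + "N" + exon[41:]
        contig = random_dna(rng, 300) + "AG" + exon + "GT" + random_dna(rng, 300)
        hit = ExonHit("Cyt__q", "c", (302, 392), "+", 150.0, 1e-12, 1.0, 0.99,
                      (0, 90), 90)
        call = refine_exon_boundaries(hit, contig, expected_length=90)
        assert call.contains_n
        assert call.refined_interval == (302, 392)


def _substitute(seq: str, positions) -> str:
    swap = {"A": "C", "C": "G", "G": "T", "T": "A"}
    out = list(seq)
    for p in positions:
        out[p] = swap[out[p]]
    return "".join(out)


def test_iterative_mining_reaches_distant_paralog_via_intermediate():
    """A paralog invisible from the seed is recovered through an
    intermediate relative (oracle: single-round searches per query).

    Constructed so that word seeding provably fails seed->far (no clean
    11-mer: combined substitutions every 10 nt) but succeeds seed->near
    and near->far (substitutions 20 nt apart leave seed words intact).
    """
    rng = np.random.default_rng(40)
    seed_exon = random_dna(rng, 240)
    near = _substitute(seed_exon, range(20, 240, 20))
    far = _substitute(near, range(10, 240, 20))
    spacer = lambda n: random_dna(rng, n)
    contig = (
        spacer(800) + "AG" + near + "GT" + spacer(1500) + "AG" + far + "GT" + spacer(800)
    )
    contigs = {"c": contig}
    queries = {"N__seed": seed_exon}
    # oracle: the seed alone must find `near` but not `far`
    direct = seeded_local_search(contigs, queries)
    assert len(direct) == 1
    # ...while a single-round search from `near` does find `far`
    via = seeded_local_search(contigs, {"N__near": near})
    assert len(via) == 2
    one_round = iterative_mine(contigs, queries, {"N": 240}, max_rounds=1)
    assert len(one_round) == 1
    two_rounds = iterative_mine(contigs, queries, {"N": 240}, max_rounds=3)
    assert len(two_rounds) == 2


def test_mining_recovers_planted_exons_with_exact_boundaries(small_truth, small_calls):
    truth_exons = {
        (g.contig_id, e.start, e.end): e.domain
        for g in small_truth.genes
        for e in g.exons
    }
    called = {(c.contig_id, *c.refined_interval): c.domain_type for c in small_calls}
    exact = sum(1 for k in called if k in truth_exons)
    assert exact / len(truth_exons) >= 0.95
    # no false positives outside planted loci
    assert len(called) - exact == 0


def test_identical_paralogs_fixed_point_in_round_one():
    rng = np.random.default_rng(50)
    exon = random_dna(rng, 150)
    contig = (
        random_dna(rng, 500) + "AG" + exon + "GT"
        + random_dna(rng, 900) + "AG" + exon + "GT" + random_dna(rng, 500)
    )
    calls_1 = iterative_mine({"c": contig}, {"N__q": exon}, {"N": 150}, max_rounds=1)
    calls_many = iterative_mine({"c": contig}, {"N__q": exon}, {"N": 150}, max_rounds=5)
    assert len(calls_1) == len(calls_many) == 2


def test_multi_species_mode_searches_each_species_separately():
    from famscan.mine import iterative_mine_multi

    rng = np.random.default_rng(60)
    exon = random_dna(rng, 150)
    with_gene = random_dna(rng, 400) + "AG" + exon + "GT" + random_dna(rng, 400)
    without = random_dna(rng, len(with_gene))
    result = iterative_mine_multi(
        {"spA": {"c1": with_gene}, "spB": {"c2": without}},
        {"N__q": exon},
        {"N": 150},
    )
    assert len(result["spA"]) == 1
    assert result["spB"] == []
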