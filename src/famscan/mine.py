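"""Homology-seeded exon mining in genome contigs.

Candidate exons are found by exact k-mer seeding followed by local
Smith-Waterman alignment (Biopython's PairwiseAligner, C implementation)
inside a window around each seed cluster, on both strands.  Hits are kept
when they pass two significance gates: an E-value computed from the
alignment score with a Karlin-Altschul-style formula using fixed internal
constants, and a minimum query-cover fraction.  Because seeding only
restricts *where* the dynamic program runs, the hit set on small inputs is
identical to an exhaustive Smith-Waterman scan whenever a seed word
survives in the homologous region.

Raw alignment boundaries are then refined against splice biology: the
refiner searches a window around each alignment end for the canonical
intron dinucleotides (AG upstream of the acceptor boundary, GT downstream
of the donor boundary) consistent with the expected domain length, and
flags exons whose sites are mutated or truncated by a contig edge.

Mining iterates: exons called in round k join the query set for round
k+1, so distant paralogs reachable only through intermediate relatives are
still recovered; short cytoplasmic exons are additionally sought in 2 kb
windows downstream of each transmembrane exon call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .simulate import revcomp

# Scoring scheme (pinned for deterministic gates): match +2, mismatch -3,
# gap of length L costs 5 + 2L.  N is treated as a mismatch against
# everything, including itself.
MATCH = 2
MISMATCH = -3
GAP_OPEN = -5
GAP_EXTEND = -2

# Karlin-Altschul-style surrogate constants for nucleotide scoring
KA_K = 0.1
KA_LAMBDA = 0.33

DEFAULT_WORD_SIZE = 11
DEFAULT_MAX_EVALUE = 1e-10
DEFAULT_MIN_COVER = 0.5
LOCUS_OVERLAP = 0.5          # interval overlap above which two hits are one locus
SPLICE_WINDOW = 30           # nt scanned around each raw boundary
LENGTH_TOLERANCE = 6         # nt slack on the expected domain length
DOWNSTREAM_WINDOW = 2000     # nt searched past TM exons for short exons


@dataclass(frozen=True)
class Contig:
    id: str
    seq: str

    def __post_init__(self):
        if not self.seq:
            raise ValueError(f"contig {self.id} is empty")
        if set(self.seq) - set("ACGTN"):
            raise ValueError(f"contig {self.id} has characters outside ACGTN")


@dataclass
class ExonHit:
    query_id: str
    contig_id: str
    interval: tuple[int, int]   # 0-based half-open, plus-strand coordinates
    strand: str
    score: float
    evalue: float
    query_cover: float
    identity: float
    # aligned query span in the query's own orientation, and query length;
    # used to project the full exon extent past trimmed alignment ends
    query_span: tuple[int, int] = (0, 0)
    query_len: int = 0


@dataclass
class ExonCall:
    hit: ExonHit
    refined_interval: tuple[int, int]
    domain_type: str
    acceptor_ok: bool
    donor_ok: bool
    length_ok: bool
    sequence: str               # coding-strand sequence of the refined exon
    contains_n: bool = False

    @property
    def contig_id(self) -> str:
        return self.hit.contig_id

    @property
    def strand(self) -> str:
        return self.hit.strand


@dataclass
class MiningParams:
    word_size: int = DEFAULT_WORD_SIZE
    max_evalue: float = DEFAULT_MAX_EVALUE
    min_cover: float = DEFAULT_MIN_COVER
    length_tolerance: int = LENGTH_TOLERANCE
    splice_window: int = SPLICE_WINDOW

    def validate(self):
        if self.word_size < 4:
            raise ValueError("word_size must be >= 4")
        if not (0 <= self.min_cover <= 1):
            raise ValueError("min_cover must be in [0,1]")


# ---------------------------------------------------------------------------
# alignment plumbing

def _nt_matrix():
    alphabet = "ACGTN"
    m = substitution_matrices.Array(alphabet, dims=2)
    for a in alphabet:
        for b in alphabet:
            if a == b and a != "N":
                m[a, b] = MATCH
            else:
                m[a, b] = MISMATCH
    return m


def make_aligner(mode: str = "local") -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = _nt_matrix()
    # Biopython charges open_gap_score for the first gapped position
    aligner.open_gap_score = GAP_OPEN + GAP_EXTEND
    aligner.extend_gap_score = GAP_EXTEND
    return aligner


def alignment_score(a: str, b: str) -> float:
    """Best local alignment score of two sequences under the package scheme."""
    if not a or not b:
        return 0.0
    return float(make_aligner().score(a, b))


def evalue(score: float, query_len: int, space_len: int) -> float:
    """E = K * m * n * exp(-lambda * S) with pinned nucleotide constants."""
    return KA_K * query_len * max(space_len, 1) * math.exp(-KA_LAMBDA * score)


# ---------------------------------------------------------------------------
# k-mer seeding

def _encode(seq: str) -> np.ndarray:
    a = np.frombuffer(seq.encode(), dtype=np.uint8)
    code = np.full(len(a), -1, dtype=np.int64)
    for i, b in enumerate(b"ACGT"):
        code[a == b] = i
    return code


def _kmer_codes(seq: str, w: int) -> tuple[np.ndarray, np.ndarray]:
    code = _encode(seq)
    n = len(seq) - w + 1
    if n <= 0:
        return np.empty(0, np.int64), np.empty(0, bool)
    codes = np.zeros(n, dtype=np.int64)
    ok = np.ones(n, dtype=bool)
    for j in range(w):
        window = code[j : j + n]
        ok &= window >= 0
        codes = codes * 4 + np.where(window >= 0, window, 0)
    return codes, ok


class ContigIndex:
    """Sorted k-mer table over one contig for O(log n) seed lookup."""

    def __init__(self, seq: str, word_size: int):
        self.word_size = word_size
        self.length = len(seq)
        codes, ok = _kmer_codes(seq, word_size)
        pos = np.nonzero(ok)[0]
        c = codes[pos]
        order = np.argsort(c, kind="stable")
        self._codes = c[order]
        self._pos = pos[order]

    def seed_positions(self, query: str) -> np.ndarray:
        """Diagonals (contig_pos - query_pos) of all exact word matches."""
        qcodes, qok = _kmer_codes(query, self.word_size)
        if len(qcodes) == 0 or len(self._codes) == 0:
            return np.empty(0, np.int64)
        left = np.searchsorted(self._codes, qcodes, "left")
        right = np.searchsorted(self._codes, qcodes, "right")
        diags = []
        for qpos in np.nonzero(qok & (right > left))[0]:
            diags.append(self._pos[left[qpos] : right[qpos]] - qpos)
        if not diags:
            return np.empty(0, np.int64)
        return np.unique(np.concatenate(diags))


def _seed_windows(diags: np.ndarray, qlen: int, contig_len: int) -> list[tuple[int, int]]:
    """Merge seed diagonals into candidate alignment windows."""
    if len(diags) == 0:
        return []
    margin = max(20, qlen // 3)
    windows: list[tuple[int, int]] = []
    group_start = prev = int(diags[0])
    for d in diags[1:]:
        d = int(d)
        if d - prev > 2 * margin:
            windows.append((group_start, prev))
            group_start = d
        prev = d
    windows.append((group_start, prev))
    merged: list[tuple[int, int]] = []
    for lo, hi in windows:
        a = max(0, lo - margin)
        b = min(contig_len, hi + qlen + margin)
        if merged and a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return merged


# ---------------------------------------------------------------------------
# seeded search

def _overlap_frac(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = min(a[1], b[1]) - max(a[0], b[0])
    if inter <= 0:
        return 0.0
    return inter / min(a[1] - a[0], b[1] - b[0])


def _as_contig_dict(contigs) -> dict[str, str]:
    if isinstance(contigs, dict):
        return {k: v.upper() for k, v in contigs.items()}
    return {c.id: c.seq.upper() for c in contigs}


def seeded_local_search(
    contigs,
    queries: dict[str, str],
    params: MiningParams | None = None,
    indexes: dict[str, ContigIndex] | None = None,
    exclude: dict[str, list[tuple[int, int]]] | None = None,
) -> list[ExonHit]:
    """Find significant local alignments of each query on both strands.

    ``exclude`` maps contig id to intervals that are already called;
    candidate windows falling entirely inside an excluded locus are
    skipped (used by iterative mining to avoid re-aligning known loci).
    Overlapping hits are collapsed to the best-scoring one per locus.
    """
    params = params or MiningParams()
    params.validate()
    contig_seqs = _as_contig_dict(contigs)
    if not queries:
        raise ValueError("query set is empty")
    space = sum(len(s) for s in contig_seqs.values())
    if space == 0:
        return []
    aligner = make_aligner()
    indexes = indexes if indexes is not None else {}
    exclude = exclude or {}

    raw_hits: list[ExonHit] = []
    for cid, cseq in contig_seqs.items():
        if cid not in indexes:
            indexes[cid] = ContigIndex(cseq, params.word_size)
        index = indexes[cid]
        masked = exclude.get(cid, [])
        for qid, qseq in queries.items():
            qseq = qseq.upper()
            if not qseq:
                continue
            for strand in "+-":
                q = qseq if strand == "+" else revcomp(qseq)
                diags = index.seed_positions(q)
                for lo, hi in _seed_windows(diags, len(q), len(cseq)):
                    if any(_overlap_frac((lo, hi), m) > 0.9 for m in masked):
                        continue
                    hit = _align_window(
                        aligner, cseq, lo, hi, q, qid, cid, strand, len(qseq), space
                    )
                    if (
                        hit is not None
                        and hit.evalue < params.max_evalue
                        and hit.query_cover > params.min_cover
                    ):
                        raw_hits.append(hit)

    # collapse per locus: best score wins, ties by coordinate for determinism
    raw_hits.sort(key=lambda h: (-h.score, h.contig_id, h.interval, h.strand, h.query_id))
    kept: list[ExonHit] = []
    for hit in raw_hits:
        if any(
            k.contig_id == hit.contig_id
            and _overlap_frac(k.interval, hit.interval) > LOCUS_OVERLAP
            for k in kept
        ):
            continue
        kept.append(hit)
    kept.sort(key=lambda h: (h.contig_id, h.interval, h.strand))
    return kept


def _align_window(aligner, cseq, lo, hi, q, qid, cid, strand, qlen, space):
    target = cseq[lo:hi]
    alignments = aligner.align(target, q)
    try:
        best = alignments[0]
    except IndexError:
        return None
    score = float(best.score)
    if score <= 0:
        return None
    tblocks, qblocks = best.aligned
    t_start, t_end = int(tblocks[0][0]), int(tblocks[-1][1])
    q_start, q_end = int(qblocks[0][0]), int(qblocks[-1][1])
    counts = best.counts()
    columns = counts.gaps + counts.identities + counts.mismatches
    identity = counts.identities / columns if columns else 0.0
    start, end = lo + t_start, lo + t_end
    if strand == "+":
        span = (q_start, q_end)
    else:  # q was reverse-complemented; map back to query orientation
        span = (qlen - q_end, qlen - q_start)
    return ExonHit(
        query_id=qid,
        contig_id=cid,
        interval=(start, end),
        strand=strand,
        score=score,
        evalue=evalue(score, qlen, space),
        query_cover=(q_end - q_start) / qlen,
        identity=identity,
        query_span=span,
        query_len=qlen,
    )


# ---------------------------------------------------------------------------
# boundary refinement

def refine_exon_boundaries(
    hit: ExonHit,
    contig: str,
    expected_length: int | tuple[int, ...],
    domain_type: str | None = None,
    tolerance: int = LENGTH_TOLERANCE,
    window: int = SPLICE_WINDOW,
) -> ExonCall:
    """Snap raw alignment ends to AG...exon...GT boundaries of plausible length.

    Works in coding-strand coordinates; on the minus strand the contig is
    reverse-complemented and the interval mirrored.  If no consistent
    (acceptor, donor) pair exists the call is retained as partial with the
    corresponding flags set false.
    """
    lengths = (
        (expected_length,) if isinstance(expected_length, int) else tuple(expected_length)
    )
    clen = len(contig)
    if hit.strand == "+":
        work, (raw_s, raw_e) = contig, hit.interval
    else:
        work = revcomp(contig)
        raw_s, raw_e = clen - hit.interval[1], clen - hit.interval[0]

    # project the full exon extent from the aligned query span: seeds are
    # complete exons, so unaligned query overhang estimates how far the
    # local alignment trimmed each diverged end
    qs, qe = hit.query_span
    if hit.query_len:
        est_s = raw_s - qs
        est_e = raw_e + (hit.query_len - qe)
    else:
        est_s, est_e = raw_s, raw_e

    acceptors = {
        s: 0
        for s in range(max(2, est_s - window), min(clen, est_s + window) + 1)
        if work[s - 2 : s] == "AG"
    }
    donors = {
        e: 0
        for e in range(max(0, est_e - window), min(clen - 2, est_e + window) + 1)
        if work[e : e + 2] == "GT"
    }
    # homology-projected ends are admissible even without a canonical
    # dinucleotide (mutated splice sites are part of the biology), at a
    # mild penalty so a nearby canonical site only wins when it agrees
    # with the expected length and the homology signal
    NONCANONICAL = 3
    s_cands = dict(acceptors)
    s_cands.setdefault(max(est_s, 0), NONCANONICAL)
    e_cands = dict(donors)
    e_cands.setdefault(min(est_e, clen), NONCANONICAL)
    for s in list(s_cands):
        for L in lengths:
            if s + L <= clen:
                e_cands.setdefault(s + L, NONCANONICAL)

    best = None
    for s, pen_s in s_cands.items():
        for e, pen_e in e_cands.items():
            if e <= s:
                continue
            ldiff = min(abs((e - s) - L) for L in lengths)
            if ldiff > tolerance:
                continue
            dist = abs(s - est_s) + abs(e - est_e)
            badness = 2 * ldiff + dist + pen_s + pen_e
            key = (badness, dist, pen_s + pen_e, s)
            if best is None or key < best[0]:
                best = (key, s, e)

    if best is not None:
        s, e = best[1], best[2]
    else:
        s, e = max(est_s, 0), min(max(est_e, est_s + 1), clen)

    seq = work[s:e]
    acceptor_ok = s >= 2 and work[s - 2 : s] == "AG"
    donor_ok = e + 2 <= clen and work[e : e + 2] == "GT"
    length_ok = min(abs((e - s) - L) for L in lengths) <= tolerance
    if hit.strand == "+":
        refined = (s, e)
    else:
        refined = (clen - e, clen - s)
    return ExonCall(
        hit=hit,
        refined_interval=refined,
        domain_type=domain_type or hit.query_id.split("__")[0],
        acceptor_ok=acceptor_ok,
        donor_ok=donor_ok,
        length_ok=length_ok,
        sequence=seq,
        contains_n="N" in seq,
    )


# ---------------------------------------------------------------------------
# iterative mining

def _call_key(call: ExonCall) -> tuple:
    return (call.contig_id, call.refined_interval, call.strand)


def iterative_mine(
    contigs,
    seed_queries: dict[str, str],
    expected_lengths: dict[str, int | tuple[int, ...]],
    params: MiningParams | None = None,
    max_rounds: int = 6,
) -> list[ExonCall]:
    """Mine exons, feeding each round's calls back as queries.

    ``seed_queries`` names carry the domain label before a double
    underscore (``N__ceacam1``); calls inherit the label of the query that
    found them.  Terminates at a fixed point (a round adds no call) or
    after ``max_rounds``.  Cytoplasmic exons are additionally sought in
    windows downstream of each TM call.
    """
    if max_rounds < 1:
        raise ValueError("max_rounds must be >= 1")
    params = params or MiningParams()
    contig_seqs = _as_contig_dict(contigs)
    if not contig_seqs:
        return []
    indexes: dict[str, ContigIndex] = {}

    calls: dict[tuple, ExonCall] = {}
    called_regions: dict[str, list[tuple[int, int]]] = {}
    queries = dict(seed_queries)
    new_queries = dict(queries)
    seen_query_seqs = {s.upper() for s in queries.values()}

    for _ in range(max_rounds):
        hits = seeded_local_search(
            contig_seqs, new_queries, params, indexes=indexes, exclude=called_regions
        )
        fresh: list[ExonCall] = []
        for hit in hits:
            dom = hit.query_id.split("__")[0]
            expected = expected_lengths.get(dom, hit.interval[1] - hit.interval[0])
            call = refine_exon_boundaries(
                hit,
                contig_seqs[hit.contig_id],
                expected,
                domain_type=dom,
                tolerance=params.length_tolerance,
                window=params.splice_window,
            )
            key = _call_key(call)
            if key in calls:
                continue
            if any(
                c.contig_id == call.contig_id
                and _overlap_frac(c.refined_interval, call.refined_interval) > LOCUS_OVERLAP
                for c in calls.values()
            ):
                continue
            calls[key] = call
            fresh.append(call)
            called_regions.setdefault(call.contig_id, []).append(call.refined_interval)

        fresh.extend(
            _downstream_cyt_search(
                contig_seqs, calls, called_regions, seed_queries, expected_lengths, params
            )
        )
        if not fresh:
            break
        new_queries = {}
        for i, call in enumerate(fresh):
            if call.sequence and call.sequence.upper() not in seen_query_seqs:
                name = f"{call.domain_type}__r{len(queries) + i}"
                new_queries[name] = call.sequence
                seen_query_seqs.add(call.sequence.upper())
        queries.update(new_queries)
        if not new_queries:
            break

    out = list(calls.values())
    out.sort(key=lambda c: (c.contig_id, c.refined_interval, c.strand))
    return out


def _downstream_cyt_search(
    contig_seqs, calls, called_regions, seed_queries, expected_lengths, params
):
    """Look for short cytoplasmic exons just downstream of TM exon calls."""
    cyt_queries = {
        name: seq for name, seq in seed_queries.items() if name.split("__")[0] == "Cyt"
    }
    if not cyt_queries:
        return []
    fresh: list[ExonCall] = []
    tm_calls = [c for c in calls.values() if c.domain_type == "TM"]
    for tm in tm_calls:
        contig = contig_seqs[tm.contig_id]
        s, e = tm.refined_interval
        if tm.strand == "+":
            lo, hi = e, min(len(contig), e + DOWNSTREAM_WINDOW)
        else:
            lo, hi = max(0, s - DOWNSTREAM_WINDOW), s
        if hi - lo < 30:
            continue
        sub = contig[lo:hi]
        hits = seeded_local_search({tm.contig_id: sub}, cyt_queries, params)
        for hit in hits:
            shifted = ExonHit(
                query_id=hit.query_id,
                contig_id=hit.contig_id,
                interval=(hit.interval[0] + lo, hit.interval[1] + lo),
                strand=hit.strand,
                score=hit.score,
                evalue=hit.evalue,
                query_cover=hit.query_cover,
                identity=hit.identity,
            )
            call = refine_exon_boundaries(
                shifted,
                contig,
                expected_lengths.get("Cyt", 90),
                domain_type="Cyt",
                tolerance=params.length_tolerance,
                window=params.splice_window,
            )
            key = _call_key(call)
            if key in calls:
                continue
            if any(
                c.contig_id == call.contig_id
                and _overlap_frac(c.refined_interval, call.refined_interval) > LOCUS_OVERLAP
                for c in calls.values()
            ):
                continue
            calls[key] = call
            called_regions.setdefault(call.contig_id, []).append(call.refined_interval)
            fresh.append(call)
    return fresh


def iterative_mine_multi(
    species_contigs: dict[str, dict[str, str]],
    seed_queries: dict[str, str],
    expected_lengths: dict[str, int | tuple[int, ...]],
    params: MiningParams | None = None,
    max_rounds: int = 6,
) -> dict[str, list[ExonCall]]:
    """Run iterative mining independently per species' contig set."""
    return {
        species: iterative_mine(contigs, seed_queries, expected_lengths, params, max_rounds)
        for species, contigs in species_contigs.items()
    }
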