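"""Alignment, neighbor-joining trees with bootstrap, and subgroup assignment.

Distance-based neighbor-joining (with nonparametric bootstrap support)
stands in for likelihood tree search: every downstream decision in this
package depends on clustering structure, not on likelihoods, and NJ is
exact on additive distances.  Family members are assigned to the CEACAM /
PSG I / PSG II subgroups by smallest patristic distance to user-supplied
anchor leaves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .codons import translate
from .mine import GAP_EXTEND, GAP_OPEN, MATCH, MISMATCH

log = logging.getLogger("famscan.phylo")


class ConfigurationError(ValueError):
    pass


@dataclass
class Alignment:
    names: list[str]
    rows: list[str]
    is_codon_aligned: bool = False
    flagged: list[str] = field(default_factory=list)  # rows with internal stops

    def __post_init__(self):
        if len(self.names) != len(self.rows):
            raise ValueError("names and rows differ in length")
        if self.rows and len({len(r) for r in self.rows}) != 1:
            raise ValueError("alignment rows differ in length")
        if self.is_codon_aligned and self.rows and len(self.rows[0]) % 3:
            raise ValueError("codon alignment length not divisible by 3")

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def as_dict(self) -> dict[str, str]:
        return dict(zip(self.names, self.rows))


# ---------------------------------------------------------------------------
# pairwise and progressive alignment

def _pairwise_aligner(mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    if mode == "aa":
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -11
        aligner.extend_gap_score = -1
    else:
        aligner.match_score = MATCH
        aligner.mismatch_score = MISMATCH
        aligner.open_gap_score = GAP_OPEN + GAP_EXTEND
        aligner.extend_gap_score = GAP_EXTEND
    try:
        aligner.open_end_gap_score = aligner.open_gap_score
        aligner.extend_end_gap_score = aligner.extend_gap_score
    except AttributeError:  # older Biopython naming
        aligner.end_open_gap_score = aligner.open_gap_score
        aligner.end_extend_gap_score = aligner.extend_gap_score
    return aligner


def pairwise_align(a: str, b: str, mode: str = "nt") -> tuple[str, str, float]:
    """Optimal global (Needleman-Wunsch) alignment of two sequences."""
    aligner = _pairwise_aligner(mode)
    best = aligner.align(a, b)[0]
    rows = str(best).splitlines()
    # Alignment.__getitem__ gives gapped rows directly
    return best[0], best[1], float(best.score)


_AA_ORDER = "ARNDCQEGHILKMFPSTWYVBZX*"


def _profile_matrices(mode: str):
    if mode == "aa":
        sub = substitution_matrices.load("BLOSUM62")
        alphabet = sub.alphabet
        S = np.array(sub)
        open_s, ext_s = -11.0, -1.0
    else:
        alphabet = "ACGTN"
        S = np.full((5, 5), float(MISMATCH))
        for i in range(4):
            S[i, i] = MATCH
        open_s, ext_s = float(GAP_OPEN + GAP_EXTEND), float(GAP_EXTEND)
    return alphabet, S, open_s, ext_s


def _to_profile(rows: list[str], alphabet: str) -> np.ndarray:
    idx = {c: i for i, c in enumerate(alphabet)}
    L = len(rows[0])
    prof = np.zeros((L, len(alphabet)))
    for row in rows:
        for j, c in enumerate(row):
            if c != "-":
                prof[j, idx.get(c, idx.get("X", 0))] += 1
    total = prof.sum(axis=1, keepdims=True)
    total[total == 0] = 1
    return prof / total


def _profile_align(rows_a: list[str], rows_b: list[str], mode: str) -> tuple[list[str], list[str]]:
    """Gotoh affine profile-profile alignment; returns gapped row groups."""
    alphabet, S, open_s, ext_s = _profile_matrices(mode)
    A = _to_profile(rows_a, alphabet)
    B = _to_profile(rows_b, alphabet)
    m, n = len(A), len(B)
    col_score = A @ S @ B.T  # expected substitution score between columns

    NEG = -1e18
    M = np.full((m + 1, n + 1), NEG)
    X = np.full((m + 1, n + 1), NEG)  # gap in B (A column unmatched)
    Y = np.full((m + 1, n + 1), NEG)  # gap in A
    M[0, 0] = 0.0
    for i in range(1, m + 1):
        X[i, 0] = open_s + (i - 1) * ext_s
    for j in range(1, n + 1):
        Y[0, j] = open_s + (j - 1) * ext_s
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            best_prev = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            M[i, j] = best_prev + col_score[i - 1, j - 1]
            X[i, j] = max(M[i - 1, j] + open_s, X[i - 1, j] + ext_s)
            Y[i, j] = max(M[i, j - 1] + open_s, Y[i, j - 1] + ext_s)
    # traceback
    i, j = m, n
    state = int(np.argmax([M[i, j], X[i, j], Y[i, j]]))
    ops: list[str] = []
    while i > 0 or j > 0:
        if i > 0 and j > 0 and state == 0:
            prev = [M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]]
            state = int(np.argmax(prev))
            ops.append("M")
            i, j = i - 1, j - 1
        elif i > 0 and (state == 1 or j == 0):
            if X[i, j] == M[i - 1, j] + open_s:
                state = 0
            ops.append("X")
            i -= 1
        else:
            if Y[i, j] == M[i, j - 1] + open_s:
                state = 0
            ops.append("Y")
            j -= 1
    ops.reverse()
    out_a = ["" for _ in rows_a]
    out_b = ["" for _ in rows_b]
    ia = ib = 0
    for op in ops:
        if op == "M":
            for k, r in enumerate(rows_a):
                out_a[k] += r[ia]
            for k, r in enumerate(rows_b):
                out_b[k] += r[ib]
            ia += 1
            ib += 1
        elif op == "X":
            for k, r in enumerate(rows_a):
                out_a[k] += r[ia]
            for k in range(len(rows_b)):
                out_b[k] += "-"
            ia += 1
        else:
            for k in range(len(rows_a)):
                out_a[k] += "-"
            for k, r in enumerate(rows_b):
                out_b[k] += r[ib]
            ib += 1
    return out_a, out_b


def _kmer_distance_matrix(seqs: list[str], k: int) -> np.ndarray:
    sets = [
        {s[i : i + k] for i in range(max(1, len(s) - k + 1))} if s else set()
        for s in seqs
    ]
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            union = sets[i] | sets[j]
            shared = len(sets[i] & sets[j]) / len(union) if union else 1.0
            d[i, j] = d[j, i] = 1.0 - shared
    return d


def progressive_align(seqs: dict[str, str], mode: str = "nt") -> Alignment:
    """Progressive multiple alignment (k-mer guide tree, affine profiles).

    Modes: ``nt`` (nucleotide), ``aa`` (amino acid, BLOSUM62), ``codon``
    (align translations, then thread the nucleotide triplets back through
    the gapped protein alignment so no codon is ever split).
    """
    names = list(seqs)
    raw = [seqs[n].upper() for n in names]
    if len(names) == 0:
        return Alignment([], [], is_codon_aligned=(mode == "codon"))

    flagged: list[str] = []
    if mode == "codon":
        trimmed = [s[: len(s) - len(s) % 3] for s in raw]
        prots = [translate(s) for s in trimmed]
        flagged = [n for n, p in zip(names, prots) if "*" in p[:-1]]
        aa_aln = _progressive(names, prots, "aa")
        rows = [
            _thread_codons(nt, gapped) for nt, gapped in zip(trimmed, aa_aln)
        ]
        return Alignment(names, rows, is_codon_aligned=True, flagged=flagged)

    rows = _progressive(names, raw, mode)
    return Alignment(names, rows, is_codon_aligned=False)


def _progressive(names: list[str], seqs: list[str], mode: str) -> list[str]:
    if len(seqs) == 1:
        return list(seqs)
    if len(seqs) == 2:
        a, b = pairwise_align(seqs[0], seqs[1], mode)[:2]
        return [a, b]
    k = 3 if mode == "aa" else 6
    d = _kmer_distance_matrix(seqs, k)
    # UPGMA-style merge order over the k-mer distances as guide
    clusters: dict[int, list[int]] = {i: [i] for i in range(len(seqs))}
    rows: dict[int, list[str]] = {i: [seqs[i]] for i in range(len(seqs))}
    members = dict(clusters)
    dist = {
        (i, j): d[i, j]
        for i in range(len(seqs))
        for j in range(i + 1, len(seqs))
    }
    next_id = len(seqs)
    order: dict[int, list[int]] = {i: [i] for i in range(len(seqs))}
    while len(rows) > 1:
        (i, j), _ = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        merged_a, merged_b = _profile_align(rows[i], rows[j], mode)
        rows[next_id] = merged_a + merged_b
        order[next_id] = order[i] + order[j]
        members[next_id] = members[i] + members[j]
        for key in [k_ for k_ in dist if i in k_ or j in k_]:
            del dist[key]
        del rows[i], rows[j]
        for other in list(rows):
            if other == next_id:
                continue
            pairs = [
                d[a, b] for a in members[next_id] for b in members[other]
            ]
            key = (min(other, next_id), max(other, next_id))
            dist[key] = float(np.mean(pairs))
        next_id += 1
    (final_id,) = rows
    out_rows = rows[final_id]
    # restore input order
    result = [""] * len(seqs)
    for pos, orig in enumerate(order[final_id]):
        result[orig] = out_rows[pos]
    return result


def _thread_codons(nt: str, gapped_aa: str) -> str:
    out = []
    i = 0
    for c in gapped_aa:
        if c == "-":
            out.append("---")
        else:
            out.append(nt[i : i + 3])
            i += 3
    return "".join(out)


# ---------------------------------------------------------------------------
# distances

def p_distance(aln: Alignment, mode: str = "nt") -> DistanceMatrix:
    """Proportion of differing sites, pairwise deletion of gap columns."""
    n = len(aln.names)
    arr = np.array(
        [np.frombuffer(r.encode(), dtype="S1") for r in aln.rows]
    )
    non_gap = arr != b"-"
    d = np.zeros((n, n))
    for i in range(n):
        valid = non_gap & non_gap[i]
        diffs = ((arr != arr[i]) & valid).sum(axis=1)
        total = valid.sum(axis=1)
        with np.errstate(invalid="ignore"):
            row = np.where(total > 0, diffs / np.maximum(total, 1), 0.0)
        d[i, :] = row
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, ids=aln.names)


def jc_distance(aln: Alignment) -> DistanceMatrix:
    """Jukes-Cantor corrected nucleotide distance; saturated pairs are
    clamped just below the correction singularity."""
    p = p_distance(aln)
    data = np.array(p.data)
    capped = np.minimum(data, 0.749)
    with np.errstate(divide="ignore"):
        jc = -0.75 * np.log(1 - (4.0 / 3.0) * capped)
    np.fill_diagonal(jc, 0.0)
    return DistanceMatrix(jc, ids=p.ids)


# ---------------------------------------------------------------------------
# neighbor joining and bootstrap

def nj_tree(dm: DistanceMatrix | np.ndarray, ids: list[str] | None = None) -> TreeNode:
    """Neighbor-joining tree; negative branch estimates are clamped to 0."""
    data = np.asarray(dm.data if isinstance(dm, DistanceMatrix) else dm, dtype=float)
    if np.isnan(data).any():
        raise ValueError("distance matrix contains NaN")
    if (data < 0).any():
        raise ValueError("distance matrix contains negative distances")
    if data.shape[0] < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if not isinstance(dm, DistanceMatrix):
        try:
            dm = DistanceMatrix(data, ids=ids)
        except Exception as exc:
            raise ValueError(f"invalid distance matrix: {exc}") from exc
    tree = nj(dm)
    clamped = 0
    for node in tree.traverse(include_self=False):
        if node.length is not None and node.length < 0:
            node.length = 0.0
            clamped += 1
    if clamped:
        log.warning("clamped %d negative NJ branch lengths to 0", clamped)
    return tree


def _bipartitions(tree: TreeNode, taxa: frozenset[str]) -> set[frozenset[str]]:
    ref = min(taxa)
    parts: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if not (1 < len(side) < len(taxa) - 1):
            continue
        if ref in side:
            side = taxa - side
        parts.add(side)
    return parts


def bootstrap_support(
    aln: Alignment,
    n_replicates: int = 500,
    seed: int | np.random.Generator = 0,
    distance: str = "jc",
) -> TreeNode:
    """NJ tree with bootstrap supports from column resampling.

    Codon alignments are resampled in whole-codon blocks.  Supports are
    proportions in [0,1], stored on internal nodes as ``support`` and as
    the node name (the Newick internal-label dialect).
    """
    if n_replicates < 1:
        raise ConfigurationError("n_replicates must be >= 1")
    if len(aln.names) < 4:
        raise ConfigurationError("bootstrap needs an alignment of >= 4 taxa")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    dist_fn = jc_distance if distance == "jc" else p_distance

    base = nj_tree(dist_fn(aln))
    taxa = frozenset(aln.names)
    counts: dict[frozenset[str], int] = {}
    block = 3 if aln.is_codon_aligned else 1
    n_cols = aln.length // block
    arr = np.array([list(r) for r in aln.rows])
    for _ in range(n_replicates):
        cols = rng.integers(0, n_cols, size=n_cols)
        if block == 3:
            take = np.concatenate([np.arange(c * 3, c * 3 + 3) for c in cols])
        else:
            take = cols
        rows = ["".join(r) for r in arr[:, take]]
        rep_aln = Alignment(list(aln.names), rows, aln.is_codon_aligned)
        try:
            rep_tree = nj_tree(dist_fn(rep_aln))
        except ValueError:
            continue
        for part in _bipartitions(rep_tree, taxa):
            counts[part] = counts.get(part, 0) + 1

    ref = min(taxa)
    for node in base.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if not (1 < len(side) < len(taxa) - 1):
            continue
        if ref in side:
            side = taxa - side
        support = counts.get(side, 0) / n_replicates
        node.support = support
        node.name = f"{support:.3f}"
    return base


def rf_distance(a: TreeNode, b: TreeNode) -> int:
    """Robinson-Foulds symmetric difference between two trees."""
    taxa = frozenset(t.name for t in a.tips())
    pa, pb = _bipartitions(a, taxa), _bipartitions(b, taxa)
    return len(pa ^ pb)


# ---------------------------------------------------------------------------
# subgroup assignment

def assign_subgroups(
    tree: TreeNode, anchors: dict[str, str]
) -> tuple[dict[str, str], dict[str, bool]]:
    """Label every leaf by its nearest anchor (patristic distance).

    ``anchors`` maps subgroup label -> anchor leaf name.  Returns
    (labels per leaf, monophyly flag per label).  Labels are invariant to
    re-rooting because patristic distances are.
    """
    tips = {t.name for t in tree.tips()}
    for label, leaf in anchors.items():
        if leaf not in tips:
            raise ConfigurationError(f"anchor leaf {leaf!r} ({label}) not in tree")
    dm = tree.tip_tip_distances()
    labels: dict[str, str] = {}
    for tip in sorted(tips):
        best = min(
            sorted(anchors.items()),
            key=lambda kv: (dm[tip, kv[1]], kv[0]),
        )
        labels[tip] = best[0]
    taxa = frozenset(tips)
    parts = _bipartitions(tree, taxa)
    monophyly: dict[str, bool] = {}
    for label in anchors:
        group = frozenset(t for t, lab in labels.items() if lab == label)
        if len(group) <= 1 or len(group) >= len(taxa) - 1:
            monophyly[label] = True
        else:
            norm = taxa - group if min(taxa) in group else group
            monophyly[label] = norm in parts
    return labels, monophyly


# ---------------------------------------------------------------------------
# synthetic trees (testing and benchmarking aid)

def random_tree(
    n_taxa: int,
    rng: np.random.Generator | int = 0,
    min_branch: float = 0.05,
    max_branch: float = 0.3,
) -> TreeNode:
    """Random binary tree with uniform branch lengths on [min, max]."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    nodes = [TreeNode(name=f"t{i}") for i in range(n_taxa)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        for child in (a, b):
            child.length = float(rng.uniform(min_branch, max_branch))
        parent = TreeNode(children=[a, b])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = nodes[0]
    root.length = None
    return root


def patristic_matrix(tree: TreeNode) -> DistanceMatrix:
    return tree.tip_tip_distances()
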