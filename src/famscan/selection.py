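"""Counting-based molecular-evolution analysis of codon alignments.

The core is the Nei-Gojobori (1986) counting scheme: every codon position
contributes fractional synonymous/nonsynonymous *site* counts (renormalized
over non-stop single-base changes so each codon always contributes exactly
3 sites), and every codon pair contributes substitution counts averaged
over all minimal mutational pathways that avoid stop codons.

Three analyses build on it:

* ``pairwise_dnds`` — per-pair dN/dS with the Jukes-Cantor multiple-hit
  correction applied to the proportions pS, pN;
* ``slac_analyze`` — a tree-aware counting analysis: ancestral codons are
  reconstructed per site by Fitch parsimony (deterministic lexical
  tie-break), substitutions are counted on every branch, and each site is
  classified positive/neutral/negative by a two-tailed binomial test of
  the nonsynonymous fraction against its neutral expectation;
* ``cumulative_profile`` — cumulative average synonymous/nonsynonymous
  substitution curves along the coding region (plus an indel curve), the
  classic way to localize diversifying regions.

Ancestral reconstruction by parsimony (rather than likelihood) is this
package's deliberate, deterministic substitute for likelihood-based
ancestor counting; random-effects likelihood models are out of scope and
the per-site binomial test is labeled as their counting substitute.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.stats import binomtest
from skbio import TreeNode

from .codons import BASES, SENSE_CODONS, STOP_CODONS, codons_of, translate

log = logging.getLogger("famscan.selection")


class StopCodonError(ValueError):
    pass


# ---------------------------------------------------------------------------
# NG86 counting core

@lru_cache(maxsize=None)
def ng86_site_counts(codon: str) -> tuple[float, float]:
    """Fractional (synonymous, nonsynonymous) site counts of one codon.

    Per position the synonymous fraction is the number of synonymous
    single-base changes over the number of non-stop single-base changes;
    the three fractions sum with their complements to exactly 3 sites.
    """
    codon = codon.upper()
    if codon in STOP_CODONS:
        raise StopCodonError(f"stop codon {codon}")
    if codon not in SENSE_CODONS:
        raise ValueError(f"not a sense codon: {codon!r}")
    aa = translate(codon)
    s = 0.0
    for pos in range(3):
        syn = non_stop = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if alt in STOP_CODONS:
                continue
            non_stop += 1
            if translate(alt) == aa:
                syn += 1
        if non_stop:
            s += syn / non_stop
    return s, 3.0 - s


@lru_cache(maxsize=None)
def ng86_pair_counts(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(Sd, Nd) between two sense codons, averaged over all minimal
    mutational pathways that avoid stop codons.

    If every ordering of the differing positions passes through a stop,
    the average falls back to all orderings (degenerate but defined).
    """
    a, b = codon_a.upper(), codon_b.upper()
    for c in (a, b):
        if c in STOP_CODONS:
            raise StopCodonError(f"stop codon {c}")
        if c not in SENSE_CODONS:
            raise ValueError(f"not a sense codon: {c!r}")
    diffs = [i for i in range(3) if a[i] != b[i]]
    if not diffs:
        return 0.0, 0.0
    valid: list[tuple[float, float]] = []
    fallback: list[tuple[float, float]] = []
    for order in itertools.permutations(diffs):
        cur = a
        sd = nd = 0.0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS and nxt != b:
                blocked = True
            if translate_or_star(nxt) == translate_or_star(cur):
                sd += 1
            else:
                nd += 1
            cur = nxt
        (fallback if blocked else valid).append((sd, nd))
    paths = valid or fallback
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def translate_or_star(codon: str) -> str:
    return "*" if codon in STOP_CODONS else translate(codon)


# ---------------------------------------------------------------------------
# codon alignment container

@dataclass
class CodonAlignment:
    names: list[str]
    rows: list[str]           # gapped, in-frame, length divisible by 3

    def __post_init__(self):
        if len(self.names) != len(self.rows):
            raise ValueError("names and rows differ in length")
        if self.rows:
            lengths = {len(r) for r in self.rows}
            if len(lengths) != 1:
                raise ValueError("rows differ in length")
            if len(self.rows[0]) % 3:
                raise ValueError("row length not divisible by 3")

    @property
    def n_codons(self) -> int:
        return len(self.rows[0]) // 3 if self.rows else 0

    def codon_rows(self) -> list[list[str]]:
        return [codons_of(r) for r in self.rows]

    def drop_stop_rows(self) -> tuple["CodonAlignment", list[str]]:
        """Remove rows with internal stop codons (they are logged, not analyzed)."""
        keep_n, keep_r, dropped = [], [], []
        for name, row in zip(self.names, self.rows):
            codons = [c for c in codons_of(row) if "-" not in c]
            internal = [c for c in codons[:-1] if c in STOP_CODONS]
            if internal:
                dropped.append(name)
            else:
                keep_n.append(name)
                keep_r.append(row)
        if dropped:
            log.warning("excluding %d rows with internal stops: %s", len(dropped), dropped)
        return CodonAlignment(keep_n, keep_r), dropped


def _usable_columns(rows: list[list[str]], pair: tuple[int, int] | None = None) -> list[int]:
    """Codon columns free of gaps and stops (complete deletion by default,
    or pairwise over the given row pair)."""
    idx = range(len(rows[0]))
    members = rows if pair is None else [rows[pair[0]], rows[pair[1]]]
    cols = []
    for j in idx:
        ok = True
        for r in members:
            c = r[j]
            if "-" in c or c in STOP_CODONS or any(b not in BASES for b in c):
                ok = False
                break
        if ok:
            cols.append(j)
    return cols


# ---------------------------------------------------------------------------
# pairwise dN/dS

def _jc_correct(p: float) -> float:
    if p >= 0.75:
        return float("nan")
    if p == 0.0:
        return 0.0
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p)


def pairwise_dnds(
    aln: CodonAlignment, pairwise_deletion: bool = False
) -> pd.DataFrame:
    """Per-pair NG86 dN/dS table.

    Columns: Sd, Nd, S, N, pS, pN, dS, dN, dnds (Jukes-Cantor corrected,
    NaN when dS is 0 or a proportion saturates) and pnps (uncorrected
    counting ratio).  Swapping the two sequences of a pair leaves every
    value unchanged.
    """
    if len(aln.names) < 2:
        raise ValueError("need at least two sequences")
    rows = aln.codon_rows()
    out = []
    for i, j in itertools.combinations(range(len(rows)), 2):
        cols = _usable_columns(rows, (i, j) if pairwise_deletion else None)
        sd = nd = s_i = s_j = 0.0
        for c in cols:
            a, b = rows[i][c], rows[j][c]
            dsd, dnd = ng86_pair_counts(a, b)
            sd += dsd
            nd += dnd
            s_i += ng86_site_counts(a)[0]
            s_j += ng86_site_counts(b)[0]
        S = (s_i + s_j) / 2.0
        N = 3.0 * len(cols) - S
        pS = sd / S if S else 0.0
        pN = nd / N if N else 0.0
        dS, dN = _jc_correct(pS), _jc_correct(pN)
        if math.isnan(dS) or math.isnan(dN) or dS == 0.0:
            ratio = float("nan")
        else:
            ratio = dN / dS
        pnps = (nd / N) / (sd / S) if S and N and sd else float("nan")
        out.append(
            {
                "seq_a": aln.names[i],
                "seq_b": aln.names[j],
                "codons": len(cols),
                "Sd": sd,
                "Nd": nd,
                "S": S,
                "N": N,
                "pS": pS,
                "pN": pN,
                "dS": dS,
                "dN": dN,
                "dnds": ratio,
                "pnps": pnps,
            }
        )
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# SLAC-style tree-aware analysis

@dataclass
class SelectionResult:
    mean_dnds: float
    per_site: pd.DataFrame
    total_Sd: float
    total_Nd: float
    total_ES: float
    total_EN: float
    excluded_rows: list[str] = field(default_factory=list)
    branch_counts: pd.DataFrame | None = None
    method_note: str = (
        "per-site classification by binomial counting test "
        "(substitute for random-effects likelihood models)"
    )


def _fitch_states(tree: TreeNode, leaf_codons: dict[str, str]) -> dict[int, str]:
    """Fitch parsimony codon assignment for one site; lexical tie-break."""
    sets: dict[int, frozenset[str]] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            sets[id(node)] = frozenset([leaf_codons[node.name]])
        else:
            child_sets = [sets[id(c)] for c in node.children]
            inter = frozenset.intersection(*child_sets)
            sets[id(node)] = inter if inter else frozenset.union(*child_sets)
    states: dict[int, str] = {}
    for node in tree.preorder(include_self=True):
        options = sets[id(node)]
        if node.parent is None:
            states[id(node)] = min(options)
        else:
            parent_state = states[id(node.parent)]
            states[id(node)] = parent_state if parent_state in options else min(options)
    return states


def _benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    n = len(pvals)
    order = np.argsort(pvals)
    q = np.empty(n)
    prev = 1.0
    for rank_idx in range(n - 1, -1, -1):
        i = order[rank_idx]
        val = pvals[i] * n / (rank_idx + 1)
        prev = min(prev, val)
        q[i] = prev
    return q


def slac_analyze(
    aln: CodonAlignment,
    tree: TreeNode,
    alpha: float = 0.1,
) -> SelectionResult:
    """Tree-aware counting analysis of selection on a codon alignment.

    Ancestral codons come from per-site Fitch parsimony; substitutions are
    counted on every branch with pathway-averaged NG86 counts; expected
    site proportions come from the mean NG86 site counts of the observed
    codons.  ``mean_dnds`` is (sum Nd / sum EN) / (sum Sd / sum ES), NaN
    when no substitution (or no synonymous substitution) was inferred.
    """
    aln, dropped = aln.drop_stop_rows()
    if len(aln.names) < 2:
        raise ValueError("fewer than two usable rows after stop filtering")
    tips = {t.name for t in tree.tips()}
    if tips != set(aln.names):
        if set(aln.names) <= tips:
            tree = tree.shear(aln.names)
        else:
            raise ValueError("tree leaves do not cover alignment names")
    rows = aln.codon_rows()
    name_to_row = dict(zip(aln.names, rows))
    cols = _usable_columns(rows)

    n_sites = len(cols)
    site_Sd = np.zeros(n_sites)
    site_Nd = np.zeros(n_sites)
    site_ES = np.zeros(n_sites)
    site_EN = np.zeros(n_sites)
    branch_acc: dict[str, list[float]] = {}

    for k, j in enumerate(cols):
        leaf_codons = {name: name_to_row[name][j] for name in aln.names}
        es = np.mean([ng86_site_counts(c)[0] for c in leaf_codons.values()])
        site_ES[k] = es
        site_EN[k] = 3.0 - es
        states = _fitch_states(tree, leaf_codons)
        for node in tree.preorder(include_self=False):
            parent = states[id(node.parent)]
            child = states[id(node)]
            if parent == child:
                continue
            sd, nd = ng86_pair_counts(parent, child)
            site_Sd[k] += sd
            site_Nd[k] += nd
            bid = node.name if node.is_tip() and node.name else f"internal_{id(node) % 10_000}"
            acc = branch_acc.setdefault(bid, [0.0, 0.0])
            acc[0] += sd
            acc[1] += nd

    total_Sd, total_Nd = float(site_Sd.sum()), float(site_Nd.sum())
    total_ES, total_EN = float(site_ES.sum()), float(site_EN.sum())
    if total_Sd + total_Nd == 0 or total_Sd == 0 or total_ES == 0:
        mean = float("nan")
    else:
        mean = (total_Nd / total_EN) / (total_Sd / total_ES)

    records = []
    for k, j in enumerate(cols):
        subs = site_Sd[k] + site_Nd[k]
        p_exp = site_EN[k] / 3.0
        if subs >= 1:
            k_obs = int(round(site_Nd[k]))
            n_obs = max(int(round(subs)), k_obs, 1)
            pval = binomtest(k_obs, n_obs, p_exp).pvalue
            obs_frac = site_Nd[k] / subs
            if pval < alpha and obs_frac > p_exp:
                cls = "positive"
            elif pval < alpha and obs_frac < p_exp:
                cls = "negative"
            else:
                cls = "neutral"
        else:
            pval, cls = float("nan"), ""
        records.append(
            {
                "site": j,
                "ES": site_ES[k],
                "EN": site_EN[k],
                "Sd": site_Sd[k],
                "Nd": site_Nd[k],
                "dN_minus_dS": site_Nd[k] / site_EN[k] - site_Sd[k] / site_ES[k]
                if site_ES[k] and site_EN[k]
                else float("nan"),
                "p": pval,
                "class": cls,
            }
        )
    per_site = pd.DataFrame(
        records, columns=["site", "ES", "EN", "Sd", "Nd", "dN_minus_dS", "p", "class"]
    )
    tested = per_site["p"].notna()
    qvals = np.full(len(per_site), np.nan)
    if tested.any():
        qvals[tested.to_numpy()] = _benjamini_hochberg(
            per_site.loc[tested, "p"].to_numpy()
        )
    per_site["q"] = qvals

    branch_df = pd.DataFrame(
        [(b, sd, nd) for b, (sd, nd) in sorted(branch_acc.items())],
        columns=["branch", "Sd", "Nd"],
    )
    return SelectionResult(
        mean_dnds=mean,
        per_site=per_site,
        total_Sd=total_Sd,
        total_Nd=total_Nd,
        total_ES=total_ES,
        total_EN=total_EN,
        excluded_rows=dropped,
        branch_counts=branch_df,
    )


# ---------------------------------------------------------------------------
# cumulative substitution profile (SNAP-style)

def cumulative_profile(aln: CodonAlignment) -> pd.DataFrame:
    """Cumulative average synonymous/nonsynonymous substitutions along the
    coding region, averaged over all sequence pairs, plus an indel curve
    counting gap openings per codon position.

    The final cumulative values equal the alignment-wide mean pairwise Sd
    and Nd (pairwise deletion), so the curves integrate to the pairwise
    counting totals.
    """
    if len(aln.names) < 2:
        raise ValueError("need at least two sequences")
    rows = aln.codon_rows()
    n_codons = aln.n_codons
    pairs = list(itertools.combinations(range(len(rows)), 2))
    syn = np.zeros(n_codons)
    non = np.zeros(n_codons)
    for i, j in pairs:
        for c in range(n_codons):
            a, b = rows[i][c], rows[j][c]
            if "-" in a or "-" in b or a in STOP_CODONS or b in STOP_CODONS:
                continue
            if any(x not in BASES for x in a + b):
                continue
            sd, nd = ng86_pair_counts(a, b)
            syn[c] += sd
            non[c] += nd
    syn /= len(pairs)
    non /= len(pairs)

    indel = np.zeros(n_codons)
    for row in rows:
        in_gap = False
        for c in range(n_codons):
            gapped = "-" in row[c]
            if gapped and not in_gap:
                indel[c] += 1
            in_gap = gapped

    return pd.DataFrame(
        {
            "codon": np.arange(n_codons),
            "mean_Sd": syn,
            "mean_Nd": non,
            "cum_Sd": np.cumsum(syn),
            "cum_Nd": np.cumsum(non),
            "indel_openings": indel,
            "cum_indel": np.cumsum(indel),
        }
    )
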