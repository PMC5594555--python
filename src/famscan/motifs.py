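"""Tyrosine-based immunoreceptor motif detection and receptor classification.

Cytoplasmic tails of transmembrane CEA-family receptors signal through
short tyrosine-centered motifs: ITIMs (inhibitory), ITSMs (switch) and
ITAMs (activating).  The consensus patterns used here are the standard
immunology definitions; they are configuration, not constants, and can be
overridden per call:

    ITIM  [ILVS]-x-Y-x-x-[ILV]
    ITSM  T-x-Y-x-x-[VI]
    ITAM  Y-x-x-[LI]-x(6,12)-Y-x-x-[LI]

A receptor whose splice-donor site downstream of the transmembrane exon is
mutated cannot splice its signaling exons onto the mRNA and is classified
nonfunctional regardless of the motifs its genomic sequence still encodes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .codons import translate

DEFAULT_PATTERNS: dict[str, str] = {
    "ITIM": r"[ILVS].Y..[ILV]",
    "ITSM": r"T.Y..[VI]",
    "ITAM": r"Y..[LI].{6,12}Y..[LI]",
}

#: offset of the (first) motif tyrosine within each consensus match
_TYR_OFFSET = {"ITIM": 2, "ITSM": 2, "ITAM": 0}

_AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY*X")


@dataclass(frozen=True)
class MotifHit:
    kind: str                # ITIM / ITSM / ITAM
    tyrosine_position: int   # 0-based index of the motif tyrosine
    span: tuple[int, int]    # 0-based half-open aa interval
    matched_text: str


@dataclass
class ReceptorClass:
    tm_type: str                       # CEACAM1-like / CEACAM3-like / none
    motif_summary: list[MotifHit]
    signaling: str                     # inhibitory / inhibitory-ITSM / activating / nonfunctional / secreted
    tm_scores: dict[str, float] = field(default_factory=dict)
    tie_broken: bool = False


def detect_tyrosine_motifs(
    aa_seq: str, patterns: dict[str, str] | None = None
) -> list[MotifHit]:
    """Scan a translated cytoplasmic sequence for ITIM/ITSM/ITAM motifs.

    Overlapping occurrences are reported (lookahead scan), with two
    specificity rules: a tyrosine engaged by an ITAM half-site is not
    separately reported as ITIM/ITSM (the bipartite motif wins), and when
    an ITIM and an ITSM share the same tyrosine the hit is reported as
    ITSM only, because the switch motif consensus is the more specific.
    """
    if any(c not in _AA_ALPHABET for c in aa_seq):
        bad = sorted({c for c in aa_seq if c not in _AA_ALPHABET})
        raise ValueError(f"non-amino-acid characters in sequence: {bad}")
    patterns = patterns or DEFAULT_PATTERNS
    hits: list[MotifHit] = []
    for kind, pat in patterns.items():
        rx = re.compile(f"(?=({pat}))")
        for m in rx.finditer(aa_seq):
            text = m.group(1)
            start = m.start()
            hits.append(
                MotifHit(
                    kind=kind,
                    tyrosine_position=start + _TYR_OFFSET.get(kind, 0),
                    span=(start, start + len(text)),
                    matched_text=text,
                )
            )
    itam_tyrosines = _itam_engaged_tyrosines(aa_seq, hits)
    hits = [
        h
        for h in hits
        if not (h.kind in ("ITIM", "ITSM") and h.tyrosine_position in itam_tyrosines)
    ]
    itsm_tyrosines = {h.tyrosine_position for h in hits if h.kind == "ITSM"}
    hits = [
        h
        for h in hits
        if not (h.kind == "ITIM" and h.tyrosine_position in itsm_tyrosines)
    ]
    hits.sort(key=lambda h: (h.span[0], h.kind))
    return hits


_HALF_SITE = re.compile(r"(?=(Y..[LI]))")


def _itam_engaged_tyrosines(aa_seq: str, hits: list[MotifHit]) -> set[int]:
    """Tyrosines of every Y-x-x-[LI] half-site participating in any ITAM
    occurrence (all admissible spacer lengths, not just the greedy match)."""
    engaged: set[int] = set()
    half_starts = [m.start() for m in _HALF_SITE.finditer(aa_seq)]
    itam_starts = {h.span[0] for h in hits if h.kind == "ITAM"}
    for i in itam_starts:
        for j in half_starts:
            if i + 4 + 6 <= j <= i + 4 + 12:
                engaged.add(i)
                engaged.add(j)
    return engaged


def check_splice_donor(model, contig: str | None) -> list[tuple[int, str]]:
    """Label each inter-exon junction of a gene model canonical or mutated.

    Junction ``i`` is the donor site immediately downstream of exon ``i``
    on the coding strand.  Returns ``[(junction_index, status)]`` with
    status in {"canonical", "mutated", "unknown"}.
    """
    exons = model.exons
    statuses: list[tuple[int, str]] = []
    for i in range(len(exons) - 1):
        if contig is None:
            statuses.append((i, "unknown"))
            continue
        exon = exons[i]
        start, end = exon.refined_interval
        if exon.strand == "+":
            dinuc = contig[end : end + 2]
        else:
            from .simulate import revcomp

            dinuc = revcomp(contig[start - 2 : start])
        statuses.append((i, "canonical" if dinuc == "GT" else "mutated"))
    return statuses


def _tm_identity_scores(tm_seq: str, tm_references: dict[str, str]) -> dict[str, float]:
    from .mine import alignment_score

    return {name: alignment_score(tm_seq, ref) for name, ref in tm_references.items()}


_TM_LABELS = {"CEACAM1_TM": "CEACAM1-like", "CEACAM3_TM": "CEACAM3-like"}


def classify_receptor_signaling(
    model,
    tm_references: dict[str, str] | None = None,
    contig: str | None = None,
    patterns: dict[str, str] | None = None,
) -> ReceptorClass:
    """Assign transmembrane type and signaling class to one gene model.

    Secreted models (no TM exon) are classified ``secreted`` with an empty
    motif summary.  Otherwise the cytoplasmic exons are translated and
    scanned for motifs; ITIM+ITSM beats ITIM beats ITAM when several motif
    kinds co-occur (inhibitory context dominates, as in CEACAM1-type
    receptors).  Any mutated donor junction downstream of the TM exon
    overrides the motif call with ``nonfunctional``.
    """
    exons = model.exons
    tm_idx = next((i for i, e in enumerate(exons) if e.domain_type == "TM"), None)
    if tm_idx is None:
        return ReceptorClass(tm_type="none", motif_summary=[], signaling="secreted")

    tm_type, scores, tie = "CEACAM1-like", {}, False
    if tm_references:
        scores = _tm_identity_scores(exons[tm_idx].sequence, tm_references)
        best = max(scores.values())
        winners = sorted(name for name, s in scores.items() if s == best)
        tie = len(winners) > 1
        tm_type = _TM_LABELS.get(winners[0], winners[0])

    cyt_aa = "".join(translate(e.sequence) for e in exons if e.domain_type == "Cyt")
    hits = detect_tyrosine_motifs(cyt_aa, patterns=patterns)
    kinds = {h.kind for h in hits}

    donor_statuses = check_splice_donor(model, contig)
    donor_broken = any(
        status == "mutated" for i, status in donor_statuses if i >= tm_idx
    )

    if donor_broken:
        signaling = "nonfunctional"
    elif "ITIM" in kinds and "ITSM" in kinds:
        signaling = "inhibitory-ITSM"
    elif "ITIM" in kinds:
        signaling = "inhibitory"
    elif "ITAM" in kinds:
        signaling = "activating"
    else:
        signaling = "nonfunctional"
    return ReceptorClass(
        tm_type=tm_type,
        motif_summary=hits,
        signaling=signaling,
        tm_scores=scores,
        tie_broken=tie,
    )
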