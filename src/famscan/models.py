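"""Gene-model assembly, architecture classification and the family census.

Exon calls on one contig are chained into gene models following the
canonical CEA-family exon grammar (leader < N < A1 < B < A2 < TM < Cyt):
a model is extended only while the domain rank increases and the genomic
gap stays below a configurable bound, and never accepts a second N exon —
each family gene carries exactly one IgV-like (N) domain exon.

Architectures: a model with a transmembrane exon is a membrane receptor
(``CEACAM-TM``); a secreted model is a PSG whose IgC-like exon carries an
in-frame stop either in the terminal codon region (two-domain PSG) or
deeper inside the exon (one-domain PSG).  An N exon with an internal stop
marks the gene as a pseudogene.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .codons import BASES, codons_of, is_stop, translate
from .mine import ExonCall, alignment_score

DOMAIN_RANK = {"leader": 0, "N": 1, "A1": 2, "B": 3, "A2": 4, "TM": 5, "Cyt": 6}
IGC_DOMAINS = {"A1", "B", "A2", "IgC"}
DEFAULT_MAX_GENE_GAP = 25_000
#: a first in-frame stop within this many codons of the IgC exon end makes
#: the model a two-domain PSG; an earlier stop truncates the IgC domain
PSG_TERMINAL_CODONS = 6


@dataclass
class GeneModel:
    gene_id: str
    contig_id: str
    exons: list[ExonCall]              # transcription order
    strand: str = "+"
    species: str = ""
    architecture: str = "orphan"       # PSG-1dom / PSG-2dom / CEACAM-TM / orphan
    igc_subtypes: list[str] = field(default_factory=list)
    orf_intact: bool = True
    stop_positions: dict[str, list[int]] = field(default_factory=dict)
    n_glyc_sites: int = 0
    signaling: str = ""                # filled in by the receptor classifier
    name: str = ""

    @property
    def domains(self) -> list[str]:
        return [e.domain_type for e in self.exons]

    @property
    def n_exon(self) -> ExonCall | None:
        return next((e for e in self.exons if e.domain_type == "N"), None)

    @property
    def coding_sequence(self) -> str:
        return "".join(e.sequence for e in self.exons)


def call_orf_status(exon) -> tuple[bool, list[int]]:
    """ORF flag and 0-based codon indices of in-frame stops in one exon.

    The reading frame is the exon's own phase-0 frame.  A stop at the
    exon's final codon does not break the ORF (it may be the genuine
    translation stop); any earlier stop does.
    """
    seq = exon.sequence if isinstance(exon, ExonCall) else str(exon)
    seq = seq.upper()
    if len(seq) < 3:
        raise ValueError("exon sequence shorter than one codon")
    if set(seq) - set(BASES) - {"N"}:
        raise ValueError("exon sequence has characters outside ACGTN")
    codons = codons_of(seq)
    stops = [i for i, c in enumerate(codons) if is_stop(c)]
    orf_intact = all(i >= len(codons) - 1 for i in stops)
    return orf_intact, stops


def _transcription_sorted(calls: list[ExonCall], strand: str) -> list[ExonCall]:
    ordered = sorted(calls, key=lambda c: c.refined_interval)
    return ordered if strand == "+" else ordered[::-1]


def assemble_gene_models(
    calls: list[ExonCall],
    max_gap: int = DEFAULT_MAX_GENE_GAP,
    species: str = "",
) -> list[GeneModel]:
    """Chain exon calls on each contig/strand into gene models.

    A new model opens whenever the next exon's domain rank does not
    increase (which also enforces the single-N rule), or the genomic gap
    to the previous exon exceeds ``max_gap``.  Exons that cannot extend
    any chain simply start their own (possibly orphan) model.
    """
    groups: dict[tuple[str, str], list[ExonCall]] = {}
    for call in calls:
        groups.setdefault((call.contig_id, call.strand), []).append(call)

    models: list[GeneModel] = []
    for (contig_id, strand) in sorted(groups):
        ordered = _transcription_sorted(groups[(contig_id, strand)], strand)
        current: list[ExonCall] = []
        for call in ordered:
            if current:
                prev = current[-1]
                gap = _genomic_gap(prev, call)
                rank_prev = DOMAIN_RANK.get(prev.domain_type, 99)
                rank_next = DOMAIN_RANK.get(call.domain_type, 99)
                if gap > max_gap or rank_next <= rank_prev:
                    models.append(_finalize(current, contig_id, strand, species, len(models)))
                    current = []
            current.append(call)
        if current:
            models.append(_finalize(current, contig_id, strand, species, len(models)))
    return models


def _genomic_gap(a: ExonCall, b: ExonCall) -> int:
    (a0, a1), (b0, b1) = a.refined_interval, b.refined_interval
    if b0 >= a1:
        return b0 - a1
    if a0 >= b1:
        return a0 - b1
    return 0


def _finalize(
    exons: list[ExonCall], contig_id: str, strand: str, species: str, idx: int
) -> GeneModel:
    model = GeneModel(
        gene_id=f"{contig_id}:{strand}:{idx:03d}",
        contig_id=contig_id,
        exons=list(exons),
        strand=strand,
        species=species,
    )
    stop_positions: dict[str, list[int]] = {}
    for e in exons:
        intact, stops = call_orf_status(e)
        if stops:
            stop_positions[e.domain_type] = stops
    model.stop_positions = stop_positions
    n = model.n_exon
    if n is not None:
        intact, _ = call_orf_status(n)
        model.orf_intact = intact
    else:
        model.orf_intact = not stop_positions
    n_aa = translate(n.sequence) if n is not None else ""
    model.n_glyc_sites = count_nglyc(n_aa)
    return model


def classify_architecture(
    model: GeneModel,
    igc_references: dict[str, str] | None = None,
    terminal_codons: int = PSG_TERMINAL_CODONS,
) -> GeneModel:
    """Assign the architecture class and (optionally) IgC subtype labels.

    Mutates and returns ``model``.  IgC exons are typed by the highest
    local-alignment score against the A1/B/A2 reference sequences; ties
    break lexically.
    """
    domains = set(model.domains)
    has_tm = "TM" in domains
    igc_exons = [e for e in model.exons if e.domain_type in IGC_DOMAINS]

    if igc_references:
        model.igc_subtypes = [
            _type_igc(e.sequence, igc_references) for e in igc_exons
        ]
    if has_tm:
        model.architecture = "CEACAM-TM"
        return model
    if not igc_exons:
        model.architecture = "orphan"
        return model
    last_igc = igc_exons[-1]
    _, stops = call_orf_status(last_igc)
    if not stops:
        model.architecture = "orphan"
        return model
    n_codons = len(last_igc.sequence) // 3
    first_stop = stops[0]
    if first_stop >= n_codons - terminal_codons:
        model.architecture = "PSG-2dom"
    else:
        model.architecture = "PSG-1dom"
    return model


def _type_igc(seq: str, references: dict[str, str]) -> str:
    scores = {name: alignment_score(seq, ref) for name, ref in references.items()}
    best = max(scores.values())
    return sorted(name for name, s in scores.items() if s == best)[0]


def count_nglyc(aa_seq: str) -> int:
    """Count N-glycosylation sequons N-X-[S/T] (X != P), non-overlapping
    from the left; the scanned region ends at the first stop character."""
    stop = aa_seq.find("*")
    if stop != -1:
        aa_seq = aa_seq[:stop]
    count = 0
    i = 0
    while i + 2 < len(aa_seq):
        if aa_seq[i] == "N" and aa_seq[i + 1] != "P" and aa_seq[i + 2] in "ST":
            count += 1
            i += 3
        else:
            i += 1
    return count


# ---------------------------------------------------------------------------
# census and nomenclature

def census(models_by_species: dict[str, list[GeneModel]]) -> pd.DataFrame:
    """Per-species family census (one row per species, species-sorted).

    ``n_exons_total``/``n_exons_orf`` count N-domain exons; architecture
    tallies count gene models; TM tallies require ``signaling`` to have
    been filled in by the receptor classifier.
    """
    rows = []
    for species in sorted(models_by_species):
        models = models_by_species[species]
        n_models = [m for m in models if m.n_exon is not None]
        rows.append(
            {
                "species": species,
                "n_exons_total": len(n_models),
                "n_exons_orf": sum(1 for m in n_models if m.orf_intact),
                "n_psg1dom": sum(1 for m in models if m.architecture == "PSG-1dom"),
                "n_psg2dom": sum(1 for m in models if m.architecture == "PSG-2dom"),
                "n_tm_itim": sum(
                    1
                    for m in models
                    if m.signaling in ("inhibitory", "inhibitory-ITSM")
                ),
                "n_tm_itam": sum(1 for m in models if m.signaling == "activating"),
            }
        )
    columns = [
        "species",
        "n_exons_total",
        "n_exons_orf",
        "n_psg1dom",
        "n_psg2dom",
        "n_tm_itim",
        "n_tm_itam",
    ]
    return pd.DataFrame(rows, columns=columns)


def name_genes(models: list[GeneModel], species_prefix: str) -> None:
    """Assign family-style names: <prefix>_PSGk for secreted models,
    CEACAM1-like_k / CEACAM3-like_k for inhibitory / activating receptors."""
    counters = {"PSG": 0, "CEACAM1-like": 0, "CEACAM3-like": 0, "CEACAM-like": 0}
    for m in models:
        if m.architecture.startswith("PSG"):
            counters["PSG"] += 1
            m.name = f"{species_prefix}_PSG{counters['PSG']}"
        elif m.architecture == "CEACAM-TM":
            base = "CEACAM3-like" if m.signaling == "activating" else "CEACAM1-like"
            counters[base] += 1
            m.name = f"{species_prefix}_{base}_{counters[base]}"
        else:
            counters["CEACAM-like"] += 1
            m.name = f"{species_prefix}_CEACAM-like_{counters['CEACAM-like']}"
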