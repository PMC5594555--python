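"""Synthetic multi-contig genomes with planted CEA-family genes.

The generator emulates the genomic structures this package is built to
recover: duplicated gene cassettes of leader / IgV-like (N) / IgC-like /
transmembrane / cytoplasmic exons separated by GT...AG introns, secreted
PSG architectures whose IgC exon carries an in-frame stop (exon-internal
for one-domain PSGs, exon-terminal for two-domain PSGs) followed by a
polyadenylation signal, pseudogenes with stops in the N exon, two
transmembrane reference types (CEACAM1-like inhibitory, CEACAM3-like
activating), cytoplasmic exons carrying ITIM/ITSM or ITAM motifs, and
optionally mutated splice-donor sites that render a receptor
non-functional.  Every planted feature is recorded in a machine-readable
truth set so downstream stages can be scored without any external data.

Default proportions emulate the published census scale for a strongly
expanded vespertilionid family: on the order of a hundred genes, roughly
half of the N exons pseudogenized, ~90% of gene models secreted (PSG),
and a balanced split of inhibitory vs activating transmembrane receptors.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .codons import BASES, SENSE_CODONS, STOP_CODONS, translate
from .io import Feature, write_fasta, write_gff3

# canonical splice dinucleotides
DONOR = "GT"
ACCEPTOR = "AG"
POLYA_SIGNAL = "AATAAA"

DEFAULT_EXON_LENGTHS: dict[str, int] = {
    "leader": 102,
    "N": 321,
    "A1": 279,
    "B": 279,
    "A2": 279,
    "TM": 108,
    "Cyt": 90,       # inhibitory cytoplasmic exon (2 ITIM or ITIM+ITSM)
    "Cyt_ITAM": 150,  # activating cytoplasmic exon
}

PSG_LAYOUT = ("leader", "N", "A2")
CEACAM_LAYOUT = ("leader", "N", "A1", "B", "A2", "TM", "Cyt")

ARCHITECTURES = (
    "PSG-1dom",
    "PSG-2dom",
    "CEACAM-ITIM",
    "CEACAM-ITSM",
    "CEACAM-ITAM",
    "CEACAM-nonfunctional",
)

SUBGROUPS = ("CEACAM", "PSG-I", "PSG-II")


class ConfigurationError(ValueError):
    pass


@dataclass
class FamilySpec:
    """Parameters of one synthetic family; same seed gives identical bytes."""

    n_genes: int = 100
    psg_fraction: float = 0.9
    pseudogene_fraction: float = 0.5
    tm_activating_fraction: float = 0.5
    itsm_fraction: float = 0.25          # of inhibitory receptors, carry ITIM+ITSM
    donor_mutated_fraction: float = 0.3  # of TM-bearing genes, mutated donor after TM
    paralog_divergence: float = 0.10     # expected substitutions/site from the ancestor
    intron_length_range: tuple[int, int] = (200, 1200)
    contig_count: int = 8
    exon_lengths: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_EXON_LENGTHS))
    strand_randomize: bool = False
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "psg_fraction",
            "pseudogene_fraction",
            "tm_activating_fraction",
            "itsm_fraction",
            "donor_mutated_fraction",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name}={v} outside [0,1]")
        if not (0.0 <= self.paralog_divergence <= 0.5):
            raise ConfigurationError("paralog_divergence outside [0,0.5]")
        if self.n_genes < 0:
            raise ConfigurationError("n_genes must be >= 0")
        if self.contig_count < 1:
            raise ConfigurationError("contig_count must be >= 1")
        lo, hi = self.intron_length_range
        if lo < 10 or hi < lo:
            raise ConfigurationError("intron_length_range must satisfy 10 <= lo <= hi")
        for dom, length in self.exon_lengths.items():
            if length % 3 != 0 or length < 9:
                raise ConfigurationError(
                    f"exon length for {dom} must be a positive multiple of 3 (phase-0 junctions)"
                )


@dataclass
class PlantedExon:
    domain: str                 # leader/N/A1/B/A2/TM/Cyt
    start: int                  # 0-based half-open, contig coordinates
    end: int
    strand: str
    seq: str                    # coding-strand sequence
    stop_codons: list[int] = field(default_factory=list)  # planted in-frame stops


@dataclass
class PlantedGene:
    gene_id: str
    contig_id: str
    architecture_truth: str
    subgroup: str               # ancestry of the N exon: CEACAM / PSG-I / PSG-II
    is_pseudogene: bool
    exons: list[PlantedExon]
    donor_mutated_junctions: list[int] = field(default_factory=list)  # exon index whose donor is mutated
    strand: str = "+"

    @property
    def n_exon(self) -> PlantedExon:
        return next(e for e in self.exons if e.domain == "N")


@dataclass
class Ancestors:
    """Ancestral cassette sequences plus the derived reference sets."""

    exons: dict[str, str]                  # canonical exon sequences by role
    n_by_subgroup: dict[str, str]          # subgroup -> ancestral N exon
    seed_queries: dict[str, str]           # mining seeds, names '<domain>__<label>'
    anchors: dict[str, str]                # subgroup anchors for the N-domain tree
    igc_references: dict[str, str]         # A1/B/A2 typing references
    tm_references: dict[str, str]          # CEACAM1_TM / CEACAM3_TM
    motif_nt_ranges: dict[str, list[tuple[int, int]]]  # protected nt spans per cyt role


@dataclass
class Truth:
    spec: FamilySpec
    genes: list[PlantedGene]
    contigs: dict[str, str]
    ancestors: Ancestors

    def truth_table(self):
        """Planted ground truth as a pandas DataFrame."""
        import pandas as pd

        rows = []
        for g in self.genes:
            n = g.n_exon
            rows.append(
                {
                    "gene_id": g.gene_id,
                    "contig_id": g.contig_id,
                    "architecture": g.architecture_truth,
                    "subgroup": g.subgroup,
                    "is_pseudogene": g.is_pseudogene,
                    "strand": g.strand,
                    "n_exon_start": n.start,
                    "n_exon_end": n.end,
                    "donor_mutated_junctions": ",".join(map(str, g.donor_mutated_junctions)),
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# low-level sequence construction

_AA_CODONS: dict[str, list[str]] = collections.defaultdict(list)
for _c in SENSE_CODONS:
    _AA_CODONS[translate(_c)].append(_c)
_AMINO_ACIDS = sorted(_AA_CODONS)


def random_dna(rng: np.random.Generator, n: int, gc: float = 0.4) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list(BASES))[rng.choice(4, size=n, p=p)]) if n else ""


def _encode_protein(rng: np.random.Generator, aa: str) -> str:
    """Back-translate with per-residue random codon choice."""
    return "".join(_AA_CODONS[a][rng.integers(len(_AA_CODONS[a]))] for a in aa)


def _random_protein(rng: np.random.Generator, n: int) -> str:
    return "".join(_AMINO_ACIDS[i] for i in rng.integers(len(_AMINO_ACIDS), size=n))


def mutate_sequence(
    rng: np.random.Generator,
    seq: str,
    rate: float,
    protected: set[int] | None = None,
    keep_orf: bool = True,
) -> str:
    """Mutate i.i.d. per site at `rate`, uniform over the 3 alternative bases.

    Protected positions are left untouched.  With keep_orf, any codon that
    the mutations turned into a stop is reverted to its original codons so
    planted reading frames stay intact.
    """
    if rate <= 0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").astype("U1")
    hit = rng.random(len(arr)) < rate
    if protected:
        for i in protected:
            if i < len(arr):
                hit[i] = False
    idx = np.nonzero(hit)[0]
    for i in idx:
        alts = [b for b in BASES if b != arr[i]]
        arr[i] = alts[rng.integers(3)]
    out = list("".join(arr))
    if keep_orf:
        for c in range(0, len(out) - len(out) % 3, 3):
            if "".join(out[c : c + 3]) in STOP_CODONS:
                out[c : c + 3] = seq[c : c + 3]
    return "".join(out)


def _plant_stop(rng: np.random.Generator, seq: str, codon_index: int) -> str:
    stop = sorted(STOP_CODONS)[rng.integers(3)]
    return seq[: 3 * codon_index] + stop + seq[3 * codon_index + 3 :]


# ---------------------------------------------------------------------------
# ancestors

def _build_cyt_exon(rng: np.random.Generator, n_aa: int, planted: dict[int, str], want_kinds):
    """Random cytoplasmic exon with exact planted motif content.

    `planted` maps aa offset -> motif amino-acid text.  Random filler is
    re-drawn until the motif scan reports exactly the wanted kinds, so no
    spurious signaling motif survives in the ancestor.
    """
    from .motifs import detect_tyrosine_motifs

    fixed = {}
    for off, text in planted.items():
        for j, a in enumerate(text):
            fixed[off + j] = a
    for _ in range(200):
        aa = list(_random_protein(rng, n_aa))
        for pos, a in fixed.items():
            aa[pos] = a
        aa_s = "".join(aa)
        kinds = sorted(h.kind for h in detect_tyrosine_motifs(aa_s))
        if kinds == sorted(want_kinds):
            nt = _encode_protein(rng, aa_s)
            ranges = [(3 * off, 3 * (off + len(text))) for off, text in planted.items()]
            return nt, ranges
    raise RuntimeError("could not realize cytoplasmic motif layout")  # pragma: no cover


def build_ancestors(spec: FamilySpec, rng: np.random.Generator) -> Ancestors:
    L = spec.exon_lengths

    leader_aa = "M" + _random_protein(rng, L["leader"] // 3 - 1)
    leader = _encode_protein(rng, leader_aa)

    # N exon: one planted N-glycosylation sequon (N-x-T, x != P) at aa 20
    n_aa = list(_random_protein(rng, L["N"] // 3))
    n_aa[20:23] = ["N", "A", "T"]
    n_root = _encode_protein(rng, "".join(n_aa))
    glyc_protect = set(range(60, 69))
    n_ceacam = mutate_sequence(rng, n_root, 0.10, protected=glyc_protect)
    n_psg_root = mutate_sequence(rng, n_root, 0.10, protected=glyc_protect)
    n_psg1 = mutate_sequence(rng, n_psg_root, 0.12, protected=glyc_protect)
    n_psg2 = mutate_sequence(rng, n_psg_root, 0.12, protected=glyc_protect)

    # IgC subtypes diverge from one IgC ancestor so identity-typing is a
    # real discrimination task, not a string match
    igc_root = _encode_protein(rng, _random_protein(rng, L["A1"] // 3))
    a1 = mutate_sequence(rng, igc_root, 0.22)
    b = mutate_sequence(rng, igc_root, 0.22)
    a2 = mutate_sequence(rng, igc_root, 0.22)

    tm1 = _encode_protein(rng, _random_protein(rng, L["TM"] // 3))
    tm3 = mutate_sequence(rng, tm1, 0.35)

    cyt_itim, r_itim = _build_cyt_exon(
        rng, L["Cyt"] // 3, {4: "SAYTTL", 20: "VEYATV"}, ["ITIM", "ITIM"]
    )
    cyt_itsm, r_itsm = _build_cyt_exon(
        rng, L["Cyt"] // 3, {4: "SAYTTL", 20: "TEYASV"}, ["ITIM", "ITSM"]
    )
    cyt_itam, r_itam = _build_cyt_exon(
        rng, L["Cyt_ITAM"] // 3, {10: "YQPLGDESSPAYENL"}, ["ITAM"]
    )

    exons = {
        "leader": leader,
        "A1": a1,
        "B": b,
        "A2": a2,
        "TM1": tm1,
        "TM3": tm3,
        "Cyt_ITIM": cyt_itim,
        "Cyt_ITIM_ITSM": cyt_itsm,
        "Cyt_ITAM": cyt_itam,
    }
    n_by_subgroup = {"CEACAM": n_ceacam, "PSG-I": n_psg1, "PSG-II": n_psg2}
    seed_queries = {
        "leader__ref": leader,
        "N__ceacam1": n_ceacam,
        "A1__ceacam1": a1,
        "B__ceacam1": b,
        "A2__ceacam1": a2,
        "TM__ceacam1": tm1,
        "TM__ceacam3": tm3,
        "Cyt__itim": cyt_itim,
        "Cyt__itam": cyt_itam,
    }
    anchors = {
        "CEACAM_anchor": n_ceacam,
        "PSG1_anchor": n_psg1,
        "PSG2_anchor": n_psg2,
    }
    return Ancestors(
        exons=exons,
        n_by_subgroup=n_by_subgroup,
        seed_queries=seed_queries,
        anchors=anchors,
        igc_references={"A1": a1, "B": b, "A2": a2},
        tm_references={"CEACAM1_TM": tm1, "CEACAM3_TM": tm3},
        motif_nt_ranges={
            "Cyt_ITIM": r_itim,
            "Cyt_ITIM_ITSM": r_itsm,
            "Cyt_ITAM": r_itam,
        },
    )


# ---------------------------------------------------------------------------
# truth generation

def _draw_architecture(spec: FamilySpec, rng: np.random.Generator) -> tuple[str, str, str]:
    """Return (architecture, subgroup, cyt_role)."""
    if rng.random() < spec.psg_fraction:
        arch = "PSG-1dom" if rng.random() < 0.5 else "PSG-2dom"
        subgroup = "PSG-I" if rng.random() < 0.5 else "PSG-II"
        return arch, subgroup, ""
    activating = rng.random() < spec.tm_activating_fraction
    mutated = rng.random() < spec.donor_mutated_fraction
    if activating:
        arch, cyt = "CEACAM-ITAM", "Cyt_ITAM"
    else:
        if rng.random() < spec.itsm_fraction:
            arch, cyt = "CEACAM-ITSM", "Cyt_ITIM_ITSM"
        else:
            arch, cyt = "CEACAM-ITIM", "Cyt_ITIM"
    if mutated:
        arch = "CEACAM-nonfunctional"
    return arch, "CEACAM", cyt


def generate_truth(spec: FamilySpec) -> Truth:
    """Draw the planted gene set, lay genes out on contigs, build sequences."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    ancestors = build_ancestors(spec, rng)
    d = spec.paralog_divergence
    L = spec.exon_lengths

    genes: list[PlantedGene] = []
    per_contig: dict[str, list[PlantedGene]] = {
        f"contig{1 + i:03d}": [] for i in range(spec.contig_count)
    }
    contig_names = list(per_contig)

    for i in range(spec.n_genes):
        gene_id = f"g{i:04d}"
        arch, subgroup, cyt_role = _draw_architecture(spec, rng)
        is_pseudo = rng.random() < spec.pseudogene_fraction
        is_psg = arch.startswith("PSG")
        layout = PSG_LAYOUT if is_psg else CEACAM_LAYOUT

        exon_seqs: dict[str, str] = {}
        stop_map: dict[str, list[int]] = collections.defaultdict(list)
        for dom in layout:
            if dom == "N":
                anc = ancestors.n_by_subgroup[subgroup]
                protected = set(range(60, 69))
            elif dom == "TM":
                anc = ancestors.exons["TM3" if cyt_role == "Cyt_ITAM" else "TM1"]
                protected = set()
            elif dom == "Cyt":
                anc = ancestors.exons[cyt_role]
                protected = {
                    p
                    for lo, hi in ancestors.motif_nt_ranges[cyt_role]
                    for p in range(lo, hi)
                }
            else:
                anc = ancestors.exons[dom]
                protected = set()
            exon_seqs[dom] = mutate_sequence(rng, anc, d, protected=protected)

        # PSG stop: terminal region of the IgC exon for two-domain PSGs,
        # deep inside it for one-domain PSGs (far enough upstream that the
        # polyadenylation signal downstream of the exon stays within 200 nt
        # of the stop)
        n_igc_codons = L["A2"] // 3
        if arch == "PSG-2dom":
            pos = int(rng.integers(n_igc_codons - 5, n_igc_codons - 1))
            exon_seqs["A2"] = _plant_stop(rng, exon_seqs["A2"], pos)
            stop_map["A2"].append(pos)
        elif arch == "PSG-1dom":
            lo = max(10, n_igc_codons - 64)
            pos = int(rng.integers(lo, n_igc_codons - 25))
            exon_seqs["A2"] = _plant_stop(rng, exon_seqs["A2"], pos)
            stop_map["A2"].append(pos)

        if is_pseudo:
            pos = int(rng.integers(5, L["N"] // 3 - 5))
            exon_seqs["N"] = _plant_stop(rng, exon_seqs["N"], pos)
            stop_map["N"].append(pos)

        donor_mutated = [layout.index("TM")] if arch == "CEACAM-nonfunctional" else []
        strand = "-" if (spec.strand_randomize and rng.random() < 0.5) else "+"
        exons = [
            PlantedExon(dom, -1, -1, strand, exon_seqs[dom], stop_map.get(dom, []))
            for dom in layout
        ]
        gene = PlantedGene(
            gene_id=gene_id,
            contig_id=contig_names[i % spec.contig_count],
            architecture_truth=arch,
            subgroup=subgroup,
            is_pseudogene=is_pseudo,
            exons=exons,
            donor_mutated_junctions=donor_mutated,
            strand=strand,
        )
        genes.append(gene)
        per_contig[gene.contig_id].append(gene)

    contigs = {
        name: _render_contig(spec, rng, members) for name, members in per_contig.items()
    }
    return Truth(spec=spec, genes=genes, contigs=contigs, ancestors=ancestors)


def _render_gene_cassette(
    spec: FamilySpec, rng: np.random.Generator, gene: PlantedGene
) -> tuple[str, list[tuple[int, int]]]:
    """Plus-strand cassette string and per-exon intervals within it."""
    lo, hi = spec.intron_length_range
    parts: list[str] = []
    intervals: list[tuple[int, int]] = []
    pos = 0
    last = len(gene.exons) - 1
    for j, exon in enumerate(gene.exons):
        parts.append(exon.seq)
        intervals.append((pos, pos + len(exon.seq)))
        pos += len(exon.seq)
        donor = "AT" if j in gene.donor_mutated_junctions else DONOR
        if j < last:
            ilen = int(rng.integers(lo, hi + 1))
            intron = donor + random_dna(rng, ilen - 4) + ACCEPTOR
            parts.append(intron)
            pos += len(intron)
        else:
            tail = donor
            if gene.architecture_truth.startswith("PSG"):
                # polyadenylation signal in near proximity downstream of the stop
                tail += random_dna(rng, 4) + POLYA_SIGNAL
            parts.append(tail)
            pos += len(tail)
    return "".join(parts), intervals


_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _render_contig(
    spec: FamilySpec, rng: np.random.Generator, members: list[PlantedGene]
) -> str:
    parts: list[str] = []
    pos = 0
    for gene in members:
        spacer = random_dna(rng, int(rng.integers(400, 1200)) - 2) + ACCEPTOR
        cassette, intervals = _render_gene_cassette(spec, rng, gene)
        if gene.strand == "-":
            clen = len(cassette)
            # leader acceptor context lands downstream on the plus strand
            cassette = revcomp(cassette) + revcomp(ACCEPTOR)
            intervals = [(clen - e, clen - s) for s, e in intervals][::-1]
            exon_order = gene.exons[::-1]
        else:
            exon_order = gene.exons
        parts.append(spacer)
        pos += len(spacer)
        for exon, (s, e) in zip(exon_order, intervals):
            exon.start, exon.end = pos + s, pos + e
        parts.append(cassette)
        pos += len(cassette)
    parts.append(random_dna(rng, int(rng.integers(400, 1200))))
    return "".join(parts)


# ---------------------------------------------------------------------------
# emission

def emit_genome(truth: Truth, out_dir: str | Path) -> dict[str, Path]:
    """Write contig FASTA, truth GFF3/TSV, mining seeds and reference sets."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": out / "genome.fa",
        "truth_gff3": out / "truth.gff3",
        "truth_tsv": out / "truth.tsv",
        "seeds": out / "seeds.fa",
        "anchors": out / "anchors.fa",
        "igc_references": out / "igc_references.fa",
        "tm_references": out / "tm_references.fa",
    }
    write_fasta(truth.contigs, paths["genome"])

    features: list[Feature] = []
    for g in truth.genes:
        gstart = min(e.start for e in g.exons)
        gend = max(e.end for e in g.exons)
        features.append(
            Feature(
                g.contig_id,
                gstart,
                gend,
                "gene",
                g.strand,
                {
                    "ID": g.gene_id,
                    "architecture": g.architecture_truth,
                    "subgroup": g.subgroup,
                    "pseudogene": str(g.is_pseudogene).lower(),
                },
            )
        )
        for e in g.exons:
            features.append(
                Feature(
                    g.contig_id,
                    e.start,
                    e.end,
                    "exon",
                    g.strand,
                    {
                        "ID": f"{g.gene_id}.{e.domain}",
                        "Parent": g.gene_id,
                        "domain": e.domain,
                    },
                )
            )
    write_gff3(features, paths["truth_gff3"])
    truth.truth_table().to_csv(paths["truth_tsv"], sep="\t", index=False)
    write_fasta(truth.ancestors.seed_queries, paths["seeds"])
    write_fasta(truth.ancestors.anchors, paths["anchors"])
    write_fasta(truth.ancestors.igc_references, paths["igc_references"])
    write_fasta(truth.ancestors.tm_references, paths["tm_references"])
    return paths


def simulate(spec: FamilySpec, out_dir: str | Path) -> tuple[Truth, dict[str, Path]]:
    truth = generate_truth(spec)
    return truth, emit_genome(truth, out_dir)


# ---------------------------------------------------------------------------
# codon-level sequence evolution (for selection-analysis benchmarks)

def evolve_codon_sequences(
    tree,
    n_codons: int,
    omega: float,
    rng: np.random.Generator | int,
) -> dict[str, str]:
    """Evolve in-frame codon sequences down a phylogeny under a simple
    mutation-selection process.

    Each codon evolves as a continuous-time chain over sense codons: every
    single-base neighbor is reachable at relative rate 1 (synonymous) or
    ``omega`` (nonsynonymous); changes into stop codons are forbidden.
    Rates are normalized so that one unit of branch length corresponds to
    one expected substitution per codon (averaged over sense codons), so
    ``omega`` changes the synonymous/nonsynonymous mix but not the overall
    divergence. Returns {leaf name: sequence}.

    ``tree`` is an skbio TreeNode (or a Newick string).
    """
    from skbio import TreeNode

    if isinstance(tree, str):
        import io as _io

        tree = TreeNode.read(_io.StringIO(tree), format="newick")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))

    neighbors: dict[str, list[tuple[str, float]]] = {}
    for codon in SENSE_CODONS:
        nb = []
        for p in range(3):
            for b in BASES:
                if b == codon[p]:
                    continue
                alt = codon[:p] + b + codon[p + 1 :]
                if alt in STOP_CODONS:
                    continue
                rate = 1.0 if translate(alt) == translate(codon) else omega
                nb.append((alt, rate))
        neighbors[codon] = nb

    # one unit of branch length == one expected substitution per codon
    scale = float(np.mean([sum(r for _, r in nb) for nb in neighbors.values()]))

    def evolve(seq: list[str], t: float) -> list[str]:
        out = list(seq)
        for i in range(len(out)):
            elapsed = 0.0
            while True:
                nb = neighbors[out[i]]
                total = sum(r for _, r in nb) / scale
                elapsed += rng.exponential(1.0 / total)
                if elapsed >= t:
                    break
                probs = np.array([r for _, r in nb])
                out[i] = nb[rng.choice(len(nb), p=probs / probs.sum())][0]
        return out

    root_seq = [SENSE_CODONS[i] for i in rng.integers(len(SENSE_CODONS), size=n_codons)]
    states = {id(tree): root_seq}
    result: dict[str, str] = {}
    for node in tree.preorder(include_self=True):
        if node.parent is not None:
            t = node.length or 0.0
            states[id(node)] = evolve(states[id(node.parent)], t)
        if node.is_tip():
            result[node.name] = "".join(states[id(node)])
    return result
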