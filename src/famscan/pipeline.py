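"""End-to-end pipeline driver: mine -> annotate -> receptors -> tree ->
subgroups -> selection.

Every run writes a manifest recording the configuration, the seed and a
content hash of each output, so reruns with an identical configuration
yield byte-identical manifest-tracked outputs.  A failing stage aborts
with a stage-labeled error and leaves that stage's files behind with a
``.partial`` suffix.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as fio
from .io import PipelineConfig
from .mine import ExonCall, MiningParams, iterative_mine
from .models import (
    GeneModel,
    assemble_gene_models,
    census,
    classify_architecture,
    name_genes,
)
from .motifs import ReceptorClass, classify_receptor_signaling
from .phylo import assign_subgroups, bootstrap_support, jc_distance, nj_tree, progressive_align
from .selection import CodonAlignment, SelectionResult, cumulative_profile, slac_analyze

log = logging.getLogger("famscan.pipeline")

#: expected exon lengths used for boundary refinement; the cytoplasmic
#: exon comes in two reference lengths (inhibitory 90 nt, activating 150 nt)
EXPECTED_EXON_LENGTHS: dict[str, int | tuple[int, ...]] = {
    "leader": 102,
    "N": 321,
    "A1": 279,
    "B": 279,
    "A2": 279,
    "TM": 108,
    "Cyt": (90, 150),
}


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineResult:
    calls: list[ExonCall] = field(default_factory=list)
    models: list[GeneModel] = field(default_factory=list)
    receptors: dict[str, ReceptorClass] = field(default_factory=dict)
    census: pd.DataFrame | None = None
    tree: object | None = None
    subgroup_labels: dict[str, str] = field(default_factory=dict)
    selection: SelectionResult | None = None
    paths: dict[str, Path] = field(default_factory=dict)


class _Stage:
    """Write-through-temp helper: files become final only if the stage ends."""

    def __init__(self, name: str, out_dir: Path):
        self.name = name
        self.out_dir = out_dir
        self.pending: list[tuple[Path, Path]] = []

    def path(self, filename: str) -> Path:
        final = self.out_dir / filename
        partial = self.out_dir / (filename + ".partial")
        self.pending.append((partial, final))
        return partial

    def commit(self) -> list[Path]:
        finals = []
        for partial, final in self.pending:
            if partial.exists():
                partial.replace(final)
                finals.append(final)
        return finals

    def __enter__(self):
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc_type is None:
            return False
        raise PipelineError(f"stage {self.name!r} failed: {exc}") from exc


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _calls_table(calls: list[ExonCall]) -> pd.DataFrame:
    rows = [
        {
            "contig_id": c.contig_id,
            "start": c.refined_interval[0],
            "end": c.refined_interval[1],
            "strand": c.strand,
            "domain": c.domain_type,
            "acceptor_ok": c.acceptor_ok,
            "donor_ok": c.donor_ok,
            "length_ok": c.length_ok,
            "score": c.hit.score,
            "evalue": c.hit.evalue,
            "identity": round(c.hit.identity, 4),
            "query_id": c.hit.query_id,
        }
        for c in calls
    ]
    columns = [
        "contig_id", "start", "end", "strand", "domain", "acceptor_ok",
        "donor_ok", "length_ok", "score", "evalue", "identity", "query_id",
    ]
    return pd.DataFrame(rows, columns=columns)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    result = PipelineResult()
    seed_seq = np.random.SeedSequence(config.seed)
    stage_seeds = {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(
            ["tree", "selection"], seed_seq.spawn(2)
        )
    }
    params = MiningParams(
        word_size=config.word_size,
        max_evalue=config.max_evalue,
        min_cover=config.min_cover,
        length_tolerance=config.length_tolerance,
    )
    contigs = fio.read_fasta(config.genome) if config.genome else {}
    seeds = fio.read_fasta(config.seeds) if config.seeds else {}
    igc_refs = fio.read_fasta(config.igc_references) if config.igc_references else {}
    tm_refs = fio.read_fasta(config.tm_references) if config.tm_references else {}
    anchors = fio.read_fasta(config.anchors) if config.anchors else {}

    log.info(
        "stage=mine seed=%d params=%s", config.seed,
        hashlib.sha256(repr(params).encode()).hexdigest()[:12],
    )

    # -- mine --------------------------------------------------------------
    with _Stage("mine", out_dir) as st:
        calls = (
            iterative_mine(contigs, seeds, EXPECTED_EXON_LENGTHS, params, config.rounds)
            if contigs and seeds
            else []
        )
        result.calls = calls
        _calls_table(calls).to_csv(st.path("exon_calls.tsv"), sep="\t", index=False)
        feats = [
            fio.Feature(
                c.contig_id, *c.refined_interval, "exon", c.strand,
                {"ID": f"call{i:04d}", "domain": c.domain_type},
            )
            for i, c in enumerate(calls)
        ]
        fio.write_gff3(feats, st.path("exon_calls.gff3"))
        fio.write_bed(feats, st.path("exon_calls.bed"))
        result.paths.update({"exon_calls": out_dir / "exon_calls.tsv"})
    _commit(st)

    # -- annotate ----------------------------------------------------------
    with _Stage("annotate", out_dir) as st:
        models = assemble_gene_models(calls, config.max_gene_gap, config.species)
        for m in models:
            classify_architecture(m, igc_refs or None)
        result.models = models
        gene_feats = []
        for m in models:
            lo = min(e.refined_interval[0] for e in m.exons)
            hi = max(e.refined_interval[1] for e in m.exons)
            gene_feats.append(
                fio.Feature(
                    m.contig_id, lo, hi, "gene", m.strand,
                    {"ID": m.gene_id, "architecture": m.architecture},
                )
            )
            for e in m.exons:
                gene_feats.append(
                    fio.Feature(
                        m.contig_id, *e.refined_interval, "exon", e.strand,
                        {"ID": f"{m.gene_id}.{e.domain_type}", "Parent": m.gene_id,
                         "domain": e.domain_type},
                    )
                )
        fio.write_gff3(gene_feats, st.path("gene_models.gff3"))
    _commit(st)

    # -- receptors ---------------------------------------------------------
    with _Stage("receptors", out_dir) as st:
        receptors: dict[str, ReceptorClass] = {}
        for m in models:
            rc = classify_receptor_signaling(
                m, tm_refs or None, contigs.get(m.contig_id)
            )
            m.signaling = rc.signaling
            receptors[m.gene_id] = rc
        name_genes(models, config.species)
        result.receptors = receptors
        rows = [
            {
                "gene_id": m.gene_id,
                "name": m.name,
                "architecture": m.architecture,
                "tm_type": receptors[m.gene_id].tm_type,
                "signaling": receptors[m.gene_id].signaling,
                "motifs": ";".join(
                    f"{h.kind}@{h.tyrosine_position}"
                    for h in receptors[m.gene_id].motif_summary
                ),
                "orf_intact": m.orf_intact,
                "n_glyc_sites": m.n_glyc_sites,
            }
            for m in models
        ]
        pd.DataFrame(
            rows,
            columns=["gene_id", "name", "architecture", "tm_type", "signaling",
                     "motifs", "orf_intact", "n_glyc_sites"],
        ).to_csv(st.path("receptors.tsv"), sep="\t", index=False)
        cen = census({config.species: models})
        result.census = cen
        cen.to_csv(st.path("census.tsv"), sep="\t", index=False)
        fio.write_fasta(
            [(m.gene_id, m.coding_sequence) for m in models if m.coding_sequence],
            st.path("genes_nt.fa"),
        )
    _commit(st)

    # -- tree + subgroups --------------------------------------------------
    with _Stage("tree", out_dir) as st:
        n_seqs = {
            m.gene_id: m.n_exon.sequence
            for m in models
            if m.n_exon is not None and m.orf_intact
        }
        tree = None
        labels: dict[str, str] = {}
        anchor_map = {name.replace("_anchor", ""): name for name in anchors}
        if len(n_seqs) + len(anchors) >= 4 and len(n_seqs) >= 1:
            aln = progressive_align({**n_seqs, **anchors}, mode="nt")
            fio.write_fasta(aln.as_dict(), st.path("n_domains.aln.fa"))
            tree = bootstrap_support(
                aln,
                n_replicates=config.bootstrap_replicates,
                seed=stage_seeds["tree"],
            )
            fio.write_newick(tree, st.path("n_domains.nwk"))
            if anchors:
                leaf_labels, mono = assign_subgroups(
                    tree, {label: leaf for label, leaf in anchor_map.items()}
                )
                labels = {
                    leaf: lab for leaf, lab in leaf_labels.items() if leaf not in anchors
                }
                pd.DataFrame(
                    sorted(labels.items()), columns=["gene_id", "subgroup"]
                ).to_csv(st.path("subgroups.tsv"), sep="\t", index=False)
        result.tree = tree
        result.subgroup_labels = labels
    _commit(st)

    # -- selection ---------------------------------------------------------
    with _Stage("selection", out_dir) as st:
        log.warning(
            "recombination screening skipped (not part of this pipeline); "
            "interpret per-site results accordingly"
        )
        psg_seqs = {
            m.gene_id: m.n_exon.sequence
            for m in models
            if m.architecture.startswith("PSG") and m.orf_intact and m.n_exon is not None
        }
        sel = None
        if len(psg_seqs) >= 3:
            codon_aln_obj = progressive_align(psg_seqs, mode="codon")
            caln = CodonAlignment(codon_aln_obj.names, codon_aln_obj.rows)
            sel_tree = nj_tree(jc_distance(codon_aln_obj))
            sel = slac_analyze(caln, sel_tree, alpha=config.alpha)
            sel.per_site.to_csv(st.path("selection_sites.tsv"), sep="\t", index=False)
            cumulative_profile(caln).to_csv(
                st.path("selection_profile.tsv"), sep="\t", index=False
            )
            with open(st.path("selection_summary.json"), "w") as fh:
                json.dump(
                    {
                        "mean_dnds": None if np.isnan(sel.mean_dnds) else sel.mean_dnds,
                        "total_Sd": sel.total_Sd,
                        "total_Nd": sel.total_Nd,
                        "n_sequences": len(psg_seqs),
                        "method_note": sel.method_note,
                    },
                    fh,
                    indent=2,
                    sort_keys=True,
                )
        result.selection = sel
    _commit(st)

    # -- manifest ----------------------------------------------------------
    manifest = {
        "config": {k: getattr(config, k) for k in vars(config)},
        "seed": config.seed,
        "outputs": {
            p.name: _sha256(p)
            for p in sorted(out_dir.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    result.paths["manifest"] = out_dir / "manifest.json"
    return result


def _commit(stage: _Stage) -> None:
    stage.commit()
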