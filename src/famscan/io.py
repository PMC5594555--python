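"""File formats and configuration.

All coordinates are 0-based half-open inside the package; conversion to the
1-based inclusive GFF3 convention (and back) happens only here, at the
serialization boundary.  BED stays 0-based half-open.  FASTA is wrapped at
60 columns.  Newick trees carry bootstrap supports as internal node labels.
"""

from __future__ import annotations

import dataclasses
import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

FASTA_WRAP = 60


class FormatError(ValueError):
    """Malformed record in an input file; message carries file and line."""


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered {name: sequence} mapping."""
    path = Path(path)
    records: dict[str, str] = {}
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            records[rec.id] = str(rec.seq).upper()
    except ValueError as exc:  # Biopython raises ValueError on bad records
        raise FormatError(f"{path}: {exc}") from exc
    if not records and path.stat().st_size > 0:
        # non-empty file that yielded no records is malformed
        with open(path) as fh:
            first = fh.readline().rstrip("\n")
        raise FormatError(f"{path}:1: not a FASTA file (first line {first!r})")
    return records


def write_fasta(seqs: dict[str, str] | Iterable[tuple[str, str]], path: str | Path) -> None:
    items = seqs.items() if isinstance(seqs, dict) else seqs
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in items]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=FASTA_WRAP)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# Intervals / GFF3 / BED

@dataclass(frozen=True)
class Feature:
    """One genomic feature in the internal 0-based half-open convention."""

    seqid: str
    start: int  # 0-based inclusive
    end: int    # exclusive
    ftype: str = "exon"
    strand: str = "+"
    attributes: dict[str, str] = field(default_factory=dict)
    source: str = "famscan"
    score: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad interval [{self.start},{self.end}) on {self.seqid}")


def _fmt_attrs(attrs: dict[str, str]) -> str:
    if not attrs:
        return "."
    return ";".join(f"{k}={v}" for k, v in attrs.items())


def write_gff3(features: Iterable[Feature], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            fh.write(
                "\t".join(
                    [
                        f.seqid,
                        f.source,
                        f.ftype,
                        str(f.start + 1),  # GFF3 is 1-based inclusive
                        str(f.end),
                        f.score,
                        f.strand,
                        ".",
                        _fmt_attrs(f.attributes),
                    ]
                )
                + "\n"
            )


def read_gff3(path: str | Path) -> list[Feature]:
    path = Path(path)
    feats: list[Feature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns, got {len(parts)}")
            seqid, source, ftype, start, end, score, strand, _phase, attrs = parts
            try:
                start_i, end_i = int(start) - 1, int(end)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            attributes = {}
            if attrs != ".":
                for kv in attrs.split(";"):
                    if kv and "=" in kv:
                        k, v = kv.split("=", 1)
                        attributes[k] = v
            feats.append(
                Feature(seqid, start_i, end_i, ftype, strand, attributes, source, score)
            )
    return feats


def write_bed(features: Iterable[Feature], path: str | Path) -> None:
    with open(path, "w") as fh:
        for f in features:
            name = f.attributes.get("ID", f.ftype)
            fh.write(f"{f.seqid}\t{f.start}\t{f.end}\t{name}\t0\t{f.strand}\n")


def read_bed(path: str | Path) -> list[Feature]:
    path = Path(path)
    feats: list[Feature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: BED needs >=3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            name = parts[3] if len(parts) > 3 else "feature"
            strand = parts[5] if len(parts) > 5 else "+"
            feats.append(Feature(parts[0], start, end, "exon", strand, {"ID": name}))
    return feats


# ---------------------------------------------------------------------------
# Newick (thin wrapper; supports-as-internal-node-labels dialect)

def read_newick(path_or_handle):
    """Parse a Newick tree (internal node labels read as bootstrap supports)."""
    from skbio import TreeNode

    if isinstance(path_or_handle, (str, Path)):
        return TreeNode.read(str(path_or_handle), format="newick")
    return TreeNode.read(path_or_handle, format="newick")


def write_newick(tree, path: str | Path) -> None:
    tree.write(str(path), format="newick")


def newick_string(tree) -> str:
    buf = _io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


# ---------------------------------------------------------------------------
# Pipeline configuration

@dataclass
class PipelineConfig:
    """Parameters of one end-to-end run; round-trips through YAML."""

    genome: str = ""
    seeds: str = ""
    anchors: str = ""
    igc_references: str = ""
    tm_references: str = ""
    out_dir: str = "famscan_out"
    species: str = "synthetic"
    max_evalue: float = 1e-10
    min_cover: float = 0.5
    word_size: int = 11
    length_tolerance: int = 6
    max_gene_gap: int = 25_000
    rounds: int = 6
    bootstrap_replicates: int = 500
    alpha: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.min_cover <= 1.0):
            raise ValueError("min_cover must be in [0,1]")
        if self.max_evalue <= 0:
            raise ValueError("max_evalue must be positive")
        if self.word_size < 4:
            raise ValueError("word_size must be >= 4")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0,1)")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
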