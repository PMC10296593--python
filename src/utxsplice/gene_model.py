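"""Exon-level gene model and Δ-nomenclature for splice isoforms.

A single gene is represented as an ordered list of numbered exons with their
genomic intervals and sequences, plus a designated *alternative splicing
region* (ASR): the contiguous sub-range of exon numbers in which all observed
splicing variation concentrates.  Isoforms over the ASR are named by the exons
they exclude ("Δ14Δ16"); the isoform including every ASR exon is called
"long".  Exon numbering follows the longest annotated transcript so that every
possible exon has a stable number.

Coordinates are 0-based half-open internally.  BED12 is read and written
as-is; GFF3 (1-based closed) is converted at the boundary.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

DELTA = "Δ"

__all__ = [
    "DELTA",
    "asr_exon_set",
    "Exon",
    "ExonModel",
    "IsoformPattern",
    "name_pattern",
    "parse_pattern",
    "load_gene_model",
    "write_bed12",
    "write_exon_fasta",
    "write_genome_fasta",
    "model_summary",
]


@dataclass(frozen=True)
class Exon:
    """One exon: 1-based number, 0-based half-open genomic interval, sequence."""

    number: int
    start: int
    end: int
    sequence: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"exon {self.number}: empty interval {self.start}-{self.end}")
        if len(self.sequence) != self.end - self.start:
            raise ValueError(
                f"exon {self.number}: sequence length {len(self.sequence)} != "
                f"interval length {self.end - self.start}"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ExonModel:
    """Ordered exon structure of one gene with the ASR sub-range marked.

    Exons are ordered 5'->3' on the coding strand with strictly increasing
    numbers and non-overlapping genomic intervals.  ``asr_range`` is the
    inclusive (first, last) pair of exon numbers delimiting the alternative
    splicing region; its endpoints double as the anchor exons that every
    amplicon read must contain.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[Exon, ...]
    asr_range: tuple[int, int]

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        numbers = [e.number for e in self.exons]
        if not numbers:
            raise ValueError("model has no exons")
        if any(b <= a for a, b in zip(numbers, numbers[1:])):
            raise ValueError("exon numbers must be strictly increasing")
        ivals = sorted((e.start, e.end) for e in self.exons)
        if any(b_start < a_end for (_, a_end), (b_start, _) in zip(ivals, ivals[1:])):
            raise ValueError("exon intervals overlap")
        first, last = self.asr_range
        known = set(numbers)
        if first > last or first not in known or last not in known:
            raise ValueError(f"invalid ASR: ({first}, {last}) not a sub-range of exon numbers")

    @property
    def exon_numbers(self) -> tuple[int, ...]:
        return tuple(e.number for e in self.exons)

    @property
    def asr_exons(self) -> tuple[int, ...]:
        first, last = self.asr_range
        return tuple(n for n in self.exon_numbers if first <= n <= last)

    @property
    def anchor_exons(self) -> tuple[int, int]:
        """The ASR-flanking exons present in every amplicon (the primer sites)."""
        return self.asr_range

    def exon(self, number: int) -> Exon:
        for e in self.exons:
            if e.number == number:
                return e
        raise KeyError(f"no exon {number} in model of {self.gene_id}")

    def isoform_sequence(self, included: Iterable[int]) -> str:
        """Concatenated sequence of the given exons, in transcript order."""
        wanted = set(included)
        unknown = wanted - set(self.exon_numbers)
        if unknown:
            raise KeyError(f"unknown exons: {sorted(unknown)}")
        return "".join(e.sequence for e in self.exons if e.number in wanted)


@dataclass(frozen=True)
class IsoformPattern:
    """An exon-inclusion pattern over the ASR with its canonical Δ-name."""

    included: frozenset[int]
    name: str

    @classmethod
    def from_included(cls, included: Iterable[int], model: ExonModel) -> "IsoformPattern":
        inc = frozenset(included)
        return cls(included=inc, name=name_pattern(inc, model))

    @classmethod
    def from_name(cls, name: str, model: ExonModel) -> "IsoformPattern":
        inc = parse_pattern(name, model)
        return cls(included=inc, name=name_pattern(inc, model))


def asr_exon_set(model_or_asr: "ExonModel | Iterable[int]") -> frozenset[int]:
    """ASR exon numbers from either a full model or a bare collection."""
    if isinstance(model_or_asr, ExonModel):
        return frozenset(model_or_asr.asr_exons)
    return frozenset(int(n) for n in model_or_asr)


def name_pattern(included: Iterable[int], model: "ExonModel | Iterable[int]") -> str:
    """Canonical Δ-name for a set of included ASR exons.

    Excluded ASR exons are listed ascending, each prefixed with Δ; a pattern
    including every ASR exon is named "long".  ``model`` may be an
    :class:`ExonModel` or just the collection of ASR exon numbers.
    """
    inc = set(included)
    asr = set(asr_exon_set(model))
    outside = inc - asr
    if outside:
        raise ValueError(f"not an ASR exon: {sorted(outside)}")
    excluded = sorted(asr - inc)
    if not excluded:
        return "long"
    return "".join(f"{DELTA}{n}" for n in excluded)


_PATTERN_RE = re.compile(rf"(?:{DELTA}|[dD])(\d+)")


def parse_pattern(name: str, model: "ExonModel | Iterable[int]") -> frozenset[int]:
    """Inverse of :func:`name_pattern`; accepts 'd'/'D' as ASCII aliases for Δ."""
    asr = set(asr_exon_set(model))
    if name == "long":
        return frozenset(asr)
    stripped = _PATTERN_RE.sub("", name)
    if stripped or not name:
        raise ValueError(f"pattern parse error: {name!r}")
    excluded = [int(m.group(1)) for m in _PATTERN_RE.finditer(name)]
    bad = set(excluded) - asr
    if bad:
        raise ValueError(f"pattern parse error: {name!r} excludes non-ASR exons {sorted(bad)}")
    if excluded != sorted(set(excluded)):
        raise ValueError(f"pattern parse error: {name!r} not in canonical ascending form")
    return frozenset(asr - set(excluded))


# ---------------------------------------------------------------------------
# annotation + sequence I/O


def _read_bed12(stream) -> pd.DataFrame:
    cols = [
        "chrom", "start", "end", "name", "score", "strand",
        "thick_start", "thick_end", "rgb", "block_count", "block_sizes", "block_starts",
    ]
    df = pd.read_csv(stream, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 12:
        raise ValueError(f"BED12 requires 12 columns, found {df.shape[1]}")
    df = df.iloc[:, :12]
    df.columns = cols
    for c in ("start", "end", "block_count"):
        df[c] = df[c].astype(int)
    return df


def _blocks_from_bed12(row: pd.Series) -> list[tuple[int, int]]:
    sizes = [int(x) for x in str(row.block_sizes).rstrip(",").split(",")]
    offsets = [int(x) for x in str(row.block_starts).rstrip(",").split(",")]
    if len(sizes) != row.block_count or len(offsets) != row.block_count:
        raise ValueError(f"BED12 block fields inconsistent for {row['name']}")
    return [(row.start + o, row.start + o + s) for o, s in zip(offsets, sizes)]


def _exons_from_gff3(stream, gene_id: str) -> tuple[str, str, list[tuple[int, int]]]:
    import gffutils

    text = stream.read() if hasattr(stream, "read") else str(stream)
    db = gffutils.create_db(text, ":memory:", from_string=True, merge_strategy="create_unique")
    exons = []
    chrom = strand = None
    for feat in db.all_features(featuretype="exon"):
        attrs = {k: ",".join(v) for k, v in feat.attributes.items()}
        hay = " ".join([feat.id or "", attrs.get("Parent", ""), attrs.get("gene_id", ""),
                        attrs.get("ID", ""), attrs.get("Name", "")])
        if gene_id in hay:
            chrom, strand = feat.seqid, feat.strand
            exons.append((feat.start - 1, feat.end))  # 1-based closed -> half-open
    if not exons:
        raise KeyError(f"gene not found: {gene_id}")
    return chrom, strand, sorted(exons)


def load_gene_model(
    annotation,
    sequences,
    gene_id: str,
    asr_range: tuple[int, int],
    fmt: str | None = None,
) -> ExonModel:
    """Build an :class:`ExonModel` from a BED12 or GFF3 annotation and a FASTA.

    Parameters
    ----------
    annotation
        Path or text stream carrying a BED12 record (the transcript named
        ``gene_id``) or GFF3 exon features whose ID/Parent mentions ``gene_id``.
    sequences
        Path or stream of a FASTA with the genomic sequence of the model's
        chromosome (record id must match the annotation's chromosome).
    gene_id
        Transcript/gene identifier to extract.
    asr_range
        Inclusive (first, last) exon numbers of the alternative splicing region.
    fmt
        "bed12" or "gff3"; inferred from content when omitted.

    Exon numbers are assigned 1..n in 5'->3' transcript order; on the minus
    strand exon 1 is the rightmost genomic block and sequences are
    reverse-complemented.
    """
    ann_text = annotation.read() if hasattr(annotation, "read") else open(annotation).read()
    if fmt is None:
        fmt = "gff3" if ("\tgene\t" in ann_text or "\texon\t" in ann_text or
                         ann_text.startswith("##gff")) else "bed12"

    if fmt == "bed12":
        df = _read_bed12(io.StringIO(ann_text))
        hit = df[df["name"] == gene_id]
        if hit.empty:
            raise KeyError(f"gene not found: {gene_id}")
        row = hit.iloc[0]
        chrom, strand = row.chrom, row.strand
        blocks = _blocks_from_bed12(row)
    elif fmt == "gff3":
        chrom, strand, blocks = _exons_from_gff3(io.StringIO(ann_text), gene_id)
    else:
        raise ValueError(f"unknown annotation format {fmt!r}")

    if hasattr(sequences, "read"):
        records = {r.id: r for r in SeqIO.parse(sequences, "fasta")}
    else:
        records = {r.id: r for r in SeqIO.parse(str(sequences), "fasta")}
    if chrom not in records:
        raise KeyError(f"gene not found: chromosome {chrom!r} absent from FASTA")
    genome = str(records[chrom].seq)

    if strand == "-":
        ordered = sorted(blocks, key=lambda b: -b[0])  # exon 1 = rightmost
    else:
        ordered = sorted(blocks)

    exons = []
    for i, (start, end) in enumerate(ordered, start=1):
        if end > len(genome) or start < 0:
            raise ValueError(f"sequence out of range: exon {i} {start}-{end}")
        seq = genome[start:end]
        if strand == "-":
            seq = str(Seq(seq).reverse_complement())
        exons.append(Exon(number=i, start=start, end=end, sequence=seq.upper()))

    try:
        return ExonModel(gene_id=gene_id, chrom=chrom, strand=strand,
                         exons=tuple(exons), asr_range=tuple(asr_range))
    except ValueError as e:
        if "invalid ASR" in str(e):
            raise ValueError("invalid ASR") from e
        raise


def write_bed12(model: ExonModel, stream) -> None:
    """Emit the model as one BED12 line (blocks in genomic order)."""
    blocks = sorted((e.start, e.end) for e in model.exons)
    start = blocks[0][0]
    end = blocks[-1][1]
    sizes = ",".join(str(b - a) for a, b in blocks)
    offsets = ",".join(str(a - start) for a, b in blocks)
    fields = [model.chrom, start, end, model.gene_id, 0, model.strand,
              start, end, "0,0,0", len(blocks), sizes, offsets]
    stream.write("\t".join(str(f) for f in fields) + "\n")


def write_exon_fasta(model: ExonModel, stream, width: int = 60) -> None:
    """Per-exon FASTA wrapped at ``width`` columns."""
    for e in model.exons:
        stream.write(f">{model.gene_id}_exon{e.number}\n")
        for i in range(0, len(e.sequence), width):
            stream.write(e.sequence[i:i + width] + "\n")


def write_genome_fasta(model: ExonModel, stream, width: int = 60) -> None:
    """Single-record FASTA of the model's chromosome span.

    Exon sequences are placed at their genomic coordinates (minus-strand
    models are reverse-complemented back to the + strand); intronic and
    flanking positions are filled with N.
    """
    length = max(e.end for e in model.exons)
    chars = ["N"] * length
    for e in model.exons:
        seq = e.sequence if model.strand == "+" else str(Seq(e.sequence).reverse_complement())
        chars[e.start:e.end] = list(seq)
    genome = "".join(chars)
    stream.write(f">{model.chrom}\n")
    for i in range(0, length, width):
        stream.write(genome[i:i + width] + "\n")


def model_summary(model: ExonModel) -> pd.DataFrame:
    """Summary table: exon, start, end, length, in_ASR."""
    first, last = model.asr_range
    return pd.DataFrame(
        {
            "exon": [e.number for e in model.exons],
            "start": [e.start for e in model.exons],
            "end": [e.end for e in model.exons],
            "length": [len(e) for e in model.exons],
            "in_ASR": [first <= e.number <= last for e in model.exons],
        }
    )
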