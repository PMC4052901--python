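"""Genome, gene and promoter data model plus standard-format I/O.

Internal coordinates are 0-based half-open throughout.  GFF3 input/output
converts from/to the 1-based inclusive convention of that format; BED output
stays 0-based half-open.  Promoter windows default to (-400, +100) around the
translational start of the anchor gene, oriented so that increasing position
approaches the start codon, and are clipped only at contig boundaries (sites
inside coding regions are a real, if rare, phenomenon, so upstream genes do
not truncate the window).
"""

from __future__ import annotations

import urllib.parse
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DEFAULT_PROMOTER_WINDOW = (-400, 100)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Gene:
    """A protein-coding gene feature on a contig.

    ``start``/``end`` are a 0-based half-open genomic interval.  The
    translational start is ``start`` on the + strand and ``end - 1`` on the
    - strand.
    """

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    locus_tag: str = ""
    function_label: str = ""
    is_tf: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"gene {self.gene_id!r}: malformed strand {self.strand!r}"
            )
        if not self.start < self.end:
            raise ValueError(
                f"gene {self.gene_id!r}: start must be < end "
                f"(got [{self.start}, {self.end}))"
            )

    @property
    def translation_start(self) -> int:
        """Genomic coordinate of the first base of the start codon."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class Genome:
    """One organism: contig sequences, ordered gene features, proteins."""

    genome_id: str
    contigs: dict[str, str]
    genes: list[Gene] = field(default_factory=list)
    proteins: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene_id {g.gene_id!r}")
            seen.add(g.gene_id)
            if g.contig_id not in self.contigs:
                raise ValueError(
                    f"gene {g.gene_id!r} references unknown contig "
                    f"{g.contig_id!r}"
                )
            if g.end > len(self.contigs[g.contig_id]):
                raise ValueError(
                    f"gene {g.gene_id!r} extends beyond contig "
                    f"{g.contig_id!r} (length {len(self.contigs[g.contig_id])})"
                )
        # Deterministic order: per contig by start, ties by gene_id.
        self.genes.sort(key=lambda g: (g.contig_id, g.start, g.gene_id))
        self._by_id = {g.gene_id: g for g in self.genes}

    def gene(self, gene_id: str) -> Gene:
        return self._by_id[gene_id]

    def genes_on(self, contig_id: str) -> list[Gene]:
        return [g for g in self.genes if g.contig_id == contig_id]

    @property
    def tf_genes(self) -> list[Gene]:
        return [g for g in self.genes if g.is_tf]


@dataclass
class PromoterRegion:
    """An oriented promoter window anchored at a gene's translation start.

    ``sequence`` runs 5'->3' relative to the anchored gene, so increasing
    position approaches the start codon.  ``offset_of_start_codon`` is the
    index of the translation start within the oriented window (it may equal
    ``len(sequence)`` when the downstream part of the window was clipped).
    """

    anchor_operon_id: str
    contig_id: str
    interval: tuple[int, int]
    sequence: str
    offset_of_start_codon: int
    strand: str = "+"
    genome_id: str = ""

    def __len__(self) -> int:
        return len(self.sequence)

    def to_genomic(self, pos: int, width: int) -> tuple[int, int]:
        """Genomic half-open interval of the oriented window [pos, pos+width)."""
        lo, hi = self.interval
        if self.strand == "+":
            return lo + pos, lo + pos + width
        return hi - pos - width, hi - pos

    def center_offset(self, pos: int, width: int) -> float:
        """Offset of a window's center from the start codon (negative=upstream)."""
        return pos + width / 2.0 - self.offset_of_start_codon

    def end_offset(self, pos: int, width: int) -> int:
        """Offset of a window's 3' end from the start codon."""
        return pos + width - self.offset_of_start_codon


def extract_promoter(
    genome: Genome,
    anchor: Gene,
    window: tuple[int, int] = DEFAULT_PROMOTER_WINDOW,
    anchor_operon_id: str | None = None,
) -> PromoterRegion:
    """Extract the oriented promoter window around ``anchor``'s start codon.

    ``window`` is (lo, hi) in gene-oriented coordinates relative to the
    translational start (position 0); the default (-400, +100) yields a
    500-bp window.  Clipping happens only at contig boundaries.
    """
    lo, hi = window
    if lo >= hi:
        raise ValueError(f"promoter window must have lo < hi, got {window}")
    if anchor.gene_id not in genome._by_id:
        raise ValueError(f"anchor gene {anchor.gene_id!r} not in genome")
    contig = genome.contigs[anchor.contig_id]
    t = anchor.translation_start
    if anchor.strand == "+":
        gstart, gend = t + lo, t + hi
    else:
        gstart, gend = t - hi + 1, t - lo + 1
    gstart = max(0, gstart)
    gend = min(len(contig), gend)
    raw = contig[gstart:gend]
    if anchor.strand == "+":
        seq = raw
        offset = t - gstart
    else:
        seq = reverse_complement(raw)
        offset = gend - 1 - t
    return PromoterRegion(
        anchor_operon_id=anchor_operon_id or anchor.gene_id,
        contig_id=anchor.contig_id,
        interval=(gstart, gend),
        sequence=seq,
        offset_of_start_codon=offset,
        strand=anchor.strand,
        genome_id=genome.genome_id,
    )


# ---------------------------------------------------------------------------
# I/O: FASTA, GFF3, TSV feature tables, BED6
# ---------------------------------------------------------------------------

_TSV_COLUMNS = [
    "contig_id",
    "start",
    "end",
    "strand",
    "gene_id",
    "locus_tag",
    "function_label",
    "is_tf",
]


def _escape_gff3(value: str) -> str:
    return urllib.parse.quote(str(value), safe=" ./:^*$@!+?|_-()")


def _unescape_gff3(value: str) -> str:
    return urllib.parse.unquote(value)


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def _parse_gff3(path: str | Path) -> list[Gene]:
    genes = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            contig, _source, ftype, start, end, _score, strand, _phase, attrs = fields
            if ftype != "gene":
                continue
            attr_map = {}
            for item in attrs.split(";"):
                if not item:
                    continue
                key, _, val = item.partition("=")
                attr_map[key] = _unescape_gff3(val)
            genes.append(
                Gene(
                    gene_id=attr_map.get("ID", f"{contig}:{start}-{end}"),
                    contig_id=contig,
                    start=int(start) - 1,  # 1-based inclusive -> 0-based half-open
                    end=int(end),
                    strand=strand,
                    locus_tag=attr_map.get("locus_tag", ""),
                    function_label=attr_map.get("product", ""),
                    is_tf=attr_map.get("is_tf", "false").lower() == "true",
                )
            )
    return genes


def _parse_feature_tsv(path: str | Path) -> list[Gene]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(_TSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"feature table missing columns: {sorted(missing)}")
    return [
        Gene(
            gene_id=row.gene_id,
            contig_id=row.contig_id,
            start=int(row.start),
            end=int(row.end),
            strand=row.strand,
            locus_tag=row.locus_tag,
            function_label=row.function_label,
            is_tf=str(row.is_tf).lower() in ("true", "1"),
        )
        for row in df.itertuples()
    ]


def read_genome(
    sequence_file: str | Path,
    features: str | Path,
    proteins: str | Path | None = None,
    genome_id: str | None = None,
) -> Genome:
    """Load a genome from FASTA + features (GFF3 or TSV) + optional proteins.

    GFF3 is detected by file suffix (.gff/.gff3); anything else is read as the
    documented TSV feature table, whose coordinates are already 0-based
    half-open.
    """
    contigs = read_fasta(sequence_file)
    suffix = Path(features).suffix.lower()
    genes = _parse_gff3(features) if suffix in (".gff", ".gff3") else _parse_feature_tsv(features)
    prots = read_fasta(proteins) if proteins else {}
    gid = genome_id or Path(sequence_file).stem
    return Genome(genome_id=gid, contigs=contigs, genes=genes, proteins=prots)


def write_genome(
    genome: Genome,
    sequence_file: str | Path,
    features: str | Path,
    proteins: str | Path | None = None,
) -> None:
    """Write FASTA + GFF3 (or TSV by suffix) + optional protein FASTA."""
    write_fasta(genome.contigs, sequence_file)
    suffix = Path(features).suffix.lower()
    if suffix in (".gff", ".gff3"):
        with open(features, "w") as fh:
            fh.write("##gff-version 3\n")
            for cid, seq in genome.contigs.items():
                fh.write(f"##sequence-region {cid} 1 {len(seq)}\n")
            for g in genome.genes:
                attrs = ";".join(
                    [
                        f"ID={_escape_gff3(g.gene_id)}",
                        f"locus_tag={_escape_gff3(g.locus_tag)}",
                        f"product={_escape_gff3(g.function_label)}",
                        f"is_tf={'true' if g.is_tf else 'false'}",
                    ]
                )
                fh.write(
                    "\t".join(
                        [
                            g.contig_id,
                            "regulonkit",
                            "gene",
                            str(g.start + 1),
                            str(g.end),
                            ".",
                            g.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )
    else:
        df = pd.DataFrame(
            [
                {
                    "contig_id": g.contig_id,
                    "start": g.start,
                    "end": g.end,
                    "strand": g.strand,
                    "gene_id": g.gene_id,
                    "locus_tag": g.locus_tag,
                    "function_label": g.function_label,
                    "is_tf": g.is_tf,
                }
                for g in genome.genes
            ],
            columns=_TSV_COLUMNS,
        )
        df.to_csv(features, sep="\t", index=False)
    if proteins:
        write_fasta(genome.proteins, proteins)


def write_bed6(
    records: Iterable[tuple[str, int, int, str, float, str]],
    path: str | Path,
) -> None:
    """Write (contig, start, end, name, score, strand) rows as BED6."""
    with open(path, "w") as fh:
        for contig, start, end, name, score, strand in records:
            fh.write(f"{contig}\t{start}\t{end}\t{name}\t{score:.3f}\t{strand}\n")
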