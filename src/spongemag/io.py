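"""Readers and writers for the external formats the pipeline touches.

All public coordinates are 1-based and inclusive on both ends, the native
convention of both GFF3 and VCF; any half-open arithmetic stays internal.
Readers and their paired writers round-trip losslessly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger("spongemag.io")


class ParseError(ValueError):
    """A malformed line in an input file; the message names the line."""


@dataclass(frozen=True)
class GeneFeature:
    """One annotated gene (or protein-domain) interval on a contig.

    ``feature_id`` is the functional annotation identifier (KO, Pfam, EC,
    gene symbol) or ``"hypothetical"`` when the gene has none.
    """

    genome_id: str
    contig_id: str
    start: int  # 1-based, inclusive
    end: int  # inclusive, end >= start
    strand: str  # "+" or "-"
    feature_id: str = "hypothetical"
    product: str = ""

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start={self.start} < 1 for {self.feature_id}")
        if self.end < self.start:
            raise ValueError(
                f"end={self.end} < start={self.start} for {self.feature_id}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class VariantSite:
    """One row of a variant table (VCF subset).

    ``depth`` is ``None`` when no DP was present in the source row; the
    depth-based filters skip such sites.
    """

    contig_id: str
    pos: int  # 1-based
    qual: float
    depth: int | None
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos={self.pos} < 1")
        if self.qual < 0:
            raise ValueError(f"qual={self.qual} < 0")
        if self.depth is not None and self.depth < 0:
            raise ValueError(f"depth={self.depth} < 0")


# Attribute keys promoted to feature_id, in priority order.  EnrichM-style KO
# tags first, then domain/EC/gene-symbol tags.
_ID_KEYS = ("ko", "KO", "pfam", "Pfam", "ec", "EC", "gene", "Name")


def _parse_gff_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "=" in chunk:
            key, _, val = chunk.partition("=")
            attrs[key.strip()] = val.strip()
    return attrs


def read_gene_table(
    path: str | Path,
    dialect: str = "gff3",
    genome_id: str | None = None,
) -> list[GeneFeature]:
    """Read a gene annotation table in GFF3 or 6-column TSV dialect.

    The TSV dialect is ``contig  start  end  strand  feature_id  product``.
    Identical domain annotations repeated on one interval are collapsed to a
    single record so proteins are not double-counted.  Output is sorted by
    (contig, start).
    """
    path = Path(path)
    if dialect not in ("gff3", "tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    gid = genome_id if genome_id is not None else path.stem
    feats: list[GeneFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            try:
                if dialect == "gff3":
                    if len(cols) < 9:
                        raise ValueError(f"expected 9 columns, got {len(cols)}")
                    contig, _, _, start, end, _, strand, _, attr_text = cols[:9]
                    attrs = _parse_gff_attributes(attr_text)
                    fid = next(
                        (attrs[k] for k in _ID_KEYS if k in attrs), "hypothetical"
                    )
                    product = attrs.get("product", "")
                else:
                    if len(cols) < 5:
                        raise ValueError(f"expected >= 5 columns, got {len(cols)}")
                    contig, start, end, strand = cols[:4]
                    fid = cols[4] if len(cols) > 4 and cols[4] else "hypothetical"
                    product = cols[5] if len(cols) > 5 else ""
                feat = GeneFeature(
                    genome_id=gid,
                    contig_id=contig,
                    start=int(start),
                    end=int(end),
                    strand=strand,
                    feature_id=fid,
                    product=product,
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            feats.append(feat)
    # collapse duplicated identical annotations on one interval
    seen: set[tuple] = set()
    unique: list[GeneFeature] = []
    for f in feats:
        key = (f.contig_id, f.start, f.end, f.strand, f.feature_id)
        if key in seen:
            continue
        seen.add(key)
        unique.append(f)
    n_dup = len(feats) - len(unique)
    if n_dup:
        log.info("%s: collapsed %d duplicated domain annotations", path, n_dup)
    unique.sort(key=lambda f: (f.contig_id, f.start, f.end))
    return unique


def write_gene_table(
    features: Iterable[GeneFeature], path: str | Path, dialect: str = "tsv"
) -> None:
    """Write a gene table; the TSV dialect round-trips with the reader."""
    with open(Path(path), "w") as fh:
        if dialect == "tsv":
            for f in features:
                fh.write(
                    f"{f.contig_id}\t{f.start}\t{f.end}\t{f.strand}"
                    f"\t{f.feature_id}\t{f.product}\n"
                )
        elif dialect == "gff3":
            fh.write("##gff-version 3\n")
            for f in features:
                attrs = f"ID={f.feature_id}"
                if f.feature_id != "hypothetical":
                    attrs += f";gene={f.feature_id}"
                if f.product:
                    attrs += f";product={f.product}"
                fh.write(
                    f"{f.contig_id}\tspongemag\tgene\t{f.start}\t{f.end}\t."
                    f"\t{f.strand}\t.\t{attrs}\n"
                )
        else:
            raise ValueError(f"unknown dialect {dialect!r}")


def read_vcf_subset(path: str | Path) -> list[VariantSite]:
    """Read the (CHROM, POS, QUAL, DP, alleles) subset of a VCF 4.x file.

    Missing QUAL becomes 0 with a warning; missing DP leaves depth unknown.
    Multiallelic rows are kept as one site with comma-joined ALT alleles,
    as written.
    """
    sites: list[VariantSite] = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            qual = rec.qual
            if qual is None:
                warnings.warn(
                    f"{path}: missing QUAL at {rec.chrom}:{rec.pos}, treating as 0",
                    stacklevel=2,
                )
                qual = 0.0
            depth = rec.info.get("DP")
            if depth is None:
                for sample in rec.samples.values():
                    dp = sample.get("DP")
                    if dp is not None:
                        depth = dp
                        break
            alt = ",".join(rec.alts) if rec.alts else "."
            sites.append(
                VariantSite(
                    contig_id=rec.chrom,
                    pos=rec.pos,
                    qual=float(qual),
                    depth=int(depth) if depth is not None else None,
                    ref_allele=rec.ref or ".",
                    alt_allele=alt,
                )
            )
    return sites


def write_vcf(
    sites: Sequence[VariantSite],
    path: str | Path,
    contig_lengths: dict[str, int] | None = None,
) -> None:
    """Write variant sites as a minimal VCF 4.2 text file (DP in INFO)."""
    contigs: dict[str, int] = dict(contig_lengths or {})
    for s in sites:
        if s.contig_id not in contigs or contigs[s.contig_id] < s.pos:
            contigs[s.contig_id] = max(contigs.get(s.contig_id, 0), s.pos)
    with open(Path(path), "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Raw depth">\n')
        for cid, length in contigs.items():
            fh.write(f"##contig=<ID={cid},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for s in sorted(sites, key=lambda s: (s.contig_id, s.pos)):
            info = f"DP={s.depth}" if s.depth is not None else "."
            qual = f"{s.qual:g}"
            fh.write(
                f"{s.contig_id}\t{s.pos}\t.\t{s.ref_allele}\t{s.alt_allele}"
                f"\t{qual}\t.\t{info}\n"
            )


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a MAG x feature copy-number TSV (rows = MAGs, columns = features).

    Cells must be non-negative integers; a violation is reported with its
    row and column labels.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise ValueError(f"{path}: duplicate MAG or feature identifiers")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() | (numeric < 0) | (numeric % 1 != 0)
    if bad.to_numpy().any():
        row = bad.index[bad.any(axis=1)][0]
        col = bad.columns[bad.loc[row]][0]
        raise ValueError(
            f"{path}: invalid copy number at row {row!r}, column {col!r}: "
            f"{df.loc[row, col]!r}"
        )
    return numeric.astype(int)


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an ordered {id: sequence} mapping."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str] | Iterable[SeqRecord], path: str | Path) -> None:
    if isinstance(seqs, dict):
        records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    else:
        records = list(seqs)
    SeqIO.write(records, str(path), "fasta")
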