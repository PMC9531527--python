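"""Detection of syntenic steroid-biosynthesis gene clusters (CSGs).

A CSG is the three-gene operon delta14-sterol reductase (ERG24/TM7SF2) ->
sterol 14alpha-demethylase (CYP51) -> lanosterol synthase (ERG7/LSS): all
three core genes on one contig and one strand, near-adjacent, typically
flanked 5' by dihydroflavonol-4-reductase (DFR) plus a hypothetical protein
on the same strand and 3' by SMT1/ERG6 or FDFT1 on the opposite strand.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from spongemag.io import GeneFeature, read_fasta

log = logging.getLogger("spongemag.clusters")

#: canonical core genes in cluster order
CORE_ORDER = ("ERG24", "CYP51", "ERG7")

#: identifier aliases (EC numbers, gene symbols) -> canonical core name.
#: KO identifiers can be appended here once verified for a given annotation
#: pipeline.
DEFAULT_SYNONYMS: dict[str, str] = {
    "ERG24": "ERG24", "TM7SF2": "ERG24", "1.3.1.70": "ERG24", "EC:1.3.1.70": "ERG24",
    "CYP51": "CYP51", "1.14.14.154": "CYP51", "EC:1.14.14.154": "CYP51",
    "ERG7": "ERG7", "LSS": "ERG7", "5.4.99.7": "ERG7", "EC:5.4.99.7": "ERG7",
}

#: product-text patterns -> canonical core name (fallback when the feature
#: identifier is uninformative)
DEFAULT_PRODUCT_PATTERNS: dict[str, str] = {
    r"delta.{0,2}14.{0,2}sterol reductase": "ERG24",
    r"sterol.?14.?alpha.?demethylase": "CYP51",
    r"lanosterol synthase": "ERG7",
}

DEFAULT_FLANK_5PRIME = ("DFR", "hypothetical")
DEFAULT_FLANK_3PRIME = ("SMT1", "ERG6", "FDFT1")


@dataclass(frozen=True)
class CoreGeneSet:
    """The core trio, its identifier synonym map, and the expected flanks."""

    core: tuple[str, ...] = CORE_ORDER
    synonyms: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_SYNONYMS))
    product_patterns: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_PRODUCT_PATTERNS)
    )
    flank_5prime: tuple[str, ...] = DEFAULT_FLANK_5PRIME
    flank_3prime: tuple[str, ...] = DEFAULT_FLANK_3PRIME

    def __post_init__(self) -> None:
        if len(set(self.core)) != len(self.core):
            raise ValueError("core gene names must be distinct")
        missing = set(self.core) - set(self.synonyms.values())
        if missing:
            raise ValueError(f"synonym map does not cover core genes {missing}")

    def canonical(self, feature: GeneFeature) -> str | None:
        """Canonical core name for a gene, or None if it is not a core gene."""
        if feature.feature_id in self.synonyms:
            return self.synonyms[feature.feature_id]
        for pattern, name in self.product_patterns.items():
            if re.search(pattern, feature.product, flags=re.IGNORECASE):
                return name
        return None


@dataclass
class GeneCluster:
    """One detected CSG: its member genes, span, and flank evaluation."""

    genome_id: str
    contig_id: str
    member_features: list[GeneFeature]  # sorted by start; cores + intervening
    core_order: tuple[str, ...]  # observed order along the contig
    strand: str
    span_bp: int  # max(end) - min(start) + 1
    flank_5prime_match: bool
    flank_3prime_match: bool
    flank_5prime_ids: tuple[str, ...] = ()
    flank_3prime_ids: tuple[str, ...] = ()

    @property
    def start(self) -> int:
        return self.member_features[0].start

    @property
    def end(self) -> int:
        return self.member_features[-1].end

    @property
    def canonical_order(self) -> bool:
        return self.core_order == CORE_ORDER or self.core_order == CORE_ORDER[::-1]


def find_clusters(
    genes: Sequence[GeneFeature],
    core: CoreGeneSet | None = None,
    max_intervening: int = 1,
    max_gap_bp: int = 2000,
) -> list[GeneCluster]:
    """Scan one genome's gene table for steroid gene clusters.

    A cluster requires all three core genes on a single contig and strand,
    with at most ``max_intervening`` non-core genes and at most
    ``max_gap_bp`` intergenic bp between consecutive core genes.  Candidate
    windows are resolved greedily left-to-right.  Non-canonical core orders
    are reported (see :attr:`GeneCluster.core_order`) rather than rejected.
    Flanks are judged on the genes immediately adjacent to the cluster:
    the 3' flank must additionally sit on the opposite strand.
    """
    cs = core or CoreGeneSet()
    by_contig: dict[str, list[GeneFeature]] = {}
    for g in sorted(genes, key=lambda g: (g.contig_id, g.start, g.end)):
        by_contig.setdefault(g.contig_id, []).append(g)

    clusters: list[GeneCluster] = []
    for contig, feats in by_contig.items():
        labels = [cs.canonical(g) for g in feats]
        i = 0
        while i < len(feats):
            if labels[i] is None:
                i += 1
                continue
            window = _grow_window(feats, labels, i, cs, max_intervening, max_gap_bp)
            if window is None:
                i += 1
                continue
            first, last = window
            clusters.append(
                _build_cluster(feats, labels, first, last, cs)
            )
            i = last + 1  # greedy: continue past the accepted window
    return clusters


def _grow_window(feats, labels, start_idx, cs, max_intervening, max_gap_bp):
    """Try to extend a window from a core gene to cover all three cores."""
    strand = feats[start_idx].strand
    found = {labels[start_idx]}
    last_core = start_idx
    j = start_idx + 1
    while j < len(feats) and len(found) < len(cs.core):
        lab = labels[j]
        if lab is None:
            j += 1
            continue
        # a core gene: check strand, gap and intervening count since last core
        if feats[j].strand != strand:
            return None
        if lab in found:
            return None  # duplicated core before completion: reject window
        gap = feats[j].start - feats[last_core].end - 1
        if gap > max_gap_bp:
            return None
        if j - last_core - 1 > max_intervening:
            return None
        found.add(lab)
        last_core = j
        j += 1
    if len(found) == len(cs.core):
        return start_idx, last_core
    return None


def _build_cluster(feats, labels, first, last, cs) -> GeneCluster:
    members = feats[first : last + 1]
    strand = members[0].strand
    order = tuple(lab for lab in labels[first : last + 1] if lab is not None)
    span = members[-1].end - members[0].start + 1

    # adjacent genes outside the window, in genome order
    upstream = feats[first - 1] if first > 0 else None  # lower coordinates
    downstream = feats[last + 1] if last + 1 < len(feats) else None
    # 5'/3' relative to the core genes' strand
    five, three = (upstream, downstream) if strand == "+" else (downstream, upstream)

    def flank_label(g: GeneFeature | None) -> str | None:
        if g is None:
            return None
        return g.feature_id

    five_id = flank_label(five)
    three_id = flank_label(three)
    five_match = (
        five is not None
        and five.feature_id in cs.flank_5prime
        and five.strand == strand
    )
    three_match = (
        three is not None
        and three.feature_id in cs.flank_3prime
        and three.strand != strand
    )
    return GeneCluster(
        genome_id=members[0].genome_id,
        contig_id=members[0].contig_id,
        member_features=list(members),
        core_order=order,
        strand=strand,
        span_bp=span,
        flank_5prime_match=five_match,
        flank_3prime_match=three_match,
        flank_5prime_ids=(five_id,) if five_id else (),
        flank_3prime_ids=(three_id,) if three_id else (),
    )


def cluster_stats(
    clusters: Sequence[GeneCluster] | str | Path,
    groups: Mapping[str, str] | None = None,
) -> dict:
    """Length and prevalence summary of detected clusters.

    ``clusters`` is either detected :class:`GeneCluster` objects or a path
    to a FASTA of cluster sequences (record lengths are the spans).  The
    standard deviation is the sample (n-1) form.  With a genome -> group
    mapping, prevalence per group = fraction of the group's genomes with at
    least one cluster.
    """
    if isinstance(clusters, (str, Path)):
        seqs = read_fasta(clusters)
        spans = [len(s) for s in seqs.values()]
        genomes: list[str] = [name.split("|")[0] for name in seqs]
    else:
        spans = [c.span_bp for c in clusters]
        genomes = [c.genome_id for c in clusters]
    out: dict = {"count": len(spans)}
    if spans:
        s = pd.Series(spans, dtype=float)
        out.update(
            mean_bp=float(s.mean()),
            sd_bp=float(s.std(ddof=1)) if len(s) > 1 else math.nan,
            min_bp=int(s.min()),
            max_bp=int(s.max()),
        )
    if groups is not None:
        with_cluster = set(genomes)
        by_group: dict[str, list[str]] = {}
        for genome, grp in groups.items():
            by_group.setdefault(grp, []).append(genome)
        out["prevalence"] = {
            grp: sum(g in with_cluster for g in members) / len(members)
            for grp, members in by_group.items()
        }
    return out


def extract_cluster_sequence(
    cluster: GeneCluster, contigs: Mapping[str, str] | str | Path
) -> SeqRecord:
    """Nucleotide sequence of a cluster from its genome's contigs.

    The slice runs from the cluster's minimum start to maximum end; minus-
    strand clusters are reverse-complemented.  The header encodes
    genome|contig|start|end|strand.
    """
    if isinstance(contigs, (str, Path)):
        contigs = read_fasta(contigs)
    if cluster.contig_id not in contigs:
        raise KeyError(f"contig {cluster.contig_id!r} not in sequence source")
    contig = contigs[cluster.contig_id]
    if cluster.end > len(contig):
        raise ValueError(
            f"cluster span {cluster.start}-{cluster.end} exceeds contig "
            f"{cluster.contig_id!r} length {len(contig)}"
        )
    seq = Seq(contig[cluster.start - 1 : cluster.end])
    if cluster.strand == "-":
        seq = seq.reverse_complement()
    name = (
        f"{cluster.genome_id}|{cluster.contig_id}|{cluster.start}"
        f"|{cluster.end}|{cluster.strand}"
    )
    return SeqRecord(seq, id=name, description="")


def clusters_to_frame(clusters: Iterable[GeneCluster]) -> pd.DataFrame:
    """Tabular cluster report (one row per detected cluster)."""
    rows = []
    for c in clusters:
        rows.append(
            {
                "genome_id": c.genome_id,
                "contig_id": c.contig_id,
                "start": c.start,
                "end": c.end,
                "strand": c.strand,
                "span_bp": c.span_bp,
                "core_order": ">".join(c.core_order),
                "canonical_order": c.canonical_order,
                "n_intervening": len(c.member_features) - len(c.core_order),
                "flank_5prime_match": c.flank_5prime_match,
                "flank_3prime_match": c.flank_3prime_match,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "genome_id", "contig_id", "start", "end", "strand", "span_bp",
            "core_order", "canonical_order", "n_intervening",
            "flank_5prime_match", "flank_3prime_match",
        ],
    )
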