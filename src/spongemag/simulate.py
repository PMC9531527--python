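"""Synthetic inputs with the statistical structure the pipeline assumes.

Every generator is a pure function of its spec and seed, and emits a truth
table alongside the data; downstream tests read ground truth only from the
truth tables.  The defaults emulate the scale of a two-group comparative MAG
study: tens of host-associated genomes per species against ~100 free-living
reference genomes, thousands of sparse annotation features with zero-
inflated copy numbers, genomes carrying a plantable three-gene steroid
cluster, per-gene variant rates with a depressed rate in the planted core
genes, and codon alignments evolved under a known omega.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from spongemag.clusters import CORE_ORDER
from spongemag.io import GeneFeature, VariantSite
from spongemag.qc import MagRecord
from spongemag.selection import SENSE_CODONS, _CODON_TABLE, _is_transition

DEFAULT_PHYLA = {
    "Proteobacteria": 0.28,
    "Chloroflexota": 0.20,
    "Poribacteria": 0.10,
    "Actinobacteriota": 0.12,
    "Bacteroidota": 0.10,
    "Acidobacteriota": 0.06,
    "Gemmatimonadota": 0.05,
    "Nitrospirota": 0.04,
    "Binatota": 0.03,
    "Cyanobacteria": 0.02,
}


# ---------------------------------------------------------------------------
# cohort generator (enrichment inputs)
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Two-group MAG cohort with planted per-feature effects.

    ``planted_effects`` maps feature index -> (direction, fold) with
    direction in {"enriched", "depleted"} and fold > 1 applied to the
    focal group's mean copy number (multiplied or divided).
    """

    n_focal_mags: int = 40
    n_reference_mags: int = 101
    n_features: int = 2000
    phylum_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PHYLA)
    )
    genome_size_range: tuple[int, int] = (1500, 6000)
    prevalence_range: tuple[float, float] = (0.05, 0.9)
    mean_copy_scale: float = 0.8  # exponential scale of per-feature mean extra copies
    planted_effects: dict[int, tuple[str, float]] = field(default_factory=dict)
    planted_prevalence: float = 0.5
    planted_mean: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.phylum_proportions.values())
        if not math.isclose(total, 1.0, rel_tol=1e-6):
            raise ValueError(f"phylum proportions sum to {total}, expected 1")
        for idx, (direction, fold) in self.planted_effects.items():
            if direction not in ("enriched", "depleted"):
                raise ValueError(f"bad direction {direction!r} for feature {idx}")
            if fold <= 0:
                raise ValueError(f"fold must be > 0 (feature {idx})")
            if not 0 <= idx < self.n_features:
                raise ValueError(f"planted feature index {idx} out of range")
        if self.n_focal_mags < 2 or self.n_reference_mags < 2:
            raise ValueError("need >= 2 MAGs per group")
        if self.n_features < 1:
            raise ValueError("need >= 1 feature")


def default_planted_effects(
    n_enriched: int = 30,
    n_depleted: int = 30,
    fold_range: tuple[float, float] = (2.0, 8.0),
    seed: int = 0,
) -> dict[int, tuple[str, float]]:
    """Planted effect map over the first n_enriched + n_depleted features."""
    rng = np.random.default_rng(seed)
    effects: dict[int, tuple[str, float]] = {}
    for i in range(n_enriched):
        effects[i] = ("enriched", float(rng.uniform(*fold_range)))
    for i in range(n_enriched, n_enriched + n_depleted):
        effects[i] = ("depleted", float(rng.uniform(*fold_range)))
    return effects


def _sample_taxa(rng, n, phylum_proportions):
    phyla = list(phylum_proportions)
    probs = np.array([phylum_proportions[p] for p in phyla])
    chosen = rng.choice(phyla, size=n, p=probs / probs.sum())
    classes = []
    for p in chosen:
        if p == "Proteobacteria":
            classes.append(rng.choice(["Alphaproteobacteria", "Gammaproteobacteria"]))
        else:
            classes.append(str(p))
    return list(chosen), classes


def gen_cohort(spec: CohortSpec) -> dict:
    """Generate focal/reference count matrices, MAG tables, and truth table.

    Returns a dict with keys ``focal_counts``, ``reference_counts`` (MAG x
    feature integer DataFrames), ``focal_mags``, ``reference_mags`` (lists of
    :class:`~spongemag.qc.MagRecord`), and ``truth`` (per planted feature:
    direction and fold).
    """
    rng = np.random.default_rng(spec.seed)
    feature_ids = [f"K{10000 + i:05d}" for i in range(spec.n_features)]

    prevalence = rng.uniform(*spec.prevalence_range, size=spec.n_features)
    mean_copy = 1.0 + rng.exponential(spec.mean_copy_scale, size=spec.n_features)
    for idx in spec.planted_effects:
        prevalence[idx] = spec.planted_prevalence
        mean_copy[idx] = spec.planted_mean

    def make_group(group: str, n: int, planted: bool) -> tuple[pd.DataFrame, list]:
        mags = []
        phyla, classes = _sample_taxa(rng, n, spec.phylum_proportions)
        totals = rng.integers(*spec.genome_size_range, size=n, endpoint=True)
        for i in range(n):
            mags.append(
                MagRecord(
                    mag_id=f"{group}_{i:03d}",
                    source_group=(
                        "host_associated" if group == "focal" else "free_living"
                    ),
                    completeness=float(np.round(rng.uniform(85, 100), 2)),
                    contamination=float(np.round(rng.uniform(0, 5), 2)),
                    total_proteins=int(totals[i]),
                    phylum=phyla[i],
                    class_=classes[i],
                )
            )
        # an effect acts on the overall mean (prevalence x conditional mean);
        # as with real gene-family gains/losses it moves both, so the fold is
        # split geometrically between the two components
        means = np.tile(mean_copy, (n, 1))
        prev = prevalence.copy()
        if planted:
            for idx, (direction, fold) in spec.planted_effects.items():
                root = math.sqrt(fold)
                if direction == "enriched":
                    f_p = min(root, 1.0 / prev[idx])
                    prev[idx] = prev[idx] * f_p
                    means[:, idx] *= fold / f_p
                else:
                    prev[idx] = prev[idx] / root
                    means[:, idx] /= root
        nonzero = rng.random((n, spec.n_features)) < prev
        counts = rng.poisson(means) * nonzero
        df = pd.DataFrame(
            counts.astype(int),
            index=[m.mag_id for m in mags],
            columns=feature_ids,
        )
        return df, mags

    focal_counts, focal_mags = make_group("focal", spec.n_focal_mags, planted=True)
    ref_counts, ref_mags = make_group("ref", spec.n_reference_mags, planted=False)
    truth = pd.DataFrame(
        [
            {
                "feature_id": feature_ids[idx],
                "direction": direction,
                "fold_change": fold,
            }
            for idx, (direction, fold) in sorted(spec.planted_effects.items())
        ],
        columns=["feature_id", "direction", "fold_change"],
    )
    return {
        "focal_counts": focal_counts,
        "reference_counts": ref_counts,
        "focal_mags": focal_mags,
        "reference_mags": ref_mags,
        "truth": truth,
    }


def gen_ani(
    mag_ids: Sequence[str],
    n_clusters: int,
    within_range: tuple[float, float] = (97.0, 99.9),
    between_range: tuple[float, float] = (80.0, 95.0),
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Symmetric ANI matrix with a planted replicate-cluster partition.

    MAGs are assigned round-robin to ``n_clusters`` groups; within-group ANI
    is drawn above the dereplication cutoff, between-group ANI below it.
    Returns (matrix, truth partition mag_id -> cluster index).
    """
    if n_clusters < 1 or n_clusters > len(mag_ids):
        raise ValueError("n_clusters must be in [1, n_mags]")
    rng = np.random.default_rng(seed)
    truth = {mid: i % n_clusters for i, mid in enumerate(mag_ids)}
    n = len(mag_ids)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            same = truth[mag_ids[i]] == truth[mag_ids[j]]
            lo, hi = within_range if same else between_range
            mat[i, j] = mat[j, i] = rng.uniform(lo, hi)
    np.fill_diagonal(mat, 100.0)
    df = pd.DataFrame(mat, index=list(mag_ids), columns=list(mag_ids))
    return df, truth


# ---------------------------------------------------------------------------
# genome generator (cluster-detection and selection inputs)
# ---------------------------------------------------------------------------

@dataclass
class GenomeSpec:
    """One synthetic annotated genome, optionally carrying a steroid cluster.

    ``plant_cluster`` plants a detector-valid cluster (with flanks);
    ``plant_negative`` instead scatters the three core genes across contigs
    and strands so no valid cluster exists, while keeping all three
    identifiers present.
    """

    genome_id: str = "genome"
    n_genes: int = 200
    n_contigs: int = 3
    gene_length_range: tuple[int, int] = (300, 2400)
    intergenic_range: tuple[int, int] = (20, 300)
    plant_cluster: bool = False
    plant_negative: bool = False
    cluster_span_range: tuple[int, int] = (5700, 6100)
    cluster_intervening: int = 0  # hypothetical genes inside the cluster (0 or 1)
    cluster_strand: str | None = None  # None -> random
    seed: int = 0

    def __post_init__(self) -> None:
        if self.plant_cluster and self.plant_negative:
            raise ValueError("a genome cannot be both positive and negative")
        if self.n_contigs < 1 or self.n_genes < 10:
            raise ValueError("need >= 1 contig and >= 10 genes")
        if self.plant_negative and self.n_contigs < 2:
            raise ValueError("negatives need >= 2 contigs to scatter core genes")
        lo, hi = self.cluster_span_range
        # three cores + optional intervening gene + two gaps must fit the span
        min_needed = 3 * 150 + self.cluster_intervening * 100 + 2 * 20
        if lo < min_needed or hi < lo:
            raise ValueError("cluster_span_range unsatisfiable")
        if self.cluster_intervening not in (0, 1):
            raise ValueError("cluster_intervening must be 0 or 1")


_FILLER_IDS = ("K00001", "K00161", "PF00005", "PF07690", "hypothetical")


def gen_genome(spec: GenomeSpec) -> dict:
    """Generate a gene table, contig sequences, and planted-cluster truth.

    Returns ``{"genes": [GeneFeature...], "contigs": {id: seq},
    "truth": [ {contig_id, start, end, strand, span_bp, sequence} ... ]}``.
    """
    rng = np.random.default_rng(spec.seed)
    strand_of = lambda: "+" if rng.random() < 0.5 else "-"

    # distribute filler genes over contigs, then build coordinates
    per_contig = np.array_split(np.arange(spec.n_genes), spec.n_contigs)
    layout: dict[str, list[GeneFeature]] = {}
    for ci, idxs in enumerate(per_contig):
        contig = f"{spec.genome_id}_ctg{ci + 1}"
        pos = 1
        feats = []
        for _ in idxs:
            pos += int(rng.integers(*spec.intergenic_range, endpoint=True))
            length = int(rng.integers(*spec.gene_length_range, endpoint=True))
            feats.append(
                GeneFeature(
                    genome_id=spec.genome_id,
                    contig_id=contig,
                    start=pos,
                    end=pos + length - 1,
                    strand=strand_of(),
                    feature_id=str(rng.choice(_FILLER_IDS)),
                    product="",
                )
            )
            pos += length
        layout[contig] = feats

    truth: list[dict] = []
    contig_names = list(layout)
    if spec.plant_cluster:
        contig = contig_names[int(rng.integers(len(contig_names)))]
        _plant_cluster(layout[contig], spec, rng, truth)
    elif spec.plant_negative:
        _plant_negative(layout, spec, rng)

    genes: list[GeneFeature] = []
    contigs: dict[str, str] = {}
    for contig, feats in layout.items():
        feats.sort(key=lambda f: f.start)
        genes.extend(feats)
        length = feats[-1].end + int(rng.integers(*spec.intergenic_range, endpoint=True))
        contigs[contig] = "".join(rng.choice(list("ACGT"), size=length))
    for rec in truth:
        rec["sequence"] = _slice(contigs, rec)
    return {"genes": genes, "contigs": contigs, "truth": truth}


def _slice(contigs: dict[str, str], rec: dict) -> str:
    from Bio.Seq import Seq

    raw = contigs[rec["contig_id"]][rec["start"] - 1 : rec["end"]]
    return str(Seq(raw).reverse_complement()) if rec["strand"] == "-" else raw


def _plant_cluster(feats: list[GeneFeature], spec, rng, truth: list) -> None:
    """Insert a valid cluster (with flanks) after the last filler gene."""
    genome = feats[0].genome_id
    contig = feats[0].contig_id
    strand = spec.cluster_strand or ("+" if rng.random() < 0.5 else "-")
    span = int(rng.integers(*spec.cluster_span_range, endpoint=True))
    gaps = rng.integers(20, 150, size=2 + spec.cluster_intervening)
    intervening_len = int(rng.integers(150, 400)) if spec.cluster_intervening else 0
    core_total = span - int(gaps.sum()) - intervening_len
    # split the remaining span over the three cores at roughly realistic ratios
    fracs = np.array([0.24, 0.28, 0.48])
    lengths = np.maximum((fracs * core_total).astype(int), 150)
    lengths[-1] = core_total - lengths[:-1].sum()

    five_len, three_len = int(rng.integers(600, 1200)), int(rng.integers(600, 1200))
    hyp_len = int(rng.integers(200, 500))
    gap5a, gap5b, gap3 = (int(g) for g in rng.integers(20, 150, size=3))
    # reserve room below the cluster start for whichever flank genes sit at
    # lower coordinates (5' flanks on "+", the 3' flank on "-")
    reserve = (
        five_len + gap5b + hyp_len + gap5a
        if strand == "+"
        else three_len + gap3
    )
    start = (
        feats[-1].end
        + int(rng.integers(*spec.intergenic_range, endpoint=True))
        + reserve
    )
    order = CORE_ORDER if strand == "+" else CORE_ORDER[::-1]
    # optional intervening hypothetical goes between the 2nd and 3rd core
    pieces: list[tuple[str, int]] = []
    for k, name in enumerate(order):
        pieces.append((name, int(lengths[k])))
        if k < 2:
            pieces.append(("", int(gaps[k])))  # intergenic gap
            if spec.cluster_intervening and k == 1:
                pieces.append(("hypothetical", intervening_len))
                pieces.append(("", int(gaps[2])))

    pos = start
    members = []
    for name, length in pieces:
        if name:
            members.append(
                GeneFeature(
                    genome_id=genome, contig_id=contig, start=pos,
                    end=pos + length - 1, strand=strand, feature_id=name,
                )
            )
        pos += length
    cl_start, cl_end = members[0].start, members[-1].end

    # flanks: DFR + hypothetical 5' (same strand), SMT1/FDFT1 3' (opposite)
    opposite = "-" if strand == "+" else "+"
    three_id = str(rng.choice(["SMT1", "FDFT1"]))
    if strand == "+":
        hyp = GeneFeature(genome, contig, cl_start - gap5a - hyp_len,
                          cl_start - gap5a - 1, strand, "hypothetical")
        dfr = GeneFeature(genome, contig, hyp.start - gap5b - five_len,
                          hyp.start - gap5b - 1, strand, "DFR")
        three = GeneFeature(genome, contig, cl_end + gap3,
                            cl_end + gap3 + three_len - 1, opposite, three_id)
    else:
        hyp = GeneFeature(genome, contig, cl_end + gap5a,
                          cl_end + gap5a + hyp_len - 1, strand, "hypothetical")
        dfr = GeneFeature(genome, contig, hyp.end + gap5b,
                          hyp.end + gap5b + five_len - 1, strand, "DFR")
        three = GeneFeature(genome, contig, cl_start - gap3 - three_len,
                            cl_start - gap3 - 1, opposite, three_id)
    if dfr.start < 1 or three.start < 1:
        raise ValueError("cluster planting ran off the contig start")
    feats.extend(members + [hyp, dfr, three])
    truth.append(
        {
            "contig_id": contig,
            "start": cl_start,
            "end": cl_end,
            "strand": strand,
            "span_bp": cl_end - cl_start + 1,
        }
    )


def _plant_negative(layout: dict[str, list[GeneFeature]], spec, rng) -> None:
    """Scatter the three core identifiers so the syntenic rule fails."""
    contigs = list(layout)
    mode = rng.choice(["split_contigs", "mixed_strands"])
    if mode == "split_contigs" and len(contigs) >= 2:
        # each core gene on a different contig (recycled if fewer contigs)
        for k, name in enumerate(CORE_ORDER):
            feats = layout[contigs[k % len(contigs)]]
            start = feats[-1].end + int(rng.integers(*spec.intergenic_range,
                                                     endpoint=True))
            length = int(rng.integers(900, 2400))
            feats.append(
                GeneFeature(feats[0].genome_id, feats[0].contig_id, start,
                            start + length - 1, "+" if rng.random() < 0.5 else "-",
                            name)
            )
    else:
        # adjacent trio but the middle core gene on the opposite strand
        feats = layout[contigs[0]]
        pos = feats[-1].end + int(rng.integers(*spec.intergenic_range, endpoint=True))
        for k, name in enumerate(CORE_ORDER):
            length = int(rng.integers(900, 2400))
            strand = "-" if k == 1 else "+"
            feats.append(
                GeneFeature(feats[0].genome_id, feats[0].contig_id, pos,
                            pos + length - 1, strand, name)
            )
            pos += length + int(rng.integers(20, 150))


# ---------------------------------------------------------------------------
# variant generator
# ---------------------------------------------------------------------------

@dataclass
class VariantSpec:
    """Per-gene Poisson variant rates with QUAL/depth artefacts.

    ``low_rate_genes`` (typically the planted core genes) get
    ``low_rate_fraction`` of the baseline per-bp rate.  ``high_depth_fraction``
    of sites get a depth spike well above twice the mean, and
    ``low_qual_fraction`` get QUAL below 20, so the variant filter has known
    targets.
    """

    rate_per_bp: float = 0.003
    low_rate_genes: tuple[str, ...] = ()
    low_rate_fraction: float = 0.3
    mean_depth: float = 30.0
    high_depth_fraction: float = 0.05
    high_depth_factor: float = 5.0
    qual_mean: float = 60.0
    low_qual_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate_per_bp < 0:
            raise ValueError("rate_per_bp must be >= 0")
        if not 0 < self.low_rate_fraction <= 1:
            raise ValueError("low_rate_fraction must be in (0, 1]")
        for name in ("high_depth_fraction", "low_qual_fraction"):
            if not 0 <= getattr(self, name) < 1:
                raise ValueError(f"{name} must be in [0, 1)")


def gen_variants(
    genes: Sequence[GeneFeature], spec: VariantSpec
) -> tuple[list[VariantSite], pd.DataFrame]:
    """Poisson variants per gene, plus a truth table of realised counts/rates.

    Truth columns: gene_id, contig_id, start, end, rate_per_bp, n_variants,
    n_low_qual, n_high_depth.
    """
    rng = np.random.default_rng(spec.seed)
    sites: list[VariantSite] = []
    rows = []
    bases = "ACGT"
    for g in genes:
        rate = spec.rate_per_bp * (
            spec.low_rate_fraction if g.feature_id in spec.low_rate_genes else 1.0
        )
        n = int(rng.poisson(rate * g.length))
        n = min(n, g.length)
        positions = rng.choice(np.arange(g.start, g.end + 1), size=n, replace=False)
        n_low_qual = n_high_depth = 0
        for pos in sorted(int(p) for p in positions):
            if rng.random() < spec.low_qual_fraction:
                qual = float(np.round(rng.uniform(2, 19.99), 2))
                n_low_qual += 1
            else:
                qual = float(np.round(rng.uniform(20, 2 * spec.qual_mean), 2))
            depth = int(rng.poisson(spec.mean_depth)) + 1
            if rng.random() < spec.high_depth_fraction:
                depth = int(depth * spec.high_depth_factor)
                n_high_depth += 1
            ref = bases[int(rng.integers(4))]
            alt = bases[(bases.index(ref) + int(rng.integers(1, 4))) % 4]
            sites.append(
                VariantSite(
                    contig_id=g.contig_id, pos=pos, qual=qual, depth=depth,
                    ref_allele=ref, alt_allele=alt,
                )
            )
        rows.append(
            {
                "gene_id": g.feature_id, "contig_id": g.contig_id,
                "start": g.start, "end": g.end, "rate_per_bp": rate,
                "n_variants": n, "n_low_qual": n_low_qual,
                "n_high_depth": n_high_depth,
            }
        )
    truth = pd.DataFrame(
        rows,
        columns=["gene_id", "contig_id", "start", "end", "rate_per_bp",
                 "n_variants", "n_low_qual", "n_high_depth"],
    )
    return sites, truth


# ---------------------------------------------------------------------------
# codon-alignment simulator (GY94-style)
# ---------------------------------------------------------------------------

def _codon_rates(omega: float, kappa: float):
    """Per-codon single-nucleotide substitution rates, stops inaccessible."""
    neighbours: dict[str, list[tuple[str, float]]] = {}
    for codon in SENSE_CODONS:
        out = []
        for i in range(3):
            for b in "ACGT":
                if b == codon[i]:
                    continue
                mut = codon[:i] + b + codon[i + 1 :]
                if _CODON_TABLE[mut] == "*":
                    continue
                rate = kappa if _is_transition(codon[i], b) else 1.0
                if _CODON_TABLE[mut] != _CODON_TABLE[codon]:
                    rate *= omega
                out.append((mut, rate))
        neighbours[codon] = out
    mean_rate = float(
        np.mean([sum(r for _, r in out) for out in neighbours.values()])
    )
    return neighbours, mean_rate


def _evolve_seq(codons: list[str], branch_length: float, neighbours, mean_rate, rng):
    """Gillespie jumps per codon site; branch length in substitutions/site."""
    if mean_rate == 0 or branch_length == 0:
        return list(codons)
    out = []
    for codon in codons:
        t = 0.0
        while True:
            total = sum(r for _, r in neighbours[codon]) / mean_rate
            if total == 0:
                break
            t += rng.exponential(1.0 / total)
            if t >= branch_length:
                break
            rates = np.array([r for _, r in neighbours[codon]])
            k = rng.choice(len(rates), p=rates / rates.sum())
            codon = neighbours[codon][k][0]
        out.append(codon)
    return out


def evolve_codon_alignment(
    n_codons: int,
    divergence: float,
    omega: float,
    kappa: float = 2.0,
    n_sequences: int = 2,
    seed: int = 0,
) -> list[tuple[str, str]]:
    """Simulate a codon alignment on a star tree under a GY94-style model.

    The root is uniform over the 61 sense codons per site; each sequence
    evolves independently for ``divergence / 2`` expected substitutions per
    codon site, so any two sequences are separated by ``divergence``.
    Substitution rates scale with ``kappa`` for transitions and ``omega``
    for nonsynonymous changes; stop codons are inaccessible.
    """
    if omega < 0 or divergence < 0:
        raise ValueError("omega and divergence must be >= 0")
    if n_sequences < 2:
        raise ValueError("need >= 2 sequences")
    rng = np.random.default_rng(seed)
    neighbours, mean_rate = _codon_rates(omega, kappa)
    root = [SENSE_CODONS[int(i)] for i in rng.integers(len(SENSE_CODONS), size=n_codons)]
    out = []
    for k in range(n_sequences):
        leaf = _evolve_seq(root, divergence / 2.0, neighbours, mean_rate, rng)
        out.append((f"seq{k + 1}", "".join(leaf)))
    return out
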