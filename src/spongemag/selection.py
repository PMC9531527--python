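"""Selection inference on cluster core genes.

Two complementary lines of evidence for purifying selection:

* **Within-population variability** — per-gene variable sites per nucleotide
  from a filtered variant table, compared against the genome-wide coding
  baseline (core genes excluded) by a paired sign-flip permutation test per
  bacterial class, with BH-FDR star tiers.
* **Between-sequence divergence** — dN/dS (omega) per gene by the
  Nei-Gojobori counting method with Jukes-Cantor correction, placed within
  an empirical omega background of randomly chosen genes that pass a
  tree-support filter.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from itertools import combinations, permutations, product
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from spongemag.enrichment import bh_adjust
from spongemag.io import GeneFeature, VariantSite

log = logging.getLogger("spongemag.selection")

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

SENSE_CODONS = tuple(c for c, aa in _CODON_TABLE.items() if aa != "*")

_NUCS = "ACGT"


# ---------------------------------------------------------------------------
# variant filtering and per-gene variability
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneDiversity:
    """Variable-site proportion of one gene in one MAG, with its baseline."""

    mag_id: str
    gene_id: str
    n_variable_sites: int
    gene_length_bp: int
    proportion: float
    baseline_proportion: float | None = None

    def __post_init__(self) -> None:
        if self.gene_length_bp <= 0:
            raise ValueError("gene_length_bp must be positive")
        if not 0 <= self.proportion <= 1:
            raise ValueError(f"proportion {self.proportion} outside [0, 1]")


def filter_variants(
    sites: Sequence[VariantSite],
    min_qual: float = 20.0,
    depth_multiplier: float = 2.0,
) -> list[VariantSite]:
    """Drop low-QUAL variants and anomalously deep ones.

    Retained iff QUAL >= ``min_qual`` (the rule is strict "less than" for
    removal) and depth <= ``depth_multiplier`` x mean depth, the mean taken
    over the input's sites with known depth.  If no depth is known the depth
    rule is skipped with a warning; sites of unknown depth pass it.
    """
    depths = [s.depth for s in sites if s.depth is not None]
    if depths:
        mean_depth = float(np.mean(depths))
        cutoff = depth_multiplier * mean_depth
        log.info(
            "filter_variants: mean depth %.2f, depth cutoff %.2f, min QUAL %g",
            mean_depth, cutoff, min_qual,
        )
    else:
        cutoff = math.inf
        if sites:
            warnings.warn("no depths known; depth rule skipped", stacklevel=2)
    return [
        s
        for s in sites
        if s.qual >= min_qual and (s.depth is None or s.depth <= cutoff)
    ]


def gene_variability(
    variants: Sequence[VariantSite], gene: GeneFeature, mag_id: str = ""
) -> GeneDiversity:
    """Distinct variant positions inside the gene, per nucleotide."""
    positions = {
        v.pos
        for v in variants
        if v.contig_id == gene.contig_id and gene.start <= v.pos <= gene.end
    }
    return GeneDiversity(
        mag_id=mag_id,
        gene_id=gene.feature_id,
        n_variable_sites=len(positions),
        gene_length_bp=gene.length,
        proportion=len(positions) / gene.length,
    )


def _merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def coding_baseline(
    variants: Sequence[VariantSite],
    coding: Sequence[GeneFeature],
    exclude: Iterable[str] = (),
) -> float:
    """Genome-wide coding variable-site proportion, excluded genes removed.

    Overlapping coding intervals are merged before both the bp and the
    variant-position counts, so shared positions are not double-counted.
    """
    exclude = set(exclude)
    found = {g.feature_id for g in coding}
    absent = exclude - found
    if absent:
        warnings.warn(
            f"exclusion ids not in coding table: {sorted(absent)}", stacklevel=2
        )
    retained = [g for g in coding if g.feature_id not in exclude]
    if not retained:
        raise ValueError("no coding sequence left after exclusion")
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for g in retained:
        by_contig.setdefault(g.contig_id, []).append((g.start, g.end))
    merged = {c: _merge_intervals(iv) for c, iv in by_contig.items()}
    total_bp = sum(e - s + 1 for iv in merged.values() for s, e in iv)
    n_var = 0
    seen: set[tuple[str, int]] = set()
    for v in variants:
        key = (v.contig_id, v.pos)
        if key in seen:
            continue
        for s, e in merged.get(v.contig_id, ()):
            if s <= v.pos <= e:
                n_var += 1
                seen.add(key)
                break
    return n_var / total_bp


# ---------------------------------------------------------------------------
# paired sign-flip permutation comparison
# ---------------------------------------------------------------------------

def sign_flip_test(
    differences: Sequence[float],
    n_iter: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Two-sided paired permutation test on per-MAG differences.

    The statistic is the one-sample t of the differences; the null flips the
    sign of each difference.  All 2^n patterns are enumerated when feasible
    (exact tail); otherwise Monte-Carlo flips with the add-one estimate.
    """
    d = np.asarray(differences, dtype=float)
    n = len(d)
    if n < 2:
        raise ValueError("need >= 2 paired differences")

    def t_stat(vals: np.ndarray) -> np.ndarray:
        mean = vals.mean(axis=-1)
        sd = vals.std(axis=-1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = mean / (sd / math.sqrt(n))
        return np.where(sd > 0, t, np.where(mean == 0, 0.0, np.copysign(np.inf, mean)))

    t_obs = abs(float(t_stat(d)))
    if t_obs == 0.0:
        return 1.0
    if 2**n <= n_iter:
        signs = np.array(list(product((-1.0, 1.0), repeat=n)))
        t = np.abs(t_stat(signs * d))
        return float(np.count_nonzero(t >= t_obs - 1e-12)) / 2**n
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    signs = rng.choice((-1.0, 1.0), size=(n_iter, n))
    t = np.abs(t_stat(signs * d))
    hits = int(np.count_nonzero(t >= t_obs - 1e-12))
    return (1 + hits) / (1 + n_iter)


def significance_tier(p_adj: float) -> str:
    if p_adj < 0.001:
        return "***"
    if p_adj < 0.01:
        return "**"
    if p_adj < 0.05:
        return "*"
    return "n.s."


def compare_variability(
    diversity: pd.DataFrame,
    n_iter: int = 10_000,
    seed: int = 0,
    min_mags: int = 3,
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Per-class, per-gene comparison of gene vs baseline variability.

    ``diversity`` columns: mag_id, class_, gene_id, proportion,
    baseline_proportion.  Classes with fewer than ``min_mags`` MAGs are
    skipped with a reason.  BH-FDR is applied across the whole
    (class x gene) family; tiers follow adjusted p < 0.05 / 0.01 / 0.001.
    """
    from spongemag.enrichment import child_seed

    results = []
    skipped: list[tuple[str, str]] = []
    for (cls, gene), sub in diversity.groupby(["class_", "gene_id"], sort=True):
        n = len(sub)
        if n < min_mags:
            skipped.append((str(cls), f"only {n} MAGs with {gene} (need {min_mags})"))
            continue
        diffs = (sub["proportion"] - sub["baseline_proportion"]).to_numpy()
        p = sign_flip_test(diffs, n_iter=n_iter, seed=child_seed(seed, f"{cls}:{gene}"))
        results.append(
            {
                "class_": cls,
                "gene_id": gene,
                "n_mags": n,
                "mean_gene": float(sub["proportion"].mean()),
                "mean_baseline": float(sub["baseline_proportion"].mean()),
                "mean_difference": float(np.mean(diffs)),
                "p_raw": p,
            }
        )
    table = pd.DataFrame(
        results,
        columns=[
            "class_", "gene_id", "n_mags", "mean_gene", "mean_baseline",
            "mean_difference", "p_raw",
        ],
    )
    if len(table):
        table["p_adj"] = bh_adjust(table["p_raw"].to_numpy())
        table["tier"] = table["p_adj"].map(significance_tier)
    else:
        table["p_adj"] = []
        table["tier"] = []
    return table, skipped


# ---------------------------------------------------------------------------
# Nei-Gojobori dN/dS
# ---------------------------------------------------------------------------

@dataclass
class OmegaEstimate:
    """Per-gene counting-method selection estimate."""

    gene_id: str
    dN: float
    dS: float
    omega: float | None  # None when dS == 0
    n_sequences: int
    mean_support: float | None = None  # tree-wide mean bootstrap %, if known
    support_missing: bool = False


def _is_transition(a: str, b: str) -> bool:
    return {a, b} in ({"A", "G"}, {"C", "T"})


def ng86_sites(codon: str) -> tuple[float, float]:
    """Synonymous and nonsynonymous site counts of one sense codon.

    Each position contributes the fraction of its three single-nucleotide
    changes that are synonymous; mutations creating stop codons count as
    nonsynonymous.  S + N = 3 for every sense codon.
    """
    codon = codon.upper()
    if len(codon) != 3 or any(b not in _NUCS for b in codon):
        raise ValueError(f"not an unambiguous codon: {codon!r}")
    aa = _CODON_TABLE[codon]
    if aa == "*":
        raise ValueError(f"stop codon {codon!r} has no site counts")
    s = 0.0
    for i in range(3):
        for b in _NUCS:
            if b == codon[i]:
                continue
            mut = codon[:i] + b + codon[i + 1 :]
            if _CODON_TABLE[mut] == aa:
                s += 1 / 3
    return s, 3.0 - s


def _codon_path_counts(c1: str, c2: str) -> tuple[float, float] | None:
    """Synonymous/nonsynonymous difference counts between two codons.

    Averages with equal weight over all orderings of the differing positions,
    excluding any pathway that passes through (or ends in) a stop codon.
    Returns None when every pathway is blocked by stops.
    """
    diffs = [i for i in range(3) if c1[i] != c2[i]]
    syn_tot, nonsyn_tot, n_paths = 0.0, 0.0, 0
    for order in permutations(diffs):
        cur = c1
        syn, nonsyn = 0, 0
        ok = True
        for i in order:
            nxt = cur[:i] + c2[i] + cur[i + 1 :]
            if _CODON_TABLE[nxt] == "*":
                ok = False
                break
            if _CODON_TABLE[nxt] == _CODON_TABLE[cur]:
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        if ok:
            syn_tot += syn
            nonsyn_tot += nonsyn
            n_paths += 1
    if n_paths == 0:
        return None
    return syn_tot / n_paths, nonsyn_tot / n_paths


def jukes_cantor(p: float) -> float:
    """JC69 distance correction d = -(3/4) ln(1 - 4p/3); undefined at p >= 3/4."""
    if p >= 0.75:
        raise ValueError(f"proportion {p} >= 3/4: correction undefined")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def ng86_pair(seq1: str, seq2: str) -> tuple[float, float] | None:
    """Pairwise (dN, dS) by NG86 with JC correction; None if saturated.

    Codons containing gaps, ambiguity codes, or stops in either sequence are
    skipped, as are codon pairs whose every mutational pathway crosses a
    stop.
    """
    if len(seq1) != len(seq2):
        raise ValueError("sequences differ in length")
    if len(seq1) % 3:
        raise ValueError("alignment length not a multiple of 3")
    S = N = Sd = Nd = 0.0
    for i in range(0, len(seq1), 3):
        c1, c2 = seq1[i : i + 3].upper(), seq2[i : i + 3].upper()
        if any(b not in _NUCS for b in c1 + c2):
            continue
        if _CODON_TABLE[c1] == "*" or _CODON_TABLE[c2] == "*":
            continue
        if c1 != c2:
            counts = _codon_path_counts(c1, c2)
            if counts is None:
                continue
            Sd += counts[0]
            Nd += counts[1]
        s1, n1 = ng86_sites(c1)
        s2, n2 = ng86_sites(c2)
        S += (s1 + s2) / 2
        N += (n1 + n2) / 2
    if S == 0 or N == 0:
        raise ValueError("no comparable codons in pair")
    pS, pN = Sd / S, Nd / N
    if pS >= 0.75 or pN >= 0.75:
        return None
    return jukes_cantor(pN), jukes_cantor(pS)


def ng86_dnds(
    alignment: Sequence[tuple[str, str]] | Mapping[str, str],
    gene_id: str = "",
    mean_support: float | None = None,
) -> OmegaEstimate:
    """Gene-level omega: dN and dS averaged over all sequence pairs.

    ``alignment`` is a codon-aware nucleotide alignment as (name, sequence)
    pairs or a mapping.  Pairs saturated beyond the Jukes-Cantor domain are
    excluded with a warning.  omega is None when dS = 0.
    """
    if isinstance(alignment, Mapping):
        seqs = list(alignment.values())
    else:
        seqs = [s for _, s in alignment]
    if len(seqs) < 2:
        raise ValueError("need >= 2 sequences")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError("sequences differ in length")
    if lengths.pop() % 3:
        raise ValueError("alignment length not a multiple of 3")
    dn_vals, ds_vals, n_skipped = [], [], 0
    for i, j in combinations(range(len(seqs)), 2):
        pair = ng86_pair(seqs[i], seqs[j])
        if pair is None:
            n_skipped += 1
            continue
        dn_vals.append(pair[0])
        ds_vals.append(pair[1])
    if n_skipped:
        warnings.warn(
            f"{gene_id or 'gene'}: {n_skipped} saturated pairs excluded",
            stacklevel=2,
        )
    if not dn_vals:
        raise ValueError("all sequence pairs saturated; no estimate")
    dN = float(np.mean(dn_vals))
    dS = float(np.mean(ds_vals))
    return OmegaEstimate(
        gene_id=gene_id,
        dN=dN,
        dS=dS,
        omega=(dN / dS) if dS > 0 else None,
        n_sequences=len(seqs),
        mean_support=mean_support,
    )


def support_filter(
    estimates: Sequence[OmegaEstimate], threshold: float = 70.0
) -> list[OmegaEstimate]:
    """Keep genes with tree-wide mean bootstrap support >= threshold.

    Genes lacking support metadata pass with ``support_missing`` flagged.
    """
    kept = []
    for e in estimates:
        if e.mean_support is None:
            e.support_missing = True
            kept.append(e)
        elif e.mean_support >= threshold:
            kept.append(e)
    return kept


def omega_background(
    csg_estimates: Sequence[OmegaEstimate],
    background: Sequence[OmegaEstimate],
) -> pd.DataFrame:
    """Empirical percentile of each query omega in the background distribution.

    Percentile = fraction of background omegas strictly below the query plus
    half the tied fraction.  Genes without an omega (dS = 0) are skipped.
    """
    bg = np.array([e.omega for e in background if e.omega is not None], dtype=float)
    if bg.size == 0:
        raise ValueError("empty background distribution")
    rows = []
    for e in csg_estimates:
        if e.omega is None:
            continue
        below = float(np.count_nonzero(bg < e.omega))
        ties = float(np.count_nonzero(bg == e.omega))
        rows.append(
            {
                "gene_id": e.gene_id,
                "omega": e.omega,
                "percentile": (below + 0.5 * ties) / bg.size,
            }
        )
    return pd.DataFrame(rows, columns=["gene_id", "omega", "percentile"])
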