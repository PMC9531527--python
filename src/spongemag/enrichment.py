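"""Permutational enrichment/depletion analysis of gene-content matrices.

Compares per-MAG copy numbers of annotation features (KO or Pfam) between a
host-associated (focal) and a free-living (reference) genome set:

1. normalise each MAG's counts by its total predicted proteins;
2. drop features present in fewer than 10% of the MAGs in *both* groups;
3. per feature, a two-sided permutational t-test over MAG labels
   (10,000 iterations, or exact enumeration when feasible);
4. Benjamini-Hochberg FDR with the full feature count of the annotation
   category as denominator;
5. call enriched/depleted at adjusted p < 0.01 by the sign of the mean
   difference.

A taxon-stratified variant runs the same procedure per phylum (per class for
Proteobacteria) wherever both groups contribute at least ten MAGs.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from spongemag.config import RunConfig

log = logging.getLogger("spongemag.enrichment")

_T_TOL = 1e-12  # absolute slack when comparing |t*| against |t_obs|


def child_seed(master_seed: int, feature_id: str) -> int:
    """Deterministic per-feature seed, independent of iteration order."""
    digest = hashlib.sha256(f"{master_seed}:{feature_id}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def normalize_counts(matrix: pd.DataFrame, totals: pd.Series | Mapping) -> pd.DataFrame:
    """Divide each MAG's feature counts by its total predicted proteins."""
    totals = pd.Series(totals)
    missing = matrix.index.difference(totals.index)
    if len(missing):
        raise KeyError(f"no protein total for MAG {missing[0]!r}")
    tot = totals.loc[matrix.index]
    bad = tot[tot <= 0]
    if len(bad):
        raise ValueError(f"non-positive protein total for MAG {bad.index[0]!r}")
    return matrix.div(tot, axis=0)


def prevalence_filter(
    focal: pd.DataFrame, reference: pd.DataFrame, threshold: float = 0.10
) -> pd.Index:
    """Features present (count > 0) in >= threshold of MAGs in at least one group.

    A feature below the threshold in *both* groups is removed; exactly at the
    threshold in one group is retained (the rule is strict "less than").
    Features absent from one matrix count as all-zero there.
    """
    features = focal.columns.union(reference.columns, sort=False)
    prev_f = (focal.reindex(columns=features, fill_value=0) > 0).mean(axis=0)
    prev_r = (reference.reindex(columns=features, fill_value=0) > 0).mean(axis=0)
    keep = (prev_f >= threshold) | (prev_r >= threshold)
    return features[keep]


def _welch_t(mx, my, vx, vy, nx, ny):
    """Welch t from means and ddof-1 variances; vectorised over leading axis.

    Zero pooled variance: t = 0 when the means agree, +/-inf otherwise.
    """
    se2 = vx / nx + vy / ny
    diff = mx - my
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
    return np.where(se2 > 0, t, np.where(diff == 0, 0.0, np.copysign(np.inf, diff)))


def _student_t(mx, my, vx, vy, nx, ny):
    sp2 = ((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2)
    se2 = sp2 * (1 / nx + 1 / ny)
    diff = mx - my
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
    return np.where(se2 > 0, t, np.where(diff == 0, 0.0, np.copysign(np.inf, diff)))


_STATS = {
    "welch": _welch_t,
    "student": _student_t,
    "meandiff": lambda mx, my, vx, vy, nx, ny: mx - my,
}


def _group_stats(values: np.ndarray, axis=-1):
    return values.mean(axis=axis), values.var(axis=axis, ddof=1)


def permutation_t_test(
    x: Sequence[float],
    y: Sequence[float],
    n_iter: int = 10_000,
    seed: int | np.random.Generator = 0,
    statistic: str = "welch",
) -> float:
    """Two-sided permutation test for a difference in group means.

    When the number of distinct label assignments C(nx+ny, nx) is at most
    ``n_iter`` the null distribution is enumerated exactly and the unadjusted
    exact tail is returned; otherwise ``n_iter`` Monte-Carlo permutations are
    drawn and the add-one estimate ``(1 + hits) / (1 + n_iter)`` is returned,
    which never reaches 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError(f"each group needs >= 2 values (got {nx}, {ny})")
    stat = _STATS[statistic]
    pooled = np.concatenate([x, y])
    mx, vx = _group_stats(x)
    my, vy = _group_stats(y)
    t_obs = abs(float(stat(mx, my, vx, vy, nx, ny)))

    n_total = math.comb(nx + ny, nx)
    if n_total <= n_iter:
        hits = 0
        idx_all = frozenset(range(nx + ny))
        for combo in combinations(range(nx + ny), nx):
            xs = pooled[list(combo)]
            ys = pooled[list(idx_all - set(combo))]
            mxs, vxs = _group_stats(xs)
            mys, vys = _group_stats(ys)
            t = abs(float(stat(mxs, mys, vxs, vys, nx, ny)))
            if t >= t_obs - _T_TOL:
                hits += 1
        return hits / n_total

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm = np.argsort(rng.random((n_iter, nx + ny)), axis=1)
    xs = pooled[perm[:, :nx]]
    ys = pooled[perm[:, nx:]]
    mxs, vxs = _group_stats(xs)
    mys, vys = _group_stats(ys)
    t = np.abs(stat(mxs, mys, vxs, vys, nx, ny))
    hits = int(np.count_nonzero(t >= t_obs - _T_TOL))
    return (1 + hits) / (1 + n_iter)


def bh_adjust(p_values: Sequence[float], m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment with an explicit family size.

    ``m`` defaults to the number of p-values but may be larger (e.g. the
    total feature count of an annotation category when only a subset was
    testable); q_(i) = min_{j >= i} min(1, m * p_(j) / j), returned in input
    order.
    """
    p = np.asarray(p_values, dtype=float)
    n = len(p)
    if n == 0:
        return p.copy()
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    if m is None:
        m = n
    if m < n:
        raise ValueError(f"family size m={m} smaller than number of tests {n}")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, n + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(n)
    q[order] = q_sorted
    return q


def log10_ratio(mean_focal: float, mean_reference: float) -> tuple[float, bool]:
    """Signed log10 effect size: magnitude log10(larger/smaller), sign = direction.

    Returns (value, infinite_flag); a zero mean on exactly one side yields a
    signed infinity sentinel with the flag set.
    """
    if mean_focal == mean_reference:
        return 0.0, False
    if mean_focal > 0 and mean_reference > 0:
        return math.log10(mean_focal / mean_reference), False
    return (math.inf if mean_focal > mean_reference else -math.inf), True


def run_enrichment(
    focal_counts: pd.DataFrame,
    focal_totals: pd.Series | Mapping,
    reference_counts: pd.DataFrame,
    reference_totals: pd.Series | Mapping,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Full enrichment pipeline; one row per feature of the category.

    Columns: feature_id, mean_focal, mean_reference, log10_ratio,
    ratio_infinite, prevalence_focal, prevalence_reference, p_raw, p_adj,
    call.  Features failing the prevalence filter get ``call = "filtered"``
    and NaN p-values.
    """
    cfg = config or RunConfig()
    if len(focal_counts) < 2 or len(reference_counts) < 2:
        raise ValueError("each group needs >= 2 MAGs")
    focal = normalize_counts(focal_counts, focal_totals)
    reference = normalize_counts(reference_counts, reference_totals)
    features = focal.columns.union(reference.columns, sort=False)
    focal = focal.reindex(columns=features, fill_value=0.0)
    reference = reference.reindex(columns=features, fill_value=0.0)
    tested = prevalence_filter(focal, reference, cfg.prevalence_threshold)

    prev_f = (focal > 0).mean(axis=0)
    prev_r = (reference > 0).mean(axis=0)
    mean_f = focal.mean(axis=0)
    mean_r = reference.mean(axis=0)

    fv = focal.to_numpy()
    rv = reference.to_numpy()
    col = {f: i for i, f in enumerate(features)}
    p_raw = pd.Series(np.nan, index=features)
    for f in tested:
        p_raw[f] = permutation_t_test(
            fv[:, col[f]],
            rv[:, col[f]],
            n_iter=cfg.n_permutations,
            seed=child_seed(cfg.rng_seed, str(f)),
            statistic=cfg.test_statistic,
        )
    m = len(features) if cfg.bh_family == "all_features" else len(tested)
    log.info(
        "enrichment: %d features, %d tested, BH family m=%d",
        len(features), len(tested), m,
    )
    p_adj = pd.Series(np.nan, index=features)
    if len(tested):
        p_adj[tested] = bh_adjust(p_raw[tested].to_numpy(), m=m)

    rows = []
    for f in features:
        if f in set(tested):
            if p_adj[f] < cfg.alpha and mean_f[f] > mean_r[f]:
                call = "enriched"
            elif p_adj[f] < cfg.alpha and mean_f[f] < mean_r[f]:
                call = "depleted"
            else:
                call = "ns"
        else:
            call = "filtered"
        ratio, inf_flag = log10_ratio(float(mean_f[f]), float(mean_r[f]))
        rows.append(
            {
                "feature_id": f,
                "mean_focal": mean_f[f],
                "mean_reference": mean_r[f],
                "log10_ratio": ratio,
                "ratio_infinite": inf_flag,
                "prevalence_focal": prev_f[f],
                "prevalence_reference": prev_r[f],
                "p_raw": p_raw[f],
                "p_adj": p_adj[f],
                "call": call,
            }
        )
    return pd.DataFrame(rows)


def stratified_enrichment(
    focal_counts: pd.DataFrame,
    focal_totals: pd.Series | Mapping,
    focal_taxa: pd.DataFrame,
    reference_counts: pd.DataFrame,
    reference_totals: pd.Series | Mapping,
    reference_taxa: pd.DataFrame,
    config: RunConfig | None = None,
) -> tuple[dict[str, pd.DataFrame], list[tuple[str, str]]]:
    """Per-taxon enrichment runs with a minimum-MAG gate.

    ``*_taxa`` are MAG-indexed frames with ``phylum`` and ``class_`` columns.
    Strata are phyla, except Proteobacteria which is analysed per class.  A
    stratum runs only when both life-history groups contribute at least
    ``config.min_mags_per_category`` MAGs; others are listed with a reason.
    """
    cfg = config or RunConfig()

    def strata(taxa: pd.DataFrame) -> pd.Series:
        s = taxa["phylum"].copy()
        is_proteo = s == "Proteobacteria"
        s[is_proteo] = taxa.loc[is_proteo, "class_"]
        return s

    sf = strata(focal_taxa.loc[focal_counts.index])
    sr = strata(reference_taxa.loc[reference_counts.index])
    results: dict[str, pd.DataFrame] = {}
    skipped: list[tuple[str, str]] = []
    for taxon in sorted(set(sf) | set(sr)):
        n_f = int((sf == taxon).sum())
        n_r = int((sr == taxon).sum())
        if min(n_f, n_r) < cfg.min_mags_per_category:
            skipped.append(
                (taxon, f"only {n_f} host-associated / {n_r} free-living MAGs "
                        f"(need {cfg.min_mags_per_category} each)")
            )
            continue
        results[taxon] = run_enrichment(
            focal_counts.loc[sf[sf == taxon].index],
            focal_totals,
            reference_counts.loc[sr[sr == taxon].index],
            reference_totals,
            cfg,
        )
    for taxon, reason in skipped:
        log.info("stratified_enrichment: skipped %s (%s)", taxon, reason)
    return results, skipped
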