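"""MAG quality scoring, completeness gating, ANI dereplication, sharing.

Quality is the CheckM-style score ``completeness - 5 x contamination``; MAGs
are retained when the score is at least 40 *and* completeness is at least
85%.  Dereplication collapses MAGs above a 96.5% average-nucleotide-identity
cutoff by greedy centroid clustering within a user-supplied scope (per host
species for the enrichment dataset, across species for the selection
dataset).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger("spongemag.qc")


@dataclass
class MagRecord:
    """Per-MAG metadata: provenance, taxonomy, and CheckM-style QC metrics."""

    mag_id: str
    source_group: str  # "host_associated" | "free_living"
    completeness: float  # percent
    contamination: float  # percent
    total_proteins: int = 1
    host_species: str | None = None
    region: str | None = None
    phylum: str = ""
    class_: str = ""
    domain: str = "Bacteria"
    quality: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.source_group not in ("host_associated", "free_living"):
            raise ValueError(f"unknown source_group {self.source_group!r}")
        if self.total_proteins < 1:
            raise ValueError(f"total_proteins={self.total_proteins} < 1")
        if self.quality is None:
            self.quality = compute_quality(self.completeness, self.contamination)


def compute_quality(completeness: float, contamination: float) -> float:
    """Quality score = completeness - 5 x contamination (may be negative)."""
    for name, v in (("completeness", completeness), ("contamination", contamination)):
        if not 0 <= v <= 100:
            raise ValueError(f"{name}={v} outside [0, 100]")
    return completeness - 5.0 * contamination


def filter_mags(
    records: Sequence[MagRecord],
    quality_cutoff: float = 40.0,
    min_completeness: float = 85.0,
) -> list[MagRecord]:
    """Retain MAGs with quality >= cutoff and completeness >= minimum.

    Both boundaries are inclusive.  Order is preserved; the numbers removed
    by each criterion are logged.
    """
    kept, n_quality, n_compl = [], 0, 0
    for r in records:
        q_ok = r.quality >= quality_cutoff
        c_ok = r.completeness >= min_completeness
        if not q_ok:
            n_quality += 1
        if not c_ok:
            n_compl += 1
        if q_ok and c_ok:
            kept.append(r)
    log.info(
        "filter_mags: %d/%d retained (%d failed quality >= %g, %d failed "
        "completeness >= %g)",
        len(kept), len(records), n_quality, quality_cutoff, n_compl, min_completeness,
    )
    return kept


def drop_non_bacterial(records: Sequence[MagRecord]) -> list[MagRecord]:
    """Keep only MAGs labelled domain Bacteria (archaea are set aside)."""
    kept = [r for r in records if r.domain == "Bacteria"]
    if len(kept) != len(records):
        log.info("dropped %d non-bacterial MAGs", len(records) - len(kept))
    return kept


class AniMatrix:
    """Symmetric pairwise average-nucleotide-identity matrix in percent.

    Validates symmetry (to 1e-9) and an exact 100 diagonal on construction.
    """

    def __init__(self, values: pd.DataFrame):
        if list(values.index) != list(values.columns):
            raise ValueError("ANI matrix rows and columns must match")
        arr = values.to_numpy(dtype=float)
        if not np.allclose(arr, arr.T, atol=1e-9):
            raise ValueError("ANI matrix is not symmetric")
        if not np.all(np.diag(arr) == 100.0):
            raise ValueError("ANI matrix diagonal must be exactly 100")
        if arr.min() < 0 or arr.max() > 100:
            raise ValueError("ANI values must lie in [0, 100]")
        self.values = values.astype(float)
        self.mag_ids = list(values.index)

    def get(self, a: str, b: str) -> float:
        try:
            return float(self.values.at[a, b])
        except KeyError as exc:
            raise KeyError(f"missing ANI entry for pair ({a}, {b})") from exc

    @classmethod
    def from_tsv(cls, path) -> "AniMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t")


@dataclass
class DereplicationResult:
    """Partition of MAGs into ANI clusters with one representative each."""

    clusters: dict[str, list[str]]  # representative -> members (incl. itself)

    @property
    def representatives(self) -> list[str]:
        return list(self.clusters)

    @property
    def members(self) -> list[str]:
        return [m for ms in self.clusters.values() for m in ms]


def dereplicate(
    records: Sequence[MagRecord],
    ani: AniMatrix,
    threshold: float = 96.5,
    scope: Callable[[MagRecord], object] | None = None,
) -> DereplicationResult:
    """Greedy centroid clustering of MAGs at an ANI threshold.

    Within each scope cell, MAGs are ranked by (quality desc, completeness
    desc, id asc); the best unassigned MAG becomes a representative and every
    unassigned MAG with ANI >= threshold joins its cluster.  ``scope`` maps a
    record to its grouping key (e.g. host species); ``None`` clusters all
    records together.
    """
    for r in records:
        if r.mag_id not in ani.values.index:
            raise KeyError(f"missing ANI entry for pair ({r.mag_id}, *)")
    cells: dict[object, list[MagRecord]] = {}
    for r in records:
        cells.setdefault(scope(r) if scope else None, []).append(r)
    clusters: dict[str, list[str]] = {}
    for key in cells:
        ranked = sorted(
            cells[key], key=lambda r: (-r.quality, -r.completeness, r.mag_id)
        )
        unassigned = list(ranked)
        while unassigned:
            rep = unassigned.pop(0)
            members = [rep.mag_id]
            rest = []
            for r in unassigned:
                if ani.get(rep.mag_id, r.mag_id) >= threshold:
                    members.append(r.mag_id)
                else:
                    rest.append(r)
            unassigned = rest
            clusters[rep.mag_id] = members
    log.info(
        "dereplicate: %d MAGs -> %d clusters at ANI >= %g",
        len(records), len(clusters), threshold,
    )
    return DereplicationResult(clusters=clusters)


def sharing_summary(
    presence: pd.DataFrame,
    regions: Mapping[str, str] | None = None,
    detection_threshold: float = 0.0,
) -> dict[str, float]:
    """Cross-host sharing percentages from a MAG x host-species table.

    ``presence`` may be boolean or an abundance table; abundances above
    ``detection_threshold`` count as present.  Returns the percent of MAGs
    present in exactly one species, in at least half (ceil(n/2)) of the
    species, and — when a MAG -> region mapping is given — the percent unique
    to one region and present in all regions.
    """
    if presence.empty:
        raise ValueError("empty presence matrix")
    present = presence.astype(float) > detection_threshold
    n_species = present.shape[1]
    counts = present.sum(axis=1)
    half = math.ceil(n_species / 2)
    out = {
        "pct_unique_species": float((counts == 1).mean() * 100),
        "pct_in_half_species": float((counts >= half).mean() * 100),
    }
    if regions is not None:
        region_of = pd.Series(dict(regions))
        all_regions = sorted(set(region_of))
        # a MAG's regions = regions of the species in which it is present
        n_reg, n_all = 0, 0
        for mag in present.index:
            hit = {region_of[sp] for sp in present.columns[present.loc[mag]]}
            if len(hit) == 1:
                n_reg += 1
            if hit == set(all_regions):
                n_all += 1
        out["pct_unique_region"] = 100.0 * n_reg / len(present)
        out["pct_all_regions"] = 100.0 * n_all / len(present)
    return out
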