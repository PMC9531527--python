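"""Run configuration: every tunable threshold of the pipeline in one place.

A config file is a flat YAML mapping mirroring :class:`RunConfig`; values on
the command line of the analysis scripts override file values.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import yaml

log = logging.getLogger("spongemag")


@dataclass
class RunConfig:
    """Tunable thresholds with their pipeline-wide defaults.

    Attributes
    ----------
    quality_cutoff:
        Minimum MAG quality score (completeness - 5 x contamination).
    min_completeness:
        Minimum genome completeness percentage for MAG retention.
    ani_threshold:
        Average nucleotide identity (%) above which two MAGs are collapsed
        during dereplication.
    n_permutations:
        Monte-Carlo iterations for the permutational tests.
    alpha:
        Adjusted-p significance cutoff for enrichment calls.
    prevalence_threshold:
        A feature present in less than this fraction of MAGs in *both*
        groups is excluded from testing.
    min_mags_per_category:
        Minimum MAGs per life-history category for a taxon-stratified run.
    min_qual:
        Minimum phred-scaled QUAL for a variant to be retained.
    depth_multiplier:
        Variants with read depth above ``depth_multiplier x mean depth`` are
        discarded as anomalous.
    support_threshold:
        Minimum tree-wide mean ultrafast-bootstrap support (%) for a gene to
        enter the omega background distribution.
    bh_family:
        Benjamini-Hochberg denominator: "all_features" uses the full feature
        count of the annotation category, "tested" only the features that
        survived the prevalence filter.
    test_statistic:
        "welch" (default), "student", or "meandiff" for the two-sample
        permutation test.
    paired_variability:
        If True the gene-vs-baseline diversity comparison uses the paired
        sign-flip design; if False, the plain two-sample permutation test.
    rng_seed:
        Master seed; all per-feature randomness derives from it.
    """

    quality_cutoff: float = 40.0
    min_completeness: float = 85.0
    ani_threshold: float = 96.5
    n_permutations: int = 10_000
    alpha: float = 0.01
    prevalence_threshold: float = 0.10
    min_mags_per_category: int = 10
    min_qual: float = 20.0
    depth_multiplier: float = 2.0
    support_threshold: float = 70.0
    bh_family: str = "all_features"
    test_statistic: str = "welch"
    paired_variability: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("min_completeness", "ani_threshold", "support_threshold"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name}={v} outside [0, 100]")
        if not 0 < self.alpha <= 1:
            raise ValueError(f"alpha={self.alpha} outside (0, 1]")
        if not 0 <= self.prevalence_threshold <= 1:
            raise ValueError(
                f"prevalence_threshold={self.prevalence_threshold} outside [0, 1]"
            )
        for name in ("n_permutations", "min_mags_per_category"):
            v = getattr(self, name)
            if v < 1:
                raise ValueError(f"{name}={v} must be >= 1")
        if self.min_qual < 0:
            raise ValueError("min_qual must be non-negative")
        if self.depth_multiplier <= 0:
            raise ValueError("depth_multiplier must be positive")
        if self.bh_family not in ("all_features", "tested"):
            raise ValueError(f"unknown bh_family {self.bh_family!r}")
        if self.test_statistic not in ("welch", "student", "meandiff"):
            raise ValueError(f"unknown test_statistic {self.test_statistic!r}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a flat key/value YAML config; keyword overrides win."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a flat mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        data.update(overrides)
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def setup_logging(level: int = logging.INFO) -> None:
    """Console logging for the analysis scripts."""
    logging.basicConfig(
        level=level, format="%(asctime)s %(name)s %(levelname)s: %(message)s"
    )
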