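"""Analysis configuration and deterministic random-stream management.

A single global seed is supplied per run; every stochastic stage derives an
independent child generator from it, keyed by a stage label, so that adding,
removing or reordering stages never perturbs the random numbers any other
stage sees.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

# High-recombination (crossover rate > 0.5 cM/Mb) intervals per chromosome
# arm, in base pairs.  Blocks used to build the F_ST permutation null are
# restricted to these regions.
DEFAULT_ARM_INTERVALS: dict[str, tuple[int, int]] = {
    "X": (2_300_000, 21_400_000),
    "2L": (500_000, 17_500_000),
    "2R": (5_200_000, 20_800_000),
    "3L": (600_000, 17_700_000),
    "3R": (6_900_000, 26_600_000),
}

CHROM_ARMS = ("X", "2L", "2R", "3L", "3R")


@dataclass
class AnalysisConfig:
    """Tunable parameters shared across pipeline stages.

    Parameters
    ----------
    pst_outlier_quantile : float
        Upper-tail fraction of the P_ST distribution called as outliers.
    min_total_counts : int
        A feature is retained only if its summed raw counts across all
        within-population samples of a stage strictly exceed this value.
    bootstrap_reps : int
        Resampling replicates for the cis/trans confidence intervals.
    permutation_reps : int
        Draws for every permutation null distribution.
    seed : int
        Global seed; all stage generators derive from it.
    focal_flank_bp : int
        Flank added on each side of a gene span to form its focal region
        for the F_ST maxima scan.
    window_site_count : int
        Non-singleton variable sites (in the reference population) per
        F_ST window.
    arm_intervals : dict
        Per-arm high-recombination intervals (bp) used as the permutation
        mask for F_ST outlier calling.
    """

    pst_outlier_quantile: float = 0.05
    min_total_counts: int = 200
    bootstrap_reps: int = 1000
    permutation_reps: int = 10_000
    seed: int = 0
    focal_flank_bp: int = 2000
    window_site_count: int = 250
    arm_intervals: dict = field(
        default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_ARM_INTERVALS.items()}
    )
    normalize_median_ratio: bool = True
    trim_extremes: bool = True

    def __post_init__(self) -> None:
        self.arm_intervals = {k: tuple(v) for k, v in self.arm_intervals.items()}
        if not (0.0 < self.pst_outlier_quantile <= 0.5):
            raise ValueError("pst_outlier_quantile must be in (0, 0.5]")
        for name in ("min_total_counts", "bootstrap_reps", "permutation_reps",
                     "focal_flank_bp", "window_site_count"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def child_rng(seed: int, label: str) -> np.random.Generator:
    """Independent generator for one named stochastic stage.

    The stage label is hashed (CRC-32) into the seed sequence, so streams
    for distinct labels are statistically independent and a stage always
    receives the same stream for a given global seed, regardless of what
    other stages run.
    """
    key = zlib.crc32(label.encode("utf8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))
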