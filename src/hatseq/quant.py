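"""Quantification of somatic L1Hs load and spike-in performance modelling.

Somatic insertion content is measured relative to germline insertions
from the same library (same primer, same amplification), which cancels
library-depth effects; the per-cell insertion rate then follows from the
known germline KNR copy number of the individual (KNRs are almost all
heterozygous, so the KNR insertion count is taken as the per-cell copy
number).  The spike-in dilution series is modelled by Poisson sampling
of insertion copies at the ~3,000-cell library input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .simdata import SpikeInDesign

__all__ = [
    "SampleLibrary",
    "RateEstimate",
    "relative_somatic_content",
    "somatic_rate_per_cell",
    "expected_sampled_insertions",
    "spike_lambda",
    "expected_per_cell_rate",
    "sensitivity",
    "precision_lower_bound",
    "min_detectable_mosaicism",
    "group_rates",
]


@dataclass
class SampleLibrary:
    """Per-sample read-count ledger for normalisation and rate estimation."""

    sample: str
    individual: str
    tissue_class: str  # brain | non_brain
    reads_somatic: int = 0
    reads_knr: int = 0
    reads_kr: int = 0
    reads_unk: int = 0
    knr_count: int = 0  # germline KNR insertions (per-cell copy proxy)
    input_cells: int = 3000

    def __post_init__(self) -> None:
        for name in ("reads_somatic", "reads_knr", "reads_kr", "reads_unk",
                     "knr_count", "input_cells"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class RateEstimate:
    mean: float
    sem: float
    ci: tuple[float, float]
    minimum: float
    maximum: float
    n: int


def relative_somatic_content(library: SampleLibrary, normalizer: str = "KNR") -> float:
    """Somatic-to-germline read-count ratio for one library."""
    denom = {"KNR": library.reads_knr, "KR": library.reads_kr,
             "UNK": library.reads_unk}[normalizer]
    if denom <= 0:
        raise ValueError(f"zero {normalizer} read count")
    return library.reads_somatic / denom


def somatic_rate_per_cell(library: SampleLibrary) -> float:
    """Somatic insertions per cell: (somatic/KNR read ratio) x KNR count.

    Scale-invariant in the read counts; requires a known germline KNR
    insertion count for the individual.
    """
    if library.reads_knr <= 0:
        raise ValueError("zero KNR read count")
    return relative_somatic_content(library, "KNR") * library.knr_count


def spike_lambda(design: SpikeInDesign) -> float:
    """Copies of each donor-specific insertion in the diluted input."""
    return design.lam


def expected_per_cell_rate(design: SpikeInDesign) -> float:
    """Expected spiked-in insertions per cell of library input."""
    return design.n_sites * design.dilution_fraction * design.copies_per_cell


def expected_sampled_insertions(n_sites: int, lam: float) -> float:
    """Expected number of sites with >= 1 sampled copy: N(1 - e^-lambda)."""
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    return n_sites * (1.0 - math.exp(-lam))


def sensitivity(identified: int, expected_sampled: float) -> float:
    """Identified sites over the expected number of sampled sites."""
    if expected_sampled <= 0:
        raise ValueError("expected sampled count must be > 0")
    return identified / expected_sampled


def precision_lower_bound(total_candidates: int, n_libraries: int,
                          fp_per_library_bound: int) -> float:
    """Cohort-level precision lower bound from a per-library false-positive
    ceiling: (total - n_libraries * bound) / total, clamped at 0."""
    if total_candidates <= 0:
        raise ValueError("no candidates")
    numerator = total_candidates - n_libraries * fp_per_library_bound
    if numerator < 0:
        import warnings
        warnings.warn("false-positive bound exceeds candidate count; clamping to 0")
        return 0.0
    return numerator / total_candidates


def min_detectable_mosaicism(signal_min: int, input_cells: int) -> float:
    """Smallest detectable cell fraction given a minimum signal count."""
    if input_cells <= 0:
        raise ValueError("input_cells must be > 0")
    return signal_min / input_cells


def _estimate(values: np.ndarray) -> RateEstimate:
    n = len(values)
    mean = float(np.mean(values))
    if n > 1 and np.std(values) > 0:
        sem = float(stats.sem(values))
        lo, hi = stats.t.interval(0.95, n - 1, loc=mean, scale=sem)
    else:
        sem, lo, hi = 0.0, mean, mean
    return RateEstimate(mean=mean, sem=sem, ci=(float(lo), float(hi)),
                        minimum=float(np.min(values)), maximum=float(np.max(values)), n=n)


def group_rates(rates: pd.DataFrame, cohort_col: Optional[str] = None):
    """Group-level summaries of per-cell somatic insertion rates.

    ``rates`` needs columns ``individual``, ``tissue_class`` and ``rate``
    (plus ``cohort_col`` for per-cohort summaries).  Returns per-group
    :class:`RateEstimate` objects (mean, S.E.M., t-based 95% CI with n-1
    degrees of freedom, min, max) and a two-sided paired t-test on the
    per-individual brain minus non-brain differences; individuals missing
    either tissue are excluded from the paired test with a warning.
    """
    groups: dict[str, RateEstimate] = {}
    for tissue, grp in rates.groupby("tissue_class"):
        groups[tissue] = _estimate(grp["rate"].to_numpy(float))
        if cohort_col:
            for cohort, sub in grp.groupby(cohort_col):
                groups[f"{cohort}_{tissue}"] = _estimate(sub["rate"].to_numpy(float))
    wide = rates.pivot_table(index="individual", columns="tissue_class",
                             values="rate", aggfunc="mean")
    paired = None
    if {"brain", "non_brain"} <= set(wide.columns):
        complete = wide.dropna(subset=["brain", "non_brain"])
        if len(complete) < len(wide):
            import warnings
            warnings.warn("unpaired individuals excluded from the paired test")
        if len(complete) >= 2:
            t, p = stats.ttest_rel(complete["brain"], complete["non_brain"])
            paired = {"t": float(t), "p_value": float(p), "n": int(len(complete)),
                      "mean_difference": float((complete["brain"] - complete["non_brain"]).mean())}
    return {"groups": groups, "paired_test": paired}
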