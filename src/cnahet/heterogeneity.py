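"""Intrapatient intermetastatic CNA heterogeneity estimators.

Four per-patient scores are provided, all symmetric in lesion order:

* ``het_euclidean`` — mean pairwise Euclidean distance between the
  lesions' region-level copy-number vectors;
* ``het_correlation`` — mean pairwise Pearson correlation distance
  (1 - r), in [0, 2];
* ``het_discordant_fraction`` — among genes aberrant in at least one
  lesion, the fraction whose ternary call is not identical across all
  lesions (amplitude differences with agreeing calls count as
  concordant);
* ``het_variance_filtered`` — mean pairwise Euclidean distance over
  regions whose across-lesion variance exceeds a threshold (default
  0.03), the legacy variance-filtered variant.

Missing regions are handled pairwise-complete; a lesion pair sharing
fewer than ``min_shared_regions`` regions is refused with a status
rather than silently scored.  Scores are dichotomized at the cohort
median (strictly above the median is "high").
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .harmonize import CallMatrix, GeneCallResult, RegionMatrix

OK = "ok"
UNDEFINED = "undefined"

DEFAULT_VARIANCE_THRESHOLD = 0.03
MIN_SHARED_REGIONS = 10

MEASURES = ("euclidean", "correlation", "discordant", "variance_filtered")


@dataclass
class ScoreStatus:
    value: float  # NaN when undefined
    status: str  # "ok" | "undefined"
    detail: str = ""

    def __float__(self) -> float:
        return self.value


@dataclass
class HeterogeneityResult:
    """All four heterogeneity scores for one patient."""

    patient_id: str
    n_lesions: int
    euclidean_score: ScoreStatus
    correlation_score: ScoreStatus
    discordant_fraction: ScoreStatus
    variance_filtered_score: ScoreStatus


def _mean_pairwise_euclidean(
    values: np.ndarray,
    lengths: np.ndarray | None = None,
    length_weighted: bool = False,
    min_shared: int = MIN_SHARED_REGIONS,
) -> ScoreStatus:
    n_regions, n_lesions = values.shape
    if n_lesions < 2:
        return ScoreStatus(np.nan, UNDEFINED, "fewer than 2 lesions")
    if length_weighted and lengths is None:
        raise ValueError("length_weighted mode requires region lengths")
    dists = []
    for i, j in combinations(range(n_lesions), 2):
        mask = ~np.isnan(values[:, i]) & ~np.isnan(values[:, j])
        if mask.sum() < min_shared:
            return ScoreStatus(
                np.nan, UNDEFINED, f"a lesion pair shares < {min_shared} regions"
            )
        diff = values[mask, i] - values[mask, j]
        if length_weighted:
            # base-pair fractions of the shared footprint: the score is
            # then independent of how the footprint is partitioned
            w = np.asarray(lengths, float)[mask]
            w = w / w.sum()
        else:
            w = np.ones(mask.sum())
        dists.append(float(np.sqrt(np.sum(w * diff**2))))
    return ScoreStatus(float(np.mean(dists)), OK)


def het_euclidean(
    matrix: RegionMatrix,
    length_weighted: bool = False,
    min_shared: int = MIN_SHARED_REGIONS,
) -> ScoreStatus:
    """Mean pairwise Euclidean distance among one patient's lesions."""
    return _mean_pairwise_euclidean(
        matrix.values, matrix.lengths, length_weighted, min_shared
    )


def het_correlation(
    matrix: RegionMatrix, min_shared: int = MIN_SHARED_REGIONS
) -> ScoreStatus:
    """Mean pairwise Pearson correlation distance (1 - r)."""
    values = matrix.values
    n_lesions = values.shape[1]
    if n_lesions < 2:
        return ScoreStatus(np.nan, UNDEFINED, "fewer than 2 lesions")
    dists = []
    for i, j in combinations(range(n_lesions), 2):
        mask = ~np.isnan(values[:, i]) & ~np.isnan(values[:, j])
        if mask.sum() < min_shared:
            return ScoreStatus(
                np.nan, UNDEFINED, f"a lesion pair shares < {min_shared} regions"
            )
        x, y = values[mask, i], values[mask, j]
        if np.std(x) == 0 or np.std(y) == 0:
            continue  # r undefined for a constant profile
        if np.array_equal(x, y):
            dists.append(0.0)  # identical vectors: exactly r = 1
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        dists.append(1.0 - r)
    if not dists:
        return ScoreStatus(np.nan, UNDEFINED, "all lesion pairs had a constant profile")
    return ScoreStatus(float(np.mean(dists)), OK)


def het_discordant_fraction(
    gene_calls: pd.DataFrame,
) -> ScoreStatus:
    """Fraction of aberrant genes not aberrant identically in all lesions.

    ``gene_calls``: genes x lesions ternary call frame for one patient.
    Denominator: genes with a nonzero call in at least one lesion.
    Numerator: those whose calls are not identical across all lesions
    (a missing call in any lesion keeps the gene out of both counts).
    """
    if gene_calls.shape[1] < 2:
        return ScoreStatus(np.nan, UNDEFINED, "fewer than 2 lesions")
    arr = gene_calls.to_numpy(dtype=float)
    complete = ~np.isnan(arr).any(axis=1)
    arr = arr[complete]
    aberrant = (arr != 0).any(axis=1)
    denom = int(aberrant.sum())
    if denom == 0:
        return ScoreStatus(np.nan, UNDEFINED, "no aberrant genes")
    rows = arr[aberrant]
    discordant = (rows.min(axis=1) != rows.max(axis=1)).sum()
    return ScoreStatus(float(discordant) / denom, OK)


def het_variance_filtered(
    matrix: RegionMatrix,
    variance_threshold: float = DEFAULT_VARIANCE_THRESHOLD,
    length_weighted: bool = False,
    min_shared: int = 1,
) -> ScoreStatus:
    """Mean pairwise Euclidean distance over high-variance regions.

    Regions whose across-lesion variance is <= ``variance_threshold``
    are dropped first; when no region survives, the score is 0 with an
    explanatory status.
    """
    if variance_threshold < 0:
        raise ValueError("variance_threshold must be non-negative")
    values = matrix.values
    if values.shape[1] < 2:
        return ScoreStatus(np.nan, UNDEFINED, "fewer than 2 lesions")
    with np.errstate(invalid="ignore"):
        known = (~np.isnan(values)).sum(axis=1)
        var = np.full(values.shape[0], np.nan)
        rows = known >= 2
        var[rows] = np.nanvar(values[rows], axis=1, ddof=1)
    keep = var > variance_threshold
    if not keep.any():
        return ScoreStatus(0.0, OK, "no region exceeded the variance threshold")
    sub = values[keep]
    lengths = matrix.lengths[keep]
    return _mean_pairwise_euclidean(sub, lengths, length_weighted, min_shared)


def dichotomize_by_median(scores: pd.Series) -> pd.Series:
    """Label each patient high/low against the cohort median.

    Strictly above the median is ``high``; at or below is ``low``;
    undefined (NaN) scores are labelled ``missing`` and excluded from
    the median.
    """
    defined = scores.dropna()
    if len(defined) < 2:
        raise ValueError("need >= 2 patients with defined scores")
    median = float(defined.median())
    labels = pd.Series("missing", index=scores.index, dtype=object)
    labels[defined.index] = np.where(defined > median, "high", "low")
    labels.name = scores.name
    return labels


def compare_heterogeneity_estimators(scores: pd.DataFrame) -> pd.DataFrame:
    """Spearman rank-correlation matrix among the score columns."""
    if len(scores.dropna()) < 3:
        raise ValueError("need >= 3 patients with all measures defined")
    return scores.corr(method="spearman")


def cohort_heterogeneity(
    matrix: RegionMatrix,
    gene_calls: GeneCallResult | None = None,
    variance_threshold: float = DEFAULT_VARIANCE_THRESHOLD,
    length_weighted: bool = False,
) -> pd.DataFrame:
    """Per-patient table of all four scores plus high/low labels.

    Patients with fewer than two lesions are skipped.  The discordant
    fraction requires gene-level calls and is NaN when absent.
    """
    patients = list(dict.fromkeys(matrix.patient_ids))
    rows = []
    for patient in patients:
        sub = matrix.subset_patient(patient)
        if sub.n_lesions < 2:
            continue
        eu = het_euclidean(sub, length_weighted=length_weighted)
        co = het_correlation(sub)
        vf = het_variance_filtered(
            sub, variance_threshold=variance_threshold, length_weighted=length_weighted
        )
        if gene_calls is not None:
            lesions = [
                l for l, p in gene_calls.patient_of_lesion.items() if p == patient
            ]
            df = het_discordant_fraction(gene_calls.calls[lesions])
        else:
            df = ScoreStatus(np.nan, UNDEFINED, "no gene calls supplied")
        rows.append(
            {
                "patient_id": patient,
                "n_lesions": sub.n_lesions,
                "euclidean": eu.value,
                "correlation": co.value,
                "discordant": df.value,
                "variance_filtered": vf.value,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["patient_id", "n_lesions"] + list(MEASURES),
    ).set_index("patient_id")
    for measure in MEASURES:
        col = table[measure]
        if col.notna().sum() >= 2:
            table[f"{measure}_label"] = dichotomize_by_median(col)
        else:
            table[f"{measure}_label"] = "missing"
    return table
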