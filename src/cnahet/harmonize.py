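"""Multi-sample segment harmonization, gain/loss calling, and CNA burden.

Per-lesion segmentations are split at the union of all breakpoints in
the cohort ("smallest regions of overlap"), giving a region x lesion
copy-number matrix on which all lesions are position-wise comparable.
Gains and losses are then called per lesion relative to its median
genome-wide copy number (length-weighted median of segment values), and
CNA burden is the percentage of covered base pairs with a non-neutral
call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import GeneInterval, LesionProfile, _chrom_sort_key

logger = logging.getLogger(__name__)


@dataclass
class RegionMatrix:
    """Harmonized region x lesion copy numbers.

    ``values[i, j]`` is the copy number of lesion ``j`` over region
    ``i``, or NaN where that lesion has no segment.  Regions are
    non-overlapping, sorted, and jointly cover the union of all input
    segment footprints.
    """

    chromosomes: np.ndarray  # object array of str
    starts: np.ndarray  # int64
    ends: np.ndarray  # int64
    values: np.ndarray  # float64, shape (n_regions, n_lesions)
    lesion_ids: list[str]
    patient_ids: list[str]
    ploidies: np.ndarray = field(default=None)  # float64 per lesion, NaN if absent

    def __post_init__(self) -> None:
        if self.ploidies is None:
            self.ploidies = np.full(len(self.lesion_ids), np.nan)

    @property
    def lengths(self) -> np.ndarray:
        return self.ends - self.starts

    @property
    def n_regions(self) -> int:
        return len(self.starts)

    @property
    def n_lesions(self) -> int:
        return len(self.lesion_ids)

    def lesion_index(self, lesion_id: str) -> int:
        return self.lesion_ids.index(lesion_id)

    def subset_patient(self, patient_id: str) -> "RegionMatrix":
        """Restrict columns to one patient's lesions."""
        cols = [i for i, p in enumerate(self.patient_ids) if p == patient_id]
        if not cols:
            raise KeyError(f"no lesions for patient {patient_id!r}")
        return RegionMatrix(
            chromosomes=self.chromosomes,
            starts=self.starts,
            ends=self.ends,
            values=self.values[:, cols],
            lesion_ids=[self.lesion_ids[i] for i in cols],
            patient_ids=[self.patient_ids[i] for i in cols],
            ploidies=self.ploidies[cols],
        )

    def region_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chromosome": self.chromosomes, "start": self.starts, "end": self.ends}
        )

    def to_frame(self) -> pd.DataFrame:
        values = pd.DataFrame(self.values, columns=self.lesion_ids)
        return pd.concat([self.region_frame(), values], axis=1)


@dataclass
class CallMatrix:
    """Ternary gain/neutral/loss calls on the harmonized region grid.

    ``calls`` holds -1/0/+1 as floats with NaN for missing.  A call is
    +1 iff ``value - baseline >= gain_threshold`` and -1 iff
    ``value - baseline <= loss_threshold`` (closed comparisons).
    """

    chromosomes: np.ndarray
    starts: np.ndarray
    ends: np.ndarray
    calls: np.ndarray  # float64 in {-1, 0, 1, nan}
    baselines: np.ndarray  # per-lesion median genome-wide copy number
    gain_threshold: float
    loss_threshold: float
    lesion_ids: list[str]
    patient_ids: list[str]

    @property
    def lengths(self) -> np.ndarray:
        return self.ends - self.starts

    def subset_patient(self, patient_id: str) -> "CallMatrix":
        cols = [i for i, p in enumerate(self.patient_ids) if p == patient_id]
        if not cols:
            raise KeyError(f"no lesions for patient {patient_id!r}")
        return CallMatrix(
            chromosomes=self.chromosomes,
            starts=self.starts,
            ends=self.ends,
            calls=self.calls[:, cols],
            baselines=self.baselines[cols],
            gain_threshold=self.gain_threshold,
            loss_threshold=self.loss_threshold,
            lesion_ids=[self.lesion_ids[i] for i in cols],
            patient_ids=[self.patient_ids[i] for i in cols],
        )

    def to_frame(self) -> pd.DataFrame:
        regions = pd.DataFrame(
            {"chromosome": self.chromosomes, "start": self.starts, "end": self.ends}
        )
        calls = pd.DataFrame(self.calls, columns=self.lesion_ids)
        return pd.concat([regions, calls], axis=1)


@dataclass
class BurdenResult:
    """CNA burden (percent of covered base pairs aberrant)."""

    per_lesion: pd.Series  # index lesion_id
    per_patient: pd.Series  # index patient_id, mean over lesions


def harmonize(profiles: Sequence[LesionProfile]) -> RegionMatrix:
    """Split sample-wise segments into the smallest regions of overlap.

    Breakpoints are the union of every segment start and end over all
    lesions; candidate intervals not covered by any lesion are dropped,
    so the region footprint equals the union of input footprints.  The
    operation is idempotent and preserves each lesion's covered length.
    """
    if not profiles:
        raise ValueError("harmonize requires at least one profile")

    lesion_ids = [p.lesion_id for p in profiles]
    if len(set(lesion_ids)) != len(lesion_ids):
        raise ValueError("duplicate lesion ids")
    patient_ids = [p.patient_id for p in profiles]
    ploidies = np.array(
        [np.nan if p.ploidy is None else float(p.ploidy) for p in profiles]
    )

    chroms = sorted(
        {s.chromosome for p in profiles for s in p.segments}, key=_chrom_sort_key
    )
    out_chrom: list[str] = []
    out_start: list[int] = []
    out_end: list[int] = []
    out_vals: list[np.ndarray] = []

    for chrom in chroms:
        bps: set[int] = set()
        per_lesion: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
        for p in profiles:
            segs = [s for s in p.segments if s.chromosome == chrom]
            starts = np.array([s.start for s in segs], dtype=np.int64)
            ends = np.array([s.end for s in segs], dtype=np.int64)
            vals = np.array([s.copy_number for s in segs])
            per_lesion.append((starts, ends, vals))
            bps.update(starts.tolist())
            bps.update(ends.tolist())
        grid = np.array(sorted(bps), dtype=np.int64)
        reg_start, reg_end = grid[:-1], grid[1:]
        n_reg = len(reg_start)
        vals_block = np.full((n_reg, len(profiles)), np.nan)
        for j, (starts, ends, vals) in enumerate(per_lesion):
            if len(starts) == 0:
                continue
            # index of the segment whose start is <= region start
            idx = np.searchsorted(starts, reg_start, side="right") - 1
            ok = (idx >= 0) & (reg_start < ends[np.clip(idx, 0, None)])
            vals_block[ok, j] = vals[idx[ok]]
        covered = ~np.all(np.isnan(vals_block), axis=1)
        out_chrom += [chrom] * int(covered.sum())
        out_start += reg_start[covered].tolist()
        out_end += reg_end[covered].tolist()
        out_vals.append(vals_block[covered])

    values = (
        np.vstack(out_vals) if out_vals else np.empty((0, len(profiles)))
    )
    return RegionMatrix(
        chromosomes=np.array(out_chrom, dtype=object),
        starts=np.array(out_start, dtype=np.int64),
        ends=np.array(out_end, dtype=np.int64),
        values=values,
        lesion_ids=lesion_ids,
        patient_ids=patient_ids,
        ploidies=ploidies,
    )


def weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Weighted median, matching ``np.median`` on unit-expanded data."""
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.size == 0 or weights.sum() <= 0:
        raise ValueError("weighted_median needs positive total weight")
    order = np.argsort(values, kind="stable")
    values, weights = values[order], weights[order]
    cum = np.cumsum(weights)
    half = cum[-1] / 2.0
    idx = int(np.searchsorted(cum, half, side="left"))
    if cum[idx] == half and idx + 1 < len(values):
        return 0.5 * (values[idx] + values[idx + 1])
    return float(values[idx])


def lesion_baseline(profile: LesionProfile) -> float:
    """Median genome-wide copy number: length-weighted median of segments."""
    values = np.array([s.copy_number for s in profile.segments])
    lengths = np.array([s.length for s in profile.segments], dtype=float)
    return weighted_median(values, lengths)


def matrix_baselines(matrix: RegionMatrix) -> np.ndarray:
    """Per-lesion length-weighted median over non-missing regions."""
    lengths = matrix.lengths.astype(float)
    out = np.empty(matrix.n_lesions)
    for j in range(matrix.n_lesions):
        mask = ~np.isnan(matrix.values[:, j])
        out[j] = weighted_median(matrix.values[mask, j], lengths[mask])
    return out


def call_aberrations(
    matrix: RegionMatrix,
    gain_threshold: float = 1.0,
    loss_threshold: float = -1.0,
) -> CallMatrix:
    """Call gains/losses relative to each lesion's median copy number."""
    if gain_threshold <= 0:
        raise ValueError("gain_threshold must be positive")
    if loss_threshold >= 0:
        raise ValueError("loss_threshold must be negative")
    baselines = matrix_baselines(matrix)
    delta = matrix.values - baselines[np.newaxis, :]
    calls = np.where(delta >= gain_threshold, 1.0, 0.0)
    calls = np.where(delta <= loss_threshold, -1.0, calls)
    calls[np.isnan(delta)] = np.nan
    return CallMatrix(
        chromosomes=matrix.chromosomes,
        starts=matrix.starts,
        ends=matrix.ends,
        calls=calls,
        baselines=baselines,
        gain_threshold=gain_threshold,
        loss_threshold=loss_threshold,
        lesion_ids=list(matrix.lesion_ids),
        patient_ids=list(matrix.patient_ids),
    )


def cna_burden(calls: CallMatrix) -> BurdenResult:
    """Percent of covered base pairs with aberrant copy number.

    Per lesion: 100 * (aberrant length) / (non-missing covered length).
    Per patient: arithmetic mean over that patient's lesions.
    """
    lengths = calls.lengths.astype(float)
    per_lesion = {}
    for j, lesion in enumerate(calls.lesion_ids):
        col = calls.calls[:, j]
        mask = ~np.isnan(col)
        denom = lengths[mask].sum()
        if denom <= 0:
            raise ValueError(f"lesion {lesion} has zero covered length")
        aberrant = lengths[mask & (col != 0)].sum()
        per_lesion[lesion] = 100.0 * aberrant / denom
    series = pd.Series(per_lesion, name="burden_percent")
    patient_of = pd.Series(calls.patient_ids, index=calls.lesion_ids)
    per_patient = series.groupby(patient_of).mean()
    per_patient.name = "burden_percent"
    return BurdenResult(per_lesion=series, per_patient=per_patient)


def ploidy_stats(ploidies: Sequence[float]) -> tuple[float, float]:
    """Patient-wise (median ploidy, ploidy range) over lesions."""
    arr = np.asarray(list(ploidies), dtype=float)
    if arr.size == 0 or np.any(np.isnan(arr)):
        raise ValueError("every lesion needs a ploidy estimate")
    return float(np.median(arr)), float(arr.max() - arr.min())


@dataclass
class GeneCallResult:
    """Gene-level ternary calls and per-patient heterogeneity flags.

    ``calls``: genes x lesions DataFrame of {-1, 0, 1, NaN}.
    ``heterogeneity``: genes x patients DataFrame of booleans, True when
    the gene's call differs among that patient's lesions.
    """

    calls: pd.DataFrame
    heterogeneity: pd.DataFrame
    patient_of_lesion: pd.Series


def gene_level_calls(
    calls: CallMatrix, genes: Sequence[GeneInterval]
) -> GeneCallResult:
    """Assign each gene the call of its largest-overlap region.

    Ties are broken toward the earlier region; a gene with no
    overlapping region gets NaN status with a warning.
    """
    region_idx = _assign_genes_to_regions(
        calls.chromosomes, calls.starts, calls.ends, genes
    )
    gene_names = [g.gene_name for g in genes]
    data = np.full((len(genes), len(calls.lesion_ids)), np.nan)
    for gi, ri in enumerate(region_idx):
        if ri >= 0:
            data[gi] = calls.calls[ri]
    n_orphan = int(np.sum(region_idx < 0))
    if n_orphan:
        logger.warning("gene_level_calls: %d genes overlap no region", n_orphan)
    frame = pd.DataFrame(data, index=gene_names, columns=calls.lesion_ids)

    het_cols = {}
    patient_of = pd.Series(calls.patient_ids, index=calls.lesion_ids)
    for patient in dict.fromkeys(calls.patient_ids):
        sub = frame.loc[:, patient_of[patient_of == patient].index]
        arr = sub.to_numpy()
        with np.errstate(invalid="ignore"):
            known = ~np.isnan(arr)
            mins = np.nanmin(np.where(known, arr, np.inf), axis=1)
            maxs = np.nanmax(np.where(known, arr, -np.inf), axis=1)
        any_known = known.any(axis=1)
        het_cols[patient] = np.where(any_known, mins != maxs, False)
    het = pd.DataFrame(het_cols, index=gene_names)
    return GeneCallResult(calls=frame, heterogeneity=het, patient_of_lesion=patient_of)


def _assign_genes_to_regions(
    chroms: np.ndarray,
    starts: np.ndarray,
    ends: np.ndarray,
    genes: Sequence[GeneInterval],
) -> np.ndarray:
    """Largest-overlap region index per gene (-1 when none overlaps)."""
    out = np.full(len(genes), -1, dtype=np.int64)
    by_chrom: dict[str, np.ndarray] = {}
    for chrom in np.unique(chroms.astype(str)):
        by_chrom[chrom] = np.flatnonzero(chroms == chrom)
    for gi, gene in enumerate(genes):
        idx = by_chrom.get(gene.chromosome)
        if idx is None:
            continue
        ov = np.minimum(ends[idx], gene.end) - np.maximum(starts[idx], gene.start)
        ov = np.clip(ov, 0, None)
        if ov.max(initial=0) <= 0:
            continue
        # ties toward the earlier region: argmax takes the first maximum
        out[gi] = idx[int(np.argmax(ov))]
    return out


def cohort_cna_frequency(calls: CallMatrix) -> pd.DataFrame:
    """Per-region gain/loss frequencies across patients.

    A patient contributes a gain in a region when at least one of their
    lesions carries a +1 call there, and a loss when at least one
    carries -1; a patient can contribute to both in the same region.
    """
    patients = list(dict.fromkeys(calls.patient_ids))
    if not patients:
        raise ValueError("no patients")
    gains = np.zeros(len(calls.starts))
    losses = np.zeros(len(calls.starts))
    for patient in patients:
        cols = [i for i, p in enumerate(calls.patient_ids) if p == patient]
        block = calls.calls[:, cols]
        with np.errstate(invalid="ignore"):
            gains += np.any(block == 1.0, axis=1)
            losses += np.any(block == -1.0, axis=1)
    out = pd.DataFrame(
        {
            "chromosome": calls.chromosomes,
            "start": calls.starts,
            "end": calls.ends,
            "gain_frequency": gains / len(patients),
            "loss_frequency": losses / len(patients),
        }
    )
    return out
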