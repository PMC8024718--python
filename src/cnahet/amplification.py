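"""High-level amplification detection and intermetastatic concordance.

Amplifications are measured in *additional copies*: copy number minus
the lesion's estimated ploidy.  A region is a high-level amplification
when any lesion of the patient carries at least ``high_level_threshold``
(default 15) additional copies; adjacent qualifying regions merge into
one event.  Per event, intrapatient concordance is classified from the
minimum over lesions:

* ``homogeneous`` — every lesion at or above the high-level threshold;
* ``intermediate_concordant`` — every lesion at or above the
  intermediate threshold (default 5 additional copies) but not all
  high-level;
* ``heterogeneous`` — at least one lesion below the intermediate
  threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .harmonize import RegionMatrix, matrix_baselines
from .io_formats import GeneInterval


@dataclass(frozen=True)
class AmpConfig:
    """Thresholds in additional copies relative to estimated ploidy."""

    high_level_threshold: float = 15.0
    intermediate_threshold: float = 5.0
    legacy_low_threshold: float = 6.0

    def __post_init__(self) -> None:
        if not self.high_level_threshold > self.intermediate_threshold > 0:
            raise ValueError("need high_level_threshold > intermediate_threshold > 0")


HOMOGENEOUS = "homogeneous"
INTERMEDIATE = "intermediate_concordant"
HETEROGENEOUS = "heterogeneous"


@dataclass
class AmpEvent:
    """One merged amplified region in one patient."""

    patient_id: str
    chromosome: str
    start: int
    end: int
    additional_copies: dict[str, float]  # lesion_id -> additional copies
    concordance_class: str | None = None
    genes: list[str] = field(default_factory=list)
    cancer_critical_genes: list[str] = field(default_factory=list)
    single_lesion: bool = False

    @property
    def copy_range(self) -> tuple[float, float]:
        vals = list(self.additional_copies.values())
        return (min(vals), max(vals))


def lesion_ploidies(matrix: RegionMatrix) -> np.ndarray:
    """Per-lesion ploidy: supplied estimate, else median-copy-number fallback."""
    ploidies = matrix.ploidies.copy()
    missing = np.isnan(ploidies)
    if missing.any():
        ploidies[missing] = matrix_baselines(matrix)[missing]
    return ploidies


def additional_copies(
    matrix: RegionMatrix, ploidies: np.ndarray | None = None
) -> np.ndarray:
    """Copy number minus lesion ploidy, unrounded, per (region, lesion)."""
    if ploidies is None:
        ploidies = lesion_ploidies(matrix)
    return matrix.values - np.asarray(ploidies, dtype=float)[np.newaxis, :]


def classify_concordance(
    per_lesion_additional_copies: Sequence[float],
    config: AmpConfig = AmpConfig(),
) -> str:
    """Concordance class from per-lesion additional copies of one event.

    Depends only on the minimum over lesions (the maximum already meets
    the high-level threshold by construction of the event).
    """
    vals = np.asarray(list(per_lesion_additional_copies), dtype=float)
    if vals.size == 0:
        raise ValueError("no lesions")
    low = vals.min()
    if low >= config.high_level_threshold:
        return HOMOGENEOUS
    if low >= config.intermediate_threshold:
        return INTERMEDIATE
    return HETEROGENEOUS


def detect_amplifications(
    matrix: RegionMatrix,
    config: AmpConfig = AmpConfig(),
    ploidies: np.ndarray | None = None,
) -> list[AmpEvent]:
    """Genome-wide search for high-level amplification events.

    ``matrix`` should hold one patient's lesions.  A region qualifies
    when any lesion reaches the high-level threshold; runs of
    coordinate-adjacent qualifying regions on one chromosome merge, and
    the merged event's per-lesion additional copies are the maxima over
    member regions.  Classification is attached; patients with a single
    lesion are classified homogeneous but flagged ``single_lesion``.
    """
    patients = set(matrix.patient_ids)
    if len(patients) != 1:
        raise ValueError("detect_amplifications expects a single-patient matrix")
    patient_id = next(iter(patients))
    addcp = additional_copies(matrix, ploidies)
    with np.errstate(invalid="ignore"):
        qualifies = np.any(addcp >= config.high_level_threshold, axis=1)
    idx = np.flatnonzero(qualifies)
    events: list[AmpEvent] = []
    if idx.size == 0:
        return events

    runs: list[list[int]] = [[int(idx[0])]]
    for i in idx[1:]:
        prev = runs[-1][-1]
        adjacent = (
            i == prev + 1
            and matrix.chromosomes[i] == matrix.chromosomes[prev]
            and matrix.starts[i] == matrix.ends[prev]
        )
        if adjacent:
            runs[-1].append(int(i))
        else:
            runs.append([int(i)])

    single = matrix.n_lesions < 2
    for run in runs:
        block = addcp[run, :]
        per_lesion = np.nanmax(block, axis=0)
        copies = {
            lesion: float(per_lesion[j])
            for j, lesion in enumerate(matrix.lesion_ids)
            if not np.isnan(per_lesion[j])
        }
        events.append(
            AmpEvent(
                patient_id=patient_id,
                chromosome=str(matrix.chromosomes[run[0]]),
                start=int(matrix.starts[run[0]]),
                end=int(matrix.ends[run[-1]]),
                additional_copies=copies,
                concordance_class=classify_concordance(list(copies.values()), config),
                single_lesion=single,
            )
        )
    return events


def annotate_cancer_genes(
    event: AmpEvent, genes: Sequence[GeneInterval]
) -> AmpEvent:
    """Attach genes overlapping the event region; flag the COSMIC subset."""
    hits = [
        g
        for g in genes
        if g.chromosome == event.chromosome
        and g.start < event.end
        and g.end > event.start
    ]
    return replace(
        event,
        genes=[g.gene_name for g in hits],
        cancer_critical_genes=[g.gene_name for g in hits if g.cancer_critical],
    )


def events_table(events: Sequence[AmpEvent]) -> pd.DataFrame:
    """Flatten events into the TSV-ready table layout."""
    rows = []
    for e in events:
        lo, hi = e.copy_range if e.additional_copies else (np.nan, np.nan)
        rows.append(
            {
                "patient_id": e.patient_id,
                "chromosome": e.chromosome,
                "start": e.start,
                "end": e.end,
                "min_additional_copies": lo,
                "max_additional_copies": hi,
                "genes": ",".join(e.genes),
                "cancer_critical_genes": ",".join(e.cancer_critical_genes),
                "concordance_class": e.concordance_class,
                "single_lesion": e.single_lesion,
            }
        )
    columns = [
        "patient_id",
        "chromosome",
        "start",
        "end",
        "min_additional_copies",
        "max_additional_copies",
        "genes",
        "cancer_critical_genes",
        "concordance_class",
        "single_lesion",
    ]
    return pd.DataFrame(rows, columns=columns)
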