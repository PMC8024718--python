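"""Patient-level mutation status aggregation and co-mutation grouping.

Lesion-level calls for KRAS, NRAS, BRAF (V600E) and TP53 are aggregated
per patient: any mutated lesion makes the patient mutated (intrapatient
heterogeneity is flagged but does not demote the status).  Patients are
then classified by the RAS/BRAF-TP53 co-mutation scheme:

* ``co_mut`` — RAS or BRAF mutated together with TP53 mutated;
* ``ras_braf_only`` — RAS or BRAF mutated, TP53 wild-type;
* ``tp53_only`` — TP53 mutated, RAS and BRAF wild-type;
* ``double_wt`` — all four genes wild-type.

KRAS, NRAS and BRAF V600E mutations are expected to be mutually
exclusive; violations are surfaced, not silently resolved.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .io_formats import MUTATION_GENES, PatientRecord

RAS_BRAF_GENES = ("KRAS", "NRAS", "BRAF")

CO_MUT = "co_mut"
RAS_BRAF_ONLY = "ras_braf_only"
TP53_ONLY = "tp53_only"
DOUBLE_WT = "double_wt"
GROUPS = (CO_MUT, RAS_BRAF_ONLY, TP53_ONLY, DOUBLE_WT)


@dataclass(frozen=True)
class GeneStatus:
    status: str  # mutated | wild-type | unknown
    heterogeneous: bool  # both mutated and wild-type calls among lesions


def patient_mutation_status(lesion_calls: Sequence[str]) -> GeneStatus:
    """Aggregate one gene's per-lesion calls to a patient status.

    Mutated if any lesion is mutated; wild-type if every known call is
    wild-type; unknown only when no lesion has a known call.
    """
    if not lesion_calls:
        raise ValueError("need at least one lesion call")
    has_mut = "mutated" in lesion_calls
    has_wt = "wild-type" in lesion_calls
    if has_mut:
        return GeneStatus("mutated", heterogeneous=has_wt)
    if has_wt:
        return GeneStatus("wild-type", heterogeneous=False)
    return GeneStatus("unknown", heterogeneous=False)


def classify_group(statuses: dict[str, str]) -> str | None:
    """Map per-gene patient statuses to a co-mutation group.

    Returns None when a defining gene is unresolved (TP53 unknown, or
    no RAS/BRAF gene mutated but not all known wild-type); such
    patients are excluded from group-stratified analyses.
    """
    ras_statuses = [statuses.get(g, "unknown") for g in RAS_BRAF_GENES]
    tp53 = statuses.get("TP53", "unknown")
    if "mutated" in ras_statuses:
        ras = "mutated"
    elif all(s == "wild-type" for s in ras_statuses):
        ras = "wild-type"
    else:
        ras = "unknown"
    if ras == "unknown" or tp53 == "unknown":
        return None
    if ras == "mutated" and tp53 == "mutated":
        return CO_MUT
    if ras == "mutated":
        return RAS_BRAF_ONLY
    if tp53 == "mutated":
        return TP53_ONLY
    return DOUBLE_WT


def exclusivity_check(records: Iterable[PatientRecord]) -> list[str]:
    """Patients carrying mutations in two or more of KRAS/NRAS/BRAF."""
    violators = []
    for rec in records:
        n_mut = sum(
            patient_mutation_status(rec.mutation_calls[g]).status == "mutated"
            for g in RAS_BRAF_GENES
            if rec.mutation_calls.get(g)
        )
        if n_mut >= 2:
            violators.append(rec.patient_id)
    return violators


def cohort_groups(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Per-patient gene statuses, heterogeneity flags, and group label."""
    rows = []
    for rec in records:
        row: dict[str, object] = {"patient_id": rec.patient_id}
        statuses: dict[str, str] = {}
        for gene in MUTATION_GENES:
            calls = rec.mutation_calls.get(gene)
            if calls:
                gs = patient_mutation_status(calls)
            else:
                gs = GeneStatus("unknown", False)
            statuses[gene] = gs.status
            row[f"{gene}_status"] = gs.status
            row[f"{gene}_heterogeneous"] = gs.heterogeneous
        group = classify_group(statuses)
        row["group"] = group if group is not None else "unresolved"
        rows.append(row)
    return pd.DataFrame(rows).set_index("patient_id")
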