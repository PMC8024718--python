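"""End-to-end pipeline: load -> harmonize -> call -> burden / heterogeneity
/ amplification -> mutation groups -> survival, with a run manifest.

Outputs are plain TSV tables plus a JSON manifest recording the tool
version, configuration hash, thresholds, and the nested analysis
denominators (all patients -> patients with >= 2 profiled lesions ->
MSS + R0/R1 patients).  Rerunning with identical inputs and config is
byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .amplification import (
    AmpConfig,
    annotate_cancer_genes,
    detect_amplifications,
    events_table,
)
from .harmonize import (
    call_aberrations,
    cna_burden,
    cohort_cna_frequency,
    gene_level_calls,
    harmonize,
    ploidy_stats,
)
from .heterogeneity import DEFAULT_VARIANCE_THRESHOLD, cohort_heterogeneity
from .io_formats import (
    check_cross_references,
    config_hash,
    read_gene_intervals,
    read_patient_table,
    read_segments,
)
from .mutation_groups import CO_MUT, cohort_groups, exclusivity_check
from .survival import (
    eligible,
    km_estimate,
    stratified_analysis,
    survival_frame,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    segments_path: str
    patients_path: str
    genes_path: str | None = None
    dialect: str = "absolute_cn"
    gain_threshold: float = 1.0
    loss_threshold: float = -1.0
    amp_high_threshold: float = 15.0
    amp_intermediate_threshold: float = 5.0
    variance_threshold: float = DEFAULT_VARIANCE_THRESHOLD
    length_weighted: bool = False
    heterogeneity_measure: str = "euclidean"  # feeds the survival strata
    survival_covariates: list[str] = field(default_factory=list)
    out_dir: str = "results"
    seed: int = 0

    def validate(self) -> None:
        if self.gain_threshold <= 0:
            raise ValueError("gain_threshold must be > 0")
        if self.loss_threshold >= 0:
            raise ValueError("loss_threshold must be < 0")
        if not self.amp_high_threshold > self.amp_intermediate_threshold > 0:
            raise ValueError("amplification thresholds out of order")
        if self.variance_threshold < 0:
            raise ValueError("variance_threshold must be >= 0")

    def analysis_params(self) -> dict:
        """Config without the output location (not part of the analysis)."""
        params = asdict(self)
        params.pop("out_dir")
        return params

    def hash(self) -> str:
        return config_hash(self.analysis_params())


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns the result bundle and writes TSVs.

    Fails before any computation when the inputs are cross-inconsistent
    (a lesion whose patient is absent from the patient table).
    """
    config.validate()
    records = read_patient_table(config.patients_path)
    lesion_to_patient = {
        lesion: rec.patient_id for rec in records for lesion in rec.lesion_ids
    }
    profiles = read_segments(
        config.segments_path, dialect=config.dialect, patient_map=lesion_to_patient
    )
    check_cross_references(profiles, records)
    genes = read_gene_intervals(config.genes_path) if config.genes_path else []

    matrix = harmonize(profiles)
    calls = call_aberrations(
        matrix, config.gain_threshold, config.loss_threshold
    )
    burden = cna_burden(calls)
    frequency = cohort_cna_frequency(calls)

    gene_calls = gene_level_calls(calls, genes) if genes else None
    het = cohort_heterogeneity(
        matrix,
        gene_calls,
        variance_threshold=config.variance_threshold,
        length_weighted=config.length_weighted,
    )

    amp_cfg = AmpConfig(
        high_level_threshold=config.amp_high_threshold,
        intermediate_threshold=config.amp_intermediate_threshold,
    )
    amp_events = []
    for patient in dict.fromkeys(matrix.patient_ids):
        for event in detect_amplifications(matrix.subset_patient(patient), amp_cfg):
            amp_events.append(annotate_cancer_genes(event, genes))
    amp_table = events_table(amp_events)

    groups = cohort_groups(records)
    violations = exclusivity_check(records)
    if violations:
        logger.warning("RAS/BRAF exclusivity violated by: %s", violations)

    # ploidy summaries per patient
    ploidy_rows = []
    for patient in dict.fromkeys(matrix.patient_ids):
        sub = matrix.subset_patient(patient)
        pl = sub.ploidies
        if np.all(np.isnan(pl)):
            continue
        med, rng_ = ploidy_stats(pl[~np.isnan(pl)])
        ploidy_rows.append(
            {"patient_id": patient, "median_ploidy": med, "ploidy_range": rng_}
        )
    ploidy_table = pd.DataFrame(
        ploidy_rows, columns=["patient_id", "median_ploidy", "ploidy_range"]
    ).set_index("patient_id")

    survival_tables, denominators = _survival_block(
        records, het, burden, groups, config
    )

    manifest = {
        "tool": "cnahet",
        "version": __version__,
        "config": config.analysis_params(),
        "config_hash": config.hash(),
        "denominators": denominators,
        "exclusivity_violations": violations,
        "n_amplification_events": len(amp_events),
    }

    bundle = {
        "region_matrix": matrix.to_frame(),
        "call_matrix": calls.to_frame(),
        "burden_per_lesion": burden.per_lesion.to_frame(),
        "burden_per_patient": burden.per_patient.to_frame(),
        "cna_frequency": frequency,
        "heterogeneity": het,
        "amplification_events": amp_table,
        "mutation_groups": groups,
        "ploidy": ploidy_table,
        **survival_tables,
        "manifest": manifest,
    }
    _write_bundle(bundle, config)
    return bundle


def _survival_block(records, het, burden, groups, config):
    """Survival analyses on the nested eligible cohorts."""
    n_all = len(records)
    multi = set(het.index)
    kept, excl = eligible(records)
    denominators = {
        "patients_total": n_all,
        "patients_multi_lesion": len(multi),
        "patients_survival_eligible": len(kept),
        **excl,
    }
    tables: dict[str, pd.DataFrame] = {}
    frame = survival_frame(kept)
    if frame.empty or frame["event"].sum() == 0:
        logger.warning("survival block skipped: no analyzable events")
        tables["survival_overall_km"] = pd.DataFrame(
            columns=["time", "survival", "at_risk"]
        )
        return tables, denominators

    km_all = km_estimate(frame["time"], frame["event"])
    tables["survival_overall_km"] = km_all.to_frame()
    denominators["five_year_css_overall"] = km_all.five_year_css

    measure = config.heterogeneity_measure
    label_col = f"{measure}_label"
    strata_rows = []
    group_of = groups["group"]
    for pid in frame.index:
        grp = group_of.get(pid)
        lbl = het[label_col].get(pid) if label_col in het else None
        if grp in (None, "unresolved") or lbl not in ("high", "low"):
            continue
        if grp == CO_MUT:
            strata_rows.append((pid, f"co_mut_{lbl}"))
        else:
            strata_rows.append((pid, "no_co_mut"))
    if strata_rows:
        strata = pd.Series(dict(strata_rows), name="stratum")
        common = strata.index.intersection(frame.index)
        strata = strata.loc[common]
        levels = ["co_mut_high", "co_mut_low", "no_co_mut"]
        present = [lv for lv in levels if (strata == lv).any()]
        if len(present) >= 2 and frame.loc[common, "event"].sum() > 0:
            result = stratified_analysis(
                frame.loc[common],
                strata,
                ordered_levels=levels,
                reference="no_co_mut",
            )
            rows = []
            for lv, km in result.km_per_stratum.items():
                rows.append(
                    {
                        "stratum": lv,
                        "n": int((strata == lv).sum()),
                        "five_year_css": km.five_year_css,
                    }
                )
            summary = pd.DataFrame(rows).set_index("stratum")
            summary["test"] = result.test_kind
            summary["statistic"] = result.test.statistic
            summary["p_value"] = result.test.p_value
            tables["survival_strata"] = summary
            if result.cox.converged:
                tables["survival_cox"] = result.cox.table
    return tables, denominators


def _write_bundle(bundle: dict, config: PipelineConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = f"# cnahet v{__version__} config={config.hash()}\n"
    for name, obj in bundle.items():
        if name == "manifest":
            (out / "manifest.json").write_text(
                json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n"
            )
            continue
        path = out / f"{name}.tsv"
        with open(path, "w") as fh:
            fh.write(header)
            obj.to_csv(fh, sep="\t", float_format="%.6g")
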