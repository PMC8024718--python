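"""Readers and writers for the file formats the pipeline touches.

Formats
-------
* SEG-style segment tables: tab-delimited with columns
  ``sample, chrom, start, end, value``; coordinates 1-based inclusive on
  disk (SEG convention), converted to 0-based half-open in memory.
* BED gene intervals (0-based half-open), with an optional fifth column
  flagging cancer-critical genes.
* Long-format patient/lesion TSV tables with per-lesion mutation calls
  and patient-level clinical covariates.

Sex chromosomes are dropped at load time; all downstream analysis is
autosome-only.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import __version__

logger = logging.getLogger(__name__)

AUTOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23))
SEX_CHROMOSOMES = frozenset({"X", "Y", "chrX", "chrY", "23", "24"})

MUTATION_GENES: tuple[str, ...] = ("KRAS", "NRAS", "BRAF", "TP53")
MUTATION_LEVELS = frozenset({"mutated", "wild-type", "unknown"})
EVENT_LEVELS = ("CRC death", "other death", "alive")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def normalize_chromosome(label: object) -> str:
    """Strip a ``chr`` prefix and return the bare chromosome name."""
    text = str(label).strip()
    if text.lower().startswith("chr"):
        text = text[3:]
    return text


@dataclass(frozen=True)
class GenomicSegment:
    """One copy-number segment, 0-based half-open coordinates."""

    chromosome: str
    start: int
    end: int
    copy_number: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise FormatError(
                f"segment {self.chromosome}:{self.start}-{self.end} has end <= start"
            )
        if self.copy_number < 0:
            raise FormatError(
                f"negative copy number {self.copy_number} at "
                f"{self.chromosome}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class LesionProfile:
    """All segments of one lesion, sorted by (chromosome, start)."""

    lesion_id: str
    patient_id: str
    segments: list[GenomicSegment]
    ploidy: float | None = None
    aberrant_cell_fraction: float | None = None

    def __post_init__(self) -> None:
        self.segments = sorted(
            self.segments, key=lambda s: (_chrom_sort_key(s.chromosome), s.start)
        )
        self._check_nonoverlap()
        if self.covered_length <= 0:
            raise FormatError(f"lesion {self.lesion_id} covers zero base pairs")

    def _check_nonoverlap(self) -> None:
        for prev, cur in zip(self.segments, self.segments[1:]):
            if prev.chromosome == cur.chromosome and cur.start < prev.end:
                raise FormatError(
                    f"overlapping segments in sample {self.lesion_id}: "
                    f"{prev.chromosome}:{prev.start}-{prev.end} and "
                    f"{cur.chromosome}:{cur.start}-{cur.end}"
                )

    @property
    def covered_length(self) -> int:
        return sum(s.length for s in self.segments)


@dataclass(frozen=True)
class GeneInterval:
    """A gene locus with a cancer-critical flag (0-based half-open)."""

    gene_name: str
    chromosome: str
    start: int
    end: int
    cancer_critical: bool = False

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise FormatError(f"gene {self.gene_name} has end <= start")


@dataclass
class PatientRecord:
    """Patient-level clinical data plus per-lesion mutation calls.

    ``mutation_calls`` maps each gene to the ordered list of per-lesion
    calls (``mutated`` / ``wild-type`` / ``unknown``), aligned with
    ``lesion_ids``.
    """

    patient_id: str
    lesion_ids: list[str] = field(default_factory=list)
    mutation_calls: dict[str, list[str]] = field(default_factory=dict)
    msi_status: str | None = None
    r_status: str | None = None
    extrahepatic_disease: bool | None = None
    followup_months: float | None = None
    event: str | None = None
    covariates: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.followup_months is not None and self.followup_months < 0:
            raise FormatError(
                f"patient {self.patient_id}: negative follow-up {self.followup_months}"
            )
        if self.event is not None and self.event not in EVENT_LEVELS:
            raise FormatError(
                f"patient {self.patient_id}: event {self.event!r} not one of {EVENT_LEVELS}"
            )
        for gene, calls in self.mutation_calls.items():
            for call in calls:
                if call not in MUTATION_LEVELS:
                    raise FormatError(
                        f"patient {self.patient_id}: {gene} call {call!r} invalid"
                    )


def _chrom_sort_key(chrom: str) -> int:
    try:
        return int(chrom)
    except ValueError:
        return 1000 + hash(chrom) % 1000


def _is_sex_chromosome(chrom: str) -> bool:
    return chrom in ("X", "Y") or chrom in SEX_CHROMOSOMES


def config_hash(config: Mapping[str, object]) -> str:
    """Stable short hash of a configuration mapping, for output headers."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def _header_comment(extra: Mapping[str, object] | None = None) -> str:
    tag = f"# cnahet v{__version__}"
    if extra:
        tag += " config=" + config_hash(extra)
    return tag


# ---------------------------------------------------------------------------
# SEG-style segments
# ---------------------------------------------------------------------------

_SEG_COLUMNS = ("sample", "chrom", "start", "end", "value")


def read_segments(
    path: str | Path,
    dialect: str = "absolute_cn",
    patient_map: Mapping[str, str] | None = None,
) -> list[LesionProfile]:
    """Load a SEG-style tab-delimited segment file.

    Parameters
    ----------
    path
        Tab-delimited file with header columns ``sample, chrom, start,
        end, value``; coordinates 1-based inclusive.
    dialect
        ``absolute_cn`` takes ``value`` as total copy number directly;
        ``log2_ratio`` converts via ``2 * 2**value`` (diploid baseline).
    patient_map
        Optional mapping lesion/sample label -> patient label.  Without
        it the patient id defaults to the sample label itself.
    """
    if dialect not in ("absolute_cn", "log2_ratio"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", comment="#", dtype={1: str})
    cols = [c.lower() for c in df.columns[:5]]
    if cols != list(_SEG_COLUMNS):
        if len(df.columns) < 5:
            raise FormatError(f"{path}: expected 5 columns {_SEG_COLUMNS}")
        df = df.iloc[:, :5]
    df.columns = list(_SEG_COLUMNS) + list(df.columns[5:])

    df["chrom"] = df["chrom"].map(normalize_chromosome)
    n_sex = int(df["chrom"].isin(("X", "Y", "23", "24")).sum())
    if n_sex:
        logger.info("read_segments: dropped %d X/Y rows from %s", n_sex, path)
        df = df[~df["chrom"].isin(("X", "Y", "23", "24"))]
    unknown = set(df["chrom"]) - set(AUTOSOMES)
    if unknown:
        raise FormatError(f"{path}: unknown chromosome labels {sorted(unknown)}")

    profiles: list[LesionProfile] = []
    for sample, rows in df.groupby("sample", sort=True):
        segments = []
        for row in rows.itertuples(index=False):
            value = float(row.value)
            if dialect == "log2_ratio":
                value = 2.0 * 2.0**value
            # SEG 1-based inclusive -> 0-based half-open
            segments.append(
                GenomicSegment(
                    chromosome=str(row.chrom),
                    start=int(row.start) - 1,
                    end=int(row.end),
                    copy_number=value,
                )
            )
        sample = str(sample)
        patient = patient_map.get(sample, sample) if patient_map else sample
        profiles.append(
            LesionProfile(lesion_id=sample, patient_id=patient, segments=segments)
        )
    return profiles


def write_segments(
    profiles: Sequence[LesionProfile],
    path: str | Path,
    config: Mapping[str, object] | None = None,
) -> None:
    """Write profiles as a SEG-style table (1-based inclusive, absolute CN)."""
    lines = [_header_comment(config), "\t".join(_SEG_COLUMNS)]
    for profile in profiles:
        for seg in profile.segments:
            lines.append(
                f"{profile.lesion_id}\t{seg.chromosome}\t{seg.start + 1}"
                f"\t{seg.end}\t{seg.copy_number:.6g}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# BED gene intervals
# ---------------------------------------------------------------------------


def read_gene_intervals(path: str | Path) -> list[GeneInterval]:
    """Load gene intervals from a BED4+1 file (0-based half-open).

    The optional fifth column is a 0/1 cancer-critical flag.  Duplicate
    gene names are rejected; X/Y genes are dropped.
    """
    genes: list[GeneInterval] = []
    seen: set[str] = set()
    text = Path(path).read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 4:
            raise FormatError(f"{path}:{lineno}: expected >=4 BED columns")
        chrom = normalize_chromosome(parts[0])
        if _is_sex_chromosome(chrom):
            continue
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: malformed coordinates") from exc
        name = parts[3]
        if name in seen:
            raise FormatError(f"{path}:{lineno}: duplicate gene name {name!r}")
        seen.add(name)
        flag = bool(int(parts[4])) if len(parts) > 4 and parts[4] != "" else False
        genes.append(GeneInterval(name, chrom, start, end, cancer_critical=flag))
    if not genes:
        logger.warning("read_gene_intervals: no genes loaded from %s", path)
    return genes


def write_gene_intervals(genes: Iterable[GeneInterval], path: str | Path) -> None:
    lines = [
        f"{g.chromosome}\t{g.start}\t{g.end}\t{g.gene_name}\t{int(g.cancer_critical)}"
        for g in genes
    ]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Patient / lesion table
# ---------------------------------------------------------------------------

_PATIENT_LEVEL_FIELDS = (
    "msi_status",
    "r_status",
    "extrahepatic_disease",
    "followup_months",
    "event",
)

_CORE_COLUMNS = ("patient_id", "lesion_id") + tuple(
    g.lower() for g in MUTATION_GENES
) + _PATIENT_LEVEL_FIELDS


def read_patient_table(path: str | Path) -> list[PatientRecord]:
    """Load a long-format patient table (one row per lesion).

    Patient-level fields must agree across a patient's rows; any extra
    columns become clinical covariates, with missing values preserved.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"patient_id": str, "lesion_id": str})
    missing = {"patient_id", "lesion_id"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing required columns {sorted(missing)}")
    covariate_cols = [c for c in df.columns if c not in _CORE_COLUMNS]

    records: list[PatientRecord] = []
    for patient_id, rows in df.groupby("patient_id", sort=True):
        calls: dict[str, list[str]] = {}
        for gene in MUTATION_GENES:
            col = gene.lower()
            if col in rows:
                calls[gene] = [
                    "unknown" if pd.isna(v) else str(v) for v in rows[col]
                ]
        first = rows.iloc[0]

        def _patient_field(name: str):
            if name not in rows:
                return None
            vals = rows[name].dropna().unique()
            if len(vals) > 1:
                raise FormatError(
                    f"{path}: patient {patient_id}: inconsistent {name} values {vals}"
                )
            return vals[0] if len(vals) else None

        extrahepatic = _patient_field("extrahepatic_disease")
        if extrahepatic is not None:
            extrahepatic = str(extrahepatic).lower() in ("1", "true", "yes")
        followup = _patient_field("followup_months")
        covariates = {
            c: (None if pd.isna(first[c]) else first[c]) for c in covariate_cols
        }
        records.append(
            PatientRecord(
                patient_id=str(patient_id),
                lesion_ids=[str(x) for x in rows["lesion_id"]],
                mutation_calls=calls,
                msi_status=_patient_field("msi_status"),
                r_status=_patient_field("r_status"),
                extrahepatic_disease=extrahepatic,
                followup_months=None if followup is None else float(followup),
                event=_patient_field("event"),
                covariates=covariates,
            )
        )
    return records


def write_patient_table(
    records: Sequence[PatientRecord],
    path: str | Path,
    config: Mapping[str, object] | None = None,
) -> None:
    """Write records in the long one-row-per-lesion layout."""
    covariate_cols = sorted({c for r in records for c in r.covariates})
    header = list(_CORE_COLUMNS) + covariate_cols
    lines = [_header_comment(config), "\t".join(header)]
    for rec in records:
        for i, lesion in enumerate(rec.lesion_ids):
            row = [rec.patient_id, lesion]
            for gene in MUTATION_GENES:
                calls = rec.mutation_calls.get(gene)
                row.append(calls[i] if calls else "")
            row += [
                rec.msi_status or "",
                rec.r_status or "",
                "" if rec.extrahepatic_disease is None else str(int(rec.extrahepatic_disease)),
                "" if rec.followup_months is None else f"{rec.followup_months:.6g}",
                rec.event or "",
            ]
            for c in covariate_cols:
                v = rec.covariates.get(c)
                if v is None:
                    row.append("")
                elif isinstance(v, float):
                    row.append(f"{v:.6g}")
                else:
                    row.append(str(v))
            lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def check_cross_references(
    profiles: Sequence[LesionProfile], records: Sequence[PatientRecord]
) -> None:
    """Fail if any lesion profile references a patient absent from the table."""
    known = {r.patient_id for r in records}
    orphans = sorted({p.patient_id for p in profiles} - known)
    if orphans:
        raise FormatError(f"lesions reference unknown patients: {orphans}")
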