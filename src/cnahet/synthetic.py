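"""Synthetic multi-lesion cohort generator with ground-truth records.

Generates cohorts with the statistical structure the downstream
analysis assumes: per-patient multi-lesion copy-number profiles built
from shared (truncal) and lesion-private arm-level events, occasional
high-level amplifications, mutually exclusive KRAS/NRAS/BRAF V600E
driver mutations plus TP53 at colorectal-cancer prevalences, clinical
covariates, and exponential survival times under stratum-specific
hazards with administrative and other-cause censoring.

Event placement defaults to an arm-level prior weighted toward the
recurrently altered arms of colorectal cancer (gains of 7, 8q, 13q,
20q; losses of 1p, 4, 8p, 17p, 18); a uniform mode exists for unbiased
property tests.  Every cohort carries a truth record (event lists,
true discordant-gene fraction, group label, generative hazard) that is
reproducible from (config, seed) and computed from the event lists
independently of the analysis code, so estimator-recovery tests have a
genuine target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    GeneInterval,
    GenomicSegment,
    LesionProfile,
    PatientRecord,
)
from .mutation_groups import CO_MUT, DOUBLE_WT, RAS_BRAF_ONLY, TP53_ONLY

# hg19 autosome lengths (bp) and approximate centromere positions
_HG19_LENGTHS = {
    "1": 249250621, "2": 243199373, "3": 198022430, "4": 191154276,
    "5": 180915260, "6": 171115067, "7": 159138663, "8": 146364022,
    "9": 141213431, "10": 135534747, "11": 135006516, "12": 133851895,
    "13": 115169878, "14": 107349540, "15": 102531392, "16": 90354753,
    "17": 81195210, "18": 78077248, "19": 59128983, "20": 63025520,
    "21": 48129895, "22": 51304566,
}
_HG19_CENTROMERES = {
    "1": 125000000, "2": 93300000, "3": 91000000, "4": 50400000,
    "5": 48400000, "6": 61000000, "7": 59900000, "8": 45600000,
    "9": 49000000, "10": 40200000, "11": 53700000, "12": 35800000,
    "13": 17900000, "14": 17600000, "15": 19000000, "16": 36600000,
    "17": 24000000, "18": 17200000, "19": 26500000, "20": 27500000,
    "21": 13200000, "22": 14700000,
}

# Arms recurrently gained / lost in colorectal cancer
_RECURRENT_GAIN_ARMS = {("7", "p"), ("7", "q"), ("8", "q"), ("13", "q"), ("20", "q")}
_RECURRENT_LOSS_ARMS = {
    ("1", "p"), ("4", "p"), ("4", "q"), ("8", "p"),
    ("17", "p"), ("18", "p"), ("18", "q"),
}


@dataclass(frozen=True)
class GenomeModel:
    """Autosome lengths and centromere positions defining the arm grid."""

    lengths: dict[str, int]
    centromeres: dict[str, int]

    @classmethod
    def hg19(cls) -> "GenomeModel":
        return cls(dict(_HG19_LENGTHS), dict(_HG19_CENTROMERES))

    @classmethod
    def miniature(cls, chrom_length: int = 1_000_000) -> "GenomeModel":
        """22 equal autosomes; small enough for per-base oracles."""
        lengths = {str(i): chrom_length for i in range(1, 23)}
        centromeres = {str(i): int(0.4 * chrom_length) for i in range(1, 23)}
        return cls(lengths, centromeres)

    @property
    def chromosomes(self) -> list[str]:
        return list(self.lengths)

    def arms(self) -> list[tuple[str, str, int, int]]:
        out = []
        for chrom, length in self.lengths.items():
            cen = self.centromeres[chrom]
            out.append((chrom, "p", 0, cen))
            out.append((chrom, "q", cen, length))
        return out

    @property
    def total_length(self) -> int:
        return sum(self.lengths.values())


DEFAULT_PREVALENCES = {"KRAS": 0.427, "NRAS": 0.047, "BRAF": 0.018, "TP53": 0.725}


@dataclass
class GeneratorConfig:
    """All knobs of the cohort generator.

    Rates are expected event counts (Poisson); hazards are per-month.
    The default mutation prevalences, lesion-count range and survival
    scale emulate a resected colorectal-liver-metastasis series.
    """

    n_patients: int = 64
    lesions_min: int = 2
    lesions_max: int = 8
    genome: GenomeModel = field(default_factory=GenomeModel.hg19)
    # copy-number events
    truncal_event_rate: float = 8.0
    private_event_rate: float = 2.0
    whole_arm_probability: float = 0.4
    event_length_fraction: tuple[float, float] = (0.2, 0.9)
    gain_two_copy_probability: float = 0.3
    arm_prior: str = "crc"  # "crc" | "uniform"
    # ploidy
    ploidy_levels: tuple[float, ...] = (2.0, 3.5)
    ploidy_level_probs: tuple[float, ...] = (0.55, 0.45)
    ploidy_jitter_sd: float = 0.1
    # high-level amplifications
    amp_probability: float = 0.34
    amp_high_range: tuple[float, float] = (15.0, 60.0)
    amp_intermediate_range: tuple[float, float] = (5.0, 14.0)
    amp_low_range: tuple[float, float] = (0.0, 4.0)
    amp_pattern_probs: tuple[float, float, float] = (0.31, 0.38, 0.31)
    amp_length_fraction: float = 0.02  # of the chromosome
    # genes
    n_genes: int = 2500
    cancer_critical_fraction: float = 0.1
    # mutations
    prevalences: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCES)
    )
    tp53_heterogeneity_rate: float = 0.08
    # clinical / survival
    msi_rate: float = 0.006
    r_status_probs: tuple[float, float, float] = (0.77, 0.2, 0.03)  # R0, R1, R2
    extrahepatic_rate: float = 0.2
    # per-month CRC-death hazard of the reference (double wild-type,
    # low-heterogeneity) stratum; calibrated so the default hazard-ratio
    # mixture yields a marginal 5-year CSS near 0.4
    base_hazard: float = 0.006
    group_hazard_ratios: dict[str, float] = field(
        default_factory=lambda: {
            CO_MUT: 3.9,
            RAS_BRAF_ONLY: 1.5,
            TP53_ONLY: 1.2,
            DOUBLE_WT: 1.0,
        }
    )
    het_high_probability: float = 0.5
    het_high_rate_multiplier: float = 3.0  # private-event rate scale when "high"
    het_high_hazard_ratio: float = 1.8
    other_cause_hazard: float = 0.002
    admin_censor_range: tuple[float, float] = (36.0, 120.0)

    def validate(self) -> None:
        ras = sum(self.prevalences[g] for g in ("KRAS", "NRAS", "BRAF"))
        if ras > 1:
            raise ValueError("KRAS+NRAS+BRAF prevalence exceeds 1")
        for gene, p in self.prevalences.items():
            if not 0 <= p <= 1:
                raise ValueError(f"prevalence of {gene} outside [0, 1]")
        if self.truncal_event_rate < 0 or self.private_event_rate < 0:
            raise ValueError("event rates must be non-negative")
        if self.lesions_min < 1 or self.lesions_max < self.lesions_min:
            raise ValueError("invalid lesion count range")
        if abs(sum(self.ploidy_level_probs) - 1) > 1e-9:
            raise ValueError("ploidy_level_probs must sum to 1")


@dataclass
class CNAEvent:
    """One generated copy-number event (coordinates 0-based half-open)."""

    chromosome: str
    start: int
    end: int
    delta: float  # additive copies; amplifications use override instead
    override: float | None = None  # absolute additional copies over ploidy


@dataclass
class PatientTruth:
    patient_id: str
    lesion_ids: list[str]
    ploidy: float
    truncal_events: list[CNAEvent]
    private_events: dict[str, list[CNAEvent]]
    amp_events: list[dict]  # region + per-lesion additional copies + class
    group: str
    het_class: str  # "high" | "low"
    hazard: float
    discordant_fraction_true: float  # NaN when no aberrant gene


@dataclass
class CohortTruth:
    seed: int
    patients: dict[str, PatientTruth]
    extras: dict = field(default_factory=dict)


@dataclass
class Cohort:
    profiles: list[LesionProfile]
    genes: list[GeneInterval]
    records: list[PatientRecord]
    truth: CohortTruth


# ---------------------------------------------------------------------------
# Mutation drawing (exposed separately for prevalence checks at large n)
# ---------------------------------------------------------------------------


def draw_mutation_statuses(
    n: int,
    prevalences: dict[str, float] | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw patient-level mutation statuses with RAS/BRAF exclusivity.

    KRAS/NRAS/BRAF come from one categorical draw (so at most one of
    them is mutated per patient); TP53 is an independent Bernoulli.
    """
    prev = dict(DEFAULT_PREVALENCES if prevalences is None else prevalences)
    if prev["KRAS"] + prev["NRAS"] + prev["BRAF"] > 1:
        raise ValueError("RAS/BRAF prevalences sum above 1")
    rng = np.random.default_rng() if rng is None else rng
    u = rng.random(n)
    kras = u < prev["KRAS"]
    nras = (~kras) & (u < prev["KRAS"] + prev["NRAS"])
    braf = (~kras) & (~nras) & (u < prev["KRAS"] + prev["NRAS"] + prev["BRAF"])
    tp53 = rng.random(n) < prev["TP53"]
    return pd.DataFrame(
        {"KRAS": kras, "NRAS": nras, "BRAF": braf, "TP53": tp53}
    )


# ---------------------------------------------------------------------------
# Event sampling and profile construction
# ---------------------------------------------------------------------------


def _arm_weights(config: GeneratorConfig) -> np.ndarray:
    arms = config.genome.arms()
    if config.arm_prior == "uniform":
        w = np.array([end - start for _, _, start, end in arms], float)
    elif config.arm_prior == "crc":
        w = []
        for chrom, arm, start, end in arms:
            base = float(end - start)
            if (chrom, arm) in _RECURRENT_GAIN_ARMS | _RECURRENT_LOSS_ARMS:
                base *= 6.0
            w.append(base)
        w = np.array(w)
    else:
        raise ValueError(f"unknown arm prior {config.arm_prior!r}")
    return w / w.sum()


def _draw_event(rng: np.random.Generator, config: GeneratorConfig,
                arms: list, weights: np.ndarray) -> CNAEvent:
    idx = int(rng.choice(len(arms), p=weights))
    chrom, arm, a_start, a_end = arms[idx]
    arm_len = a_end - a_start
    if rng.random() < config.whole_arm_probability:
        start, end = a_start, a_end
    else:
        lo, hi = config.event_length_fraction
        length = max(1, int(rng.uniform(lo, hi) * arm_len))
        start = a_start + int(rng.integers(0, max(1, arm_len - length + 1)))
        end = min(start + length, a_end)
    key = (chrom, arm)
    if config.arm_prior == "crc" and key in _RECURRENT_GAIN_ARMS:
        is_gain = rng.random() < 0.8
    elif config.arm_prior == "crc" and key in _RECURRENT_LOSS_ARMS:
        is_gain = rng.random() >= 0.8
    else:
        is_gain = rng.random() < 0.5
    if is_gain:
        delta = 2.0 if rng.random() < config.gain_two_copy_probability else 1.0
    else:
        delta = -1.0
    return CNAEvent(chrom, int(start), int(end), delta)


def _build_profile(
    lesion_id: str,
    patient_id: str,
    ploidy: float,
    events: Sequence[CNAEvent],
    genome: GenomeModel,
) -> LesionProfile:
    """Apply events over a flat baseline at the patient's ploidy.

    Additive deltas accumulate; override events (amplifications) set
    the value to ploidy + additional copies outright, the largest
    override winning where several overlap.  Values floor at zero.
    Adjacent equal-valued intervals are merged into single segments.
    """
    segments: list[GenomicSegment] = []
    by_chrom: dict[str, list[CNAEvent]] = {}
    for ev in events:
        by_chrom.setdefault(ev.chromosome, []).append(ev)
    for chrom in genome.chromosomes:
        length = genome.lengths[chrom]
        evs = by_chrom.get(chrom, [])
        bps = sorted({0, length} | {e.start for e in evs} | {e.end for e in evs})
        prev_val = None
        run_start = 0
        for lo, hi in zip(bps[:-1], bps[1:]):
            delta = sum(e.delta for e in evs if e.override is None and e.start <= lo < e.end)
            overrides = [e.override for e in evs if e.override is not None and e.start <= lo < e.end]
            if overrides:
                value = ploidy + max(overrides)
            else:
                value = max(0.0, ploidy + delta)
            if prev_val is None:
                prev_val, run_start = value, lo
            elif value != prev_val:
                segments.append(GenomicSegment(chrom, run_start, lo, prev_val))
                prev_val, run_start = value, lo
        segments.append(GenomicSegment(chrom, run_start, length, prev_val))
    return LesionProfile(
        lesion_id=lesion_id,
        patient_id=patient_id,
        segments=segments,
        ploidy=ploidy,
    )


def _value_at(events: Sequence[CNAEvent], ploidy: float, chrom: str, pos: int) -> float:
    """Copy number at one position, mirroring ``_build_profile``."""
    delta = 0.0
    override = None
    for e in events:
        if e.chromosome == chrom and e.start <= pos < e.end:
            if e.override is not None:
                override = e.override if override is None else max(override, e.override)
            else:
                delta += e.delta
    if override is not None:
        return ploidy + override
    return max(0.0, ploidy + delta)


def _true_discordant_fraction(
    lesion_events: dict[str, list[CNAEvent]],
    ploidy: float,
    genes: Sequence[GeneInterval],
    gain_threshold: float = 1.0,
    loss_threshold: float = -1.0,
) -> float:
    """Discordant aberrant-gene fraction from the event lists alone.

    Gene status is evaluated at the gene midpoint against the patient's
    ploidy (the genome-wide median baseline of the generated profiles,
    since events never cover half the genome).
    """
    n_aberrant = n_discordant = 0
    lesion_ids = list(lesion_events)
    for gene in genes:
        mid = (gene.start + gene.end) // 2
        calls = []
        for lid in lesion_ids:
            value = _value_at(lesion_events[lid], ploidy, gene.chromosome, mid)
            diff = value - ploidy
            calls.append(1 if diff >= gain_threshold else (-1 if diff <= loss_threshold else 0))
        if any(c != 0 for c in calls):
            n_aberrant += 1
            if len(set(calls)) > 1:
                n_discordant += 1
    return n_discordant / n_aberrant if n_aberrant else float("nan")


def make_gene_panel(
    genome: GenomeModel,
    n_genes: int,
    cancer_critical_fraction: float,
    rng: np.random.Generator,
) -> list[GeneInterval]:
    """Evenly tiled gene panel with a random cancer-critical subset."""
    total = genome.total_length
    genes: list[GeneInterval] = []
    counts = {
        chrom: max(1, round(n_genes * length / total))
        for chrom, length in genome.lengths.items()
    }
    i = 0
    for chrom, count in counts.items():
        length = genome.lengths[chrom]
        spacing = length / count
        gene_len = max(100, int(spacing * 0.2))
        for k in range(count):
            start = int((k + 0.4) * spacing)
            genes.append(
                GeneInterval(
                    gene_name=f"G{i:05d}",
                    chromosome=chrom,
                    start=start,
                    end=min(start + gene_len, length),
                    cancer_critical=bool(rng.random() < cancer_critical_fraction),
                )
            )
            i += 1
    return genes


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


def generate_cohort(config: GeneratorConfig, seed: int) -> Cohort:
    """Generate a full synthetic cohort; deterministic in (config, seed)."""
    config.validate()
    rng = np.random.default_rng(seed)
    genome = config.genome
    arms = genome.arms()
    weights = _arm_weights(config)
    genes = make_gene_panel(
        genome, config.n_genes, config.cancer_critical_fraction, rng
    )

    mut = draw_mutation_statuses(config.n_patients, config.prevalences, rng)

    profiles: list[LesionProfile] = []
    records: list[PatientRecord] = []
    truths: dict[str, PatientTruth] = {}

    for p in range(config.n_patients):
        patient_id = f"P{p + 1:03d}"
        n_lesions = int(rng.integers(config.lesions_min, config.lesions_max + 1))
        lesion_ids = [f"{patient_id}_L{i + 1}" for i in range(n_lesions)]

        level = int(rng.choice(len(config.ploidy_levels), p=config.ploidy_level_probs))
        ploidy = float(
            config.ploidy_levels[level] + rng.normal(0, config.ploidy_jitter_sd)
        )
        ploidy = max(1.5, ploidy)

        het_high = bool(rng.random() < config.het_high_probability)
        private_rate = config.private_event_rate * (
            config.het_high_rate_multiplier if het_high else 1.0
        )

        truncal = [
            _draw_event(rng, config, arms, weights)
            for _ in range(rng.poisson(config.truncal_event_rate))
        ]
        private: dict[str, list[CNAEvent]] = {}
        for lid in lesion_ids:
            private[lid] = [
                _draw_event(rng, config, arms, weights)
                for _ in range(rng.poisson(private_rate))
            ]

        # high-level amplification injection
        amp_truth: list[dict] = []
        if rng.random() < config.amp_probability:
            chrom = str(rng.choice(genome.chromosomes))
            clen = genome.lengths[chrom]
            alen = max(1000, int(config.amp_length_fraction * clen))
            astart = int(rng.integers(0, max(1, clen - alen)))
            pattern = ("homogeneous", "intermediate", "heterogeneous")[
                int(rng.choice(3, p=np.asarray(config.amp_pattern_probs) /
                               np.sum(config.amp_pattern_probs)))
            ]
            if config.private_event_rate == 0:
                # no lesion-private variation at all: amplitudes identical
                copies = [float(rng.uniform(*config.amp_high_range))] * n_lesions
            elif pattern == "homogeneous":
                copies = list(rng.uniform(*config.amp_high_range, size=n_lesions))
            elif pattern == "intermediate":
                copies = list(rng.uniform(*config.amp_intermediate_range, size=n_lesions))
                copies[int(rng.integers(n_lesions))] = float(
                    rng.uniform(*config.amp_high_range)
                )
            else:
                copies = list(rng.uniform(*config.amp_low_range, size=n_lesions))
                copies[int(rng.integers(n_lesions))] = float(
                    rng.uniform(*config.amp_high_range)
                )
            for lid, c in zip(lesion_ids, copies):
                private[lid].append(
                    CNAEvent(chrom, astart, astart + alen, 0.0, override=float(c))
                )
            amp_truth.append(
                {
                    "chromosome": chrom,
                    "start": astart,
                    "end": astart + alen,
                    "additional_copies": {l: float(c) for l, c in zip(lesion_ids, copies)},
                    "pattern": pattern,
                }
            )

        lesion_events = {lid: truncal + private[lid] for lid in lesion_ids}
        for lid in lesion_ids:
            profiles.append(
                _build_profile(lid, patient_id, ploidy, lesion_events[lid], genome)
            )

        # mutations -> lesion-level calls
        row = mut.iloc[p]
        calls: dict[str, list[str]] = {}
        for gene in ("KRAS", "NRAS", "BRAF", "TP53"):
            status = "mutated" if bool(row[gene]) else "wild-type"
            calls[gene] = [status] * n_lesions
        if (
            bool(row["TP53"])
            and n_lesions >= 2
            and rng.random() < config.tp53_heterogeneity_rate
        ):
            calls["TP53"][int(rng.integers(n_lesions))] = "wild-type"

        if row["KRAS"] or row["NRAS"] or row["BRAF"]:
            group = CO_MUT if row["TP53"] else RAS_BRAF_ONLY
        else:
            group = TP53_ONLY if row["TP53"] else DOUBLE_WT

        hazard = config.base_hazard * config.group_hazard_ratios[group]
        if het_high:
            hazard *= config.het_high_hazard_ratio
        t_crc = rng.exponential(1.0 / hazard)
        t_other = (
            rng.exponential(1.0 / config.other_cause_hazard)
            if config.other_cause_hazard > 0
            else math.inf
        )
        c_admin = rng.uniform(*config.admin_censor_range)
        t = min(t_crc, t_other, c_admin)
        if t == t_crc:
            event = "CRC death"
        elif t == t_other:
            event = "other death"
        else:
            event = "alive"

        msi = "MSI" if rng.random() < config.msi_rate else "MSS"
        r_status = ("R0", "R1", "R2")[
            int(rng.choice(3, p=config.r_status_probs))
        ]
        covariates = {
            "sex": "M" if rng.random() < 0.6 else "F",
            "age": float(np.clip(rng.normal(64, 10), 30, 88)),
            "size_largest_lesion_mm": float(rng.lognormal(3.3, 0.5)),
            "n_lesions": n_lesions,
            "chemo_cycles": int(rng.poisson(4)),
        }
        records.append(
            PatientRecord(
                patient_id=patient_id,
                lesion_ids=lesion_ids,
                mutation_calls=calls,
                msi_status=msi,
                r_status=r_status,
                extrahepatic_disease=bool(rng.random() < config.extrahepatic_rate),
                followup_months=round(float(t), 1),
                event=event,
                covariates=covariates,
            )
        )

        truths[patient_id] = PatientTruth(
            patient_id=patient_id,
            lesion_ids=lesion_ids,
            ploidy=ploidy,
            truncal_events=truncal,
            private_events=private,
            amp_events=amp_truth,
            group=group,
            het_class="high" if het_high else "low",
            hazard=hazard,
            discordant_fraction_true=_true_discordant_fraction(
                lesion_events, ploidy, genes
            ),
        )

    return Cohort(
        profiles=profiles,
        genes=genes,
        records=records,
        truth=CohortTruth(seed=seed, patients=truths),
    )


# ---------------------------------------------------------------------------
# Direct amplification injection (fixture building)
# ---------------------------------------------------------------------------


def inject_amplification(
    profiles: Sequence[LesionProfile],
    chromosome: str,
    start: int,
    end: int,
    additional_copies: Sequence[float],
    genome: GenomeModel,
) -> list[LesionProfile]:
    """Raise copy numbers over a region to ploidy + additional copies.

    ``additional_copies`` is aligned with ``profiles`` (one value per
    lesion).  Returns new profiles; the inputs are left untouched.
    """
    if chromosome not in genome.lengths:
        raise ValueError(f"chromosome {chromosome!r} not in genome")
    if start < 0 or end > genome.lengths[chromosome] or end <= start:
        raise ValueError(f"region {chromosome}:{start}-{end} outside genome")
    if len(additional_copies) != len(profiles):
        raise ValueError("need one additional-copies value per lesion")
    out = []
    for profile, copies in zip(profiles, additional_copies):
        ploidy = profile.ploidy if profile.ploidy is not None else 2.0
        target = ploidy + float(copies)
        segments: list[GenomicSegment] = []
        for seg in profile.segments:
            if seg.chromosome != chromosome or seg.end <= start or seg.start >= end:
                segments.append(seg)
                continue
            if seg.start < start:
                segments.append(replace(seg, end=start))
            segments.append(
                GenomicSegment(
                    chromosome, max(seg.start, start), min(seg.end, end), target
                )
            )
            if seg.end > end:
                segments.append(replace(seg, start=end))
        out.append(replace(profile, segments=segments))
    return out


# ---------------------------------------------------------------------------
# Fixture registry
# ---------------------------------------------------------------------------

# Published-style worked example: six patients, fifteen amplified
# regions with per-lesion additional copies spanning the stated ranges.
# (region coordinates hg19; 1-based inclusive as printed, converted on use)
AMP_EXAMPLE_ROWS: list[dict] = [
    {"patient": 1, "n_lesions": 7, "chrom": "6", "start": 39863162, "end": 42671542,
     "genes": ["CCND3", "TFEB"], "range": (14, 16), "expected": "intermediate_concordant"},
    {"patient": 2, "n_lesions": 3, "chrom": "1", "start": 65183880, "end": 66527443,
     "genes": ["JAK1"], "range": (10, 15), "expected": "intermediate_concordant"},
    {"patient": 2, "n_lesions": 3, "chrom": "7", "start": 54576560, "end": 56118007,
     "genes": ["EGFR"], "range": (37, 58), "expected": "homogeneous"},
    {"patient": 2, "n_lesions": 3, "chrom": "7", "start": 90792390, "end": 92573683,
     "genes": ["AKAP9", "CDK6"], "range": (0, 22), "expected": "heterogeneous"},
    {"patient": 2, "n_lesions": 3, "chrom": "18", "start": 41497284, "end": 42716881,
     "genes": ["SETBP1"], "range": (18, 20), "expected": "homogeneous"},
    {"patient": 3, "n_lesions": 2, "chrom": "12", "start": 4279446, "end": 4431071,
     "genes": ["CCND2"], "range": (29, 47), "expected": "homogeneous"},
    {"patient": 3, "n_lesions": 2, "chrom": "16", "start": 40873444, "end": 53153010,
     "genes": ["CYLD", "TOX3"], "range": (0, 16), "expected": "heterogeneous"},
    {"patient": 4, "n_lesions": 6, "chrom": "13", "start": 20528021, "end": 21570265,
     "genes": ["ZMYM2"], "range": (3, 15), "expected": "heterogeneous"},
    {"patient": 4, "n_lesions": 6, "chrom": "13", "start": 28302602, "end": 28662578,
     "genes": ["CDX2", "FLT3"], "range": (3, 15), "expected": "heterogeneous"},
    {"patient": 5, "n_lesions": 5, "chrom": "17", "start": 37604254, "end": 37701703,
     "genes": ["CDK12"], "range": (16, 41), "expected": "homogeneous"},
    {"patient": 5, "n_lesions": 5, "chrom": "17", "start": 37704051, "end": 38191836,
     "genes": ["ERBB2"], "range": (41, 55), "expected": "homogeneous"},
    {"patient": 6, "n_lesions": 2, "chrom": "17", "start": 36841569, "end": 37669141,
     "genes": ["LASP1", "MLLT6"], "range": (12, 18), "expected": "intermediate_concordant"},
    {"patient": 6, "n_lesions": 2, "chrom": "17", "start": 37669143, "end": 37993556,
     "genes": ["CDK12b", "ERBB2b"], "range": (17, 18), "expected": "homogeneous"},
    {"patient": 6, "n_lesions": 2, "chrom": "17", "start": 53268056, "end": 53593625,
     "genes": ["HLF"], "range": (14, 18), "expected": "intermediate_concordant"},
    {"patient": 6, "n_lesions": 2, "chrom": "17", "start": 56250122, "end": 57541594,
     "genes": ["RNF43"], "range": (14, 18), "expected": "intermediate_concordant"},
]

_NON_COSMIC_GENES = {"TOX3"}

FIXTURE_NAMES = ("table1", "null_survival", "gradient_het", "paper_like")


def _amp_example_cohort() -> Cohort:
    """Six flat-diploid patients carrying the fifteen worked-example
    amplifications; each event's per-lesion additional copies span the
    published min-max range (linear interpolation between lesions)."""
    genome = GenomeModel.hg19()
    by_patient: dict[int, list[dict]] = {}
    for row in AMP_EXAMPLE_ROWS:
        by_patient.setdefault(row["patient"], []).append(row)
    profiles: list[LesionProfile] = []
    records: list[PatientRecord] = []
    genes: list[GeneInterval] = []
    truths: dict[str, PatientTruth] = {}
    for pnum in sorted(by_patient):
        rows = by_patient[pnum]
        n_lesions = rows[0]["n_lesions"]
        patient_id = f"T{pnum}"
        lesion_ids = [f"{patient_id}_L{i+1}" for i in range(n_lesions)]
        pats = [
            _build_profile(lid, patient_id, 2.0, [], genome) for lid in lesion_ids
        ]
        amp_truth = []
        for row in rows:
            lo, hi = row["range"]
            copies = np.linspace(lo, hi, n_lesions)
            start0 = row["start"] - 1  # printed 1-based -> half-open
            pats = inject_amplification(
                pats, row["chrom"], start0, row["end"], copies, genome
            )
            amp_truth.append(
                {
                    "chromosome": row["chrom"],
                    "start": start0,
                    "end": row["end"],
                    "additional_copies": dict(zip(lesion_ids, copies.tolist())),
                    "expected_class": row["expected"],
                }
            )
            span = row["end"] - start0
            for gi, gene in enumerate(row["genes"]):
                gstart = start0 + gi * span // len(row["genes"])
                gend = start0 + (gi + 1) * span // len(row["genes"])
                genes.append(
                    GeneInterval(
                        gene, row["chrom"], gstart, gend,
                        cancer_critical=gene not in _NON_COSMIC_GENES,
                    )
                )
        profiles.extend(pats)
        records.append(
            PatientRecord(
                patient_id=patient_id,
                lesion_ids=lesion_ids,
                mutation_calls={},
                msi_status="MSS",
                r_status="R0",
                followup_months=60.0,
                event="alive",
            )
        )
        truths[patient_id] = PatientTruth(
            patient_id=patient_id,
            lesion_ids=lesion_ids,
            ploidy=2.0,
            truncal_events=[],
            private_events={lid: [] for lid in lesion_ids},
            amp_events=amp_truth,
            group=DOUBLE_WT,
            het_class="low",
            hazard=float("nan"),
            discordant_fraction_true=float("nan"),
        )
    return Cohort(
        profiles=profiles,
        genes=genes,
        records=records,
        truth=CohortTruth(seed=0, patients=truths),
    )


def make_fixture(name: str, seed: int = 0):
    """Deterministic bundled cohorts for tests and demonstrations.

    * ``table1`` — six flat-diploid patients with the fifteen
      worked-example amplifications and their expected concordance
      classes (returns a Cohort);
    * ``null_survival`` — 60 patients with all stratum hazards equal
      (returns a Cohort);
    * ``gradient_het`` — dict of private-event rate -> miniature Cohort
      over eight rate levels;
    * ``paper_like`` — 64 patients, 2-8 lesions each, defaults
      throughout (returns a Cohort).
    """
    if name == "table1":
        return _amp_example_cohort()
    if name == "null_survival":
        config = GeneratorConfig(
            n_patients=60,
            genome=GenomeModel.miniature(),
            n_genes=500,
            group_hazard_ratios={g: 1.0 for g in (CO_MUT, RAS_BRAF_ONLY, TP53_ONLY, DOUBLE_WT)},
            het_high_hazard_ratio=1.0,
        )
        return generate_cohort(config, seed)
    if name == "gradient_het":
        rates = [0.0, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0]
        out = {}
        for i, rate in enumerate(rates):
            config = GeneratorConfig(
                n_patients=8,
                genome=GenomeModel.miniature(),
                n_genes=500,
                private_event_rate=rate,
                amp_probability=0.0,
            )
            out[rate] = generate_cohort(config, seed + i)
        return out
    if name == "paper_like":
        return generate_cohort(GeneratorConfig(), seed)
    raise KeyError(f"unknown fixture {name!r}; known: {FIXTURE_NAMES}")
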