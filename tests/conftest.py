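"""Shared fixtures: tiny profile builders and per-base brute-force oracles.

The oracle functions expand segment lists to one value per base pair on
miniature genomes, so harmonization, baselines, calls and burden can be
checked against direct enumeration, independently of the implementation
under test.
"""

from __future__ import annotations

import numpy as np
import pytest

from cnahet.io_formats import GenomicSegment, LesionProfile


def profile(lesion_id, segs, patient_id=None, ploidy=None):
    """Build a LesionProfile from (chrom, start, end, cn) tuples."""
    return LesionProfile(
        lesion_id=lesion_id,
        patient_id=patient_id or lesion_id,
        segments=[GenomicSegment(c, s, e, v) for c, s, e, v in segs],
        ploidy=ploidy,
    )


def random_mini_profiles(
    rng: np.random.Generator,
    n_lesions: int,
    n_chroms: int = 2,
    chrom_len: int = 120,
    gap_probability: float = 0.2,
    patient_id: str = "P",
) -> list[LesionProfile]:
    """Random small profiles with random breakpoints, values, and gaps."""
    profiles = []
    for j in range(n_lesions):
        segs = []
        for c in range(1, n_chroms + 1):
            n_bp = int(rng.integers(1, 5))
            bps = np.sort(rng.choice(np.arange(1, chrom_len), size=n_bp, replace=False))
            bounds = [0, *bps.tolist(), chrom_len]
            for lo, hi in zip(bounds[:-1], bounds[1:]):
                if rng.random() < gap_probability:
                    continue  # uncovered gap
                value = float(rng.integers(0, 7))
                segs.append((str(c), lo, hi, value))
        if not segs:  # a profile must cover something
            segs.append((str(1), 0, chrom_len, 2.0))
        profiles.append(profile(f"{patient_id}_L{j + 1}", segs, patient_id=patient_id))
    return profiles


def per_base_values(prof: LesionProfile, chroms: list[str], chrom_len: int) -> dict:
    """chrom -> per-base copy-number array (NaN where uncovered)."""
    out = {c: np.full(chrom_len, np.nan) for c in chroms}
    for seg in prof.segments:
        out[seg.chromosome][seg.start : seg.end] = seg.copy_number
    return out


def oracle_baseline(prof: LesionProfile, chroms: list[str], chrom_len: int) -> float:
    """Median over covered base pairs (the unit-expansion definition)."""
    arrays = per_base_values(prof, chroms, chrom_len)
    flat = np.concatenate([a[~np.isnan(a)] for a in arrays.values()])
    return float(np.median(flat))


def oracle_calls_and_burden(
    profiles: list[LesionProfile],
    chroms: list[str],
    chrom_len: int,
    gain: float = 1.0,
    loss: float = -1.0,
):
    """Per-base ternary calls and burden percent for every lesion."""
    calls = {}
    burden = {}
    for prof in profiles:
        base = oracle_baseline(prof, chroms, chrom_len)
        per_chrom = {}
        n_cov = n_ab = 0
        for c in chroms:
            vals = per_base_values(prof, chroms, chrom_len)[c]
            call = np.full(chrom_len, np.nan)
            known = ~np.isnan(vals)
            delta = vals[known] - base
            ternary = np.where(delta >= gain, 1.0, np.where(delta <= loss, -1.0, 0.0))
            call[known] = ternary
            per_chrom[c] = call
            n_cov += int(known.sum())
            n_ab += int((ternary != 0).sum())
        calls[prof.lesion_id] = per_chrom
        burden[prof.lesion_id] = 100.0 * n_ab / n_cov
    return calls, burden


@pytest.fixture
def rng():
    return np.random.default_rng(20241007)
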