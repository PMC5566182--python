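"""Synthetic aCGH signals and qPCR Ct tables.

The generator reproduces the statistical structure the downstream callers
assume: each probe inside a region at copy number ``c`` (diploid reference)
draws a log2 ratio from Normal(log2(c/2), sigma_i), where sigma_i is the
baseline array noise scaled by a per-probe jitter factor and is recorded in
the output as the probe's error estimate (the quantity the error-weighted
caller consumes).  Optional uniform outliers and a sinusoidal "wave"
artifact stress-test the callers; both are off or rare by default.

The qPCR side emits threshold-cycle (Ct) triplicates under the ideal
doubling model: a locus at relative dosage q amplifies log2(q) cycles
earlier than the same locus at dosage 1, so Ct = C0 - log2(q) + noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .panel_io import GenomicInterval, Probe, ProbeSignal


@dataclass(frozen=True)
class CnvSpec:
    """One simulated aberration: an interval at a non-diploid copy number."""

    interval: GenomicInterval
    copy_number: int

    def __post_init__(self) -> None:
        if self.copy_number < 0:
            raise ValueError("copy_number must be >= 0")
        if self.copy_number == 2:
            raise ValueError("copy_number 2 is the reference state, not a CNV")


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters.

    sigma is the baseline probe noise SD in log2 units; each probe's own
    sigma_i is sigma times a jitter drawn uniformly from
    ``probe_error_jitter``.  ``homozygous_floor`` stands in for the
    undefined log2(0/2) at copy number 0.
    """

    seed: int = 0
    sigma: float = 0.2
    probe_error_jitter: tuple[float, float] = (0.8, 1.2)
    outlier_prob: float = 0.01
    outlier_range: float = 2.0
    wave_amplitude: float = 0.0
    wave_period_bp: float = 1e6
    homozygous_floor: float = -4.0

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError("sigma must be > 0")
        if not 0.0 <= self.outlier_prob <= 1.0:
            raise ValueError("outlier_prob must be in [0, 1]")
        lo, hi = self.probe_error_jitter
        if not 0 < lo <= hi:
            raise ValueError("probe_error_jitter bounds must be positive, lo <= hi")


def expected_log2(copy_number: int, homozygous_floor: float = -4.0) -> float:
    """Expected centered log2 ratio at a given copy number (diploid ref)."""
    if copy_number == 0:
        return homozygous_floor
    return math.log2(copy_number / 2.0)


def _check_specs(specs: Sequence[CnvSpec]) -> None:
    by_chrom: dict[str, list[CnvSpec]] = {}
    for s in specs:
        by_chrom.setdefault(s.interval.chrom, []).append(s)
    for chrom, group in by_chrom.items():
        group.sort(key=lambda s: s.interval.start)
        for a, b in zip(group, group[1:]):
            if a.interval.stop > b.interval.start:
                raise ValueError(
                    f"overlapping CNV specs on {chrom}: "
                    f"{a.interval.start}-{a.interval.stop} and "
                    f"{b.interval.start}-{b.interval.stop}"
                )


def simulate_signals(
    probes: Sequence[Probe],
    cnv_specs: Sequence[CnvSpec],
    config: SimConfig | None = None,
) -> list[ProbeSignal]:
    """Draw one log2 ratio per probe.

    A probe belongs to a CNV when its midpoint falls inside the spec
    interval; everything else is diploid.  Fully reproducible under the
    config seed; per-probe sigma_i values are recorded in the output.
    """
    cfg = config or SimConfig()
    _check_specs(cnv_specs)
    rng = np.random.default_rng(cfg.seed)
    n = len(probes)
    mids = np.array([p.interval.midpoint for p in probes])
    mu = np.zeros(n)
    for spec in cnv_specs:
        inside = np.array(
            [
                p.interval.chrom == spec.interval.chrom
                and spec.interval.start <= m < spec.interval.stop
                for p, m in zip(probes, mids)
            ]
        )
        mu[inside] = expected_log2(spec.copy_number, cfg.homozygous_floor)
    lo, hi = cfg.probe_error_jitter
    sigma_i = cfg.sigma * rng.uniform(lo, hi, n)
    r = mu + rng.normal(0.0, 1.0, n) * sigma_i
    outlier_draw = rng.uniform(-cfg.outlier_range, cfg.outlier_range, n)
    outlier_mask = rng.random(n) < cfg.outlier_prob
    r[outlier_mask] = outlier_draw[outlier_mask]
    if cfg.wave_amplitude:
        r += cfg.wave_amplitude * np.sin(2 * np.pi * mids / cfg.wave_period_bp)
    return [
        ProbeSignal(p.probe_id, p.interval, float(ri), float(si))
        for p, ri, si in zip(probes, r, sigma_i)
    ]


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------

CT_COLUMNS = ["sample", "locus", "role", "replicate", "Ct"]


def simulate_qpcr(
    loci: Mapping[str, float],
    replicates: int = 3,
    noise_sd: float = 0.05,
    seed: int = 0,
    reference_locus: str = "REF",
    sample_name: str = "sample1",
    calibrator_name: str = "calibrator",
    target_base_ct: float = 24.0,
    reference_base_ct: float = 22.0,
) -> pd.DataFrame:
    """Ct triplicate table for target loci at given relative dosages.

    ``loci`` maps locus name -> dosage q (> 0) in the test sample; the
    reference locus and the whole calibrator sample are at q = 1.  Columns
    match the validation reader: sample, locus, role, replicate, Ct.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    for locus, q in loci.items():
        if not q > 0:
            raise ValueError(f"dosage for {locus} must be > 0, got {q}")
    rng = np.random.default_rng(seed)
    rows = []

    def emit(sample: str, locus: str, role: str, base: float, q: float) -> None:
        for rep in range(1, replicates + 1):
            noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
            rows.append(
                {
                    "sample": sample,
                    "locus": locus,
                    "role": role,
                    "replicate": rep,
                    "Ct": base - math.log2(q) + noise,
                }
            )

    for sample, dosages in (
        (sample_name, loci),
        (calibrator_name, {locus: 1.0 for locus in loci}),
    ):
        for locus, q in dosages.items():
            emit(sample, locus, "target", target_base_ct, q)
        emit(sample, reference_locus, "reference", reference_base_ct, 1.0)
    return pd.DataFrame(rows, columns=CT_COLUMNS)
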