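"""Relative-dosage qPCR validation by the delta-delta-Ct method.

For a target locus and a reference (normalizer) locus assayed in a test
sample and a healthy diploid calibrator sample:

    dCt  = Ct_target - Ct_reference          (per sample)
    ddCt = dCt_sample - dCt_calibrator
    RQ   = 2^-ddCt

Under ideal doubling, RQ estimates the target's dosage relative to the
diploid calibrator (heterozygous loss -> 0.5, normal -> 1, heterozygous
gain -> 1.5).  RQ is computed replicate-wise (each target replicate
against the mean reference Ct) and summarized by its mean and SD.
Classification uses fixed bands on the RQ scale: <= 0.6 loss, 0.8-1.2
normal diploid, >= 1.4 gain, with the band gaps reported as
``indeterminate`` rather than forced into a call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .panel_io import CNV_GAIN, CNV_LOSS, CnvCall, GenomicInterval
from .cgh_sim import CT_COLUMNS

LOSS_MAX_RQ = 0.6
NORMAL_MIN_RQ = 0.8
NORMAL_MAX_RQ = 1.2
GAIN_MIN_RQ = 1.4

CALL_LOSS = "loss"
CALL_NORMAL = "normal"
CALL_GAIN = "gain"
CALL_INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class DosageResult:
    locus: str
    rq_mean: float
    rq_sd: float
    call: str

    def __post_init__(self) -> None:
        if not self.rq_mean > 0:
            raise ValueError("rq_mean must be > 0")


def read_ct_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in CT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"Ct table missing columns {missing}")
    return df


def classify_dosage(rq: float) -> str:
    """Three-way dosage class from a relative quantity, with explicit
    indeterminate gaps between the bands.  Boundaries are inclusive as
    written: 0.6 -> loss, 0.8 and 1.2 -> normal, 1.4 -> gain."""
    if not rq > 0:
        raise ValueError("RQ must be > 0")
    if rq <= LOSS_MAX_RQ:
        return CALL_LOSS
    if NORMAL_MIN_RQ <= rq <= NORMAL_MAX_RQ:
        return CALL_NORMAL
    if rq >= GAIN_MIN_RQ:
        return CALL_GAIN
    return CALL_INDETERMINATE


def _mean_ct(df: pd.DataFrame, sample: str, locus: str, path_desc: str) -> float:
    sel = df[(df["sample"] == sample) & (df["locus"] == locus)]["Ct"]
    if sel.empty:
        raise ValueError(f"no Ct rows for {path_desc} (sample={sample}, locus={locus})")
    if not np.isfinite(sel).all():
        raise ValueError(f"non-finite Ct for sample={sample}, locus={locus}")
    return float(sel.mean())


def relative_dosage(
    ct_table: pd.DataFrame,
    locus: str,
    reference_locus: str,
    calibrator_sample: str,
    sample: str | None = None,
) -> DosageResult:
    """RQ = 2^-ddCt of ``locus`` in ``sample`` vs the diploid calibrator.

    When ``sample`` is omitted the table must contain exactly one
    non-calibrator sample.  Replicate-wise RQ values (one per target
    replicate in the test sample) give the reported mean and SD; the call
    classifies the mean.
    """
    if sample is None:
        others = sorted(set(ct_table["sample"]) - {calibrator_sample})
        if len(others) != 1:
            raise ValueError(
                f"sample is ambiguous: found {others}; pass sample= explicitly"
            )
        sample = others[0]
    ref_sample = _mean_ct(ct_table, sample, reference_locus, "reference")
    ref_calib = _mean_ct(ct_table, calibrator_sample, reference_locus, "calibrator reference")
    target_calib = _mean_ct(ct_table, calibrator_sample, locus, "calibrator target")
    dct_calibrator = target_calib - ref_calib

    reps = ct_table[
        (ct_table["sample"] == sample) & (ct_table["locus"] == locus)
    ]["Ct"]
    if reps.empty:
        raise ValueError(f"no Ct rows for target locus {locus} in sample {sample}")
    if not np.isfinite(reps).all():
        raise ValueError(f"non-finite Ct for target locus {locus}")
    ddct = (reps.to_numpy() - ref_sample) - dct_calibrator
    rq = 2.0 ** (-ddct)
    rq_mean = float(rq.mean())
    rq_sd = float(rq.std(ddof=1)) if len(rq) > 1 else 0.0
    return DosageResult(
        locus=locus, rq_mean=rq_mean, rq_sd=rq_sd, call=classify_dosage(rq_mean)
    )


def concordance(
    array_calls: Sequence[CnvCall],
    dosage_results: Sequence[DosageResult],
    assay_loci: Mapping[str, GenomicInterval],
) -> float:
    """Fraction of qPCR assays agreeing with the array.

    Each assay locus is matched to the array call its amplicon interval
    overlaps (absence of an overlapping call means the array claims
    normal).  Agreement is gain<->gain, loss<->loss, and no-call<->normal;
    an indeterminate qPCR class counts as discordant.
    """
    if not dosage_results:
        raise ValueError("concordance is undefined with zero assays")
    agree = 0
    for res in dosage_results:
        try:
            amplicon = assay_loci[res.locus]
        except KeyError:
            raise ValueError(f"no amplicon interval for assay locus {res.locus}")
        expected = CALL_NORMAL
        for call in array_calls:
            if call.interval.overlap(amplicon) > 0:
                expected = CALL_GAIN if call.cnv_type == CNV_GAIN else CALL_LOSS
                break
        if res.call == expected:
            agree += 1
    return agree / len(dosage_results)


def write_dosage_results(results: Sequence[DosageResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("locus\trq_mean\trq_sd\tcall\n")
        for r in results:
            fh.write(f"{r.locus}\t{r.rq_mean:.4f}\t{r.rq_sd:.4f}\t{r.call}\n")
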