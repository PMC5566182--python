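"""Two-tier interval-score CNV calling over per-probe log2 ratios.

The detector flags contiguous probe runs whose summed deviation from zero
is large relative to noise.  An interval I spanning probes i..j scores

    global   (ADM-1-like):  S(I) = |sum_k r_k| / (sigma_hat * sqrt(|I|))
    weighted (ADM-2-like):  S(I) = |sum_k r_k / sigma_k| / sqrt(|I|)

where sigma_hat is a robust global noise estimate (derivative log-ratio
spread, DLRS) and sigma_k the per-probe errors carried in the signal
table.  With uniform per-probe errors equal to sigma_hat the two scores
coincide.  Calling proceeds per chromosome by recursive maximal-interval
search: the highest-scoring contiguous interval is found exhaustively, and
if it clears the score threshold it is emitted and the flanks are searched
independently.  Integration of the two modes' call sets (reciprocal
overlap matching) retains calls seen by only one algorithm, since a
strictly error-weighted analysis can drop real events that the
global-noise analysis recovers.

These statistics follow the published outline of the commercial ADM
aberration detectors; equivalence with any proprietary implementation is
not claimed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from statistics import median
from typing import Sequence

import numpy as np

from .panel_io import (
    CNV_GAIN,
    CNV_LOSS,
    CnvCall,
    GenomicInterval,
    ProbeSignal,
    TIER_BOTH,
    TIER_SINGLE_ALGORITHM,
    round_half_up,
)

logger = logging.getLogger(__name__)

MODE_GLOBAL = "global"
MODE_WEIGHTED = "weighted"
ALG_LABEL = {MODE_GLOBAL: "ADM1-like", MODE_WEIGHTED: "ADM2-like"}

# 1.4826 * MAD of successive differences, rescaled by sqrt(2) because a
# difference of two iid draws has variance 2*sigma^2.
_MAD_SCALE = 1.4826


@dataclass(frozen=True)
class CallerConfig:
    threshold_t: float = 6.0
    min_probes: int = 3
    max_interval_probes: int = 10_000
    gain_cut: float = 0.30
    loss_cut: float = -0.30
    centering: str = "mode"
    mode_bin_width: float = 0.01

    def __post_init__(self) -> None:
        if not self.threshold_t > 0:
            raise ValueError("threshold_t must be > 0")
        if self.min_probes < 1:
            raise ValueError("min_probes must be >= 1")
        if not self.loss_cut < 0 < self.gain_cut:
            raise ValueError("typing cuts must bracket zero")


def _sorted_check(signals: Sequence[ProbeSignal]) -> None:
    keys = [(s.interval.chrom, s.interval.start) for s in signals]
    if keys != sorted(keys):
        raise ValueError("signals must be sorted by chromosome and position")


def center_signal(
    signals: Sequence[ProbeSignal],
    method: str = "mode",
    bin_width: float = 0.01,
) -> tuple[list[ProbeSignal], float]:
    """Centralize log2 ratios so the dominant (diploid) state sits at 0.

    ``mode`` subtracts the center of the densest histogram bin (default
    width 0.01 log2 units), which is robust to a minority CNV fraction;
    ``median`` subtracts the median.  Returns (centered signals, offset).
    """
    if len(signals) < 10:
        raise ValueError("centering needs >= 10 probes")
    r = np.array([s.log2_ratio for s in signals])
    if method == "median":
        offset = float(np.median(r))
    elif method == "mode":
        lo, hi = r.min(), r.max()
        if hi - lo < bin_width:  # zero spread: all (near-)identical ratios
            logger.warning("signal has (near-)zero spread; offset = %g", lo)
            offset = float((lo + hi) / 2)
        else:
            # densest-bin peak on a smoothed histogram, refined by flat-
            # kernel mean-shift iterations; the refinement converges to the
            # center of the diploid bulk and is stable against a minority
            # CNV fraction, unlike a raw narrow-bin mode
            edges = np.arange(lo, hi + bin_width, bin_width)
            counts, edges = np.histogram(r, bins=edges)
            kernel = np.ones(11) / 11.0
            smooth = np.convolve(counts.astype(float), kernel, mode="same")
            k = int(np.argmax(smooth))
            offset = float((edges[k] + edges[k + 1]) / 2)
            for _ in range(5):
                window = r[np.abs(r - offset) <= 25 * bin_width]
                if window.size == 0:
                    break
                offset = float(window.mean())
    else:
        raise ValueError(f"unknown centering method {method!r}")
    centered = [replace(s, log2_ratio=s.log2_ratio - offset) for s in signals]
    return centered, offset


def dlrs(signals: Sequence[ProbeSignal]) -> float:
    """Derivative log-ratio spread: robust per-probe noise SD.

    sigma_hat = 1.4826 * median(|r_{i+1} - r_i|) / sqrt(2) within each
    chromosome (probes in genome order), pooled across chromosomes by the
    median.
    """
    if len(signals) < 2:
        raise ValueError("DLRS needs >= 2 probes")
    _sorted_check(signals)
    per_chrom: dict[str, list[float]] = {}
    for s in signals:
        per_chrom.setdefault(s.interval.chrom, []).append(s.log2_ratio)
    estimates = []
    for values in per_chrom.values():
        if len(values) < 2:
            continue
        d = np.abs(np.diff(values))
        estimates.append(_MAD_SCALE * float(np.median(d)) / np.sqrt(2.0))
    if not estimates:
        raise ValueError("no chromosome has >= 2 probes")
    return float(median(estimates))


def score_interval(
    signals: Sequence[ProbeSignal],
    i: int,
    j: int,
    mode: str = MODE_GLOBAL,
    sigma_hat: float | None = None,
) -> float:
    """Interval score S over probes i..j (inclusive indices)."""
    if not 0 <= i <= j < len(signals):
        raise IndexError("interval indices out of range")
    r = np.array([s.log2_ratio for s in signals[i : j + 1]])
    n = j - i + 1
    if mode == MODE_GLOBAL:
        if sigma_hat is None or not sigma_hat > 0:
            raise ValueError("global mode needs sigma_hat > 0")
        return float(abs(r.sum()) / (sigma_hat * np.sqrt(n)))
    if mode == MODE_WEIGHTED:
        err = np.array([s.error for s in signals[i : j + 1]])
        if np.any(err <= 0):
            raise ValueError("weighted mode needs all probe errors > 0")
        return float(abs((r / err).sum()) / np.sqrt(n))
    raise ValueError(f"unknown scoring mode {mode!r}")


def _best_interval(
    prefix: np.ndarray, lo: int, hi: int, denom_global: float | None, max_len: int
) -> tuple[float, int, int]:
    """Highest-scoring contiguous interval within [lo, hi) over weights whose
    prefix sums are given.  Ties break longest-then-leftmost.  Returns
    (score, i, j) with j inclusive."""
    n = hi - lo
    best = (-1.0, lo, lo)
    for L in range(min(n, max_len), 0, -1):
        sums = prefix[lo + L : hi + 1] - prefix[lo : hi + 1 - L]
        denom = (denom_global or 1.0) * np.sqrt(L)
        scores = np.abs(sums) / denom
        k = int(np.argmax(scores))
        if scores[k] > best[0]:
            best = (float(scores[k]), lo + k, lo + k + L - 1)
    return best


def find_aberrations(
    signals: Sequence[ProbeSignal],
    config: CallerConfig | None = None,
    mode: str = MODE_GLOBAL,
    sigma_hat: float | None = None,
    centered: bool = False,
) -> list[CnvCall]:
    """Recursive maximal-interval search per chromosome.

    The caller must pass already-centered signals (``centered=True``);
    sigma_hat defaults to the DLRS estimate.  Intervals clearing the score
    threshold are typed gain/loss by their mean centered log2 ratio against
    the configured cuts; intervals typing neither (or with fewer than
    ``min_probes`` probes) are discarded, but their flanks are still
    searched, so an isolated outlier cannot mask a real call.
    """
    cfg = config or CallerConfig()
    if mode not in ALG_LABEL:
        raise ValueError(f"unknown mode {mode!r}")
    if not centered:
        raise ValueError(
            "find_aberrations expects centered signals (run center_signal "
            "and pass centered=True)"
        )
    _sorted_check(signals)
    if sigma_hat is None:
        sigma_hat = dlrs(signals)
    if not sigma_hat > 0:
        raise ValueError("sigma_hat must be > 0 (flat signal?)")

    calls: list[CnvCall] = []
    offset = 0
    by_chrom: dict[str, list[ProbeSignal]] = {}
    for s in signals:
        by_chrom.setdefault(s.interval.chrom, []).append(s)

    for chrom in sorted(by_chrom):
        group = by_chrom[chrom]
        r = np.array([s.log2_ratio for s in group])
        if mode == MODE_GLOBAL:
            w, denom = r, sigma_hat
        else:
            err = np.array([s.error for s in group])
            if np.any(err <= 0):
                raise ValueError("weighted mode needs all probe errors > 0")
            w, denom = r / err, None
        prefix = np.concatenate([[0.0], np.cumsum(w)])
        segments = [(0, len(group))]
        while segments:
            lo, hi = segments.pop()
            if hi - lo < 1:
                continue
            score, i, j = _best_interval(
                prefix, lo, hi, denom, cfg.max_interval_probes
            )
            if score < cfg.threshold_t:
                continue
            n_probes = j - i + 1
            mean_log2 = float(r[i : j + 1].mean())
            if n_probes >= cfg.min_probes:
                cnv_type = None
                if mean_log2 >= cfg.gain_cut:
                    cnv_type = CNV_GAIN
                elif mean_log2 <= cfg.loss_cut:
                    cnv_type = CNV_LOSS
                if cnv_type is not None:
                    calls.append(
                        CnvCall(
                            interval=GenomicInterval(
                                chrom,
                                group[i].interval.start,
                                group[j].interval.stop,
                                group[i].interval.assembly,
                            ),
                            cnv_type=cnv_type,
                            n_probes=n_probes,
                            mean_log2=mean_log2,
                            score=score,
                            algorithms=(ALG_LABEL[mode],),
                            tier=TIER_SINGLE_ALGORITHM,
                            cn_estimate=copy_number_estimate(mean_log2),
                        )
                    )
            segments.append((lo, i))
            segments.append((j + 1, hi))
    calls.sort(key=lambda c: (c.interval.chrom, c.interval.start))
    return calls


def copy_number_estimate(mean_log2: float) -> int:
    """Integer copy number from a mean centered log2 ratio: round(2*2^m),
    clamped to [0, 8].  Maps +0.58 -> 3 and -1 -> 1."""
    return int(min(8, max(0, round_half_up(2.0 * 2.0 ** mean_log2))))


def call_aberrations(
    signals: Sequence[ProbeSignal],
    config: CallerConfig | None = None,
    mode: str = MODE_GLOBAL,
) -> tuple[list[CnvCall], dict]:
    """Convenience wrapper: center, estimate noise, search.

    Returns (calls, metadata) where metadata records the centering offset
    and the DLRS noise estimate."""
    cfg = config or CallerConfig()
    centered, offset = center_signal(
        signals, method=cfg.centering, bin_width=cfg.mode_bin_width
    )
    sigma_hat = dlrs(centered)
    calls = find_aberrations(
        centered, cfg, mode=mode, sigma_hat=sigma_hat, centered=True
    )
    return calls, {"offset": offset, "sigma_hat": sigma_hat}


# ---------------------------------------------------------------------------
# Integration of the two algorithms
# ---------------------------------------------------------------------------


def _reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> float:
    ov = a.overlap(b)
    if ov == 0:
        return 0.0
    return min(ov / a.length, ov / b.length)


def integrate_calls(
    calls_adm1: Sequence[CnvCall],
    calls_adm2: Sequence[CnvCall],
    min_reciprocal_overlap: float = 0.5,
) -> list[CnvCall]:
    """Merge the two algorithms' call sets.

    Calls on the same chromosome with the same type and reciprocal overlap
    >= the cutoff merge into one call (union interval, max score, union of
    algorithm labels, tier "both"); unmatched calls from either side are
    retained with tier "single-algorithm" — a call seen by only one
    algorithm may still be real and is kept for orthogonal validation.
    """
    unmatched2 = list(calls_adm2)
    merged: list[CnvCall] = []
    for c1 in calls_adm1:
        best_j, best_ro = None, 0.0
        for j, c2 in enumerate(unmatched2):
            if c2.cnv_type != c1.cnv_type:
                continue
            ro = _reciprocal_overlap(c1.interval, c2.interval)
            if ro >= min_reciprocal_overlap and ro > best_ro:
                best_j, best_ro = j, ro
        if best_j is None:
            merged.append(replace(c1, tier=TIER_SINGLE_ALGORITHM))
            continue
        c2 = unmatched2.pop(best_j)
        lead = c1 if c1.score >= c2.score else c2
        union = GenomicInterval(
            c1.interval.chrom,
            min(c1.interval.start, c2.interval.start),
            max(c1.interval.stop, c2.interval.stop),
            c1.interval.assembly,
        )
        merged.append(
            CnvCall(
                interval=union,
                cnv_type=c1.cnv_type,
                n_probes=max(c1.n_probes, c2.n_probes),
                mean_log2=lead.mean_log2,
                score=max(c1.score, c2.score),
                algorithms=tuple(sorted(set(c1.algorithms) | set(c2.algorithms))),
                tier=TIER_BOTH,
                cn_estimate=lead.cn_estimate,
                genes=lead.genes,
                db_status=lead.db_status,
            )
        )
    merged.extend(replace(c, tier=TIER_SINGLE_ALGORITHM) for c in unmatched2)
    merged.sort(key=lambda c: (c.interval.chrom, c.interval.start))
    return merged
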