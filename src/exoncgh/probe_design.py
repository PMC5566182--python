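"""Isothermal ~60-mer probe selection over exon targets.

Candidate windows are slid across each exon, scored on sequence-intrinsic
quality (melting temperature, GC content, homopolymer runs,
self-complementarity), and the best few per exon are kept, mirroring how a
commercial array designer draws "best-performing" probes from a
pre-validated high-density library.  Exons where no candidate survives the
filters fall back to plain genomic tiling with relaxed thresholds; exons
where even tiling yields nothing are reported as uncovered.

The melting-temperature model is the unified nearest-neighbor
thermodynamic parameter set (SantaLucia & Hicks 2004) as implemented in
Biopython, evaluated at fixed, documented buffer constants chosen so that
a balanced random 60-mer sits near the 80 degC isothermal design target:
150 mM Na+, 250 nM of each strand, entropic salt correction.

Specificity is approximated by sequence-intrinsic penalties only; no
genome-wide uniqueness search is performed (a k-mer uniqueness hook can be
layered on top of :func:`score_candidate` by callers that need it).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from Bio.SeqUtils import MeltingTemp as _mt

from .panel_io import HD_LIBRARY, TILING, ExonTarget, GenomicInterval, Probe

logger = logging.getLogger(__name__)

# Fixed hybridization-buffer constants of the Tm model (documented above).
TM_NA_MM = 150.0
TM_OLIGO_NM = 250.0
TM_SALT_CORRECTION = 5  # entropic correction, 0.368*(N-1)*ln[Na+]

_ACGT = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class DesignConfig:
    """Tunable parameters of probe selection.

    All lengths in bases, temperatures in degC.  ``default_probe_error`` is
    the per-probe log2-ratio error assigned to freshly designed probes.
    """

    probe_length: int = 60
    tm_target_c: float = 80.0
    tm_tolerance_c: float = 5.0
    max_probes_per_exon: int = 2
    min_probes_per_exon: int = 1
    step_bp: int = 1
    max_homopolymer: int = 6
    gc_min: float = 0.30
    gc_max: float = 0.70
    max_self_complement: int = 12
    default_probe_error: float = 0.2

    def __post_init__(self) -> None:
        if self.min_probes_per_exon > self.max_probes_per_exon:
            raise ValueError("min_probes_per_exon must be <= max_probes_per_exon")
        if self.probe_length < 20:
            raise ValueError("probe_length must be >= 20")
        if self.step_bp < 1:
            raise ValueError("step_bp must be >= 1")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def melting_temperature(sequence: str, config: DesignConfig | None = None) -> float:
    """Nearest-neighbor duplex Tm in degC at the fixed buffer constants."""
    seq = sequence.upper()
    if len(seq) < 8:
        raise ValueError("sequence too short for a nearest-neighbor Tm (need >= 8 nt)")
    if not set(seq) <= _ACGT:
        raise ValueError("ambiguous or non-DNA bases in sequence")
    return float(
        _mt.Tm_NN(
            seq,
            nn_table=_mt.DNA_NN4,
            Na=TM_NA_MM,
            dnac1=TM_OLIGO_NM,
            dnac2=TM_OLIGO_NM,
            saltcorr=TM_SALT_CORRECTION,
        )
    )


def gc_fraction(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq)


def max_homopolymer_run(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def self_complement_run(seq: str) -> int:
    """Length of the longest stretch of ``seq`` that base-pairs with another
    stretch of itself (longest common substring with the reverse
    complement), a cheap self-dimer/hairpin proxy."""
    rc = reverse_complement(seq)

    def has_common_kmer(k: int) -> bool:
        if k == 0:
            return True
        kmers = {seq[i : i + k] for i in range(len(seq) - k + 1)}
        return any(rc[i : i + k] in kmers for i in range(len(rc) - k + 1))

    lo, hi = 0, len(seq)
    while lo < hi:  # binary search for the largest k with a common k-mer
        mid = (lo + hi + 1) // 2
        if has_common_kmer(mid):
            lo = mid
        else:
            hi = mid - 1
    return lo


def score_candidate(
    sequence: str,
    config: DesignConfig | None = None,
    tm_c: float | None = None,
) -> float:
    """Quality score in [0, 1]; 0 iff a hard filter fails.

    Hard filters: non-ACGT bases, homopolymer run > max, GC outside bounds,
    self-complementary stretch > cap.  Surviving candidates get a product
    of soft penalties for Tm deviation from target, GC deviation from 50 %,
    homopolymer run length and self-complementarity.
    """
    cfg = config or DesignConfig()
    seq = sequence.upper()
    if not seq or not set(seq) <= _ACGT:
        return 0.0
    run = max_homopolymer_run(seq)
    if run > cfg.max_homopolymer:
        return 0.0
    gc = gc_fraction(seq)
    if not cfg.gc_min <= gc <= cfg.gc_max:
        return 0.0
    sc = self_complement_run(seq)
    if sc > cfg.max_self_complement:
        return 0.0
    if tm_c is None:
        tm_c = melting_temperature(seq, cfg)
    f_tm = max(0.0, 1.0 - 0.5 * ((tm_c - cfg.tm_target_c) / cfg.tm_tolerance_c) ** 2)
    f_gc = 1.0 - ((gc - 0.5) / 0.5) ** 2
    f_run = 1.0 - 0.5 * (run - 1) / cfg.max_homopolymer
    f_sc = 1.0 - 0.5 * (sc / cfg.max_self_complement) ** 2
    return f_tm * f_gc * f_run * f_sc


# ---------------------------------------------------------------------------
# Selection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _Candidate:
    start: int  # 0-based genomic start of the window
    sequence: str
    tm_c: float
    score: float


def _chrom_sequence(genome, chrom: str) -> str:
    try:
        rec = genome[chrom]
    except KeyError:
        raise ValueError(f"chromosome {chrom!r} absent from genome FASTA") from None
    return str(rec[:]).upper()


def _window_starts(target: GenomicInterval, L: int, step: int, chrom_len: int):
    """Candidate window starts across the target; a target shorter than the
    probe extends symmetrically into flanking sequence."""
    if target.length >= L:
        return range(target.start, target.stop - L + 1, step)
    anchor = max(0, min(target.midpoint - L // 2, chrom_len - L))
    return range(anchor, anchor + 1)


def _candidates(
    chrom_seq: str, target: GenomicInterval, cfg: DesignConfig,
    tm_tolerance: float, step: int,
) -> list[_Candidate]:
    out = []
    L = cfg.probe_length
    for w in _window_starts(target, L, step, len(chrom_seq)):
        seq = chrom_seq[w : w + L]
        if len(seq) < L or not set(seq) <= _ACGT:
            continue
        try:
            tm = melting_temperature(seq, cfg)
        except ValueError:
            continue
        if abs(tm - cfg.tm_target_c) > tm_tolerance:
            continue
        score = score_candidate(seq, cfg, tm_c=tm)
        if score > 0:
            out.append(_Candidate(w, seq, tm, score))
    return out


def _spread_pick(
    candidates: list[_Candidate], target: GenomicInterval, k: int
) -> list[_Candidate]:
    """Up to k candidates, best score per equal-width positional bin so the
    picks are maximally spread across the exon; empty bins are backfilled
    with the next-best remaining candidates.  Ties break leftmost."""
    if k >= len(candidates):
        return sorted(candidates, key=lambda c: c.start)
    lo = min(c.start for c in candidates)
    hi = max(c.start for c in candidates) + 1
    width = (hi - lo) / k
    best_per_bin: dict[int, _Candidate] = {}
    for c in candidates:
        b = min(k - 1, int((c.start - lo) / width))
        cur = best_per_bin.get(b)
        if cur is None or (c.score, -c.start) > (cur.score, -cur.start):
            best_per_bin[b] = c
    picked = list(best_per_bin.values())
    if len(picked) < k:
        rest = sorted(
            (c for c in candidates if c not in picked),
            key=lambda c: (-c.score, c.start),
        )
        picked.extend(rest[: k - len(picked)])
    return sorted(picked, key=lambda c: c.start)


def _to_probes(
    cands: list[_Candidate], target: ExonTarget, cfg: DesignConfig,
    source: str, assembly: str,
) -> list[Probe]:
    return [
        Probe(
            probe_id=f"{target.gene}_e{target.exon_index}_p{i + 1}",
            interval=GenomicInterval(
                target.interval.chrom, c.start, c.start + cfg.probe_length, assembly
            ),
            sequence=c.sequence,
            tm_c=c.tm_c,
            source=source,
            error=cfg.default_probe_error,
        )
        for i, c in enumerate(cands)
    ]


def tile_region(
    target: ExonTarget, genome, config: DesignConfig | None = None
) -> list[Probe]:
    """Fallback placement: end-to-end windows at probe-length stride with a
    doubled Tm tolerance; hard-fail windows are skipped, neighbors kept."""
    cfg = config or DesignConfig()
    chrom_seq = _chrom_sequence(genome, target.interval.chrom)
    cands = _candidates(
        chrom_seq, target.interval, cfg,
        tm_tolerance=2 * cfg.tm_tolerance_c, step=cfg.probe_length,
    )
    return _to_probes(cands, target, cfg, TILING, target.interval.assembly)


def select_probes(
    targets: Sequence[ExonTarget], genome, config: DesignConfig | None = None
) -> tuple[list[Probe], list[ExonTarget]]:
    """Select up to ``max_probes_per_exon`` probes per exon target.

    ``genome`` is a mapping of chromosome name to sequence record
    (e.g. ``pyfaidx.Fasta``).  Returns (probes, uncovered targets); the
    covered and uncovered targets partition the input.  Selection is
    deterministic: equal scores break to the leftmost start.
    """
    cfg = config or DesignConfig()
    probes: list[Probe] = []
    uncovered: list[ExonTarget] = []
    chrom_cache: dict[str, str] = {}
    for target in targets:
        chrom = target.interval.chrom
        if chrom not in chrom_cache:
            chrom_cache[chrom] = _chrom_sequence(genome, chrom)
        cands = _candidates(
            chrom_cache[chrom], target.interval, cfg,
            tm_tolerance=cfg.tm_tolerance_c, step=cfg.step_bp,
        )
        # drop duplicated sequences, keeping the leftmost occurrence
        seen: set[str] = set()
        unique = [c for c in cands if not (c.sequence in seen or seen.add(c.sequence))]
        if unique:
            picked = _spread_pick(unique, target.interval, cfg.max_probes_per_exon)
            probes.extend(
                _to_probes(picked, target, cfg, HD_LIBRARY, target.interval.assembly)
            )
            continue
        tiles = tile_region(target, genome, cfg)
        if tiles:
            probes.extend(tiles)
        else:
            logger.info(
                "target %s|%s left uncovered", target.gene, target.exon_index
            )
            uncovered.append(target)
    probes.sort(key=lambda p: (p.interval.chrom, p.interval.start, p.probe_id))
    return probes, uncovered
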