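"""Domain model and file I/O for exon-targeted aCGH panels.

This module holds the shared genomic value types (intervals, exon targets,
probes, per-probe signals, CNV calls, gene panels) and the readers/writers
for the plain-text formats the toolkit speaks: BED for targets/probes/
annotation databases, TSV for probe signals and call reports, VCF 4.2 for
calls, and JSON/TSV for gene-panel definitions.

Coordinate conventions
----------------------
Internally every interval is **0-based half-open** (BED-style).  BED files
are read and written unchanged.  TSV reports and signal tables print
**1-based inclusive** positions, matching genome-browser display; the
conversion happens exactly once, at the I/O boundary.
"""

from __future__ import annotations

import json
import logging
import math
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from statistics import median
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

DEFAULT_ASSEMBLY = "GRCh37/hg19"

HD_LIBRARY = "HD_library"
TILING = "tiling"
PROBE_SOURCES = (HD_LIBRARY, TILING)


def round_half_up(x: float) -> int:
    """Round to nearest integer, halves away from zero-bias (0.5 -> 1)."""
    return int(math.floor(x + 0.5))


# ---------------------------------------------------------------------------
# Value types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval on a named assembly."""

    chrom: str
    start: int
    stop: int
    assembly: str = DEFAULT_ASSEMBLY

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not self.start < self.stop:
            raise ValueError(
                f"degenerate interval {self.chrom}:{self.start}-{self.stop} "
                "(start must be < stop)"
            )

    @classmethod
    def from_1based_inclusive(
        cls, chrom: str, start: int, stop: int, assembly: str = DEFAULT_ASSEMBLY
    ) -> "GenomicInterval":
        return cls(chrom, start - 1, stop, assembly)

    def to_1based_inclusive(self) -> tuple[str, int, int]:
        return (self.chrom, self.start + 1, self.stop)

    @property
    def length(self) -> int:
        return self.stop - self.start

    @property
    def size_kb(self) -> float:
        """Length in kb; equals (stop1 - start1 + 1)/1000 for the printed
        1-based inclusive coordinates."""
        return self.length / 1000.0

    @property
    def midpoint(self) -> int:
        return (self.start + self.stop) // 2

    def overlap(self, other: "GenomicInterval") -> int:
        """Overlap in bp (0 if disjoint or on different chromosomes)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.stop, other.stop) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.stop <= self.stop
        )


@dataclass(frozen=True)
class ExonTarget:
    """One exon-level target region of a panel gene."""

    gene: str
    exon_index: int
    interval: GenomicInterval

    def __post_init__(self) -> None:
        if self.exon_index < 1:
            raise ValueError("exon_index is 1-based (must be >= 1)")


@dataclass(frozen=True)
class Probe:
    """A placed oligonucleotide probe.

    ``error`` is the per-probe log2-ratio error sigma_i used by the
    error-weighted caller; probes fresh from design carry the design-time
    default until a hybridization provides a measured value.
    """

    probe_id: str
    interval: GenomicInterval
    sequence: str | None = None
    tm_c: float | None = None
    source: str = HD_LIBRARY
    error: float = 0.2

    def __post_init__(self) -> None:
        if self.source not in PROBE_SOURCES:
            raise ValueError(f"unknown probe source {self.source!r}")
        if not self.error > 0:
            raise ValueError("probe error must be > 0")


@dataclass(frozen=True)
class ProbeSignal:
    """A probe with its observed (or simulated) log2 ratio r_i and error."""

    probe_id: str
    interval: GenomicInterval
    log2_ratio: float
    error: float

    def __post_init__(self) -> None:
        if not self.error > 0:
            raise ValueError("probe error must be > 0")


@dataclass(frozen=True)
class PanelEntry:
    gene: str
    intervals: tuple[GenomicInterval, ...] = ()
    panels: frozenset[str] = frozenset()
    causative: bool = False

    def __post_init__(self) -> None:
        if not self.panels:
            raise ValueError(f"gene {self.gene}: every entry needs >=1 panel label")


@dataclass
class GenePanel:
    """Gene -> disease-panel assignment with causative flags.

    A gene may belong to several disease panels (e.g. shared between the
    Parkinson panel and an epilepsy panel); panel-overlap accounting follows
    that multiplicity.
    """

    entries: dict[str, PanelEntry] = field(default_factory=dict)

    def add(self, entry: PanelEntry) -> None:
        if entry.gene in self.entries:
            raise ValueError(f"duplicate gene symbol {entry.gene}")
        self.entries[entry.gene] = entry

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, gene: str) -> bool:
        return gene in self.entries

    def get(self, gene: str) -> PanelEntry | None:
        return self.entries.get(gene)

    def counts(self, focal_panel: str) -> dict[str, int]:
        """Total / focal-specific / shared gene counts for one disease panel.

        A gene is *specific* when the focal panel is its only label and
        *shared* when it carries the focal label plus at least one other.
        """
        total = len(self.entries)
        specific = sum(
            1 for e in self.entries.values() if e.panels == {focal_panel}
        )
        shared = sum(
            1
            for e in self.entries.values()
            if focal_panel in e.panels and len(e.panels) > 1
        )
        return {"total": total, "specific": specific, "shared": shared}

    def genes_overlapping(self, interval: GenomicInterval) -> tuple[str, ...]:
        """Panel genes whose interval overlaps ``interval`` by >= 1 bp."""
        hits = [
            e.gene
            for e in self.entries.values()
            if any(interval.overlap(iv) > 0 for iv in e.intervals)
        ]
        return tuple(sorted(hits))


@dataclass(frozen=True)
class DesignSummary:
    """Coverage accounting for one probe design over one target set."""

    total_genes: int
    total_targets: int
    covered_targets: int
    uncovered_targets: int
    coverage_pct: int
    coverage_fraction: float
    total_probes: int
    probes_by_source: Mapping[str, int]
    median_probe_spacing_bp: float | None
    mean_target_size_bp: float

    def __post_init__(self) -> None:
        if self.covered_targets + self.uncovered_targets != self.total_targets:
            raise ValueError("covered + uncovered must equal total targets")
        if self.total_probes != sum(self.probes_by_source.values()):
            raise ValueError("total_probes must equal sum over sources")


CNV_GAIN = "gain"
CNV_LOSS = "loss"

TIER_BOTH = "both"
TIER_SINGLE_ALGORITHM = "single-algorithm"
TIER_SINGLE_PROBE = "single-probe"


@dataclass(frozen=True)
class CnvCall:
    """A contiguous aberrant interval emitted by the caller."""

    interval: GenomicInterval
    cnv_type: str
    n_probes: int
    mean_log2: float
    score: float
    algorithms: tuple[str, ...] = ()
    tier: str = TIER_SINGLE_ALGORITHM
    cn_estimate: int = 2
    genes: tuple[str, ...] = ()
    db_status: str = "not reported"

    def __post_init__(self) -> None:
        if self.cnv_type not in (CNV_GAIN, CNV_LOSS):
            raise ValueError(f"cnv_type must be gain/loss, got {self.cnv_type!r}")
        if self.n_probes < 1:
            raise ValueError("n_probes must be >= 1")
        if self.cnv_type == CNV_GAIN and not self.mean_log2 > 0:
            raise ValueError("gain call requires positive mean_log2")
        if self.cnv_type == CNV_LOSS and not self.mean_log2 < 0:
            raise ValueError("loss call requires negative mean_log2")
        if not 0 <= self.cn_estimate <= 8:
            raise ValueError("cn_estimate outside [0, 8]")

    @property
    def size_kb(self) -> float:
        return self.interval.size_kb


# ---------------------------------------------------------------------------
# BED / TSV parsing helpers
# ---------------------------------------------------------------------------


def _read_header(fh) -> tuple[list[str], int]:
    """First non-comment line split on tabs, plus its 1-based line number."""
    lineno = 0
    for raw in fh:
        lineno += 1
        if raw.startswith("#"):
            continue
        return raw.rstrip("\n").split("\t"), lineno
    return [], lineno


class ParseError(ValueError):
    """A malformed line in an input file; carries the 1-based line number."""

    def __init__(self, path: str | Path, lineno: int, msg: str):
        super().__init__(f"{path}:{lineno}: {msg}")
        self.path = str(path)
        self.lineno = lineno


def _bed_rows(path: str | Path, min_cols: int):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < min_cols:
                raise ParseError(
                    path, lineno, f"expected >= {min_cols} columns, got {len(cols)}"
                )
            yield lineno, cols


def _bed_interval(path, lineno, cols, assembly) -> GenomicInterval:
    try:
        start, stop = int(cols[1]), int(cols[2])
    except ValueError as exc:
        raise ParseError(path, lineno, f"non-integer coordinates: {exc}") from None
    try:
        return GenomicInterval(cols[0], start, stop, assembly)
    except ValueError as exc:
        raise ParseError(path, lineno, str(exc)) from None


def load_targets(
    path: str | Path, assembly: str = DEFAULT_ASSEMBLY
) -> list[ExonTarget]:
    """Read exon targets from a >=4-column BED whose name is ``gene|exon``."""
    targets: list[ExonTarget] = []
    seen: set[tuple[str, int]] = set()
    for lineno, cols in _bed_rows(path, 4):
        interval = _bed_interval(path, lineno, cols, assembly)
        name = cols[3]
        if "|" not in name:
            raise ParseError(path, lineno, f"name {name!r} is not gene|exon")
        gene, _, exon_s = name.partition("|")
        try:
            exon = int(exon_s)
        except ValueError:
            raise ParseError(path, lineno, f"exon ordinal {exon_s!r} not an integer")
        if (gene, exon) in seen:
            raise ParseError(path, lineno, f"duplicate exon {gene}|{exon}")
        seen.add((gene, exon))
        targets.append(ExonTarget(gene, exon, interval))
    if not targets:
        logger.warning("no targets parsed from %s", path)
    targets.sort(key=lambda t: (t.interval.chrom, t.interval.start))
    return targets


def write_targets(targets: Sequence[ExonTarget], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in targets:
            iv = t.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.stop}\t{t.gene}|{t.exon_index}\n")


_PROBE_TSV_COLS = [
    "probe_id", "chrom", "start", "stop", "sequence", "tm_c", "source", "error",
]


def write_probes(probes: Sequence[Probe], path: str | Path) -> None:
    """Probe table as TSV (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("\t".join(_PROBE_TSV_COLS) + "\n")
        for p in probes:
            chrom, s1, e1 = p.interval.to_1based_inclusive()
            tm = "" if p.tm_c is None else format(p.tm_c, ".17g")
            fh.write(
                f"{p.probe_id}\t{chrom}\t{s1}\t{e1}\t{p.sequence or ''}\t"
                f"{tm}\t{p.source}\t{format(p.error, '.17g')}\n"
            )


def load_probes(path: str | Path, assembly: str = DEFAULT_ASSEMBLY) -> list[Probe]:
    """Read probes from the TSV dialect written by :func:`write_probes`."""
    probes: list[Probe] = []
    with open(path) as fh:
        header, hline = _read_header(fh)
        if header[:4] != _PROBE_TSV_COLS[:4]:
            raise ParseError(path, hline, f"unexpected header {header!r}")
        for lineno, raw in enumerate(fh, hline + 1):
            if not raw.strip():
                continue
            cols = raw.rstrip("\n").split("\t")
            row = dict(zip(header, cols))
            interval = GenomicInterval.from_1based_inclusive(
                row["chrom"], int(row["start"]), int(row["stop"]), assembly
            )
            probes.append(
                Probe(
                    probe_id=row["probe_id"],
                    interval=interval,
                    sequence=row.get("sequence") or None,
                    tm_c=float(row["tm_c"]) if row.get("tm_c") else None,
                    source=row.get("source") or HD_LIBRARY,
                    error=float(row.get("error") or 0.2),
                )
            )
    return probes


def load_probes_bed(
    path: str | Path, assembly: str = DEFAULT_ASSEMBLY, error: float = 0.2
) -> list[Probe]:
    """Read probes from a >=4-column BED (name column = probe id)."""
    probes = []
    for lineno, cols in _bed_rows(path, 4):
        interval = _bed_interval(path, lineno, cols, assembly)
        probes.append(Probe(probe_id=cols[3], interval=interval, error=error))
    return probes


_SIGNAL_TSV_COLS = ["probe_id", "chrom", "start", "stop", "log2_ratio", "probe_error"]


def write_signals(
    signals: Sequence[ProbeSignal], path: str | Path,
    header_comment: str | None = None,
) -> None:
    """Per-probe log2-ratio table, a simplified Feature-Extraction-like TSV."""
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("\t".join(_SIGNAL_TSV_COLS) + "\n")
        for s in signals:
            chrom, s1, e1 = s.interval.to_1based_inclusive()
            fh.write(
                f"{s.probe_id}\t{chrom}\t{s1}\t{e1}\t"
                f"{format(s.log2_ratio, '.17g')}\t{format(s.error, '.17g')}\n"
            )


def read_signals(
    path: str | Path, assembly: str = DEFAULT_ASSEMBLY
) -> list[ProbeSignal]:
    signals: list[ProbeSignal] = []
    with open(path) as fh:
        header, hline = _read_header(fh)
        if header != _SIGNAL_TSV_COLS:
            raise ParseError(path, hline, f"unexpected header {header!r}")
        for lineno, raw in enumerate(fh, hline + 1):
            if not raw.strip():
                continue
            cols = raw.rstrip("\n").split("\t")
            if len(cols) != len(header):
                raise ParseError(path, lineno, "wrong column count")
            signals.append(
                ProbeSignal(
                    probe_id=cols[0],
                    interval=GenomicInterval.from_1based_inclusive(
                        cols[1], int(cols[2]), int(cols[3]), assembly
                    ),
                    log2_ratio=float(cols[4]),
                    error=float(cols[5]),
                )
            )
    signals.sort(key=lambda s: (s.interval.chrom, s.interval.start))
    return signals


def load_panel(path: str | Path, assembly: str = DEFAULT_ASSEMBLY) -> GenePanel:
    """Gene-panel definitions from JSON (list of entries) or TSV.

    JSON: ``[{"gene": ..., "panels": [...], "causative": bool,
    "intervals": [["chr1", start, stop], ...]}, ...]``.
    TSV columns: gene, chrom, start, stop, panels (';'-separated), causative.
    """
    path = Path(path)
    panel = GenePanel()
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            data = json.load(fh)
        for rec in data:
            panel.add(
                PanelEntry(
                    gene=rec["gene"],
                    intervals=tuple(
                        GenomicInterval(c, int(a), int(b), assembly)
                        for c, a, b in rec.get("intervals", [])
                    ),
                    panels=frozenset(rec["panels"]),
                    causative=bool(rec.get("causative", False)),
                )
            )
        return panel
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for lineno, raw in enumerate(fh, 2):
            if not raw.strip():
                continue
            row = dict(zip(header, raw.rstrip("\n").split("\t")))
            try:
                panel.add(
                    PanelEntry(
                        gene=row["gene"],
                        intervals=(
                            GenomicInterval(
                                row["chrom"], int(row["start"]), int(row["stop"]),
                                assembly,
                            ),
                        )
                        if row.get("chrom")
                        else (),
                        panels=frozenset(row["panels"].split(";")),
                        causative=row.get("causative", "").lower()
                        in ("1", "true", "yes"),
                    )
                )
            except (KeyError, ValueError) as exc:
                raise ParseError(path, lineno, str(exc)) from None
    return panel


def write_panel(panel: GenePanel, path: str | Path) -> None:
    data = [
        {
            "gene": e.gene,
            "panels": sorted(e.panels),
            "causative": e.causative,
            "intervals": [[iv.chrom, iv.start, iv.stop] for iv in e.intervals],
        }
        for e in panel.entries.values()
    ]
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_interval_db(
    path: str | Path, assembly: str = DEFAULT_ASSEMBLY
) -> list[tuple[GenomicInterval, str]]:
    """Annotation database: BED with the variant accession in the name column."""
    db = []
    for lineno, cols in _bed_rows(path, 4):
        db.append((_bed_interval(path, lineno, cols, assembly), cols[3]))
    db.sort(key=lambda t: (t[0].chrom, t[0].start))
    return db


# ---------------------------------------------------------------------------
# Coverage accounting
# ---------------------------------------------------------------------------


def _probe_trees(probes: Iterable[Probe]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for p in probes:
        trees.setdefault(p.interval.chrom, IntervalTree()).addi(
            p.interval.start, p.interval.stop, p.probe_id
        )
    return trees


def compute_design_summary(
    targets: Sequence[ExonTarget], probes: Sequence[Probe]
) -> DesignSummary:
    """Coverage statistics of a probe set over a target set.

    A target counts as covered iff at least one probe overlaps it by >= 1 bp.
    ``coverage_pct`` is rounded half-up to a whole percent; the exact
    fraction is kept alongside.  Median probe spacing pools consecutive
    start-to-start distances within each chromosome.
    """
    if not targets:
        raise ValueError("coverage is undefined for an empty target list")
    trees = _probe_trees(probes)
    covered = sum(
        1
        for t in targets
        if t.interval.chrom in trees
        and trees[t.interval.chrom].overlap(t.interval.start, t.interval.stop)
    )
    total = len(targets)
    fraction = covered / total
    starts_by_chrom: dict[str, list[int]] = {}
    for p in probes:
        starts_by_chrom.setdefault(p.interval.chrom, []).append(p.interval.start)
    spacings: list[int] = []
    for starts in starts_by_chrom.values():
        starts.sort()
        spacings.extend(b - a for a, b in zip(starts, starts[1:]))
    return DesignSummary(
        total_genes=len({t.gene for t in targets}),
        total_targets=total,
        covered_targets=covered,
        uncovered_targets=total - covered,
        coverage_pct=round_half_up(100.0 * fraction),
        coverage_fraction=fraction,
        total_probes=len(probes),
        probes_by_source=dict(Counter(p.source for p in probes)),
        median_probe_spacing_bp=float(median(spacings)) if spacings else None,
        mean_target_size_bp=sum(t.interval.length for t in targets) / total,
    )


def compare_designs(
    targets: Sequence[ExonTarget], probe_sets: Mapping[str, Sequence[Probe]]
) -> dict[str, DesignSummary]:
    """One DesignSummary per named probe set over the same targets."""
    if not probe_sets:
        raise ValueError("need at least one probe set")
    assemblies = {t.interval.assembly for t in targets}
    for name, probes in probe_sets.items():
        assemblies |= {p.interval.assembly for p in probes}
    if len(assemblies) > 1:
        raise ValueError(f"mismatched assembly labels: {sorted(assemblies)}")
    return {name: compute_design_summary(targets, ps) for name, ps in probe_sets.items()}


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

ALMOST_CONTAINED_FRACTION = 0.9


def classify_containment(
    call: GenomicInterval, db: Sequence[tuple[GenomicInterval, str]]
) -> str:
    """Classify a call interval against a structural-variant database.

    Returns one of: ``completely contained within <labels>``, ``almost
    completely contained within <labels>`` (contained fraction >= 0.9 but
    < 1), ``overlaps <labels>``, or ``not reported``.  Categories are
    mutually exclusive and exhaustive; the strongest applicable one wins.
    """
    containing = [lab for iv, lab in db if iv.contains(call)]
    if containing:
        return "completely contained within " + ", ".join(sorted(containing))
    fractions = {
        lab: call.overlap(iv) / call.length for iv, lab in db if call.overlap(iv) > 0
    }
    if not fractions:
        return "not reported"
    best = max(fractions.values())
    if best >= ALMOST_CONTAINED_FRACTION:
        labels = sorted(
            lab for lab, f in fractions.items() if f >= ALMOST_CONTAINED_FRACTION
        )
        return "almost completely contained within " + ", ".join(labels)
    return "overlaps " + ", ".join(sorted(fractions))


def annotate_calls(
    calls: Sequence[CnvCall],
    panel: GenePanel | None = None,
    db: Sequence[tuple[GenomicInterval, str]] = (),
) -> list[CnvCall]:
    """Attach overlapping panel genes and database containment status."""
    out = []
    for c in calls:
        genes = panel.genes_overlapping(c.interval) if panel is not None else c.genes
        out.append(
            replace(c, genes=genes, db_status=classify_containment(c.interval, db))
        )
    return out


# ---------------------------------------------------------------------------
# Call writers / readers
# ---------------------------------------------------------------------------

_CALL_TSV_COLS = [
    "cnv_type", "chrom", "start", "stop", "size_kb", "n_probes", "mean_log2",
    "score", "algorithms", "tier", "cn_estimate", "genes", "db_status",
]


def _fmt_size_kb(kb: float) -> str:
    return str(round_half_up(kb)) if kb >= 1.0 else format(kb, ".2f")


def _call_tsv_row(c: CnvCall) -> str:
    chrom, s1, e1 = c.interval.to_1based_inclusive()
    return "\t".join(
        [
            c.cnv_type, chrom, str(s1), str(e1), _fmt_size_kb(c.size_kb),
            str(c.n_probes), format(c.mean_log2, ".17g"), format(c.score, ".17g"),
            ";".join(c.algorithms) or ".", c.tier, str(c.cn_estimate),
            ";".join(c.genes) or ".", c.db_status,
        ]
    )


def write_calls(
    calls: Sequence[CnvCall], path: str | Path, format: str = "tsv",
    header_comment: str | None = None,
) -> None:
    """Write calls as ``tsv`` (report columns, 1-based inclusive), ``bed``
    (0-based, attributes packed into the name field), or ``vcf`` (4.2,
    symbolic DEL/DUP alleles).  TSV and BED round-trip via
    :func:`read_calls`."""
    fmt = format.lower()
    if fmt == "tsv":
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            fh.write("\t".join(_CALL_TSV_COLS) + "\n")
            for c in calls:
                fh.write(_call_tsv_row(c) + "\n")
    elif fmt == "bed":
        with open(path, "w") as fh:
            for c in calls:
                iv = c.interval
                name = "|".join(
                    [
                        f"cnv_type={c.cnv_type}",
                        f"n_probes={c.n_probes}",
                        f"mean_log2={c.mean_log2:.17g}",
                        f"score={c.score:.17g}",
                        f"algorithms={';'.join(c.algorithms)}",
                        f"tier={c.tier}",
                        f"cn_estimate={c.cn_estimate}",
                        f"genes={';'.join(c.genes)}",
                        f"db_status={c.db_status}",
                    ]
                )
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.stop}\t{name}\n")
    elif fmt == "vcf":
        _write_calls_vcf(calls, path, header_comment)
    else:
        raise ValueError(f"unknown call format {format!r}")


_VCF_INFO = [
    ("END", "1", "Integer", "End position of the variant"),
    ("SVTYPE", "1", "String", "Type of structural variant"),
    ("NPROBES", "1", "Integer", "Number of supporting array probes"),
    ("SCORE", "1", "Float", "Interval score of the call"),
    ("MEANLOG2", "1", "Float", "Mean centered log2 ratio over the interval"),
    ("CN", "1", "Integer", "Estimated integer copy number"),
    ("TIER", "1", "String", "Call tier from algorithm integration"),
]


def _write_calls_vcf(
    calls: Sequence[CnvCall], path: str | Path, header_comment: str | None = None
) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=exoncgh\n")
        if header_comment:
            fh.write(f"##{header_comment}\n")
        fh.write('##ALT=<ID=DEL,Description="Deletion">\n')
        fh.write('##ALT=<ID=DUP,Description="Duplication">\n')
        for key, num, typ, desc in _VCF_INFO:
            fh.write(f'##INFO=<ID={key},Number={num},Type={typ},Description="{desc}">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for i, c in enumerate(calls, 1):
            chrom, s1, e1 = c.interval.to_1based_inclusive()
            alt = "<DUP>" if c.cnv_type == CNV_GAIN else "<DEL>"
            svtype = "DUP" if c.cnv_type == CNV_GAIN else "DEL"
            info = (
                f"END={e1};SVTYPE={svtype};NPROBES={c.n_probes};"
                f"SCORE={c.score:.4f};MEANLOG2={c.mean_log2:.4f};"
                f"CN={c.cn_estimate};TIER={c.tier.replace(' ', '_')}"
            )
            fh.write(f"{chrom}\t{s1}\tcnv{i}\tN\t{alt}\t.\tPASS\t{info}\n")


def read_calls(
    path: str | Path, format: str = "tsv", assembly: str = DEFAULT_ASSEMBLY
) -> list[CnvCall]:
    fmt = format.lower()
    calls: list[CnvCall] = []
    if fmt == "tsv":
        with open(path) as fh:
            header, hline = _read_header(fh)
            if header != _CALL_TSV_COLS:
                raise ParseError(path, hline, f"unexpected header {header!r}")
            for lineno, raw in enumerate(fh, hline + 1):
                if not raw.strip():
                    continue
                row = dict(zip(header, raw.rstrip("\n").split("\t")))
                calls.append(
                    CnvCall(
                        interval=GenomicInterval.from_1based_inclusive(
                            row["chrom"], int(row["start"]), int(row["stop"]), assembly
                        ),
                        cnv_type=row["cnv_type"],
                        n_probes=int(row["n_probes"]),
                        mean_log2=float(row["mean_log2"]),
                        score=float(row["score"]),
                        algorithms=tuple(
                            a for a in row["algorithms"].split(";") if a != "."
                        ),
                        tier=row["tier"],
                        cn_estimate=int(row["cn_estimate"]),
                        genes=tuple(g for g in row["genes"].split(";") if g != "."),
                        db_status=row["db_status"],
                    )
                )
    elif fmt == "bed":
        for lineno, cols in _bed_rows(path, 4):
            interval = _bed_interval(path, lineno, cols, assembly)
            attrs = dict(kv.split("=", 1) for kv in cols[3].split("|"))
            calls.append(
                CnvCall(
                    interval=interval,
                    cnv_type=attrs["cnv_type"],
                    n_probes=int(attrs["n_probes"]),
                    mean_log2=float(attrs["mean_log2"]),
                    score=float(attrs["score"]),
                    algorithms=tuple(a for a in attrs["algorithms"].split(";") if a),
                    tier=attrs["tier"],
                    cn_estimate=int(attrs["cn_estimate"]),
                    genes=tuple(g for g in attrs["genes"].split(";") if g),
                    db_status=attrs["db_status"],
                )
            )
    else:
        raise ValueError(f"read_calls supports tsv/bed, not {format!r}")
    return calls
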