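"""Single-probe exon-level calling, clustered by disease panel.

Multi-probe interval calling ignores imbalances shorter than its minimum
probe run, so single-exon deletions/duplications covered by one or two
probes are invisible to it.  This module flags individual exonic probes
whose z-value r_i / sigma_i is extreme, calls an exon aberrant only when
*all* of its probes agree in sign and magnitude, reports exons without any
probe as explicitly ``uncovered`` (never ``normal``), and groups the
aberrant exons by disease panel and gene.  The approach is sensitive but
false-positive-prone; by default aberrant statuses are only reported for
genes flagged causative, with suppressed hits kept for use as a validation
track.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

from intervaltree import IntervalTree

from .panel_io import ExonTarget, GenePanel, ProbeSignal

logger = logging.getLogger(__name__)

STATUS_GAIN = "gain"
STATUS_LOSS = "loss"
STATUS_NORMAL = "normal"
STATUS_UNCOVERED = "uncovered"


@dataclass(frozen=True)
class ExonCallerConfig:
    z_min: float = 3.0
    restrict_to_causative: bool = True


@dataclass(frozen=True)
class ExonCall:
    gene: str
    exon_index: int
    status: str
    n_probes: int
    probe_zs: tuple[float, ...]
    panels: frozenset[str] = frozenset()
    causative: bool = False

    def __post_init__(self) -> None:
        if (self.status == STATUS_UNCOVERED) != (self.n_probes == 0):
            raise ValueError("status 'uncovered' iff the exon has zero probes")

    @property
    def max_abs_z(self) -> float:
        return max((abs(z) for z in self.probe_zs), default=0.0)


@dataclass
class ExonReport:
    """All per-exon calls plus the aberrant calls suppressed by the
    causative-gene restriction (kept, and logged, for validation use)."""

    calls: list[ExonCall]
    suppressed: list[ExonCall]


def call_exons(
    signals: Sequence[ProbeSignal],
    targets: Sequence[ExonTarget],
    panel: GenePanel,
    config: ExonCallerConfig | None = None,
) -> ExonReport:
    """Per-exon status from single-probe z-values.

    Signals must be centered and carry per-probe errors.  A probe supports
    every exon it overlaps by >= 1 bp; probes on chromosomes with no
    targets are ignored with a warning.  An exon is ``gain`` when all of
    its probes have z >= z_min, ``loss`` when all have z <= -z_min,
    ``uncovered`` with no probes, else ``normal``.  With the causative
    restriction on, aberrant statuses on non-causative genes are demoted to
    ``normal`` in the main report and the aberrant version is kept in
    ``suppressed``.
    """
    cfg = config or ExonCallerConfig()
    trees: dict[str, IntervalTree] = {}
    for idx, t in enumerate(targets):
        trees.setdefault(t.interval.chrom, IntervalTree()).addi(
            t.interval.start, t.interval.stop, idx
        )
    zs_per_target: dict[int, list[float]] = {i: [] for i in range(len(targets))}
    warned: set[str] = set()
    for s in signals:
        chrom = s.interval.chrom
        tree = trees.get(chrom)
        if tree is None:
            if chrom not in warned:
                logger.warning("probes on %s overlap no target; ignored", chrom)
                warned.add(chrom)
            continue
        for hit in tree.overlap(s.interval.start, s.interval.stop):
            zs_per_target[hit.data].append(s.log2_ratio / s.error)

    calls: list[ExonCall] = []
    suppressed: list[ExonCall] = []
    for idx, t in enumerate(targets):
        zs = tuple(zs_per_target[idx])
        entry = panel.get(t.gene)
        panels = entry.panels if entry else frozenset()
        causative = entry.causative if entry else False
        if not zs:
            status = STATUS_UNCOVERED
        elif all(z >= cfg.z_min for z in zs):
            status = STATUS_GAIN
        elif all(z <= -cfg.z_min for z in zs):
            status = STATUS_LOSS
        else:
            status = STATUS_NORMAL
        call = ExonCall(
            gene=t.gene, exon_index=t.exon_index, status=status,
            n_probes=len(zs), probe_zs=zs, panels=panels, causative=causative,
        )
        if (
            status in (STATUS_GAIN, STATUS_LOSS)
            and cfg.restrict_to_causative
            and not causative
        ):
            logger.info(
                "suppressed %s call on non-causative %s exon %d (max |z| %.2f)",
                status, t.gene, t.exon_index, call.max_abs_z,
            )
            suppressed.append(call)
            call = replace(call, status=STATUS_NORMAL)
        calls.append(call)
    return ExonReport(calls=calls, suppressed=suppressed)


def cluster_by_panel(
    exon_calls: Sequence[ExonCall],
) -> dict[str, dict[str, list[ExonCall]]]:
    """Group aberrant exon calls by disease panel, then gene.

    A gene shared between panels appears under each of its panels, so the
    total group membership can exceed the number of aberrant calls.
    """
    groups: dict[str, dict[str, list[ExonCall]]] = {}
    for call in exon_calls:
        if call.status not in (STATUS_GAIN, STATUS_LOSS):
            continue
        for panel_label in sorted(call.panels):
            groups.setdefault(panel_label, {}).setdefault(call.gene, []).append(call)
    return groups


def panel_gene_counts(
    groups: dict[str, dict[str, list[ExonCall]]]
) -> dict[str, int]:
    """Number of distinct aberrant genes per disease panel."""
    return {panel: len(genes) for panel, genes in groups.items()}
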