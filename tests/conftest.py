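"""Shared fixtures: programmatically generated toy genomes, probe grids,
and simulated signal tables."""

from __future__ import annotations

import random

import pytest

from exoncgh.panel_io import ExonTarget, GenomicInterval, Probe
from exoncgh.cgh_sim import CnvSpec, SimConfig, simulate_signals


def make_probes(
    n: int,
    chrom: str = "chr1",
    spacing: int = 1000,
    start: int = 0,
    length: int = 60,
    error: float = 0.2,
    prefix: str = "p",
) -> list[Probe]:
    return [
        Probe(
            probe_id=f"{prefix}{i}",
            interval=GenomicInterval(chrom, start + i * spacing,
                                     start + i * spacing + length),
            error=error,
        )
        for i in range(n)
    ]


def flat_signals(n: int, sigma: float = 0.2, seed: int = 0, chrom: str = "chr1",
                 jitter: tuple[float, float] = (1.0, 1.0)):
    """Pure-noise (diploid) signals for n probes."""
    cfg = SimConfig(seed=seed, sigma=sigma, outlier_prob=0.0,
                    probe_error_jitter=jitter)
    return simulate_signals(make_probes(n, chrom=chrom), [], cfg)


def cnv_signals(n: int, cnv_lo: int, cnv_hi: int, copy_number: int,
                sigma: float = 0.2, seed: int = 0, chrom: str = "chr1",
                jitter: tuple[float, float] = (1.0, 1.0)):
    """Signals for n probes with probes [cnv_lo, cnv_hi) inside a CNV."""
    probes = make_probes(n, chrom=chrom)
    spec = CnvSpec(
        GenomicInterval(chrom, probes[cnv_lo].interval.start,
                        probes[cnv_hi - 1].interval.stop),
        copy_number,
    )
    cfg = SimConfig(seed=seed, sigma=sigma, outlier_prob=0.0,
                    probe_error_jitter=jitter)
    return simulate_signals(probes, [spec], cfg)


@pytest.fixture(scope="session")
def toy_genome_path(tmp_path_factory):
    """Small FASTA with one clean random chromosome and one all-N one."""
    rng = random.Random(20240917)
    seq = "".join(rng.choice("ACGT") for _ in range(30_000))
    path = tmp_path_factory.mktemp("genome") / "toy.fa"
    with open(path, "w") as fh:
        fh.write(">chrT\n")
        for i in range(0, len(seq), 80):
            fh.write(seq[i : i + 80] + "\n")
        fh.write(">chrN\n")
        for _ in range(60):
            fh.write("N" * 80 + "\n")
    return path


@pytest.fixture(scope="session")
def toy_genome(toy_genome_path):
    from pyfaidx import Fasta

    return Fasta(str(toy_genome_path))


@pytest.fixture(scope="session")
def toy_targets() -> list[ExonTarget]:
    """10 genes x 8 exons of 150 bp tiled across chrT."""
    targets = []
    pos = 150
    for g in range(10):
        for e in range(1, 9):
            targets.append(
                ExonTarget(f"G{g}", e, GenomicInterval("chrT", pos, pos + 150))
            )
            pos += 350
    return targets
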