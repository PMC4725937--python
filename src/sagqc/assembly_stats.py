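"""Per-SAG assembly summary statistics (contig count, total length, longest,
smallest, average, N50)."""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .records import SAGAssembly

__all__ = ["AssemblyStats", "compute_stats", "stats_table", "round_half_away"]


def round_half_away(x: float) -> int:
    """Round to the nearest integer, ties away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class AssemblyStats:
    n_contigs: int
    total_length: int
    longest: int
    smallest: int
    average: int
    n50: int


def compute_stats(assembly: SAGAssembly) -> AssemblyStats:
    """Summary statistics of one assembly.

    ``average`` is total/count rounded half away from zero; ``n50`` is the
    length of the contig at which the cumulative length (contigs in
    descending length order) first reaches ≥ 50% of the total.
    """
    if not assembly.contigs:
        raise ValueError(f"assembly {assembly.sag_id!r}: empty assembly")
    lengths = sorted((c.length for c in assembly.contigs), reverse=True)
    total = sum(lengths)
    cum = 0
    n50 = lengths[0]
    for L in lengths:
        cum += L
        if cum * 2 >= total:
            n50 = L
            break
    return AssemblyStats(
        n_contigs=len(lengths),
        total_length=total,
        longest=lengths[0],
        smallest=lengths[-1],
        average=round_half_away(total / len(lengths)),
        n50=n50,
    )


def stats_table(
    assemblies: list[SAGAssembly],
    completeness: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One row per SAG, sorted by sag_id; completeness columns joined in
    when a completeness matrix (indexed by sag_id) is supplied."""
    if not assemblies:
        raise ValueError("no assemblies")
    rows = []
    for asm in sorted(assemblies, key=lambda a: a.sag_id):
        s = compute_stats(asm)
        rows.append(
            {
                "sag_id": asm.sag_id,
                "contigs": s.n_contigs,
                "length_bp": s.total_length,
                "longest": s.longest,
                "smallest": s.smallest,
                "average": s.average,
                "n50": s.n50,
            }
        )
    table = pd.DataFrame(rows)
    if completeness is not None:
        table = table.merge(
            completeness, how="left", left_on="sag_id", right_index=True
        )
    return table
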