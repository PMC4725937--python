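"""Single-copy-marker genome completeness.

Completeness of a SAG is the percentage of a reference marker set detected at
least once in the assembly (presence is binary; copy number is reported
separately, since extra copies of single-copy genes signal contamination or
spurious assembly rather than extra completeness).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .records import MarkerSet, SAGAssembly

logger = logging.getLogger(__name__)

__all__ = [
    "MarkerProfile",
    "completeness",
    "duplication_report",
    "completeness_matrix",
]


def _pct_half_up(numerator: int, denominator: int) -> float:
    """Percentage rounded half-up to 1 decimal (Table-style formatting)."""
    pct = Decimal(100 * numerator) / Decimal(denominator)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class MarkerProfile:
    marker_set: MarkerSet
    present: set[str]
    copy_counts: dict[str, int]
    completeness_pct: float


def completeness(
    marker_hits: dict[str, list[str]], marker_set: MarkerSet
) -> MarkerProfile:
    """Completeness = 100 × |markers present| / |marker set|, half-up to one
    decimal.  Hits outside the set are ignored (count logged)."""
    if marker_set.size < 1:
        raise ValueError("empty marker set")
    members = set(marker_set.marker_ids)
    present: set[str] = set()
    copy_counts: dict[str, int] = {}
    ignored = 0
    for marker, carriers in marker_hits.items():
        if marker not in members:
            ignored += 1
            continue
        if carriers:
            present.add(marker)
            copy_counts[marker] = len(carriers)
    if ignored:
        logger.info("ignored %d marker hits outside set %r", ignored, marker_set.name)
    return MarkerProfile(
        marker_set=marker_set,
        present=present,
        copy_counts=copy_counts,
        completeness_pct=_pct_half_up(len(present), marker_set.size),
    )


def duplication_report(marker_hits: dict[str, list[str]]) -> pd.DataFrame:
    """Markers seen on more than one contig: (marker_id, copies, contigs),
    sorted by marker_id.  Feeds duplicate-marker resolution in the QC step."""
    rows = [
        {
            "marker_id": marker,
            "copies": len(carriers),
            "contigs": ",".join(sorted(carriers)),
        }
        for marker, carriers in sorted(marker_hits.items())
        if len(carriers) > 1
    ]
    return pd.DataFrame(rows, columns=["marker_id", "copies", "contigs"])


def completeness_matrix(
    assemblies: list[SAGAssembly], marker_sets: list[MarkerSet]
) -> pd.DataFrame:
    """SAG × marker-set completeness percentages, indexed by sag_id with one
    ``completeness_<set name>`` column per set."""
    if not assemblies or not marker_sets:
        raise ValueError("need ≥ 1 assembly and ≥ 1 marker set")
    rows = {}
    for asm in sorted(assemblies, key=lambda a: a.sag_id):
        hits = asm.marker_hits()
        rows[asm.sag_id] = {
            f"completeness_{ms.name}": completeness(hits, ms).completeness_pct
            for ms in marker_sets
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "sag_id"
    return table
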