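"""Protein isoelectric point (pI) and proteome pI profiling.

The net charge of a protein at a given pH is the Henderson–Hasselbalch sum
over its ionizable groups

    Z(pH) = Σ_bases n_b / (1 + 10^(pH − pKa_b)) − Σ_acids n_a / (1 + 10^(pKa_a − pH))

with the free N- and C-termini contributing one basic and one acidic group
each.  Z is strictly decreasing in pH whenever any ionizable group is
present, so the pI — the pH at which Z crosses zero — is found by a coarse
step scan followed by bisection.  Proteome-level profiles (median / mode /
mean pI, acidic fraction) distinguish "salt-in" halophiles, whose proteomes
are strongly acid-shifted, from ordinary marine organisms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data import data_path

logger = logging.getLogger(__name__)

__all__ = [
    "PKaTable",
    "default_pka_table",
    "net_charge",
    "isoelectric_point",
    "ProteomeProfile",
    "proteome_profile",
]

_STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")
_BASE_GROUPS = frozenset({"Nterm", "H", "K", "R"})
_ACID_GROUPS = frozenset({"Cterm", "C", "D", "E", "Y"})


@dataclass(frozen=True)
class PKaTable:
    """pKa values per ionizable group.  Groups are the side chains of
    C, D, E, H, K, R, Y plus the two termini; H/K/R and the N-terminus are
    bases (cationic when protonated), the rest acids."""

    pka: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = (_BASE_GROUPS | _ACID_GROUPS) - set(self.pka)
        if missing:
            raise ValueError(f"pKa table missing groups {sorted(missing)}")
        for group, value in self.pka.items():
            if not 0.0 < value < 14.0:
                raise ValueError(f"pKa for {group} out of range: {value}")


def load_pka_table(path: str | Path) -> PKaTable:
    table = pd.read_csv(path, sep="\t")
    return PKaTable(pka=dict(zip(table["group"], table["pka"].astype(float))))


def default_pka_table() -> PKaTable:
    return load_pka_table(data_path("emboss_like_pka.tsv"))


def _group_counts(protein: str) -> tuple[dict[str, int], int]:
    counts: dict[str, int] = {}
    skipped = 0
    for ch in protein.upper():
        if ch not in _STANDARD_AA:
            skipped += 1
            continue
        if ch in "CDEHKRY":
            counts[ch] = counts.get(ch, 0) + 1
    return counts, skipped


def net_charge(
    protein: str,
    ph: float,
    table: PKaTable | None = None,
    n_termini: int = 1,
    use_termini: bool = True,
) -> float:
    """Net charge of ``protein`` at ``ph``.

    Residues outside the 20-letter alphabet are ignored (count logged).
    ``n_termini`` scales the terminal-group contribution (multi-chain
    convention); termini are included by default.
    """
    table = table or default_pka_table()
    counts, skipped = _group_counts(protein)
    if skipped:
        logger.info("net_charge: ignored %d non-standard residues", skipped)
    if use_termini:
        counts = dict(counts)
        counts["Nterm"] = counts.get("Nterm", 0) + n_termini
        counts["Cterm"] = counts.get("Cterm", 0) + n_termini
    if not counts:
        logger.warning("net_charge: no ionizable group; charge identically 0")
        return 0.0
    charge = 0.0
    for group, n in counts.items():
        pka = table.pka[group]
        if group in _BASE_GROUPS:
            charge += n / (1.0 + 10.0 ** (ph - pka))
        else:
            charge -= n / (1.0 + 10.0 ** (pka - ph))
    return charge


def isoelectric_point(
    protein: str,
    table: PKaTable | None = None,
    step: float = 0.2,
    refine_tol: float = 1e-3,
    n_termini: int = 1,
    use_termini: bool = True,
) -> float | None:
    """The pH at which net charge is zero.

    A pH 0→14 scan at ``step`` brackets the (unique, since charge is
    strictly decreasing) sign change; bisection then refines until
    |charge| < ``refine_tol``.  Returns None when the protein has no
    ionizable group of one polarity, in which case the charge never crosses
    zero and the pI is undefined.
    """
    table = table or default_pka_table()
    counts, _ = _group_counts(protein)
    n_base = sum(counts.get(g, 0) for g in ("H", "K", "R"))
    n_acid = sum(counts.get(g, 0) for g in ("C", "D", "E", "Y"))
    if use_termini:
        n_base += n_termini
        n_acid += n_termini
    if n_base == 0 or n_acid == 0:
        return None

    charge = lambda ph: net_charge(protein, ph, table, n_termini, use_termini)
    lo, hi = 0.0, 0.0
    c_lo = charge(0.0)
    if c_lo < 0:  # cannot happen with a basic group present, but be safe
        return 0.0
    found = False
    ph = step
    while ph <= 14.0 + 1e-9:
        c = charge(ph)
        if c < 0:
            lo, hi = ph - step, ph
            found = True
            break
        ph += step
    if not found:
        return None
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        c = charge(mid)
        if abs(c) < refine_tol:
            return mid
        if c > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@dataclass
class ProteomeProfile:
    proteome_id: str
    pi_values: pd.Series          # indexed by protein id
    median: float
    mode: float                   # center of the peak 0.2-wide histogram bin
    mean: float
    acidic_fraction: float        # fraction of proteins with pI < 7
    histogram: pd.DataFrame       # bin_left, bin_right, count
    n_undefined: int


def proteome_profile(
    proteins: list[tuple[str, str]],
    table: PKaTable | None = None,
    step: float = 0.2,
    proteome_id: str = "proteome",
    use_termini: bool = True,
) -> ProteomeProfile:
    """Per-protein pI values plus distribution summaries for one proteome.

    Proteins with undefined pI (one ionization polarity absent) are excluded
    with a logged reason.  The mode is the center of the tallest bin of a
    fixed 0.2-wide histogram over [0, 14] (ties resolved toward low pH).
    """
    table = table or default_pka_table()
    values = {}
    undefined = 0
    for pid, seq in proteins:
        pi = isoelectric_point(seq, table, step=step, use_termini=use_termini)
        if pi is None:
            undefined += 1
            logger.info("protein %s: pI undefined (single-polarity)", pid)
            continue
        values[pid] = pi
    if not values:
        raise ValueError("no protein with a defined pI")
    s = pd.Series(values, name="pI")
    edges = np.arange(0.0, 14.0 + 1e-9, 0.2)
    hist, _ = np.histogram(s.to_numpy(), bins=edges)
    peak = int(np.argmax(hist))
    histogram = pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": hist}
    )
    return ProteomeProfile(
        proteome_id=proteome_id,
        pi_values=s,
        median=float(s.median()),
        mode=float(0.5 * (edges[peak] + edges[peak + 1])),
        mean=float(s.mean()),
        acidic_fraction=float((s < 7.0).mean()),
        histogram=histogram,
        n_undefined=undefined,
    )
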