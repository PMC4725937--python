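"""Tetranucleotide frequency vectors and correspondence-analysis ordination.

Contig composition is summarized as canonical 4-mer counts (each 4-mer merged
with its reverse complement — 136 features — so strand choice cannot change
the signature).  The contigs × 4-mer count table is ordinated by simple
correspondence analysis: chi-square standardization of the relative table
followed by an SVD, with row principal coordinates returned.  An
unconstrained canonical correspondence analysis is exactly this simple CA,
which is what a vegan ``cca()`` call without constraining variables computes.

Outliers against a reference set (typically the provisional clean bin) are
flagged by a robust MAD distance on the first two axes; flags feed the
suspicious, manual-review tier of the QC pipeline — they never auto-discard.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .records import Contig

logger = logging.getLogger(__name__)

__all__ = [
    "CANONICAL_KMERS",
    "TNFVector",
    "tnf",
    "tnf_table",
    "OrdinationResult",
    "correspondence_analysis",
    "flag_outliers",
    "ordination_plot",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(kmer: str) -> str:
    return kmer.translate(_COMPLEMENT)[::-1]


def _canonical(kmer: str) -> str:
    rc = _revcomp(kmer)
    return kmer if kmer <= rc else rc


CANONICAL_KMERS: tuple[str, ...] = tuple(
    sorted({_canonical("".join(p)) for p in itertools.product("ACGT", repeat=4)})
)
_KMER_INDEX = {k: i for i, k in enumerate(CANONICAL_KMERS)}
_LOOKUP = {
    "".join(p): _KMER_INDEX[_canonical("".join(p))]
    for p in itertools.product("ACGT", repeat=4)
}


@dataclass
class TNFVector:
    contig_id: str
    counts: np.ndarray  # (136,) int
    n_valid_windows: int

    @property
    def frequencies(self) -> np.ndarray:
        return self.counts / self.n_valid_windows


def tnf(contig: Contig) -> TNFVector | None:
    """Canonical tetranucleotide counts over all step-1 windows of the
    forward strand; windows containing N are skipped.  Returns None (TNF
    undefined) for contigs shorter than 4 bp or with zero valid windows."""
    seq = contig.sequence
    if len(seq) < 4:
        return None
    counts = np.zeros(len(CANONICAL_KMERS), dtype=np.int64)
    n_valid = 0
    for i in range(len(seq) - 3):
        idx = _LOOKUP.get(seq[i : i + 4])
        if idx is None:  # window crosses an N
            continue
        counts[idx] += 1
        n_valid += 1
    if n_valid == 0:
        return None
    return TNFVector(contig_id=contig.id, counts=counts, n_valid_windows=n_valid)


def tnf_table(contigs: list[Contig]) -> tuple[pd.DataFrame, list[str]]:
    """Counts DataFrame (contigs × 136) for all contigs with defined TNF,
    plus the IDs of contigs where TNF was unavailable."""
    rows, index, unavailable = [], [], []
    for c in contigs:
        v = tnf(c)
        if v is None:
            unavailable.append(c.id)
        else:
            rows.append(v.counts)
            index.append(c.id)
    table = pd.DataFrame(rows, index=index, columns=list(CANONICAL_KMERS))
    return table, unavailable


@dataclass
class OrdinationResult:
    axes: pd.DataFrame        # contigs × k principal coordinates
    inertia_fractions: np.ndarray
    total_inertia: float
    flagged: dict[str, str]   # contig_id -> reason


def correspondence_analysis(counts: pd.DataFrame, k: int = 2) -> OrdinationResult:
    """Simple correspondence analysis of a nonnegative count table.

    Row principal coordinates are returned for the top-k axes; at full rank
    the inter-row Euclidean distances in principal coordinates equal the
    chi-square distances between table rows, and the total inertia equals
    the table's chi-square statistic divided by its grand total.  Axis signs
    are fixed by making each axis's largest-magnitude column loading
    positive, so results are reproducible.
    """
    if k < 1:
        raise ValueError("k must be ≥ 1")
    if len(counts) < 3:
        raise ValueError("need ≥ 3 rows for ordination")
    N = counts.to_numpy(dtype=float)
    if (N < 0).any():
        raise ValueError("counts must be nonnegative")
    # Columns never observed carry no information and would divide by zero.
    col_mask = N.sum(axis=0) > 0
    N = N[:, col_mask]
    grand = N.sum()
    if grand == 0:
        raise ValueError("empty count table")
    P = N / grand
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    if (r == 0).any():
        raise ValueError("rows with zero total are not ordinatable")
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sv, Vt = np.linalg.svd(S, full_matrices=False)
    total_inertia = float((sv**2).sum())

    rank = int(min(len(counts) - 1, col_mask.sum() - 1))
    sv = sv[:rank]
    U = U[:, :rank]
    Vt = Vt[:rank]

    if total_inertia <= 1e-12 or rank == 0:
        warnings.warn("zero inertia: all rows identical; returning zero coordinates")
        axes = pd.DataFrame(
            np.zeros((len(counts), k)),
            index=counts.index,
            columns=[f"axis{i + 1}" for i in range(k)],
        )
        return OrdinationResult(axes, np.zeros(k), 0.0, {})

    # sign convention: largest-|loading| per axis positive
    for j in range(rank):
        jmax = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, jmax] < 0:
            Vt[j] *= -1
            U[:, j] *= -1

    F = (U * sv) / np.sqrt(r)[:, None]  # row principal coordinates
    k_eff = min(k, rank)
    coords = np.zeros((len(counts), k))
    coords[:, :k_eff] = F[:, :k_eff]
    axes = pd.DataFrame(
        coords, index=counts.index, columns=[f"axis{i + 1}" for i in range(k)]
    )
    fractions = np.zeros(k)
    fractions[:k_eff] = (sv[:k_eff] ** 2) / total_inertia
    return OrdinationResult(axes, fractions, total_inertia, {})


def row_chi_square_distances(counts: pd.DataFrame) -> np.ndarray:
    """Direct chi-square inter-row distances (the quantity CA's principal
    coordinates reproduce at full rank); used as an oracle."""
    N = counts.to_numpy(dtype=float)
    N = N[:, N.sum(axis=0) > 0]
    grand = N.sum()
    P = N / grand
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    profiles = P / r[:, None]
    n = len(P)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = np.sqrt((((profiles[i] - profiles[j]) ** 2) / c).sum())
            D[i, j] = D[j, i] = d
    return D


def flag_outliers(
    ordination: OrdinationResult,
    reference: set[str],
    cutoff: float = 3.5,
    n_axes: int = 2,
) -> dict[str, str]:
    """Flag contigs far from the reference cloud on the leading axes.

    Distance is the max over axes of |coord − reference median| scaled by
    1.4826 × MAD of the reference; axes with zero MAD are skipped.  Flagged
    contigs go to the suspicious tier for manual review.
    """
    if not reference:
        raise ValueError("reference set is empty")
    axes = ordination.axes
    ref = axes.loc[axes.index.isin(reference)]
    if ref.empty:
        raise ValueError("no reference contig present in the ordination")
    usable = []
    for col in axes.columns[:n_axes]:
        med = float(ref[col].median())
        mad = float((ref[col] - med).abs().median())
        if mad > 0:
            usable.append((col, med, mad * 1.4826))
    if not usable:
        warnings.warn("all reference MADs are zero; nothing flagged")
        return {}
    flagged: dict[str, str] = {}
    for cid, row in axes.iterrows():
        dist = max(abs(row[col] - med) / scale for col, med, scale in usable)
        if dist > cutoff:
            flagged[cid] = f"tnf_outlier(d={dist:.2f})"
    ordination.flagged = dict(flagged)
    return flagged


def ordination_plot(
    ordination: OrdinationResult,
    bins: dict[str, str],
    out_prefix: str | Path,
) -> tuple[Path, Path]:
    """Axis-1 vs axis-2 scatter colored by bin; the coordinates are always
    also written as TSV so downstream checks assert on numbers, not pixels."""
    out_prefix = Path(out_prefix)
    table = ordination.axes.copy()
    table.insert(0, "contig_id", table.index)
    table["bin"] = [bins.get(cid, "unbinned") for cid in table.index]
    table["flagged"] = [cid in ordination.flagged for cid in table.index]
    tsv_path = out_prefix.with_suffix(".tsv")
    table.to_csv(tsv_path, sep="\t", index=False, float_format="%.6g")

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    colors = {"clean": "tab:blue", "contaminated": "tab:red",
              "suspicious": "tab:orange", "unbinned": "tab:gray"}
    for name, sub in table.groupby("bin"):
        ax.scatter(sub["axis1"], sub["axis2"], s=14,
                   c=colors.get(name, "tab:gray"), label=name, alpha=0.8)
    fl = table[table["flagged"]]
    if not fl.empty:
        ax.scatter(fl["axis1"], fl["axis2"], s=60, facecolors="none",
                   edgecolors="black", label="flagged")
    ax.set_xlabel(f"CA axis 1 ({100 * ordination.inertia_fractions[0]:.1f}% inertia)")
    if len(ordination.inertia_fractions) > 1:
        ax.set_ylabel(f"CA axis 2 ({100 * ordination.inertia_fractions[1]:.1f}% inertia)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    png_path = out_prefix.with_suffix(".png")
    fig.savefig(png_path, dpi=120)
    plt.close(fig)
    return png_path, tsv_path
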