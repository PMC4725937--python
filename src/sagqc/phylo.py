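"""Alignment site statistics and Fitch-parsimony indices.

Given a character matrix and a tree this module computes the quantities a
parsimony analysis reports alongside its trees: counts of constant /
variable / parsimony-informative sites, the Fitch parsimony length, and the
ensemble consistency (CI) and retention (RI) indices.  Tree *search* is out
of scope — these are scoring statistics over a supplied topology.

Missing and ambiguity symbols (- ? X N by default) are treated as fully
missing: ignored in site classification and given the full state set in the
Fitch pass, matching common parsimony-software convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import pandas as pd

__all__ = [
    "CharacterMatrix",
    "DEFAULT_MISSING",
    "classify_sites",
    "fitch_length",
    "consistency_retention",
    "concatenate_markers",
]

DEFAULT_MISSING = frozenset("-?XN")


@dataclass(frozen=True)
class CharacterMatrix:
    """taxa × sites character grid; all rows equal length, ≥ 2 taxa."""

    taxa: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.taxa) < 2:
            raise ValueError("need ≥ 2 taxa")
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa / rows length mismatch")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon labels")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError(f"unequal row lengths {sorted(lengths)}")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return len(self.rows[0])

    def column(self, j: int) -> list[str]:
        return [r[j] for r in self.rows]

    @classmethod
    def from_alignment(cls, alignment) -> "CharacterMatrix":
        """From a Bio.Align.MultipleSeqAlignment."""
        return cls(
            taxa=tuple(rec.id for rec in alignment),
            rows=tuple(str(rec.seq).upper() for rec in alignment),
        )


def _observed(column: list[str], missing: frozenset[str]) -> list[str]:
    return [ch.upper() for ch in column if ch.upper() not in missing]


def classify_sites(
    matrix: CharacterMatrix, missing: frozenset[str] = DEFAULT_MISSING
) -> tuple[list[str], dict[str, int]]:
    """Per-site class and counts.

    constant: ≤ 1 distinct observed state (all-missing columns count here);
    parsimony_informative: ≥ 2 states each observed in ≥ 2 taxa;
    variable_uninformative: the remaining varying sites.
    """
    classes = []
    for j in range(matrix.n_sites):
        obs = _observed(matrix.column(j), missing)
        distinct = set(obs)
        if len(distinct) <= 1:
            classes.append("constant")
        else:
            shared = sum(1 for s in distinct if obs.count(s) >= 2)
            classes.append(
                "parsimony_informative" if shared >= 2 else "variable_uninformative"
            )
    counts = {
        "constant": classes.count("constant"),
        "variable": matrix.n_sites - classes.count("constant"),
        "parsimony_informative": classes.count("parsimony_informative"),
    }
    return classes, counts


def _postorder_structure(tree: dendropy.Tree, matrix: CharacterMatrix):
    """Flatten the tree into a postorder list of (node, child indices) with
    leaves mapped to matrix rows; errors on tree leaves absent from the
    matrix."""
    row_of = {t: i for i, t in enumerate(matrix.taxa)}
    nodes = list(tree.postorder_node_iter())
    index_of = {id(n): i for i, n in enumerate(nodes)}
    structure = []
    for n in nodes:
        if n.is_leaf():
            label = n.taxon.label if n.taxon else None
            if label not in row_of:
                raise ValueError(f"tree leaf {label!r} absent from the matrix")
            structure.append(("leaf", row_of[label]))
        else:
            structure.append(
                ("internal", [index_of[id(ch)] for ch in n.child_nodes()])
            )
    return structure


def fitch_length(
    tree: dendropy.Tree,
    matrix: CharacterMatrix,
    missing: frozenset[str] = DEFAULT_MISSING,
) -> tuple[int, list[int]]:
    """Fitch parsimony length of the matrix on the tree.

    Bottom-up state-set pass per site: child sets are folded by intersection
    when nonempty, else union with one extra change.  Missing symbols take
    the full set of states observed at the site.  The score is invariant to
    where the (possibly arbitrary) root sits.
    """
    structure = _postorder_structure(tree, matrix)
    per_site: list[int] = []
    for j in range(matrix.n_sites):
        col = [ch.upper() for ch in matrix.column(j)]
        observed = frozenset(ch for ch in col if ch not in missing)
        if len(observed) <= 1:
            per_site.append(0)
            continue
        sets: list[frozenset[str]] = [frozenset()] * len(structure)
        changes = 0
        for i, (kind, payload) in enumerate(structure):
            if kind == "leaf":
                ch = col[payload]
                sets[i] = observed if ch in missing else frozenset(ch)
            else:
                acc = None
                for ci in payload:
                    if acc is None:
                        acc = sets[ci]
                        continue
                    inter = acc & sets[ci]
                    if inter:
                        acc = inter
                    else:
                        acc = acc | sets[ci]
                        changes += 1
                sets[i] = acc if acc is not None else observed
        per_site.append(changes)
    return sum(per_site), per_site


def _site_min_max(col: list[str], missing: frozenset[str]) -> tuple[int, int]:
    """(m, g): the minimum changes any tree needs for this site and the
    maximum any tree can need (total observed taxa minus the largest state
    class)."""
    obs = _observed(col, missing)
    counts: dict[str, int] = {}
    for ch in obs:
        counts[ch] = counts.get(ch, 0) + 1
    if len(counts) <= 1:
        return 0, 0
    m = len(counts) - 1
    g = len(obs) - max(counts.values())
    return m, g


def consistency_retention(
    tree: dendropy.Tree,
    matrix: CharacterMatrix,
    missing: frozenset[str] = DEFAULT_MISSING,
) -> tuple[float | None, float | None]:
    """Ensemble consistency and retention indices on the given tree.

    CI = Σm / Σs and RI = (Σg − Σs) / (Σg − Σm) with m the per-site minimum
    changes, g the per-site maximum over trees, s the Fitch changes here;
    sites with g == m are excluded from the RI sums.  CI is None when the
    matrix fits with zero changes (Σs = 0); RI is None when no site has
    g > m.
    """
    _, per_site = fitch_length(tree, matrix, missing)
    sum_m = sum_s = 0
    ri_m = ri_g = ri_s = 0
    for j in range(matrix.n_sites):
        m, g = _site_min_max(matrix.column(j), missing)
        s = per_site[j]
        sum_m += m
        sum_s += s
        if g > m:
            ri_m += m
            ri_g += g
            ri_s += s
    ci = (sum_m / sum_s) if sum_s > 0 else None
    ri = ((ri_g - ri_s) / (ri_g - ri_m)) if ri_g > ri_m else None
    return ci, ri


def concatenate_markers(
    alignments: list[tuple[str, CharacterMatrix]],
    taxa_order: list[str],
    missing_symbol: str = "?",
) -> tuple[CharacterMatrix, pd.DataFrame]:
    """Concatenate per-marker alignments in a fixed order for every taxon.

    Taxa missing from a marker are padded with the missing symbol across
    that marker's columns.  Returns the supermatrix and a partition table
    with each marker's 1-based inclusive column range.
    """
    names = [name for name, _ in alignments]
    if len(set(names)) != len(names):
        dup = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate marker names {dup}")
    rows = {t: [] for t in taxa_order}
    partitions = []
    start = 1
    for name, aln in alignments:
        width = aln.n_sites
        row_of = dict(zip(aln.taxa, aln.rows))
        for t in taxa_order:
            rows[t].append(row_of.get(t, missing_symbol * width))
        partitions.append(
            {"marker": name, "start": start, "end": start + width - 1}
        )
        start += width
    matrix = CharacterMatrix(
        taxa=tuple(taxa_order),
        rows=tuple("".join(rows[t]) for t in taxa_order),
    )
    return matrix, pd.DataFrame(partitions, columns=["marker", "start", "end"])
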