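"""The SAG decontamination filters and bin assembly.

A contig enters the clean bin only if it passes every filter: a GC window
around a robust "seed contig" average, a minimum-size threshold, and a
gene-taxonomy majority vote.  Contigs carrying extra copies of single-copy
markers are demoted, and tetranucleotide-ordination outlier flags (computed
separately) fold into a suspicious, manually-reviewable tier rather than an
automatic discard.

The three filters are evaluated independently on every contig — no
short-circuiting — so the report records every filter a contig failed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .records import Contig, SAGAssembly

__all__ = [
    "FilterConfig",
    "QCReport",
    "gc_content",
    "select_seed_contigs",
    "select_seed_contigs_group",
    "gc_filter",
    "size_filter",
    "taxon_filter",
    "resolve_duplicate_markers",
    "run_qc",
]


@dataclass(frozen=True)
class FilterConfig:
    """Filter thresholds.

    gc_window is a half-width: in "absolute" mode it is percentage points
    around the seed-contig GC average (the default reading of a ±10% GC
    range); in "relative" mode it is a fraction of that average.  Contigs
    shorter than min_length but longer than suspicious_floor are retained
    for manual review rather than silently dropped — small contigs can still
    carry important genes.
    """

    gc_window: float = 10.0
    gc_window_mode: str = "absolute"  # or "relative"
    min_length: int = 2000
    suspicious_floor: int = 500
    majority_threshold: float = 0.5
    target_domain: str = "Archaea"
    target_phylum: str | None = None
    seed_mode: str = "n50"  # or "marker_contigs", "group_marker_contigs"
    gc_weighting: str = "length_weighted"  # or "unweighted"
    tnf_flag_cutoff: float = 3.5

    def __post_init__(self) -> None:
        if not 0.0 < self.majority_threshold <= 1.0:
            raise ValueError("majority_threshold must be in (0,1]")
        if self.suspicious_floor >= self.min_length:
            raise ValueError("suspicious_floor must be < min_length")
        if self.gc_window_mode not in {"absolute", "relative"}:
            raise ValueError("gc_window_mode must be 'absolute' or 'relative'")
        if self.seed_mode not in {"n50", "marker_contigs", "group_marker_contigs"}:
            raise ValueError(f"unknown seed_mode {self.seed_mode!r}")
        if self.gc_weighting not in {"length_weighted", "unweighted"}:
            raise ValueError("gc_weighting must be 'length_weighted' or 'unweighted'")


@dataclass
class QCReport:
    """Per-contig filter outcomes plus assembly-level provenance."""

    sag_id: str
    per_contig: pd.DataFrame
    seed_gc_mean: float
    gc_bounds: tuple[float, float]
    seed_contigs: set[str]
    duplicate_marker_resolutions: list[dict]

    def bin_ids(self, name: str) -> set[str]:
        sub = self.per_contig[self.per_contig["bin"] == name]
        return set(sub["contig_id"])

    def summary(self) -> dict:
        counts = self.per_contig["bin"].value_counts().to_dict()
        return {
            "sag_id": self.sag_id,
            "n_contigs": int(len(self.per_contig)),
            "bins": {b: int(counts.get(b, 0)) for b in ("clean", "contaminated", "suspicious")},
            "seed_gc_mean": round(self.seed_gc_mean, 6),
            "gc_bounds": [round(x, 6) for x in self.gc_bounds],
            "n_seed_contigs": len(self.seed_contigs),
            "duplicate_marker_resolutions": self.duplicate_marker_resolutions,
        }


def gc_content(contig: Contig) -> float | None:
    """(G+C)/(A+C+G+T); N excluded from both sides.  None when the contig
    has no unambiguous base (GC undefined)."""
    seq = contig.sequence
    gc = seq.count("G") + seq.count("C")
    denom = gc + seq.count("A") + seq.count("T")
    if denom == 0:
        return None
    return gc / denom


def _mean_gc(contigs: list[Contig], weighting: str) -> float:
    num = den = 0.0
    for c in contigs:
        gc = gc_content(c)
        if gc is None:
            continue
        w = c.length if weighting == "length_weighted" else 1.0
        num += w * gc
        den += w
    if den == 0:
        raise ValueError("no seed contig with defined GC")
    return num / den


def _n50_set(assembly: SAGAssembly) -> set[str]:
    # descending length, ID as deterministic tie-break
    order = sorted(assembly.contigs, key=lambda c: (-c.length, c.id))
    total = sum(c.length for c in order)
    seeds: set[str] = set()
    cum = 0
    for c in order:
        seeds.add(c.id)
        cum += c.length
        if cum * 2 >= total:
            break
    return seeds


def select_seed_contigs(
    assembly: SAGAssembly,
    config: FilterConfig,
    marker_hits: dict[str, list[str]] | None = None,
) -> tuple[set[str], float]:
    """Pick the seed-contig set and its average GC.

    "n50" mode seeds on the largest contigs making up ≥ half the assembly;
    "marker_contigs" seeds on every contig carrying ≥ 1 single-copy marker.
    The average is length-weighted unless configured otherwise.
    """
    if config.seed_mode == "n50":
        seeds = _n50_set(assembly)
    else:
        if marker_hits is None:
            marker_hits = assembly.marker_hits()
        seeds = {cid for carriers in marker_hits.values() for cid in carriers}
        if not seeds:
            raise ValueError(
                "no marker-bearing contigs to seed on; use seed_mode='n50'"
            )
    seed_contigs = [c for c in assembly.contigs if c.id in seeds]
    return seeds, _mean_gc(seed_contigs, config.gc_weighting)


def select_seed_contigs_group(
    assemblies: list[SAGAssembly],
    config: FilterConfig,
    marker_hits_by_sag: dict[str, dict[str, list[str]]] | None = None,
) -> tuple[dict[str, set[str]], float]:
    """Group mode: pool marker-bearing contigs across SAGs of the same taxon
    and compute one shared seed GC average applied to all of them."""
    seeds_by_sag: dict[str, set[str]] = {}
    pooled: list[Contig] = []
    for asm in assemblies:
        hits = (
            marker_hits_by_sag.get(asm.sag_id) if marker_hits_by_sag else None
        ) or asm.marker_hits()
        seeds = {cid for carriers in hits.values() for cid in carriers}
        seeds_by_sag[asm.sag_id] = seeds
        pooled.extend(c for c in asm.contigs if c.id in seeds)
    if not pooled:
        raise ValueError("no marker-bearing contigs in any SAG; use seed_mode='n50'")
    return seeds_by_sag, _mean_gc(pooled, config.gc_weighting)


def _gc_bounds(seed_gc_mean: float, config: FilterConfig) -> tuple[float, float]:
    if config.gc_window_mode == "absolute":
        half = config.gc_window / 100.0
        return seed_gc_mean - half, seed_gc_mean + half
    frac = config.gc_window / 100.0
    return seed_gc_mean * (1 - frac), seed_gc_mean * (1 + frac)


def gc_filter(
    assembly: SAGAssembly, config: FilterConfig, seed_gc_mean: float
) -> dict[str, bool | None]:
    """Closed-interval GC window around the seed average; None marks contigs
    with undefined GC (all-N)."""
    lo, hi = _gc_bounds(seed_gc_mean, config)
    out: dict[str, bool | None] = {}
    for c in assembly.contigs:
        gc = gc_content(c)
        out[c.id] = None if gc is None else (lo <= gc <= hi)
    return out


def size_filter(assembly: SAGAssembly, config: FilterConfig) -> dict[str, str]:
    """pass (≥ min_length) / suspicious (floor < length < min_length) /
    discard (≤ floor)."""
    out = {}
    for c in assembly.contigs:
        if c.length >= config.min_length:
            out[c.id] = "pass"
        elif c.length > config.suspicious_floor:
            out[c.id] = "suspicious"
        else:
            out[c.id] = "discard"
    return out


def taxon_filter(
    assembly: SAGAssembly, config: FilterConfig
) -> dict[str, dict]:
    """Majority vote on gene taxonomy per contig.

    A contig fails when ≥ majority_threshold of its classified genes hit a
    non-target taxon ("50% or more" fails at exactly half).  Unclassified
    genes vote in neither direction; a contig with no classified gene passes
    vacuously but is flagged no_taxonomic_evidence.  majority_threshold = 1.0
    is the filter-off limit: since the non-target fraction can never exceed
    1, nothing fails there and every contig passes.
    """
    level = "taxon_phylum" if config.target_phylum else "taxon_domain"
    target = config.target_phylum or config.target_domain
    out: dict[str, dict] = {}
    genes_by_contig: dict[str, list] = {c.id: [] for c in assembly.contigs}
    for g in assembly.genes:
        genes_by_contig[g.contig_id].append(g)
    for c in assembly.contigs:
        t = nt = u = 0
        for g in genes_by_contig[c.id]:
            label = getattr(g, level)
            if label == "unclassified":
                u += 1
            elif label == target:
                t += 1
            else:
                nt += 1
        classified = t + nt
        if classified == 0:
            passed, flag = True, "no_taxonomic_evidence"
        else:
            if config.majority_threshold >= 1.0:
                passed = True  # neutral limit: a fraction cannot exceed 1
            else:
                passed = (nt / classified) < config.majority_threshold
            flag = ""
        out[c.id] = {
            "passed": passed,
            "votes": (t, nt, u),
            "flag": flag,
        }
    return out


def resolve_duplicate_markers(
    assembly: SAGAssembly, marker_hits: dict[str, list[str]]
) -> tuple[dict[str, str], set[str], list[dict]]:
    """For each single-copy marker found on more than one contig, retain the
    carrier maximizing (length, then gene count, then lexicographically
    smallest ID); demote the rest to the suspicious bin.

    Returns (retained carrier per duplicated marker, demoted contig IDs,
    resolution records for the report).
    """
    gene_counts = {c.id: 0 for c in assembly.contigs}
    for g in assembly.genes:
        gene_counts[g.contig_id] += 1
    lengths = {c.id: c.length for c in assembly.contigs}

    retained: dict[str, str] = {}
    demoted: set[str] = set()
    resolutions: list[dict] = []
    for marker in sorted(marker_hits):
        carriers = sorted(set(marker_hits[marker]))
        if len(carriers) <= 1:
            continue
        best = min(carriers, key=lambda cid: (-lengths[cid], -gene_counts[cid], cid))
        retained[marker] = best
        losers = [cid for cid in carriers if cid != best]
        demoted.update(losers)
        resolutions.append(
            {"marker_id": marker, "retained": best, "demoted": losers}
        )
    return retained, demoted, resolutions


def run_qc(
    assembly: SAGAssembly,
    config: FilterConfig = FilterConfig(),
    marker_hits: dict[str, list[str]] | None = None,
    tnf_flags: set[str] | None = None,
    seed_gc_mean: float | None = None,
    seed_contigs: set[str] | None = None,
) -> QCReport:
    """Run every filter independently on every contig and assemble bins.

    clean      — passed size, GC and taxonomy, not demoted, not TNF-flagged
    suspicious — size-suspicious, duplicate-demoted, all-N, or TNF-flagged
                 contigs with no harder evidence (the manual-review tier)
    contaminated — failed GC or taxonomy, or below the suspicious floor
    """
    if marker_hits is None:
        marker_hits = assembly.marker_hits()
    tnf_flags = tnf_flags or set()

    if seed_gc_mean is None:
        seed_contigs, seed_gc_mean = select_seed_contigs(assembly, config, marker_hits)
    elif seed_contigs is None:
        seed_contigs = set()

    gc_pass = gc_filter(assembly, config, seed_gc_mean)
    size_class = size_filter(assembly, config)
    taxon = taxon_filter(assembly, config)
    _, demoted, resolutions = resolve_duplicate_markers(assembly, marker_hits)

    marker_count = {c.id: 0 for c in assembly.contigs}
    for carriers in marker_hits.values():
        for cid in carriers:
            if cid in marker_count:
                marker_count[cid] += 1

    rows = []
    for c in assembly.contigs:
        gcv = gc_content(c)
        g_ok = gc_pass[c.id]
        s_cls = size_class[c.id]
        t = taxon[c.id]
        is_demoted = c.id in demoted
        is_flagged = c.id in tnf_flags

        fired = []
        if g_ok is None:
            fired.append("gc_undefined")
        elif not g_ok:
            fired.append("gc")
        if s_cls == "discard":
            fired.append("size")
        elif s_cls == "suspicious":
            fired.append("size_suspicious")
        if not t["passed"]:
            fired.append("taxon")
        if is_demoted:
            fired.append("duplicate_marker")
        if is_flagged:
            fired.append("tnf")

        if g_ok is None:
            bin_ = "suspicious"
        elif (not g_ok) or (not t["passed"]) or s_cls == "discard":
            bin_ = "contaminated"
        elif s_cls == "suspicious" or is_demoted or is_flagged:
            bin_ = "suspicious"
        else:
            bin_ = "clean"

        rows.append(
            {
                "contig_id": c.id,
                "length": c.length,
                "gc": float("nan") if gcv is None else gcv,
                "seed_contig": c.id in seed_contigs,
                "passed_gc": bool(g_ok) if g_ok is not None else False,
                "size_class": s_cls,
                "passed_size": s_cls == "pass",
                "passed_taxon": t["passed"],
                "votes_target": t["votes"][0],
                "votes_non_target": t["votes"][1],
                "votes_unclassified": t["votes"][2],
                "taxon_flag": t["flag"],
                "n_markers": marker_count[c.id],
                "demoted_duplicate": is_demoted,
                "tnf_flagged": is_flagged,
                "fired_filters": ",".join(fired),
                "bin": bin_,
            }
        )
    per_contig = pd.DataFrame(rows)
    return QCReport(
        sag_id=assembly.sag_id,
        per_contig=per_contig,
        seed_gc_mean=seed_gc_mean,
        gc_bounds=_gc_bounds(seed_gc_mean, config),
        seed_contigs=seed_contigs,
        duplicate_marker_resolutions=resolutions,
    )
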