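"""Synthetic contaminated-SAG generator with ground truth.

Real single-cell amplified genomes are incomplete, fragmented and carry
contaminant contigs from co-sorted or reagent organisms.  This module builds
assemblies with that statistical structure — a target organism with a
characteristic GC/tetranucleotide composition, implanted single-copy marker
genes at a chosen completeness, and contaminant contigs with offset GC, a
distinct compositional signature and non-target taxonomy labels — so every
downstream filter can be scored against known truth.

Composition models: order-0 draws i.i.d. bases at the requested GC; order-3
(the default) draws each class's sequence from its own randomized third-order
Markov chain whose per-context transition probabilities are Dirichlet
perturbations around the requested base composition, giving each class a
genuine 4-mer signature rather than a pure GC shift.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .data import default_marker_set
from .records import Contig, GeneCall, MarkerSet, SAGAssembly

__all__ = [
    "SimulationConfig",
    "SynthTruth",
    "simulate_sag",
    "simulate_proteome",
    "simulate_matrix",
]

_BASES = "ACGT"

# Dirichlet concentration for order-3 per-context transition probabilities:
# large enough that the stationary GC stays within ~0.01 of the request,
# small enough that each class gets a distinctive tetranucleotide signature.
_DIRICHLET_CONCENTRATION = 50.0

# Length of the gene body used for implanted marker genes (bp).
_MARKER_GENE_LEN = 600


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic contaminated SAG.

    Defaults describe a moderately fragmented archaeal SAG with 20%
    contaminant contigs whose GC is offset by +0.15 — comfortably outside the
    ±10-point GC window the QC pipeline applies — and phylum labels distinct
    from the target's.
    """

    seed: int = 0
    target_gc: float = 0.45
    contaminant_gc: float = 0.60
    n_target_contigs: int = 60
    n_contaminant_contigs: int = 15
    length_median: float = 5000.0
    length_sigma: float = 0.6
    min_length: int = 500
    markov_order: int = 3
    marker_universe: MarkerSet = field(default_factory=lambda: default_marker_set(104))
    target_completeness: float = 0.5
    n_duplicated_markers: int = 0
    genes_per_kb: float = 1.0
    target_domain: str = "Archaea"
    target_phylum: str = "Euryarchaeota"
    contaminant_domain: str = "Bacteria"
    contaminant_phylum: str = "Proteobacteria"
    sag_id: str = "SYN001"

    def __post_init__(self) -> None:
        for name in ("target_gc", "contaminant_gc"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0,1), got {v}")
        if not 0.0 <= self.target_completeness <= 1.0:
            raise ValueError("target_completeness must be in [0,1]")
        if self.n_target_contigs < 1:
            raise ValueError("n_target_contigs must be ≥ 1")
        if self.markov_order not in (0, 3):
            raise ValueError("markov_order must be 0 or 3")


@dataclass
class SynthTruth:
    """Ground-truth labels recorded at generation time."""

    labels: dict[str, str]  # contig_id -> "target" | "contaminant"
    implanted_markers: set[str]
    duplicated_markers: set[str]


def _base_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def _order0_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    idx = rng.choice(4, size=n, p=_base_probs(gc))
    return "".join(_BASES[i] for i in idx)


def _markov3_model(rng: np.random.Generator, gc: float) -> np.ndarray:
    """Per-context (64, 4) transition probabilities, Dirichlet around the
    base composition implied by ``gc``."""
    base = _base_probs(gc)
    return rng.dirichlet(_DIRICHLET_CONCENTRATION * base, size=64)


def _markov3_seq(rng: np.random.Generator, n: int, model: np.ndarray, gc: float) -> str:
    if n <= 3:
        return _order0_seq(rng, n, gc)
    out = np.empty(n, dtype=np.int64)
    out[:3] = rng.choice(4, size=3, p=_base_probs(gc))
    cum = np.cumsum(model, axis=1)
    u = rng.random(n)
    ctx = out[0] * 16 + out[1] * 4 + out[2]
    for i in range(3, n):
        b = int(np.searchsorted(cum[ctx], u[i], side="right"))
        b = min(b, 3)
        out[i] = b
        ctx = (ctx % 16) * 4 + b
    return "".join(_BASES[i] for i in out)


def _draw_lengths(rng: np.random.Generator, n: int, cfg: SimulationConfig) -> list[int]:
    """Log-normal contig lengths, rejection-resampled to stay above
    ``min_length`` (no mass piles up exactly at the floor)."""
    mu = np.log(cfg.length_median)
    lengths: list[int] = []
    while len(lengths) < n:
        draw = int(round(float(rng.lognormal(mu, cfg.length_sigma))))
        if draw > cfg.min_length:
            lengths.append(draw)
    return lengths


def _place_background_genes(
    rng: np.random.Generator,
    contig: Contig,
    domain: str,
    phylum: str,
    genes_per_kb: float,
    counter: list[int],
) -> list[GeneCall]:
    n_genes = int(rng.poisson(genes_per_kb * contig.length / 1000.0))
    genes = []
    for _ in range(n_genes):
        glen = min(int(rng.integers(300, 1200)), contig.length)
        start = int(rng.integers(1, contig.length - glen + 2))
        counter[0] += 1
        genes.append(
            GeneCall(
                gene_id=f"g{counter[0]:05d}",
                contig_id=contig.id,
                start=start,
                end=start + glen - 1,
                strand="+" if rng.random() < 0.5 else "-",
                taxon_domain=domain,
                taxon_phylum=phylum,
            )
        )
    return genes


def simulate_sag(config: SimulationConfig) -> tuple[SAGAssembly, SynthTruth]:
    """Generate one contaminated SAG assembly plus its ground truth.

    Identical configs (including seed) reproduce byte-identical output.
    """
    rng = np.random.default_rng(config.seed)
    target_model = _markov3_model(rng, config.target_gc)
    contaminant_model = _markov3_model(rng, config.contaminant_gc)

    t_lengths = _draw_lengths(rng, config.n_target_contigs, config)
    c_lengths = _draw_lengths(rng, config.n_contaminant_contigs, config)

    contigs: list[Contig] = []
    labels: dict[str, str] = {}
    idx = 0
    for length, label in [(L, "target") for L in t_lengths] + [
        (L, "contaminant") for L in c_lengths
    ]:
        idx += 1
        gc = config.target_gc if label == "target" else config.contaminant_gc
        model = target_model if label == "target" else contaminant_model
        if config.markov_order == 0:
            seq = _order0_seq(rng, length, gc)
        else:
            seq = _markov3_seq(rng, length, model, gc)
        cid = f"{config.sag_id}_c{idx:04d}"
        contigs.append(Contig(id=cid, sequence=seq, source_sag=config.sag_id))
        labels[cid] = label

    counter = [0]
    genes: list[GeneCall] = []
    for contig in contigs:
        if labels[contig.id] == "target":
            genes.extend(
                _place_background_genes(
                    rng, contig, config.target_domain, config.target_phylum,
                    config.genes_per_kb, counter,
                )
            )
        else:
            genes.extend(
                _place_background_genes(
                    rng, contig, config.contaminant_domain, config.contaminant_phylum,
                    config.genes_per_kb, counter,
                )
            )

    # Implant single-copy markers on target contigs at the requested completeness.
    universe = config.marker_universe
    n_implant = int(np.floor(config.target_completeness * universe.size + 0.5))
    implanted: set[str] = set()
    duplicated: set[str] = set()
    hosts = [c for c in contigs if labels[c.id] == "target" and c.length >= _MARKER_GENE_LEN]
    if n_implant > 0 and not hosts:
        raise ValueError(
            "target_completeness > 0 but no target contig is long enough to host a marker"
        )
    if n_implant > 0:
        chosen = rng.choice(universe.size, size=n_implant, replace=False)
        chosen_markers = [universe.marker_ids[i] for i in sorted(chosen)]
        n_dup = min(config.n_duplicated_markers, n_implant)
        if n_dup > 0 and len(hosts) < 2:
            raise ValueError("marker duplication requires ≥ 2 eligible target contigs")
        dup_markers = set(chosen_markers[:n_dup])
        for marker in chosen_markers:
            n_copies = 2 if marker in dup_markers else 1
            host_idx = rng.choice(len(hosts), size=n_copies, replace=False)
            for hi in host_idx:
                host = hosts[int(hi)]
                start = int(rng.integers(1, host.length - _MARKER_GENE_LEN + 2))
                counter[0] += 1
                genes.append(
                    GeneCall(
                        gene_id=f"g{counter[0]:05d}",
                        contig_id=host.id,
                        start=start,
                        end=start + _MARKER_GENE_LEN - 1,
                        strand="+" if rng.random() < 0.5 else "-",
                        taxon_domain=config.target_domain,
                        taxon_phylum=config.target_phylum,
                        marker_id=marker,
                    )
                )
            implanted.add(marker)
            if n_copies == 2:
                duplicated.add(marker)

    assembly = SAGAssembly(
        sag_id=config.sag_id,
        contigs=contigs,
        genes=genes,
        metadata={"synthetic": "true", "seed": str(config.seed)},
    )
    return assembly, SynthTruth(
        labels=labels, implanted_markers=implanted, duplicated_markers=duplicated
    )


def config_to_dict(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    d["marker_universe"] = {
        "name": config.marker_universe.name,
        "size": config.marker_universe.size,
    }
    return d


# ---------------------------------------------------------------------------
# Proteome generator

_AA = "ACDEFGHIKLMNPQRSTVWY"


def _aa_probs(acidic_bias: float) -> np.ndarray:
    """Near-uniform residue composition with D+E at 0.11 baseline; the bias
    multiplies the D and E frequencies before renormalization."""
    if acidic_bias < 0:
        raise ValueError("acidic_bias must be ≥ 0")
    p = np.full(20, (1.0 - 0.11) / 18.0)
    for aa in "DE":
        p[_AA.index(aa)] = 0.055 * acidic_bias
    return p / p.sum()


def simulate_proteome(
    seed: int,
    n_proteins: int,
    length_range: tuple[int, int] = (80, 400),
    acidic_bias: float = 1.0,
) -> list[tuple[str, str]]:
    """I.i.d.-residue protein records with a tunable acidic (D/E) enrichment.

    ``acidic_bias`` = 1 reproduces the baseline composition; > 1 shifts the
    proteome acidic, emulating the salt-in strategy of extreme halophiles;
    0 removes D and E entirely.
    """
    if n_proteins < 1:
        raise ValueError("n_proteins must be ≥ 1")
    lo, hi = length_range
    if not 1 <= lo <= hi:
        raise ValueError(f"invalid length_range {length_range}")
    rng = np.random.default_rng(seed)
    probs = _aa_probs(acidic_bias)
    records = []
    for i in range(1, n_proteins + 1):
        n = int(rng.integers(lo, hi + 1))
        seq = "".join(_AA[j] for j in rng.choice(20, size=n, p=probs))
        records.append((f"prot{i:05d}", seq))
    return records


# ---------------------------------------------------------------------------
# Character-matrix generator

def simulate_matrix(
    seed: int,
    n_taxa: int,
    n_sites: int,
    p_variable: float,
    states: str = "ACGT",
):
    """Random character matrix with per-site ground-truth classes.

    Each site is constant with probability 1 − ``p_variable``; otherwise a
    random non-constant state assignment is drawn.  Returns
    ``(taxa, rows, site_classes)`` where ``site_classes[i]`` is one of
    "constant", "variable_uninformative", "parsimony_informative", computed
    at construction by the standard definitions (≥2 states, each in ≥2 taxa,
    for informativeness).
    """
    if n_taxa < 4:
        raise ValueError("n_taxa must be ≥ 4")
    if not 0.0 <= p_variable <= 1.0:
        raise ValueError("p_variable must be in [0,1]")
    rng = np.random.default_rng(seed)
    state_arr = list(states)
    k = len(state_arr)
    columns: list[list[str]] = []
    classes: list[str] = []
    for _ in range(n_sites):
        if rng.random() >= p_variable:
            s = state_arr[int(rng.integers(k))]
            columns.append([s] * n_taxa)
            classes.append("constant")
            continue
        while True:
            col = [state_arr[int(j)] for j in rng.integers(0, k, size=n_taxa)]
            if len(set(col)) >= 2:
                break
        columns.append(col)
        counts = {s: col.count(s) for s in set(col)}
        n_shared = sum(1 for v in counts.values() if v >= 2)
        classes.append(
            "parsimony_informative" if n_shared >= 2 else "variable_uninformative"
        )
    taxa = [f"t{i + 1}" for i in range(n_taxa)]
    rows = ["".join(columns[j][i] for j in range(n_sites)) for i in range(n_taxa)]
    return taxa, rows, classes
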