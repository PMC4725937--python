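"""End-to-end orchestration: load/simulate → seed-contig GC → filters →
duplicate-marker resolution → TNF ordination + outlier flags → final bins →
assembly stats + completeness (+ optional proteome pI), with a manifest for
reproducibility.

Stage order is fixed: the deterministic filters run first, then the
ordination is computed over all contigs and outliers are judged against the
provisional clean bin, whose flags fold back into the suspicious tier.
Identical configurations produce byte-identical tabular outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .assembly_stats import stats_table
from .completeness import completeness, duplication_report
from .data import default_marker_set
from .io import read_fasta, read_gene_table, read_marker_list, write_fasta, write_gene_table, write_report
from .qc import FilterConfig, run_qc, select_seed_contigs
from .records import Contig, MarkerSet, SAGAssembly
from .simulate import SimulationConfig, config_to_dict, simulate_sag
from .tnf import correspondence_analysis, flag_outliers, ordination_plot, tnf_table

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "evaluate_against_truth"]


@dataclass
class RunConfig:
    """One pipeline run: either a synthetic simulation or FASTA+gene-table
    inputs, plus filter/ordination/marker-set settings."""

    out_dir: str | Path = "sagqc_run"
    seed: int = 42
    simulate: SimulationConfig | None = None
    fasta: str | Path | None = None
    genes: str | Path | None = None
    sag_id: str = "SAG"
    filters: FilterConfig = field(default_factory=FilterConfig)
    ordination_axes: int = 2
    marker_set_paths: list[str] = field(default_factory=list)
    proteome_faa: str | Path | None = None
    make_plot: bool = False

    def marker_sets(self) -> list[MarkerSet]:
        if self.marker_set_paths:
            return [read_marker_list(p) for p in self.marker_set_paths]
        return [default_marker_set(104), default_marker_set(191)]

    def to_dict(self) -> dict:
        d = {
            "seed": self.seed,
            "sag_id": self.sag_id,
            "filters": dataclasses.asdict(self.filters),
            "ordination_axes": self.ordination_axes,
            "marker_set_paths": list(self.marker_set_paths),
            "fasta": str(self.fasta) if self.fasta else None,
            "genes": str(self.genes) if self.genes else None,
            "proteome_faa": str(self.proteome_faa) if self.proteome_faa else None,
            "simulate": config_to_dict(self.simulate) if self.simulate else None,
        }
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _load_assembly(config: RunConfig) -> tuple[SAGAssembly, "object | None"]:
    if config.simulate is not None:
        assembly, truth = simulate_sag(config.simulate)
        return assembly, truth
    if config.fasta is None:
        raise ValueError("RunConfig needs either a simulate block or a fasta path")
    contigs = [
        Contig(id=cid, sequence=seq, source_sag=config.sag_id)
        for cid, seq in read_fasta(config.fasta)
    ]
    genes = read_gene_table(config.genes) if config.genes else []
    return SAGAssembly(sag_id=config.sag_id, contigs=contigs, genes=genes), None


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages into ``config.out_dir``; returns the run directory.

    Any stage error propagates (the CLI maps it to a nonzero exit naming the
    stage).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: list[str] = []

    assembly, truth = _load_assembly(config)
    stages.append("load")
    if truth is not None:
        pd.DataFrame(
            sorted(truth.labels.items()), columns=["contig_id", "label"]
        ).to_csv(out / "truth.tsv", sep="\t", index=False)
        with open(out / "truth.json", "w") as fh:
            json.dump(
                {
                    "implanted_markers": sorted(truth.implanted_markers),
                    "duplicated_markers": sorted(truth.duplicated_markers),
                },
                fh,
                indent=2,
            )
            fh.write("\n")
        write_gene_table(assembly.genes, out / "genes.tsv")
        write_fasta(
            [(c.id, c.sequence) for c in assembly.contigs], out / "contigs.fasta"
        )

    marker_hits = assembly.marker_hits()
    seed_ids, seed_gc_mean = select_seed_contigs(assembly, config.filters, marker_hits)
    stages.append("seed_gc")

    provisional = run_qc(
        assembly, config.filters, marker_hits,
        seed_gc_mean=seed_gc_mean, seed_contigs=seed_ids,
    )
    stages.append("filters")

    counts, tnf_unavailable = tnf_table(assembly.contigs)
    tnf_out = counts.copy()
    tnf_out.insert(0, "contig_id", tnf_out.index)
    tnf_out.to_csv(out / "tnf.tsv", sep="\t", index=False)
    flags: set[str] = set()
    ordination = None
    provisional_clean = provisional.bin_ids("clean")
    if len(counts) >= 3 and provisional_clean & set(counts.index):
        ordination = correspondence_analysis(counts, k=config.ordination_axes)
        flagged = flag_outliers(
            ordination,
            reference=provisional_clean & set(counts.index),
            cutoff=config.filters.tnf_flag_cutoff,
        )
        flags = set(flagged)
    stages.append("tnf_ordination")

    report = run_qc(
        assembly, config.filters, marker_hits,
        tnf_flags=flags, seed_gc_mean=seed_gc_mean, seed_contigs=seed_ids,
    )
    stages.append("final_bins")
    write_report(report, out)

    bins = dict(zip(report.per_contig["contig_id"], report.per_contig["bin"]))
    for name in ("clean", "contaminated", "suspicious"):
        ids = report.bin_ids(name)
        write_fasta(
            [(c.id, c.sequence) for c in assembly.contigs if c.id in ids],
            out / f"{name}.fasta",
        )
    if ordination is not None:
        if config.make_plot:
            ordination_plot(ordination, bins, out / "ordination")
        else:
            table = ordination.axes.copy()
            table.insert(0, "contig_id", table.index)
            table["bin"] = [bins.get(cid, "unbinned") for cid in table.index]
            table["flagged"] = [cid in flags for cid in table.index]
            table.to_csv(out / "ordination.tsv", sep="\t", index=False,
                         float_format="%.6g")

    clean_ids = report.bin_ids("clean")
    stats_source = assembly.subset(clean_ids) if clean_ids else assembly
    marker_sets = config.marker_sets()
    clean_hits = stats_source.marker_hits()
    comp_rows = []
    for ms in marker_sets:
        profile = completeness(clean_hits, ms)
        comp_rows.append(
            {
                "sag_id": assembly.sag_id,
                "marker_set": ms.name,
                "set_size": ms.size,
                "markers_present": len(profile.present),
                "completeness_pct": profile.completeness_pct,
            }
        )
    comp_table = pd.DataFrame(comp_rows)
    comp_table.to_csv(out / "completeness.tsv", sep="\t", index=False)
    duplication_report(marker_hits).to_csv(
        out / "marker_duplications.tsv", sep="\t", index=False
    )
    comp_wide = comp_table.pivot_table(
        index="sag_id", columns="marker_set", values="completeness_pct"
    )
    comp_wide.columns = [f"completeness_{c}" for c in comp_wide.columns]
    stats_table([stats_source], comp_wide).to_csv(
        out / "stats.tsv", sep="\t", index=False
    )
    stages.append("stats_completeness")

    if config.proteome_faa:
        from .io import read_protein_fasta
        from .isoelectric import proteome_profile

        profile = proteome_profile(
            read_protein_fasta(config.proteome_faa), proteome_id=assembly.sag_id
        )
        pi_table = (
            profile.pi_values.round(2).rename("pI").rename_axis("protein_id").reset_index()
        )
        pi_table.to_csv(out / "pi_profile.tsv", sep="\t", index=False)
        with open(out / "pi_summary.json", "w") as fh:
            json.dump(
                {
                    "proteome_id": profile.proteome_id,
                    "n_proteins": int(len(profile.pi_values)),
                    "median": round(profile.median, 3),
                    "mode": round(profile.mode, 3),
                    "mean": round(profile.mean, 3),
                    "acidic_fraction": round(profile.acidic_fraction, 4),
                    "n_undefined": profile.n_undefined,
                },
                fh,
                indent=2,
            )
            fh.write("\n")
        stages.append("proteome_pi")

    manifest = {
        "sagqc_version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "stages": stages,
        "n_contigs": len(assembly.contigs),
        "tnf_unavailable": tnf_unavailable,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out


def evaluate_against_truth(run_dir: str | Path, truth_path: str | Path | None = None) -> dict:
    """Score a run's bins against ground-truth contig labels.

    Positive calls for recall are contaminated ∪ suspicious; precision is
    computed on the contaminated bin alone (the suspicious tier is a
    manual-review holding bin, not a call).  Adds the completeness error
    |estimated − implanted| when the run recorded implanted markers.
    """
    run_dir = Path(run_dir)
    report = pd.read_csv(run_dir / "qc_report.tsv", sep="\t")
    truth_path = Path(truth_path) if truth_path else run_dir / "truth.tsv"
    truth = pd.read_csv(truth_path, sep="\t")
    labels = dict(zip(truth["contig_id"], truth["label"]))
    missing = [cid for cid in report["contig_id"] if cid not in labels]
    if missing:
        raise ValueError(f"unlabelled contigs: {missing[:5]}...")

    bins = dict(zip(report["contig_id"], report["bin"]))
    contaminants = {cid for cid, lab in labels.items() if lab == "contaminant"}
    called_positive = {cid for cid, b in bins.items() if b in ("contaminated", "suspicious")}
    contaminated_bin = {cid for cid, b in bins.items() if b == "contaminated"}
    clean_bin = {cid for cid, b in bins.items() if b == "clean"}

    recall = (
        len(contaminants & called_positive) / len(contaminants) if contaminants else 1.0
    )
    precision = (
        len(contaminated_bin & contaminants) / len(contaminated_bin)
        if contaminated_bin
        else 1.0
    )
    f1 = (
        2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    )
    clean_contamination = (
        len(clean_bin & contaminants) / len(clean_bin) if clean_bin else 0.0
    )
    result = {
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "clean_bin_contamination": clean_contamination,
        "n_clean": len(clean_bin),
        "n_contaminated": len(contaminated_bin),
        "n_truth_contaminants": len(contaminants),
    }

    truth_json = run_dir / "truth.json"
    comp_path = run_dir / "completeness.tsv"
    if truth_json.exists() and comp_path.exists():
        with open(truth_json) as fh:
            tj = json.load(fh)
        comp = pd.read_csv(comp_path, sep="\t")
        for _, row in comp.iterrows():
            implanted_in_set = len(tj["implanted_markers"])
            implanted_pct = 100.0 * implanted_in_set / row["set_size"]
            result[f"completeness_error_{row['marker_set']}"] = abs(
                float(row["completeness_pct"]) - implanted_pct
            )
    return result
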