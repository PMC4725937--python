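"""Decontamination filters: GC window, seed contigs, size and taxonomy
filters, duplicate-marker resolution and bin assembly."""

import math

import pytest

from sagqc.qc import (
    FilterConfig,
    gc_content,
    gc_filter,
    resolve_duplicate_markers,
    run_qc,
    select_seed_contigs,
    select_seed_contigs_group,
    size_filter,
    taxon_filter,
)
from sagqc.records import Contig, GeneCall, SAGAssembly
from sagqc.simulate import SimulationConfig, simulate_sag


def _contig(cid, seq):
    return Contig(id=cid, sequence=seq)


def _asm(contigs, genes=(), sag_id="T"):
    return SAGAssembly(sag_id=sag_id, contigs=list(contigs), genes=list(genes))


class TestGCContent:
    @pytest.mark.parametrize(
        "seq,expected",
        [("GGCC", 1.0), ("ATATAT", 0.0), ("ACGTN", 0.5)],
    )
    def test_values(self, seq, expected):
        assert gc_content(_contig("c", seq)) == pytest.approx(expected)

    def test_all_n_undefined(self):
        assert gc_content(_contig("c", "NNNN")) is None


class TestSeedContigs:
    def test_n50_prefix(self):
        asm = _asm([_contig("a", "A" * 10_000), _contig("b", "A" * 6_000),
                    _contig("c", "A" * 4_000)])
        seeds, _ = select_seed_contigs(asm, FilterConfig())
        assert seeds == {"a"}

    def test_length_weighted_mean_of_equal_lengths(self):
        # three equal-length contigs: the N50 prefix is the first two, so
        # the seed mean averages GC 0.40 and 0.50 and excludes the third
        asm = _asm([_contig("a", "ACGTATGCAT" * 100),   # GC 0.4
                    _contig("b", "ACGCATGCAT" * 100),   # GC 0.5
                    _contig("c", "GCGCGCGCGC" * 100)])  # GC 1.0, not a seed
        seeds, mean = select_seed_contigs(asm, FilterConfig())
        assert seeds == {"a", "b"}
        assert mean == pytest.approx(0.45)

    def test_marker_mode_without_markers_errors(self):
        asm = _asm([_contig("a", "ACGT" * 1000)])
        with pytest.raises(ValueError, match="n50"):
            select_seed_contigs(asm, FilterConfig(seed_mode="marker_contigs"))

    def test_marker_mode_selects_carriers(self):
        asm = _asm(
            [_contig("a", "ACGT" * 1000), _contig("b", "ACGT" * 1000)],
            [GeneCall("g1", "a", 1, 600, "+", "Archaea", "P", marker_id="m1")],
        )
        seeds, _ = select_seed_contigs(
            asm, FilterConfig(seed_mode="marker_contigs")
        )
        assert seeds == {"a"}

    def test_group_mode_shares_one_mean(self):
        a1 = _asm([_contig("a", "ACGTATGCAT" * 200)],
                  [GeneCall("g1", "a", 1, 600, "+", "Archaea", "P", marker_id="m1")],
                  sag_id="S1")
        a2 = _asm([_contig("b", "ACGCATGCAT" * 200)],
                  [GeneCall("g2", "b", 1, 600, "+", "Archaea", "P", marker_id="m2")],
                  sag_id="S2")
        seeds, mean = select_seed_contigs_group(
            [a1, a2], FilterConfig(seed_mode="group_marker_contigs")
        )
        assert seeds == {"S1": {"a"}, "S2": {"b"}}
        assert mean == pytest.approx(0.45)

    def test_synthetic_seed_mean_near_target_gc(self):
        cfg = SimulationConfig(seed=42, markov_order=0, target_gc=0.45,
                               n_contaminant_contigs=0, n_target_contigs=30)
        asm, _ = simulate_sag(cfg)
        _, mean = select_seed_contigs(asm, FilterConfig())
        assert abs(mean - 0.45) < 0.01


class TestGCFilter:
    def test_closed_interval_boundary(self):
        asm = _asm([_contig("in", "CG" * 550 + "AT" * 450),    # GC 0.55
                    _contig("out", "CG" * 551 + "AT" * 449)])  # GC 0.551
        res = gc_filter(asm, FilterConfig(gc_window=10), seed_gc_mean=0.45)
        assert res == {"in": True, "out": False}

    def test_zero_window_degenerate(self):
        asm = _asm([_contig("a", "ACGT" * 100), _contig("b", "ACGTT" * 100)])
        res = gc_filter(asm, FilterConfig(gc_window=0), seed_gc_mean=0.5)
        assert res == {"a": True, "b": False}

    def test_relative_mode(self):
        asm = _asm([_contig("a", "CG" * 500 + "AT" * 500)])  # GC 0.50
        cfg = FilterConfig(gc_window=10, gc_window_mode="relative")
        # bounds are mean×[0.9, 1.1]: 0.45 → [0.405, 0.495] excludes 0.50
        assert gc_filter(asm, cfg, seed_gc_mean=0.45)["a"] is False
        assert gc_filter(asm, cfg, seed_gc_mean=0.46)["a"] is True

    def test_synthetic_contaminants_fail(self, default_sim):
        asm, truth = default_sim
        cfg = FilterConfig()
        _, mean = select_seed_contigs(asm, cfg)
        res = gc_filter(asm, cfg, mean)
        contaminants = [c for c in asm.contigs
                        if truth.labels[c.id] == "contaminant" and c.length >= 2000]
        failed = sum(1 for c in contaminants if not res[c.id])
        assert failed / len(contaminants) >= 0.95


class TestSizeFilter:
    @pytest.mark.parametrize(
        "length,expected",
        [(2000, "pass"), (1999, "suspicious"), (3000, "pass"),
         (501, "suspicious"), (500, "discard"), (100, "discard")],
    )
    def test_boundaries(self, length, expected):
        asm = _asm([_contig("c", "A" * length)])
        assert size_filter(asm, FilterConfig())["c"] == expected


class TestTaxonFilter:
    def _asm_with_votes(self, n_target, n_non, n_uncl=0):
        genes = []
        for i in range(n_target):
            genes.append(GeneCall(f"t{i}", "c", 1, 9, "+", "Archaea", "Eury"))
        for i in range(n_non):
            genes.append(GeneCall(f"n{i}", "c", 1, 9, "+", "Bacteria", "Proteo"))
        for i in range(n_uncl):
            genes.append(GeneCall(f"u{i}", "c", 1, 9, "+", "unclassified", "unclassified"))
        return _asm([_contig("c", "ACGT" * 10)], genes)

    def test_half_or_more_fails(self):
        res = taxon_filter(self._asm_with_votes(2, 2), FilterConfig())
        assert res["c"]["passed"] is False
        assert res["c"]["votes"] == (2, 2, 0)

    def test_minority_passes(self):
        res = taxon_filter(self._asm_with_votes(3, 1), FilterConfig())
        assert res["c"]["passed"] is True

    def test_unclassified_excluded_from_vote(self):
        res = taxon_filter(self._asm_with_votes(1, 0, n_uncl=5), FilterConfig())
        assert res["c"]["passed"] is True
        assert res["c"]["votes"] == (1, 0, 5)

    def test_no_evidence_passes_with_flag(self):
        res = taxon_filter(self._asm_with_votes(0, 0), FilterConfig())
        assert res["c"]["passed"] is True
        assert res["c"]["flag"] == "no_taxonomic_evidence"

    def test_phylum_level_when_configured(self):
        genes = [GeneCall("g", "c", 1, 9, "+", "Archaea", "Crenarchaeota")]
        asm = _asm([_contig("c", "ACGT" * 10)], genes)
        cfg = FilterConfig(target_phylum="Euryarchaeota")
        assert taxon_filter(asm, cfg)["c"]["passed"] is False


class TestDuplicateResolution:
    def test_largest_retained(self):
        asm = _asm(
            [_contig("big", "A" * 8000), _contig("small", "A" * 3000)],
            [GeneCall(f"g{i}", "small", 1, 9, "+") for i in range(9)]
            + [GeneCall(f"h{i}", "big", 1, 9, "+") for i in range(5)],
        )
        retained, demoted, _ = resolve_duplicate_markers(
            asm, {"m1": ["big", "small"]}
        )
        assert retained == {"m1": "big"} and demoted == {"small"}

    def test_single_carrier_untouched(self):
        asm = _asm([_contig("a", "A" * 1000)])
        retained, demoted, res = resolve_duplicate_markers(asm, {"m1": ["a"]})
        assert not retained and not demoted and not res

    def test_lexicographic_tie_break(self):
        asm = _asm([_contig("cA", "A" * 1000), _contig("cB", "A" * 1000)])
        retained, demoted, _ = resolve_duplicate_markers(asm, {"m1": ["cB", "cA"]})
        assert retained == {"m1": "cA"} and demoted == {"cB"}


class TestRunQC:
    def test_gc_only_failure_is_contaminated(self):
        # seed mean from the two big AT-rich contigs; the GC-rich one fails GC only
        contigs = [_contig("a", "AT" * 2000), _contig("b", "AT" * 2000),
                   _contig("x", "GC" * 1500)]
        asm = _asm(contigs)
        report = run_qc(asm, FilterConfig(target_domain="Archaea"))
        row = report.per_contig.set_index("contig_id").loc["x"]
        assert row["bin"] == "contaminated"
        assert row["fired_filters"] == "gc"

    def test_tnf_flag_only_is_suspicious(self):
        contigs = [_contig("a", "AT" * 2000), _contig("b", "AT" * 2000)]
        asm = _asm(contigs)
        report = run_qc(asm, FilterConfig(), tnf_flags={"b"})
        row = report.per_contig.set_index("contig_id").loc["b"]
        assert row["bin"] == "suspicious" and row["fired_filters"] == "tnf"

    def test_all_n_contig_suspicious(self):
        contigs = [_contig("a", "AT" * 2000), _contig("n", "N" * 3000)]
        report = run_qc(_asm(contigs), FilterConfig())
        row = report.per_contig.set_index("contig_id").loc["n"]
        assert row["bin"] == "suspicious"
        assert "gc_undefined" in row["fired_filters"]

    def test_bins_partition(self, default_sim):
        asm, _ = default_sim
        report = run_qc(asm, FilterConfig())
        assert set(report.per_contig["bin"]) <= {"clean", "contaminated", "suspicious"}
        assert len(report.per_contig) == len(asm.contigs)

    def test_recovery_on_synthetic(self, default_sim):
        """Defaults on the reference scenario: ≥95% of true contaminants ≥2 kb
        land outside clean, and ≥95% of the contaminated bin is truly
        contaminant."""
        asm, truth = default_sim
        report = run_qc(asm, FilterConfig())
        bins = dict(zip(report.per_contig["contig_id"], report.per_contig["bin"]))
        big = {c.id for c in asm.contigs if c.length >= 2000}
        contam = {cid for cid in big if truth.labels[cid] == "contaminant"}
        called = {cid for cid in big if bins[cid] in ("contaminated", "suspicious")}
        assert len(contam & called) / len(contam) >= 0.95
        cbin = {cid for cid, b in bins.items() if b == "contaminated"}
        truly = {cid for cid in cbin if truth.labels[cid] == "contaminant"}
        assert len(truly) / len(cbin) >= 0.95

    def test_idempotent_on_clean_bin(self, default_sim):
        asm, _ = default_sim
        cfg = FilterConfig()
        report = run_qc(asm, cfg)
        clean_ids = report.bin_ids("clean")
        clean_asm = asm.subset(clean_ids)
        report2 = run_qc(clean_asm, cfg, seed_gc_mean=report.seed_gc_mean)
        assert report2.bin_ids("clean") == clean_ids

    def test_tightening_thresholds_never_admits_clean(self, default_sim):
        asm, _ = default_sim
        base = run_qc(asm, FilterConfig()).bin_ids("clean")
        for cfg in (
            FilterConfig(gc_window=5),
            FilterConfig(gc_window=2),
            FilterConfig(min_length=3000),
            FilterConfig(min_length=5000, gc_window=5),
        ):
            assert run_qc(asm, cfg).bin_ids("clean") <= base

    def test_neutral_filter_limit(self, default_sim):
        """With an infinite GC window, majority threshold 1 and the size
        threshold at the floor, everything not demoted is clean."""
        asm, _ = default_sim
        cfg = FilterConfig(gc_window=math.inf, majority_threshold=1.0,
                           min_length=501, suspicious_floor=500)
        report = run_qc(asm, cfg)
        demoted = set(
            report.per_contig[report.per_contig["demoted_duplicate"]]["contig_id"]
        )
        assert report.bin_ids("clean") == {c.id for c in asm.contigs} - demoted
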