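import gzip

import numpy as np
import pandas as pd
import pytest

from oracles import binomial_99ci

from amplimeth.panel import AmpliconPanel, AmpliconRegion, VariantLocus
from amplimeth.synthetic import (CohortDesign, ConversionModel, EffectSpec,
                                 make_fixture, simulate_cohort,
                                 simulate_methylation_counts, simulate_reads)


def one_site_panel(seq="TTTACGTTTCTT", variants=()):
    return AmpliconPanel([AmpliconRegion("R", "chr1", 0, len(seq), seq,
                                         gene="R")], variants=list(variants))


def cohort(panel, con=50.0, dhd=0.0, dlc=0.0, dispersion=0.0,
           design=None, freqs=None, seed=0):
    effects = [EffectSpec(sid, con, dhd, dlc, dispersion=dispersion)
               for sid in panel.site_ids()]
    design = design or CohortDesign(n_con=4, n_hd=4, n_lc=4,
                                    batch_shifts={"E1": 0.0})
    return simulate_cohort(panel, design, effects, freqs or {}, seed=seed)


class TestEffectSpec:
    @pytest.mark.parametrize("dhd,dlc,pattern", [
        (0, 0, "null"),
        (3, -3, "bidirectional"),
        (-2, 1.5, "bidirectional"),
        (4, 2, "ordered_increase"),
        (-4, -2, "ordered_decrease"),
        (3, 0, "unidirectional"),
        (2, 2, "unidirectional"),
    ])
    def test_pattern_from_deltas(self, dhd, dlc, pattern):
        assert EffectSpec("R:CpG_1", 10.0, dhd, dlc).pattern == pattern

    def test_con_mean_bounds(self):
        with pytest.raises(ValueError):
            EffectSpec("R:CpG_1", 101.0)


class TestSimulateCohort:
    def test_null_zero_dispersion_gives_shared_mean(self):
        truth = cohort(one_site_panel(), con=42.0)
        assert (truth.meth_prob.to_numpy() == 42.0).all()

    def test_frequency_zero_gives_all_ref(self):
        panel = one_site_panel(variants=[VariantLocus("R", 1, "T", "A")])
        truth = cohort(panel, freqs={"R:1T>A": 0.0})
        assert (truth.genotypes.to_numpy() == 0).all()

    def test_heterozygote_fraction_matches_hardy_weinberg(self):
        panel = one_site_panel(variants=[VariantLocus("R", 1, "T", "A")])
        design = CohortDesign(n_con=334, n_hd=333, n_lc=333,
                              batch_shifts={"E1": 0.0})
        truth = cohort(panel, design=design, freqs={"R:1T>A": 0.5}, seed=5)
        het = (truth.genotypes["R:1T>A"] == 1).mean()
        lo, hi = binomial_99ci(0.5, 1000)
        assert lo <= het <= hi

    def test_effects_must_cover_every_site(self):
        panel = one_site_panel()
        with pytest.raises(ValueError, match="missing"):
            simulate_cohort(panel, CohortDesign(1, 1, 1, batch_shifts={"b": 0}),
                            [], {})
        with pytest.raises(ValueError, match="unknown"):
            simulate_cohort(panel, CohortDesign(1, 1, 1, batch_shifts={"b": 0}),
                            [EffectSpec("R:CpG_1", 1), EffectSpec("X:CpG_9", 1)],
                            {})

    def test_batch_shift_recoverable_at_null_sites(self):
        design = CohortDesign(n_con=40, n_hd=40, n_lc=40,
                              batch_shifts={"E1": 0.0, "E2": 5.0})
        truth = cohort(one_site_panel(), con=30.0, dispersion=2.0,
                       design=design, seed=2)
        by_batch = truth.meth_prob.iloc[:, 0].groupby(truth.samples["batch"]).mean()
        assert by_batch["E2"] - by_batch["E1"] == pytest.approx(5.0, abs=1.0)


class TestSimulateReads:
    def _reads(self, truth, panel, model, tmp_path, seed=0):
        sim = simulate_reads(panel, truth, model, tmp_path, seed=seed)
        out = {}
        for sample, path in sim.fastq_paths.items():
            with gzip.open(path, "rt") as fh:
                lines = fh.read().splitlines()
            out[sample] = lines[1::4]
        return sim, out

    def test_fully_methylated_site_always_reads_c(self, tmp_path):
        panel = one_site_panel()
        truth = cohort(panel, con=100.0)
        model = ConversionModel(conversion_rate=1.0, inappropriate_conversion=0.0,
                                seq_error=0.0, depth=40, read_length=50)
        sim, reads = self._reads(truth, panel, model, tmp_path)
        sc = pd.read_csv(sim.sidecar_path, sep="\t").set_index("read_id")
        # CpG C at offset 4, G at 5
        for sample, seqs in reads.items():
            for rid_line, seq in zip(
                    open_read_ids(sim.fastq_paths[sample]), seqs):
                strand = sc.at[rid_line, "strand"]
                base = seq[4] if strand == "OT" else seq[5]
                assert base == ("C" if strand == "OT" else "G")

    def test_unmethylated_site_full_conversion_always_reads_t(self, tmp_path):
        panel = one_site_panel()
        truth = cohort(panel, con=0.0)
        model = ConversionModel(conversion_rate=1.0, inappropriate_conversion=0.0,
                                seq_error=0.0, depth=40, read_length=50)
        sim, reads = self._reads(truth, panel, model, tmp_path)
        sc = pd.read_csv(sim.sidecar_path, sep="\t").set_index("read_id")
        for sample in reads:
            for rid_line, seq in zip(
                    open_read_ids(sim.fastq_paths[sample]), reads[sample]):
                strand = sc.at[rid_line, "strand"]
                base = seq[4] if strand == "OT" else seq[5]
                assert base == ("T" if strand == "OT" else "A")

    def test_noncpg_retention_matches_conversion_rate(self, tmp_path):
        """Retained-C fraction at non-CpG cytosines ~ 1 - conversion_rate."""
        seq = "TCT" * 40  # non-CpG cytosines only
        panel = one_site_panel(seq=seq)
        effects = []  # no CpGs at all
        design = CohortDesign(2, 2, 2, batch_shifts={"E1": 0.0})
        truth = simulate_cohort(panel, design, effects, {}, seed=0)
        model = ConversionModel(conversion_rate=0.99, inappropriate_conversion=0.0,
                                seq_error=0.0, depth=200, read_length=60)
        sim, reads = self._reads(truth, panel, model, tmp_path)
        sc = pd.read_csv(sim.sidecar_path, sep="\t").set_index("read_id")
        retained = total = 0
        for sample in reads:
            for rid_line, s in zip(open_read_ids(sim.fastq_paths[sample]),
                                   reads[sample]):
                if sc.at[rid_line, "strand"] != "OT":
                    continue
                start = sc.at[rid_line, "offset"]
                for k, b in enumerate(s):
                    if seq[start + k] == "C":
                        total += 1
                        retained += b == "C"
        lo, hi = binomial_99ci(0.01, total)
        assert lo <= retained / total <= hi

    def test_deterministic_reads_are_pure_function_of_template(self, tmp_path):
        """With extreme probabilities reads follow the template exactly."""
        panel = one_site_panel()
        truth = cohort(panel, con=0.0)
        model = ConversionModel(conversion_rate=1.0, inappropriate_conversion=0.0,
                                seq_error=0.0, depth=30, read_length=50)
        sim, reads = self._reads(truth, panel, model, tmp_path)
        seq = panel.regions["R"].sequence
        expect_ot = seq.replace("C", "T")
        expect_ob = "".join("A" if b == "G" else b for b in seq)
        sc = pd.read_csv(sim.sidecar_path, sep="\t").set_index("read_id")
        for sample in reads:
            for rid_line, s in zip(open_read_ids(sim.fastq_paths[sample]),
                                   reads[sample]):
                want = expect_ot if sc.at[rid_line, "strand"] == "OT" else expect_ob
                assert s == want

    def test_empirical_site_fraction_converges_to_truth(self):
        """Binomial sampling at depth 2000 recovers the truth within 3 SD."""
        panel = one_site_panel()
        truth = cohort(panel, con=30.0)
        m = simulate_methylation_counts(truth, depth=2000, seed=3)
        p = 0.30
        sd = 100 * np.sqrt(p * (1 - p) / 2000)
        assert (np.abs(m.percent.to_numpy() - 30.0) <= 3 * sd).all()


def open_read_ids(path):
    with gzip.open(path, "rt") as fh:
        return [line[1:].strip() for line in fh.read().splitlines()[0::4]]


class TestMakeFixture:
    def test_unknown_preset_lists_presets(self):
        with pytest.raises(ValueError, match="tiny.*paper_like.*null_only"):
            make_fixture("nope", 0)

    def test_same_seed_byte_identical_fastq(self, tmp_path):
        a = make_fixture("tiny", 11, out_dir=tmp_path / "a")
        b = make_fixture("tiny", 11, out_dir=tmp_path / "b")
        for sample in a.reads.fastq_paths:
            assert a.reads.fastq_paths[sample].read_bytes() == \
                b.reads.fastq_paths[sample].read_bytes()

    def test_null_only_has_only_null_patterns(self):
        fx = make_fixture("null_only", 2)
        assert set(fx.truth.patterns.unique()) == {"null"}

    def test_paper_like_bookkeeping(self, paper_fixture):
        fx = paper_fixture
        assert (fx.design.n_con, fx.design.n_hd, fx.design.n_lc) == (31, 31, 42)
        classes = fx.expected_region_classes()
        assert sum(c == "hypomethylated" for c in classes.values()) >= 12
        assert sum(c == "hypermethylated" for c in classes.values()) >= 1
        assert fx.n_bidirectional_sites >= 5
        effects = {v.cpg_effect for v in _annotated(fx)}
        assert {"creates", "destroys"} <= effects
        assert len(fx.panel.variants) >= 3
        # declared bidirectional count matches the truth table
        assert (fx.truth.patterns == "bidirectional").sum() == \
            fx.n_bidirectional_sites

    def test_paper_like_truth_is_complete(self, paper_fixture):
        t = paper_fixture.truth
        assert not t.meth_prob.isna().any().any()
        assert not t.genotypes.isna().any().any()
        assert set(t.samples["group"]) == {"CON", "HD", "LC"}


def _annotated(fx):
    from amplimeth.snp import annotate_cpg_change
    from dataclasses import replace
    return [replace(v, cpg_effect=annotate_cpg_change(v, fx.panel.regions[v.region_id]))
            for v in fx.panel.variants]
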