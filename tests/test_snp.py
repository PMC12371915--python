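import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from oracles import kruskal_permutation, mann_whitney_exact

from amplimeth.calling import AssignmentResult, ReadAssignment, assign_reads
from amplimeth.panel import AmpliconPanel, AmpliconRegion, VariantLocus
from amplimeth.snp import (allele_aware_methylation, ambiguity_flag,
                           annotate_cpg_change, detect_variants,
                           genotype_association, informative_strands,
                           write_vcf)
from amplimeth.synthetic import (CohortDesign, ConversionModel, EffectSpec,
                                 simulate_cohort, simulate_reads)


class TestAmbiguityRules:
    @pytest.mark.parametrize("ref,alt,strands", [
        ("G", "A", ("OT",)), ("A", "G", ("OT",)),
        ("C", "T", ()), ("T", "C", ()),
        ("A", "T", ("OT", "OB")), ("C", "G", ("OT", "OB")),
        ("A", "C", ("OT", "OB")), ("T", "G", ("OT", "OB")),
    ])
    def test_informative_strands(self, ref, alt, strands):
        assert informative_strands(ref, alt) == strands

    def test_flags(self):
        assert ambiguity_flag("C", "T") == "both"
        assert ambiguity_flag("G", "A") == "OB"
        assert ambiguity_flag("A", "T") is None


class TestAnnotateCpgChange:
    def region(self, seq):
        return AmpliconRegion("R", "chr1", 0, len(seq), seq)

    @pytest.mark.parametrize("seq,off,ref,alt,effect", [
        ("TTCGTT", 3, "G", "A", "destroys"),   # C[G->A]
        ("TTCTTT", 3, "T", "G", "creates"),    # C[T->G]
        ("TTATTT", 2, "A", "G", "neutral"),    # no C before
        ("TTCGTT", 4, "T", "A", "neutral"),    # adjacent to retained CpG
        ("TTTGTT", 2, "T", "C", "creates"),    # T/C completing CG
    ])
    def test_effects(self, seq, off, ref, alt, effect):
        v = VariantLocus("R", off, ref, alt)
        assert annotate_cpg_change(v, self.region(seq)) == effect

    def test_offset_out_of_range(self):
        with pytest.raises(ValueError, match="outside region"):
            annotate_cpg_change(VariantLocus("R", 9, "A", "T"),
                                self.region("ACGT"))

    @given(st.text(alphabet="ACGT", min_size=3, max_size=30),
           st.integers(0, 29), st.sampled_from("ACGT"))
    @settings(max_examples=300, deadline=None)
    def test_involution(self, seq, off, alt):
        """Applying alt then annotating the reverse substitution flips the
        label (creates<->destroys, neutral<->neutral)."""
        if off >= len(seq) or seq[off] == alt:
            return
        fwd = VariantLocus("R", off, seq[off], alt)
        effect = annotate_cpg_change(fwd, self.region(seq))
        alt_seq = seq[:off] + alt + seq[off + 1:]
        rev = VariantLocus("R", off, alt, seq[off])
        back = annotate_cpg_change(rev, self.region(alt_seq))
        assert back == {"creates": "destroys", "destroys": "creates",
                        "neutral": "neutral"}[effect]


def snp_cohort(tmp_path, seq, variants, freqs, con=30.0, depth=120,
               n=8, seed=0, conv=None):
    panel = AmpliconPanel(
        [AmpliconRegion("R", "chr1", 0, len(seq), seq, gene="R")],
        variants=variants)
    effects = [EffectSpec(sid, con, dispersion=1.0)
               for sid in panel.site_ids()]
    design = CohortDesign(n, n, n, batch_shifts={"E1": 0.0})
    truth = simulate_cohort(panel, design, effects, freqs, seed=seed)
    model = conv or ConversionModel(depth=depth, read_length=200)
    sim = simulate_reads(panel, truth, model, tmp_path, seed=seed + 1)
    res = assign_reads(sim.fastq_paths, panel)
    return panel, truth, res


class TestDetectVariants:
    # amplicon: CpG at 10, G/A variant at 25, non-CpG Cs elsewhere
    seq = "TTATTCTTTACGTTTATTCTTTATTGTTTATTCTTTATT"

    def test_heterozygous_ga_call_from_ot_reads(self, tmp_path):
        v = VariantLocus("R", 25, "G", "A")
        panel, truth, res = snp_cohort(tmp_path, self.seq, [v],
                                       {"R:25G>A": 0.5}, seed=3)
        calls = detect_variants(res, panel)
        assert len(calls) == 1
        c = calls[0]
        assert (c.offset, c.ref, c.alt, c.ambiguity) == (25, "G", "A", "OB")
        truth_g = truth.genotypes["R:25G>A"]
        mapped = truth_g.map({0: "0/0", 1: "0/1", 2: "1/1"})
        called = c.per_sample["genotype"]
        agree = (called == mapped[called.index]).mean()
        assert agree >= 0.95

    def test_converted_reference_c_not_called_as_variant(self, tmp_path):
        """All-T evidence at a reference C: conversion explanation wins."""
        panel, truth, res = snp_cohort(tmp_path, self.seq, [], {}, con=0.0,
                                       seed=4)
        calls = detect_variants(res, panel)
        assert calls == []

    def test_tc_variant_reported_ambiguous_no_genotype(self, tmp_path):
        # T at 14 followed by G? build T->C in a TG context -> creates CpG,
        # methylated at 80% so the C allele is visible on OT reads
        seq = self.seq[:14] + "TG" + self.seq[16:]
        v = VariantLocus("R", 14, "T", "C")
        panel, truth, res = snp_cohort(tmp_path, seq, [v], {"R:14T>C": 0.5},
                                       con=80.0, seed=5)
        calls = detect_variants(res, panel)
        tc = [c for c in calls if c.offset == 14]
        assert len(tc) == 1
        assert tc[0].ambiguity == "both"
        assert (tc[0].per_sample["genotype"] == "./.").all()
        assert tc[0].cpg_effect == "creates"

    def test_no_call_from_ambiguous_evidence_alone(self, tiny_run):
        """Audit: every called variant rests on informative-strand evidence
        and no C->T call is ever emitted."""
        fx, assignments, _ = tiny_run
        calls = detect_variants(assignments, fx.panel)
        for c in calls:
            assert not (c.ref == "C" and c.alt == "T")
            if c.ambiguity == "both":
                assert (c.per_sample["genotype"] == "./.").all()
        # only the planted locus is detected in the tiny fixture
        assert {(c.region_id, c.offset) for c in calls} == \
            {(v.region_id, v.offset) for v in fx.panel.variants}

    def test_genotype_recovery_rate_on_fixture(self, tmp_path):
        """>= 99% correct genotypes at depth >= 100 for unambiguous SNPs."""
        v = VariantLocus("R", 25, "G", "A")
        panel, truth, res = snp_cohort(tmp_path, self.seq, [v],
                                       {"R:25G>A": 0.3}, depth=200, n=12,
                                       seed=6)
        calls = detect_variants(res, panel)
        c = calls[0]
        mapped = truth.genotypes["R:25G>A"].map({0: "0/0", 1: "0/1", 2: "1/1"})
        agree = (c.per_sample["genotype"] == mapped[c.per_sample.index]).mean()
        assert agree >= 0.99

    def test_vcf_output_parses(self, tiny_run, tmp_path):
        import pysam

        fx, assignments, _ = tiny_run
        calls = detect_variants(assignments, fx.panel)
        path = tmp_path / "out.vcf"
        write_vcf(calls, fx.panel, path)
        with pysam.VariantFile(str(path)) as vcf:
            records = list(vcf)
        assert len(records) == len(calls)
        rec = records[0]
        assert rec.pos == calls[0].offset + 1
        assert "CPG" in rec.info


class TestAlleleAwareMethylation:
    def test_destroyed_allele_reported_site_absent(self, tmp_path):
        seq = TestDetectVariants.seq
        v = VariantLocus("R", 11, "G", "A")  # destroys the CpG at 10
        panel, truth, res = snp_cohort(tmp_path, seq, [v], {"R:11G>A": 0.5},
                                       con=40.0, depth=300, seed=7)
        out, log = allele_aware_methylation(res, panel, v, "R:CpG_1",
                                            min_depth=10)
        assert out["A"].site_absent
        assert out["A"].percent is None
        assert not out["G"].site_absent
        assert out["G"].percent == pytest.approx(40.0, abs=6.0)
        assert log["uninformative_strand"] > 0  # OB reads cannot type G/A

    def test_homozygous_sample_matches_plain_calling(self, tmp_path):
        from amplimeth.calling import call_methylation

        seq = TestDetectVariants.seq
        v = VariantLocus("R", 25, "G", "A")  # away from the CpG
        clean = ConversionModel(depth=300, read_length=200, seq_error=0.0)
        panel, truth, res = snp_cohort(tmp_path, seq, [v], {"R:25G>A": 0.0},
                                       con=35.0, seed=8, conv=clean)
        hom = truth.genotypes.index[truth.genotypes["R:25G>A"] == 0]
        out, _ = allele_aware_methylation(res, panel, v, "R:CpG_1",
                                          sample_ids=set(hom))
        matrix = call_methylation(
            AssignmentResult([a for a in res.assignments
                              if a.sample_id in set(hom)
                              and a.strand == "OT"]), panel, min_depth=1)
        pooled = (100 * matrix.meth["R:CpG_1"].sum()
                  / matrix.total["R:CpG_1"].sum())
        # allele partition uses OT reads only here (G/A pair)
        assert out["G"].percent == pytest.approx(pooled, abs=1e-9)

    def test_site_and_variant_must_share_amplicon(self, tiny_run):
        fx, assignments, _ = tiny_run
        v = fx.panel.variants[0]
        with pytest.raises(ValueError, match="same amplicon"):
            allele_aware_methylation(assignments, fx.panel, v, "APOE:CpG_1")


class TestGenotypeAssociation:
    def series(self, values, genos):
        idx = [f"s{i}" for i in range(len(values))]
        return (pd.Series(values, index=idx, dtype=float),
                pd.Series(genos, index=idx))

    def test_identical_values_kw_p_one(self):
        m, g = self.series([5.0] * 8, ["0/0"] * 4 + ["1/1"] * 4)
        res = genotype_association(m, g)
        assert res.kw_p == 1.0

    def test_complete_separation_exact_p_2_over_70(self):
        m, g = self.series([1, 2, 3, 4, 10, 11, 12, 13],
                           ["0/0"] * 4 + ["1/1"] * 4)
        res = genotype_association(m, g)
        p, mode = res.pairwise[("0/0", "1/1")]
        assert mode == "exact"
        assert p == pytest.approx(2 / 70)
        assert p == pytest.approx(
            mann_whitney_exact([1, 2, 3, 4], [10, 11, 12, 13]))

    def test_single_class_not_testable(self):
        m, g = self.series([1, 2, 3], ["0/0"] * 3)
        res = genotype_association(m, g)
        assert not res.testable
        assert res.reason == "single genotype class"

    def test_no_calls_excluded(self):
        m, g = self.series([1, 2, 3, 4], ["0/0", "0/0", "./.", "1/1"])
        res = genotype_association(m, g)
        assert sum(n for n, _ in res.classes.values()) == 3

    def test_large_sample_uses_normal_approximation(self, rng):
        m, g = self.series(rng.normal(10, 2, 30).tolist(),
                           ["0/0"] * 15 + ["0/1"] * 15)
        res = genotype_association(m, g)
        assert res.kw_mode == "normal_approx"
        assert res.pairwise[("0/0", "0/1")][1] == "normal_approx"

    @pytest.mark.parametrize("n1,n2", [(3, 3), (4, 4), (5, 6), (2, 9)])
    def test_exact_mw_matches_enumeration(self, n1, n2, rng):
        vals = rng.permutation(np.arange(1.0, n1 + n2 + 1))
        m, g = self.series(vals.tolist(), ["0/0"] * n1 + ["1/1"] * n2)
        res = genotype_association(m, g)
        p, mode = res.pairwise[("0/0", "1/1")]
        assert mode == "exact"
        assert p == pytest.approx(
            mann_whitney_exact(vals[:n1], vals[n1:]), abs=1e-12)

    def test_exact_kw_matches_permutation_oracle(self, rng):
        vals = rng.permutation(np.arange(1.0, 10.0))
        m, g = self.series(vals.tolist(),
                           ["0/0"] * 3 + ["0/1"] * 3 + ["1/1"] * 3)
        res = genotype_association(m, g)
        assert res.kw_mode == "exact"
        groups = [vals[:3], vals[3:6], vals[6:]]
        assert res.kw_p == pytest.approx(kruskal_permutation(groups), abs=1e-9)

    def test_power_for_planted_10pp_effect(self, rng):
        """10 pp genotype effect at n=20 per class: KW p < 0.05 in >= 80%."""
        hits = 0
        reps = 200
        for _ in range(reps):
            a = rng.normal(20, 8, 20)
            b = rng.normal(30, 8, 20)
            m, g = self.series(np.concatenate([a, b]).tolist(),
                               ["0/0"] * 20 + ["1/1"] * 20)
            res = genotype_association(m, g)
            hits += res.kw_p < 0.05
        assert hits / reps >= 0.8
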