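"""Generator contracts: determinism, anchors, construction oracles, feasibility."""

import numpy as np
import pytest

from clonelc import (
    make_germline_repertoire,
    simulate_cohort,
    simulate_fastq,
    simulate_rearrangement,
    simulate_sample,
    write_germline_fasta,
)
from clonelc.io_formats import _infer_cys104, _infer_jmotif


class TestGermlineRepertoire:
    def test_composition_and_anchors(self, repertoire):
        vs = repertoire.select("V")
        js = repertoire.select("J")
        cs = repertoire.select("C")
        assert (len(vs), len(js), len(cs)) == (30, 4, 2)
        for v in vs:
            assert v.sequence[v.cys104_offset:v.cys104_offset + 3] in ("TGT", "TGC")
            assert _infer_cys104(v.sequence) == v.cys104_offset
        for j in js:
            assert _infer_jmotif(j.sequence) == j.jmotif_offset

    def test_pairwise_v_identity_bounded(self, repertoire):
        from clonelc.synthetic_data import _identity_at_zero
        vs = [g.sequence for g in repertoire.select("V")]
        for i in range(len(vs)):
            for k in range(i + 1, len(vs)):
                assert _identity_at_zero(vs[i], vs[k]) <= 0.90

    def test_seed_determinism_byte_identical_fasta(self, tmp_path):
        p1, p2 = tmp_path / "a.fasta", tmp_path / "b.fasta"
        make_germline_repertoire(n_v=10, n_j=2, seed=9, out_path=p1)
        make_germline_repertoire(n_v=10, n_j=2, seed=9, out_path=p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_too_few_v_genes_rejected(self):
        with pytest.raises(ValueError):
            make_germline_repertoire(n_v=1, n_j=2, seed=0)


class TestSimulateRearrangement:
    def test_zero_mutation_is_exact_concatenation(self, repertoire):
        v = repertoire.select("V", "IGL")[0]
        j = repertoire.select("J", "IGL")[0]
        c = repertoire.select("C", "IGL")[0]
        rr = simulate_rearrangement(v, j, c, junction_len=6, mutation_rate=0.0,
                                    seed=2, leader_len=100)
        body = rr.sequence[100:]
        expected = (v.sequence[:v.cys104_offset + 3] + rr.junction
                    + j.sequence[j.jmotif_offset - 3:] + c.sequence)
        assert body == expected
        assert rr.cdr3_nt == rr.sequence[rr.cys_pos:rr.j_anchor]
        assert rr.productive

    def test_mutation_count_matches_binomial_expectation(self, repertoire):
        """Mean planted mutations over 200 draws within 3 s.e. of
        rate x mutable length."""
        v = repertoire.select("V", "IGK")[0]
        j = repertoire.select("J", "IGK")[0]
        rate = 0.02
        draws = [simulate_rearrangement(v, j, junction_len=6, mutation_rate=rate,
                                        seed=s).n_mutations
                 for s in range(200)]
        rr0 = simulate_rearrangement(v, j, junction_len=6, mutation_rate=rate, seed=0)
        mutable = (rr0.j_end - rr0.v_start) - 18  # minus the two anchor guards
        expect = rate * mutable
        se = np.sqrt(rate * (1 - rate) * mutable / 200)
        assert abs(np.mean(draws) - expect) < 3 * se + 0.5

    def test_forced_stop_is_nonproductive(self, repertoire):
        v = repertoire.select("V", "IGK")[1]
        j = repertoire.select("J", "IGK")[1]
        rr = simulate_rearrangement(v, j, mutation_rate=0.0, seed=3, force_stop=True)
        assert not rr.productive and "*" in rr.protein

    def test_mixed_locus_rejected(self, repertoire):
        v = repertoire.select("V", "IGK")[0]
        j = repertoire.select("J", "IGL")[0]
        with pytest.raises(ValueError):
            simulate_rearrangement(v, j, seed=1)

    def test_typical_length_near_cohort_median(self, repertoire):
        lengths = []
        for s in range(30):
            locus = ["IGK", "IGL"][s % 2]
            v = repertoire.select("V", locus)[s % 15]
            j = repertoire.select("J", locus)[0]
            c = repertoire.select("C", locus)[0]
            lengths.append(len(simulate_rearrangement(v, j, c, seed=s).sequence))
        assert 560 <= np.median(lengths) <= 650


class TestSimulateSample:
    def test_planted_fractions_respect_category_rules(self, repertoire):
        for cat, seed in [(1, 5), (2, 6), (3, 7), (4, 8)]:
            sim = simulate_sample(cat, repertoire, seed=seed)
            lc = [r for r in sim.rows if r.locus in ("IGK", "IGL")]
            total = sum(r.count for r in lc)
            top = max(r.count for r in lc)
            if cat == 1:
                assert top / total >= 0.95
            elif cat == 2:
                counts = sorted((r.count for r in lc), reverse=True)
                assert (counts[0] + counts[1]) / total >= 0.95
                assert counts[1] >= 100 and counts[1] / total > 0.01
            elif cat == 3:
                others = sorted((r.count for r in lc), reverse=True)[1:]
                assert 0.50 < top / total < 0.95
                assert all(c / total < 0.05 for c in others)
            else:
                counts = sorted((r.count for r in lc), reverse=True)
                assert counts[0] / total <= 0.50 and counts[1] / total > 0.10

    def test_category2_split_shares_exact_overlap(self, repertoire):
        sim = simulate_sample(2, repertoire, seed=12, mutation_rate=0.0)
        frag_a = sim.rows[0].fragments[0]
        frag_b = sim.rows[1].fragments[0]
        p = sim.truth.split["split_point"]
        olen = sim.truth.split["overlap_length"]
        assert frag_a[p:p + olen] == frag_b[:olen]
        assert frag_a[:p] + frag_b == sim.truth.clone_sequence
        # the overlap spans the CDR3 of the planted clone
        cpos, cend = sim.truth.cdr3_span
        assert sim.truth.clone_sequence[cpos:cend] == sim.truth.cdr3_nt
        assert p <= cpos and cend <= p + olen

    def test_infeasible_parameters_rejected(self, repertoire):
        with pytest.raises(ValueError):
            simulate_sample(1, repertoire, seed=1, clonal_fraction=0.80)
        with pytest.raises(ValueError):
            simulate_sample(3, repertoire, seed=1, clonal_fraction=0.96)
        with pytest.raises(ValueError):
            simulate_sample(4, repertoire, seed=1, clonal_fraction=0.60)

    def test_concordant_and_discordant_clinical(self, repertoire):
        sim = simulate_sample(1, repertoire, seed=20, locus="IGK")
        assert sim.clinical.serum_kappa > sim.clinical.serum_lambda
        sim_d = simulate_sample(1, repertoire, seed=20, locus="IGK", discordant=True)
        assert sim_d.clinical.serum_kappa < sim_d.clinical.serum_lambda
        assert sim_d.truth.concordance_status == "discordant"

    def test_fragmented_clone_keeps_full_sequence_longest(self, repertoire):
        sim = simulate_sample(1, repertoire, seed=21, fragmented=True)
        frags = sim.rows[0].fragments
        assert len(frags) == 2 and max(frags, key=len) == sim.truth.clone_sequence


class TestSimulateCohort:
    def test_category_mix_apportioned_exactly(self, repertoire):
        sim = simulate_cohort(50, category_mix=(0.5, 0.2, 0.2, 0.1), seed=3,
                              repertoire=repertoire, lc_total=5000)
        from collections import Counter
        planted = Counter(s.truth.category for s in sim.samples)
        assert planted == {1: 25, 2: 10, 3: 10, 4: 5}

    def test_truth_files_deterministic(self, tmp_path, repertoire):
        for name in ("a", "b"):
            simulate_cohort(6, seed=17, repertoire=repertoire, lc_total=3000,
                            out_dir=tmp_path / name)
        for fn in ("clonotypes.tsv", "clinical.csv", "truth.json", "germline.fasta"):
            assert (tmp_path / "a" / fn).read_bytes() == (tmp_path / "b" / fn).read_bytes()

    def test_bad_mix_rejected(self, repertoire):
        with pytest.raises(ValueError):
            simulate_cohort(10, category_mix=(0.5, 0.2, 0.2, 0.2), seed=1,
                            repertoire=repertoire)


class TestSimulateFastq:
    def test_record_counts_and_length(self, tmp_path):
        r1, r2 = simulate_fastq(500, 100, seed=2, out_r1=tmp_path / "r1.fastq",
                                out_r2=tmp_path / "r2.fastq")
        for p in (r1, r2):
            lines = p.read_text().splitlines()
            assert len(lines) == 2000
            assert all(len(s) == 100 for s in lines[1::4])

    def test_byte_determinism(self, tmp_path):
        a = simulate_fastq(200, 80, seed=5, out_r1=tmp_path / "a1", out_r2=tmp_path / "a2")
        b = simulate_fastq(200, 80, seed=5, out_r1=tmp_path / "b1", out_r2=tmp_path / "b2")
        assert a[0].read_bytes() == b[0].read_bytes()
        assert a[1].read_bytes() == b[1].read_bytes()

    def test_zero_read_len_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            simulate_fastq(10, 0, seed=1, out_r1=tmp_path / "x1", out_r2=tmp_path / "x2")
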