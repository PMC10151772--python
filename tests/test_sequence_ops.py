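"""Overlap search, identical-clone merging, germline assignment, CDR3, translation."""

import numpy as np
import pytest

from clonelc import (
    ClonotypeRecordRow,
    MergeRefusal,
    MergeResult,
    assign_germline,
    attempt_merge,
    build_table,
    classify_coverage,
    extract_cdr3,
    find_overlap,
    longest_fragment,
    make_germline_repertoire,
    simulate_rearrangement,
    simulate_sample,
    translate_clone,
)


def _bases(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def clone(cid, frags, count=1000, locus="IGL", cdr3=None):
    return ClonotypeRecordRow(sample_id="S", clone_id=cid, locus=locus,
                              count=count, fragments=frags, cdr3_nt=cdr3)


class TestLongestFragment:
    def test_longest_wins(self):
        c = clone("a", ["A" * 300, "C" * 450])
        assert longest_fragment(c) == "C" * 450

    def test_single_fragment_identity(self):
        assert longest_fragment(clone("a", ["ACGT"])) == "ACGT"

    def test_tie_keeps_first(self):
        c = clone("a", ["A" * 400, "C" * 400])
        assert longest_fragment(c) == "A" * 400


class TestFindOverlap:
    def test_suffix_prefix_overlap_recovered(self):
        rng = np.random.default_rng(1)
        x, y, z = _bases(rng, 200), _bases(rng, 254), _bases(rng, 180)
        ov = find_overlap(x + y, y + z)
        assert (ov.length, ov.mismatches, ov.offset) == (254, 0, 200)

    def test_containment_overlap(self):
        rng = np.random.default_rng(2)
        a = _bases(rng, 500)
        b = a[100:400]
        ov = find_overlap(a, b)
        assert (ov.length, ov.mismatches) == (300, 0)
        assert ov.a_span == (100, 400)

    def test_random_sequences_have_no_overlap(self):
        # Monte-Carlo oracle: expected best exact run between unrelated
        # 300-mers is far below the 16 nt reporting floor
        rng = np.random.default_rng(3)
        for _ in range(20):
            assert find_overlap(_bases(rng, 300), _bases(rng, 300)) is None

    def test_single_mismatch_still_reported(self):
        rng = np.random.default_rng(4)
        x, y, z = _bases(rng, 150), _bases(rng, 254), _bases(rng, 150)
        y_mut = y[:100] + ("A" if y[100] != "A" else "C") + y[101:]
        ov = find_overlap(x + y, y_mut + z)
        assert ov.length == 254 and ov.mismatches == 1

    def test_n_counts_as_mismatch(self):
        a = "ACGT" * 20
        b = a[:40] + "N" + a[41:]
        ov = find_overlap(a, b)
        assert ov.mismatches == 1


def _truth_locator(sim):
    """Oracle locator: planted CDR3 coordinates on each known fragment."""
    p = sim.truth.split["split_point"]
    cpos, cend = sim.truth.cdr3_span
    spans = {
        sim.rows[0].fragments[0]: (cpos, cend),
        sim.rows[1].fragments[0]: (cpos - p, cend - p),
    }
    return lambda seq: spans.get(seq)


@pytest.fixture(scope="module")
def split_sample(repertoire):
    return simulate_sample(category=2, repertoire=repertoire, seed=11,
                           sample_id="M", mutation_rate=0.0)


class TestAttemptMerge:
    def test_planted_split_recovers_full_sequence(self, split_sample):
        sim = split_sample
        table = build_table("M", sim.rows)
        major, secondary = sim.rows[0], sim.rows[1]
        res = attempt_merge(major, secondary, table,
                            cdr3_locator=_truth_locator(sim))
        assert isinstance(res, MergeResult)
        assert res.merged_sequence == sim.truth.clone_sequence
        assert res.overlap_length >= 200
        assert res.combined_count == major.count + secondary.count

    def test_merge_symmetric_in_sequence_content(self, split_sample):
        sim = split_sample
        table = build_table("M", sim.rows)
        loc = _truth_locator(sim)
        r1 = attempt_merge(sim.rows[0], sim.rows[1], table, cdr3_locator=loc)
        r2 = attempt_merge(sim.rows[1], sim.rows[0], table, cdr3_locator=loc)
        assert r1.merged_sequence == r2.merged_sequence

    def test_substitution_in_overlap_refused(self, split_sample):
        sim = split_sample
        table = build_table("M", sim.rows)
        b = sim.rows[1]
        frag = b.fragments[0]
        mid = len(frag) // 4
        mutated = frag[:mid] + ("A" if frag[mid] != "A" else "C") + frag[mid + 1:]
        b2 = clone(b.clone_id, [mutated], count=b.count, locus=b.locus)
        res = attempt_merge(sim.rows[0], b2, table, cdr3_locator=_truth_locator(sim))
        assert isinstance(res, MergeRefusal) and res.reason == "mismatch"

    def test_short_overlap_refused(self):
        rng = np.random.default_rng(9)
        shared = _bases(rng, 150)
        a = clone("a", [_bases(rng, 300) + shared], count=6000)
        b = clone("b", [shared + _bases(rng, 300)], count=3700)
        table = build_table("S", [a, b])
        res = attempt_merge(a, b, table, cdr3_locator=lambda s: (0, 9))
        assert isinstance(res, MergeRefusal) and res.reason == "short_overlap"

    def test_insufficient_combined_fraction_refused(self, split_sample, repertoire):
        sim = split_sample
        rows = sim.rows + [clone("extra", ["ACGT" * 100], count=sim.rows[0].count,
                                 locus=sim.rows[0].locus)]
        table = build_table("M", rows)
        res = attempt_merge(sim.rows[0], sim.rows[1], table,
                            cdr3_locator=_truth_locator(sim))
        assert isinstance(res, MergeRefusal)
        assert res.reason == "insufficient_combined_fraction"

    def test_cdr3_outside_overlap_refused(self, split_sample):
        sim = split_sample
        table = build_table("M", sim.rows)
        res = attempt_merge(sim.rows[0], sim.rows[1], table, cdr3_locator=lambda s: (0, 9))
        assert isinstance(res, MergeRefusal) and res.reason == "no_cdr3_in_overlap"


class TestAssignGermline:
    def test_unmutated_rearrangement_recovered_exactly(self, repertoire):
        v = repertoire.select("V", "IGL")[3]
        j = repertoire.select("J", "IGL")[1]
        c = repertoire.select("C", "IGL")[0]
        rr = simulate_rearrangement(v, j, c, mutation_rate=0.0, seed=21)
        ga = assign_germline(rr.sequence, repertoire)
        assert (ga.v_gene, ga.j_gene, ga.c_gene) == (v.name, j.name, c.name)
        assert ga.v_mutations == 0
        assert ga.cdr3_nt == rr.cdr3_nt and ga.cdr3_aa == rr.cdr3_aa
        assert ga.coverage == "complete"
        assert ga.protein == rr.protein and ga.productive

    def test_recovery_under_2pct_mutation(self, repertoire):
        """Truth oracle over 100 seeded clones at 2% substitution: correct
        V and J in at least 95%, mutation counts near the planted number."""
        rng = np.random.default_rng(5)
        hits = 0
        for i in range(100):
            locus = ["IGK", "IGL"][i % 2]
            vs, js = repertoire.select("V", locus), repertoire.select("J", locus)
            v = vs[int(rng.integers(0, len(vs)))]
            j = js[int(rng.integers(0, len(js)))]
            rr = simulate_rearrangement(v, j, mutation_rate=0.02, seed=1000 + i)
            ga = assign_germline(rr.sequence, repertoire)
            if ga is not None and ga.v_gene == v.name and ga.j_gene == j.name:
                hits += 1
                assert abs(ga.v_mutations - rr.n_mutations) <= 6
        assert hits >= 95

    def test_non_ig_sequence_unassigned(self, repertoire):
        rng = np.random.default_rng(6)
        assert assign_germline(_bases(rng, 600), repertoire) is None


class TestCdr3AndCoverage:
    def test_planted_junction_extracted_exactly(self, repertoire):
        v = repertoire.select("V", "IGK")[0]
        j = repertoire.select("J", "IGK")[0]
        rr = simulate_rearrangement(v, j, junction_len=9, mutation_rate=0.0, seed=30)
        ga = assign_germline(rr.sequence, repertoire)
        nt, aa, span = extract_cdr3(rr.sequence, ga.v_hit, ga.j_hit)
        assert nt == rr.cdr3_nt
        assert rr.sequence[span[0]:span[1]] == nt
        assert len(nt) == 6 + 9  # cys codon + junction + pre-anchor codon

    def test_mutated_cys_anchor_gives_missing_cdr3(self, repertoire):
        v = repertoire.select("V", "IGK")[0]
        j = repertoire.select("J", "IGK")[0]
        rr = simulate_rearrangement(v, j, mutation_rate=0.0, seed=31)
        seq = rr.sequence[:rr.cys_pos] + "GCA" + rr.sequence[rr.cys_pos + 3:]
        ga = assign_germline(seq, repertoire)
        assert ga is not None and ga.cdr3_nt is None

    def test_extraction_deterministic(self, repertoire):
        v = repertoire.select("V", "IGL")[1]
        j = repertoire.select("J", "IGL")[0]
        rr = simulate_rearrangement(v, j, mutation_rate=0.0, seed=32)
        runs = {assign_germline(rr.sequence, repertoire).cdr3_nt for _ in range(2)}
        assert runs == {rr.cdr3_nt}

    def test_full_length_clone_is_complete(self, repertoire):
        v = repertoire.select("V", "IGK")[2]
        j = repertoire.select("J", "IGK")[1]
        c = repertoire.select("C", "IGK")[0]
        rr = simulate_rearrangement(v, j, c, mutation_rate=0.0, seed=33)
        ga = assign_germline(rr.sequence, repertoire)
        assert classify_coverage(ga.v_hit, ga.j_hit) == "complete"

    @pytest.mark.parametrize("trim5,trim3", [(30, 0), (0, 3), (1, 1)])
    def test_truncation_gives_partial(self, repertoire, trim5, trim3):
        v = repertoire.select("V", "IGK")[2]
        # the J with the longest 3' tail keeps its alignment callable after trimming
        j = max(repertoire.select("J", "IGK"),
                key=lambda g: len(g.sequence) - g.jmotif_offset)
        rr = simulate_rearrangement(v, j, mutation_rate=0.0, seed=34, leader_len=0)
        seq = rr.sequence[trim5:len(rr.sequence) - trim3 or None]
        ga = assign_germline(seq, repertoire)
        assert classify_coverage(ga.v_hit, ga.j_hit) == "partial"


class TestTranslateClone:
    def test_planted_protein_recovered(self, repertoire):
        v = repertoire.select("V", "IGL")[4]
        j = repertoire.select("J", "IGL")[1]
        rr = simulate_rearrangement(v, j, mutation_rate=0.0, seed=40)
        ga = assign_germline(rr.sequence, repertoire)
        protein, productive = translate_clone(rr.sequence, ga.v_hit,
                                              end=ga.j_hit.t_span[1])
        assert protein == rr.protein and productive

    def test_planted_stop_is_nonproductive(self, repertoire):
        v = repertoire.select("V", "IGL")[4]
        j = repertoire.select("J", "IGL")[1]
        rr = simulate_rearrangement(v, j, mutation_rate=0.0, seed=41, force_stop=True)
        assert not rr.productive
        ga = assign_germline(rr.sequence, repertoire)
        _, productive = translate_clone(rr.sequence, ga.v_hit,
                                        end=ga.j_hit.t_span[1], j_anchor=rr.j_anchor)
        assert not productive

    def test_partial_trailing_codon_dropped(self, repertoire):
        v = repertoire.select("V", "IGL")[4]
        j = repertoire.select("J", "IGL")[1]
        rr = simulate_rearrangement(v, j, mutation_rate=0.0, seed=42)
        ga = assign_germline(rr.sequence, repertoire)
        seq = rr.sequence[:len(rr.sequence) - (len(rr.sequence) - ga.v_hit.t_span[0]) % 3 - 1]
        protein, _ = translate_clone(seq, ga.v_hit)
        assert len(protein) == (len(seq) - (ga.v_hit.t_span[0])) // 3
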