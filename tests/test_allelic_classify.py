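import numpy as np
import pytest

from allelesplice.allelic_classify import (
    EstSnpPattern,
    allelic_fraction_by_type,
    build_groups,
    classify_source,
)
from allelesplice.snp_call import SnpCall
from allelesplice.tsv_detect import TsvEvent
from conftest import make_aln


def pat(est_id, positions, bases):
    return EstSnpPattern(est_id, tuple(positions), tuple(bases))


class TestClassifySource:
    def test_distinct_patterns_mean_allelic(self):
        """Pattern T-A-T in one isoform group vs G-G-C in the other at three
        shared mSNP sites: distinct alleles."""
        g1 = [pat("e1", (10, 20, 30), "TAT")]
        g2 = [pat("e2", (10, 20, 30), "GGC")]
        call = classify_source(g1, g2)
        assert call.verdict == "allelic"
        assert call.n_informative_pairs == 1
        assert call.evidence[0][3] is False

    def test_identical_patterns_mean_alternative_splicing(self):
        g1 = [pat("e1", (10, 20, 30), "TAT")]
        g2 = [pat("e2", (10, 20, 30), "TAT")]
        assert classify_source(g1, g2).verdict == "alternative_splicing"

    def test_no_shared_positions_undetermined(self):
        g1 = [pat("e1", (10, 20), "TA")]
        g2 = [pat("e2", (40, 50), "GC")]
        call = classify_source(g1, g2)
        assert call.verdict == "undetermined"
        assert call.n_informative_pairs == 0

    def test_one_match_outweighs_many_mismatches(self):
        g1 = [pat("e1", (10,), "T"), pat("e2", (10,), "G")]
        g2 = [pat("e3", (10,), "T")]
        assert classify_source(g1, g2).verdict == "alternative_splicing"

    def test_partial_overlap_agreement_counts_as_match(self):
        g1 = [pat("e1", (10, 20, 30), "TAT")]
        g2 = [pat("e2", (20, 30, 40), "ATC")]  # agrees at shared 20, 30
        assert classify_source(g1, g2).verdict == "alternative_splicing"

    def test_symmetry_under_group_swap(self):
        rng = np.random.default_rng(9)
        sites = list(range(0, 100, 10))
        for _ in range(200):
            g1 = [
                pat(
                    f"a{i}",
                    (pos := sorted(
                        int(p) for p in rng.choice(sites, int(rng.integers(1, 5)), replace=False)
                    )),
                    [str(b) for b in rng.choice(list("ACGT"), len(pos))],
                )
                for i in range(int(rng.integers(1, 4)))
            ]
            g2 = [
                pat(
                    f"b{i}",
                    (pos := sorted(
                        int(p) for p in rng.choice(sites, int(rng.integers(1, 5)), replace=False)
                    )),
                    [str(b) for b in rng.choice(list("ACGT"), len(pos))],
                )
                for i in range(int(rng.integers(1, 4)))
            ]
            assert classify_source(g1, g2).verdict == classify_source(g2, g1).verdict

    def test_adding_an_est_never_unmakes_a_match(self):
        rng = np.random.default_rng(10)
        sites = list(range(0, 60, 10))
        for _ in range(200):
            def rand_pat(tag, i):
                pos = sorted(
                    int(p)
                    for p in rng.choice(sites, int(rng.integers(1, 4)), replace=False)
                )
                return pat(tag + str(i), pos, [str(b) for b in rng.choice(list("AC"), len(pos))])

            g1 = [rand_pat("a", i) for i in range(int(rng.integers(1, 3)))]
            g2 = [rand_pat("b", i) for i in range(int(rng.integers(1, 3)))]
            before = classify_source(g1, g2).verdict
            after = classify_source(g1 + [rand_pat("a", 99)], g2).verdict
            if before == "alternative_splicing":
                assert after == "alternative_splicing"

    def test_matches_pair_enumeration_oracle(self):
        rng = np.random.default_rng(11)
        sites = list(range(0, 60, 10))
        for _ in range(300):
            def rand_pat(tag, i):
                pos = sorted(
                    int(p)
                    for p in rng.choice(sites, int(rng.integers(1, 4)), replace=False)
                )
                return pat(tag + str(i), pos, [str(b) for b in rng.choice(list("ACG"), len(pos))])

            g1 = [rand_pat("a", i) for i in range(int(rng.integers(1, 4)))]
            g2 = [rand_pat("b", i) for i in range(int(rng.integers(1, 4)))]
            # brute force: explicit double loop over pairs and positions
            informative = matched = 0
            for p in g1:
                for q in g2:
                    shared = sorted(set(p.positions) & set(q.positions))
                    if not shared:
                        continue
                    informative += 1
                    if all(
                        p.bases[p.positions.index(s)] == q.bases[q.positions.index(s)]
                        for s in shared
                    ):
                        matched += 1
            if informative == 0:
                expected = "undetermined"
            elif matched:
                expected = "alternative_splicing"
            else:
                expected = "allelic"
            assert classify_source(g1, g2).verdict == expected


class TestBuildGroups:
    def event(self, a=("estA",), b=("estB",)):
        return TsvEvent(
            event_id="ev1",
            cluster_id="c",
            chrom="chr1",
            strand="+",
            type="IntronR",
            variable_region=(300, 400),
            isoform_a_ests=frozenset(a),
            isoform_b_ests=frozenset(b),
            length_difference=100,
            in_frame=False,
        )

    def msnps(self):
        return [
            SnpCall("chr1", 110, "A", "T", frozenset({"estA", "estX"}), True),
            SnpCall("chr1", 140, "C", "A", frozenset({"estA", "estX"}), True),
            SnpCall("chr1", 210, "G", "T", frozenset({"estA", "estX"}), True),
        ]

    def test_pattern_lists_bases_at_covered_sites(self):
        alns = [
            make_aln(est_id="estA", blocks=((100, 150), (200, 250), (400, 500))),
            make_aln(est_id="estB", blocks=((100, 150), (200, 250), (400, 500))),
        ]
        g1, g2 = build_groups(self.event(), alns, self.msnps())
        (pa,) = g1
        assert pa.positions == (110, 140, 210)
        assert pa.bases == ("T", "A", "T")  # supported alts
        (pb,) = g2
        assert pb.bases == ("A", "C", "G")  # reference bases at covered sites

    def test_est_covering_no_site_is_removed(self):
        alns = [
            make_aln(est_id="estA", blocks=((100, 150), (200, 250))),
            make_aln(est_id="estB", blocks=((600, 700), (800, 900))),
        ]
        g1, g2 = build_groups(self.event(), alns, self.msnps())
        assert len(g1) == 1 and g2 == []

    def test_unknown_est_raises(self):
        with pytest.raises(KeyError, match="estB"):
            build_groups(self.event(), [make_aln(est_id="estA")], self.msnps())


class TestAllelicFractions:
    def make_call(self, event_id, verdict):
        from allelesplice.allelic_classify import SourceCall

        return SourceCall(event_id, verdict, 1 if verdict != "undetermined" else 0, [])

    def make_event(self, event_id, etype):
        return TsvEvent(
            event_id=event_id,
            cluster_id="c",
            chrom="chr1",
            strand="+",
            type=etype,
            variable_region=(0, 9),
            isoform_a_ests=frozenset({"a"}),
            isoform_b_ests=frozenset({"b"}),
            length_difference=9,
            in_frame=True,
        )

    def test_fraction_excludes_undetermined(self):
        events = [self.make_event(f"e{i}", "IntronR") for i in range(11)]
        calls = (
            [self.make_call(f"e{i}", "allelic") for i in range(3)]
            + [self.make_call(f"e{i}", "alternative_splicing") for i in range(3, 10)]
            + [self.make_call("e10", "undetermined")]
        )
        table = allelic_fraction_by_type(calls, events).set_index("type")
        assert table.loc["IntronR", "fraction_allelic"] == pytest.approx(0.30)
        assert table.loc["all", "fraction_allelic"] == pytest.approx(0.30)
        assert table.loc["IntronR", "undetermined"] == 1

    def test_all_undetermined_reports_missing_fraction(self):
        events = [self.make_event("e0", "AltA")]
        calls = [self.make_call("e0", "undetermined")]
        table = allelic_fraction_by_type(calls, events).set_index("type")
        assert np.isnan(table.loc["AltA", "fraction_allelic"])
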