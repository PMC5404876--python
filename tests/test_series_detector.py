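import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from rrfscan.align import ANTISENSE, SENSE, AlignmentRecord
from rrfscan.classify import classify_all
from rrfscan.reference import AnnotatedReference, Region
from rrfscan.series import (
    FIVE_PRIME,
    THREE_PRIME,
    anchor_table,
    call_series,
    end_vs_body_enrichment,
    enrichment_table,
    group_by_anchor,
    max_ladder_run,
    RRFSeries,
)


def _aln(start, end, strand=SENSE, count=1):
    return AlignmentRecord(
        read_sequence="A" * (end - start), count=count, ref_start=start, ref_end=end,
        strand=strand, n_mismatch=0, n_gap=0, cigar=f"{end - start}M",
    )


@pytest.fixture(scope="module")
def ref():
    return AnnotatedReference(
        id="r", sequence="A" * 500,
        regions=(Region("5.8S", 100, 260, role="gene"),
                 Region("ITS2", 260, 300, role="spacer"),
                 Region("28S", 300, 500, role="gene")),
    )


class TestMaxLadderRun:
    @pytest.mark.parametrize(
        "hist,min_count,expected",
        [
            ({29: 5, 30: 7, 31: 3, 33: 2}, 1, 3),
            ({}, 1, 0),
            ({20: 1}, 2, 0),
            ({L: 1 for L in range(15, 41)}, 1, 26),
            ({10: 2, 11: 1, 12: 2, 13: 2}, 2, 2),
        ],
    )
    def test_examples(self, hist, min_count, expected):
        assert max_ladder_run(hist, min_count) == expected

    @given(
        hist=st.dictionaries(st.integers(15, 45), st.integers(1, 10_000), max_size=20),
        factor=st.integers(1, 50),
    )
    def test_invariant_under_count_scaling(self, hist, factor):
        scaled = {L: c * factor for L, c in hist.items()}
        assert max_ladder_run(scaled, 1) == max_ladder_run(hist, 1)


class TestGroupByAnchor:
    def test_five_prime_series_construction(self, ref):
        pairs = classify_all([_aln(100, 129), _aln(100, 130), _aln(100, 131)], ref)
        (series,) = group_by_anchor(pairs, ref)
        assert (series.region_name, series.terminus, series.anchor) == ("5.8S", FIVE_PRIME, 100)
        assert series.length_histogram == {29: 1, 30: 1, 31: 1}
        assert series.max_run == 3 and series.total_count == 3

    def test_no_terminal_fragments(self, ref):
        pairs = classify_all([_aln(120, 150)], ref)
        assert group_by_anchor(pairs, ref) == []

    def test_both_ends_give_two_series(self, ref):
        pairs = classify_all([_aln(100, 130), _aln(230, 260)], ref)
        series = group_by_anchor(pairs, ref)
        assert {(s.terminus, s.anchor) for s in series} == {(FIVE_PRIME, 100), (THREE_PRIME, 260)}

    def test_antisense_excluded_by_default(self, ref):
        pairs = classify_all([_aln(100, 130, strand=ANTISENSE)], ref)
        assert group_by_anchor(pairs, ref) == []
        assert len(group_by_anchor(pairs, ref, include_antisense=True)) == 1

    def test_gapped_member_counts_at_reference_span(self, ref):
        rec = AlignmentRecord(read_sequence="A" * 29, count=2, ref_start=100, ref_end=130,
                              strand=SENSE, n_mismatch=0, n_gap=1, cigar="10M1D19M")
        pairs = classify_all([rec], ref)
        (series,) = group_by_anchor(pairs, ref)
        assert series.length_histogram == {30: 2}


class TestCallSeries:
    def _series(self, run, total):
        return RRFSeries("5.8S", FIVE_PRIME, 100, {}, total_count=total, max_run=run)

    def test_threshold_rule(self):
        called = call_series([self._series(3, 50)])
        assert called[0].called

    def test_long_run_required_regardless_of_depth(self):
        called = call_series([self._series(2, 10**6)])
        assert not called[0].called

    def test_sorted_by_total_desc(self):
        out = call_series([self._series(3, 10), self._series(5, 999)])
        assert [s.total_count for s in out] == [999, 10]

    def test_empty(self):
        assert call_series([]) == []


class TestEnrichment:
    def test_everything_on_boundary(self):
        region = Region("g", 0, 100, role="gene")
        table = np.zeros(100, dtype=int)
        table[0] = 100
        res = end_vs_body_enrichment(table, region, FIVE_PRIME, tol=0)
        assert res.fold_enrichment == pytest.approx(100.0)
        assert np.log10(res.p_value) == pytest.approx(-200, abs=1e-6)

    def test_no_terminal_fragments(self):
        region = Region("g", 0, 50, role="gene")
        table = np.ones(50, dtype=int)
        table[0] = 0
        res = end_vs_body_enrichment(table, region, FIVE_PRIME, tol=0)
        assert res.fold_enrichment == 0.0 and res.p_value == 1.0

    def test_three_prime_window_at_far_edge(self):
        region = Region("g", 0, 60, role="gene")
        table = np.zeros(60, dtype=int)
        table[-1] = 7
        table[10] = 3
        res = end_vs_body_enrichment(table, region, THREE_PRIME, tol=0)
        assert res.observed_terminal_count == 7 and res.total_region_count == 10

    def test_tolerance_widens_window_clipped_at_edge(self):
        region = Region("g", 0, 100, role="gene")
        table = np.zeros(100, dtype=int)
        table[0], table[1], table[2] = 5, 4, 3
        res = end_vs_body_enrichment(table, region, FIVE_PRIME, tol=1)
        assert res.observed_terminal_count == 9
        assert res.expected_fraction == pytest.approx(2 / 100)  # 1 + tol at the edge

    def test_degenerate_region_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            end_vs_body_enrichment(np.array([5]), Region("g", 0, 1), FIVE_PRIME)

    def test_uniform_null_calibration_direct(self):
        """p-values are uniform under multinomial sampling of anchor positions."""
        rng = np.random.default_rng(1234)
        region = Region("g", 0, 100, role="gene")
        n_reps, n_frag = 1000, 10_000
        counts = rng.multinomial(n_frag, np.full(100, 0.01), size=n_reps)
        pvals = np.array([
            end_vs_body_enrichment(c, region, FIVE_PRIME).p_value for c in counts
        ])
        rej = float(np.mean(pvals < 0.05))
        assert 0.03 <= rej <= 0.07
        assert float(np.mean(pvals < 0.01)) <= 0.03
        # distribution is approximately Uniform(0,1)
        ks = sps.kstest(pvals, "uniform")
        assert ks.statistic < 0.05


class TestAnchorTable:
    def test_five_prime_counts_starts_in_region(self, ref):
        alns = [_aln(100, 130, count=4), _aln(150, 180), _aln(50, 120), _aln(259, 290)]
        table = anchor_table(alns, ref.region_by_name("5.8S"), FIVE_PRIME)
        assert table[0] == 4 and table[50] == 1 and table[159] == 1
        assert table.sum() == 6  # the fragment starting before the region is excluded

    def test_three_prime_counts_ends_in_region(self, ref):
        alns = [_aln(230, 260, count=2), _aln(90, 110), _aln(250, 280)]
        table = anchor_table(alns, ref.region_by_name("5.8S"), THREE_PRIME)
        assert table[-1] == 2 and table[9] == 1
        assert table.sum() == 3

    def test_antisense_excluded(self, ref):
        alns = [_aln(100, 130, strand=ANTISENSE)]
        assert anchor_table(alns, ref.region_by_name("5.8S"), FIVE_PRIME).sum() == 0


class TestEnrichmentTable:
    def test_bh_matches_statsmodels(self, ref, rng):
        """BH q-values agree with the independent statsmodels implementation."""
        from statsmodels.stats.multitest import multipletests

        alns = []
        for _ in range(300):
            L = int(rng.integers(15, 41))
            s = int(rng.integers(0, len(ref) - L))
            alns.append(_aln(s, s + L))
        alns += [_aln(100, 120, count=30)]  # enrich the 5.8S 5' end
        df = enrichment_table(alns, ref, tol=0)
        mask = df["p_value"].notna()
        _, q_sm, _, _ = multipletests(df.loc[mask, "p_value"], method="fdr_bh")
        assert np.allclose(df.loc[mask, "q_value"].to_numpy(), q_sm)

    def test_one_row_per_gene_terminus(self, ref):
        df = enrichment_table([_aln(100, 130)], ref)
        assert len(df) == 4  # two genes x two termini
        assert set(df["terminus"]) == {FIVE_PRIME, THREE_PRIME}
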