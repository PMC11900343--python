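import numpy as np
import pandas as pd
import pytest

from popsweep.genotypes import MISSING
from popsweep.simulate import SimConfig, simulate_panel
from popsweep.sweep import (
    GeneModels,
    GroupAssignment,
    WindowSpec,
    common_genes,
    log2_pi_ratio,
    make_windows,
    merge_and_annotate,
    merge_windows,
    select_candidates,
    site_pi,
    split_hy_ly,
    wc_site_components,
    window_fst,
    window_pi,
    z_fst,
)

from .conftest import make_gm, random_two_group_calls
from .oracles import pi_pairwise_enumeration, wc_components_scalar


def sample_table(yields, prefix="s"):
    return pd.DataFrame(
        {
            "sample_id": [f"{prefix}{i}" for i in range(len(yields))],
            "phenotype": yields,
        }
    )


class TestSplitHyLy:
    def test_quartiles_of_eight(self):
        table = sample_table([10, 9, 8, 7, 6, 5, 4, 3])
        groups = split_hy_ly(table)
        assert groups.hy == ["s0", "s1"]
        assert groups.ly == ["s7", "s6"] or groups.ly == ["s6", "s7"]
        assert len(groups.excluded) == 4

    def test_all_missing_phenotypes_rejected(self):
        table = sample_table([np.nan] * 6)
        with pytest.raises(RuntimeError):
            split_hy_ly(table)

    def test_ceiling_rule_n10(self):
        table = sample_table(list(range(10, 0, -1)))
        groups = split_hy_ly(table)
        assert len(groups.hy) == 3 and len(groups.ly) == 3
        assert len(groups.excluded) == 4

    def test_ties_broken_by_sample_id(self):
        table = sample_table([5.0, 5.0, 5.0, 5.0, 1.0, 1.0, 1.0, 1.0])
        groups = split_hy_ly(table)
        assert groups.hy == ["s0", "s1"]

    def test_missing_phenotypes_excluded_first(self):
        table = sample_table([8, np.nan, 7, 6, 5, np.nan, 4, 3])
        groups = split_hy_ly(table)
        assert "s1" in groups.excluded and "s5" in groups.excluded
        assert len(groups.hy) == 2  # ceil(6/4)


class TestMakeWindows:
    def test_window_arithmetic(self):
        w = make_windows({"c": 100_000}, WindowSpec(50_000, 20_000))
        assert w["start"].tolist() == [0, 20_000, 40_000]
        assert (w["end"] - w["start"] == 50_000).all()

    def test_exact_fit_single_window(self):
        w = make_windows({"c": 50_000}, WindowSpec(50_000, 20_000))
        assert len(w) == 1

    def test_short_contig_warns_and_empty(self):
        with pytest.warns(UserWarning, match="shorter"):
            w = make_windows({"c": 49_999}, WindowSpec(50_000, 20_000))
        assert len(w) == 0

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            WindowSpec(10_000, 20_000)


def _two_group_gm(calls1, calls2, positions=None, contig_length=None):
    calls = np.vstack([calls1, calls2])
    gm = make_gm(calls, positions=positions, contig_length=contig_length)
    hy = gm.sample_ids[: len(calls1)]
    ly = gm.sample_ids[len(calls1):]
    return gm, GroupAssignment(hy=hy, ly=ly, excluded=[])


class TestWindowFst:
    def test_fixed_difference_is_one(self):
        gm, groups = _two_group_gm(
            np.zeros((4, 3), dtype=np.int8), np.full((4, 3), 2, dtype=np.int8),
            contig_length=50_000,
        )
        w = make_windows(gm.contig_lengths, WindowSpec(50_000, 50_000))
        out = window_fst(gm, groups, w)
        assert out["fst"].iloc[0] == pytest.approx(1.0)
        assert out["n_sites"].iloc[0] == 3

    def test_single_site_toy_against_scalar_oracle(self):
        g1 = np.array([[0], [0], [1], [1]], dtype=np.int8)
        g2 = np.array([[1], [1], [2], [2]], dtype=np.int8)
        a, b, c, elig = wc_site_components(g1, g2)
        oa, ob, oc = wc_components_scalar(g1[:, 0], g2[:, 0])
        assert elig[0]
        assert a[0] == pytest.approx(oa, abs=1e-12)
        assert b[0] == pytest.approx(ob, abs=1e-12)
        assert c[0] == pytest.approx(oc, abs=1e-12)

    def test_random_instances_match_oracle(self, rng):
        """Ratio-of-sums window Fst equals the independently coded per-site
        a, b, c oracle on random two-group matrices."""
        for _ in range(20):
            n1, n2 = rng.integers(3, 10, size=2)
            m = int(rng.integers(5, 50))
            g1, g2 = random_two_group_calls(rng, n1, n2, m)
            a, b, c, elig = wc_site_components(g1, g2)
            num = den = 0.0
            for j in range(m):
                res = wc_components_scalar(g1[:, j], g2[:, j])
                if res is None:
                    assert not elig[j]
                    continue
                assert elig[j]
                oa, ob, oc = res
                assert abs(a[j] - oa) <= 1e-12
                assert abs((a[j] + b[j] + c[j]) - (oa + ob + oc)) <= 1e-12
                num += oa
                den += oa + ob + oc
            gm, groups = _two_group_gm(g1, g2, contig_length=1000 * (m + 1))
            w = make_windows(gm.contig_lengths, WindowSpec(1000 * (m + 1), 1000 * (m + 1)))
            out = window_fst(gm, groups, w)
            if den != 0:
                assert out["fst"].iloc[0] == pytest.approx(num / den, abs=1e-12)

    def test_null_panel_mean_fst_near_zero(self):
        """Both groups drawn from one population → genome-mean ≈ 0."""
        rng = np.random.default_rng(12)
        g1, g2 = random_two_group_calls(rng, 20, 20, 20_000, missing_rate=0.0)
        gm, groups = _two_group_gm(
            g1, g2,
            positions=np.arange(1, 20_001) * 250,
            contig_length=5_000_000,
        )
        w = make_windows(gm.contig_lengths, WindowSpec(50_000, 20_000))
        out = window_fst(gm, groups, w)
        assert abs(np.nanmean(out["fst"])) < 0.01

    def test_empty_group_rejected(self):
        gm = make_gm(np.zeros((4, 2), dtype=np.int8))
        groups = GroupAssignment(hy=gm.sample_ids, ly=[], excluded=[])
        with pytest.raises(RuntimeError):
            window_fst(gm, groups, make_windows({"chr1": 50_000},
                                                WindowSpec(50_000, 50_000)))


class TestWindowPi:
    def test_monomorphic_window_zero(self):
        gm, groups = _two_group_gm(
            np.zeros((3, 4), dtype=np.int8), np.zeros((3, 4), dtype=np.int8),
            contig_length=50_000,
        )
        w = make_windows(gm.contig_lengths, WindowSpec(50_000, 50_000))
        out = window_pi(gm, groups.hy, w, "pi")
        assert out["pi"].iloc[0] == 0.0

    def test_balanced_site_closed_form(self):
        # 10 diploids, alt count 10 of 20 → π_site = 200/380
        calls = np.array([[1]] * 10, dtype=np.int8)
        gm = make_gm(calls, contig_length=50_000)
        w = make_windows(gm.contig_lengths, WindowSpec(50_000, 50_000))
        out = window_pi(gm, gm.sample_ids, w, "pi")
        assert out["pi"].iloc[0] == pytest.approx((200 / 380) / 50_000)

    def test_doubling_window_span_halves_pi(self):
        calls = np.array([[0, 1], [1, 2], [2, 0]], dtype=np.int8)
        gm = make_gm(calls, positions=[100, 200])
        w1 = pd.DataFrame({"contig": ["chr1"], "start": [0], "end": [1000]})
        w2 = pd.DataFrame({"contig": ["chr1"], "start": [0], "end": [2000]})
        p1 = window_pi(gm, gm.sample_ids, w1, "pi")["pi"].iloc[0]
        p2 = window_pi(gm, gm.sample_ids, w2, "pi")["pi"].iloc[0]
        assert p1 == pytest.approx(2 * p2)

    def test_random_instances_match_enumeration(self, rng):
        """Windowed π equals exhaustive pairwise-allele enumeration."""
        for _ in range(20):
            n = int(rng.integers(2, 10))
            m = int(rng.integers(5, 50))
            g1, _ = random_two_group_calls(rng, n, 2, m)
            pi = site_pi(g1)
            for j in range(m):
                assert pi[j] == pytest.approx(
                    pi_pairwise_enumeration(g1[:, j]), abs=1e-12
                )


class TestZFst:
    def test_standardization_identity(self, rng):
        w = pd.DataFrame(
            {"contig": "c", "start": 0, "end": 1,
             "fst": rng.uniform(0, 0.5, size=200)}
        )
        z = z_fst(w)["z_fst"]
        assert z.mean() == pytest.approx(0.0, abs=1e-10)
        assert z.std(ddof=0) == pytest.approx(1.0, abs=1e-10)

    def test_three_value_hand_computation(self):
        w = pd.DataFrame({"contig": "c", "start": 0, "end": 1,
                          "fst": [0.1, 0.2, 0.3]})
        z = z_fst(w)["z_fst"].tolist()
        expected = (0.1 - 0.2) / np.sqrt(0.02 / 3)
        assert z == pytest.approx([expected, 0.0, -expected], abs=1e-4)
        assert z[0] == pytest.approx(-1.2247, abs=1e-4)

    def test_constant_fst_rejected(self):
        w = pd.DataFrame({"contig": "c", "start": 0, "end": 1, "fst": [0.2] * 5})
        with pytest.raises(ValueError):
            z_fst(w)

    def test_undefined_windows_ignored(self):
        w = pd.DataFrame({"contig": "c", "start": 0, "end": 1,
                          "fst": [0.1, np.nan, 0.3]})
        z = z_fst(w)["z_fst"]
        assert np.isnan(z.iloc[1])
        assert z.iloc[0] == pytest.approx(-1.0)


class TestLog2Ratio:
    def test_equal_pi_gives_zero(self):
        w = pd.DataFrame({"pi_hy": [0.002], "pi_ly": [0.002]})
        assert log2_pi_ratio(w)["log2_ratio"].iloc[0] == 0.0

    def test_doubled_pi_gives_one(self):
        w = pd.DataFrame({"pi_hy": [0.004], "pi_ly": [0.002]})
        assert log2_pi_ratio(w)["log2_ratio"].iloc[0] == pytest.approx(1.0)

    def test_zero_pi_flagged_undefined(self):
        w = pd.DataFrame({"pi_hy": [0.0, 0.0], "pi_ly": [0.002, 0.0]})
        out = log2_pi_ratio(w)["log2_ratio"]
        assert out.isna().all()


def ranked_windows(n=100):
    ranks = np.arange(1, n + 1) / n
    return pd.DataFrame(
        {
            "contig": "c",
            "start": np.arange(n) * 20_000,
            "end": np.arange(n) * 20_000 + 50_000,
            "fst": ranks,
            "z_fst": ranks,
            "log2_ratio": ranks,
        }
    )


class TestSelectCandidates:
    def test_order_statistics_construction(self):
        res = select_candidates(ranked_windows(), quantile=0.05)
        assert len(res.high_ratio_windows) == 5
        assert len(res.low_ratio_windows) == 0
        assert res.thresholds["z_fst_upper"] == pytest.approx(0.9505)

    def test_nested_quantiles(self):
        w = ranked_windows()
        sets = [
            set(select_candidates(w, q).high_ratio_windows["start"])
            for q in (0.10, 0.05, 0.01)
        ]
        assert sets[2] <= sets[1] <= sets[0]

    def test_too_few_ranked_windows_rejected(self):
        with pytest.raises(ValueError):
            select_candidates(ranked_windows(10))


class TestMergeAndAnnotate:
    GENES = pd.DataFrame(
        {
            "gene_id": ["gA", "gB", "gC"],
            "contig": ["c", "c", "c"],
            "start": [69_000, 70_000, 200_000],
            "end": [80_000, 80_000, 210_000],
            "strand": ["+", "+", "-"],
        }
    )

    def selected(self, spans):
        return pd.DataFrame(
            [{"contig": "c", "start": a, "end": b} for a, b in spans]
        )

    def test_overlap_merge(self):
        merged = merge_windows(self.selected([(0, 50_000), (20_000, 70_000)]))
        assert merged.to_dict("records") == [
            {"contig": "c", "start": 0, "end": 70_000}
        ]

    def test_bookend_merge(self):
        merged = merge_windows(self.selected([(0, 50_000), (50_000, 100_000)]))
        assert len(merged) == 1

    def test_gene_overlap_boundary_conventions(self):
        res = select_candidates(ranked_windows(), quantile=0.05)
        res.high_ratio_windows = self.selected([(0, 50_000), (20_000, 70_000)])
        res.low_ratio_windows = self.selected([])
        res = merge_and_annotate(res, self.GENES)
        # gA overlaps [0, 70k) by 1 kb; gB abuts it exactly (half-open → no)
        assert res.high_ratio_genes == ["gA"]
        assert res.low_ratio_genes == []

    def test_gene_lists_invariant_to_window_order(self):
        res1 = select_candidates(ranked_windows(), quantile=0.05)
        res1.high_ratio_windows = self.selected([(20_000, 70_000), (0, 50_000)])
        res1 = merge_and_annotate(res1, self.GENES)
        res2 = select_candidates(ranked_windows(), quantile=0.05)
        res2.high_ratio_windows = self.selected([(0, 50_000), (20_000, 70_000)])
        res2 = merge_and_annotate(res2, self.GENES)
        assert res1.high_ratio_genes == res2.high_ratio_genes

    def test_contig_mismatch_rejected(self):
        res = select_candidates(ranked_windows(), quantile=0.05)
        genes = self.GENES.assign(contig="weird_contig")
        with pytest.raises(ValueError, match="weird_contig"):
            merge_and_annotate(res, genes)

    def test_union_and_intersection_counting(self):
        res_a = select_candidates(ranked_windows(), quantile=0.05)
        res_a.high_ratio_genes = ["g1", "g2"]
        res_a.low_ratio_genes = ["g2", "g3"]
        res_b = select_candidates(ranked_windows(), quantile=0.05)
        res_b.high_ratio_genes = ["g3"]
        res_b.low_ratio_genes = ["g4"]
        assert res_a.gene_union == ["g1", "g2", "g3"]
        assert len(res_a.gene_union) == 2 + 2 - 1
        assert common_genes(res_a, res_b) == ["g3"]

    def test_orientation_mapping(self):
        res = select_candidates(ranked_windows(), quantile=0.05)
        res.high_ratio_genes = ["hi"]
        res.low_ratio_genes = ["lo"]
        assert res.oriented_genes("reduced-diversity") == {"HY": ["lo"], "LY": ["hi"]}
        assert res.oriented_genes("paper-figure") == {"HY": ["hi"], "LY": ["lo"]}
        with pytest.raises(ValueError):
            res.oriented_genes("sideways")


GFF_TEXT = """\
##gff-version 3
##sequence-region c 1 100000
c\ttest\tgene\t10001\t20000\t.\t+\t.\tID=gplus
c\ttest\tmRNA\t10001\t20000\t.\t+\t.\tID=gplus.t1;Parent=gplus
c\ttest\tfive_prime_UTR\t10001\t10200\t.\t+\t.\tID=gplus.u5;Parent=gplus.t1
c\ttest\texon\t10201\t12000\t.\t+\t.\tID=gplus.e1;Parent=gplus.t1
c\ttest\texon\t15001\t16000\t.\t+\t.\tID=gplus.e2;Parent=gplus.t1
c\ttest\tthree_prime_UTR\t19801\t20000\t.\t+\t.\tID=gplus.u3;Parent=gplus.t1
c\ttest\tgene\t50001\t60000\t.\t-\t.\tID=gminus
c\ttest\tmRNA\t50001\t60000\t.\t-\t.\tID=gminus.t1;Parent=gminus
c\ttest\texon\t52001\t54000\t.\t-\t.\tID=gminus.e1;Parent=gminus.t1
"""


@pytest.fixture(scope="module")
def models(tmp_path_factory):
    path = tmp_path_factory.mktemp("gff") / "toy.gff3"
    path.write_text(GFF_TEXT)
    return GeneModels.from_gff(path)


class TestClassifySiteRegion:
    @pytest.mark.parametrize(
        "position,expected",
        [
            (11_000, "exonic"),
            (10_100, "UTR5"),
            (19_900, "UTR3"),
            (12_001, "splicing"),  # 1 bp past an exon end, inside the gene
            (13_500, "intronic"),
            (9_800, "upstream"),  # 500 bp 5' of the plus-strand gene
            (20_500, "downstream"),
            (60_500, "upstream"),  # 500 bp past span end of the minus-strand gene
            (49_600, "downstream"),
            (40_000, "intergenic"),
        ],
    )
    def test_precedence_and_strand(self, models, position, expected):
        assert models.classify("c", position) == expected

    def test_unknown_contig_is_intergenic(self, models):
        assert models.classify("other", 5) == "intergenic"
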