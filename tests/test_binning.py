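"""Geometric cis bins, uniform trans bins, size selection, counting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rdpeaks import binning
from rdpeaks.io import GeneRecord
from .conftest import make_contacts


class TestCisBinsize:
    @pytest.mark.parametrize(
        "i,expected", [(0, 100), (1, 200), (2, 400), (5, 400), (50, 400)]
    )
    def test_geometric_with_cap(self, i, expected):
        assert binning.cis_binsize(i, 100, 2.0, 400) == expected

    def test_factor_must_exceed_one(self):
        with pytest.raises(ValueError):
            binning.cis_binsize(0, 100, 1.0, 400)

    def test_startsize_must_not_exceed_cap(self):
        with pytest.raises(ValueError):
            binning.cis_binsize(0, 500, 2.0, 400)


class TestMakeCisBins:
    def test_worked_example(self, toy_gene):
        # gene [1000,2000) on a 10 kb chromosome, startsize 100, factor 2,
        # trans 400: widths 100,200,400,... on both sides, truncated at the
        # chromosome boundaries
        t = binning.make_cis_bins(toy_gene, 10_000, 100, 2.0, 400)
        up = t[t.end <= 1000]
        assert up.start.tolist() == [0, 300, 700, 900]
        assert up.end.tolist() == [300, 700, 900, 1000]  # widths 300,400,200,100
        body = t[t.is_gene_body]
        assert len(body) == 1
        assert (body.start.iloc[0], body.end.iloc[0]) == (1000, 2000)
        down = t[t.start >= 2000]
        assert down.start.head(4).tolist() == [2000, 2100, 2300, 2700]
        assert (down.end - down.start).iloc[3:].eq(400).iloc[:-1].all()
        assert down.end.iloc[-1] == 10_000 and down.start.iloc[-1] == 9900

    def test_gene_flush_at_start_has_no_upstream(self):
        gene = GeneRecord("c", 0, 500, "g")
        t = binning.make_cis_bins(gene, 5000, 100, 2.0, 400)
        assert t.start.iloc[0] == 0 and t.is_gene_body.iloc[0]

    def test_distances_increase_from_gene(self, toy_gene):
        t = binning.make_cis_bins(toy_gene, 100_000, 100, 2.0, 400)
        up = t[t.end <= 1000].distance.to_numpy()
        down = t[t.start >= 2000].distance.to_numpy()
        assert (np.diff(up) < 0).all() and (np.diff(down) > 0).all()
        assert (t[~t.is_gene_body].distance >= 1).all()

    @given(
        chrom_length=st.integers(5_000, 2_000_000),
        gene_start=st.integers(0, 1_000_000),
        gene_len=st.integers(1, 50_000),
        startsize=st.integers(10, 5_000),
        factor=st.floats(1.05, 4.0),
        cap_mult=st.integers(1, 50),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_tiling_invariant(
        self, chrom_length, gene_start, gene_len, startsize, factor, cap_mult
    ):
        gene_start = min(gene_start, chrom_length - 1)
        gene_end = min(gene_start + gene_len, chrom_length)
        gene = GeneRecord("c", gene_start, gene_end, "g")
        trans = startsize * cap_mult
        t = binning.make_cis_bins(gene, chrom_length, startsize, factor, trans)
        assert t.start.iloc[0] == 0 and t.end.iloc[-1] == chrom_length
        assert (t.start.to_numpy()[1:] == t.end.to_numpy()[:-1]).all()
        assert (t.end > t.start).all()

    def test_geometric_growth_until_cap(self, toy_gene):
        t = binning.make_cis_bins(toy_gene, 10_000_000, 100, 2.0, 51_200)
        down = t[t.start >= 2000]
        widths = (down.end - down.start).to_numpy()[:-1]  # drop truncated last
        growing = widths[widths < 51_200]
        ratios = growing[1:] / growing[:-1]
        assert np.allclose(ratios, 2.0)
        assert (widths[len(growing):] == 51_200).all()


class TestMakeTransBins:
    def test_truncated_tail(self):
        t = binning.make_trans_bins({"c": 1050}, 400)
        assert t.start.tolist() == [0, 400, 800]
        assert t.end.tolist() == [400, 800, 1050]

    def test_excluding_only_chromosome_gives_empty(self, caplog):
        t = binning.make_trans_bins({"c": 1000}, 400, exclude_chrom="c")
        assert t.empty

    def test_order_follows_chromsizes(self):
        t = binning.make_trans_bins({"b": 500, "a": 500}, 250)
        assert t.chrom.tolist() == ["b", "b", "a", "a"]


class TestSelectTransBinsize:
    def test_single_contact_falls_to_coarsest(self):
        # brute-force the cost over the candidate grid as the oracle; a
        # single contact cannot support fine bins, so the optimum sits at
        # the coarse end of the grid
        contacts = make_contacts([("c", 100, 200, "R")])
        length, lo, hi, step = 1_000_000, 1000, 100_000, 1000
        candidates = np.arange(lo, hi + 1, step)
        costs = []
        for s in candidates:
            counts = np.bincount([150 // s], minlength=-(-length // s))
            costs.append(binning.shimazaki_cost(counts, int(s)))
        expected = int(candidates[int(np.argmin(costs))])
        got = binning.select_trans_binsize(contacts, {"c": length}, None, lo, hi, step)
        assert got == expected
        assert got >= hi * 0.9

    def test_no_trans_contacts_falls_back_with_warning(self, caplog):
        contacts = make_contacts([("cis", 1, 2, "R")])
        s = binning.select_trans_binsize(
            contacts, {"cis": 1000, "t": 10_000}, "cis", 100, 1000, 100
        )
        assert s == 1000

    def test_tie_breaks_to_smallest(self, monkeypatch):
        monkeypatch.setattr(binning, "shimazaki_cost", lambda c, s, winsor=None: 1.0)
        contacts = make_contacts([("c", i * 10, i * 10 + 5, "R") for i in range(50)])
        s = binning.select_trans_binsize(contacts, {"c": 10_000}, None, 100, 1000, 100)
        assert s == 100

    def test_doubling_depth_never_coarsens(self, rng):
        # clumpy background: selection is scale-consistent under duplication
        pos = np.sort(rng.choice(2_000_000, 3000)) + rng.integers(0, 3, 3000)
        contacts = make_contacts([("c", int(p), int(p) + 10, "R") for p in pos])
        doubled = pd.concat([contacts, contacts], ignore_index=True)
        kw = dict(chromsizes={"c": 2_000_000}, exclude_chrom=None,
                  trans_min=5_000, trans_max=200_000, trans_step=5_000)
        s1 = binning.select_trans_binsize(contacts, **kw)
        s2 = binning.select_trans_binsize(doubled, **kw)
        assert s2 <= s1


class TestCountInBins:
    def grid(self, toy_gene):
        return binning.build_grid(
            toy_gene, {"chr1": 10_000, "chr2": 4_000}, 100, 2.0, 400
        )

    def test_midpoint_rule(self, toy_gene):
        grid = binning.build_grid(toy_gene, {"chr1": 10_000}, 100, 2.0, 400)
        # contact [2050,2150): midpoint 2100 -> bin [2100,2300), not [2000,2100)
        counts = binning.count_in_bins(
            make_contacts([("chr1", 2050, 2150, "toyRNA")]), grid
        )
        t = grid.table
        hit = t[(counts.counts > 0)]
        assert (hit.start.iloc[0], hit.end.iloc[0]) == (2100, 2300)

    def test_gene_body_excluded_from_n(self, toy_gene, rng):
        grid = self.grid(toy_gene)
        inside = [("chr1", 1200, 1300, "toyRNA")] * 10
        outside = [("chr1", int(p), int(p) + 50, "toyRNA") for p in rng.integers(2500, 9500, 90)]
        counts = binning.count_in_bins(make_contacts(inside + outside), grid)
        gene_body = grid.table.is_gene_body.to_numpy()
        assert counts.counts.sum() == 100
        assert counts.counts[~gene_body].sum() == 90

    def test_empty_contacts(self, toy_gene):
        counts = binning.count_in_bins(make_contacts([]), self.grid(toy_gene))
        assert counts.counts.sum() == 0 and counts.n_rejected == 0

    def test_conservation_with_rejects(self, toy_gene):
        rows = [("chr1", 100, 200, "r"), ("chrX", 1, 2, "r"), ("chr2", 100, 110, "r")]
        counts = binning.count_in_bins(make_contacts(rows), self.grid(toy_gene))
        assert counts.counts.sum() + counts.n_rejected == 3
        assert counts.n_rejected == 1
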