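"""Differential-editing statistics: levels, FDR, fold change, DES selection,
and the Alu Editing Index."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from editscape.core import EditingMatrix, GenomicSite, site_frame
from editscape.diffedit import (
    HIGH_SENSITIVITY,
    LOW_SENSITIVITY,
    bh_fdr,
    compute_aei,
    differential_editing,
    editing_level,
    fold_change,
    select_des,
)
from editscape.repeats import ALU, NON_ALU_REPEAT, RepeatInterval

from conftest import brute_force_bh


class TestEditingLevel:
    @pytest.mark.parametrize("alt,ref,expected", [(5, 95, 0.05), (0, 50, 0.0), (10, 0, 1.0)])
    def test_definition(self, alt, ref, expected):
        assert editing_level(alt, ref) == pytest.approx(expected)

    def test_undefined_on_empty_cell(self):
        with pytest.raises(ValueError):
            editing_level(0, 0)


class TestBhFdr:
    def test_textbook_example(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_single_p_unchanged(self):
        assert bh_fdr([0.037]) == pytest.approx([0.037])

    def test_empty_input(self):
        assert bh_fdr([]).size == 0

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=1e-12, max_value=1.0), min_size=1, max_size=80))
    def test_matches_brute_force_definition(self, pvals):
        assert np.allclose(bh_fdr(pvals), brute_force_bh(pvals), atol=1e-12)


class TestFoldChange:
    def test_ratio_arithmetic(self):
        assert fold_change(0.4, 0.1) == pytest.approx(np.log2(0.4001 / 0.1001), abs=1e-9)
        assert fold_change(0.4, 0.1) == pytest.approx(2.0, abs=0.01)

    def test_symmetry_and_zero(self):
        assert fold_change(0.3, 0.3) == 0.0
        assert fold_change(0.0, 0.0) == 0.0
        assert fold_change(0.2, 0.05) == pytest.approx(-fold_change(0.05, 0.2), abs=1e-12)

    def test_threshold_inverse(self):
        # 0.1 * 2**2.5 ~ 0.566: the planted fold change is recovered
        assert fold_change(0.566, 0.1, pseudo=0) == pytest.approx(2.5, abs=0.01)


class TestSelectDes:
    def _results(self, rows):
        df = pd.DataFrame(
            rows, columns=["pvalue", "fdr", "mean_g1", "mean_g2"],
        )
        df["llr"] = 1.0
        df["log2fc"] = [fold_change(a, b) for a, b in zip(df["mean_g1"], df["mean_g2"])]
        df["delta"] = df["mean_g1"] - df["mean_g2"]
        df.index.name = "site_id"
        return df

    def test_conjunction_of_thresholds(self):
        res = self._results(
            [
                (0.01, 0.05, 0.60, 0.1),    # everything passes -> DES
                (0.01, 0.05, 0.2, 0.1),     # |log2fc| ~ 1 -> not DES
                (0.2, 0.05, 0.60, 0.1),     # p too large -> not DES
                (0.01, 0.2, 0.60, 0.1),     # fdr too large -> not DES
            ]
        )
        out = select_des(res)
        assert out["is_des"].tolist() == [True, False, False, False]

    def test_direction_follows_delta_sign(self):
        res = self._results([(0.01, 0.01, 0.6, 0.05), (0.01, 0.01, 0.05, 0.6)])
        out = select_des(res)
        assert out["direction"].tolist() == [LOW_SENSITIVITY, HIGH_SENSITIVITY]

    def test_matches_hand_enumeration(self):
        rng = np.random.default_rng(9)
        rows = [
            (rng.uniform(0, 0.2), rng.uniform(0, 0.3), rng.uniform(0, 1), rng.uniform(0, 1))
            for _ in range(20)
        ]
        res = self._results(rows)
        out = select_des(res, p_max=0.05, fdr_max=0.1, fc_min=2.5)
        expected = [
            p < 0.05 and f < 0.1 and abs(fold_change(m1, m2)) >= 2.5 and not (m1 == m2 == 0)
            for p, f, m1, m2 in rows
        ]
        assert out["is_des"].tolist() == expected

    def test_ratio_scale_option(self):
        res = self._results([(0.01, 0.01, 0.4, 0.1)])  # log2fc ~ 2, ratio ~ 4
        assert not select_des(res, fc_min=2.5, fc_scale="log2")["is_des"].iloc[0]
        assert select_des(res, fc_min=2.5, fc_scale="ratio")["is_des"].iloc[0]


def _make_matrix(cells, strands=None):
    """cells: list of per-site dicts sample -> (alt, total)."""
    sites = site_frame(
        [GenomicSite("chr1", 100 * (i + 1), (strands or "+" * len(cells))[i]) for i in range(len(cells))]
    )
    samples = sorted({s for c in cells for s in c})
    alt = pd.DataFrame(np.nan, index=sites.index, columns=samples)
    tot = pd.DataFrame(np.nan, index=sites.index, columns=samples)
    for sid, cell in zip(sites.index, cells):
        for s, (a, t) in cell.items():
            alt.loc[sid, s] = a
            tot.loc[sid, s] = t
    return EditingMatrix(sites, alt, tot)


class TestDifferentialEditing:
    def test_skips_sites_without_enough_cells(self):
        cells = [
            {"a1": (2, 20), "a2": (3, 30), "b1": (10, 20), "b2": (15, 30)},
            {"a1": (2, 20), "b1": (10, 20), "b2": (15, 30)},  # one g1 cell only
        ]
        m = _make_matrix(cells)
        res, skipped = differential_editing(m, ["a1", "a2"], ["b1", "b2"])
        assert len(res) == 1 and len(skipped) == 1
        assert skipped[0].site_id == "chr1:200:+"

    def test_no_coverage_cells_dropped_not_imputed(self):
        cells = [{"a1": (2, 20), "a2": (3, 30), "a3": (1, 15), "b1": (9, 20), "b2": (14, 30)}]
        m = _make_matrix(cells)
        res, _ = differential_editing(m, ["a1", "a2", "a3"], ["b1", "b2"])
        assert res["n_obs_g1"].iloc[0] == 3 and res["n_obs_g2"].iloc[0] == 2

    def test_overlapping_groups_rejected(self):
        m = _make_matrix([{"a": (1, 10), "b": (1, 10)}])
        with pytest.raises(ValueError):
            differential_editing(m, ["a"], ["a", "b"])


class TestAei:
    REPEATS = [
        RepeatInterval("chr1", 99, 150, ALU),        # covers pos 100
        RepeatInterval("chr1", 180, 220, ALU),       # covers pos 200
        RepeatInterval("chr1", 280, 330, NON_ALU_REPEAT),  # covers pos 300, not Alu
    ]

    def test_single_site_equals_editing_level(self):
        m = _make_matrix([{"s": (3, 10)}])
        res = compute_aei(m, self.REPEATS, "s")
        assert res.aei == pytest.approx(editing_level(3, 7))
        assert res.n_sites_used == 1

    def test_pooled_ratio_not_mean_of_ratios(self):
        m = _make_matrix([{"s": (3, 10)}, {"s": (7, 10)}])
        res = compute_aei(m, self.REPEATS, "s")
        assert res.aei == pytest.approx(0.5)  # (3+7)/(10+10)

    def test_non_alu_sites_excluded(self):
        m = _make_matrix([{"s": (3, 10)}, {"s": (5, 10)}, {"s": (9, 10)}])
        # site 3 (pos 300) sits in a non-Alu repeat: excluded entirely
        res = compute_aei(m, self.REPEATS, "s")
        assert res.aei == pytest.approx((3 + 5) / 20)

    def test_undefined_without_alu_reads(self):
        m = _make_matrix([{"s": (3, 10)}])
        res = compute_aei(m, [], "s")
        assert np.isnan(res.aei) and not res.defined
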