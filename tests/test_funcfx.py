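"""Pathway filtering, regulator classification and the FE_g score."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thermotol.funcfx import (
    _exact_2xk,
    _g_test_2xk,
    classify_regulators,
    compute_feg,
    feg_table,
    filter_pathways,
)


def _pathways(rows):
    return pd.DataFrame(rows, columns=["pathway", "z", "p"])


class TestFilterPathways:
    @pytest.mark.parametrize(
        "z,p,status",
        [
            (1.5, 0.1, "filtered-out"),  # directional, -log10 p = 1.0 < 1.3
            (np.nan, 0.01, "neutral"),  # neutral, -log10 p = 2 > 1.3
            (-2.0, 0.001, "repressed"),
            (2.0, 0.001, "enhanced"),
            (0.0, 0.5, "filtered-out"),  # neutral but weak
            (np.nan, 0.5, "filtered-out"),
        ],
    )
    def test_rule_cases(self, z, p, status):
        out = filter_pathways(_pathways([("pw", z, p)]))
        assert out["status"].iloc[0] == status

    def test_nonpositive_p_errors(self):
        with pytest.raises(ValueError, match="pw"):
            filter_pathways(_pathways([("pw", 1.0, 0.0)]))

    def test_neg_log10_column(self):
        out = filter_pathways(_pathways([("pw", 1.0, 0.05)]))
        assert out["neg_log10_p"].iloc[0] == pytest.approx(1.30103, abs=1e-5)


def _consolidated(lfcs):
    df = pd.DataFrame(
        {
            "selected_log2fc_s1": {k: v for k, v in lfcs.items()},
            "selected_log2fc_s2": {k: v for k, v in lfcs.items()},
            "mismatch": False,
        }
    )
    df.index.name = "ortholog_id"
    df.attrs["strains"] = ("s1", "s2")
    return df


class TestClassifyRegulators:
    def test_rule_cases(self):
        regs = pd.DataFrame(
            {"ortholog_id": ["r1", "r2", "r3"], "z": [2.5, -2.5, 1.0], "p": [1e-3] * 3}
        )
        cons = _consolidated({"r1": 1.2, "r2": 0.8, "r3": -0.5})
        recs, summary = classify_regulators(regs, cons)
        recs = recs.set_index("ortholog_id")
        assert bool(recs.loc["r1", "is_major"]) and bool(recs.loc["r1", "is_match"])
        assert recs.loc["r1", "group"] == "H"
        assert bool(recs.loc["r2", "is_major"]) and not bool(recs.loc["r2", "is_match"])
        assert not bool(recs.loc["r3", "is_major"])

    def test_nonsignificant_regulators_dropped(self):
        regs = pd.DataFrame({"ortholog_id": ["r1", "zz"], "z": [2.5, 3.0], "p": [1e-3] * 2})
        cons = _consolidated({"r1": 1.0})
        recs, summary = classify_regulators(regs, cons)
        assert summary.n_input == 2
        assert summary.n_significant == 1

    def test_empty_table_errors(self):
        with pytest.raises(ValueError, match="empty"):
            classify_regulators(pd.DataFrame(columns=["ortholog_id", "z", "p"]), _consolidated({"r": 1.0}))

    def test_top_lists_match_brute_force_sort(self):
        rng = np.random.default_rng(0)
        n = 20
        ids = [f"r{i:02d}" for i in range(n)]
        z = rng.normal(0, 3, n).round(2)
        lfc = rng.normal(0, 2, n).round(2)
        regs = pd.DataFrame({"ortholog_id": ids, "z": z, "p": 1e-3})
        cons = _consolidated(dict(zip(ids, lfc)))
        recs, summary = classify_regulators(regs, cons, top_k=10)
        match = [
            (i, zz, ll)
            for i, zz, ll in zip(ids, z, lfc)
            if (zz >= 2 and ll > 0) or (zz <= -2 and ll < 0)
        ]
        for grp, sign in (("H", 1), ("L", -1)):
            grp_match = [(i, zz, ll) for i, zz, ll in match if np.sign(ll) == sign]
            by_z = [i for i, zz, ll in sorted(grp_match, key=lambda t: (-abs(t[1]), t[0]))][:10]
            by_e = [i for i, zz, ll in sorted(grp_match, key=lambda t: (-abs(t[2]), t[0]))][:10]
            assert summary.top_by_z[grp] == by_z
            assert summary.top_by_expression[grp] == by_e

    def test_input_order_invariance(self):
        rng = np.random.default_rng(1)
        ids = [f"r{i}" for i in range(15)]
        regs = pd.DataFrame(
            {"ortholog_id": ids, "z": rng.normal(0, 3, 15), "p": 1e-3}
        )
        cons = _consolidated(dict(zip(ids, rng.normal(0, 2, 15))))
        recs1, sum1 = classify_regulators(regs, cons)
        recs2, sum2 = classify_regulators(regs.iloc[::-1].reset_index(drop=True), cons)
        pd.testing.assert_frame_equal(recs1, recs2)
        assert sum1.top_by_z == sum2.top_by_z


def _assoc(rows):
    return pd.DataFrame(rows, columns=["ortholog_id", "function_id", "effect"])


class TestComputeFeg:
    def test_all_affects_is_null(self):
        rows = [(f"h{i}", "F", "affects") for i in range(5)] + [
            (f"l{i}", "F", "affects") for i in range(5)
        ]
        dirs = {f"h{i}": "H" for i in range(5)} | {f"l{i}": "L" for i in range(5)}
        res = compute_feg(_assoc(rows), dirs)
        assert res[0].feg == {"H": 0.0, "L": 0.0}
        assert res[0].direction == {"H": "indeterminate", "L": "indeterminate"}

    def test_hand_worked_opposed_mixes(self):
        """H counts (8,2,0), L counts (2,8,0): FE_g = +/-0.6 and the G-test
        on the 2x2 (empty affect column dropped) rejects at alpha 0.05."""
        rows = (
            [(f"h{i}", "F", "increases") for i in range(8)]
            + [(f"h{i}", "F", "decreases") for i in range(8, 10)]
            + [(f"l{i}", "F", "increases") for i in range(2)]
            + [(f"l{i}", "F", "decreases") for i in range(2, 10)]
        )
        dirs = {f"h{i}": "H" for i in range(10)} | {f"l{i}": "L" for i in range(10)}
        res = compute_feg(_assoc(rows), dirs)
        r = res[0]
        assert r.feg["H"] == pytest.approx(0.6)
        assert r.feg["L"] == pytest.approx(-0.6)
        # oracle: direct G = 2 sum O ln(O/E) on [[8,2],[2,8]]
        g_oracle = 2 * (2 * 8 * np.log(8 / 5) + 2 * 2 * np.log(2 / 5))
        assert r.statistic == pytest.approx(g_oracle, abs=1e-9)
        assert r.p <= 0.05
        assert r.direction == {"H": "increased", "L": "decreased"}

    def test_one_group_empty_gives_no_test(self):
        rows = [("h1", "F", "increases"), ("h2", "F", "increases")]
        res = compute_feg(_assoc(rows), {"h1": "H", "h2": "H"})
        r = res[0]
        assert r.feg["H"] == pytest.approx(1.0)
        assert np.isnan(r.feg["L"])
        assert np.isnan(r.p)

    def test_function_without_covered_genes_skipped(self):
        rows = [("x1", "F", "increases")]
        assert compute_feg(_assoc(rows), {}) == []

    def test_unknown_effect_label_errors(self):
        with pytest.raises(ValueError, match="boosts"):
            compute_feg(_assoc([("a", "F", "boosts")]), {"a": "H"})

    def test_invalid_alpha_errors(self):
        with pytest.raises(ValueError, match="alpha"):
            compute_feg(_assoc([("a", "F", "affects")]), {"a": "H"}, alpha=0.0)

    @given(
        st.lists(
            st.tuples(st.integers(0, 30), st.integers(0, 30), st.integers(0, 30)),
            min_size=2,
            max_size=2,
        )
    )
    @settings(max_examples=60, deadline=None)
    def test_antisymmetry_under_label_swap(self, counts):
        """Swapping increase/decrease labels negates FE_g exactly."""
        rows, dirs = [], {}
        k = 0
        for grp, (ni, nd, na) in zip(("H", "L"), counts):
            for eff, n in (("increases", ni), ("decreases", nd), ("affects", na)):
                for _ in range(n):
                    rows.append((f"g{k}", "F", eff))
                    dirs[f"g{k}"] = grp
                    k += 1
        if not rows:
            return
        swap = {"increases": "decreases", "decreases": "increases", "affects": "affects"}
        a = compute_feg(_assoc(rows), dirs)
        b = compute_feg(
            _assoc([(g, f, swap[e]) for g, f, e in rows]), dirs
        )
        if not a:
            return
        for grp in ("H", "L"):
            x, y = a[0].feg[grp], b[0].feg[grp]
            if np.isnan(x):
                assert np.isnan(y)
            else:
                assert x == pytest.approx(-y, abs=1e-12)

    def test_exact_fallback_agrees_with_enumeration_oracle(self):
        # tiny counts force the exact path; oracle = scipy Fisher on the 2x2
        from scipy.stats import fisher_exact

        mat = np.array([[3, 0], [0, 3]])
        p_exact = _exact_2xk(mat)
        assert p_exact == pytest.approx(fisher_exact(mat)[1], abs=1e-9)

    def test_feg_table_flattens(self):
        rows = [("h1", "F", "increases"), ("l1", "F", "decreases")]
        res = compute_feg(_assoc(rows), {"h1": "H", "l1": "L"})
        tab = feg_table(res)
        assert list(tab.columns)[:3] == ["function_id", "statistic", "p"]
        assert tab["feg_H"].iloc[0] == pytest.approx(1.0)
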