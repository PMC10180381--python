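import json

import numpy as np
import pytest

from d4refit import (
    DispersionComponents,
    EnergyRecord,
    error_stats,
    interaction_deviation,
    mae_per_molecule,
    optimize_s6_s8,
    optimize_s8,
    pair_records,
    report_tables,
    scan_s8,
)
from d4refit.fitting import ErrorStats, display_round
from d4refit.exceptions import DataError


def _dev(structure_id, deviation, n_monomers=9):
    """DeviationRecord with a prescribed deviation (one-body set to zero)."""
    rec = EnergyRecord(structure_id, n_monomers, {"dft": deviation, "mc": 0.0})
    return interaction_deviation(rec, "dft", "mc")


def make_instance(rng, n=30, s6=1.0, s8=2.0, noise=0.0, n_monomers=9):
    """Synthetic (deviation, components) pairs with known factors."""
    e6 = rng.uniform(0.5, 8.0, size=n)
    e8 = rng.uniform(0.0, 4.0, size=n)
    d = s6 * e6 + s8 * e8 + (rng.normal(0, noise, size=n) if noise else 0.0)
    return [
        (_dev(f"r{i}", d[i], n_monomers), DispersionComponents(f"r{i}", e6[i], e8[i]))
        for i in range(n)
    ]


class TestErrorStats:
    def test_symmetric_pair(self):
        st = error_stats([_dev("a", 1.0), _dev("b", -1.0)])
        assert (st.err, st.mse, st.mae) == (0.0, 1.0, 1.0)

    def test_constant_deviations(self):
        st = error_stats([_dev(f"x{i}", -2.5) for i in range(4)])
        assert st.err == -2.5 and st.mae == 2.5 and st.mse == 6.25

    def test_mae_per_molecule_printed_cell(self):
        # a 9-mer MAE of 19.7 kcal/mol is 2.19 kcal/mol per monomer at display precision
        assert display_round(mae_per_molecule(19.7, 9)) == 2.19

    def test_empty_and_mixed_sizes_rejected(self):
        with pytest.raises(DataError):
            error_stats([])
        with pytest.raises(DataError, match="group"):
            error_stats([_dev("a", 1.0, 9), _dev("b", 1.0, 15)])

    def test_inequalities_on_random_sets(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            devs = [
                _dev(f"r{i}", float(v))
                for i, v in enumerate(rng.normal(scale=rng.uniform(0.1, 30), size=12))
            ]
            st = error_stats(devs)
            assert st.mae >= abs(st.err) - 1e-12
            assert st.mse >= st.err**2 - 1e-12
            assert st.mae**2 <= st.mse + 1e-12
            assert st.mae_per_mol == pytest.approx(st.mae / st.n_monomers)

    def test_violating_stats_rejected_at_construction(self):
        with pytest.raises(DataError):
            ErrorStats(err=2.0, mse=4.0, mae=1.0, mae_per_mol=0.1,
                       n_configs=3, n_monomers=9)


class TestOptimizeS8:
    def test_noiseless_construction_recovered_exactly(self):
        rng = np.random.default_rng(1)
        records = make_instance(rng, s6=1.0, s8=1.5)
        res = optimize_s8(records, s6_fixed=1.0)
        assert res.scaling.s8 == pytest.approx(1.5, abs=1e-10)
        assert res.objective_value == pytest.approx(0.0, abs=1e-10)
        assert not res.flat_flag

    def test_flat_objective_when_e8_all_zero(self):
        records = [
            (_dev(f"r{i}", 1.0 + i), DispersionComponents(f"r{i}", 1.0 + i, 0.0))
            for i in range(5)
        ]
        res = optimize_s8(records, s6_fixed=1.0, bounds=(0.25, 5.0))
        assert res.flat_flag
        assert res.scaling.s8 == 0.25

    def test_breakpoint_optimum_beats_dense_grid(self):
        """Exact breakpoint minimizer <= the best of a 1e-4-step grid scan."""
        rng = np.random.default_rng(23)
        grid = np.arange(0.0, 5.0 + 1e-9, 1e-4)
        for _ in range(20):
            n = int(rng.integers(2, 51))
            records = make_instance(rng, n=n, s6=rng.uniform(0, 2),
                                    s8=rng.uniform(0, 4), noise=rng.uniform(0, 3))
            s6 = rng.uniform(0, 2)
            res = optimize_s8(records, s6_fixed=s6)
            d = np.array([r.deviation for r, _ in records])
            e6 = np.array([c.e6_raw for _, c in records])
            e8 = np.array([c.e8_raw for _, c in records])
            resid = d - s6 * e6
            grid_vals = np.mean(np.abs(resid[None, :] - np.outer(grid, e8)), axis=1)
            assert res.objective_value <= grid_vals.min() + 1e-12

    def test_tie_breaks_to_smallest_s8(self):
        # |1 - s8| + |3 - s8| is flat on [1, 3]: every point minimizes,
        # the smallest breakpoint must be returned
        records = [
            (_dev("a", 1.0), DispersionComponents("a", 0.0, 1.0)),
            (_dev("b", 3.0), DispersionComponents("b", 0.0, 1.0)),
        ]
        res = optimize_s8(records, s6_fixed=0.0, bounds=(0.0, 5.0))
        assert res.scaling.s8 == pytest.approx(1.0, abs=1e-12)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(31)
        base = make_instance(rng, s6=0.8, s8=2.5, noise=1.0)
        scaled = [
            (_dev(r.structure_id, 7.0 * r.deviation, r.n_monomers),
             DispersionComponents(c.structure_id, 7.0 * c.e6_raw, 7.0 * c.e8_raw))
            for r, c in base
        ]
        r1 = optimize_s8(base, s6_fixed=1.0)
        r2 = optimize_s8(scaled, s6_fixed=1.0)
        assert r2.scaling.s8 == pytest.approx(r1.scaling.s8, abs=1e-10)


class TestOptimizeS6S8:
    def test_pbe_style_refit_recovers_construction(self):
        rng = np.random.default_rng(4)
        records = make_instance(rng, s6=0.4, s8=0.0)
        res = optimize_s6_s8(records, mode="s6_only_s8_zero")
        assert res.scaling.s6 == pytest.approx(0.4, abs=1e-10)
        assert res.scaling.s8 == 0.0
        assert res.objective_value == pytest.approx(0.0, abs=1e-10)

    def test_joint_recovers_both_factors(self):
        rng = np.random.default_rng(5)
        records = make_instance(rng, s6=1.0, s8=2.0)
        res = optimize_s6_s8(records, mode="joint")
        assert res.scaling.s6 == pytest.approx(1.0, abs=1e-8)
        assert res.scaling.s8 == pytest.approx(2.0, abs=1e-8)

    def test_joint_objective_not_worse_than_s8_only(self):
        rng = np.random.default_rng(6)
        records = make_instance(rng, s6=0.9, s8=1.8, noise=2.0)
        only = optimize_s8(records, s6_fixed=1.0)
        joint = optimize_s6_s8(records, mode="joint")
        assert joint.objective_value <= only.objective_value + 1e-12

    def test_mse_objective_matches_least_squares(self):
        rng = np.random.default_rng(12)
        records = make_instance(rng, s6=1.0, s8=2.2, noise=1.0)
        res = optimize_s8(records, s6_fixed=1.0, objective="mse")
        d = np.array([r.deviation for r, _ in records])
        e6 = np.array([c.e6_raw for _, c in records])
        e8 = np.array([c.e8_raw for _, c in records])
        resid = d - e6
        closed_form = float(np.dot(resid, e8) / np.dot(e8, e8))
        assert res.scaling.s8 == pytest.approx(closed_form, rel=1e-12)

    def test_unknown_mode_rejected(self):
        rng = np.random.default_rng(7)
        with pytest.raises(DataError):
            optimize_s6_s8(make_instance(rng), mode="bogus")


class TestScanS8:
    def test_single_point(self):
        rng = np.random.default_rng(8)
        records = make_instance(rng)
        ((s, v),) = scan_s8(records, 1.0, [2.0])
        assert s == 2.0 and v == pytest.approx(0.0, abs=1e-12)

    def test_agrees_with_per_structure_recomputation(self):
        from d4refit import ScalingFactors, apply_dispersion

        rng = np.random.default_rng(9)
        records = make_instance(rng, noise=1.5)
        grid = np.linspace(0.0, 5.0, 21)
        curve = scan_s8(records, 1.0, grid)
        for s8, mae in curve:
            sf = ScalingFactors(1.0, s8)
            direct = np.mean(
                [abs(apply_dispersion(r, c, sf).deviation) for r, c in records]
            )
            assert mae == pytest.approx(direct, abs=1e-10)

    def test_curves_are_convex(self):
        rng = np.random.default_rng(10)
        for _ in range(10):
            records = make_instance(rng, noise=rng.uniform(0, 2))
            vals = [v for _, v in scan_s8(records, 1.0, np.linspace(0, 5, 101))]
            second = np.diff(vals, 2)
            assert second.min() >= -1e-9


class TestReportTables:
    def test_empty_map_yields_valid_empty_files(self, tmp_path):
        df, payload = report_tables({}, tmp_path / "t.tsv", tmp_path / "t.json")
        assert len(df) == 0
        assert (tmp_path / "t.tsv").read_text().startswith("cluster_size")
        assert json.loads((tmp_path / "t.json").read_text()) == {}

    def test_one_row_matches_stats(self, tmp_path):
        st = error_stats([_dev("a", 0.1911, 9), _dev("b", 0.1911, 9)])
        df, payload = report_tables({"model": {9: st}}, tmp_path / "t.tsv",
                                    tmp_path / "t.json")
        row = df.iloc[0]
        assert row["mae_kcal_mol"] == "0.19"  # display rounding
        assert payload["model"]["9"]["mae"] == pytest.approx(0.1911)

    @pytest.mark.parametrize(
        "value,rounded", [(0.1911, 0.19), (2.905, 2.91), (-0.005, -0.01), (1.0, 1.0)]
    )
    def test_display_rounding_half_away_from_zero(self, value, rounded):
        assert display_round(value) == rounded
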