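"""Unit tests for nested-grid Px/Ex measurement and the slope fits."""

import numpy as np
import pandas as pd
import pytest

from pxarsim import (
    PointCommunity,
    compute_grain_table,
    extinction_scaling,
    fit_exar,
    fit_pxar,
    summarize_grains,
)

# frozen two-point line: (A=1, px=0), (A=1/4, px=1/3)
TOY_PXAR_SLOPE = -0.2404491734814939


def random_community(rng, max_points=30):
    n = int(rng.integers(1, max_points + 1))
    pts = rng.uniform(size=(n, 2))
    species = rng.integers(1, 6, size=n)
    alive = rng.uniform(size=n) < 0.6
    return PointCommunity(pts[:, 0], pts[:, 1], species, alive)


def brute_force_cells(comm, levels):
    """Independent O(points x cells) enumeration, tracking species sets."""
    out = {}
    for k in levels:
        for cy in range(k):
            for cx in range(k):
                present, survived = set(), set()
                for i in range(len(comm)):
                    ix = min(int(comm.x[i] * k), k - 1)
                    iy = min(int(comm.y[i] * k), k - 1)
                    if (ix, iy) == (cx, cy):
                        present.add(int(comm.species[i]))
                        if comm.alive_t2[i]:
                            survived.add(int(comm.species[i]))
                out[(k, cy * k + cx)] = (present, present - survived)
    return out


class TestGrainTable:
    def test_toy_hand_enumeration(self, toy_community):
        table = compute_grain_table(toy_community, levels=[1, 2])
        k1 = table[table.k == 1].iloc[0]
        assert (k1.s1, k1.ex) == (2, 0)  # species 1 survives elsewhere
        k2 = table[table.k == 2].sort_values("cell_id")
        occupied = k2[k2.s1 > 0]
        assert sorted(zip(occupied.s1, occupied.ex)) == [(1, 0), (1, 0), (1, 1)]
        assert len(k2) == 4 and (k2.s1 == 0).sum() == 1

    def test_nobody_dies_no_extinctions(self, rng):
        comm = random_community(rng)
        comm.alive_t2[:] = True
        table = compute_grain_table(comm, levels=[1, 2, 4])
        assert (table.ex == 0).all()

    def test_everybody_dies_px_one_in_occupied_cells(self, rng):
        comm = random_community(rng)
        comm.alive_t2[:] = False
        table = compute_grain_table(comm, levels=[1, 2, 4])
        assert (table.loc[table.s1 > 0, "px"] == 1).all()

    def test_matches_brute_force_enumeration(self, make_rng):
        levels = [1, 2, 4]
        for seed in range(30):
            comm = random_community(make_rng(seed))
            table = compute_grain_table(comm, levels=levels)
            oracle = brute_force_cells(comm, levels)
            for row in table.itertuples():
                present, lost = oracle[(row.k, row.cell_id)]
                assert row.s1 == len(present) and row.ex == len(lost)

    def test_loss_is_nested_across_grains(self, make_rng):
        """A species lost at the whole-region grain is lost from every cell
        it occupied, at every finer grain."""
        for seed in range(20):
            comm = random_community(make_rng(100 + seed))
            oracle = brute_force_cells(comm, [1, 2, 4])
            region_lost = oracle[(1, 0)][1]
            for (k, _), (present, lost) in oracle.items():
                assert region_lost & present <= lost

    def test_coordinate_one_clamped_to_last_cell(self):
        comm = PointCommunity([1.0], [0.999], [1], [True])
        table = compute_grain_table(comm, levels=[4])
        occupied = table[table.s1 > 0]
        assert occupied.cell_id.tolist() == [15]

    def test_empty_community_empty_table(self):
        comm = PointCommunity(np.array([]), np.array([]), np.array([], dtype=int))
        assert compute_grain_table(comm, levels=[2]).empty


class TestSummary:
    def test_toy_means_and_ratio(self, toy_community):
        summary = summarize_grains(
            compute_grain_table(toy_community, levels=[1, 2])
        ).set_index("k")
        assert summary.loc[2, "mean_s1"] == pytest.approx(3 / 4)
        assert summary.loc[2, "px"] == pytest.approx(1 / 3)
        assert summary.loc[1, "px"] == 0

    def test_identity_ex_equals_s1_times_px(self, make_rng):
        """Under the ratio-of-means definition, mean Ex over occupied cells
        is exactly mean S1 * Px at every grain."""
        for seed in range(20):
            comm = random_community(make_rng(200 + seed))
            table = compute_grain_table(comm, levels=[1, 2, 4])
            summary = summarize_grains(table)
            for row in summary.itertuples():
                occ = table[(table.k == row.k) & (table.s1 > 0)]
                if not occ.empty:
                    assert occ.ex.mean() == pytest.approx(
                        occ.s1.mean() * row.px, abs=1e-12
                    )

    def test_mean_s1_nondecreasing_in_area(self, make_rng):
        for seed in range(100):
            comm = random_community(make_rng(300 + seed))
            summary = summarize_grains(
                compute_grain_table(comm, levels=[1, 2, 4, 8])
            ).sort_values("area")
            assert (np.diff(summary.mean_s1) >= -1e-12).all()

    def test_mean_of_ratios_mode(self, toy_community):
        summary = summarize_grains(
            compute_grain_table(toy_community, levels=[2]),
            px_mode="mean_of_ratios",
        )
        assert summary.px.iloc[0] == pytest.approx(1 / 3)  # (0 + 0 + 1)/3

    def test_unknown_mode_rejected(self, toy_community):
        with pytest.raises(ValueError):
            summarize_grains(
                compute_grain_table(toy_community, levels=[2]), px_mode="median"
            )


class TestFitPxar:
    def test_two_grain_toy_slope(self, toy_community):
        summary = summarize_grains(compute_grain_table(toy_community, levels=[1, 2]))
        fit = fit_pxar(summary)
        assert fit.slope == pytest.approx(TOY_PXAR_SLOPE, abs=1e-12)

    def test_constant_px_zero_slope(self):
        summary = pd.DataFrame(
            {"k": [1, 2, 4], "area": [1, 0.25, 0.0625], "px": [0.4, 0.4, 0.4],
             "mean_s1": [3, 1, 0.5], "mean_ex": [1, 0.4, 0.2]}
        )
        assert fit_pxar(summary).slope == pytest.approx(0.0, abs=1e-14)

    def test_exact_linear_recovered_to_machine_precision(self):
        areas = np.array([1.0, 0.25, 0.0625, 0.015625])
        c, b = -0.07, 0.3
        summary = pd.DataFrame(
            {"k": [1, 2, 4, 8], "area": areas, "px": c * np.log(areas) + b,
             "mean_s1": 1.0, "mean_ex": 0.5}
        )
        fit = fit_pxar(summary)
        assert fit.slope == pytest.approx(c, abs=1e-14)
        assert fit.intercept == pytest.approx(b, abs=1e-14)
        assert np.allclose(fit.residuals, 0, atol=1e-14)

    def test_single_usable_grain_is_an_error(self):
        summary = pd.DataFrame(
            {"k": [1, 2], "area": [1, 0.25], "px": [0.2, np.nan],
             "mean_s1": [1, 0.5], "mean_ex": [0.2, 0]}
        )
        with pytest.raises(ValueError, match="PxAR"):
            fit_pxar(summary)


def _irls_poisson_slope(y, log_area, iters=60):
    """Independent iteratively-reweighted-least-squares Poisson fit."""
    X = np.column_stack([np.ones_like(log_area), log_area])
    beta = np.array([np.log(max(y.mean(), 1e-8)), 0.0])
    for _ in range(iters):
        mu = np.exp(X @ beta)
        z = X @ beta + (y - mu) / mu
        beta = np.linalg.solve(X.T @ (mu[:, None] * X), X.T @ (mu * z))
    return beta[1]


def _table(ks, ex_by_k):
    rows = []
    for k in ks:
        for cell in range(k * k):
            rows.append({"k": k, "cell_id": cell, "area": 1 / k**2,
                         "s1": 5, "ex": ex_by_k[k](cell)})
    df = pd.DataFrame(rows)
    df["px"] = df.ex / df.s1
    return df


class TestFitExar:
    def test_two_support_point_count_ratio(self):
        # every 2x2 cell loses 2 species, every 4x4 cell loses 1:
        # slope = ln(2/1) / ln((1/4)/(1/16)) = 0.5
        table = _table([2, 4], {2: lambda c: 2, 4: lambda c: 1})
        assert fit_exar(table).slope == pytest.approx(0.5, abs=1e-10)

    def test_constant_ex_zero_slope(self):
        table = _table([2, 4], {2: lambda c: 3, 4: lambda c: 3})
        assert fit_exar(table).slope == pytest.approx(0.0, abs=1e-10)

    def test_doubling_counts_shifts_intercept_not_slope(self):
        t1 = _table([2, 4], {2: lambda c: 2, 4: lambda c: 1})
        t2 = _table([2, 4], {2: lambda c: 4, 4: lambda c: 2})
        f1, f2 = fit_exar(t1), fit_exar(t2)
        assert f2.slope == pytest.approx(f1.slope, abs=1e-10)
        assert f2.intercept == pytest.approx(f1.intercept + np.log(2), abs=1e-8)

    def test_matches_independent_irls(self, make_rng):
        for seed in range(5):
            rng = make_rng(400 + seed)
            table = _table(
                [2, 4, 8],
                {k: (lambda c, k=k, r=rng.integers(0, 3, 64): int(r[c % 64]))
                 for k in (2, 4, 8)},
            )
            if not (table.ex > 0).any():
                continue
            got = fit_exar(table).slope
            want = _irls_poisson_slope(
                table.ex.to_numpy(float), np.log(table.area.to_numpy())
            )
            assert got == pytest.approx(want, abs=1e-8)

    def test_all_zero_ex_is_an_error_not_zero(self):
        table = _table([2, 4], {2: lambda c: 0, 4: lambda c: 0})
        with pytest.raises(ValueError, match="ExAR"):
            fit_exar(table)


def test_extinction_scaling_handles_degenerate_fits(rng):
    comm = random_community(rng)
    comm.alive_t2[:] = True  # no deaths anywhere
    table, summary, pxar, exar = extinction_scaling(comm, levels=[1, 2, 4])
    assert exar is None
    assert pxar is not None and pxar.slope == pytest.approx(0.0, abs=1e-12)
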