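import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from organgrowth.axes_distance import fit_axis_grid
from organgrowth.core_model import CellPolygon
from organgrowth.growth_quant import (
    anisotropy,
    area_expansion,
    compute_growth_map,
    directional_expansion,
    growth_tensor,
)
from organgrowth.synthetic_tissue import GrowthFieldSpec, make_initial_tissue, step
from organgrowth.synthetic_tissue.fields import uniform_rate, uniform_stretch

RECT = np.array([[0.0, 0.0], [60.0, 0.0], [60.0, 120.0], [0.0, 120.0]])

UNIT_SQUARE_PTS = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])


class TestAreaExpansion:
    @pytest.mark.parametrize(
        "a0,a1,expected", [(100, 100, 0.0), (50, 100, 100.0), (80, 60, -25.0)]
    )
    def test_forced_cases(self, a0, a1, expected):
        assert area_expansion(a0, a1) == pytest.approx(expected)

    def test_nonpositive_mother_area(self):
        with pytest.raises(ValueError):
            area_expansion(0.0, 10.0)
        with pytest.raises(ValueError):
            area_expansion(-5.0, 10.0)

    @given(
        a0=st.floats(1e-3, 1e6),
        a1=st.floats(0.0, 1e6),
    )
    @settings(max_examples=100, deadline=None)
    def test_formula_on_arbitrary_inputs(self, a0, a1):
        assert area_expansion(a0, a1) == pytest.approx((a1 / a0 - 1.0) * 100.0)
        assert area_expansion(a0, a1) >= -100.0


def apply_map(A, points):
    return points @ np.asarray(A).T


class TestGrowthTensor:
    def test_identity(self):
        pts = UNIT_SQUARE_PTS * 3.0
        pairs = list(zip(pts, pts))
        lam_max, lam_min, direction, rms = growth_tensor(pairs)
        assert lam_max == pytest.approx(1.0, abs=1e-12)
        assert lam_min == pytest.approx(1.0, abs=1e-12)
        assert direction is None  # undefined for isotropic deformation
        assert rms == pytest.approx(0.0, abs=1e-12)

    def test_uniform_scaling(self):
        pts = UNIT_SQUARE_PTS
        pairs = list(zip(pts, 1.2 * pts))
        lam_max, lam_min, direction, _ = growth_tensor(pairs)
        assert lam_max == pytest.approx(1.2, abs=1e-12)
        assert lam_min == pytest.approx(1.2, abs=1e-12)
        assert anisotropy(lam_max, lam_min) == pytest.approx(1.0, abs=1e-9)
        assert direction is None

    def test_diagonal_stretch(self):
        A = np.diag([2.0, 1.0])
        pairs = list(zip(UNIT_SQUARE_PTS, apply_map(A, UNIT_SQUARE_PTS)))
        lam_max, lam_min, direction, _ = growth_tensor(pairs)
        assert (lam_max, lam_min) == pytest.approx((2.0, 1.0), abs=1e-12)
        assert abs(direction @ [1.0, 0.0]) == pytest.approx(1.0, abs=1e-12)

    def test_recovers_singular_values_of_random_map(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            A = rng.normal(size=(2, 2))
            while abs(np.linalg.det(A)) < 0.05:
                A = rng.normal(size=(2, 2))
            p0 = rng.uniform(-5, 5, size=(6, 2))
            pairs = list(zip(p0, apply_map(A, p0)))
            lam_max, lam_min, _, rms = growth_tensor(pairs)
            # independent oracle: SVD of the imposed map itself
            expected = np.linalg.svd(A, compute_uv=False)
            assert lam_max == pytest.approx(expected[0], abs=1e-9)
            assert lam_min == pytest.approx(expected[1], abs=1e-9)
            assert rms < 1e-9

    def test_under_determined(self):
        with pytest.raises(ValueError, match="under-determined"):
            growth_tensor([([0, 0], [0, 0]), ([1, 0], [1, 0])])

    def test_collinear_junctions(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0], [3.0, 0.0]])
        with pytest.raises(ValueError, match="collinear"):
            growth_tensor(list(zip(pts, pts)))

    def test_rotation_equivariance(self):
        rng = np.random.default_rng(3)
        A = np.array([[1.8, 0.3], [-0.2, 1.1]])
        p0 = rng.uniform(-2, 2, size=(7, 2))
        p1 = apply_map(A, p0)
        lam_max, lam_min, direction, _ = growth_tensor(list(zip(p0, p1)))
        for theta in (0.3, 1.2, -2.0):
            R = np.array(
                [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
            )
            lm, ln, d, _ = growth_tensor(list(zip(apply_map(R, p0), apply_map(R, p1))))
            assert lm == pytest.approx(lam_max, abs=1e-12)
            assert ln == pytest.approx(lam_min, abs=1e-12)
            # direction rotates with the frame (up to sign)
            assert abs(d @ (R @ direction)) == pytest.approx(1.0, abs=1e-9)

    def test_translation_removed(self):
        p0 = UNIT_SQUARE_PTS
        p1 = 1.5 * p0 + np.array([10.0, -4.0])
        lam_max, lam_min, _, rms = growth_tensor(list(zip(p0, p1)))
        assert (lam_max, lam_min) == pytest.approx((1.5, 1.5), abs=1e-12)
        assert rms < 1e-12


class TestAnisotropy:
    def test_values(self):
        assert anisotropy(1.2, 1.2) == pytest.approx(1.0)
        assert anisotropy(2.0, 1.0) == pytest.approx(2.0)

    def test_invalid(self):
        with pytest.raises(ValueError):
            anisotropy(1.0, 0.0)
        with pytest.raises(ValueError):
            anisotropy(1.0, 2.0)

    def test_uniform_anisotropy_recovered_from_simulation(self):
        """Imposed stretch ratio 1.5 at zero-mean rates: median recovered
        anisotropy within [1.45, 1.55]."""
        snap = make_initial_tissue(40, RECT, seed=5)
        la = np.log(1.5)
        spec = GrowthFieldSpec(
            domain=RECT, stretch_rates=uniform_stretch(0.1 + la / 2, 0.1 - la / 2)
        )
        s1, lin, _ = step(snap, spec, 1.0, seed=1)
        res = compute_growth_map(snap, s1, lin)
        ratios = [r.anisotropy for r in res.records]
        assert 1.45 < np.median(ratios) < 1.55


def straight_grid(width=60.0, height=120.0):
    """Rectilinear grid: longitudinal along +y at x=0, mediolateral along +x."""
    return fit_axis_grid(None, [[0, 0], [0, height]], [[0, 0], [width, 0]])


class TestDirectionalExpansion:
    def test_axis_aligned_stretch(self):
        # grid aligned so that "longitudinal" is the x-axis here
        grid = fit_axis_grid(None, [[0, 0], [120, 0]], [[0, 0], [0, 60]])
        parent = CellPolygon(label=1, vertices=[[0, 0], [10, 0], [10, 10], [0, 10]])
        daughters = np.array([[0, 0], [20, 0], [20, 10], [0, 10]], dtype=float)
        assert directional_expansion(parent, daughters, grid, "longitudinal") == pytest.approx(100.0, abs=1e-6)
        assert directional_expansion(parent, daughters, grid, "mediolateral") == pytest.approx(0.0, abs=1e-6)

    def test_no_deformation(self):
        grid = straight_grid()
        parent = CellPolygon(label=1, vertices=[[5, 5], [15, 5], [15, 15], [5, 15]])
        for axis in ("longitudinal", "mediolateral"):
            assert directional_expansion(parent, parent.vertices, grid, axis) == pytest.approx(0.0, abs=1e-6)

    def test_unknown_axis(self):
        grid = straight_grid()
        parent = CellPolygon(label=1, vertices=[[0, 0], [1, 0], [1, 1], [0, 1]])
        with pytest.raises(ValueError, match="axis"):
            directional_expansion(parent, parent.vertices, grid, "diagonal")

    @pytest.mark.parametrize("fx,fy", [(1.3, 1.1), (1.0, 1.6), (0.9, 1.2)])
    def test_consistency_with_area_formula(self, fx, fy):
        """Axis-aligned growth: product of the two axis factors equals the
        area factor within 2%."""
        grid = straight_grid()
        parent = CellPolygon(label=1, vertices=[[4, 6], [16, 6], [16, 18], [4, 18]])
        daughters = parent.vertices * [fx, fy]
        u = directional_expansion(parent, daughters, grid, "longitudinal")
        v = directional_expansion(parent, daughters, grid, "mediolateral")
        from shapely.geometry import Polygon

        area_pct = area_expansion(parent.area, Polygon(daughters).area)
        assert (1 + u / 100) * (1 + v / 100) == pytest.approx(
            1 + area_pct / 100, rel=0.02
        )


class TestComputeGrowthMap:
    def test_uniform_growth_values(self):
        snap = make_initial_tissue(30, RECT, seed=6)
        spec = GrowthFieldSpec(domain=RECT, areal_rate=uniform_rate(0.2))
        s1, lin, _ = step(snap, spec, 1.0, seed=1)
        res = compute_growth_map(snap, s1, lin)
        expected = 100.0 * (np.exp(0.2) - 1.0)
        assert len(res.records) == 30
        for r in res.records:
            assert r.area_expansion_pct == pytest.approx(expected, rel=1e-2)

    def test_daughters_inherit_parent_values(self, mini_series):
        hit = False
        for s0, s1, lin in zip(
            mini_series.snapshots, mini_series.snapshots[1:], mini_series.lineages
        ):
            res = compute_growth_map(s0, s1, lin)
            for r in res.records:
                if r.n_daughters < 2:
                    continue
                children = lin.children_of(r.parent_label)
                vals = {
                    tuple(res.heatmap.loc[c].values) for c in children
                }
                assert len(vals) == 1  # identical rows for all daughters
                hit = True
        assert hit, "no divisions in the series"

    def test_heatmap_keyed_by_t1_labels(self, mini_series):
        s0, s1 = mini_series.snapshots[0], mini_series.snapshots[1]
        res = compute_growth_map(s0, s1, mini_series.lineages[0])
        assert set(res.heatmap.index) <= set(s1.cells)

    def test_det_consistency(self, mini_series):
        """lambda_max * lambda_min agrees with 1 + area_expansion/100 within
        5% for noise-free simulated cells."""
        for s0, s1, lin in zip(
            mini_series.snapshots[:3], mini_series.snapshots[1:4], mini_series.lineages
        ):
            res = compute_growth_map(s0, s1, lin)
            assert res.records
            for r in res.records:
                det = r.lambda_max * r.lambda_min
                assert det == pytest.approx(1 + r.area_expansion_pct / 100, rel=0.05)

    def test_anisotropy_at_least_one(self, mini_series):
        for s0, s1, lin in zip(
            mini_series.snapshots, mini_series.snapshots[1:], mini_series.lineages
        ):
            res = compute_growth_map(s0, s1, lin)
            for r in res.records:
                assert r.anisotropy >= 1.0

    def test_gynoecium_replum_adjacent_valves_grow_faster(self, gyn_series):
        """During the active window, valve cells near the replum expand more
        than lateral valve cells."""
        s0 = gyn_series.snapshot_at(4.0)
        s1 = gyn_series.snapshot_at(5.0)
        res = compute_growth_map(s0, s1, gyn_series.lineage_for(4.0, 5.0))
        xs = np.array([c.centroid[0] for c in s1.cells.values()])
        xmid = xs.mean()
        xhalf = np.abs(xs - xmid).max()
        near, far = [], []
        for lab in res.heatmap.index:
            c = s1.cells[int(lab)]
            if c.region != "valve":
                continue
            vm = abs(c.centroid[0] - xmid) / xhalf
            val = res.heatmap.loc[lab, "area_expansion_pct"]
            (near if vm < 0.4 else far if vm > 0.6 else []).append(val)
        assert np.mean(near) > np.mean(far) + 5.0

    def test_directional_columns_with_grid(self, mini_series):
        from organgrowth.io_cli.pipeline import default_grid

        s0, s1 = mini_series.snapshots[0], mini_series.snapshots[1]
        res = compute_growth_map(
            s0, s1, mini_series.lineages[0], grid=default_grid(s1)
        )
        assert "longitudinal_expansion_pct" in res.heatmap.columns
        assert "mediolateral_expansion_pct" in res.heatmap.columns
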