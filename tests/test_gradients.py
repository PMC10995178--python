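import numpy as np
import pytest

from organgrowth.core_model import DistanceField, TissueSnapshot
from organgrowth.gradients import (
    GradientStat,
    cell_size_profile,
    dominant_axis,
    gradient_stat,
    onset_time,
    profile,
    stomata_distribution,
)
from tests.conftest import square_cell


def make_field(normalized):
    return DistanceField(
        source_labels={0},
        distance={k: v * 100 for k, v in normalized.items()},
        normalized=dict(normalized),
        domain_labels=set(normalized),
    )


class TestProfile:
    def test_constant_values(self):
        field = make_field({i: i / 9 for i in range(10)})
        prof = profile({i: 5.0 for i in range(10)}, field, n_bins=4)
        assert np.allclose(prof.mean, 5.0)
        assert np.allclose(prof.sd[prof.n > 1], 0.0)
        assert prof.n_total == 10

    def test_linear_values(self):
        n = 4000
        field = make_field({i: i / (n - 1) for i in range(n)})
        prof = profile({i: i / (n - 1) for i in range(n)}, field, n_bins=4)
        assert np.allclose(prof.mean, [0.125, 0.375, 0.625, 0.875], atol=2e-3)

    def test_matches_groupby_oracle(self):
        rng = np.random.default_rng(5)
        n = 200
        dist = {i: float(rng.uniform()) for i in range(n)}
        vals = {i: float(rng.normal()) for i in range(n)}
        n_bins = 7
        prof = profile(vals, make_field(dist), n_bins=n_bins)
        edges = np.linspace(0, 1, n_bins + 1)
        for b in range(n_bins):
            members = [
                vals[i]
                for i in range(n)
                if (edges[b] <= dist[i] < edges[b + 1])
                or (b == n_bins - 1 and dist[i] >= edges[b])
            ]
            assert prof.n[b] == len(members)
            if members:
                assert prof.mean[b] == pytest.approx(np.mean(members))
                expected_sd = np.std(members, ddof=1) if len(members) > 1 else 0.0
                assert prof.sd[b] == pytest.approx(expected_sd)

    def test_singleton_bins_flagged(self):
        field = make_field({1: 0.1, 2: 0.9})
        prof = profile({1: 3.0, 2: 4.0}, field, n_bins=2)
        assert prof.singleton_bins == [0, 1]
        assert np.allclose(prof.sd, 0.0)

    def test_no_overlap_error(self):
        with pytest.raises(ValueError, match="shared"):
            profile({1: 1.0}, make_field({2: 0.5}), n_bins=2)

    def test_excluded_counted(self):
        field = make_field({1: 0.2, 2: 0.8})
        prof = profile({1: 1.0, 2: 2.0, 3: 9.0}, field, n_bins=2)
        assert prof.n_excluded == 1
        assert prof.n_total == 2

    def test_bin_count_validated(self):
        with pytest.raises(ValueError, match="n_bins"):
            profile({1: 1.0}, make_field({1: 0.5}), n_bins=1)

    def test_weighted_recombination_recovers_global_mean(self):
        rng = np.random.default_rng(8)
        n = 137
        dist = {i: float(rng.uniform()) for i in range(n)}
        vals = {i: float(rng.normal(3.0)) for i in range(n)}
        prof = profile(vals, make_field(dist), n_bins=5)
        recombined = np.nansum(prof.mean * prof.n) / prof.n.sum()
        assert recombined == pytest.approx(np.mean(list(vals.values())), abs=1e-12)


class TestGradientStat:
    def test_perfectly_increasing(self):
        n = 30
        field = make_field({i: i / (n - 1) for i in range(n)})
        stat = gradient_stat(
            {i: float(i) for i in range(n)}, field, n_permutations=199, seed=0
        )
        assert stat.rank_correlation == pytest.approx(1.0)
        assert stat.permutation_p == pytest.approx(1 / 200)
        assert stat.slope > 0

    def test_zero_variance_flagged(self):
        n = 20
        field = make_field({i: i / (n - 1) for i in range(n)})
        stat = gradient_stat({i: 7.0 for i in range(n)}, field, n_permutations=99)
        assert stat.flagged
        assert stat.rank_correlation == 0.0
        assert stat.permutation_p == 1.0

    def test_minimum_cells(self):
        field = make_field({i: i / 8 for i in range(9)})
        with pytest.raises(ValueError, match=">= 10"):
            gradient_stat({i: float(i) for i in range(9)}, field)

    def test_null_calibration_quick(self):
        """Values independent of distance: |rho| small and p > 0.05 in at
        least 90% of seeds (Monte-Carlo under the null)."""
        n = 500
        ok = 0
        trials = 40
        for seed in range(trials):
            rng = np.random.default_rng(seed)
            field = make_field({i: float(rng.uniform()) for i in range(n)})
            vals = {i: float(rng.normal()) for i in range(n)}
            stat = gradient_stat(vals, field, n_permutations=199, seed=seed)
            if abs(stat.rank_correlation) < 0.1 and stat.permutation_p > 0.05:
                ok += 1
        assert ok >= 0.9 * trials

    def test_determinism(self):
        n = 40
        rng = np.random.default_rng(1)
        field = make_field({i: float(rng.uniform()) for i in range(n)})
        vals = {i: float(rng.normal()) for i in range(n)}
        s1 = gradient_stat(vals, field, n_permutations=299, seed=5)
        s2 = gradient_stat(vals, field, n_permutations=299, seed=5)
        assert s1 == s2


class TestDominantAxis:
    def _fields(self, n=60, seed=0):
        rng = np.random.default_rng(seed)
        u = {i: float(rng.uniform()) for i in range(n)}
        v = {i: float(rng.uniform()) for i in range(n)}
        return make_field(u), make_field(v), u, v

    def test_pure_function_of_v(self):
        uf, vf, u, v = self._fields()
        vals = {i: 3.0 * v[i] + 1.0 for i in v}
        verdict = dominant_axis(vals, uf, vf, n_permutations=199, seed=1)
        assert verdict.verdict == "mediolateral"

    def test_pure_function_of_u(self):
        uf, vf, u, v = self._fields(seed=2)
        vals = {i: -2.0 * u[i] for i in u}
        verdict = dominant_axis(vals, uf, vf, n_permutations=199, seed=1)
        assert verdict.verdict == "longitudinal"

    def test_no_gradient_gives_none(self):
        uf, vf, u, v = self._fields(seed=3)
        rng = np.random.default_rng(9)
        vals = {i: float(rng.normal()) for i in u}
        verdict = dominant_axis(vals, uf, vf, n_permutations=199, seed=1)
        assert verdict.verdict == "none"

    def test_swap_invariance(self):
        uf, vf, u, v = self._fields(seed=4)
        vals = {i: v[i] ** 2 for i in v}
        a = dominant_axis(vals, uf, vf, n_permutations=199, seed=1)
        b = dominant_axis(vals, vf, uf, n_permutations=199, seed=1)
        swap = {"longitudinal": "mediolateral", "mediolateral": "longitudinal", "none": "none"}
        assert b.verdict == swap[a.verdict]


class TestOnsetTime:
    def _series(self, ps, rhos=None):
        rhos = rhos or [0.5] * len(ps)
        return [
            GradientStat(
                axis="longitudinal", interval=(float(i), float(i + 1)),
                slope=1.0, rank_correlation=r, permutation_p=p, n_cells=50,
            )
            for i, (p, r) in enumerate(zip(ps, rhos))
        ]

    def test_example_series(self):
        stats = self._series([0.8, 0.6, 0.01, 0.02, 0.01])
        assert onset_time(stats, alpha=0.05, min_consecutive=2) == (2.0, 3.0)

    def test_no_significant_interval(self):
        stats = self._series([0.8, 0.6, 0.5])
        assert onset_time(stats) is None

    def test_empty_series(self):
        assert onset_time([]) is None

    def test_sign_consistency_required(self):
        stats = self._series([0.01, 0.01, 0.01], rhos=[0.5, -0.5, 0.5])
        assert onset_time(stats, min_consecutive=2) is None

    def test_min_consecutive(self):
        stats = self._series([0.01, 0.5, 0.01, 0.01, 0.01])
        assert onset_time(stats, min_consecutive=3) == (2.0, 3.0)
        assert onset_time(stats, min_consecutive=1) == (0.0, 1.0)


def snapshot_with_states(states, size=10.0):
    """Row of cells with given states, 1-indexed labels."""
    cells = {
        i + 1: square_cell(i + 1, size * i, 0.0, size=size, state=s)
        for i, s in enumerate(states)
    }
    adjacency = {(i, i + 1) for i in range(1, len(states))}
    return TissueSnapshot(time_dai=0.0, cells=cells, adjacency=adjacency)


class TestStomataDistribution:
    def test_no_stomata_zero_flagged(self):
        snap = snapshot_with_states(["proliferative"] * 6)
        h_base, h_medial = stomata_distribution(snap, [1], [3], n_bins=4)
        assert h_base.empty and h_medial.empty
        assert h_base.counts.sum() == 0

    def test_stomata_at_max_distance(self):
        states = ["proliferative"] * 5 + ["stoma"]
        snap = snapshot_with_states(states)
        h_base, _ = stomata_distribution(snap, [1], [1], n_bins=5)
        assert h_base.counts[-1] == 1
        assert h_base.counts[:-1].sum() == 0
        assert h_base.total == 1

    def test_counts_sum_to_total(self, gyn_series):
        from organgrowth.axes_distance import reference_labels

        s = gyn_series.snapshots[-1]
        n_stoma = sum(1 for c in s.cells.values() if c.state == "stoma")
        h_base, h_medial = stomata_distribution(
            s,
            reference_labels(s, "base"),
            reference_labels(s, "medial"),
            n_bins=8,
        )
        assert h_base.total <= n_stoma  # domain may exclude some
        assert h_base.counts.sum() == h_base.total
        assert h_medial.counts.sum() == h_medial.total

    def test_empty_reference_error(self):
        snap = snapshot_with_states(["stoma", "proliferative"])
        with pytest.raises(ValueError, match="reference"):
            stomata_distribution(snap, [], [1], n_bins=2)

    def test_replum_histogram_shifts_toward_replum(self, gyn_series):
        """Lateral-first stomatal appearance: the mean normalized distance
        from the replum decreases over successive days."""
        from organgrowth.axes_distance import reference_labels

        means = []
        for s in gyn_series.snapshots:
            valves = s.region_labels("valve")
            if not any(
                s.cells[l].state == "stoma" for l in valves
            ):
                continue
            _, h_medial = stomata_distribution(
                s,
                reference_labels(s, "base"),
                reference_labels(s, "medial"),
                n_bins=10,
                domain_labels=valves,
            )
            if h_medial.total < 5:
                continue
            centers = 0.5 * (h_medial.bin_edges[:-1] + h_medial.bin_edges[1:])
            means.append((h_medial.counts * centers).sum() / h_medial.total)
        assert len(means) >= 3
        assert means[-1] < means[0]


class TestCellSizeProfile:
    def test_uniform_areas_flat(self):
        snap = snapshot_with_states(["proliferative"] * 8)
        field = make_field({i + 1: i / 7 for i in range(8)})
        prof = cell_size_profile(snap, field, n_bins=4)
        assert np.allclose(prof.mean, 100.0)

    def test_differentiated_bins_larger(self):
        """Under spatially uniform growth with a one-sided differentiation
        onset, mean cell area in differentiated bins strictly exceeds
        proliferative bins: division arrest is the size readout."""
        from organgrowth.synthetic_tissue import (
            GrowthFieldSpec,
            make_initial_tissue,
            step,
        )
        from organgrowth.synthetic_tissue.fields import uniform_stretch

        rect = np.array([[0.0, 0.0], [100.0, 0.0], [100.0, 50.0], [0.0, 50.0]])
        spec = GrowthFieldSpec(
            domain=rect,
            stretch_rates=uniform_stretch(0.15, 0.15),
            division_area_threshold=160.0,
            # left half differentiates after day 1, right half never
            differentiation_onset=lambda xy: np.where(xy[:, 0] < 50.0, 1.0, 99.0),
        )
        snap = make_initial_tissue(50, rect, seed=6)
        for k in range(4):
            snap, _, _ = step(snap, spec, 1.0, seed=k)
        diff_areas = [c.area for c in snap.cells.values() if c.state == "differentiated"]
        prol_areas = [c.area for c in snap.cells.values() if c.state == "proliferative"]
        assert len(diff_areas) > 5 and len(prol_areas) > 5
        assert np.mean(diff_areas) > np.mean(prol_areas)

    def test_valveless_larger_cells_near_tip(self):
        from organgrowth.axes_distance import (
            cell_distance,
            normalize_distance,
            reference_labels,
        )
        from organgrowth.synthetic_tissue import scenario

        series = scenario("valveless", seed=4)
        s = series.snapshots[-1]
        fld = normalize_distance(
            cell_distance(s, reference_labels(s, "tip")), s.labels
        )
        prof = cell_size_profile(s, fld, n_bins=4)
        # basipetal differentiation: cells near the tip stopped dividing
        # earlier and are therefore larger
        assert prof.mean[0] > prof.mean[-1]
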