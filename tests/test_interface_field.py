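import warnings

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lungstress import (
    PlausibilityWarning,
    SimulationConfig,
    UnitField,
    amplifier_distribution,
    count_heterogeneous_edges,
    dispersal_calibration_curve,
    estimate_dispersal,
    generate_field,
    heterogeneous_interface_fraction,
    total_edges,
)


class TestGenerateField:
    def test_segregated_half_grid(self, segregated_cfg):
        """4x4 half abnormal, dispersal 0: left two columns abnormal, 4/24 edges heterogeneous."""
        field = generate_field(segregated_cfg)
        assert field.labels[:, :2].all() and not field.labels[:, 2:].any()
        assert total_edges(field) == 24
        assert count_heterogeneous_edges(field) == 4

    def test_exhaustive_edge_enumeration_on_segregated_grid(self, segregated_cfg):
        """Brute-force enumeration of all 4-neighbour pairs agrees with the vector count."""
        field = generate_field(segregated_cfg)
        lab = field.labels
        hetero = total_count = 0
        for i in range(4):
            for j in range(4):
                for di, dj in ((0, 1), (1, 0)):
                    ni, nj = i + di, j + dj
                    if ni < 4 and nj < 4:
                        total_count += 1
                        hetero += lab[i, j] != lab[ni, nj]
        assert total_count == total_edges(field) == 24
        assert hetero == count_heterogeneous_edges(field) == 4

    def test_checkerboard_all_edges_heterogeneous(self, checkerboard_field):
        assert count_heterogeneous_edges(checkerboard_field) == 24
        assert heterogeneous_interface_fraction(checkerboard_field) == 1.0

    def test_uniform_grid_warns_and_has_no_interfaces(self):
        cfg = SimulationConfig(nx=4, ny=4, abnormal_fraction=0.0, dispersal=0.5, seed=0)
        with pytest.warns(PlausibilityWarning):
            field = generate_field(cfg)
        assert heterogeneous_interface_fraction(field) == 0.0

    def test_same_seed_identical_field(self):
        cfg = SimulationConfig(nx=12, ny=9, abnormal_fraction=0.4, dispersal=0.6, seed=11)
        a, b = generate_field(cfg), generate_field(cfg)
        assert np.array_equal(a.labels, b.labels)
        assert np.array_equal(a.compliances, b.compliances)

    @given(
        st.integers(2, 12),
        st.integers(2, 12),
        st.floats(0.1, 0.9),
        st.floats(0.0, 1.0),
        st.integers(0, 1000),
    )
    def test_edge_count_and_abnormal_count_conserved(self, nx, ny, frac, d, seed):
        cfg = SimulationConfig(nx=nx, ny=ny, abnormal_fraction=frac, dispersal=d, seed=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", PlausibilityWarning)
            field = generate_field(cfg)
        assert total_edges(field) == nx * (ny - 1) + ny * (nx - 1)
        assert field.labels.sum() == round(frac * nx * ny)
        # heterogeneous + homogeneous edges partition all edges
        hetero = count_heterogeneous_edges(field)
        assert 0 <= hetero <= total_edges(field)

    def test_dispersal_one_is_random_placement(self):
        cfg = SimulationConfig(nx=30, ny=30, abnormal_fraction=0.5, dispersal=1.0, seed=5)
        field = generate_field(cfg)
        # a random half/half field has about half its edges heterogeneous;
        # a segregated one would have ~1/30
        assert heterogeneous_interface_fraction(field) > 0.4


class TestAmplifierDistribution:
    def test_constant_compliances_give_constant_multiplier(self):
        labels = np.zeros((4, 4), dtype=np.int8)
        labels[:, :2] = 1
        compliances = np.where(labels == 1, 0.25, 2.0)
        summary = amplifier_distribution(UnitField(labels=labels, compliances=compliances))
        assert summary.n_edges == 4
        assert summary.mean == pytest.approx(2.0, rel=1e-12)  # (8)^(1/3)
        assert summary.median == pytest.approx(2.0, rel=1e-12)
        assert summary.max == pytest.approx(2.0, rel=1e-12)

    def test_threshold_one_full_exceedance(self, checkerboard_field):
        summary = amplifier_distribution(checkerboard_field, threshold=1.0)
        assert summary.exceedance_fraction == 1.0

    def test_no_heterogeneous_edges_sentinel(self):
        field = UnitField(labels=np.zeros((3, 3), dtype=np.int8), compliances=np.ones((3, 3)))
        summary = amplifier_distribution(field)
        assert summary.n_edges == 0
        assert np.isnan(summary.mean)

    def test_summary_reproducible_for_fixed_seed(self):
        cfg = SimulationConfig(nx=15, ny=15, abnormal_fraction=0.3, dispersal=0.5, seed=21)
        s1 = amplifier_distribution(generate_field(cfg), threshold=1.5)
        s2 = amplifier_distribution(generate_field(cfg), threshold=1.5)
        assert s1 == s2
        # frozen regression values recorded from this generator and seed
        assert s1.n_edges == 144
        assert s1.mean == pytest.approx(1.9873947143598376, rel=1e-12)
        assert s1.max == pytest.approx(2.6209483352964975, rel=1e-12)


class TestDispersal:
    def test_interface_fraction_monotone_in_dispersal(self):
        """Mean interface fraction strictly increases across d on a 20x20 grid."""
        means = []
        for d in (0.0, 0.25, 0.5, 0.75, 1.0):
            fracs = [
                heterogeneous_interface_fraction(
                    generate_field(
                        SimulationConfig(
                            nx=20, ny=20, abnormal_fraction=0.3, dispersal=d, seed=s
                        )
                    )
                )
                for s in range(30)
            ]
            means.append(np.mean(fracs))
        assert all(b > a for a, b in zip(means, means[1:]))

    def test_calibration_curve_monotone(self):
        _, means = dispersal_calibration_curve(20, 20, 0.3, replicates=50)
        assert all(b >= a for a, b in zip(means, means[1:]))
        assert means[-1] > means[0]

    @pytest.mark.parametrize("d_true, lo, hi", [(0.0, 0.0, 0.05), (1.0, 0.9, 1.0)])
    def test_recovery_at_extremes(self, d_true, lo, hi):
        cfg = SimulationConfig(nx=50, ny=50, abnormal_fraction=0.3, dispersal=d_true, seed=17)
        field = generate_field(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", PlausibilityWarning)
            est = estimate_dispersal(field, cfg, replicates=100)
        assert lo <= est <= hi

    def test_recovery_midrange(self):
        cfg = SimulationConfig(nx=50, ny=50, abnormal_fraction=0.3, dispersal=0.6, seed=23)
        est = estimate_dispersal(generate_field(cfg), cfg, replicates=100)
        assert abs(est - 0.6) <= 0.1
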