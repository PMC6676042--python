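"""Synthetic-cohort generator: determinism, latent structure, ground truth."""

import numpy as np
import pytest

from lesiongrad import (
    CohortSpec,
    SimulatedSubject,
    apply_perturbation,
    make_latent_layout,
    make_lesion,
    simulate_bold,
    simulate_clinical,
    simulate_cohort,
)
from lesiongrad.cohort import latent_distances, perturbation_amplitude, source_weights


def morans_i_6neighbour(values_3d, mask):
    """Brute-force Moran's I with 6-neighbour binary weights (direct double sum)."""
    idx = np.array(np.nonzero(mask)).T
    x = values_3d[mask]
    xc = x - x.mean()
    pos = {tuple(p): i for i, p in enumerate(idx)}
    num = 0.0
    w_sum = 0
    offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    for i, p in enumerate(idx):
        for off in offsets:
            q = (p[0] + off[0], p[1] + off[1], p[2] + off[2])
            j = pos.get(q)
            if j is not None:
                num += xc[i] * xc[j]
                w_sum += 1
    return (len(x) / w_sum) * num / (xc**2).sum()


class TestLatentLayout:
    def test_coordinates_span_unit_interval(self):
        lay = make_latent_layout((10, 10, 10), G=2, seed=0)
        assert lay.latent_coords.shape == (1000, 2)
        assert np.allclose(lay.latent_coords.min(axis=0), 0)
        assert np.allclose(lay.latent_coords.max(axis=0), 1)

    def test_deterministic_for_fixed_seed(self):
        a = make_latent_layout((8, 8, 6), G=3, seed=42)
        b = make_latent_layout((8, 8, 6), G=3, seed=42)
        assert np.array_equal(a.latent_coords, b.latent_coords)
        assert np.array_equal(a.anchor_points, b.anchor_points)

    def test_smooth_field_is_spatially_autocorrelated(self):
        lay = make_latent_layout((10, 10, 10), G=1, seed=3)
        vol = np.zeros(lay.grid_dims)
        vol[lay.gm_mask] = lay.latent_coords[:, 0]
        assert morans_i_6neighbour(vol, lay.gm_mask) > 0.3

    def test_scrambled_field_has_no_spatial_structure(self):
        lay = make_latent_layout((10, 10, 10), G=1, seed=3, field_type="scrambled")
        vol = np.zeros(lay.grid_dims)
        vol[lay.gm_mask] = lay.latent_coords[:, 0]
        assert abs(morans_i_6neighbour(vol, lay.gm_mask)) < 0.1
        assert lay.latent_metric == "ring"

    def test_degenerate_grid_rejected(self):
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[:2, :2, :2] = True  # 8 voxels, below the floor of 50
        with pytest.raises(ValueError, match="degenerate"):
            make_latent_layout((4, 4, 4), G=1, seed=0, gm_mask=mask)

    @pytest.mark.parametrize("bad", [dict(grid_dims=(3, 8, 8)), dict(G=4), dict(G=0)])
    def test_invalid_arguments(self, bad):
        kwargs = dict(grid_dims=(8, 8, 8), G=1, seed=0)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            make_latent_layout(kwargs.pop("grid_dims"), **kwargs)

    def test_ring_metric_wraps(self):
        a = np.array([[0.95]])
        b = np.array([[0.05]])
        assert latent_distances(a, b, "ring")[0, 0] == pytest.approx(0.1)
        assert latent_distances(a, b, "euclidean")[0, 0] == pytest.approx(0.9)


class TestSimulateBold:
    def test_single_source_no_noise_gives_unit_correlations(self, small_layout):
        spec = CohortSpec(n_sources=1, snr=np.inf, n_timepoints=50)
        ts = simulate_bold(small_layout, spec, seed=0)
        fc = np.corrcoef(ts)
        assert np.allclose(np.abs(fc), 1.0, atol=1e-10)

    def test_latent_near_pairs_correlate_more_than_far_pairs(self):
        lay = make_latent_layout((8, 5, 5), G=1, seed=2)  # 200 voxels
        ts = simulate_bold(lay, CohortSpec(), seed=3)
        fc = np.corrcoef(ts)
        d = latent_distances(lay.latent_coords, lay.latent_coords)
        iu = np.triu_indices_from(d, k=1)
        dv, rv = d[iu], fc[iu]
        order = np.argsort(dv)
        tenth = len(order) // 10
        near = rv[order[:tenth]].mean()
        far = rv[order[-tenth:]].mean()
        assert near > far

    def test_reproducible(self, small_layout):
        a = simulate_bold(small_layout, CohortSpec(), seed=11)
        b = simulate_bold(small_layout, CohortSpec(), seed=11)
        assert np.array_equal(a, b)

    def test_rows_standardised(self, small_layout):
        ts = simulate_bold(small_layout, CohortSpec(), seed=0)
        assert np.allclose(ts.mean(axis=1), 0, atol=1e-12)
        assert np.allclose(ts.std(axis=1), 1, atol=1e-12)

    def test_bad_snr_rejected(self, small_layout):
        with pytest.raises(ValueError):
            CohortSpec(snr=0.0)
        with pytest.raises(ValueError, match="timepoints"):
            simulate_bold(small_layout, CohortSpec(n_timepoints=10), seed=0)


class TestMakeLesion:
    def test_radius_zero_is_single_voxel(self, small_layout):
        mask = make_lesion(small_layout, (4, 4, 3), 0)
        assert mask.sum() == 1

    def test_radius_two_interior_ball_has_33_voxels(self):
        # lattice points with x^2+y^2+z^2 <= 4: enumerated independently
        count = sum(
            1
            for x in range(-2, 3)
            for y in range(-2, 3)
            for z in range(-2, 3)
            if x * x + y * y + z * z <= 4
        )
        lay = make_latent_layout((9, 9, 9), G=1, seed=0)
        mask = make_lesion(lay, (4, 4, 4), 2)
        assert mask.sum() == count == 33

    def test_mask_subset_of_grey_matter(self):
        gm = np.ones((8, 8, 8), dtype=bool)
        gm[:, :, :2] = False
        lay = make_latent_layout((8, 8, 8), G=1, seed=0, gm_mask=gm)
        mask = make_lesion(lay, (4, 4, 3), 2)
        assert not (mask & ~gm).any()

    def test_center_outside_grid_rejected(self, small_layout):
        with pytest.raises(ValueError, match="outside"):
            make_lesion(small_layout, (50, 0, 0), 1)


class TestPerturbation:
    def _patient(self, layout, radius=1):
        mask = make_lesion(layout, tuple(layout.voxel_ijk[0]), radius)
        return SimulatedSubject("pat-x", [], lesion_mask=mask)

    def test_amplitude_closed_form(self, small_layout):
        spec = CohortSpec(perturbation_mode="gradient", gamma=0.5, tau=0.2)
        subj = self._patient(small_layout)
        amp, d_lat = perturbation_amplitude(small_layout, spec, subj.lesion_mask)
        at_zero = amp[np.isclose(d_lat, 0)]
        assert np.allclose(at_zero, spec.gamma)
        # verify the decay law at every voxel, not just special points
        assert np.allclose(amp, spec.gamma * np.exp(-d_lat / spec.tau))

    def test_uniform_mode_constant_amplitude(self, small_layout):
        spec = CohortSpec(perturbation_mode="uniform", gamma=0.3)
        amp, _ = perturbation_amplitude(small_layout, spec, self._patient(small_layout).lesion_mask)
        assert np.allclose(amp, 0.3)

    def test_gradient_amplitude_nonincreasing_in_latent_distance(self, small_layout):
        spec = CohortSpec(perturbation_mode="gradient")
        amp, d_lat = perturbation_amplitude(small_layout, spec, self._patient(small_layout).lesion_mask)
        order = np.argsort(d_lat)
        assert np.all(np.diff(amp[order]) <= 1e-12)

    def test_none_mode_warns_and_zeroes_amplitude(self, small_layout):
        spec = CohortSpec(perturbation_mode="none")
        subj = self._patient(small_layout)
        with pytest.warns(UserWarning, match="re-draws"):
            apply_perturbation(subj, small_layout, spec, seed=0)
        assert np.allclose(subj.truth["amplitude"], 0)
        assert len(subj.sessions) == spec.n_sessions

    def test_lesioned_series_are_noise(self, small_layout):
        spec = CohortSpec(perturbation_mode="gradient", n_timepoints=60)
        subj = self._patient(small_layout, radius=1)
        apply_perturbation(subj, small_layout, spec, seed=4)
        rows = subj.lesion_mask[small_layout.gm_mask]
        intact = ~rows
        # lesioned voxels decorrelate from the sources that drive intact voxels
        fc = np.corrcoef(subj.sessions[0])
        cross = np.abs(fc[np.ix_(rows, intact)]).mean()
        within = np.abs(fc[np.ix_(intact, intact)]).mean()
        assert cross < within

    def test_requires_lesion(self, small_layout):
        subj = SimulatedSubject("ctrl", [], lesion_mask=None)
        with pytest.raises(ValueError, match="lesion"):
            apply_perturbation(subj, small_layout, CohortSpec(), seed=0)


class TestClinicalScores:
    def test_scores_within_valid_ranges(self):
        truths = np.linspace(0, 1, 30)
        df = simulate_clinical(truths, noise_sd=5.0, seed=0)
        assert df["nihss_day0"].between(0, 42).all()
        assert df["nihss_day5"].between(0, 42).all()
        assert df["mrs_day0"].between(0, 5).all()
        assert df["mrs_day5"].between(0, 5).all()
        assert all(np.issubdtype(df[c].dtype, np.integer) for c in df.columns)

    def test_noise_free_map_is_monotone(self):
        truths = np.linspace(0, 1, 20)
        df = simulate_clinical(truths, noise_sd=0.0, seed=0)
        assert np.all(np.diff(df["nihss_day5"].to_numpy()) >= 0)

    def test_reproducible(self):
        truths = [0.1, 0.4, 0.9]
        a = simulate_clinical(truths, seed=3)
        b = simulate_clinical(truths, seed=3)
        assert a.equals(b)


class TestSimulateCohort:
    def test_byte_identical_for_fixed_seed(self):
        spec = CohortSpec(n_controls=2, n_patients=2, n_timepoints=40)
        a = simulate_cohort(spec, seed=9, grid_dims=(6, 6, 4))
        b = simulate_cohort(spec, seed=9, grid_dims=(6, 6, 4))
        assert np.array_equal(a.layout.latent_coords, b.layout.latent_coords)
        for sa, sb in zip(a.patients, b.patients):
            assert np.array_equal(sa.lesion_mask, sb.lesion_mask)
            for ta, tb in zip(sa.sessions, sb.sessions):
                assert np.array_equal(ta, tb)
        assert a.clinical.equals(b.clinical)

    def test_structure_matches_spec(self, small_cohort):
        spec = small_cohort.spec
        assert len(small_cohort.controls) == spec.n_controls
        assert len(small_cohort.patients) == spec.n_patients
        for c in small_cohort.controls:
            assert len(c.sessions) == 1 and c.lesion_mask is None
        for p in small_cohort.patients:
            assert len(p.sessions) == spec.n_sessions
            assert p.lesion_mask.any()
            assert p.truth is not None
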