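"""CN-correlation geometry, UNM decomposition, CMPI and polarity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.mixture import GaussianMixture

from cncorr.cn import (CNProfile, MOTION_FLOOR_UM, cmpi,
                       compute_cn_data, convergence_check, polarity_histogram,
                       relative_sem, unm_decompose, UNMDecomposer)
from cncorr.mixtures import PHASE_MIXTURES
from cncorr.simulate import CellMovie, MovieGenConfig, generate_cell_movie

from conftest import mask_movie


def track_movie(cell_track, nuc_track, interval=1.0):
    cell = np.asarray(cell_track, float)
    times = np.arange(len(cell), dtype=float) * interval
    return CellMovie(times, cell, np.asarray(nuc_track, float))


# -- geometric identities ---------------------------------------------------

def test_rigid_translation_is_45_deg():
    cell = [[0, 0], [3, 4]]
    p = compute_cn_data(track_movie(cell, cell))
    assert p.angle[0] == pytest.approx(45.0, abs=1e-12)
    assert p.ccd[0] == pytest.approx(5.0)
    assert p.ncd_par[0] == pytest.approx(5.0)


def test_cell_only_motion_is_90_deg():
    p = compute_cn_data(track_movie([[0, 0], [2, 0]], [[0, 0], [0, 0]]))
    assert p.angle[0] == pytest.approx(90.0, abs=1e-12)
    assert p.ncd_par[0] == pytest.approx(0.0, abs=1e-12)


def test_backward_nucleus_gives_obtuse_angle():
    # ccd = 1, ncd_par = -0.5 -> atan2(1, -0.5) = 116.565 deg
    p = compute_cn_data(track_movie([[0, 0], [1, 0]], [[0, 0], [-0.5, 0]]))
    assert p.angle[0] == pytest.approx(116.56505117707799, abs=1e-9)


def test_orthogonal_nucleus_motion_projects_out():
    # nucleus moves perpendicular to the cell displacement: ncd_par = 0
    p = compute_cn_data(track_movie([[0, 0], [1, 0]], [[0, 0], [0, 3]]))
    assert p.angle[0] == pytest.approx(90.0, abs=1e-12)


def test_mask_movie_identities():
    # from binary masks: cell-only shift -> 90 deg, rigid shift -> 45 deg
    p90 = compute_cn_data(mask_movie((8, 0), (0, 0)))
    assert p90.angle[0] == pytest.approx(90.0, abs=1e-9)
    assert p90.ccd[0] == pytest.approx(2.0, abs=1e-9)  # 8 px * 0.25 µm
    p45 = compute_cn_data(mask_movie((6, 0), (6, 0)))
    assert p45.angle[0] == pytest.approx(45.0, abs=1e-9)
    assert p45.ncd_par[0] == pytest.approx(1.5, abs=1e-9)


@settings(derandomize=True, max_examples=40, deadline=None)
@given(st.floats(min_value=-180.0, max_value=180.0, allow_nan=False))
def test_rotation_invariance(theta_deg):
    """Rotating the lab frame leaves CCD, NCD_par and the angle unchanged."""
    rng = np.random.default_rng(7)
    cell = np.cumsum(rng.normal(0, 1, (12, 2)), axis=0)
    nuc = np.cumsum(rng.normal(0, 0.5, (12, 2)), axis=0)
    th = np.deg2rad(theta_deg)
    R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    p0 = compute_cn_data(track_movie(cell, nuc))
    p1 = compute_cn_data(track_movie(cell @ R.T, nuc @ R.T))
    assert np.allclose(p0.angle, p1.angle, atol=1e-6)
    assert np.allclose(p0.ccd, p1.ccd, atol=1e-6)
    assert np.allclose(p0.ncd_par, p1.ncd_par, atol=1e-6)


def test_motion_floor_exclusion():
    eps = MOTION_FLOOR_UM / 10.0
    cell = [[0, 0], [eps, 0], [1 + eps, 0]]
    nuc = [[0, 0], [0, 0], [0, 0]]
    p = compute_cn_data(track_movie(cell, nuc))
    assert len(p) == 1
    assert p.n_excluded == 1


def test_profile_concatenate_and_dataframe():
    movies = [generate_cell_movie(PHASE_MIXTURES["S"], MovieGenConfig(seed=s))
              for s in (0, 1)]
    profiles = [compute_cn_data(m, cell_id=i) for i, m in enumerate(movies)]
    pooled = CNProfile.concatenate(profiles)
    assert len(pooled) == sum(len(p) for p in profiles)
    df = pooled.to_dataframe()
    assert set(df.columns) == {"ccd_um", "ncd_par_um", "angle_deg", "cell_id"}
    assert set(df["cell_id"]) == {0, 1}


def test_missing_nucleus_rejected():
    m = track_movie([[0, 0], [1, 0]], [[0, 0], [1, 0]])
    m.nucleus_centroids = None
    with pytest.raises(ValueError, match="nucleus"):
        compute_cn_data(m)


def test_generated_movie_angles_match_truth():
    """The analysis recovers the generator's per-step angles exactly
    when no centroid noise is added."""
    m = generate_cell_movie(PHASE_MIXTURES["G2"],
                            MovieGenConfig(duration=60.0, seed=5))
    p = compute_cn_data(m)
    assert len(p) == 60
    assert np.allclose(p.angle, m.step_angles, atol=1e-9)
    assert np.allclose(p.ccd, m.step_ccd, atol=1e-9)


# -- UNM decomposition ------------------------------------------------------

def test_unm_recovers_two_separated_components():
    rng = np.random.default_rng(0)
    x = np.concatenate([rng.normal(45, 8, 700), rng.normal(115, 8, 300)])
    fit = unm_decompose(x, k=2)
    assert fit.means_[0] == pytest.approx(45, abs=2)
    assert fit.means_[1] == pytest.approx(115, abs=2)
    assert fit.weights_[0] == pytest.approx(0.7, abs=0.03)
    assert fit.labels_ == ("trailing_edge_detachment", "side_protrusion")


def test_unm_matches_sklearn_oracle():
    """On well-separated data our EM agrees with sklearn's GaussianMixture."""
    rng = np.random.default_rng(1)
    x = np.concatenate([rng.normal(45, 8, 600), rng.normal(115, 8, 400)])
    ours = unm_decompose(x, k=2, sd_mode="free")
    gm = GaussianMixture(2, random_state=0, n_init=5).fit(x[:, None])
    order = np.argsort(gm.means_.ravel())
    assert np.allclose(ours.means_, gm.means_.ravel()[order], atol=0.5)
    assert np.allclose(ours.weights_, gm.weights_[order], atol=0.01)
    assert np.allclose(ours.sds_,
                       np.sqrt(gm.covariances_.ravel()[order]), atol=0.5)


def test_unm_bic_selects_reasonable_k():
    rng = np.random.default_rng(2)
    x = np.concatenate([rng.normal(45, 8, 500), rng.normal(90, 8, 700),
                        rng.normal(145, 8, 300)])
    fit = unm_decompose(x)  # k=None -> BIC
    assert fit.k_ == 3


def test_unm_weight_near_and_to_dict():
    rng = np.random.default_rng(3)
    x = np.concatenate([rng.normal(90, 8, 800), rng.normal(45, 8, 200)])
    fit = unm_decompose(x, k=2)
    assert fit.weight_near(90.0) == pytest.approx(0.8, abs=0.03)
    d = fit.to_dict()
    assert d["k"] == 2 and d["n"] == 1000
    assert {c["activity"] for c in d["components"]} == {
        "leading_edge_protrusion", "trailing_edge_detachment"}


def test_unm_input_validation():
    with pytest.raises(ValueError, match="at least 50"):
        unm_decompose(np.full(10, 90.0), k=2)
    with pytest.raises(ValueError, match="distinct"):
        unm_decompose(np.full(60, 90.0), k=3)
    with pytest.raises(ValueError, match="sd_mode"):
        rng = np.random.default_rng(0)
        unm_decompose(rng.normal(90, 8, 100), k=1, sd_mode="bogus")


def test_unm_custom_signature_sequence():
    rng = np.random.default_rng(4)
    x = np.concatenate([rng.normal(30, 8, 500), rng.normal(150, 8, 500)])
    fit = unm_decompose(x, signatures=[30.0, 150.0], k=2)
    assert fit.labels_ == ("sig_30", "sig_150")


def test_unm_estimator_clonable():
    from sklearn.base import clone

    est = UNMDecomposer(k=3, fixed_sd=6.0)
    c = clone(est)
    assert c.k == 3 and c.fixed_sd == 6.0


# -- CMPI -------------------------------------------------------------------

def test_cmpi_is_occurrence_times_mean():
    m = generate_cell_movie(PHASE_MIXTURES["earlyG1"],
                            MovieGenConfig(duration=720.0, seed=0))
    p = compute_cn_data(m)
    r = cmpi(p)
    assert r.cmpi == pytest.approx(r.occurrence * r.mean_ncd, abs=1e-9)
    assert r.cutoff == 75.0
    assert r.n == len(p)


def test_cmpi_cutoff_and_empty_subset():
    p = CNProfile(ccd=np.array([1.0, 1.0]), ncd_par=np.array([0.0, -0.2]),
                  angle=np.array([90.0, 100.0]),
                  cell_ids=np.zeros(2, dtype=object))
    r = cmpi(p)
    assert r.occurrence == 0.0 and r.mean_ncd == 0.0 and r.cmpi == 0.0
    with pytest.raises(ValueError, match="empty"):
        cmpi(CNProfile(np.empty(0), np.empty(0), np.empty(0),
                       np.empty(0, dtype=object)))


def test_cmpi_per_hour_sum():
    p = CNProfile(ccd=np.ones(60), ncd_par=np.full(60, 0.5),
                  angle=np.full(60, 45.0), cell_ids=np.zeros(60, dtype=object),
                  interval=1.0)
    r = cmpi(p, per_hour_sum=True)
    # 60 one-minute steps = 1 h of observation, sum of NCD_par = 30 µm
    assert r.cmpi == pytest.approx(30.0)


# -- polarity ---------------------------------------------------------------

def test_polarity_straight_run_concentrates_at_zero():
    cell = np.column_stack([np.arange(20.0), np.zeros(20)])
    m = track_movie(cell, cell)
    h = polarity_histogram(m)
    assert h.reference_direction == pytest.approx(0.0)
    assert np.all(h.relative_angles == 0.0)
    assert h.circular_variance == pytest.approx(0.0, abs=1e-12)
    assert h.counts.sum() == 19


def test_polarity_counts_sum_to_steps():
    m = generate_cell_movie(PHASE_MIXTURES["G2"],
                            MovieGenConfig(duration=120.0, seed=9))
    h = polarity_histogram(m)
    assert h.counts.sum() == len(h.relative_angles) == 120
    assert np.all((h.relative_angles >= -180) & (h.relative_angles < 180))


def test_polarity_persistent_less_variable_than_erratic():
    def mean_cv(phase):
        cvs = [polarity_histogram(generate_cell_movie(
            PHASE_MIXTURES[phase],
            MovieGenConfig(duration=720.0, seed=s))).circular_variance
            for s in range(10)]
        return float(np.mean(cvs))

    # a mixture dominated by persistent forward protrusion keeps step
    # directions more aligned than one rich in side protrusions/retractions
    assert mean_cv("earlyG1") < mean_cv("G2")


def test_polarity_requires_two_frames():
    m = CellMovie(np.array([0.0]), np.zeros((1, 2)), np.zeros((1, 2)))
    with pytest.raises(ValueError, match="two frames"):
        polarity_histogram(m)


# -- convergence ------------------------------------------------------------

def test_convergence_check_first_qualifying_prefix():
    vals = [1.0, 1.0, 1.0, 5.0]
    # n=2: sem=0 -> immediately below threshold
    assert convergence_check(vals) == 2
    noisy = [1.0, 1.5, 1.1, 0.9, 1.0, 1.05, 0.95, 1.0, 1.0, 1.0]
    n = convergence_check(noisy, threshold=0.10)
    assert n == 5
    assert relative_sem(noisy, n) <= 0.10
    assert relative_sem(noisy, n - 1) > 0.10


def test_convergence_check_never_converges():
    assert convergence_check([1.0, 3.0, 0.1, 5.0, -2.0, 4.0], 0.1) is None


def test_convergence_check_validation():
    with pytest.raises(ValueError):
        convergence_check([1.0])
    with pytest.raises(ValueError, match="zero"):
        convergence_check([1.0, -1.0, 5.0])
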