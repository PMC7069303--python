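"""Geometric morphometrics: TPS I/O, centroid size, GPA, allometry, DFA."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as stn

import respoly
from respoly import ScenarioConfig
from respoly.morpho import (LandmarkConfig, allometry_correct, centroid_size,
                            dfa, full_procrustes_fit, procrustes_distance,
                            read_tps, write_tps)

rng0 = np.random.default_rng(0)


def random_config(k, rng, structure="unknown", spec_id="s"):
    return LandmarkConfig(spec_id, structure, rng.normal(size=(k, 2)))


# ---------------------------------------------------------------------------
# TPS
# ---------------------------------------------------------------------------

def test_tps_round_trip(tmp_path, data):
    path = tmp_path / "body.tps"
    write_tps(data["body"][:10], path)
    back = read_tps(path)
    assert len(back) == 10
    for a, b in zip(data["body"][:10], back):
        assert a.specimen_id == b.specimen_id
        np.testing.assert_allclose(a.coords, b.coords, atol=1e-9)


def test_tps_scale_halves_coordinates(tmp_path):
    path = tmp_path / "scaled.tps"
    path.write_text("LM=3\n2 0\n0 2\n2 2\nID=x\nSCALE=0.5\n"
                    "LM=3\n1 0\n0 1\n1 1\nID=y\n")
    configs = read_tps(path)
    assert len(configs) == 2
    np.testing.assert_allclose(configs[0].coords, configs[1].coords)


def test_tps_truncated_record_reports_line(tmp_path):
    path = tmp_path / "bad.tps"
    path.write_text("LM=4\n0 0\n1 0\n")
    with pytest.raises(ValueError, match="line"):
        read_tps(path)


def test_tps_inconsistent_counts_names_record(tmp_path):
    path = tmp_path / "mix.tps"
    path.write_text("LM=3\n0 0\n1 0\n0 1\nID=ok\nLM=4\n0 0\n1 0\n0 1\n1 1\nID=bad\n")
    with pytest.raises(ValueError, match="bad"):
        read_tps(path)


# ---------------------------------------------------------------------------
# Centroid size
# ---------------------------------------------------------------------------

def test_centroid_size_unit_square():
    square = LandmarkConfig("sq", "unknown",
                            [(0, 0), (1, 0), (1, 1), (0, 1)])
    assert centroid_size(square) == pytest.approx(np.sqrt(2), abs=1e-12)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(stn.integers(0, 10_000), stn.floats(0.1, 50),
       stn.floats(0, 2 * np.pi))
def test_centroid_size_similarity_properties(seed, scale, angle):
    """CS is invariant to rotation/translation and homogeneous under scaling."""
    rng = np.random.default_rng(seed)
    coords = rng.normal(size=(8, 2))
    cs = centroid_size(LandmarkConfig("a", "unknown", coords))
    rot = np.array([[np.cos(angle), -np.sin(angle)],
                    [np.sin(angle), np.cos(angle)]])
    moved = coords @ rot.T + [3.5, -1.2]
    assert centroid_size(LandmarkConfig("b", "unknown", moved)) == \
        pytest.approx(cs, rel=1e-9)
    assert centroid_size(LandmarkConfig("c", "unknown", coords * scale)) == \
        pytest.approx(cs * scale, rel=1e-9)


def test_centroid_size_degenerate_warns():
    with pytest.warns(UserWarning, match="degenerate"):
        assert centroid_size(LandmarkConfig("d", "unknown",
                                            np.ones((5, 2)))) == 0.0


# ---------------------------------------------------------------------------
# GPA
# ---------------------------------------------------------------------------

def _similarity_copies(shape, n, rng):
    out = []
    for i in range(n):
        ang = rng.uniform(0, 2 * np.pi)
        rot = np.array([[np.cos(ang), -np.sin(ang)],
                        [np.sin(ang), np.cos(ang)]])
        c = shape @ rot.T * rng.lognormal(0, 0.5) + rng.normal(0, 10, 2)
        out.append(LandmarkConfig(f"c{i}", "unknown", c))
    return out


def test_gpa_removes_similarity_transforms():
    rng = np.random.default_rng(1)
    shape = rng.normal(size=(6, 2))
    aligned = full_procrustes_fit(_similarity_copies(shape, 8, rng))
    flat = aligned.procrustes_coords
    d = np.linalg.norm(flat[:, None, :] - flat[None, :, :], axis=2)
    assert d.max() < 1e-8


def test_gpa_consensus_is_fixed_point(data):
    aligned = full_procrustes_fit(data["body"][:40])
    consensus_cfg = LandmarkConfig("cons", "unknown", aligned.consensus)
    # consensus aligned against itself: zero Procrustes distance
    assert procrustes_distance(aligned.consensus, consensus_cfg.coords) < 1e-12
    # consensus is the mean of the aligned configurations
    mean = aligned.procrustes_coords.mean(axis=0).reshape(-1, 2)
    mean /= np.sqrt((mean**2).sum())
    np.testing.assert_allclose(mean, aligned.consensus, atol=1e-6)
    # unit centroid size for every aligned configuration
    cs = np.sqrt((aligned.procrustes_coords**2).sum(axis=1))
    np.testing.assert_allclose(cs, 1.0, atol=1e-9)


def test_gpa_invariant_to_input_order(data):
    configs = data["chela"][:30]
    a = full_procrustes_fit(configs)
    b = full_procrustes_fit(configs[::-1])
    def dists(al):
        f = al.procrustes_coords
        return np.linalg.norm(f[:, None, :] - f[None, :, :], axis=2)
    np.testing.assert_allclose(dists(a), dists(b)[::-1, ::-1], atol=1e-8)


def test_gpa_landmark_count_mismatch():
    rng = np.random.default_rng(2)
    configs = [random_config(5, rng, spec_id="a"), random_config(6, rng, spec_id="b")]
    with pytest.raises(ValueError, match="mismatch"):
        full_procrustes_fit(configs)


def grid_oracle_distance(a, b, n_grid=20_000):
    """Brute-force partial Procrustes distance: minimize over a fine rotation
    grid (written independently of the closed-form fit)."""
    a = np.asarray(a, float); b = np.asarray(b, float)
    a = a - a.mean(axis=0); a /= np.sqrt((a**2).sum())
    b = b - b.mean(axis=0); b /= np.sqrt((b**2).sum())
    best = np.inf
    for ang in np.linspace(0, 2 * np.pi, n_grid, endpoint=False):
        rot = np.array([[np.cos(ang), -np.sin(ang)],
                        [np.sin(ang), np.cos(ang)]])
        best = min(best, np.linalg.norm(b @ rot.T - a))
    return best


@pytest.mark.parametrize("k", [3, 4, 5])
def test_procrustes_distance_matches_grid_oracle(k):
    rng = np.random.default_rng(10 + k)
    for _ in range(3):
        a, b = rng.normal(size=(k, 2)), rng.normal(size=(k, 2))
        assert procrustes_distance(a, b) == pytest.approx(
            grid_oracle_distance(a, b), abs=1e-4)


def test_triangle_distance_matches_complex_closed_form():
    """For planar shapes the rotation-aligned distance has the closed form
    sqrt(2 - 2|<z1, z2>|) with shapes as centered unit complex vectors."""
    rng = np.random.default_rng(3)
    for _ in range(10):
        a, b = rng.normal(size=(3, 2)), rng.normal(size=(3, 2))
        za = (a[:, 0] + 1j * a[:, 1]); za -= za.mean(); za /= np.linalg.norm(za)
        zb = (b[:, 0] + 1j * b[:, 1]); zb -= zb.mean(); zb /= np.linalg.norm(zb)
        closed = np.sqrt(max(0.0, 2 - 2 * abs(np.vdot(zb, za))))
        assert procrustes_distance(a, b) == pytest.approx(closed, abs=1e-10)


# ---------------------------------------------------------------------------
# Allometry
# ---------------------------------------------------------------------------

def test_no_allometry_means_residuals_equal_centered_tangent():
    """Zero generating allometry and zero landmark noise: the pooled
    within-group slope is exactly 0, so residuals are just the centered
    tangent coordinates; residuals are also orthogonal to group-centered
    size by least squares."""
    cfg = ScenarioConfig(seed=4, allometric_slope=0.0, landmark_noise_sd=0.0,
                         sex_effect_body=0.0, n_lakes=3, n_per_habitat=10)
    specimens = respoly.generate_specimens(cfg)
    aligned = full_procrustes_fit(respoly.generate_landmarks(cfg, "body", specimens))
    groups = specimens.set_index("specimen_id").loc[aligned.specimens,
                                                    "habitat"].to_numpy()
    resid = allometry_correct(aligned, groups)
    centered = aligned.tangent_coords - aligned.tangent_coords.mean(axis=0)
    assert np.abs(resid - centered).max() < 1e-8

    # least-squares orthogonality holds with noise too
    cfg2 = cfg.with_(landmark_noise_sd=0.01)
    aligned2 = full_procrustes_fit(respoly.generate_landmarks(cfg2, "body", specimens))
    resid2 = allometry_correct(aligned2, groups)
    cs_c = aligned2.centroid_sizes.astype(float).copy()
    r2 = resid2.copy()
    for g in np.unique(groups):
        m = groups == g
        cs_c[m] -= cs_c[m].mean()
        r2[m] -= r2[m].mean(axis=0)
    corr = (cs_c[:, None] * r2).sum(axis=0) / len(cs_c)
    assert np.abs(corr).max() < 1e-10


def test_allometric_slope_recovered():
    """Pooled within-habitat regression on log size recovers the generating
    allometric magnitude within 2 SE."""
    from respoly.synth import allometry_pattern
    cfg = ScenarioConfig(seed=5, allometric_slope=0.02, n_lakes=5,
                         n_per_habitat=20, landmark_noise_sd=0.005)
    specimens = respoly.generate_specimens(cfg)
    aligned = full_procrustes_fit(respoly.generate_landmarks(cfg, "body", specimens))
    groups = specimens.set_index("specimen_id").loc[aligned.specimens,
                                                    "habitat"].to_numpy()
    y = aligned.tangent_coords
    x = np.log(aligned.centroid_sizes)
    xc = x.copy(); yc = y.copy()
    for g in np.unique(groups):
        m = groups == g
        xc[m] -= xc[m].mean(); yc[m] -= yc[m].mean(axis=0)
    slope_vec = (xc[:, None] * yc).sum(axis=0) / (xc @ xc)
    # express the generating pattern in the consensus frame (the GPA
    # orientation is arbitrary) before projecting
    m, c = cfg.mean_shape_body, aligned.consensus
    ang = np.arctan2(float(m[:, 0] @ c[:, 1] - m[:, 1] @ c[:, 0]),
                     float((m * c).sum()))
    rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
    pattern = (allometry_pattern(m) @ rot.T).reshape(-1)
    pattern /= np.linalg.norm(pattern)
    est = float(slope_vec @ pattern)
    resid = yc - np.outer(xc, slope_vec)
    se = float(np.sqrt((resid @ pattern).var(ddof=2) / (xc @ xc)))
    assert abs(est - cfg.allometric_slope) < 2 * se


# ---------------------------------------------------------------------------
# DFA
# ---------------------------------------------------------------------------

def test_dfa_label_swap_symmetry():
    rng = np.random.default_rng(6)
    y = rng.normal(size=(60, 8))
    y[30:] += 0.8
    labels = np.array(["littoral"] * 30 + ["pelagic"] * 30)
    a = dfa(y, labels, n_permutations=99, seed=0)
    swapped = np.where(labels == "littoral", "pelagic", "littoral")
    b = dfa(y, swapped, n_permutations=99, seed=0)
    assert a.t_square == pytest.approx(b.t_square, rel=1e-10)
    assert a.p_value == b.p_value
    assert a.cv_accuracy == b.cv_accuracy
    np.testing.assert_allclose(a.scores, -b.scores, atol=1e-8)


def test_dfa_perfect_separation_classifies_perfectly():
    rng = np.random.default_rng(7)
    y = rng.normal(size=(40, 5))
    y[20:, 0] += 10.0
    labels = np.array(["littoral"] * 20 + ["pelagic"] * 20)
    res = dfa(y, labels, n_permutations=99, seed=0)
    assert res.cv_accuracy == 1.0
    assert res.group_means["pelagic"] > 0  # sign convention


def test_dfa_invariant_to_linear_reparameterization():
    """Any invertible linear change of shape basis (e.g. partial warps vs
    tangent coordinates) yields identical discriminant scores."""
    rng = np.random.default_rng(8)
    y = rng.normal(size=(80, 10))
    y[40:] += 0.5
    labels = np.array(["littoral"] * 40 + ["pelagic"] * 40)
    t = rng.normal(size=(10, 10))  # invertible w.p. 1
    a = dfa(y, labels, n_permutations=49, seed=0)
    b = dfa(y @ t, labels, n_permutations=49, seed=0)
    assert a.t_square == pytest.approx(b.t_square, rel=1e-8)
    sign = np.sign(a.scores @ b.scores)
    np.testing.assert_allclose(a.scores, sign * b.scores, atol=1e-6)


def test_dfa_t_square_matches_direct_formula():
    rng = np.random.default_rng(9)
    y = rng.normal(size=(50, 4))
    y[25:] += 0.7
    labels = np.array(["littoral"] * 25 + ["pelagic"] * 25)
    res = dfa(y, labels, n_permutations=49, seed=0)
    m1 = y[:25].mean(axis=0); m2 = y[25:].mean(axis=0)
    s = (np.cov(y[:25].T) * 24 + np.cov(y[25:].T) * 24) / 48
    d = m2 - m1
    t2 = 25 * 25 / 50 * d @ np.linalg.solve(s, d)
    assert res.t_square == pytest.approx(t2, rel=1e-10)


def test_dfa_requires_three_per_group():
    y = np.random.default_rng(0).normal(size=(10, 3))
    labels = np.array(["a"] * 2 + ["b"] * 8)
    with pytest.raises(ValueError, match="fewer than 3"):
        dfa(y, labels, n_permutations=9)


def test_dfa_permutation_p_is_seed_reproducible():
    rng = np.random.default_rng(12)
    y = rng.normal(size=(40, 6))
    labels = np.array(["littoral", "pelagic"] * 20)
    p1 = dfa(y, labels, n_permutations=199, seed=5).p_value
    p2 = dfa(y, labels, n_permutations=199, seed=5).p_value
    assert p1 == p2
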