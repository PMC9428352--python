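"""Forward-model tests: analytic sphere potentials, lead fields, ROIs."""

import json

import numpy as np
import pytest

from smrsim.forward_model import (
    LeadField,
    Montage,
    SourceSpace,
    build_spherical_leadfield,
    label_hand_knob,
    load_leadfield,
    multishell_dipole_potential,
)

from conftest import fib_points


# -- brute-force surface-charge oracle ---------------------------------


def bem_sphere_potential(elec_idx, p, q, R=0.1, sigma=0.33, n_surf=1500):
    """Collocation solution of the dipole-in-homogeneous-sphere boundary
    problem: surface potential from the second-kind integral equation for
    the double-layer density, independent of the Legendre series."""
    y = R * fib_points(n_surf)
    d = y - p
    vinf = (d @ q) / (4 * np.pi * sigma * np.linalg.norm(d, axis=1) ** 3)
    w = 4 * np.pi * R * R / n_surf
    nrm = y / R
    diff = y[:, None, :] - y[None, :, :]
    num = np.einsum("ijk,jk->ij", diff, nrm)
    dist = np.linalg.norm(diff, axis=2)
    np.fill_diagonal(dist, 1.0)
    K = w / (2 * np.pi) * num / dist**3
    np.fill_diagonal(K, 0.0)
    rows = K.sum(axis=1)
    np.fill_diagonal(K, -1.0 - rows)  # closed-surface solid-angle identity
    A = np.eye(n_surf) + K + np.ones((n_surf, n_surf)) / n_surf  # deflated
    v = np.linalg.solve(A, 2 * vinf)
    v -= v.mean()
    return y[elec_idx] / R, v[elec_idx]


@pytest.mark.parametrize(
    "p, q",
    [
        (np.array([0, 0, 0.05]), np.array([0, 0, 1e-9])),  # radial
        (np.array([0, 0, 0.05]), np.array([1e-9, 0, 0])),  # tangential
        (np.array([0.03, 0.02, 0.04]), np.array([0.5e-9, -0.3e-9, 0.8e-9])),
    ],
)
def test_single_shell_matches_surface_charge_oracle(p, q):
    """Analytic Legendre-series potentials agree with a brute-force BEM
    solution of the same boundary problem to better than 1% at 16 sites."""
    n_surf = 1500
    sel = np.linspace(0, n_surf - 1, 16).astype(int)
    elec, v_bem = bem_sphere_potential(sel, p, q, n_surf=n_surf)
    v_ana = multishell_dipole_potential(
        elec, p, q, radii=(0.1,), conductivities=(0.33,), n_terms=80
    )
    v_ana = v_ana - v_ana.mean()
    v_bem = v_bem - v_bem.mean()
    rel = np.linalg.norm(v_ana - v_bem) / np.linalg.norm(v_ana)
    assert rel < 0.01


def test_radial_dipole_axisymmetry():
    """Electrodes placed symmetrically about the dipole axis see equal
    potentials from a radial dipole."""
    ang = np.deg2rad(40)
    elec = np.array(
        [
            [np.sin(ang), 0, np.cos(ang)],
            [-np.sin(ang), 0, np.cos(ang)],
            [0, np.sin(ang), np.cos(ang)],
            [0, -np.sin(ang), np.cos(ang)],
        ]
    )
    v = multishell_dipole_potential(elec, [0, 0, 0.06], [0, 0, 1e-9])
    assert np.allclose(v, v[0], rtol=1e-10)


def test_potential_linear_in_moment():
    elec = fib_points(8)
    p = np.array([0.02, 0.01, 0.05])
    q = np.array([0.3e-9, -0.2e-9, 0.9e-9])
    v1 = multishell_dipole_potential(elec, p, q)
    v2 = multishell_dipole_potential(elec, p, 2 * q)
    assert np.allclose(v2, 2 * v1, rtol=1e-12)


def test_equal_conductivities_reduce_to_single_shell():
    """A 3-shell model with identical conductivities is a homogeneous
    sphere of the outer radius."""
    elec = fib_points(10)
    p, q = np.array([0, 0.02, 0.05]), np.array([1e-9, 0, 0.5e-9])
    v3 = multishell_dipole_potential(
        elec, p, q, radii=(0.087, 0.092, 0.1), conductivities=(0.33, 0.33, 0.33)
    )
    v1 = multishell_dipole_potential(elec, p, q, radii=(0.1,), conductivities=(0.33,))
    assert np.allclose(v3, v1, rtol=1e-8)


def test_rotation_invariance():
    """Jointly rotating electrodes and dipole leaves potentials unchanged."""
    from scipy.spatial.transform import Rotation

    rot = Rotation.from_euler("zyx", [37, -21, 64], degrees=True).as_matrix()
    elec = fib_points(12)
    p, q = np.array([0.01, -0.03, 0.05]), np.array([0.4e-9, 0.7e-9, -0.2e-9])
    v = multishell_dipole_potential(elec, p, q)
    v_rot = multishell_dipole_potential(elec @ rot.T, rot @ p, rot @ q)
    assert np.allclose(v, v_rot, atol=1e-12 + 1e-8 * np.abs(v).max())


def test_source_outside_innermost_shell_errors():
    with pytest.raises(ValueError, match="innermost"):
        multishell_dipole_potential(fib_points(4), [0, 0, 0.09], [0, 0, 1e-9])


# -- montage -----------------------------------------------------------


def test_standard_montage_has_required_channels():
    m = Montage.standard_1020()
    for name in ("C3", "C4", "F3", "T7", "Cz", "P3", "F4", "T8", "P4"):
        m.index(name)
    assert np.allclose(np.linalg.norm(m.channel_positions, axis=1), 1.0)


def test_montage_missing_channel_rejected():
    m = Montage.standard_1020()
    names = tuple(n for n in m.channel_names if n != "C4")
    pos = np.delete(m.channel_positions, m.index("C4"), axis=0)
    with pytest.raises(ValueError, match="C4"):
        Montage(names, pos)


def test_montage_duplicate_names_rejected():
    m = Montage.standard_1020()
    names = list(m.channel_names)
    names[0] = "C3"
    with pytest.raises(ValueError, match="unique"):
        Montage(tuple(names), m.channel_positions)


# -- ROI labeling ------------------------------------------------------


def _symmetric_source_space(n=400):
    pts = fib_points(n)
    left = pts[pts[:, 0] < -1e-9]
    sym = np.concatenate([left, left * [-1, 1, 1]])
    return SourceSpace(0.078 * sym, sym)


def test_cap_radius_zero_selects_single_vertex():
    ss = SourceSpace.fibonacci_sphere(200)
    center = ss.vertex_positions[17] / np.linalg.norm(ss.vertex_positions[17])
    out = label_hand_knob(ss, {"m1_hand_L": (center, 0.0)})
    assert set(out.roi_labels["m1_hand_L"]) == {17}


def test_mirrored_caps_have_equal_counts_on_symmetric_space():
    ss = _symmetric_source_space()
    c = np.array([-0.6, 0.1, 0.79])
    c = c / np.linalg.norm(c)
    spec = {"m1_hand_L": (c, 12.0), "m1_hand_R": (c * [-1, 1, 1], 12.0)}
    out = label_hand_knob(ss, spec)
    assert len(out.roi_labels["left_hand_knob"]) == len(out.roi_labels["right_hand_knob"])
    assert len(out.roi_labels["left_hand_knob"]) > 0


def test_explicit_index_list_round_trips():
    ss = SourceSpace.fibonacci_sphere(50)
    out = label_hand_knob(ss, {"m1_hand_L": [3, 7, 9], "m1_hand_R": [1, 2, 4]})
    assert set(out.roi_labels["m1_hand_L"]) == {3, 7, 9}
    assert set(out.roi_labels["left_hand_knob"]) == {3, 7, 9}


def test_empty_roi_errors():
    ss = SourceSpace.fibonacci_sphere(50)
    with pytest.raises(ValueError, match="no vertices"):
        label_hand_knob(ss, {"m1_hand_L": np.array([], dtype=int)})


def test_overlapping_hand_knobs_rejected():
    ss = SourceSpace.fibonacci_sphere(50)
    with pytest.raises(ValueError, match="disjoint"):
        label_hand_knob(ss, {"m1_hand_L": [1, 2], "m1_hand_R": [2, 3]})


# -- projection --------------------------------------------------------


def test_projection_identities(leadfield):
    rng = np.random.default_rng(0)
    n = leadfield.n_vertices
    assert np.allclose(leadfield.project(np.zeros(n)), 0.0)
    a = rng.standard_normal((n, 3))
    b = rng.standard_normal((n, 3))
    assert np.allclose(
        leadfield.project(a + b), leadfield.project(a) + leadfield.project(b)
    )
    one_hot = np.zeros(n)
    one_hot[123] = 1.0
    assert np.allclose(leadfield.project(one_hot), leadfield.gain[:, 123])
    with pytest.raises(ValueError, match="rows"):
        leadfield.project(np.zeros(n - 1))


def test_column_normalization_sets_unit_peak(leadfield):
    peaks = np.abs(leadfield.gain).max(axis=0)
    assert np.allclose(peaks, 1.0)
    assert leadfield.calibrated


# -- persistence -------------------------------------------------------


def test_leadfield_save_load_round_trip(tmp_path, montage):
    rng = np.random.default_rng(1)
    gain = rng.standard_normal((len(montage), 40))
    ss = SourceSpace.fibonacci_sphere(40)
    ss = label_hand_knob(ss, {"m1_hand_L": [0, 1], "m1_hand_R": [5, 6]})
    lf = LeadField(gain, montage, source_space=ss)
    path = tmp_path / "lf.npz"
    lf.save(path)
    back = load_leadfield(path)
    assert np.array_equal(back.gain, gain)  # bit-exact
    assert back.montage.channel_names == montage.channel_names
    assert set(back.source_space.roi_labels["m1_hand_L"]) == {0, 1}


def test_load_reorders_and_detects_missing_channels(tmp_path, montage):
    rng = np.random.default_rng(2)
    gain = rng.standard_normal((len(montage), 10))
    lf = LeadField(gain, montage)
    path = tmp_path / "lf.npz"
    lf.save(path)
    reordered = load_leadfield(path, montage=montage)
    assert np.array_equal(reordered.gain, gain)

    # a montage wanting a channel the file lacks errors, naming it
    names = montage.channel_names + ("Oz",)
    pos = np.vstack([montage.channel_positions, [0, -1, 0]])
    with pytest.raises(ValueError, match="Oz"):
        load_leadfield(path, montage=Montage(names, pos))


def test_text_importer(tmp_path, montage):
    rng = np.random.default_rng(3)
    gain = rng.standard_normal((len(montage), 5))
    np.savetxt(tmp_path / "gain.txt", gain)
    sidecar = {"channel_names": list(montage.channel_names)}
    (tmp_path / "gain.json").write_text(json.dumps(sidecar))
    lf = LeadField.from_text(tmp_path / "gain.txt", tmp_path / "gain.json")
    assert np.allclose(lf.gain, gain)


def test_built_leadfield_shape_and_finite(montage):
    ss = SourceSpace.fibonacci_sphere(30)
    lf = build_spherical_leadfield(montage, ss)
    assert lf.gain.shape == (len(montage), 30)
    assert np.all(np.isfinite(lf.gain))
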