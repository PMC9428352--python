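"""EEG forward model: montages, source spaces, and lead fields.

The forward problem maps cortical current-dipole amplitudes to scalp
potentials through a lead-field matrix ``G`` (channels x vertices):
``phi = G @ s``.  Lead fields can be loaded from an external file (e.g.
exported from a BEM pipeline) or built with the analytic multi-shell
concentric-sphere model, which expresses the potential of a dipole inside
a layered conducting sphere as a Legendre series and is the standard
closed-form alternative to numerical solvers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

from functools import lru_cache

import numpy as np

__all__ = [
    "Montage",
    "SourceSpace",
    "LeadField",
    "build_spherical_leadfield",
    "load_leadfield",
    "label_hand_knob",
    "default_hand_knob_spec",
    "LAPLACIAN_NEIGHBORS",
]

#: Small-Laplacian neighbor sets used by the online decoder.
LAPLACIAN_NEIGHBORS = {
    "C3": ("F3", "T7", "Cz", "P3"),
    "C4": ("F4", "T8", "Cz", "P4"),
}

_REQUIRED_CHANNELS = frozenset({"C3", "C4", "F3", "T7", "Cz", "P3", "F4", "T8", "P4"})


def _unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


@dataclass(frozen=True)
class Montage:
    """An ordered electrode set with positions.

    Positions are unit vectors on the scalp sphere for the built-in
    spherical model, or arbitrary 3D coordinates for loaded lead fields.
    """

    channel_names: tuple[str, ...]
    channel_positions: np.ndarray  # (n_channels, 3)

    def __post_init__(self) -> None:
        names = tuple(self.channel_names)
        if len(set(names)) != len(names):
            raise ValueError("channel names must be unique")
        missing = sorted(_REQUIRED_CHANNELS - set(names))
        if missing:
            raise ValueError(f"montage is missing required channels: {missing}")
        pos = np.asarray(self.channel_positions, dtype=float)
        if pos.shape != (len(names), 3):
            raise ValueError("channel_positions must have shape (n_channels, 3)")
        object.__setattr__(self, "channel_names", names)
        object.__setattr__(self, "channel_positions", pos)

    def __len__(self) -> int:
        return len(self.channel_names)

    def index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in montage") from None

    @classmethod
    def standard_1020(cls) -> "Montage":
        """Idealized 19-channel 10-20 montage on the unit sphere.

        Coordinates: +x through the right ear, +y through the nasion,
        +z through the vertex.  The temporal ring sits on the equator at
        36-degree steps; C3/C4, Fz/Pz at 45 degrees inclination; F3/F4 and
        P3/P4 are geodesic midpoints of their 10-20 neighbors, which is the
        defining construction of the 10-20 system on a sphere.
        """

        def sph(inc_deg: float, az_deg: float) -> np.ndarray:
            inc, az = np.deg2rad(inc_deg), np.deg2rad(az_deg)
            return np.array(
                [np.sin(inc) * np.cos(az), np.sin(inc) * np.sin(az), np.cos(inc)]
            )

        pos: dict[str, np.ndarray] = {
            "Cz": sph(0, 0),
            "C4": sph(45, 0),
            "C3": sph(45, 180),
            "Fz": sph(45, 90),
            "Pz": sph(45, 270),
            "T8": sph(90, 0),
            "F8": sph(90, 36),
            "Fp2": sph(90, 72),
            "Fp1": sph(90, 108),
            "F7": sph(90, 144),
            "T7": sph(90, 180),
            "P7": sph(90, 216),
            "O1": sph(90, 252),
            "O2": sph(90, 288),
            "P8": sph(90, 324),
        }
        pos["F3"] = _unit(pos["Fz"] + pos["F7"])
        pos["F4"] = _unit(pos["Fz"] + pos["F8"])
        pos["P3"] = _unit(pos["Pz"] + pos["P7"])
        pos["P4"] = _unit(pos["Pz"] + pos["P8"])
        order = (
            "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
            "T7", "C3", "Cz", "C4", "T8",
            "P7", "P3", "Pz", "P4", "P8", "O1", "O2",
        )
        return cls(order, np.array([pos[n] for n in order]))


@dataclass(frozen=True)
class SourceSpace:
    """Dipole locations/orientations plus named ROI vertex sets."""

    vertex_positions: np.ndarray  # (n_vertices, 3), meters
    vertex_orientations: np.ndarray  # (n_vertices, 3), unit norm
    roi_labels: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        pos = np.asarray(self.vertex_positions, dtype=float)
        ori = np.asarray(self.vertex_orientations, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3 or ori.shape != pos.shape:
            raise ValueError("positions/orientations must be matching (n, 3) arrays")
        norms = np.linalg.norm(ori, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("vertex orientations must be unit norm")
        labels = {}
        for name, idx in self.roi_labels.items():
            idx = np.asarray(idx, dtype=int)
            if idx.size and (idx.min() < 0 or idx.max() >= len(pos)):
                raise ValueError(f"ROI {name!r} has vertex indices out of range")
            labels[name] = idx
        left = labels.get("left_hand_knob")
        right = labels.get("right_hand_knob")
        if left is not None and right is not None and np.intersect1d(left, right).size:
            raise ValueError("left and right hand-knob ROIs must be disjoint")
        object.__setattr__(self, "vertex_positions", pos)
        object.__setattr__(self, "vertex_orientations", ori)
        object.__setattr__(self, "roi_labels", labels)

    @property
    def n_vertices(self) -> int:
        return len(self.vertex_positions)

    @classmethod
    def fibonacci_sphere(cls, n_vertices: int = 2000, radius: float = 0.078) -> "SourceSpace":
        """Quasi-uniform source shell: Fibonacci lattice, radial orientations."""
        i = np.arange(n_vertices)
        golden = (1 + np.sqrt(5)) / 2
        z = 1 - (2 * i + 1) / n_vertices
        theta = 2 * np.pi * i / golden
        r_xy = np.sqrt(np.clip(1 - z**2, 0, None))
        dirs = np.column_stack([r_xy * np.cos(theta), r_xy * np.sin(theta), z])
        return cls(radius * dirs, dirs)


def default_hand_knob_spec(montage: Montage, angular_radius_deg: float = 10.0) -> dict:
    """Cap-based ROI spec for the spherical model.

    Two caps per hemisphere — a primary-motor hand area centered at the
    projection of C3/C4 onto the source shell, and a caudal dorsal premotor
    cap rotated just anterior of it — mirroring the two hand-knob parcels
    per hemisphere used in atlas-based labeling.
    """
    c3 = _unit(montage.channel_positions[montage.index("C3")])
    c4 = _unit(montage.channel_positions[montage.index("C4")])
    shift = np.deg2rad(angular_radius_deg)

    def anterior(center: np.ndarray) -> np.ndarray:
        # rotate the cap center toward +y (nasion) by one cap radius
        y = np.array([0.0, 1.0, 0.0])
        t = _unit(y - np.dot(y, center) * center)
        return _unit(np.cos(shift) * center + np.sin(shift) * t)

    return {
        "m1_hand_L": (c3, angular_radius_deg),
        "pmd_hand_L": (anterior(c3), angular_radius_deg),
        "m1_hand_R": (c4, angular_radius_deg),
        "pmd_hand_R": (anterior(c4), angular_radius_deg),
    }


def label_hand_knob(source_space: SourceSpace, roi_spec: dict) -> SourceSpace:
    """Populate hand-knob ROI labels.

    ``roi_spec`` maps ROI names either to ``(center_unit_vector,
    angular_radius_deg)`` caps (spherical model) or to explicit vertex index
    lists (loaded source spaces).  Names ending in ``_L``/``_R`` are merged
    into ``left_hand_knob``/``right_hand_knob``.
    """
    dirs = source_space.vertex_positions / np.linalg.norm(
        source_space.vertex_positions, axis=1, keepdims=True
    )
    labels = dict(source_space.roi_labels)
    for name, spec in roi_spec.items():
        if isinstance(spec, tuple) and len(spec) == 2 and np.ndim(spec[0]) == 1:
            center, radius_deg = spec
            cos_ang = dirs @ _unit(center)
            idx = np.nonzero(cos_ang >= np.cos(np.deg2rad(radius_deg)) - 1e-12)[0]
        else:
            idx = np.asarray(spec, dtype=int)
        if idx.size == 0:
            raise ValueError(f"ROI {name!r} selects no vertices")
        labels[name] = idx

    def merged(suffix: str) -> np.ndarray:
        parts = [labels[n] for n in roi_spec if n.endswith(suffix)]
        return np.unique(np.concatenate(parts)) if parts else np.array([], dtype=int)

    left, right = merged("_L"), merged("_R")
    if left.size:
        labels["left_hand_knob"] = left
    if right.size:
        labels["right_hand_knob"] = right
    return replace(source_space, roi_labels=labels)


@dataclass(frozen=True)
class LeadField:
    """Gain matrix linking source dipole amplitudes to scalp potentials."""

    gain: np.ndarray  # (n_channels, n_vertices)
    montage: Montage
    source_space: SourceSpace | None = None
    calibrated: bool = False

    def __post_init__(self) -> None:
        g = np.asarray(self.gain, dtype=float)
        if g.ndim != 2:
            raise ValueError("gain must be 2D (channels x vertices)")
        if g.shape[0] != len(self.montage):
            raise ValueError("gain row count must match the montage channel count")
        if not np.all(np.isfinite(g)):
            raise ValueError("gain matrix contains non-finite entries")
        object.__setattr__(self, "gain", g)

    @property
    def n_channels(self) -> int:
        return self.gain.shape[0]

    @property
    def n_vertices(self) -> int:
        return self.gain.shape[1]

    def project(self, source_amplitudes: np.ndarray) -> np.ndarray:
        """Forward projection: ``gain @ amplitudes``.

        Accepts a vector (n_vertices,) or frame matrix (n_vertices, n_samples).
        """
        s = np.asarray(source_amplitudes, dtype=float)
        if s.shape[0] != self.n_vertices:
            raise ValueError(
                f"source amplitudes have {s.shape[0]} rows, expected {self.n_vertices}"
            )
        return self.gain @ s

    def normalize_columns(self, peak: float = 1.0) -> "LeadField":
        """Rescale each vertex's gain column so its largest-|gain| channel
        responds with ``peak`` to a unit source amplitude.

        After this calibration, source waveforms expressed in
        microvolt-equivalent peak amplitude produce that peak at the vertex's
        nearest (best-coupled) channel, which makes the generator's
        signal-to-noise specification operational at the scalp.
        """
        colmax = np.abs(self.gain).max(axis=0)
        colmax[colmax == 0] = 1.0
        return replace(self, gain=self.gain * (peak / colmax), calibrated=True)

    # -- persistence ---------------------------------------------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        ss = self.source_space
        payload = {
            "gain": self.gain,
            "channel_names": np.array(self.montage.channel_names),
            "channel_positions": self.montage.channel_positions,
            "calibrated": np.array(self.calibrated),
        }
        if ss is not None:
            payload["vertex_positions"] = ss.vertex_positions
            payload["vertex_orientations"] = ss.vertex_orientations
            payload["roi_json"] = np.array(
                json.dumps({k: v.tolist() for k, v in ss.roi_labels.items()})
            )
        np.savez(path, **payload)

    @classmethod
    def load(cls, path: str | Path, montage: Montage | None = None) -> "LeadField":
        return load_leadfield(path, montage=montage)

    @classmethod
    def from_text(cls, matrix_path: str | Path, sidecar_path: str | Path,
                  montage: Montage | None = None) -> "LeadField":
        """Import a plain-text gain matrix with a JSON sidecar.

        The sidecar must provide ``channel_names`` and may provide
        ``channel_positions``, ``vertex_positions``, ``vertex_orientations``
        and ``roi_labels`` — the interchange format for matrices exported
        from external EEG toolboxes.
        """
        gain = np.loadtxt(matrix_path, ndmin=2)
        meta = json.loads(Path(sidecar_path).read_text())
        names = list(meta["channel_names"])
        positions = np.asarray(
            meta.get("channel_positions", np.zeros((len(names), 3))), dtype=float
        )
        ss = None
        if "vertex_positions" in meta:
            vp = np.asarray(meta["vertex_positions"], dtype=float)
            vo = np.asarray(meta.get("vertex_orientations", vp), dtype=float)
            vo = vo / np.linalg.norm(vo, axis=1, keepdims=True)
            rois = {k: np.asarray(v, int) for k, v in meta.get("roi_labels", {}).items()}
            ss = SourceSpace(vp, vo, rois)
        lf = cls(gain, Montage(tuple(names), positions), source_space=ss)
        return _reorder(lf, montage) if montage is not None else lf


def _reorder(lf: LeadField, montage: Montage) -> LeadField:
    missing = sorted(set(montage.channel_names) - set(lf.montage.channel_names))
    if missing:
        raise ValueError(f"lead field is missing required channels: {missing}")
    order = [lf.montage.index(n) for n in montage.channel_names]
    return replace(lf, gain=lf.gain[order], montage=montage)


def load_leadfield(path: str | Path, montage: Montage | None = None) -> LeadField:
    """Load a LeadField container saved by :meth:`LeadField.save`.

    If ``montage`` is given, channels are reconciled against it by name and
    reordered; missing channels raise an error naming them.
    """
    with np.load(path, allow_pickle=False) as data:
        gain = np.asarray(data["gain"], dtype=float)
        if not np.all(np.isfinite(gain)):
            raise ValueError("gain matrix contains NaN or infinite entries")
        names = tuple(str(n) for n in data["channel_names"])
        file_montage = Montage(names, np.asarray(data["channel_positions"], float))
        ss = None
        if "vertex_positions" in data:
            rois = {
                k: np.asarray(v, int)
                for k, v in json.loads(str(data["roi_json"])).items()
            }
            ss = SourceSpace(
                np.asarray(data["vertex_positions"], float),
                np.asarray(data["vertex_orientations"], float),
                rois,
            )
        lf = LeadField(gain, file_montage, source_space=ss,
                       calibrated=bool(data["calibrated"]))
    return _reorder(lf, montage) if montage is not None else lf


# -- analytic multi-shell sphere ---------------------------------------


def _legendre_tables(n_max: int, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """P_n(x) and P_n^1(x) for n = 1..n_max by upward recurrence.

    P_n^1 uses the Condon-Shortley convention, P_n^1 = -sqrt(1-x^2) P_n'(x).
    Returns arrays of shape (len(x), n_max).
    """
    x = np.asarray(x, float)
    pn = np.empty((len(x), n_max + 1))
    pn1 = np.empty((len(x), n_max + 1))
    pn[:, 0] = 1.0
    pn[:, 1] = x
    s = np.sqrt(np.clip(1.0 - x * x, 0.0, None))
    pn1[:, 0] = 0.0
    pn1[:, 1] = -s
    for n in range(1, n_max):
        pn[:, n + 1] = ((2 * n + 1) * x * pn[:, n] - n * pn[:, n - 1]) / (n + 1)
        pn1[:, n + 1] = ((2 * n + 1) * x * pn1[:, n] - (n + 1) * pn1[:, n - 1]) / n
    return pn[:, 1:], pn1[:, 1:]


@lru_cache(maxsize=32)
def _cached_shell_coeffs(n_max: int, radii_scaled: tuple, sigmas: tuple) -> np.ndarray:
    return _shell_surface_coeffs(n_max, np.array(radii_scaled), np.array(sigmas))


def _shell_surface_coeffs(n_max: int, radii_scaled: np.ndarray,
                          sigmas: np.ndarray) -> np.ndarray:
    """Per-degree surface-potential coefficient of a layered sphere.

    For each Legendre degree n, the potential in layer k is
    ``A_k r^n + B_k r^-(n+1)``.  Starting from a unit source coefficient
    (B_1 = 1, radial part regular at the origin), the interface continuity
    conditions (potential and radial current) are propagated outward and
    the insulating outer boundary closes the system.  Returns c[n] such
    that the surface potential per unit source coefficient is c[n]; for a
    homogeneous sphere c[n] = (2n+1)/n, the classic single-shell result.
    Radii must be scaled by the outer radius (outermost == 1).
    """
    n_shells = len(radii_scaled)
    coeffs = np.empty(n_max + 1)
    coeffs[0] = 0.0
    for n in range(1, n_max + 1):
        def propagate(a1: float, b1: float) -> tuple[float, float]:
            a, b = a1, b1
            for k in range(n_shells - 1):
                r = radii_scaled[k]
                s = sigmas[k] / sigmas[k + 1]
                lhs = np.array(
                    [
                        [r**n, r ** (-(n + 1))],
                        [n * r ** (n - 1), -(n + 1) * r ** (-(n + 2))],
                    ]
                )
                rhs = np.array(
                    [
                        a * r**n + b * r ** (-(n + 1)),
                        s * (n * a * r ** (n - 1) - (n + 1) * b * r ** (-(n + 2))),
                    ]
                )
                a, b = np.linalg.solve(lhs, rhs)
            return a, b

        pa, pb = propagate(0.0, 1.0)  # contribution of the source term
        qa, qb = propagate(1.0, 0.0)  # contribution of the interior regular term
        denom = n * qa - (n + 1) * qb
        a1 = -(n * pa - (n + 1) * pb) / denom
        an, bn = pa + a1 * qa, pb + a1 * qb
        coeffs[n] = an + bn  # potential at scaled radius 1
    return coeffs


def multishell_dipole_potential(
    electrode_dirs: np.ndarray,
    dipole_pos: np.ndarray,
    dipole_moment: np.ndarray,
    radii: tuple[float, ...] = (0.087, 0.092, 0.100),
    conductivities: tuple[float, ...] = (0.33, 0.33 / 80, 0.33),
    n_terms: int = 60,
    tail_tol: float = 1e-4,
) -> np.ndarray:
    """Scalp potential of one current dipole inside a layered sphere.

    ``electrode_dirs`` are unit vectors to electrodes on the outer surface;
    ``dipole_pos`` in meters (strictly inside the innermost shell),
    ``dipole_moment`` in A*m.  Series truncated at ``n_terms`` Legendre
    degrees with a tail-magnitude convergence check.
    """
    radii = np.asarray(radii, float)
    sigmas = np.asarray(conductivities, float)
    R = radii[-1]
    e = np.asarray(electrode_dirs, float)
    e = e / np.linalg.norm(e, axis=1, keepdims=True)
    p = np.asarray(dipole_pos, float)
    q = np.asarray(dipole_moment, float)
    b = np.linalg.norm(p)
    if b >= radii[0]:
        raise ValueError(
            f"dipole at radius {b:.4g} m is not strictly inside the innermost "
            f"shell (radius {radii[0]:.4g} m)"
        )

    if b < 1e-12 * R:
        # dipole at the center: the radial axis is arbitrary, align it with q
        zhat = q / np.linalg.norm(q)
        m_r, q_t = float(np.linalg.norm(q)), np.zeros(3)
    else:
        zhat = p / b
        m_r = float(q @ zhat)
        q_t = q - m_r * zhat
    m_t = float(np.linalg.norm(q_t))
    xhat = q_t / m_t if m_t > 0 else np.zeros(3)

    cosg = np.clip(e @ zhat, -1.0, 1.0)
    e_t = e - np.outer(cosg, zhat)
    et_norm = np.linalg.norm(e_t, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosphi = np.where(et_norm > 1e-12, (e_t @ xhat) / np.maximum(et_norm, 1e-300), 0.0)

    bs = b / R
    ns = np.arange(1, n_terms + 1)
    c = _cached_shell_coeffs(n_terms, tuple(radii / R), tuple(sigmas))[1:]
    radial_w = c * ns * m_r * bs ** (ns - 1)
    # lpmv includes the Condon-Shortley phase: lpmv(1,n,x) = -sqrt(1-x^2) P_n'(x)
    tang_w = -c * m_t * bs ** (ns - 1)

    tail = (abs(radial_w[-1]) + abs(tang_w[-1]))
    head = max(np.abs(radial_w).max(), np.abs(tang_w).max(), 1e-300)
    if tail / head > tail_tol:
        raise ValueError(
            f"Legendre series not converged after {n_terms} terms "
            f"(tail/head = {tail / head:.2e}); increase n_terms"
        )

    pn, pn1 = _legendre_tables(n_terms, cosg)
    v = pn @ radial_w + (pn1 @ tang_w) * cosphi
    return v / (4 * np.pi * sigmas[0] * R**2)


def build_spherical_leadfield(
    montage: Montage,
    source_space: SourceSpace,
    radii: tuple[float, ...] = (0.087, 0.092, 0.100),
    conductivities: tuple[float, ...] = (0.33, 0.33 / 80, 0.33),
    n_terms: int = 60,
    moment_scale: float = 1e-9,
) -> LeadField:
    """Analytic lead field: one fixed-orientation dipole per vertex.

    Dipole orientations follow the source space's stored normals (radial
    for the built-in Fibonacci shell).  ``moment_scale`` sets the unit
    dipole moment in A*m (default 1 nA*m, so gain is in V per nA*m).
    """
    pos = source_space.vertex_positions
    if np.linalg.norm(pos, axis=1).max() >= radii[0]:
        raise ValueError("all source vertices must lie strictly inside the innermost shell")
    gain = np.empty((len(montage), source_space.n_vertices))
    edirs = montage.channel_positions / np.linalg.norm(
        montage.channel_positions, axis=1, keepdims=True
    )
    for j in range(source_space.n_vertices):
        gain[:, j] = multishell_dipole_potential(
            edirs,
            pos[j],
            moment_scale * source_space.vertex_orientations[j],
            radii=radii,
            conductivities=conductivities,
            n_terms=n_terms,
        )
    return LeadField(gain, montage, source_space=source_space)
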