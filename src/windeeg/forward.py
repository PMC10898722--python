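"""Forward modelling: scalp potentials from cortical dipoles.

The spherical mode implements the classical analytic solution for a current
dipole inside three concentric spherical shells (brain, skull, scalp) with
piecewise-constant conductivity. For each spherical-harmonic degree n the
radial two-point boundary problem is solved exactly (a 5x5 linear system per
degree), and the scalp potential is accumulated as a Legendre series

    V(theta, phi) = 1/(4 pi sigma_1 R^2) * sum_n c_n (b/R)^(n-1)
                    [ n q_r P_n(cos theta) + q_t P_n^1(cos theta) cos phi ]

(P_n^1 without the Condon-Shortley sign, i.e. P_1^1 = sin theta)

where b is the dipole eccentricity, q_r/q_t its radial/tangential moment,
and c_n the (dimensionless) layered-conductor transfer coefficient. For a
homogeneous sphere c_n reduces to (2n+1)/n, the textbook result.

A seeded random mode (bounded condition number) is provided for fast tests
of the inverse machinery that do not need physical geometry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidGeometryError, InvalidParameterError
from .geometry import BRAIN_RADIUS, SCALP_RADIUS, SKULL_RADIUS, SourceSpace

#: Conductivities (S/m) of brain, skull, scalp.
CONDUCTIVITIES = (0.33, 0.0042, 0.33)

#: 64-channel subset of the extended 10/10 electrode system.
CHANNEL_NAMES_64 = (
    "Fp1", "Fpz", "Fp2",
    "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "O1", "Oz", "O2",
    "P9", "P10", "Iz",
)


@dataclass
class ForwardModel:
    """Lead field mapping fixed-orientation dipole moments to scalp potentials.

    ``lead_field`` is (n_channels, n_sources) in sensor units per unit dipole
    moment; column j corresponds to source j of the originating space.
    """

    lead_field: np.ndarray
    channel_names: tuple[str, ...]
    channel_positions: np.ndarray
    shell_radii: tuple[float, float, float] = (BRAIN_RADIUS, SKULL_RADIUS, SCALP_RADIUS)
    conductivities: tuple[float, float, float] = CONDUCTIVITIES
    mode: str = "spherical"
    roi_patterns: dict = field(default_factory=dict, repr=False)

    @property
    def n_channels(self) -> int:
        return self.lead_field.shape[0]

    @property
    def n_sources(self) -> int:
        return self.lead_field.shape[1]


def standard_channel_positions(
    n_channels: int = 64, scalp_radius: float = SCALP_RADIUS
) -> tuple[tuple[str, ...], np.ndarray]:
    """Names and spherical-scalp positions of the 64 default electrodes.

    Positions come from the template 10/10 montage and are projected radially
    onto the scalp sphere of the head model.
    """
    if n_channels != len(CHANNEL_NAMES_64):
        raise InvalidParameterError(
            f"only the {len(CHANNEL_NAMES_64)}-channel montage is built in; "
            f"got n_channels={n_channels}"
        )
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        montage = mne.channels.make_standard_montage("standard_1020")
    pos = montage.get_positions()["ch_pos"]
    xyz = np.array([pos[name] for name in CHANNEL_NAMES_64])
    xyz = xyz / np.linalg.norm(xyz, axis=1, keepdims=True) * scalp_radius
    return CHANNEL_NAMES_64, xyz


def _layered_transfer_coefficients(
    n_max: int,
    radii: tuple[float, float, float],
    sigmas: tuple[float, float, float],
) -> np.ndarray:
    """Transfer coefficients c_n (n = 1..n_max) of the 3-shell conductor.

    Radii are normalised to the outer radius; c_n is the scalp-surface
    coefficient for a unit source term r^-(n+1) in the inner layer.
    """
    r1, r2, r3 = (r / radii[2] for r in radii)
    s1, s2, s3 = sigmas
    out = np.empty(n_max + 1)
    out[0] = 0.0
    for n in range(1, n_max + 1):
        # unknowns x = [A1, A2, B2, A3, B3]
        a = np.zeros((5, 5))
        b = np.zeros(5)
        # potential continuity at r1: A1 r1^n + r1^-(n+1) = A2 r1^n + B2 r1^-(n+1)
        a[0] = [r1**n, -(r1**n), -(r1 ** -(n + 1)), 0.0, 0.0]
        b[0] = -(r1 ** -(n + 1))
        # radial current continuity at r1
        a[1] = [
            s1 * n * r1 ** (n - 1),
            -s2 * n * r1 ** (n - 1),
            s2 * (n + 1) * r1 ** -(n + 2),
            0.0,
            0.0,
        ]
        b[1] = s1 * (n + 1) * r1 ** -(n + 2)
        # potential continuity at r2
        a[2] = [0.0, r2**n, r2 ** -(n + 1), -(r2**n), -(r2 ** -(n + 1))]
        # current continuity at r2
        a[3] = [
            0.0,
            s2 * n * r2 ** (n - 1),
            -s2 * (n + 1) * r2 ** -(n + 2),
            -s3 * n * r2 ** (n - 1),
            s3 * (n + 1) * r2 ** -(n + 2),
        ]
        # no current through the scalp surface at r3
        a[4] = [0.0, 0.0, 0.0, s3 * n * r3 ** (n - 1), -s3 * (n + 1) * r3 ** -(n + 2)]
        x = np.linalg.solve(a, b)
        out[n] = x[3] * r3**n + x[4] * r3 ** -(n + 1)
    return out


def _layered_solution(n: int, radii, sigmas) -> np.ndarray:
    """Full per-layer coefficients [A1, A2, B2, A3, B3] for one degree (tests)."""
    r1, r2, r3 = (r / radii[2] for r in radii)
    s1, s2, s3 = sigmas
    a = np.zeros((5, 5))
    b = np.zeros(5)
    a[0] = [r1**n, -(r1**n), -(r1 ** -(n + 1)), 0.0, 0.0]
    b[0] = -(r1 ** -(n + 1))
    a[1] = [s1 * n * r1 ** (n - 1), -s2 * n * r1 ** (n - 1),
            s2 * (n + 1) * r1 ** -(n + 2), 0.0, 0.0]
    b[1] = s1 * (n + 1) * r1 ** -(n + 2)
    a[2] = [0.0, r2**n, r2 ** -(n + 1), -(r2**n), -(r2 ** -(n + 1))]
    a[3] = [0.0, s2 * n * r2 ** (n - 1), -s2 * (n + 1) * r2 ** -(n + 2),
            -s3 * n * r2 ** (n - 1), s3 * (n + 1) * r2 ** -(n + 2)]
    a[4] = [0.0, 0.0, 0.0, s3 * n * r3 ** (n - 1), -s3 * (n + 1) * r3 ** -(n + 2)]
    return np.linalg.solve(a, b)


def sphere_dipole_potential(
    dipole_positions: np.ndarray,
    dipole_moments: np.ndarray,
    electrode_positions: np.ndarray,
    radii: tuple[float, float, float] = (BRAIN_RADIUS, SKULL_RADIUS, SCALP_RADIUS),
    sigmas: tuple[float, float, float] = CONDUCTIVITIES,
    n_terms: int = 80,
) -> np.ndarray:
    """Scalp potentials of dipoles in the 3-shell spherical conductor.

    Parameters
    ----------
    dipole_positions : (n_dip, 3) positions in metres, inside the inner shell.
    dipole_moments : (n_dip, 3) dipole moment vectors.
    electrode_positions : (n_elec, 3) points on the scalp sphere.

    Returns
    -------
    (n_elec, n_dip) potential matrix.
    """
    dipole_positions = np.atleast_2d(np.asarray(dipole_positions, float))
    dipole_moments = np.atleast_2d(np.asarray(dipole_moments, float))
    elec = np.asarray(electrode_positions, float)
    R = radii[2]

    ecc = np.linalg.norm(dipole_positions, axis=1)
    if np.any(ecc >= radii[0]):
        raise InvalidGeometryError(
            "dipole at eccentricity "
            f"{ecc.max():.4f} m lies outside the inner shell ({radii[0]} m)"
        )

    # dipole-local frames: z' along the dipole radius, x' along the
    # tangential moment component
    zp = np.zeros_like(dipole_positions)
    deep = ecc < 1e-12
    zp[~deep] = dipole_positions[~deep] / ecc[~deep, None]
    zp[deep] = [0.0, 0.0, 1.0]  # axis arbitrary for a central dipole

    q_r = np.einsum("ij,ij->i", dipole_moments, zp)
    q_tan_vec = dipole_moments - q_r[:, None] * zp
    q_t = np.linalg.norm(q_tan_vec, axis=1)
    xp = np.zeros_like(zp)
    has_tan = q_t > 1e-15 * np.maximum(np.linalg.norm(dipole_moments, axis=1), 1e-300)
    xp[has_tan] = q_tan_vec[has_tan] / q_t[has_tan, None]

    e_hat = elec / np.linalg.norm(elec, axis=1, keepdims=True)
    cos_t = e_hat @ zp.T  # (n_elec, n_dip)
    cos_t = np.clip(cos_t, -1.0, 1.0)
    # azimuth of each electrode in the dipole frame
    e_perp = e_hat[:, None, :] - cos_t[:, :, None] * zp[None, :, :]
    perp_norm = np.linalg.norm(e_perp, axis=2)
    sin_t = np.clip(perp_norm, 0.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos_phi = np.einsum("edk,dk->ed", e_perp, xp) / np.where(
            perp_norm > 1e-12, perp_norm, 1.0
        )

    c = _layered_transfer_coefficients(n_terms, radii, sigmas)
    b_over_R = ecc / R

    # Legendre recurrences, vectorised over (electrode, dipole)
    p_prev = np.ones_like(cos_t)       # P_0
    p_curr = cos_t.copy()              # P_1
    p1_prev = np.zeros_like(cos_t)     # P_0^1
    p1_curr = sin_t.copy()             # P_1^1 (without Condon-Shortley sign)

    v = np.zeros_like(cos_t)
    radial_pow = np.ones(len(ecc))  # (b/R)^(n-1)
    for n in range(1, n_terms + 1):
        term = c[n] * radial_pow[None, :] * (
            n * q_r[None, :] * p_curr + q_t[None, :] * p1_curr * cos_phi
        )
        v += term
        radial_pow = radial_pow * b_over_R
        if n < n_terms:
            p_next = ((2 * n + 1) * cos_t * p_curr - n * p_prev) / (n + 1)
            p1_next = ((2 * n + 1) * cos_t * p1_curr - (n + 1) * p1_prev) / n
            p_prev, p_curr = p_curr, p_next
            p1_prev, p1_curr = p1_curr, p1_next

    return v / (4.0 * np.pi * sigmas[0] * R**2)


def build_lead_field(
    space: SourceSpace,
    n_channels: int = 64,
    model: str = "spherical",
    seed: int = 0,
    n_terms: int = 80,
) -> ForwardModel:
    """Lead field for fixed-orientation dipoles at the source-space vertices.

    ``model="spherical"`` uses the analytic three-shell conductor;
    ``model="random"`` draws a seeded matrix with condition number <= 100
    (useful for inverse-solver tests that need no physical geometry).
    """
    if n_channels < 2:
        raise InvalidParameterError("need at least 2 channels")
    names, elec = standard_channel_positions(n_channels)

    if model == "spherical":
        gain = sphere_dipole_potential(
            space.vertices, space.orientations, elec, n_terms=n_terms
        )
    elif model == "random":
        rng = np.random.default_rng(seed)
        g = rng.standard_normal((n_channels, space.n_sources))
        u, s, vt = np.linalg.svd(g, full_matrices=False)
        s = np.geomspace(1.0, 0.01, len(s))
        gain = u @ (s[:, None] * vt)
    else:
        raise InvalidParameterError(f"unknown forward model {model!r}")

    if not np.all(np.isfinite(gain)):
        raise InvalidGeometryError("lead field contains non-finite entries")
    if np.any(np.linalg.norm(gain, axis=0) == 0.0):
        raise InvalidGeometryError("lead field contains a zero column")

    return ForwardModel(
        lead_field=gain,
        channel_names=names,
        channel_positions=elec,
        mode=model,
    )
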