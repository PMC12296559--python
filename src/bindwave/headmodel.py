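"""Analytic spherical-head EEG forward model.

A single homogeneous conducting sphere stands in for a realistic BEM head
model: the surface potential of a current dipole inside a homogeneous sphere
has an exact closed form, so lead fields for a regular source grid can be
computed without any external geometry files.  The closed form is obtained by
summing the classical Legendre expansion of the eccentric-dipole potential
with generating functions; with ``x = b/R`` (source eccentricity), ``c`` the
cosine of the angle between source and electrode, and
``Q = sqrt(1 - 2xc + x^2)`` (electrode-source distance over ``R``),

    4*pi*sigma*R^2 * V = p_r * [2(c - x)/Q^3 + (1/Q - 1)/x]
                       + p_t*cos(phi)*sin(theta) * [2/Q^3 + (Q+1)/(Q(1-xc+Q))]

where ``p_r``/``p_t`` are the radial/tangential dipole components.  Potentials
are average-referenced, matching common EEG re-referencing practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SensorArray",
    "SourceGrid",
    "LeadField",
    "fibonacci_sensors",
    "build_grid",
    "octant_labels",
    "spherical_leadfield",
]


@dataclass(frozen=True)
class SensorArray:
    """EEG electrode positions on the scalp sphere.

    Parameters
    ----------
    positions : ndarray, shape (n_channels, 3)
        Electrode coordinates in meters, head-centered.
    names : tuple of str
        Unique channel labels.
    reference : str
        Reference scheme; only ``"average"`` is produced here.
    """

    positions: np.ndarray
    names: tuple
    reference: str = "average"

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError("positions must have shape (n_channels, 3)")
        if len(self.names) != pos.shape[0]:
            raise ValueError("number of names must match number of positions")
        if len(set(self.names)) != len(self.names):
            raise ValueError("channel names must be unique")

    @property
    def n_channels(self) -> int:
        return self.positions.shape[0]

    @property
    def radius(self) -> float:
        return float(np.linalg.norm(self.positions, axis=1).max())


@dataclass(frozen=True)
class SourceGrid:
    """Regular cubic lattice of candidate source locations inside the head.

    Voxels are ordered lexicographically by (x, y, z) so that voxel indices,
    spatial-filter rows and cluster identities are reproducible.
    """

    positions: np.ndarray
    spacing: float
    region_labels: np.ndarray | None = None

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.region_labels is not None:
            labels = np.asarray(self.region_labels)
            if labels.shape[0] != pos.shape[0]:
                raise ValueError("one region label per voxel required")
            object.__setattr__(self, "region_labels", labels)

    @property
    def n_voxels(self) -> int:
        return self.positions.shape[0]

    def with_labels(self, labels: np.ndarray) -> "SourceGrid":
        return SourceGrid(self.positions, self.spacing, np.asarray(labels))


@dataclass(frozen=True)
class LeadField:
    """Sensor gain of unit dipoles at every grid voxel.

    ``gain[i, v, k]`` is the average-referenced potential (V per A*m) at
    channel ``i`` from a unit dipole at voxel ``v`` oriented along axis ``k``.
    """

    gain: np.ndarray
    grid: SourceGrid
    sensors: SensorArray

    def __post_init__(self):
        g = np.asarray(self.gain, dtype=float)
        object.__setattr__(self, "gain", g)
        if g.shape != (self.sensors.n_channels, self.grid.n_voxels, 3):
            raise ValueError("gain must have shape (n_channels, n_voxels, 3)")

    @property
    def n_channels(self) -> int:
        return self.gain.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.gain.shape[1]


def fibonacci_sensors(
    n_channels: int = 60,
    radius: float = 0.09,
    cap_angle_deg: float = 130.0,
    prefix: str = "E",
) -> SensorArray:
    """Deterministic quasi-uniform electrode cap on the scalp sphere.

    A golden-angle spiral over the spherical cap extending ``cap_angle_deg``
    down from the vertex emulates an equidistant EEG cap layout.
    """
    if n_channels < 1:
        raise ValueError("need at least one channel")
    z_min = np.cos(np.deg2rad(cap_angle_deg))
    i = np.arange(n_channels)
    z = 1.0 - (1.0 - z_min) * (i + 0.5) / n_channels
    phi = i * np.pi * (3.0 - np.sqrt(5.0))  # golden angle
    s = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    pos = radius * np.column_stack([s * np.cos(phi), s * np.sin(phi), z])
    names = tuple(f"{prefix}{k + 1:03d}" for k in range(n_channels))
    return SensorArray(pos, names)


def build_grid(radius: float, spacing: float = 0.005) -> SourceGrid:
    """Cubic source lattice clipped to the open sphere ``|p| < radius``.

    Raises if no lattice point falls inside the sphere.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if radius <= 0:
        raise ValueError("radius must be positive")
    kmax = int(np.floor(radius / spacing))
    axis = np.arange(-kmax, kmax + 1) * spacing
    xx, yy, zz = np.meshgrid(axis, axis, axis, indexing="ij")
    pts = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    inside = np.einsum("ij,ij->i", pts, pts) < radius**2
    pts = pts[inside]
    if pts.shape[0] == 0:
        raise ValueError("no lattice point inside the sphere; increase radius")
    order = np.lexsort((pts[:, 2], pts[:, 1], pts[:, 0]))
    return SourceGrid(pts[order], spacing)


def octant_labels(grid: SourceGrid, excluded_label: str = "inferior-posterior") -> SourceGrid:
    """Attach geometric octant labels as an atlas substitute.

    Octants are named by sign pattern (e.g. ``oct+-+``); the inferior-posterior
    octant (x<0, z<0 quadrant, both y) is collapsed into a single label that
    callers may exclude, mimicking the removal of cerebellar voxels from an
    anatomical atlas.
    """
    p = grid.positions
    signs = np.where(p >= 0, "+", "-")
    labels = np.array(["oct" + "".join(row) for row in signs], dtype=object)
    inferior_posterior = (p[:, 0] < 0) & (p[:, 2] < 0)
    labels[inferior_posterior] = excluded_label
    return grid.with_labels(labels.astype(str))


def _dipole_potential(
    elec: np.ndarray, dip_pos: np.ndarray, sphere_radius: float, conductivity: float
) -> np.ndarray:
    """Potential at surface electrodes from unit dipoles along x/y/z.

    Returns shape (n_elec, n_dip, 3), not yet average-referenced.
    """
    n_e, n_d = elec.shape[0], dip_pos.shape[0]
    R = sphere_radius
    rhat = elec / np.linalg.norm(elec, axis=1, keepdims=True)  # (n_e, 3)
    b = np.linalg.norm(dip_pos, axis=1)  # (n_d,)
    out = np.empty((n_e, n_d, 3))
    scale = 1.0 / (4.0 * np.pi * conductivity * R**2)

    central = b < 1e-10 * R
    if np.any(central):
        # n=1 term only survives: V = 3 (p . rhat) / (4 pi sigma R^2)
        out[:, central, :] = 3.0 * scale * rhat[:, None, :]

    idx = np.where(~central)[0]
    if idx.size:
        bb = b[idx]
        u = dip_pos[idx] / bb[:, None]  # (m, 3)
        x = bb / R  # (m,)
        c = rhat @ u.T  # (n_e, m)
        Q = np.sqrt(np.clip(1.0 - 2.0 * x[None, :] * c + x[None, :] ** 2, 1e-300, None))
        S_r = 2.0 * (c - x[None, :]) / Q**3 + (1.0 / Q - 1.0) / x[None, :]
        T = 2.0 / Q**3 + (Q + 1.0) / (Q * (1.0 - x[None, :] * c + Q))
        # tangential electrode direction scaled by sin(theta): rhat - c*u
        tvec = rhat[:, None, :] - c[:, :, None] * u[None, :, :]  # (n_e, m, 3)
        # unit dipole along axis k: p_r = u_k, p_t_vec = e_k - u_k * u
        for k in range(3):
            p_r = u[:, k]  # (m,)
            pt = -p_r[:, None] * u  # (m, 3)
            pt[:, k] += 1.0
            out[:, idx, k] = scale * (
                p_r[None, :] * S_r + np.einsum("emj,mj->em", tvec, pt) * T
            )
    return out


def spherical_leadfield(
    grid: SourceGrid,
    sensors: SensorArray,
    sphere_radius: float | None = None,
    conductivity: float = 0.33,
) -> LeadField:
    """Closed-form homogeneous-sphere lead field, average-referenced.

    Parameters
    ----------
    sphere_radius : float, optional
        Scalp sphere radius (m).  Defaults to the sensor shell radius; the
        electrodes must lie on this sphere.
    conductivity : float
        Homogeneous volume conductivity (S/m); 0.33 is the conventional
        brain/scalp value.
    """
    R = sensors.radius if sphere_radius is None else float(sphere_radius)
    if conductivity <= 0:
        raise ValueError("conductivity must be positive")
    elec_r = np.linalg.norm(sensors.positions, axis=1)
    if np.any(elec_r < 0.999 * R) or np.any(elec_r > 1.001 * R):
        raise ValueError("sensors must lie on the scalp sphere surface")
    depth = np.linalg.norm(grid.positions, axis=1)
    if np.any(depth >= R * (1.0 - 1e-9)):
        raise ValueError("source voxels on or outside the sphere surface are singular")
    gain = _dipole_potential(sensors.positions, grid.positions, R, conductivity)
    gain -= gain.mean(axis=0, keepdims=True)  # average reference
    return LeadField(gain, grid, sensors)
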