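"""Nanoparticle geometry: patch layouts, rigid-body poses, box bookkeeping.

A nanoparticle is a rigid sphere of effective diameter ``d_np`` carrying
``n_sites`` ionizable surface sites.  The sites occupy a single spherical-cap
patch covering a fraction ``1 - theta`` of the surface, where ``theta`` is the
degree of patchiness: ``theta = 0`` spreads the sites over the whole sphere,
``theta = 0.9`` confines them to 10% of the surface.  Within the patch the
sites are spread approximately uniformly by minimizing the Thomson-style
objective ``sum_{i<j} 1/|r_i - r_j|`` under the cap constraint.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

AVOGADRO_PER_NM3_MOLAR = 0.6022140857  # N_A * 1 mol/L in particles per nm^3

__all__ = [
    "NanoparticleTemplate",
    "BoxSpec",
    "Pose",
    "place_patch_sites",
    "mean_site_distance",
    "box_from_salt",
    "volume_fraction",
    "world_site_positions",
    "cap_polar_angle",
]


class InvalidPatchinessError(ValueError):
    """theta outside [0, 1)."""


class EmptyTemplateError(ValueError):
    """A template must carry at least one ionizable site."""


def cap_polar_angle(theta: float) -> float:
    """Half-opening angle of the spherical cap with area fraction ``1 - theta``.

    The cap of polar half-angle ``t`` on the unit sphere has area
    ``2 pi (1 - cos t)``, i.e. area fraction ``(1 - cos t)/2``.  Setting this
    equal to ``1 - theta`` gives ``cos t = 1 - 2 (1 - theta)``.
    """
    if not 0.0 <= theta < 1.0:
        raise InvalidPatchinessError(f"degree of patchiness must be in [0, 1), got {theta}")
    return float(np.arccos(np.clip(1.0 - 2.0 * (1.0 - theta), -1.0, 1.0)))


def _project_to_cap(vecs: np.ndarray, cos_cap: float) -> np.ndarray:
    """Renormalize to the unit sphere and clamp polar angles to the cap.

    Points outside the cap are rotated toward the +z patch axis (along their
    meridian) onto the cap boundary; azimuth is preserved.
    """
    vecs = vecs / np.linalg.norm(vecs, axis=1, keepdims=True)
    z = vecs[:, 2]
    outside = z < cos_cap
    if np.any(outside):
        v = vecs[outside]
        rho = np.hypot(v[:, 0], v[:, 1])
        sin_cap = np.sqrt(max(0.0, 1.0 - cos_cap * cos_cap))
        # degenerate azimuth (point at -z): pick x-direction deterministically
        safe = rho > 1e-15
        ux = np.where(safe, v[:, 0] / np.where(safe, rho, 1.0), 1.0)
        uy = np.where(safe, v[:, 1] / np.where(safe, rho, 1.0), 0.0)
        v = np.stack([ux * sin_cap, uy * sin_cap, np.full(len(v), cos_cap)], axis=1)
        vecs = vecs.copy()
        vecs[outside] = v
    return vecs


def place_patch_sites(
    n_sites: int,
    theta: float,
    seed: int,
    max_iter: int = 10_000,
    tol: float = 1e-10,
) -> np.ndarray:
    """Spread ``n_sites`` unit vectors approximately uniformly over a cap.

    Minimizes ``sum_{i<j} 1 / |r_i - r_j|`` (electrostatic-style repulsion
    between the sites) by projected gradient descent on the unit sphere,
    constrained to the cap of area fraction ``1 - theta`` centered on +z.
    Deterministic for a fixed seed.

    Returns an ``(n_sites, 3)`` array of unit vectors.
    """
    if n_sites < 1:
        raise EmptyTemplateError("a template needs at least one ionizable site")
    if n_sites > 1000:
        raise ValueError("n_sites > 1000 not supported")
    t_cap = cap_polar_angle(theta)
    cos_cap = np.cos(t_cap)
    rng = np.random.default_rng(seed)

    if n_sites == 1:
        return np.array([[0.0, 0.0, 1.0]])

    # random init uniform over the cap (area-uniform in cos(polar angle))
    z = rng.uniform(cos_cap, 1.0, size=n_sites)
    phi = rng.uniform(0.0, 2.0 * np.pi, size=n_sites)
    rho = np.sqrt(1.0 - z * z)
    pts = np.stack([rho * np.cos(phi), rho * np.sin(phi), z], axis=1)

    def objective(p: np.ndarray) -> float:
        d = np.linalg.norm(p[:, None, :] - p[None, :, :], axis=-1)
        iu = np.triu_indices(n_sites, k=1)
        return float(np.sum(1.0 / d[iu]))

    step = 1e-2
    prev = objective(pts)
    for _ in range(max_iter):
        diff = pts[:, None, :] - pts[None, :, :]
        d = np.linalg.norm(diff, axis=-1)
        np.fill_diagonal(d, np.inf)
        # grad of sum 1/d wrt r_i  =  - sum_j (r_i - r_j) / d_ij^3
        grad = -np.sum(diff / d[:, :, None] ** 3, axis=1)
        # remove radial component (motion constrained to the sphere)
        grad -= pts * np.sum(grad * pts, axis=1, keepdims=True)
        trial = _project_to_cap(pts - step * grad, cos_cap)
        val = objective(trial)
        if val < prev:
            pts = trial
            if prev - val < tol * max(1.0, abs(prev)):
                prev = val
                break
            prev = val
            step *= 1.1
        else:
            step *= 0.5
            if step < 1e-14:
                break
    return pts


@dataclass(frozen=True)
class NanoparticleTemplate:
    """Rigid-body blueprint of a patchy nanoparticle.

    Parameters
    ----------
    core_diameter : float
        Effective core diameter ``d_np`` in nm (default 1.42 nm, four ion
        diameters).
    site_dirs : ndarray
        ``(n_sites, 3)`` unit vectors in the body frame; the patch axis is +z.
    theta : float
        Degree of patchiness in [0, 1).
    pKa : float
        Acidity constant exponent of the surface groups.
    charge_mode : str
        ``"titrating"`` (sites flip between HA and A-), ``"fixed_fraction"``
        (every site carries the constant partial charge ``-alpha_fixed``),
        or ``"neutral"``.
    """

    core_diameter: float = 1.42
    site_dirs: np.ndarray = field(default_factory=lambda: place_patch_sites(10, 0.0, 0))
    theta: float = 0.0
    pKa: float = 4.0
    charge_mode: str = "titrating"
    alpha_fixed: float = 0.0
    site_radius: float | None = None  # defaults to core_diameter / 2

    def __post_init__(self) -> None:
        dirs = np.asarray(self.site_dirs, dtype=float)
        object.__setattr__(self, "site_dirs", dirs)
        if dirs.ndim != 2 or dirs.shape[1] != 3 or len(dirs) == 0:
            raise EmptyTemplateError("site_dirs must be a non-empty (n, 3) array")
        norms = np.linalg.norm(dirs, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-12):
            raise ValueError("site directions must be unit vectors")
        cos_cap = np.cos(cap_polar_angle(self.theta))
        if np.any(dirs[:, 2] < cos_cap - 1e-9):
            raise ValueError("site directions must lie inside the patch cap")
        if self.charge_mode not in ("titrating", "fixed_fraction", "neutral"):
            raise ValueError(f"unknown charge_mode {self.charge_mode!r}")
        if self.charge_mode == "fixed_fraction" and not 0.0 <= self.alpha_fixed <= 1.0:
            raise ValueError("alpha_fixed must be in [0, 1]")
        if self.site_radius is None:
            object.__setattr__(self, "site_radius", self.core_diameter / 2.0)

    @property
    def n_sites(self) -> int:
        return len(self.site_dirs)

    @classmethod
    def build(
        cls,
        n_sites: int = 10,
        theta: float = 0.0,
        pKa: float = 4.0,
        core_diameter: float = 1.42,
        seed: int = 0,
        charge_mode: str = "titrating",
        alpha_fixed: float = 0.0,
        site_radius: float | None = None,
    ) -> "NanoparticleTemplate":
        """Place the patch sites and assemble a template."""
        return cls(
            core_diameter=core_diameter,
            site_dirs=place_patch_sites(n_sites, theta, seed),
            theta=theta,
            pKa=pKa,
            charge_mode=charge_mode,
            alpha_fixed=alpha_fixed,
            site_radius=site_radius,
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "core_diameter": self.core_diameter,
                "theta": self.theta,
                "pKa": self.pKa,
                "charge_mode": self.charge_mode,
                "alpha_fixed": self.alpha_fixed,
                "site_radius": self.site_radius,
                "site_dirs": [[float(f"{x:.12g}") for x in v] for v in self.site_dirs],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "NanoparticleTemplate":
        d = json.loads(text)
        dirs = np.asarray(d.pop("site_dirs"), dtype=float)
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        return cls(site_dirs=dirs, **d)


@dataclass(frozen=True)
class BoxSpec:
    """Cubic periodic simulation box; ``edge_length`` in nm."""

    edge_length: float
    periodic: bool = True

    def __post_init__(self) -> None:
        if self.edge_length <= 0:
            raise ValueError("edge_length must be positive")

    @property
    def volume(self) -> float:
        """Box volume in nm^3."""
        return self.edge_length**3


@dataclass
class Pose:
    """Rigid-body pose: center position (nm) and orientation quaternion.

    The quaternion is stored scalar-last ``(x, y, z, w)`` as in
    :class:`scipy.spatial.transform.Rotation`.
    """

    position: np.ndarray
    orientation: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 0.0, 1.0]))

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        q = np.asarray(self.orientation, dtype=float)
        n = np.linalg.norm(q)
        if abs(n - 1.0) > 1e-12:
            raise ValueError("orientation quaternion must have unit norm")
        self.orientation = q

    def rotation(self) -> Rotation:
        return Rotation.from_quat(self.orientation)


def world_site_positions(
    template: NanoparticleTemplate, pose: Pose, site_radius: float | None = None
) -> np.ndarray:
    """Site positions in the lab frame (not wrapped: rigid-body integrity)."""
    r = template.site_radius if site_radius is None else site_radius
    body = r * template.site_dirs
    return pose.position + pose.rotation().apply(body)


def mean_site_distance(
    template: NanoparticleTemplate, site_radius: float | None = None, bjerrum: float = 0.71
) -> dict:
    """Average distance between ionizable sites and its ratio to lambda_B.

    Returns both the mean nearest-neighbour distance (primary statistic
    ``d_q``) and the all-pairs mean (secondary), each in nm and in units of
    the Bjerrum length.
    """
    if template.n_sites < 2:
        raise ValueError("site distances undefined for fewer than 2 sites")
    r = template.site_radius if site_radius is None else site_radius
    pos = r * template.site_dirs
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    d_nn = float(np.mean(np.min(d, axis=1)))
    iu = np.triu_indices(template.n_sites, k=1)
    d_all = float(np.mean(d[iu]))
    return {
        "d_q": d_nn,
        "d_q_over_lB": d_nn / bjerrum,
        "d_allpairs": d_all,
        "d_allpairs_over_lB": d_all / bjerrum,
    }


def box_from_salt(c_salt: float, n_salt_pairs: int = 250) -> BoxSpec:
    """Box sized to hold ``n_salt_pairs`` NaCl pairs at reservoir concentration.

    ``V_box = N_salt / (N_A c_salt)``; ``c_salt`` in mol/L, edge in nm.
    """
    if c_salt <= 0:
        raise ValueError("c_salt must be positive")
    if n_salt_pairs < 1:
        raise ValueError("need at least one salt pair")
    volume = n_salt_pairs / (AVOGADRO_PER_NM3_MOLAR * c_salt)
    return BoxSpec(edge_length=volume ** (1.0 / 3.0))


def volume_fraction(n_np: int, d_np: float, box: BoxSpec) -> float:
    """Nanoparticle volume fraction ``n_np (pi/6) d_np^3 / V_box``."""
    if n_np < 0:
        raise ValueError("n_np must be non-negative")
    return n_np * (np.pi / 6.0) * d_np**3 / box.volume


def n_np_for_phi(phi: float, d_np: float, box: BoxSpec, minimum: int = 0) -> int:
    """Integer nanoparticle count closest to the requested volume fraction."""
    n = round(phi * box.volume / ((np.pi / 6.0) * d_np**3))
    return max(int(n), minimum)
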