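"""Synthetic 3D immuno-FISH scenes with exact ground truth.

The simulator emulates fixed U2OS-like cells imaged in three
fluorescence channels: a DNA counterstain filling each nucleus, FISH
foci marking gene loci (or transcriptional foci), and immunostained
nuclear bodies.  Nuclei are random ellipsoids flattened along z; bodies
and foci are diffraction-limited points rendered as anisotropic
Gaussians with Poisson shot noise and Gaussian read noise.

Foci are placed in one of two modes:

``csr``
    complete spatial randomness — uniform over the nucleus interior,
    the behaviour expected of a locus with no relationship to the
    bodies (the unassociated control, e.g. *BCL2*);
``tethered``
    each focus is displaced from a uniformly chosen body by a distance
    drawn from a truncated normal (mean/sd configurable, support >= 0)
    in a uniform random 3D direction, rejection-sampled to remain
    inside the nucleus (the associated case, e.g. *DDIT4*).

Every generated object position is recorded, together with each focus's
true nearest-body distance, so downstream detection and proximity
statistics can be validated against exact ground truth.

Coordinates are micrometres, axis order ``(z, y, x)``, and voxel ``i``
is centred at ``(i + 0.5) * voxel_size``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import truncnorm

from .image_ops import ImageStack

__all__ = [
    "SceneConfig",
    "Nucleus",
    "PointObject",
    "GroundTruthScene",
    "PlacementError",
    "generate_scene",
    "generate_truth",
    "place_foci",
    "render",
    "truth_to_label_map",
]

CHANNEL_NAMES = ("dna", "foci", "bodies")

#: rejection-sampling budget per object before giving up loudly
MAX_ATTEMPTS = 10_000


class PlacementError(RuntimeError):
    """Raised when rejection sampling cannot place an object.

    Signals an infeasible configuration (field too small, tether mean
    too large for the nucleus, minimum separation too strict) rather
    than silently degrading the geometry.
    """


def _as_range(value: int | tuple[int, int]) -> tuple[int, int]:
    if isinstance(value, (tuple, list)):
        lo, hi = int(value[0]), int(value[1])
    else:
        lo = hi = int(value)
    if lo < 0 or hi < lo:
        raise ValueError(f"invalid count range {value!r}")
    return lo, hi


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of one synthetic field of view.

    Defaults emulate a 63x widefield z-stack of a single flat U2OS-like
    nucleus containing ~10 nuclear bodies.  With 10 bodies uniformly
    distributed in an ellipsoid of these dimensions, the expected
    CSR focus-to-nearest-body distance is close to 2 um, matching the
    distance regime reported for unassociated loci; the tethered mode
    default of 1.4 um matches the associated regime.

    Attributes
    ----------
    field_shape
        Voxels per axis (z, y, x).
    voxel_size
        Micrometres per voxel per axis (z, y, x).
    n_nuclei
        Number of non-overlapping nuclei to place.
    nucleus_radii_um
        ``((z_min, z_max), (xy_min, xy_max))`` semi-axis ranges; each
        nucleus draws its z semi-axis from the first range and its two
        lateral semi-axes independently from the second.
    n_bodies_per_nucleus, n_foci_per_nucleus
        Fixed count or inclusive ``(lo, hi)`` range.
    placement_mode
        ``"csr"`` or ``"tethered"`` (see module docstring).
    tether_mean_um, tether_sd_um
        Parameters of the truncated-normal tether distance (tethered
        mode only).
    min_separation_um
        Minimum pairwise distance enforced among objects of the same
        class within a nucleus, so that distinct objects remain
        resolvable after blurring.
    psf_sigma_um
        Per-axis Gaussian PSF sigma.
    background_level, photon_scale, read_noise_sd, shot_noise
        Noise model: each point object integrates to ``photon_scale``
        counts; Poisson noise is applied to signal + background when
        ``shot_noise`` is true; read noise is additive Gaussian.
    dna_level
        Plateau intensity of the rendered nuclear counterstain.
    seed
        Default RNG seed (overridable per call).
    """

    field_shape: tuple[int, int, int] = (32, 176, 176)
    voxel_size: tuple[float, float, float] = (0.25, 0.10, 0.10)
    n_nuclei: int = 1
    nucleus_radii_um: tuple[tuple[float, float], tuple[float, float]] = (
        (2.2, 2.6),
        (6.0, 7.5),
    )
    n_bodies_per_nucleus: int | tuple[int, int] = 10
    n_foci_per_nucleus: int | tuple[int, int] = 2
    placement_mode: str = "csr"
    tether_mean_um: float = 1.4
    tether_sd_um: float = 0.3
    min_separation_um: float = 0.6
    psf_sigma_um: tuple[float, float, float] = (0.35, 0.13, 0.13)
    background_level: float = 10.0
    photon_scale: float = 5000.0
    read_noise_sd: float = 2.0
    shot_noise: bool = True
    dna_level: float = 150.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.field_shape) != 3 or any(int(s) <= 0 for s in self.field_shape):
            raise ValueError(f"field_shape must be 3 positive ints, got {self.field_shape}")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size entries must be strictly positive")
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be >= 0")
        (z_lo, z_hi), (xy_lo, xy_hi) = self.nucleus_radii_um
        if not (0 < z_lo <= z_hi and 0 < xy_lo <= xy_hi):
            raise ValueError(f"invalid nucleus_radii_um {self.nucleus_radii_um}")
        _as_range(self.n_bodies_per_nucleus)
        _as_range(self.n_foci_per_nucleus)
        if self.placement_mode not in ("csr", "tethered"):
            raise ValueError(f"unknown placement_mode {self.placement_mode!r}")
        if self.placement_mode == "tethered":
            if self.tether_mean_um < 0 or self.tether_sd_um < 0:
                raise ValueError("tether parameters must be non-negative")
            if self.tether_mean_um >= max(z_hi, xy_hi):
                raise ValueError(
                    f"tether_mean_um={self.tether_mean_um} must be smaller than "
                    f"the maximum nucleus semi-axis {max(z_hi, xy_hi)}"
                )
        if any(s <= 0 for s in self.psf_sigma_um):
            raise ValueError("psf_sigma_um entries must be strictly positive")
        if min(self.background_level, self.photon_scale, self.read_noise_sd) < 0:
            raise ValueError("noise parameters must be non-negative")

    @property
    def field_size_um(self) -> np.ndarray:
        return np.asarray(self.field_shape) * np.asarray(self.voxel_size)

    @property
    def half_voxel_diag_um(self) -> float:
        return float(np.linalg.norm(np.asarray(self.voxel_size)) / 2)

    def with_(self, **kwargs) -> "SceneConfig":
        return replace(self, **kwargs)


@dataclass
class Nucleus:
    id: int
    center_um: np.ndarray
    semi_axes_um: np.ndarray

    def contains(self, points: np.ndarray, margin_um: float = 0.0) -> np.ndarray:
        """True where points lie inside the ellipsoid shrunk by ``margin_um``."""
        pts = np.atleast_2d(points)
        semi = np.maximum(self.semi_axes_um - margin_um, 1e-9)
        q = ((pts - self.center_um) / semi) ** 2
        return q.sum(axis=1) <= 1.0


@dataclass
class PointObject:
    id: int
    nucleus_id: int
    position_um: np.ndarray
    nearest_body_id: int | None = None
    nearest_distance_um: float | None = None


@dataclass
class GroundTruthScene:
    """True geometry of a simulated field: the recovery oracle."""

    nuclei: list[Nucleus]
    bodies: list[PointObject]
    foci: list[PointObject]
    config: SceneConfig

    def objects_frame(self) -> pd.DataFrame:
        rows = []
        for nuc in self.nuclei:
            rows.append(
                dict(object_id=nuc.id, object_class="nucleus", nucleus_id=nuc.id,
                     z_um=nuc.center_um[0], y_um=nuc.center_um[1], x_um=nuc.center_um[2],
                     semi_z_um=nuc.semi_axes_um[0], semi_y_um=nuc.semi_axes_um[1],
                     semi_x_um=nuc.semi_axes_um[2],
                     nearest_body_id=np.nan, nearest_distance_um=np.nan)
            )
        for cls, objs in (("body", self.bodies), ("focus", self.foci)):
            for o in objs:
                rows.append(
                    dict(object_id=o.id, object_class=cls, nucleus_id=o.nucleus_id,
                         z_um=o.position_um[0], y_um=o.position_um[1], x_um=o.position_um[2],
                         semi_z_um=np.nan, semi_y_um=np.nan, semi_x_um=np.nan,
                         nearest_body_id=o.nearest_body_id if o.nearest_body_id is not None else np.nan,
                         nearest_distance_um=o.nearest_distance_um if o.nearest_distance_um is not None else np.nan)
                )
        return pd.DataFrame(rows)

    def true_nearest_distances(self) -> np.ndarray:
        return np.array([f.nearest_distance_um for f in self.foci], dtype=float)

    def per_nucleus_mean_distance(self) -> dict[int, float]:
        acc: dict[int, list[float]] = {}
        for f in self.foci:
            acc.setdefault(f.nucleus_id, []).append(float(f.nearest_distance_um))
        return {k: float(np.mean(v)) for k, v in acc.items()}


# ---------------------------------------------------------------------------
# geometry sampling

def _unit_vectors(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    norms = np.linalg.norm(v, axis=1, keepdims=True)
    # resample the (measure-zero) degenerate draws
    while (bad := norms[:, 0] < 1e-12).any():
        v[bad] = rng.normal(size=(int(bad.sum()), 3))
        norms = np.linalg.norm(v, axis=1, keepdims=True)
    return v / norms


def _sample_in_ellipsoid(
    rng: np.random.Generator,
    center: np.ndarray,
    semi_axes: np.ndarray,
    n: int = 1,
) -> np.ndarray:
    """Uniform samples inside an axis-aligned ellipsoid.

    Uniform-in-ball samples (direction x cube-root radius) are mapped by
    the diagonal linear map ``diag(semi_axes)``, which preserves
    uniformity.
    """
    direction = _unit_vectors(rng, n)
    radius = rng.uniform(size=(n, 1)) ** (1.0 / 3.0)
    return center + direction * radius * semi_axes


def _sample_separated(
    rng: np.random.Generator,
    propose,
    n: int,
    min_sep: float,
    what: str,
) -> np.ndarray:
    """Sequentially draw ``n`` points keeping pairwise distance >= min_sep."""
    points: list[np.ndarray] = []
    for _ in range(n):
        for _attempt in range(MAX_ATTEMPTS):
            p = propose()
            if p is None:
                continue
            if not points or min_sep <= 0:
                points.append(p)
                break
            d = np.linalg.norm(np.vstack(points) - p, axis=1)
            if d.min() >= min_sep:
                points.append(p)
                break
        else:
            raise PlacementError(
                f"could not place {what} after {MAX_ATTEMPTS} attempts; "
                f"the configuration is too crowded (check field size, nucleus "
                f"radii, min_separation_um and tether parameters)"
            )
    return np.vstack(points) if points else np.empty((0, 3))


def _place_nuclei(cfg: SceneConfig, rng: np.random.Generator) -> list[Nucleus]:
    (z_lo, z_hi), (xy_lo, xy_hi) = cfg.nucleus_radii_um
    field = cfg.field_size_um
    nuclei: list[Nucleus] = []
    for k in range(1, cfg.n_nuclei + 1):
        semi = np.array([
            rng.uniform(z_lo, z_hi),
            rng.uniform(xy_lo, xy_hi),
            rng.uniform(xy_lo, xy_hi),
        ])
        if (2 * semi > field).any():
            raise PlacementError(
                f"nucleus semi-axes {semi} do not fit in the field {field} um; "
                "enlarge field_shape or shrink nucleus_radii_um"
            )
        for _attempt in range(MAX_ATTEMPTS):
            center = rng.uniform(semi, field - semi)
            # conservative ellipsoid-overlap proxy: normalized centre distance
            ok = True
            for other in nuclei:
                delta = center - other.center_um
                scale = semi + other.semi_axes_um
                if ((delta / scale) ** 2).sum() < 1.0:
                    ok = False
                    break
            if ok:
                nuclei.append(Nucleus(id=k, center_um=center, semi_axes_um=semi))
                break
        else:
            raise PlacementError(
                f"could not place nucleus {k} of {cfg.n_nuclei} after "
                f"{MAX_ATTEMPTS} attempts; the field is too crowded for "
                "n_nuclei at these nucleus_radii_um"
            )
    return nuclei


def _truncated_normal_distance(
    rng: np.random.Generator, mean: float, sd: float
) -> float:
    if sd == 0:
        return mean
    a = (0.0 - mean) / sd
    return float(truncnorm.rvs(a, np.inf, loc=mean, scale=sd, random_state=rng))


def place_foci(
    nucleus: Nucleus,
    bodies: np.ndarray,
    mode: str,
    rng: np.random.Generator,
    n: int = 1,
    tether_mean_um: float = 1.4,
    tether_sd_um: float = 0.3,
    min_separation_um: float = 0.0,
    margin_um: float = 0.0,
) -> np.ndarray:
    """Place ``n`` focus positions inside a nucleus.

    ``csr`` mode draws uniformly over the nucleus ellipsoid (shrunk by
    ``margin_um``).  ``tethered`` mode displaces each focus from a
    uniformly chosen body by a truncated-normal distance in a uniform
    random direction, rejection-sampling the displacement until the
    focus lies inside the nucleus.
    """
    bodies = np.atleast_2d(bodies) if np.size(bodies) else np.empty((0, 3))
    if mode == "tethered" and bodies.shape[0] == 0:
        raise ValueError("tethered placement requires at least one body in the nucleus")
    semi = nucleus.semi_axes_um

    if mode == "csr":
        def propose():
            return _sample_in_ellipsoid(
                rng, nucleus.center_um, np.maximum(semi - margin_um, 1e-9)
            )[0]
    elif mode == "tethered":
        def propose():
            anchor = bodies[rng.integers(bodies.shape[0])]
            d = _truncated_normal_distance(rng, tether_mean_um, tether_sd_um)
            p = anchor + d * _unit_vectors(rng, 1)[0]
            return p if nucleus.contains(p, margin_um=margin_um)[0] else None
    else:
        raise ValueError(f"unknown placement mode {mode!r}")

    return _sample_separated(rng, propose, n, min_separation_um, f"focus in nucleus {nucleus.id}")


def _nearest_body(
    position: np.ndarray, body_positions: np.ndarray, body_ids: np.ndarray
) -> tuple[float, int]:
    d = cdist(position[None], body_positions)[0]
    order = np.argsort(body_ids)
    best = order[np.argmin(d[order])]  # ties -> lowest body id
    return float(d[best]), int(body_ids[best])


def generate_truth(
    cfg: SceneConfig, seed: int | None | np.random.Generator = None
) -> GroundTruthScene:
    """Sample scene geometry only (no rendering).

    Object positions are kept at least half a voxel diagonal inside
    their nucleus ellipsoid so that every object also falls inside the
    rasterized nuclear mask.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(
        cfg.seed if seed is None else seed
    )
    margin = cfg.half_voxel_diag_um
    nuclei = _place_nuclei(cfg, rng)
    bodies: list[PointObject] = []
    foci: list[PointObject] = []
    b_lo, b_hi = _as_range(cfg.n_bodies_per_nucleus)
    f_lo, f_hi = _as_range(cfg.n_foci_per_nucleus)
    body_id = 1
    focus_id = 1
    for nuc in nuclei:
        n_bodies = int(rng.integers(b_lo, b_hi + 1))
        n_foci = int(rng.integers(f_lo, f_hi + 1))

        def propose_body(nuc=nuc):
            return _sample_in_ellipsoid(
                rng, nuc.center_um, np.maximum(nuc.semi_axes_um - margin, 1e-9)
            )[0]

        body_pos = _sample_separated(
            rng, propose_body, n_bodies, cfg.min_separation_um,
            f"body in nucleus {nuc.id}",
        )
        ids = np.arange(body_id, body_id + n_bodies)
        for i, p in zip(ids, body_pos):
            bodies.append(PointObject(id=int(i), nucleus_id=nuc.id, position_um=p))
        body_id += n_bodies

        if n_foci:
            focus_pos = place_foci(
                nuc, body_pos, cfg.placement_mode, rng, n=n_foci,
                tether_mean_um=cfg.tether_mean_um, tether_sd_um=cfg.tether_sd_um,
                min_separation_um=cfg.min_separation_um, margin_um=margin,
            )
            for p in focus_pos:
                if n_bodies:
                    dist, nb = _nearest_body(p, body_pos, ids)
                else:
                    dist, nb = None, None
                foci.append(
                    PointObject(
                        id=focus_id, nucleus_id=nuc.id, position_um=p,
                        nearest_body_id=nb, nearest_distance_um=dist,
                    )
                )
                focus_id += 1
    return GroundTruthScene(nuclei=nuclei, bodies=bodies, foci=foci, config=cfg)


# ---------------------------------------------------------------------------
# rendering

def _axis_centers_um(n: int, voxel: float) -> np.ndarray:
    return (np.arange(n) + 0.5) * voxel


def _add_gaussian_spot(
    volume: np.ndarray,
    position_um: np.ndarray,
    sigma_um: np.ndarray,
    voxel_size: np.ndarray,
    integrated: float,
) -> None:
    """Accumulate a separable anisotropic Gaussian of given integral."""
    shape = np.asarray(volume.shape)
    centre_vox = position_um / voxel_size - 0.5
    half_width = np.maximum(np.ceil(4 * sigma_um / voxel_size).astype(int), 2)
    lo = np.maximum(np.floor(centre_vox).astype(int) - half_width, 0)
    hi = np.minimum(np.floor(centre_vox).astype(int) + half_width + 1, shape)
    if (lo >= hi).any():
        return
    profiles = []
    for ax in range(3):
        x = _axis_centers_um(shape[ax], voxel_size[ax])[lo[ax]:hi[ax]]
        profiles.append(np.exp(-0.5 * ((x - position_um[ax]) / sigma_um[ax]) ** 2))
    norm = integrated * np.prod(voxel_size) / (
        (2 * np.pi) ** 1.5 * np.prod(sigma_um)
    )
    volume[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += norm * (
        profiles[0][:, None, None] * profiles[1][None, :, None] * profiles[2][None, None, :]
    )


def _ellipsoid_mask_in_box(
    nucleus: Nucleus, shape: tuple[int, int, int], voxel_size: np.ndarray
) -> tuple[tuple[slice, slice, slice], np.ndarray]:
    lo = np.maximum(
        np.floor((nucleus.center_um - nucleus.semi_axes_um) / voxel_size).astype(int), 0
    )
    hi = np.minimum(
        np.ceil((nucleus.center_um + nucleus.semi_axes_um) / voxel_size).astype(int) + 1,
        np.asarray(shape),
    )
    axes = [
        (_axis_centers_um(shape[ax], voxel_size[ax])[lo[ax]:hi[ax]]
         - nucleus.center_um[ax]) / nucleus.semi_axes_um[ax]
        for ax in range(3)
    ]
    q = (
        axes[0][:, None, None] ** 2
        + axes[1][None, :, None] ** 2
        + axes[2][None, None, :] ** 2
    )
    box = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    return box, q <= 1.0


def render(
    truth: GroundTruthScene,
    cfg: SceneConfig | None = None,
    rng: int | None | np.random.Generator = None,
) -> ImageStack:
    """Render a ground-truth scene into a 3-channel stack (dna, foci, bodies).

    Nuclei are filled ellipsoids in the DNA channel; each body/focus is
    an anisotropic Gaussian integrating to ``photon_scale`` counts.
    Poisson noise is applied to signal + background (when enabled) and
    Gaussian read noise added; intensities are clipped at zero.
    """
    cfg = cfg or truth.config
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    shape = tuple(int(s) for s in cfg.field_shape)
    voxel = np.asarray(cfg.voxel_size)
    sigma = np.asarray(cfg.psf_sigma_um)
    data = np.zeros((3,) + shape, dtype=float)

    for nuc in truth.nuclei:
        box, mask = _ellipsoid_mask_in_box(nuc, shape, voxel)
        data[0][box][mask] += cfg.dna_level
    for chan, objects in ((1, truth.foci), (2, truth.bodies)):
        for obj in objects:
            _add_gaussian_spot(data[chan], obj.position_um, sigma, voxel, cfg.photon_scale)

    data += cfg.background_level
    if cfg.shot_noise:
        data = rng.poisson(data).astype(float)
    if cfg.read_noise_sd > 0:
        data += rng.normal(0.0, cfg.read_noise_sd, size=data.shape)
    np.clip(data, 0.0, None, out=data)
    return ImageStack(data=data, voxel_size=cfg.voxel_size, channel_names=CHANNEL_NAMES)


def generate_scene(
    cfg: SceneConfig, seed: int | None = None
) -> tuple[ImageStack, GroundTruthScene]:
    """Generate geometry and render it; identical (cfg, seed) is bit-identical."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    truth = generate_truth(cfg, rng)
    stack = render(truth, cfg, rng)
    return stack, truth


def truth_to_label_map(truth: GroundTruthScene, cfg: SceneConfig | None = None):
    """Rasterize the true nuclear ellipsoids into a NucleusLabelMap.

    Voxels whose centres fall inside a nucleus ellipsoid get that
    nucleus's id; later nuclei never overwrite earlier ones (nuclei are
    non-overlapping by construction).
    """
    from .image_ops import NucleusLabelMap

    cfg = cfg or truth.config
    shape = tuple(int(s) for s in cfg.field_shape)
    voxel = np.asarray(cfg.voxel_size)
    labels = np.zeros(shape, dtype=np.int32)
    for nuc in truth.nuclei:
        box, mask = _ellipsoid_mask_in_box(nuc, shape, voxel)
        region = labels[box]
        region[mask & (region == 0)] = nuc.id
    return NucleusLabelMap(labels=labels, voxel_size=cfg.voxel_size)
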