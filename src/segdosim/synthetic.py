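"""Synthetic multi-reader lesion cohorts with co-registered dose maps.

Real multi-observer contour studies are expensive and the underlying patient
data are rarely shareable, so every downstream stage of this package can be
exercised on a synthetic cohort that emulates the essential structure of such
a study:

* ~20 liver lesions with volumes spanning two orders of magnitude (2-200 mL),
  modelled as star-shaped bodies: an ellipsoid with a smooth, band-limited
  random radial modulation;
* a read design of 3 readers, two of whom contour in 3 rounds and one in a
  single round (7 reads per lesion, 140 reads for 20 lesions);
* observer disagreement modelled as a radial displacement of the true surface
  about the lesion centroid, split into a *reader bias* field (one smooth
  random field per (lesion, reader), fixed across that reader's rounds, RMS
  ``sigma_inter`` mm) and *session noise* (a fresh field per read, RMS
  ``sigma_intra`` mm) — exactly the separation the downstream variance
  decomposition assumes;
* absorbed-dose maps with log-normal intra-lesion texture and a lower
  background, blurred with an isotropic Gaussian emulating the limited
  spatial resolution of Y-90 PET.

Randomness is fully reproducible: a single master seed is expanded into
per-(lesion), per-(lesion, reader) and per-(lesion, reader, round) substreams
keyed by index, so adding lesions to a config does not reshuffle the
realizations of existing ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter
from scipy.special import sph_harm_y

from .dosimetry import DoseMap
from .masks import ReadRecord, VoxelMask, mask_volume, recist_diameter


class DegenerateContourError(ValueError):
    """A perturbation erased the contour entirely."""


# ---------------------------------------------------------------------------
# smooth random fields on the unit sphere
# ---------------------------------------------------------------------------

_SQRT2 = math.sqrt(2.0)


@lru_cache(maxsize=4)
def _grid_angles(n_theta: int, n_phi: int):
    """Flattened (theta, phi) meshgrid of the standard sampling lattice."""
    theta = np.linspace(0.0, math.pi, n_theta)
    phi = np.linspace(-math.pi, math.pi, n_phi)
    T, P = np.meshgrid(theta, phi, indexing="ij")
    return theta, phi, T.ravel(), P.ravel()


@lru_cache(maxsize=128)
def _grid_sph_basis(n_theta: int, n_phi: int, l: int, m: int) -> np.ndarray:
    """Complex Y_l^m (m >= 0) tabulated on the standard lattice, cached."""
    _, _, T, P = _grid_angles(n_theta, n_phi)
    return sph_harm_y(l, m, T, P)


@lru_cache(maxsize=4)
def _grid_dirs(n_theta: int, n_phi: int) -> np.ndarray:
    _, _, T, P = _grid_angles(n_theta, n_phi)
    st = np.sin(T)
    return np.stack([st * np.cos(P), st * np.sin(P), np.cos(T)], axis=-1)


def fibonacci_directions(n: int) -> np.ndarray:
    """n approximately uniform unit vectors (Fibonacci sphere)."""
    i = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    golden = math.pi * (3.0 - math.sqrt(5.0))
    phi = golden * i
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


class RadialField:
    """Band-limited random scalar field on the sphere.

    A linear combination of real spherical harmonics of degree 1..lmax with
    i.i.d. normal coefficients, rescaled so the root-mean-square of the field
    over the sphere equals ``rms`` exactly. Degree 0 is excluded so the field
    is mean-zero: perturbations displace the surface without a systematic
    volume offset.
    """

    def __init__(self, coeffs: Mapping[tuple[int, int], float]):
        self.coeffs = dict(coeffs)

    @classmethod
    def random(cls, rms: float, rng: np.random.Generator, lmax: int = 4) -> "RadialField":
        if rms < 0:
            raise ValueError("rms must be non-negative")
        terms = [(l, m) for l in range(1, lmax + 1) for m in range(-l, l + 1)]
        c = rng.standard_normal(len(terms))
        # orthonormal basis: mean square over sphere = sum(c^2) / (4*pi)
        norm = math.sqrt(float(np.sum(c * c)) / (4.0 * math.pi))
        scale = 0.0 if norm == 0 else rms / norm
        return cls({t: scale * ci for t, ci in zip(terms, c)})

    def __call__(self, dirs: np.ndarray) -> np.ndarray:
        """Evaluate on an (N, 3) array of unit vectors."""
        dirs = np.atleast_2d(dirs)
        theta = np.arccos(np.clip(dirs[:, 2], -1.0, 1.0))
        phi = np.arctan2(dirs[:, 1], dirs[:, 0])
        out = np.zeros(len(dirs))
        if not self.coeffs:
            return out
        lmax = max(l for l, _ in self.coeffs)
        for l in range(1, lmax + 1):
            for m in range(0, l + 1):
                cp = self.coeffs.get((l, m), 0.0)
                cm = self.coeffs.get((l, -m), 0.0) if m > 0 else 0.0
                if cp == 0.0 and cm == 0.0:
                    continue
                y = sph_harm_y(l, m, theta, phi)
                if m == 0:
                    out += cp * y.real
                else:
                    sgn = _SQRT2 * (-1.0) ** m
                    out += cp * sgn * y.real + cm * sgn * y.imag

        return out

    def sample_grid(self, n_theta: int, n_phi: int) -> np.ndarray:
        """Field values on the standard (theta, phi) lattice, flattened.

        Uses a process-wide cache of the spherical-harmonic basis on that
        lattice, so repeated voxelizations cost only dot products. Subclasses
        that override ``__call__`` are evaluated directly instead.
        """
        if type(self).__call__ is not RadialField.__call__:
            return self(_grid_dirs(n_theta, n_phi))
        out = np.zeros(n_theta * n_phi)
        for (l, m), c in self.coeffs.items():
            if c == 0.0:
                continue
            y = _grid_sph_basis(n_theta, n_phi, l, abs(m))
            if m == 0:
                out += c * y.real
            elif m > 0:
                out += c * _SQRT2 * (-1.0) ** m * y.real
            else:
                out += c * _SQRT2 * (-1.0) ** (-m) * y.imag
        return out

    def max_abs(self, n_probe: int = 2048) -> float:
        return float(np.max(np.abs(self(fibonacci_directions(n_probe)))))


class ZeroField(RadialField):
    """The identically-zero displacement field (no reader bias)."""

    def __init__(self):
        super().__init__({})

    def __call__(self, dirs: np.ndarray) -> np.ndarray:
        return np.zeros(len(np.atleast_2d(dirs)))


# ---------------------------------------------------------------------------
# star-shaped lesion geometry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StarShape:
    """Star-shaped surface about the origin: r(u) = ellipsoid(u) * modulation(u).

    ``semi_axes_mm`` are the ellipsoid semi-axes; ``modulation`` is a smooth,
    dimensionless multiplicative factor 1 + irregularity * field(u), clipped
    below at 0.3 to keep the radius positive.
    """

    semi_axes_mm: tuple[float, float, float]
    modulation: RadialField
    irregularity: float

    def _ellipsoid_radius(self, dirs: np.ndarray) -> np.ndarray:
        a, b, c = self.semi_axes_mm
        inv = np.sqrt((dirs[:, 0] / a) ** 2 + (dirs[:, 1] / b) ** 2 + (dirs[:, 2] / c) ** 2)
        return 1.0 / np.maximum(inv, 1e-12)

    def radius(self, dirs: np.ndarray) -> np.ndarray:
        dirs = np.atleast_2d(dirs)
        mod = np.clip(1.0 + self.irregularity * self.modulation(dirs), 0.3, None)
        return self._ellipsoid_radius(dirs) * mod

    def sample_grid(self, n_theta: int, n_phi: int) -> np.ndarray:
        """Radius on the standard lattice via the cached harmonic basis."""
        mod = np.clip(
            1.0 + self.irregularity * self.modulation.sample_grid(n_theta, n_phi), 0.3, None
        )
        return self._ellipsoid_radius(_grid_dirs(n_theta, n_phi)) * mod

    def scaled(self, factor: float) -> "StarShape":
        a, b, c = self.semi_axes_mm
        return replace(self, semi_axes_mm=(a * factor, b * factor, c * factor))


@dataclass
class TrueLesion:
    """Ground-truth lesion: analytic surface plus its voxelization.

    ``size_class`` follows the convention that lesions with volume of 8 mL or
    less are "small"; ``boundary_class`` records whether the lesion was
    simulated as well- or poorly-defined (poorly-defined lesions receive
    larger observer perturbations).
    """

    lesion_id: str
    mask: VoxelMask
    true_volume_ml: float
    shape: StarShape
    center_mm: np.ndarray
    boundary_class: str = "well"

    def __post_init__(self):
        if self.boundary_class not in ("well", "poor"):
            raise ValueError("boundary_class must be 'well' or 'poor'")
        got = mask_volume(self.mask)
        voxvol = self.mask.voxel_volume_mm3 / 1000.0
        if abs(got - self.true_volume_ml) > voxvol + 1e-9:
            raise ValueError("true_volume_ml inconsistent with mask voxel count")

    @property
    def size_class(self) -> str:
        return "small" if self.true_volume_ml <= 8.0 else "large"


def _sample_radius_grid(
    radius_fn: Callable[[np.ndarray], np.ndarray],
    n_theta: int = 128,
    n_phi: int = 256,
):
    """Tabulate a radius function on a (theta, phi) grid for fast lookup.

    The radius fields used here are band-limited (spherical harmonics of
    degree <= 4), so bilinear interpolation on a 128 x 256 angular grid is
    accurate to well below a voxel. Returns (table, theta_axis, phi_axis).
    """
    theta, phi, _, _ = _grid_angles(n_theta, n_phi)
    if hasattr(radius_fn, "sample_grid"):
        table = radius_fn.sample_grid(n_theta, n_phi).reshape(n_theta, n_phi)
    else:
        table = radius_fn(_grid_dirs(n_theta, n_phi)).reshape(n_theta, n_phi)
    return table, theta, phi


def _voxelize(
    radius_fn: Callable[[np.ndarray], np.ndarray],
    center_mm: np.ndarray,
    grid_shape: tuple[int, int, int],
    spacing_mm: tuple[float, float, float],
) -> np.ndarray:
    """Binary occupancy: voxel center inside the star-shaped surface.

    The surface radius is tabulated on an angular grid and bilinearly
    interpolated at the voxel directions; voxels strictly inside the minimum
    radius or outside the maximum radius skip the lookup entirely.
    """
    table, theta_ax, phi_ax = _sample_radius_grid(radius_fn)
    rmin, rmax = float(table.min()), float(table.max())

    axes = [np.arange(n) * s for n, s in zip(grid_shape, spacing_mm)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    vec = np.stack([X - center_mm[0], Y - center_mm[1], Z - center_mm[2]], axis=-1)
    rho = np.sqrt((vec**2).sum(-1))

    occ = (rho <= rmin) & (rmax > 0)  # zero-radius body occupies nothing
    shell = (rho > rmin) & (rho <= rmax)
    if shell.any():
        v = vec[shell]
        r = rho[shell]
        th = np.arccos(np.clip(v[:, 2] / r, -1.0, 1.0))
        ph = np.arctan2(v[:, 1], v[:, 0])
        # bilinear interpolation on the (theta, phi) table
        ti = np.clip(th / (theta_ax[1] - theta_ax[0]), 0, len(theta_ax) - 1.000001)
        pi_ = np.clip((ph + math.pi) / (phi_ax[1] - phi_ax[0]), 0, len(phi_ax) - 1.000001)
        t0 = ti.astype(int)
        p0 = pi_.astype(int)
        ft = ti - t0
        fp = pi_ - p0
        r_surf = (
            table[t0, p0] * (1 - ft) * (1 - fp)
            + table[t0 + 1, p0] * ft * (1 - fp)
            + table[t0, p0 + 1] * (1 - ft) * fp
            + table[t0 + 1, p0 + 1] * ft * fp
        )
        occ[shell] = r <= r_surf
    return occ


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate_true_lesion(
    target_volume_ml: float,
    shape_irregularity: float,
    grid_spacing_mm: Sequence[float],
    seed,
    margin_mm: float = 5.0,
    lesion_id: str = "L01",
    boundary_class: str = "well",
) -> TrueLesion:
    """Generate a connected ground-truth lesion mask of a target volume.

    The base shape is an ellipsoid with mildly random axis ratios, modulated
    by a smooth low-order random radial field with amplitude
    ``shape_irregularity``; the overall scale is calibrated (analytically,
    then by one voxel-count correction pass) so the voxelized volume matches
    ``target_volume_ml``. Star-shaped bodies are connected by construction.

    ``margin_mm`` pads the grid beyond the lesion surface so that later
    surface perturbations and dose blur stay inside the array.
    """
    if target_volume_ml <= 0:
        raise ValueError("target_volume_ml must be positive")
    spacing = tuple(float(s) for s in grid_spacing_mm)
    if any(s <= 0 for s in spacing):
        raise ValueError("grid spacing must be positive")
    voxvol_ml = spacing[0] * spacing[1] * spacing[2] / 1000.0
    if target_volume_ml < 8 * voxvol_ml:
        raise ValueError("volume below grid resolution (needs at least 8 voxels)")

    rng = _as_rng(seed)
    ratios = 1.0 + shape_irregularity * rng.uniform(-0.3, 0.3, size=3)
    ratios /= ratios.prod() ** (1.0 / 3.0)
    modulation = RadialField.random(1.0, rng, lmax=3)
    unit = StarShape(semi_axes_mm=tuple(ratios), modulation=modulation,
                     irregularity=float(shape_irregularity))

    # analytic scale: volume of a star body is (1/3) * integral of r^3 dOmega
    probe = fibonacci_directions(4096)
    r_unit = unit.radius(probe)
    v_unit_mm3 = (4.0 * math.pi / 3.0) * float(np.mean(r_unit**3))
    scale = (target_volume_ml * 1000.0 / v_unit_mm3) ** (1.0 / 3.0)
    shape = unit.scaled(scale)

    rmax = float(np.max(shape.radius(probe)))
    half = rmax + margin_mm + max(spacing)
    grid_shape = tuple(2 * int(math.ceil(half / s)) + 1 for s in spacing)
    center = np.array([(n // 2) * s for n, s in zip(grid_shape, spacing)])

    occ = _voxelize(shape, center, grid_shape, spacing)
    # one multiplicative correction pass absorbs the voxelization bias
    for _ in range(3):
        got_ml = occ.sum() * voxvol_ml
        if got_ml > 0 and abs(got_ml - target_volume_ml) / target_volume_ml <= 0.02:
            break
        factor = (target_volume_ml / max(got_ml, voxvol_ml)) ** (1.0 / 3.0)
        shape = shape.scaled(factor)
        occ = _voxelize(shape, center, grid_shape, spacing)

    mask = VoxelMask(occ, spacing)
    return TrueLesion(
        lesion_id=lesion_id,
        mask=mask,
        true_volume_ml=mask_volume(mask),
        shape=shape,
        center_mm=center,
        boundary_class=boundary_class,
    )


class _PerturbedRadius:
    """True surface radius plus reader bias and session noise, floored at 0."""

    def __init__(self, shape: StarShape, bias: RadialField, noise: RadialField):
        self.shape = shape
        self.bias = bias
        self.noise = noise

    def __call__(self, dirs: np.ndarray) -> np.ndarray:
        return np.clip(self.shape.radius(dirs) + self.bias(dirs) + self.noise(dirs), 0.0, None)

    def sample_grid(self, n_theta: int, n_phi: int) -> np.ndarray:
        total = (
            self.shape.sample_grid(n_theta, n_phi)
            + self.bias.sample_grid(n_theta, n_phi)
            + self.noise.sample_grid(n_theta, n_phi)
        )
        return np.clip(total, 0.0, None)


def perturb_mask(
    true_lesion: TrueLesion,
    reader_bias_field: Optional[RadialField],
    sigma_intra: float,
    seed,
    noise_lmax: int = 4,
) -> VoxelMask:
    """One observer read: displace the true surface radially and re-voxelize.

    The displacement at direction u is ``bias(u) + noise(u)``: the reader's
    fixed bias field (RMS ``sigma_inter``, shared across that reader's
    rounds) plus fresh session noise of RMS ``sigma_intra`` drawn from
    ``seed``. With no bias and ``sigma_intra == 0`` the voxelization is
    bit-identical to the ground-truth mask.
    """
    if sigma_intra < 0:
        raise ValueError("sigma_intra must be non-negative")
    bias = reader_bias_field if reader_bias_field is not None else ZeroField()
    if sigma_intra > 0:
        noise = RadialField.random(sigma_intra, _as_rng(seed), lmax=noise_lmax)
    else:
        noise = ZeroField()

    occ = _voxelize(
        _PerturbedRadius(true_lesion.shape, bias, noise),
        true_lesion.center_mm,
        true_lesion.mask.occupancy.shape,
        true_lesion.mask.spacing_mm,
    )
    if not occ.any():
        raise DegenerateContourError(
            f"degenerate contour: perturbation erased lesion {true_lesion.lesion_id}"
        )
    return VoxelMask(occ, true_lesion.mask.spacing_mm)


def generate_dose_map(
    true_lesion: TrueLesion,
    dose_peak_gy: float,
    psf_sigma_mm: float,
    background_fraction: float = 0.1,
    seed=0,
    texture_sigma: float = 0.3,
) -> DoseMap:
    """Absorbed-dose map on the lesion's grid, blurred to emission resolution.

    The unblurred map is ``dose_peak_gy`` inside the true lesion (with
    multiplicative log-normal texture of log-SD ``texture_sigma``, mean 1, so
    D10 > mean > D90 generically) and ``background_fraction * dose_peak_gy``
    outside; it is then convolved with an isotropic Gaussian of
    ``psf_sigma_mm``. Convolution conserves the dose-volume integral away
    from the grid edges.
    """
    if dose_peak_gy <= 0:
        raise ValueError("dose_peak_gy must be positive")
    if psf_sigma_mm < 0:
        raise ValueError("psf_sigma_mm must be non-negative")
    occ = true_lesion.mask.occupancy
    spacing = true_lesion.mask.spacing_mm
    rng = _as_rng(seed)
    dose = np.full(occ.shape, background_fraction * dose_peak_gy, dtype=float)
    if texture_sigma > 0:
        tex = np.exp(rng.normal(-0.5 * texture_sigma**2, texture_sigma, size=int(occ.sum())))
    else:
        tex = 1.0
    dose[occ] = dose_peak_gy * tex
    if psf_sigma_mm > 0:
        sigma_vox = tuple(psf_sigma_mm / s for s in spacing)
        if any(8 * sv >= n for sv, n in zip(sigma_vox, occ.shape)):
            raise ValueError("psf kernel larger than grid")
        dose = gaussian_filter(dose, sigma=sigma_vox, mode="constant", cval=0.0)
    return DoseMap(np.maximum(dose, 0.0), spacing)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


@dataclass
class CohortConfig:
    """Study conditions for a synthetic multi-reader cohort.

    Defaults emulate a 20-lesion, 3-reader contouring study in which readers
    A and B each contour in three rounds and reader C once (7 reads per
    lesion, 140 in total), lesion volumes span 2-200 mL log-uniformly, and
    dose maps carry a 5-mm Gaussian blur as in a Y-90 PET chain.
    """

    n_lesions: int = 20
    volume_range_ml: tuple[float, float] = (2.0, 200.0)
    readers: dict[str, int] = field(default_factory=lambda: {"A": 3, "B": 3, "C": 1})
    sigma_inter: float = 2.0  # reader-bias field RMS, mm
    sigma_intra: float = 1.25  # session-noise field RMS, mm
    grid_spacing_mm: tuple[float, float, float] = (1.5, 1.5, 2.5)
    dose_peak_gy: float = 150.0
    background_fraction: float = 0.1
    texture_sigma: float = 0.3
    psf_sigma_mm: float = 5.0
    shape_irregularity: float = 0.25
    poor_fraction: float = 0.4  # fraction of lesions with poorly-defined margins
    poor_sigma_factor: float = 2.0  # perturbation multiplier for poor lesions
    seed: int = 0

    def __post_init__(self):
        if self.n_lesions < 1:
            raise ValueError("n_lesions must be >= 1")
        lo, hi = self.volume_range_ml
        if not 0 < lo <= hi:
            raise ValueError("volume_range_ml must satisfy 0 < low <= high")
        if any(s <= 0 for s in self.grid_spacing_mm):
            raise ValueError("grid spacing must be positive")
        if self.sigma_inter < 0 or self.sigma_intra < 0:
            raise ValueError("sigma_inter and sigma_intra must be >= 0")
        if not self.readers or any(r < 1 for r in self.readers.values()):
            raise ValueError("each reader needs at least one round")
        if not 0 <= self.poor_fraction <= 1:
            raise ValueError("poor_fraction must be in [0, 1]")

    @property
    def reads_per_lesion(self) -> int:
        return sum(self.readers.values())

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "CohortConfig":
        kwargs = dict(raw)
        for key in ("volume_range_ml", "grid_spacing_mm"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


# substream tags for seed derivation
_STREAM_TRUTH = 0
_STREAM_DOSE = 1
_STREAM_BIAS = 2
_STREAM_NOISE = 3
_STREAM_LESION = 4


def _substream(master_seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=tuple(key)))


def read_design(config: CohortConfig) -> pd.DataFrame:
    """Expand the read design into one row per (lesion, reader, round)."""
    rows = [
        {"lesion_id": f"L{i + 1:02d}", "reader_id": reader, "round": rnd}
        for i in range(config.n_lesions)
        for reader, n_rounds in config.readers.items()
        for rnd in range(1, n_rounds + 1)
    ]
    return pd.DataFrame(rows, columns=["lesion_id", "reader_id", "round"])


@dataclass
class SyntheticCohort:
    """Everything a downstream analysis needs: truths, dose maps, reads."""

    config: CohortConfig
    lesions: list[TrueLesion]
    dose_maps: dict[str, DoseMap]
    reads: list[ReadRecord]

    def reads_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "lesion_id": r.lesion_id,
                    "reader_id": r.reader_id,
                    "round": r.round,
                    "volume_ml": r.volume_ml,
                    "diameter_mm": r.diameter_mm,
                }
                for r in self.reads
            ]
        )

    def truth_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "lesion_id": t.lesion_id,
                    "true_volume_ml": t.true_volume_ml,
                    "boundary_class": t.boundary_class,
                    "size_class": t.size_class,
                }
                for t in self.lesions
            ]
        )


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate the full cohort: truths, dose maps and all observer reads.

    Deterministic under ``config.seed``; per-lesion and per-read substreams
    are keyed by (lesion index, reader index, round) so realizations are
    stable when lesions are appended.
    """
    reader_ids = list(config.readers)
    lesions: list[TrueLesion] = []
    dose_maps: dict[str, DoseMap] = {}
    reads: list[ReadRecord] = []
    lo, hi = config.volume_range_ml

    for i in range(config.n_lesions):
        lesion_id = f"L{i + 1:02d}"
        try:
            rng_lesion = _substream(config.seed, _STREAM_LESION, i)
            volume = float(np.exp(rng_lesion.uniform(np.log(lo), np.log(hi))))
            poor = bool(rng_lesion.uniform() < config.poor_fraction)
            sig_factor = config.poor_sigma_factor if poor else 1.0
            s_inter = config.sigma_inter * sig_factor
            s_intra = config.sigma_intra * sig_factor
            margin = 3.5 * (s_inter + s_intra) + 2.0 * config.psf_sigma_mm + max(config.grid_spacing_mm)

            truth = generate_true_lesion(
                volume,
                config.shape_irregularity,
                config.grid_spacing_mm,
                seed=_substream(config.seed, _STREAM_TRUTH, i),
                margin_mm=margin,
                lesion_id=lesion_id,
                boundary_class="poor" if poor else "well",
            )
            lesions.append(truth)

            # mild lesion-to-lesion dose-level variation, emulating uptake spread
            peak = config.dose_peak_gy * float(np.exp(rng_lesion.normal(0.0, 0.5)))
            dose_maps[lesion_id] = generate_dose_map(
                truth,
                peak,
                config.psf_sigma_mm,
                config.background_fraction,
                seed=_substream(config.seed, _STREAM_DOSE, i),
                texture_sigma=config.texture_sigma,
            )

            for ri, reader in enumerate(reader_ids):
                if s_inter > 0:
                    bias = RadialField.random(
                        s_inter, _substream(config.seed, _STREAM_BIAS, i, ri), lmax=4
                    )
                else:
                    bias = ZeroField()
                for rnd in range(1, config.readers[reader] + 1):
                    mask = perturb_mask(
                        truth,
                        bias,
                        s_intra,
                        seed=_substream(config.seed, _STREAM_NOISE, i, ri, rnd),
                    )
                    reads.append(
                        ReadRecord(
                            lesion_id=lesion_id,
                            reader_id=reader,
                            round=rnd,
                            volume_ml=mask_volume(mask),
                            diameter_mm=recist_diameter(mask),
                            mask=mask,
                        )
                    )
        except Exception as exc:
            raise type(exc)(f"lesion {lesion_id}: {exc}") from exc

    return SyntheticCohort(config=config, lesions=lesions, dose_maps=dose_maps, reads=reads)
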