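"""Physics-grounded synthetic inputs: 1D random media, exact transfer-matrix
reflectance spectra, 2D cell phantoms with ground truth, and synthetic cohorts.

The measurement geometry being emulated: a cell of mean refractive index n0
sits on a substrate that matches its index (no back-surface reflection) while
the front surface faces the ambient medium and is mismatched.  The front
reflection supplies a reference wave; Rayleigh scattering from the internal
refractive-index fluctuations delta_n(z) supplies the partial waves whose
interference with the reference makes the reflectance spectrum R(lambda)
wiggle.  In the weak-scattering (Born) regime the spectral variance of those
wiggles scales as sigma_n^2 * l_c * L * kbar^2 for Gaussian-correlated
fluctuations with SD sigma_n and correlation length l_c short compared with
the wavelength in the medium.

The solver is the exact 1D characteristic-matrix method at normal incidence,
so the scaling laws above are *outcomes*, not assumptions, and the simulator
can arbitrate them.  Refractive index relates to macromolecular mass density
rho through n = n_water + alpha * rho with alpha = 0.18 ml/g.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage.draw import ellipse as draw_ellipse

from .cohort_stats import PatientSummary
from .hypercube_io import SpectralAxis, SpectralCube
from .segmentation import LabelMask
from .spectral_core import FilterSpec, compute_sigma_map

__all__ = [
    "RefractiveModel",
    "LayeredMedium",
    "MediumParams",
    "PhantomSpec",
    "EnsembleResult",
    "CalibrationResult",
    "density_to_ri",
    "gaussian_correlated_profile",
    "transfer_matrix_reflectance",
    "simulate_pws_ensemble",
    "calibrate_ld",
    "make_phantom_scene",
    "make_phantom_cube",
    "make_cohort",
]

#: default mean cellular refractive index
N_CELL = 1.38
#: weak-scattering advisory bound on sigma_n * kbar * L
WEAK_SCATTERING_BOUND = 2.0


@dataclass(frozen=True)
class RefractiveModel:
    """Linear density-to-index relation n = n_water + alpha * rho."""

    n_water: float = 1.333
    alpha_ml_per_g: float = 0.18

    def __post_init__(self) -> None:
        if self.alpha_ml_per_g <= 0:
            raise ValueError("alpha must be positive")


def density_to_ri(rho, model: RefractiveModel = RefractiveModel()):
    """Refractive index of a macromolecular density field (g/ml), elementwise."""
    rho = np.asarray(rho, dtype=float)
    if not np.all(np.isfinite(rho)):
        raise ValueError("density must be finite")
    return model.n_water + model.alpha_ml_per_g * rho


@dataclass
class LayeredMedium:
    """A 1D refractive-index profile n(z) = n0 + delta_n on a uniform grid.

    ``sigma_n`` and ``corr_len_nm`` record the *target* statistics the profile
    was drawn with; the grid step must resolve the correlation length
    (dz <= l_c / 4) and never exceed 10 nm.
    """

    delta_n: np.ndarray
    dz_nm: float
    n0: float = N_CELL
    n_ambient: float = 1.0
    n_substrate: float | None = None  # None -> matched to n0
    sigma_n: float = 0.0
    corr_len_nm: float = 40.0

    def __post_init__(self) -> None:
        self.delta_n = np.asarray(self.delta_n, dtype=float)
        if self.delta_n.ndim != 1 or self.delta_n.size < 1:
            raise ValueError("delta_n must be a non-empty 1-D array")
        if self.dz_nm <= 0:
            raise ValueError("dz_nm must be positive")
        if self.sigma_n < 0:
            raise ValueError("sigma_n must be >= 0")
        if self.corr_len_nm <= 0:
            raise ValueError("corr_len_nm must be positive")
        if self.dz_nm > min(self.corr_len_nm / 4.0, 10.0) + 1e-9:
            raise ValueError(
                f"grid step {self.dz_nm} nm too coarse: must be <= min(l_c/4, 10 nm) "
                f"= {min(self.corr_len_nm / 4.0, 10.0):.3g} nm"
            )
        if self.n_substrate is None:
            self.n_substrate = self.n0

    @property
    def thickness_nm(self) -> float:
        return float(self.delta_n.size * self.dz_nm)

    @property
    def layer_indices(self) -> np.ndarray:
        return self.n0 + self.delta_n

    @property
    def z_grid(self) -> np.ndarray:
        """Layer-centre depths in nm."""
        return (np.arange(self.delta_n.size) + 0.5) * self.dz_nm


def _default_dz(corr_len_nm: float) -> float:
    return min(corr_len_nm / 4.0, 10.0)


def _gaussian_profiles(
    n_profiles: int,
    sigma_n: float,
    corr_len_nm: float,
    thickness_nm: float,
    dz_nm: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Batch of zero-mean Gaussian profiles with Gaussian autocorrelation.

    White noise is circularly convolved with a Gaussian kernel of width
    w = l_c / 2, which yields the target autocorrelation
    sigma_n^2 * exp(-(tau / l_c)^2) (1/e half-width l_c) exactly in the
    ensemble sense; the amplitude normalization is analytic, not empirical.
    """
    n_layers = int(round(thickness_nm / dz_nm))
    if n_layers < 4:
        raise ValueError("medium too thin for the requested grid")
    if sigma_n == 0.0:
        return np.zeros((n_profiles, n_layers))
    w = corr_len_nm / 2.0
    z = np.arange(n_layers) * dz_nm
    z = np.minimum(z, n_layers * dz_nm - z)  # circular lattice distance
    kernel = np.exp(-(z**2) / (2.0 * w**2))
    norm = np.sqrt(np.sum(kernel**2))
    white = rng.standard_normal((n_profiles, n_layers))
    kf = np.fft.rfft(kernel)
    out = np.fft.irfft(np.fft.rfft(white, axis=1) * kf[None, :], n=n_layers, axis=1)
    return sigma_n * out / norm


def gaussian_correlated_profile(
    sigma_n: float,
    corr_len_nm: float,
    thickness_nm: float,
    dz_nm: float | None = None,
    seed: int | None = None,
    n0: float = N_CELL,
    n_ambient: float = 1.0,
    n_substrate: float | None = None,
) -> LayeredMedium:
    """Draw one Gaussian-correlated refractive-index profile.

    Deterministic given ``seed``.  ``dz_nm`` defaults to min(l_c/4, 10 nm);
    a coarser grid raises.
    """
    if dz_nm is None:
        dz_nm = _default_dz(corr_len_nm)
    if dz_nm > _default_dz(corr_len_nm) + 1e-9:
        raise ValueError(
            f"dz_nm={dz_nm} too coarse for l_c={corr_len_nm} nm "
            f"(max {_default_dz(corr_len_nm):.3g} nm)"
        )
    rng = np.random.default_rng(seed)
    delta = _gaussian_profiles(1, sigma_n, corr_len_nm, thickness_nm, dz_nm, rng)[0]
    return LayeredMedium(
        delta_n=delta,
        dz_nm=dz_nm,
        n0=n0,
        n_ambient=n_ambient,
        n_substrate=n_substrate,
        sigma_n=sigma_n,
        corr_len_nm=corr_len_nm,
    )


def _tmm_batch(
    layer_indices: np.ndarray,
    dz_nm: float,
    n_ambient: float,
    n_substrate: float,
    wavelengths_nm: np.ndarray,
    return_transmission: bool = False,
):
    """Characteristic-matrix reflectance of a batch of layered stacks.

    ``layer_indices`` is (B, J): B independent stacks of J layers of equal
    thickness ``dz_nm`` between the ambient and substrate half-spaces.
    Normal incidence, lossless, non-dispersive.  Returns R of shape (B, W)
    (and T if requested), with R + T = 1 up to round-off.
    """
    nl = np.asarray(layer_indices, dtype=float)
    if nl.ndim != 2:
        raise ValueError("layer_indices must be 2-D (batch, layers)")
    if np.any(nl <= 0) or n_ambient <= 0 or n_substrate <= 0:
        raise ValueError("non-physical refractive index (<= 0)")
    wl = np.asarray(wavelengths_nm, dtype=float)
    k = 2.0 * np.pi / wl  # (W,)
    B, J = nl.shape
    W = wl.size
    m11 = np.ones((B, W), dtype=complex)
    m12 = np.zeros((B, W), dtype=complex)
    m21 = np.zeros((B, W), dtype=complex)
    m22 = np.ones((B, W), dtype=complex)
    for j in range(J):
        nj = nl[:, j : j + 1]  # (B, 1)
        delta = nj * dz_nm * k[None, :]  # (B, W)
        c = np.cos(delta)
        s = np.sin(delta)
        a12 = 1j * s / nj
        a21 = 1j * nj * s
        n11 = m11 * c + m12 * a21
        n12 = m11 * a12 + m12 * c
        n21 = m21 * c + m22 * a21
        n22 = m21 * a12 + m22 * c
        m11, m12, m21, m22 = n11, n12, n21, n22
    b = m11 + m12 * n_substrate
    c_ = m21 + m22 * n_substrate
    denom = n_ambient * b + c_
    r = (n_ambient * b - c_) / denom
    R = np.abs(r) ** 2
    if return_transmission:
        t = 2.0 * n_ambient / denom
        T = (n_substrate / n_ambient) * np.abs(t) ** 2
        return R, T
    return R


def transfer_matrix_reflectance(
    medium: LayeredMedium,
    axis: SpectralAxis,
    return_transmission: bool = False,
):
    """Exact 1D reflectance spectrum R(lambda) of a layered medium.

    Energy is conserved for these lossless stacks: 0 <= R <= 1 and R + T = 1.
    """
    out = _tmm_batch(
        medium.layer_indices[None, :],
        medium.dz_nm,
        medium.n_ambient,
        medium.n_substrate,
        axis.wavelengths_nm,
        return_transmission=return_transmission,
    )
    if return_transmission:
        return out[0][0], out[1][0]
    return out[0]


@dataclass
class EnsembleResult:
    """Spectra and Sigma^2 summary of a random-medium ensemble."""

    spectra: np.ndarray  # (n_realizations, n_wl)
    sigma: np.ndarray  # per-realization spectral SD
    sigma2_mean: float
    sigma2_se: float
    params: dict = field(default_factory=dict)

    @property
    def sigma2(self) -> np.ndarray:
        return self.sigma**2


def simulate_pws_ensemble(
    sigma_n: float,
    corr_len_nm: float,
    thickness_nm: float,
    axis: SpectralAxis,
    n_realizations: int,
    noise_sd: float = 0.0,
    seed: int | None = None,
    dz_nm: float | None = None,
    n0: float = N_CELL,
    n_ambient: float = 1.0,
    n_substrate: float | None = None,
    filter: FilterSpec | None = FilterSpec(),
    poly_order: int = 0,
) -> EnsembleResult:
    """Simulate an ensemble of interference spectra and summarize Sigma^2.

    Each realization draws a fresh Gaussian-correlated profile, solves the
    exact transfer-matrix reflectance, optionally adds white detector noise,
    and computes Sigma through the standard spectral pipeline
    (:func:`pwsnano.spectral_core.compute_sigma_map`).  The baseline default
    here is mean removal only (``poly_order=0``): the simulated background is
    a flat Fresnel constant, and higher-order detrending needlessly absorbs
    low-delay interference components over the finite band.
    """
    if n_realizations < 1:
        raise ValueError("n_realizations must be >= 1")
    if dz_nm is None:
        dz_nm = _default_dz(corr_len_nm)
    kbar = axis.center_wavenumber
    if sigma_n * kbar * thickness_nm > WEAK_SCATTERING_BOUND:
        warnings.warn(
            f"sigma_n*kbar*L = {sigma_n * kbar * thickness_nm:.2f} exceeds the "
            f"weak-scattering bound {WEAK_SCATTERING_BOUND}; Born scaling laws may not hold",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    profiles = _gaussian_profiles(n_realizations, sigma_n, corr_len_nm, thickness_nm, dz_nm, rng)
    n_sub = n0 if n_substrate is None else n_substrate
    R = _tmm_batch(n0 + profiles, dz_nm, n_ambient, n_sub, axis.wavelengths_nm)
    if noise_sd > 0:
        R = R + rng.normal(0.0, noise_sd, size=R.shape)
    cube = SpectralCube(R[:, None, :], axis, metadata={"value_kind": "reflectance"})
    sig = compute_sigma_map(cube, filter=filter, poly_order=poly_order).values[:, 0]
    sigma2 = sig**2
    return EnsembleResult(
        spectra=R,
        sigma=sig,
        sigma2_mean=float(sigma2.mean()),
        sigma2_se=float(sigma2.std(ddof=1) / np.sqrt(n_realizations)) if n_realizations > 1 else 0.0,
        params={
            "sigma_n": sigma_n,
            "corr_len_nm": corr_len_nm,
            "thickness_nm": thickness_nm,
            "dz_nm": dz_nm,
            "n_realizations": n_realizations,
            "noise_sd": noise_sd,
            "seed": seed,
            "n0": n0,
            "n_ambient": n_ambient,
            "n_substrate": n_sub,
            "poly_order": poly_order,
        },
    )


@dataclass(frozen=True)
class CalibrationResult:
    """Least-squares constant mapping measured L_d onto sigma_n^2 * l_c (or sigma_n * l_c)."""

    constant: float
    r_squared: float
    convention: str
    x: np.ndarray  # ground-truth disorder products per grid point
    y: np.ndarray  # measured (uncalibrated) L_d per grid point


def calibrate_ld(
    reference_grid: Sequence[tuple[float, float, float]],
    axis: SpectralAxis,
    convention: str = "variance",
    n_realizations: int = 100,
    seed: int | None = None,
    initial_calibration: float = 1.0,
    **sim_kwargs,
) -> CalibrationResult:
    """Fit the proportionality constant between measured and true disorder.

    ``reference_grid`` is a sequence of (sigma_n, l_c_nm, L_nm) points inside
    the weak-scattering regime.  For each point the ensemble-mean Sigma^2 is
    simulated and reduced to an uncalibrated disorder strength
    y = Sigma^2 / (kbar^2 L) (variance convention) or y = Sigma / L (linear);
    the returned constant C minimizes sum (C*y - x)^2 with x = sigma_n^2*l_c
    (resp. sigma_n*l_c).  Raises if the through-origin fit explains the grid
    poorly (R^2 < 0.9), which indicates a regime violation.
    """
    grid = list(reference_grid)
    if len(grid) < 2:
        raise ValueError("degenerate reference grid: need >= 2 distinct points")
    if convention not in ("variance", "linear"):
        raise ValueError(f"unknown convention {convention!r}")
    kbar = axis.center_wavenumber
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    xs, ys = [], []
    for (sn, lc, L), child in zip(grid, ss.spawn(len(grid))):
        ens = simulate_pws_ensemble(
            sn, lc, L, axis, n_realizations, seed=child, **sim_kwargs
        )
        if convention == "variance":
            xs.append(sn**2 * lc)
            ys.append(initial_calibration * ens.sigma2_mean / (kbar**2 * L))
        else:
            xs.append(sn * lc)
            ys.append(initial_calibration * float(np.mean(ens.sigma)) / L)
    x = np.asarray(xs)
    y = np.asarray(ys)
    constant = float(np.sum(x * y) / np.sum(y * y))
    pred = constant * y
    ss_res = float(np.sum((x - pred) ** 2))
    ss_tot = float(np.sum((x - x.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    if r2 < 0.9:
        raise ValueError(
            f"calibration fit poor (R^2 = {r2:.3f}); check that the reference grid "
            "lies in the weak-scattering, small-l_c regime"
        )
    return CalibrationResult(constant=constant, r_squared=r2, convention=convention, x=x, y=y)


@dataclass(frozen=True)
class MediumParams:
    """Disorder parameters of one tissue class."""

    sigma_n: float
    corr_len_nm: float
    thickness_nm: float


@dataclass(frozen=True)
class PhantomSpec:
    """A 2D cell phantom: dark nuclei on a cytoplasm background.

    Nucleus positions are drawn to be non-touching unless given explicitly;
    radii are in micrometres and converted through ``pixel_size_um``.  The
    nucleus and cytoplasm classes carry distinct 1D disorder parameters, so
    the rendered cube has genuinely different spectral statistics in the two
    compartments.
    """

    shape: tuple[int, int] = (96, 96)
    n_nuclei: int = 4
    pixel_size_um: float = 0.5
    nucleus_radius_um: tuple[float, float] = (3.0, 4.5)
    positions: tuple[tuple[int, int], ...] | None = None
    nucleus: MediumParams = MediumParams(0.03, 40.0, 1500.0)
    cytoplasm: MediumParams = MediumParams(0.015, 40.0, 1500.0)
    noise_sd: float = 5e-4
    transmission_background: float = 0.8
    transmission_nucleus: float = 0.35
    transmission_noise_sd: float = 0.02
    #: optical blur of the transmission image.  Lateral resolution of the
    #: collection optics is ~ lambda / (2 NA_c) ~ 0.5 um FWHM at NA_c = 0.6,
    #: i.e. a Gaussian sigma of ~0.21 um = 0.42 px at 0.5 um pixels.
    psf_sigma_px: float = 0.5
    max_overlap_fraction: float = 0.0
    n0: float = N_CELL
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be >= 0")
        if self.nucleus_radius_um[0] > self.nucleus_radius_um[1]:
            raise ValueError("nucleus_radius_um must be (min, max)")
        for p in (self.nucleus, self.cytoplasm):
            if p.sigma_n < 0 or p.corr_len_nm <= 0 or p.thickness_nm <= 0:
                raise ValueError("invalid class parameters")


def _phantom_layout(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Ground-truth label image for a phantom (0 background, 1..K nuclei)."""
    h, w = spec.shape
    labels = np.zeros((h, w), dtype=np.int64)
    r_px = np.asarray(spec.nucleus_radius_um) / spec.pixel_size_um
    radii = rng.uniform(r_px[0], r_px[1], size=spec.n_nuclei)
    stretch = rng.uniform(0.85, 1.15, size=spec.n_nuclei)
    if spec.positions is not None:
        if len(spec.positions) != spec.n_nuclei:
            raise ValueError("positions length must equal n_nuclei")
        centers = [tuple(p) for p in spec.positions]
    else:
        centers = []
        margin = r_px[1] * 1.2 + 2
        for i in range(spec.n_nuclei):
            for _ in range(20000):
                r0 = rng.uniform(margin, h - margin)
                c0 = rng.uniform(margin, w - margin)
                if all((r0 - rr) ** 2 + (c0 - cc) ** 2 > (2.3 * r_px[1]) ** 2 for rr, cc in centers):
                    centers.append((r0, c0))
                    break
            else:
                raise ValueError(
                    f"could not place {spec.n_nuclei} non-touching nuclei in a "
                    f"{h}x{w} image; enlarge the image or shrink the nuclei"
                )
    overlap_px = 0
    total_px = 0
    for i, ((r0, c0), rad, st) in enumerate(zip(centers, radii, stretch), start=1):
        rr, cc = draw_ellipse(r0, c0, rad, rad * st, shape=(h, w))
        total_px += rr.size
        overlap_px += int(np.count_nonzero(labels[rr, cc]))
        labels[rr, cc] = i
    if total_px and overlap_px / total_px > spec.max_overlap_fraction:
        raise ValueError(
            f"nuclei overlap fraction {overlap_px / total_px:.3f} exceeds allowed "
            f"{spec.max_overlap_fraction}"
        )
    return labels


def make_phantom_scene(spec: PhantomSpec) -> tuple[LabelMask, np.ndarray]:
    """Ground-truth mask and transmission image only (no spectra).

    Deterministic given ``spec.seed``; :func:`make_phantom_cube` reproduces
    exactly this scene for the same spec.
    """
    ss = np.random.SeedSequence(spec.seed)
    layout_rng, trans_rng, _ = (np.random.default_rng(s) for s in ss.spawn(3))
    labels = _phantom_layout(spec, layout_rng)
    trans = np.full(spec.shape, spec.transmission_background, dtype=float)
    trans[labels > 0] = spec.transmission_nucleus
    trans = ndi.gaussian_filter(trans, sigma=spec.psf_sigma_px)
    if spec.transmission_noise_sd > 0:
        trans = trans + trans_rng.normal(0.0, spec.transmission_noise_sd, size=trans.shape)
    trans = np.clip(trans, 0.0, 1.0)
    return LabelMask(labels, spec.pixel_size_um), trans


def make_phantom_cube(
    spec: PhantomSpec,
    axis: SpectralAxis,
    chunk_px: int = 2048,
) -> tuple[SpectralCube, LabelMask, np.ndarray]:
    """Render a full phantom cube: per-pixel spectra from class parameters.

    Every pixel gets an independent 1D medium drawn with its class's
    (sigma_n, l_c, L), solved exactly; white detector noise of SD
    ``spec.noise_sd`` is added to the reflectance.  Bit-wise deterministic
    given ``spec.seed``.
    """
    mask, trans = make_phantom_scene(spec)
    ss = np.random.SeedSequence(spec.seed)
    _, _, cube_seed = ss.spawn(3)
    rng = np.random.default_rng(cube_seed)
    h, w = spec.shape
    n_wl = len(axis)
    values = np.empty((h, w, n_wl), dtype=float)
    flat_labels = mask.labels.reshape(-1) > 0
    for cls_params, cls_sel in (
        (spec.cytoplasm, ~flat_labels),
        (spec.nucleus, flat_labels),
    ):
        idx = np.flatnonzero(cls_sel)
        dz = _default_dz(cls_params.corr_len_nm)
        for start in range(0, idx.size, chunk_px):
            chunk = idx[start : start + chunk_px]
            profiles = _gaussian_profiles(
                chunk.size, cls_params.sigma_n, cls_params.corr_len_nm,
                cls_params.thickness_nm, dz, rng,
            )
            R = _tmm_batch(spec.n0 + profiles, dz, 1.0, spec.n0, axis.wavelengths_nm)
            values.reshape(-1, n_wl)[chunk] = R
    if spec.noise_sd > 0:
        values = values + rng.normal(0.0, spec.noise_sd, size=values.shape)
    values = np.clip(values, 0.0, None)
    cube = SpectralCube(
        values,
        axis,
        spec.pixel_size_um,
        metadata={"value_kind": "reflectance", "phantom_seed": spec.seed},
    )
    return cube, mask, trans


def make_cohort(
    n_per_group: int,
    group_ld_means: dict[str, float],
    group_ld_sds: dict[str, float],
    seed: int | None = None,
    n_nuclei: int = 30,
    cellular_slope: float = 0.8,
    cellular_noise_sd: float | None = None,
) -> list[PatientSummary]:
    """Draw Gaussian patient-level mean L_d values per diagnostic group.

    If ``cellular_noise_sd`` is given, a cellular mean is generated as
    ``cellular_slope * nuclear + noise`` so compartment correlation can be
    exercised; otherwise cellular means are left unset.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    if set(group_ld_means) != set(group_ld_sds):
        raise ValueError("group mean/SD dictionaries must share keys")
    rng = np.random.default_rng(seed)
    out: list[PatientSummary] = []
    for group in group_ld_means:
        sd = group_ld_sds[group]
        if sd <= 0:
            raise ValueError("group SDs must be positive")
        nuclear = rng.normal(group_ld_means[group], sd, size=n_per_group)
        cellular = None
        if cellular_noise_sd is not None:
            cellular = cellular_slope * nuclear + rng.normal(0.0, cellular_noise_sd, size=n_per_group)
        for i in range(n_per_group):
            out.append(
                PatientSummary(
                    patient_id=f"{group}_{i:03d}",
                    group=group,
                    mean_nuclear_ld=float(nuclear[i]),
                    mean_cellular_ld=None if cellular is None else float(cellular[i]),
                    n_nuclei=n_nuclei,
                )
            )
    return out
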