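"""Preprocessing: rigid T2-to-T1 registration, adaptive denoising,
white-matter intensity uniformization, mask erosion, and the T1/T2
contrast-enhancement map.

These are the stages applied to each subject before PVS detection. All
operations preserve grid geometry: outputs are congruent with their inputs
(or, for registration, with the fixed grid).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk
from scipy import ndimage
from scipy.cluster.vq import kmeans2
from skimage.filters import threshold_otsu
from skimage.restoration import denoise_nl_means, estimate_sigma

from .image import (
    BinaryMask,
    ImageVolume,
    NonFiniteIntensityError,
    RigidTransform,
    assert_congruent,
    euler_from_matrix,
)


class RegistrationError(RuntimeError):
    """Registration failed; carries the best transform found so far."""

    def __init__(self, message: str, best_transform: RigidTransform | None = None):
        super().__init__(message)
        self.best_transform = best_transform


# --------------------------------------------------------------------------
# SimpleITK bridge (RAS <-> LPS)

_RAS2LPS = np.diag([-1.0, -1.0, 1.0])


def _to_sitk(vol: ImageVolume | BinaryMask) -> sitk.Image:
    data = np.asarray(vol.data, dtype=np.float64)
    img = sitk.GetImageFromArray(np.ascontiguousarray(data.transpose(2, 1, 0)))
    A = vol.affine
    sp = np.linalg.norm(A[:3, :3], axis=0)
    direction = _RAS2LPS @ (A[:3, :3] / sp)
    origin = _RAS2LPS @ A[:3, 3]
    img.SetSpacing(tuple(sp))
    img.SetDirection(tuple(direction.flatten()))
    img.SetOrigin(tuple(origin))
    return img


def _rigid_to_sitk(t: RigidTransform) -> sitk.Euler3DTransform:
    M = t.matrix()
    R_lps = _RAS2LPS @ M[:3, :3] @ _RAS2LPS
    t_lps = _RAS2LPS @ M[:3, 3]
    e = sitk.Euler3DTransform()
    e.SetMatrix(tuple(R_lps.flatten()))
    e.SetTranslation(tuple(t_lps))
    return e


def _rigid_from_sitk(e: sitk.Euler3DTransform) -> RigidTransform:
    R_lps = np.asarray(e.GetMatrix()).reshape(3, 3)
    c = np.asarray(e.GetCenter())
    t = np.asarray(e.GetTranslation())
    # full affine action in LPS: x -> R (x - c) + c + t
    offset = c + t - R_lps @ c
    R_ras = _RAS2LPS @ R_lps @ _RAS2LPS
    off_ras = _RAS2LPS @ offset
    return RigidTransform(
        rotation=euler_from_matrix(R_ras),
        translation=tuple(off_ras),
        center=(0.0, 0.0, 0.0),
    )


def resample_to(
    moving: ImageVolume,
    fixed: ImageVolume,
    transform: RigidTransform,
    interpolation: str = "linear",
) -> ImageVolume:
    """Resample ``moving`` onto the grid of ``fixed`` through ``transform``.

    ``transform`` maps fixed-space mm points to moving-space mm points.
    Intensities use trilinear interpolation; pass ``"nearest"`` for masks.
    """
    interp = sitk.sitkLinear if interpolation == "linear" else sitk.sitkNearestNeighbor
    out = sitk.Resample(
        _to_sitk(moving),
        _to_sitk(fixed),
        _rigid_to_sitk(transform),
        interp,
        0.0,
        sitk.sitkFloat64,
    )
    data = sitk.GetArrayFromImage(out).transpose(2, 1, 0)
    return ImageVolume(data, fixed.affine.copy(), moving.modality)


def rigid_register(
    moving: ImageVolume,
    fixed: ImageVolume,
    initial_transform: RigidTransform | None = None,
    max_iterations: int = 500,
    shrink_factors=(4, 2, 1),
    smoothing_sigmas=(2.0, 1.0, 0.0),
) -> tuple[RigidTransform, ImageVolume]:
    """6-DOF rigid registration by normalized mutual information.

    Multi-resolution (coarse-to-fine) Mattes mutual-information registration
    suited to cross-contrast (T2 onto T1) alignment. Returns the transform
    mapping fixed-space mm points to moving-space mm points, and the moving
    volume resampled onto the fixed grid by trilinear interpolation.

    A user-supplied ``initial_transform`` bypasses optimization entirely
    (useful to reproduce an externally computed alignment).
    """
    for v, name in ((moving, "moving"), (fixed, "fixed")):
        v.assert_finite()
        if np.ptp(v.data) == 0:
            raise ValueError(f"degenerate (constant) {name} image")

    if initial_transform is not None:
        return initial_transform, resample_to(moving, fixed, initial_transform)

    f_img = _to_sitk(fixed)
    m_img = _to_sitk(moving)
    init = sitk.CenteredTransformInitializer(
        f_img,
        m_img,
        sitk.Euler3DTransform(),
        sitk.CenteredTransformInitializerFilter.GEOMETRY,
    )
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=50)
    # dense metric evaluation: deterministic and accurate; these volumes
    # are small enough that sampling buys little
    reg.SetMetricSamplingStrategy(reg.NONE)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0,
        minStep=1e-4,
        numberOfIterations=max_iterations,
        relaxationFactor=0.5,
        gradientMagnitudeTolerance=1e-6,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetShrinkFactorsPerLevel(list(shrink_factors))
    reg.SetSmoothingSigmasPerLevel(list(smoothing_sigmas))
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOn()
    reg.SetInitialTransform(init, inPlace=False)

    final = reg.Execute(f_img, m_img).Downcast()
    if isinstance(final, sitk.CompositeTransform):
        final = final.GetNthTransform(0).Downcast()
    transform = _rigid_from_sitk(final)
    stop = reg.GetOptimizerStopConditionDescription()
    if "Maximum number of iterations" in stop and max_iterations > 10:
        raise RegistrationError(
            f"registration did not converge: {stop}", best_transform=transform
        )
    return transform, resample_to(moving, fixed, transform)


# --------------------------------------------------------------------------
# Adaptive denoising


def estimate_noise_sigma(volume: ImageVolume, slice_axis: int | None = None) -> float:
    """Noise level from the median absolute deviation of wavelet-domain
    high-pass residuals, taken per axial slice and combined by the median
    (robust to slices dominated by structure rather than noise)."""
    if slice_axis is None:
        try:
            slice_axis = volume.slice_axis()
        except Exception:
            slice_axis = 2
    sigmas = []
    for s in range(volume.shape[slice_axis]):
        plane = np.take(volume.data, s, axis=slice_axis)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sigmas.append(float(estimate_sigma(plane)))
    return float(np.nanmedian(sigmas))


def denoise_adaptive(
    volume: ImageVolume,
    h_factor: float = 0.8,
    patch_size: int = 3,
    patch_distance: int = 6,
    slice_axis: int | None = None,
) -> ImageVolume:
    """Edge-preserving non-local-means filtering with self-estimated noise.

    The noise level is estimated from the volume itself; filtering runs
    2D per axial slice (the 4.4 mm slice gap makes through-plane patches
    dissimilar), which preserves thin linear structures far better than
    Gaussian smoothing. A clean volume (estimated sigma ~ 0) passes through
    essentially unchanged.
    """
    volume.assert_finite()
    if slice_axis is None:
        try:
            slice_axis = volume.slice_axis()
        except Exception:
            slice_axis = 2
    sigma = estimate_noise_sigma(volume, slice_axis)
    scale = float(np.ptp(volume.data))
    if sigma <= 0 or scale == 0 or sigma < 1e-6 * scale:
        return volume.like(volume.data.copy())
    out = np.empty_like(volume.data)
    for s in range(volume.shape[slice_axis]):
        plane = np.take(volume.data, s, axis=slice_axis)
        den = denoise_nl_means(
            plane,
            h=h_factor * sigma,
            sigma=sigma,
            patch_size=patch_size,
            patch_distance=patch_distance,
            fast_mode=True,
        )
        idx: list = [slice(None)] * 3
        idx[slice_axis] = s
        out[tuple(idx)] = den
    return volume.like(out)


# --------------------------------------------------------------------------
# White-matter intensity uniformization


def _poly_design(coords: np.ndarray, degree: int) -> np.ndarray:
    """Design matrix of 3D monomials x^a y^b z^c with a+b+c <= degree."""
    x, y, z = coords[:, 0], coords[:, 1], coords[:, 2]
    cols = []
    for a in range(degree + 1):
        for b in range(degree + 1 - a):
            for c in range(degree + 1 - a - b):
                cols.append((x**a) * (y**b) * (z**c))
    return np.stack(cols, axis=1)


def uniformize_wm(
    volume: ImageVolume,
    wm: BinaryMask,
    target_level: float = 1000.0,
    degree: int = 2,
    n_trim_iter: int = 3,
    trim_nmad: float = 2.5,
) -> ImageVolume:
    """Remove smooth multiplicative intensity bias and anchor the WM median.

    A low-order 3D polynomial is fitted to WM voxel intensities with
    iterative trimming (robust to the hyperintense PVS minority), divided
    out over the whole volume, and the result rescaled so the WM median
    equals ``target_level`` (default 1000 — the scale on which the PVS
    detection threshold of 60 is defined, i.e. 6% of the WM level).
    """
    assert_congruent(volume, wm)
    volume.assert_finite()
    n_coef = _poly_design(np.zeros((1, 3)), degree).shape[1]
    if wm.count() < 2 * n_coef:
        raise ValueError(
            f"WM mask ({wm.count()} voxels) too small for a degree-{degree} "
            f"bias polynomial ({n_coef} coefficients)"
        )
    finite_pos = wm.data & (volume.data > 0)
    if finite_pos.sum() < 2 * n_coef:
        raise ValueError("too few positive WM voxels for bias estimation")
    idx = np.argwhere(finite_pos)
    # normalized coordinates in [-1, 1] for conditioning
    shape = np.asarray(volume.shape, dtype=float)
    coords = 2.0 * idx / np.maximum(shape - 1, 1) - 1.0
    X = _poly_design(coords, degree)
    # multiplicative bias is additive in the log domain, which also makes
    # repeated application a near-projection (idempotent)
    y = np.log(volume.data[finite_pos])

    keep = np.ones(len(y), dtype=bool)
    beta = None
    for _ in range(n_trim_iter):
        beta, *_ = np.linalg.lstsq(X[keep], y[keep], rcond=None)
        resid = y - X @ beta
        mad = np.median(np.abs(resid - np.median(resid)))
        if mad == 0:
            break
        keep = np.abs(resid - np.median(resid)) < trim_nmad * 1.4826 * mad
        if keep.sum() < 2 * n_coef:
            break

    all_idx = np.indices(volume.shape).reshape(3, -1).T
    all_coords = 2.0 * all_idx / np.maximum(shape - 1, 1) - 1.0
    log_field = (_poly_design(all_coords, degree) @ beta).reshape(volume.shape)
    log_field -= np.mean(log_field[wm.data])
    corrected = volume.data / np.exp(log_field)
    med = float(np.median(corrected[wm.data]))
    if med == 0:
        raise ValueError("WM median is zero after bias correction")
    return volume.like(corrected * (target_level / med))


# --------------------------------------------------------------------------
# Mask erosion


def erode_mask(
    mask: BinaryMask,
    iterations: int = 1,
    mode: str = "3d",
    slice_axis: int | None = None,
) -> BinaryMask:
    """Morphological erosion of a binary mask.

    ``mode="3d"`` uses the face-connected (6-neighbor) structuring element.
    ``mode="inplane"`` erodes 2D (4-neighbor) independently per axial slice
    — with 4.4 mm slices, 3D erosion removes every single-slice structure,
    so the in-plane option is exposed.
    """
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    if iterations == 0 or mask.count() == 0:
        return mask.like(mask.data.copy())
    if mode == "3d":
        struct = ndimage.generate_binary_structure(3, 1)
        out = ndimage.binary_erosion(mask.data, struct, iterations=iterations)
    elif mode == "inplane":
        if slice_axis is None:
            slice_axis = mask.slice_axis()
        struct2d = ndimage.generate_binary_structure(2, 1)
        out = np.zeros_like(mask.data)
        for s in range(mask.shape[slice_axis]):
            plane = np.take(mask.data, s, axis=slice_axis)
            idx: list = [slice(None)] * 3
            idx[slice_axis] = s
            out[tuple(idx)] = ndimage.binary_erosion(
                plane, struct2d, iterations=iterations
            )
    else:
        raise ValueError(f"unknown erosion mode {mode!r}")
    return mask.like(out)


# --------------------------------------------------------------------------
# T1/T2 contrast-enhancement map


def compute_epc(
    t1: ImageVolume, t2: ImageVolume, mask: BinaryMask | None = None
) -> ImageVolume:
    """Voxel-wise T1/T2 ratio — the multimodal PVS contrast-enhancement map.

    PVS are T1-hypointense and T2-hyperintense, so the ratio is depressed
    along PVS relative to WM. Provided as a visualization/QC product;
    detection itself runs on the uniformized T2.
    """
    assert_congruent(t1, t2)
    t1.assert_finite()
    t2.assert_finite()
    region = mask.data if mask is not None else np.ones(t2.shape, dtype=bool)
    bad = int(np.sum((t2.data <= 0) & region))
    if bad:
        raise ValueError(
            f"{bad} voxels with non-positive T2 inside the mask: ratio undefined"
        )
    out = np.zeros_like(t1.data)
    with np.errstate(divide="ignore", invalid="ignore"):
        np.divide(t1.data, t2.data, out=out, where=region & (t2.data != 0))
    return t1.like(out, modality="derived")


# --------------------------------------------------------------------------
# Phantom-grade WM segmentation fallback


def segment_wm_fallback(
    t1: ImageVolume, n_classes: int = 3, seed: int = 0
) -> BinaryMask:
    """Intensity-clustering WM segmentation — phantom-grade only.

    A brain mask is taken by thresholding away background and keeping the
    largest connected component; voxel intensities within it are k-means
    clustered into ``n_classes`` 1D classes and the brightest-in-T1 class
    is returned as white matter. This is a stand-in adequate for synthetic
    phantoms; clinical-grade accuracy is explicitly out of contract —
    supply an externally produced WM mask for real data.
    """
    t1.assert_finite()
    if np.ptp(t1.data) == 0:
        raise ValueError("constant image: no intensity classes separable")
    # light in-plane smoothing stabilises both the brain mask and the
    # intensity clustering against noise (slices are too thick to smooth
    # through-plane)
    data = ndimage.gaussian_filter(t1.data, sigma=(1.0, 1.0, 0.0))
    brain = data > threshold_otsu(data)
    lab, n = ndimage.label(brain)
    if n == 0:
        raise ValueError("no foreground found")
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=range(1, n + 1))
    brain = lab == (1 + int(np.argmax(sizes)))
    brain = ndimage.binary_fill_holes(brain)

    vals = data[brain].astype(float)[:, None]
    rng = np.random.default_rng(seed)
    qs = np.quantile(vals, np.linspace(0.15, 0.85, n_classes))
    centers, labels = kmeans2(vals, qs[:, None].copy(), minit="matrix", seed=rng)
    centers = centers.ravel()
    order = np.argsort(centers)
    spread = np.ptp(vals)
    if spread == 0 or np.min(np.diff(np.sort(centers))) < 0.02 * spread:
        raise ValueError(
            f"fewer than {n_classes} separable intensity classes in T1"
        )
    wm_class = order[-1]  # brightest in T1
    out = np.zeros(t1.shape, dtype=bool)
    out[brain] = labels == wm_class
    # PVS are T1-hypointense holes inside WM; a WM mask should contain them
    # (they are intra-WM structures), so fill in-plane holes per slice
    for s in range(out.shape[2]):
        out[:, :, s] = ndimage.binary_fill_holes(out[:, :, s])
    return BinaryMask(out, t1.affine.copy())
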