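"""Feature-volume filter bank.

Every filter maps a 3D scalar volume to a same-shaped float32 feature volume
and is looked up in a registry by name with a typed parameter schema, so that
pipeline configs can be validated before execution. The inventory covers the
basic point operations (invert, threshold, rescale, gamma), blob/edge
descriptors (Hessian eigenvalues, structure-tensor determinant, Frangi
vesselness, gradients, Laplacian, difference of Gaussians), denoisers
(Gaussian, median, total variation, wavelet), binary morphology with a ball
structuring element, the Euclidean distance transform, and the local
Gaussian-neighborhood statistics ``gaussian_centre`` / ``gaussian_norm``.

All convolutions use reflect border handling, and voxel spacing is assumed
isotropic (sigma and radius parameters are in voxels).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import filters as skfilters
from skimage import morphology, restoration

from .errors import ValidationError

_EPS_NORM = 1e-6


@dataclass(frozen=True)
class ParamSpec:
    """Schema for one filter parameter."""

    name: str
    default: float
    minimum: float | None = None
    maximum: float | None = None
    integer: bool = False

    def validate(self, value) -> float:
        try:
            value = float(value)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"parameter {self.name!r} must be numeric, got {value!r}") from exc
        if not np.isfinite(value):
            raise ValidationError(f"parameter {self.name!r} must be finite")
        if self.minimum is not None and value < self.minimum:
            raise ValidationError(f"parameter {self.name!r}={value} below minimum {self.minimum}")
        if self.maximum is not None and value > self.maximum:
            raise ValidationError(f"parameter {self.name!r}={value} above maximum {self.maximum}")
        if self.integer:
            value = int(round(value))
        return value


@dataclass(frozen=True)
class FilterSpec:
    """A named filter plus its parameter values (validated on application)."""

    name: str
    params: dict = field(default_factory=dict)


_REGISTRY: dict[str, tuple] = {}


def register_filter(name: str, *param_specs: ParamSpec):
    def deco(func):
        _REGISTRY[name] = (func, param_specs)
        return func

    return deco


def list_filters() -> dict[str, dict[str, ParamSpec]]:
    """Registered filter names mapped to their parameter schemas."""
    return {name: {p.name: p for p in specs} for name, (_, specs) in _REGISTRY.items()}


def apply_filter(volume: np.ndarray, spec: FilterSpec) -> np.ndarray:
    """Apply a registered filter; output is float32 with the input's shape."""
    if spec.name not in _REGISTRY:
        raise ValidationError(f"unknown filter {spec.name!r}")
    func, param_specs = _REGISTRY[spec.name]
    volume = np.asarray(volume, dtype=np.float64)
    if volume.ndim != 3:
        raise ValidationError(f"expected a 3D volume, got shape {volume.shape}")
    if not np.all(np.isfinite(volume)):
        raise ValidationError("volume contains non-finite values")
    schema = {p.name: p for p in param_specs}
    unknown = set(spec.params) - set(schema)
    if unknown:
        raise ValidationError(f"unknown parameter(s) {sorted(unknown)} for filter {spec.name!r}")
    kwargs = {n: p.validate(spec.params.get(n, p.default)) for n, p in schema.items()}
    out = func(volume, **kwargs)
    return np.ascontiguousarray(out, dtype=np.float32)


def _binarize(volume, threshold):
    return volume >= threshold


# ---------------------------------------------------------------- basic ----


@register_filter("simple_invert")
def _simple_invert(v):
    return v.max() - v


@register_filter("threshold", ParamSpec("threshold", 0.5, 0.0, 1.0))
def _threshold(v, threshold):
    return (v >= threshold).astype(np.float32)


@register_filter("invert_threshold", ParamSpec("threshold", 0.5, 0.0, 1.0))
def _invert_threshold(v, threshold):
    return (v < threshold).astype(np.float32)


@register_filter("rescale")
def _rescale(v):
    lo, hi = v.min(), v.max()
    if hi == lo:
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


@register_filter("gamma_correct", ParamSpec("gamma", 1.0, 1e-3))
def _gamma(v, gamma):
    return np.clip(v, 0.0, None) ** gamma


# ------------------------------------------------------------ denoising ----


@register_filter("gaussian_blur", ParamSpec("sigma", 1.0, 0.0))
def _gaussian_blur(v, sigma):
    return ndi.gaussian_filter(v, sigma=sigma, mode="reflect")


@register_filter("median", ParamSpec("radius", 1.0, 1.0, integer=True))
def _median(v, radius):
    return ndi.median_filter(v, footprint=morphology.ball(radius), mode="reflect")


@register_filter(
    "total_variation",
    ParamSpec("weight", 0.1, 1e-6),
    ParamSpec("max_iter", 200, 1, integer=True),
)
def _total_variation(v, weight, max_iter):
    # Chambolle-style isotropic TV; tolerance fixed at 1e-4
    return restoration.denoise_tv_chambolle(v, weight=weight, eps=1e-4, max_num_iter=int(max_iter))


@register_filter("wavelet", ParamSpec("sigma", 0.1, 1e-6))
def _wavelet(v, sigma):
    return restoration.denoise_wavelet(v, sigma=sigma, rescale_sigma=True)


# ---------------------------------------------------------------- edges ----


@register_filter(
    "difference_of_gaussians", ParamSpec("sigma1", 1.0, 0.0), ParamSpec("sigma2", 2.0, 0.0)
)
def _dog(v, sigma1, sigma2):
    return ndi.gaussian_filter(v, sigma1, mode="reflect") - ndi.gaussian_filter(
        v, sigma2, mode="reflect"
    )


@register_filter("laplacian")
def _laplacian(v):
    # 6-neighbor discrete Laplacian
    return ndi.laplace(v, mode="reflect")


@register_filter("spatial_gradient_3d")
def _spatial_gradient(v):
    gz, gy, gx = np.gradient(v)
    return np.sqrt(gz**2 + gy**2 + gx**2)


# ----------------------------------------------------------------- blob ----


def _hessian_matrix(v, sigma):
    v = v - v.mean()  # differentiation is offset-free; keeps constants exactly zero
    axes = [(0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2)]
    elems = {}
    for a, b in axes:
        order = [0, 0, 0]
        order[a] += 1
        order[b] += 1
        elems[(a, b)] = ndi.gaussian_filter(v, sigma=sigma, order=order, mode="reflect")
    H = np.empty(v.shape + (3, 3))
    for (a, b), e in elems.items():
        H[..., a, b] = e
        H[..., b, a] = e
    return H


def hessian_eigenvalues_all(v: np.ndarray, sigma: float = 1.0) -> np.ndarray:
    """All three eigenvalues of the sigma-smoothed Hessian, sorted ascending.

    Returns an array of shape ``v.shape + (3,)``.
    """
    return np.linalg.eigvalsh(_hessian_matrix(np.asarray(v, dtype=np.float64), sigma))


@register_filter(
    "hessian_eigenvalues",
    ParamSpec("sigma", 1.0, 0.0),
    ParamSpec("channel", 0, 0, 2, integer=True),
)
def _hessian_eig(v, sigma, channel):
    return hessian_eigenvalues_all(v, sigma)[..., int(channel)]


@register_filter("structure_tensor_determinant", ParamSpec("sigma", 1.0, 0.0))
def _structure_tensor_det(v, sigma):
    # det of the sigma-smoothed structure tensor (gradient outer products)
    g = np.gradient(v)
    T = np.empty(v.shape + (3, 3))
    for a in range(3):
        for b in range(a, 3):
            e = ndi.gaussian_filter(g[a] * g[b], sigma=sigma, mode="reflect")
            T[..., a, b] = e
            T[..., b, a] = e
    return np.linalg.det(T)


@register_filter(
    "frangi",
    ParamSpec("sigma_min", 1.0, 0.1),
    ParamSpec("sigma_max", 3.0, 0.1),
    ParamSpec("num_sigma", 3, 1, integer=True),
)
def _frangi(v, sigma_min, sigma_max, num_sigma):
    sigmas = np.linspace(sigma_min, sigma_max, int(num_sigma))
    return skfilters.frangi(v, sigmas=sigmas, black_ridges=False)


# ----------------------------------------------------------- morphology ----


@register_filter(
    "dilation", ParamSpec("radius", 1.0, 1.0, integer=True), ParamSpec("threshold", 0.5, 0.0, 1.0)
)
def _dilation(v, radius, threshold):
    return ndi.binary_dilation(_binarize(v, threshold), structure=morphology.ball(radius)).astype(
        np.float32
    )


@register_filter(
    "erosion", ParamSpec("radius", 1.0, 1.0, integer=True), ParamSpec("threshold", 0.5, 0.0, 1.0)
)
def _erosion(v, radius, threshold):
    # border_value=1: the region outside the volume counts as foreground, so
    # erosion does not eat the border (and closing(A) stays a superset of A)
    return ndi.binary_erosion(
        _binarize(v, threshold), structure=morphology.ball(radius), border_value=1
    ).astype(np.float32)


@register_filter(
    "closing", ParamSpec("radius", 1.0, 1.0, integer=True), ParamSpec("threshold", 0.5, 0.0, 1.0)
)
def _closing(v, radius, threshold):
    ball = morphology.ball(radius)
    dilated = ndi.binary_dilation(_binarize(v, threshold), structure=ball)
    return ndi.binary_erosion(dilated, structure=ball, border_value=1).astype(np.float32)


@register_filter("distance_transform", ParamSpec("threshold", 0.5, 0.0, 1.0))
def _distance_transform(v, threshold):
    return ndi.distance_transform_edt(_binarize(v, threshold))


@register_filter("skeletonize", ParamSpec("threshold", 0.5, 0.0, 1.0))
def _skeletonize(v, threshold):
    return morphology.skeletonize(_binarize(v, threshold)).astype(np.float32)


# --------------------------------------------------------- neighborhood ----


@register_filter("gaussian_centre", ParamSpec("sigma", 1.0, 0.0))
def _gaussian_centre(v, sigma):
    return v - ndi.gaussian_filter(v, sigma=sigma, mode="reflect")


@register_filter("gaussian_norm", ParamSpec("sigma", 1.0, 0.0))
def _gaussian_norm(v, sigma):
    mean = ndi.gaussian_filter(v, sigma=sigma, mode="reflect")
    sq_mean = ndi.gaussian_filter(v * v, sigma=sigma, mode="reflect")
    var = np.maximum(sq_mean - mean * mean, _EPS_NORM)
    return (v - mean) / np.sqrt(var)
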