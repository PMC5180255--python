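"""V1-like encoding of stimulus images and a model-based dissimilarity metric.

The encoder follows the canonical simple-cell cascade: local divisive
normalization of the input image, convolution with a Gabor filter bank
(multiple orientations, spatial frequencies and phases), pointwise output
nonlinearities (half-wave threshold and response saturation), and a final
local divisive normalization of the response maps.  Responses are compared
with a correlation distance, ``1 - corr``.

Receptive fields default to 31 px at 2 px/deg — narrower than the 34 px
central arm of the cross stimuli — so every model unit (including its 3x3
normalization pool) depends on at most one lateral arm.  This V1-scale
locality is what makes the symmetry (XOR) task provably unsolvable by a
linear readout of the model: the two class sums of any one-sided feature
coincide, so the class means collide exactly in feature space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter
from scipy.signal import fftconvolve
from sklearn.base import BaseEstimator, TransformerMixin

from .stimuli import StimulusImage

__all__ = [
    "FilterBankSpec",
    "ModelStageParams",
    "V1Encoder",
    "encode",
    "model_distance",
    "response_matrix",
]


@dataclass(frozen=True)
class FilterBankSpec:
    """Gabor filter bank: orientations x spatial frequencies x phases.

    Frequencies are in cycles/degree and are converted to cycles/pixel with
    the geometry's raster scale.  The Gaussian envelope scales with the
    wavelength (sigma = bandwidth_factor * wavelength), the classic ~1-octave
    simple-cell bandwidth; ``gabor_aspect`` elongates the envelope along the
    filter's preferred orientation.
    """

    orientations: tuple[float, ...] = tuple(np.arange(16) * 180.0 / 16)
    spatial_frequencies: tuple[float, ...] = (0.05, 0.1, 0.2, 0.3, 0.4, 0.5)
    phases: tuple[float, ...] = (0.0, np.pi)
    filter_size: int = 31
    gabor_aspect: float = 0.5
    bandwidth_factor: float = 0.56

    def __post_init__(self) -> None:
        if len(self.orientations) < 2 or len(self.spatial_frequencies) < 2:
            raise ValueError("filter bank needs >=2 orientations and >=2 spatial frequencies")
        if self.filter_size < 3 or self.filter_size % 2 == 0:
            raise ValueError("filter_size must be an odd integer >= 3")

    @property
    def n_filters(self) -> int:
        return len(self.orientations) * len(self.spatial_frequencies) * len(self.phases)

    def kernels(self, pixels_per_degree: float = 2.0) -> np.ndarray:
        """Stack of (n_filters, size, size) Gabor kernels."""
        size = self.filter_size
        half = size // 2
        y, x = np.mgrid[-half : half + 1, -half : half + 1].astype(np.float64)
        out = []
        for theta_deg in self.orientations:
            th = np.deg2rad(theta_deg)
            xr = x * np.cos(th) + y * np.sin(th)
            yr = -x * np.sin(th) + y * np.cos(th)
            for cpd in self.spatial_frequencies:
                f_px = cpd / pixels_per_degree  # cycles per pixel
                lam = 1.0 / f_px
                sigma = self.bandwidth_factor * lam
                env = np.exp(-(xr**2 + (self.gabor_aspect * yr) ** 2) / (2 * sigma**2))
                for phase in self.phases:
                    g = env * np.cos(2 * np.pi * f_px * xr + phase)
                    g -= g.mean()  # zero DC response
                    out.append(g)
        return np.stack(out)


@dataclass(frozen=True)
class ModelStageParams:
    """Nonlinearity and normalization constants of the encoding cascade."""

    input_norm_neighborhood: int = 3
    norm_stabilizer: float = 1e-4
    activation_threshold: float = 0.0
    saturation_ceiling: float = 1.0
    output_norm_neighborhood: int = 3

    def __post_init__(self) -> None:
        if self.norm_stabilizer <= 0:
            raise ValueError("norm_stabilizer must be positive")
        if not self.activation_threshold < self.saturation_ceiling:
            raise ValueError("activation_threshold must be below saturation_ceiling")


def _divisive_normalize(arr: np.ndarray, neighborhood: int, eps: float) -> np.ndarray:
    """Divide each value by the local L2 norm over a square neighborhood.

    The pool includes the value itself, so for non-negative input the output
    is bounded by 1; this keeps the final response within the saturation
    ceiling after the output-stage normalization.
    """
    mean_sq = uniform_filter(arr.astype(np.float64) ** 2, size=neighborhood, mode="constant")
    energy = mean_sq * neighborhood**2  # local sum of squares
    return arr / (np.sqrt(np.maximum(energy, 0.0)) + eps)


@dataclass(frozen=True)
class ModelResponse:
    """Flattened non-negative activations, one per (filter, retained position)."""

    values: np.ndarray
    image_id: str = ""
    spec_id: str = ""


class V1Encoder(BaseEstimator, TransformerMixin):
    """Stateless sklearn-style transformer: binary images -> V1 feature vectors.

    Parameters
    ----------
    filterbank : FilterBankSpec
        Gabor bank definition (orientations, frequencies, phases, size).
    params : ModelStageParams
        Normalization / nonlinearity constants.
    stride : int
        Spatial subsampling of the response maps (applied after the output
        normalization); qualitative results are stride-invariant.
    pixels_per_degree : float
        Raster scale used to convert cycles/degree to cycles/pixel.
    """

    def __init__(
        self,
        filterbank: FilterBankSpec | None = None,
        params: ModelStageParams | None = None,
        stride: int = 4,
        pixels_per_degree: float = 2.0,
    ):
        self.filterbank = filterbank
        self.params = params
        self.stride = stride
        self.pixels_per_degree = pixels_per_degree

    def _resolved(self) -> tuple[FilterBankSpec, ModelStageParams]:
        return self.filterbank or FilterBankSpec(), self.params or ModelStageParams()

    def fit(self, X=None, y=None):
        spec, params = self._resolved()
        self.kernels_ = spec.kernels(self.pixels_per_degree)
        self.n_filters_ = spec.n_filters
        return self

    def transform(self, X) -> np.ndarray:
        """Encode a sequence of images; returns (n_images, n_features)."""
        if not hasattr(self, "kernels_"):
            self.fit()
        rows = [self.encode_one(img) for img in X]
        return np.stack(rows)

    def encode_one(self, img: StimulusImage | np.ndarray) -> np.ndarray:
        return self.stages(img)["response"]

    def stages(self, img: StimulusImage | np.ndarray) -> dict[str, np.ndarray]:
        """Run the cascade, returning every intermediate stage by name.

        Keys: ``input_normed`` (after input normalization), ``linear`` (raw
        Gabor maps), ``nonlinear`` (after threshold/saturation), ``normed``
        (after output normalization) and ``response`` (strided flat vector).
        """
        spec, params = self._resolved()
        if not hasattr(self, "kernels_"):
            self.fit()
        px = img.pixels if isinstance(img, StimulusImage) else np.asarray(img)
        px = px.astype(np.float64)
        if min(px.shape) < spec.filter_size:
            raise ValueError(
                f"image {px.shape} smaller than filter size {spec.filter_size}"
            )
        # 1. local divisive normalization of the input
        normed = _divisive_normalize(px, params.input_norm_neighborhood, params.norm_stabilizer)
        # 2. Gabor convolution, valid region only (no padding artifacts)
        linear = np.stack([fftconvolve(normed, k, mode="valid") for k in self.kernels_])
        # 3. threshold floor and saturation ceiling
        clipped = np.clip(linear, params.activation_threshold, params.saturation_ceiling)
        # 4. local divisive normalization of the output maps (per filter)
        out = np.stack(
            [_divisive_normalize(m, params.output_norm_neighborhood, params.norm_stabilizer) for m in clipped]
        )
        s = max(int(self.stride), 1)
        return {
            "input_normed": normed,
            "linear": linear,
            "nonlinear": clipped,
            "normed": out,
            "response": out[:, ::s, ::s].ravel(),
        }


def encode(
    img: StimulusImage | np.ndarray,
    spec: FilterBankSpec | None = None,
    params: ModelStageParams | None = None,
    stride: int = 4,
    pixels_per_degree: float = 2.0,
) -> ModelResponse:
    """Run the full encoding cascade on one image."""
    enc = V1Encoder(spec, params, stride=stride, pixels_per_degree=pixels_per_degree).fit()
    image_id = img.source_config.id if isinstance(img, StimulusImage) else ""
    return ModelResponse(enc.encode_one(img), image_id=image_id)


def model_distance(r_i, r_j) -> float:
    """Correlation distance between two model responses: 1 - Pearson r, in [0, 2]."""
    a = np.asarray(r_i.values if isinstance(r_i, ModelResponse) else r_i, dtype=np.float64)
    b = np.asarray(r_j.values if isinstance(r_j, ModelResponse) else r_j, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("responses have different lengths")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("correlation undefined for a zero-variance response")
    return float(1.0 - np.corrcoef(a, b)[0, 1])


def response_matrix(
    images,
    spec: FilterBankSpec | None = None,
    params: ModelStageParams | None = None,
    stride: int = 4,
    pixels_per_degree: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Stacked responses and the symmetric pairwise model-distance matrix."""
    images = list(images)
    if len(images) < 2:
        raise ValueError("need at least two stimuli")
    enc = V1Encoder(spec, params, stride=stride, pixels_per_degree=pixels_per_degree).fit()
    rows = []
    for img in images:
        try:
            rows.append(enc.encode_one(img))
        except ValueError as e:
            sid = img.source_config.id if isinstance(img, StimulusImage) else "?"
            raise ValueError(f"encoding failed for stimulus {sid}: {e}") from e
    R = np.stack(rows)
    n = len(rows)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = model_distance(rows[i], rows[j])
    return R, D
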