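"""Bone threshold estimation from the ROI intensity histogram.

A three-component 1-D Gaussian mixture is fitted to the voxel
intensities (air / soft tissue / bone, relabeled by ascending center)
and the bone threshold is placed at the mixture-density minimum between
the soft-tissue and bone peaks — the Bayes boundary under the fitted
model — falling back to the midpoint when no interior minimum exists.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize, signal, special
from sklearn.mixture import GaussianMixture

from .errors import FitError, ParameterError
from .volume_io import VolumeImage

#: at most this many voxel intensities enter the EM fit
MAX_FIT_SAMPLES = 200_000
_MIN_WEIGHT = 1e-4

COMPONENT_NAMES = ("air", "soft_tissue", "bone")


@dataclass(frozen=True)
class IntensityHistogramModel:
    """Fitted air / soft-tissue / bone peaks of the ROI histogram."""

    centers: np.ndarray   # ascending: air, soft_tissue, bone
    widths: np.ndarray    # per-peak standard deviations
    weights: np.ndarray   # mixing proportions, sum 1

    def __post_init__(self):
        object.__setattr__(self, "centers", np.asarray(self.centers, dtype=float))
        object.__setattr__(self, "widths", np.asarray(self.widths, dtype=float))
        object.__setattr__(self, "weights", np.asarray(self.weights, dtype=float))
        if self.centers.shape != (3,) or self.widths.shape != (3,) or self.weights.shape != (3,):
            raise ParameterError("histogram model needs three peaks")
        if not np.all(np.diff(self.centers) > 0):
            raise FitError(f"peak centers must be strictly increasing, got {self.centers}")
        if np.any(self.widths <= 0):
            raise FitError("peak widths must be positive")
        if np.any(self.weights <= 0) or np.any(self.weights >= 1) or \
                abs(self.weights.sum() - 1.0) > 1e-9:
            raise FitError(f"weights must lie in (0,1) and sum to 1, got {self.weights}")

    def density(self, x) -> np.ndarray:
        """Mixture probability density at intensity x."""
        return np.exp(self.log_density(x))

    def log_density(self, x) -> np.ndarray:
        """Log mixture density (stable far from every peak)."""
        x = np.asarray(x, dtype=float)[..., np.newaxis]
        log_comp = (
            np.log(self.weights)
            - np.log(self.widths * np.sqrt(2 * np.pi))
            - 0.5 * ((x - self.centers) / self.widths) ** 2
        )
        return special.logsumexp(log_comp, axis=-1)


@dataclass(frozen=True)
class BoneThreshold:
    """An intensity threshold plus its provenance (automatic or user)."""

    value: float
    source: str = "automatic"

    def __post_init__(self):
        if self.source not in ("automatic", "user"):
            raise ParameterError(f"threshold source must be automatic|user, got {self.source}")


def smooth_intensities(vol: VolumeImage, kernel_width_voxels: float) -> VolumeImage:
    """Gaussian pre-smoothing with sigma given in voxels per axis.

    Width 0 returns the input unchanged.
    """
    if kernel_width_voxels < 0:
        raise ParameterError(f"smoothing width must be >= 0, got {kernel_width_voxels}")
    if kernel_width_voxels == 0:
        return vol
    smoothed = ndimage.gaussian_filter(
        vol.data.astype(np.float64), sigma=kernel_width_voxels, mode="nearest"
    )
    return vol.with_data(smoothed)


def _subsample(values: np.ndarray, seed: int) -> np.ndarray:
    if values.size <= MAX_FIT_SAMPLES:
        return values
    rng = np.random.default_rng(seed)
    return rng.choice(values, size=MAX_FIT_SAMPLES, replace=False)


def _model_from_gmm(gmm: GaussianMixture) -> IntensityHistogramModel:
    centers = gmm.means_.ravel()
    order = np.argsort(centers)
    widths = np.sqrt(gmm.covariances_.ravel()[order])
    weights = gmm.weights_[order]
    weights = weights / weights.sum()
    return IntensityHistogramModel(centers[order], widths, weights)


def _validate(model: IntensityHistogramModel) -> None:
    if np.any(model.weights < _MIN_WEIGHT):
        raise FitError(
            f"vanishing mixture component (weights {model.weights}); "
            "set the bone threshold manually"
        )
    gaps = np.diff(model.centers)
    spreads = model.widths[:-1] + model.widths[1:]
    if np.any(gaps < 0.5 * spreads):
        raise FitError(
            f"mixture peaks are not separated (centers {model.centers}, "
            f"widths {model.widths}); set the bone threshold manually"
        )


def _find_modes(sample: np.ndarray) -> np.ndarray | None:
    """Locate the three dominant modes of the intensity histogram.

    Returns ascending mode intensities, or None when fewer than three
    distinct peaks stand out.
    """
    lo, hi = np.percentile(sample, [0.5, 99.5])
    if hi <= lo:
        return None
    counts, edges = np.histogram(sample, bins=128, range=(lo, hi))
    smooth = ndimage.gaussian_filter1d(counts.astype(float), sigma=1.5, mode="constant")
    # zero-pad so modes hugging the range ends are still local maxima
    padded = np.concatenate([[0.0], smooth, [0.0]])
    peaks, props = signal.find_peaks(padded, prominence=padded.max() * 1e-3)
    peaks = np.clip(peaks - 1, 0, len(smooth) - 1)
    if len(peaks) < 3:
        return None
    top = peaks[np.argsort(props["prominences"])[-3:]]
    centers = 0.5 * (edges[top] + edges[top + 1])
    return np.sort(centers)


def _anchored_model(sample: np.ndarray, modes: np.ndarray) -> IntensityHistogramModel:
    """Robust mixture estimate with centers pinned to the histogram modes.

    Widths come from an iteratively trimmed standard deviation around
    each mode and weights from hard assignment, so the flat
    partial-volume background between the peaks can drag neither the
    centers nor the widths (unlike free EM).
    """
    half_gap = 0.5 * np.min(np.diff(modes))
    widths = np.empty(3)
    for k in range(3):
        # MAD in a narrow window around the mode, refined once; the MAD
        # tolerates the uniform background where a std estimate cannot
        window = half_gap / 4.0
        sigma = None
        for _ in range(2):
            member = sample[np.abs(sample - modes[k]) <= window]
            if member.size < 2:
                raise FitError(f"no samples near the {COMPONENT_NAMES[k]} peak")
            sigma = max(1.4826 * float(np.median(np.abs(member - modes[k]))), 1e-12)
            window = min(4.0 * sigma, half_gap)
        widths[k] = min(sigma, half_gap)

    bounds = 0.5 * (modes[:-1] + modes[1:])
    labels = np.digitize(sample, bounds)
    weights = np.array([(labels == k).sum() for k in range(3)], dtype=float)
    if np.any(weights < 2):
        raise FitError("a histogram peak has almost no samples")
    weights /= weights.sum()
    return IntensityHistogramModel(modes, widths, weights)


def fit_histogram_peaks(vol: VolumeImage, seed: int = 0) -> IntensityHistogramModel:
    """Fit the air / soft-tissue / bone peaks of the ROI histogram.

    A three-component Gaussian mixture is EM-fitted to a (seeded)
    subsample of at most 200k intensities, initialized at the three
    dominant histogram modes (falling back to the 10th/50th/90th
    percentiles). When partial-volume voxels between the peaks drag an
    EM component off its mode — common at coarse voxel sizes — a robust
    mode-anchored estimate is used instead.
    """
    values = np.asarray(vol.data, dtype=np.float64).ravel()
    if np.unique(values).size < 3:
        raise FitError("volume has fewer than 3 distinct intensities; cannot fit peaks")
    sample = _subsample(values, seed)
    modes = _find_modes(sample)
    col = sample[:, np.newaxis]

    inits = []
    if modes is not None:
        inits.append(modes[:, np.newaxis])
    inits.append(np.percentile(col, [10, 50, 90])[:, np.newaxis])

    candidates = []
    for means_init in inits:
        try:
            gmm = GaussianMixture(
                n_components=3, covariance_type="full", random_state=seed,
                max_iter=300, reg_covar=1e-6, means_init=means_init,
            ).fit(col)
            model = _model_from_gmm(gmm)
            _validate(model)
            if modes is not None:
                drift_tol = 0.25 * np.min(np.diff(modes))
                if np.any(np.abs(model.centers - modes) > drift_tol):
                    raise FitError("EM drifted off the histogram modes")
            candidates.append((gmm.lower_bound_, model))
        except FitError:
            continue
    if candidates:
        return max(candidates, key=lambda c: c[0])[1]
    if modes is not None:
        model = _anchored_model(sample, modes)
        _validate(model)
        return model
    raise FitError(
        "EM failed to fit three separated intensity peaks; "
        "set the bone threshold manually"
    )


def estimate_bone_threshold(model: IntensityHistogramModel) -> BoneThreshold:
    """Place the bone threshold between the soft-tissue and bone peaks.

    The threshold is the intensity minimizing the mixture density on the
    open interval between the two centers. When no meaningful interior
    minimum exists — a flat density, or peaks so far apart that the
    minimum lies many decades below both (then its location only
    reflects which peak is narrower, not any real boundary) — the
    midpoint of the two centers is used instead.
    """
    lo, hi = model.centers[1], model.centers[2]
    xs = np.linspace(lo, hi, 2001)
    dens = model.log_density(xs)
    k = int(np.argmin(dens))
    peak_floor = min(model.log_density(lo), model.log_density(hi)) - 12.0
    if k == 0 or k == len(xs) - 1 or dens[k] < peak_floor:
        value = 0.5 * (lo + hi)  # no meaningful interior minimum
    else:
        res = optimize.minimize_scalar(
            lambda x: float(model.log_density(x)), bracket=(xs[k - 1], xs[k], xs[k + 1])
        )
        value = float(res.x) if res.success and lo < res.x < hi else float(xs[k])
    return BoneThreshold(float(value), source="automatic")


def bone_mask(vol: VolumeImage, t: BoneThreshold) -> np.ndarray:
    """Boolean bone mask: intensity >= threshold (bone inclusive)."""
    return np.asarray(vol.data) >= t.value
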