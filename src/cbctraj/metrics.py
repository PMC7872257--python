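"""VOI-restricted image-quality scoring.

Two full-reference metrics drive and evaluate the trajectory search:

* **FSIM** — feature similarity: per-pixel agreement of phase-congruency
  maps (computed with a multi-scale log-Gabor filter bank) and gradient
  magnitudes (Scharr), pooled with the maximum phase congruency as weight.
  FSIM is the optimization objective.
* **UQI** — the universal quality index: the product of local correlation,
  mean-luminance similarity and contrast similarity in sliding windows.
  UQI is used for evaluation only.

Both metrics are symmetric and equal 1 on identical inputs.  Because they
were defined for display-range images, volume pairs are jointly min-max
normalized to [0, 255] before scoring so that results do not depend on an
arbitrary display window.

The study protocol compares trajectories through *relative deviations*: the
metric between a baseline circular reconstruction and the prior volume is
the reference value, the metric between a candidate reconstruction and the
prior is the measured value, and the percentage deviation between the two
summarizes how close the candidate comes to circular-scan quality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter
from scipy.signal import convolve2d

from .projector import Volume

_GRADIENT_KERNELS = {
    "scharr": np.array([[3.0, 0.0, -3.0], [10.0, 0.0, -10.0], [3.0, 0.0, -3.0]]) / 16.0,
    "sobel": np.array([[1.0, 0.0, -1.0], [2.0, 0.0, -2.0], [1.0, 0.0, -1.0]]) / 4.0,
    "prewitt": np.array([[1.0, 0.0, -1.0], [1.0, 0.0, -1.0], [1.0, 0.0, -1.0]]) / 3.0,
}


@dataclass(frozen=True)
class VOI:
    """An axis-aligned voxel box, half-open index ranges ``[lo, hi)`` per axis."""

    lo: tuple[int, int, int]
    hi: tuple[int, int, int]

    def __post_init__(self) -> None:
        if any(h <= l for l, h in zip(self.lo, self.hi)):
            raise ValueError("VOI must be nonempty on every axis")
        if any(l < 0 for l in self.lo):
            raise ValueError("VOI indices must be nonnegative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(h - l for l, h in zip(self.lo, self.hi))

    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(l, h) for l, h in zip(self.lo, self.hi))

    def contains_index(self, idx: tuple[int, int, int]) -> bool:
        return all(l <= i < h for i, l, h in zip(idx, self.lo, self.hi))


@dataclass(frozen=True)
class FsimConfig:
    """FSIM filter-bank and stabilization parameters.

    Defaults follow the metric's original publication: a 4-scale /
    4-orientation log-Gabor bank (smallest wavelength 6 px, scale factor 2,
    radial bandwidth ``sigma_onf`` 0.55), stabilization constants
    ``t1`` (phase congruency) and ``t2`` (gradient, for a 0–255 range), and
    a Scharr gradient.  ``slice_axis`` selects how 3D volumes are scored:
    slice-wise along that axis, averaged.
    """

    n_scales: int = 4
    n_orientations: int = 4
    min_wavelength: float = 6.0
    wavelength_mult: float = 2.0
    sigma_onf: float = 0.55
    dtheta_on_sigma: float = 1.2
    noise_k: float = 2.0
    t1: float = 0.85
    t2: float = 160.0
    gradient: str = "scharr"
    slice_axis: int = 2

    def __post_init__(self) -> None:
        if self.t1 <= 0 or self.t2 <= 0:
            raise ValueError("stabilization constants must be positive")
        if self.n_scales < 1 or self.n_orientations < 1:
            raise ValueError("need at least one scale and orientation")
        if self.gradient not in _GRADIENT_KERNELS:
            raise ValueError(f"unknown gradient operator {self.gradient!r}")


def crop_voi(volume: Volume, voi: VOI) -> Volume:
    """Sub-volume copy of a VOI, with the origin shifted accordingly."""
    shape = volume.voxels.shape
    if any(h > s for h, s in zip(voi.hi, shape)):
        raise ValueError(f"VOI {voi} exceeds volume shape {shape}")
    sub = volume.voxels[voi.slices()].copy()
    origin = volume.origin + np.array(voi.lo) * volume.spacing
    return Volume(sub, volume.spacing.copy(), origin)


def joint_minmax_normalize(
    a: np.ndarray, b: np.ndarray, out_range: float = 255.0
) -> tuple[np.ndarray, np.ndarray]:
    """Scale two arrays to ``[0, out_range]`` with one shared affine map."""
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    scale = out_range / (hi - lo) if hi > lo else 0.0
    return (a - lo) * scale, (b - lo) * scale


# ---------------------------------------------------------------------------
# Phase congruency (multi-scale log-Gabor, with the standard noise threshold)
# ---------------------------------------------------------------------------


def _frequency_grid(rows: int, cols: int) -> tuple[np.ndarray, np.ndarray]:
    if cols % 2:
        xr = np.arange(-(cols - 1) / 2, (cols - 1) / 2 + 1) / (cols - 1)
    else:
        xr = np.arange(-cols / 2, cols / 2) / cols
    if rows % 2:
        yr = np.arange(-(rows - 1) / 2, (rows - 1) / 2 + 1) / (rows - 1)
    else:
        yr = np.arange(-rows / 2, rows / 2) / rows
    x, y = np.meshgrid(xr, yr)
    radius = np.fft.ifftshift(np.sqrt(x * x + y * y))
    theta = np.fft.ifftshift(np.arctan2(-y, x))
    radius[0, 0] = 1.0
    return radius, theta


def _lowpass(radius: np.ndarray, cutoff: float = 0.45, order: int = 15) -> np.ndarray:
    return 1.0 / (1.0 + (radius / cutoff) ** (2 * order))


def phase_congruency(image: np.ndarray, config: FsimConfig = FsimConfig()) -> np.ndarray:
    """Phase-congruency map of a 2D image, in [0, 1].

    Log-Gabor responses are accumulated over scales per orientation; the
    orientation energies (with the Kovesi noise threshold subtracted) are
    summed and normalized by the total response amplitude.
    """
    image = np.asarray(image, dtype=np.float64)
    rows, cols = image.shape
    radius, theta = _frequency_grid(rows, cols)
    lp = _lowpass(radius)
    epsilon = 1e-4
    theta_sigma = np.pi / config.n_orientations / config.dtheta_on_sigma

    log_gabor = []
    for s in range(config.n_scales):
        wavelength = config.min_wavelength * config.wavelength_mult**s
        fo = 1.0 / wavelength
        g = np.exp(-(np.log(radius / fo) ** 2) / (2.0 * np.log(config.sigma_onf) ** 2))
        g *= lp
        g[0, 0] = 0.0
        log_gabor.append(g)

    imfft = np.fft.fft2(image)
    sin_t, cos_t = np.sin(theta), np.cos(theta)
    energy_all = np.zeros((rows, cols))
    an_all = np.zeros((rows, cols))

    for o in range(config.n_orientations):
        angl = o * np.pi / config.n_orientations
        ds = sin_t * np.cos(angl) - cos_t * np.sin(angl)
        dc = cos_t * np.cos(angl) + sin_t * np.sin(angl)
        dtheta = np.abs(np.arctan2(ds, dc))
        spread = np.exp(-(dtheta**2) / (2.0 * theta_sigma**2))

        eo = []
        ifft_filters = []
        sum_e = np.zeros((rows, cols))
        sum_o = np.zeros((rows, cols))
        sum_an = np.zeros((rows, cols))
        em_n = 0.0
        for s in range(config.n_scales):
            filt = log_gabor[s] * spread
            ifft_filters.append(np.real(np.fft.ifft2(filt)) * np.sqrt(rows * cols))
            response = np.fft.ifft2(imfft * filt)
            eo.append(response)
            an = np.abs(response)
            sum_an += an
            sum_e += np.real(response)
            sum_o += np.imag(response)
            if s == 0:
                em_n = float(np.sum(filt**2))
        x_energy = np.sqrt(sum_e**2 + sum_o**2) + epsilon
        mean_e, mean_o = sum_e / x_energy, sum_o / x_energy
        energy = np.zeros((rows, cols))
        for response in eo:
            e_part, o_part = np.real(response), np.imag(response)
            energy += e_part * mean_e + o_part * mean_o \
                - np.abs(e_part * mean_o - o_part * mean_e)

        # noise threshold estimated from the smallest-scale response
        median_e2n = float(np.median(np.abs(eo[0]) ** 2))
        mean_e2n = -median_e2n / np.log(0.5)
        noise_power = mean_e2n / em_n if em_n > 0 else 0.0
        est_sum_an2 = sum(f**2 for f in ifft_filters)
        est_sum_aiaj = np.zeros((rows, cols))
        for si in range(config.n_scales - 1):
            for sj in range(si + 1, config.n_scales):
                est_sum_aiaj += ifft_filters[si] * ifft_filters[sj]
        est_noise_energy2 = 2.0 * noise_power * float(np.sum(est_sum_an2)) \
            + 4.0 * noise_power * float(np.sum(est_sum_aiaj))
        tau = np.sqrt(max(est_noise_energy2, 0.0) / 2.0)
        est_noise_energy = tau * np.sqrt(np.pi / 2.0)
        est_noise_sigma = np.sqrt((2.0 - np.pi / 2.0) * tau**2)
        threshold = (est_noise_energy + config.noise_k * est_noise_sigma) / 1.7
        energy = np.maximum(energy - threshold, 0.0)

        energy_all += energy
        an_all += sum_an
    return energy_all / (an_all + epsilon)


def _gradient_magnitude(image: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    gx = convolve2d(image, kernel, mode="same", boundary="fill")
    gy = convolve2d(image, kernel.T, mode="same", boundary="fill")
    return np.sqrt(gx * gx + gy * gy)


def fsim(
    reference: np.ndarray,
    test: np.ndarray,
    config: FsimConfig = FsimConfig(),
    normalize: bool = True,
) -> float:
    """Feature similarity between two 2D images, in (0, 1].

    With ``normalize`` the pair is jointly scaled to [0, 255] first (a
    shared affine map, so the metric stays symmetric).  The standard
    downsampling-by-``round(min(shape)/256)`` preprocessing is applied for
    large images.
    """
    reference = np.asarray(reference, dtype=np.float64)
    test = np.asarray(test, dtype=np.float64)
    if reference.shape != test.shape:
        raise ValueError("images must share a shape")
    if not (np.all(np.isfinite(reference)) and np.all(np.isfinite(test))):
        raise ValueError("images must be finite")
    if normalize:
        reference, test = joint_minmax_normalize(reference, test)

    factor = max(1, int(round(min(reference.shape) / 256)))
    if factor > 1:
        kernel = np.ones((factor, factor)) / factor**2
        reference = convolve2d(reference, kernel, mode="same")[::factor, ::factor]
        test = convolve2d(test, kernel, mode="same")[::factor, ::factor]

    pc1 = phase_congruency(reference, config)
    pc2 = phase_congruency(test, config)
    kernel = _GRADIENT_KERNELS[config.gradient]
    g1 = _gradient_magnitude(reference, kernel)
    g2 = _gradient_magnitude(test, kernel)

    sim_pc = (2.0 * pc1 * pc2 + config.t1) / (pc1**2 + pc2**2 + config.t1)
    sim_g = (2.0 * g1 * g2 + config.t2) / (g1**2 + g2**2 + config.t2)
    pc_max = np.maximum(pc1, pc2)
    weight = float(np.sum(pc_max))
    if weight < 1e-9:
        # (near-)constant images carry no phase congruency anywhere; fall back
        # to the unweighted mean so identical flat images still score 1
        score = float(np.mean(sim_pc * sim_g))
    else:
        score = float(np.sum(sim_pc * sim_g * pc_max) / weight)
    return float(np.clip(score, np.finfo(float).tiny, 1.0))


def _volume_slices(voxels: np.ndarray, axis: int):
    for i in range(voxels.shape[axis]):
        yield np.take(voxels, i, axis=axis)


def fsim_voi(
    reference: Volume,
    test: Volume,
    voi: VOI,
    config: FsimConfig = FsimConfig(),
) -> float:
    """Mean slice-wise FSIM inside a VOI.

    Both volumes are cropped to the VOI and jointly normalized to [0, 255];
    the score is the mean of the 2D FSIM over slices along
    ``config.slice_axis``.
    """
    a = crop_voi(reference, voi).voxels
    b = crop_voi(test, voi).voxels
    a, b = joint_minmax_normalize(a, b)
    scores = [
        fsim(sa, sb, config, normalize=False)
        for sa, sb in zip(_volume_slices(a, config.slice_axis),
                          _volume_slices(b, config.slice_axis))
    ]
    return float(np.mean(scores))


def uqi(
    reference: np.ndarray,
    test: np.ndarray,
    window: int = 8,
    normalize: bool = False,
) -> float:
    """Universal quality index between two 2D images, in [−1, 1].

    Sliding-window (side ``window``, stride 1) product of correlation,
    luminance similarity ``2x̄ȳ/(x̄²+ȳ²)`` and contrast similarity
    ``2σxσy/(σx²+σy²)``, averaged over fully interior windows.  Degenerate
    factors (both means zero, or both windows constant) are taken at their
    limiting value of 1.
    """
    x = np.asarray(reference, dtype=np.float64)
    y = np.asarray(test, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("images must share a shape")
    if window > min(x.shape) or window < 2:
        raise ValueError("window must be >= 2 and fit inside the image")
    if normalize:
        x, y = joint_minmax_normalize(x, y)

    n = window * window
    bessel = n / (n - 1.0)

    def win_mean(a: np.ndarray) -> np.ndarray:
        full = uniform_filter(a, size=window, mode="constant")
        # keep only windows fully inside the image; uniform_filter centers a
        # window starting at s on output index s + window//2
        off = window // 2
        rows = a.shape[0] - window + 1
        cols = a.shape[1] - window + 1
        return full[off : off + rows, off : off + cols]

    mx, my = win_mean(x), win_mean(y)
    sxx = np.clip((win_mean(x * x) - mx * mx) * bessel, 0.0, None)
    syy = np.clip((win_mean(y * y) - my * my) * bessel, 0.0, None)
    sxy = (win_mean(x * y) - mx * my) * bessel

    # degeneracy tolerance relative to the data scale: moments below this are
    # numerically indistinguishable from zero (sliding-sum roundoff)
    eps = 1e-9 * (float(np.mean(x * x) + np.mean(y * y)) + 1e-300)
    lum_den = mx * mx + my * my
    lum = np.where(lum_den > eps, 2.0 * mx * my / np.where(lum_den > eps, lum_den, 1.0), 1.0)
    con_den = sxx + syy
    con = np.where(
        con_den > eps,
        2.0 * np.sqrt(sxx * syy) / np.where(con_den > eps, con_den, 1.0),
        1.0,
    )
    cor_den = np.sqrt(sxx * syy)
    cor = np.where(cor_den > eps, sxy / np.where(cor_den > eps, cor_den, 1.0), 1.0)
    q = lum * con * cor
    return float(np.clip(np.mean(q), -1.0, 1.0))


def uqi_voi(
    reference: Volume,
    test: Volume,
    voi: VOI,
    window: int = 8,
    slice_axis: int = 2,
) -> float:
    """Mean slice-wise UQI inside a VOI (jointly normalized, like FSIM)."""
    a = crop_voi(reference, voi).voxels
    b = crop_voi(test, voi).voxels
    a, b = joint_minmax_normalize(a, b)
    scores = [
        uqi(sa, sb, window=window)
        for sa, sb in zip(_volume_slices(a, slice_axis), _volume_slices(b, slice_axis))
    ]
    return float(np.mean(scores))


def relative_deviation(reference_value: float, measured_value: float) -> float:
    """Percentage deviation ``100·|ref − meas| / |ref|`` of a quality score."""
    if reference_value == 0:
        raise ValueError("reference value must be nonzero")
    return 100.0 * abs(reference_value - measured_value) / abs(reference_value)
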