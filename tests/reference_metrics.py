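"""Independent, loop-oriented reference implementations of FSIM and UQI.

These are deliberately plain transliterations of the published algorithms
(log-Gabor phase congruency with the standard noise threshold for FSIM; the
windowed quality index for UQI), sharing no code with ``cbctraj.metrics``.
They exist purely as cross-implementation oracles for the test suite and
favour clarity over speed.
"""

from __future__ import annotations

import numpy as np


def _ref_lowpass(rows: int, cols: int, cutoff: float = 0.45, n: int = 15) -> np.ndarray:
    xs = (
        np.arange(-(cols - 1) / 2, (cols - 1) / 2 + 1) / (cols - 1)
        if cols % 2
        else np.arange(-cols / 2, cols / 2) / cols
    )
    ys = (
        np.arange(-(rows - 1) / 2, (rows - 1) / 2 + 1) / (rows - 1)
        if rows % 2
        else np.arange(-rows / 2, rows / 2) / rows
    )
    out = np.empty((rows, cols))
    for r in range(rows):
        for cidx in range(cols):
            radius = np.hypot(xs[cidx], ys[r])
            out[r, cidx] = 1.0 / (1.0 + (radius / cutoff) ** (2 * n))
    return np.fft.ifftshift(out)


def reference_phase_congruency(
    image: np.ndarray,
    nscale: int = 4,
    norient: int = 4,
    min_wavelength: float = 6.0,
    mult: float = 2.0,
    sigma_onf: float = 0.55,
    dtheta_on_sigma: float = 1.2,
    k: float = 2.0,
) -> np.ndarray:
    image = np.asarray(image, dtype=float)
    rows, cols = image.shape
    epsilon = 1e-4
    xs = (
        np.arange(-(cols - 1) / 2, (cols - 1) / 2 + 1) / (cols - 1)
        if cols % 2
        else np.arange(-cols / 2, cols / 2) / cols
    )
    ys = (
        np.arange(-(rows - 1) / 2, (rows - 1) / 2 + 1) / (rows - 1)
        if rows % 2
        else np.arange(-rows / 2, rows / 2) / rows
    )
    radius = np.empty((rows, cols))
    theta = np.empty((rows, cols))
    for r in range(rows):
        for cidx in range(cols):
            radius[r, cidx] = np.hypot(xs[cidx], ys[r])
            theta[r, cidx] = np.arctan2(-ys[r], xs[cidx])
    radius = np.fft.ifftshift(radius)
    theta = np.fft.ifftshift(theta)
    radius[0, 0] = 1.0
    lp = _ref_lowpass(rows, cols)

    theta_sigma = np.pi / norient / dtheta_on_sigma
    imfft = np.fft.fft2(image)
    energy_all = np.zeros((rows, cols))
    an_all = np.zeros((rows, cols))
    for o in range(norient):
        angl = o * np.pi / norient
        ds = np.sin(theta) * np.cos(angl) - np.cos(theta) * np.sin(angl)
        dc = np.cos(theta) * np.cos(angl) + np.sin(theta) * np.sin(angl)
        spread = np.exp(-np.abs(np.arctan2(ds, dc)) ** 2 / (2 * theta_sigma**2))

        responses = []
        ifft_filters = []
        em_n = 0.0
        for s in range(nscale):
            fo = 1.0 / (min_wavelength * mult**s)
            gabor = np.exp(
                -((np.log(radius / fo)) ** 2) / (2 * np.log(sigma_onf) ** 2)
            ) * lp
            gabor[0, 0] = 0.0
            filt = gabor * spread
            if s == 0:
                em_n = float((filt**2).sum())
            ifft_filters.append(np.real(np.fft.ifft2(filt)) * np.sqrt(rows * cols))
            responses.append(np.fft.ifft2(imfft * filt))

        sum_e = sum(np.real(r) for r in responses)
        sum_o = sum(np.imag(r) for r in responses)
        sum_an = sum(np.abs(r) for r in responses)
        x_energy = np.sqrt(sum_e**2 + sum_o**2) + epsilon
        mean_e, mean_o = sum_e / x_energy, sum_o / x_energy
        energy = np.zeros((rows, cols))
        for r in responses:
            e, od = np.real(r), np.imag(r)
            energy += e * mean_e + od * mean_o - np.abs(e * mean_o - od * mean_e)

        median_e2n = float(np.median(np.abs(responses[0]) ** 2))
        noise_power = (-median_e2n / np.log(0.5)) / em_n if em_n > 0 else 0.0
        sum_an2 = 0.0
        sum_aiaj = 0.0
        for si in range(nscale):
            sum_an2 += float((ifft_filters[si] ** 2).sum())
            for sj in range(si + 1, nscale):
                sum_aiaj += float((ifft_filters[si] * ifft_filters[sj]).sum())
        noise_energy2 = 2.0 * noise_power * sum_an2 + 4.0 * noise_power * sum_aiaj
        tau = np.sqrt(max(noise_energy2, 0.0) / 2.0)
        t_threshold = (tau * np.sqrt(np.pi / 2) + k * np.sqrt((2 - np.pi / 2) * tau**2)) / 1.7
        energy_all += np.maximum(energy - t_threshold, 0.0)
        an_all += sum_an
    return energy_all / (an_all + epsilon)


def reference_fsim(img1: np.ndarray, img2: np.ndarray, t1: float = 0.85,
                   t2: float = 160.0) -> float:
    """Reference FSIM for images already on a common [0, 255]-like scale."""
    img1 = np.asarray(img1, dtype=float)
    img2 = np.asarray(img2, dtype=float)
    pc1 = reference_phase_congruency(img1)
    pc2 = reference_phase_congruency(img2)
    scharr_x = np.array([[3, 0, -3], [10, 0, -10], [3, 0, -3]], dtype=float) / 16.0

    def grad_mag(img: np.ndarray) -> np.ndarray:
        rows, cols = img.shape
        padded = np.pad(img, 2)
        gx = np.zeros_like(img)
        gy = np.zeros_like(img)
        for r in range(rows):
            for cidx in range(cols):
                # full convolution (kernel flipped) restricted to 'same'
                acc_x = 0.0
                acc_y = 0.0
                for dr in range(3):
                    for dcol in range(3):
                        v = padded[r + 1 + (2 - dr), cidx + 1 + (2 - dcol)]
                        acc_x += scharr_x[dr, dcol] * v
                        acc_y += scharr_x.T[dr, dcol] * v
                gx[r, cidx] = acc_x
                gy[r, cidx] = acc_y
        return np.sqrt(gx**2 + gy**2)

    g1, g2 = grad_mag(img1), grad_mag(img2)
    num = 0.0
    den = 0.0
    rows, cols = img1.shape
    for r in range(rows):
        for cidx in range(cols):
            s_pc = (2 * pc1[r, cidx] * pc2[r, cidx] + t1) / (
                pc1[r, cidx] ** 2 + pc2[r, cidx] ** 2 + t1
            )
            s_g = (2 * g1[r, cidx] * g2[r, cidx] + t2) / (
                g1[r, cidx] ** 2 + g2[r, cidx] ** 2 + t2
            )
            w = max(pc1[r, cidx], pc2[r, cidx])
            num += s_pc * s_g * w
            den += w
    return num / (den + 1e-12)


def reference_uqi(img1: np.ndarray, img2: np.ndarray, window: int = 8) -> float:
    """Reference UQI: explicit loop over all fully interior windows."""
    x = np.asarray(img1, dtype=float)
    y = np.asarray(img2, dtype=float)
    rows, cols = x.shape
    values = []
    for r in range(rows - window + 1):
        for cidx in range(cols - window + 1):
            wx = x[r : r + window, cidx : cidx + window].ravel()
            wy = y[r : r + window, cidx : cidx + window].ravel()
            mx, my = wx.mean(), wy.mean()
            sxx = wx.var(ddof=1)
            syy = wy.var(ddof=1)
            sxy = float(np.cov(wx, wy, ddof=1)[0, 1])
            lum_den = mx * mx + my * my
            lum = 2 * mx * my / lum_den if lum_den > 1e-12 else 1.0
            con_den = sxx + syy
            con = 2 * np.sqrt(sxx * syy) / con_den if con_den > 1e-12 else 1.0
            cor_den = np.sqrt(sxx * syy)
            cor = sxy / cor_den if cor_den > 1e-12 else 1.0
            values.append(lum * con * cor)
    return float(np.mean(values))
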