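"""Signal conditioning: wavelet ECG denoising and PPG baseline removal.

ECG is decomposed with the Symlet-8 wavelet into eight scales; the scale-8
approximation is zeroed (baseline drift), the scale-1 detail is zeroed
(high-frequency muscle noise) and the remaining detail scales are soft-
thresholded with the universal ("sqtwolog") threshold, each level using its
own robust noise estimate.

PPG baseline drift is fitted by a natural cubic spline through the pulse
valleys and subtracted, which pins the corrected signal to zero at every
valley.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy.interpolate import CubicSpline

__all__ = [
    "WaveletConfig",
    "universal_threshold",
    "denoise_ecg",
    "remove_ppg_baseline",
]


@dataclass
class WaveletConfig:
    """ECG denoising settings.

    ``noise_est`` selects where the noise scale sigma comes from: 'finest'
    (default) estimates it once from the level-1 detail coefficients, which
    are nearly pure noise at ECG sampling rates; 'per_level' estimates it
    from each level's own coefficients, which over-thresholds coarse scales
    where the heartbeat itself dominates.
    """

    wavelet_name: str = "sym8"
    levels: int = 8
    zeroed_approx_level: int = 8
    zeroed_detail_level: int = 1
    threshold_rule: str = "universal"
    threshold_mode: str = "soft"
    noise_est: str = "finest"

    def validate(self) -> None:
        if not 1 <= self.zeroed_detail_level <= self.levels:
            raise ValueError("zeroed_detail_level must lie in [1, levels]")
        if self.zeroed_approx_level != self.levels:
            raise ValueError("zeroed_approx_level must equal levels")
        if self.threshold_rule != "universal":
            raise ValueError(f"unsupported threshold rule {self.threshold_rule!r}")
        if self.threshold_mode != "soft":
            raise ValueError(f"unsupported threshold mode {self.threshold_mode!r}")
        if self.noise_est not in ("finest", "per_level"):
            raise ValueError(f"unsupported noise estimate {self.noise_est!r}")


def universal_threshold(detail_coeffs: np.ndarray) -> float:
    """Universal (sqtwolog) threshold sigma*sqrt(2 ln N).

    The noise scale sigma is the median absolute coefficient divided by
    0.6745, the MAD-consistent estimate under Gaussian noise.
    """
    d = np.asarray(detail_coeffs, dtype=float)
    if d.size == 0:
        raise ValueError("detail coefficient sequence is empty")
    sigma = np.median(np.abs(d)) / 0.6745
    return float(sigma * np.sqrt(2.0 * np.log(d.size)))


def denoise_ecg(signal: np.ndarray, cfg: WaveletConfig | None = None) -> np.ndarray:
    """Wavelet-threshold denoise an ECG trace; output has the input's length."""
    cfg = cfg or WaveletConfig()
    cfg.validate()
    x = np.asarray(signal, dtype=float)
    min_len = 2 ** cfg.levels
    if x.size < min_len:
        raise ValueError(
            f"signal too short for a {cfg.levels}-level decomposition: "
            f"need at least {min_len} samples, got {x.size}"
        )
    coeffs = pywt.wavedec(x, cfg.wavelet_name, level=cfg.levels, mode="symmetric")
    # coeffs = [cA_L, cD_L, ..., cD_1]
    coeffs[0] = np.zeros_like(coeffs[0])
    sigma_finest = np.median(np.abs(coeffs[-1])) / 0.6745
    for level in range(1, cfg.levels + 1):
        pos = cfg.levels - level + 1  # detail level -> position in coeffs
        if level == cfg.zeroed_detail_level:
            coeffs[pos] = np.zeros_like(coeffs[pos])
        else:
            if cfg.noise_est == "finest":
                thr = sigma_finest * np.sqrt(2.0 * np.log(coeffs[pos].size))
            else:
                thr = universal_threshold(coeffs[pos])
            if thr > 0:
                coeffs[pos] = pywt.threshold(coeffs[pos], thr, mode=cfg.threshold_mode)
    rec = pywt.waverec(coeffs, cfg.wavelet_name, mode="symmetric")
    return rec[: x.size]


def remove_ppg_baseline(signal: np.ndarray, valley_indices: np.ndarray) -> np.ndarray:
    """Subtract a natural cubic spline fitted through the pulse valleys.

    The corrected signal is exactly zero at every valley index. At least
    four strictly increasing valleys are required for a stable cubic fit.
    """
    x = np.asarray(signal, dtype=float)
    v = np.asarray(valley_indices, dtype=int)
    if v.size < 4:
        raise ValueError(
            "need at least 4 pulse valleys to fit the baseline spline; "
            "supply a longer segment"
        )
    if np.any(np.diff(v) <= 0):
        raise ValueError("valley indices must be strictly increasing")
    if v[0] < 0 or v[-1] >= x.size:
        raise ValueError("valley index out of bounds")
    spline = CubicSpline(v, x[v], bc_type="natural")
    baseline = spline(np.arange(x.size))
    out = x - baseline
    out[v] = 0.0  # exact at the knots by construction; remove float residue
    return out
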