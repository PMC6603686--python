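"""Synthetic paired ECG/PPG/ABP generator and feature-table simulator.

Every downstream stage (denoising, fiducial detection, feature extraction,
model fitting, feature-impact analysis) is exercised against this module's
output, for which the ground truth is known by construction.

Two generators are provided:

``simulate_subject``
    Emits a beat-by-beat record: an impulse-like ECG R wave per beat, a PPG
    pulse whose five fiducial landmarks (onset *b*, maximum-slope point *a*,
    systolic peak *c*, minimum-slope point *e*, dicrotic peak *g*) are known
    in closed form, and an ABP waveform whose per-beat extrema equal the
    stored reference SBP/DBP exactly (noise-free case). The PPG pulse is a
    piecewise raised-cosine: systolic rise, fall to a dicrotic notch, a
    smaller dicrotic wave, and a slow decay back to the baseline, so all
    landmark positions and heights are analytic functions of the shape
    fractions.

``simulate_feature_dataset``
    Skips the waveform layer and draws per-beat feature vectors directly,
    with SBP/DBP labels produced by a known smooth mapping of a *causal*
    feature subset plus Gaussian noise; the remaining features are inert.
    This is the substrate for parameter-recovery and feature-ranking tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import SignalRecord

__all__ = [
    "SimConfig",
    "GroundTruth",
    "EffectSpec",
    "EFFECTS",
    "simulate_subject",
    "simulate_feature_dataset",
]


@dataclass
class SimConfig:
    """Generator settings for one synthetic subject.

    Morphology fractions are expressed relative to the pulse cycle length:
    the systolic peak sits at ``rise_frac``, the dicrotic notch at
    ``notch_frac`` and the dicrotic peak at ``dicrotic_peak_frac`` of the
    onset-to-onset interval. ``ptt_s`` is the R-peak to pulse-onset delay.
    """

    duration_s: float = 60.0
    fs: float = 125.0
    hr_bpm: float | np.ndarray = 75.0
    ptt_s: float | np.ndarray = 0.25
    sbp_mmhg: float | np.ndarray = 120.0
    dbp_mmhg: float | np.ndarray = 80.0
    pulse_amp: float = 1.0
    dicrotic_rel_height: float = 0.30
    notch_rel_height: float = 0.12
    rise_frac: float = 0.18
    notch_frac: float = 0.42
    dicrotic_peak_frac: float = 0.54
    r_wave_width_s: float = 0.02  # Gaussian sigma; ~0.1 s QRS footprint
    drift_amp: float = 0.0
    drift_freq: float = 0.25
    noise_sigma: float = 0.0
    abp_noise_sigma: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        hr = np.atleast_1d(np.asarray(self.hr_bpm, dtype=float))
        if np.any(hr < 20) or np.any(hr > 220):
            raise ValueError("hr_bpm must lie in [20, 220]")
        ptt = np.atleast_1d(np.asarray(self.ptt_s, dtype=float))
        if np.any(ptt <= 0):
            raise ValueError("ptt_s must be positive")
        if np.max(ptt) >= np.min(60.0 / hr):
            raise ValueError("ptt_s must be smaller than the beat period 60/hr_bpm")
        if not (0 < self.rise_frac < self.notch_frac < self.dicrotic_peak_frac < 1):
            raise ValueError("shape fractions must satisfy 0 < rise < notch < dicrotic < 1")
        if not (0 <= self.notch_rel_height < self.dicrotic_rel_height < 1):
            raise ValueError("need notch below dicrotic peak below systolic peak")


@dataclass
class GroundTruth:
    """Per-beat truth for a simulated record (only fully contained beats)."""

    r_peaks: np.ndarray
    i_b: np.ndarray
    i_a: np.ndarray
    i_c: np.ndarray
    i_e: np.ndarray
    i_g: np.ndarray
    sbp: np.ndarray
    dbp: np.ndarray
    h_a: np.ndarray
    h_c: np.ndarray
    h_e: np.ndarray
    h_g: np.ndarray

    @property
    def n_beats(self) -> int:
        return len(self.r_peaks)

    def validate(self, n_samples: int) -> None:
        for name in ("r_peaks", "i_b"):
            idx = getattr(self, name)
            if np.any(np.diff(idx) <= 0):
                raise ValueError(f"{name} must be strictly increasing")
        for arr in (self.i_b, self.i_a, self.i_c, self.i_e, self.i_g):
            if np.any(arr < 0) or np.any(arr >= n_samples):
                raise ValueError("landmark index out of record bounds")
        ok = (self.i_b < self.i_a) & (self.i_a <= self.i_c) & (self.i_c < self.i_e) & (
            self.i_e <= self.i_g
        )
        if not np.all(ok):
            raise ValueError("landmark ordering b < a <= c < e <= g violated")


def _per_beat(value, n: int, name: str) -> np.ndarray:
    """Broadcast a scalar or per-beat sequence to n beats (last value repeats)."""
    arr = np.atleast_1d(np.asarray(value, dtype=float))
    if arr.size >= n:
        return arr[:n].astype(float)
    return np.concatenate([arr, np.full(n - arr.size, arr[-1])])


def _pulse_template(u: np.ndarray, cfg: SimConfig) -> np.ndarray:
    """Piecewise raised-cosine pulse on normalized cycle time u in [0, 1)."""
    t1, t2, t3 = cfg.rise_frac, cfg.notch_frac, cfg.dicrotic_peak_frac
    hc = cfg.pulse_amp
    hn = cfg.notch_rel_height * hc
    hg = cfg.dicrotic_rel_height * hc
    out = np.empty_like(u)
    m = u < t1
    out[m] = hc * (1 - np.cos(np.pi * u[m] / t1)) / 2
    m = (u >= t1) & (u < t2)
    out[m] = hn + (hc - hn) * (1 + np.cos(np.pi * (u[m] - t1) / (t2 - t1))) / 2
    m = (u >= t2) & (u < t3)
    out[m] = hn + (hg - hn) * (1 - np.cos(np.pi * (u[m] - t2) / (t3 - t2))) / 2
    m = u >= t3
    out[m] = hg * (1 + np.cos(np.pi * (u[m] - t3) / (1 - t3))) / 2
    return out


def simulate_subject(config: SimConfig) -> tuple[SignalRecord, GroundTruth]:
    """Generate one synthetic subject record with per-beat ground truth.

    Deterministic for a given seed: all noise streams are spawned from
    ``config.seed``. Reference SBP/DBP are realized exactly as the per-beat
    ABP extrema before any ABP noise is added.
    """
    config.validate()
    fs = config.fs
    n = int(round(config.duration_s * fs))

    # --- beat grid ---------------------------------------------------------
    max_beats = int(np.ceil(config.duration_s * 220 / 60)) + 2
    hr = _per_beat(config.hr_bpm, max_beats, "hr_bpm")
    rr = np.round(60.0 / hr * fs).astype(int)
    r0 = int(round(0.1 * fs))
    r_peaks = []
    r = r0
    k = 0
    while r < n:
        r_peaks.append(r)
        r += rr[min(k, len(rr) - 1)]
        k += 1
    r_peaks = np.array(r_peaks, dtype=int)
    nb = len(r_peaks)
    ptt = _per_beat(config.ptt_s, nb, "ptt_s")
    sbp = _per_beat(config.sbp_mmhg, nb, "sbp_mmhg")
    dbp = _per_beat(config.dbp_mmhg, nb, "dbp_mmhg")
    if np.any(sbp <= dbp):
        raise ValueError("sbp_mmhg must exceed dbp_mmhg for every beat")

    onsets = r_peaks + np.round(ptt * fs).astype(int)

    # --- ECG: Ricker (Mexican-hat) R wave centered on each beat; zero-mean
    # like an AC-coupled ECG, with Q/S-like side lobes ----------------------
    ecg = np.zeros(n)
    t = np.arange(n)
    w = config.r_wave_width_s * fs
    for r in r_peaks:
        lo, hi = max(0, r - int(6 * w)), min(n, r + int(6 * w) + 1)
        u = (t[lo:hi] - r) / w
        ecg[lo:hi] += (1 - u**2) * np.exp(-0.5 * u**2)

    # --- PPG and ABP, cycle by cycle ---------------------------------------
    ppg = np.zeros(n)
    abp_base = np.mean(dbp)
    abp = np.full(n, abp_base)
    t1, t2, t3 = config.rise_frac, config.notch_frac, config.dicrotic_peak_frac
    hc = config.pulse_amp
    kept = []  # beats with a complete cycle inside the record
    for k in range(nb):
        o = onsets[k]
        o_next = onsets[k + 1] if k + 1 < nb else None
        L = (o_next - o) if o_next is not None else rr[min(k, len(rr) - 1)]
        stop = min(n, o + L)
        if o >= n or stop <= o:
            continue
        u = (np.arange(o, stop) - o) / L
        ppg[o:stop] = _pulse_template(u, config)
        # ABP: raised cosine rescaled so the sampled extrema hit SBP/DBP exactly
        shape = (1 - np.cos(2 * np.pi * u)) / 2
        peak = shape.max()
        if peak > 0:
            shape = shape / peak
        abp[o:stop] = dbp[k] + (sbp[k] - dbp[k]) * shape
        if o_next is not None and stop == o + L and stop <= n:
            kept.append(k)

    kept = np.array(kept, dtype=int)
    L_kept = onsets[kept + 1] - onsets[kept]
    gt = GroundTruth(
        r_peaks=r_peaks[kept],
        i_b=onsets[kept],
        i_a=onsets[kept] + np.round(t1 / 2 * L_kept).astype(int),
        i_c=onsets[kept] + np.round(t1 * L_kept).astype(int),
        i_e=onsets[kept] + np.round((t1 + t2) / 2 * L_kept).astype(int),
        i_g=onsets[kept] + np.round(t3 * L_kept).astype(int),
        sbp=sbp[kept],
        dbp=dbp[kept],
        h_a=np.full(len(kept), hc / 2),
        h_c=np.full(len(kept), hc),
        h_e=np.full(len(kept), (hc + config.notch_rel_height * hc) / 2),
        h_g=np.full(len(kept), config.dicrotic_rel_height * hc),
    )
    gt.validate(n)

    # --- drift and noise ----------------------------------------------------
    tt = t / fs
    if config.drift_amp:
        drift = config.drift_amp * np.sin(2 * np.pi * config.drift_freq * tt)
        ecg = ecg + drift
        ppg = ppg + drift
    if config.noise_sigma or config.abp_noise_sigma:
        streams = np.random.SeedSequence(config.seed).spawn(3)
        if config.noise_sigma:
            ecg = ecg + np.random.default_rng(streams[0]).normal(0, config.noise_sigma, n)
            ppg = ppg + np.random.default_rng(streams[1]).normal(0, config.noise_sigma, n)
        if config.abp_noise_sigma:
            abp = abp + np.random.default_rng(streams[2]).normal(
                0, config.abp_noise_sigma, n
            )

    record = SignalRecord(ecg=ecg, ppg=ppg, abp=abp, fs=fs, meta={"seed": config.seed})
    return record, gt


# ---------------------------------------------------------------------------
# Direct feature-table generator
# ---------------------------------------------------------------------------

#: canonical feature order shared with :mod:`pttbp.features`
_FEATURE_NAMES = [
    "PTTb", "PTTa", "PTTc", "K", "HR", "Tupr", "Tdownr",
    "Cslope", "Har", "Her", "Hgr", "S1", "S2", "S1_over_S2",
]


@dataclass
class EffectSpec:
    """A named smooth feature→BP mapping with declared causal subsets."""

    name: str
    causal_sbp: list[str]
    causal_dbp: list[str]
    sbp_fn: callable = field(repr=False, default=None)
    dbp_fn: callable = field(repr=False, default=None)

    def inert(self, target: str) -> list[str]:
        causal = self.causal_sbp if target == "SBP" else self.causal_dbp
        return [f for f in _FEATURE_NAMES if f not in causal]


def _sbp_nonlinear(f: dict) -> np.ndarray:
    return (
        102.0
        + 13.2 * np.exp(-5.0 * (f["PTTc"] - 0.38))
        + 50.0 * (f["K"] - 0.40)
        + 0.155 * (f["HR"] - 77.5)
        + 0.83 * (f["Cslope"] - 5.0)
        + 11.7 * (f["Hgr"] - 0.25)
        + 10.0 * (f["Her"] - 0.40)
        + 15.0 * (f["Har"] - 0.50)
        + 15.0 * (f["K"] - 0.40) * (f["Cslope"] - 5.0)
    )


def _dbp_nonlinear(f: dict) -> np.ndarray:
    return (
        58.0
        + 6.1 * np.exp(-5.0 * (f["PTTc"] - 0.38))
        + 0.178 * (f["HR"] - 77.5)
        + 15.0 * (f["Her"] - 0.40)
        + 11.7 * (f["Hgr"] - 0.25)
        + 15.0 * (f["K"] - 0.40)
        + 0.50 * (f["Cslope"] - 5.0)
        + 15.0 * (f["Har"] - 0.50)
        + 1.0 * (f["Her"] - 0.40) * (f["HR"] - 77.5)
    )


def _sbp_linear(f: dict) -> np.ndarray:
    return 80.0 - 100.0 * f["PTTc"] + 60.0 * f["K"] + 0.30 * f["HR"]


def _dbp_linear(f: dict) -> np.ndarray:
    return 50.0 - 60.0 * f["PTTc"] + 0.25 * f["HR"]


EFFECTS: dict[str, EffectSpec] = {
    "nonlinear": EffectSpec(
        name="nonlinear",
        causal_sbp=["PTTc", "K", "HR", "Cslope", "Hgr", "Her", "Har"],
        causal_dbp=["HR", "PTTc", "Her", "Hgr", "K", "Cslope", "Har"],
        sbp_fn=_sbp_nonlinear,
        dbp_fn=_dbp_nonlinear,
    ),
    "linear": EffectSpec(
        name="linear",
        causal_sbp=["PTTc", "K", "HR"],
        causal_dbp=["PTTc", "HR"],
        sbp_fn=_sbp_linear,
        dbp_fn=_dbp_linear,
    ),
}


#: share of a tone-driven feature's spread owed to the latent factor
_TONE_MIX = 0.7


def _sample_features(rng: np.random.Generator, n: int) -> dict[str, np.ndarray]:
    """Draw physiologically plausible per-beat feature values.

    The waveform-shape features do not vary independently in real pulses:
    they all reflect the same underlying vascular state. A latent "tone"
    factor (higher = stiffer/more constricted) therefore drives PTTc, K,
    Cslope, Her, Hgr and Har jointly, each with independent residual
    variation. PTTb (pre-ejection plus proximal transit) is kept nearly
    constant, as for a single resting subject, and the complementary pairs
    (Tupr/Tdownr, S1/S2) are exact complements by definition.
    """
    tone = rng.uniform(0.0, 1.0, n)

    def mixed(sign: int = +1) -> np.ndarray:
        t = tone if sign > 0 else 1.0 - tone
        return _TONE_MIX * t + (1.0 - _TONE_MIX) * rng.uniform(0.0, 1.0, n)

    f: dict[str, np.ndarray] = {}
    f["PTTb"] = rng.uniform(0.19, 0.21, n)
    f["PTTa"] = f["PTTb"] + rng.uniform(0.035, 0.045, n)
    f["PTTc"] = f["PTTa"] + 0.06 + 0.16 * mixed(-1)  # stiffer -> faster wave
    f["K"] = 0.30 + 0.20 * mixed()
    f["HR"] = rng.uniform(55.0, 100.0, n)
    f["Tupr"] = rng.uniform(0.25, 0.40, n)
    f["Tdownr"] = 1.0 - f["Tupr"]
    f["Cslope"] = 2.0 + 6.0 * mixed()
    f["Har"] = 0.40 + 0.20 * mixed()
    f["Her"] = 0.25 + 0.30 * mixed()
    f["Hgr"] = 0.10 + 0.30 * mixed()
    f["S1"] = rng.uniform(0.55, 0.75, n)
    f["S2"] = 1.0 - f["S1"]
    f["S1_over_S2"] = f["S1"] / f["S2"]
    return f


def simulate_feature_dataset(
    n: int,
    effect: str | EffectSpec = "nonlinear",
    noise_sigma: float = 1.0,
    seed: int = 0,
):
    """Draw ``n`` feature rows and noisy SBP/DBP labels from a known mapping.

    Parameters
    ----------
    n
        Number of beats (rows); at least 10.
    effect
        Name of a registered :class:`EffectSpec` or a spec instance. The
        default ``"nonlinear"`` mapping combines an exponential transit-time
        term, linear waveform terms of graded strength and a mild
        K-by-Cslope (SBP) / Her-by-HR (DBP) interaction.
    noise_sigma
        Standard deviation of the Gaussian label noise, mmHg. The default of
        1 mmHg reflects beat-to-beat reference ABP reading variability.
    seed
        Seed for both feature sampling and label noise.

    Returns
    -------
    FeatureDataset
        With ``meta['effect']`` set to the effect spec used.
    """
    from .features import FeatureDataset  # local import avoids a cycle

    if n < 10:
        raise ValueError(f"need at least 10 rows, got {n}")
    spec = EFFECTS[effect] if isinstance(effect, str) else effect
    rng = np.random.default_rng(seed)
    f = _sample_features(rng, n)
    sbp = spec.sbp_fn(f) + rng.normal(0, noise_sigma, n)
    dbp = spec.dbp_fn(f) + rng.normal(0, noise_sigma, n)

    import pandas as pd

    features = pd.DataFrame({name: f[name] for name in _FEATURE_NAMES})
    labels = pd.DataFrame({"SBP": sbp, "DBP": dbp})
    provenance = [f"synthetic:{spec.name}:{seed}"] * n
    return FeatureDataset(
        features=features,
        labels=labels,
        provenance=provenance,
        meta={"effect": spec, "noise_sigma": noise_sigma, "seed": seed},
    )
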