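"""Fiducial-point detection and beat assembly.

Detects ECG R-peaks, locates the five PPG landmarks per pulse (onset *b*,
maximum-slope point *a*, systolic peak *c*, minimum-slope point *e*,
dicrotic peak *g*), pairs each R-peak with its pulse, and reads per-cycle
reference SBP/DBP from the ABP channel. Pulses missing any landmark (e.g.
a monotone decay with no dicrotic wave) are dropped, not patched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

from .io import SignalRecord

__all__ = [
    "PulseLandmarks",
    "Beat",
    "detect_r_peaks",
    "detect_pulse_valleys",
    "detect_pulse_landmarks",
    "pair_beats",
    "reference_bp",
    "annotate_beats",
]

log = logging.getLogger(__name__)

#: minimum spacing between R-peaks (ventricular refractory period), seconds
REFRACTORY_S = 0.2


@dataclass
class PulseLandmarks:
    """Sample indices and onset-referenced heights of one pulse's landmarks."""

    i_b: int
    i_a: int
    i_c: int
    i_e: int
    i_g: int
    h_a: float
    h_c: float
    h_e: float
    h_g: float

    def is_valid(self) -> bool:
        order = self.i_b < self.i_a <= self.i_c < self.i_e <= self.i_g
        heights = (
            self.h_c > 0
            and 0 <= self.h_a <= self.h_c
            and 0 <= self.h_e <= self.h_c
            and 0 <= self.h_g <= self.h_c
        )
        return bool(order and heights)


@dataclass
class Beat:
    """One cardiac cycle: R-peak, pulse landmarks, cycle bounds, references."""

    r_index: int
    landmarks: PulseLandmarks
    cycle: tuple[int, int]  # half-open [i_b, i_b_next)
    rr_s: float
    sbp_ref: float | None = None
    dbp_ref: float | None = None

    def validate(self) -> None:
        if self.rr_s <= 0:
            raise ValueError("rr_s must be positive")
        lo, hi = self.cycle
        lm = self.landmarks
        if not (lo <= lm.i_b and lm.i_g < hi):
            raise ValueError("cycle does not contain all landmark indices")
        if self.sbp_ref is not None and self.dbp_ref is not None:
            if self.sbp_ref <= self.dbp_ref:
                raise ValueError("sbp_ref must exceed dbp_ref")


def detect_r_peaks(ecg: np.ndarray, fs: float) -> np.ndarray:
    """Detect R-peaks by a differentiate–square–moving-average energy detector.

    The squared first difference is smoothed over a 150 ms window; peaks of
    that envelope above an adaptive fraction of its maximum, separated by at
    least the 200 ms refractory period, are refined to the local ECG maximum.
    A flat trace yields an empty index array.
    """
    x = np.asarray(ecg, dtype=float)
    if fs <= 0:
        raise ValueError("fs must be positive")
    if x.size < int(2 * fs):
        raise ValueError("need at least 2 s of ECG")
    d = np.diff(x)
    if not np.any(d):
        return np.array([], dtype=int)
    energy = uniform_filter1d(d * d, size=max(3, int(0.15 * fs)))
    refractory = max(1, int(REFRACTORY_S * fs))
    height = 0.25 * energy.max()
    cand, _ = find_peaks(energy, height=height, distance=refractory)
    if cand.size == 0:
        return np.array([], dtype=int)
    # refine each detection to the ECG maximum in a +/-80 ms neighborhood
    half = max(1, int(0.08 * fs))
    peaks = []
    for c in cand:
        lo, hi = max(0, c - half), min(x.size, c + half + 1)
        peaks.append(lo + int(np.argmax(x[lo:hi])))
    peaks = np.unique(peaks)
    # enforce the refractory period, keeping the taller of two close peaks
    out: list[int] = []
    for p in peaks:
        if out and p - out[-1] < refractory:
            if x[p] > x[out[-1]]:
                out[-1] = p
        else:
            out.append(p)
    return np.array(out, dtype=int)


def _walk_back_to_valley(x: np.ndarray, start: int, lo: int) -> int:
    """Last local minimum before ``start``: step left while strictly rising."""
    i = start
    while i > lo and x[i - 1] < x[i]:
        i -= 1
    return i


def detect_pulse_valleys(ppg: np.ndarray, fs: float) -> np.ndarray:
    """Pulse-foot (valley) indices, e.g. as knots for baseline removal.

    Runs on a lightly smoothed copy so that broadband noise does not spoof
    the valley walk-back; indices refer to the original signal.
    """
    x = np.asarray(ppg, dtype=float)
    smooth = uniform_filter1d(x, size=max(3, int(0.06 * fs)))
    peaks, _ = find_peaks(
        smooth, distance=max(1, int(0.3 * fs)), prominence=0.25 * np.ptp(smooth)
    )
    valleys = []
    prev = 0
    for p in peaks:
        seg = smooth[prev:p]
        if seg.size:
            # last index attaining the minimum: the pulse foot, not an
            # earlier point of a flat or drifting diastolic tail
            valleys.append(prev + seg.size - 1 - int(np.argmin(seg[::-1])))
        prev = p
    return np.array(sorted(set(valleys)), dtype=int)


def detect_pulse_landmarks(
    ppg: np.ndarray, fs: float, with_stats: bool = False
) -> list[PulseLandmarks] | tuple[list[PulseLandmarks], dict]:
    """Locate the five landmarks of each pulse in a baseline-removed PPG.

    Per pulse: *b* is the local minimum preceding the systolic peak, *a* the
    maximum of the first difference on (b, c), *c* the pulse maximum, *e*
    the minimum of the first difference on (c, next b) and *g* the first
    local maximum after *e* (the dicrotic wave). Pulses missing any
    landmark, or violating the ordering/height invariants, are dropped and
    counted; set ``with_stats=True`` to receive the drop counter.
    """
    x = np.asarray(ppg, dtype=float)
    peaks, _ = find_peaks(
        x, distance=max(1, int(0.3 * fs)), prominence=0.25 * np.ptp(x) if np.ptp(x) else 1.0
    )
    stats = {"n_pulses": int(peaks.size), "n_dropped": 0}
    out: list[PulseLandmarks] = []
    if peaks.size == 0:
        return (out, stats) if with_stats else out

    onsets = []
    prev = 0
    for p in peaks:
        onsets.append(_walk_back_to_valley(x, p, prev))
        prev = p

    for k, c in enumerate(peaks):
        b = onsets[k]
        bound = onsets[k + 1] if k + 1 < len(peaks) else x.size - 1
        lm = _locate_one(x, b, c, bound)
        if lm is None:
            stats["n_dropped"] += 1
            log.debug("pulse at sample %d dropped: missing/invalid landmarks", c)
        else:
            out.append(lm)
    if stats["n_dropped"]:
        log.info(
            "dropped %d of %d pulses lacking a full landmark set",
            stats["n_dropped"], stats["n_pulses"],
        )
    return (out, stats) if with_stats else out


def _extreme_plateau_mid(d: np.ndarray, sign: int) -> int:
    """Index of the extreme of ``sign*d``; ties (flat ramps) resolve to the
    middle of the extremal plateau, so a triangle's max-slope point is the
    midpoint of its rise."""
    v = sign * d
    m = v.max()
    tol = 1e-9 * max(1.0, abs(m))
    idx = np.flatnonzero(v >= m - tol)
    return int(idx[(len(idx) - 1) // 2])


def _locate_one(x: np.ndarray, b: int, c: int, bound: int) -> PulseLandmarks | None:
    if not (b < c < bound):
        return None
    rise = np.diff(x[b : c + 1])
    if rise.size == 0:
        return None
    a = b + _extreme_plateau_mid(rise, sign=+1)
    if a <= b:
        a = b + 1
    fall = np.diff(x[c : bound + 1])
    if fall.size == 0:
        return None
    e = c + _extreme_plateau_mid(fall, sign=-1)
    if e <= c:
        e = c + 1
    # first local maximum strictly after e (dicrotic peak)
    g = None
    for i in range(e + 1, bound):
        if x[i - 1] < x[i] and x[i] >= x[i + 1]:
            g = i
            break
    if g is None:
        return None
    base = x[b]
    lm = PulseLandmarks(
        i_b=b, i_a=a, i_c=c, i_e=e, i_g=g,
        h_a=float(x[a] - base), h_c=float(x[c] - base),
        h_e=float(x[e] - base), h_g=float(x[g] - base),
    )
    return lm if lm.is_valid() else None


def pair_beats(
    r_peaks: np.ndarray,
    landmark_sets: list[PulseLandmarks],
    fs: float,
    max_delay_s: float = 0.6,
) -> list[Beat]:
    """Pair R-peaks with pulses whose onset follows within ``max_delay_s``.

    Each R-peak takes the first unconsumed pulse with onset in
    ``(r, r + max_delay_s]``; unpaired R-peaks and pulses are skipped. The
    beat's cycle runs from its pulse onset to the next detected pulse onset,
    and RR comes from consecutive detected R-peaks, so a beat whose R-peak
    or pulse has no successor is dropped.
    """
    r_peaks = np.asarray(r_peaks, dtype=int)
    if r_peaks.size == 0 or not landmark_sets:
        return []
    max_delay = max_delay_s * fs
    onsets = np.array([lm.i_b for lm in landmark_sets])
    beats: list[Beat] = []
    j = 0
    for i, r in enumerate(r_peaks):
        while j < len(landmark_sets) and onsets[j] <= r:
            j += 1
        if j >= len(landmark_sets):
            break
        if onsets[j] - r > max_delay:
            continue  # no pulse for this beat
        if i + 1 >= r_peaks.size or j + 1 >= len(landmark_sets):
            break  # need a successor for RR and the cycle end
        lm = landmark_sets[j]
        cycle = (lm.i_b, int(onsets[j + 1]))
        rr_s = (r_peaks[i + 1] - r) / fs
        if lm.i_g < cycle[1]:
            beats.append(Beat(r_index=int(r), landmarks=lm, cycle=cycle, rr_s=rr_s))
        j += 1
    return beats


def reference_bp(abp: np.ndarray, cycle: tuple[int, int]) -> tuple[float, float]:
    """Reference (SBP, DBP) = per-cycle (max, min) of the ABP waveform."""
    lo, hi = cycle
    x = np.asarray(abp, dtype=float)
    if not (0 <= lo < hi <= x.size):
        raise ValueError(f"empty or out-of-bounds cycle {cycle}")
    seg = x[lo:hi]
    return float(seg.max()), float(seg.min())


def annotate_beats(
    record: SignalRecord,
    max_delay_s: float = 0.6,
    require_abp: bool = True,
) -> list[Beat]:
    """Full fiducial chain on a conditioned record: R-peaks, landmarks, pairing
    and (when ABP is present) reference SBP/DBP per cycle."""
    r_peaks = detect_r_peaks(record.ecg, record.fs)
    landmarks = detect_pulse_landmarks(record.ppg, record.fs)
    beats = pair_beats(r_peaks, landmarks, record.fs, max_delay_s=max_delay_s)
    if record.abp is None:
        if require_abp:
            raise ValueError("record has no ABP channel; reference BP unavailable")
        return beats
    for beat in beats:
        sbp, dbp = reference_bp(record.abp, beat.cycle)
        beat.sbp_ref, beat.dbp_ref = sbp, dbp
    return [b for b in beats if b.sbp_ref > b.dbp_ref]
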