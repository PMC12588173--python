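"""Greenwood frequency-position mapping and tonotopic-rate analysis.

The organ of Corti (OC) tonotopic map follows Greenwood's function

    F(x) = A * (10**(a*x) - k),

where ``x`` is the *proportional distance from the apex* along the basilar
membrane (x = 0 at the helicotrema, x = 1 at the base), so frequency
increases basally.  Default constants are the standard human values
A = 165.4 Hz, a = 2.1, k = 0.88.

Spiral-ganglion (SG) tonotopy is obtained by transfer: each traced
peripheral dendrite carries the OC frequency at its basilar-membrane
attachment to its ganglion attachment, which captures the non-radial
dendrite trajectories of the cochlear apex.

Frequency differences are expressed in semitones (12 * log2 of the
frequency ratio); rate-of-change profiles give semitones per millimeter or
per degree of angular depth.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import (
    AttachmentError,
    DomainError,
    FitFailureError,
    InvalidInputError,
)
from .geometry import AngleProfile, Centerline3D

__all__ = [
    "GreenwoodParams",
    "DEFAULT_GREENWOOD",
    "TonotopicMap",
    "DendriteTrace",
    "RateProfile",
    "greenwood_forward",
    "greenwood_inverse",
    "fit_greenwood",
    "GreenwoodFit",
    "map_oc_frequencies",
    "attach_dendrites",
    "transfer_to_sg",
    "semitone_difference",
    "rate_of_change",
    "octave_bands",
]


@dataclass(frozen=True)
class GreenwoodParams:
    """Constants of the Greenwood function F(x) = A*(10**(a*x) - k).

    A is in Hz; a and k are dimensionless.  The defaults are the standard
    human cochlear values (A = 165.4, a = 2.1, k = 0.88), which place the
    apical limit at ~20 Hz and the basal limit at ~20.7 kHz.
    """

    A: float = 165.4
    a: float = 2.1
    k: float = 0.88

    def __post_init__(self):
        if not (self.A > 0 and self.a > 0 and 0 <= self.k < 1):
            raise InvalidInputError(
                f"invalid Greenwood parameters A={self.A}, a={self.a}, k={self.k}"
            )

    @property
    def f_min(self) -> float:
        """Apical (x = 0) frequency, Hz."""
        return self.A * (1.0 - self.k)

    @property
    def f_max(self) -> float:
        """Basal (x = 1) frequency, Hz."""
        return self.A * (10.0 ** self.a - self.k)


DEFAULT_GREENWOOD = GreenwoodParams()


def _greenwood(x, p: GreenwoodParams):
    return p.A * (10.0 ** (p.a * np.asarray(x, dtype=float)) - p.k)


def greenwood_forward(x, params: GreenwoodParams = DEFAULT_GREENWOOD):
    """Frequency (Hz) at proportional distance ``x`` from the apex.

    ``x`` may be a scalar or array in [0, 1]; strictly increasing in x.
    """
    xa = np.asarray(x, dtype=float)
    if np.any(xa < 0) or np.any(xa > 1):
        raise DomainError("proportional distance x must lie in [0, 1]")
    out = _greenwood(xa, params)
    return float(out) if np.isscalar(x) or xa.ndim == 0 else out


def greenwood_inverse(f, params: GreenwoodParams = DEFAULT_GREENWOOD):
    """Proportional distance from apex at frequency ``f`` (Hz).

    Inverse of :func:`greenwood_forward`: x = log10(f/A + k) / a, defined for
    f in [A*(1-k), A*(10**a - k)].
    """
    fa = np.asarray(f, dtype=float)
    lo, hi = params.f_min, params.f_max
    tol = 1e-9 * hi
    if np.any(fa < lo - tol) or np.any(fa > hi + tol):
        raise DomainError(
            f"frequency outside the Greenwood range [{lo:.6g}, {hi:.6g}] Hz"
        )
    out = np.log10(np.clip(fa, lo, hi) / params.A + params.k) / params.a
    out = np.clip(out, 0.0, 1.0)
    return float(out) if np.isscalar(f) or fa.ndim == 0 else out


@dataclass(frozen=True)
class GreenwoodFit:
    """Result of :func:`fit_greenwood`."""

    params: GreenwoodParams
    converged: bool
    cost: float
    message: str


def fit_greenwood(samples, init: GreenwoodParams | None = None) -> GreenwoodFit:
    """Nonlinear least-squares fit of Greenwood constants to (x, f) samples.

    Residuals are taken in log10-frequency space, since cochlear frequencies
    span three decades and the perceptually meaningful error is relative.
    Requires at least 4 samples with distinct x in [0, 1] and positive f.
    """
    arr = np.asarray(samples, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise InvalidInputError("samples must be an iterable of (x, frequency) pairs")
    x, f = arr[:, 0], arr[:, 1]
    if len(np.unique(x)) < 4:
        raise InvalidInputError("need >= 4 samples with distinct x")
    if np.any(x < 0) or np.any(x > 1):
        raise DomainError("sample x values must lie in [0, 1]")
    if np.any(f <= 0):
        raise DomainError("sample frequencies must be positive")
    p0 = init or DEFAULT_GREENWOOD
    logf = np.log10(f)

    def resid(theta):
        A, a, k = theta
        return np.log10(A * (10.0 ** (a * x) - k)) - logf

    res = optimize.least_squares(
        resid,
        x0=[p0.A, p0.a, p0.k],
        bounds=([1e-9, 1e-9, 0.0], [np.inf, np.inf, 1.0 - 1e-12]),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
        max_nfev=2000,
    )
    if not res.success:
        raise FitFailureError(
            f"Greenwood fit did not converge: {res.message}",
            last_params=GreenwoodParams(*res.x),
        )
    return GreenwoodFit(
        params=GreenwoodParams(*res.x),
        converged=True,
        cost=float(res.cost),
        message=res.message,
    )


@dataclass(frozen=True)
class TonotopicMap:
    """Per-point tonotopic record for one structure (OC or SG).

    Arrays are aligned: ``s`` arc position (mm from base), ``x`` proportional
    distance from apex, ``angle_deg`` unwrapped angular depth and ``freq_hz``
    characteristic frequency.  Frequencies decrease from base to apex.
    """

    s: np.ndarray
    x: np.ndarray
    angle_deg: np.ndarray
    freq_hz: np.ndarray
    label: str = "OC"

    def __post_init__(self):
        s = np.asarray(self.s, dtype=float)
        x = np.asarray(self.x, dtype=float)
        ang = np.asarray(self.angle_deg, dtype=float)
        f = np.asarray(self.freq_hz, dtype=float)
        if not (len(s) == len(x) == len(ang) == len(f)):
            raise InvalidInputError("tonotopic map arrays must be aligned")
        if len(s) < 2:
            raise InvalidInputError("a tonotopic map needs at least 2 points")
        if np.any(np.diff(s) <= 0):
            raise InvalidInputError("arc positions must be strictly increasing")
        if np.any(f <= 0):
            raise DomainError("frequencies must be positive")
        for name, a in (("s", s), ("x", x), ("angle_deg", ang), ("freq_hz", f)):
            object.__setattr__(self, name, a)

    def freq_at_s(self, s):
        """Frequency at arc position(s) ``s``, interpolated in log2-frequency."""
        out = 2.0 ** np.interp(np.asarray(s, dtype=float), self.s, np.log2(self.freq_hz))
        return float(out) if np.ndim(s) == 0 else out

    def freq_at_angle(self, angle_deg):
        """Frequency at angular depth(s), interpolated in log2-frequency."""
        out = 2.0 ** np.interp(
            np.asarray(angle_deg, dtype=float), self.angle_deg, np.log2(self.freq_hz)
        )
        return float(out) if np.ndim(angle_deg) == 0 else out

    @property
    def angular_length(self) -> float:
        return float(self.angle_deg[-1] - self.angle_deg[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "s_mm": self.s,
                "x": self.x,
                "angle_deg": self.angle_deg,
                "freq_hz": self.freq_hz,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, label: str = "OC") -> "TonotopicMap":
        need = {"s_mm", "x", "angle_deg", "freq_hz"}
        if not need.issubset(df.columns):
            raise InvalidInputError(f"map table needs columns {sorted(need)}")
        return cls(
            df["s_mm"].to_numpy(),
            df["x"].to_numpy(),
            df["angle_deg"].to_numpy(),
            df["freq_hz"].to_numpy(),
            label=label,
        )


def map_oc_frequencies(
    bm: Centerline3D,
    angles: AngleProfile,
    params: GreenwoodParams = DEFAULT_GREENWOOD,
) -> TonotopicMap:
    """Build the organ-of-Corti tonotopic map from the BM centerline.

    Each landmark's proportional distance from the apex is
    x = (L_total - s) / L_total and its frequency is Greenwood's F(x); the
    resulting map is strictly decreasing in arc position (base to apex).
    """
    if len(angles.angles_deg) != len(bm.points):
        raise InvalidInputError("angle profile not aligned with centerline")
    s = bm.cum_length
    x = (bm.total_length - s) / bm.total_length
    return TonotopicMap(s, x, angles.angles_deg, greenwood_forward(x, params), label="OC")


@dataclass(frozen=True)
class DendriteTrace:
    """A traced peripheral dendrite linking the BM to the spiral ganglion.

    ``points`` run from the basilar-membrane end (index 0) to the ganglion
    end; ``bm_attach``/``sg_attach`` are arc positions (mm) on the BM and SG
    centerlines, set at construction or by :func:`attach_dendrites`.
    """

    points: np.ndarray
    bm_attach: float | None = None
    sg_attach: float | None = None
    name: str = ""

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 2:
            raise InvalidInputError("a dendrite trace needs >= 2 3D points")
        object.__setattr__(self, "points", pts)


def attach_dendrites(
    dendrites,
    bm: Centerline3D,
    sg: Centerline3D,
    tol: float = 0.2,
) -> list[DendriteTrace]:
    """Project dendrite endpoints onto their centerlines and record arc positions.

    The first point of each trace attaches to the BM, the last to the SG.
    An endpoint farther than ``tol`` mm from its centerline raises
    :class:`AttachmentError` identifying the trace.
    """
    out = []
    for i, tr in enumerate(dendrites):
        name = tr.name or f"dendrite[{i}]"
        s_bm, d_bm = bm.project(tr.points[0])
        if d_bm > tol:
            raise AttachmentError(
                f"{name}: BM endpoint is {d_bm:.3f} mm from the BM centerline (tol {tol})"
            )
        s_sg, d_sg = sg.project(tr.points[-1])
        if d_sg > tol:
            raise AttachmentError(
                f"{name}: SG endpoint is {d_sg:.3f} mm from the SG centerline (tol {tol})"
            )
        out.append(replace(tr, bm_attach=s_bm, sg_attach=s_sg))
    return out


def transfer_to_sg(
    oc_map: TonotopicMap,
    dendrites,
    sg: Centerline3D,
    sg_angles: AngleProfile,
    tol: float = 0.2,
) -> TonotopicMap:
    """Transfer OC frequencies to the spiral ganglion along traced dendrites.

    Each dendrite contributes one SG record: its frequency is the OC map
    frequency at the dendrite's BM attachment (log2-linear interpolation in
    arc position) and its position/angle are those of the SG attachment.
    Records are sorted by SG arc position; coincident attachments are
    averaged geometrically (semitone linearity).
    """
    dendrites = list(dendrites)
    if len(dendrites) < 2:
        raise InvalidInputError("need at least 2 dendrites to map the SG")
    if len(sg_angles.angles_deg) != len(sg.points):
        raise InvalidInputError("SG angle profile not aligned with SG centerline")

    s_list, f_list = [], []
    for i, tr in enumerate(dendrites):
        name = tr.name or f"dendrite[{i}]"
        if tr.bm_attach is None:
            raise AttachmentError(
                f"{name}: missing BM attachment; run attach_dendrites first"
            )
        s_sg = tr.sg_attach
        if s_sg is None:
            s_sg, d_sg = sg.project(tr.points[-1])
            if d_sg > tol:
                raise AttachmentError(
                    f"{name}: SG endpoint is {d_sg:.3f} mm from the SG centerline (tol {tol})"
                )
        s_list.append(float(s_sg))
        f_list.append(oc_map.freq_at_s(tr.bm_attach))

    s_arr = np.asarray(s_list)
    f_arr = np.asarray(f_list)
    order = np.argsort(s_arr, kind="stable")
    s_arr, f_arr = s_arr[order], f_arr[order]

    # geometric mean over coincident SG positions
    uniq, inv = np.unique(np.round(s_arr, 9), return_inverse=True)
    log_f = np.zeros(len(uniq))
    counts = np.bincount(inv)
    np.add.at(log_f, inv, np.log2(f_arr))
    log_f /= counts

    ang = np.interp(uniq, sg.cum_length, sg_angles.angles_deg)
    x = (sg.total_length - uniq) / sg.total_length
    return TonotopicMap(uniq, x, ang, 2.0 ** log_f, label="SG")


def semitone_difference(f1: float, f2: float) -> float:
    """Absolute semitone difference between two frequencies: |12*log2(f1/f2)|."""
    if f1 <= 0 or f2 <= 0:
        raise DomainError("frequencies must be positive")
    return abs(12.0 * np.log2(f1 / f2))


@dataclass(frozen=True)
class RateProfile:
    """Tonotopic rate of change: semitones per mm or per degree."""

    position: np.ndarray
    rate: np.ndarray
    unit: str  # "semitones/mm" or "semitones/deg"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"position": self.position, f"rate_{self.unit.replace('/', '_per_')}": self.rate})

    def total_semitones(self) -> float:
        """Integral of the rate over the structure (trapezoid rule)."""
        return float(np.trapezoid(self.rate, self.position))


def _moving_average_window(p: np.ndarray, y: np.ndarray, window: float) -> np.ndarray:
    """Boxcar-average y over a window in p-units, shrunk symmetrically at edges.

    Symmetric shrinking keeps a linear series exactly linear at the ends, so
    an exponential frequency map yields a constant rate everywhere.
    """
    half = np.minimum(window / 2.0, np.minimum(p - p[0], p[-1] - p))
    lo = np.searchsorted(p, p - half, side="left")
    hi = np.searchsorted(p, p + half, side="right")
    csum = np.concatenate([[0.0], np.cumsum(y)])
    return (csum[hi] - csum[lo]) / (hi - lo)


def rate_of_change(
    tmap: TonotopicMap,
    axis: str = "length",
    smoothing_window: float | None = None,
) -> RateProfile:
    """Semitones of tonotopic change per unit position along the structure.

    ``axis`` selects curvilinear length (mm) or angular depth (degrees);
    the log2-frequency series is smoothed by a moving average over
    ``smoothing_window`` position units (default 1 mm or 30 degrees), then
    differentiated by central finite differences (one-sided at the ends).
    """
    if axis == "length":
        p = tmap.s
        unit = "semitones/mm"
        window = 1.0 if smoothing_window is None else smoothing_window
    elif axis == "angle":
        p = tmap.angle_deg
        unit = "semitones/deg"
        window = 30.0 if smoothing_window is None else smoothing_window
    else:
        raise InvalidInputError("axis must be 'length' or 'angle'")
    if len(p) < 3:
        raise InvalidInputError("need at least 3 points for a rate profile")
    if np.any(np.diff(p) <= 0):
        raise InvalidInputError(f"{axis} positions must be strictly increasing")

    log2f = np.log2(tmap.freq_hz)
    smooth = _moving_average_window(p, log2f, window) if window > 0 else log2f
    rate = 12.0 * np.abs(np.gradient(smooth, p))
    return RateProfile(position=p.copy(), rate=rate, unit=unit)


def octave_bands(tmap: TonotopicMap, ref_hz: float) -> pd.DataFrame:
    """Octave-band boundary positions along a tonotopic map.

    Boundaries are placed at ``ref_hz * 2**n`` for every integer n within
    the map's frequency range; positions come from monotone interpolation of
    the map.  Returns a DataFrame with columns freq_hz, s_mm, angle_deg,
    sorted by ascending frequency.
    """
    f = tmap.freq_hz
    fmin, fmax = float(f.min()), float(f.max())
    if not (fmin <= ref_hz <= fmax):
        raise DomainError(f"reference {ref_hz} Hz outside map range [{fmin:.6g}, {fmax:.6g}]")
    rel_tol = 1e-9
    n_lo = int(np.ceil(np.log2(fmin / ref_hz) - rel_tol))
    n_hi = int(np.floor(np.log2(fmax / ref_hz) + rel_tol))
    freqs = ref_hz * 2.0 ** np.arange(n_lo, n_hi + 1)

    log2f = np.log2(f)
    order = np.argsort(log2f)
    s_b = np.interp(np.log2(freqs), log2f[order], tmap.s[order])
    a_b = np.interp(np.log2(freqs), log2f[order], tmap.angle_deg[order])
    return pd.DataFrame({"freq_hz": freqs, "s_mm": s_b, "angle_deg": a_b})
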