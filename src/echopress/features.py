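"""Echo feature extraction: envelope, peak detection, parabolic sub-sample fit.

The echo amplitude that enters the impedance inversion is the peak of the
signal envelope, and the time of flight is the (sub-sample) location of
that peak.  The envelope is the magnitude of the analytic signal; each
echo's peak is refined by a least-squares parabola over the samples near
the local maximum, which gives both quantities with sub-sample resolution
and a goodness-of-fit diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, hilbert

from .exceptions import AggregationError, DetectionError, FitError
from .synthetic import ALineRecord

__all__ = [
    "EchoFeature",
    "analytic_envelope",
    "detect_echoes",
    "parabolic_peak_fit",
    "extract_features",
    "build_feature_table",
    "aggregate_features",
]

# Peaks below this fraction of the strongest envelope sample are treated as
# noise, not candidate echoes.
_PEAK_HEIGHT_FRACTION = 0.1

FEATURE_COLUMNS = [
    "iop_mmHg", "eye_id", "repeat_id", "aline_id",
    "ant_amp", "ant_tof_s", "post_amp", "post_tof_s",
    "tof_diff_s", "polarity_post",
]


@dataclass(frozen=True)
class EchoFeature:
    """Fitted envelope peak of one echo.

    amplitude: envelope magnitude at the parabola vertex (>= 0);
    tof: vertex time in seconds (sub-sample); polarity: sign of the RF
    waveform at the peak (+1/-1); fit_window: [start, stop) sample range
    used for the fit; r2_of_fit: coefficient of determination of the
    parabola over that window.
    """

    amplitude: float
    tof: float
    polarity: int
    fit_window: tuple[int, int]
    r2_of_fit: float

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.polarity not in (1, -1):
            raise ValueError("polarity must be +1 or -1")


def analytic_envelope(samples: np.ndarray) -> np.ndarray:
    """Envelope as the magnitude of the analytic signal (Hilbert transform).

    Nonnegative, same length as the input, and invariant under sign flip
    of the waveform.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("record is empty")
    return np.abs(hilbert(samples))


def detect_echoes(
    envelope: np.ndarray,
    dt: float,
    min_separation: float = 0.2e-6,
) -> tuple[tuple[int, int], tuple[int, int]]:
    """Locate the two echo windows (anterior first) in an envelope.

    Finds local maxima at least ``min_separation`` apart and above 10% of
    the global maximum, keeps the two largest, and returns disjoint
    half-open sample windows centred on them, each clipped at the midpoint
    between the peaks.
    """
    envelope = np.asarray(envelope, dtype=float)
    if dt <= 0:
        raise ValueError("dt must be > 0")
    min_sep_samples = max(1, int(round(min_separation / dt)))
    height = _PEAK_HEIGHT_FRACTION * envelope.max() if envelope.size else 0.0
    peaks, props = find_peaks(envelope, height=height, distance=min_sep_samples)
    if len(peaks) < 2:
        raise DetectionError(
            f"found {len(peaks)} resolvable echo(es), need 2 "
            f"(min_separation = {min_separation:g} s)"
        )
    # Two strongest, then time order.
    strongest = peaks[np.argsort(props["peak_heights"])[-2:]]
    p_a, p_p = int(strongest.min()), int(strongest.max())
    if p_p - p_a < min_sep_samples:
        raise DetectionError("the two strongest peaks overlap within min_separation")
    half = min_sep_samples // 2
    mid = (p_a + p_p) // 2
    win_a = (max(0, p_a - half), min(p_a + half + 1, mid))
    win_p = (max(mid + 1, p_p - half), min(p_p + half + 1, envelope.size))
    return win_a, win_p


def parabolic_peak_fit(
    envelope: np.ndarray,
    window: tuple[int, int],
    dt: float,
    threshold_frac: float = 0.7,
) -> EchoFeature:
    """Least-squares parabola over the samples near a local envelope maximum.

    The fit uses the contiguous run of samples at or above
    ``threshold_frac`` of the window maximum, always including the maximum
    and its two neighbours (so at least three points enter the fit).  The
    vertex gives the amplitude and a sub-sample time of flight.  Raises
    :class:`FitError` if the maximum sits at a window edge or the fitted
    parabola does not open downward.
    """
    envelope = np.asarray(envelope, dtype=float)
    start, stop = window
    if not (0 <= start < stop <= envelope.size):
        raise ValueError(f"window {window} outside record of {envelope.size} samples")
    seg = envelope[start:stop]
    imax = int(np.argmax(seg))
    if imax == 0 or imax == seg.size - 1:
        raise FitError(f"envelope maximum at window edge (index {start + imax})")
    peak = seg[imax]
    thr = threshold_frac * peak
    lo = imax
    while lo > 0 and seg[lo - 1] >= thr:
        lo -= 1
    hi = imax
    while hi < seg.size - 1 and seg[hi + 1] >= thr:
        hi += 1
    # Guarantee the three samples around the maximum.
    lo = min(lo, imax - 1)
    hi = max(hi, imax + 1)
    if hi - lo + 1 < 3:
        raise FitError("fewer than 3 samples available for the parabola fit")

    x = np.arange(lo, hi + 1, dtype=float) - imax  # centred for conditioning
    y = seg[lo : hi + 1]
    a, b, c = np.polyfit(x, y, 2)
    if a >= 0:
        raise FitError("fitted parabola does not open downward")
    x_vertex = -b / (2.0 * a)
    amplitude = float(c - b * b / (4.0 * a))
    tof = (start + imax + x_vertex) * dt
    resid = y - np.polyval([a, b, c], x)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - float(np.sum(resid**2)) / ss_tot)
    return EchoFeature(
        amplitude=max(amplitude, 0.0),
        tof=float(tof),
        polarity=1,
        fit_window=(start + lo, start + hi + 1),
        r2_of_fit=min(r2, 1.0),
    )


def extract_features(
    record: ALineRecord,
    min_separation: float = 0.2e-6,
    threshold_frac: float = 0.7,
) -> tuple[EchoFeature, EchoFeature]:
    """Envelope -> detect -> fit for one A-line; returns (anterior, posterior).

    Each feature's polarity is the sign of the raw RF waveform at the
    sample of largest magnitude inside its fit window, so a phase-inverted
    posterior echo (Z2 > Z3) is flagged -1.
    """
    env = analytic_envelope(record.samples)
    win_a, win_p = detect_echoes(env, record.dt, min_separation)
    feats = []
    for win in (win_a, win_p):
        f = parabolic_peak_fit(env, win, record.dt, threshold_frac)
        lo, hi = f.fit_window
        seg = record.samples[lo:hi]
        pol = 1 if seg[np.argmax(np.abs(seg))] >= 0 else -1
        feats.append(
            EchoFeature(
                amplitude=f.amplitude, tof=f.tof, polarity=pol,
                fit_window=f.fit_window, r2_of_fit=f.r2_of_fit,
            )
        )
    ant, post = feats
    if not ant.tof < post.tof:
        raise DetectionError("anterior echo must precede posterior echo")
    return ant, post


def build_feature_table(
    records: list[ALineRecord],
    min_separation: float = 0.2e-6,
    threshold_frac: float = 0.7,
) -> pd.DataFrame:
    """Feature table with one row per A-line (columns ``FEATURE_COLUMNS``)."""
    rows = []
    for rec in records:
        ant, post = extract_features(rec, min_separation, threshold_frac)
        rows.append(
            {
                "iop_mmHg": rec.iop,
                "eye_id": rec.eye_id,
                "repeat_id": rec.repeat_id,
                "aline_id": rec.aline_id,
                "ant_amp": ant.amplitude,
                "ant_tof_s": ant.tof,
                "post_amp": post.amplitude,
                "post_tof_s": post.tof,
                "tof_diff_s": post.tof - ant.tof,
                "polarity_post": post.polarity,
            }
        )
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)


def aggregate_features(table: pd.DataFrame) -> pd.DataFrame:
    """Per-IOP means and standard deviations of the echo features.

    A-lines are pooled within each repeat, then repeats averaged with
    equal weight (identical to a grand mean for the balanced default
    design); the dispersion is the standard deviation over all A-lines.
    """
    if table.empty:
        raise AggregationError("feature table is empty")
    quantities = {"ant_amp": "ant_amp", "post_amp": "post_amp", "tof_diff_s": "tof_diff"}
    per_repeat = table.groupby(["iop_mmHg", "eye_id", "repeat_id"], as_index=False)[
        list(quantities)
    ].mean()
    means = per_repeat.groupby("iop_mmHg")[list(quantities)].mean()
    sds = table.groupby("iop_mmHg")[list(quantities)].std(ddof=1).fillna(0.0)
    out = pd.DataFrame(index=means.index)
    for col, label in quantities.items():
        out[f"{label}_mean"] = means[col]
        out[f"{label}_sd"] = sds[col]
    out["n_alines"] = table.groupby("iop_mmHg").size()
    return out.reset_index()
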