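"""Time-series toolkit: Morlet wavelets, multi-resolution analysis,
cross-correlation causality and transfer-function gains.

The toolkit serves one purpose: detect cyclical structure in
strategy-frequency and abundance series from the simulator, attribute each
time scale to a process (density-dependent recruitment vs. the mating
game), and read directional influence between strategies off lag
asymmetries of their cross-correlation functions.

Conventions
-----------
* Morlet central frequency ``omega0 = 6``, so a wavelet scale corresponds
  closely to a Fourier period; dyadic period grid, 8 voices per octave.
* MRA components are labelled by the lower period edge of their dyadic
  band: component ``2**j`` covers periods in ``[2**j, 2**(j+1))``.
* ``cross_correlation(x, y)`` evaluates ``r(l) = corr(x_t, y_{t+l})``; a
  positive asymmetry ``sum_{l>0} (r(l) - r(-l))`` means x's past
  co-varies with y's future, read as x driving y with the sign of the
  peak correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy import signal

MORLET_OMEGA0 = 6.0
_MORLET_CENTER = MORLET_OMEGA0 / (2.0 * np.pi)
_MORLET_WAVELET = f"cmor2.0-{_MORLET_CENTER:.8f}"
#: Cone-of-influence slope: e-folding distance sqrt(2)*scale expressed as
#: the maximum trustworthy period at distance d from the nearest edge.
_COI_PERIOD_PER_STEP = 1.0 / (_MORLET_CENTER * np.sqrt(2.0))

MIN_SPECTRAL_LENGTH = 64
DYADIC_BANDS = (4, 8, 16, 32)


def _as_series(x, min_length=2) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if x.size < min_length:
        raise ValueError(f"series too short ({x.size} < {min_length})")
    if not np.isfinite(x).all():
        raise ValueError("series contains non-finite values")
    return x


@dataclass
class WaveletSpectrum:
    """Morlet continuous-wavelet power of one series."""

    power: np.ndarray  # (n_periods, n_times)
    periods: np.ndarray
    coi: np.ndarray  # max trustworthy period per time point
    global_power: np.ndarray  # time-averaged power outside the cone of influence

    def band_peak(self, period_min: float, period_max: float):
        """Period and power of the global-spectrum maximum within a band."""
        sel = (self.periods >= period_min) & (self.periods <= period_max)
        if not sel.any():
            raise ValueError("no analysed periods inside the requested band")
        idx = np.flatnonzero(sel)
        best = idx[np.argmax(self.global_power[idx])]
        return float(self.periods[best]), float(self.global_power[best])


def dyadic_periods(n: int, voices_per_octave: int = 8, max_fraction: float = 1 / 16):
    """Dyadic period grid from 2 up to ``n * max_fraction``.

    The default ceiling of n/16 keeps at least a dozen cone-of-influence-free
    cycles at the largest period, so the time-averaged (global) spectrum
    retains enough degrees of freedom to be flat on white noise; pass an
    explicit grid for slower structure at the cost of estimator variance.
    """
    top = np.log2(n * max_fraction)
    return 2.0 ** np.arange(1.0, top + 1e-9, 1.0 / voices_per_octave)


def cwt_power(
    series,
    periods=None,
    voices_per_octave: int = 8,
    detrend: bool = True,
) -> WaveletSpectrum:
    """Morlet continuous wavelet transform power of a series.

    The series mean is removed before the transform.  The global spectrum
    is the time average of power at each period, restricted to the region
    outside the cone of influence (edge-affected values are excluded; for
    periods with no interior support the full-time average is used).
    """
    x = _as_series(series, MIN_SPECTRAL_LENGTH)
    if detrend:
        x = x - x.mean()
    n = x.size
    if periods is None:
        periods = dyadic_periods(n, voices_per_octave)
    periods = np.asarray(periods, dtype=float)
    if np.any(np.diff(periods) <= 0):
        raise ValueError("periods must be strictly increasing")
    scales = _MORLET_CENTER * periods
    # precision=14: the default sampling of the wavelet is too coarse at
    # large scales and leaks spurious power there
    coef, _ = pywt.cwt(x, scales, _MORLET_WAVELET, precision=14)
    power = np.abs(coef) ** 2
    edge_dist = np.minimum(np.arange(n), np.arange(n)[::-1]).astype(float)
    coi = _COI_PERIOD_PER_STEP * edge_dist
    valid = periods[:, None] <= coi[None, :]
    with np.errstate(invalid="ignore"):
        global_power = np.where(
            valid.any(axis=1),
            np.nansum(np.where(valid, power, np.nan), axis=1)
            / np.maximum(valid.sum(axis=1), 1),
            power.mean(axis=1),
        )
    return WaveletSpectrum(power=power, periods=periods, coi=coi, global_power=global_power)


# ---------------------------------------------------------------------------
# multi-resolution analysis


@dataclass
class MRADecomposition:
    """Additive multi-resolution decomposition at dyadic scales.

    ``details[s]`` is the component at scale label ``s`` (periods s..2s);
    ``smooth`` is the remaining coarse trend.  Components sum to the
    original series to numerical precision.
    """

    details: dict
    smooth: np.ndarray
    original: np.ndarray

    @property
    def scales(self):
        return tuple(sorted(self.details))

    def reconstruct(self) -> np.ndarray:
        return sum(self.details.values()) + self.smooth

    def band_energy(self) -> dict:
        total = float(np.sum(self.original**2))
        if total == 0.0:
            return {s: 0.0 for s in self.details}
        return {s: float(np.sum(c**2)) / total for s, c in self.details.items()}


def mra_split(series, max_level: int = 6, wavelet: str = "sym8") -> MRADecomposition:
    """Maximal-overlap (stationary) wavelet multi-resolution decomposition.

    Uses a least-asymmetric 8-tap filter by default.  The series is
    symmetrically padded to a multiple of ``2**max_level`` internally and
    components are cropped back, preserving additivity exactly.
    """
    x = _as_series(series)
    n = x.size
    if n < 2**max_level:
        raise ValueError(f"series of length {n} too short for level {max_level}")
    m = int(np.ceil(n / 2**max_level)) * 2**max_level
    xp = np.pad(x, (0, m - n), mode="symmetric") if m > n else x
    comps = pywt.mra(xp, wavelet, level=max_level, transform="swt")
    # pywt returns [approx, detail_maxlevel, ..., detail_1]
    smooth = comps[0][:n]
    details = {
        2**level: comps[len(comps) - level][:n] for level in range(1, max_level + 1)
    }
    return MRADecomposition(details=details, smooth=smooth, original=x)


# ---------------------------------------------------------------------------
# cross-correlation and lag asymmetry


@dataclass
class CrossCorrelation:
    lags: np.ndarray
    values: np.ndarray
    asymmetry: float
    peak_lag: int
    peak_value: float

    @property
    def sign(self) -> int:
        """Sign of the correlation at the dominant lag."""
        return int(np.sign(self.peak_value))


def cross_correlation(x, y, max_lag: int) -> CrossCorrelation:
    """Normalized cross-correlation ``r(l) = corr(x_t, y_{t+l})`` for
    ``l in [-max_lag, max_lag]`` with the lag-asymmetry statistic
    ``sum_{l>0}(r(l) - r(-l))``.

    Both series are standardized internally; r(0) = 1 when ``y is x``.
    A symmetric function (asymmetry near 0) indicates no directed
    influence; the sign of the deviation carries the direction of the
    effect.
    """
    x = _as_series(x)
    y = _as_series(y)
    if x.size != y.size:
        raise ValueError("series must have equal length")
    n = x.size
    if max_lag >= n:
        raise ValueError("max_lag must be smaller than the series length")
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        raise ValueError("cross-correlation undefined for constant series")
    xs = (x - x.mean()) / sx
    ys = (y - y.mean()) / sy
    full = signal.correlate(ys, xs, mode="full") / n  # index n-1+l <-> lag l
    lags = np.arange(-max_lag, max_lag + 1)
    values = full[n - 1 - max_lag : n + max_lag]
    asym = float(np.sum(values[max_lag + 1 :] - values[:max_lag][::-1]))
    peak = int(np.argmax(np.abs(values)))
    return CrossCorrelation(
        lags=lags,
        values=values,
        asymmetry=asym,
        peak_lag=int(lags[peak]),
        peak_value=float(values[peak]),
    )


def asymmetry_pvalue(x, y, max_lag: int, n_perm: int = 200, rng=None) -> float:
    """Permutation p-value for the lag-asymmetry statistic.

    The null is built from random circular shifts of y, which preserve the
    autocorrelation of both series while destroying their alignment.
    """
    if rng is None:
        rng = np.random.default_rng()
    x = _as_series(x)
    y = _as_series(y)
    obs = abs(cross_correlation(x, y, max_lag).asymmetry)
    n = y.size
    exceed = 0
    for _ in range(n_perm):
        shift = int(rng.integers(1, n))
        null = abs(cross_correlation(x, np.roll(y, shift), max_lag).asymmetry)
        if null >= obs:
            exceed += 1
    return (1 + exceed) / (n_perm + 1)


def band_asymmetries(
    x,
    y,
    bands=DYADIC_BANDS,
    n_perm: int = 200,
    rng=None,
    max_level: int = 6,
):
    """Cross-correlation asymmetry of x -> y per dyadic MRA band.

    Both series are MRA-decomposed; for each band scale ``b`` the
    asymmetry between the two band components is computed over a lag
    window of ``2 b`` steps, with a circular-shift permutation p-value.
    Returns a list of dicts (band, asymmetry, pvalue, peak_lag, peak_value).
    """
    if rng is None:
        rng = np.random.default_rng()
    mx = mra_split(x, max_level=max_level)
    my = mra_split(y, max_level=max_level)
    out = []
    for b in bands:
        cx, cy = mx.details[b], my.details[b]
        cc = cross_correlation(cx, cy, max_lag=2 * b)
        p = asymmetry_pvalue(cx, cy, max_lag=2 * b, n_perm=n_perm, rng=rng)
        out.append(
            {
                "band": b,
                "asymmetry": cc.asymmetry,
                "pvalue": p,
                "peak_lag": cc.peak_lag,
                "peak_value": cc.peak_value,
            }
        )
    return out


def dominant_band(band_stats, alpha: float = 0.05):
    """Band with the largest significant |asymmetry| (None if none is)."""
    sig = [b for b in band_stats if b["pvalue"] <= alpha]
    if not sig:
        return None
    return max(sig, key=lambda b: abs(b["asymmetry"]))["band"]


# ---------------------------------------------------------------------------
# transfer-function gain


@dataclass
class GainSpectrum:
    frequencies: np.ndarray
    periods: np.ndarray
    gain: np.ndarray

    def band_gain(self, period_min: float, period_max: float) -> float:
        sel = (self.periods >= period_min) & (self.periods <= period_max)
        if not sel.any():
            raise ValueError("no estimated frequencies inside the requested band")
        return float(self.gain[sel].mean())


def gain_function(input_series, output_series, nperseg: int | None = None) -> GainSpectrum:
    """Frequency-domain transfer gain |cross-spectrum| / input auto-spectrum.

    Welch-type estimate with Hann taper and 50% overlap; the default
    segment length gives about eight overlapping segments.  Gain 1 means
    the input's cyclical variance passes through unattenuated; gain < 1
    means attenuation.
    """
    x = _as_series(input_series, MIN_SPECTRAL_LENGTH)
    y = _as_series(output_series, MIN_SPECTRAL_LENGTH)
    if x.size != y.size:
        raise ValueError("series must have equal length")
    n = x.size
    if nperseg is None:
        nperseg = max(MIN_SPECTRAL_LENGTH, int(round(2 * n / 9)))
    nperseg = min(nperseg, n)
    f, pxx = signal.welch(x, nperseg=nperseg, window="hann", detrend="constant")
    _, pxy = signal.csd(x, y, nperseg=nperseg, window="hann", detrend="constant")
    keep = f > 0
    f, pxx, pxy = f[keep], pxx[keep], pxy[keep]
    gain = np.abs(pxy) / pxx
    return GainSpectrum(frequencies=f, periods=1.0 / f, gain=gain)


# ---------------------------------------------------------------------------
# band attribution of spectral peaks


def dominant_periods(spectrum: WaveletSpectrum, bands=DYADIC_BANDS):
    """Local maxima of the global wavelet spectrum within dyadic bands.

    Band ``b`` spans periods [b, 2b).  Returns a list of dicts with the
    peak period, its power, and the power relative to the spectrum-wide
    median (a unitless prominence measure).
    """
    median = float(np.median(spectrum.global_power))
    out = []
    for b in bands:
        try:
            # half-open band [b, 2b) so adjacent bands never share a period
            period, power = spectrum.band_peak(b, 2 * b * (1 - 1e-9))
        except ValueError:
            continue
        out.append(
            {
                "band": b,
                "peak_period": period,
                "peak_power": power,
                "relative_power": power / median if median > 0 else np.inf,
            }
        )
    return out


def nearest_dyadic(period: float) -> int:
    """Dyadic period nearest to `period` in log2 space."""
    if period <= 0:
        raise ValueError("period must be positive")
    return int(2 ** round(np.log2(period)))
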