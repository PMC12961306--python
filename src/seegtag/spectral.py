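"""Low-frequency (broadband) neural-tracking core.

Implements the per-contact spectral pipeline used for frequency-tagged
speech paradigms: epoching around stimulus onset, baseline removal,
exclusion of the onset transient, per-trial Fourier spectra on the
remaining analysis segment, inter-trial phase coherence (ITPC), and
Rayleigh-Z normalization.

The analysis segment is 9 s by default (1--10 s post-onset), giving a
frequency resolution of 1/9 Hz, so the tagged linguistic rates of 1, 2,
and 4 Hz fall exactly on FFT bins 9, 18, and 36. No taper or zero
padding is applied: either would smear energy off that exact bin grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

#: Default epoch window relative to stimulus onset, seconds.
DEFAULT_WINDOW = (-0.5, 10.0)
#: Default analysis segment (post-onset), seconds. The first second is
#: discarded to avoid the transient auditory onset response.
DEFAULT_SEGMENT = (1.0, 10.0)
#: Band retained for low-frequency tracking statistics, Hz.
DEFAULT_BAND = (0.5, 4.5)


class SpectralError(ValueError):
    """Raised on contract violations in the spectral pipeline."""


@dataclass
class EpochedTrials:
    """Trials x time array for one contact and condition.

    Attributes
    ----------
    data : ndarray, shape (n_trials, n_times)
        Epoched signal, one row per trial.
    sfreq : float
        Sampling rate in Hz.
    window : tuple of float
        Epoch limits in seconds relative to stimulus onset.
    contact_id : str
    condition : str
    """

    data: np.ndarray
    sfreq: float
    window: tuple[float, float] = DEFAULT_WINDOW
    contact_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise SpectralError("epoch data must be 2-D (trials x time)")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds relative to stimulus onset."""
        n = self.data.shape[1]
        return self.window[0] + np.arange(n) / self.sfreq


@dataclass
class TrialSpectra:
    """Complex per-trial Fourier coefficients on a common frequency axis."""

    coeffs: np.ndarray  # complex, (n_trials, n_bins)
    freqs: np.ndarray  # Hz, (n_bins,)
    contact_id: str = ""
    condition: str = ""

    @property
    def n_trials(self) -> int:
        return self.coeffs.shape[0]

    def phases(self) -> np.ndarray:
        """Per-trial phase angles; NaN where the coefficient is exactly zero."""
        ph = np.angle(self.coeffs)
        ph = np.where(np.abs(self.coeffs) == 0.0, np.nan, ph)
        return ph


@dataclass
class ZSpectrum:
    """ITPC and Rayleigh-Z values on a frequency axis for one contact/condition.

    ``kind`` distinguishes the broadband low-frequency spectrum from the
    high-gamma envelope spectrum; both share this container.
    """

    freqs: np.ndarray
    itpc: np.ndarray
    z: np.ndarray
    n_trials: int
    contact_id: str = ""
    condition: str = ""
    kind: str = "broadband"

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.itpc = np.asarray(self.itpc, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if not (len(self.freqs) == len(self.itpc) == len(self.z)):
            raise SpectralError("freqs, itpc and z must be equal length")


def epoch_trials(
    signal: np.ndarray,
    sfreq: float,
    onsets: np.ndarray,
    window: tuple[float, float] = DEFAULT_WINDOW,
    contact_id: str = "",
    condition: str = "",
) -> EpochedTrials:
    """Cut a continuous single-channel signal into stimulus-locked epochs.

    Parameters
    ----------
    signal : 1-D array
        Continuous recording for one contact.
    onsets : array of float
        Stimulus onsets in seconds from the start of the recording, in
        presentation order (order is preserved in the output).
    window : (tmin, tmax)
        Epoch limits in seconds relative to each onset.

    Events whose full window does not fit inside the recording are
    dropped with a logged reason; if no event survives, an error is
    raised.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 1:
        raise SpectralError("epoch_trials expects a single channel (1-D signal)")
    tmin, tmax = window
    if not tmax > tmin:
        raise SpectralError(f"empty epoch window {window!r}")
    n_samp = int(round((tmax - tmin) * sfreq))
    if n_samp <= 0:
        raise SpectralError(f"empty epoch window {window!r}")

    rows = []
    for k, onset in enumerate(np.asarray(onsets, dtype=float)):
        start = int(round((onset + tmin) * sfreq))
        stop = start + n_samp
        if start < 0 or stop > signal.size:
            logger.warning(
                "dropping trial %d (onset %.3f s): window [%g, %g] s "
                "falls outside the recording",
                k, onset, onset + tmin, onset + tmax,
            )
            continue
        rows.append(signal[start:stop])
    if not rows:
        raise SpectralError("no usable trials: every event fell outside the recording")
    return EpochedTrials(
        np.stack(rows), sfreq, window, contact_id=contact_id, condition=condition
    )


def remove_baseline(
    epochs: EpochedTrials, baseline: tuple[float, float] = (-0.5, 0.0)
) -> EpochedTrials:
    """Subtract each trial's mean over the pre-stimulus baseline interval."""
    lo, hi = baseline
    if epochs.window[0] > lo or epochs.window[1] < hi:
        raise SpectralError(
            f"baseline {baseline!r} not contained in epoch window {epochs.window!r}"
        )
    t = epochs.times
    mask = (t >= lo) & (t < hi)
    if not mask.any():
        raise SpectralError("no pre-stimulus samples available for baseline removal")
    means = epochs.data[:, mask].mean(axis=1, keepdims=True)
    return replace(epochs, data=epochs.data - means)


def trim_transient(
    epochs: EpochedTrials, segment: tuple[float, float] = DEFAULT_SEGMENT
) -> EpochedTrials:
    """Restrict epochs to the analysis segment (default 1--10 s post-onset).

    The first second after stimulus onset carries the transient auditory
    onset response and is excluded; the remaining 9-s segment fixes the
    1/9 Hz bin grid.
    """
    lo, hi = segment
    if epochs.window[0] > lo or epochs.window[1] < hi:
        raise SpectralError(
            f"analysis segment {segment!r} not covered by epoch window {epochs.window!r}"
        )
    t = epochs.times
    # half-sample tolerance so tmax = window end is included exactly once
    mask = (t >= lo - 0.5 / epochs.sfreq) & (t < hi - 0.5 / epochs.sfreq)
    n_expect = int(round((hi - lo) * epochs.sfreq))
    idx = np.flatnonzero(mask)[:n_expect]
    if idx.size < n_expect:
        raise SpectralError(
            f"analysis segment shorter than {hi - lo:g} s "
            f"({idx.size} of {n_expect} samples)"
        )
    return replace(
        epochs, data=epochs.data[:, idx], window=(lo, hi)
    )


def trial_spectra(epochs: EpochedTrials) -> TrialSpectra:
    """Per-trial FFT of the analysis segment.

    Rectangular window, no zero padding: the bin spacing is exactly
    1/segment-length (1/9 Hz for the default 9-s segment) and the tagged
    rates fall on integer bins.
    """
    data = epochs.data
    n = data.shape[1]
    if n == 0:
        raise SpectralError("cannot compute spectra of empty trials")
    coeffs = np.fft.rfft(data, axis=1)
    freqs = np.fft.rfftfreq(n, d=1.0 / epochs.sfreq)
    return TrialSpectra(
        coeffs, freqs, contact_id=epochs.contact_id, condition=epochs.condition
    )


def compute_itpc(spectra: TrialSpectra) -> np.ndarray:
    """Inter-trial phase coherence per frequency bin.

    ITPC(f) = | (1/n) sum_r exp(i phi_r(f)) | where phi_r(f) is the
    Fourier phase of trial r at bin f. Bins where any trial has an
    exactly-zero coefficient (undefined phase) are returned as NaN
    rather than silently biased toward zero.
    """
    if spectra.n_trials < 2:
        raise SpectralError("ITPC requires at least 2 trials")
    coeffs = spectra.coeffs
    mag = np.abs(coeffs)
    undefined = (mag == 0.0).any(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(mag > 0, coeffs / np.where(mag == 0, 1.0, mag), 0.0)
    itpc = np.abs(unit.mean(axis=0))
    itpc = np.minimum(itpc, 1.0)  # clip fp overshoot at perfect coherence
    itpc[undefined] = np.nan
    return itpc


def rayleigh_z(itpc: np.ndarray | float, n_trials: int) -> np.ndarray | float:
    """Rayleigh Z statistic: z = n * ITPC**2.

    Under the null of uniform phases, E[z] = 1 and z is asymptotically
    Exp(1); z ranges over [0, n].
    """
    if n_trials < 2:
        raise SpectralError("Rayleigh Z requires at least 2 trials")
    itpc = np.asarray(itpc, dtype=float)
    if np.nanmin(itpc, initial=0.0) < 0 or np.nanmax(itpc, initial=0.0) > 1.0:
        raise SpectralError("ITPC values must lie in [0, 1]")
    z = n_trials * itpc**2
    return float(z) if z.ndim == 0 else z


def rayleigh_p(z: np.ndarray | float, n_trials: int) -> np.ndarray | float:
    """One-sided p-value of the Rayleigh test statistic z = n R**2.

    Uses the standard finite-n series correction to the asymptotic
    exp(-z) tail; accurate to ~1e-3 for n >= 10.
    """
    z = np.asarray(z, dtype=float)
    n = float(n_trials)
    p = np.exp(-z) * (
        1.0
        + (2.0 * z - z**2) / (4.0 * n)
        - (24.0 * z - 132.0 * z**2 + 76.0 * z**3 - 9.0 * z**4) / (288.0 * n**2)
    )
    p = np.clip(p, 0.0, 1.0)
    return float(p) if p.ndim == 0 else p


def zspectrum_from_epochs(
    epochs: EpochedTrials,
    baseline: tuple[float, float] = (-0.5, 0.0),
    segment: tuple[float, float] = DEFAULT_SEGMENT,
    kind: str = "broadband",
    do_baseline: bool = True,
) -> ZSpectrum:
    """Full broadband path: baseline removal, transient trim, FFT, ITPC, Z."""
    if do_baseline:
        epochs = remove_baseline(epochs, baseline)
    epochs = trim_transient(epochs, segment)
    spectra = trial_spectra(epochs)
    itpc = compute_itpc(spectra)
    z = rayleigh_z(itpc, spectra.n_trials)
    return ZSpectrum(
        spectra.freqs, itpc, z, spectra.n_trials,
        contact_id=epochs.contact_id, condition=epochs.condition, kind=kind,
    )


def extract_band(
    zspec: ZSpectrum, lo: float = DEFAULT_BAND[0], hi: float = DEFAULT_BAND[1]
) -> ZSpectrum:
    """Restrict a Z spectrum to [lo, hi] Hz inclusive."""
    if lo > hi:
        raise SpectralError(f"empty band [{lo}, {hi}]")
    eps = 1e-9
    mask = (zspec.freqs >= lo - eps) & (zspec.freqs <= hi + eps)
    if not mask.any():
        raise SpectralError(f"band [{lo}, {hi}] Hz contains no frequency bins")
    return ZSpectrum(
        zspec.freqs[mask], zspec.itpc[mask], zspec.z[mask], zspec.n_trials,
        contact_id=zspec.contact_id, condition=zspec.condition, kind=zspec.kind,
    )


def value_at_frequency(zspec: ZSpectrum, f_tag: float) -> float:
    """Z value at the bin nearest to ``f_tag``.

    The match must be within half a bin spacing; for 9-s segments the
    tagged rates 1, 2, 4 Hz match their bins exactly.
    """
    freqs = zspec.freqs
    if freqs.size == 0:
        raise SpectralError("empty spectrum")
    if f_tag < freqs.min() - 1e-9 or f_tag > freqs.max() + 1e-9:
        raise SpectralError(
            f"tag frequency {f_tag} Hz outside spectrum axis "
            f"[{freqs.min():g}, {freqs.max():g}] Hz"
        )
    i = int(np.argmin(np.abs(freqs - f_tag)))
    spacing = np.median(np.diff(freqs)) if freqs.size > 1 else np.inf
    if abs(freqs[i] - f_tag) > spacing / 2 + 1e-9:
        raise SpectralError(
            f"no bin within half a spacing of {f_tag} Hz (nearest {freqs[i]:g} Hz)"
        )
    return float(zspec.z[i])
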