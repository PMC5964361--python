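"""Filtering, stimulus-epoch detection, trial windowing and trial rejection.

Conventions used throughout: sample indexing is 0-based, time-to-sample
conversion uses round-half-even (``np.rint``), and analysis windows are
half-open ``[start, stop)``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import fft as sfft
from scipy import signal

from .synth import RawRecording

__all__ = [
    "FilterSpec",
    "TrialWindow",
    "design_bandpass_fir",
    "apply_filter",
    "detect_onsets_from_markers",
    "detect_onsets_from_fsr",
    "extract_trial_windows",
    "reject_noisy_trials",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterSpec:
    """Bandpass FIR design parameters (windowed-sinc, Hamming)."""

    low_cut: float = 800.0
    high_cut: float = 2200.0
    fs: float = 30000.0
    n_taps: int = 401
    design: str = "windowed_sinc_hamming"

    def __post_init__(self):
        if not (0 < self.low_cut < self.high_cut < self.fs / 2):
            raise ValueError(
                f"band edges must satisfy 0 < {self.low_cut} < "
                f"{self.high_cut} < fs/2 = {self.fs / 2}"
            )
        if self.n_taps % 2 != 1:
            raise ValueError("n_taps must be odd (symmetric, linear phase)")
        if self.design != "windowed_sinc_hamming":
            raise ValueError(f"unknown design {self.design!r}")


@dataclass
class TrialWindow:
    """One filtered analysis window (channels x samples) with its label."""

    class_id: int
    t_start: float
    t_len: float
    samples: np.ndarray
    trial_id: int

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]


def design_bandpass_fir(spec: FilterSpec) -> np.ndarray:
    """Linear-phase Hamming-window FIR bandpass taps.

    The default 401-tap design at 30 kHz holds the 900-2100 Hz band within
    +-0.5 dB of unity and attenuates 100 Hz and 10 kHz by more than 40 dB.
    """
    taps = signal.firwin(
        spec.n_taps,
        [spec.low_cut, spec.high_cut],
        pass_zero=False,
        window="hamming",
        fs=spec.fs,
    )
    # null the DC gain exactly (demeaning preserves symmetry and has
    # negligible effect elsewhere in the response)
    return taps - taps.mean()


def apply_filter(rec: RawRecording, taps: np.ndarray) -> RawRecording:
    """Zero-phase bandpass: forward FIR pass with group-delay compensation.

    For symmetric odd-length taps a 'same'-mode convolution centres the
    filter, i.e. shifts the forward pass back by (n_taps - 1) / 2 samples.
    Output length equals input length; markers, force trace and metadata
    are carried through unchanged.
    """
    taps = np.asarray(taps)
    if rec.n_samples < len(taps):
        raise ValueError(
            f"recording of {rec.n_samples} samples is shorter than the "
            f"{len(taps)}-tap filter"
        )
    # FFT convolution, 'same' windowing == forward pass shifted back by
    # (n_taps - 1) / 2 samples for symmetric odd-length taps
    n, m = rec.n_samples, len(taps)
    nfft = sfft.next_fast_len(n + m - 1)
    spectrum = sfft.rfft(rec.samples, nfft, axis=1) * sfft.rfft(taps, nfft)
    full = sfft.irfft(spectrum, nfft, axis=1)
    start = (m - 1) // 2
    filtered = full[:, start:start + n]
    return RawRecording(
        samples=filtered,
        fs=rec.fs,
        markers=list(rec.markers),
        fsr=None if rec.fsr is None else rec.fsr.copy(),
        layout=rec.layout,
        meta={**rec.meta, "filtered": True},
    )


def detect_onsets_from_markers(rec: RawRecording) -> list[tuple[float, int]]:
    """Return the recording's event markers, time-sorted."""
    if not rec.markers:
        warnings.warn("recording has no event markers", stacklevel=2)
        return []
    return sorted(rec.markers, key=lambda m: m[0])


def detect_onsets_from_fsr(
    fsr: np.ndarray,
    fs: float,
    threshold_k: float = 5.0,
    *,
    baseline_s: float = 1.0,
    sustain_s: float = 0.02,
) -> list[tuple[float, float]]:
    """Stimulus ON/OFF epochs from a force-sensor trace.

    The threshold is baseline_median + threshold_k * baseline_MAD computed
    over the first ``baseline_s`` of the trace.  An onset is the first
    upward crossing sustained for at least ``sustain_s``; the matching
    offset is the first downward crossing sustained equally long.
    """
    fsr = np.asarray(fsr)
    n_base = int(np.rint(baseline_s * fs))
    if len(fsr) < n_base:
        raise ValueError(
            f"trace must include at least {baseline_s} s of leading baseline"
        )
    base = fsr[:n_base]
    med = np.median(base)
    mad = np.median(np.abs(base - med))
    thr = med + threshold_k * mad
    above = fsr > thr

    sustain = max(1, int(np.rint(sustain_s * fs)))
    events: list[tuple[float, float]] = []
    i = 0
    n = len(above)
    while i < n:
        if above[i] and bool(np.all(above[i:i + sustain])):
            onset = i / fs
            j = i + sustain
            while j < n:
                if not above[j] and bool(np.all(~above[j:j + sustain])):
                    break
                j += 1
            offset = min(j, n) / fs
            events.append((onset, offset))
            i = j + sustain
        else:
            i += 1
    return events


def extract_trial_windows(
    rec: RawRecording,
    onsets: Sequence[tuple[float, int]],
    offset_s: float,
    len_s: float,
    *,
    on_durations: Optional[Mapping[int, float]] = None,
) -> list[TrialWindow]:
    """Cut one labelled analysis window per stimulus onset.

    Window k covers samples ``[rint((onset_k + offset_s) * fs),
    rint((onset_k + offset_s + len_s) * fs))``.  If ``on_durations`` maps
    class_ids to their ON-epoch lengths, windows that would overrun their
    epoch are rejected with a logged reason; windows overrunning the
    recording are always rejected.  Trial ids are sequential from 0 over
    the kept windows.
    """
    if offset_s < 0:
        raise ValueError("offset_s must be nonnegative")
    if len_s <= 0:
        raise ValueError("len_s must be positive")
    windows: list[TrialWindow] = []
    trial_id = 0
    for onset, class_id in onsets:
        if on_durations is not None:
            on = on_durations.get(class_id)
            if on is not None and offset_s + len_s > on + 1e-9:
                logger.warning(
                    "trial at %.3f s (class %d) rejected: window "
                    "[%.3f, %.3f] s exceeds its %.3f s ON epoch",
                    onset, class_id, offset_s, offset_s + len_s, on,
                )
                continue
        i0 = int(np.rint((onset + offset_s) * rec.fs))
        i1 = int(np.rint((onset + offset_s + len_s) * rec.fs))
        if i0 < 0 or i1 > rec.n_samples:
            logger.warning(
                "trial at %.3f s (class %d) rejected: window outside recording",
                onset, class_id,
            )
            continue
        windows.append(
            TrialWindow(
                class_id=class_id,
                t_start=onset + offset_s,
                t_len=len_s,
                samples=rec.samples[:, i0:i1].copy(),
                trial_id=trial_id,
            )
        )
        trial_id += 1
    return windows


def reject_noisy_trials(
    windows: Sequence[TrialWindow],
    k_mad: float = 8.0,
    *,
    by_class: bool = False,
) -> tuple[list[TrialWindow], list[int]]:
    """Drop trials with outlying peak amplitude on any channel.

    A trial is rejected if on any channel its peak absolute amplitude
    exceeds median + k_mad * MAD of that channel's per-trial peaks.  With
    ``by_class=True`` the peak statistics are computed within each class
    separately — required when stimulus classes modulate channel amplitude
    strongly, otherwise a channel-selective class looks like an outlier.
    """
    if len(windows) < 10:
        raise ValueError("need at least 10 windows to estimate peak statistics")
    peaks = np.stack([np.max(np.abs(w.samples), axis=1) for w in windows])
    if by_class:
        labels = np.array([w.class_id for w in windows])
        bad = np.zeros(len(windows), dtype=bool)
        for cid in np.unique(labels):
            rows = labels == cid
            med = np.median(peaks[rows], axis=0)
            mad = np.median(np.abs(peaks[rows] - med), axis=0)
            bad[rows] = np.any(peaks[rows] > med + k_mad * mad, axis=1)
    else:
        med = np.median(peaks, axis=0)
        mad = np.median(np.abs(peaks - med), axis=0)
        bad = np.any(peaks > med + k_mad * mad, axis=1)
    if bool(np.all(bad)):
        raise ValueError(
            "all trials rejected; k_mad is likely misconfigured"
        )
    kept = [w for w, b in zip(windows, bad) if not b]
    rejected = [w.trial_id for w, b in zip(windows, bad) if b]
    if rejected:
        logger.info("rejected %d noisy trials: %s", len(rejected), rejected)
    return kept, rejected
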