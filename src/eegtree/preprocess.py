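"""Signal conditioning: band-pass filtering, resampling, channel exclusion,
epoching with amplitude-based selection, average re-referencing, band
decomposition and spectral band power.

All filters are zero-phase (forward-backward 4th-order Butterworth by
default) because the downstream phase-lag-index depends on instantaneous
phase: any net filter phase shift would bias the phase-difference
distribution the connectivity stage measures.
"""

from __future__ import annotations

from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .containers import BROADBAND, BandDefinition, EpochSet, Recording

__all__ = [
    "condition_signal",
    "drop_channels",
    "epoch_and_select",
    "rereference_average",
    "band_decompose",
    "band_power",
]


def _bandpass_sos(low: float, high: float, rate: float, order: int = 4) -> np.ndarray:
    nyq = rate / 2.0
    if not (0 < low < high):
        raise ValueError(f"need 0 < low < high, got [{low}, {high}]")
    if high > nyq:
        raise ValueError(f"high edge {high} Hz above Nyquist {nyq} Hz")
    return signal.butter(order, [low / nyq, high / nyq], btype="band", output="sos")


def _filtfilt(data: np.ndarray, sos: np.ndarray) -> np.ndarray:
    return signal.sosfiltfilt(sos, data, axis=-1)


def condition_signal(
    rec: Recording,
    low: float = 0.5,
    high: float = 30.0,
    target_rate: float = 500.0,
    order: int = 4,
) -> Recording:
    """Band-pass filter (zero phase) and resample a continuous recording.

    Filtering is applied at the original rate, then the signal is resampled
    to ``target_rate`` by polyphase filtering with a rational rate ratio.

    Raises
    ------
    ValueError
        If the recording is empty or ``high`` exceeds the Nyquist frequency
        of ``target_rate``.
    """
    if rec.n_samples == 0:
        raise ValueError("empty recording")
    if high > target_rate / 2.0:
        raise ValueError(
            f"band edge {high} Hz above Nyquist of target rate {target_rate} Hz"
        )
    sos = _bandpass_sos(low, high, rec.rate, order=order)
    out = _filtfilt(rec.data, sos)
    if target_rate != rec.rate:
        frac = Fraction(target_rate / rec.rate).limit_denominator(1000)
        out = signal.resample_poly(out, frac.numerator, frac.denominator, axis=-1)
    return Recording(out, rec.labels, target_rate, rec.subject_id, rec.condition)


def drop_channels(rec: Recording, labels: Iterable[str]) -> Recording:
    """Remove the named channels, preserving the order of the rest.

    Used for the eye-movement channel exclusion (128 - 8 = 120 retained
    under the default list).  Unknown labels are an error; dropping every
    channel is an error.
    """
    drop = list(labels)
    unknown = [lab for lab in drop if lab not in rec.labels]
    if unknown:
        raise KeyError(f"unknown channel label(s): {unknown}")
    keep = [i for i, lab in enumerate(rec.labels) if lab not in set(drop)]
    if not keep:
        raise ValueError("cannot drop all channels")
    return Recording(
        rec.data[keep], [rec.labels[i] for i in keep], rec.rate,
        rec.subject_id, rec.condition,
    )


def epoch_and_select(
    rec: Recording,
    length_s: float = 2.0,
    n_keep: int | None = 72,
    reject_threshold: float | None = None,
) -> EpochSet:
    """Cut non-overlapping consecutive epochs and head-select clean ones.

    Epochs whose peak absolute amplitude exceeds ``reject_threshold`` are
    discarded; of the survivors the first ``n_keep`` in time order are
    returned (``n_keep=None`` keeps all survivors).  This amplitude
    criterion is a deterministic surrogate for visual/ICA artifact
    screening, which operates on information this pipeline does not model.

    Raises
    ------
    ValueError
        If fewer than ``n_keep`` epochs survive — the subject is unusably
        artifacted at this threshold.
    """
    n_per = int(round(length_s * rec.rate))
    if n_per <= 0:
        raise ValueError("epoch length must be positive")
    n_total = rec.n_samples // n_per
    if n_keep is not None and n_total < n_keep:
        raise ValueError(
            f"recording holds only {n_total} epochs of {length_s} s; "
            f"{n_keep} requested"
        )
    epochs = rec.data[:, : n_total * n_per].reshape(rec.n_channels, n_total, n_per)
    epochs = np.moveaxis(epochs, 0, 1)  # (epochs, channels, samples)
    if reject_threshold is not None:
        peak = np.abs(epochs).max(axis=(1, 2))
        epochs = epochs[peak <= reject_threshold]
    if n_keep is not None:
        if epochs.shape[0] < n_keep:
            raise ValueError(
                f"only {epochs.shape[0]} epochs below threshold "
                f"{reject_threshold}; {n_keep} required"
            )
        epochs = epochs[:n_keep]
    return EpochSet(
        epochs, rec.labels, rec.rate, length_s,
        band=BROADBAND, subject_id=rec.subject_id, condition=rec.condition,
    )


def rereference_average(ep: EpochSet) -> EpochSet:
    """Common-average reference: subtract the cross-channel mean per sample.

    Must be applied after eye-channel exclusion so the reference is the
    average of retained scalp channels only.  The operation is idempotent
    mathematically, but a second application is rejected via the
    ``rereferenced`` flag to catch pipeline wiring mistakes.
    """
    if ep.rereferenced:
        raise ValueError("EpochSet is already average-referenced")
    out = ep.data - ep.data.mean(axis=1, keepdims=True)
    return ep.copy_with(data=out, rereferenced=True)


def _check_bands(bands: Sequence[BandDefinition], nyq: float) -> None:
    ordered = sorted(bands, key=lambda b: b.low)
    for b in ordered:
        if b.high > nyq:
            raise ValueError(f"band {b.name!r} exceeds Nyquist {nyq} Hz")
    for a, b in zip(ordered, ordered[1:]):
        if b.low < a.high - 1e-12:
            raise ValueError(f"bands {a.name!r} and {b.name!r} overlap")


def band_decompose(
    ep: EpochSet,
    bands: Sequence[BandDefinition],
    order: int = 4,
) -> dict[str, EpochSet]:
    """Zero-phase band-pass filter the broadband epochs into each band.

    Returns one :class:`EpochSet` per band with identical epoch structure.
    Bands may share edges but must not overlap in the interior.
    """
    if ep.band != BROADBAND:
        raise ValueError(f"expected broadband input, got {ep.band!r}")
    _check_bands(bands, ep.rate / 2.0)
    out: dict[str, EpochSet] = {}
    for b in bands:
        sos = _bandpass_sos(b.low, b.high, ep.rate, order=order)
        out[b.name] = ep.copy_with(data=_filtfilt(ep.data, sos), band=b.name)
    return out


def band_power(
    ep: EpochSet,
    bands: Sequence[BandDefinition],
    total_band: tuple[float, float] = (0.5, 30.0),
) -> pd.DataFrame:
    """Welch band power and relative power per channel.

    The periodogram is estimated per epoch (one Welch segment per 2-s
    epoch), averaged across epochs, then integrated over each band.
    Relative power is band power divided by total power in ``total_band``;
    for an all-zero channel relative power is reported missing (NaN).

    Returns
    -------
    DataFrame with columns ``channel, band, power, rel_power``.
    """
    lo_tot, hi_tot = total_band
    for b in bands:
        if b.low < lo_tot - 1e-9 or b.high > hi_tot + 1e-9:
            raise ValueError(
                f"band {b.name!r} outside analyzed range {total_band}"
            )
    nper = min(ep.n_samples, int(ep.rate * 2))
    freqs, psd = signal.welch(ep.data, fs=ep.rate, nperseg=nper, axis=-1)
    psd = psd.mean(axis=0)  # average across epochs -> (channels, freqs)
    df = freqs[1] - freqs[0]

    def integrate(lo: float, hi: float) -> np.ndarray:
        sel = (freqs >= lo) & (freqs <= hi)
        return psd[:, sel].sum(axis=1) * df

    total = integrate(lo_tot, hi_tot)
    rows = []
    with np.errstate(invalid="ignore", divide="ignore"):
        for b in bands:
            p = integrate(b.low, b.high)
            rel = np.where(total > 0, p / np.where(total > 0, total, 1.0), np.nan)
            for ch, lab in enumerate(ep.labels):
                rows.append((lab, b.name, p[ch], rel[ch]))
    return pd.DataFrame(rows, columns=["channel", "band", "power", "rel_power"])
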