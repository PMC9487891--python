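"""Phase-lag-index (PLI) functional connectivity.

The PLI of two signals is the absolute mean of the sign of the sine of
their instantaneous phase difference,

    PLI = | < sign(sin(dphi(t_k))) > |,

i.e. the asymmetry of the phase-difference distribution around zero.  It is
0 for coupling with a phase difference centered on 0 (mod pi) — the
signature of volume conduction — and 1 for perfect locking at any other
lag.  Instantaneous phase comes from the analytic signal (Hilbert
transform) of band-limited epochs; a configurable fraction of samples at
each epoch edge is excluded from the PLI sums to suppress transform edge
artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import EpochSet

__all__ = [
    "PhaseEpoch",
    "ConnectivityStack",
    "DEFAULT_ROIS",
    "instantaneous_phase",
    "pli_pair",
    "pli_matrix",
    "roi_mean_pli",
]


#: Regions of interest over the 128-channel montage: temporal (auditory),
#: occipital (visual) and parietal (somatosensory) cortex, left/right.
DEFAULT_ROIS: dict[str, tuple[str, ...]] = {
    "TL": ("E35", "E39", "E40", "E41", "E45", "E46", "E50"),
    "TR": ("E101", "E102", "E103", "E108", "E109", "E110", "E115"),
    "OL": ("E58", "E59", "E60", "E64", "E65", "E66", "E67", "E70", "E71"),
    "OR": ("E76", "E77", "E83", "E84", "E85", "E90", "E91", "E95", "E96"),
    "PL": ("E31", "E37", "E42", "E47", "E51", "E52", "E53", "E54", "E61"),
    "PR": ("E78", "E79", "E80", "E86", "E87", "E92", "E93", "E97", "E98"),
}


@dataclass
class PhaseEpoch:
    """Instantaneous phase per epoch: ``(epochs, channels, samples)``,
    wrapped to (-pi, pi].  ``edge_fraction`` is the per-edge fraction of
    each epoch excluded from subsequent PLI sums."""

    phases: np.ndarray
    labels: list[str]
    band: str
    edge_fraction: float = 0.05

    def __post_init__(self) -> None:
        self.phases = np.asarray(self.phases, dtype=float)
        if self.phases.ndim != 3:
            raise ValueError("phases must be 3-D (epochs x channels x samples)")
        if not 0 <= self.edge_fraction < 0.5:
            raise ValueError("edge_fraction must be in [0, 0.5)")

    def trimmed(self) -> np.ndarray:
        """Phases with the edge fraction removed from both ends."""
        n = self.phases.shape[2]
        k = int(np.floor(self.edge_fraction * n))
        return self.phases[:, :, k : n - k if k else n]


@dataclass
class ConnectivityStack:
    """Per-epoch PLI adjacency matrices: ``(epochs, N, N)``, symmetric,
    zero diagonal, entries in [0, 1]."""

    values: np.ndarray
    labels: list[str]
    band: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[1] != self.values.shape[2]:
            raise ValueError("values must be (epochs, N, N)")

    @property
    def n_epochs(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    def epoch(self, i: int) -> np.ndarray:
        return self.values[i]

    def mean(self) -> np.ndarray:
        """Epoch-average PLI matrix."""
        return self.values.mean(axis=0)


#: sin values below this magnitude count as exactly zero in the signum,
#: so that mathematically zero/pi phase differences contribute 0 despite
#: floating-point round-off (sin(pi) ~ 1e-16 numerically).
_SIN_ZERO_TOL = 1e-9


def _signum(s: np.ndarray) -> np.ndarray:
    out = np.sign(s)
    out[np.abs(s) < _SIN_ZERO_TOL] = 0.0
    return out


def instantaneous_phase(ep: EpochSet, edge_fraction: float = 0.05) -> PhaseEpoch:
    """Analytic-signal phase of each band-limited epoch.

    Raises on a constant (zero-variance) channel, whose phase is undefined.
    """
    from scipy.signal import hilbert

    var = ep.data.var(axis=-1)
    if np.any(var == 0):
        bad = [ep.labels[i] for i in sorted(set(np.where(var == 0)[1]))]
        raise ValueError(f"zero-variance channel(s): {bad}")
    phases = np.angle(hilbert(ep.data, axis=-1))
    return PhaseEpoch(phases, list(ep.labels), ep.band, edge_fraction)


def pli_pair(phase_a: np.ndarray, phase_b: np.ndarray) -> float:
    """PLI of two equal-length instantaneous-phase series.

    Samples where sin(dphi) is exactly 0 (phase difference 0 or pi)
    contribute 0 to the mean — they reduce, never inflate, the index.
    """
    a = np.asarray(phase_a, dtype=float)
    b = np.asarray(phase_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.size == 0:
        raise ValueError("empty phase series")
    return float(np.abs(np.mean(_signum(np.sin(a - b)))))


def pli_matrix(ph: PhaseEpoch, block: int = 16) -> ConnectivityStack:
    """PLI over all unordered channel pairs, per epoch.

    Evaluates sign(sin(phi_i - phi_j)) averaged over the edge-trimmed
    samples; computed in channel blocks to bound memory at 120 channels.
    """
    phases = ph.trimmed()
    n_ep, n_ch, n_t = phases.shape
    if n_ch < 2:
        raise ValueError("need at least 2 channels")
    out = np.zeros((n_ep, n_ch, n_ch))
    for e in range(n_ep):
        p = phases[e]
        for i0 in range(0, n_ch, block):
            i1 = min(i0 + block, n_ch)
            d = p[i0:i1, None, :] - p[None, :, :]
            out[e, i0:i1, :] = np.abs(_signum(np.sin(d)).mean(axis=-1))
    for e in range(n_ep):
        np.fill_diagonal(out[e], 0.0)
    # the formula is symmetric in the pair; enforce exact symmetry
    out = 0.5 * (out + np.swapaxes(out, 1, 2))
    return ConnectivityStack(out, list(ph.labels), ph.band)


def roi_mean_pli(
    matrix: np.ndarray,
    roi_a: str,
    roi_b: str,
    rois: dict[str, tuple[str, ...]],
    labels: list[str],
) -> float:
    """Unweighted mean PLI over all cross-region electrode pairs.

    ``roi_a`` and ``roi_b`` must be distinct named regions; within-region
    pairs are excluded by construction (only the |A| x |B| cross pairs
    enter the mean).
    """
    if roi_a == roi_b:
        raise ValueError("roi_a and roi_b must differ")
    for r in (roi_a, roi_b):
        if r not in rois:
            raise KeyError(f"undefined region {r!r}")
    index = {lab: i for i, lab in enumerate(labels)}
    try:
        ia = [index[lab] for lab in rois[roi_a]]
        ib = [index[lab] for lab in rois[roi_b]]
    except KeyError as exc:
        raise KeyError(f"ROI electrode {exc} not in montage") from exc
    m = np.asarray(matrix, dtype=float)
    return float(m[np.ix_(ia, ib)].mean())
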