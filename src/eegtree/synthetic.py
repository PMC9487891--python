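"""Synthetic phase-coupled multichannel signals and whole cohorts.

Real resting-state recordings for this kind of study are rarely released,
so the pipeline is exercised on signals with *known* coupling ground
truth.  Each channel carries, per frequency band, an amplitude-scaled
cosine of a latent phase process.  Latent phases are frequency-jittered
random walks (base frequency at the band center plus white phase-increment
noise), so signals are band-limited but not strictly periodic — identical
pure sinusoids would make the phase-lag index degenerate for every pair.

Coupling is a graph: for each edge (i, j) the instantaneous phase
difference phi_i - phi_j equals a constant lag delta plus von Mises noise
of concentration kappa (kappa = inf means perfect locking; kappa -> 0
approaches independence).  Channels not reached by any edge get
independent phase walks.  A lag of 0 with finite noise emulates the
volume-conduction case the PLI is designed to ignore.

A cohort adds group structure (per-group, per-condition coupling
templates), covariates, and a behavioral accuracy score generated from a
linear model on each subject's ground-truth coupling strength, so that a
behavior-topology association of known sign and size exists by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import DEFAULT_BANDS, BandDefinition, Recording, montage_labels

__all__ = [
    "CouplingEdge",
    "CouplingSpec",
    "BehaviorModel",
    "CohortSpec",
    "generate_recording",
    "generate_cohort",
    "study_cohort_spec",
]

_BAND_CENTERS = {b.name: b.center for b in DEFAULT_BANDS}


@dataclass(frozen=True)
class CouplingEdge:
    """Directed-in-definition coupling: phi_i - phi_j = lag + noise.

    ``kappa`` is the von Mises concentration of the wrapped phase noise;
    ``numpy.inf`` means no phase noise (perfect locking at ``lag``).
    """

    i: int
    j: int
    lag: float
    kappa: float = np.inf

    def __post_init__(self) -> None:
        if self.i == self.j:
            raise ValueError(f"self-edge on channel {self.i}")
        if not (-np.pi < self.lag < np.pi):
            raise ValueError(f"lag must lie in (-pi, pi), got {self.lag}")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")


@dataclass(frozen=True)
class CouplingSpec:
    """One band's worth of signal structure.

    Parameters
    ----------
    band
        Band label; ``center_hz`` defaults to the band's center frequency
        for the classical band definitions.
    edges
        Coupling graph over channel indices.
    amplitude
        Cosine amplitude (signal units), scalar applied to all channels.
    noise_sd
        Additive white-noise standard deviation (signal units).
    freq_jitter
        Standard deviation of the per-sample phase-increment noise
        (radians); 0 gives a pure sinusoid.  The default 0.1 yields a
        sub-hertz linewidth at typical rates while decorrelating
        independent channels within a fraction of a second.
    start_phase
        Initial phase of each phase-walk root; ``None`` draws it uniformly.
    """

    band: str = "alpha"
    center_hz: float | None = None
    edges: tuple[CouplingEdge, ...] = ()
    amplitude: float = 1.0
    noise_sd: float = 0.0
    freq_jitter: float = 0.1
    start_phase: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "edges", tuple(self.edges))
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.freq_jitter < 0:
            raise ValueError("freq_jitter must be >= 0")

    @property
    def frequency(self) -> float:
        if self.center_hz is not None:
            return self.center_hz
        try:
            return _BAND_CENTERS[self.band]
        except KeyError:
            raise ValueError(
                f"unknown band {self.band!r}; give center_hz explicitly"
            ) from None

    def scaled(self, factor: float) -> "CouplingSpec":
        """Copy with every finite edge concentration multiplied by ``factor``."""
        edges = tuple(
            replace(e, kappa=e.kappa * factor if np.isfinite(e.kappa) else e.kappa)
            for e in self.edges
        )
        return replace(self, edges=edges)


def _phase_walk(
    n: int, freq: float, rate: float, jitter: float,
    start: float, rng: np.random.Generator,
) -> np.ndarray:
    incr = np.full(n, 2 * np.pi * freq / rate)
    if jitter > 0:
        incr = incr + jitter * rng.standard_normal(n)
    ph = np.cumsum(incr)
    return start + ph - incr[0]  # phase at t=0 equals start


def _von_mises(kappa: float, n: int, rng: np.random.Generator) -> np.ndarray:
    if np.isinf(kappa):
        return np.zeros(n)
    if kappa == 0:
        return rng.uniform(-np.pi, np.pi, n)
    return rng.vonmises(0.0, kappa, n)


def _coupled_phases(
    spec: CouplingSpec, n_channels: int, n: int, rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Latent phases honoring the coupling graph (BFS from component roots)."""
    for e in spec.edges:
        for ch in (e.i, e.j):
            if not 0 <= ch < n_channels:
                raise ValueError(
                    f"edge ({e.i}, {e.j}) references invalid channel index "
                    f"for {n_channels} channels"
                )
    adj: dict[int, list[tuple[int, float, float]]] = {c: [] for c in range(n_channels)}
    for e in spec.edges:
        # store as (neighbor, lag such that phi_self - phi_neighbor = lag, kappa)
        adj[e.i].append((e.j, e.lag, e.kappa))
        adj[e.j].append((e.i, -e.lag, e.kappa))

    phases = np.empty((n_channels, n))
    seen = [False] * n_channels
    for root in range(n_channels):
        if seen[root]:
            continue
        start = (spec.start_phase if spec.start_phase is not None
                 else rng.uniform(-np.pi, np.pi))
        phases[root] = _phase_walk(n, spec.frequency, rate, spec.freq_jitter,
                                   start, rng)
        seen[root] = True
        queue = [root]
        while queue:
            node = queue.pop(0)
            for nb, lag, kappa in adj[node]:
                if seen[nb]:
                    continue
                # phi_node - phi_nb = lag + eps  =>  phi_nb = phi_node - lag - eps
                phases[nb] = phases[node] - lag - _von_mises(kappa, n, rng)
                seen[nb] = True
                queue.append(nb)
    return phases


def generate_recording(
    spec: CouplingSpec | Sequence[CouplingSpec],
    n_channels: int,
    duration_s: float,
    rate: float,
    seed: int | np.random.Generator | None = None,
    subject_id: str = "S0",
    condition: str = "EC",
) -> Recording:
    """Synthesize a multichannel recording from one or more band specs.

    Each channel is the sum over specs of ``amplitude * cos(phi_band(t))``
    plus white noise; coupled pairs hold their lag up to the specified
    phase noise, uncoupled channels drift independently.  Deterministic
    under a fixed seed.
    """
    if duration_s <= 0 or rate <= 0:
        raise ValueError("duration and rate must be positive")
    if n_channels < 1:
        raise ValueError("need at least one channel")
    specs = [spec] if isinstance(spec, CouplingSpec) else list(spec)
    n = int(round(duration_s * rate))
    for s in specs:
        if n < 2 * rate / s.frequency:
            raise ValueError(
                f"duration too short for two cycles of {s.frequency} Hz"
            )
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    data = np.zeros((n_channels, n))
    for s in specs:
        phases = _coupled_phases(s, n_channels, n, rate, rng)
        data += s.amplitude * np.cos(phases)
        if s.noise_sd > 0:
            data += s.noise_sd * rng.standard_normal((n_channels, n))
    return Recording(data, montage_labels(n_channels)[:n_channels], rate,
                     subject_id, condition)


@dataclass(frozen=True)
class BehaviorModel:
    """Linear behavioral model: acc = intercept(group) + slope * g + noise.

    ``g`` is the subject's ground-truth coupling strength (a multiplier on
    all template edge concentrations, centered on 1); scores are clipped
    to the [0, 100] accuracy scale after the linear model.
    """

    intercept: float | Mapping[str, float] = 75.0
    slope: float = 12.0
    noise_sd: float = 5.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def intercept_for(self, group: str) -> float:
        if isinstance(self.intercept, Mapping):
            return float(self.intercept[group])
        return float(self.intercept)


@dataclass(frozen=True)
class CohortSpec:
    """A whole study: groups, per-group/condition templates, behavior.

    ``templates[group][condition]`` is the list of :class:`CouplingSpec`
    used to synthesize that cell's recordings.  Each subject draws a
    coupling-strength multiplier ``g ~ Normal(1, subject_sd)`` (floored at
    0.05) applied to every finite edge concentration; ``g`` is the
    ground-truth topology quantity the behavioral model slopes on.
    """

    group_sizes: Mapping[str, int]
    templates: Mapping[str, Mapping[str, Sequence[CouplingSpec]]]
    behavior: BehaviorModel = BehaviorModel()
    covariates: Mapping[str, Mapping[str, tuple[float, float]]] | None = None
    subject_sd: float = 0.25
    n_channels: int = 16
    duration_s: float = 30.0
    rate: float = 250.0
    conditions: tuple[str, ...] = ("EC", "EO")
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.group_sizes:
            raise ValueError("at least one group is required")
        for g, n in self.group_sizes.items():
            if n < 1:
                raise ValueError(f"group {g!r} has size {n}; must be >= 1")
            if g not in self.templates:
                raise ValueError(f"no coupling template for group {g!r}")
        if self.subject_sd < 0:
            raise ValueError("subject_sd must be >= 0")


_DEFAULT_COVARIATES: dict[str, dict[str, tuple[float, float]]] = {
    # age (years) and nonverbal IQ, loosely matched to a school-age cohort
    "eCI": {"age": (8.8, 2.9), "iq": (100.0, 12.0)},
    "lCI": {"age": (10.8, 2.9), "iq": (95.0, 12.0)},
    "NH": {"age": (9.1, 1.7), "iq": (105.0, 12.0)},
}


def generate_cohort(
    spec: CohortSpec,
) -> tuple[pd.DataFrame, dict[tuple[str, str], Recording]]:
    """Generate the subject table and one recording per subject x condition.

    Returns
    -------
    subjects : DataFrame
        Columns ``subject_id, group, age, iq, acc, coupling_strength`` —
        the last is the ground-truth multiplier behavior was generated
        from (kept for validation; a real study would not observe it).
    recordings : dict
        ``(subject_id, condition) -> Recording``.
    """
    master = np.random.SeedSequence(spec.seed)
    covs = spec.covariates or _DEFAULT_COVARIATES
    rows = []
    recordings: dict[tuple[str, str], Recording] = {}
    idx = 0
    for group in spec.group_sizes:
        for _ in range(spec.group_sizes[group]):
            idx += 1
            sid = f"S{idx:03d}"
            rng = np.random.default_rng(master.spawn(1)[0])
            g_strength = max(0.05, 1.0 + spec.subject_sd * rng.standard_normal())
            cv = covs.get(group, {"age": (10.0, 2.0), "iq": (100.0, 15.0)})
            age = cv["age"][0] + cv["age"][1] * rng.standard_normal()
            iq = cv["iq"][0] + cv["iq"][1] * rng.standard_normal()
            acc = (spec.behavior.intercept_for(group)
                   + spec.behavior.slope * (g_strength - 1.0)
                   + spec.behavior.noise_sd * rng.standard_normal())
            acc = float(np.clip(acc, 0.0, 100.0))
            rows.append((sid, group, float(age), float(iq), acc, g_strength))
            for cond in spec.conditions:
                try:
                    tmpl = spec.templates[group][cond]
                except KeyError:
                    raise ValueError(
                        f"no template for group {group!r}, condition {cond!r}"
                    ) from None
                scaled = [s.scaled(g_strength) for s in tmpl]
                recordings[(sid, cond)] = generate_recording(
                    scaled, spec.n_channels, spec.duration_s, spec.rate,
                    seed=rng, subject_id=sid, condition=cond,
                )
    subjects = pd.DataFrame(
        rows, columns=["subject_id", "group", "age", "iq", "acc",
                       "coupling_strength"],
    )
    return subjects, recordings


def _hub_template(
    n_channels: int,
    kappa: float,
    band: str = "theta",
    lag: float = np.pi / 2,
    noise_sd: float = 0.3,
    freq_jitter: float = 0.25,
) -> list[CouplingSpec]:
    """Hub coupling: one channel phase-locked (lag pi/2) to ~60% of the
    montage.  The tree's star-likeness (leaf number, kappa) rises
    monotonically with the coupling concentration, because hub edges must
    out-rank the per-epoch noise floor of uncoupled pairs to enter the
    MST."""
    n_hub = max(3, int(0.6 * n_channels) + 1)
    edges = tuple(
        CouplingEdge(0, j, lag, kappa) for j in range(1, min(n_hub, n_channels))
    )
    return [CouplingSpec(band=band, edges=edges, noise_sd=noise_sd,
                         freq_jitter=freq_jitter)]


def study_cohort_spec(
    n_channels: int = 16,
    duration_s: float = 30.0,
    rate: float = 250.0,
    seed: int = 0,
    kappa_strong: float = 2.5,
    kappa_weak: float = 1.0,
    interaction: bool = True,
) -> CohortSpec:
    """The default study-like cohort: groups of 31/24/29 subjects.

    The late-implantation group's eyes-closed recordings get weaker
    theta-band coupling than every other group x condition cell
    (``kappa_weak`` vs ``kappa_strong``), injecting a group-by-condition
    interaction on tree topology; behavioral accuracy slopes on each
    subject's coupling strength, injecting a positive topology-behavior
    association.  ``interaction=False`` gives every cell the same template
    (a null cohort for calibration checks).
    """
    strong = _hub_template(n_channels, kappa_strong)
    weak = _hub_template(n_channels, kappa_weak)
    lci_ec = weak if interaction else strong
    templates = {
        "eCI": {"EC": strong, "EO": strong},
        "lCI": {"EC": lci_ec, "EO": strong},
        "NH": {"EC": strong, "EO": strong},
    }
    behavior = BehaviorModel(
        intercept={"eCI": 77.0, "lCI": 65.0, "NH": 89.0},
        slope=12.0,
        noise_sd=5.0,
    )
    return CohortSpec(
        group_sizes={"eCI": 31, "lCI": 24, "NH": 29},
        templates=templates,
        behavior=behavior,
        subject_sd=0.25,
        n_channels=n_channels,
        duration_s=duration_s,
        rate=rate,
        seed=seed,
    )
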