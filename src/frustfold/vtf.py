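"""Variable-temperature folding (VTF) sampling.

The protocol alternates fixed-temperature Langevin epochs with a
temperature correction: after each epoch of ``n_t`` steps the fraction of
native contacts Q of the collected snapshots is histogrammed; if the
unfolded (low-Q) peak of the resulting density is higher than the folded
(high-Q) peak the temperature is lowered by ``delta_T``, in the opposite
case it is raised, and on an exact tie the sign is drawn at random.  The
trace of epoch temperatures then oscillates around the collapse
temperature, where the chain shuttles between the two basins and both
peaks balance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .params import ModelParams
from .topology import NativeTopology
from .energetics import System, _positions
from .dynamics import IntegratorState, Trajectory, run_segment, extended_chain

__all__ = [
    "compute_Q",
    "FoldingHistogram",
    "VTFConfig",
    "VTFResult",
    "build_histogram",
    "contact_count_bins",
    "update_temperature",
    "run_vtf",
    "mean_collapse_temperature",
    "estimate_initial_temperature",
    "DryRunPropagator",
]


def compute_Q(frame, topology: NativeTopology, hold_ratio: float = 1.2) -> float:
    """Fraction of native contacts held: a contact (i, j) counts when the
    instantaneous Calpha distance satisfies r_ij <= hold_ratio * r_ij,0."""
    if topology.n_contacts == 0:
        raise ValueError("topology has no native contacts; Q is undefined")
    pos = _positions(frame)
    d = np.linalg.norm(pos[topology.contact_j] - pos[topology.contact_i], axis=1)
    return float(np.mean(d <= hold_ratio * topology.contact_r0))


@dataclass
class FoldingHistogram:
    """Binned probability density of Q with identified peaks.

    ``density`` integrates (times bin width) to one.  When the
    distribution is bimodal, ``unfolded_peak_Q < valley_Q <
    folded_peak_Q``; otherwise ``bimodal`` is False and ``mode_Q`` holds
    the single mode.
    """

    bin_edges: np.ndarray
    density: np.ndarray
    bimodal: bool
    unfolded_peak_Q: float | None = None
    folded_peak_Q: float | None = None
    valley_Q: float | None = None
    unfolded_height: float | None = None
    folded_height: float | None = None
    mode_Q: float | None = None

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def contact_count_bins(n_contacts: int) -> np.ndarray:
    """Bin edges giving one bin per possible contact count: Q = k/M falls
    in the bin centred on it.  Removes binning bias for small systems."""
    m = int(n_contacts)
    return (np.arange(m + 2) - 0.5) / m


def _smooth(y: np.ndarray, window: int = 3) -> np.ndarray:
    if len(y) < window:
        return y.copy()
    kernel = np.ones(window) / window
    pad = window // 2
    yp = np.pad(y, pad, mode="edge")
    return np.convolve(yp, kernel, mode="valid")


def build_histogram(q_series, bins=None) -> FoldingHistogram:
    """Histogram a Q series and locate its peaks and valley.

    ``bins``: bin edges array, an integer bin count over [0, 1], or None
    for 50 uniform bins.  The density is smoothed with a 3-bin moving
    average before peak picking; the two highest local maxima (boundary
    bins included) are the unfolded/folded peaks and the valley is the
    density minimum between them.
    """
    q = np.asarray(q_series, dtype=float)
    if q.size == 0:
        raise ValueError("empty Q series")
    if bins is None:
        bins = 50
    edges = np.linspace(0.0, 1.0, bins + 1) if np.isscalar(bins) \
        else np.asarray(bins, dtype=float)
    density, edges = np.histogram(q, bins=edges, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])

    sm = _smooth(density)
    peaks, _ = find_peaks(sm)
    peaks = list(peaks)
    if len(sm) >= 2 and sm[0] > sm[1]:
        peaks.append(0)
    if len(sm) >= 2 and sm[-1] > sm[-2]:
        peaks.append(len(sm) - 1)
    peaks = sorted(set(p for p in peaks if sm[p] > 0))

    if len(peaks) < 2:
        mode = centers[int(np.argmax(sm))]
        return FoldingHistogram(edges, density, False, mode_Q=float(mode))

    top_two = sorted(sorted(peaks, key=lambda p: sm[p])[-2:])
    lo, hi = top_two
    valley_idx = lo + int(np.argmin(sm[lo:hi + 1]))
    return FoldingHistogram(
        edges, density, True,
        unfolded_peak_Q=float(centers[lo]),
        folded_peak_Q=float(centers[hi]),
        valley_Q=float(centers[valley_idx]),
        unfolded_height=float(sm[lo]),
        folded_height=float(sm[hi]),
    )


def update_temperature(T: float, hist: FoldingHistogram, delta_T: float,
                       rng: np.random.Generator) -> float:
    """One VTF temperature correction.

    Bimodal: lower T when the unfolded (nonnative) peak is higher, raise
    it when the folded (native) peak is higher, pick a random sign on an
    exact tie.  Unimodal: steer toward bimodality — raise T when the
    single mode sits in the folded half (Q > 0.5), lower it when it sits
    in the unfolded half.
    """
    if hist.bimodal:
        if hist.unfolded_height > hist.folded_height:
            return T - delta_T
        if hist.folded_height > hist.unfolded_height:
            return T + delta_T
        return T + delta_T * (1 if rng.random() < 0.5 else -1)
    if hist.mode_Q > 0.5:
        return T + delta_T
    if hist.mode_Q < 0.5:
        return T - delta_T
    return T + delta_T * (1 if rng.random() < 0.5 else -1)


@dataclass
class VTFConfig:
    """Protocol settings.  ``n_t`` is the epoch length in integration
    steps (2e7 at production scale; scale it down for small systems),
    ``delta_T`` the temperature increment (0.002, about 0.5% of a typical
    collapse temperature)."""

    n_t: int = 20_000_000
    delta_T: float = 0.002
    n_epochs: int = 100
    initial_T: float | None = None     # None -> automatic bracketing pre-scan
    n_bins: int | None = None          # None -> one bin per contact count
    save_stride: int = 100
    seed: int = 0
    cumulative: bool = True            # histogram the up-to-now trajectory
    start: str = "native"              # "native" | "extended"

    def __post_init__(self) -> None:
        if self.n_t < 1:
            raise ValueError("n_t must be >= 1")
        if self.delta_T < 0:
            raise ValueError("delta_T must be >= 0")
        if self.n_epochs < 1:
            raise ValueError("n_epochs must be >= 1")


@dataclass
class VTFResult:
    """Outcome of a VTF run: per-epoch temperatures (the temperature each
    epoch was run at), all collected Q samples, saved frames, and the
    final histogram."""

    T_series: np.ndarray
    q_series: np.ndarray
    trajectory: Trajectory
    histogram: FoldingHistogram
    final_T: float

    @property
    def n_updates(self) -> int:
        return len(self.T_series)


class DryRunPropagator:
    """Accounting-only propagator: emits seeded synthetic bimodal Q samples
    and never touches the integrator.  Used to audit the epoch/update
    bookkeeping of a production-scale schedule in no time."""

    def __init__(self, seed: int = 0, n_samples_per_epoch: int = 100):
        self.rng = np.random.default_rng(seed)
        self.n_samples = n_samples_per_epoch

    def __call__(self, state, system, n_steps, save_stride, temperature):
        half = self.n_samples // 2
        q = np.concatenate([
            np.clip(self.rng.normal(0.2, 0.05, half), 0, 1),
            np.clip(self.rng.normal(0.85, 0.05, self.n_samples - half), 0, 1),
        ])
        state.step_count += n_steps
        n_beads = system.n_beads if system is not None else 1
        return q, Trajectory.empty(n_beads)


class _LangevinPropagator:
    """Default epoch propagator: one fixed-temperature Langevin segment."""

    def __call__(self, state, system, n_steps, save_stride, temperature):
        state.temperature = temperature
        traj = run_segment(state, system, system.params, n_steps, save_stride)
        return traj.q, traj


def run_vtf(topology: NativeTopology | None, params: ModelParams | None,
            config: VTFConfig, propagator=None) -> VTFResult:
    """Run the full VTF protocol: ``n_epochs`` epochs of ``n_t`` steps,
    each followed by a histogram over the collected (cumulative by
    default) Q samples and one temperature update."""
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 1]).generate_state(1)[0])

    if propagator is None:
        propagator = _LangevinPropagator()
        system = System(topology, params)
        start_pos = topology.ca0.copy() if config.start == "native" \
            else extended_chain(topology, seed=config.seed)
        state = IntegratorState(start_pos, np.zeros_like(start_pos), 1.0,
                                rng=np.random.default_rng(
                                    np.random.SeedSequence(
                                        [config.seed, 2]).generate_state(1)[0]))
        bins = contact_count_bins(topology.n_contacts) if config.n_bins is None \
            else config.n_bins
        T = config.initial_T if config.initial_T is not None else \
            estimate_initial_temperature(topology, params, seed=config.seed)
    else:
        system = System(topology, params) if topology is not None else None
        n_beads = system.n_beads if system is not None else 1
        state = IntegratorState(np.zeros((n_beads, 3)), np.zeros((n_beads, 3)),
                                1.0, rng=np.random.default_rng(config.seed))
        bins = config.n_bins if config.n_bins is not None else 50
        T = config.initial_T if config.initial_T is not None else 1.0

    T_series = np.zeros(config.n_epochs)
    all_q: list[np.ndarray] = []
    traj = None
    hist = None
    for epoch in range(config.n_epochs):
        T_series[epoch] = T
        q_epoch, t_epoch = propagator(state, system, config.n_t,
                                      config.save_stride, T)
        all_q.append(np.asarray(q_epoch, dtype=float))
        traj = t_epoch if traj is None else traj.extend(t_epoch)
        data = np.concatenate(all_q) if config.cumulative else all_q[-1]
        hist = build_histogram(data, bins)
        T = update_temperature(T, hist, config.delta_T, rng)

    return VTFResult(T_series, np.concatenate(all_q), traj, hist, T)


def mean_collapse_temperature(T_series, burn_in_fraction: float = 0.25) -> float:
    """Mean of the post-burn-in epoch temperatures: the averaged collapse
    temperature used as the free-energy temperature factor."""
    T = np.asarray(T_series, dtype=float)
    if T.size == 0:
        raise ValueError("empty temperature series")
    if not 0.0 <= burn_in_fraction < 1.0:
        raise ValueError("burn_in_fraction must lie in [0, 1)")
    start = int(np.floor(burn_in_fraction * T.size))
    if start >= T.size:
        raise ValueError("burn-in consumes every sample")
    return float(T[start:].mean())


def estimate_initial_temperature(topology: NativeTopology,
                                 params: ModelParams | None = None,
                                 seed: int = 0, t_low: float = 0.02,
                                 t_high: float = 2.0, n_points: int = 8,
                                 n_steps: int = 20_000) -> float:
    """Automatic initial-guess collapse temperature.

    Short fixed-temperature segments are run on a geometric temperature
    grid; the guess is the temperature whose mean Q is closest to 0.5
    (refined by log-linear interpolation between the bracketing grid
    points when the crossing is sampled on both sides).
    """
    params = params if params is not None else ModelParams()
    system = System(topology, params)
    temps = np.geomspace(t_low, t_high, n_points)
    mean_q = np.zeros(n_points)
    for k, T in enumerate(temps):
        state = IntegratorState.from_native(
            system, T, seed=int(np.random.SeedSequence([seed, 7, k])
                                .generate_state(1)[0]))
        traj = run_segment(state, system, params, n_steps,
                           max(1, n_steps // 200))
        # discard the first half as equilibration at this temperature
        mean_q[k] = traj.q[len(traj.q) // 2:].mean()
    above = np.where(mean_q >= 0.5)[0]
    below = np.where(mean_q < 0.5)[0]
    if len(above) == 0:
        return float(temps[0])
    if len(below) == 0:
        return float(temps[-1])
    hi = above[-1]          # warmest temperature still mostly folded
    lo = hi + 1 if hi + 1 < n_points else hi
    if lo == hi:
        return float(temps[hi])
    f = (mean_q[hi] - 0.5) / max(1e-12, mean_q[hi] - mean_q[lo])
    return float(np.exp(np.log(temps[hi]) + f * (np.log(temps[lo]) - np.log(temps[hi]))))
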