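"""LIF neural field driven by a saliency map, with a WTA readout layer.

The model has two layers of leaky integrate-and-fire neurons, one per
saliency-map location.  The first (saliency) layer receives a constant
input current obtained from the map through the input conductivity
``Ginput``; each of its spikes delivers a one-step excitatory
conductance pulse (``LIFParams.Gexc``) to the corresponding neuron of
the winner-take-all (WTA) layer.  The first WTA neuron to cross the
firing threshold defines the predicted first fixation: its crossing
time is the latency and its location the landing point.  Global
inhibition / inhibition of return only engage *after* a winner has
fired, so they are no-ops for the first-fixation analysis and the
corresponding parameters (``WTAParams.Ginh``, ``GinhDecay``) are inert
here.

Membrane update (explicit Euler, one step of length ``dt``)::

    V <- V + (dt / C) * (I - Gleak (V - Eleak)
                           - Gexc (V - Eexc) - Ginh (V - Einh))

A neuron fires if V > Vthresh (strict) after the update, and is reset
to ``Eleak``.

Noise enters only through the initial input current: per run, each
location receives ``I = Ginput * (S + noise_const + noise_ampl * U)``
with U ~ Uniform(0, 1) drawn once at initialization and never redrawn,
so with small noise the dynamics stay deterministic up to the initial
condition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from salif._kernel import simulate_runs
from salif.synthetic import SaliencyMap

log = logging.getLogger(__name__)

__all__ = [
    "LIFParams",
    "WTAParams",
    "NoiseParams",
    "NeuronFieldState",
    "SimulatedSaccade",
    "init_input_current",
    "euler_step",
    "first_spike",
    "batch_simulate",
    "count_distinct_latencies",
    "saccades_to_frame",
    "write_saccades_csv",
]


@dataclass(frozen=True)
class LIFParams:
    """Constants of the saliency-layer LIF neurons (SI units).

    ``Gexc`` doubles as the coupling conductance: the one-step
    excitatory pulse a saliency-layer spike delivers to its WTA neuron.
    ``GinhDecay`` is retained for completeness but inert before the
    first spike.
    """

    dt: float = 1e-4          # s, integration step (0.1 ms)
    Eleak: float = 0.0        # V
    Eexc: float = 100e-3      # V
    Einh: float = -20e-3      # V
    Gleak: float = 1e-8       # S
    Gexc: float = 2e-7        # S, pulse to the WTA layer per spike
    Ginh: float = 0.0         # S
    GinhDecay: float = 1.0    # s, inert pre-first-spike
    Ginput: float = 5e-2      # S, saliency -> current conversion
    Vthresh: float = 1e-3     # V
    C: float = 1e-9           # F

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.C <= 0:
            raise ValueError("C must be > 0")
        for name in ("Gleak", "Gexc", "Ginh", "Ginput"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.Vthresh > self.Eleak:
            raise ValueError("Vthresh must exceed Eleak")


@dataclass(frozen=True)
class WTAParams:
    """Constants of the WTA layer (shares dt, reversal potentials and
    Vthresh with the saliency layer)."""

    C: float = 1e-8       # F
    Gleak: float = 1e-8   # S
    Ginh: float = 0.0     # S, global inhibition; engages only post-spike

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be > 0")
        if self.Gleak < 0 or self.Ginh < 0:
            raise ValueError("conductances must be >= 0")


@dataclass(frozen=True)
class NoiseParams:
    """Noise/scale parameters applied to the saliency input.

    ``map_range`` rescales the map so its nominal range becomes
    ``map_range`` (the "range of the saliency map output"); the noise
    amplitudes are in the same (map) units.
    """

    noise_ampl: float = 1e-17
    noise_const: float = 1e-14
    map_range: float = 1e-9

    def __post_init__(self) -> None:
        if self.noise_ampl < 0 or self.noise_const < 0:
            raise ValueError("noise amplitudes must be >= 0")
        if self.map_range <= 0:
            raise ValueError("map_range must be > 0")


@dataclass
class NeuronFieldState:
    """State of one LIF field: potentials, input currents, spikes, time."""

    V: np.ndarray
    I: np.ndarray
    fired: np.ndarray
    t: float = 0.0  # ms

    def copy(self) -> "NeuronFieldState":
        return NeuronFieldState(self.V.copy(), self.I.copy(), self.fired.copy(), self.t)


@dataclass(frozen=True)
class SimulatedSaccade:
    """Model-produced first fixation for one run on one image."""

    image_id: int
    run_id: int
    latency_ms: float       # nan when censored
    censored: bool
    winner: tuple[int, int]         # (row, col) at map scale; (-1, -1) censored
    winner_xy: tuple[float, float]  # (x, y) image coordinates
    seed: int = 0


def _effective_map(smap: SaliencyMap, noise: NoiseParams) -> np.ndarray:
    """Map values rescaled so the nominal range equals noise.map_range."""
    if smap.value_range <= 0:
        raise ValueError("SaliencyMap.value_range must be > 0")
    return smap.values * (noise.map_range / smap.value_range)


def init_input_current(
    smap: SaliencyMap,
    lif: LIFParams,
    noise: NoiseParams,
    seed: int | np.random.Generator | None = None,
) -> NeuronFieldState:
    """Initialize a saliency-layer field from a map.

    I(x) = Ginput * (S(x) + noise_const + noise_ampl * U(x)), with the
    uniform noise drawn once here; V starts at the leak potential.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    s = _effective_map(smap, noise)
    if noise.noise_ampl > 0:
        u = rng.uniform(0.0, 1.0, size=s.shape)
    else:
        u = np.zeros_like(s)
    current = lif.Ginput * (s + noise.noise_const + noise.noise_ampl * u)
    v = np.full(s.shape, lif.Eleak, dtype=np.float64)
    return NeuronFieldState(V=v, I=current.astype(np.float64),
                            fired=np.zeros(s.shape, dtype=bool), t=0.0)


def euler_step(
    state: NeuronFieldState,
    params: LIFParams,
    Gexc_field: np.ndarray | float = 0.0,
    Ginh_field: np.ndarray | float = 0.0,
    form: str = "dt_over_C",
) -> NeuronFieldState:
    """Advance one field by one Euler step; fire-and-reset above threshold.

    ``form="dt_times_C"`` selects the update with a dt*C prefactor
    instead of dt/C, for sensitivity checks against the alternative
    reading of the published update rule.
    """
    if form == "dt_over_C":
        a = params.dt / params.C
    elif form == "dt_times_C":
        a = params.dt * params.C
    else:
        raise ValueError(f"unknown form {form!r}")
    v = state.V + a * (
        state.I
        - params.Gleak * (state.V - params.Eleak)
        - Gexc_field * (state.V - params.Eexc)
        - Ginh_field * (state.V - params.Einh)
    )
    if not np.all(np.isfinite(v)):
        raise FloatingPointError(
            "non-finite membrane potential; check the scale of dt/C "
            f"(dt={params.dt}, C={params.C}) relative to the conductances"
        )
    fired = v > params.Vthresh
    v = np.where(fired, params.Eleak, v)
    return NeuronFieldState(V=v, I=state.I, fired=fired,
                            t=state.t + params.dt * 1000.0)


def _winner_rowcol(idx: int, shape: tuple[int, int]) -> tuple[int, int]:
    return int(idx // shape[1]), int(idx % shape[1])


def _saccade(image_id, run_id, step, winner_idx, shape, map_scale, dt, timeout_ms, seed):
    if step < 0:
        return SimulatedSaccade(image_id, run_id, float("nan"), True,
                                (-1, -1), (float("nan"), float("nan")), seed)
    row, col = _winner_rowcol(winner_idx, shape)
    xy = ((col + 0.5) * map_scale, (row + 0.5) * map_scale)
    return SimulatedSaccade(image_id, run_id, step * dt * 1000.0, False,
                            (row, col), xy, seed)


def _simulate_current_stack(
    I: np.ndarray,
    lif: LIFParams,
    wta: WTAParams,
    timeout_ms: float,
    engine: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Run the two-layer model on a stack of input currents (R, N).

    Returns (spike_step, winner_index) per run; step -1 means censored.
    ``engine="reduced"`` integrates only the maximally driven location
    of each run — exact, because locations do not interact before the
    first WTA spike and the first spike always comes from the strongest
    input (spike rate and WTA accumulation are both monotone in I).
    """
    max_steps = int(round(timeout_ms / 1000.0 / lif.dt))
    I = np.ascontiguousarray(I, dtype=np.float64)
    if engine == "full":
        steps, winners, err = simulate_runs(
            I, lif.dt, lif.C, lif.Gleak, lif.Eleak, lif.Gexc, lif.Eexc,
            lif.Einh, lif.Vthresh, wta.C, wta.Gleak, max_steps)
        winners_out = winners
    elif engine == "reduced":
        cand = np.argmax(I, axis=1)
        I_red = np.ascontiguousarray(I[np.arange(I.shape[0]), cand][:, None])
        steps, w0, err = simulate_runs(
            I_red, lif.dt, lif.C, lif.Gleak, lif.Eleak, lif.Gexc, lif.Eexc,
            lif.Einh, lif.Vthresh, wta.C, wta.Gleak, max_steps)
        winners_out = np.where(steps >= 0, cand, -1)
    else:
        raise ValueError(f"unknown engine {engine!r}")
    if np.any(err):
        raise FloatingPointError(
            "non-finite membrane potential during simulation; check the "
            f"scale of dt/C (dt={lif.dt}, C={lif.C}) and Ginput={lif.Ginput}"
        )
    return steps, winners_out


def first_spike(
    smap: SaliencyMap,
    lif: LIFParams,
    wta: WTAParams,
    noise: NoiseParams,
    timeout_ms: float = 2000.0,
    seed: int | None = None,
    engine: str = "full",
    image_id: int = 0,
    run_id: int = 0,
) -> SimulatedSaccade:
    """Simulate one run; return the first WTA spike (or a censored record).

    With zero noise the winner is the argmax of the saliency map and the
    latency is exactly reproducible across seeds.  A run that produces
    no WTA spike within ``timeout_ms`` is returned censored, not raised.
    """
    if timeout_ms <= 0:
        raise ValueError("timeout_ms must be > 0")
    state = init_input_current(smap, lif, noise, seed)
    I = state.I.reshape(1, -1)
    steps, winners = _simulate_current_stack(I, lif, wta, timeout_ms, engine)
    return _saccade(image_id, run_id, int(steps[0]), int(winners[0]),
                    smap.values.shape, smap.map_scale, lif.dt, timeout_ms,
                    seed if seed is not None else 0)


def batch_simulate(
    maps: list[SaliencyMap],
    lif: LIFParams,
    wta: WTAParams,
    noise: NoiseParams,
    runs_per_image: int = 1,
    seed: int | None = None,
    timeout_ms: float = 2000.0,
    engine: str = "reduced",
) -> list[SimulatedSaccade]:
    """Independent first-fixation runs over a set of maps.

    Each run re-initializes the fields (no inhibition of return, no
    state carry-over).  Deterministic given the master seed.
    """
    if runs_per_image < 1:
        raise ValueError("runs_per_image must be >= 1")
    if not maps:
        return []
    shape = maps[0].values.shape
    if any(m.values.shape != shape for m in maps):
        raise ValueError("all maps in a batch must share one shape")
    rng = np.random.default_rng(seed)
    n_maps, R = len(maps), len(maps) * runs_per_image
    s_stack = np.stack([_effective_map(m, noise).ravel() for m in maps])
    s_all = np.repeat(s_stack, runs_per_image, axis=0)
    if noise.noise_ampl > 0:
        u = rng.uniform(0.0, 1.0, size=s_all.shape)
    else:
        u = 0.0
    I = lif.Ginput * (s_all + noise.noise_const + noise.noise_ampl * u)
    steps, winners = _simulate_current_stack(I, lif, wta, timeout_ms, engine)
    out = []
    for k in range(R):
        im, run = divmod(k, runs_per_image)
        out.append(_saccade(im, run, int(steps[k]), int(winners[k]), shape,
                            maps[im].map_scale, lif.dt, timeout_ms,
                            seed if seed is not None else 0))
    return out


def count_distinct_latencies(saccades: list[SimulatedSaccade]) -> int:
    """Number of distinct non-censored latency values for one image."""
    if not saccades:
        raise ValueError("empty saccade list")
    ids = {s.image_id for s in saccades}
    if len(ids) != 1:
        raise ValueError("saccades must all belong to one image")
    lat = [s.latency_ms for s in saccades if not s.censored]
    return int(len(np.unique(np.asarray(lat))))


def saccades_to_frame(saccades: list[SimulatedSaccade]):
    """Simulation results as a DataFrame (CSV-ready)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "image_id": [s.image_id for s in saccades],
            "run_id": [s.run_id for s in saccades],
            "latency_ms": [s.latency_ms for s in saccades],
            "censored": [s.censored for s in saccades],
            "winner_row": [s.winner[0] for s in saccades],
            "winner_col": [s.winner[1] for s in saccades],
            "seed": [s.seed for s in saccades],
        }
    )


def write_saccades_csv(saccades: list[SimulatedSaccade], path) -> None:
    saccades_to_frame(saccades).to_csv(path, index=False)
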