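"""Adaptive maximum-likelihood resting-motor-threshold estimation.

Implements ML-PEST-style sequential threshold estimation: a uniform
prior over an integer %MSO grid, a probit trial likelihood with fixed
slope, stimulation at the running maximum-likelihood estimate, and a
confirmation stage in which ten further pulses are delivered after
initial convergence; if the running estimate moves by more than a
stability bound (default 2 %MSO) during confirmation, thresholding is
restarted once from the current estimate.

Trials flagged as facilitated (pre-pulse EMG activity at or above the
MEP criterion) are logged but never contribute to the likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

_P_FLOOR = 1e-12


@dataclass
class LikelihoodState:
    """Grid log-likelihood for the threshold, plus full pulse history."""

    grid: np.ndarray = field(default_factory=lambda: np.arange(1.0, 101.0))
    slope: float = 2.0  # probit sigma of the assumed psychometric, %MSO
    loglik: np.ndarray = None
    history: list = field(default_factory=list)  # (amplitude, response, facilitated)

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if self.grid[0] <= 0 or self.grid[-1] > 100:
            raise ValueError("grid must lie within (0, 100] %MSO")
        if self.slope <= 0:
            raise ValueError("slope must be positive")
        if self.loglik is None:
            self.loglik = np.zeros_like(self.grid)

    @property
    def n_valid(self) -> int:
        """Number of non-facilitated trials incorporated so far."""
        return sum(1 for _, _, fac in self.history if not fac)

    def estimate(self) -> float:
        """Current ML threshold estimate (%MSO); ties break toward lower.

        Raises if no valid trial has been incorporated (argmax undefined
        under the flat prior).
        """
        if self.n_valid == 0:
            raise ValueError("no valid trials yet: ML estimate undefined")
        return float(self.grid[int(np.argmax(self.loglik))])


def trial_loglik(grid: np.ndarray, amplitude: float, response: bool, slope: float) -> np.ndarray:
    """Per-candidate log-likelihood of one trial under the probit model."""
    p = norm.cdf((amplitude - np.asarray(grid, dtype=float)) / slope)
    p = np.clip(p, _P_FLOOR, 1 - _P_FLOOR)
    return np.log(p) if response else np.log1p(-p)


def mlpest_update(state: LikelihoodState, amplitude: float, response: bool, facilitated: bool = False) -> LikelihoodState:
    """Incorporate one pulse into the likelihood (in place; returns state).

    Facilitated trials enter the history only; the likelihood and hence
    the running estimate are untouched.
    """
    if not state.grid[0] <= amplitude <= state.grid[-1]:
        raise ValueError(f"amplitude {amplitude} outside grid bounds")
    state.history.append((float(amplitude), bool(response), bool(facilitated)))
    if not facilitated:
        state.loglik = state.loglik + trial_loglik(state.grid, amplitude, response, state.slope)
    return state


def next_amplitude(state: LikelihoodState, start: float | None = None) -> int:
    """Next stimulation amplitude: the ML estimate, rounded to integer %MSO.

    For an empty state the configured start amplitude is required (the
    protocol starts at the hotspot-search amplitude).
    """
    if state.n_valid == 0:
        if start is None:
            raise ValueError("start amplitude required before any valid trial")
        return int(round(start))
    est = state.estimate()
    # round-half-down so ties between adjacent integers go to the lower
    return int(np.ceil(est - 0.5))


@dataclass(frozen=True)
class RMTConfig:
    """Protocol constants for adaptive RMT estimation."""

    slope: float = 2.0  # assumed probit slope, %MSO
    grid_lo: float = 1.0
    grid_hi: float = 100.0
    converge_streak: int = 3  # estimate unchanged over this many pulses
    min_pulses: int = 10  # before initial convergence may be declared
    confirmation_pulses: int = 10
    stability_bound: float = 2.0  # max estimate span tolerated, %MSO
    max_restarts: int = 1
    max_pulses: int = 200  # total budget across restarts


@dataclass
class RMTResult:
    """Outcome of one adaptive thresholding session."""

    rmt: float  # %MSO
    n_pulses: int
    restarted: bool
    confirmation_span: float  # max - min of estimates over confirmation pulses
    converged: bool = True
    state: LikelihoodState | None = None


def _run_cycle(responder, start, config, pulse_counter):
    """One estimation cycle: adaptive phase to convergence + confirmation."""
    state = LikelihoodState(
        grid=np.arange(config.grid_lo, config.grid_hi + 1.0),
        slope=config.slope,
    )
    recent: list[int] = []
    # --- adaptive phase ---
    while True:
        if pulse_counter[0] >= config.max_pulses:
            return state, None, None, pulse_counter
        amp = next_amplitude(state, start=start)
        mep, facilitated = responder(amp)
        pulse_counter[0] += 1
        mlpest_update(state, amp, bool(mep >= 50.0), facilitated)
        if facilitated:
            continue
        est = next_amplitude(state)
        recent.append(est)
        if (
            state.n_valid >= config.min_pulses
            and len(recent) >= config.converge_streak
            and len(set(recent[-config.converge_streak:])) == 1
        ):
            break
    # --- confirmation phase ---
    confirm_estimates: list[int] = []
    while len(confirm_estimates) < config.confirmation_pulses:
        if pulse_counter[0] >= config.max_pulses:
            return state, None, None, pulse_counter
        amp = next_amplitude(state)
        mep, facilitated = responder(amp)
        pulse_counter[0] += 1
        mlpest_update(state, amp, bool(mep >= 50.0), facilitated)
        if facilitated:
            continue
        confirm_estimates.append(next_amplitude(state))
    span = float(max(confirm_estimates) - min(confirm_estimates))
    return state, confirm_estimates[-1], span, pulse_counter


def estimate_rmt(responder, start: float, config: RMTConfig | None = None) -> RMTResult:
    """Full adaptive RMT session with confirmation and single-restart logic.

    ``responder(amplitude) -> (mep_pp_uV, facilitated)`` simulates or
    relays one pulse. The session runs the adaptive loop to initial
    convergence, delivers the confirmation pulses while continuing to
    update the estimate, and, if the estimate spans more than the
    stability bound across the confirmation pulses, restarts once from
    the current estimate. Exhausting the pulse budget yields an explicit
    non-converged result.
    """
    config = config or RMTConfig()
    counter = [0]
    state, final_est, span, counter = _run_cycle(responder, start, config, counter)
    restarted = False
    if final_est is None:  # budget exhausted
        return RMTResult(rmt=float("nan"), n_pulses=counter[0], restarted=False,
                         confirmation_span=float("nan"), converged=False, state=state)
    if span > config.stability_bound and config.max_restarts > 0:
        restarted = True
        state2, final2, span2, counter = _run_cycle(responder, final_est, config, counter)
        if final2 is None:
            return RMTResult(rmt=float(final_est), n_pulses=counter[0], restarted=True,
                             confirmation_span=span, converged=False, state=state)
        state, final_est, span = state2, final2, span2
    return RMTResult(rmt=float(final_est), n_pulses=counter[0], restarted=restarted,
                     confirmation_span=span, converged=True, state=state)
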