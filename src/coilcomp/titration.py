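"""Two-coil 2AFC loudness-matching staircase.

Each pair presents one reference pulse (quiet coil, fixed at 80, 100 or
120 %RMT) and one test pulse (conventional coil, variable amplitude);
the listener reports which sounded louder. A transformed staircase
lowers the test amplitude after "test louder" and raises it otherwise.
A choice flip relative to the previous pair is a reversal; the run
terminates at the 11th reversal and the match point is the mean of the
last six reversal amplitudes. Pair order within every block of ten is
counterbalanced (five reference-first, five test-first) in seeded
random order.

The step rule is pluggable; the default is a geometric rule that starts
at 16 %RMT, halves at every reversal and is floored at 1 %RMT, which
reproduces the ~20-pair run lengths typical of equal-loudness
titrations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .simulate import LoudnessObserver, simulate_2afc

TEST = "test_louder"
REFERENCE = "reference_louder"


@dataclass(frozen=True)
class GeometricStepRule:
    """Step magnitude = initial * factor**n_reversals, floored."""

    initial: float = 16.0
    factor: float = 0.5
    floor: float = 1.0

    def step(self, n_reversals: int) -> float:
        return max(self.initial * self.factor**n_reversals, self.floor)


@dataclass(frozen=True)
class TitrationConfig:
    reference_amplitude: float = 100.0  # %RMT, one of {80, 100, 120} in the protocol
    start_amplitude: float | None = None  # defaults to the reference
    step_rule: GeometricStepRule = GeometricStepRule()
    n_reversals_stop: int = 11
    n_last_reversals_for_mean: int = 6
    block_size: int = 10
    min_amplitude: float = 1.0  # %RMT floor for the test coil
    max_pairs: int = 200

    def __post_init__(self):
        if self.n_last_reversals_for_mean > self.n_reversals_stop:
            raise ValueError("n_last_reversals_for_mean must be <= n_reversals_stop")
        start = self.start_amplitude if self.start_amplitude is not None else self.reference_amplitude
        if start <= 0:
            raise ValueError("start amplitude must be positive")

    @property
    def start(self) -> float:
        return self.start_amplitude if self.start_amplitude is not None else self.reference_amplitude


@dataclass
class TitrationState:
    """Running record of one staircase."""

    amplitudes: list = field(default_factory=list)  # test amplitude per pair, %RMT
    responses: list = field(default_factory=list)  # TEST or REFERENCE per pair
    pair_orders: list = field(default_factory=list)  # 'reference_first'/'test_first'
    reversal_indices: list = field(default_factory=list)  # 0-based pair indices

    @property
    def n_reversals(self) -> int:
        return len(self.reversal_indices)

    def reversal_amplitudes(self) -> list:
        return [self.amplitudes[i] for i in self.reversal_indices]


@dataclass
class TitrationResult:
    match: float  # %RMT: mean of the last six reversal amplitudes
    n_pairs: int
    reversal_amplitudes: list
    state: TitrationState


def pair_order(block_index: int, seed, block_size: int = 10) -> list:
    """Presentation orders for one block: half reference-first, half test-first.

    Seeded per (seed, block_index) so that blocks are independent but the
    whole sequence is reproducible.
    """
    if block_size % 2:
        raise ValueError("block size must be even")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), int(block_index)]))
    orders = ["reference_first"] * (block_size // 2) + ["test_first"] * (block_size // 2)
    rng.shuffle(orders)
    return orders


def detect_reversal(state: TitrationState) -> bool:
    """True iff the latest choice differs from the previous one."""
    if len(state.responses) < 2:
        raise ValueError("need at least two responses to detect a reversal")
    return state.responses[-1] != state.responses[-2]


def update_amplitude(state: TitrationState, response: str, config: TitrationConfig) -> float:
    """Next test amplitude after the given response.

    Decreases when the test coil was judged louder, increases otherwise;
    the magnitude follows the step rule at the current reversal count and
    the result is floored at a positive minimum.
    """
    current = state.amplitudes[-1] if state.amplitudes else config.start
    step = config.step_rule.step(state.n_reversals)
    nxt = current - step if response == TEST else current + step
    return max(nxt, config.min_amplitude)


def run_titration(observer: LoudnessObserver, config: TitrationConfig | None = None, seed=0) -> TitrationResult:
    """Run one staircase to the 11th reversal and extract the match point.

    Raises RuntimeError if the pair budget is exhausted before the
    required number of reversals.
    """
    config = config or TitrationConfig()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xA5]))
    state = TitrationState()
    amplitude = float(config.start)
    orders: list = []
    while state.n_reversals < config.n_reversals_stop:
        if len(state.amplitudes) >= config.max_pairs:
            raise RuntimeError(
                f"pair budget ({config.max_pairs}) exhausted with "
                f"{state.n_reversals} reversals"
            )
        pair_idx = len(state.amplitudes)
        if pair_idx % config.block_size == 0:
            orders = pair_order(pair_idx // config.block_size, seed, config.block_size)
        state.pair_orders.append(orders[pair_idx % config.block_size])
        choice = simulate_2afc(observer, amplitude, rng)
        state.amplitudes.append(amplitude)
        state.responses.append(choice)
        if len(state.responses) >= 2 and detect_reversal(state):
            state.reversal_indices.append(pair_idx)
        amplitude = update_amplitude(state, choice, config)
    rev_amps = state.reversal_amplitudes()
    last = rev_amps[-config.n_last_reversals_for_mean:]
    return TitrationResult(
        match=float(np.mean(last)),
        n_pairs=len(state.amplitudes),
        reversal_amplitudes=rev_amps,
        state=state,
    )


def normalize_amplitudes(amplitudes, mean_rmt):
    """Log-normalized amplitudes: ln(amplitude / mean RMT of the condition).

    Dividing by the condition's mean RMT puts both coils on a common
    relative scale; the log transform reduces heteroscedasticity across
    coils. Invertible via exp(x) * mean_rmt.
    """
    a = np.asarray(amplitudes, dtype=float)
    m = np.asarray(mean_rmt, dtype=float)
    if np.any(a <= 0) or np.any(m <= 0):
        raise ValueError("amplitudes and mean RMT must be positive")
    return np.log(a / m)


def percent_reduction(matched_means, reference_amplitudes) -> float:
    """Mean relative amplitude reduction at matched loudness, in percent.

    100 * (1 - mean over conditions of matched/reference).
    """
    m = np.asarray(matched_means, dtype=float)
    r = np.asarray(reference_amplitudes, dtype=float)
    if m.shape != r.shape:
        raise ValueError("inputs must have equal length")
    if np.any(r == 0):
        raise ValueError("zero reference amplitude")
    if np.any(m <= 0) or np.any(r < 0):
        raise ValueError("amplitudes must be positive")
    return float(100.0 * (1.0 - np.mean(m / r)))
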