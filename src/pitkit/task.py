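"""Coin approach/withdraw task engine.

Simulates the instrumental game used in aversive PIT experiments: on each
trial a coin moves for 5 s while its horizontal position follows a random
walk with negative-exponential drift toward a default target (a vending
machine in the screen center or a black dot on the right).  Each key press
adds a Gaussian horizontal displacement directed away from the default
target.  A trial is won if the coin ends inside the desired target window,
lost if it ends inside the punitive window, and is otherwise incomplete.

The four instrumental conditions crossed here are Approach/Withdraw (which
target is rewarding) and Go/NoGo (whether the default route already leads
to the rewarding target).  On Go trials the default target is the undesired
one, so the participant must press repeatedly; on NoGo trials withholding
presses wins the trial.

Horizontal positions are in normalized screen units in [0, 1]; one step is
one monitor frame (60 Hz).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Sequence

import numpy as np

__all__ = [
    "TaskParams",
    "TrialSpec",
    "TrialLog",
    "Policy",
    "AbsentPolicy",
    "IdealPolicy",
    "ScheduledPolicy",
    "CalibrationError",
    "default_params",
    "step_coin",
    "simulate_trial",
    "classify_outcome",
    "calibrate_params",
    "required_presses_stat",
    "simulate_go_trials_ideal",
    "simulate_trials_batch",
]

Frame = Literal["approach", "withdraw"]
GoNoGo = Literal["go", "nogo"]
CS = Literal["cs+", "cs-", "none"]
Outcome = Literal["win", "lose", "incomplete"]

#: step displacement noise as a fraction of the mean press displacement
PRESS_SIGMA_RATIO = 0.30


@dataclass(frozen=True)
class TaskParams:
    """Physical parameters of the coin game.

    ``lambda_drift`` is the rate (1/s) of the exponential relaxation of the
    coin toward the default target column; ``press_mu``/``press_sigma``
    parameterize the Gaussian displacement added per key press; the target
    window is ``window_width`` wide so that roughly
    ``window_width / press_mu`` presses cross it.
    """

    dt: float = 1.0 / 60.0
    response_duration: float = 5.0
    preview_duration: float = 1.0
    lambda_drift: float = 0.25
    press_mu: float = 0.0217367
    press_sigma: float = field(default=0.0217367 * PRESS_SIGMA_RATIO)
    sigma_walk: float = 0.008
    window_width: float = field(default=4 * 0.0217367)
    x_machine: float = 0.5
    x_dot: float = 0.9
    x_start: Optional[float] = None  # None: start at the default target column
    max_press_rate: float = 8.0

    def __post_init__(self) -> None:
        if not (self.dt > 0 and math.isfinite(self.dt)):
            raise ValueError("dt must be a positive finite number")
        if self.response_duration <= 0:
            raise ValueError("response_duration must be positive")
        if self.window_width <= 0:
            raise ValueError("window_width must be positive")
        if self.press_sigma < 0 or self.sigma_walk < 0:
            raise ValueError("noise scales must be non-negative")
        for name in ("x_machine", "x_dot"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.x_start is not None and not (0.0 <= self.x_start <= 1.0):
            raise ValueError("x_start must lie in [0, 1]")
        # reject geometries where the two target windows overlap, which
        # would let a final position be classified as both win and lose
        if abs(self.x_machine - self.x_dot) <= self.window_width:
            raise ValueError("target windows overlap; reduce window_width")
        if self.max_press_rate <= 0:
            raise ValueError("max_press_rate must be positive")

    @property
    def n_steps(self) -> int:
        return round(self.response_duration / self.dt)

    @property
    def press_interval_steps(self) -> int:
        """Minimum number of frames between presses at the rate cap."""
        return max(1, math.ceil(1.0 / (self.max_press_rate * self.dt)))


def default_params() -> TaskParams:
    """Packaged default parameters.

    ``press_mu`` was calibrated once with :func:`calibrate_params` so that
    the ideal responder needs 32.12 ± 0.5 key presses on average to win a
    5-s Go trial; the window is four mean presses wide.
    """
    return TaskParams()


@dataclass(frozen=True)
class TrialSpec:
    """Configuration of one trial: instrumental condition and CS context."""

    frame: Frame
    go: GoNoGo
    cs: CS = "none"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.frame not in ("approach", "withdraw"):
            raise ValueError(f"invalid frame: {self.frame!r}")
        if self.go not in ("go", "nogo"):
            raise ValueError(f"invalid go/nogo: {self.go!r}")
        if self.cs not in ("cs+", "cs-", "none"):
            raise ValueError(f"invalid cs: {self.cs!r}")

    @property
    def desired_target(self) -> str:
        """Rewarding target: the machine under Approach, the dot under Withdraw."""
        return "machine" if self.frame == "approach" else "dot"

    @property
    def punitive_target(self) -> str:
        return "dot" if self.frame == "approach" else "machine"

    @property
    def default_target(self) -> str:
        # Go: drift leads to the undesired target (action required);
        # NoGo: drift leads to the desired target (withhold presses).
        return self.punitive_target if self.go == "go" else self.desired_target


def trial_geometry(spec: TrialSpec, params: TaskParams) -> tuple[float, float, float, float, float]:
    """Resolve (x_desired, x_punitive, x_default, x_start, press_direction)."""
    coords = {"machine": params.x_machine, "dot": params.x_dot}
    x_des = coords[spec.desired_target]
    x_pun = coords[spec.punitive_target]
    x_def = coords[spec.default_target]
    x_start = params.x_start if params.x_start is not None else x_def
    direction = math.copysign(1.0, x_des - x_def) if x_des != x_def else 1.0
    return x_des, x_pun, x_def, x_start, direction


@dataclass
class TrialLog:
    """Full record of one simulated trial."""

    spec: TrialSpec
    press_times: list[float]
    trajectory: np.ndarray
    outcome: Outcome

    @property
    def n_presses(self) -> int:
        return len(self.press_times)

    @property
    def first_press_latency(self) -> Optional[float]:
        """Seconds from response-period onset to the first press, if any."""
        return self.press_times[0] if self.press_times else None


def step_coin(
    x: float,
    pressed: bool,
    params: TaskParams,
    x_default: float,
    press_direction: float,
    rng: np.random.Generator,
) -> float:
    """Advance the coin by one frame.

    x' = x_def + (x - x_def) e^(-lambda dt) + N(0, sigma_walk sqrt(dt))
         + pressed * direction * N(press_mu, press_sigma),
    clamped to [0, 1].
    """
    if not (math.isfinite(x) and math.isfinite(x_default)):
        raise ValueError("non-finite position")
    if not (0.0 <= x <= 1.0):
        raise ValueError("position outside [0, 1]")
    rho = math.exp(-params.lambda_drift * params.dt)
    x_new = x_default + (x - x_default) * rho
    x_new += rng.normal(0.0, params.sigma_walk * math.sqrt(params.dt))
    if pressed:
        x_new += press_direction * rng.normal(params.press_mu, params.press_sigma)
    return min(1.0, max(0.0, x_new))


def classify_outcome(final_x: float, spec: TrialSpec, params: TaskParams) -> Outcome:
    """Win inside the desired window, lose inside the punitive window."""
    if not (0.0 <= final_x <= 1.0):
        raise ValueError("final position outside [0, 1]")
    x_des, x_pun, _, _, _ = trial_geometry(spec, params)
    half = params.window_width / 2.0
    if abs(final_x - x_des) <= half:
        return "win"
    if abs(final_x - x_pun) <= half:
        return "lose"
    return "incomplete"


class Policy:
    """Responder policy: decides, frame by frame, whether to press."""

    kind = "abstract"

    def start_trial(self, spec: TrialSpec, params: TaskParams, rng: np.random.Generator) -> None:
        """Reset per-trial state (and pre-draw any open-loop schedule)."""

    def wants_press(self, step: int, t: float, x: float, spec: TrialSpec, params: TaskParams) -> bool:
        raise NotImplementedError


class AbsentPolicy(Policy):
    """Never presses: the coin follows its default route."""

    kind = "absent"

    def wants_press(self, step, t, x, spec, params):
        return False


class IdealPolicy(Policy):
    """Bang-bang controller: press at the rate cap whenever the coin is
    outside the desired window column, stop once inside it."""

    kind = "ideal"

    def start_trial(self, spec, params, rng):
        self._since = params.press_interval_steps
        self._x_des, *_ = trial_geometry(spec, params)

    def wants_press(self, step, t, x, spec, params):
        outside = abs(x - self._x_des) > params.window_width / 2.0
        if outside and self._since >= params.press_interval_steps:
            self._since = 1
            return True
        self._since += 1
        return False


class ScheduledPolicy(Policy):
    """Open-loop policy pressing at pre-drawn times (used for human-like
    responders whose press schedule is sampled per trial by the cohort
    generator)."""

    kind = "scheduled"

    def __init__(self, press_times: Sequence[float]):
        self.press_times = sorted(float(t) for t in press_times)

    def start_trial(self, spec, params, rng):
        self._steps = {min(int(t / params.dt), params.n_steps - 1) for t in self.press_times
                       if 0.0 <= t < params.response_duration}

    def wants_press(self, step, t, x, spec, params):
        return step in self._steps


def simulate_trial(
    spec: TrialSpec,
    params: TaskParams,
    policy: Policy,
    rng: np.random.Generator | int | None = None,
) -> TrialLog:
    """Run one trial: preview (no presses possible), then the 5-s response
    period stepped at the frame rate, then outcome classification."""
    rng = np.random.default_rng(spec.seed if rng is None else rng)
    x_des, x_pun, x_def, x_start, direction = trial_geometry(spec, params)
    policy.start_trial(spec, params, rng)
    x = x_start
    trajectory = [x]
    press_times: list[float] = []
    for step in range(params.n_steps):
        t = step * params.dt
        pressed = policy.wants_press(step, t, x, spec, params)
        if pressed:
            press_times.append(t)
        x = step_coin(x, pressed, params, x_def, direction, rng)
        trajectory.append(x)
    outcome = classify_outcome(x, spec, params)
    return TrialLog(spec=spec, press_times=press_times,
                    trajectory=np.asarray(trajectory), outcome=outcome)


# ---------------------------------------------------------------------------
# vectorized batch simulation (same dynamics, trials advanced in lockstep)

def simulate_go_trials_ideal(
    params: TaskParams,
    n_trials: int,
    rng: np.random.Generator | int | None = None,
    spec: TrialSpec | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate ``n_trials`` Go trials under the ideal policy, vectorized
    across trials.  Returns (press counts, win mask)."""
    rng = np.random.default_rng(rng)
    spec = spec or TrialSpec(frame="withdraw", go="go")
    if spec.go != "go":
        raise ValueError("ideal-policy batch expects a Go spec")
    x_des, x_pun, x_def, x_start, direction = trial_geometry(spec, params)
    half = params.window_width / 2.0
    rho = math.exp(-params.lambda_drift * params.dt)
    interval = params.press_interval_steps
    sw = params.sigma_walk * math.sqrt(params.dt)

    x = np.full(n_trials, x_start)
    since = np.full(n_trials, interval)
    n_press = np.zeros(n_trials, dtype=int)
    for _ in range(params.n_steps):
        outside = np.abs(x - x_des) > half
        press = outside & (since >= interval)
        eps = rng.normal(0.0, sw, n_trials)
        dk = rng.normal(params.press_mu, params.press_sigma, n_trials)
        x = np.clip(x_def + (x - x_def) * rho + eps + press * direction * dk, 0.0, 1.0)
        since = np.where(press, 1, since + 1)
        n_press += press
    win = np.abs(x - x_des) <= half
    return n_press, win


def simulate_trials_batch(
    specs: Sequence[TrialSpec],
    press_times: Sequence[Sequence[float]],
    params: TaskParams,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Advance many open-loop trials in lockstep and classify each outcome.

    Used by the cohort generator: press schedules are pre-drawn per trial,
    so the per-frame update is identical for every trial and can be run as
    vector operations.  Returns an array of outcome strings.
    """
    rng = np.random.default_rng(rng)
    n = len(specs)
    if len(press_times) != n:
        raise ValueError("specs and press_times length mismatch")
    geom = np.array([trial_geometry(s, params) for s in specs])  # (n, 5)
    x_des, x_pun, x_def, x_start, direction = geom.T
    n_steps = params.n_steps
    rho = math.exp(-params.lambda_drift * params.dt)
    sw = params.sigma_walk * math.sqrt(params.dt)

    # per-frame press indicator matrix, assembled from the flattened times
    pressed = np.zeros((n_steps, n), dtype=bool)
    counts = np.array([len(ts) for ts in press_times])
    if counts.sum():
        flat_t = np.concatenate([np.asarray(ts, dtype=float) for ts in press_times
                                 if len(ts)])
        flat_j = np.repeat(np.arange(n), counts)
        ok = (flat_t >= 0.0) & (flat_t < params.response_duration)
        steps = np.minimum((flat_t[ok] / params.dt).astype(int), n_steps - 1)
        pressed[steps, flat_j[ok]] = True

    x = x_start.copy()
    for step in range(n_steps):
        eps = rng.normal(0.0, sw, n)
        dk = rng.normal(params.press_mu, params.press_sigma, n)
        x = np.clip(x_def + (x - x_def) * rho + eps
                    + pressed[step] * direction * dk, 0.0, 1.0)
    half = params.window_width / 2.0
    out = np.where(np.abs(x - x_des) <= half, "win",
                   np.where(np.abs(x - x_pun) <= half, "lose", "incomplete"))
    return out


def required_presses_stat(
    params: TaskParams,
    n_trials: int = 5000,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float]:
    """Mean and SD of press counts among winning ideal-policy Go trials."""
    if n_trials < 100:
        raise ValueError("n_trials must be >= 100")
    n_press, win = simulate_go_trials_ideal(params, n_trials, rng)
    if not win.any():
        raise CalibrationError("no winning trials; parameters are not calibrated")
    wins = n_press[win]
    sd = float(wins.std(ddof=1)) if wins.size > 1 else 0.0
    return float(wins.mean()), sd


class CalibrationError(RuntimeError):
    """Raised when dynamics calibration cannot reach its target."""


def calibrate_params(
    target_mean_presses: float = 32.12,
    window_in_presses: float = 4.0,
    base: TaskParams | None = None,
    seed: int = 7,
    tolerance: float = 0.5,
    n_trials: int = 4000,
    mu_bounds: tuple[float, float] = (0.004, 0.06),
    max_iter: int = 40,
) -> TaskParams:
    """Tune the mean press displacement so that the ideal responder needs
    ``target_mean_presses`` key presses (on average, among winning trials)
    to bring the coin home within one trial.

    The target window is pegged at ``window_in_presses`` mean displacements
    and the press noise at its fixed fraction of the displacement, so a
    single bisection on ``press_mu`` suffices; the drift rate is taken from
    ``base``.  Deterministic given ``seed`` (the same Monte-Carlo stream is
    replayed at every bisection step).
    """
    base = base or TaskParams()

    def with_mu(mu: float) -> TaskParams:
        return replace(base, press_mu=mu, press_sigma=PRESS_SIGMA_RATIO * mu,
                       window_width=window_in_presses * mu)

    def mean_at(mu: float) -> float:
        mean, _ = required_presses_stat(with_mu(mu), n_trials, np.random.default_rng(seed))
        return mean

    lo, hi = mu_bounds
    # mean press count decreases in press_mu: check the bracket
    try:
        f_lo = mean_at(lo)
    except CalibrationError:
        f_lo = math.inf
    f_hi = mean_at(hi)
    if not (f_hi <= target_mean_presses <= f_lo):
        raise CalibrationError(
            f"target {target_mean_presses} not bracketed by mu bounds "
            f"({f_hi:.2f} .. {f_lo if math.isfinite(f_lo) else 'inf'})")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        try:
            f_mid = mean_at(mid)
        except CalibrationError:
            f_mid = math.inf
        if abs(f_mid - target_mean_presses) <= tolerance:
            return with_mu(mid)
        if f_mid > target_mean_presses:
            lo = mid
        else:
            hi = mid
    raise CalibrationError(f"no convergence within {max_iter} bisection steps")
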