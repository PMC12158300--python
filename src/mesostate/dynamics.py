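"""Adaptive linear state-space fitting of session chains.

A session is a short Markov chain of block-structured observation
matrices.  Under the constant-map assumption every transition in the
chain should be carried by the same block-structured linear map, so the
spread of the per-transition least-squares estimates (the ``f1`` loss)
measures how much trial-to-trial process noise contaminates the chain.
The fitting loop removes that noise adaptively: the unexplained residual
of each state against the consensus map is folded into the noise
estimate at a step size set by a small fuzzy rule on the change of
``f1``, updates are only accepted when ``f1`` does not increase, and the
procedure stops once ``f1`` stalls.  A second loop (session alignment)
drives a per-session bias term that removes constant offsets between
sessions, shrinking the cross-session dispersion ``f2``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .types import (
    TRANSITION_VECTOR_LENGTH,
    InvalidConfigError,
    InvalidInputError,
    ObservationMatrix,
    ProcessNoise,
    SessionChain,
    TransitionMatrix,
)

logger = logging.getLogger(__name__)


class DivergenceError(RuntimeError):
    """The fitting loop blew up instead of converging."""


# ---------------------------------------------------------------------------
# fuzzy step-size rule
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FuzzyRule:
    """Triangular-membership rule mapping a loss change to a gain.

    The loss change is normalised by ``scale`` and fuzzified into three
    categories -- improving (d <= -1), flat (d == 0), worsening
    (d >= +1) -- with triangular memberships; the output gain is the
    membership-weighted average of the category gains, clipped to
    ``bounds``.
    """

    improving: float = 1.2
    flat: float = 1.0
    worsening: float = 0.7
    scale: float = 1e-6
    bounds: tuple[float, float] = (0.5, 1.5)

    def __post_init__(self) -> None:
        lo, hi = self.bounds
        if not (0.0 < lo <= hi < 2.0):
            raise InvalidConfigError("fuzzy gain bounds must satisfy 0 < lo <= hi < 2")
        if self.scale <= 0:
            raise InvalidConfigError("fuzzy scale must be positive")

    def memberships(self, delta: float) -> tuple[float, float, float]:
        d = delta / self.scale
        improving = min(1.0, max(0.0, -d))
        worsening = min(1.0, max(0.0, d))
        flat = max(0.0, 1.0 - abs(d))
        return improving, flat, worsening

    def __call__(self, delta: float) -> float:
        if not np.isfinite(delta):
            raise InvalidInputError("loss change must be finite")
        m_imp, m_flat, m_wor = self.memberships(delta)
        total = m_imp + m_flat + m_wor
        gain = (m_imp * self.improving + m_flat * self.flat + m_wor * self.worsening) / total
        return float(np.clip(gain, *self.bounds))


@dataclass
class FitConfig:
    """Configuration of the adaptive-noise fitting and alignment loops.

    The control-input term of the underlying state equation is fixed to
    zero (the task protocol is constant), so only the noise-update
    machinery is configurable.
    """

    theta1_rule: FuzzyRule = field(default_factory=FuzzyRule)
    theta2_rule: FuzzyRule = field(default_factory=FuzzyRule)
    b0: ProcessNoise | None = None  # per-session bias, None == zero blocks
    tol_f1: float = 1e-12
    max_iter: int = 50
    relax: float = 0.5  # base step toward the residual noise direction
    tol_f2: float = 1e-10
    max_iter_align: int = 10
    b0_mode: str = "scalar"  # "scalar" broadcast or full "matrix" bias
    divergence_factor: float = 10.0
    control_matrix_B: float = 0.0
    control_input_u: float = 0.0

    def __post_init__(self) -> None:
        if self.tol_f1 <= 0:
            raise InvalidConfigError("tol_f1 must be positive")
        if self.max_iter < 1:
            raise InvalidConfigError("max_iter must be at least 1")
        if not (0 < self.relax <= 1):
            raise InvalidConfigError("relax must be in (0, 1]")
        if self.b0_mode not in ("scalar", "matrix"):
            raise InvalidConfigError("b0_mode must be 'scalar' or 'matrix'")
        if self.control_matrix_B != 0.0 or self.control_input_u != 0.0:
            raise InvalidConfigError("control terms are fixed to zero in this model")


@dataclass
class SessionFit:
    """Converged fit of one session."""

    session_id: str
    condition: str
    consensus_A: TransitionMatrix
    per_iteration_f1: list[float]
    final_noise: list[ProcessNoise]
    final_transitions: list[TransitionMatrix]
    b0_final: ProcessNoise
    iterations_used: int
    converged: bool
    chain: SessionChain | None = None

    @property
    def initial_f1(self) -> float:
        return self.per_iteration_f1[0]

    @property
    def final_f1(self) -> float:
        return self.per_iteration_f1[-1]


# ---------------------------------------------------------------------------
# transition estimation
# ---------------------------------------------------------------------------


def _ls_map(curr: np.ndarray, prev: np.ndarray, name: str) -> np.ndarray:
    if not np.any(prev):
        raise InvalidInputError(
            f"block '{name}' of the previous state is all zero; transition unidentifiable"
        )
    return curr @ np.linalg.pinv(prev)


def estimate_transition(
    x_prev: ObservationMatrix, x_curr: ObservationMatrix
) -> TransitionMatrix:
    """Minimum-norm least-squares map carrying ``x_prev`` to ``x_curr``.

    Each block is solved independently: ``A = x_curr @ pinv(x_prev)``.
    The rectangular cross block yields a square 3x3 left-multiplying map.
    """
    return TransitionMatrix(
        **{
            name: _ls_map(getattr(x_curr, name), getattr(x_prev, name), name)
            for name in TransitionMatrix.SHAPES
        }
    )


def linearize(A: TransitionMatrix) -> np.ndarray:
    """Deterministic row-major flattening, length 43 (9 + 16 + 9 + 9)."""
    vec = A.to_vector()
    assert vec.size == TRANSITION_VECTOR_LENGTH
    return vec


def delinearize(vec: np.ndarray) -> TransitionMatrix:
    return TransitionMatrix.from_vector(vec)


def f1_loss(transitions: list[TransitionMatrix]) -> float:
    """Scalar spread of the chain's transition estimates.

    Mean, over the 43 weight positions, of the across-transition sample
    variance (ddof=1) -- i.e. trace of the linearised covariance divided
    by the number of positions.
    """
    if len(transitions) < 2:
        raise InvalidInputError("f1 needs at least 2 transitions")
    stacked = np.stack([linearize(a) for a in transitions])
    return float(np.var(stacked, axis=0, ddof=1).mean())


def consensus_transition(states: list[ObservationMatrix]) -> TransitionMatrix:
    """Joint least squares of a single map over every chain transition.

    Per block, minimises sum_k ||x_k - A x_(k-1)||_F^2 via the normal
    equations ``A = (sum x_k x_(k-1)^T)(sum x_(k-1) x_(k-1)^T)^+``.
    """
    out = {}
    for name in TransitionMatrix.SHAPES:
        cross = np.zeros(TransitionMatrix.SHAPES[name])
        gram = np.zeros((cross.shape[1], cross.shape[1]))
        for prev, curr in zip(states[:-1], states[1:]):
            p, c = getattr(prev, name), getattr(curr, name)
            cross = cross + c @ p.T
            gram = gram + p @ p.T
        if not np.any(gram):
            raise InvalidInputError(f"block '{name}' is all zero along the chain")
        out[name] = cross @ np.linalg.pinv(gram)
    return TransitionMatrix(**out)


# ---------------------------------------------------------------------------
# noise update and session fit
# ---------------------------------------------------------------------------


def update_process_noise(
    w: ProcessNoise, delta_f1: float, config: FitConfig
) -> ProcessNoise:
    """One multiplicative noise update: ``w_new = theta1(df1) * w + b0``."""
    if not np.isfinite(delta_f1):
        raise InvalidInputError("delta_f1 must be finite")
    gain = config.theta1_rule(delta_f1)
    b0 = config.b0 if config.b0 is not None else ProcessNoise.zeros()
    return gain * w + b0


def _denoise(
    states: list[ObservationMatrix],
    noise: list[ProcessNoise],
    b0: ProcessNoise,
) -> list[ObservationMatrix]:
    """States with the session bias and current noise estimates removed."""
    out = [ObservationMatrix.from_vector(states[0].to_vector() - b0.to_vector())]
    for x, w in zip(states[1:], noise):
        out.append(ObservationMatrix.from_vector(x.to_vector() - b0.to_vector() - w.to_vector()))
    return out


def _chain_transitions(states: list[ObservationMatrix]) -> list[TransitionMatrix]:
    return [estimate_transition(p, c) for p, c in zip(states[:-1], states[1:])]


def _propose_noise(
    states: list[ObservationMatrix],
    noise: list[ProcessNoise],
    b0: ProcessNoise,
    consensus: TransitionMatrix,
    step: float,
) -> tuple[list[ProcessNoise], list[ObservationMatrix]]:
    """Move each noise estimate toward its consensus residual, sequentially.

    Residuals are taken against the already-updated previous state so a
    full step (step == 1) reproduces the consensus dynamics exactly and
    any partial step contracts every residual by (1 - step).
    """
    b0_vec = b0.to_vector()
    denoised = [ObservationMatrix.from_vector(states[0].to_vector() - b0_vec)]
    new_noise = []
    for k, w_old in enumerate(noise):
        raw = states[k + 1].to_vector() - b0_vec
        predicted = consensus.apply(denoised[-1]).to_vector()
        residual = raw - w_old.to_vector() - predicted
        w_vec = w_old.to_vector() + step * residual
        new_noise.append(ProcessNoise.from_vector(w_vec))
        denoised.append(ObservationMatrix.from_vector(raw - w_vec))
    return new_noise, denoised


def fit_session(chain: SessionChain, config: FitConfig | None = None) -> SessionFit:
    """Fit one session chain with adaptive process-noise removal.

    Each iteration: (a) remove the current noise estimates from the
    states, (b) re-estimate the per-transition maps and the loss ``f1``,
    (c) compute the consensus map by joint least squares and the residual
    of every state against it, (d) move each noise estimate toward its
    residual at a step ``relax * theta1(delta_f1)``; an update is only
    accepted if ``f1`` does not increase (one halved retry, else the
    previous estimates are kept).  Stops when ``|delta_f1| < tol_f1`` or
    ``max_iter`` is reached.
    """
    config = config or FitConfig()
    b0 = config.b0 if config.b0 is not None else ProcessNoise.zeros()
    K = len(chain.states)
    noise = [ProcessNoise.zeros() for _ in range(K - 1)]

    denoised = _denoise(chain.states, noise, b0)
    transitions = _chain_transitions(denoised)
    f1 = f1_loss(transitions)
    f1_init = f1
    history = [f1]
    delta_f1 = 0.0
    converged = False
    iterations = 0

    for iterations in range(1, config.max_iter + 1):
        consensus = consensus_transition(denoised)
        step = min(config.relax * config.theta1_rule(delta_f1), 1.0)

        accepted = False
        # retry ladder: proposed step, halved step, then the full consensus
        # projection (step 1), which cannot increase the spread
        for try_step in (step, step * 0.5, 1.0):
            candidate_noise, candidate_denoised = _propose_noise(
                chain.states, noise, b0, consensus, try_step
            )
            candidate_transitions = _chain_transitions(candidate_denoised)
            candidate_f1 = f1_loss(candidate_transitions)
            if candidate_f1 <= f1:
                accepted = True
                break

        if accepted:
            delta_f1 = candidate_f1 - f1
            noise = candidate_noise
            denoised = candidate_denoised
            transitions = candidate_transitions
            f1 = candidate_f1
            history.append(f1)
        else:
            delta_f1 = 0.0
            history.append(f1)

        if f1 > config.divergence_factor * max(f1_init, np.finfo(float).tiny):
            raise DivergenceError(
                f"f1 grew to {f1:.3e} from initial {f1_init:.3e} "
                f"(> {config.divergence_factor}x); aborting session "
                f"'{chain.session_id}'"
            )
        logger.debug(
            "session %s iter %d: f1=%.3e delta=%.3e accepted=%s",
            chain.session_id, iterations, f1, delta_f1, accepted,
        )
        if abs(delta_f1) < config.tol_f1:
            converged = True
            break

    consensus = consensus_transition(denoised)
    return SessionFit(
        session_id=chain.session_id,
        condition=chain.condition,
        consensus_A=consensus,
        per_iteration_f1=history,
        final_noise=noise,
        final_transitions=transitions,
        b0_final=b0.copy(),
        iterations_used=iterations,
        converged=converged,
        chain=chain,
    )


# ---------------------------------------------------------------------------
# session alignment
# ---------------------------------------------------------------------------


def f2_loss(fits: list[SessionFit]) -> float:
    """Mean pairwise distance between per-session mean linearised maps."""
    if len(fits) < 2:
        raise InvalidInputError("f2 needs at least 2 sessions")
    means = [
        np.mean([linearize(a) for a in fit.final_transitions], axis=0) for fit in fits
    ]
    dists = [
        np.linalg.norm(means[i] - means[j])
        for i in range(len(means))
        for j in range(i + 1, len(means))
    ]
    return float(np.mean(dists))


def estimate_session_offset(chain: SessionChain) -> ProcessNoise:
    """Residual-based estimate of a constant state offset.

    A constant offset ``c`` added to every state of a chain governed by a
    fixed map ``A`` leaves a constant residual ``(I - A) c`` against the
    consensus fit, so ``c`` is recovered per block as
    ``pinv(I - A) @ mean_residual``.  Part of the offset is absorbed into
    the fitted map, so the estimate is conservative; the alignment loop
    compensates by rescaling.
    """
    A = consensus_transition(chain.states)
    residuals = [
        curr.to_vector() - A.apply(prev).to_vector()
        for prev, curr in zip(chain.states[:-1], chain.states[1:])
    ]
    rbar = ProcessNoise.from_vector(np.mean(residuals, axis=0))
    blocks = {}
    for name in A.SHAPES:
        a_block = getattr(A, name)
        eye = np.eye(a_block.shape[0])
        blocks[name] = np.linalg.pinv(eye - a_block) @ getattr(rbar, name)
    return ProcessNoise(**blocks)


def align_sessions(
    fits: list[SessionFit], config: FitConfig | None = None
) -> list[SessionFit]:
    """Learn per-session biases that shrink cross-session dispersion.

    Seeds each session's bias from its residual-based offset estimate
    (centred across sessions; scalar broadcast by default, which is far
    less noisy than the per-entry estimate), refits every session, then
    rescales the biases multiplicatively by ``theta2(delta_f2)`` while
    ``f2`` keeps decreasing.  Updates that would increase ``f2`` are
    rolled back, so the returned fits never disperse more than the input.
    """
    config = config or FitConfig()
    if len(fits) < 2:
        warnings.warn("alignment needs at least 2 sessions; returning input unchanged")
        return fits
    for fit in fits:
        if fit.chain is None:
            raise InvalidInputError("fits must retain their chains for alignment")

    chains = [fit.chain for fit in fits]
    offsets = [estimate_session_offset(c).to_vector() for c in chains]
    if config.b0_mode == "scalar":
        offsets = [np.full_like(o, o.mean()) for o in offsets]
    center = np.mean(offsets, axis=0)
    directions = [ProcessNoise.from_vector(o - center) for o in offsets]

    def refit(scale: float) -> list[SessionFit]:
        return [
            fit_session(chain, replace(config, b0=scale * d))
            for chain, d in zip(chains, directions)
        ]

    best_fits = fits
    best_f2 = f2_loss(fits)
    delta_f2 = 0.0
    scale = 1.0
    for j in range(config.max_iter_align):
        candidate_fits = refit(scale)
        candidate_f2 = f2_loss(candidate_fits)
        logger.debug("align iter %d: scale=%.3f f2=%.3e -> %.3e",
                     j, scale, best_f2, candidate_f2)
        if candidate_f2 <= best_f2:
            delta_f2 = candidate_f2 - best_f2
            best_fits, best_f2 = candidate_fits, candidate_f2
        else:
            break
        if abs(delta_f2) < config.tol_f2:
            break
        scale *= config.theta2_rule(delta_f2)
    return best_fits
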