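"""Synthetic session generator.

Two levels of synthesis back the test pyramid:

* **network level** -- chains of observation matrices propagated through
  exact linear dynamics ``x_k = A x_(k-1) + w_(k-1)``, for testing the
  dynamics-estimation stack in isolation;
* **signal level** -- 7-channel band-limited EEG whose inter-channel
  Spearman correlation approaches a target network, for end-to-end tests
  of the preprocessing and network stages without clinical data.

The signal generator drives every channel through the same resonant
AR(2) filter (alpha-band peak) with instantaneously correlated Gaussian
innovations, so the stationary cross-correlation equals the innovation
correlation.  Targets are specified on the Spearman scale and converted
to the Pearson scale of the Gaussian innovations via the exact relation
``rho_pearson = 2 sin(pi rho_spearman / 6)``.  The training condition is
emulated by attenuating the Pz channel so its alpha-band power drops
below the configured fraction of the resting reference.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sp_signal

from .networks import FCNet
from .types import (
    CANONICAL_CHANNELS,
    LOC_CHANNELS,
    MC_CHANNELS,
    EEGRecording,
    InvalidConfigError,
    InvalidInputError,
    ObservationMatrix,
    ProcessNoise,
    SessionChain,
    TransitionMatrix,
)

CONDITION_NFT = "NFT"
CONDITION_RESTING = "resting"
CONDITIONS = (CONDITION_NFT, CONDITION_RESTING)

#: Per-position diagonal suppression factors applied to the resting-state
#: ground-truth map to obtain the training-condition map (motor block
#: suppressed most strongly on the right, occipital suppression growing
#: away from the midline, cross block untouched).
_NFT_DIAG_FACTORS = {
    "mc": np.array([0.4771, 0.4025, 0.1372]),          # C3, Cz, C4
    "loc": np.array([0.35, 0.75, 0.55, 0.40]),          # P7, Pz, PO3, Oz
    "mc_loc": np.array([1.0, 1.0, 1.0]),                # unchanged
    "mnet": np.array([0.45, 0.30, 0.50]),               # LMC, RMC, LOC
}


def default_ground_truth(separation: float = 1.0) -> dict[str, TransitionMatrix]:
    """Stable condition-dependent transition maps.

    The resting map is diagonal-dominant with small fixed off-diagonal
    coupling; the training map scales the diagonals by condition-specific
    suppression factors.  ``separation`` interpolates between identical
    classes (0) and full suppression (1).
    """
    rng = np.random.default_rng(987654321)  # fixed: part of the default truth
    rest_blocks = {}
    for name, shape in TransitionMatrix.SHAPES.items():
        n = shape[0]
        off = 0.05 * rng.standard_normal(shape)
        block = 0.85 * np.eye(*shape) + off - np.diag(np.diag(off))
        # cap spectral radius for stability of the noiseless dynamics
        radius = max(abs(np.linalg.eigvals(block)))
        if radius >= 0.95:
            block *= 0.94 / radius
        rest_blocks[name] = block
    rest = TransitionMatrix(**rest_blocks)

    nft_blocks = {}
    for name, block in rest_blocks.items():
        factors = _NFT_DIAG_FACTORS[name]
        target = block.copy()
        target[np.diag_indices(min(target.shape))] *= factors
        nft_blocks[name] = block + separation * (target - block)
    nft = TransitionMatrix(**nft_blocks)
    return {CONDITION_RESTING: rest, CONDITION_NFT: nft}


@dataclass
class SimConfig:
    """Knobs of the synthetic-session generator."""

    n_sessions: int = 40
    runs_per_session: int = 10
    run_duration: float = 134.0           # seconds
    sampling_rate: float = 250.0          # Hz
    ground_truth_A: dict[str, TransitionMatrix] = field(default_factory=default_ground_truth)
    process_noise_sd: float = 0.01
    measurement_noise_sd: float = 1.0     # microvolts
    alpha_freq: float = 10.0              # Hz
    alpha_threshold_fraction: float = 0.60
    seed: int = 0
    signal_amplitude_uv: float = 10.0     # per-channel RMS of the clean signal
    alpha_pole_radius: float = 0.97       # AR(2) resonance sharpness
    init_shrink: float = 0.5              # shrinkage of the random initial state

    def __post_init__(self) -> None:
        if self.runs_per_session < 2:
            raise InvalidConfigError("runs_per_session must be >= 2")
        if self.process_noise_sd < 0 or self.measurement_noise_sd < 0:
            raise InvalidConfigError("noise standard deviations must be >= 0")
        if not (0 < self.alpha_threshold_fraction <= 1):
            raise InvalidConfigError("alpha_threshold_fraction must be in (0, 1]")
        if self.run_duration <= 0 or self.sampling_rate <= 0:
            raise InvalidConfigError("duration and sampling rate must be positive")
        for cond, A in self.ground_truth_A.items():
            if not np.all(np.isfinite(A.to_vector())):
                raise InvalidConfigError(f"ground-truth map for '{cond}' is not finite")


@dataclass
class ChainTruth:
    """Injected ground truth of one simulated chain."""

    transition: TransitionMatrix
    preclip_states: list[ObservationMatrix]
    noise: list[ProcessNoise]


@dataclass
class SyntheticSession:
    """Labelled synthetic session holding one chain per condition."""

    session_id: str
    chains: dict[str, SessionChain]
    truth: dict[str, ChainTruth]
    eeg_runs: dict[str, list[EEGRecording]] | None = None

    @property
    def condition_labels(self) -> list[str]:
        return [
            cond for cond, chain in self.chains.items() for _ in chain.states
        ]


# ---------------------------------------------------------------------------
# random correlation-structured initial states
# ---------------------------------------------------------------------------


def _random_correlation(rng: np.random.Generator, n: int, shrink: float) -> np.ndarray:
    """Shrunk random correlation matrix (factor-model PSD construction)."""
    loadings = rng.standard_normal((n, max(2, n - 1)))
    cov = loadings @ loadings.T + np.diag(rng.uniform(0.5, 1.5, size=n))
    d = np.sqrt(np.diag(cov))
    corr = cov / np.outer(d, d)
    return shrink * np.eye(n) + (1.0 - shrink) * corr


def _random_cross_block(rng: np.random.Generator) -> np.ndarray:
    """Random 3x4 cross block with entries in [-1, 1].

    Singular values are kept bounded away from zero so the cross-block
    transition stays identifiable along the whole chain.
    """
    g = rng.standard_normal((3, 4))
    u, _, vt = np.linalg.svd(g, full_matrices=False)
    cross = u @ np.diag(rng.uniform(0.5, 1.0, 3)) @ vt
    scale = 0.8 / max(np.abs(cross).max(), 1e-12)
    return cross * min(scale, 1.0)


def _random_initial_state(rng: np.random.Generator, shrink: float) -> ObservationMatrix:
    return ObservationMatrix(
        mc=_random_correlation(rng, len(MC_CHANNELS), shrink),
        loc=_random_correlation(rng, len(LOC_CHANNELS), shrink),
        mc_loc=_random_cross_block(rng),
        mnet=_random_correlation(rng, 3, shrink),
    )


# ---------------------------------------------------------------------------
# network-level simulation
# ---------------------------------------------------------------------------


def simulate_network_chain(
    config: SimConfig, condition: str, seed: int
) -> SyntheticSession:
    """Propagate a chain of observation matrices through linear dynamics.

    ``x_k = A x_(k-1) + w_(k-1)`` with i.i.d. zero-mean Gaussian noise of
    per-element standard deviation ``process_noise_sd``; stored states
    are clipped to [-1, 1] after noise injection while the pre-clip truth
    is recorded alongside.
    """
    if condition not in config.ground_truth_A:
        raise InvalidConfigError(f"no ground-truth map for condition '{condition}'")
    A = config.ground_truth_A[condition]
    rng = np.random.default_rng(seed)

    x = _random_initial_state(rng, config.init_shrink)
    states = [x]
    preclip = [x]
    noise_seq: list[ProcessNoise] = []
    for _ in range(config.runs_per_session - 1):
        w = ProcessNoise(
            **{
                name: config.process_noise_sd * rng.standard_normal(shape)
                for name, shape in ProcessNoise.SHAPES.items()
            }
        )
        propagated = A.apply(states[-1])
        x_next = ObservationMatrix.from_vector(propagated.to_vector() + w.to_vector())
        preclip.append(x_next)
        noise_seq.append(w)
        states.append(x_next.clip(-1.0, 1.0))

    sid = f"{condition}-{seed}"
    chain = SessionChain(
        session_id=sid, condition=condition, states=states, noise=noise_seq
    )
    return SyntheticSession(
        session_id=sid,
        chains={condition: chain},
        truth={condition: ChainTruth(transition=A, preclip_states=preclip, noise=noise_seq)},
    )


# ---------------------------------------------------------------------------
# signal-level simulation
# ---------------------------------------------------------------------------


def _target_to_full_matrix(target) -> np.ndarray:
    if isinstance(target, FCNet):
        return np.asarray(target.matrix, dtype=np.float64)
    if isinstance(target, ObservationMatrix):
        names = list(CANONICAL_CHANNELS)
        mc_idx = [names.index(c) for c in MC_CHANNELS]
        loc_idx = [names.index(c) for c in LOC_CHANNELS]
        full = np.eye(len(names))
        full[np.ix_(mc_idx, mc_idx)] = target.mc
        full[np.ix_(loc_idx, loc_idx)] = target.loc
        full[np.ix_(mc_idx, loc_idx)] = target.mc_loc
        full[np.ix_(loc_idx, mc_idx)] = target.mc_loc.T
        return full
    full = np.asarray(target, dtype=np.float64)
    if full.shape != (7, 7):
        raise InvalidInputError("target network must be 7x7")
    return full


def _nearest_correlation_factor(target: np.ndarray) -> np.ndarray:
    """Cholesky-like factor of the PSD-projected, unit-diagonal target."""
    sym = 0.5 * (target + target.T)
    vals, vecs = np.linalg.eigh(sym)
    vals = np.clip(vals, 1e-6, None)
    psd = vecs @ np.diag(vals) @ vecs.T
    d = np.sqrt(np.diag(psd))
    psd = psd / np.outer(d, d)
    return np.linalg.cholesky(psd + 1e-12 * np.eye(psd.shape[0]))


def simulate_eeg_run(
    config: SimConfig, condition: str, target_network, seed: int
) -> EEGRecording:
    """Generate one 7-channel run whose Spearman network approaches a target.

    ``target_network`` may be an :class:`FCNet`, a 7x7 array of Spearman
    correlations, or an :class:`ObservationMatrix` (re-embedded into the
    full channel grid).  The training condition attenuates the Pz channel
    so its alpha-band power falls below ``alpha_threshold_fraction`` of
    the resting reference.
    """
    if config.signal_amplitude_uv <= 0:
        raise InvalidInputError(
            "zero-amplitude configuration is degenerate: correlation undefined"
        )
    n_samples = int(round(config.run_duration * config.sampling_rate))
    rng = np.random.default_rng(seed)

    rho_s = _target_to_full_matrix(target_network)
    rho_p = 2.0 * np.sin(np.pi * rho_s / 6.0)  # Gaussian Spearman -> Pearson
    np.fill_diagonal(rho_p, 1.0)
    factor = _nearest_correlation_factor(rho_p)

    # resonant AR(2) shared by all channels: poles at r * exp(+-i w0)
    r = config.alpha_pole_radius
    w0 = 2.0 * np.pi * config.alpha_freq / config.sampling_rate
    a = np.array([1.0, -2.0 * r * np.cos(w0), r * r])
    if np.max(np.abs(np.roots(a))) >= 1.0:
        raise InvalidConfigError(
            f"unstable generator: AR pole radius {r} gives spectral radius >= 1"
        )

    burn_in = 2000
    innovations = factor @ rng.standard_normal((7, n_samples + burn_in))
    series = sp_signal.lfilter([1.0], a, innovations, axis=1)[:, burn_in:]

    # fix per-channel RMS (scale-invariant for rank correlation)
    rms = np.sqrt(np.mean(series**2, axis=1, keepdims=True))
    series = series / rms * config.signal_amplitude_uv

    if condition == CONDITION_NFT:
        power_fraction = 0.8 * config.alpha_threshold_fraction
        series[list(CANONICAL_CHANNELS).index("Pz")] *= np.sqrt(power_fraction)

    if config.measurement_noise_sd > 0:
        series = series + config.measurement_noise_sd * rng.standard_normal(series.shape)

    return EEGRecording(
        data=series,
        channel_names=CANONICAL_CHANNELS,
        sampling_rate=config.sampling_rate,
        device="synthetic",
    )


# ---------------------------------------------------------------------------
# labelled datasets
# ---------------------------------------------------------------------------


def make_two_class_dataset(config: SimConfig) -> list[SyntheticSession]:
    """Balanced labelled corpus: each session holds one chain per condition."""
    maps = config.ground_truth_A
    for cond in CONDITIONS:
        if cond not in maps:
            raise InvalidConfigError(f"ground_truth_A lacks condition '{cond}'")
    if maps[CONDITION_NFT].allclose(maps[CONDITION_RESTING]):
        warnings.warn(
            "conditions share the same ground-truth map; classes are not "
            "separable by construction"
        )

    sessions = []
    for i in range(config.n_sessions):
        sid = f"S{i:03d}"
        chains, truth = {}, {}
        for j, cond in enumerate(CONDITIONS):
            seed = config.seed * 1_000_003 + 2 * i + j
            sim = simulate_network_chain(config, cond, seed)
            chain = sim.chains[cond]
            chain.session_id = sid
            chains[cond] = chain
            truth[cond] = sim.truth[cond]
        sessions.append(SyntheticSession(session_id=sid, chains=chains, truth=truth))
    return sessions


# ---------------------------------------------------------------------------
# dataset (de)serialisation: plain JSON, one file per dataset
# ---------------------------------------------------------------------------


def save_dataset(
    sessions: list[SyntheticSession], path, meta: dict | None = None
) -> None:
    from .io import _wrap, chain_to_jsonable as _chain_to_jsonable
    payload = []
    for s in sessions:
        payload.append(
            {
                "session_id": s.session_id,
                "chains": {c: _chain_to_jsonable(ch) for c, ch in s.chains.items()},
                "truth": {
                    c: {
                        "transition": t.transition.to_jsonable(),
                        "preclip_states": [x.to_jsonable() for x in t.preclip_states],
                        "noise": [w.to_jsonable() for w in t.noise],
                    }
                    for c, t in s.truth.items()
                },
            }
        )
    Path(path).write_text(_wrap(payload, meta))


def load_dataset(path) -> list[SyntheticSession]:
    from .io import _unwrap, chain_from_jsonable as _chain_from_jsonable

    payload, _ = _unwrap(path)
    sessions = []
    for obj in payload:
        chains = {c: _chain_from_jsonable(ch) for c, ch in obj["chains"].items()}
        truth = {
            c: ChainTruth(
                transition=TransitionMatrix.from_jsonable(t["transition"]),
                preclip_states=[
                    ObservationMatrix.from_jsonable(x) for x in t["preclip_states"]
                ],
                noise=[ProcessNoise.from_jsonable(w) for w in t["noise"]],
            )
            for c, t in obj["truth"].items()
        }
        sessions.append(
            SyntheticSession(session_id=obj["session_id"], chains=chains, truth=truth)
        )
    return sessions
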