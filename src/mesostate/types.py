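"""Core data structures shared across the pipeline.

The central objects are block-structured matrices: the brain-state
observation (four labelled correlation blocks), the transition matrix
mapping one observation to the next, and the process-noise term that is
adaptively estimated and removed.  All blocks are plain float64 numpy
arrays with fixed shapes; the classes add validation, block-wise
arithmetic and (de)serialisation, nothing clever.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np

#: Fixed channel order every aligned run must follow.
CANONICAL_CHANNELS: tuple[str, ...] = ("C3", "Cz", "C4", "P7", "Pz", "PO3", "Oz")

MC_CHANNELS: tuple[str, ...] = ("C3", "Cz", "C4")
LOC_CHANNELS: tuple[str, ...] = ("P7", "Pz", "PO3", "Oz")

BLOCK_NAMES: tuple[str, ...] = ("mc", "loc", "mc_loc", "mnet")

#: Shapes of the observation blocks (motor, occipital, cross, mesoscale).
OBS_BLOCK_SHAPES: dict[str, tuple[int, int]] = {
    "mc": (3, 3),
    "loc": (4, 4),
    "mc_loc": (3, 4),
    "mnet": (3, 3),
}

#: Shapes of the transition blocks.  The cross block is driven by a
#: left-multiplying 3x3 map so its transition is square even though the
#: state block is rectangular.
TRANS_BLOCK_SHAPES: dict[str, tuple[int, int]] = {
    "mc": (3, 3),
    "loc": (4, 4),
    "mc_loc": (3, 3),
    "mnet": (3, 3),
}

#: Length of a linearised transition matrix: 9 + 16 + 9 + 9.
TRANSITION_VECTOR_LENGTH = sum(r * c for r, c in TRANS_BLOCK_SHAPES.values())


class InvalidConfigError(ValueError):
    """A configuration value violates its contract."""


class InvalidInputError(ValueError):
    """An input object violates a precondition."""


def _coerce_block(value, shape: tuple[int, int], name: str) -> np.ndarray:
    arr = np.asarray(value, dtype=np.float64)
    if arr.shape != shape:
        raise InvalidInputError(
            f"block '{name}' must have shape {shape}, got {arr.shape}"
        )
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError(f"block '{name}' contains non-finite entries")
    return arr


class _BlockMatrix:
    """Mixin providing block-wise arithmetic and dict/vector conversion.

    Subclasses define ``SHAPES`` mapping block name -> (rows, cols).
    """

    SHAPES: dict[str, tuple[int, int]] = {}

    # -- construction -------------------------------------------------
    def __init__(self, **blocks) -> None:
        missing = set(self.SHAPES) - set(blocks)
        if missing:
            raise InvalidInputError(f"missing blocks: {sorted(missing)}")
        for name, shape in self.SHAPES.items():
            setattr(self, name, _coerce_block(blocks[name], shape, name))

    @classmethod
    def zeros(cls):
        return cls(**{n: np.zeros(s) for n, s in cls.SHAPES.items()})

    @classmethod
    def from_blocks(cls, blocks: Mapping[str, np.ndarray]):
        return cls(**{n: blocks[n] for n in cls.SHAPES})

    # -- views ---------------------------------------------------------
    def blocks(self) -> dict[str, np.ndarray]:
        return {n: getattr(self, n) for n in self.SHAPES}

    def to_vector(self) -> np.ndarray:
        """Row-major concatenation of the blocks in declaration order."""
        return np.concatenate([getattr(self, n).ravel() for n in self.SHAPES])

    @classmethod
    def from_vector(cls, vec: np.ndarray):
        vec = np.asarray(vec, dtype=np.float64).ravel()
        expected = sum(r * c for r, c in cls.SHAPES.values())
        if vec.size != expected:
            raise InvalidInputError(
                f"expected vector of length {expected}, got {vec.size}"
            )
        out, i = {}, 0
        for name, (r, c) in cls.SHAPES.items():
            out[name] = vec[i : i + r * c].reshape(r, c)
            i += r * c
        return cls(**out)

    # -- arithmetic ----------------------------------------------------
    def _zip(self, other, op):
        return type(self)(
            **{n: op(getattr(self, n), getattr(other, n)) for n in self.SHAPES}
        )

    def __add__(self, other):
        return self._zip(other, np.add)

    def __sub__(self, other):
        return self._zip(other, np.subtract)

    def __mul__(self, scalar: float):
        return type(self)(**{n: getattr(self, n) * scalar for n in self.SHAPES})

    __rmul__ = __mul__

    def clip(self, lo: float = -1.0, hi: float = 1.0):
        return type(self)(**{n: np.clip(getattr(self, n), lo, hi) for n in self.SHAPES})

    def copy(self):
        return type(self)(**{n: getattr(self, n).copy() for n in self.SHAPES})

    def allclose(self, other, **kw) -> bool:
        return all(
            np.allclose(getattr(self, n), getattr(other, n), **kw)
            for n in self.SHAPES
        )

    def norm(self) -> float:
        """Frobenius norm over all blocks jointly."""
        return float(np.linalg.norm(self.to_vector()))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        shapes = ", ".join(f"{n}{s}" for n, s in self.SHAPES.items())
        return f"<{type(self).__name__} {shapes}>"

    # -- serialisation -------------------------------------------------
    def to_jsonable(self) -> dict:
        return {n: getattr(self, n).tolist() for n in self.SHAPES}

    @classmethod
    def from_jsonable(cls, obj: Mapping):
        return cls(**{n: np.asarray(obj[n]) for n in cls.SHAPES})


class ObservationMatrix(_BlockMatrix):
    """Structured brain state: four labelled correlation blocks.

    ``mc`` (3x3) and ``loc`` (4x4) are sub-networks of the full-channel
    correlation matrix, ``mc_loc`` (3x4) the rectangular cross block, and
    ``mnet`` (3x3) the mesoscale network over region-pooled signals.
    Data-derived observations are symmetric with unit diagonal on the
    square blocks; states propagated through linear dynamics are not
    required to be (``validate_correlation`` checks the strict form).
    """

    SHAPES = OBS_BLOCK_SHAPES

    def validate_correlation(self, atol: float = 1e-8) -> None:
        """Assert the strict correlation-matrix form of the square blocks."""
        for name in ("mc", "loc", "mnet"):
            b = getattr(self, name)
            if not np.allclose(b, b.T, atol=atol):
                raise InvalidInputError(f"block '{name}' is not symmetric")
            if not np.allclose(np.diag(b), 1.0, atol=atol):
                raise InvalidInputError(f"block '{name}' has non-unit diagonal")
        for name in BLOCK_NAMES:
            b = getattr(self, name)
            if np.any(b < -1 - atol) or np.any(b > 1 + atol):
                raise InvalidInputError(f"block '{name}' has entries outside [-1, 1]")


class ProcessNoise(_BlockMatrix):
    """Trial-to-trial state fluctuation; observation-shaped blocks."""

    SHAPES = OBS_BLOCK_SHAPES


class TransitionMatrix(_BlockMatrix):
    """Block-structured linear map carrying one observation to the next."""

    SHAPES = TRANS_BLOCK_SHAPES

    @classmethod
    def identity(cls) -> "TransitionMatrix":
        return cls(**{n: np.eye(s[0], s[1]) for n, s in cls.SHAPES.items()})

    def apply(self, x: ObservationMatrix) -> ObservationMatrix:
        """Left-multiply each state block by the matching transition block."""
        return ObservationMatrix(
            mc=self.mc @ x.mc,
            loc=self.loc @ x.loc,
            mc_loc=self.mc_loc @ x.mc_loc,
            mnet=self.mnet @ x.mnet,
        )


@dataclass
class Annotation:
    """Run/rest event in seconds, half-open interval [onset, onset+duration)."""

    onset: float
    duration: float
    label: str
    valid: bool = True

    @property
    def end(self) -> float:
        return self.onset + self.duration


@dataclass
class EEGRecording:
    """Raw multichannel signal plus metadata.

    ``data`` is channels x samples in microvolts; ``device`` is one of
    ``gtec32 | flex8 | neusenw32 | synthetic``.
    """

    data: np.ndarray
    channel_names: Sequence[str]
    sampling_rate: float
    device: str = "synthetic"
    annotations: list[Annotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.channel_names = list(self.channel_names)
        if self.data.ndim != 2:
            raise InvalidInputError("data must be 2-D (channels x samples)")
        if len(self.channel_names) != self.data.shape[0]:
            raise InvalidInputError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} data rows"
            )
        if self.sampling_rate <= 0:
            raise InvalidConfigError("sampling_rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise InvalidInputError("data contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def copy_with(self, **kw) -> "EEGRecording":
        base = dict(
            data=self.data.copy(),
            channel_names=list(self.channel_names),
            sampling_rate=self.sampling_rate,
            device=self.device,
            annotations=[dataclasses.replace(a) for a in self.annotations],
        )
        base.update(kw)
        return EEGRecording(**base)


@dataclass
class AlignedRun:
    """A harmonized 7-channel segment in canonical channel order."""

    data: np.ndarray
    sampling_rate: float
    condition: str
    session_id: str = ""
    run_index: int = 0
    partial: bool = False
    channel_names: tuple[str, ...] = CANONICAL_CHANNELS

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channel_names):
            raise InvalidInputError(
                f"aligned run must be {len(self.channel_names)} x samples, "
                f"got {self.data.shape}"
            )

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class ArtifactDecomposition:
    """ICA factorisation of a recording with rejected-component bookkeeping."""

    mixing: np.ndarray          # channels x components
    sources: np.ndarray         # components x samples
    mean: np.ndarray            # per-channel mean removed before unmixing
    rejected: dict[int, str] = field(default_factory=dict)  # index -> reason

    def reconstruct(self, exclude: Sequence[int] = ()) -> np.ndarray:
        keep = [i for i in range(self.sources.shape[0]) if i not in set(exclude)]
        return self.mixing[:, keep] @ self.sources[keep] + self.mean[:, None]


@dataclass
class SessionChain:
    """One session's Markov chain of observations, transitions and noise."""

    session_id: str
    condition: str
    states: list[ObservationMatrix]
    noise: list[ProcessNoise] | None = None
    transitions: list[TransitionMatrix] | None = None

    def __post_init__(self) -> None:
        if len(self.states) < 2:
            raise InvalidInputError("a chain needs at least 2 states")
        k = len(self.states)
        if self.transitions is not None and len(self.transitions) != k - 1:
            raise InvalidInputError("len(transitions) must equal len(states) - 1")
        if self.noise is not None and len(self.noise) != k - 1:
            raise InvalidInputError("len(noise) must equal len(states) - 1")

    def __len__(self) -> int:
        return len(self.states)

    def __iter__(self) -> Iterator[ObservationMatrix]:
        return iter(self.states)
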