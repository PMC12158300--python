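"""EEG harmonization pipeline.

Heterogeneous-device recordings are brought onto a common footing:
resample to 250 Hz, zero-phase Butterworth band-pass, common average
reference, ICA-based artifact removal, alignment to the canonical
7-channel montage, segmentation into annotated runs, baseline
correction, and session-level z-scoring -- in that order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal as sp_signal
from sklearn.decomposition import FastICA

from .types import (
    CANONICAL_CHANNELS,
    AlignedRun,
    Annotation,
    ArtifactDecomposition,
    EEGRecording,
    InvalidConfigError,
    InvalidInputError,
)

#: Label appended when the original reference electrode is retained
#: during re-referencing to preserve rank.
REFERENCE_LABEL = "REF"


@dataclass
class ICACriteria:
    """Automated component-rejection thresholds.

    A component is flagged ocular when the fraction of its spectral power
    below ``low_freq_hz`` exceeds ``low_fraction``, muscular when the
    fraction above ``high_freq_hz`` exceeds ``high_fraction``.
    """

    enabled: bool = True
    low_freq_hz: float = 4.0
    low_fraction: float = 0.6
    high_freq_hz: float = 20.0
    high_fraction: float = 0.6
    seed: int = 0
    max_iter: int = 1000


@dataclass
class PreprocessConfig:
    target_rate: float = 250.0
    band: tuple[float, float] = (0.5, 38.0)
    filter_order: int = 8
    car_keep_reference: bool = True
    ica: ICACriteria = field(default_factory=ICACriteria)
    baseline_s: float = 0.5
    run_length_s: float = 134.0


# ---------------------------------------------------------------------------
# individual steps
# ---------------------------------------------------------------------------


def resample_to(rec: EEGRecording, target_rate: float) -> EEGRecording:
    """Polyphase resampling with anti-alias filtering.

    Annotations are stored in seconds and therefore unchanged.
    """
    if target_rate <= 0:
        raise InvalidConfigError("target_rate must be positive")
    if target_rate == rec.sampling_rate:
        return rec.copy_with()
    if target_rate > 4 * rec.sampling_rate:
        warnings.warn(
            f"upsampling from {rec.sampling_rate} Hz to {target_rate} Hz "
            "exceeds 4x the original support"
        )
    frac = Fraction(target_rate / rec.sampling_rate).limit_denominator(10_000)
    data = sp_signal.resample_poly(rec.data, frac.numerator, frac.denominator, axis=1)
    return rec.copy_with(data=data, sampling_rate=target_rate)


def bandpass_zero_phase(
    rec: EEGRecording,
    low: float = 0.5,
    high: float = 38.0,
    order: int = 8,
) -> EEGRecording:
    """Zero-phase Butterworth band-pass (forward-backward filtering).

    ``order`` is the overall band-pass order and must be even; the
    effective magnitude response is squared by the forward-backward pass.
    """
    nyquist = rec.sampling_rate / 2.0
    if not (0 < low < high < nyquist):
        raise InvalidConfigError(
            f"band ({low}, {high}) must satisfy 0 < low < high < Nyquist ({nyquist})"
        )
    if order < 2 or order % 2:
        raise InvalidConfigError("band-pass order must be a positive even number")
    sos = sp_signal.butter(
        order // 2, [low, high], btype="bandpass", fs=rec.sampling_rate, output="sos"
    )
    data = sp_signal.sosfiltfilt(sos, rec.data, axis=1)
    return rec.copy_with(data=data)


def bandpass_gain(
    freq: float, low: float, high: float, order: int, sampling_rate: float
) -> float:
    """Analytic zero-phase gain (|H|^2) of the band-pass at ``freq``."""
    sos = sp_signal.butter(
        order // 2, [low, high], btype="bandpass", fs=sampling_rate, output="sos"
    )
    _, h = sp_signal.sosfreqz(sos, worN=[freq], fs=sampling_rate)
    return float(np.abs(h[0]) ** 2)


def common_average_reference(
    rec: EEGRecording, keep_original_reference: bool = False
) -> EEGRecording:
    """Subtract the cross-channel mean at every sample.

    With ``keep_original_reference`` the (implicitly zero) original
    reference electrode is appended as an extra channel before averaging,
    preserving the rank of the data matrix.
    """
    if rec.n_channels < 2:
        raise InvalidInputError("common average reference needs at least 2 channels")
    data, names = rec.data, list(rec.channel_names)
    if keep_original_reference and REFERENCE_LABEL not in names:
        data = np.vstack([data, np.zeros(rec.n_samples)])
        names = names + [REFERENCE_LABEL]
    data = data - data.mean(axis=0, keepdims=True)
    return rec.copy_with(data=data, channel_names=names)


def remove_artifacts_ica(
    rec: EEGRecording, criteria: ICACriteria | None = None
) -> tuple[EEGRecording, ArtifactDecomposition]:
    """Decompose, flag ocular/muscular components spectrally, reconstruct.

    Returns the cleaned recording and the bookkeeping decomposition.
    With ``criteria.enabled`` false nothing is rejected and the output
    reproduces the input up to reconstruction error.
    """
    criteria = criteria or ICACriteria()
    if rec.n_channels < 2:
        raise InvalidInputError("ICA needs at least 2 channels")
    # common-average referencing with a retained reference leaves rank
    # n_channels - 1; decompose into exactly rank components
    rank = np.linalg.matrix_rank(rec.data)
    if rank < 2:
        raise InvalidInputError(
            f"rank-deficient input (rank {rank} of {rec.n_channels} channels); "
            "ICA decomposition would be degenerate"
        )

    ica = FastICA(
        n_components=rank,
        random_state=criteria.seed,
        max_iter=criteria.max_iter,
        whiten="unit-variance",
    )
    sources = ica.fit_transform(rec.data.T).T       # components x samples
    mixing = ica.mixing_                            # channels x components
    mean = ica.mean_

    rejected: dict[int, str] = {}
    if criteria.enabled:
        nperseg = min(rec.n_samples, 2048)
        freqs, psd = sp_signal.welch(sources, fs=rec.sampling_rate, nperseg=nperseg)
        total = psd.sum(axis=1)
        low_frac = psd[:, freqs < criteria.low_freq_hz].sum(axis=1) / total
        high_frac = psd[:, freqs > criteria.high_freq_hz].sum(axis=1) / total
        for i in range(sources.shape[0]):
            if low_frac[i] > criteria.low_fraction:
                rejected[i] = "ocular"
            elif high_frac[i] > criteria.high_fraction:
                rejected[i] = "muscular"

    decomposition = ArtifactDecomposition(
        mixing=mixing, sources=sources, mean=mean, rejected=rejected
    )
    if len(rejected) == sources.shape[0]:
        warnings.warn("all independent components rejected; cleaned signal is zero")
    cleaned = decomposition.reconstruct(exclude=list(rejected))
    return rec.copy_with(data=cleaned), decomposition


#: Channel recipe per device: canonical name -> source channels averaged.
_DEVICE_RECIPES: dict[str, dict[str, tuple[str, ...]]] = {
    "flex8": {
        "C3": ("C3",), "Cz": ("Cz",), "C4": ("C4",),
        "P7": ("P7",), "Pz": ("Pz",), "PO3": ("P3", "O1"), "Oz": ("Oz",),
    },
}
for _dev in ("gtec32", "neusenw32", "synthetic"):
    _DEVICE_RECIPES[_dev] = {c: (c,) for c in CANONICAL_CHANNELS}


def align_channels(rec: EEGRecording) -> EEGRecording:
    """Map a device's montage onto the canonical 7-channel order.

    For the reduced 8-channel montage the missing PO3 channel is the
    sample-wise mean of P3 and O1; the 32-channel layouts select the
    seven canonical electrodes directly.
    """
    recipe = _DEVICE_RECIPES.get(rec.device)
    if recipe is None:
        raise InvalidInputError(f"unknown device '{rec.device}'")
    names = list(rec.channel_names)
    missing = sorted(
        {src for srcs in recipe.values() for src in srcs} - set(names)
    )
    if missing:
        raise InvalidInputError(f"missing required channels: {missing}")
    rows = []
    for canonical in CANONICAL_CHANNELS:
        idx = [names.index(src) for src in recipe[canonical]]
        rows.append(rec.data[idx].mean(axis=0))
    return rec.copy_with(data=np.vstack(rows), channel_names=list(CANONICAL_CHANNELS))


def segment_runs(
    rec: EEGRecording, run_length_s: float = 134.0, session_id: str = ""
) -> list[AlignedRun]:
    """Cut the recording into annotated condition segments.

    Invalid annotations are dropped; segments shorter than
    ``run_length_s`` are flagged partial; overlapping valid annotations
    are an error.
    """
    if list(rec.channel_names) != list(CANONICAL_CHANNELS):
        raise InvalidInputError("segment_runs expects a channel-aligned recording")
    valid = sorted(
        (a for a in rec.annotations if a.valid), key=lambda a: a.onset
    )
    for a, b in zip(valid[:-1], valid[1:]):
        if b.onset < a.end:
            raise InvalidInputError(
                f"overlapping annotations at {a.onset:.3f}s and {b.onset:.3f}s"
            )
    if not valid:
        warnings.warn("no valid annotations; nothing to segment")
        return []

    fs = rec.sampling_rate
    target = int(round(run_length_s * fs))
    runs = []
    for idx, ann in enumerate(valid):
        start = int(round(ann.onset * fs))
        stop = min(start + target, int(round(ann.end * fs)), rec.n_samples)
        data = rec.data[:, start:stop]
        runs.append(
            AlignedRun(
                data=data,
                sampling_rate=fs,
                condition=ann.label,
                session_id=session_id,
                run_index=idx,
                partial=data.shape[1] < target,
            )
        )
    return runs


def baseline_correct(run: AlignedRun, baseline: float = 0.5) -> AlignedRun:
    """Subtract each channel's mean over the first ``baseline`` seconds."""
    if baseline <= 0:
        raise InvalidConfigError("baseline must be positive")
    n = int(round(baseline * run.sampling_rate))
    if n > run.n_samples:
        raise InvalidInputError("baseline window exceeds run duration")
    corrected = run.data - run.data[:, :n].mean(axis=1, keepdims=True)
    return AlignedRun(
        data=corrected,
        sampling_rate=run.sampling_rate,
        condition=run.condition,
        session_id=run.session_id,
        run_index=run.run_index,
        partial=run.partial,
    )


def zscore_session(runs: list[AlignedRun]) -> list[AlignedRun]:
    """Per-channel z-score with mean/sd pooled over all runs of a session."""
    if not runs:
        raise InvalidInputError("zscore_session needs at least one run")
    pooled = np.concatenate([r.data for r in runs], axis=1)
    mean = pooled.mean(axis=1, keepdims=True)
    sd = pooled.std(axis=1, keepdims=True)
    for i, s in enumerate(sd.ravel()):
        if s == 0:
            raise InvalidInputError(
                f"channel '{runs[0].channel_names[i]}' has zero variance in session"
            )
    out = []
    for r in runs:
        out.append(
            AlignedRun(
                data=(r.data - mean) / sd,
                sampling_rate=r.sampling_rate,
                condition=r.condition,
                session_id=r.session_id,
                run_index=r.run_index,
                partial=r.partial,
            )
        )
    return out


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

PIPELINE_ORDER = (
    "resample", "bandpass", "car", "ica", "align", "segment", "baseline", "zscore",
)


def preprocess_recording(
    rec: EEGRecording,
    config: PreprocessConfig | None = None,
    session_id: str = "",
) -> tuple[list[AlignedRun], dict]:
    """Run the full harmonization pipeline in the contracted order.

    Returns the z-scored aligned runs and a provenance record listing
    the applied steps and their parameters.
    """
    config = config or PreprocessConfig()
    rec = resample_to(rec, config.target_rate)
    rec = bandpass_zero_phase(rec, *config.band, order=config.filter_order)
    rec = common_average_reference(rec, keep_original_reference=config.car_keep_reference)
    rec, decomposition = remove_artifacts_ica(rec, config.ica)
    rec = align_channels(rec)
    runs = segment_runs(rec, run_length_s=config.run_length_s, session_id=session_id)
    runs = [baseline_correct(r, config.baseline_s) for r in runs]
    runs = zscore_session(runs)
    provenance = {
        "order": list(PIPELINE_ORDER),
        "target_rate": config.target_rate,
        "band": list(config.band),
        "filter_order": config.filter_order,
        "car_keep_reference": config.car_keep_reference,
        "ica_rejected": {str(k): v for k, v in decomposition.rejected.items()},
        "baseline_s": config.baseline_s,
        "run_length_s": config.run_length_s,
    }
    return runs, provenance
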