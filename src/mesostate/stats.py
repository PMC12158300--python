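"""Mass-univariate comparison of transition weights between conditions.

For each of the 43 linearised weight positions: assumption checks
(Shapiro-Wilk normality, Levene homogeneity), Welch two-sample t-tests,
Benjamini-Hochberg step-up FDR control, and condition weight ratios at
the significant positions (with a bootstrap confidence interval).
Figure-ready exports use the zero-for-non-significant fill convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sp_stats

from .dynamics import SessionFit, linearize
from .types import (
    TRANSITION_VECTOR_LENGTH,
    InvalidInputError,
    TransitionMatrix,
)

#: (block, row label, col label) for every linearised weight position.
_MC = ("C3", "Cz", "C4")
_LOC = ("P7", "Pz", "PO3", "Oz")
_MNET = ("LMC", "RMC", "LOC")
POSITION_LABELS: list[tuple[str, str, str]] = (
    [("mc", r, c) for r in _MC for c in _MC]
    + [("loc", r, c) for r in _LOC for c in _LOC]
    + [("mc_loc", r, c) for r in _MC for c in _MC]
    + [("mnet", r, c) for r in _MNET for c in _MNET]
)
assert len(POSITION_LABELS) == TRANSITION_VECTOR_LENGTH


@dataclass
class WeightTestResult:
    block: str
    position: tuple[str, str]
    index: int
    t_stat: float
    p_value: float
    q_value: float
    significant: bool
    degenerate: bool = False
    ratio_nft_over_rest: float | None = None
    ratio_ci: tuple[float, float] | None = None

    def to_jsonable(self) -> dict:
        return {
            "block": self.block,
            "row": self.position[0],
            "col": self.position[1],
            "index": self.index,
            "t_stat": self.t_stat,
            "p_value": self.p_value,
            "q_value": self.q_value,
            "significant": self.significant,
            "degenerate": self.degenerate,
            "ratio_nft_over_rest": self.ratio_nft_over_rest,
            "ratio_ci": list(self.ratio_ci) if self.ratio_ci else None,
        }


# ---------------------------------------------------------------------------
# assumption checks
# ---------------------------------------------------------------------------


def assumption_checks(
    samples_a: np.ndarray, samples_b: np.ndarray, alpha: float = 0.05
) -> dict:
    """Shapiro-Wilk per group plus Levene across groups."""
    a = np.asarray(samples_a, dtype=np.float64)
    b = np.asarray(samples_b, dtype=np.float64)
    if len(a) < 3 or len(b) < 3:
        raise InvalidInputError("assumption checks need n >= 3 per group")
    sw_a = sp_stats.shapiro(a)
    sw_b = sp_stats.shapiro(b)
    lev = sp_stats.levene(a, b)
    return {
        "shapiro_p_a": float(sw_a.pvalue),
        "shapiro_p_b": float(sw_b.pvalue),
        "levene_p": float(lev.pvalue),
        "normality_violated": bool(min(sw_a.pvalue, sw_b.pvalue) < alpha),
        "variance_violated": bool(lev.pvalue < alpha),
    }


# ---------------------------------------------------------------------------
# BH step-up FDR
# ---------------------------------------------------------------------------


def fdr_bh(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: returns (q_values, rejection_mask).

    q-values are the standard monotone adjusted p-values
    ``q_(i) = min_{j >= i} m * p_(j) / j`` (capped at 1); the mask
    rejects every position with ``q < alpha`` is *not* used -- rejection
    follows the step-up rule directly, which coincides with
    ``q <= alpha``.
    """
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p)):
        raise InvalidInputError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q_sorted = ranked * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    reject = q <= alpha
    return q, reject


# ---------------------------------------------------------------------------
# weight-wise tests and ratios
# ---------------------------------------------------------------------------


def _stack_weights(fits_or_arrays) -> np.ndarray:
    """Rows = observations (one per transition), cols = 43 positions."""
    rows = []
    for item in fits_or_arrays:
        if isinstance(item, SessionFit):
            rows.extend(linearize(a) for a in item.final_transitions)
        elif isinstance(item, TransitionMatrix):
            rows.append(linearize(item))
        else:
            rows.append(np.asarray(item, dtype=np.float64).ravel())
    out = np.stack(rows)
    if out.shape[1] != TRANSITION_VECTOR_LENGTH:
        raise InvalidInputError(
            f"expected {TRANSITION_VECTOR_LENGTH} weight positions, got {out.shape[1]}"
        )
    return out


def weightwise_ttests(
    nft_weights,
    rest_weights,
    alpha: float = 0.05,
    equal_var: bool = False,
) -> list[WeightTestResult]:
    """Per-position two-tailed two-sample t-tests with BH correction.

    Welch's unequal-variance form by default.  Positions where both
    groups have zero variance are flagged degenerate (p set to 1, never
    significant).
    """
    a = _stack_weights(nft_weights)
    b = _stack_weights(rest_weights)
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise InvalidInputError("each group needs at least 2 observations")

    m = a.shape[1]
    t_stats = np.zeros(m)
    p_vals = np.ones(m)
    degenerate = np.zeros(m, dtype=bool)
    for i in range(m):
        if np.var(a[:, i]) == 0 and np.var(b[:, i]) == 0:
            degenerate[i] = True
            if np.mean(a[:, i]) == np.mean(b[:, i]):
                t_stats[i], p_vals[i] = 0.0, 1.0
            else:
                t_stats[i], p_vals[i] = np.inf, 1.0  # undefined, flagged
            continue
        res = sp_stats.ttest_ind(a[:, i], b[:, i], equal_var=equal_var)
        t_stats[i], p_vals[i] = float(res.statistic), float(res.pvalue)

    q_vals, reject = fdr_bh(p_vals, alpha=alpha)
    results = []
    for i, (block, row, col) in enumerate(POSITION_LABELS):
        results.append(
            WeightTestResult(
                block=block,
                position=(row, col),
                index=i,
                t_stat=float(t_stats[i]),
                p_value=float(p_vals[i]),
                q_value=float(q_vals[i]),
                significant=bool(reject[i] and not degenerate[i]),
                degenerate=bool(degenerate[i]),
            )
        )
    return results


def _groupwise_means(fits_or_arrays) -> np.ndarray:
    """One mean weight vector per input item (e.g. per session fit)."""
    means = []
    for item in fits_or_arrays:
        means.append(_stack_weights([item]).mean(axis=0))
    return np.stack(means)


def weight_ratio(
    nft_weights,
    rest_weights,
    results: list[WeightTestResult],
    n_boot: int = 1000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> list[WeightTestResult]:
    """Attach mean(NFT)/mean(rest) ratios at the significant positions.

    Non-significant positions keep ``ratio_nft_over_rest = None`` (the
    zero-fill convention is applied only at presentation time).  The
    bootstrap percentile CI resamples the top-level items of each group
    (sessions when fits are given) -- transitions within a fitted session
    are not independent, so resampling them would understate the CI.
    """
    a = _stack_weights(nft_weights)
    b = _stack_weights(rest_weights)
    a_means = _groupwise_means(nft_weights)
    b_means = _groupwise_means(rest_weights)
    rng = np.random.default_rng(seed)
    lo_q = (1 - ci_level) / 2
    for res in results:
        if not res.significant:
            continue
        i = res.index
        mean_rest = float(np.mean(b[:, i]))
        if mean_rest == 0:
            res.ratio_nft_over_rest = None
            res.degenerate = True
            continue
        res.ratio_nft_over_rest = float(np.mean(a[:, i]) / mean_rest)
        boots = np.empty(n_boot)
        na, nb = len(a_means), len(b_means)
        for t in range(n_boot):
            ra = a_means[rng.integers(0, na, na), i].mean()
            rb = b_means[rng.integers(0, nb, nb), i].mean()
            boots[t] = ra / rb if rb != 0 else np.nan
        boots = boots[np.isfinite(boots)]
        res.ratio_ci = (
            float(np.quantile(boots, lo_q)),
            float(np.quantile(boots, 1 - lo_q)),
        )
    return results


def ratio_matrices(results: list[WeightTestResult]) -> dict[str, np.ndarray]:
    """Figure-ready per-block ratio matrices, zero-filled where not significant."""
    shapes = {"mc": (3, 3), "loc": (4, 4), "mc_loc": (3, 3), "mnet": (3, 3)}
    labels = {"mc": _MC, "loc": _LOC, "mc_loc": _MC, "mnet": _MNET}
    out = {b: np.zeros(s) for b, s in shapes.items()}
    for res in results:
        if res.ratio_nft_over_rest is None:
            continue
        rows = labels[res.block]
        cols = labels[res.block]
        r = rows.index(res.position[0])
        c = cols.index(res.position[1])
        out[res.block][r, c] = res.ratio_nft_over_rest
    return out


def compare_conditions(
    nft_fits: list[SessionFit],
    rest_fits: list[SessionFit],
    alpha: float = 0.05,
    n_boot: int = 1000,
    seed: int = 0,
) -> list[WeightTestResult]:
    """Full comparison: t-tests, BH correction, ratios with bootstrap CI."""
    results = weightwise_ttests(nft_fits, rest_fits, alpha=alpha)
    return weight_ratio(nft_fits, rest_fits, results, n_boot=n_boot, seed=seed)
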