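"""The interaction-score chain: frequencies, null model, noise filter, IS.

The readout of a pooled screen is a pair of count matrices per replicate:
N_RS (recombination-selection, clone representation only) and N_RIS
(recombination-interaction-selection). Scores are derived per replicate and
then combined:

1. ``normalize_counts``   F(x,y) = N(x,y) / sum N           (both conditions)
2. ``null_matrix``        F_phi(x,y) = F_RS(x) * F_RS(y)    (marginal product)
3. ``noise_filter``       zero RIS frequencies assigned to the lower-mean
                          component of a two-Gaussian mixture (most pairs do
                          not interact, so the bulk of non-zero frequencies
                          is noise)
4. ``interaction_score``  IS(x,y) = F_RIS'(x,y) / F_phi(x,y)
5. ``average_is``         element-wise mean over replicates
6. ``subtract_q3``        IS_FINAL(x,y) = IS(x,y) - Q3(IS(x,.)), clamped at 0

Dividing by the marginal-product null corrects for clone overrepresentation
and sequencing-depth artefacts; averaging replicates suppresses stochastic
false positives; the per-bait upper-quartile subtraction removes residual
row-wise auto-activation signal (Q3 of a well-behaved bait row is 0, so
ordinary rows are untouched).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.mixture import GaussianMixture

from .matrix import CountMatrix, FrequencyMatrix, ISMatrix, NullMatrix

__all__ = [
    "MixtureFit",
    "normalize_counts",
    "null_matrix",
    "noise_filter",
    "interaction_score",
    "average_is",
    "upper_quartile",
    "subtract_q3",
    "sn_ratio",
    "score_replicate",
    "score_screen",
]


def normalize_counts(counts: CountMatrix) -> FrequencyMatrix:
    """Counts to detection frequencies F(x,y) = N(x,y) / sum N.

    An all-zero count matrix yields an all-zero frequency matrix (with a
    warning) rather than an error, so empty conditions propagate visibly.
    """
    total = counts.values.sum()
    if total == 0:
        warnings.warn("all-zero count matrix: frequencies are all zero")
        values = np.zeros(counts.shape, dtype=float)
    else:
        values = counts.values / float(total)
    return FrequencyMatrix(
        baits=counts.baits,
        preys=counts.preys,
        values=values,
        condition=counts.condition,
    )


def null_matrix(f_rs: FrequencyMatrix) -> NullMatrix:
    """Independence null from the RS marginals: F_phi = F_RS(x) * F_RS(y)."""
    rows = f_rs.row_marginals()
    cols = f_rs.col_marginals()
    return NullMatrix(
        baits=f_rs.baits,
        preys=f_rs.preys,
        values=np.outer(rows, cols),
        row_marginal=rows,
        col_marginal=cols,
    )


@dataclass
class MixtureFit:
    """Two-component univariate normal mixture over non-zero frequencies."""

    means: np.ndarray  # (2,)
    stds: np.ndarray  # (2,)
    weights: np.ndarray  # (2,), sums to 1
    responsibilities: np.ndarray  # (n_values, 2) posteriors, rows sum to 1
    noise_component: int  # index of the lower-mean component
    log_space: bool
    converged: bool

    @property
    def signal_component(self) -> int:
        return 1 - self.noise_component


def _passthrough(f_ris: FrequencyMatrix) -> tuple[FrequencyMatrix, None]:
    copy = FrequencyMatrix(
        baits=f_ris.baits,
        preys=f_ris.preys,
        values=f_ris.values.copy(),
        condition=f_ris.condition,
    )
    return copy, None


def noise_filter(
    f_ris: FrequencyMatrix,
    seed: int = 0,
    log_space: bool = False,
    min_values: int = 4,
    max_iter: int = 1000,
    tol: float = 1e-8,
) -> tuple[FrequencyMatrix, MixtureFit | None]:
    """Zero out RIS frequencies more likely noise than signal.

    A two-component normal mixture is fitted by EM to the non-zero
    frequencies (optionally in log space). Values whose posterior
    probability under the lower-mean ("noise") component exceeds that under
    the higher-mean ("signal") component are set to 0; zeros stay zero and
    retained values are unchanged.

    EM is initialised deterministically: component means at the 25th/75th
    percentiles of the data, equal weights, pooled standard deviation.
    Degenerate inputs (fewer than ``min_values`` non-zero values, no spread,
    coincident initial means) and non-converged fits fall back to returning
    the input unchanged, with a warning, rather than filtering on an
    unreliable fit.
    """
    nz_mask = f_ris.values > 0
    nz_values = f_ris.values[nz_mask]
    if nz_values.size < min_values:
        warnings.warn(
            f"noise filter skipped: only {nz_values.size} non-zero values"
        )
        return _passthrough(f_ris)
    data = np.log(nz_values) if log_space else nz_values
    if np.ptp(data) == 0:
        warnings.warn("noise filter skipped: all non-zero values identical")
        return _passthrough(f_ris)
    q25, q75 = np.percentile(data, [25, 75])
    if q25 == q75:
        warnings.warn("noise filter skipped: degenerate initial means")
        return _passthrough(f_ris)
    pooled_var = float(np.var(data))
    model = GaussianMixture(
        n_components=2,
        covariance_type="spherical",
        means_init=np.array([[q25], [q75]]),
        weights_init=np.array([0.5, 0.5]),
        precisions_init=np.array([1.0 / pooled_var, 1.0 / pooled_var]),
        tol=tol,
        max_iter=max_iter,
        n_init=1,
        random_state=seed,
    )
    column = data.reshape(-1, 1)
    model.fit(column)
    if not model.converged_:
        warnings.warn("noise filter skipped: EM did not converge")
        return _passthrough(f_ris)
    means = model.means_.ravel()
    if means[0] == means[1]:
        warnings.warn("noise filter skipped: mixture collapsed to one mode")
        return _passthrough(f_ris)
    responsibilities = model.predict_proba(column)
    noise_component = int(np.argmin(means))
    fit = MixtureFit(
        means=means,
        stds=np.sqrt(model.covariances_.ravel()),
        weights=model.weights_.ravel(),
        responsibilities=responsibilities,
        noise_component=noise_component,
        log_space=log_space,
        converged=True,
    )
    is_noise = (
        responsibilities[:, noise_component]
        > responsibilities[:, fit.signal_component]
    )
    filtered = f_ris.values.copy()
    nz_idx = np.flatnonzero(nz_mask.ravel())
    filtered.ravel()[nz_idx[is_noise]] = 0.0
    out = FrequencyMatrix(
        baits=f_ris.baits,
        preys=f_ris.preys,
        values=filtered,
        condition=f_ris.condition,
    )
    return out, fit


def interaction_score(
    f_ris_prime: FrequencyMatrix, f_phi: NullMatrix
) -> ISMatrix:
    """IS(x,y) = F_RIS'(x,y) / F_phi(x,y).

    Cells with zero null expectation and zero signal score 0. Cells with
    zero null but positive signal (clones never sampled under RS but seen
    under RIS) are scored against a floor equal to the smallest positive
    null entry and flagged, rather than silently dropped, so rarely sampled
    clones are not biased against.
    """
    if f_ris_prime.shape != f_phi.shape:
        raise ValueError("signal and null matrices differ in shape")
    f_ris_prime.require_same_labels(f_phi)
    null = f_phi.values
    signal = f_ris_prime.values
    scores = np.zeros_like(signal, dtype=float)
    flagged = np.zeros_like(signal, dtype=bool)
    positive_null = null > 0
    scores[positive_null] = signal[positive_null] / null[positive_null]
    orphan = (~positive_null) & (signal > 0)
    if orphan.any():
        if positive_null.any():
            floor = null[positive_null].min()
            scores[orphan] = signal[orphan] / floor
            flagged[orphan] = True
            warnings.warn(
                f"{int(orphan.sum())} cell(s) had signal but zero null "
                "expectation; scored against the smallest positive null entry"
            )
        else:
            warnings.warn(
                "null matrix is entirely zero; scores with signal set to 0"
            )
    return ISMatrix(
        baits=f_ris_prime.baits,
        preys=f_ris_prime.preys,
        values=scores,
        flagged=flagged,
    )


def average_is(replicates: Sequence[ISMatrix]) -> ISMatrix:
    """Element-wise mean of per-replicate IS matrices (same id ordering)."""
    if not replicates:
        raise ValueError("at least one replicate required")
    first = replicates[0]
    for other in replicates[1:]:
        first.require_same_labels(other)
    stacked = np.stack([r.values for r in replicates])
    flags = None
    if any(r.flagged is not None for r in replicates):
        flags = np.any(
            [r.flagged for r in replicates if r.flagged is not None], axis=0
        )
    return ISMatrix(
        baits=first.baits,
        preys=first.preys,
        values=stacked.mean(axis=0),
        flagged=flags,
    )


def upper_quartile(values: np.ndarray) -> float:
    """Q3 as the ceil(3n/4)-th ascending order statistic (no interpolation)."""
    values = np.asarray(values, dtype=float).ravel()
    n = values.size
    if n == 0:
        raise ValueError("empty row")
    rank = math.ceil(3 * n / 4)  # 1-based
    return float(np.sort(values)[rank - 1])


def subtract_q3(avg: ISMatrix) -> ISMatrix:
    """Per-bait upper-quartile subtraction, clamped at zero.

    Removes basal auto-activation: an auto-activating bait elevates its
    whole row, so its row Q3 captures the basal level; a well-behaved bait
    row has Q3 = 0 (most pairs do not interact) and is unchanged.
    """
    q3 = np.apply_along_axis(upper_quartile, 1, avg.values)
    values = np.clip(avg.values - q3[:, None], 0.0, None)
    return ISMatrix(
        baits=avg.baits,
        preys=avg.preys,
        values=values,
        flagged=None if avg.flagged is None else avg.flagged.copy(),
    )


def sn_ratio(
    scores: ISMatrix,
    positives: Sequence[tuple[str, str]],
    negatives: Sequence[tuple[str, str]],
) -> float:
    """Signal-to-noise: mean IS over expected positive pairs divided by the
    mean over expected negative pairs (infinite, with a warning, if the
    negative mean is zero)."""
    if not positives or not negatives:
        raise ValueError("both pair sets must be non-empty")
    pos_mean = float(np.mean([scores[p] for p in positives]))
    neg_mean = float(np.mean([scores[p] for p in negatives]))
    if neg_mean == 0:
        warnings.warn("negative-set mean IS is zero: SN ratio is infinite")
        return math.inf
    return pos_mean / neg_mean


def score_replicate(
    n_rs: CountMatrix,
    n_ris: CountMatrix,
    seed: int = 0,
    apply_noise_filter: bool = True,
    log_space: bool = False,
) -> tuple[ISMatrix, MixtureFit | None]:
    """Per-replicate chain: normalise both conditions, build the null from
    RS, noise-filter RIS, and form the IS ratio."""
    n_rs.require_same_labels(n_ris)
    f_rs = normalize_counts(n_rs)
    f_ris = normalize_counts(n_ris)
    f_phi = null_matrix(f_rs)
    if apply_noise_filter:
        f_ris_prime, fit = noise_filter(f_ris, seed=seed, log_space=log_space)
    else:
        f_ris_prime, fit = f_ris, None
    return interaction_score(f_ris_prime, f_phi), fit


def score_screen(
    replicates: Sequence[tuple[CountMatrix, CountMatrix]],
    seed: int = 0,
    apply_noise_filter: bool = True,
    log_space: bool = False,
) -> ISMatrix:
    """Full chain over (N_RS, N_RIS) replicate pairs.

    Per replicate: normalise, noise-filter, score; then average across
    replicates and subtract the per-bait upper quartile. Returns IS_FINAL.
    """
    per_replicate = [
        score_replicate(
            n_rs,
            n_ris,
            seed=seed + i,
            apply_noise_filter=apply_noise_filter,
            log_space=log_space,
        )[0]
        for i, (n_rs, n_ris) in enumerate(replicates)
    ]
    return subtract_q3(average_is(per_replicate))
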