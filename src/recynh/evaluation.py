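"""QC and benchmarking of a screen against a reference interaction set.

Covers a-priori auto-activator detection from bait-level RIS/RS read-count
ratios, sampling/pair complexity under RS, confusion statistics against a
user-supplied reference positive set (unordered pairs; everything else is
treated as a true negative), F1/MCC cut-off optimisation, rank-based
ROC-AUC, and the hypergeometric enrichment tail.

Reference positives are unordered protein pairs; the score matrix is ordered
(bait x prey), so each ordered cell is an evaluation unit whose true label
is membership of its unordered pair in the reference set. Homodimer cells
(bait id == prey id) are excluded by default: the assay underdetects
homodimers for library-preparation reasons, so including them would distort
the benchmark.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats
from sklearn.metrics import roc_auc_score

from .matrix import CountMatrix, ISMatrix

__all__ = [
    "BaitRatioReport",
    "ComplexityReport",
    "ConfusionCounts",
    "CutoffScanResult",
    "detect_autoactivators",
    "complexity",
    "normalize_pairs",
    "load_reference_pairs",
    "confusion",
    "f1_score",
    "mcc",
    "cutoff_scan",
    "roc_auc",
    "hypergeom_tail",
    "wilcoxon_rank_sum",
]

AUTOACTIVATOR_FOLD = 2.5


@dataclass
class BaitRatioReport:
    """Per-bait RIS/RS read-count ratios and auto-activator flags.

    A bait is flagged when its ratio exceeds ``AUTOACTIVATOR_FOLD`` (2.5x)
    times the mean ratio over all baits: reporter activation without any
    interacting prey inflates a bait's whole RIS row, so its total mapped
    reads rise relative to its RS representation.
    """

    baits: list[str]
    reads_ris: np.ndarray
    reads_rs: np.ndarray
    ratio: np.ndarray  # inf where reads_RS == 0 but reads_RIS > 0
    mean_ratio: float
    flagged: np.ndarray

    @property
    def flagged_baits(self) -> list[str]:
        return [b for b, f in zip(self.baits, self.flagged) if f]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "reads_RIS": self.reads_ris,
                "reads_RS": self.reads_rs,
                "ratio": self.ratio,
                "flagged": self.flagged,
            },
            index=self.baits,
        )


def detect_autoactivators(
    n_ris: CountMatrix, n_rs: CountMatrix
) -> BaitRatioReport:
    """Flag auto-activating baits from bait-level RIS/RS read-count ratios.

    The flag threshold is 2.5x the mean ratio; baits with RIS reads but no
    RS reads have an undefined (infinite) ratio and are flagged with a
    warning. The mean is taken over baits with a defined ratio.
    """
    if n_ris.baits != n_rs.baits:
        raise ValueError("bait ids differ between conditions")
    reads_ris = n_ris.values.sum(axis=1).astype(float)
    reads_rs = n_rs.values.sum(axis=1).astype(float)
    ratio = np.full(len(reads_rs), np.nan)
    defined = reads_rs > 0
    ratio[defined] = reads_ris[defined] / reads_rs[defined]
    undefined_active = (~defined) & (reads_ris > 0)
    ratio[undefined_active] = np.inf
    ratio[(~defined) & (reads_ris == 0)] = 0.0
    finite = np.isfinite(ratio)
    mean_ratio = float(ratio[finite].mean()) if finite.any() else 0.0
    flagged = ratio > AUTOACTIVATOR_FOLD * mean_ratio
    if undefined_active.any():
        names = [b for b, u in zip(n_ris.baits, undefined_active) if u]
        warnings.warn(
            f"bait(s) {names} have RIS reads but no RS reads; "
            "ratio undefined, flagged as auto-activators"
        )
        flagged |= undefined_active
    return BaitRatioReport(
        baits=list(n_ris.baits),
        reads_ris=reads_ris,
        reads_rs=reads_rs,
        ratio=ratio,
        mean_ratio=mean_ratio,
        flagged=flagged,
    )


@dataclass(frozen=True)
class ComplexityReport:
    """Fractions of the combinatorial space observed under RS.

    ``sample_complexity`` counts ordered bait-prey fusions; ``pair_complexity``
    counts unordered ORF pairs (self-pairs included in the denominator)
    observed in at least one orientation.
    """

    sample_complexity: float
    pair_complexity: float


def complexity(n_rs: CountMatrix) -> ComplexityReport:
    observed = n_rs.values > 0
    n_cells = observed.size
    sample = observed.sum() / n_cells if n_cells else 0.0
    universe = sorted(set(n_rs.baits) | set(n_rs.preys))
    u = len(universe)
    n_unordered = u * (u + 1) // 2  # includes self-pairs
    seen: set[frozenset[str]] = set()
    for i, bait in enumerate(n_rs.baits):
        for j, prey in enumerate(n_rs.preys):
            if observed[i, j]:
                seen.add(frozenset((bait, prey)))
    pair = len(seen) / n_unordered if n_unordered else 0.0
    return ComplexityReport(sample_complexity=float(sample), pair_complexity=float(pair))


def normalize_pairs(pairs: Iterable[tuple[str, str]]) -> set[frozenset[str]]:
    """Reference pairs as unordered sets (a homodimer is a singleton set)."""
    return {frozenset(p) for p in pairs}


def load_reference_pairs(path: str | Path) -> set[frozenset[str]]:
    """Load a two-column TSV of reference positive pairs (no header needed;
    a first line reading 'a<TAB>b' or 'bait<TAB>prey' is skipped)."""
    frame = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if frame.shape[1] < 2:
        raise ValueError("reference pair file must have two columns")
    first = tuple(frame.iloc[0, :2].str.lower())
    if first in (("a", "b"), ("bait", "prey")):
        frame = frame.iloc[1:]
    return normalize_pairs(
        (str(row[0]), str(row[1])) for row in frame.itertuples(index=False)
    )


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _evaluation_cells(
    scores: ISMatrix,
    reference_positives: Iterable[tuple[str, str]] | set[frozenset[str]],
    exclude_homodimers: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell score vector and true-label vector for ordered cells.

    Reference pairs are unordered, so both orientations of a reference pair
    are labelled positive. Reference pairs mentioning ids absent from the
    matrix are skipped with a warning.
    """
    # idempotent: accepts tuples or already-frozenset pairs
    positives = normalize_pairs(reference_positives)
    universe = set(scores.baits) | set(scores.preys)
    known = {p for p in positives if p <= universe}
    skipped = len(positives) - len(known)
    if skipped:
        warnings.warn(
            f"{skipped} reference pair(s) mention ids absent from the score "
            "matrix and were skipped"
        )
    cell_scores: list[float] = []
    labels: list[bool] = []
    for i, bait in enumerate(scores.baits):
        for j, prey in enumerate(scores.preys):
            if exclude_homodimers and bait == prey:
                continue
            cell_scores.append(scores.values[i, j])
            labels.append(frozenset((bait, prey)) in known)
    return np.asarray(cell_scores, dtype=float), np.asarray(labels, dtype=bool)


def confusion(
    scores: ISMatrix,
    cutoff: float,
    reference_positives: Iterable[tuple[str, str]] | set[frozenset[str]],
    exclude_homodimers: bool = True,
) -> ConfusionCounts:
    """Confusion counts calling a cell positive iff score >= cutoff.

    All cells whose unordered pair is not in the reference set count as true
    negatives; homodimer cells are excluded when the flag is set.
    """
    values, labels = _evaluation_cells(scores, reference_positives, exclude_homodimers)
    called = values >= cutoff
    return ConfusionCounts(
        tp=int((called & labels).sum()),
        fp=int((called & ~labels).sum()),
        tn=int((~called & ~labels).sum()),
        fn=int((~called & labels).sum()),
    )


def f1_score(c: ConfusionCounts) -> float:
    """F1 = 2 TP / (2 TP + FP + FN); 0 (with warning) when undefined."""
    denom = 2 * c.tp + c.fp + c.fn
    if denom == 0:
        warnings.warn("F1 undefined (no positives called or present); using 0")
        return 0.0
    return 2 * c.tp / denom


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 (with warning) when the
    denominator vanishes."""
    denom = (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    if denom == 0:
        warnings.warn("MCC denominator is zero; using 0")
        return 0.0
    return (c.tp * c.tn - c.fp * c.fn) / float(np.sqrt(denom))


@dataclass
class CutoffScanResult:
    table: pd.DataFrame  # columns: cutoff, tp, fp, tn, fn, f1, mcc
    best_f1_cutoff: float
    best_mcc_cutoff: float


def cutoff_scan(
    scores: ISMatrix,
    reference_positives: Iterable[tuple[str, str]] | set[frozenset[str]],
    grid: Sequence[float],
    exclude_homodimers: bool = True,
) -> CutoffScanResult:
    """F1 and MCC at each candidate cut-off, with the argmax of each
    (ties resolved to the smallest cut-off)."""
    if len(grid) == 0:
        raise ValueError("cut-off grid must be non-empty")
    positives = normalize_pairs(reference_positives)
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # degenerate cut-offs are expected mid-scan
        for cutoff in grid:
            c = confusion(scores, cutoff, positives, exclude_homodimers)
            rows.append(
                {
                    "cutoff": cutoff,
                    "tp": c.tp,
                    "fp": c.fp,
                    "tn": c.tn,
                    "fn": c.fn,
                    "f1": f1_score(c),
                    "mcc": mcc(c),
                }
            )
    table = pd.DataFrame(rows)
    # idxmax returns the first (smallest-cut-off) row on ties for a sorted grid
    table_sorted = table.sort_values("cutoff", kind="stable").reset_index(drop=True)
    best_f1 = float(table_sorted.loc[table_sorted["f1"].idxmax(), "cutoff"])
    best_mcc = float(table_sorted.loc[table_sorted["mcc"].idxmax(), "cutoff"])
    return CutoffScanResult(table=table, best_f1_cutoff=best_f1, best_mcc_cutoff=best_mcc)


def roc_auc(
    scores: ISMatrix,
    reference_positives: Iterable[tuple[str, str]] | set[frozenset[str]],
    exclude_homodimers: bool = True,
) -> float:
    """Rank-based ROC-AUC: probability a random positive cell outscores a
    random negative cell, ties counted one half."""
    values, labels = _evaluation_cells(scores, reference_positives, exclude_homodimers)
    if labels.all() or not labels.any():
        raise ValueError("ROC-AUC needs at least one positive and one negative")
    return float(roc_auc_score(labels, values))


def hypergeom_tail(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail P(X >= k) for k successes in a sample of n, drawn without
    replacement from a population of N containing K successes."""
    if not (0 <= k <= n <= N and k <= K <= N):
        raise ValueError(
            f"invalid hypergeometric bounds: k={k}, n={n}, K={K}, N={N}"
        )
    return float(_stats.hypergeom.sf(k - 1, N, K, n))


def wilcoxon_rank_sum(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sample Wilcoxon rank-sum test (thin wrapper; two-sided p)."""
    result = _stats.ranksums(a, b)
    return float(result.statistic), float(result.pvalue)
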