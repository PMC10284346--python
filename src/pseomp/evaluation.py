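"""Evaluation: confusion counts, metrics, ROC/auROC, jackknife, grid search.

The metric suite for a binary OMP/non-OMP classifier:

    Sn  = TP / (TP + FN)                    sensitivity (recall on OMPs)
    Sp  = TN / (TN + FP)                    specificity
    MCC = (TP·TN − FP·FN) / sqrt((TP+FN)(TP+FP)(TN+FP)(TN+FN))
    OA  = (TP + TN) / n                     overall accuracy
    AA  = (Sn + Sp) / 2                     average accuracy

auROC is computed by tie-grouped trapezoidal integration of the ROC
curve (Sn against 1−Sp), which equals the Mann–Whitney pair statistic
with ties counted half.

The jackknife (leave-one-out) protocol trains n models for n samples;
sample i is scored by the model that never saw it.  Fold order follows
manifest order, and parallel execution is bit-identical to serial
because each fold is a pure function reduced in index order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable, Optional, Sequence

import numpy as np
from joblib import Parallel, delayed

from . import classifier as clf
from .classifier import SVMConfig
from .indices import AminoAcidIndexTable
from .pseaac import PseAACConfig, encode_dataset
from .seq_io import DatasetManifest


def round_pct(fraction: float, decimals: int = 2) -> float:
    """Percentage rounded half-away-from-zero, the convention of printed
    performance tables (0.93102 → 93.10)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(fraction) * 100.0)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FN/FP/TN tallies of a binary prediction."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "fp", "tn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.tn + self.fp

    @property
    def n(self) -> int:
        return self.n_pos + self.n_neg


@dataclass(frozen=True)
class MetricsReport:
    """Sn, Sp, OA, AA as fractions; MCC in [−1, 1]; optional auROC.

    ``mcc`` is ``None`` (undefined, not 0) when a confusion-table
    marginal is zero.
    """

    sn: float
    sp: float
    oa: float
    aa: float
    mcc: Optional[float]
    auroc: Optional[float] = None
    counts: Optional[ConfusionCounts] = None

    def as_dict(self, percent: bool = False) -> dict:
        """JSON-friendly view; with ``percent`` the rates use the
        2-decimal percent convention and auROC stays a fraction."""
        if percent:
            d = {
                "sn_pct": round_pct(self.sn),
                "sp_pct": round_pct(self.sp),
                "oa_pct": round_pct(self.oa),
                "aa_pct": round_pct(self.aa),
                "mcc_pct": None if self.mcc is None else round_pct(self.mcc),
            }
        else:
            d = {"sn": self.sn, "sp": self.sp, "oa": self.oa, "aa": self.aa,
                 "mcc": self.mcc}
        d["auroc"] = self.auroc
        if self.counts is not None:
            d["counts"] = {
                "tp": self.counts.tp, "fn": self.counts.fn,
                "fp": self.counts.fp, "tn": self.counts.tn,
            }
        return d


def confusion_from_predictions(
    y_true: Sequence[int], y_pred: Sequence[int]
) -> ConfusionCounts:
    """Tally TP/FN/FP/TN from 0/1 truth and prediction vectors."""
    yt = np.asarray(y_true, dtype=int)
    yp = np.asarray(y_pred, dtype=int)
    if yt.shape != yp.shape or yt.ndim != 1:
        raise ValueError(
            f"y_true and y_pred must be equal-length 1-D vectors, "
            f"got {yt.shape} and {yp.shape}"
        )
    if yt.size < 1:
        raise ValueError("need at least one sample")
    for arr, name in ((yt, "y_true"), (yp, "y_pred")):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{name} must be binary 0/1")
    return ConfusionCounts(
        tp=int(np.sum((yt == 1) & (yp == 1))),
        fn=int(np.sum((yt == 1) & (yp == 0))),
        fp=int(np.sum((yt == 0) & (yp == 1))),
        tn=int(np.sum((yt == 0) & (yp == 0))),
    )


def compute_metrics(
    c: ConfusionCounts,
    auroc: Optional[float] = None,
) -> MetricsReport:
    """Derive Sn, Sp, MCC, OA, AA from confusion counts.

    Requires at least one positive and one negative sample.  MCC is
    reported as undefined (``None``) with a warning when any marginal
    (TP+FN, TP+FP, TN+FP, TN+FN) is zero.
    """
    if c.n_pos < 1 or c.n_neg < 1:
        raise ValueError("need at least one positive and one negative sample")
    sn = c.tp / c.n_pos
    sp = c.tn / c.n_neg
    oa = (c.tp + c.tn) / c.n
    aa = (sn + sp) / 2.0
    marginals = (c.tp + c.fn, c.tp + c.fp, c.tn + c.fp, c.tn + c.fn)
    if 0 in marginals:
        warnings.warn("MCC undefined: a confusion-table marginal is zero",
                      stacklevel=2)
        mcc = None
    else:
        num = c.tp * c.tn - c.fp * c.fn
        den = float(marginals[0]) * marginals[1] * marginals[2] * marginals[3]
        mcc = num / np.sqrt(den)
    return MetricsReport(sn=sn, sp=sp, oa=oa, aa=aa, mcc=mcc, auroc=auroc,
                         counts=c)


def roc_curve_points(
    y_true: Sequence[int], scores: Sequence[float]
) -> np.ndarray:
    """ROC points as an array of (threshold, 1−Sp, Sn) rows.

    Scores are sorted descending with ties grouped, so each distinct
    score contributes one point; (−inf → (0,0)) and (+inf handled by the
    final (1,1)) endpoints included.
    """
    yt = np.asarray(y_true, dtype=int)
    s = np.asarray(scores, dtype=float)
    if yt.shape != s.shape or yt.ndim != 1:
        raise ValueError("y_true and scores must be equal-length 1-D vectors")
    n_pos = int(np.sum(yt == 1))
    n_neg = int(np.sum(yt == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present")
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = yt[order]
    pts = [(np.inf, 0.0, 0.0)]
    tp = fp = 0
    i = 0
    n = len(s_sorted)
    while i < n:
        j = i
        while j < n and s_sorted[j] == s_sorted[i]:
            j += 1
        tp += int(np.sum(y_sorted[i:j] == 1))
        fp += int(np.sum(y_sorted[i:j] == 0))
        pts.append((float(s_sorted[i]), fp / n_neg, tp / n_pos))
        i = j
    return np.array(pts)


def roc_auc(y_true: Sequence[int], scores: Sequence[float]) -> float:
    """Area under the ROC curve by tie-grouped trapezoidal integration.

    Equals the Mann–Whitney statistic: the fraction of (positive,
    negative) pairs where the positive outscores the negative, ties
    counted half.
    """
    pts = roc_curve_points(y_true, scores)
    x = pts[:, 1]
    y = pts[:, 2]
    return float(np.trapezoid(y, x))


def counts_from_rates(
    sn_pct: float, sp_pct: float, n_pos: int, n_neg: int
) -> ConfusionCounts:
    """Reconstruct integer confusion counts from printed Sn/Sp percentages.

    TP = round(Sn·n⁺), TN = round(Sp·n⁻); FN and FP by complement.  The
    reconstruction is verified by a round trip: the recomputed Sn/Sp
    must agree with the inputs to ±0.005 percentage points under either
    half-up rounding or truncation to 2 decimals (published tables mix
    the two conventions).
    """
    if not (0 <= sn_pct <= 100 and 0 <= sp_pct <= 100):
        raise ValueError("percentages must lie in [0, 100]")
    if n_pos < 1 or n_neg < 1:
        raise ValueError("class sizes must be >= 1")
    tp = int(round(sn_pct / 100.0 * n_pos))
    tn = int(round(sp_pct / 100.0 * n_neg))
    c = ConfusionCounts(tp=tp, fn=n_pos - tp, fp=n_neg - tn, tn=tn)

    def _consistent(printed: float, recomputed_frac: float) -> bool:
        pct = recomputed_frac * 100.0
        truncated = np.floor(pct * 100.0) / 100.0
        return (
            abs(pct - printed) <= 0.005
            or round_pct(recomputed_frac) == printed
            or abs(truncated - printed) < 1e-9
        )

    if not (_consistent(sn_pct, tp / n_pos) and _consistent(sp_pct, tn / n_neg)):
        raise ValueError(
            f"rates inconsistent with class sizes: Sn={sn_pct}, Sp={sp_pct} "
            f"cannot arise from n_pos={n_pos}, n_neg={n_neg}"
        )
    return c


def _jackknife_fold(
    X: np.ndarray, y: np.ndarray, i: int, svm: SVMConfig, scale: bool
) -> float:
    mask = np.ones(len(y), dtype=bool)
    mask[i] = False
    model = clf.train(X[mask], y[mask], svm, scale=scale)
    return float(clf.predict_scores(model, X[i : i + 1])[0])


def jackknife_evaluate(
    manifest: DatasetManifest,
    pse: PseAACConfig,
    svm: SVMConfig,
    *,
    scale: bool = False,
    n_jobs: int = 1,
) -> tuple[MetricsReport, np.ndarray]:
    """Leave-one-out evaluation of the full encode→train→score pipeline.

    Trains exactly n models; sample i is scored by the model fitted
    without it.  Every fold's training set must contain both classes.
    Returns the metrics (with auROC) and the n held-out scores in
    manifest order.
    """
    X, y = encode_dataset(manifest, pse)
    n = len(y)
    if n < 3:
        raise ValueError("jackknife needs at least 3 samples")
    n_pos = int(y.sum())
    n_neg = n - n_pos
    if n_pos < 2 or n_neg < 2:
        raise ValueError(
            "dataset too small/imbalanced for jackknife: every fold's "
            "training set must contain both classes "
            f"(n_pos={n_pos}, n_neg={n_neg})"
        )
    if n_jobs == 1:
        scores = np.array(
            [_jackknife_fold(X, y, i, svm, scale) for i in range(n)]
        )
    else:
        scores = np.array(
            Parallel(n_jobs=n_jobs)(
                delayed(_jackknife_fold)(X, y, i, svm, scale) for i in range(n)
            )
        )
    y_pred = (scores > 0).astype(int)
    counts = confusion_from_predictions(y, y_pred)
    report = compute_metrics(counts, auroc=roc_auc(y, scores))
    return report, scores


@dataclass(frozen=True)
class GridPoint:
    omega: float
    lam: int
    gamma: float
    cost: float
    report: Optional[MetricsReport]
    error: Optional[str] = None


@dataclass
class GridSearchResult:
    """All evaluated (ω, λ, γ, C) points with the selected winner."""

    rows: list[GridPoint]
    best: int
    criterion: str

    @property
    def best_point(self) -> GridPoint:
        return self.rows[self.best]

    def to_tsv(self, path) -> None:
        cols = ("omega", "lam", "gamma", "cost",
                "sn_pct", "sp_pct", "mcc_pct", "oa_pct", "aa_pct", "auroc",
                "status")
        with open(path, "w") as fh:
            fh.write("\t".join(cols) + "\n")
            for p in self.rows:
                if p.report is None:
                    vals = ["NA"] * 6 + [f"failed: {p.error}"]
                else:
                    r = p.report
                    vals = [
                        f"{round_pct(r.sn):.2f}", f"{round_pct(r.sp):.2f}",
                        "NA" if r.mcc is None else f"{round_pct(r.mcc):.2f}",
                        f"{round_pct(r.oa):.2f}", f"{round_pct(r.aa):.2f}",
                        "NA" if r.auroc is None else f"{r.auroc:.3f}",
                        "ok",
                    ]
                fh.write("\t".join(
                    [repr(p.omega), str(p.lam), repr(p.gamma), repr(p.cost)]
                    + vals) + "\n")


def _selection_key(p: GridPoint, criterion: str) -> tuple:
    r = p.report
    crit = r.sn if criterion == "sn" else r.oa
    # ties: higher auROC, then higher MCC, then smaller lam, then smaller gamma
    return (
        crit,
        -1.0 if r.auroc is None else r.auroc,
        -1.0 if r.mcc is None else r.mcc,
        -p.lam,
        -p.gamma,
    )


def grid_search(
    manifest: DatasetManifest,
    omega_grid: Sequence[float],
    lam_grid: Sequence[int],
    gamma_grid: Sequence[float],
    cost_grid: Sequence[float],
    criterion: str = "oa",
    *,
    index_table: Optional[AminoAcidIndexTable] = None,
    scale: bool = False,
    n_jobs: int = 1,
    evaluate_fn: Optional[
        Callable[[DatasetManifest, PseAACConfig, SVMConfig], MetricsReport]
    ] = None,
) -> GridSearchResult:
    """Jackknife-evaluate every (ω, λ, γ, C) combination and select a winner.

    Selection maximizes overall accuracy (default) or sensitivity; ties
    break by higher auROC, then higher MCC, then smaller λ, then smaller
    γ.  A failing grid point is recorded with its error, never silently
    skipped.  ``evaluate_fn`` substitutes the per-point evaluator (used
    for fast protocol-level checks).
    """
    if criterion not in ("oa", "sn"):
        raise ValueError(f"criterion must be 'oa' or 'sn', got {criterion!r}")
    for name, g in (("omega", omega_grid), ("lam", lam_grid),
                    ("gamma", gamma_grid), ("cost", cost_grid)):
        if len(g) == 0:
            raise ValueError(f"empty {name} grid")

    if evaluate_fn is None:
        def evaluate_fn(m, pse, svm):  # noqa: F811 - default evaluator
            report, _ = jackknife_evaluate(m, pse, svm, scale=scale,
                                           n_jobs=n_jobs)
            return report

    kwargs = {} if index_table is None else {"index_table": index_table}
    rows: list[GridPoint] = []
    for omega in omega_grid:
        for lam in lam_grid:
            pse = PseAACConfig(lam=lam, weight=omega, **kwargs)
            for gamma in gamma_grid:
                for cost in cost_grid:
                    svm = SVMConfig(gamma=gamma, cost=cost)
                    try:
                        report = evaluate_fn(manifest, pse, svm)
                        rows.append(GridPoint(omega, lam, gamma, cost, report))
                    except Exception as exc:  # recorded, not skipped
                        rows.append(GridPoint(omega, lam, gamma, cost, None,
                                              error=str(exc)))
    ok = [i for i, p in enumerate(rows) if p.report is not None]
    if not ok:
        raise RuntimeError("every grid point failed")
    best = max(ok, key=lambda i: _selection_key(rows[i], criterion))
    return GridSearchResult(rows=rows, best=best, criterion=criterion)
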