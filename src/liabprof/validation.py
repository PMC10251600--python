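"""Model validation: regression metrics, internal/external protocols and
virtual-screening enrichment.

Metrics follow the OECD-style validation battery for QSAR regressors:
Pearson R = cov(X,Y)/(s_X s_Y), determination coefficient R2 = 1 - Rss/Tss,
and RMSE = sqrt(mean squared error), where X are observed and Y predicted
pACTIVITY values. Internal validation offers 5-fold cross-validation,
repeated 90/10 resampling ("bootstrap") and y-scrambling (response
permutation before refitting, scored by CV — a sound model collapses to
R ~ 0). External validation scores a fitted model on a held-out partition
that never touched training or tuning.

Screening power is quantified by the enrichment factor
EF = (A_chi / M_chi) / (A / M) at top fractions chi of the prediction-sorted
list, with "true actives" defined as the top 2% of compounds by observed
pACTIVITY, plus the ranking ROC AUC (Mann-Whitney formulation with midrank
tie correction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .modeling import QSARRegressor

__all__ = [
    "Metrics",
    "ProtocolReport",
    "EnrichmentResult",
    "regression_metrics",
    "internal_validate",
    "external_validate",
    "enrichment_factor",
    "ranking_auc",
]


@dataclass(frozen=True)
class Metrics:
    r: float
    r2: float
    rmse: float
    r_defined: bool = True


@dataclass(frozen=True)
class ProtocolReport:
    """Mean and SD of each metric over the protocol's iterations."""

    protocol: str
    iterations: int
    r_mean: float
    r_sd: float
    r2_mean: float
    r2_sd: float
    rmse_mean: float
    rmse_sd: float

    def as_dict(self) -> dict:
        return {
            "protocol": self.protocol,
            "iterations": self.iterations,
            "R": {"mean": self.r_mean, "sd": self.r_sd},
            "R2": {"mean": self.r2_mean, "sd": self.r2_sd},
            "RMSE": {"mean": self.rmse_mean, "sd": self.rmse_sd},
        }


@dataclass(frozen=True)
class EnrichmentResult:
    chi: float
    a_chi: int  # actives in the top chi fraction
    m_chi: int  # molecules in the top chi fraction
    a: int  # total actives
    m: int  # total molecules
    ef: float
    auc: float


def regression_metrics(x, y) -> Metrics:
    """Pearson R, determination coefficient and RMSE for paired vectors.

    ``x`` holds observed values, ``y`` predictions. With a zero-variance
    vector R is undefined and reported as NaN with ``r_defined=False``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = len(x)
    if n < 2:
        raise ValueError("need at least two observations")
    rmse = float(np.sqrt(np.mean((x - y) ** 2)))
    tss = float(np.sum((x - x.mean()) ** 2))
    r2 = 1.0 - float(np.sum((x - y) ** 2)) / tss if tss > 0 else math.nan
    sx, sy = x.std(ddof=1), y.std(ddof=1)
    if sx == 0 or sy == 0:
        return Metrics(math.nan, r2, rmse, r_defined=False)
    cov = float(np.sum((x - x.mean()) * (y - y.mean())) / (n - 1))
    return Metrics(cov / (sx * sy), r2, rmse)


def _summarise(protocol: str, metrics: list[Metrics]) -> ProtocolReport:
    rs = np.array([m.r for m in metrics], dtype=float)
    r2s = np.array([m.r2 for m in metrics], dtype=float)
    rmses = np.array([m.rmse for m in metrics], dtype=float)
    sd = lambda v: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
    return ProtocolReport(
        protocol, len(metrics),
        float(np.nanmean(rs)), sd(rs[np.isfinite(rs)]) if np.isfinite(rs).any() else 0.0,
        float(np.nanmean(r2s)), sd(r2s[np.isfinite(r2s)]) if np.isfinite(r2s).any() else 0.0,
        float(np.mean(rmses)), sd(rmses),
    )


def _cv_metrics(X, y, algorithm, config, k, seed) -> Metrics:
    """Out-of-fold predictions over one shuffled k-fold pass."""
    from sklearn.model_selection import KFold

    pred = np.empty_like(y)
    for tr, va in KFold(n_splits=k, shuffle=True, random_state=seed).split(X):
        model = QSARRegressor(algorithm, config, seed).fit(X[tr], y[tr])
        pred[va] = model.predict(X[va])
    return regression_metrics(y, pred)


def internal_validate(
    X,
    y,
    algorithm: str = "gb",
    config: dict | None = None,
    protocol: str = "cv",
    iterations: int = 20,
    seed: int = 0,
    cv_folds: int = 5,
    holdout_fraction: float = 0.1,
) -> ProtocolReport:
    """Run one internal-validation protocol and summarise over iterations.

    Protocols
    ---------
    ``cv``
        k-fold cross-validation (default k=5); each compound is held out
        exactly once per iteration and metrics are computed on the pooled
        out-of-fold predictions.
    ``bootstrap``
        repeated 90/10 resampling: a random 90% trains, the held-out 10%
        is scored.
    ``y_scrambling``
        the response vector is permuted before refitting; metrics come from
        cross-validation against the permuted response, so chance
        correlation is the only signal left.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    results: list[Metrics] = []
    for it in range(iterations):
        sub_seed = int(rng.integers(2**31 - 1))
        if protocol == "cv":
            results.append(_cv_metrics(X, y, algorithm, config, cv_folds, sub_seed))
        elif protocol == "bootstrap":
            perm = np.random.default_rng(sub_seed).permutation(len(y))
            n_test = max(1, int(round(holdout_fraction * len(y))))
            te, tr = perm[:n_test], perm[n_test:]
            model = QSARRegressor(algorithm, config, sub_seed).fit(X[tr], y[tr])
            results.append(regression_metrics(y[te], model.predict(X[te])))
        elif protocol == "y_scrambling":
            y_perm = np.random.default_rng(sub_seed).permutation(y)
            results.append(_cv_metrics(X, y_perm, algorithm, config, cv_folds, sub_seed))
        else:
            raise ValueError(f"unknown protocol {protocol!r}")
    return _summarise(protocol, results)


def external_validate(
    model: QSARRegressor,
    X_test,
    y_test,
    train_index=None,
    test_index=None,
) -> ProtocolReport:
    """Score a fitted model on its held-out test partition.

    When both index vectors are supplied, any overlap between train and test
    raises — the external set must never have participated in training.
    """
    if train_index is not None and test_index is not None:
        overlap = np.intersect1d(np.asarray(train_index), np.asarray(test_index))
        if overlap.size:
            raise ValueError(f"train/test overlap on indices {overlap[:5].tolist()}")
    m = regression_metrics(np.asarray(y_test, float), model.predict(X_test))
    return _summarise("external", [m])


def ranking_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """ROC AUC of ``scores`` against binary ``labels`` via the Mann-Whitney
    rank statistic with midrank tie correction."""
    labels = np.asarray(labels, dtype=bool)
    a = int(labels.sum())
    m = len(labels)
    if a == 0 or a == m:
        raise ValueError("AUC needs both actives and inactives")
    ranks = rankdata(scores)  # midranks
    return float((ranks[labels].sum() - a * (a + 1) / 2) / (a * (m - a)))


def enrichment_factor(
    y_true,
    y_score,
    chi: float = 0.05,
    active_fraction: float = 0.02,
    tiebreak: list[str] | None = None,
) -> EnrichmentResult:
    """Enrichment factor at top fraction ``chi`` with top-quantile actives.

    The top ``ceil(active_fraction * M)`` compounds by observed pACTIVITY are
    labelled true actives (ties broken by descending activity then by the
    ``tiebreak`` key, e.g. canonical SMILES, else input position, so the
    active set is deterministic). The selection is the top ``ceil(chi * M)``
    compounds by predicted score. EF = (A_chi/M_chi) / (A/M); the ROC AUC of
    the full ranking is reported alongside.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_score = np.asarray(y_score, dtype=float)
    m = len(y_true)
    if m == 0 or len(y_score) != m:
        raise ValueError("y_true and y_score must be equal-length, non-empty")
    a = int(math.ceil(active_fraction * m))
    if a < 1:
        raise ValueError("no actives after labeling; increase active_fraction")
    keys = tiebreak if tiebreak is not None else [str(i) for i in range(m)]
    order = sorted(range(m), key=lambda i: (-y_true[i], keys[i]))
    labels = np.zeros(m, dtype=bool)
    labels[order[:a]] = True

    m_chi = int(math.ceil(chi * m))
    sel_order = sorted(range(m), key=lambda i: (-y_score[i], keys[i]))
    selection = sel_order[:m_chi]
    a_chi = int(labels[selection].sum())
    ef = (a_chi / m_chi) / (a / m)
    return EnrichmentResult(chi, a_chi, m_chi, a, m, float(ef), ranking_auc(labels, y_score))
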