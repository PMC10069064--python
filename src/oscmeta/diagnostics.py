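"""Diagnostic-accuracy meta-analysis for a continuous expression marker.

Per cohort: Mann–Whitney AUC, a Youden-optimal 2x2 table.  Across cohorts:
DerSimonian–Laird pooling of logit sensitivity/specificity and log
diagnostic likelihood ratios, and a bivariate random-effects summary-ROC
(SROC) fit with a trapezoid summary AUC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats
from scipy.special import expit, logit

from .effects import Z95


@dataclass(frozen=True)
class Diag2x2:
    """Confusion counts for one cohort at one expression threshold."""

    dataset_id: str
    tp: int
    fp: int
    fn: int
    tn: int
    threshold: float

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)


@dataclass
class SROCFit:
    """Bivariate summary-ROC parameters and the traced curve."""

    mu_se: float  # mean logit sensitivity
    mu_sp: float  # mean logit specificity
    var_se: float
    var_sp: float
    cov: float
    fpr: np.ndarray = field(repr=False)
    tpr: np.ndarray = field(repr=False)
    auc: float = np.nan
    converged: bool = True
    se_mu_se: float = np.nan
    se_mu_sp: float = np.nan

    @property
    def summary_point(self) -> tuple[float, float]:
        """(FPR, TPR) at the pooled means."""
        return float(1 - expit(self.mu_sp)), float(expit(self.mu_se))


def auc_mw(
    tumor_values: Sequence[float], normal_values: Sequence[float]
) -> tuple[float, float, tuple[float, float]]:
    """Mann–Whitney AUC with Hanley–McNeil standard error.

    AUC = (#concordant pairs + 0.5 * #ties) / (n_T * n_N); the CI is the
    normal interval truncated to [0, 1].
    """
    t = np.asarray(tumor_values, dtype=float)
    n = np.asarray(normal_values, dtype=float)
    if t.size == 0 or n.size == 0:
        raise ValueError("both groups must be non-empty")
    # rank-based count of concordant pairs, ties counted half
    combined = np.concatenate([t, n])
    ranks = stats.rankdata(combined)
    auc = (ranks[: t.size].sum() - t.size * (t.size + 1) / 2.0) / (t.size * n.size)
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    nt, nn = t.size, n.size
    var = (auc * (1 - auc) + (nt - 1) * (q1 - auc**2) + (nn - 1) * (q2 - auc**2)) / (nt * nn)
    se = float(np.sqrt(max(var, 0.0)))
    lo = max(0.0, auc - Z95 * se)
    hi = min(1.0, auc + Z95 * se)
    return float(auc), se, (lo, hi)


def youden_2x2(
    tumor_values: Sequence[float],
    normal_values: Sequence[float],
    dataset_id: str = "",
    *,
    rule: str = "youden",
) -> Diag2x2:
    """Dichotomize a cohort at the Youden-optimal threshold.

    Candidate thresholds are midpoints between sorted unique pooled values;
    a sample is called positive when value >= threshold.  Ties in the
    Youden index J = Se + Sp - 1 break toward higher sensitivity (the lower
    threshold).  ``rule='median'`` instead thresholds at the pooled median.
    """
    t = np.asarray(tumor_values, dtype=float)
    n = np.asarray(normal_values, dtype=float)
    if t.size == 0 or n.size == 0:
        raise ValueError("both groups must be non-empty")

    def counts(thr: float) -> tuple[int, int, int, int]:
        tp = int((t >= thr).sum())
        fn = t.size - tp
        fp = int((n >= thr).sum())
        tn = n.size - fp
        return tp, fp, fn, tn

    if rule == "median":
        thr = float(np.median(np.concatenate([t, n])))
        return Diag2x2(dataset_id, *counts(thr), threshold=thr)
    uniq = np.unique(np.concatenate([t, n]))
    cands = (uniq[:-1] + uniq[1:]) / 2.0 if uniq.size > 1 else uniq
    best_thr, best_j, best_se = None, -np.inf, -np.inf
    for thr in cands:  # ascending: lower thresholds have higher Se
        tp, fp, fn, tn = counts(thr)
        j = tp / t.size + tn / n.size - 1.0
        if j > best_j + 1e-12:
            best_thr, best_j, best_se = thr, j, tp / t.size
    return Diag2x2(dataset_id, *counts(best_thr), threshold=float(best_thr))


def _corrected(tables: Sequence[Diag2x2]) -> list[tuple[float, float, float, float]]:
    """Add 0.5 to every cell of a study that contains any zero cell."""
    out = []
    for tb in tables:
        cells = (tb.tp, tb.fp, tb.fn, tb.tn)
        if any(c == 0 for c in cells):
            out.append(tuple(c + 0.5 for c in cells))
        else:
            out.append(tuple(float(c) for c in cells))
    return out


def _dl_pool(y: np.ndarray, v: np.ndarray) -> tuple[float, float, float]:
    """Generic DL pooling on an arbitrary transformed scale."""
    k = y.size
    w = 1.0 / v
    yf = (w * y).sum() / w.sum()
    Q = float((w * (y - yf) ** 2).sum())
    if k > 1:
        denom = w.sum() - (w**2).sum() / w.sum()
        tau2 = max(0.0, (Q - (k - 1)) / denom) if denom > 0 else 0.0
    else:
        tau2 = 0.0
    ws = 1.0 / (v + tau2)
    pooled = float((ws * y).sum() / ws.sum())
    se = float(1.0 / np.sqrt(ws.sum()))
    return pooled, se, tau2


def pool_logit(
    props: Sequence[tuple[float, float]]
) -> tuple[float, tuple[float, float]]:
    """DL random-effects pooling of proportions on the logit scale.

    ``props`` is a sequence of (numerator, denominator).  Studies with a
    zero or full numerator get the 0.5 continuity correction (numerator
    +0.5, denominator +1).  Returns the back-transformed pooled proportion
    and 95% CI.
    """
    y, v = [], []
    for num, den in props:
        if den < 1:
            raise ValueError("denominator must be >= 1")
        if num == 0 or num == den:
            num, den = num + 0.5, den + 1.0
        p = num / den
        y.append(logit(p))
        v.append(1.0 / num + 1.0 / (den - num))
    pooled, se, _ = _dl_pool(np.array(y), np.array(v))
    return float(expit(pooled)), (
        float(expit(pooled - Z95 * se)),
        float(expit(pooled + Z95 * se)),
    )


def pool_dlr(
    tables: Sequence[Diag2x2],
) -> tuple[tuple[float, tuple[float, float]], tuple[float, tuple[float, float]]]:
    """Pool positive and negative diagnostic likelihood ratios.

    DLR+ = Se/(1-Sp), DLR- = (1-Se)/Sp per study on continuity-corrected
    cells; pooled by DL on the log scale and back-transformed.
    """
    if len(tables) == 0:
        raise ValueError("need at least one 2x2 table")
    out = []
    for which in ("pos", "neg"):
        y, v = [], []
        for tp, fp, fn, tn in _corrected(tables):
            se_ = tp / (tp + fn)
            sp_ = tn / (tn + fp)
            if which == "pos":
                dlr = se_ / (1 - sp_)
            else:
                dlr = (1 - se_) / sp_
            # delta-method variance of log DLR (Simel et al. form)
            if which == "pos":
                var = (1 - se_) / (se_ * (tp + fn)) + sp_ / ((1 - sp_) * (tn + fp))
            else:
                var = se_ / ((1 - se_) * (tp + fn)) + (1 - sp_) / (sp_ * (tn + fp))
            y.append(np.log(dlr))
            v.append(var)
        pooled, se, _ = _dl_pool(np.array(y), np.array(v))
        out.append(
            (
                float(np.exp(pooled)),
                (float(np.exp(pooled - Z95 * se)), float(np.exp(pooled + Z95 * se))),
            )
        )
    return out[0], out[1]


def _sroc_curve(
    mu_se: float, mu_sp: float, var_se: float, var_sp: float, cov: float, npts: int = 1000
) -> tuple[np.ndarray, np.ndarray]:
    """Trace TPR(FPR) as the regression of logit Se on logit FPR.

    With u = logit Se and w = logit FPR = -logit Sp, the implied line is
    E[u|w] = mu_se + b (w + mu_sp) with b = -cov/var_sp.  Near-zero
    specificity variance degenerates to the flat line u = mu_se.
    """
    eps = 1e-6
    fpr = np.linspace(eps, 1 - eps, npts)
    w = logit(fpr)
    b = -cov / var_sp if var_sp > 1e-10 else 0.0
    u = mu_se + b * (w + mu_sp)
    return fpr, expit(u)


def fit_sroc(tables: Sequence[Diag2x2], *, npts: int = 1000) -> SROCFit:
    """Bivariate random-effects (Reitsma-type) summary-ROC fit.

    (logit Se_i, logit Sp_i) ~ N(mu, Sigma + S_i) with S_i the within-study
    diagonal variances from the (continuity-corrected) counts; mu and
    Sigma are estimated by maximum likelihood.  The summary AUC integrates
    the implied curve over FPR in [0, 1] by trapezoid with ``npts`` points.
    Fewer than 3 studies, or optimizer failure, falls back to univariate DL
    pooling of the two logits with zero covariance (flagged on the result).
    """
    if len(tables) == 0:
        raise ValueError("need at least one 2x2 table")
    ys, yp, vs, vp = [], [], [], []
    for tp, fp, fn, tn in _corrected(tables):
        se_, sp_ = tp / (tp + fn), tn / (tn + fp)
        ys.append(logit(se_))
        yp.append(logit(sp_))
        vs.append(1.0 / tp + 1.0 / fn)
        vp.append(1.0 / tn + 1.0 / fp)
    ys, yp, vs, vp = map(np.array, (ys, yp, vs, vp))
    k = ys.size

    def fallback() -> SROCFit:
        mu_se, _, t2s = _dl_pool(ys, vs)
        mu_sp, _, t2p = _dl_pool(yp, vp)
        fpr, tpr = _sroc_curve(mu_se, mu_sp, t2s, t2p, 0.0, npts)
        auc = float(np.trapezoid(tpr, fpr))
        return SROCFit(mu_se, mu_sp, t2s, t2p, 0.0, fpr, tpr, auc, converged=False)

    if k < 3:
        return fallback()

    def nll(theta: np.ndarray) -> float:
        mu = theta[:2]
        # Cholesky parameterization of Sigma keeps it PSD
        l11, l21, l22 = np.exp(theta[2]), theta[3], np.exp(theta[4])
        s11 = l11 * l11
        s12 = l11 * l21
        s22 = l21 * l21 + l22 * l22
        total = 0.0
        for i in range(k):
            a = s11 + vs[i]
            c = s22 + vp[i]
            b = s12
            det = a * c - b * b
            if det <= 0:
                return 1e10
            du = ys[i] - mu[0]
            dv = yp[i] - mu[1]
            quad = (c * du * du - 2 * b * du * dv + a * dv * dv) / det
            total += 0.5 * (np.log(det) + quad)
        return total

    x0 = np.array([ys.mean(), yp.mean(), np.log(0.5), 0.0, np.log(0.5)])
    res = optimize.minimize(nll, x0, method="Nelder-Mead",
                            options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10})
    if not res.success:
        return fallback()
    mu_se, mu_sp = float(res.x[0]), float(res.x[1])
    l11, l21, l22 = np.exp(res.x[2]), res.x[3], np.exp(res.x[4])
    var_se = float(l11 * l11)
    cov = float(l11 * l21)
    var_sp = float(l21 * l21 + l22 * l22)
    fpr, tpr = _sroc_curve(mu_se, mu_sp, var_se, var_sp, cov, npts)
    auc = float(np.trapezoid(tpr, fpr))
    # standard errors of the means from a numerical Hessian on (mu | Sigma-hat)
    se_mu_se, se_mu_sp = _mu_se_from_hessian(nll, res.x)
    return SROCFit(mu_se, mu_sp, var_se, var_sp, cov, fpr, tpr, auc,
                   converged=True, se_mu_se=se_mu_se, se_mu_sp=se_mu_sp)


def _mu_se_from_hessian(nll, xhat: np.ndarray, h: float = 1e-4) -> tuple[float, float]:
    """Numerical 2x2 Hessian in the mean parameters at the ML solution."""
    H = np.zeros((2, 2))
    for i in range(2):
        for j in range(2):
            x = xhat.copy()
            def f(a, b):
                y = xhat.copy()
                y[i] += a
                y[j] += b
                return nll(y)
            H[i, j] = (f(h, h) - f(h, -h) - f(-h, h) + f(-h, -h)) / (4 * h * h)
    try:
        cov = np.linalg.inv(H)
        return float(np.sqrt(max(cov[0, 0], 0))), float(np.sqrt(max(cov[1, 1], 0)))
    except np.linalg.LinAlgError:
        return np.nan, np.nan
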