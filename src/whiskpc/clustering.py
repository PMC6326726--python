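"""Responder classification by univariate Gaussian mixture modelling.

The heterogeneity of complex-spike responses across Purkinje cells is
captured almost entirely by one variable — the peak amplitude of the
convolved complex-spike PSTH — so units are clustered by fitting 1-D
Gaussian mixtures with k ∈ {1, 2, 3} components under equal- and
unequal-variance models, selecting the candidate with the lowest BIC
(-2 lnL + p ln n), and labelling units 'strong' or 'weak' relative to the
posterior-equality boundary between the two components of the winning k=2
model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["GmmResult", "fit_gmm_1d", "classify_responders"]

_LOG2PI = math.log(2.0 * math.pi)


@dataclass
class CandidateModel:
    k: int
    variance_model: str  # 'equal' | 'unequal'
    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    log_likelihood: float
    bic: float
    ll_trajectory: np.ndarray  # per-iteration LL of the winning restart
    converged: bool

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "variance_model": self.variance_model,
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "variances": self.variances.tolist(),
            "log_likelihood": float(self.log_likelihood),
            "bic": float(self.bic),
            "converged": bool(self.converged),
        }


@dataclass
class GmmResult:
    candidates: dict  # (k, variance_model) -> CandidateModel
    selected: tuple[int, str]
    labels: np.ndarray | None = None  # 'strong' | 'weak' per unit (k=2 only)
    boundary: float | None = None
    degenerate: bool = False
    warnings: list[str] = field(default_factory=list)

    @property
    def best(self) -> CandidateModel:
        return self.candidates[self.selected]


def _log_gauss(x: np.ndarray, mean: float, var: float) -> np.ndarray:
    return -0.5 * (_LOG2PI + math.log(var) + (x - mean) ** 2 / var)


def _em_1d(
    x: np.ndarray,
    k: int,
    variance_model: str,
    init_means: np.ndarray,
    var_floor: float,
    tol: float,
    max_iter: int = 300,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, bool]:
    """EM for a 1-D Gaussian mixture from given initial means.

    Returns (weights, means, variances, ll_trajectory, converged).  The
    log-likelihood is checked to be non-decreasing at every iteration; a
    decrease beyond numerical noise indicates an implementation defect and
    raises.
    """
    n = x.size
    weights = np.full(k, 1.0 / k)
    means = init_means.astype(float).copy()
    variances = np.full(k, max(x.var(), var_floor))
    xx = x ** 2
    ll_prev = -np.inf
    traj = []
    converged = False
    for _ in range(max_iter):
        # E step (broadcast: k x n)
        logp = (
            np.log(weights)[:, None]
            - 0.5 * (_LOG2PI + np.log(variances))[:, None]
            - 0.5 * (x[None, :] - means[:, None]) ** 2 / variances[:, None]
        )
        m = logp.max(axis=0)
        lse = m + np.log(np.exp(logp - m).sum(axis=0))
        ll = float(lse.sum())
        traj.append(ll)
        if ll < ll_prev - 1e-8 * max(1.0, abs(ll_prev)):
            raise AssertionError("EM log-likelihood decreased")
        if ll_prev > -np.inf and (ll - ll_prev) <= tol * max(1.0, abs(ll_prev)):
            converged = True
            break
        ll_prev = ll
        resp = np.exp(logp - lse)  # k x n
        # M step
        nk = np.maximum(resp.sum(axis=1), 1e-12)
        weights = nk / n
        means = (resp @ x) / nk
        sq = resp @ xx / nk - means ** 2
        if variance_model == "equal":
            pooled = float((nk * sq).sum() / n)
            variances = np.full(k, max(pooled, var_floor))
        else:
            variances = np.maximum(sq, var_floor)
    return weights, means, variances, np.array(traj), converged


def _n_params(k: int, variance_model: str) -> int:
    # k-1 weights + k means + (k or 1) variances
    return (k - 1) + k + (k if variance_model == "unequal" else 1)


def fit_gmm_1d(
    x: np.ndarray,
    ks: tuple[int, ...] = (1, 2, 3),
    variance_models: tuple[str, ...] = ("equal", "unequal"),
    n_restarts: int = 20,
    tol: float = 1e-6,
    seed: int | None = None,
) -> GmmResult:
    """Fit all (k, variance model) candidates and select by lowest BIC.

    Each candidate runs EM to convergence (relative log-likelihood change
    below ``tol``) from ``n_restarts`` starts (an equal-count quantile split
    of the sorted sample — the 1-D k-means fixed point — plus random
    data-point draws), keeping
    the restart with the highest likelihood.  Degenerate data (all values
    identical) forces k=1 with a floored variance and a warning in the
    result.  Restarts are cheap in one dimension and guard against the real
    multimodality of the mixture likelihood.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 10:
        raise ValueError("need at least 10 observations")
    if not np.isfinite(x).all():
        raise ValueError("observations must be finite")
    rng = np.random.default_rng(seed)
    sample_var = float(x.var())
    var_floor = max(1e-6 * sample_var, 1e-12)
    warnings_list: list[str] = []

    degenerate = sample_var == 0.0
    if degenerate:
        warnings_list.append(
            "all observations identical: k=1 forced with floored variance"
        )
        ks = (1,)

    candidates: dict[tuple[int, str], CandidateModel] = {}
    for k in ks:
        for vm in variance_models:
            best = None
            xs = np.sort(x)
            for restart in range(max(1, n_restarts if k > 1 else 1)):
                if k == 1:
                    init = np.array([x.mean()])
                elif restart == 0:
                    # k-means-style split of the sorted sample into k
                    # equal-count blocks (the 1-D Lloyd fixed point for
                    # well-separated data)
                    init = np.array([
                        blk.mean() for blk in np.array_split(xs, k)
                    ])
                else:
                    init = np.sort(rng.choice(x, size=k, replace=False))
                w, mu, var, traj, conv = _em_1d(
                    x, k, vm, init, var_floor, tol)
                ll = traj[-1]
                if best is None or ll > best[0]:
                    best = (ll, w, mu, var, traj, conv)
            ll, w, mu, var, traj, conv = best
            order = np.argsort(mu)
            bic = -2.0 * ll + _n_params(k, vm) * math.log(x.size)
            candidates[(k, vm)] = CandidateModel(
                k=k, variance_model=vm, weights=w[order], means=mu[order],
                variances=var[order], log_likelihood=ll, bic=bic,
                ll_trajectory=traj, converged=conv,
            )

    selected = min(candidates, key=lambda key: candidates[key].bic)
    result = GmmResult(
        candidates=candidates, selected=selected, degenerate=degenerate,
        warnings=warnings_list,
    )
    if selected[0] == 2:
        labels, boundary = classify_responders(result, x)
        result.labels = labels
        result.boundary = boundary
    return result


def _posterior_equality_boundary(model: CandidateModel) -> float:
    """Amplitude where posterior membership is equal between the two
    components: solve w1 N(x; m1, v1) = w2 N(x; m2, v2).

    With unequal variances this is a quadratic in x; the root between the
    component means is returned (for equal variances the equation is linear
    and the solution is unique).
    """
    (w1, w2), (m1, m2), (v1, v2) = (
        model.weights, model.means, model.variances)
    # equal-posterior condition, after taking logs and multiplying by 2:
    # (x-m2)^2/v2 - (x-m1)^2/v1 = 2 ln(w2/w1) + ln(v2/v1)
    a = 1.0 / v2 - 1.0 / v1
    b = 2.0 * (m1 / v1 - m2 / v2)
    c = (m2 ** 2 / v2 - m1 ** 2 / v1
         + math.log(v2 / v1) - 2.0 * math.log(w2 / w1))
    if abs(a) < 1e-15:
        if abs(b) < 1e-15:
            return 0.5 * (m1 + m2)
        return -c / b
    disc = b * b - 4.0 * a * c
    if disc < 0:
        return 0.5 * (m1 + m2)
    roots = np.array([(-b - math.sqrt(disc)) / (2 * a),
                      (-b + math.sqrt(disc)) / (2 * a)])
    inside = roots[(roots >= min(m1, m2)) & (roots <= max(m1, m2))]
    if inside.size:
        return float(inside[0])
    # fall back to the root nearest the midpoint
    return float(roots[np.argmin(np.abs(roots - 0.5 * (m1 + m2)))])


def classify_responders(
    gmm: GmmResult, x: np.ndarray
) -> tuple[np.ndarray, float]:
    """Label each unit 'strong' (above the boundary) or 'weak'.

    The boundary is the peak amplitude at which posterior membership is
    equal between the two components of the selected k=2 model; it always
    lies between the two component means.  Refuses when the selected model
    does not have two components.
    """
    if gmm.selected[0] != 2:
        raise ValueError(
            f"classification requires a selected 2-component model; BIC "
            f"selected k={gmm.selected[0]} ({gmm.selected[1]} variances)"
        )
    x = np.asarray(x, dtype=float).ravel()
    boundary = _posterior_equality_boundary(gmm.best)
    labels = np.where(x > boundary, "strong", "weak")
    return labels, float(boundary)
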