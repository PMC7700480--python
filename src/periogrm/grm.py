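"""Samejima graded response model: likelihood, EM estimation, information.

The graded response model (GRM) describes an ordinal item response
``X_j in {0..m_j}`` through cumulative boundary curves sharing one
discrimination per item::

    P*_jk(theta) = 1 / (1 + exp(-a_j (theta - b_jk))),   k = 1..m_j

with strictly ordered thresholds ``b_j1 < ... < b_jm``.  Category
probabilities are the differences of successive boundary curves.  The
logistic is used in its raw ``a (theta - b)`` form, without the historical
1.7 scaling constant, so that a dichotomous item's information integral
over the latent axis equals its discrimination.

Estimation is marginal maximum likelihood under a standard-normal latent
prior via EM: the E-step computes each subject's posterior over a fixed
quadrature grid, the M-step re-maximizes the expected complete-data
log-likelihood jointly over all item parameters (thresholds kept ordered by
a log-gap reparameterization).  Missing responses simply drop out of the
subject's likelihood product (missing-at-random).

The public face is the scikit-learn style :class:`GradedResponseModel`
estimator (``fit`` on a subjects-by-items code matrix, ``transform`` to
per-subject EAP ability); module functions are thin wrappers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logsumexp
from scipy.stats import norm
from sklearn.base import BaseEstimator, TransformerMixin

from .chart import MISSING, OrdinalResponseMatrix

__all__ = [
    "GRMItemParams",
    "QuadratureSpec",
    "AbilityEstimate",
    "ScoreTable",
    "GradedResponseModel",
    "CategoryCollapseError",
    "boundary_prob",
    "category_probs",
    "item_information",
    "item_information_integral",
    "information_criteria",
    "fit_grm",
    "eap_ability",
    "score_table",
]

_PMIN = 1e-12


class CategoryCollapseError(ValueError):
    """An item has an empty response category; merge categories and refit."""


@dataclass(frozen=True)
class GRMItemParams:
    """Discrimination and ordered extremity (threshold) parameters of one item.

    ``m`` thresholds mean ``m + 1`` ordered categories; a single threshold
    gives the dichotomous two-parameter logistic item.
    """

    a: float
    b: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError(f"discrimination must be positive, got {self.a}")
        b = tuple(float(x) for x in self.b)
        if len(b) < 1:
            raise ValueError("at least one threshold is required")
        if any(b2 <= b1 for b1, b2 in zip(b, b[1:])):
            raise ValueError(f"thresholds must be strictly increasing, got {b}")
        object.__setattr__(self, "b", b)

    @property
    def n_categories(self) -> int:
        return len(self.b) + 1


@dataclass(frozen=True)
class QuadratureSpec:
    """Fixed latent-trait grid used for marginal likelihood and EAP scoring.

    ``nodes`` are equally spaced; ``weights`` are the standard-normal
    density renormalized to sum to one.  ``info_range``/``info_points``
    define the separate dense trapezoid grid for information integrals.
    """

    nodes: np.ndarray
    weights: np.ndarray
    info_range: tuple[float, float] = (-10.0, 10.0)
    info_points: int = 2001

    @classmethod
    def make(
        cls,
        n_points: int = 61,
        prior_range: tuple[float, float] = (-6.0, 6.0),
        info_range: tuple[float, float] = (-10.0, 10.0),
        info_points: int = 2001,
    ) -> "QuadratureSpec":
        nodes = np.linspace(prior_range[0], prior_range[1], n_points)
        w = norm.pdf(nodes)
        return cls(nodes=nodes, weights=w / w.sum(), info_range=info_range, info_points=info_points)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, float)
        if np.any(w <= 0) or abs(w.sum() - 1.0) > 1e-8:
            raise ValueError("quadrature weights must be positive and sum to 1")


@dataclass(frozen=True)
class AbilityEstimate:
    """Posterior (EAP) summary of one subject's latent severity."""

    theta: float
    se: float


# ---------------------------------------------------------------------------
# response functions


def boundary_prob(a: float, b_k: float, theta) -> np.ndarray | float:
    """Cumulative boundary curve P(X >= k | theta) = logistic(a (theta - b_k))."""
    if a <= 0:
        raise ValueError("discrimination must be positive")
    return expit(a * (np.asarray(theta, float) - b_k))


def _boundary_matrix(a: float, b: tuple[float, ...], theta: np.ndarray) -> np.ndarray:
    """P* stacked with the fixed outer boundaries: shape (m+2, len(theta))."""
    theta = np.atleast_1d(np.asarray(theta, float))
    ps = expit(a * (theta[None, :] - np.asarray(b, float)[:, None]))
    ones = np.ones((1, theta.size))
    zeros = np.zeros((1, theta.size))
    return np.concatenate([ones, ps, zeros], axis=0)


def category_probs(params: GRMItemParams, theta) -> np.ndarray:
    """Category probabilities P_k(theta), k = 0..m; columns sum to one.

    Returns shape ``(m + 1, n_theta)`` (or ``(m + 1,)`` for scalar theta).
    """
    scalar = np.isscalar(theta)
    pstar = _boundary_matrix(params.a, params.b, theta)
    probs = pstar[:-1] - pstar[1:]
    return probs[:, 0] if scalar else probs


def item_information(params: GRMItemParams, theta) -> np.ndarray | float:
    """Fisher information of one graded item about the latent trait.

    ``I(theta) = a^2 sum_k (w_k - w_{k+1})^2 / (P*_k - P*_{k+1})`` with
    ``w_k = P*_k (1 - P*_k)`` and ``w_0 = w_{m+1} = 0``.  For a dichotomous
    item this reduces to ``a^2 P*(1 - P*)``.
    """
    scalar = np.isscalar(theta)
    pstar = _boundary_matrix(params.a, params.b, theta)
    w = pstar * (1.0 - pstar)
    num = (w[:-1] - w[1:]) ** 2
    den = pstar[:-1] - pstar[1:]
    info = params.a**2 * np.where(den > _PMIN, num / np.maximum(den, _PMIN), 0.0).sum(axis=0)
    return float(info[0]) if scalar else info


def item_information_integral(
    params: GRMItemParams,
    info_range: tuple[float, float] = (-10.0, 10.0),
    n_points: int = 2001,
) -> float:
    """Trapezoid integral of the item information over the latent range.

    For a dichotomous item the closed form is ``a (P*(hi) - P*(lo))``, which
    is ``a`` to high accuracy on the default [-10, 10] range for moderate
    discriminations — the identity that makes reported information directly
    comparable to discrimination.
    """
    grid = np.linspace(info_range[0], info_range[1], n_points)
    return float(np.trapezoid(item_information(params, grid), grid))


def information_criteria(loglik: float, p: int, n: int) -> tuple[float, float]:
    """AIC and BIC from a log-likelihood, parameter count and sample size."""
    if p < 0 or n < 1:
        raise ValueError("need p >= 0 and n >= 1")
    return -2.0 * loglik + 2.0 * p, -2.0 * loglik + p * np.log(n)


# ---------------------------------------------------------------------------
# parameter packing for the M-step

# Per item: z = (log a, b_1, log(b_2 - b_1), ..., log(b_m - b_{m-1})).
# The log-gap form keeps thresholds strictly ordered without constraints.


def _pack(a: np.ndarray, b_list: list[np.ndarray]) -> np.ndarray:
    parts = []
    for aj, bj in zip(a, b_list):
        gaps = np.diff(bj)
        parts.append(np.concatenate([[np.log(aj), bj[0]], np.log(gaps)]))
    return np.concatenate(parts)


def _unpack(z: np.ndarray, m: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
    a = np.empty(len(m))
    b_list = []
    off = 0
    for j, mj in enumerate(m):
        zj = z[off : off + 1 + mj]
        a[j] = np.exp(zj[0])
        b = np.empty(mj)
        b[0] = zj[1]
        if mj > 1:
            b[1:] = zj[1] + np.cumsum(np.exp(zj[2:]))
        b_list.append(b)
        off += 1 + mj
    return a, b_list


def _expected_loglik_and_grad(
    z: np.ndarray,
    m: np.ndarray,
    r_list: list[np.ndarray],
    nodes: np.ndarray,
) -> tuple[float, np.ndarray]:
    """Negative expected complete-data log-likelihood and its gradient.

    ``r_list[j]`` holds the E-step expected counts, shape (m_j + 1, Q).
    The objective separates over items; the gradient is assembled in the
    packed parameterization.
    """
    a, b_list = _unpack(z, m)
    total = 0.0
    grad = np.empty_like(z)
    off = 0
    for j, mj in enumerate(m):
        aj, bj, r = a[j], b_list[j], r_list[j]
        pstar = _boundary_matrix(aj, tuple(bj), nodes)  # (mj+2, Q)
        probs = np.maximum(pstar[:-1] - pstar[1:], _PMIN)  # (mj+1, Q)
        total += float((r * np.log(probs)).sum())
        g = r / probs  # (mj+1, Q)
        w = pstar * (1.0 - pstar)
        # dQ/dP*_k has coefficient (g_k - g_{k-1}) for inner boundaries k=1..mj
        coef = g[1:] - g[:-1]  # (mj, Q)
        da = (w[1:-1] * (nodes[None, :] - bj[:, None]) * coef).sum()
        db = -aj * (w[1:-1] * coef).sum(axis=1)  # (mj,)
        gj = np.empty(1 + mj)
        gj[0] = da * aj  # chain rule through log a
        gj[1] = db.sum()  # b_1 shifts every threshold
        if mj > 1:
            # gap g_k = exp(z_k) shifts thresholds k..m
            tail = np.cumsum(db[::-1])[::-1]
            gj[2:] = tail[1:] * np.exp(z[off + 2 : off + 1 + mj])
        grad[off : off + 1 + mj] = gj
        off += 1 + mj
    return -total, -grad


# ---------------------------------------------------------------------------
# estimator


class GradedResponseModel(BaseEstimator, TransformerMixin):
    """Graded response model fitted by marginal maximum likelihood EM.

    Parameters
    ----------
    n_quad : int
        Number of equally spaced quadrature nodes on ``prior_range`` used
        for the marginal likelihood, E-step and EAP scoring.
    prior_range : tuple of float
        Support of the latent grid; the prior is standard normal (fixed, to
        identify the latent scale).
    info_range, info_points : tuple, int
        Dense trapezoid grid for information integrals.
    tol : float
        EM stops when the marginal log-likelihood improves by less than
        ``tol``.
    max_iter : int
        EM iteration cap; hitting it flags non-convergence (no exception).
    mstep_maxiter : int
        L-BFGS iteration cap inside each M-step.  The M-step is warm-started
        from the current parameters, so a partial maximization still
        increases the marginal likelihood (generalized EM).
    random_state : int or None
        Unused by the deterministic EM itself; kept for API symmetry with
        stochastic estimators and for sklearn clone round-trips.

    Attributes
    ----------
    discrimination_ : ndarray of shape (n_items,)
    thresholds_ : list of ndarray
        Ordered extremity parameters per item.
    item_params_ : list of GRMItemParams
    items_ : list of (label, GRMItemParams)
    loglik_, aic_, bic_ : float
    n_parameters_, n_subjects_, n_iter_ : int
    converged_ : bool
    loglik_path_ : ndarray — marginal log-likelihood after every EM step.
    """

    def __init__(
        self,
        n_quad: int = 61,
        prior_range: tuple[float, float] = (-6.0, 6.0),
        info_range: tuple[float, float] = (-10.0, 10.0),
        info_points: int = 2001,
        tol: float = 1e-4,
        max_iter: int = 200,
        mstep_maxiter: int = 30,
        random_state: int | None = None,
    ):
        self.n_quad = n_quad
        self.prior_range = prior_range
        self.info_range = info_range
        self.info_points = info_points
        self.tol = tol
        self.max_iter = max_iter
        self.mstep_maxiter = mstep_maxiter
        self.random_state = random_state

    # -- data plumbing ------------------------------------------------------

    def _coerce(self, X, n_categories) -> tuple[np.ndarray, np.ndarray, list[str]]:
        if isinstance(X, OrdinalResponseMatrix):
            return X.responses, np.asarray(X.n_categories, int), list(X.items)
        X = np.asarray(X)
        if X.dtype.kind == "f":
            resp = np.where(np.isnan(X), MISSING, X).astype(int)
        else:
            resp = X.astype(int)
        if resp.ndim != 2:
            raise ValueError("X must be a 2-D subjects-by-items matrix")
        if n_categories is None:
            ncat = np.array(
                [resp[:, j][resp[:, j] != MISSING].max() + 1 for j in range(resp.shape[1])]
            )
        else:
            ncat = np.asarray(n_categories, int)
        labels = [f"item{j}" for j in range(resp.shape[1])]
        return resp, ncat, labels

    def _quadrature(self) -> QuadratureSpec:
        return QuadratureSpec.make(
            self.n_quad, self.prior_range, self.info_range, self.info_points
        )

    # -- likelihood pieces --------------------------------------------------

    @staticmethod
    def _log_cat_probs(
        a: np.ndarray, b_list: list[np.ndarray], nodes: np.ndarray
    ) -> list[np.ndarray]:
        out = []
        for aj, bj in zip(a, b_list):
            pstar = _boundary_matrix(aj, tuple(bj), nodes)
            out.append(np.log(np.maximum(pstar[:-1] - pstar[1:], _PMIN)))
        return out

    @staticmethod
    def _subject_node_loglik(
        resp: np.ndarray, logp: list[np.ndarray], n_nodes: int
    ) -> np.ndarray:
        n = resp.shape[0]
        ll = np.zeros((n, n_nodes))
        for j, lp in enumerate(logp):
            x = resp[:, j]
            obs = x != MISSING
            ll[obs] += lp[x[obs]]
        return ll

    # -- fitting ------------------------------------------------------------

    def fit(self, X, y=None, n_categories=None, item_labels=None):
        """Fit by EM.  ``X`` is an OrdinalResponseMatrix or an int/float
        matrix with ``-1``/NaN marking missing responses."""
        resp, ncat, labels = self._coerce(X, n_categories)
        if item_labels is not None:
            labels = list(item_labels)
        n, J = resp.shape
        if n < 1 or J < 1:
            raise ValueError("need at least one subject and one item")

        # every category of every item must be observed, else thresholds diverge
        for j in range(J):
            obs = resp[:, j][resp[:, j] != MISSING]
            seen = np.unique(obs)
            if seen.size < ncat[j]:
                raise CategoryCollapseError(
                    f"item {labels[j]!r} has empty response categories "
                    f"(observed {seen.tolist()} of {ncat[j]}); merge categories "
                    "(e.g. OrdinalResponseMatrix.collapse_sparse_categories) and refit"
                )

        quad = self._quadrature()
        nodes, logw = quad.nodes, np.log(quad.weights)
        m = ncat - 1

        # start values: a = 1, thresholds at prior quantiles of the observed
        # cumulative category frequencies
        a = np.ones(J)
        b_list = []
        for j in range(J):
            obs = resp[:, j][resp[:, j] != MISSING]
            freq = np.bincount(obs, minlength=ncat[j]) / obs.size
            tail = 1.0 - np.cumsum(freq)[:-1]  # P(X >= k), k = 1..m
            q = norm.ppf(np.clip(tail, 0.02, 0.98))
            # enforce strict ordering of the start in degenerate cases
            for k in range(1, len(q)):
                q[k] = max(q[k], q[k - 1] + 0.05)
            b_list.append(q)

        z = _pack(a, b_list)
        loglik = -np.inf
        path = []
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            logp = self._log_cat_probs(a, b_list, nodes)
            ll_iq = self._subject_node_loglik(resp, logp, nodes.size) + logw
            li = logsumexp(ll_iq, axis=1)
            new_loglik = float(li.sum())
            path.append(new_loglik)
            if new_loglik - loglik < self.tol and it > 1:
                loglik = max(loglik, new_loglik)
                converged = True
                break
            loglik = new_loglik

            post = np.exp(ll_iq - li[:, None])  # (n, Q)
            r_list = []
            for j in range(J):
                x = resp[:, j]
                r = np.zeros((ncat[j], nodes.size))
                for k in range(ncat[j]):
                    sel = x == k
                    if sel.any():
                        r[k] = post[sel].sum(axis=0)
                r_list.append(r)

            res = minimize(
                _expected_loglik_and_grad,
                z,
                args=(m, r_list, nodes),
                jac=True,
                method="L-BFGS-B",
                options={"maxiter": self.mstep_maxiter},
            )
            z = res.x
            a, b_list = _unpack(z, m)

        if not converged:
            warnings.warn(
                f"EM did not converge in {self.max_iter} iterations "
                f"(last improvement {path[-1] - path[-2]:.3g})",
                RuntimeWarning,
            )

        self.item_labels_ = labels
        self.n_categories_ = ncat
        self.discrimination_ = a
        self.thresholds_ = b_list
        self.item_params_ = [
            GRMItemParams(float(aj), tuple(float(x) for x in bj))
            for aj, bj in zip(a, b_list)
        ]
        self.items_ = list(zip(labels, self.item_params_))
        self.quadrature_ = quad
        self.loglik_ = loglik
        self.loglik_path_ = np.asarray(path)
        self.n_subjects_ = n
        self.n_parameters_ = int((1 + m).sum())
        self.aic_, self.bic_ = information_criteria(loglik, self.n_parameters_, n)
        self.converged_ = converged
        self.n_iter_ = it
        return self

    @classmethod
    def from_parameters(
        cls,
        items: list[tuple[str, GRMItemParams]],
        n_subjects: int = 0,
        loglik: float = np.nan,
        **kwargs,
    ) -> "GradedResponseModel":
        """Build a scoring-ready model from known item parameters (no data)."""
        model = cls(**kwargs)
        model.item_labels_ = [lab for lab, _ in items]
        model.item_params_ = [p for _, p in items]
        model.items_ = list(items)
        model.discrimination_ = np.array([p.a for _, p in items])
        model.thresholds_ = [np.asarray(p.b, float) for _, p in items]
        model.n_categories_ = np.array([p.n_categories for _, p in items])
        model.quadrature_ = model._quadrature()
        model.loglik_ = loglik
        model.loglik_path_ = np.array([])
        model.n_subjects_ = n_subjects
        model.n_parameters_ = int(sum(1 + len(p.b) for _, p in items))
        if np.isfinite(loglik) and n_subjects > 0:
            model.aic_, model.bic_ = information_criteria(
                loglik, model.n_parameters_, n_subjects
            )
        else:
            model.aic_ = model.bic_ = np.nan
        model.converged_ = True
        model.n_iter_ = 0
        return model

    # -- scoring ------------------------------------------------------------

    def _check_fitted(self) -> None:
        if not hasattr(self, "item_params_"):
            raise RuntimeError("model is not fitted")

    def _posterior(self, resp: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Posterior over quadrature nodes for each response-pattern row."""
        quad = self.quadrature_
        a = self.discrimination_
        logp = self._log_cat_probs(a, self.thresholds_, quad.nodes)
        ll = self._subject_node_loglik(resp, logp, quad.nodes.size)
        ll += np.log(quad.weights)
        li = logsumexp(ll, axis=1)
        return np.exp(ll - li[:, None]), li

    def eap(self, X) -> tuple[np.ndarray, np.ndarray]:
        """EAP ability (posterior mean) and posterior SD per subject."""
        self._check_fitted()
        resp, ncat, _ = self._coerce(X, self.n_categories_)
        for j in range(resp.shape[1]):
            obs = resp[:, j][resp[:, j] != MISSING]
            if obs.size and obs.max() >= self.n_categories_[j]:
                raise ValueError(f"response category out of range for item {self.item_labels_[j]!r}")
        post, _ = self._posterior(resp)
        nodes = self.quadrature_.nodes
        theta = post @ nodes
        var = post @ nodes**2 - theta**2
        return theta, np.sqrt(np.maximum(var, 1e-300))

    def transform(self, X) -> np.ndarray:
        """Per-subject EAP ability as a column vector (sklearn transformer API)."""
        return self.eap(X)[0][:, None]

    def score_samples(self, X) -> np.ndarray:
        """Marginal log-likelihood of each response pattern."""
        self._check_fitted()
        resp, _, _ = self._coerce(X, self.n_categories_)
        _, li = self._posterior(resp)
        return li

    def score(self, X, y=None) -> float:
        return float(self.score_samples(X).sum())

    # -- information --------------------------------------------------------

    def item_information(self, theta) -> np.ndarray:
        """Stacked Fisher information curves, shape (n_items, n_theta)."""
        self._check_fitted()
        theta = np.atleast_1d(theta)
        return np.vstack([item_information(p, theta) for p in self.item_params_])

    def information_integrals(self) -> np.ndarray:
        """Information integral of every item over the configured range."""
        self._check_fitted()
        return np.array(
            [
                item_information_integral(p, self.info_range, self.info_points)
                for p in self.item_params_
            ]
        )

    def parameter_table(self) -> pd.DataFrame:
        """Flat per-item parameter table (Extrmt1..., Dscrmn, information)."""
        self._check_fitted()
        max_m = max(len(p.b) for p in self.item_params_)
        rows = []
        infos = self.information_integrals()
        for (lab, p), info in zip(self.items_, infos):
            row: dict[str, object] = {"item": lab}
            for k in range(max_m):
                row[f"Extrmt{k + 1}"] = p.b[k] if k < len(p.b) else np.nan
            row["Dscrmn"] = p.a
            row["ItemInformation"] = info
            row["AIC"] = self.aic_
            row["BIC"] = self.bic_
            rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# score table


@dataclass
class ScoreTable:
    """Ability lookup: one row per response pattern, plus a sum-score digest.

    ``patterns`` maps every complete response pattern to its EAP ability and
    posterior SD; ``by_sum_score`` aggregates patterns sharing a raw sum
    score, reporting the min/mean/max ability per score — the quick
    reference an examiner can use without refitting anything.
    """

    patterns: pd.DataFrame
    by_sum_score: pd.DataFrame


def score_table(fit: GradedResponseModel, cap: int = 1000) -> ScoreTable:
    """Tabulate EAP ability for every response pattern of a fitted model."""
    fit._check_fitted()
    ncat = fit.n_categories_
    total = int(np.prod(ncat))
    if total > cap:
        raise ValueError(
            f"{total} response patterns exceed the cap of {cap}; "
            "use sum-score aggregation on sampled patterns instead"
        )
    grids = np.meshgrid(*[np.arange(c) for c in ncat], indexing="ij")
    patterns = np.stack([g.ravel() for g in grids], axis=1)
    theta, se = fit.eap(patterns)
    df = pd.DataFrame(patterns, columns=fit.item_labels_)
    df["sum_score"] = patterns.sum(axis=1)
    df["ability"] = theta
    df["se"] = se
    by_score = (
        df.groupby("sum_score")["ability"]
        .agg(["min", "mean", "max", "count"])
        .rename(columns={"min": "ability_min", "mean": "ability_mean", "max": "ability_max"})
        .reset_index()
    )
    return ScoreTable(patterns=df, by_sum_score=by_score)


# ---------------------------------------------------------------------------
# functional wrappers


def fit_grm(
    data: OrdinalResponseMatrix,
    quad: QuadratureSpec | None = None,
    tol: float = 1e-4,
    max_iter: int = 200,
    seed: int | None = None,
) -> GradedResponseModel:
    """Fit a graded response model to an ordinal response matrix."""
    kwargs: dict = {"tol": tol, "max_iter": max_iter, "random_state": seed}
    if quad is not None:
        kwargs.update(
            n_quad=len(quad.nodes),
            prior_range=(float(quad.nodes[0]), float(quad.nodes[-1])),
            info_range=quad.info_range,
            info_points=quad.info_points,
        )
    return GradedResponseModel(**kwargs).fit(data)


def eap_ability(fit: GradedResponseModel, pattern) -> AbilityEstimate:
    """EAP ability of a single response pattern (missing entries allowed)."""
    pattern = np.asarray(pattern).reshape(1, -1)
    theta, se = fit.eap(pattern)
    return AbilityEstimate(theta=float(theta[0]), se=float(se[0]))
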