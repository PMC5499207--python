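"""Three-component beta-binomial mixture of splice-site usage.

The per cent spliced in (psi) of a junction side — its split-read count
n conditioned on the side total N — is modelled as a mixture of three
beta-binomial components: background (essentially unspliced), weak
(low but consistent splicing, around 1%) and strong (canonical)
splicing. To make the components identifiable, junctions are stratified
into three groups s in {0, 1, 2} by how many of their splice sites are
annotated; the component shapes (alpha_c, beta_c) are shared across
groups while the mixing proportions pi_{s,c} are group-specific:

    n | N, s  ~  sum_c pi_{s,c} * BetaBin(n; N, alpha_c, beta_c)

The model is fitted by expectation-maximisation, initialised from the
hard classification psi < 0.001 (background), psi < 0.1 (weak),
psi >= 0.1 (strong). After convergence the fitted parameters give, for
every junction side, the posterior probability of each class.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import betaln, gammaln, logsumexp

__all__ = [
    "PsiMixture",
    "PsiMixtureResults",
    "initial_classification",
    "fit_psi_mixture",
    "classify_splice_sites",
]

COMPONENTS = ["background", "weak", "strong"]
INIT_THRESHOLDS = (0.001, 0.1)  # psi < t0 -> background, psi < t1 -> weak
_SHAPE_LOG_BOUNDS = (np.log(1e-4), np.log(1e7))


def initial_classification(psi: np.ndarray) -> np.ndarray:
    """Hard class indices from the psi thresholds used to seed the EM."""
    psi = np.asarray(psi, dtype=float)
    out = np.full(psi.shape, 2, dtype=int)
    out[psi < INIT_THRESHOLDS[1]] = 1
    out[psi < INIT_THRESHOLDS[0]] = 0
    return out


def _betabin_logpmf(n, N, a, b):
    return (
        gammaln(N + 1)
        - gammaln(n + 1)
        - gammaln(N - n + 1)
        + betaln(n + a, N - n + b)
        - betaln(a, b)
    )


def _mom_shapes(psi: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Weighted method-of-moments beta shapes from smoothed psi values."""
    wsum = w.sum()
    m = float((w * psi).sum() / wsum)
    v = float((w * (psi - m) ** 2).sum() / wsum)
    m = min(max(m, 1e-6), 1 - 1e-6)
    if v <= 0 or v >= m * (1 - m):
        t = 1.0
    else:
        t = m * (1 - m) / v - 1.0
    return max(m * t, 1e-3), max((1 - m) * t, 1e-3)


class ComponentCollapseError(RuntimeError):
    """A mixture component lost essentially all responsibility mass."""


class PsiMixture:
    """Beta-binomial mixture model of splice-site strength.

    Parameters
    ----------
    n, N : arrays of split-read counts and side totals per junction side.
    groups : array of annotation groups s in {0, 1, 2} per observation
        (number of annotated splice sites of the junction).
    """

    def __init__(self, n, N, groups):
        self.n = np.asarray(n, dtype=float)
        self.N = np.asarray(N, dtype=float)
        self.groups = np.asarray(groups, dtype=int)
        if not (self.N >= 1).all():
            raise ValueError("every observation needs a side total N >= 1")
        if self.n.shape != self.N.shape or self.n.shape != self.groups.shape:
            raise ValueError("n, N and groups must have equal length")
        if ((self.n < 0) | (self.n > self.N)).any():
            raise ValueError("counts must satisfy 0 <= n <= N")
        if not np.isin(self.groups, [0, 1, 2]).all():
            raise ValueError("groups must be 0, 1 or 2")

    # -- EM internals -----------------------------------------------------

    def _component_logpmf(self, alpha, beta):
        return np.stack(
            [_betabin_logpmf(self.n, self.N, alpha[c], beta[c]) for c in range(3)],
            axis=1,
        )

    def _init_params(self, rng: np.random.Generator | None = None):
        psi = self.n / self.N
        psi_smooth = (self.n + 0.5) / (self.N + 1.0)
        hard = initial_classification(psi)
        alpha = np.empty(3)
        beta = np.empty(3)
        overall = _mom_shapes(psi_smooth, np.ones_like(psi_smooth))
        for c in range(3):
            w = (hard == c).astype(float)
            if w.sum() < 2:
                alpha[c], beta[c] = overall
            else:
                alpha[c], beta[c] = _mom_shapes(psi_smooth, w)
        pi = np.full((3, 3), 1.0 / 3)
        for s in range(3):
            in_s = self.groups == s
            if in_s.any():
                counts = np.bincount(hard[in_s], minlength=3) + 0.5
                pi[s] = counts / counts.sum()
        if rng is not None:
            alpha *= np.exp(rng.normal(0, 0.3, 3))
            beta *= np.exp(rng.normal(0, 0.3, 3))
            pi = pi + rng.uniform(0, 0.05, (3, 3))
            pi /= pi.sum(axis=1, keepdims=True)
        return alpha, beta, pi

    def _m_step_shapes(self, resp, alpha, beta):
        """Improve (alpha_c, beta_c) for each component by a bounded
        quasi-Newton step on the responsibility-weighted log-likelihood;
        updates are only accepted when they improve it, which keeps the
        EM objective monotone."""
        new_alpha, new_beta = alpha.copy(), beta.copy()
        for c in range(3):
            w = resp[:, c]
            if w.sum() < 1e-6:
                raise ComponentCollapseError(COMPONENTS[c])

            def nll(x):
                a, b = np.exp(x)
                return -float((w * _betabin_logpmf(self.n, self.N, a, b)).sum())

            x0 = np.log([alpha[c], beta[c]])
            res = minimize(
                nll,
                x0,
                method="L-BFGS-B",
                bounds=[_SHAPE_LOG_BOUNDS] * 2,
                options={"maxiter": 40},
            )
            if res.fun < nll(x0):
                new_alpha[c], new_beta[c] = np.exp(res.x)
        return new_alpha, new_beta

    def _fit_once(self, alpha, beta, pi, tol, max_iter):
        log_pi_obs = None
        trace = []
        for it in range(max_iter):
            comp_ll = self._component_logpmf(alpha, beta)
            log_pi_obs = np.log(np.maximum(pi[self.groups], 1e-300))
            joint = comp_ll + log_pi_obs
            obs_ll = logsumexp(joint, axis=1)
            ll = float(obs_ll.sum())
            trace.append(ll)
            if it > 0:
                prev = trace[-2]
                rel = abs(ll - prev) / max(abs(prev), 1.0)
                if rel < tol:
                    return alpha, beta, pi, trace, True
            resp = np.exp(joint - obs_ll[:, None])
            # M-step: group-specific mixing proportions in closed form
            for s in range(3):
                in_s = self.groups == s
                if in_s.any():
                    pi[s] = resp[in_s].mean(axis=0)
                    pi[s] /= pi[s].sum()
            alpha, beta = self._m_step_shapes(resp, alpha, beta)
        return alpha, beta, pi, trace, False

    def fit(
        self,
        tol: float = 1e-8,
        max_iter: int = 1000,
        n_restarts: int = 2,
        seed: int = 0,
    ) -> "PsiMixtureResults":
        """Run EM to convergence (relative log-likelihood change < tol).

        On component collapse the fit restarts from a perturbed
        initialisation up to ``n_restarts`` times before failing.
        """
        rng = np.random.default_rng(seed)
        last_err: Exception | None = None
        for attempt in range(n_restarts + 1):
            alpha, beta, pi = self._init_params(rng if attempt else None)
            try:
                alpha, beta, pi, trace, conv = self._fit_once(
                    alpha, beta, pi, tol, max_iter
                )
                return PsiMixtureResults(self, alpha, beta, pi, trace, conv)
            except ComponentCollapseError as err:  # perturb and retry
                last_err = err
        raise RuntimeError(
            f"mixture component {last_err} collapsed in every EM restart; "
            "the data may not support three components"
        )


class PsiMixtureResults:
    """Fitted mixture: shapes per component, group-specific mixing
    proportions and the EM log-likelihood trace."""

    def __init__(self, model, alpha, beta, pi, loglik_trace, converged):
        self.model = model
        self.alpha_ = np.asarray(alpha)
        self.beta_ = np.asarray(beta)
        self.pi_ = np.asarray(pi)
        self.loglik_trace_ = list(loglik_trace)
        self.converged_ = bool(converged)

    @property
    def component_means(self) -> np.ndarray:
        """Mean psi of each component, alpha / (alpha + beta)."""
        return self.alpha_ / (self.alpha_ + self.beta_)

    def posterior(self, n, N, groups) -> np.ndarray:
        n = np.asarray(n, dtype=float)
        N = np.asarray(N, dtype=float)
        groups = np.asarray(groups, dtype=int)
        comp_ll = np.stack(
            [_betabin_logpmf(n, N, self.alpha_[c], self.beta_[c]) for c in range(3)],
            axis=1,
        )
        joint = comp_ll + np.log(np.maximum(self.pi_[groups], 1e-300))
        return np.exp(joint - logsumexp(joint, axis=1)[:, None])

    def classify(self, n, N, groups) -> tuple[np.ndarray, np.ndarray]:
        """Posterior class per observation; ties break toward the lower
        class (background < weak < strong)."""
        post = self.posterior(n, N, groups)
        # argmax returns the first maximal index, i.e. the lower class on ties
        classes = np.argmax(post, axis=1)
        return classes, post

    def summary(self) -> str:
        lines = ["Beta-binomial psi mixture (EM fit)"]
        lines.append(
            f"  converged: {self.converged_} after {len(self.loglik_trace_)} iterations"
        )
        for c, name in enumerate(COMPONENTS):
            lines.append(
                f"  {name:>10}: alpha={self.alpha_[c]:.4g} beta={self.beta_[c]:.4g} "
                f"mean psi={self.component_means[c]:.4g}"
            )
        for s in range(3):
            pis = ", ".join(f"{v:.3f}" for v in self.pi_[s])
            lines.append(f"  pi(s={s} annotated sides): [{pis}]")
        return "\n".join(lines)


def fit_psi_mixture(
    psi_counts: pd.DataFrame,
    tol: float = 1e-8,
    max_iter: int = 1000,
    seed: int = 0,
) -> PsiMixtureResults:
    """Fit the mixture from a table with columns n, N and s (annotation
    group per junction side)."""
    model = PsiMixture(
        psi_counts["n"].to_numpy(),
        psi_counts["N"].to_numpy(),
        psi_counts["s"].to_numpy(),
    )
    return model.fit(tol=tol, max_iter=max_iter, seed=seed)


def classify_splice_sites(
    results: PsiMixtureResults, psi_counts: pd.DataFrame
) -> pd.DataFrame:
    """Posterior class per junction side under a fitted mixture.

    ``psi_counts`` needs columns n, N and s; returns the input plus the
    posterior probability of each component and the argmax class.
    """
    classes, post = results.classify(
        psi_counts["n"].to_numpy(),
        psi_counts["N"].to_numpy(),
        psi_counts["s"].to_numpy(),
    )
    out = psi_counts.copy()
    out["psi"] = out["n"] / out["N"]
    for c, name in enumerate(COMPONENTS):
        out[f"p_{name}"] = post[:, c]
    out["class"] = [COMPONENTS[c] for c in classes]
    return out
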