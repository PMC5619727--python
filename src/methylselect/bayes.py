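"""Per-CpG marginal likelihoods, posterior model probabilities, and the
empirical-Bayes EM estimate of the g-prior scale.

Model
-----
For one CpG and one sex, the n × J observation matrix ``y`` (subjects ×
cell types) follows, under candidate model m with design X (J × P),

    y_i | mu, sigma2 ~ N_J(X mu, sigma2 I),   i = 1..n

with a Zellner g-prior on the partition means,

    mu | g, sigma2 ~ N_P(b0 1, g sigma2 / n (X'X)^-1),

and the scale-invariant prior p(sigma2) ∝ 1/sigma2.  Stacking the n
replicates, the full design is Z = 1_n ⊗ X with Z'Z = n X'X, so the prior
covariance is exactly g sigma2 (Z'Z)^-1: the textbook g-prior on the
stacked regression.  Writing w = y − b0 (centring both data and prior),
the OLS fit of w on Z has fitted sum of squares

    F = Σ_p (Σ_{ij in p} w_ij)^2 / (n c_p)

(c_p the number of cell types in group p) and residual sum of squares
SSR = Σ w² − F.  Integrating mu (normal–normal conjugacy) and then sigma2
(inverse-gamma) gives the closed-form marginal used throughout:

    log p(y | m, g) = log Γ(N/2) − (P/2) log(1+g) − (N/2) log π
                      − (N/2) log Q,          N = nJ,
    Q = SSR + F/(1+g) = Σ w² − F g/(1+g).

Posterior moments follow from the same conjugacy:
``mu | y ~ b0 + g/(1+g)(mu_OLS − b0)`` with covariance
``g/(1+g) sigma2 (Z'Z)^-1``, and ``sigma2 | y ~ InvGamma(N/2, Q/2)`` whose
mean ``Q/(N−2)`` is the plug-in point estimate.

The g-prior scale g is shared by all CpGs of a sex and estimated by
empirical Bayes: the EM algorithm treats the per-CpG model indicator as
latent and maximises the model-averaged marginal likelihood
``Σ_k log Σ_m p(y_k|m,g) Pr(m)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammaln, logsumexp

from .lineage import CandidateModel, ModelSet

__all__ = [
    "PriorConfig",
    "ModelFitPerCpG",
    "EMTrace",
    "FitResult",
    "log_marginal_likelihood",
    "posterior_model_probabilities",
    "posterior_mu",
    "posterior_sigma2",
    "estimate_g_em",
    "fit",
]

_LOG_PI = float(np.log(np.pi))


@dataclass
class PriorConfig:
    """Hyperparameters of the per-CpG model: prior centre b0, g-prior
    scale g, and the prior over candidate models (equal if None)."""

    b0: float
    g: float
    prior_model_probs: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.b0 <= 1.0):
            raise ValueError(f"b0 must lie in [0,1], got {self.b0}")
        if not self.g > 0:
            raise ValueError(f"g must be positive, got {self.g}")
        if self.prior_model_probs is not None:
            p = np.asarray(self.prior_model_probs, dtype=float)
            if not np.isclose(p.sum(), 1.0):
                raise ValueError("prior_model_probs must sum to 1")
            self.prior_model_probs = p

    @property
    def shrinkage(self) -> float:
        """Weight g/(1+g) placed on the data relative to the prior."""
        return self.g / (1.0 + self.g)


@dataclass
class ModelFitPerCpG:
    """Posterior summary of one CpG across all candidate models."""

    probe_id: str
    model_names: tuple[str, ...]
    log_marginal: np.ndarray
    posterior_prob: np.ndarray
    mu_hat: dict[str, np.ndarray]
    sigma2_hat: dict[str, float]

    def prob(self, model_name: str) -> float:
        return float(self.posterior_prob[self.model_names.index(model_name)])


@dataclass
class EMTrace:
    g_path: list[float] = field(default_factory=list)
    objective_path: list[float] = field(default_factory=list)
    converged: bool = False

    @property
    def iterations(self) -> int:
        return len(self.g_path)


# ---------------------------------------------------------------------------
# sufficient statistics


def _check_y(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if y.ndim != 2:
        raise ValueError("y must be an n x J matrix for a single CpG")
    return y


def _stats_single(y: np.ndarray, model: CandidateModel, b0: float):
    """(TSS, F, partition sample means) for one CpG; see module docstring."""
    n, J = y.shape
    c = model.partition_sizes
    Sp = y.sum(axis=0) @ model.design  # per-group sums over subjects & cells
    mean_p = Sp / (n * c)
    Sw = Sp - b0 * n * c
    F = float((Sw**2 / (n * c)).sum())
    TSS = float(((y - b0) ** 2).sum())
    return TSS, F, mean_p


def _batch_stats(beta: np.ndarray, models: ModelSet, b0: float):
    """Vectorised sufficient statistics for a K × n × J tensor.

    Returns TSS (K,), F (K, M), per-model partition means (list of K × P_m),
    and the per-model parameter counts.
    """
    K, n, J = beta.shape
    S = beta.sum(axis=1)  # K × J
    TSS = ((beta - b0) ** 2).sum(axis=(1, 2))
    M = len(models)
    F = np.empty((K, M))
    means = []
    for m, model in enumerate(models):
        c = model.partition_sizes
        Sp = S @ model.design  # K × P
        means.append(Sp / (n * c))
        Sw = Sp - b0 * n * c
        F[:, m] = (Sw**2 / (n * c)).sum(axis=1)
    pm = np.array([m.n_partitions for m in models])
    return TSS, F, means, pm


def _log_marginal_from_stats(TSS, F, pm, N: int, g: float) -> np.ndarray:
    Q = TSS[..., None] - F * (g / (1.0 + g)) if F.ndim == 2 else TSS - F * (g / (1.0 + g))
    if np.any(Q <= 0):
        raise ValueError(
            "zero residual variation: the marginal likelihood is degenerate "
            "for at least one CpG (all values equal the prior centre)"
        )
    return (
        gammaln(N / 2.0)
        - (pm / 2.0) * np.log1p(g)
        - (N / 2.0) * _LOG_PI
        - (N / 2.0) * np.log(Q)
    )


# ---------------------------------------------------------------------------
# public per-CpG operations


def log_marginal_likelihood(y, model: CandidateModel, prior: PriorConfig) -> float:
    """Closed-form log marginal p(y | model, g) for one CpG.

    Requires nJ > P so that the integrated density is proper.
    """
    y = _check_y(y)
    n, J = y.shape
    N = n * J
    P = model.n_partitions
    if N <= P:
        raise ValueError(
            f"improper marginal: need n*J > P, got n*J={N} <= P={P}"
        )
    TSS, F, _ = _stats_single(y, model, prior.b0)
    return float(_log_marginal_from_stats(np.float64(TSS), np.float64(F), P, N, prior.g))


def posterior_model_probabilities(log_marginals, prior_model_probs=None) -> np.ndarray:
    """Normalise per-model log marginals into posterior probabilities.

    Computed via log-sum-exp; accepts a vector (one CpG) or a K × M matrix
    (normalised along the last axis).
    """
    lm = np.asarray(log_marginals, dtype=float)
    if prior_model_probs is None:
        logw = lm
    else:
        p = np.asarray(prior_model_probs, dtype=float)
        with np.errstate(divide="ignore"):
            logw = lm + np.log(p)
    if np.any(np.all(np.isneginf(logw), axis=-1)):
        raise ValueError("all log marginals are -inf; probabilities undefined")
    out = np.exp(logw - logsumexp(logw, axis=-1, keepdims=True))
    return out / out.sum(axis=-1, keepdims=True)


def posterior_mu(y, model: CandidateModel, prior: PriorConfig) -> np.ndarray:
    """g-prior posterior mean of the partition means: the partition sample
    means shrunk toward b0 by the factor g/(1+g)."""
    y = _check_y(y)
    _, _, mean_p = _stats_single(y, model, prior.b0)
    return prior.b0 + prior.shrinkage * (mean_p - prior.b0)


def posterior_sigma2(y, model: CandidateModel, prior: PriorConfig) -> float:
    """Posterior point estimate of the common residual variance.

    The posterior is InvGamma(N/2, Q/2) with Q = SSR + F/(1+g); the
    estimate is its mean Q/(N−2), falling back to the mode Q/(N+2) (with a
    warning) when N ≤ 2 and the mean does not exist.
    """
    y = _check_y(y)
    n, J = y.shape
    N = n * J
    TSS, F, _ = _stats_single(y, model, prior.b0)
    Q = TSS - F * prior.shrinkage
    if Q <= 0:
        raise ValueError("zero residual variation: sigma2 posterior degenerate")
    if N <= 2:
        warnings.warn(
            "posterior degrees of freedom <= 2; using posterior mode for sigma2",
            RuntimeWarning,
        )
        return Q / (N + 2.0)
    return Q / (N - 2.0)


# ---------------------------------------------------------------------------
# empirical-Bayes estimation of g


def _observed_objective(TSS, F, pm, N, g, log_prior) -> float:
    lm = _log_marginal_from_stats(TSS, F, pm, N, g)
    return float(logsumexp(lm + log_prior, axis=1).sum())


def estimate_g_em(
    data,
    models: ModelSet,
    b0: float,
    init_g: float = 1.0,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> tuple[float, EMTrace]:
    """Empirical-Bayes estimate of g by EM over the latent model indicator.

    E-step: responsibilities q_km = Pr(m | y_k, g).  M-step: maximise
    Σ_km q_km log p(y_k | m, g) by bounded scalar optimisation on log g.
    Iterates until the relative change in the observed-data objective
    Σ_k log Σ_m p(y_k|m,g) Pr(m) drops below ``tol``.

    ``data`` is a MethylationDataset or a bare K × n × J array.

    Returns (g_hat, EMTrace); if ``max_iter`` is exhausted the best
    iterate is returned with ``converged=False`` and a warning.
    """
    beta = data.beta if hasattr(data, "beta") else np.asarray(data, dtype=float)
    if beta.ndim == 2:  # single CpG convenience
        beta = beta[None, ...]
    if init_g <= 0:
        raise ValueError("init_g must be positive")
    K, n, J = beta.shape
    N = n * J
    TSS, F, _, pm = _batch_stats(beta, models, b0)
    log_prior = np.log(models.prior)
    SSR = TSS[:, None] - F  # K × M, >= 0 by projection

    def m_step(q: np.ndarray, g0: float) -> float:
        A = (q * pm).sum() / 2.0  # total weighted parameter count

        def neg(t: float) -> float:
            g = np.exp(t)
            Q = SSR + F / (1.0 + g)
            return A * np.log1p(g) + (N / 2.0) * float(
                (q * np.log(Q)).sum()
            )

        res = minimize_scalar(
            neg, bounds=(np.log(1e-8), np.log(1e8)), method="bounded",
            options={"xatol": 1e-10},
        )
        return float(np.exp(res.x))

    g = float(init_g)
    trace = EMTrace()
    obj = _observed_objective(TSS, F, pm, N, g, log_prior)
    trace.g_path.append(g)
    trace.objective_path.append(obj)
    for _ in range(max_iter):
        lm = _log_marginal_from_stats(TSS, F, pm, N, g)
        q = posterior_model_probabilities(lm, models.prior)
        g = m_step(q, g)
        new_obj = _observed_objective(TSS, F, pm, N, g, log_prior)
        trace.g_path.append(g)
        trace.objective_path.append(new_obj)
        if new_obj < obj - 1e-8 * (abs(obj) + 1.0):
            warnings.warn("EM objective decreased beyond slack", RuntimeWarning)
        if abs(new_obj - obj) <= tol * (abs(obj) + 1.0):
            trace.converged = True
            obj = new_obj
            break
        obj = new_obj
    else:
        warnings.warn(
            f"EM did not converge in {max_iter} iterations; returning best iterate",
            RuntimeWarning,
        )
    return g, trace


# ---------------------------------------------------------------------------
# full fit


@dataclass
class FitResult:
    """Posterior fit of every candidate model at every CpG of one dataset."""

    model_set: ModelSet
    probe_ids: list[str]
    sex: str | None
    b0: float
    g: float
    n_subjects: int
    n_cell_types: int
    log_marginal: np.ndarray  # K × M
    posterior_prob: np.ndarray  # K × M
    mu_hat: list[np.ndarray]  # per model: K × P_m
    sigma2_hat: np.ndarray  # K × M
    em_trace: EMTrace | None = None

    @property
    def model_names(self) -> list[str]:
        return self.model_set.names

    @property
    def prior_config(self) -> PriorConfig:
        return PriorConfig(b0=self.b0, g=self.g, prior_model_probs=self.model_set.prior)

    def prob_for(self, model_name: str) -> np.ndarray:
        return self.posterior_prob[:, self.model_set.index(model_name)]

    def modal_models(self) -> np.ndarray:
        idx = np.argmax(self.posterior_prob, axis=1)
        names = np.array(self.model_names)
        return names[idx]

    def per_cpg(self, key) -> ModelFitPerCpG:
        k = self.probe_ids.index(key) if isinstance(key, str) else int(key)
        return ModelFitPerCpG(
            probe_id=self.probe_ids[k],
            model_names=tuple(self.model_names),
            log_marginal=self.log_marginal[k].copy(),
            posterior_prob=self.posterior_prob[k].copy(),
            mu_hat={m.name: self.mu_hat[i][k].copy() for i, m in enumerate(self.model_set)},
            sigma2_hat={m.name: float(self.sigma2_hat[k, i]) for i, m in enumerate(self.model_set)},
        )

    # -- tabular round trip ------------------------------------------------

    def to_frame(self) -> "pd.DataFrame":
        import pandas as pd

        data = {"probe_id": self.probe_ids}
        for i, m in enumerate(self.model_set):
            data[f"prob:{m.name}"] = self.posterior_prob[:, i]
        for i, m in enumerate(self.model_set):
            for p in range(m.n_partitions):
                data[f"mu:{m.name}:{m.group_label(p)}"] = self.mu_hat[i][:, p]
            data[f"sigma2:{m.name}"] = self.sigma2_hat[:, i]
        return pd.DataFrame(data)

    @classmethod
    def from_frame(cls, df, model_set: ModelSet, *, sex, b0, g, n_subjects) -> "FitResult":
        K = len(df)
        M = len(model_set)
        prob = np.column_stack([df[f"prob:{m.name}"].to_numpy() for m in model_set])
        mu = []
        sig = np.empty((K, M))
        for i, m in enumerate(model_set):
            mu.append(
                np.column_stack(
                    [df[f"mu:{m.name}:{m.group_label(p)}"].to_numpy() for p in range(m.n_partitions)]
                )
            )
            sig[:, i] = df[f"sigma2:{m.name}"].to_numpy()
        return cls(
            model_set=model_set,
            probe_ids=[str(x) for x in df["probe_id"]],
            sex=sex,
            b0=b0,
            g=g,
            n_subjects=n_subjects,
            n_cell_types=len(model_set.models[0].cell_types),
            log_marginal=np.full((K, M), np.nan),
            posterior_prob=prob,
            mu_hat=mu,
            sigma2_hat=sig,
        )


def fit(
    dataset,
    models: ModelSet,
    b0: float | str = "auto",
    g: float | str = "em",
    init_g: float = 1.0,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> FitResult:
    """Fit all candidate models at every CpG of one per-sex dataset.

    ``b0="auto"`` uses the grand mean β over all probes, subjects and cell
    types; ``g="em"`` estimates the g-prior scale by empirical Bayes
    before computing posterior quantities at the estimate.
    """
    beta = dataset.beta
    K, n, J = beta.shape
    N = n * J
    b0_val = float(beta.mean()) if b0 == "auto" else float(b0)
    trace = None
    if g == "em":
        g_val, trace = estimate_g_em(
            beta, models, b0_val, init_g=init_g, tol=tol, max_iter=max_iter
        )
    else:
        g_val = float(g)
    if g_val <= 0:
        raise ValueError("g must be positive")

    TSS, F, means, pm = _batch_stats(beta, models, b0_val)
    lm = _log_marginal_from_stats(TSS, F, pm, N, g_val)
    prob = posterior_model_probabilities(lm, models.prior)
    shrink = g_val / (1.0 + g_val)
    mu_hat = [b0_val + shrink * (mp - b0_val) for mp in means]
    Q = TSS[:, None] - F * shrink
    sigma2 = Q / (N - 2.0) if N > 2 else Q / (N + 2.0)
    return FitResult(
        model_set=models,
        probe_ids=list(dataset.probe_ids),
        sex=getattr(dataset, "sex", None),
        b0=b0_val,
        g=g_val,
        n_subjects=n,
        n_cell_types=J,
        log_marginal=lm,
        posterior_prob=prob,
        mu_hat=mu_hat,
        sigma2_hat=sigma2,
        em_trace=trace,
    )
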