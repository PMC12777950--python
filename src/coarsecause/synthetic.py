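"""Synthetic observational data with known causal structure.

The generator draws covariates from a known joint distribution, assigns
treatment from a logistic propensity e(X) = logistic(g0 + g'Z), builds
both potential outcomes from mean surfaces mu_0(Z), mu_1(Z) with additive
Gaussian noise (or Bernoulli outcomes through a logit link), and reveals
the observed outcome by consistency, Y = (1-T) Y(0) + T Y(1). Strong
ignorability holds by construction: T depends on X only, and the outcome
noise is independent of T. Positivity holds because the logistic
propensity is strictly inside (0, 1).

``Z`` is the numeric feature view of the covariates: continuous columns
as-is, each categorical column as its integer level code. Mean surfaces
are quadratic polynomials in Z, so the true ATE has a closed form for
Gaussian outcomes; Bernoulli truths are computed by Monte Carlo with a
recorded standard error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .builders import cem_coarsen, kmeans_strata, rf_proximity_strata, CoarseningSpec
from .data import Dataset, RunConfig
from .errors import ConfigError
from .estimators import ate_estimate, att_estimate, prune_strata

logger = logging.getLogger("coarsecause")

__all__ = [
    "CovariateSpec",
    "MeanSurface",
    "SyntheticTruth",
    "generate",
    "simulate_performance",
    "SimulationReport",
    "SCENARIOS",
]

_TRUTH_DRAWS = 10**6
_TRUTH_SEED = 202_401  # fixed stream for Monte-Carlo truths, independent of data seeds


@dataclass
class CovariateSpec:
    """Joint covariate distribution.

    ``n_continuous`` standard-normal columns with pairwise correlation
    ``rho`` (equicorrelated Gaussian), plus categorical columns given as
    ``(name, levels, probabilities)`` sampled independently.
    """

    n_continuous: int = 2
    rho: float = 0.0
    categoricals: list[tuple[str, list[str], list[float]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_continuous < 0 or (self.n_continuous == 0 and not self.categoricals):
            raise ConfigError("need at least one covariate column")
        if not -1 < self.rho < 1:
            raise ConfigError("rho must be in (-1, 1)")
        for name, levels, probs in self.categoricals:
            if len(levels) != len(probs) or abs(sum(probs) - 1) > 1e-9:
                raise ConfigError(f"bad level probabilities for {name!r}")

    @property
    def p(self) -> int:
        return self.n_continuous + len(self.categoricals)

    def draw(self, n: int, rng: np.random.Generator) -> pd.DataFrame:
        cols = {}
        if self.n_continuous:
            cov = np.full((self.n_continuous, self.n_continuous), self.rho)
            np.fill_diagonal(cov, 1.0)
            xc = rng.multivariate_normal(
                np.zeros(self.n_continuous), cov, size=n, method="cholesky"
            )
            for i in range(self.n_continuous):
                cols[f"x{i + 1}"] = xc[:, i]
        for name, levels, probs in self.categoricals:
            cols[name] = rng.choice(levels, size=n, p=probs)
        return pd.DataFrame(cols)

    def features(self, x: pd.DataFrame) -> np.ndarray:
        """Numeric view Z: continuous columns, then categorical level codes."""
        parts = [x[f"x{i + 1}"].to_numpy(float) for i in range(self.n_continuous)]
        for name, levels, _ in self.categoricals:
            code = {lv: float(i) for i, lv in enumerate(levels)}
            parts.append(x[name].map(code).to_numpy(float))
        return np.column_stack(parts)

    def feature_moments(self) -> tuple[np.ndarray, np.ndarray]:
        """E[Z] and E[Z^2] per feature (closed form)."""
        mean = [0.0] * self.n_continuous
        second = [1.0] * self.n_continuous
        for _, levels, probs in self.categoricals:
            codes = np.arange(len(levels), dtype=float)
            probs = np.asarray(probs)
            mean.append(float((codes * probs).sum()))
            second.append(float((codes**2 * probs).sum()))
        return np.asarray(mean), np.asarray(second)


@dataclass
class MeanSurface:
    """Quadratic-in-features outcome mean: intercept + b'Z + c'Z^2."""

    intercept: float = 0.0
    linear: np.ndarray | None = None
    quadratic: np.ndarray | None = None

    def __call__(self, z: np.ndarray) -> np.ndarray:
        out = np.full(z.shape[0], self.intercept, dtype=float)
        if self.linear is not None:
            out += z @ np.asarray(self.linear, dtype=float)
        if self.quadratic is not None:
            out += (z**2) @ np.asarray(self.quadratic, dtype=float)
        return out

    def expectation(self, mean_z: np.ndarray, second_z: np.ndarray) -> float:
        val = self.intercept
        if self.linear is not None:
            val += float(np.asarray(self.linear) @ mean_z)
        if self.quadratic is not None:
            val += float(np.asarray(self.quadratic) @ second_z)
        return val


@dataclass
class SyntheticTruth:
    """Full generating mechanism with its known causal truths.

    ``family`` is ``gaussian`` (Y(t) = mu_t(Z) + Normal(0, sigma_eps))
    or ``bernoulli`` (Y(t) ~ Bernoulli(expit(mu_t(Z))), risk-difference
    mode for binary outcomes).
    """

    mu0: MeanSurface
    mu1: MeanSurface
    gamma0: float
    gamma: np.ndarray
    sigma_eps: float = 1.0
    cov_spec: CovariateSpec = field(default_factory=CovariateSpec)
    family: str = "gaussian"
    _truths: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.family not in {"gaussian", "bernoulli"}:
            raise ConfigError(f"unknown outcome family {self.family!r}")
        if self.sigma_eps < 0:
            raise ConfigError("sigma_eps must be nonnegative")
        self.gamma = np.asarray(self.gamma, dtype=float)
        if len(self.gamma) != self.cov_spec.p:
            raise ConfigError("gamma length must equal the covariate count")

    def propensity(self, z: np.ndarray) -> np.ndarray:
        return expit(self.gamma0 + z @ self.gamma)

    def _outcome_means(self, z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        m0, m1 = self.mu0(z), self.mu1(z)
        if self.family == "bernoulli":
            return expit(m0), expit(m1)
        return m0, m1

    def true_ate(self) -> float:
        """E[mu_1(Z) - mu_0(Z)]: closed form for Gaussian outcomes with
        polynomial means, Monte Carlo (10^6 draws) otherwise."""
        if "ate" not in self._truths:
            if self.family == "gaussian":
                mean_z, second_z = self.cov_spec.feature_moments()
                self._truths["ate"] = self.mu1.expectation(
                    mean_z, second_z
                ) - self.mu0.expectation(mean_z, second_z)
                self._truths["ate_mc_se"] = 0.0
            else:
                rng = np.random.default_rng(_TRUTH_SEED)
                z = self.cov_spec.features(self.cov_spec.draw(_TRUTH_DRAWS, rng))
                m0, m1 = self._outcome_means(z)
                diff = m1 - m0
                self._truths["ate"] = float(diff.mean())
                self._truths["ate_mc_se"] = float(diff.std() / np.sqrt(len(diff)))
        return self._truths["ate"]

    def true_att(self) -> float:
        """E[mu_1 - mu_0 | T = 1] = E[e(Z)(mu_1 - mu_0)] / E[e(Z)], by
        Monte Carlo with 10^6 draws (standard error recorded)."""
        if "att" not in self._truths:
            rng = np.random.default_rng(_TRUTH_SEED + 1)
            z = self.cov_spec.features(self.cov_spec.draw(_TRUTH_DRAWS, rng))
            e = self.propensity(z)
            m0, m1 = self._outcome_means(z)
            num = e * (m1 - m0)
            att = float(num.mean() / e.mean())
            self._truths["att"] = att
            self._truths["att_mc_se"] = float(
                np.std(num - att * e) / (e.mean() * np.sqrt(len(e)))
            )
        return self._truths["att"]


def generate(truth: SyntheticTruth, n: int, seed: int = 0) -> Dataset:
    """Draw a fully reproducible observational sample of size ``n``.

    The returned :class:`~coarsecause.data.Dataset` carries ``true_ate``
    and ``true_att`` so estimates can be scored. Retries the treatment
    draw until both arms are occupied (logged when it happens).
    """
    if n < 2:
        raise ConfigError("n must be >= 2")
    rng = np.random.default_rng(seed)
    x = truth.cov_spec.draw(n, rng)
    z = truth.cov_spec.features(x)
    e = truth.propensity(z)
    if np.any(e <= 0) or np.any(e >= 1):
        logger.warning("propensity hit 0 or 1 numerically; positivity at risk")
    t = rng.binomial(1, e)
    tries = 0
    while t.sum() in (0, n):
        tries += 1
        if tries > 100:
            raise ConfigError("could not occupy both treatment arms")
        t = rng.binomial(1, e)
    if tries:
        logger.info("redrew treatment %d time(s) to occupy both arms", tries)
    if truth.family == "gaussian":
        y0 = truth.mu0(z) + rng.normal(0, truth.sigma_eps, size=n)
        y1 = truth.mu1(z) + rng.normal(0, truth.sigma_eps, size=n)
    else:
        p0, p1 = truth._outcome_means(z)
        y0 = rng.binomial(1, p0).astype(float)
        y1 = rng.binomial(1, p1).astype(float)
    y = (1 - t) * y0 + t * y1
    return Dataset(
        y=y, t=t, x=x, true_ate=truth.true_ate(), true_att=truth.true_att()
    )


def _linear_truth(effect_intercept, effect_x1, gamma=(0.15, 0.15)) -> SyntheticTruth:
    return SyntheticTruth(
        mu0=MeanSurface(0.0, np.array([1.0, 1.0])),
        mu1=MeanSurface(effect_intercept, np.array([1.0 + effect_x1, 1.0])),
        gamma0=0.0,
        gamma=np.asarray(gamma),
        sigma_eps=1.0,
        cov_spec=CovariateSpec(n_continuous=2),
    )


def _scenarios() -> dict[str, SyntheticTruth]:
    curved = SyntheticTruth(
        mu0=MeanSurface(0.0, np.array([1.0]), np.array([1.0])),
        mu1=MeanSurface(2.0, np.array([1.0]), np.array([1.0])),
        gamma0=0.0,
        gamma=np.array([1.5]),
        sigma_eps=1.0,
        cov_spec=CovariateSpec(n_continuous=1),
    )
    discrete = SyntheticTruth(
        mu0=MeanSurface(-1.0, np.array([0.6, 0.8, 0.5, 0.3])),
        mu1=MeanSurface(-0.6, np.array([0.6, 0.8, 0.5, 0.3])),
        gamma0=-0.5,
        gamma=np.array([0.7, 0.9, 0.6, 0.2]),
        sigma_eps=0.0,
        family="bernoulli",
        cov_spec=CovariateSpec(
            n_continuous=0,
            categoricals=[
                ("nulliparous", ["no", "yes"], [0.55, 0.45]),
                ("arrest", ["no", "yes"], [0.8, 0.2]),
                ("malpresentation", ["no", "yes"], [0.9, 0.1]),
                ("late_period", ["no", "yes"], [0.5, 0.5]),
            ],
        ),
    )
    return {
        "null": _linear_truth(0.0, 0.0),
        "constant": SyntheticTruth(
            mu0=MeanSurface(0.0, np.array([1.0, 1.0])),
            mu1=MeanSurface(2.0, np.array([1.0, 1.0])),
            gamma0=0.0,
            gamma=np.array([0.5, 0.5]),
            cov_spec=CovariateSpec(n_continuous=2),
        ),
        "linear": _linear_truth(1.0, 0.5),
        "curved": curved,
        "discrete": discrete,
    }


SCENARIOS = _scenarios()


@dataclass
class SimulationReport:
    """Replicated performance summary per method x scenario."""

    table: pd.DataFrame
    n_reps: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "table": self.table.to_dict(orient="records"),
            "n_reps": self.n_reps,
            "seed": self.seed,
        }


def _build(dataset: Dataset, method: str, k: int, seed: int, config: RunConfig):
    if method == "kmeans":
        return kmeans_strata(dataset.x, k=k, seed=seed, standardize=config.standardize)
    if method == "rf":
        return rf_proximity_strata(dataset.x, k=k, n_trees=config.rf_trees, seed=seed)
    if method == "cem":
        return cem_coarsen(
            dataset.x, CoarseningSpec.default(dataset.x, bins=config.k_or_bins)
        )
    raise ConfigError(f"unknown method {method!r}")


def simulate_performance(
    scenarios,
    methods,
    n: int,
    n_reps: int,
    seed: int = 0,
    k: int = 50,
    estimand: str = "ate",
    alpha: float = 0.05,
    config: RunConfig | None = None,
) -> SimulationReport:
    """Replicated generate -> stratify -> estimate loop.

    Scores each method on each scenario against the generator's known
    truth: mean bias, RMSE, empirical SE of the estimates, mean estimated
    SE, CI coverage, and mean realized strata count. Seed streams are
    spawned per replicate from the master seed, so the report is
    deterministic given ``seed``.
    """
    if n_reps < 2:
        raise ConfigError("n_reps must be >= 2")
    if isinstance(scenarios, str):
        scenarios = [scenarios]
    if isinstance(methods, str):
        methods = [methods]
    named = {name: SCENARIOS[name] if isinstance(name, str) else name
             for name in scenarios}
    if config is None:
        config = RunConfig(estimand=estimand, alpha=alpha, k_or_bins=None)
    estimate = ate_estimate if estimand == "ate" else att_estimate

    rows = []
    for scen_name, truth in named.items():
        truth_val = truth.true_ate() if estimand == "ate" else truth.true_att()
        rep_seeds = np.random.SeedSequence(seed).generate_state(2 * n_reps) % (2**31)
        for method in methods:
            taus, ses, covered, j_used = [], [], [], []
            failures = 0
            for rep in range(n_reps):
                data_seed = int(rep_seeds[2 * rep])
                strat_seed = int(rep_seeds[2 * rep + 1])
                data = generate(truth, n=n, seed=data_seed)
                try:
                    assignment = _build(data, method, k, strat_seed, config)
                    pruned = prune_strata(assignment, data.t, config.min_per_arm)
                    est = estimate(data, pruned, alpha)
                except Exception:  # noqa: BLE001 — a failed replicate is data
                    failures += 1
                    continue
                taus.append(est.tau_hat)
                ses.append(est.se)
                covered.append(est.ci[0] <= truth_val <= est.ci[1])
                j_used.append(pruned.J_used)
            if not taus:
                raise ConfigError(
                    f"every replicate failed for {method} on {scen_name}"
                )
            taus = np.asarray(taus)
            rows.append(
                {
                    "scenario": scen_name,
                    "method": method,
                    "estimand": estimand,
                    "truth": truth_val,
                    "bias": float(taus.mean() - truth_val),
                    "rmse": float(np.sqrt(((taus - truth_val) ** 2).mean())),
                    "empirical_se": float(taus.std(ddof=1)),
                    "mean_estimated_se": float(np.mean(ses)),
                    "coverage": float(np.mean(covered)),
                    "mean_J_used": float(np.mean(j_used)),
                    "n": n,
                    "reps_used": len(taus),
                    "failures": failures,
                }
            )
    return SimulationReport(table=pd.DataFrame(rows), n_reps=n_reps, seed=seed)
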