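"""Stratified causal effect estimators and diagnostics.

Given strata built from covariates alone, the average treatment effect is
estimated by the stratum-weighted contrast of arm means

    tau_hat = sum_j (n_j / n) * (ybar_1j - ybar_0j)

with estimated variance

    var_hat = sum_j (n_j / n)^2 * (s2_1j / n_1j + s2_0j / n_0j),

where ``s2_tj`` is the unbiased sample variance of the outcome in arm
``t`` of stratum ``j``. The effect on the treated replaces the control
mean by ``w_j * ybar_0j`` with the odds weight
``w_j = (n_1j / n_1) / (n_0j / n_0)`` and squares ``w_j`` in the control
variance term. Strata lacking either arm are pruned first, restricting
the estimand to the retained subpopulation (the matched sample).

An independently coded estimating-equation solver is provided as an
oracle: the same point estimate arises as the root of the per-unit score

    U(tau) = sum_i sum_j I(i in S_j) (n_j/n) (T_i Y_i / n_1j
             - (1 - T_i) Y_i / n_0j) - tau.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .builders import StrataAssignment
from .data import Dataset
from .errors import ConfigError, EstimationImpossibleError, StrataError

logger = logging.getLogger("coarsecause")

__all__ = [
    "PrunedStrata",
    "EffectEstimate",
    "prune_strata",
    "ate_estimate",
    "att_estimate",
    "estimating_equation_root",
    "wald_inference",
    "l1_imbalance",
]


@dataclass
class PrunedStrata:
    """Result of dropping strata that cannot support a within-stratum contrast."""

    retained: list[int]
    dropped: list[tuple[int, str]]
    n_used: int
    assignment: StrataAssignment
    min_per_arm: int = 1

    @property
    def J_used(self) -> int:
        return len(self.retained)

    @property
    def n_dropped(self) -> int:
        return self.assignment.n - self.n_used


@dataclass
class EffectEstimate:
    """Point estimate, variance, Wald inference, and per-stratum audit table."""

    estimand: str
    tau_hat: float
    var_hat: float
    se: float
    z: float
    p_value: float
    ci: tuple[float, float]
    alpha: float
    J_used: int
    n_used: int
    n_dropped: int
    dropped_strata: list[tuple[int, str]] = field(default_factory=list)
    strata_table: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        d = {
            "estimand": self.estimand,
            "tau_hat": self.tau_hat,
            "var_hat": self.var_hat,
            "se": self.se,
            "z": self.z,
            "p_value": self.p_value,
            "ci": list(self.ci),
            "alpha": self.alpha,
            "J_used": self.J_used,
            "n_used": self.n_used,
            "n_dropped": self.n_dropped,
            "dropped_strata": [list(pair) for pair in self.dropped_strata],
        }
        if self.strata_table is not None:
            d["strata_table"] = self.strata_table.to_dict(orient="list")
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "EffectEstimate":
        table = d.get("strata_table")
        return cls(
            estimand=d["estimand"],
            tau_hat=d["tau_hat"],
            var_hat=d["var_hat"],
            se=d["se"],
            z=d["z"],
            p_value=d["p_value"],
            ci=tuple(d["ci"]),
            alpha=d["alpha"],
            J_used=d["J_used"],
            n_used=d["n_used"],
            n_dropped=d["n_dropped"],
            dropped_strata=[tuple(pair) for pair in d["dropped_strata"]],
            strata_table=pd.DataFrame(table) if table is not None else None,
        )


def prune_strata(
    assignment: StrataAssignment, t: np.ndarray, min_per_arm: int = 1
) -> PrunedStrata:
    """Drop strata that contain fewer than ``min_per_arm`` units in either arm.

    Reasons recorded per dropped stratum: ``no_treated``, ``no_control``,
    or ``below_min_per_arm``. Raises
    :class:`~coarsecause.errors.EstimationImpossibleError` when nothing
    survives.
    """
    if min_per_arm < 1:
        raise ConfigError("min_per_arm must be >= 1")
    counts = assignment.attach_treatment(t)
    retained, dropped = [], []
    for row in counts.itertuples(index=False):
        if row.n_1j == 0:
            dropped.append((int(row.stratum), "no_treated"))
        elif row.n_0j == 0:
            dropped.append((int(row.stratum), "no_control"))
        elif row.n_1j < min_per_arm or row.n_0j < min_per_arm:
            dropped.append((int(row.stratum), "below_min_per_arm"))
        else:
            retained.append(int(row.stratum))
    if not retained:
        raise EstimationImpossibleError(
            "no stratum retains both treatment arms; cannot estimate"
        )
    n_used = int(counts.set_index("stratum").loc[retained, "n_j"].sum())
    if dropped:
        frac = 1 - n_used / assignment.n
        logger.warning(
            "pruned %d of %d strata (%.1f%% of units discarded); the estimand "
            "is restricted to the retained subpopulation",
            len(dropped), assignment.J, 100 * frac,
        )
    return PrunedStrata(
        retained=retained,
        dropped=dropped,
        n_used=n_used,
        assignment=assignment,
        min_per_arm=min_per_arm,
    )


def _stratum_stats(dataset: Dataset, pruned: PrunedStrata) -> pd.DataFrame:
    """Per-retained-stratum arm sizes, means and unbiased variances.

    A singleton arm (one unit) has no within-arm variance of its own; it
    borrows the pooled within-arm sample variance across retained strata so
    the variance formula stays computable, and a warning recommends
    ``min_per_arm = 2``.
    """
    labels = pruned.assignment.labels
    tab = pd.DataFrame({"stratum": labels, "t": dataset.t, "y": dataset.y})
    tab = tab[tab["stratum"].isin(pruned.retained)]
    rows = []
    for j, grp in tab.groupby("stratum"):
        y1 = grp.loc[grp["t"] == 1, "y"].to_numpy()
        y0 = grp.loc[grp["t"] == 0, "y"].to_numpy()
        if len(y1) == 0 or len(y0) == 0:
            raise StrataError(f"retained stratum {j} has an empty arm")
        rows.append(
            {
                "stratum": int(j),
                "n_j": len(grp),
                "n_1j": len(y1),
                "n_0j": len(y0),
                "ybar_1j": float(y1.mean()),
                "ybar_0j": float(y0.mean()),
                "s2_1j": float(y1.var(ddof=1)) if len(y1) > 1 else np.nan,
                "s2_0j": float(y0.var(ddof=1)) if len(y0) > 1 else np.nan,
            }
        )
    stats_tab = pd.DataFrame(rows)
    for arm in ("1", "0"):
        col = f"s2_{arm}j"
        n_col = f"n_{arm}j"
        if stats_tab[col].isna().any():
            ok = stats_tab[col].notna()
            dof = (stats_tab.loc[ok, n_col] - 1).sum()
            pooled = (
                float(
                    (stats_tab.loc[ok, col] * (stats_tab.loc[ok, n_col] - 1)).sum()
                    / dof
                )
                if dof > 0
                else 0.0
            )
            logger.warning(
                "singleton arm(s) in %d stratum/strata (arm %s): substituting the "
                "pooled within-arm variance %.4g; consider min_per_arm=2",
                int((~ok).sum()), arm, pooled,
            )
            stats_tab.loc[~ok, col] = pooled
    return stats_tab


def wald_inference(
    tau_hat: float, se: float, alpha: float = 0.05
) -> tuple[float, float, tuple[float, float]]:
    """Normal-theory z statistic, two-sided p-value, and (1 - alpha) CI.

    ``se = 0`` yields a degenerate CI at the point estimate with p-value 1
    when the estimate is 0 and 0 otherwise.
    """
    if se < 0:
        raise ConfigError("standard error must be nonnegative")
    if not 0 < alpha < 1:
        raise ConfigError("alpha must be in (0, 1)")
    if se == 0:
        return (0.0 if tau_hat == 0 else np.inf * np.sign(tau_hat),
                1.0 if tau_hat == 0 else 0.0,
                (tau_hat, tau_hat))
    z = tau_hat / se
    p = 2 * stats.norm.sf(abs(z))
    half = stats.norm.ppf(1 - alpha / 2) * se
    return float(z), float(p), (float(tau_hat - half), float(tau_hat + half))


def _assemble(
    estimand: str,
    tau: float,
    var: float,
    alpha: float,
    pruned: PrunedStrata,
    table: pd.DataFrame,
) -> EffectEstimate:
    var = max(float(var), 0.0)
    se = float(np.sqrt(var))
    z, p, ci = wald_inference(tau, se, alpha)
    return EffectEstimate(
        estimand=estimand,
        tau_hat=float(tau),
        var_hat=var,
        se=se,
        z=z,
        p_value=p,
        ci=ci,
        alpha=alpha,
        J_used=pruned.J_used,
        n_used=pruned.n_used,
        n_dropped=pruned.n_dropped,
        dropped_strata=pruned.dropped,
        strata_table=table,
    )


def ate_estimate(
    dataset: Dataset, pruned: PrunedStrata, alpha: float = 0.05
) -> EffectEstimate:
    """Stratified average-treatment-effect estimate with Wald inference.

    Weights are ``n_j / n`` with ``n`` the retained-strata total, so they
    sum to one and the estimand is the average effect on the retained
    subpopulation.
    """
    tab = _stratum_stats(dataset, pruned)
    w = tab["n_j"] / pruned.n_used
    tau = float((w * (tab["ybar_1j"] - tab["ybar_0j"])).sum())
    var = float(
        (w**2 * (tab["s2_1j"] / tab["n_1j"] + tab["s2_0j"] / tab["n_0j"])).sum()
    )
    tab = tab.assign(weight=w.to_numpy())
    return _assemble("ate", tau, var, alpha, pruned, tab)


def att_estimate(
    dataset: Dataset, pruned: PrunedStrata, alpha: float = 0.05
) -> EffectEstimate:
    """Average effect on the treated via odds weights ``w_j``.

    ``w_j = (n_1j / n_1) / (n_0j / n_0)`` compares each stratum's treated
    share to its control share; when treatment prevalence is constant
    across strata every ``w_j`` is one and the estimate coincides with the
    plain stratified estimator. Control-arm variances enter with ``w_j^2``.
    Strata without controls are already pruned (the estimand is restricted
    rather than extrapolated).
    """
    tab = _stratum_stats(dataset, pruned)
    n1, n0 = int(tab["n_1j"].sum()), int(tab["n_0j"].sum())
    w = tab["n_j"] / pruned.n_used
    wj = (tab["n_1j"] / n1) / (tab["n_0j"] / n0)
    tau = float((w * (tab["ybar_1j"] - wj * tab["ybar_0j"])).sum())
    var = float(
        (w**2 * (tab["s2_1j"] / tab["n_1j"] + wj**2 * tab["s2_0j"] / tab["n_0j"])).sum()
    )
    tab = tab.assign(weight=w.to_numpy(), w_j=wj.to_numpy())
    return _assemble("att", tau, var, alpha, pruned, tab)


def estimating_equation_root(dataset: Dataset, pruned: PrunedStrata) -> float:
    """Root of the per-unit estimating equation — an oracle for the ATE.

    Deliberately computed through a different code path than
    :func:`ate_estimate`: per-unit score accumulation and a bracketed
    root-find rather than grouped means.
    """
    labels = pruned.assignment.labels
    keep = np.isin(labels, pruned.retained)
    y, t, lab = dataset.y[keep], dataset.t[keep], labels[keep]
    n = keep.sum()
    n1 = {j: int(((lab == j) & (t == 1)).sum()) for j in pruned.retained}
    n0 = {j: int(((lab == j) & (t == 0)).sum()) for j in pruned.retained}
    nj = {j: int((lab == j).sum()) for j in pruned.retained}

    def score(tau: float) -> float:
        total = 0.0
        for yi, ti, j in zip(y, t, lab):
            share = nj[j] / n
            total += share * (ti * yi / n1[j] - (1 - ti) * yi / n0[j])
        return total - tau

    s0 = score(0.0)
    return float(optimize.brentq(score, s0 - 1.0, s0 + 1.0))


def l1_imbalance(assignment: StrataAssignment, t: np.ndarray) -> float:
    """L1 covariate-balance statistic over all strata of the assignment.

    Half the summed absolute difference between the treated and control
    stratum proportions: 0 means the arms are distributed identically
    across strata (perfect balance), 1 means every stratum is pure (the
    arms never share a stratum). Computed on the unpruned assignment.
    """
    t = np.asarray(t, dtype=int).ravel()
    counts = assignment.attach_treatment(t)
    n1 = counts["n_1j"].sum()
    n0 = counts["n_0j"].sum()
    if n1 == 0 or n0 == 0:
        raise EstimationImpossibleError("an arm is empty overall")
    return float(0.5 * np.abs(counts["n_1j"] / n1 - counts["n_0j"] / n0).sum())
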