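"""Log-rank testing, maximally selected cutpoints and Cox PH modelling.

A continuous abundance score (e.g. the within-fibroblast percentage of a
subpopulation) is dichotomised by sweeping every admissible cutpoint and
recording the signed standardized log-rank statistic ``U / sqrt(Var)``; the
optimal cutpoint maximizes its absolute value. The sweep is returned
uncorrected — significance of a chosen cutpoint should be assessed on
independent validation cohorts, mirroring a test/validation design.
Multivariable Cox proportional-hazards models (Efron or Breslow ties,
optional administrative censoring horizon) adjust the dichotomised or
continuous score for clinical covariates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "logrank_statistic",
    "logrank_test",
    "cutpoint_sweep",
    "cox_ph",
    "CutpointResult",
    "apply_horizon",
]


def _check_records(time, event) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    if (t <= 0).any():
        raise ValueError("survival times must be > 0")
    if not np.isin(e, [0, 1]).all():
        raise ValueError("event indicator must be 0/1")
    return t, e


def logrank_statistic(time, event, group) -> tuple[float, float]:
    """Signed two-group log-rank score U and its variance.

    At each distinct event time the observed number of events in group 1 is
    compared with its hypergeometric expectation given the risk sets;
    U sums observed - expected and Var the hypergeometric variances.
    """
    t, e = _check_records(time, event)
    g = np.asarray(group).astype(bool)
    if g.all() or not g.any():
        raise ValueError("both groups must be non-empty")
    if e.sum() == 0:
        raise ValueError("no events observed")

    order = np.argsort(t, kind="stable")
    t, e, g = t[order], e[order], g[order]
    event_times = np.unique(t[e == 1])
    U = 0.0
    V = 0.0
    for et in event_times:
        at_risk = t >= et
        n = at_risk.sum()
        n1 = (at_risk & g).sum()
        d = ((t == et) & (e == 1)).sum()
        d1 = ((t == et) & (e == 1) & g).sum()
        U += d1 - d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return float(U), float(V)


def logrank_test(time, event, group) -> tuple[float, float]:
    """Two-group log-rank test: (chi2, p) with 1 degree of freedom."""
    U, V = logrank_statistic(time, event, group)
    if V == 0:
        return 0.0, 1.0
    chi2 = U * U / V
    return chi2, float(stats.chi2.sf(chi2, 1))


@dataclass
class CutpointResult:
    """Full cutpoint sweep plus the maximally selected cutpoint."""

    table: pd.DataFrame  # cutpoint, n_high, n_low, statistic (signed standardized)
    optimal_cutpoint: float
    optimal_statistic: float
    min_prop: float

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def cutpoint_sweep(
    time, event, score, min_prop: float = 0.1
) -> CutpointResult:
    """Standardized log-rank statistic at every admissible dichotomisation.

    Candidates are the distinct score values whose induced split
    (``score > cutpoint`` vs the rest) keeps both groups at least
    ``min_prop`` of subjects. The optimal cutpoint maximizes the absolute
    standardized statistic ``U / sqrt(Var)``. No multiplicity correction is
    applied to the maximally selected statistic.
    """
    t, e = _check_records(time, event)
    s = np.asarray(score, dtype=float)
    n = len(s)
    if n < 20:
        raise ValueError("need >= 20 subjects for a cutpoint sweep")
    if np.ptp(s) == 0:
        raise ValueError("score is constant")
    if e.sum() == 0:
        raise ValueError("no events observed")
    cands = np.array(
        [
            c
            for c in np.unique(s)
            if min_prop * n <= (s > c).sum() <= (1 - min_prop) * n
        ]
    )
    if cands.size == 0:
        raise ValueError(f"no cutpoint keeps both groups above min_prop={min_prop}")
    # joint tabulation over (event time, candidate): n1 and d1 via matrix
    # products against the high-group indicators
    et = np.unique(t[e == 1])
    at_risk = t[:, None] >= et[None, :]  # n x m
    ev_at = (t[:, None] == et[None, :]) & (e[:, None] == 1)
    high = s[:, None] > cands[None, :]  # n x C
    n_risk = at_risk.sum(axis=0).astype(float)  # m
    d = ev_at.sum(axis=0).astype(float)  # m
    n1 = at_risk.T.astype(float) @ high  # m x C
    d1 = ev_at.T.astype(float) @ high  # m x C
    frac = n1 / n_risk[:, None]
    U = (d1 - d[:, None] * frac).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        vterm = d[:, None] * frac * (1 - frac) * ((n_risk - d) / np.maximum(n_risk - 1, 1))[:, None]
    V = vterm.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = np.where(V > 0, U / np.sqrt(V), 0.0)
    table = pd.DataFrame(
        {
            "cutpoint": cands,
            "n_high": (s[:, None] > cands[None, :]).sum(axis=0),
            "n_low": n - (s[:, None] > cands[None, :]).sum(axis=0),
            "statistic": stat,
        }
    )
    best = table.loc[table["statistic"].abs().idxmax()]
    return CutpointResult(
        table=table,
        optimal_cutpoint=float(best["cutpoint"]),
        optimal_statistic=float(best["statistic"]),
        min_prop=min_prop,
    )


def apply_horizon(records: pd.DataFrame, horizon_months: float,
                  time_col: str = "time_months", event_col: str = "event") -> pd.DataFrame:
    """Administratively censor all follow-up at a horizon (e.g. 48 months)."""
    out = records.copy()
    over = out[time_col] > horizon_months
    out.loc[over, event_col] = 0
    out.loc[over, time_col] = horizon_months
    return out


def cox_ph(
    records: pd.DataFrame,
    covariates: list[str],
    time_col: str = "time_months",
    event_col: str = "event",
    ties: str = "efron",
    horizon_months: float | None = None,
) -> pd.DataFrame:
    """Cox proportional-hazards fit via the partial likelihood.

    Maximizes the Efron- or Breslow-corrected partial likelihood (Newton
    iterations, as implemented in statsmodels' proportional-hazards
    regression). If ``horizon_months`` is given, follow-up is
    administratively censored there first. Returns one row per covariate
    with coefficient, HR, 95% Wald CI and p.
    """
    import statsmodels.api as sm

    if ties not in {"efron", "breslow"}:
        raise ValueError("ties must be 'efron' or 'breslow'")
    df = records
    if horizon_months is not None:
        df = apply_horizon(df, horizon_months, time_col, event_col)
    X = df[covariates].astype(float)
    const = [c for c in covariates if X[c].nunique() <= 1]
    if const:
        raise ValueError(f"constant covariates: {const}")
    n_events = int(df[event_col].sum())
    if n_events < 5 * len(covariates):
        warnings.warn(
            f"only {n_events} events for {len(covariates)} covariates", stacklevel=2
        )
    model = sm.PHReg(
        df[time_col].to_numpy(),
        X.to_numpy(),
        status=df[event_col].to_numpy(),
        ties=ties,
    )
    try:
        fit = model.fit(maxiter=100)
    except Exception as err:  # pragma: no cover - backend-specific failures
        raise RuntimeError(f"Cox PH fit failed: {err}") from err
    coef = fit.params
    if not np.isfinite(coef).all() or np.abs(coef).max() > 50:
        raise RuntimeError("monotone likelihood (perfect separation?) in Cox PH fit")
    se = fit.bse
    out = pd.DataFrame(
        {
            "covariate": covariates,
            "coef": coef,
            "HR": np.exp(coef),
            "ci_lower": np.exp(coef - 1.96 * se),
            "ci_upper": np.exp(coef + 1.96 * se),
            "se": se,
            "p": fit.pvalues,
        }
    ).set_index("covariate")
    out.attrs["ties"] = ties
    out.attrs["horizon_months"] = horizon_months
    out.attrs["n_events"] = n_events
    return out
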