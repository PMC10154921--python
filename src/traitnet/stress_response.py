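"""Effect sizes of enrichment on network metrics, t-tests, and
quantile-regression assessment of variance convergence.

The treatment effect size of a metric at a site is the treatment value
divided by the control value — dimensionless, with values below 1 meaning
the metric was reduced by enrichment. Effect sizes are joined to the site's
*baseline network complexity* (control mean node eigencentrality), and the
analysis asks two questions:

1. directional: are effect sizes shifted away from 1 (one-sample t-test
   against 1), and do the medium and high enrichment levels differ
   (two-sample t-test)?
2. variance: does the spread of effect sizes shrink as baseline complexity
   grows? Linear quantile regressions of effect size on baseline
   complexity are fitted at taus 0.1 … 0.9, and the predicted 90th–10th
   inter-quantile spread is compared between the low and high end of the
   complexity range: a positive spread difference means the quantile lines
   converge — the signature of more predictable responses in complex
   networks.

Quantile fits minimize the pinball (check) loss exactly, via the standard
linear-programming formulation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

#: The four count metrics whose treatment response is analysed.
COUNT_METRICS = ["n_nodes", "n_connections", "n_reg_rece", "n_reg_rese"]

#: Default quantile levels: 10th to 90th, every 10th.
DEFAULT_TAUS = tuple(np.round(np.arange(0.1, 0.95, 0.1), 10))


class StressResponseError(ValueError):
    """Raised on malformed stress-response inputs."""


# ---------------------------------------------------------------------------
# Effect sizes


def effect_sizes(
    metrics: pd.DataFrame, metric_names: Sequence[str] = COUNT_METRICS
) -> pd.DataFrame:
    """Per-site treatment/control ratios for each metric.

    Input: the metrics table (one row per site-treatment, including a
    control row per site). Output: one row per site x {medium, high} x
    metric with columns ``site, level, metric, effect,
    baseline_complexity``. Sites where the control metric is 0 yield an
    undefined (NaN) effect, logged and excluded from downstream tests.
    """
    required = {"site", "treatment", "mean_eigencentrality", *metric_names}
    missing = required - set(metrics.columns)
    if missing:
        raise StressResponseError(f"metrics table missing columns: {sorted(missing)}")
    rows = []
    for site, grp in metrics.groupby("site", sort=True):
        by_tr = grp.set_index("treatment")
        if "control" not in by_tr.index:
            raise StressResponseError(f"site {site!r} has no control row")
        control = by_tr.loc["control"]
        baseline = float(control["mean_eigencentrality"])
        for level in ("medium", "high"):
            if level not in by_tr.index:
                continue
            treat = by_tr.loc[level]
            for name in metric_names:
                c = float(control[name])
                if c == 0:
                    logger.warning(
                        "site %r metric %s: control value 0, effect size "
                        "undefined and excluded", site, name,
                    )
                    eff = np.nan
                else:
                    eff = float(treat[name]) / c
                rows.append({
                    "site": site, "level": level, "metric": name,
                    "effect": eff, "baseline_complexity": baseline,
                })
    return pd.DataFrame(
        rows, columns=["site", "level", "metric", "effect", "baseline_complexity"]
    )


# ---------------------------------------------------------------------------
# t-tests


def one_sample_t(values: Sequence[float], mu: float = 1.0) -> tuple[float, float]:
    """Two-sided one-sample t-test of mean(values) against ``mu``.

    t = (mean - mu) / (sd / sqrt(n)) with the sample standard deviation
    (n - 1 denominator); p from Student's t with n - 1 degrees of freedom.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    n = x.size
    if n < 2:
        raise StressResponseError("one-sample t-test needs at least 2 values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise StressResponseError("one-sample t-test undefined for zero variance")
    t = (x.mean() - mu) / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return float(t), float(p)


def two_sample_t(
    a: Sequence[float], b: Sequence[float], equal_var: bool = False
) -> tuple[float, float]:
    """Two-sided two-sample t-test; Welch (unequal variance) by default.

    Welch: t = (mean_a - mean_b) / sqrt(s_a^2/n_a + s_b^2/n_b) with
    Welch–Satterthwaite degrees of freedom. ``equal_var=True`` switches to
    the pooled-variance form.
    """
    xa = np.asarray(a, dtype=float)
    xb = np.asarray(b, dtype=float)
    xa, xb = xa[~np.isnan(xa)], xb[~np.isnan(xb)]
    na, nb = xa.size, xb.size
    if na < 2 or nb < 2:
        raise StressResponseError("two-sample t-test needs >= 2 values per sample")
    va, vb = xa.var(ddof=1), xb.var(ddof=1)
    if va == 0 and vb == 0 and xa.mean() == xb.mean():
        raise StressResponseError("both samples constant and equal; t undefined")
    if va == 0 and vb == 0:
        # constant samples with different means: infinitely strong evidence
        t = math.inf if xa.mean() > xb.mean() else -math.inf
        return t, 0.0
    if equal_var:
        df = na + nb - 2
        sp2 = ((na - 1) * va + (nb - 1) * vb) / df
        se = np.sqrt(sp2 * (1 / na + 1 / nb))
    else:
        se2a, se2b = va / na, vb / nb
        se = np.sqrt(se2a + se2b)
        df = (se2a + se2b) ** 2 / (
            se2a**2 / (na - 1) + se2b**2 / (nb - 1)
        )
    t = (xa.mean() - xb.mean()) / se
    p = 2.0 * stats.t.sf(abs(t), df=df)
    return float(t), float(p)


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (step-up FDR)."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(ranked, 1.0)
    return adj


def metric_tests(
    effects: pd.DataFrame,
    mu: float = 1.0,
    equal_var: bool = False,
    fdr: bool = False,
) -> pd.DataFrame:
    """t-tests on effect sizes, per metric.

    For each metric: one-sample tests of the medium and high effect sizes
    against 1, and a Welch two-sample test medium vs high. Undefined
    effects (NaN) are excluded; a test that is itself undefined (too few
    values, zero variance) is reported with NaN statistics and logged.
    No multiple-testing correction by default; ``fdr=True`` appends
    Benjamini–Hochberg adjusted p-values.
    """

    def attempt(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except StressResponseError as exc:
            logger.warning("test undefined: %s", exc)
            return (np.nan, np.nan)

    rows = []
    for metric, grp in effects.groupby("metric", sort=True):
        med = grp.loc[grp["level"] == "medium", "effect"].dropna()
        high = grp.loc[grp["level"] == "high", "effect"].dropna()
        for level, vals in (("medium", med), ("high", high)):
            t, p = attempt(one_sample_t, vals, mu=mu)
            rows.append({
                "metric": metric, "test": f"{level}_vs_control",
                "t": t, "p": p, "n": len(vals),
            })
        t, p = attempt(two_sample_t, med, high, equal_var=equal_var)
        rows.append({
            "metric": metric, "test": "medium_vs_high",
            "t": t, "p": p, "n": len(med) + len(high),
        })
    out = pd.DataFrame(rows)
    if fdr:
        p = out["p"].to_numpy()
        adj = np.full_like(p, np.nan)
        finite = np.isfinite(p)
        if finite.any():
            adj[finite] = benjamini_hochberg(p[finite])
        out["p_adj"] = adj
    return out


# ---------------------------------------------------------------------------
# Quantile regression


@dataclass(frozen=True)
class QuantileFit:
    """A linear quantile-regression fit y ≈ intercept + slope * x at level tau."""

    tau: float
    intercept: float
    slope: float
    loss: float

    def predict(self, x) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=float)


def pinball_loss(y: np.ndarray, pred: np.ndarray, tau: float) -> float:
    """Check loss: tau * positive residuals + (1 - tau) * negative residuals."""
    r = np.asarray(y, dtype=float) - np.asarray(pred, dtype=float)
    return float(np.sum(np.where(r >= 0, tau * r, (tau - 1) * r)))


def quantile_fit(x: Sequence[float], y: Sequence[float], tau: float) -> QuantileFit:
    """Exact linear quantile regression by linear programming.

    Minimizes sum_i rho_tau(y_i - a - b x_i) over (a, b), where
    rho_tau(r) = r (tau - 1[r < 0]). Variables split residuals into
    positive/negative parts; solved with the HiGHS simplex, whose vertex
    solution passes through data points. With ties the minimizer may be
    non-unique; only loss optimality is guaranteed.
    """
    if not 0 < tau < 1:
        raise StressResponseError("tau must lie strictly within (0, 1)")
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    keep = ~(np.isnan(xv) | np.isnan(yv))
    xv, yv = xv[keep], yv[keep]
    n = xv.size
    if n < 3:
        raise StressResponseError("quantile regression needs at least 3 points")
    if np.all(xv == xv[0]):
        raise StressResponseError("degenerate predictor: all x values equal")
    # variables: a+, a-, b+, b-, u (n), v (n); y - a - b x = u - v
    c = np.concatenate([[0, 0, 0, 0], np.full(n, tau), np.full(n, 1 - tau)])
    a_eq = np.zeros((n, 4 + 2 * n))
    a_eq[:, 0] = 1.0
    a_eq[:, 1] = -1.0
    a_eq[:, 2] = xv
    a_eq[:, 3] = -xv
    a_eq[:, 4:4 + n] = np.eye(n)
    a_eq[:, 4 + n:] = -np.eye(n)
    res = optimize.linprog(c, A_eq=a_eq, b_eq=yv, method="highs")
    if not res.success:  # pragma: no cover - LP on bounded data always solvable
        raise StressResponseError(f"quantile LP failed: {res.message}")
    a = res.x[0] - res.x[1]
    b = res.x[2] - res.x[3]
    return QuantileFit(
        tau=tau, intercept=float(a), slope=float(b),
        loss=pinball_loss(yv, a + b * xv, tau),
    )


def quantile_fits(
    x: Sequence[float], y: Sequence[float], taus: Sequence[float] = DEFAULT_TAUS
) -> list[QuantileFit]:
    return [quantile_fit(x, y, tau) for tau in taus]


def rearrange_predictions(
    fits: Sequence[QuantileFit], x_grid: Sequence[float]
) -> pd.DataFrame:
    """Quantile predictions on a grid, made non-crossing by monotone
    rearrangement (sorting across tau at each x). Raw fitted lines may
    cross; rearrangement is applied only at reporting time."""
    taus = [f.tau for f in fits]
    preds = np.array([f.predict(x_grid) for f in sorted(fits, key=lambda f: f.tau)])
    preds = np.sort(preds, axis=0)
    return pd.DataFrame(preds.T, index=np.asarray(x_grid), columns=sorted(taus))


@dataclass(frozen=True)
class ConvergenceSummary:
    """Inter-quantile spread of effect size at the ends of the complexity range.

    ``spread_difference`` = spread at min(x) − spread at max(x); positive
    values mean the quantile lines converge as complexity increases.
    """

    x_min: float
    x_max: float
    spread_at_min: float
    spread_at_max: float

    @property
    def spread_difference(self) -> float:
        return self.spread_at_min - self.spread_at_max


def convergence_summary(
    fits: Sequence[QuantileFit], x: Sequence[float],
    tau_low: float = 0.1, tau_high: float = 0.9,
) -> ConvergenceSummary:
    """Predicted 90th–10th quantile spread at the low and high end of x.

    Spreads are computed from the monotone-rearranged predictions so they
    are non-negative even where raw fitted lines cross.
    """
    by_tau = {round(f.tau, 10): f for f in fits}
    for tau in (round(tau_low, 10), round(tau_high, 10)):
        if tau not in by_tau:
            raise StressResponseError(f"no quantile fit at tau={tau}")
    xv = np.asarray(x, dtype=float)
    xv = xv[~np.isnan(xv)]
    x_min, x_max = float(xv.min()), float(xv.max())
    grid = rearrange_predictions(list(fits), [x_min, x_max])
    lo, hi = round(tau_low, 10), round(tau_high, 10)
    return ConvergenceSummary(
        x_min=x_min, x_max=x_max,
        spread_at_min=float(grid.loc[x_min, hi] - grid.loc[x_min, lo]),
        spread_at_max=float(grid.loc[x_max, hi] - grid.loc[x_max, lo]),
    )


def fits_to_frame(fits_by_metric: Mapping[str, Sequence[QuantileFit]]) -> pd.DataFrame:
    rows = [
        {"metric": metric, "tau": f.tau, "intercept": f.intercept,
         "slope": f.slope, "pinball_loss": f.loss}
        for metric, fits in fits_by_metric.items()
        for f in fits
    ]
    return pd.DataFrame(rows, columns=["metric", "tau", "intercept", "slope",
                                       "pinball_loss"])
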