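"""Data reduction and nonlinear least-squares fitting for transporter assays.

Implements the standard reduction of plate data (control subtraction,
vehicle normalisation, ATP-minus-AMP vesicle differences) and the three
fits used downstream:

* IC50 from a fixed-slope log-logistic inhibition curve (single free
  parameter, log10 IC50);
* Km and Vmax from the Michaelis-Menten equation, with explicit,
  user-supplied exclusion of saturation-deviant concentrations;
* Ki from a global competitive-inhibition fit over a substrate x inhibitor
  grid.

All fits are unweighted least squares on per-concentration means. Positive
parameters are fit on the log10 scale; 95% confidence intervals are Wald
intervals on the log scale back-transformed to the linear scale, which
yields the asymmetric intervals customary for IC50/Km/Ki reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .curves import michaelis_menten

__all__ = [
    "FitResult",
    "percent_activity",
    "vesicle_net_transport",
    "net_uptake_rates",
    "fit_ic50",
    "fit_mm",
    "fit_ki_competitive",
]


@dataclass
class FitResult:
    """Fitted parameters with 95% confidence intervals and diagnostics."""

    params: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    residual_sum_squares: float
    n_points: int
    excluded_points: list[float] = field(default_factory=list)
    converged: bool = True
    message: str = ""

    def __post_init__(self) -> None:
        for name, (low, high) in self.ci95.items():
            value = self.params[name]
            if not (low <= value <= high):
                raise ValueError(f"CI for {name} does not bracket the estimate")


# ---------------------------------------------------------------------------
# data reduction
# ---------------------------------------------------------------------------

def percent_activity(data: pd.DataFrame) -> pd.DataFrame:
    """Reduce a cell-assay table to percent transport activity per concentration.

    Within each experiment, the mean control-cell signal is subtracted from
    the mean transporter-cell signal at each inhibitor concentration, and the
    difference is normalised to the vehicle (0 μM) net signal, which defines
    100% activity. Per-experiment activities are then averaged across
    experiments. Values above 100% or below 0% are retained.

    The returned frame carries ``attrs["anchor_se"]``: the fractional
    standard error of the pooled 100% normalisation anchor, estimated from
    vehicle-well replicate scatter. Every activity in the table is divided
    by the same noisy vehicle mean, so this coherent scale uncertainty is
    invisible to fit residuals; :func:`fit_ic50` folds it into the
    confidence interval.
    """
    required = {"experiment_id", "cell_line", "inhibitor_conc_uM", "signal"}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")

    per_experiment = []
    anchor_vars = []
    for exp, sub in data.groupby("experiment_id"):
        means = (
            sub.groupby(["inhibitor_conc_uM", "cell_line"])["signal"].mean().unstack()
        )
        if "transporter" not in means.columns:
            raise ValueError(f"experiment {exp}: no transporter-cell records")
        control = means["control"] if "control" in means.columns else 0.0
        net = means["transporter"] - control
        if 0.0 not in net.index:
            raise ValueError(f"experiment {exp}: no vehicle (0 μM) records")
        vehicle_net = net.loc[0.0]
        if vehicle_net <= 0:
            raise ValueError(
                f"experiment {exp}: vehicle net uptake {vehicle_net:.3g} <= 0; "
                "assay is non-functional"
            )
        per_experiment.append(100.0 * net / vehicle_net)
        anchor_vars.append(_vehicle_anchor_variance(sub, vehicle_net))

    pooled = pd.concat(per_experiment, axis=1).mean(axis=1)
    out = pooled.rename("percent_activity").reset_index()
    out = out.sort_values("inhibitor_conc_uM", ignore_index=True)
    out.attrs["anchor_se"] = float(np.sqrt(sum(anchor_vars)) / len(anchor_vars))
    return out


def _vehicle_anchor_variance(sub: pd.DataFrame, vehicle_net: float) -> float:
    """Fractional variance of one experiment's vehicle net-uptake mean."""
    vehicle = sub[sub["inhibitor_conc_uM"] == 0.0]
    var = 0.0
    for _, wells in vehicle.groupby("cell_line")["signal"]:
        if len(wells) > 1:
            var += wells.var(ddof=1) / len(wells)
    return var / vehicle_net**2


def vesicle_net_transport(data: pd.DataFrame) -> pd.DataFrame:
    """Reduce a vesicle-assay table to percent activity per concentration.

    Net active transport is mean(ATP wells) - mean(AMP wells) at each
    inhibitor concentration, normalised to the vehicle net transport (100%).
    """
    required = {"energy_source", "inhibitor_conc_uM", "signal"}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    means = data.groupby(["inhibitor_conc_uM", "energy_source"])["signal"].mean().unstack()
    for source in ("ATP", "AMP"):
        if source not in means.columns or means[source].isna().any():
            raise ValueError(f"every concentration needs at least one {source} record")
    net = means["ATP"] - means["AMP"]
    if 0.0 not in net.index:
        raise ValueError("no vehicle (0 μM) records")
    vehicle_net = net.loc[0.0]
    if vehicle_net <= 0:
        raise ValueError(f"vehicle net transport {vehicle_net:.3g} <= 0")
    out = (100.0 * net / vehicle_net).rename("percent_activity").reset_index()
    out = out.sort_values("inhibitor_conc_uM", ignore_index=True)
    vehicle = data[data["inhibitor_conc_uM"] == 0.0]
    var = 0.0
    for _, wells in vehicle.groupby("energy_source")["signal"]:
        if len(wells) > 1:
            var += wells.var(ddof=1) / len(wells)
    out.attrs["anchor_se"] = float(np.sqrt(var) / vehicle_net)
    return out


def net_uptake_rates(data: pd.DataFrame) -> pd.DataFrame:
    """Reduce a kinetics assay table to net transporter-mediated rates.

    Mean control-cell rate is subtracted from the mean transporter-cell rate
    at each substrate concentration (pooling experiments), yielding the
    ``(substrate_conc_uM, net_rate)`` table that :func:`fit_mm` consumes.
    """
    required = {"cell_line", "substrate_conc_uM", "signal"}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    means = data.groupby(["substrate_conc_uM", "cell_line"])["signal"].mean().unstack()
    if "transporter" not in means.columns:
        raise ValueError("no transporter-cell records")
    control = means["control"] if "control" in means.columns else 0.0
    net = (means["transporter"] - control).rename("net_rate")
    return net.reset_index().sort_values("substrate_conc_uM", ignore_index=True)


# ---------------------------------------------------------------------------
# fitting helpers
# ---------------------------------------------------------------------------

def _wald_ci_log(theta: np.ndarray, jac: np.ndarray, rss: float, n: int):
    """95% Wald CIs for log10-scale parameters, back-transformed to linear."""
    p = theta.size
    dof = max(n - p, 1)
    s2 = rss / dof
    try:
        cov = s2 * np.linalg.inv(jac.T @ jac)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        se = np.full(p, np.inf)
    tcrit = stats.t.ppf(0.975, dof)
    lows = 10.0 ** (theta - tcrit * se)
    highs = 10.0 ** (theta + tcrit * se)
    return lows, highs


def _least_squares_restarts(residual, theta0: np.ndarray, bounds, seed: int = 12345):
    """least_squares with up to 3 jittered restarts on failure/boundary hits."""
    rng = np.random.default_rng(seed)
    best = None
    for attempt in range(4):
        start = theta0 if attempt == 0 else theta0 + rng.normal(0, 0.5, theta0.size)
        start = np.clip(start, bounds[0] + 1e-9, bounds[1] - 1e-9)
        try:
            sol = optimize.least_squares(residual, start, bounds=bounds, method="trf")
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
        at_boundary = np.any(np.abs(sol.x - bounds[0]) < 1e-6) or np.any(
            np.abs(sol.x - bounds[1]) < 1e-6
        )
        if sol.success and not at_boundary:
            break
    if best is None:
        raise RuntimeError("optimizer failed from all starting points")
    return best


def _check_activity_table(activity: pd.DataFrame):
    if "inhibitor_conc_uM" in activity.columns:
        conc = activity["inhibitor_conc_uM"].to_numpy(float)
    else:
        conc = activity.iloc[:, 0].to_numpy(float)
    y = activity["percent_activity"].to_numpy(float)
    mask = conc > 0
    return conc[mask], y[mask]


# ---------------------------------------------------------------------------
# fits
# ---------------------------------------------------------------------------

def fit_ic50(activity: pd.DataFrame, anchor_se: float | None = None) -> FitResult:
    """Fit a fixed-slope log-logistic curve to percent-activity data.

    The model ``activity = 100 / (1 + 10**(log10(I) - log10(IC50)))`` has
    log10(IC50) as its single free parameter (Hill slope 1, asymptotes 0 and
    100%). Vehicle rows (0 μM) are the normalisation anchor and are not part
    of the objective. The result is flagged non-convergent when the data show
    no decline with concentration or the optimum sits at the search boundary.

    ``anchor_se`` is the fractional standard error of the 100% normalisation
    anchor (defaults to ``activity.attrs["anchor_se"]`` when the reduction
    step recorded it). A noisy anchor rescales the whole curve coherently,
    which shifts the IC50 estimate without inflating fit residuals, so its
    contribution is added to the Wald variance of log10(IC50) by the delta
    method.
    """
    if anchor_se is None:
        anchor_se = float(activity.attrs.get("anchor_se", 0.0))
    conc, y = _check_activity_table(activity)
    if np.unique(conc).size < 3:
        raise ValueError("need >= 3 distinct nonzero concentrations")
    span = np.log10(conc.max() / conc.min())
    message = "" if span >= 1 else "concentration span below one order of magnitude"

    logc = np.log10(conc)
    bounds = (np.array([logc.min() - 3.0]), np.array([logc.max() + 3.0]))

    def residual(theta):
        return 100.0 / (1.0 + 10.0 ** (logc - theta[0])) - y

    theta0 = np.array([0.5 * (logc.min() + logc.max())])
    sol = _least_squares_restarts(residual, theta0, bounds)

    declines = stats.linregress(logc, y).slope < 0
    at_boundary = (
        abs(sol.x[0] - bounds[0][0]) < 1e-4 or abs(sol.x[0] - bounds[1][0]) < 1e-4
    )
    converged = bool(sol.success and declines and not at_boundary)
    if not declines:
        message = "no decline in activity with concentration"
    elif at_boundary:
        message = "IC50 estimate at search boundary"

    rss = float(2 * sol.cost)
    dof = max(conc.size - 1, 1)
    jtj = float(sol.jac[:, 0] @ sol.jac[:, 0])
    wald_var = (rss / dof) / jtj if jtj > 0 else np.inf
    # delta-method term for the shared normalisation-anchor uncertainty:
    # scaling the data by (1+d) moves log10(IC50) by ~ s_scale * d
    fitted = 100.0 / (1.0 + 10.0 ** (logc - sol.x[0]))
    s_scale = float(sol.jac[:, 0] @ fitted) / jtj if jtj > 0 else 0.0
    se = np.sqrt(wald_var + (s_scale * anchor_se) ** 2)
    tcrit = stats.t.ppf(0.975, dof)
    low, high = 10.0 ** (sol.x[0] - tcrit * se), 10.0 ** (sol.x[0] + tcrit * se)
    ic50 = float(10.0 ** sol.x[0])
    return FitResult(
        params={"ic50": ic50},
        ci95={"ic50": (min(low, ic50), max(high, ic50))},
        residual_sum_squares=rss,
        n_points=int(conc.size),
        converged=converged,
        message=message,
    )


def fit_mm(kinetics: pd.DataFrame, exclusions: list[float] | None = None) -> FitResult:
    """Fit the Michaelis-Menten equation to net uptake rates.

    ``kinetics`` holds columns ``substrate_conc_uM`` and ``net_rate``.
    Concentrations listed in ``exclusions`` (e.g. points deviating from
    saturable kinetics at high substrate) are dropped from the objective and
    recorded in ``FitResult.excluded_points``. Km and Vmax are fit on the
    log10 scale to enforce positivity.
    """
    exclusions = list(exclusions or [])
    s = kinetics["substrate_conc_uM"].to_numpy(float)
    v = kinetics["net_rate"].to_numpy(float)
    keep = ~np.isin(s, exclusions)
    s, v = s[keep], v[keep]
    if np.unique(s).size < 3:
        raise ValueError("need >= 3 distinct concentrations after exclusions")

    bounds = (
        np.array([np.log10(s.min()) - 4.0, np.log10(max(v.max(), 1e-12)) - 4.0]),
        np.array([np.log10(s.max()) + 4.0, np.log10(max(v.max(), 1e-12)) + 4.0]),
    )

    def residual(theta):
        km, vmax = 10.0 ** theta
        return vmax * s / (km + s) - v

    theta0 = np.array([np.log10(np.median(s)), np.log10(max(v.max(), 1e-12))])
    sol = _least_squares_restarts(residual, theta0, bounds)
    at_boundary = np.any(np.abs(sol.x - bounds[0]) < 1e-4) or np.any(
        np.abs(sol.x - bounds[1]) < 1e-4
    )

    rss = float(2 * sol.cost)
    lows, highs = _wald_ci_log(sol.x, sol.jac, rss, s.size)
    km, vmax = (float(10.0 ** x) for x in sol.x)
    return FitResult(
        params={"km": km, "vmax": vmax},
        ci95={"km": (min(lows[0], km), max(highs[0], km)),
              "vmax": (min(lows[1], vmax), max(highs[1], vmax))},
        residual_sum_squares=rss,
        n_points=int(s.size),
        excluded_points=exclusions,
        converged=bool(sol.success and not at_boundary),
        message="parameter at search boundary" if at_boundary else "",
    )


def fit_ki_competitive(grid: pd.DataFrame) -> FitResult:
    """Globally fit Vmax, Km and Ki to a substrate x inhibitor rate grid.

    The competitive model ``v = Vmax*S / (Km*(1 + I/Ki) + S)`` is fit jointly
    over all (substrate, inhibitor) pairs, which is how a mechanistic Ki is
    obtained from a designed inhibition-kinetics experiment. The grid must
    contain at least two substrate levels and two inhibitor levels (one of
    them 0, the uninhibited arm); otherwise Ki is unidentifiable.
    """
    s = grid["substrate_conc_uM"].to_numpy(float)
    i = grid["inhibitor_conc_uM"].to_numpy(float)
    v = grid["net_rate"].to_numpy(float)
    if np.unique(s).size < 2:
        raise ValueError("Ki unidentifiable: need >= 2 substrate levels")
    if np.unique(i).size < 2 or 0.0 not in np.unique(i):
        raise ValueError("need >= 2 inhibitor levels including 0")

    i_nonzero = i[i > 0]
    bounds = (
        np.array([np.log10(s.min()) - 4.0, np.log10(max(v.max(), 1e-12)) - 4.0,
                  np.log10(i_nonzero.min()) - 4.0]),
        np.array([np.log10(s.max()) + 4.0, np.log10(max(v.max(), 1e-12)) + 4.0,
                  np.log10(i_nonzero.max()) + 4.0]),
    )

    def residual(theta):
        km, vmax, ki = 10.0 ** theta
        return vmax * s / (km * (1.0 + i / ki) + s) - v

    theta0 = np.array([
        np.log10(np.median(s)),
        np.log10(max(v.max(), 1e-12)),
        np.log10(np.median(i_nonzero)),
    ])
    sol = _least_squares_restarts(residual, theta0, bounds)
    at_boundary = np.any(np.abs(sol.x - bounds[0]) < 1e-4) or np.any(
        np.abs(sol.x - bounds[1]) < 1e-4
    )

    rss = float(2 * sol.cost)
    lows, highs = _wald_ci_log(sol.x, sol.jac, rss, s.size)
    km, vmax, ki = (float(10.0 ** x) for x in sol.x)
    return FitResult(
        params={"km": km, "vmax": vmax, "ki": ki},
        ci95={"km": (min(lows[0], km), max(highs[0], km)),
              "vmax": (min(lows[1], vmax), max(highs[1], vmax)),
              "ki": (min(lows[2], ki), max(highs[2], ki))},
        residual_sum_squares=rss,
        n_points=int(s.size),
        converged=bool(sol.success and not at_boundary),
        message="parameter at search boundary" if at_boundary else "",
    )
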