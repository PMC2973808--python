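"""Rate estimation from longitudinal panel data.

The calibration procedure regresses wave-to-wave state transitions on
contact counts.  For each subject in the origin state at wave ``w`` who is
also observed at wave ``w+1``, the binary transition indicator is regressed
against the number of contacts in a given state at wave ``w``.  Under the
linearised transition probabilities

    P(S -> I | c infected contacts) ~= (a + beta c) * dt
    P(I -> S)                       ~=  g * dt

the transmission rate is the slope of the susceptible-to-infected
regression divided by ``dt``, the spontaneous rate its intercept over
``dt``, and the recovery rate the intercept of the infected-to-susceptible
regression over ``dt``.  A significant positive slope is the evidence that
a state is socially contagious.

The linearisation is biased by O(rate * dt) because double transitions
within an interval are ignored; :func:`fit_rates_mle` provides the exact
discretely-observed two-state Markov-chain likelihood as an alternative
for multi-year intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

from .network import INFECTED, SUSCEPTIBLE
from .panel import PanelDataset, bmi_to_state  # noqa: F401  (re-exported)
from .params import SISaParams

__all__ = [
    "TransitionRegression",
    "EstimationResult",
    "count_contacts",
    "transition_regression",
    "infectiousness_test",
    "extract_rates",
    "fit_rates_mle",
    "rate_trend_test",
    "bmi_to_state",
]


@dataclass(frozen=True)
class TransitionRegression:
    """One direction's transition-vs-contacts regression.

    Slope is probability per contact over the interval; intercept is the
    contact-free transition probability over the interval.
    """

    from_state: str
    to_state: str
    contact_state: str
    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    p_value: float
    n_observations: int
    method: str = "ols"

    def conf_int(self, alpha: float = 0.05) -> dict[str, tuple[float, float]]:
        """Normal-approximation confidence intervals for slope and intercept."""
        z = stats.norm.ppf(1.0 - alpha / 2.0)
        return {
            "slope": (self.slope - z * self.slope_se, self.slope + z * self.slope_se),
            "intercept": (
                self.intercept - z * self.intercept_se,
                self.intercept + z * self.intercept_se,
            ),
        }


@dataclass(frozen=True)
class InfectiousnessVerdict:
    infectious: bool
    slope: float
    p_value: float
    alpha: float

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return self.infectious


@dataclass
class EstimationResult:
    """Extracted SISa rates with 95% confidence intervals."""

    params: SISaParams
    conf_int: dict[str, tuple[float, float]]
    regressions: dict[str, TransitionRegression]
    dt: float
    method: str = "linear"
    warnings_: list[str] | None = None


def count_contacts(panel: PanelDataset, subject, wave: int, state: str) -> int:
    """Number of ``subject``'s nominated contacts in ``state`` at ``wave``.

    Contacts whose state is unobserved at that wave are excluded.
    """
    if pd.isna(panel.states.loc[subject].iloc[wave]):
        raise ValueError(f"subject {subject!r} not observed at wave {wave}")
    net = panel.network_at(wave)
    col = panel.states.iloc[:, wave]
    count = 0
    for contact in net.out_neighbors(subject):
        s = col.get(contact)
        if s == state:
            count += 1
    return count


def _transition_table(
    panel: PanelDataset,
    from_state: str,
    contact_state: str,
    interval: int | None,
) -> pd.DataFrame:
    """At-risk observations: one row per (subject, interval).

    ``y`` is the transition indicator, ``c`` the contact count at the
    earlier wave, ``dt`` the interval length.  Subjects unobserved at either
    end of an interval are dropped (no imputation).
    """
    intervals = range(panel.n_waves - 1) if interval is None else [interval]
    rows = []
    for w in intervals:
        col0 = panel.states.iloc[:, w]
        col1 = panel.states.iloc[:, w + 1]
        net = panel.network_at(w)
        at_risk = panel.states.index[(col0 == from_state) & col1.notna()]
        col0_map = col0.to_dict()
        col1_map = col1.to_dict()
        for subject in at_risk:
            contacts = net.out_neighbors(subject)
            c = sum(1 for v in contacts if col0_map.get(v) == contact_state)
            c_next = sum(1 for v in contacts if col1_map.get(v) == contact_state)
            rows.append(
                {
                    "subject": subject,
                    "interval": w,
                    "c": c,
                    "c_next": c_next,
                    "y": int(col1.loc[subject] != from_state),
                    "dt": panel.dt(w),
                }
            )
    return pd.DataFrame(
        rows, columns=["subject", "interval", "c", "c_next", "y", "dt"]
    )


def transition_regression(
    panel: PanelDataset,
    from_state: str,
    to_state: str,
    contact_state: str,
    method: str = "ols",
    interval: int | None = None,
) -> TransitionRegression:
    """Regress the wave-to-wave transition indicator on contact counts.

    ``interval=None`` pools all consecutive wave pairs; an integer selects
    a single exam pair.  ``method="logistic"`` reports the marginal-effect
    slope at the sample mean so the two methods are directly comparable.
    """
    if {from_state, to_state, contact_state} - {SUSCEPTIBLE, INFECTED}:
        raise ValueError("states must be 'S' or 'I'")
    if from_state == to_state:
        raise ValueError("transition requires distinct states")
    table = _transition_table(panel, from_state, contact_state, interval)
    if table.empty:
        raise ValueError(f"no at-risk subjects for {from_state}->{to_state}")
    y = table["y"].to_numpy(dtype=float)
    x = table["c"].to_numpy(dtype=float)
    n = len(y)
    if y.sum() == 0:
        # no transitions at all: the flat regression is exact, skip the fit
        return TransitionRegression(
            from_state, to_state, contact_state, 0.0, 0.0, np.nan, np.nan, np.nan, n, method
        )
    if n < 2 or np.unique(x).size < 2:
        raise ValueError("need >= 2 distinct contact-count values for regression")
    X = sm.add_constant(x)
    if method == "ols":
        fit = sm.OLS(y, X).fit()
        slope, intercept = fit.params[1], fit.params[0]
        slope_se, intercept_se = fit.bse[1], fit.bse[0]
        p = fit.pvalues[1]
    elif method == "logistic":
        if y.sum() == 0 or y.sum() == n:
            raise ValueError("logistic regression needs both outcomes present")
        fit = sm.Logit(y, X).fit(disp=False)
        b0, b1 = fit.params
        p_hat = 1.0 / (1.0 + np.exp(-(b0 + b1 * x.mean())))
        scale = p_hat * (1.0 - p_hat)
        slope = b1 * scale
        intercept = p_hat - slope * x.mean()
        slope_se = fit.bse[1] * scale
        intercept_se = np.sqrt(fit.cov_params().iloc[0, 0]) * scale if hasattr(fit.cov_params(), "iloc") else fit.bse[0] * scale
        p = fit.pvalues[1]
    else:
        raise ValueError(f"unknown method {method!r}")
    return TransitionRegression(
        from_state=from_state,
        to_state=to_state,
        contact_state=contact_state,
        slope=float(slope),
        intercept=float(intercept),
        slope_se=float(slope_se),
        intercept_se=float(intercept_se),
        p_value=float(p),
        n_observations=n,
        method=method,
    )


def infectiousness_test(
    reg: TransitionRegression, alpha: float = 0.05
) -> InfectiousnessVerdict:
    """A state is infectious iff the contact-count slope is positive and significant."""
    infectious = bool(reg.slope > 0 and np.isfinite(reg.p_value) and reg.p_value < alpha)
    return InfectiousnessVerdict(
        infectious=infectious, slope=reg.slope, p_value=reg.p_value, alpha=alpha
    )


def extract_rates(
    regs: dict[str, TransitionRegression],
    dt: float,
    alpha: float = 0.05,
    mean_contacts: float | None = None,
) -> EstimationResult:
    """Convert transition regressions into SISa rates with 95% CIs.

    ``regs`` must contain ``"si_vs_infected"`` (S->I on infected contacts)
    and ``"is_vs_susceptible"`` (I->S on susceptible contacts); optional
    extra directions are carried through for reporting.  Rates:
    ``beta = slope(S->I)/dt``, ``a = intercept(S->I)/dt``,
    ``g = intercept(I->S)/dt`` (the contact-independent recovery model).
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    msgs: list[str] = []
    reg_si = regs["si_vs_infected"]
    reg_is = regs["is_vs_susceptible"]
    beta = max(reg_si.slope, 0.0) / dt
    a = max(reg_si.intercept, 0.0) / dt
    g = max(reg_is.intercept, 0.0) / dt
    if reg_si.slope < 0 or reg_si.intercept < 0 or reg_is.intercept < 0:
        msgs.append("negative regression coefficient clipped to zero rate")
    rec_verdict = infectiousness_test(reg_is, alpha)
    if rec_verdict.infectious:
        msgs.append(
            "recovery slope is significantly positive: contact-independent "
            "recovery assumption of the SISa model is violated"
        )
        warnings.warn(msgs[-1])
    ci = {}
    for rate, reg, key in (
        ("beta", reg_si, "slope"),
        ("a", reg_si, "intercept"),
        ("g", reg_is, "intercept"),
    ):
        lo, hi = reg.conf_int(alpha)[key]
        ci[rate] = (lo / dt, hi / dt)
    k_bar = mean_contacts if mean_contacts is not None else 0.0
    if max(a + beta * k_bar + 0.0, g) * dt > 0.5:
        msgs.append(
            "rate*dt exceeds 0.5: double transitions within an interval are "
            "likely and the linearised rates are biased"
        )
        warnings.warn(msgs[-1])
    params = SISaParams(a=a, g=g, beta=beta)
    return EstimationResult(
        params=params, conf_int=ci, regressions=dict(regs), dt=dt, method="linear",
        warnings_=msgs,
    )


def estimate_from_panel(
    panel: PanelDataset,
    method: str = "linear",
    regression: str = "ols",
    interval: int | None = None,
) -> EstimationResult:
    """End-to-end estimation: build both directions' regressions and extract rates.

    ``method="linear"`` is the slope/intercept-over-dt procedure;
    ``method="mle"`` fits the exact discretely-observed two-state chain
    (see :func:`fit_rates_mle`).
    """
    if method == "mle":
        return fit_rates_mle(panel, interval=interval)
    regs = {
        "si_vs_infected": transition_regression(
            panel, SUSCEPTIBLE, INFECTED, INFECTED, method=regression, interval=interval
        ),
        "is_vs_susceptible": transition_regression(
            panel, INFECTED, SUSCEPTIBLE, SUSCEPTIBLE, method=regression, interval=interval
        ),
        "si_vs_susceptible": transition_regression(
            panel, SUSCEPTIBLE, INFECTED, SUSCEPTIBLE, method=regression, interval=interval
        ),
        "is_vs_infected": transition_regression(
            panel, INFECTED, SUSCEPTIBLE, INFECTED, method=regression, interval=interval
        ),
    }
    if interval is None:
        dt = panel.mean_dt
    else:
        dt = panel.dt(interval)
    table = _transition_table(panel, SUSCEPTIBLE, INFECTED, interval)
    mean_c = float(table["c"].mean()) if not table.empty else 0.0
    return extract_rates(regs, dt, mean_contacts=mean_c)


def _mle_tables(panel: PanelDataset, interval: int | None):
    si = _transition_table(panel, SUSCEPTIBLE, INFECTED, interval)
    is_ = _transition_table(panel, INFECTED, INFECTED, interval)
    return si, is_


def fit_rates_mle(
    panel: PanelDataset,
    interval: int | None = None,
    exposure: str = "midpoint",
) -> EstimationResult:
    """Exact two-state Markov-chain likelihood for discretely observed panels.

    Each subject-interval contributes a Bernoulli observation whose
    probability is the exact two-state transition probability with infection
    hazard ``a + beta*c`` and recovery hazard ``g``:

        P(S -> I) = lam/(lam+g) * (1 - exp(-(lam+g) dt)),  lam = a + beta c
        P(I -> S) =   g/(lam+g) * (1 - exp(-(lam+g) dt))

    This removes the O(rate*dt) double-transition bias of the linearised
    estimator.  ``exposure`` controls how the infected-contact count over
    the interval is approximated: ``"midpoint"`` (default) averages the
    counts at the two bracketing waves, which corrects the attenuation
    caused by contacts changing state mid-interval; ``"baseline"`` uses the
    earlier wave only (the raw regression predictor).  Confidence intervals
    come from the observed information.
    """
    if exposure not in ("midpoint", "baseline"):
        raise ValueError(f"unknown exposure model {exposure!r}")
    tab_si, tab_is = _mle_tables(panel, interval)
    if tab_si.empty and tab_is.empty:
        raise ValueError("no at-risk observations")
    if exposure == "midpoint":
        tab_si = tab_si.assign(c=0.5 * (tab_si["c"] + tab_si["c_next"]))
        tab_is = tab_is.assign(c=0.5 * (tab_is["c"] + tab_is["c_next"]))
    c_si = tab_si["c"].to_numpy(dtype=float)
    y_si = tab_si["y"].to_numpy(dtype=float)
    dt_si = tab_si["dt"].to_numpy(dtype=float)
    c_is = tab_is["c"].to_numpy(dtype=float)
    y_is = tab_is["y"].to_numpy(dtype=float)
    dt_is = tab_is["dt"].to_numpy(dtype=float)

    def nll(theta: np.ndarray) -> float:
        a, g, beta = np.exp(theta)
        lam_si = a + beta * c_si
        r = lam_si + g
        p_si = lam_si / r * -np.expm1(-r * dt_si)
        lam_is = a + beta * c_is
        r2 = lam_is + g
        p_is = g / r2 * -np.expm1(-r2 * dt_is)
        eps = 1e-12
        ll = np.sum(y_si * np.log(p_si + eps) + (1 - y_si) * np.log(1 - p_si + eps))
        ll += np.sum(y_is * np.log(p_is + eps) + (1 - y_is) * np.log(1 - p_is + eps))
        return -ll

    theta0 = np.log([0.02, 0.04, 0.005])
    res = optimize.minimize(nll, theta0, method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000})
    if not res.success:
        raise RuntimeError(f"MLE failed to converge: {res.message}")
    theta = res.x
    hess = _numerical_hessian(nll, theta)
    try:
        cov_log = np.linalg.inv(hess)
    except np.linalg.LinAlgError:  # pragma: no cover - defensive
        cov_log = np.full((3, 3), np.nan)
    rates = np.exp(theta)
    se_log = np.sqrt(np.clip(np.diag(cov_log), 0.0, None))
    z = stats.norm.ppf(0.975)
    names = ["a", "g", "beta"]
    ci = {
        name: (rates[j] * np.exp(-z * se_log[j]), rates[j] * np.exp(z * se_log[j]))
        for j, name in enumerate(names)
    }
    params = SISaParams(a=float(rates[0]), g=float(rates[1]), beta=float(rates[2]))
    dt = panel.mean_dt if interval is None else panel.dt(interval)
    return EstimationResult(
        params=params, conf_int=ci, regressions={}, dt=dt, method="mle"
    )


def _numerical_hessian(f, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    n = len(x)
    hess = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h
            ej = np.zeros(n); ej[j] = h
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h * h)
    return hess


def rate_trend_test(
    rates: np.ndarray, ses: np.ndarray, times: np.ndarray
) -> tuple[float, float]:
    """Inverse-variance-weighted linear trend of per-interval rate estimates.

    Returns the weighted-regression slope (rate units per year) and its
    two-sided p-value.  Requires >= 3 intervals and strictly positive SEs.
    """
    rates = np.asarray(rates, dtype=float)
    ses = np.asarray(ses, dtype=float)
    times = np.asarray(times, dtype=float)
    if len(rates) < 3:
        raise ValueError("trend test requires >= 3 interval estimates")
    if np.any(ses <= 0):
        raise ValueError("standard errors must be strictly positive")
    X = sm.add_constant(times)
    fit = sm.WLS(rates, X, weights=1.0 / ses**2).fit()
    return float(fit.params[1]), float(fit.pvalues[1])
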