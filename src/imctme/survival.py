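"""Survival stratification and comparison.

Any per-patient quantity (a cell-type frequency, a CN prevalence, a
functional-substate fraction) is standardized over the analysis cohort
and split at z = 0 into "high" (z >= 0) and "low" (z < 0) strata, whose
overall survival is compared with the Kaplan-Meier estimator and the
log-rank (Mantel-Cox) test.  The log-rank statistic is the standard
discrete O-E/V chi-square with 1 degree of freedom, handling tied event
times by the hypergeometric variance; Kaplan-Meier fitting delegates to
lifelines.

No multiple-testing correction is applied by default when scanning many
variables (raw log-rank p-values are reported); a Benjamini-Hochberg
switch is available via :func:`adjust_pvalues`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats


def zscore_stratify(values: pd.Series) -> pd.DataFrame:
    """Standardize a per-patient quantity and split at z = 0.

    z = (v - mean) / sd over the cohort (sample s.d.); z >= 0 is "high".
    Returns a frame indexed like ``values`` with columns value, z,
    stratum.  Zero variance is an error (no meaningful split exists).
    """
    values = pd.Series(values).astype(float)
    if len(values) < 2:
        raise ValueError("need at least 2 patients")
    sd = values.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("zero variance; cannot stratify")
    z = (values - values.mean()) / sd
    return pd.DataFrame(
        {"value": values, "z": z, "stratum": np.where(z >= 0, "high", "low")},
        index=values.index,
    )


@dataclass
class KMEstimate:
    """Product-limit estimate as a right-continuous step function."""

    event_times: np.ndarray  # distinct event times, ascending
    survival: np.ndarray  # S(t) just after each event time
    n: int

    def at(self, t: float) -> float:
        idx = np.searchsorted(self.event_times, t, side="right")
        return 1.0 if idx == 0 else float(self.survival[idx - 1])


def kaplan_meier(times, events) -> KMEstimate:
    """Kaplan-Meier product-limit estimator (censored subjects leave the
    risk set after their time)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("empty input")
    if (times < 0).any():
        raise ValueError("times must be >= 0")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_["KM_estimate"]
    ev = np.unique(times[events])
    surv = np.array([sf.loc[t] for t in ev])
    return KMEstimate(ev, surv, n=len(times))


@dataclass
class LogRankResult:
    chi_square: float
    p_value: float
    observed: np.ndarray  # events per group (A, B)
    expected: np.ndarray  # expected events per group
    variance: float
    at_risk: pd.DataFrame  # per event time: n at risk and events per group


def logrank(times_a, events_a, times_b, events_b) -> LogRankResult:
    """Two-sample log-rank (Mantel-Cox) test.

    At each distinct event time t_j with d_j pooled events, n_aj / n_bj
    at risk, the group-A expectation is d_j n_aj / n_j and the variance
    the hypergeometric d_j (n_aj/n_j)(1 - n_aj/n_j)(n_j - d_j)/(n_j - 1).
    The chi-square is (O_A - E_A)^2 / V with 1 df; p is its upper tail.
    """
    ta = np.asarray(times_a, dtype=float)
    tb = np.asarray(times_b, dtype=float)
    ea = np.asarray(events_a, dtype=bool)
    eb = np.asarray(events_b, dtype=bool)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be non-empty")
    if not (ea.any() or eb.any()):
        raise ValueError("need at least one event overall")

    event_times = np.unique(np.concatenate([ta[ea], tb[eb]]))
    rows = []
    oa = ob = e_a = e_b = var = 0.0
    for t in event_times:
        n_a = int((ta >= t).sum())
        n_b = int((tb >= t).sum())
        d_a = int(((ta == t) & ea).sum())
        d_b = int(((tb == t) & eb).sum())
        n = n_a + n_b
        d = d_a + d_b
        ea_t = d * n_a / n
        v_t = 0.0
        if n > 1:
            v_t = d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
        oa += d_a
        ob += d_b
        e_a += ea_t
        e_b += d - ea_t
        var += v_t
        rows.append(
            {"time": t, "at_risk_a": n_a, "at_risk_b": n_b, "events_a": d_a, "events_b": d_b}
        )
    if var == 0:
        chi2, p = 0.0, 1.0
    else:
        chi2 = (oa - e_a) ** 2 / var
        p = float(stats.chi2.sf(chi2, df=1))
    return LogRankResult(
        chi_square=float(chi2),
        p_value=max(p, np.finfo(float).tiny),
        observed=np.array([oa, ob]),
        expected=np.array([e_a, e_b]),
        variance=float(var),
        at_risk=pd.DataFrame(rows),
    )


@dataclass
class SurvivalAssociation:
    variable: str
    strata: pd.DataFrame
    km_high: KMEstimate
    km_low: KMEstimate
    logrank: LogRankResult


def survival_association(
    values: pd.Series,
    survival_time: pd.Series,
    event: pd.Series,
    variable: str = "",
) -> SurvivalAssociation:
    """z-stratify a per-patient value and compare strata survival."""
    strat = zscore_stratify(values)
    hi = strat.index[strat["stratum"] == "high"]
    lo = strat.index[strat["stratum"] == "low"]
    if len(hi) == 0 or len(lo) == 0:
        raise ValueError("one stratum is empty")
    res = logrank(
        survival_time.loc[hi], event.loc[hi], survival_time.loc[lo], event.loc[lo]
    )
    return SurvivalAssociation(
        variable=variable or str(values.name),
        strata=strat,
        km_high=kaplan_meier(survival_time.loc[hi], event.loc[hi]),
        km_low=kaplan_meier(survival_time.loc[lo], event.loc[lo]),
        logrank=res,
    )


def per_patient_values(
    per_core: pd.Series, core_to_patient: dict[str, str]
) -> pd.Series:
    """Aggregate a per-core quantity to patients (mean over a patient's
    cores, the convention for multi-core cohorts)."""
    s = pd.Series(per_core).astype(float)
    return s.groupby(s.index.map(core_to_patient.get)).mean()


def adjust_pvalues(pvalues: pd.Series) -> pd.Series:
    """Optional Benjamini-Hochberg adjustment for multi-variable scans."""
    p = pd.Series(pvalues).astype(float)
    adj = stats.false_discovery_control(p.to_numpy(), method="bh")
    return pd.Series(adj, index=p.index, name="p_adjusted")
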