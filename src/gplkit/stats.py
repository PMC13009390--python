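"""Reliability analysis: linear mixed-effects model per metric.

For one accuracy metric measured on every patient by each operator on each
occasion, the model is

    value ~ operator + occasion + operator:occasion + (1 | patient)

fitted by REML.  From the fit, estimated marginal means (EMMs) per
operator-by-occasion cell with 95% CIs, intra-operator contrasts (occasion
2 minus occasion 1 within each operator) and inter-operator contrasts
(operator-pair differences within each occasion) quantify reliability.
No multiplicity adjustment is applied: reporting is CI-based.

Degrees of freedom: statsmodels provides no Satterthwaite approximation,
so CIs use a t reference with df = n_patients - 1, a conservative
between-within rule; the report carries ``df_method`` so downstream
consumers can see which rule produced the intervals.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .mesh_io import MISSING, MeasurementRecord

log = logging.getLogger(__name__)


class StatsError(ValueError):
    pass


@dataclass
class LMEMSpec:
    """Model specification for one response metric."""

    response: str
    ci_level: float = 0.95


@dataclass
class FittedLMEM:
    """Fitted mixed model plus everything needed for EMMs and contrasts."""

    spec: LMEMSpec
    operators: tuple
    occasions: tuple
    fe_params: np.ndarray
    cov_fe: np.ndarray
    patient_variance: float
    residual_variance: float
    n_obs: int
    n_patients: int
    n_dropped: int
    converged: bool
    singular: bool = False
    df_method: str = "t(n_patients - 1)"

    @property
    def df(self) -> float:
        return max(self.n_patients - 1, 1)

    def cell_row(self, operator, occasion) -> np.ndarray:
        """Fixed-effects design row for one operator-by-occasion cell."""
        ops, occs = self.operators, self.occasions
        row = [1.0]
        row += [1.0 if operator == o else 0.0 for o in ops[1:]]
        row += [1.0 if occasion == k else 0.0 for k in occs[1:]]
        row += [
            1.0 if (operator == o and occasion == k) else 0.0
            for o in ops[1:]
            for k in occs[1:]
        ]
        return np.asarray(row)


def _records_to_frame(records, metric: str):
    rows = []
    n_missing = 0
    for r in records:
        if r.metric != metric:
            continue
        if r.value is MISSING:
            n_missing += 1
            continue
        rows.append((r.patient_id, r.operator_id, r.occasion, r.value))
    if n_missing:
        log.info("metric %s: dropped %d MISSING records (complete-case)", metric, n_missing)
    df = pd.DataFrame(rows, columns=["patient_id", "operator_id", "occasion", "value"])
    return df, n_missing


def fit_lmem(records, spec: LMEMSpec) -> FittedLMEM:
    """REML fit of the operator/occasion model with a patient random intercept.

    MISSING values are dropped (complete-case per metric, count logged).  An
    all-constant response yields the exact degenerate fit (all EMMs equal
    to the constant, both variance components zero) with a singular-fit
    warning, mirroring what any mixed-model optimiser would report.
    """
    df, n_dropped = _records_to_frame(records, spec.response)
    operators = tuple(sorted(str(o) for o in df["operator_id"].unique()))
    occasions = tuple(sorted(int(o) for o in df["occasion"].unique()))
    patients = df["patient_id"].unique()
    if len(operators) < 2 or len(occasions) < 2 or len(patients) < 2:
        raise StatsError(
            f"metric {spec.response!r}: need >= 2 operators, occasions and patients "
            f"(got {len(operators)}, {len(occasions)}, {len(patients)})"
        )

    shell = FittedLMEM(
        spec=spec,
        operators=operators,
        occasions=occasions,
        fe_params=np.zeros(0),
        cov_fe=np.zeros((0, 0)),
        patient_variance=0.0,
        residual_variance=0.0,
        n_obs=len(df),
        n_patients=len(patients),
        n_dropped=n_dropped,
        converged=True,
    )
    k = len(shell.cell_row(operators[0], occasions[0]))

    values = df["value"].to_numpy(float)
    if np.ptp(values) == 0.0:
        warnings.warn(
            "singular fit: response is constant; variance components are zero",
            RuntimeWarning,
            stacklevel=2,
        )
        shell.fe_params = np.zeros(k)
        shell.fe_params[0] = values[0]
        shell.cov_fe = np.zeros((k, k))
        shell.singular = True
        return shell

    exog = np.vstack(
        [shell.cell_row(o, c) for o, c in zip(df["operator_id"], df["occasion"])]
    )
    model = sm.MixedLM(values, exog, groups=df["patient_id"].to_numpy())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit(reml=True)
    if not result.converged:
        raise StatsError(
            f"metric {spec.response!r}: mixed-model optimiser did not converge"
        )

    cov_re = np.atleast_2d(np.asarray(result.cov_re))
    patient_var = float(cov_re[0, 0])
    shell.fe_params = np.asarray(result.fe_params, float)[:k]
    shell.cov_fe = np.asarray(result.cov_params())[:k, :k]
    shell.patient_variance = patient_var
    shell.residual_variance = float(result.scale)
    shell.converged = bool(result.converged)
    if patient_var <= 1e-12:
        shell.singular = True
        warnings.warn(
            "singular fit: patient-intercept variance estimated at zero; fit retained",
            RuntimeWarning,
            stacklevel=2,
        )
    return shell


def _estimate(fitted: FittedLMEM, row: np.ndarray, ci_level: float) -> dict:
    est = float(row @ fitted.fe_params)
    se = float(np.sqrt(max(row @ fitted.cov_fe @ row, 0.0)))
    tcrit = float(sps.t.ppf(0.5 + ci_level / 2, fitted.df))
    return {
        "estimate": est,
        "se": se,
        "ci_low": est - tcrit * se,
        "ci_high": est + tcrit * se,
    }


def emmeans(fitted: FittedLMEM, ci_level: float | None = None) -> list:
    """Estimated marginal mean per operator-by-occasion cell, with CI."""
    ci_level = fitted.spec.ci_level if ci_level is None else ci_level
    cells = []
    for op, occ in itertools.product(fitted.operators, fitted.occasions):
        entry = _estimate(fitted, fitted.cell_row(op, occ), ci_level)
        entry.update(operator=op, occasion=occ)
        cells.append(entry)
    return cells


def pairwise_contrasts(fitted: FittedLMEM, ci_level: float | None = None) -> dict:
    """Intra-operator (occasion 2 - 1) and inter-operator (pairwise) contrasts."""
    ci_level = fitted.spec.ci_level if ci_level is None else ci_level
    occ1, occ2 = fitted.occasions[0], fitted.occasions[-1]

    intra = []
    for op in fitted.operators:
        row = fitted.cell_row(op, occ2) - fitted.cell_row(op, occ1)
        entry = _estimate(fitted, row, ci_level)
        entry.update(operator=op, contrast=f"occasion {occ2} - occasion {occ1}")
        intra.append(entry)

    inter = []
    for occ in fitted.occasions:
        for op_a, op_b in itertools.combinations(fitted.operators, 2):
            row = fitted.cell_row(op_a, occ) - fitted.cell_row(op_b, occ)
            entry = _estimate(fitted, row, ci_level)
            entry.update(occasion=occ, contrast=f"{op_a} vs. {op_b}")
            inter.append(entry)

    return {"intra_operator": intra, "inter_operator": inter}


@dataclass
class ReliabilityReport:
    metric: str
    emm: list
    intra_operator: list
    inter_operator: list
    variance_components: dict
    n_obs: int
    n_dropped: int
    df_method: str
    singular: bool = False

    def as_dict(self) -> dict:
        return {
            "metric": self.metric,
            "emm": self.emm,
            "intra_operator": self.intra_operator,
            "inter_operator": self.inter_operator,
            "variance_components": self.variance_components,
            "n_obs": self.n_obs,
            "n_dropped": self.n_dropped,
            "df_method": self.df_method,
            "singular": self.singular,
        }


def reliability_report(records, spec: LMEMSpec) -> ReliabilityReport:
    """Fit the LMEM and assemble the full per-metric reliability report."""
    fitted = fit_lmem(records, spec)
    contrasts = pairwise_contrasts(fitted)
    return ReliabilityReport(
        metric=spec.response,
        emm=emmeans(fitted),
        intra_operator=contrasts["intra_operator"],
        inter_operator=contrasts["inter_operator"],
        variance_components={
            "patient_intercept": fitted.patient_variance,
            "residual": fitted.residual_variance,
        },
        n_obs=fitted.n_obs,
        n_dropped=fitted.n_dropped,
        df_method=fitted.df_method,
        singular=fitted.singular,
    )
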