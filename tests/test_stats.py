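"""Mixed-model reliability analysis: EMMs, contrasts, variance recovery."""

import numpy as np
import pytest

from gplkit.mesh_io import MISSING, MeasurementRecord
from gplkit.stats import (
    LMEMSpec,
    StatsError,
    emmeans,
    fit_lmem,
    pairwise_contrasts,
    reliability_report,
)

OPERATORS = ("O1", "O2", "O3")


def balanced_records(
    rng=None,
    n_patients=17,
    patient_sd=0.0,
    residual_sd=0.0,
    operator_effects=None,
    occasion_effect=0.0,
    constant=0.0,
    metric="m",
):
    operator_effects = operator_effects or {}
    rng = rng or np.random.default_rng(0)
    patient_effects = rng.normal(0.0, patient_sd, n_patients) if patient_sd else np.zeros(n_patients)
    records = []
    for i in range(n_patients):
        for op in OPERATORS:
            for occ in (1, 2):
                mu = (
                    constant
                    + patient_effects[i]
                    + operator_effects.get(op, 0.0)
                    + (occasion_effect if occ == 2 else 0.0)
                )
                noise = rng.normal(0.0, residual_sd) if residual_sd else 0.0
                records.append(MeasurementRecord(f"P{i}", op, occ, metric, mu + noise))
    return records


class TestFitLmem:
    def test_constant_response_degenerate_fit(self):
        records = balanced_records(constant=2.5)
        with pytest.warns(RuntimeWarning, match="singular"):
            fitted = fit_lmem(records, LMEMSpec("m"))
        assert fitted.patient_variance == 0.0
        assert fitted.residual_variance == 0.0
        for cell in emmeans(fitted):
            assert cell["estimate"] == pytest.approx(2.5)
            assert cell["ci_low"] == cell["ci_high"] == pytest.approx(2.5)

    def test_missing_records_dropped(self):
        records = balanced_records(residual_sd=0.1, patient_sd=0.5)
        for i in range(5):
            records[i] = MeasurementRecord(
                records[i].patient_id, records[i].operator_id,
                records[i].occasion, "m", MISSING,
            )
        fitted = fit_lmem(records, LMEMSpec("m"))
        assert fitted.n_dropped == 5
        assert fitted.n_obs == len(records) - 5

    def test_insufficient_design_rejected(self):
        records = [
            MeasurementRecord("P1", "O1", 1, "m", 1.0),
            MeasurementRecord("P1", "O1", 2, "m", 1.1),
        ]
        with pytest.raises(StatsError):
            fit_lmem(records, LMEMSpec("m"))

    def test_variance_components_recovered(self):
        """Patient sd 1.0 / residual sd 0.3: components within 30% of truth
        on average over repeated simulations."""
        rng = np.random.default_rng(42)
        pat, res = [], []
        for _ in range(50):
            records = balanced_records(rng=rng, patient_sd=1.0, residual_sd=0.3)
            fitted = fit_lmem(records, LMEMSpec("m"))
            pat.append(fitted.patient_variance)
            res.append(fitted.residual_variance)
        assert abs(np.mean(pat) - 1.0) < 0.3
        assert abs(np.mean(res) - 0.09) < 0.3 * 0.09


class TestEmmeans:
    def test_noiseless_operator_offset_exact(self):
        """Balanced, zero residual: O2 cells exceed O1 cells by exactly 0.5."""
        records = balanced_records(patient_sd=1.0, operator_effects={"O2": 0.5})
        fitted = fit_lmem(records, LMEMSpec("m"))
        cells = {(c["operator"], c["occasion"]): c["estimate"] for c in emmeans(fitted)}
        for occ in (1, 2):
            assert cells[("O2", occ)] - cells[("O1", occ)] == pytest.approx(0.5, abs=1e-8)

    def test_balanced_noiseless_emms_equal_cell_means(self):
        rng = np.random.default_rng(3)
        records = balanced_records(
            rng=rng, patient_sd=0.8,
            operator_effects={"O2": 0.3, "O3": -0.2}, occasion_effect=0.1,
        )
        fitted = fit_lmem(records, LMEMSpec("m"))
        raw = {}
        for r in records:
            raw.setdefault((r.operator_id, r.occasion), []).append(r.value)
        for cell in emmeans(fitted):
            assert cell["estimate"] == pytest.approx(
                np.mean(raw[(cell["operator"], cell["occasion"])]), abs=1e-6
            )

    def test_ci_bounds_bracket_estimate(self):
        rng = np.random.default_rng(4)
        records = balanced_records(rng=rng, patient_sd=1.0, residual_sd=0.3)
        fitted = fit_lmem(records, LMEMSpec("m"))
        for cell in emmeans(fitted):
            assert cell["ci_low"] <= cell["estimate"] <= cell["ci_high"]


class TestContrasts:
    def test_contrasts_equal_emm_differences(self):
        rng = np.random.default_rng(5)
        records = balanced_records(
            rng=rng, patient_sd=1.0, residual_sd=0.3,
            operator_effects={"O2": 0.2, "O3": -0.3}, occasion_effect=0.15,
        )
        fitted = fit_lmem(records, LMEMSpec("m"))
        cells = {(c["operator"], c["occasion"]): c["estimate"] for c in emmeans(fitted)}
        contrasts = pairwise_contrasts(fitted)
        for entry in contrasts["intra_operator"]:
            op = entry["operator"]
            assert entry["estimate"] == pytest.approx(
                cells[(op, 2)] - cells[(op, 1)], abs=1e-9
            )
        for entry in contrasts["inter_operator"]:
            a, b = entry["contrast"].split(" vs. ")
            occ = entry["occasion"]
            assert entry["estimate"] == pytest.approx(
                cells[(a, occ)] - cells[(b, occ)], abs=1e-9
            )

    def test_constant_data_zero_contrasts(self):
        records = balanced_records(constant=1.0)
        with pytest.warns(RuntimeWarning):
            fitted = fit_lmem(records, LMEMSpec("m"))
        contrasts = pairwise_contrasts(fitted)
        for entry in contrasts["intra_operator"] + contrasts["inter_operator"]:
            assert entry["estimate"] == pytest.approx(0.0)

    def test_injected_offset_detected(self):
        """A systematic O1-vs-O3 offset is flagged (CI excludes 0) at small
        residual noise in at least 90% of simulations."""
        rng = np.random.default_rng(6)
        detected = 0
        n_sims = 60
        for _ in range(n_sims):
            records = balanced_records(
                rng=rng, patient_sd=1.0, residual_sd=0.15,
                operator_effects={"O3": -0.307},
            )
            fitted = fit_lmem(records, LMEMSpec("m"))
            for entry in pairwise_contrasts(fitted)["inter_operator"]:
                if entry["contrast"] == "O1 vs. O3" and entry["occasion"] == 1:
                    if entry["ci_low"] > 0 or entry["ci_high"] < 0:
                        detected += 1
        assert detected / n_sims >= 0.9


class TestReliabilityReport:
    def test_report_structure(self):
        rng = np.random.default_rng(7)
        records = balanced_records(rng=rng, patient_sd=0.8, residual_sd=0.2)
        report = reliability_report(records, LMEMSpec("m"))
        assert len(report.emm) == 6  # 3 operators x 2 occasions
        assert len(report.intra_operator) == 3
        assert len(report.inter_operator) == 6  # 3 pairs x 2 occasions
        assert set(report.variance_components) == {"patient_intercept", "residual"}
        d = report.as_dict()
        assert d["metric"] == "m" and d["n_obs"] == 102
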