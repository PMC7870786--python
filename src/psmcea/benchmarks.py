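"""Bundled published base-case summary cells used as worked-example inputs.

These are report-table numbers (2019 USD; QALYs/LYs as printed) kept here so
regression tests and the acceptance report can recompute the derived
quantities (increments, INHB, savings) through the package's own arithmetic
rather than hard-coding the answers.
"""

WTP = 150_000.0

#: Per-scenario, per-strategy base-case cells: total cost, cost accrued in the
#: progression-free state, overall life-years and QALYs.
BASE_CASE = {
    "A": {
        "standard_care": {"total_cost": 17_243.0, "cost_pfd": 10_055.0, "lys": 0.221, "qalys": 0.109},
        "olaparib": {"total_cost": 24_626.0, "cost_pfd": 12_035.0, "lys": 0.321, "qalys": 0.173},
    },
    "B": {
        "standard_care": {"total_cost": 55_476.0, "cost_pfd": 44_261.0, "lys": 0.540, "qalys": 0.313},
        "olaparib": {"total_cost": 48_526.0, "cost_pfd": 32_096.0, "lys": 0.665, "qalys": 0.380},
    },
}

#: Published incremental results (for cross-checks only, not arithmetic targets).
REPORTED = {
    "A": {"delta_qalys": 0.063, "delta_lys": 0.100, "icer": 116_903.0, "inhb": 0.01, "inmb": 2_090.0},
    "B": {"delta_qalys": 0.068, "delta_lys": 0.125, "icer": "dominant", "inhb": 0.114, "inmb": 17_109.0},
}

#: Whole-population biomarker prevalences behind the number-needed-to-screen
#: argument: 28% for the broad 15-gene panel, of which 63% carry one of the
#: three core alterations (0.28 * 0.63 ~= 18%).
PREVALENCE = {"A": 0.18, "B": 0.28}

NGS_TEST_COST = 5_800.0
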