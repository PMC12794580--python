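"""Transfusion-dilution arithmetic for cohort confounder checks.

Fresh frozen plasma (FFP) transfused during ICU care contains donor
N-glycoproteins and could in principle skew endogenous serum glycome
measurements. The dilution check compares the total transfused FFP volume
with the cohort's total endogenous plasma volume: a small percentage argues
the confounder is negligible.
"""

from __future__ import annotations

__all__ = ["plasma_dilution_percent"]


def plasma_dilution_percent(
    transfused_ml: float = 7125.0,
    n_patients: int = 37,
    plasma_ml_per_patient: float = 4625.0,
) -> float:
    """Transfused volume as a percent of the cohort's endogenous plasma.

    Defaults are a 37-patient cohort that received 7,125 ml of FFP in total,
    against an estimated 4,625 ml plasma per patient, giving ~4.16%.
    """
    if transfused_ml < 0:
        raise ValueError("transfused_ml must be nonnegative")
    if n_patients < 1 or plasma_ml_per_patient <= 0:
        raise ValueError("cohort plasma volume must be positive")
    return 100.0 * transfused_ml / (n_patients * plasma_ml_per_patient)
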