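"""Unit conventions and the one place unit conversions live.

All times are hours post-dose, plasma concentrations ng/mL and doses mg.
Because ng/mL is identical to ug/L, converting the dose to ug makes apparent
clearance come out in L/h with no further factors:

    CL/F [L/h] = dose [ug] / AUC0-inf [ug*h/L]   (ug*h/L == h*ng/mL)

Amounts inside the PBPK state vector are kept in ug for the same reason.
"""

UG_PER_MG = 1000.0


def dose_mg_to_ug(dose_mg: float) -> float:
    return dose_mg * UG_PER_MG


def clearance_l_per_h(dose_mg: float, auc_h_ng_ml: float) -> float:
    """Apparent clearance CL/F from a dose in mg and an AUC in h*ng/mL."""
    return dose_mg_to_ug(dose_mg) / auc_h_ng_ml
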