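"""Estimated glomerular filtration rate via the 2009 CKD-EPI creatinine equation.

The equation (no race term) is

    eGFR = 141 * min(Scr/kappa, 1)**alpha * max(Scr/kappa, 1)**-1.209
           * 0.993**age * (1.018 if female)

with serum creatinine ``Scr`` in mg/dL, ``kappa`` = 0.7 (female) / 0.9 (male)
and ``alpha`` = -0.329 (female) / -0.411 (male).  eGFR is returned in
mL/min/1.73 m^2.  The race factor is never applied, following current
European laboratory-medicine recommendations.

The piecewise closed-form inverse is also provided: it is what lets a
synthetic-data generator place a patient at an exact target eGFR and emit
the creatinine value a laboratory would have reported.
"""

from __future__ import annotations

import numpy as np

KAPPA = {"female": 0.7, "male": 0.9}
ALPHA = {"female": -0.329, "male": -0.411}
_SLOPE = -1.209
_AGE_FACTOR = 0.993
_CONSTANT = 141.0
_FEMALE_MULTIPLIER = 1.018

UMOL_PER_MGDL = 88.4  # creatinine unit conversion: umol/L -> mg/dL is /88.4


def _norm_sex(sex: str) -> str:
    s = str(sex).strip().lower()
    if s in ("m", "male"):
        return "male"
    if s in ("f", "w", "female"):
        return "female"
    raise ValueError(f"unrecognized sex category: {sex!r}")


def compute_egfr(creatinine: float, age: float, sex: str) -> float:
    """CKD-EPI 2009 eGFR (mL/min/1.73 m^2) from creatinine (mg/dL), age, sex.

    Parameters
    ----------
    creatinine : float or array
        Serum creatinine in mg/dL; must be strictly positive.
    age : float or array
        Age in years at the time of measurement; must be >= 18 (the
        equation is not validated for children).
    sex : str
        ``"male"``/``"m"`` or ``"female"``/``"f"``/``"w"``.
    """
    sex = _norm_sex(sex)
    scr = np.asarray(creatinine, dtype=float)
    age_a = np.asarray(age, dtype=float)
    if np.any(scr <= 0):
        raise ValueError("creatinine must be > 0 mg/dL")
    if np.any(age_a < 18):
        raise ValueError("age must be >= 18 years")
    kappa = KAPPA[sex]
    alpha = ALPHA[sex]
    ratio = scr / kappa
    egfr = (
        _CONSTANT
        * np.minimum(ratio, 1.0) ** alpha
        * np.maximum(ratio, 1.0) ** _SLOPE
        * _AGE_FACTOR**age_a
    )
    if sex == "female":
        egfr = egfr * _FEMALE_MULTIPLIER
    if egfr.ndim == 0:
        return float(egfr)
    return egfr


def invert_egfr_to_creatinine(target_egfr: float, age: float, sex: str) -> float:
    """Creatinine (mg/dL) whose CKD-EPI 2009 eGFR equals ``target_egfr``.

    The equation is strictly decreasing in creatinine, so the inverse is
    unique.  Let ``A = 141 * 0.993**age * (1.018 if female)`` be the value
    attained at ``Scr = kappa``.  For targets below ``A`` the creatinine lies
    on the high branch (exponent -1.209); above ``A`` it lies on the low
    branch (exponent alpha).  Any positive target is reachable; non-positive
    targets raise.
    """
    sex = _norm_sex(sex)
    g = np.asarray(target_egfr, dtype=float)
    age_a = np.asarray(age, dtype=float)
    if np.any(g <= 0):
        raise ValueError("target eGFR must be > 0")
    if np.any(age_a < 18):
        raise ValueError("age must be >= 18 years")
    kappa = KAPPA[sex]
    alpha = ALPHA[sex]
    anchor = _CONSTANT * _AGE_FACTOR**age_a
    if sex == "female":
        anchor = anchor * _FEMALE_MULTIPLIER
    ratio = g / anchor
    # ratio < 1  -> Scr > kappa branch; ratio >= 1 -> Scr <= kappa branch
    scr = np.where(
        ratio < 1.0,
        kappa * ratio ** (1.0 / _SLOPE),
        kappa * ratio ** (1.0 / alpha),
    )
    if scr.ndim == 0:
        return float(scr)
    return scr
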