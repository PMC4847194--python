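"""Host metabolic phenotype scoring: HOMA-IR, insulin-resistance and NAFLD
flags, and the next-timepoint weight response.

HOMA-IR is (fasting glucose mg/dL x fasting insulin mU/L) / 405; values above
13.2 (the literature-derived upper limit of normal for age/diet-matched mice)
count as elevated. A mouse is called insulin-resistant when at least two of
{elevated HOMA-IR, impaired glucose tolerance (IPGTT), impaired insulin
sensing (IPITT)} hold; GTT/ITT impairment are clinical judgments supplied as
inputs. NAFLD is diagnostic when the activity score exceeds 5 with fibrosis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

HOMA_DENOMINATOR = 405.0
HOMA_UPPER_NORMAL = 13.2

#: Censoring conventions for raw tolerance-test curves.
GTT_CLAMP_MG_DL = 500.0
ITT_RESCUE_MG_DL = 20.0


@dataclass
class MetabolicFlags:
    homa_ir: float
    homa_elevated: bool
    gtt_impaired: bool
    itt_impaired: bool
    insulin_resistant: bool
    nafld: bool = False


def homa_ir(glucose_mg_dl: float, insulin_mU_L: float) -> float:
    """HOMA-IR = glucose [mg/dL] x insulin [mU/L] / 405."""
    g = np.asarray(glucose_mg_dl, dtype=float)
    i = np.asarray(insulin_mU_L, dtype=float)
    if np.any(g <= 0) or np.any(i <= 0):
        raise ValueError("glucose and insulin must be positive")
    out = g * i / HOMA_DENOMINATOR
    return float(out) if out.ndim == 0 else out


def homa_elevated(score: float, threshold: float = HOMA_UPPER_NORMAL):
    """Strictly above the upper-normal limit counts as elevated."""
    return np.asarray(score) > threshold if np.ndim(score) else score > threshold


def classify_ir(homa_flag: bool, gtt_impaired: bool, itt_impaired: bool) -> bool:
    """Insulin resistant iff at least two of the three criteria hold."""
    return (int(bool(homa_flag)) + int(bool(gtt_impaired))
            + int(bool(itt_impaired))) >= 2


def nafld_flag(nas_score: float, fibrosis_present: bool) -> bool:
    """Diagnostic NAFLD iff activity score strictly exceeds 5 with fibrosis."""
    return bool(nas_score > 5 and fibrosis_present)


def metabolic_flags(glucose_mg_dl: float, insulin_mU_L: float,
                    gtt_impaired: bool, itt_impaired: bool,
                    nas_score: float = 0.0,
                    fibrosis_present: bool = False) -> MetabolicFlags:
    """All host metabolic flags for one animal."""
    score = homa_ir(glucose_mg_dl, insulin_mU_L)
    h = bool(score > HOMA_UPPER_NORMAL)
    return MetabolicFlags(score, h, bool(gtt_impaired), bool(itt_impaired),
                          classify_ir(h, gtt_impaired, itt_impaired),
                          nafld_flag(nas_score, fibrosis_present))


def clamp_gtt(values) -> np.ndarray:
    """Apply the glucometer detection-limit convention to a raw GTT curve."""
    return np.minimum(np.asarray(values, dtype=float), GTT_CLAMP_MG_DL)


def weight_plus_one(weights: pd.DataFrame) -> pd.Series:
    """Next-measurement weight (Weight+1) per (subject, week).

    ``weights`` needs columns ``subject_id``, ``week``, ``Weight``. For each
    sample the response is the same subject's weight at the next later
    measurement, whatever the spacing; each subject's final measurement has
    no successor and comes back as NaN (excluded from response matrices).
    """
    req = {"subject_id", "week", "Weight"}
    if not req.issubset(weights.columns):
        raise ValueError(f"weights frame needs columns {sorted(req)}")
    out = pd.Series(np.nan, index=weights.index, name="Weight+1")
    for _, grp in weights.groupby("subject_id"):
        grp = grp.sort_values("week")
        out[grp.index[:-1]] = grp["Weight"].to_numpy()[1:]
    return out
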