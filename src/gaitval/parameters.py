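"""The 12 sagittal joint-angle parameters per gait cycle.

Per cycle: ankle peak dorsiflexion, peak plantarflexion and excursion
over the whole cycle; knee stance-phase and swing-phase peak flexion,
peak extension and excursion; hip peak flexion, peak extension and
excursion over the whole cycle.  Peak-extension (and plantarflexion)
values are reported as positive magnitudes of the most extended
(minimum signed) value, as is conventional in clinical tables; signed
variants are kept alongside.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import GaitCycle

#: Canonical parameter names in reporting order.
PARAMETER_NAMES: tuple[str, ...] = (
    "ankle_peak_dorsiflexion",
    "ankle_peak_plantarflexion",
    "ankle_excursion",
    "knee_stance_peak_flexion",
    "knee_stance_peak_extension",
    "knee_stance_excursion",
    "knee_swing_peak_flexion",
    "knee_swing_peak_extension",
    "knee_swing_excursion",
    "hip_peak_flexion",
    "hip_peak_extension",
    "hip_excursion",
)

PARAMETER_JOINT = {name: name.split("_", 1)[0] for name in PARAMETER_NAMES}


def extract_parameters(cycle: GaitCycle) -> dict:
    """The 12 named parameter values (degrees) for one gait cycle.

    Knee parameters are phase-restricted using the force-derived
    toe-off; ankle and hip parameters use the whole cycle.
    """
    pct = np.arange(101, dtype=float)
    stance = pct <= cycle.stance_pct
    swing = ~stance
    if not stance.any() or not swing.any():
        raise ValueError("empty phase slice; cannot extract phase-restricted parameters")
    ankle = np.asarray(cycle.normalized_angles["ankle"], dtype=float)
    knee = np.asarray(cycle.normalized_angles["knee"], dtype=float)
    hip = np.asarray(cycle.normalized_angles["hip"], dtype=float)

    def peaks(vals: np.ndarray) -> tuple[float, float, float]:
        hi, lo = float(np.max(vals)), float(np.min(vals))
        return hi, abs(lo), hi - lo

    a_hi, a_lo, a_exc = peaks(ankle)
    ks_hi, ks_lo, ks_exc = peaks(knee[stance])
    kw_hi, kw_lo, kw_exc = peaks(knee[swing])
    h_hi, h_lo, h_exc = peaks(hip)
    return {
        "ankle_peak_dorsiflexion": a_hi,
        "ankle_peak_plantarflexion": a_lo,
        "ankle_excursion": a_exc,
        "knee_stance_peak_flexion": ks_hi,
        "knee_stance_peak_extension": ks_lo,
        "knee_stance_excursion": ks_exc,
        "knee_swing_peak_flexion": kw_hi,
        "knee_swing_peak_extension": kw_lo,
        "knee_swing_excursion": kw_exc,
        "hip_peak_flexion": h_hi,
        "hip_peak_extension": h_lo,
        "hip_excursion": h_exc,
    }


def parameter_table(rows: list[dict]) -> pd.DataFrame:
    """Assemble a tidy parameter table.

    Each input row carries participant, trial, side, source and the 12
    parameter values; the result has one row per (…, parameter).
    """
    records = []
    for row in rows:
        meta = {k: row[k] for k in ("participant", "trial", "side", "source")}
        for name in PARAMETER_NAMES:
            records.append({**meta, "parameter": name, "value": float(row[name])})
    df = pd.DataFrame(records)
    if not df.empty and (df.loc[df["parameter"].str.endswith("excursion"), "value"] < 0).any():
        raise ValueError("excursion parameters must be non-negative")
    return df


def aggregate(table: pd.DataFrame) -> pd.DataFrame:
    """Per-participant trial means of each parameter.

    Returns one row per (participant, side, source, parameter) with the
    arithmetic mean over available trials and the trial count.
    """
    if table.empty:
        raise ValueError("cannot aggregate an empty parameter table")
    g = table.groupby(["participant", "side", "source", "parameter"], sort=True)["value"]
    out = g.agg(value="mean", n_trials="count").reset_index()
    return out
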