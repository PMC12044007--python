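"""Spectral-count triage of candidate E3-ligase substrates from IP-MS.

The funnel: per-protein fold change of median pseudo-counted PSM counts
(bait IP over empty-vector IP) with an equal-variance t-test on the +1
counts; a joint significance and fold-change filter; intersection with an
independently enriched pilot list; and a cross-reference against a
dose-titration proteome, requiring a decreasing abundance trend with
increasing inducer dose for a protein to be called a likely substrate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class SubstrateCall:
    protein_id: str
    fc_enrichment: float
    p_enrichment: float
    passed_enrichment: bool = False
    in_pilot_overlap: bool = False
    dose_slope: float = float("nan")
    p_dose: float = float("nan")
    p_dose_endpoint: float = float("nan")
    passed_dose: bool = False
    final_candidate: bool = False


def _split_conditions(
    psm: pd.DataFrame, condition_map: pd.DataFrame
) -> tuple[list[str], list[str]]:
    cm = dict(zip(condition_map["sample"], condition_map["condition"]))
    missing = [c for c in psm.columns if c not in cm]
    if missing:
        raise ValueError(f"samples without a condition: {missing}")
    bait = [c for c in psm.columns if cm[c] == "bait"]
    ctrl = [c for c in psm.columns if cm[c] == "control"]
    if len(bait) < 2 or len(ctrl) < 2:
        raise ValueError("need >= 2 samples per condition")
    return bait, ctrl


def psm_enrichment(
    psm: pd.DataFrame, condition_map: pd.DataFrame
) -> pd.DataFrame:
    """Per-protein enrichment fold change and p-value.

    fc = median(bait counts + 1) / median(control counts + 1); p from an
    unpaired two-tailed equal-variance t-test on the +1 counts.  Proteins
    with all-identical values across both conditions get p = 1.
    """
    bait_cols, ctrl_cols = _split_conditions(psm, condition_map)
    bait = psm[bait_cols].to_numpy(dtype=float) + 1.0
    ctrl = psm[ctrl_cols].to_numpy(dtype=float) + 1.0
    fc = np.median(bait, axis=1) / np.median(ctrl, axis=1)
    import warnings

    with warnings.catch_warnings(), np.errstate(invalid="ignore", divide="ignore"):
        # proteins with identical counts in both conditions trip a scipy
        # precision warning; they are assigned p = 1 below
        warnings.simplefilter("ignore", RuntimeWarning)
        t = stats.ttest_ind(bait, ctrl, axis=1, equal_var=True)
    p = np.where(np.isnan(t.pvalue), 1.0, t.pvalue)
    return pd.DataFrame(
        {"protein_id": psm.index, "fc": fc, "p": p}
    ).set_index("protein_id")


def enrichment_filter(
    enrichment: pd.DataFrame, fc_min: float = 1.5, p_max: float = 0.05
) -> list[str]:
    """Proteins with p < p_max and fold change strictly > fc_min."""
    keep = enrichment[(enrichment["p"] < p_max) & (enrichment["fc"] > fc_min)]
    return list(keep.index)


def pilot_overlap(primary: list[str], pilot: set[str] | list[str]) -> list[str]:
    """Intersection with the pilot-experiment list, in primary order."""
    pilot_set = set(pilot)
    return [p for p in primary if p in pilot_set]


def dose_trend(
    dose_table: pd.DataFrame, protein_id: str
) -> tuple[float, float, float]:
    """Least-squares slope of mean abundance vs log10(dose) for one protein.

    Returns (slope, one-sided decreasing-trend p, two-tailed endpoint p
    comparing the lowest and highest dose replicates).
    """
    sub = dose_table[dose_table["protein_id"] == protein_id]
    means = sub.groupby("dose")["abundance"].mean()
    if len(means) < 3:
        raise ValueError("need >= 3 distinct doses for trend testing")
    res = stats.linregress(np.log10(means.index.to_numpy()), means.to_numpy())
    p_one = res.pvalue / 2.0 if res.slope < 0 else 1.0 - res.pvalue / 2.0
    lo, hi = means.index.min(), means.index.max()
    end = stats.ttest_ind(
        sub.loc[sub["dose"] == lo, "abundance"],
        sub.loc[sub["dose"] == hi, "abundance"],
        equal_var=True,
    )
    return float(res.slope), float(p_one), float(end.pvalue)


def dose_decrease_filter(
    dose_table: pd.DataFrame,
    candidates: list[str],
    p_max: float = 0.05,
) -> dict[str, tuple[float, float, float, bool]]:
    """Per candidate: (slope, trend p, endpoint p, passed) where passed
    requires a negative slope with one-sided trend p < p_max."""
    out = {}
    present = set(dose_table["protein_id"])
    for pid in candidates:
        if pid not in present:
            raise KeyError(f"candidate {pid!r} missing from dose table")
        slope, p_one, p_end = dose_trend(dose_table, pid)
        out[pid] = (slope, p_one, p_end, bool(slope < 0 and p_one < p_max))
    return out


def triage(
    psm: pd.DataFrame,
    condition_map: pd.DataFrame,
    pilot: set[str] | list[str],
    dose_table: pd.DataFrame,
    fc_min: float = 1.5,
    p_max: float = 0.05,
) -> list[SubstrateCall]:
    """Full substrate funnel; ``final_candidate`` requires every gate."""
    enr = psm_enrichment(psm, condition_map)
    passed = set(enrichment_filter(enr, fc_min=fc_min, p_max=p_max))
    overlap = set(pilot_overlap(sorted(passed), pilot))
    dose_present = set(dose_table["protein_id"])
    dose_calls = dose_decrease_filter(
        dose_table, [p for p in overlap if p in dose_present], p_max=p_max
    )
    calls = []
    for pid in enr.index:
        row = enr.loc[pid]
        call = SubstrateCall(
            protein_id=pid,
            fc_enrichment=float(row["fc"]),
            p_enrichment=float(row["p"]),
            passed_enrichment=pid in passed,
            in_pilot_overlap=pid in overlap,
        )
        if pid in dose_calls:
            call.dose_slope, call.p_dose, call.p_dose_endpoint, call.passed_dose = dose_calls[pid]
        call.final_candidate = bool(
            call.passed_enrichment and call.in_pilot_overlap and call.passed_dose
        )
        calls.append(call)
    return calls
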