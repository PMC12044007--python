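"""Enumeration-based colocalization of two association signals.

Given per-variant effect estimates and standard errors for two traits over a
shared region, each variant gets a Wakefield approximate Bayes factor per
trait; the five single-causal-variant hypotheses (no association, trait 1
only, trait 2 only, two distinct causal variants, one shared causal variant)
are enumerated with priors (p1, p2, p12) and normalized with log-sum-exp
throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

#: Reference prior effect sds: 0.15 for quantitative traits, 0.2 for
#: case-control (log-odds) traits.
PRIOR_SD_QUANT = 0.15
PRIOR_SD_CC = 0.2


@dataclass
class ColocResult:
    pp: dict  # keys "pp0".."pp4"
    priors: tuple[float, float, float]
    n_variants: int
    labf1: np.ndarray
    labf2: np.ndarray

    def __getitem__(self, key: str) -> float:
        return self.pp[key]


def wakefield_abf(beta, se, prior_sd: float) -> np.ndarray | float:
    """log approximate Bayes factor for association of one variant.

    log ABF = 0.5 ln(se^2/(se^2+W)) + 0.5 z^2 W/(se^2+W), W = prior_sd^2.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be positive")
    w = prior_sd**2
    z2 = (beta / se) ** 2
    shrink = w / (se**2 + w)
    out = 0.5 * np.log(1.0 - shrink) + 0.5 * z2 * shrink
    return float(out) if out.ndim == 0 else out


def _logdiff(a: float, b: float) -> float:
    """log(exp(a) - exp(b)) for a >= b, -inf when equal."""
    if b >= a:
        return -np.inf
    return a + np.log1p(-np.exp(b - a))


def harmonize(
    trait1: pd.DataFrame, trait2: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """Inner-join two summary tables on variant_id; returns dropped count."""
    shared = trait1.merge(
        trait2, on="variant_id", suffixes=("_1", "_2"), how="inner"
    )
    dropped = len(trait1) + len(trait2) - 2 * len(shared)
    t1 = shared[["variant_id", "beta_1", "se_1"]].rename(
        columns={"beta_1": "beta", "se_1": "se"}
    )
    t2 = shared[["variant_id", "beta_2", "se_2"]].rename(
        columns={"beta_2": "beta", "se_2": "se"}
    )
    return t1, t2, dropped


def posteriors_from_labf(
    l1: np.ndarray,
    l2: np.ndarray,
    p1: float = 1e-4,
    p2: float = 1e-4,
    p12: float = 1e-5,
) -> ColocResult:
    """Five-hypothesis enumeration over aligned per-variant log ABFs."""
    l1 = np.asarray(l1, dtype=float)
    l2 = np.asarray(l2, dtype=float)
    if l1.shape != l2.shape:
        raise ValueError("log ABF vectors must be aligned")
    m = len(l1)
    s1 = float(logsumexp(l1))
    s2 = float(logsumexp(l2))
    s12 = float(logsumexp(l1 + l2))
    # sum over ordered pairs i != j = (sum_i)(sum_j) - sum_i (i==j)
    s_cross = _logdiff(s1 + s2, s12)

    lh = np.array(
        [
            0.0,
            np.log(p1) + s1,
            np.log(p2) + s2,
            np.log(p1) + np.log(p2) + s_cross,
            np.log(p12) + s12,
        ]
    )
    norm = logsumexp(lh)
    pp = np.exp(lh - norm)
    return ColocResult(
        pp={f"pp{h}": float(pp[h]) for h in range(5)},
        priors=(p1, p2, p12),
        n_variants=m,
        labf1=l1,
        labf2=l2,
    )


def coloc_posteriors(
    trait1: pd.DataFrame,
    trait2: pd.DataFrame,
    p1: float = 1e-4,
    p2: float = 1e-4,
    p12: float = 1e-5,
    prior_sd1: float = PRIOR_SD_CC,
    prior_sd2: float = PRIOR_SD_QUANT,
) -> ColocResult:
    """Posterior probabilities of the five colocalization hypotheses.

    Tables need columns variant_id, beta, se and are inner-joined on
    variant_id (at least two shared variants required).  Default prior
    effect sds assume a case-control trait 1 and a quantitative trait 2.
    """
    t1, t2, _ = harmonize(trait1, trait2)
    if len(t1) < 2:
        raise ValueError("need at least 2 shared variants")
    l1 = wakefield_abf(t1["beta"].to_numpy(), t1["se"].to_numpy(), prior_sd1)
    l2 = wakefield_abf(t2["beta"].to_numpy(), t2["se"].to_numpy(), prior_sd2)
    return posteriors_from_labf(l1, l2, p1=p1, p2=p2, p12=p12)
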