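"""Study-level odds-ratio algebra and fixed-effect inverse-variance meta-analysis.

Combines published per-study allelic odds ratios (point estimate plus 95% CI)
on the log-odds scale, with weights 1/se^2 — the classical fixed-effect IVW
scheme (equivalent to METAL's standard-error scheme).  Also recovers a crude
allelic odds ratio from printed minor-allele frequencies and sample sizes via
the 2x2 allele-count table with a Woolf standard error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

Z95 = float(stats.norm.ppf(0.975))


@dataclass
class StudySummary:
    """One study's published allelic odds ratio with its 95% CI."""

    label: str
    or_point: float
    ci_low: float
    ci_high: float
    p: float | None = None
    n_case: int | None = None
    n_control: int | None = None
    maf_case: float | None = None
    maf_control: float | None = None

    def __post_init__(self) -> None:
        if not (0 < self.ci_low <= self.or_point <= self.ci_high):
            raise ValueError(
                f"{self.label}: need 0 < ci_low <= or <= ci_high, got "
                f"({self.ci_low}, {self.or_point}, {self.ci_high})"
            )
        for maf in (self.maf_case, self.maf_control):
            if maf is not None and not (0.0 <= maf <= 0.5):
                raise ValueError(f"{self.label}: MAF {maf} outside [0, 0.5]")

    @property
    def beta(self) -> float:
        return float(np.log(self.or_point))

    @property
    def se(self) -> float:
        return se_from_ci(self.ci_low, self.ci_high)


@dataclass
class MetaResult:
    beta: float
    se: float
    z: float
    p: float

    @property
    def or_point(self) -> float:
        return float(np.exp(self.beta))

    @property
    def ci_low(self) -> float:
        return float(np.exp(self.beta - Z95 * self.se))

    @property
    def ci_high(self) -> float:
        return float(np.exp(self.beta + Z95 * self.se))


def se_from_ci(ci_low: float, ci_high: float, level: float = 0.95) -> float:
    """Standard error of the log odds ratio implied by a symmetric CI.

    se = (ln ci_high - ln ci_low) / (2 z), z the two-sided normal quantile
    for ``level``.
    """
    if not (0 < ci_low < ci_high):
        raise ValueError("need 0 < ci_low < ci_high")
    if not (0 < level < 1):
        raise ValueError("level must be in (0, 1)")
    z = stats.norm.ppf(0.5 + level / 2.0)
    return float((np.log(ci_high) - np.log(ci_low)) / (2.0 * z))


def ci_from(beta: float, se: float, level: float = 0.95) -> tuple[float, float]:
    z = stats.norm.ppf(0.5 + level / 2.0)
    return float(np.exp(beta - z * se)), float(np.exp(beta + z * se))


def ivw_fixed_meta(studies: list[tuple[float, float]]) -> MetaResult:
    """Fixed-effect inverse-variance meta-analysis of (beta, se) pairs."""
    if len(studies) == 0:
        raise ValueError("at least one study required")
    betas = np.array([b for b, _ in studies], dtype=float)
    ses = np.array([s for _, s in studies], dtype=float)
    if np.any(ses <= 0):
        raise ValueError("all standard errors must be positive")
    w = 1.0 / ses**2
    beta = float(np.sum(w * betas) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    z = beta / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return MetaResult(beta=beta, se=se, z=z, p=p)


def cochran_q(studies: list[tuple[float, float]]) -> float:
    """Cochran's heterogeneity Q (logged alongside the fixed-effect result)."""
    meta = ivw_fixed_meta(studies)
    return float(
        sum((b - meta.beta) ** 2 / s**2 for b, s in studies)
    )


def allelic_or_from_maf(
    maf_case: float,
    maf_control: float,
    n_case: int,
    n_control: int,
) -> tuple[float, float, tuple[float, float], bool]:
    """Crude allelic OR from minor-allele frequencies and subject counts.

    Allele counts are frequencies times 2N rounded half-up to integers; the
    OR is that of the resulting 2x2 allele table with a Woolf standard error
    (sqrt of the sum of reciprocal cells) and a 95% CI on the log scale.
    Zero cells get the Haldane 0.5 correction and set the returned flag.
    """
    for maf in (maf_case, maf_control):
        if not (0.0 < maf < 1.0):
            raise ValueError("frequencies must be in (0, 1)")
    if n_case <= 0 or n_control <= 0:
        raise ValueError("counts must be positive")

    def _round_half_up(x: float) -> int:
        return int(np.floor(x + 0.5))

    a = _round_half_up(2 * n_case * maf_case)
    b = 2 * n_case - a
    c = _round_half_up(2 * n_control * maf_control)
    d = 2 * n_control - c

    corrected = False
    cells = [a, b, c, d]
    if any(v == 0 for v in cells):
        corrected = True
        a, b, c, d = (v + 0.5 for v in cells)
    or_point = (a * d) / (b * c)
    se = float(np.sqrt(1 / a + 1 / b + 1 / c + 1 / d))
    ci = ci_from(float(np.log(or_point)), se)
    return float(or_point), se, ci, corrected


def meta_from_table(studies: pd.DataFrame) -> MetaResult:
    """IVW meta-analysis of a study table with columns or, ci_low, ci_high."""
    pairs = [
        (float(np.log(row["or"])), se_from_ci(row["ci_low"], row["ci_high"]))
        for _, row in studies.iterrows()
    ]
    return ivw_fixed_meta(pairs)
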