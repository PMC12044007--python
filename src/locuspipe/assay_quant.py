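"""Quantification of allelic wet-lab readouts.

Covers the four assay families used to validate a regulatory variant and its
target gene: qPCR standard curves and ChIP percent-input, TaqMan allelic
ratios (IP vs input enrichment), dual-luciferase reporter normalization, and
growth-curve fold changes.  Quantities always go through the standard curve
rather than delta-delta-Ct shortcuts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class StandardCurve:
    """Linear fit of Ct on log10(quantity).

    Amplification efficiency E = 10**(-1/slope) - 1 (E = 1 is perfect
    doubling, slope -3.3219).
    """

    slope: float
    intercept: float
    r_squared: float

    @property
    def efficiency(self) -> float:
        return float(10.0 ** (-1.0 / self.slope) - 1.0)

    @property
    def valid(self) -> bool:
        return self.slope < 0

    def quantity(self, ct) -> np.ndarray | float:
        """Invert the curve: quantity = 10**((ct - intercept)/slope)."""
        q = 10.0 ** ((np.asarray(ct, dtype=float) - self.intercept) / self.slope)
        return float(q) if q.ndim == 0 else q


@dataclass
class AllelicEnrichment:
    ratio_ip: float
    ratio_input: float
    enrichment: float
    p: float


def fit_standard_curve(quantities, cts) -> StandardCurve:
    """Least-squares standard curve from a dilution series."""
    q = np.asarray(quantities, dtype=float)
    ct = np.asarray(cts, dtype=float)
    if np.any(q <= 0):
        raise ValueError("quantities must be positive")
    if len(np.unique(q)) < 3:
        raise ValueError("need >= 3 distinct quantities")
    res = stats.linregress(np.log10(q), ct)
    return StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )


def percent_input(
    ct_ip: float,
    curve: StandardCurve,
    ct_input: float,
    input_dilution_factor: float = 1.0,
) -> float:
    """ChIP recovery as percent of (dilution-adjusted) input chromatin.

    Both Cts are converted to quantities through the standard curve; the
    input quantity is multiplied by its dilution factor (e.g. 100 for a 1%
    input aliquot) before forming the percentage.
    """
    if not curve.valid:
        raise ValueError("invalid standard curve (slope >= 0)")
    q_ip = curve.quantity(ct_ip)
    q_input = curve.quantity(ct_input) * input_dilution_factor
    return float(100.0 * q_ip / q_input)


def allelic_enrichment(ip_ratios, input_ratios) -> AllelicEnrichment:
    """Allelic (A/G) skew of IP DNA relative to input DNA.

    Replicate ratios are aggregated as the mean of per-replicate ratios;
    enrichment = mean(IP A/G) / mean(input A/G); p from an unpaired
    two-tailed t-test of the replicate ratios.
    """
    ip = np.asarray(ip_ratios, dtype=float)
    inp = np.asarray(input_ratios, dtype=float)
    if len(ip) < 2 or len(inp) < 2:
        raise ValueError("need >= 2 replicates per group")
    if np.any(ip <= 0) or np.any(inp <= 0):
        raise ValueError("allelic ratios must be positive")
    t = stats.ttest_ind(ip, inp, equal_var=True)
    return AllelicEnrichment(
        ratio_ip=float(ip.mean()),
        ratio_input=float(inp.mean()),
        enrichment=float(ip.mean() / inp.mean()),
        p=float(t.pvalue),
    )


def luciferase_fold(
    firefly,
    renilla,
    ev_firefly,
    ev_renilla,
) -> np.ndarray:
    """Per-well firefly/Renilla activity as fold over the empty vector.

    fold_i = (F_i / R_i) / mean(EV F / EV R).
    """
    f = np.asarray(firefly, dtype=float)
    r = np.asarray(renilla, dtype=float)
    evf = np.asarray(ev_firefly, dtype=float)
    evr = np.asarray(ev_renilla, dtype=float)
    if np.any(r <= 0) or np.any(evr <= 0):
        raise ValueError("Renilla activity must be positive")
    ev_mean = float(np.mean(evf / evr))
    return (f / r) / ev_mean


def allele_activity_test(fold_a, fold_g) -> tuple[float, float]:
    """Unpaired two-tailed t-test of per-well fold changes between alleles.

    Returns (mean fold ratio A/G, p).
    """
    a = np.asarray(fold_a, dtype=float)
    g = np.asarray(fold_g, dtype=float)
    t = stats.ttest_ind(a, g, equal_var=True)
    return float(a.mean() / g.mean()), float(t.pvalue)


def growth_normalize(counts) -> np.ndarray:
    """Cell-count time series as fold change relative to the first timepoint."""
    x = np.asarray(counts, dtype=float)
    if x[0] <= 0:
        raise ValueError("count at the first timepoint must be positive")
    return x / x[0]
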