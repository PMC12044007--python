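"""Allele-differential transcription-factor motif analysis.

A position frequency matrix is converted to a log-odds position weight
matrix; the p-value of a PWM score (the probability that a random background
sequence scores at least as high) is computed exactly on a discretized score
scale by dynamic programming — convolving the per-position score
distributions under the background — with an explicit bound on the
discretization error.  For a SNP, both alleles are scanned over every window
overlapping the variant on both strands; the ratio of the two best-hit
p-values (max/min) is the fold change used to rank motifs by predicted
allele-differential binding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

ALPHABET = "ACGT"
_COMP = str.maketrans("ACGT", "TGCA")
DEFAULT_SCALE_TARGET = 10_000.0


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class PWM:
    """Log-odds motif model over ACGT with its background distribution."""

    name: str
    log_odds: np.ndarray  # L x 4
    background: np.ndarray  # length-4 probabilities
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        self.log_odds = np.asarray(self.log_odds, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.log_odds.ndim != 2 or self.log_odds.shape[1] != 4:
            raise ValueError("log_odds must be L x 4")
        if not np.isclose(self.background.sum(), 1.0):
            raise ValueError("background must sum to 1")
        if not np.all(np.isfinite(self.log_odds)):
            raise ValueError("log_odds entries must be finite")

    @property
    def length(self) -> int:
        return self.log_odds.shape[0]

    def score(self, seq: str) -> float:
        if len(seq) != self.length:
            raise ValueError("sequence length must equal motif length")
        idx = [ALPHABET.index(b) for b in seq.upper()]
        return float(sum(self.log_odds[i, b] for i, b in enumerate(idx)))

    def reverse_complement(self) -> "PWM":
        return PWM(
            name=self.name,
            log_odds=self.log_odds[::-1, ::-1].copy(),
            background=self.background.copy(),
            pseudocount=self.pseudocount,
        )


@dataclass
class AlleleMotifReport:
    snp_id: str
    motif: str
    allele1: str
    allele2: str
    p_allele1: float
    p_allele2: float
    fold_change: float
    stronger_allele: str
    hit1: tuple[float, str, int]  # (score, strand, plus-strand offset)
    hit2: tuple[float, str, int]


def pfm_to_pwm(
    counts: np.ndarray,
    background: np.ndarray | None = None,
    pseudocount: float = 1.0,
    name: str = "motif",
) -> PWM:
    """Log-odds PWM from a position frequency (count) matrix.

    log_odds[i][b] = ln((c[i][b] + pc*bg[b]) / (sum_b' c[i][b'] + pc)) - ln(bg[b]).
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[1] != 4:
        raise ValueError("counts must be L x 4")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    if np.any(counts.sum(axis=1) == 0):
        raise ValueError("all-zero PFM column")
    bg = (
        np.full(4, 0.25) if background is None else np.asarray(background, float)
    )
    probs = (counts + pseudocount * bg[None, :]) / (
        counts.sum(axis=1, keepdims=True) + pseudocount
    )
    return PWM(
        name=name,
        log_odds=np.log(probs) - np.log(bg)[None, :],
        background=bg,
        pseudocount=pseudocount,
    )


def _discretize(
    pwm: PWM, scale_target: float = DEFAULT_SCALE_TARGET
) -> tuple[np.ndarray, float]:
    """Integer per-position scores: round(k * log_odds).

    k is chosen so the widest per-position score range spans ~scale_target
    integer steps; per-position rounding error is at most 0.5/k, so the
    total score error is at most L/(2k).
    """
    ranges = pwm.log_odds.max(axis=1) - pwm.log_odds.min(axis=1)
    widest = float(ranges.max())
    k = scale_target / widest if widest > 0 else 1.0
    int_scores = np.rint(k * pwm.log_odds).astype(np.int64)
    return int_scores, k


def _score_distribution(
    int_scores: np.ndarray, background: np.ndarray
) -> tuple[np.ndarray, int]:
    """Distribution of the total integer score under the background.

    Returns (probabilities, minimum total score); probabilities[i] is the
    mass at score min_total + i.
    """
    mins = int_scores.min(axis=1)
    maxs = int_scores.max(axis=1)
    total_range = int((maxs - mins).sum())
    if total_range > 50_000_000:
        raise OverflowError(
            "discretized score range too wide; reduce the scale target"
        )
    dist = np.zeros(total_range + 1)
    dist[0] = 1.0
    hi = 0
    for i in range(int_scores.shape[0]):
        new = np.zeros_like(dist)
        for b in range(4):
            off = int(int_scores[i, b] - mins[i])
            new[off : hi + off + 1] += background[b] * dist[: hi + 1]
        dist = new
        hi += int(maxs[i] - mins[i])
    return dist, int(mins.sum())


def _pvalue_from_int_score(
    pwm: PWM, int_score: int, scale_target: float = DEFAULT_SCALE_TARGET
) -> float:
    int_scores, _ = _discretize(pwm, scale_target)
    dist, min_total = _score_distribution(int_scores, pwm.background)
    idx = int_score - min_total
    if idx <= 0:
        return 1.0
    if idx > len(dist) - 1:
        return 0.0
    return float(dist[idx:].sum())


def score_pvalue(
    pwm: PWM,
    s: float,
    scale_target: float = DEFAULT_SCALE_TARGET,
    return_bound: bool = False,
):
    """P(PWM score >= s) for a background-distributed random sequence.

    The score axis is discretized with integer scaling (see ``_discretize``)
    and the exceedance mass at or above round(k*s) is summed.  With
    ``return_bound=True`` also returns (p_low, p_high), the p-values at
    thresholds shifted by the worst-case discretization error L/(2k) each
    way, bracketing the exact continuous-score p-value.
    """
    int_scores, k = _discretize(pwm, scale_target)
    dist, min_total = _score_distribution(int_scores, pwm.background)

    def tail(threshold_int: int) -> float:
        idx = threshold_int - min_total
        if idx <= 0:
            return 1.0
        if idx > len(dist) - 1:
            return 0.0
        return float(dist[idx:].sum())

    s_int = int(np.rint(k * s))
    p = tail(s_int)
    if not return_bound:
        return p
    err = int(np.ceil(pwm.length / 2.0)) + 1  # integer-units error margin
    return p, (tail(s_int + err), tail(s_int - err))


def snp_best_hit(
    pwm: PWM,
    sequence: str,
    snp_pos: int,
    allele: str,
    scale_target: float = DEFAULT_SCALE_TARGET,
) -> tuple[float, float, str, int]:
    """Best motif hit over all windows overlapping a SNP, both strands.

    ``snp_pos`` is the 1-based position of the variant within ``sequence``;
    the variant base is replaced by ``allele``.  Returns
    (best score, best-hit p-value, strand, 1-based plus-strand window start).
    Flanks of at least L-1 bases on each side of the SNP are required.
    """
    L = pwm.length
    seq = sequence.upper()
    if not (1 <= snp_pos <= len(seq)):
        raise ValueError("snp_pos outside sequence")
    if snp_pos - 1 < L - 1 or len(seq) - snp_pos < L - 1:
        raise ValueError(
            f"flank too short: need >= {L - 1} bases on each side of the SNP"
        )
    if len(allele) != 1 or allele.upper() not in ALPHABET:
        raise ValueError("allele must be a single ACGT base")
    seq = seq[: snp_pos - 1] + allele.upper() + seq[snp_pos:]

    int_scores, k = _discretize(pwm, scale_target)
    dist, min_total = _score_distribution(int_scores, pwm.background)
    suffix = np.cumsum(dist[::-1])[::-1]

    def tail(idx: int) -> float:
        if idx <= 0:
            return 1.0
        if idx > len(dist) - 1:
            return 0.0
        return float(suffix[idx])

    base_idx = {b: i for i, b in enumerate(ALPHABET)}
    best = None  # (int_score, strand, start)
    for start in range(snp_pos - L, snp_pos):  # 0-based window starts
        if start < 0 or start + L > len(seq):
            continue
        window = seq[start : start + L]
        fwd = int(
            sum(int_scores[i, base_idx[b]] for i, b in enumerate(window))
        )
        rc = reverse_complement(window)
        rev = int(sum(int_scores[i, base_idx[b]] for i, b in enumerate(rc)))
        for sc, strand in ((fwd, "+"), (rev, "-")):
            if best is None or sc > best[0]:
                best = (sc, strand, start + 1)
    int_best, strand, offset = best
    p = tail(int_best - min_total)
    return int_best / k, p, strand, offset


def fold_change_from_pvalues(
    p1: float, p2: float, allele1: str = "1", allele2: str = "2"
) -> tuple[float, str]:
    """Fold change max(p1,p2)/min(p1,p2) and the allele with the smaller p."""
    for p in (p1, p2):
        if not (0 < p <= 1):
            raise ValueError("p-values must be in (0, 1]")
    if p1 <= p2:
        return p2 / p1 if p1 < p2 else 1.0, allele1
    return p1 / p2, allele2


def snp_motif_report(
    pwm: PWM,
    sequence: str,
    snp_pos: int,
    allele1: str,
    allele2: str,
    snp_id: str = "",
    scale_target: float = DEFAULT_SCALE_TARGET,
) -> AlleleMotifReport:
    """Per-allele best hits and their p-value fold change for one motif."""
    s1, p1, st1, off1 = snp_best_hit(pwm, sequence, snp_pos, allele1, scale_target)
    s2, p2, st2, off2 = snp_best_hit(pwm, sequence, snp_pos, allele2, scale_target)
    fold, stronger = fold_change_from_pvalues(p1, p2, allele1, allele2)
    return AlleleMotifReport(
        snp_id=snp_id,
        motif=pwm.name,
        allele1=allele1,
        allele2=allele2,
        p_allele1=p1,
        p_allele2=p2,
        fold_change=fold,
        stronger_allele=stronger,
        hit1=(s1, st1, off1),
        hit2=(s2, st2, off2),
    )


def rank_disrupted_motifs(
    reports: list[AlleleMotifReport], fold_min: float = 1.0
) -> list[AlleleMotifReport]:
    """Reports with fold change >= fold_min, descending by fold change."""
    kept = [r for r in reports if r.fold_change >= fold_min]
    return sorted(kept, key=lambda r: -r.fold_change)
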