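"""Seeded generators for every input the pipeline consumes, with ground truth.

Raw inputs of the kind this pipeline is built for (case-control genotypes,
tissue eQTL summary statistics, IP-MS spectral counts, bulk RNA-seq counts,
qPCR plates) are typically controlled-access.  This module emulates each of
them with deterministic, seeded simulators that also return the planted truth
(causal variants, substrate proteins, enriched gene sets, amplification
efficiencies), so every downstream stage can be tested for calibration and
recovery.

Haplotypes are generated by a first-order Markov copy process: each site
copies the latent uniform of its left neighbour with probability ``ld_decay``
and redraws it otherwise, which gives a closed-form geometric decay of
allelic correlation (r ~ ld_decay**distance when site frequencies are equal).

All generators are pure functions of their config and a single integer seed;
independent streams are derived from the seed by the fixed offsets in
``_STREAM_OFFSETS``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

# Fixed per-generator stream offsets added to the global seed so that the
# generators stay independent yet reproducible from one integer.
_STREAM_OFFSETS = {
    "genotypes": 0,
    "phenotype": 1_000,
    "trait2": 2_000,
    "psm": 3_000,
    "rnaseq": 4_000,
    "qpcr": 5_000,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(int(seed) + _STREAM_OFFSETS[stream])


class InvalidConfigError(ValueError):
    """A simulation config violates its documented domain."""


@dataclass
class SimConfig:
    """Parameters of the LD-block case-control simulation.

    ``ld_decay`` is the adjacent-site copy probability of the haplotype
    Markov process (equal to the adjacent-pair allelic correlation when site
    frequencies are equal); ``causal_beta`` is the log-odds effect per unit
    of standardized dosage at ``causal_index``.
    """

    seed: int = 0
    n_individuals: int = 2000
    n_variants: int = 50
    ld_decay: float = 0.9
    causal_index: int | None = None  # default: middle of the block
    causal_beta: float = 0.4
    case_fraction: float = 0.5
    maf_range: tuple[float, float] = (0.2, 0.4)

    def __post_init__(self) -> None:
        if self.n_individuals < 2:
            raise InvalidConfigError("n_individuals must be >= 2")
        if self.n_variants < 1:
            raise InvalidConfigError("n_variants must be >= 1")
        if not (0.0 <= self.ld_decay < 1.0):
            raise InvalidConfigError("ld_decay must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise InvalidConfigError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if not (0.0 < self.case_fraction < 1.0):
            raise InvalidConfigError("case_fraction must be in (0, 1)")
        if self.causal_index is None:
            self.causal_index = self.n_variants // 2
        if not (0 <= self.causal_index < self.n_variants):
            raise InvalidConfigError("causal_index out of range")


@dataclass
class SyntheticTruth:
    """Planted ground truth accompanying a generated dataset."""

    causal_variants: set = field(default_factory=set)
    substrate_proteins: set = field(default_factory=set)
    enriched_gene_sets: set = field(default_factory=set)
    qpcr_efficiency: dict = field(default_factory=dict)


def variant_ids(m: int) -> list[str]:
    return [f"rs{i:05d}" for i in range(m)]


def simulate_ld_genotypes(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate an LD block of diploid dosages and its r-squared matrix.

    Returns ``(dosages, ld)`` where ``dosages`` is individuals x variants
    with values 0/1/2 and ``ld`` is the squared Pearson correlation of the
    dosage columns.
    """
    rng = _rng(config.seed, "genotypes")
    n, m = config.n_individuals, config.n_variants
    freqs = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)

    haps = np.empty((2 * n, m), dtype=np.int8)
    u = rng.uniform(size=(2 * n, m))
    copy = rng.uniform(size=(2 * n, m)) < config.ld_decay
    # Markov copy process on the latent uniforms preserves the per-site
    # marginal frequency exactly while inducing geometric LD decay.
    lat = u.copy()
    for j in range(1, m):
        lat[:, j] = np.where(copy[:, j], lat[:, j - 1], u[:, j])
    haps = (lat < freqs[None, :]).astype(np.int8)
    dos = haps[:n] + haps[n:]

    ids = variant_ids(m)
    dosages = pd.DataFrame(dos, columns=ids)
    ld = ld_matrix(dosages)
    return dosages, ld


def ld_matrix(dosages: pd.DataFrame) -> pd.DataFrame:
    """Squared Pearson correlation of dosage columns (NaN for zero variance)."""
    x = dosages.to_numpy(dtype=float)
    sd = x.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x, rowvar=False)
    r2 = r**2
    r2[sd == 0, :] = np.nan
    r2[:, sd == 0] = np.nan
    return pd.DataFrame(r2, index=dosages.columns, columns=dosages.columns)


def _solve_intercept(eta: np.ndarray, target: float) -> float:
    """Intercept alpha with mean(expit(alpha + eta)) == target."""
    from scipy.optimize import brentq

    def f(a: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(a + eta))))) - target

    return brentq(f, -30.0, 30.0)


def _score_test(g: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Single-covariate logistic score test: returns (beta, se, p).

    U = sum g_i (y_i - ybar), V = ybar(1-ybar) * sum (g_i - gbar)^2; the
    one-step estimate U/V and its standard error 1/sqrt(V) avoid iterative
    fitting instability at small counts.
    """
    ybar = y.mean()
    gc = g - g.mean()
    u = float(gc @ (y - ybar))
    v = float(ybar * (1 - ybar) * (gc @ gc))
    if v <= 0:
        return 0.0, np.inf, 1.0
    beta = u / v
    se = 1.0 / np.sqrt(v)
    z = u / np.sqrt(v)
    p = 2.0 * stats.norm.sf(abs(z))
    return beta, se, max(p, np.finfo(float).tiny)


def simulate_case_control_summary(
    dosages: pd.DataFrame, config: SimConfig
) -> pd.DataFrame:
    """Phenotype sampling plus per-variant logistic score-test summary stats.

    The phenotype follows a logistic model on the standardized dosage of the
    causal variant; each variant is then tested marginally.  Variants whose
    minor allele is carried exclusively by cases or controls (separation)
    are flagged rather than failing.
    """
    rng = _rng(config.seed, "phenotype")
    x = dosages.to_numpy(dtype=float)
    g = x[:, config.causal_index]
    sd = g.std()
    gz = (g - g.mean()) / sd if sd > 0 else np.zeros_like(g)
    eta = config.causal_beta * gz
    alpha = _solve_intercept(eta, config.case_fraction)
    y = (rng.uniform(size=len(g)) < 1.0 / (1.0 + np.exp(-(alpha + eta)))).astype(float)

    ids = list(dosages.columns)
    rows = []
    for j, vid in enumerate(ids):
        gj = x[:, j]
        beta, se, p = _score_test(gj, y)
        carriers = gj > 0
        flagged = bool(
            carriers.any()
            and (np.all(y[carriers] == 1) or np.all(y[carriers] == 0))
        )
        rows.append(
            {
                "variant_id": vid,
                "chrom": "1",
                "pos": 894_573 + j,
                "ref_allele": "G",
                "alt_allele": "A",
                "beta": beta,
                "se": se,
                "p": p,
                "flagged": flagged,
            }
        )
    return pd.DataFrame(rows)


def simulate_two_trait_summaries(
    dosages: pd.DataFrame,
    shared: bool,
    config: SimConfig,
    eqtl_beta: float = 0.5,
    max_r2_distinct: float = 0.2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """A case-control trait and a quantitative (eQTL-like) trait on one block.

    With ``shared=True`` both traits are driven by ``config.causal_index``;
    otherwise the second trait's causal variant is chosen to have r-squared
    below ``max_r2_distinct`` with the first (error if none exists).
    """
    trait1 = simulate_case_control_summary(dosages, config)

    rng = _rng(config.seed, "trait2")
    x = dosages.to_numpy(dtype=float)
    ld = ld_matrix(dosages).to_numpy()
    if shared:
        idx2 = config.causal_index
    else:
        r2_to_causal = ld[config.causal_index]
        ok = np.where(np.nan_to_num(r2_to_causal, nan=1.0) < max_r2_distinct)[0]
        if len(ok) == 0:
            raise ValueError(
                "no variant with r2 < "
                f"{max_r2_distinct} to the first causal; max available r2 = "
                f"{np.nanmin(r2_to_causal):.3f}"
            )
        # farthest-in-LD choice keeps the two signals cleanly distinct
        idx2 = int(ok[np.argmin(np.nan_to_num(r2_to_causal[ok], nan=1.0))])

    g = x[:, idx2]
    sd = g.std()
    gz = (g - g.mean()) / sd if sd > 0 else np.zeros_like(g)
    yq = eqtl_beta * gz + rng.standard_normal(len(gz))

    rows = []
    for j, vid in enumerate(dosages.columns):
        gj = x[:, j]
        sdj = gj.std()
        if sdj == 0:
            rows.append({"variant_id": vid, "beta": 0.0, "se": np.inf, "p": 1.0})
            continue
        res = stats.linregress(gj, yq)
        p = max(res.pvalue, np.finfo(float).tiny)
        rows.append(
            {"variant_id": vid, "beta": res.slope, "se": res.stderr, "p": p}
        )
    trait2 = pd.DataFrame(rows)
    return trait1, trait2


def simulate_psm_experiment(
    n_proteins: int = 200,
    n_substrates: int = 5,
    bait_reps: int = 2,
    ctrl_reps: int = 3,
    doses: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0),
    dose_reps: int = 3,
    seed: int = 0,
    enrichment_effect: float = 4.0,
    dose_halving_per_decade: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Bait-vs-control spectral counts plus a dose-titration abundance table.

    Substrate proteins get Poisson bait counts with mean
    ``enrichment_effect`` times their control mean, and an expected
    abundance that halves ``dose_halving_per_decade`` times per decade of
    inducer dose; non-substrates are exchangeable across conditions and flat
    in dose.

    Returns ``(psm_table, condition_map, dose_table, truth)``.
    """
    if n_substrates > n_proteins:
        raise InvalidConfigError("n_substrates must be <= n_proteins")
    if any(d2 <= d1 for d1, d2 in zip(doses, doses[1:])):
        raise InvalidConfigError("doses must be strictly increasing")
    rng = _rng(seed, "psm")

    proteins = [f"P{i:04d}" for i in range(n_proteins)]
    substrate_ids = set(proteins[:n_substrates])
    base = rng.lognormal(mean=np.log(8.0), sigma=0.6, size=n_proteins)

    cols = {}
    cond = {}
    for r in range(bait_reps):
        mean = base * np.where(
            np.isin(proteins, list(substrate_ids)), enrichment_effect, 1.0
        )
        cols[f"bait_{r+1}"] = rng.poisson(mean)
        cond[f"bait_{r+1}"] = "bait"
    for r in range(ctrl_reps):
        cols[f"ctrl_{r+1}"] = rng.poisson(base)
        cond[f"ctrl_{r+1}"] = "control"
    psm = pd.DataFrame(cols, index=pd.Index(proteins, name="protein_id"))
    condition_map = pd.DataFrame(
        {"sample": list(cond), "condition": list(cond.values())}
    )

    d0 = doses[0]
    dose_rows = []
    for pi, pid in enumerate(proteins):
        is_sub = pid in substrate_ids
        for d in doses:
            decades = np.log10(d / d0)
            mean = base[pi] * 10.0
            if is_sub:
                mean *= 2.0 ** (-dose_halving_per_decade * decades)
            for r in range(dose_reps):
                ab = mean * rng.lognormal(mean=0.0, sigma=0.08)
                dose_rows.append(
                    {
                        "protein_id": pid,
                        "dose": d,
                        "replicate": r + 1,
                        "abundance": ab,
                    }
                )
    dose_table = pd.DataFrame(dose_rows)
    truth = SyntheticTruth(substrate_proteins=substrate_ids)
    return psm, condition_map, dose_table, truth


# Mean contrast in the latent sample factor between the top and bottom
# quarters of a standard normal: 2 * E[Z | Z > q75] = 2 * phi(q75)/0.25 * ...
_QUARTILE_Z_CONTRAST = 2.0 * float(
    stats.norm.pdf(stats.norm.ppf(0.75)) / 0.25
)  # ~2.54


def simulate_rnaseq(
    n_genes: int = 2000,
    n_samples: int = 328,
    driver_gene: str = "DRIVER",
    planted_sets: dict[str, int] | None = None,
    planted_log2fc: float = 1.0,
    dispersion: float = 0.1,
    seed: int = 0,
    mean_log: float = 5.0,
    mean_sd: float = 1.5,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Negative-binomial RNA-seq counts whose planted sets track a driver gene.

    A latent per-sample factor u ~ N(0,1) scales the driver gene's mean as
    2**u; genes in planted sets have mean scaled by
    2**(planted_log2fc * u / c) where c is the expected top-vs-bottom
    quartile contrast of u, so the realized bottom/top-quartile log2 fold
    change of planted genes is approximately ``planted_log2fc``.
    """
    if dispersion <= 0:
        raise InvalidConfigError("dispersion must be > 0")
    planted_sets = planted_sets or {}
    rng = _rng(seed, "rnaseq")

    n_planted = sum(planted_sets.values())
    if n_planted > n_genes - 1:
        raise InvalidConfigError("planted sets exceed gene count")

    genes = [f"G{i:05d}" for i in range(n_genes - 1)]
    set_members: dict[str, list[str]] = {}
    cursor = 0
    for name, size in planted_sets.items():
        set_members[name] = genes[cursor : cursor + size]
        cursor += size

    u = rng.standard_normal(n_samples)
    base = rng.lognormal(mean=mean_log, sigma=mean_sd, size=n_genes - 1)
    mu = np.tile(base[:, None], (1, n_samples))
    scale = 2.0 ** (planted_log2fc * u / _QUARTILE_Z_CONTRAST)
    planted_mask = np.zeros(n_genes - 1, dtype=bool)
    planted_mask[:cursor] = True
    mu[planted_mask, :] *= scale[None, :]

    driver_mu = np.exp(mean_log) * 2.0**u
    mu_all = np.vstack([driver_mu[None, :], mu])
    all_genes = [driver_gene] + genes

    r = 1.0 / dispersion
    counts = rng.negative_binomial(r, r / (r + mu_all))
    cm = pd.DataFrame(
        counts,
        index=pd.Index(all_genes, name="gene_id"),
        columns=[f"S{j:03d}" for j in range(n_samples)],
    )
    truth = SyntheticTruth(enriched_gene_sets=set(planted_sets))
    truth.gene_sets = set_members  # type: ignore[attr-defined]
    return cm, truth


def simulate_qpcr(
    targets: list[str],
    efficiencies: dict[str, float],
    dilution_points: int = 5,
    top_quantity: float = 100.0,
    dilution_factor: float = 10.0,
    noise_sd: float = 0.1,
    seed: int = 0,
    intercept: float = 30.0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Dilution-series Ct values: Ct = intercept - log10(q)/log10(1+E) + noise."""
    if dilution_points < 3:
        raise InvalidConfigError("need >= 3 dilution points")
    for t in targets:
        e = efficiencies[t]
        if not (0.7 < e <= 1.1):
            raise InvalidConfigError(f"efficiency for {t} outside (0.7, 1.1]")
    rng = _rng(seed, "qpcr")
    rows = []
    for t in targets:
        e = efficiencies[t]
        for i in range(dilution_points):
            q = top_quantity / dilution_factor**i
            ct = intercept - np.log10(q) / np.log10(1.0 + e)
            rows.append(
                {
                    "target": t,
                    "quantity": q,
                    "ct": ct + rng.normal(0.0, noise_sd),
                }
            )
    truth = SyntheticTruth(qpcr_efficiency=dict(efficiencies))
    return pd.DataFrame(rows), truth
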