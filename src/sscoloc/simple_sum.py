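"""The two-stage Simple Sum (SS) colocalization test.

Stage 1 asks whether the secondary dataset (e.g. a gene×tissue eQTL set)
carries *any* association signal in the region: the sum of 1-df chi-square
statistics ``S1 = Σ T_j`` with ``T_j = Qχ²₁(1 − P^E_j)`` is referred to its
null distribution ``Σ λ_i χ²₁`` (λ = eigenvalues of the LD matrix R), a
quadratic form evaluated by Imhof-type numerical inversion.  The stage-1
p-value is Bonferroni-gated at α/m over the m secondary datasets submitted.

Stage 2 asks whether that signal *colocalizes* with the GWAS: it regresses
the chi-square evidence on centered GWAS weights ``c_j = −log10(P^G_j) − ḡ``,

    Z_SS = Σ c_j T_j / sqrt(cᵀ Σ c),   Σ_jk = 2 r_jk² + 4 δ̂ r_jk,

where δ̂ = max(mean(T) − 1, 0) estimates a common noncentrality for a region
that passed stage 1 (signal exists somewhere, location unspecified).  The
test is one-sided: colocalization predicts a positive association between
GWAS evidence and eQTL chi-squares.

Cells that cannot be tested carry sentinel codes: −1 no secondary data,
−2 stage 1 not significant, −3 computation failed (e.g. too few SNPs).
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass

import numpy as np
from scipy import integrate, optimize, stats

from .errors import DegenerateError, DomainError
from .ld_engine import LDMatrix
from .sumstats_io import P_FLOOR, Region, SummaryStatDataset, harmonize_datasets
from .errors import NoOverlapError

logger = logging.getLogger("sscoloc")

#: Minimum harmonized SNPs for a confident stage-2 assessment.
MIN_SNPS = 5

#: Default family-wise significance level for the stage-1 gate.
DEFAULT_ALPHA = 0.05


class Status(enum.Enum):
    OK = "OK"
    NO_DATA = "NO_DATA"
    NOT_SIGNIFICANT = "NOT_SIGNIFICANT"
    FAILED = "FAILED"


#: Sentinel codes emitted in the heatmap for untestable cells.
SENTINELS = {
    Status.NO_DATA: -1,
    Status.NOT_SIGNIFICANT: -2,
    Status.FAILED: -3,
}

#: Human-readable reasons matching the sentinel codes.
SENTINEL_REASONS = {
    -1: "No eQTL data",
    -2: "No significant eQTLs",
    -3: "SS test failed",
}


@dataclass
class SSResult:
    """Outcome of one Simple Sum run (one primary × one secondary dataset)."""

    status: Status
    stage1_p: float | None = None
    ss_z: float | None = None
    ss_p: float | None = None
    n_snps: int = 0
    m: int = 1
    alpha: float = DEFAULT_ALPHA
    reason: str | None = None

    @property
    def sentinel(self) -> int | None:
        return SENTINELS.get(self.status)

    @property
    def neglog10_ss_p(self) -> float | None:
        if self.status is not Status.OK:
            return None
        return float(-np.log10(max(self.ss_p, P_FLOOR)))

    @property
    def cell_value(self) -> float:
        """Heatmap cell: −log10(SS p) when OK, else the sentinel code."""
        return float(self.sentinel) if self.status is not Status.OK else self.neglog10_ss_p


def pvalues_to_chisq(p) -> np.ndarray:
    """Map p-values to 1-df chi-square evidence via the upper-tail quantile."""
    p = np.asarray(p, dtype=float)
    if np.any(~np.isfinite(p)) or np.any(p <= 0.0) or np.any(p > 1.0):
        raise DomainError("p-values must lie in (0, 1]")
    return stats.chi2.isf(p, df=1)


# --------------------------------------------------------------------------
# Null distribution of a positively weighted sum of chi-squares.

def _imhof_integrand(u: float, lambdas: np.ndarray, s: float) -> float:
    theta = 0.5 * np.sum(np.arctan(lambdas * u)) - 0.5 * s * u
    rho = np.exp(0.25 * np.sum(np.log1p((lambdas * u) ** 2)))
    if u < 1e-12:
        # limit of sin(theta)/ (u rho) as u -> 0
        return 0.5 * (np.sum(lambdas) - s)
    return np.sin(theta) / (u * rho)


def _saddlepoint_tail(s: float, lambdas: np.ndarray) -> float:
    """Kuonen's saddlepoint approximation to Pr(Σ λ χ²₁ > s); far-tail backup."""
    lmax = lambdas.max()
    mean = lambdas.sum()

    def kprime_minus_s(t: float) -> float:
        return float(np.sum(lambdas / (1.0 - 2.0 * t * lambdas)) - s)

    upper = 1.0 / (2.0 * lmax) - 1e-12
    lo, hi = (-1e6, upper) if s < mean else (0.0, upper)
    try:
        t_hat = optimize.brentq(kprime_minus_s, lo, hi, xtol=1e-14)
    except ValueError:
        return 1.0 if s < mean else P_FLOOR
    if abs(t_hat) < 1e-12:
        return 0.5
    k = -0.5 * np.sum(np.log1p(-2.0 * t_hat * lambdas))
    kpp = np.sum(2.0 * lambdas ** 2 / (1.0 - 2.0 * t_hat * lambdas) ** 2)
    w = np.sign(t_hat) * np.sqrt(max(2.0 * (t_hat * s - k), 0.0))
    v = t_hat * np.sqrt(kpp)
    if w == 0.0 or v == 0.0:
        return 0.5
    z = w + np.log(v / w) / w
    return float(stats.norm.sf(z))


def quadform_tail_prob(s: float, lambdas, acc: float = 1e-6) -> float:
    """Pr(Σ λ_i χ²₁,i > s) for nonnegative weights λ, by Imhof inversion.

    Absolute accuracy ≤ *acc*; the result is clipped to (1e-300, 1].  In the
    far tail, where the oscillatory integral loses significance, a
    saddlepoint approximation takes over.
    """
    lambdas = np.asarray(lambdas, dtype=float)
    lambdas = lambdas[lambdas > 0.0]
    if lambdas.size == 0:
        raise DegenerateError("all eigenvalues are (numerically) zero")
    if s <= 0.0:
        return 1.0
    if lambdas.size == 1:
        return float(min(max(stats.chi2.sf(s / lambdas[0], df=1), P_FLOOR), 1.0))

    # The integrand's envelope 1/(u ρ(u)) is strictly decreasing; truncate
    # where it falls below acc/50.  Beyond that point the phase θ(u) is
    # dominated by −su/2, so successive half-periods alternate in sign with
    # decreasing amplitude and the discarded tail is bounded by one
    # half-period's area, ≤ envelope(U)·2/s ≪ acc.
    def log_envelope(logu: float) -> float:
        u = np.exp(logu)
        return -logu - 0.25 * np.sum(np.log1p((lambdas * u) ** 2)) - np.log(acc / 50.0)

    upper = optimize.brentq(log_envelope, np.log(1e-12), np.log(1e15), xtol=1e-3)
    upper = float(np.exp(upper))
    n_half_periods = int(upper * s / (2.0 * np.pi)) + 10
    val, err = integrate.quad(
        _imhof_integrand, 0.0, upper, args=(lambdas, s),
        epsabs=acc / 10.0, epsrel=0.0, limit=max(200, min(n_half_periods, 20000)),
    )
    p = 0.5 + val / np.pi
    if p < max(1e-8, 10.0 * abs(err)):
        # far tail: the oscillatory integral has lost significance
        p = _saddlepoint_tail(s, lambdas)
    return float(min(max(p, P_FLOOR), 1.0))


def stage1_test(T, R: LDMatrix) -> float:
    """Region-wide signal screen: p-value of S1 = Σ T_j under the LD null."""
    T = np.asarray(T, dtype=float)
    if len(R) != T.size:
        raise DomainError(f"LD dimension {len(R)} != number of statistics {T.size}")
    s1 = float(T.sum())
    if s1 == 0.0:
        return 1.0
    lam = np.linalg.eigvalsh(R.r)
    lam = lam[lam >= 1e-10]
    return quadform_tail_prob(s1, lam)


def estimate_noncentrality(T) -> float:
    """Region-wide common-noncentrality estimate δ̂ = max(mean(T) − 1, 0)."""
    T = np.asarray(T, dtype=float)
    if T.size == 0:
        raise DomainError("empty statistic vector")
    return float(max(T.mean() - 1.0, 0.0))


@dataclass
class SSWeights:
    """GWAS evidence g = −log10 P^G and its centered version c = g − ḡ."""

    g: np.ndarray
    c: np.ndarray

    @classmethod
    def from_pvalues(cls, p_gwas) -> "SSWeights":
        p = np.asarray(p_gwas, dtype=float)
        if np.any(~np.isfinite(p)) or np.any(p <= 0.0) or np.any(p > 1.0):
            raise DomainError("GWAS p-values must lie in (0, 1]")
        g = -np.log10(p)
        return cls(g=g, c=g - g.mean())


def ss_stage2_test(T, weights: SSWeights, R: LDMatrix, delta: float) -> tuple[float, float]:
    """The Simple Sum statistic Z_SS and its one-sided p-value.

    Null covariance of the chi-square evidence under common noncentrality δ:
    Σ_jk = 2 r_jk² + 4 δ r_jk (signed r when available; with unsigned √(r²)
    input the cross terms are upper bounds).
    """
    T = np.asarray(T, dtype=float)
    c = weights.c
    if T.size != c.size or len(R) != T.size:
        raise DomainError("T, weights and R must have matching dimensions")
    if np.allclose(c, 0.0, atol=1e-12):
        raise DegenerateError("constant GWAS p-values: centered weights are all zero")
    sigma = 2.0 * R.r ** 2 + 4.0 * delta * R.r
    var = float(c @ sigma @ c)
    if not np.isfinite(var) or var <= 0.0:
        raise DegenerateError(f"non-positive null variance ({var}) for the SS statistic")
    z = float(c @ T) / np.sqrt(var)
    if not np.isfinite(z):
        raise DegenerateError("non-finite SS statistic")
    return z, float(min(max(stats.norm.sf(z), P_FLOOR), 1.0))


def run_simple_sum(
    primary: SummaryStatDataset,
    secondary: SummaryStatDataset | None,
    ld: LDMatrix,
    ss_region: Region,
    alpha: float = DEFAULT_ALPHA,
    m: int = 1,
    min_snps: int = MIN_SNPS,
) -> SSResult:
    """Run the full two-stage test for one primary × secondary pair.

    Statuses are the contract: −1 when the secondary dataset has no records
    in the region, −2 when stage 1 misses the Bonferroni-corrected gate
    α/m, −3 on numerical failure or fewer than *min_snps* harmonized SNPs.
    """
    if secondary is None or len(secondary) == 0:
        return SSResult(Status.NO_DATA, m=m, alpha=alpha, reason=SENTINEL_REASONS[-1])
    sec = secondary.restrict(ss_region)
    if len(sec) == 0:
        return SSResult(Status.NO_DATA, m=m, alpha=alpha, reason=SENTINEL_REASONS[-1])
    prim = primary.restrict(ss_region)
    try:
        h = harmonize_datasets(prim, sec, ld)
    except NoOverlapError:
        return SSResult(Status.FAILED, m=m, alpha=alpha,
                        reason="SS test failed: no overlapping SNPs")
    n = len(h)
    if n < min_snps:
        return SSResult(
            Status.FAILED, n_snps=n, m=m, alpha=alpha,
            reason=f"SS test failed: {n} SNPs < required {min_snps}",
        )
    R = ld.subset(h.ld_idx)
    try:
        T = pvalues_to_chisq(sec.pvalues[h.secondary_idx])
        stage1_p = stage1_test(T, R)
    except (DegenerateError, DomainError, np.linalg.LinAlgError) as exc:
        return SSResult(Status.FAILED, n_snps=n, m=m, alpha=alpha,
                        reason=f"SS test failed: {exc}")
    if stage1_p > alpha / m:
        return SSResult(Status.NOT_SIGNIFICANT, stage1_p=stage1_p, n_snps=n,
                        m=m, alpha=alpha, reason=SENTINEL_REASONS[-2])
    try:
        weights = SSWeights.from_pvalues(prim.pvalues[h.primary_idx])
        delta = estimate_noncentrality(T)
        z, p = ss_stage2_test(T, weights, R, delta)
    except (DegenerateError, DomainError, np.linalg.LinAlgError) as exc:
        return SSResult(Status.FAILED, stage1_p=stage1_p, n_snps=n, m=m,
                        alpha=alpha, reason=f"SS test failed: {exc}")
    return SSResult(Status.OK, stage1_p=stage1_p, ss_z=z, ss_p=p,
                    n_snps=n, m=m, alpha=alpha)
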