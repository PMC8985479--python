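"""Sequence kernel association test (SKAT) for gene-level burden of variants.

SKAT is a variance-component score test on case-control genotype data.  With
G the n × m additive dosage matrix for a gene's variants, y a binary
phenotype, X covariates (intercept always included), W = diag(w_v) per-variant
weights, and μ̂ the fitted probabilities of the null logistic model
y ~ X, the statistic is the weighted quadratic form

    Q = (y - μ̂)ᵀ G W² Gᵀ (y - μ̂).

Under the null, Q is distributed as Σ_k ξ_k χ²₁ where ξ_k are the non-zero
eigenvalues of W Gᵀ P₀ G W, with P₀ = V - V X (XᵀVX)⁻¹ XᵀV the null
projection/variance matrix and V = diag(μ̂(1-μ̂)).  The tail probability is
evaluated by numerical inversion of the characteristic function (Imhof's
integral, the method underlying Davies' algorithm), with a moment-matched
noncentral-χ² approximation as fallback when the inversion fails.

Default variant weights are the Beta(1, 25) density at the minor allele
frequency — the canonical SKAT weighting that up-weights rare variants —
with a flat-weights option.  Monomorphic variants carry no information and
are dropped; no minor-allele-frequency threshold is applied otherwise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import integrate, stats

from .errors import InputError

logger = logging.getLogger(__name__)

EIGEN_RTOL = 1e-10  # eigenvalues below rtol * max are treated as zero
IMHOF_MAX_ERROR = 1e-4  # inversion error beyond this falls back to moment matching


@dataclass
class SkatInput:
    """Genotypes, binary phenotype, and optional covariates for one gene."""

    genotypes: np.ndarray          # n samples x m variants, dosages 0/1/2, NaN = missing
    phenotype: np.ndarray          # n, binary 0/1
    covariates: np.ndarray | None = None  # n x k, without intercept
    variant_weights: np.ndarray | None = None  # m, >= 0; default Beta(1,25)(MAF)
    gene: str = "gene"


@dataclass
class SkatResult:
    gene: str
    Q: float
    pvalue: float
    p_bonferroni: float
    eigenvalues: np.ndarray
    n_variants: int
    method: str  # "imhof" or "liu"


def beta_maf_weights(G: np.ndarray, a: float = 1.0, b: float = 25.0) -> np.ndarray:
    """Beta(a, b) density evaluated at each variant's minor allele frequency."""
    maf = np.nanmean(G, axis=0) / 2.0
    maf = np.minimum(maf, 1.0 - maf)
    return stats.beta.pdf(maf, a, b)


def _imhof_pvalue(q: float, lam: np.ndarray) -> tuple[float, float]:
    """P(Σ ξ_k χ²₁ > q) by numerical inversion of the characteristic function.

    The integrand's envelope decays like u^(-1-m/2), so the integral is
    truncated at an upper limit chosen from the analytic tail bound
    1 / (π (m/2) U^(m/2) Π ξ_k^(1/2)); the bound is folded into the returned
    error estimate.  Returns (tail probability, total error estimate).
    """
    m = lam.size
    tol = 1e-8
    prod_sqrt = float(np.exp(0.5 * np.sum(np.log(lam))))
    u_tol = (1.0 / (np.pi * (m / 2) * tol * prod_sqrt)) ** (2.0 / m)
    # keep the oscillation count (~ qU/4π) within quad's subdivision budget
    u_osc = 4.0 * np.pi * 1200 / max(q, 1.0)
    upper = min(u_tol, u_osc)
    trunc = 1.0 / (np.pi * (m / 2) * upper ** (m / 2) * prod_sqrt)
    if trunc > IMHOF_MAX_ERROR:
        return np.nan, np.inf  # cannot reach tolerance; caller falls back

    lam_list = [float(x) for x in lam]  # scalar math: quad calls pointwise

    def integrand(u):
        theta = -0.5 * q * u
        logrho = 0.0
        for l in lam_list:
            x = l * u
            theta += 0.5 * math.atan(x)
            logrho += 0.25 * math.log1p(x * x)
        return math.sin(theta) / (u * math.exp(logrho))

    out = integrate.quad(integrand, 0.0, upper, limit=1500, full_output=1)
    val, abserr = out[0], out[1]
    return 0.5 + val / np.pi, abserr / np.pi + trunc


def _liu_pvalue(q: float, lam: np.ndarray) -> float:
    """Moment-matched noncentral-χ² approximation (Liu-Tang-Zhang)."""
    c1 = lam.sum()
    c2 = (lam**2).sum()
    c3 = (lam**3).sum()
    c4 = (lam**4).sum()
    s1 = c3 / c2**1.5
    s2 = c4 / c2**2
    if s1**2 > s2:
        a = 1.0 / (s1 - np.sqrt(s1**2 - s2))
        delta = s1 * a**3 - a**2
        dof = a**2 - 2 * delta
    else:
        delta = 0.0
        dof = 1.0 / s2
    mu_x = dof + delta
    sigma_x = np.sqrt(2 * (dof + 2 * delta))
    t = (q - c1) / np.sqrt(2 * c2)
    return float(stats.ncx2.sf(t * sigma_x + mu_x, dof, delta))


def mixture_chi2_sf(q: float, lam: np.ndarray) -> tuple[float, str]:
    """Upper tail of Σ ξ_k χ²₁ at q; Imhof inversion with Liu fallback."""
    lam = np.asarray(lam, dtype=float)
    if lam.size == 0 or q <= 0:
        return 1.0, "degenerate"
    if lam.size == 1:
        # one component: the mixture IS a scaled chi-square
        return float(stats.chi2.sf(q / lam[0], df=1)), "exact"
    try:
        with np.errstate(all="ignore"):
            p, abserr = _imhof_pvalue(q, lam)
        if np.isfinite(p) and 0.0 < p <= 1.0 and abserr < IMHOF_MAX_ERROR:
            return float(min(p, 1.0)), "imhof"
        # inversion failed or returned a rounding-level value: fall through
    except Exception:  # pragma: no cover - quad failures are rare
        pass
    p = _liu_pvalue(q, lam)
    return float(np.clip(p, np.finfo(float).tiny, 1.0)), "liu"


def _null_model(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Fitted probabilities of the null logistic regression y ~ X."""
    model = sm.GLM(y, X, family=sm.families.Binomial())
    try:
        res = model.fit()
    except Exception as exc:
        raise InputError(f"null logistic model failed to converge: {exc}") from exc
    return np.asarray(res.fittedvalues, dtype=float)


def skat_test(inp: SkatInput, n_genes: int = 1) -> SkatResult:
    """Run SKAT for one gene; ``n_genes`` sets the Bonferroni correction.

    Missing dosages are imputed to the variant mean.  Monomorphic variants
    are dropped.  If every variant is monomorphic (or none remain), the
    statistic is 0 with p-value 1.
    """
    G = np.asarray(inp.genotypes, dtype=float)
    y = np.asarray(inp.phenotype, dtype=float)
    if G.ndim != 2 or G.shape[0] != y.shape[0]:
        raise InputError("genotype/phenotype dimensions disagree")
    classes = np.unique(y)
    if not np.all(np.isin(classes, [0.0, 1.0])) or len(classes) < 2:
        raise InputError("phenotype must contain both classes, coded 0/1")

    # mean-impute missing dosages per variant
    if np.isnan(G).any():
        col_mean = np.nanmean(G, axis=0)
        G = np.where(np.isnan(G), col_mean, G)

    weights = (
        beta_maf_weights(G)
        if inp.variant_weights is None
        else np.asarray(inp.variant_weights, dtype=float)
    )
    if weights.shape != (G.shape[1],) or np.any(weights < 0):
        raise InputError("variant weights must be non-negative, one per variant")

    poly = G.std(axis=0) > 0
    n_dropped = int((~poly).sum())
    if n_dropped:
        logger.info("%s: dropped %d monomorphic variants", inp.gene, n_dropped)
    G, weights = G[:, poly], weights[poly]
    if G.shape[1] == 0:
        return SkatResult(inp.gene, 0.0, 1.0, 1.0, np.empty(0), 0, "degenerate")

    if inp.covariates is not None:
        C = np.asarray(inp.covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        X = np.column_stack([np.ones(len(y)), C])
    else:
        X = np.ones((len(y), 1))

    mu = _null_model(y, X)
    resid = y - mu
    B = G * weights  # n x m, columns weighted
    q_stat = float(np.square(B.T @ resid).sum())

    # eigenvalues of W G' P0 G W via P0 = V - V X (X'VX)^-1 X'V
    v = mu * (1.0 - mu)
    VB = v[:, None] * B
    XtVX = X.T @ (v[:, None] * X)
    VX_B = (v[:, None] * X) @ np.linalg.solve(XtVX, X.T @ VB)
    A = B.T @ (VB - VX_B)
    lam = np.linalg.eigvalsh((A + A.T) / 2.0)
    lam = lam[lam > EIGEN_RTOL * max(lam.max(), 1e-30)]

    if lam.size == 0 or q_stat <= 0:
        pvalue, method = 1.0, "degenerate"
    else:
        pvalue, method = mixture_chi2_sf(q_stat, lam)
    return SkatResult(
        gene=inp.gene,
        Q=q_stat,
        pvalue=pvalue,
        p_bonferroni=min(1.0, pvalue * n_genes),
        eigenvalues=lam,
        n_variants=int(G.shape[1]),
        method=method,
    )


def skat_permutation_pvalue(
    inp: SkatInput, n_permutations: int = 20_000, seed: int = 0
) -> float:
    """Permutation reference for SKAT, intercept-only null.

    Permuting the phenotype breaks any genotype association while keeping
    the genotype correlation structure; the returned p-value is
    (1 + #{Q_perm >= Q_obs}) / (1 + n_permutations).
    """
    G = np.asarray(inp.genotypes, dtype=float)
    y = np.asarray(inp.phenotype, dtype=float)
    if np.isnan(G).any():
        col_mean = np.nanmean(G, axis=0)
        G = np.where(np.isnan(G), col_mean, G)
    weights = (
        beta_maf_weights(G)
        if inp.variant_weights is None
        else np.asarray(inp.variant_weights, dtype=float)
    )
    poly = G.std(axis=0) > 0
    B = G[:, poly] * weights[poly]
    mu = y.mean()
    q_obs = float(np.square(B.T @ (y - mu)).sum())
    rng = np.random.default_rng(seed)
    count = 0
    # vectorized in chunks to bound memory
    chunk = 2000
    for start in range(0, n_permutations, chunk):
        k = min(chunk, n_permutations - start)
        Y = np.empty((k, len(y)))
        for i in range(k):
            Y[i] = rng.permutation(y)
        Qs = np.square((Y - mu) @ B).sum(axis=1)
        count += int((Qs >= q_obs).sum())
    return (1 + count) / (1 + n_permutations)


def bonferroni(pvalues: dict[str, float], n_tests: int | None = None) -> dict[str, float]:
    """Bonferroni adjustment: min(1, p × n_tests)."""
    if n_tests is None:
        n_tests = len(pvalues)
    if n_tests < len(pvalues):
        raise InputError("n_tests must be at least the number of p-values")
    return {g: min(1.0, p * n_tests) for g, p in pvalues.items()}
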