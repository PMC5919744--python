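"""Mixed-model association mapping with FDR control and effect summaries.

The single-marker scan follows the EMMAX strategy: variance components of the
null model ``y = Xb + u + e`` (``Var(u) = sigma_a2 * K``) are estimated once by
REML and then held fixed while every marker is tested by generalized least
squares on kinship-rotated data, giving a Wald chi-square per marker. The
multi-locus scan (MLMM-style) adds the most significant marker as a fixed
cofactor step by step, re-estimating variance components each time, prunes the
final model backward, and selects the step by extended BIC.

Significance is controlled per trait and data set by Benjamini–Hochberg FDR
(Q = 0.2 by default); residual confounding is diagnosed with the genomic
inflation factor lambda. Variance-explained summaries convert a set of
significant SNPs into adjusted R² and the fraction of genotypic variance
rho = R²_adj / H².
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from ._lmm import KinshipEigen, LMMFit, fit_lmm
from .genotypes import GenotypeMatrix, compute_maf

CHI2_MEDIAN_1DF = float(stats.chi2.ppf(0.5, 1))  # 0.45493...


@dataclasses.dataclass
class KinshipMatrix:
    values: np.ndarray
    ids: list[str]
    method: str = "vanraden"

    def __post_init__(self) -> None:
        V = np.asarray(self.values, dtype=float)
        if V.shape[0] != V.shape[1] or not np.allclose(V, V.T, atol=1e-8):
            raise ValueError("kinship must be square and symmetric")
        if np.any(np.diag(V) <= 0):
            raise ValueError("kinship diagonal must be positive")
        self.values = V


def kinship(G: GenotypeMatrix, method: str = "vanraden", ridge: float = 1e-6) -> KinshipMatrix:
    """VanRaden realized-relationship matrix from a complete dosage matrix.

    K = W W' / (2 * sum p_j (1 - p_j)) with W the column-centered dosages;
    a small ridge keeps K positive definite for downstream solvers.
    """
    if method != "vanraden":
        raise ValueError(f"unknown kinship method {method!r}")
    X = G.dosages
    if np.isnan(X).any():
        raise ValueError("kinship requires a complete (imputed/filtered) matrix")
    p = X.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("all markers are monomorphic")
    W = X[:, poly] - 2.0 * p[poly]
    denom = 2.0 * np.sum(p[poly] * (1.0 - p[poly]))
    K = W @ W.T / denom
    K[np.diag_indices_from(K)] += ridge
    return KinshipMatrix(values=K, ids=list(G.ids), method=method)


@dataclasses.dataclass
class AssocTable:
    """Per-marker association results for one scan."""

    table: pd.DataFrame  # marker, chrom, pos, beta, se, p, maf, significant
    sigma_a2: float
    sigma_e2: float
    lambda_gc: float
    fdr_q: float | None = None

    def significant_markers(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _prepare_scan(y, G: GenotypeMatrix, K: KinshipMatrix, covariates):
    y = np.asarray(y, dtype=float)
    if y.size != G.n_individuals:
        raise ValueError("phenotype length does not match genotype rows")
    if np.ptp(y) == 0:
        raise ValueError("phenotype is constant")
    if K.values.shape[0] != G.n_individuals:
        raise ValueError("kinship does not conform to genotypes")
    if np.isnan(G.dosages).any():
        raise ValueError("scan requires a complete dosage matrix")
    X0 = np.ones((y.size, 1))
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != y.size:
            C = C.T
        X0 = np.column_stack([X0, C])
    return y, X0


def _gls_scan(
    y_rot: np.ndarray,
    X0_rot: np.ndarray,
    M_rot: np.ndarray,
    weights: np.ndarray,
    sigma_a2: float,
    stat: str = "wald",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-marker GLS tests at fixed variance components.

    Marker and phenotype are residualized against the null covariates under
    the 1/weights inner product (Frisch–Waugh), then tested marginally.
    ``stat="wald"`` uses the chi-square on the GLS effect with the null-model
    scale; ``stat="f"`` re-estimates the scale per marker from the weighted
    residual sum of squares and uses an F test with residual df (this reduces
    exactly to the single-marker OLS F test when the kinship is the identity).
    """
    Dinv = 1.0 / weights
    X0w = X0_rot * Dinv[:, None]
    P = np.linalg.inv(X0_rot.T @ X0w)
    y_res = y_rot - X0_rot @ (P @ (X0w.T @ y_rot))
    M_res = M_rot - X0_rot @ (P @ (X0w.T @ M_rot))
    num = M_res.T @ (Dinv * y_res)
    den = np.einsum("ij,ij->j", M_res, Dinv[:, None] * M_res)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = num / den
        if stat == "f":
            n, p0 = X0_rot.shape
            dof = n - p0 - 1
            yss = float(y_res @ (Dinv * y_res))
            rss = yss - beta * num
            sigma_marker = rss / dof
            se = np.sqrt(sigma_marker / den)
            fstat = beta * num / sigma_marker
            p = stats.f.sf(fstat, 1, dof)
            p = np.where(np.isfinite(fstat), np.clip(p, np.finfo(float).tiny, 1.0), np.nan)
            return beta, se, p
        var_beta = sigma_a2 / den
        se = np.sqrt(var_beta)
        wald = beta**2 / var_beta
    p = stats.chi2.sf(wald, 1)
    p = np.where(np.isfinite(wald), np.clip(p, np.finfo(float).tiny, 1.0), np.nan)
    return beta, se, p


def emmax_scan(
    y,
    G: GenotypeMatrix,
    K: KinshipMatrix,
    covariates=None,
    fdr_q: float | None = 0.2,
    stat: str = "wald",
) -> AssocTable:
    """Single-marker mixed-model scan with variance components fixed from the
    null model (EMMAX approximation)."""
    if stat not in ("wald", "f"):
        raise ValueError(f"unknown test statistic {stat!r}")
    y, X0 = _prepare_scan(y, G, K, covariates)
    eig = KinshipEigen.from_kinship(K.values)
    null = fit_lmm(y, X=X0, eig=eig)
    weights = eig.values + null.delta
    M_rot = eig.rotate(G.dosages)
    beta, se, p = _gls_scan(
        null.y_rot, null.X_rot, M_rot, weights, null.sigma_g2, stat=stat
    )
    finite = np.isfinite(p)
    lam = inflation_factor(p[finite]) if finite.sum() >= 10 else float("nan")
    tbl = pd.DataFrame(
        {
            "marker": G.marker_names,
            "chrom": G.markers["chrom"],
            "pos": G.markers["pos"],
            "beta": beta,
            "se": se,
            "p": p,
            "maf": compute_maf(G),
        }
    )
    tbl["significant"] = False
    if fdr_q is not None:
        flags = np.zeros(len(tbl), dtype=bool)
        flags[finite] = bh_fdr(p[finite], Q=fdr_q)
        tbl["significant"] = flags
    return AssocTable(
        table=tbl,
        sigma_a2=null.sigma_g2,
        sigma_e2=null.sigma_e2,
        lambda_gc=lam,
        fdr_q=fdr_q,
    )


@dataclasses.dataclass
class MLMMStep:
    cofactors: list[int]        # marker column indices in the model
    sigma_a2: float
    sigma_e2: float
    min_p: float                # best marker p-value in this step's scan
    criterion: float            # extended BIC of this step's model


@dataclasses.dataclass
class MLMMPath:
    steps: list[MLMMStep]
    selected: list[int]         # cofactors of the criterion-optimal, pruned model
    criterion: str

    def selected_markers(self, G: GenotypeMatrix) -> list[str]:
        return [G.marker_names[i] for i in self.selected]


def _ebic(fit: LMMFit, k: int, m: int, n: int, gamma: float = 1.0) -> float:
    """Extended BIC on the ML log-likelihood: BIC plus a model-space term."""
    from scipy.special import gammaln

    log_binom = gammaln(m + 1) - gammaln(k + 1) - gammaln(m - k + 1)
    return -2.0 * fit.loglik_ml + k * np.log(n) + 2.0 * gamma * log_binom


def mlmm_scan(
    y,
    G: GenotypeMatrix,
    K: KinshipMatrix,
    max_steps: int = 10,
    criterion: str = "ebic",
    backward_alpha: float = 0.05,
) -> MLMMPath:
    """Forward–backward multi-locus scan with per-step variance re-estimation.

    Forward: at each step the currently most significant marker joins the
    fixed effects and the variance components are re-fit. The step minimizing
    the extended BIC is selected; a backward pass then drops cofactors whose
    Wald p exceeds the Bonferroni level ``backward_alpha / m``.
    """
    if criterion not in ("ebic", "bonferroni"):
        raise ValueError(f"unknown selection criterion {criterion!r}")
    y, X0 = _prepare_scan(y, G, K, None)
    n, m = G.dosages.shape
    eig = KinshipEigen.from_kinship(K.values)
    M_rot = eig.rotate(G.dosages)

    def model_fit(cof: list[int]) -> LMMFit:
        X = X0 if not cof else np.column_stack([X0, G.dosages[:, cof]])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise np.linalg.LinAlgError("collinear cofactor set")
        return fit_lmm(y, X=X, eig=eig)

    cofactors: list[int] = []
    steps: list[MLMMStep] = []
    for step in range(max_steps + 1):
        try:
            fit = model_fit(cofactors)
        except np.linalg.LinAlgError:
            warnings.warn("dropping collinear cofactor", stacklevel=2)
            cofactors = cofactors[:-1]
            break
        weights = eig.values + fit.delta
        candidates = np.setdiff1d(np.arange(m), cofactors)
        _, _, p = _gls_scan(
            fit.y_rot, fit.X_rot, M_rot[:, candidates], weights, fit.sigma_g2
        )
        good = np.isfinite(p)
        if not good.any():
            break
        best_local = int(np.nanargmin(p))
        crit = _ebic(fit, len(cofactors), m, n) if criterion == "ebic" else (
            -2.0 * fit.loglik_ml + len(cofactors) * np.log(n)
        )
        steps.append(
            MLMMStep(
                cofactors=list(cofactors),
                sigma_a2=fit.sigma_g2,
                sigma_e2=fit.sigma_e2,
                min_p=float(np.nanmin(p)),
                criterion=float(crit),
            )
        )
        if step == max_steps:
            break
        if criterion == "bonferroni" and np.nanmin(p) > backward_alpha / m:
            break
        cofactors = cofactors + [int(candidates[best_local])]

    best_step = min(steps, key=lambda s: s.criterion)
    selected = list(best_step.cofactors)
    # backward pruning on Wald p of each cofactor in the joint model
    while selected:
        fit = model_fit(selected)
        weights = eig.values + fit.delta
        pvals = []
        for i, j in enumerate(selected):
            others = [c for c in selected if c != j]
            Xo = X0 if not others else np.column_stack([X0, G.dosages[:, others]])
            _, _, pj = _gls_scan(
                fit.y_rot,
                eig.rotate(Xo),
                M_rot[:, [j]],
                weights,
                fit.sigma_g2,
            )
            pvals.append(float(pj[0]))
        worst = int(np.argmax(pvals))
        if pvals[worst] > backward_alpha / m:
            selected.pop(worst)
        else:
            break
    return MLMMPath(steps=steps, selected=selected, criterion=criterion)


def inflation_factor(pvalues) -> float:
    """Genomic inflation: observed over expected median 1-df chi-square."""
    p = np.asarray(pvalues, dtype=float)
    if p.size < 10:
        raise ValueError("need at least 10 p-values")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    chi = stats.chi2.isf(p, 1)
    return float(np.median(chi) / CHI2_MEDIAN_1DF)


def bh_fdr(pvalues, Q: float = 0.2) -> np.ndarray:
    """Benjamini–Hochberg step-up flags at FDR level Q."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if not (0.0 < Q < 1.0):
        raise ValueError("Q must be in (0, 1)")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    passing = np.flatnonzero(ranked <= (np.arange(1, m + 1) / m) * Q)
    flags = np.zeros(m, dtype=bool)
    if passing.size:
        flags[order[: passing[-1] + 1]] = True
    return flags


@dataclasses.dataclass
class VarianceExplained:
    r2: float
    r2_adj: float
    rho: float          # share of genotypic variance, R²_adj / H²
    n_snps: int
    exceeds_one: bool   # rho > 1 is reported but flagged


def genotypic_variance_explained(r2_adj: float, h2: float) -> float:
    """rho = R²_adj / H², the genotypic-variance share of an adjusted fit."""
    if not (0.0 < h2 <= 1.0):
        raise ValueError("H² must be in (0, 1]")
    return r2_adj / h2


def variance_explained(y, snps: np.ndarray, h2: float) -> VarianceExplained:
    """Adjusted R² of the joint significant-SNP fit and its genotypic share.

    R²_adj = R² - z (1 - R²) / (N - z - 1) with z predictors and N
    observations; negative adjusted values are reported as 0.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(snps, dtype=float))
    if X.shape[0] != y.size:
        X = X.T
    n, z = X.shape
    if z >= n - 1:
        raise ValueError("more predictors than the adjustment supports")
    if not (0.0 < h2 <= 1.0):
        raise ValueError("H² must be in (0, 1]")
    Xd = np.column_stack([np.ones(n), X])
    coef, *_ = np.linalg.lstsq(Xd, y, rcond=None)
    resid = y - Xd @ coef
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(resid @ resid) / sst
    r2_adj = max(r2 - z * (1.0 - r2) / (n - z - 1), 0.0)
    rho = genotypic_variance_explained(r2_adj, h2)
    return VarianceExplained(
        r2=r2, r2_adj=r2_adj, rho=rho, n_snps=z, exceeds_one=rho > 1.0
    )
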