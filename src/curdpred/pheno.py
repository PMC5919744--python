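"""Multi-environment phenotype analysis: REML variance components, H², BLUPs.

Replicated field-trial records ``y_ijk = mu + G_i + E_j + GE_ij + e_ijk`` are
fitted with all effects random except the intercept. Variance components are
estimated by EM-REML on the mixed-model equations, which handles unbalanced
tables with the same code path as balanced ones. Broad-sense heritability on
an entry-mean basis is

    H² = σg² / (σg² + σge²/e + σe²/(r·e))

with ``e`` environments and ``r`` replicates. Genotype BLUPs from the fitted
model feed genetic correlations; per-genotype adjusted means feed phenotypic
correlations and the association/prediction stages.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.linalg

ID_COLUMNS = ("genotype", "environment", "replicate")


@dataclasses.dataclass
class PhenotypeTable:
    """Long-format plot records plus helpers for per-genotype means.

    ``data`` has columns ``genotype``, ``environment``, ``replicate`` followed
    by one numeric column per trait.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(ID_COLUMNS) - set(self.data.columns)
        if missing:
            raise ValueError(f"phenotype table lacks columns {sorted(missing)}")
        self.data = self.data.reset_index(drop=True)

    @property
    def traits(self) -> list[str]:
        return [c for c in self.data.columns if c not in ID_COLUMNS]

    @property
    def genotypes(self) -> list[str]:
        return list(pd.unique(self.data["genotype"]))

    def adjusted_means(self, trait: str | None = None) -> pd.DataFrame | pd.Series:
        """Per-genotype mean over environments and replicates (BLUE-style)."""
        means = self.data.groupby("genotype", sort=False)[self.traits].mean()
        return means if trait is None else means[trait]

    def write(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path) -> "PhenotypeTable":
        return cls(pd.read_csv(path, sep="\t"))


@dataclasses.dataclass
class VarianceComponents:
    """REML variance components of the two-way random model."""

    sigma_g2: float
    sigma_ge2: float
    sigma_e2: float
    r: int
    e: int
    sigma_env2: float = float("nan")  # environment main effect; not in H²

    def __post_init__(self) -> None:
        for name in ("sigma_g2", "sigma_ge2", "sigma_e2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.r < 1 or self.e < 1:
            raise ValueError("r and e must be >= 1")


@dataclasses.dataclass
class TraitBLUPs:
    """Shrunken genotype effects and the overall mean."""

    mu: float
    blups: pd.Series  # indexed by genotype id


def heritability(vc: VarianceComponents) -> float:
    """Broad-sense heritability on an entry-mean basis."""
    denom = vc.sigma_g2 + vc.sigma_ge2 / vc.e + vc.sigma_e2 / (vc.r * vc.e)
    if denom <= 0:
        raise ValueError("all variance components are zero; H² undefined")
    return vc.sigma_g2 / denom


class ConvergenceError(RuntimeError):
    def __init__(self, message: str, trace: list[tuple[float, float, float, float]]):
        super().__init__(message)
        self.trace = trace


def _incidence(codes: np.ndarray, n_levels: int) -> np.ndarray:
    Z = np.zeros((codes.size, n_levels))
    Z[np.arange(codes.size), codes] = 1.0
    return Z


def fit_two_way_random(
    tbl: PhenotypeTable,
    trait: str,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> tuple[VarianceComponents, TraitBLUPs]:
    """EM-REML fit of the genotype/environment/interaction random model.

    The mixed-model equations are assembled once; each EM sweep re-solves them
    at the current variance ratios and updates components from the BLUPs and
    the trace of the inverse coefficient matrix. Components collapsing toward
    zero are clamped at the boundary; the residual keeps a tiny positive floor
    so the equations stay well posed in the noiseless limit. Deterministic
    given the data.
    """
    df = tbl.data.dropna(subset=[trait])
    y = df[trait].to_numpy(dtype=float)
    g_codes, g_levels = pd.factorize(df["genotype"], sort=True)
    env_codes, env_levels = pd.factorize(df["environment"], sort=True)
    if len(g_levels) < 2:
        raise ValueError("need >= 2 genotypes")
    if len(env_levels) < 2:
        raise ValueError("need >= 2 environments (interaction unidentifiable)")
    cell = df.groupby(["genotype", "environment"], sort=False, observed=True)
    r_design = int(np.median(cell.size()))
    ge_codes, _ = pd.factorize(
        df["genotype"].astype(str) + "\x00" + df["environment"].astype(str), sort=True
    )

    n = y.size
    q_g, q_env, q_ge = len(g_levels), len(env_levels), ge_codes.max() + 1
    W = np.column_stack(
        [
            np.ones((n, 1)),
            _incidence(g_codes, q_g),
            _incidence(env_codes, q_env),
            _incidence(ge_codes, q_ge),
        ]
    )
    A = W.T @ W
    rhs = W.T @ y
    yty = float(y @ y)
    blocks = {
        "g": slice(1, 1 + q_g),
        "env": slice(1 + q_g, 1 + q_g + q_env),
        "ge": slice(1 + q_g + q_env, 1 + q_g + q_env + q_ge),
    }
    sizes = {"g": q_g, "env": q_env, "ge": q_ge}

    vary = max(float(np.var(y)), np.finfo(float).tiny)
    comp = {"g": vary / 4, "env": vary / 4, "ge": vary / 4}
    sigma_e2 = vary / 4
    floor_e = 1e-12 * vary
    clamp = 1e-10 * vary
    active = {k: True for k in comp}
    trace: list[tuple[float, float, float, float]] = []

    for _ in range(max_iter):
        C = A.copy()
        diag = np.arange(C.shape[0])
        for k, sl in blocks.items():
            lam = sigma_e2 / comp[k] if active[k] else 1e12 * A.max()
            C[diag[sl], diag[sl]] += max(lam, 1e-10)
        cf = scipy.linalg.cho_factor(C, lower=True, check_finite=False)
        sol = scipy.linalg.cho_solve(cf, rhs, check_finite=False)
        Cinv = scipy.linalg.cho_solve(cf, np.eye(C.shape[0]), check_finite=False)

        new_e = max((yty - float(sol @ rhs)) / (n - 1), floor_e)
        new = {}
        for k, sl in blocks.items():
            if not active[k]:
                new[k] = 0.0
                continue
            u = sol[sl]
            new[k] = (float(u @ u) + new_e * float(np.trace(Cinv[sl, sl]))) / sizes[k]
            if new[k] < clamp:
                new[k] = 0.0
                active[k] = False
        trace.append((new["g"], new["env"], new["ge"], new_e))
        delta = max(
            abs(new_e - sigma_e2) / (sigma_e2 + clamp),
            max(abs(new[k] - comp[k]) / (comp[k] + clamp) for k in comp),
        )
        comp, sigma_e2 = new, new_e
        if delta < tol:
            break
    else:
        raise ConvergenceError(
            f"EM-REML did not reach tol={tol} in {max_iter} iterations", trace
        )

    vc = VarianceComponents(
        sigma_g2=comp["g"],
        sigma_ge2=comp["ge"],
        sigma_e2=sigma_e2 if sigma_e2 > floor_e else 0.0,
        r=r_design,
        e=q_env,
        sigma_env2=comp["env"],
    )
    blups = TraitBLUPs(
        mu=float(sol[0]),
        blups=pd.Series(sol[blocks["g"]], index=list(g_levels.astype(str))),
    )
    return vc, blups


def trait_correlations(
    blups_by_trait: pd.DataFrame,
    means_by_trait: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Genotypic (BLUP-based) and phenotypic (mean-based) Pearson matrices.

    Zero-variance traits yield NaN entries off the diagonal.
    """
    for df in (blups_by_trait, means_by_trait):
        if df.shape[0] < 3:
            raise ValueError("need >= 3 shared genotypes")
    rg = blups_by_trait.corr(method="pearson")
    rp = means_by_trait.corr(method="pearson")
    np.fill_diagonal(rg.values, 1.0)
    np.fill_diagonal(rp.values, 1.0)
    return rg, rp
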