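"""Structured genotype panels and replicated phenotypes with known truth.

The generator emulates a diverse gene-bank collection: a few differentiated
genetic clusters, distance-decaying linkage disequilibrium along each
chromosome, genotyping-by-sequencing-style per-individual missingness, and
multi-environment replicated trait records whose variance components and QTL
are recorded in a truth ledger so downstream estimators can be scored.

Genotypes are built from two haplotypes per individual. Cluster allele
frequencies follow the Balding–Nichols model around an ancestral frequency
(drift parameter ``F``); along a chromosome each haplotype is a first-order
Markov (latent AR(1) Gaussian threshold) process, so correlation between
markers decays geometrically with the number of intervening gaps, scaled by
gap length in bp. Phenotypes follow

    y_ijk = mu + g_i + E_j + GE_ij + e_ijk

with ``g_i`` the sum of planted QTL effects plus an optional polygenic term,
scaled so the realized genetic variance hits its target exactly.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .pheno import PhenotypeTable

#: Default trait battery: names and entry-mean heritabilities spanning the
#: range seen for curd morphology and development traits in diverse panels.
DEFAULT_TRAITS = (
    ("days_to_budding", 0.94),
    ("cluster_width", 0.56),
    ("curd_width", 0.45),
    ("n_branches", 0.30),
    ("nearest_branch", 0.20),
    ("apical_length", 0.10),
)


@dataclasses.dataclass
class TraitSpec:
    """Architecture of one simulated trait.

    Either give ``h2`` (variance components derived with σg²=1 and
    σge²=σe² chosen to hit the target) or explicit components.
    ``qtl_variance_fraction`` splits the genetic variance between the listed
    QTL and a genome-wide polygenic background.
    """

    name: str = "trait"
    n_qtl: int = 10
    h2: float | None = 0.6
    qtl_variance_fraction: float = 1.0
    sigma_g2: float | None = None
    sigma_ge2: float | None = None
    sigma_e2: float | None = None

    def components(self, n_env: int, n_rep: int) -> tuple[float, float, float]:
        if self.sigma_g2 is not None:
            return (self.sigma_g2, self.sigma_ge2 or 0.0, self.sigma_e2 or 0.0)
        h2 = self.h2
        if h2 is None or not (0.0 <= h2 <= 1.0):
            raise ValueError(f"target H² must be in [0,1], got {h2}")
        if h2 == 0.0:
            return (0.0, 1.0, 1.0)
        noise = (1.0 / h2 - 1.0) / (1.0 / n_env + 1.0 / (n_rep * n_env))
        return (1.0, noise, noise)


@dataclasses.dataclass
class SimConfig:
    """Panel and design parameters; defaults mirror a gene-bank GBS study:

    174 individuals over 9 chromosomes, 5 clusters, per-individual missing
    fractions spanning 19–77%, and 6 environments x 2 replicates. The drift
    parameter and adjacent-marker correlation are calibrated so the default
    panel reproduces the study's LD summaries (inter-chromosomal background
    r² near 0.17 and a decay/background crossing on the 150–200 kb scale).
    """

    n_individuals: int = 174
    n_chromosomes: int = 9
    markers_per_chromosome: int = 500
    chromosome_length_bp: int = 45_000_000
    n_clusters: int = 5
    F: float = 0.45
    ld_correlation: float = 0.72
    maf_floor: float = 0.05
    missing_range: tuple[float, float] = (0.1902, 0.7673)
    n_environments: int = 6
    n_replicates: int = 2
    env_variance: float = 1.0
    traits: tuple[TraitSpec, ...] = tuple(
        TraitSpec(name=n, h2=h) for n, h in DEFAULT_TRAITS
    )

    def __post_init__(self) -> None:
        lo, hi = self.missing_range
        if not (0.0 <= lo <= hi < 1.0):
            raise ValueError("missing_range must satisfy 0 <= low <= high < 1")
        if not (0.0 <= self.ld_correlation < 1.0):
            raise ValueError("ld_correlation must be in [0,1)")
        if not (0.0 <= self.F < 1.0):
            raise ValueError("F must be in [0,1)")
        if self.n_clusters > self.n_individuals:
            raise ValueError("n_clusters may not exceed n_individuals")


@dataclasses.dataclass
class SimTruth:
    """Ground truth recorded at generation time for recovery tests."""

    cluster_labels: np.ndarray  # values in 1..K
    F: float
    seed: int
    qtl_indices: dict[str, np.ndarray] = dataclasses.field(default_factory=dict)
    qtl_effects: dict[str, np.ndarray] = dataclasses.field(default_factory=dict)
    genetic_values: dict[str, np.ndarray] = dataclasses.field(default_factory=dict)
    variance_components: dict[str, tuple[float, float, float]] = dataclasses.field(
        default_factory=dict
    )

    def validate(self, n_markers: int, n_individuals: int) -> None:
        labels = np.asarray(self.cluster_labels)
        if labels.size != n_individuals or labels.min() < 1:
            raise ValueError("cluster labels must cover every individual, 1..K")
        for name, idx in self.qtl_indices.items():
            if np.any((idx < 0) | (idx >= n_markers)):
                raise ValueError(f"QTL index out of range for trait {name}")
        for comps in self.variance_components.values():
            if any(c < 0 for c in comps):
                raise ValueError("variance components must be >= 0")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "cluster_labels": self.cluster_labels.tolist(),
            "F": self.F,
            "seed": self.seed,
            "qtl_indices": {k: v.tolist() for k, v in self.qtl_indices.items()},
            "qtl_effects": {k: v.tolist() for k, v in self.qtl_effects.items()},
            "variance_components": {
                k: list(v) for k, v in self.variance_components.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _marker_positions(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for c in range(1, config.n_chromosomes + 1):
        mpc, L = config.markers_per_chromosome, config.chromosome_length_bp
        draw = np.unique(rng.integers(1, L + 1, size=2 * mpc + 16))
        while draw.size < mpc:
            draw = np.unique(
                np.concatenate([draw, rng.integers(1, L + 1, size=2 * mpc)])
            )
        pos = np.sort(rng.permutation(draw)[:mpc])
        for p in pos:
            rows.append((f"C{c:02d}", int(p)))
    df = pd.DataFrame(rows, columns=["chrom", "pos"])
    df["ref"] = "A"
    df["alt"] = "C"
    return df


def _adjacent_latent_corr(markers: pd.DataFrame, rho: float) -> np.ndarray:
    """Latent AR(1) coefficient for each marker given the previous one.

    Correlation at the panel's median adjacent gap equals ``rho`` and
    attenuates geometrically for wider gaps; the first marker of each
    chromosome restarts the chain (coefficient 0).
    """
    m = len(markers)
    coef = np.zeros(m)
    if rho == 0.0 or m < 2:
        return coef
    gaps_all = []
    for _, grp in markers.groupby("chrom", sort=False):
        gaps_all.append(np.diff(grp["pos"].to_numpy()))
    med_gap = float(np.median(np.concatenate(gaps_all))) if gaps_all else 1.0
    med_gap = max(med_gap, 1.0)
    offset = 0
    for _, grp in markers.groupby("chrom", sort=False):
        gaps = np.diff(grp["pos"].to_numpy())
        coef[offset + 1 : offset + len(grp)] = rho ** (gaps / med_gap)
        offset += len(grp)
    return coef


def _cluster_frequencies(p_anc: np.ndarray, F: float, u: np.ndarray) -> np.ndarray:
    """Balding–Nichols per-cluster allele frequencies, shape (K, m).

    ``u`` holds uniform quantiles (one per cluster and marker) that are
    locally correlated along each chromosome, so drift deviations — like the
    haplotypes they ride on — decay with map distance instead of being
    independent per marker. Marginally each frequency is the usual
    Beta(p(1-F)/F, (1-p)(1-F)/F) draw.
    """
    if F == 0.0:
        return np.tile(p_anc, (u.shape[0], 1))
    from scipy.stats import beta as beta_dist

    a = p_anc * (1.0 - F) / F
    b = (1.0 - p_anc) * (1.0 - F) / F
    return beta_dist.ppf(u, a[None, :], b[None, :])


def simulate_population(
    config: SimConfig, seed: int = 0
) -> tuple[GenotypeMatrix, SimTruth]:
    """Generate a complete (no-missing) structured dosage panel plus truth.

    Markers whose realized sample MAF falls below ``maf_floor`` are rejected
    and re-thresholded with frequencies redrawn closer to 0.5; the latent
    haplotype field is kept fixed so the LD structure is unaffected.
    """
    rng = np.random.default_rng(seed)
    n, K = config.n_individuals, config.n_clusters
    markers = _marker_positions(config, rng)
    m = len(markers)
    coef = _adjacent_latent_corr(markers, config.ld_correlation)

    # near-equal cluster sizes, order shuffled
    labels = np.repeat(np.arange(1, K + 1), int(np.ceil(n / K)))[:n]
    rng.shuffle(labels)

    from scipy.stats import norm

    def ar1_field(rows: int) -> np.ndarray:
        # latent AR(1) Gaussian: z_j = c_j z_{j-1} + sqrt(1-c_j^2) eps_j
        innov_sd = np.sqrt(1.0 - coef**2)
        z = np.empty((rows, m))
        eps = rng.standard_normal((rows, m))
        z[:, 0] = eps[:, 0]
        for j in range(1, m):
            z[:, j] = coef[j] * z[:, j - 1] + innov_sd[j] * eps[:, j]
        return z

    z = ar1_field(2 * n)                    # per-haplotype allele field
    u_drift = norm.cdf(ar1_field(K))        # per-cluster drift quantiles

    p_anc = rng.uniform(0.1, 0.9, size=m)
    freqs = _cluster_frequencies(p_anc, config.F, u_drift)
    hap_labels = np.repeat(labels, 2) - 1

    def realize(columns: np.ndarray) -> np.ndarray:
        thr = norm.ppf(freqs[:, columns][hap_labels, :])  # (2n, len(columns))
        hap = (z[:, columns] < thr).astype(float)
        return hap[0::2] + hap[1::2]

    dosages = realize(np.arange(m))
    for attempt in range(100):
        maf = np.minimum(dosages.mean(axis=0) / 2, 1 - dosages.mean(axis=0) / 2)
        bad = np.flatnonzero(maf < config.maf_floor)
        if bad.size == 0:
            break
        width = max(0.4 - 0.04 * attempt, 0.0)
        p_anc[bad] = rng.uniform(0.5 - width, 0.5 + width, size=bad.size)
        if attempt >= 3:
            # extreme shared drift quantiles cannot be rescued by the
            # ancestral frequency alone; refresh them for stubborn markers
            u_drift[:, bad] = rng.uniform(0.05, 0.95, size=(K, bad.size))
        freqs[:, bad] = _cluster_frequencies(
            p_anc[bad], config.F, u_drift[:, bad]
        )
        dosages[:, bad] = realize(bad)
    else:
        raise RuntimeError("MAF-floor rejection did not converge")

    G = GenotypeMatrix(
        ids=[f"ind{i + 1:03d}" for i in range(n)], markers=markers, dosages=dosages
    )
    truth = SimTruth(cluster_labels=labels.copy(), F=config.F, seed=seed)
    _plant_qtl(G, truth, config, rng)
    truth.validate(m, n)
    return G, truth


def _scale_to_var(x: np.ndarray, target: float) -> np.ndarray:
    x = x - x.mean()
    if target == 0:
        return np.zeros_like(x)
    v = x.var(ddof=1)
    if v == 0:
        raise ValueError("cannot scale a constant vector to positive variance")
    return x * np.sqrt(target / v)


def _plant_qtl(
    G: GenotypeMatrix, truth: SimTruth, config: SimConfig, rng: np.random.Generator
) -> None:
    """Draw QTL positions/effects per trait; realized genetic variance is
    scaled to the target exactly (polygenic part orthogonalized against the
    QTL part so the split is exact too)."""
    X = G.dosages
    n, m = X.shape
    for spec in config.traits:
        sg2, _, _ = spec.components(config.n_environments, config.n_replicates)
        idx = np.sort(rng.choice(m, size=min(spec.n_qtl, m), replace=False))
        beta = rng.standard_normal(idx.size)
        q_raw = (X[:, idx] - X[:, idx].mean(axis=0)) @ beta
        frac = spec.qtl_variance_fraction
        q = _scale_to_var(q_raw, sg2 * frac)
        if frac < 1.0:
            poly = (X - X.mean(axis=0)) @ rng.standard_normal(m) / np.sqrt(m)
            denom = float(q @ q)
            if denom > 0:
                poly = poly - q * float(poly @ q) / denom
            g = q + _scale_to_var(poly, sg2 * (1.0 - frac))
        else:
            g = q
        # rescale beta so stored effects reproduce the variance-scaled QTL part
        if q_raw.std(ddof=1) > 0:
            beta = beta * np.sqrt(sg2 * frac) / q_raw.std(ddof=1)
        truth.qtl_indices[spec.name] = idx
        truth.qtl_effects[spec.name] = beta
        truth.genetic_values[spec.name] = g
        truth.variance_components[spec.name] = spec.components(
            config.n_environments, config.n_replicates
        )


def inject_missingness(
    G: GenotypeMatrix,
    missing_range: tuple[float, float],
    seed: int = 0,
) -> GenotypeMatrix:
    """Mask calls completely at random with a per-individual rate drawn
    uniformly from ``missing_range``; columns that would become entirely
    missing are re-drawn."""
    lo, hi = missing_range
    if not (0.0 <= lo <= hi < 1.0):
        raise ValueError("missing_range must satisfy 0 <= low <= high < 1")
    rng = np.random.default_rng(seed)
    n, m = G.dosages.shape
    rates = rng.uniform(lo, hi, size=n)
    mask = rng.random((n, m)) < rates[:, None]
    for _ in range(100):
        dead = np.flatnonzero(mask.all(axis=0))
        if dead.size == 0:
            break
        mask[:, dead] = rng.random((n, dead.size)) < rates[:, None]
    else:
        raise RuntimeError("could not avoid fully-missing markers")
    out = G.dosages.copy()
    out[mask] = np.nan
    return GenotypeMatrix(list(G.ids), G.markers.copy(), out)


def simulate_phenotypes(
    G: GenotypeMatrix,
    truth: SimTruth,
    config: SimConfig,
    seed: int = 0,
) -> PhenotypeTable:
    """Replicated multi-environment records for every trait in the config.

    Genetic values come from the truth ledger (exactly scaled); environment,
    interaction and residual terms are drawn at their target variances, so
    their empirical variances match the targets to sampling tolerance.
    """
    rng = np.random.default_rng(seed)
    n = G.n_individuals
    n_env, n_rep = config.n_environments, config.n_replicates
    envs = [f"env{j + 1}" for j in range(n_env)]
    base = pd.DataFrame(
        [
            (gid, env, rep + 1)
            for gid in G.ids
            for env in envs
            for rep in range(n_rep)
        ],
        columns=["genotype", "environment", "replicate"],
    )
    g_idx = np.repeat(np.arange(n), n_env * n_rep)
    e_idx = np.tile(np.repeat(np.arange(n_env), n_rep), n)
    ge_idx = g_idx * n_env + e_idx
    for spec in config.traits:
        name = spec.name
        if name not in truth.genetic_values:
            raise ValueError(f"truth ledger has no genetic values for trait {name}")
        sg2, sge2, se2 = truth.variance_components[name]
        if not (0.0 <= sg2) or min(sge2, se2) < 0:
            raise ValueError("variance components must be >= 0")
        g = truth.genetic_values[name]
        E = rng.normal(0.0, np.sqrt(config.env_variance), size=n_env)
        GE = rng.normal(0.0, np.sqrt(sge2), size=n * n_env) if sge2 > 0 else np.zeros(n * n_env)
        eps = rng.normal(0.0, np.sqrt(se2), size=len(base)) if se2 > 0 else np.zeros(len(base))
        base[name] = g[g_idx] + E[e_idx] + GE[ge_idx] + eps
    return PhenotypeTable(base)
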