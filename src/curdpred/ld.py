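"""Linkage disequilibrium: pairwise r/r², decay curves, background LD, phase.

Haplotype frequencies for a pair of unphased biallelic markers are estimated
by the classic two-locus EM (only double heterozygotes are ambiguous), giving

    D  = p_ab - p_a p_b
    r  = D / sqrt(p_a (1-p_a) p_b (1-p_b))        (signed, in [-1, 1])
    r² = r²

Background LD is the 95th percentile of r² over random inter-chromosomal
marker pairs — the level chance alone produces at this sample size. Decay
with distance is summarized by the Hill–Weir drift expectation fitted by
nonlinear least squares, and the distance at which the fitted curve meets the
background defines the maximum extent of genuine linkage. Persistence of
linkage phase between subpopulations is the correlation of signed r for the
same marker pairs, averaged within 50-marker groups ordered by distance.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy.optimize import brentq, curve_fit

from .genotypes import GenotypeMatrix


def _two_locus_em(
    ga: np.ndarray, gb: np.ndarray, tol: float = 1e-10, max_iter: int = 1000
) -> np.ndarray:
    """Haplotype frequencies (p_AB, p_Ab, p_aB, p_ab) from unphased dosages.

    Allele A/B denote the alternate allele at each locus (dosage counts).
    Rows with a missing call at either locus are ignored.
    """
    ok = ~np.isnan(ga) & ~np.isnan(gb)
    ga, gb = ga[ok].astype(int), gb[ok].astype(int)
    n = ga.size
    if n == 0:
        raise ValueError("no jointly observed calls")
    counts = np.zeros((3, 3))
    np.add.at(counts, (ga, gb), 1.0)
    # unambiguous haplotype counts; cell (1,1) split by EM
    hap = np.zeros(4)  # AB, Ab, aB, ab
    hap[0] = 2 * counts[2, 2] + counts[2, 1] + counts[1, 2]
    hap[1] = 2 * counts[2, 0] + counts[2, 1] + counts[1, 0]
    hap[2] = 2 * counts[0, 2] + counts[0, 1] + counts[1, 2]
    hap[3] = 2 * counts[0, 0] + counts[0, 1] + counts[1, 0]
    ndh = counts[1, 1]  # double heterozygotes: AB/ab or Ab/aB
    total = 2.0 * n
    freqs = (hap + ndh / 2.0) / total
    if ndh == 0:
        return hap / total
    for _ in range(max_iter):
        coupling = freqs[0] * freqs[3]
        repulsion = freqs[1] * freqs[2]
        w = coupling / (coupling + repulsion) if coupling + repulsion > 0 else 0.5
        new = hap.copy()
        new[0] += ndh * w
        new[3] += ndh * w
        new[1] += ndh * (1 - w)
        new[2] += ndh * (1 - w)
        new /= total
        if np.max(np.abs(new - freqs)) < tol:
            return new
        freqs = new
    return freqs


@dataclasses.dataclass
class LDResult:
    """Pairwise LD statistics; one row per marker pair."""

    table: pd.DataFrame  # marker_a, marker_b, distance, p_a, p_b, p_ab, D, r, r2

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _pair_ld(ga: np.ndarray, gb: np.ndarray) -> tuple[float, float, float, float, float]:
    freqs = _two_locus_em(ga, gb)
    p_a = freqs[0] + freqs[1]
    p_b = freqs[0] + freqs[2]
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        raise ValueError("monomorphic marker in pair")
    D = freqs[0] - p_a * p_b
    r = D / np.sqrt(p_a * (1 - p_a) * p_b * (1 - p_b))
    return p_a, p_b, freqs[0], D, r


def pairwise_ld(G: GenotypeMatrix, pairs) -> LDResult:
    """Signed r and r² for explicit marker-index pairs via the two-locus EM."""
    names = G.marker_names
    chrom = G.markers["chrom"].to_numpy()
    pos = G.markers["pos"].to_numpy()
    rows = []
    for i, j in pairs:
        p_a, p_b, p_ab, D, r = _pair_ld(G.dosages[:, i], G.dosages[:, j])
        dist = abs(int(pos[i]) - int(pos[j])) if chrom[i] == chrom[j] else -1
        rows.append((names[i], names[j], dist, p_a, p_b, p_ab, D, r, r * r))
    return LDResult(
        table=pd.DataFrame(
            rows,
            columns=[
                "marker_a", "marker_b", "distance",
                "p_a", "p_b", "p_ab", "D", "r", "r2",
            ],
        )
    )


def _polymorphic_columns(G: GenotypeMatrix) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(G.dosages, axis=0)
    return np.flatnonzero((mean > 0) & (mean < 2))


def background_ld(
    G: GenotypeMatrix,
    n_pairs: int = 2000,
    seed: int = 0,
    percentile: float = 95.0,
) -> float:
    """Chance LD level: the 95th percentile of inter-chromosomal r².

    Marker pairs are sampled uniformly from different chromosomes; the
    percentile of their r² distribution estimates the background that genuine
    linkage must exceed.
    """
    chroms = G.markers["chrom"].to_numpy()
    if len(np.unique(chroms)) < 2:
        raise ValueError("background LD needs at least two chromosomes")
    rng = np.random.default_rng(seed)
    poly = _polymorphic_columns(G)
    r2 = []
    guard = 0
    while len(r2) < n_pairs and guard < 50 * n_pairs:
        guard += 1
        i, j = rng.choice(poly, size=2, replace=False)
        if chroms[i] == chroms[j]:
            continue
        try:
            *_, r = _pair_ld(G.dosages[:, i], G.dosages[:, j])
        except ValueError:
            continue
        r2.append(r * r)
    if not r2:
        raise ValueError("no valid inter-chromosomal pairs")
    return float(np.percentile(r2, percentile))


def hill_weir_expected_r2(d: np.ndarray, rho: float, n: int) -> np.ndarray:
    """Drift expectation of r² at recombination intensity C = rho * d,
    including the finite-sample term for n sampled individuals."""
    C = rho * np.asarray(d, dtype=float)
    term1 = (10.0 + C) / ((2.0 + C) * (11.0 + C))
    term2 = 1.0 + ((3.0 + C) * (12.0 + 12.0 * C + C * C)) / (
        n * (2.0 + C) * (11.0 + C)
    )
    return term1 * term2


@dataclasses.dataclass
class DecayCurve:
    chromosome: str
    rho: float                      # fitted recombination intensity per bp
    n: int
    background: float
    intersection_bp: float | None   # None when the curve never crosses
    n_pairs: int

    def expected_r2(self, d) -> np.ndarray:
        return hill_weir_expected_r2(d, self.rho, self.n)


def ld_decay(
    G: GenotypeMatrix,
    chromosome: str,
    background: float,
    max_pairs: int = 20000,
    seed: int = 0,
) -> DecayCurve:
    """Hill–Weir decay fit for one chromosome and its background crossing.

    All intra-chromosomal pairs are used up to ``max_pairs`` (random subsample
    beyond); the crossing distance is solved numerically on the fitted curve.
    """
    cols = np.intersect1d(
        np.flatnonzero((G.markers["chrom"] == chromosome).to_numpy()),
        _polymorphic_columns(G),
    )
    pairs = [(i, j) for a, i in enumerate(cols) for j in cols[a + 1 :]]
    if len(pairs) < 50:
        raise ValueError("need at least 50 intra-chromosomal pairs")
    if len(pairs) > max_pairs:
        rng = np.random.default_rng(seed)
        pairs = [pairs[t] for t in rng.choice(len(pairs), max_pairs, replace=False)]
    res = pairwise_ld(G, pairs).table
    d = res["distance"].to_numpy(dtype=float)
    r2 = res["r2"].to_numpy()
    n = G.n_individuals
    try:
        popt, _ = curve_fit(
            lambda dd, rho: hill_weir_expected_r2(dd, rho, n),
            d, r2, p0=[1e-5], bounds=(0.0, np.inf), maxfev=10000,
        )
    except RuntimeError as exc:
        resid = r2 - hill_weir_expected_r2(d, 1e-5, n)
        raise RuntimeError(
            f"decay fit did not converge (RMS residual {np.sqrt(np.mean(resid**2)):.4f})"
        ) from exc
    rho = float(popt[0])
    d_max = float(d.max())
    f = lambda dd: hill_weir_expected_r2(dd, rho, n) - background
    intersection = None
    if f(0.0) > 0 > f(d_max):
        intersection = float(brentq(f, 0.0, d_max))
    return DecayCurve(
        chromosome=chromosome,
        rho=rho,
        n=n,
        background=background,
        intersection_bp=intersection,
        n_pairs=len(pairs),
    )


@dataclasses.dataclass
class PhasePersistence:
    per_bin: pd.DataFrame   # bin, mean_distance, correlation, n_pairs
    overall: float          # correlation of signed r over all shared pairs


def _signed_r_adjacent(G: GenotypeMatrix, cols: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Signed r for consecutive polymorphic markers within chromosomes.

    Returns (pair ids as flat indices of the left marker, distances, r).
    Allele orientation is the alternate allele of the shared map throughout.
    """
    chroms = G.markers["chrom"].to_numpy()
    pos = G.markers["pos"].to_numpy()
    lefts, dists, rs = [], [], []
    for c in np.unique(chroms):
        cc = cols[chroms[cols] == c]
        for i, j in zip(cc[:-1], cc[1:]):
            try:
                *_, r = _pair_ld(G.dosages[:, i], G.dosages[:, j])
            except ValueError:
                continue
            lefts.append(i)
            dists.append(pos[j] - pos[i])
            rs.append(r)
    return np.asarray(lefts), np.asarray(dists, float), np.asarray(rs)


def phase_persistence(
    G_A: GenotypeMatrix,
    G_B: GenotypeMatrix,
    bin_size: int = 50,
) -> PhasePersistence:
    """Correlation of signed r between two subpopulations on a shared map.

    Both panels must carry the same markers with the same ref/alt
    orientation; signed r is computed per adjacent marker pair in each panel
    and correlated, averaged within ``bin_size``-pair groups ordered by
    distance. High values mean a marker effect estimated in one group keeps
    its phase (and hence predictive value) in the other.
    """
    if not G_A.markers[["chrom", "pos", "ref", "alt"]].equals(
        G_B.markers[["chrom", "pos", "ref", "alt"]]
    ):
        raise ValueError("subpopulations must share an identical marker map")
    poly = np.intersect1d(_polymorphic_columns(G_A), _polymorphic_columns(G_B))
    chroms = G_A.markers["chrom"].to_numpy()
    pos = G_A.markers["pos"].to_numpy()
    dists, ra, rb = [], [], []
    for c in np.unique(chroms):
        cc = poly[chroms[poly] == c]
        for i, j in zip(cc[:-1], cc[1:]):
            try:
                *_, r1 = _pair_ld(G_A.dosages[:, i], G_A.dosages[:, j])
                *_, r2 = _pair_ld(G_B.dosages[:, i], G_B.dosages[:, j])
            except ValueError:
                continue
            dists.append(pos[j] - pos[i])
            ra.append(r1)
            rb.append(r2)
    dists = np.asarray(dists, float)
    ra, rb = np.asarray(ra), np.asarray(rb)
    if dists.size == 0:
        raise ValueError("no shared polymorphic adjacent pairs")
    overall = float(np.corrcoef(ra, rb)[0, 1]) if dists.size > 1 else float("nan")
    order = np.argsort(dists, kind="stable")
    if dists.size < bin_size:
        warnings.warn("fewer pairs than bin_size; using a single bin", stacklevel=2)
    rows = []
    for b, start in enumerate(range(0, dists.size, bin_size)):
        sel = order[start : start + bin_size]
        if sel.size < 2:
            continue
        corr = float(np.corrcoef(ra[sel], rb[sel])[0, 1])
        rows.append((b, float(dists[sel].mean()), corr, int(sel.size)))
    per_bin = pd.DataFrame(
        rows, columns=["bin", "mean_distance", "correlation", "n_pairs"]
    )
    return PhasePersistence(per_bin=per_bin, overall=overall)
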