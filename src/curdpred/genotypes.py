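"""Genotype matrices: containers, I/O, filtering and imputation.

The central container is :class:`GenotypeMatrix`, an individuals x markers
dosage matrix (0/1/2 copies of the alternate allele, ``NaN`` for missing)
together with a marker map (chromosome, 1-based position, ref/alt alleles).
Genotyping-by-sequencing panels arrive with heavy, uneven missingness, so the
module provides the two pipeline routes used downstream: a strict
complete-case filter (MAF >= 0.05 and zero missing calls) and an imputation
route that fills missing calls before the MAF filter.

The imputer is a deliberately simple surrogate for haplotype-cluster HMM
imputation: a windowed k-nearest-neighbour concordance vote. It honours the
contract downstream stages rely on (complete matrix, untouched observed
calls) without modelling haplotype mosaics.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MARKER_COLUMNS = ("chrom", "pos", "ref", "alt")


@dataclasses.dataclass
class GenotypeMatrix:
    """Dosage matrix with its marker map.

    Parameters
    ----------
    ids
        Unique individual identifiers, one per row of ``dosages``.
    markers
        DataFrame with columns ``chrom``, ``pos`` (1-based), ``ref``, ``alt``;
        strictly sorted by (chrom, pos) with no duplicate coordinates.
    dosages
        Float array of shape ``(n_individuals, n_markers)`` holding the count
        of alternate alleles in {0, 1, 2}; missing calls are ``NaN``.
    """

    ids: list[str]
    markers: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("individual ids must be unique")
        self.markers = self.markers.reset_index(drop=True)
        missing_cols = set(MARKER_COLUMNS) - set(self.markers.columns)
        if missing_cols:
            raise ValueError(f"marker map lacks columns {sorted(missing_cols)}")
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.ids), len(self.markers)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.ids)} individuals x {len(self.markers)} markers"
            )
        obs = self.dosages[~np.isnan(self.dosages)]
        if obs.size and not np.isin(obs, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosages must be 0, 1, 2 or NaN")
        key = self.markers[["chrom", "pos"]].apply(tuple, axis=1)
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0]
            raise ValueError(f"duplicate marker coordinate {dup}")
        for _, grp in self.markers.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing:
                raise ValueError("markers must be sorted by position within chromosome")

    # -- basic properties -------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def marker_names(self) -> list[str]:
        return [f"{c}:{p}" for c, p in zip(self.markers["chrom"], self.markers["pos"])]

    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosages)

    def missing_fraction_per_individual(self) -> np.ndarray:
        return self.missing_mask().mean(axis=1)

    def take_markers(self, index: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            ids=list(self.ids),
            markers=self.markers.iloc[index],
            dosages=self.dosages[:, index],
        )

    def take_individuals(self, index: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            ids=[self.ids[i] for i in index],
            markers=self.markers,
            dosages=self.dosages[index, :],
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(list(self.ids), self.markers.copy(), self.dosages.copy())


@dataclasses.dataclass
class FilterReport:
    """Bookkeeping for a marker-filtering pass."""

    n_input: int
    n_removed_maf: int
    n_removed_missing: int
    n_retained: int

    def __post_init__(self) -> None:
        if self.n_removed_maf + self.n_removed_missing + self.n_retained != self.n_input:
            raise ValueError("filter report counts do not add up")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


# -- I/O -------------------------------------------------------------------


def read_genotypes(path: str | Path, format: str = "vcf") -> GenotypeMatrix:
    """Read a genotype matrix from a VCF or a delimited dosage table.

    Only biallelic SNPs are kept from VCF input; multi-allelic or indel
    records are dropped with a logged count. Positions stay 1-based.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "vcf":
        return _read_vcf(path)
    if format == "dosage":
        return _read_dosage(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    ids = list(vcf.samples)
    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    rows: list[np.ndarray] = []
    n_dropped = 0
    seen: set[tuple[str, int]] = set()
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_dropped += 1
            continue
        key = (var.CHROM, var.POS)
        if key in seen:
            raise ValueError(f"duplicate marker coordinate {var.CHROM}:{var.POS}")
        seen.add(key)
        # gts012: 0/1/2 = alt dosage, 3 = missing
        g = np.asarray(var.gt_types, dtype=float)
        g[g == 3] = np.nan
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        rows.append(g)
    if n_dropped:
        logger.info("dropped %d non-biallelic-SNP records from %s", n_dropped, path)
    markers = pd.DataFrame({"chrom": chroms, "pos": poss, "ref": refs, "alt": alts})
    dosages = np.column_stack(rows) if rows else np.empty((len(ids), 0))
    return GenotypeMatrix(ids=ids, markers=markers, dosages=dosages)


def _read_dosage(path: Path) -> GenotypeMatrix:
    tbl = pd.read_csv(path, sep="\t", index_col=0)
    chroms, poss = [], []
    for i, name in enumerate(tbl.columns):
        try:
            chrom, pos = name.rsplit(":", 1)
            poss.append(int(pos))
        except ValueError as exc:
            raise ValueError(f"malformed marker name {name!r} (column {i + 1})") from exc
        chroms.append(chrom)
    markers = pd.DataFrame(
        {"chrom": chroms, "pos": poss, "ref": "A", "alt": "B"}
    )
    return GenotypeMatrix(
        ids=list(tbl.index.astype(str)),
        markers=markers,
        dosages=tbl.to_numpy(dtype=float),
    )


def write_vcf(G: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF 4.2 with GT-only genotype fields."""
    path = Path(path)
    gt_code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(G.markers["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(G.ids) + "\n")
        for j in range(G.n_markers):
            row = G.markers.iloc[j]
            calls = [
                "./." if np.isnan(d) else gt_code[d] for d in G.dosages[:, j]
            ]
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t.\t{row['ref']}\t{row['alt']}"
                "\t.\t.\t.\tGT\t" + "\t".join(calls) + "\n"
            )


def write_dosage(G: GenotypeMatrix, path: str | Path) -> None:
    """Write a tab-delimited individuals x markers dosage table."""
    tbl = pd.DataFrame(G.dosages, index=G.ids, columns=G.marker_names)
    tbl.to_csv(path, sep="\t", na_rep="NA", index_label="id")


# -- statistics and filtering ---------------------------------------------


def compute_maf(G: GenotypeMatrix) -> np.ndarray:
    """Minor allele frequency per marker over non-missing calls."""
    d = G.dosages
    n_obs = (~np.isnan(d)).sum(axis=0)
    if (n_obs == 0).any():
        bad = int(np.flatnonzero(n_obs == 0)[0])
        raise ValueError(f"marker {G.marker_names[bad]} has no non-missing calls")
    alt = np.nansum(d, axis=0) / (2.0 * n_obs)
    return np.minimum(alt, 1.0 - alt)


def filter_markers(
    G: GenotypeMatrix,
    maf_min: float = 0.05,
    require_complete: bool = False,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Drop markers below a MAF threshold and, optionally, with any missing call.

    Mirrors the strict complete-case pipeline used for unimputed
    genotyping-by-sequencing data; the MAF rule is applied first, then the
    completeness rule, and the report records how many markers each removed.
    """
    maf = compute_maf(G)
    fail_maf = maf < maf_min
    any_missing = np.isnan(G.dosages).any(axis=0)
    fail_missing = any_missing & ~fail_maf if require_complete else np.zeros_like(fail_maf)
    keep = ~fail_maf & ~fail_missing
    report = FilterReport(
        n_input=G.n_markers,
        n_removed_maf=int(fail_maf.sum()),
        n_removed_missing=int(fail_missing.sum()),
        n_retained=int(keep.sum()),
    )
    if report.n_retained == 0:
        logger.warning("marker filter removed every marker")
    return G.take_markers(np.flatnonzero(keep)), report


def impute_missing(
    G: GenotypeMatrix,
    method: str = "knn_window",
    window: int = 20,
    k: int = 5,
    seed: int | None = 0,
) -> GenotypeMatrix:
    """Fill missing dosages; observed calls are never altered.

    ``frequency`` draws each missing call from the marker's observed genotype
    frequencies. ``knn_window`` votes the majority dosage among the ``k``
    individuals most concordant with the target over the ``window`` nearest
    flanking markers on the same chromosome (frequency-weighted draw on ties).
    Both are seed-deterministic.
    """
    if method not in ("frequency", "knn_window"):
        raise ValueError(f"unknown imputation method {method!r}")
    d = G.dosages
    if np.isnan(d).all(axis=0).any():
        raise ValueError("cannot impute a marker with no observed calls")
    out = d.copy()
    rng = np.random.default_rng(seed)
    if method == "frequency":
        _impute_frequency(out, rng)
    else:
        _impute_knn_window(out, G.markers["chrom"].to_numpy(), window, k, rng)
    return GenotypeMatrix(list(G.ids), G.markers.copy(), out)


def _genotype_freqs(col: np.ndarray) -> np.ndarray:
    obs = col[~np.isnan(col)]
    counts = np.array([(obs == 0).sum(), (obs == 1).sum(), (obs == 2).sum()], dtype=float)
    return counts / counts.sum()


def _impute_frequency(out: np.ndarray, rng: np.random.Generator) -> None:
    for j in range(out.shape[1]):
        miss = np.isnan(out[:, j])
        if miss.any():
            freqs = _genotype_freqs(out[:, j])
            out[miss, j] = rng.choice(3, size=int(miss.sum()), p=freqs)


def _impute_knn_window(
    out: np.ndarray,
    chroms: np.ndarray,
    window: int,
    k: int,
    rng: np.random.Generator,
) -> None:
    original = out.copy()  # concordance is scored against observed data only
    m = out.shape[1]
    for j in range(m):
        miss = np.flatnonzero(np.isnan(original[:, j]))
        if miss.size == 0:
            continue
        obs = np.flatnonzero(~np.isnan(original[:, j]))
        same = np.flatnonzero(chroms == chroms[j])
        flank = same[same != j]
        if flank.size:
            order = np.argsort(np.abs(flank - j), kind="stable")
            win = flank[order[:window]]
        else:
            win = np.empty(0, dtype=int)
        freqs = _genotype_freqs(original[:, j])
        if win.size == 0:
            out[miss, j] = rng.choice(3, size=miss.size, p=freqs)
            continue
        W = original[:, win]  # n x w, NaN allowed
        Wobs = W[obs]
        for i in miss:
            both = ~np.isnan(W[i]) & ~np.isnan(Wobs)
            eq = (Wobs == W[i]) & both
            n_both = both.sum(axis=1)
            with np.errstate(invalid="ignore"):
                score = np.where(n_both > 0, eq.sum(axis=1) / np.maximum(n_both, 1), 0.0)
            top = obs[np.argsort(-score, kind="stable")[:k]]
            votes = original[top, j].astype(int)
            counts = np.bincount(votes, minlength=3)
            best = np.flatnonzero(counts == counts.max())
            if best.size == 1:
                out[i, j] = best[0]
            else:  # tie: frequency-weighted draw among tied dosages
                p = freqs[best]
                p = p / p.sum() if p.sum() > 0 else np.full(best.size, 1 / best.size)
                out[i, j] = rng.choice(best, p=p)
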