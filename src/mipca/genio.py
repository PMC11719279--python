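"""Reading, encoding, filtering and imputing SNP genotype matrices.

Genotypes are held as additive minor-allele dosages: 0 = homozygous major,
1 = heterozygous, 2 = homozygous minor, the standard encoding for PCA on
SNP data.  The minor allele is the rarer allele *in the loaded cohort*,
with lexicographic tie-breaking, which may differ from the VCF ALT or the
PLINK COUNTED allele; codes are flipped accordingly and the flip is
reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import chi2

__all__ = [
    "GenotypeMatrix",
    "FilterReport",
    "AdditiveEncoding",
    "read_genotypes",
    "write_genotypes",
    "read_labels",
    "encode_additive",
    "filter_loci",
    "impute_missing",
    "hwe_chi2_pvalues",
]

MISSING_TSV = "NA"


@dataclass
class GenotypeMatrix:
    """Sample x locus table of additive genotype codes with a missingness mask.

    ``values`` is float so that mean-imputed entries can be fractional; every
    non-missing entry of an un-imputed matrix is in {0, 1, 2}.  Missing
    entries are NaN in ``values`` and True in ``missing_mask``; after
    imputation the mask is preserved for provenance.
    """

    values: np.ndarray
    missing_mask: np.ndarray
    sample_ids: list[str]
    locus_ids: list[str]
    locus_meta: pd.DataFrame | None = None
    population_labels: list[str] | None = None
    imputed: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        m, n = self.values.shape
        if m < 2 or n < 2:
            raise ValueError(f"need at least 2 samples and 2 loci, got {m}x{n}")
        if self.missing_mask.shape != (m, n):
            raise ValueError("missing_mask shape mismatch")
        if len(self.sample_ids) != m or len(self.locus_ids) != n:
            raise ValueError("ID count mismatch with matrix shape")
        if len(set(self.sample_ids)) != m or len(set(self.locus_ids)) != n:
            raise ValueError("sample and locus IDs must be unique")
        obs = self.values[~self.missing_mask]
        if not self.imputed and obs.size and not np.all(np.isin(obs, (0.0, 1.0, 2.0))):
            raise ValueError("non-missing genotype codes must be 0, 1 or 2")
        if self.population_labels is not None and len(self.population_labels) != m:
            raise ValueError("population label count mismatch")
        if m > n:
            warnings.warn(
                f"more samples ({m}) than loci ({n}); PCA on the sample "
                "correlation matrix expects m << n",
                UserWarning,
                stacklevel=3,
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_loci(self) -> int:
        return self.values.shape[1]

    def minor_allele_frequencies(self) -> np.ndarray:
        """Per-locus frequency of the coded (minor) allele among non-missing calls."""
        vals = np.where(self.missing_mask, np.nan, self.values)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(vals, axis=0) / 2.0


@dataclass
class FilterReport:
    """Locus-filter accounting; each removed locus is counted once, by the
    first rule it fails in the fixed order missing -> monomorphic -> MAF -> HWE."""

    n_input: int
    n_removed_missing: int
    n_removed_monomorphic: int
    n_removed_maf: int
    n_removed_hwe: int
    maf_min: float
    hwe_alpha: float
    missing_max: float

    @property
    def n_output(self) -> int:
        return (
            self.n_input
            - self.n_removed_missing
            - self.n_removed_monomorphic
            - self.n_removed_maf
            - self.n_removed_hwe
        )

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_output": self.n_output,
            "n_removed_missing": self.n_removed_missing,
            "n_removed_monomorphic": self.n_removed_monomorphic,
            "n_removed_maf": self.n_removed_maf,
            "n_removed_hwe": self.n_removed_hwe,
            "thresholds": {
                "maf_min": self.maf_min,
                "hwe_alpha": self.hwe_alpha,
                "missing_max": self.missing_max,
            },
        }


@dataclass(frozen=True)
class AdditiveEncoding:
    """Per-locus code assignment: counts of the cohort minor allele."""

    major: str
    minor: str
    monomorphic: bool = False

    def code(self, a1: str, a2: str) -> float:
        return float((a1 == self.minor) + (a2 == self.minor))


def encode_additive(allele_counts: dict[str, int]) -> AdditiveEncoding:
    """Designate minor/major alleles for a biallelic locus from cohort tallies.

    The minor allele is the rarer one; exact ties break to the
    lexicographically smaller label.  A single observed allele yields a
    monomorphic encoding (all codes 0).
    """
    observed = {a: c for a, c in allele_counts.items() if c > 0}
    if len(observed) > 2:
        raise ValueError(f"locus is not biallelic: alleles {sorted(observed)}")
    if len(observed) == 0:
        raise ValueError("no observed alleles at locus")
    if len(observed) == 1:
        (only,) = observed
        return AdditiveEncoding(major=only, minor="", monomorphic=True)
    (a, ca), (b, cb) = sorted(observed.items())  # a < b lexicographically
    if ca < cb:
        minor, major = a, b
    elif cb < ca:
        minor, major = b, a
    else:  # exact tie -> lexicographically smaller label is the minor allele
        minor, major = a, b
    return AdditiveEncoding(major=major, minor=minor)


# -- Readers -------------------------------------------------------------------


def _read_tsv(path: str) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[MISSING_TSV], dtype=str)
    try:
        vals = df.apply(pd.to_numeric).to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"malformed genotype TSV {path}: {exc}") from exc
    mask = np.isnan(vals)
    return GenotypeMatrix(
        values=vals,
        missing_mask=mask,
        sample_ids=[str(s) for s in df.index],
        locus_ids=[str(c) for c in df.columns],
    )


def _read_vcf(path: str) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    alt_dosage_rows: list[np.ndarray] = []
    locus_ids: list[str] = []
    meta_rows: list[dict] = []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            n_skipped += 1
            continue
        # count ALT alleles; half calls and missing -> NaN
        dos = np.full(len(samples), np.nan)
        for i, g in enumerate(var.genotypes):
            a1, a2 = g[0], g[1]
            if a1 < 0 or a2 < 0:
                continue
            dos[i] = float(a1 + a2)
        alt_dosage_rows.append(dos)
        locus_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        meta_rows.append(
            {"chrom": var.CHROM, "pos": var.POS, "ref": var.REF, "alt": var.ALT[0]}
        )
    vcf.close()
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} non-biallelic-SNP VCF records", UserWarning)
    if not alt_dosage_rows:
        raise ValueError(f"no usable biallelic SNP records in {path}")
    vals = np.column_stack(alt_dosage_rows)  # samples x loci, ALT dosage
    meta = pd.DataFrame(meta_rows, index=locus_ids)
    # recode to cohort minor allele
    flipped = np.zeros(vals.shape[1], dtype=bool)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        alt_freq = np.nanmean(vals, axis=0) / 2.0
    for j in range(vals.shape[1]):
        ref, alt = meta.iloc[j]["ref"], meta.iloc[j]["alt"]
        f = alt_freq[j]
        if np.isnan(f):
            continue
        alt_minor = f < 0.5 or (f == 0.5 and alt < ref)
        if not alt_minor:
            vals[:, j] = 2.0 - vals[:, j]
            flipped[j] = True
    meta["minor"] = np.where(flipped, meta["ref"], meta["alt"])
    meta["major"] = np.where(flipped, meta["alt"], meta["ref"])
    meta["flipped_to_minor"] = flipped
    mask = np.isnan(vals)
    return GenotypeMatrix(
        values=vals,
        missing_mask=mask,
        sample_ids=samples,
        locus_ids=locus_ids,
        locus_meta=meta,
    )


_TRAW_FIXED = ["CHR", "SNP", "(C)M", "POS", "COUNTED", "ALT"]


def _read_traw(path: str) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing_cols = [c for c in _TRAW_FIXED if c not in df.columns]
    if missing_cols:
        raise ValueError(f"traw file {path} lacks columns {missing_cols}")
    sample_cols = [c for c in df.columns if c not in _TRAW_FIXED]
    vals = df[sample_cols].apply(pd.to_numeric).to_numpy(dtype=float).T  # samples x loci
    locus_ids = [str(s) for s in df["SNP"]]
    meta = pd.DataFrame(
        {
            "chrom": df["CHR"].to_numpy(),
            "pos": pd.to_numeric(df["POS"]).to_numpy(),
            "counted": df["COUNTED"].to_numpy(),
            "alt": df["ALT"].to_numpy(),
        },
        index=locus_ids,
    )
    # COUNTED allele re-checked against the cohort minor allele
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        counted_freq = np.nanmean(vals, axis=0) / 2.0
    flip = counted_freq > 0.5
    tie = counted_freq == 0.5
    flip |= tie & (meta["alt"].to_numpy() < meta["counted"].to_numpy())
    if np.any(flip):
        vals[:, flip] = 2.0 - vals[:, flip]
        warnings.warn(
            f"{int(flip.sum())} traw loci had a majority COUNTED allele; codes flipped "
            "to count the cohort minor allele",
            UserWarning,
        )
    meta["flipped_to_minor"] = flip
    mask = np.isnan(vals)
    # PLINK sample columns are FID_IID
    return GenotypeMatrix(
        values=vals,
        missing_mask=mask,
        sample_ids=sample_cols,
        locus_ids=locus_ids,
        locus_meta=meta,
    )


def read_genotypes(path: str, format: str = "tsv") -> GenotypeMatrix:
    """Load a genotype matrix from ``tsv``, ``vcf`` or PLINK ``traw``."""
    readers = {"tsv": _read_tsv, "vcf": _read_vcf, "traw": _read_traw}
    if format not in readers:
        raise ValueError(f"unknown format {format!r}; expected one of {sorted(readers)}")
    gm = readers[format](path)
    all_missing_samples = [
        sid for sid, allmiss in zip(gm.sample_ids, gm.missing_mask.all(axis=1)) if allmiss
    ]
    all_missing_loci = [
        lid for lid, allmiss in zip(gm.locus_ids, gm.missing_mask.all(axis=0)) if allmiss
    ]
    if all_missing_samples or all_missing_loci:
        warnings.warn(
            f"fully-missing samples {all_missing_samples} / loci {all_missing_loci} retained",
            UserWarning,
        )
    return gm


def write_genotypes(gm: GenotypeMatrix, path: str) -> None:
    """Write the package TSV dialect (header = locus IDs, first column = sample ID)."""
    vals = gm.values.copy().astype(object)
    intlike = (~gm.missing_mask) & (np.asarray(gm.values) == np.round(gm.values.astype(float)))
    vals[intlike.astype(bool)] = [int(v) for v in gm.values[intlike.astype(bool)]]
    df = pd.DataFrame(vals, index=gm.sample_ids, columns=gm.locus_ids)
    df = df.mask(pd.DataFrame(gm.missing_mask, index=gm.sample_ids, columns=gm.locus_ids))
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", na_rep=MISSING_TSV)


def read_labels(path: str) -> dict[str, str]:
    """Two-column TSV sample_id -> population; a header row is auto-detected."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"labels file {path} must have two tab-separated columns")
    first = tuple(df.iloc[0])
    if first[0].lower() in {"sample", "sample_id", "id", "iid"}:
        df = df.iloc[1:]
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


# -- Filtering and imputation ---------------------------------------------------


def hwe_chi2_pvalues(gm: GenotypeMatrix) -> np.ndarray:
    """Per-locus Hardy-Weinberg chi-square (1 df) p-values from genotype counts.

    Observed counts of codes (0, 1, 2) are compared with the binomial
    expectations n*(q^2, 2pq, p^2) at the estimated minor-allele frequency p.
    Monomorphic loci get p-value 1.
    """
    m, n = gm.values.shape
    pvals = np.ones(n)
    for j in range(n):
        col = gm.values[~gm.missing_mask[:, j], j]
        nt = col.size
        if nt == 0:
            continue
        n2 = float(np.sum(col == 2))
        n1 = float(np.sum(col == 1))
        n0 = nt - n1 - n2
        p = (2 * n2 + n1) / (2 * nt)
        if p in (0.0, 1.0):
            continue
        exp = nt * np.array([(1 - p) ** 2, 2 * p * (1 - p), p * p])
        obs = np.array([n0, n1, n2])
        stat = float(np.sum((obs - exp) ** 2 / exp))
        pvals[j] = chi2.sf(stat, df=1)
    return pvals


def filter_loci(
    gm: GenotypeMatrix,
    maf_min: float = 0.01,
    hwe_alpha: float = 1e-6,
    missing_max: float = 0.1,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Remove loci by missingness, monomorphism, MAF and HWE, in that fixed order.

    ``hwe_alpha=0`` disables the HWE screen; ``maf_min=0`` together with
    ``missing_max=1`` leaves only the monomorphic screen active.
    """
    if not (0 <= maf_min <= 0.5 and 0 <= hwe_alpha <= 1 and 0 <= missing_max <= 1):
        raise ValueError("filter thresholds out of documented ranges")
    n = gm.n_loci
    removed_by = np.zeros(n, dtype=int)  # 0 keep, 1 missing, 2 mono, 3 maf, 4 hwe

    miss_frac = gm.missing_mask.mean(axis=0)
    removed_by[(miss_frac > missing_max) & (removed_by == 0)] = 1

    maf = gm.minor_allele_frequencies()
    mono = np.isnan(maf) | (np.minimum(maf, 1 - maf) == 0)
    removed_by[mono & (removed_by == 0)] = 2

    low_maf = np.minimum(np.nan_to_num(maf, nan=0.0), 1 - np.nan_to_num(maf, nan=1.0)) < maf_min
    removed_by[low_maf & (removed_by == 0)] = 3

    if hwe_alpha > 0:
        pv = hwe_chi2_pvalues(gm)
        removed_by[(pv < hwe_alpha) & (removed_by == 0)] = 4

    keep = removed_by == 0
    report = FilterReport(
        n_input=n,
        n_removed_missing=int(np.sum(removed_by == 1)),
        n_removed_monomorphic=int(np.sum(removed_by == 2)),
        n_removed_maf=int(np.sum(removed_by == 3)),
        n_removed_hwe=int(np.sum(removed_by == 4)),
        maf_min=maf_min,
        hwe_alpha=hwe_alpha,
        missing_max=missing_max,
    )
    if not np.any(keep):
        raise ValueError("no loci survive filters")
    out = replace(
        gm,
        values=gm.values[:, keep],
        missing_mask=gm.missing_mask[:, keep],
        locus_ids=[lid for lid, k in zip(gm.locus_ids, keep) if k],
        locus_meta=gm.locus_meta.loc[keep] if gm.locus_meta is not None else None,
    )
    return out, report


def impute_missing(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Replace each missing entry by its locus mean over non-missing samples."""
    if not np.any(gm.missing_mask):
        return gm
    if np.any(gm.missing_mask.all(axis=0)):
        bad = [lid for lid, b in zip(gm.locus_ids, gm.missing_mask.all(axis=0)) if b]
        raise ValueError(f"fully-missing loci {bad}: filter before imputing")
    vals = np.where(gm.missing_mask, np.nan, gm.values)
    col_means = np.nanmean(vals, axis=0)
    filled = np.where(gm.missing_mask, col_means[None, :], gm.values)
    return replace(gm, values=filled, imputed=True)
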