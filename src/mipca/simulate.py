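"""Synthetic genotype and bivariate samplers with known structure.

The genotype generator follows the Balding-Nichols model: each locus draws
an ancestral allele frequency p, each population k then draws its own
frequency from Beta(p(1-F_k)/F_k, (1-p)(1-F_k)/F_k) -- a distribution with
mean p and variance F_k * p(1-p), so F_k is interpretable as that
population's FST against the ancestral pool -- and individuals draw
genotypes Binomial(2, p_k).  This is the simplest generative model whose
divergence parameter is directly estimable from the output (via the Hudson
FST estimator), which makes every downstream module testable offline.

Bivariate Gaussian / Student-t samplers support the MI estimator checks,
and the expected-segregating-sites harmonic sum ties map distances to the
count of surviving lineages rather than to time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .genio import GenotypeMatrix

__all__ = [
    "SimulationSpec",
    "simulate_balding_nichols",
    "simulate_bivariate",
    "expected_segregating_sites",
    "hudson_fst",
]


@dataclass
class SimulationSpec:
    """Study conditions for a Balding-Nichols genotype simulation.

    Defaults describe three moderately diverged populations (F = 0.1,
    roughly continental-scale differentiation) of 50 samples each, typed at
    2000 common loci with ancestral minor-allele frequencies uniform on
    (0.05, 0.5) and no missingness.
    """

    n_pops: int = 3
    n_per_pop: int | list[int] = 50
    n_loci: int = 2000
    fst: float | list[float] = 0.1
    ancestral_maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.0
    seed: int = 0

    def per_pop_counts(self) -> list[int]:
        if isinstance(self.n_per_pop, int):
            return [self.n_per_pop] * self.n_pops
        return list(self.n_per_pop)

    def per_pop_fst(self) -> list[float]:
        if isinstance(self.fst, (int, float)):
            return [float(self.fst)] * self.n_pops
        return [float(f) for f in self.fst]

    def validate(self) -> None:
        if self.n_pops < 1:
            raise ValueError("n_pops must be >= 1")
        counts = self.per_pop_counts()
        if len(counts) != self.n_pops or any(c < 1 for c in counts):
            raise ValueError("n_per_pop must give a positive count per population")
        if sum(counts) < 2:
            raise ValueError("need at least 2 samples in total")
        if self.n_loci < 2:
            raise ValueError("n_loci must be >= 2")
        fs = self.per_pop_fst()
        if len(fs) != self.n_pops or any(not 0.0 < f < 1.0 for f in fs):
            raise ValueError("fst values must lie in (0, 1)")
        lo, hi = self.ancestral_maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("ancestral_maf_range must be within (0, 0.5]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")


def simulate_balding_nichols(spec: SimulationSpec) -> GenotypeMatrix:
    """Simulate a labelled genotype matrix under the Balding-Nichols model.

    Per-locus random streams are derived deterministically from the root
    seed (``SeedSequence.spawn``), so any locus subset is reproducible on
    its own; the missingness mask draws from a separate stream.
    """
    spec.validate()
    counts = spec.per_pop_counts()
    fs = spec.per_pop_fst()
    m = sum(counts)
    pop_of_sample = np.repeat(np.arange(spec.n_pops), counts)

    root = np.random.SeedSequence(spec.seed)
    locus_seeds = root.spawn(spec.n_loci + 1)  # last one drives missingness
    lo, hi = spec.ancestral_maf_range
    values = np.empty((m, spec.n_loci), dtype=float)
    for j in range(spec.n_loci):
        rng = np.random.default_rng(locus_seeds[j])
        p = rng.uniform(lo, hi)
        geno = np.empty(m, dtype=float)
        start = 0
        for k, (ck, fk) in enumerate(zip(counts, fs)):
            a = p * (1 - fk) / fk
            b = (1 - p) * (1 - fk) / fk
            pk = rng.beta(a, b)
            geno[start : start + ck] = rng.binomial(2, pk, size=ck)
            start += ck
        values[:, j] = geno

    miss_rng = np.random.default_rng(locus_seeds[-1])
    mask = miss_rng.random((m, spec.n_loci)) < spec.missing_rate
    values = np.where(mask, np.nan, values)

    width = len(str(spec.n_loci))
    return GenotypeMatrix(
        values=values,
        missing_mask=mask,
        sample_ids=[f"pop{pop_of_sample[i]}_s{i:04d}" for i in range(m)],
        locus_ids=[f"snp{j:0{width}d}" for j in range(spec.n_loci)],
        population_labels=[f"pop{k}" for k in pop_of_sample],
    )


def simulate_bivariate(
    rho: float, alpha: float | str, n: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Draw n correlated pairs: Gaussian, or Student-t via the chi-square mixture.

    Gaussian pairs come from the Cholesky factor of [[1, rho], [rho, 1]];
    Student-t pairs divide a Gaussian pair by sqrt(chi2_alpha / alpha),
    which gives the elliptical bivariate t whose *copula* correlation
    parameter is rho (the Pearson correlation of the t pair equals rho when
    alpha > 2).
    """
    if not -1.0 < rho < 1.0:
        raise ValueError(f"need |rho| < 1, got {rho}")
    if n < 2:
        raise ValueError("need n >= 2")
    rng = np.random.default_rng(seed)
    g = rng.standard_normal((n, 2))
    x = g[:, 0]
    y = rho * g[:, 0] + np.sqrt(1 - rho * rho) * g[:, 1]
    if alpha == "gaussian":
        return x, y
    alpha = float(alpha)
    if alpha <= 0:
        raise ValueError("alpha must be positive or 'gaussian'")
    w = np.sqrt(rng.chisquare(alpha, size=n) / alpha)
    return x / w, y / w


def expected_segregating_sites(Ne: float, mu: float, N: int) -> float:
    """Expected segregating-site count 4*Ne*mu * sum_{k<=N} 1/k.

    Grows like 4*Ne*mu*log(N): each factor-of-e increase in sample size adds
    roughly one unit of 4*Ne*mu, the lineage-counting behaviour that the
    information scale of the maps echoes.
    """
    if Ne <= 0 or mu <= 0:
        raise ValueError("Ne and mu must be positive")
    N = int(N)
    if N < 1:
        raise ValueError("N must be a positive integer")
    harm = float(np.sum(1.0 / np.arange(1, N + 1)))
    return 4.0 * Ne * mu * harm


def _pairwise_hudson(p1, p2, n1, n2) -> tuple[np.ndarray, np.ndarray]:
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def hudson_fst(gm: GenotypeMatrix, labels: list[str] | None = None) -> float:
    """Hudson FST estimate (ratio of averages) from a labelled genotype matrix.

    Allele frequencies per population come from the additive codes; for
    more than two populations the estimate is the mean over population
    pairs.  Loci monomorphic in a pair contribute nothing to that pair.
    """
    labels = labels if labels is not None else gm.population_labels
    if labels is None:
        raise ValueError("population labels required for an FST estimate")
    labels_arr = np.array(list(labels))
    pops = sorted(set(labels_arr))
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    vals = np.where(gm.missing_mask, np.nan, gm.values)
    freqs, sizes = {}, {}
    for pop in pops:
        sub = vals[labels_arr == pop]
        with np.errstate(invalid="ignore"):
            freqs[pop] = np.nanmean(sub, axis=0) / 2.0
        # allele count = 2 x non-missing individuals, per locus
        sizes[pop] = 2.0 * np.sum(~np.isnan(sub), axis=0)
    ests = []
    for pa, pb in combinations(pops, 2):
        ok = (
            ~np.isnan(freqs[pa])
            & ~np.isnan(freqs[pb])
            & (sizes[pa] > 1)
            & (sizes[pb] > 1)
        )
        num, den = _pairwise_hudson(freqs[pa][ok], freqs[pb][ok], sizes[pa][ok], sizes[pb][ok])
        usable = den > 0
        if not np.any(usable):
            continue
        ests.append(float(num[usable].sum() / den[usable].sum()))
    if not ests:
        raise ValueError("no informative loci for FST estimation")
    return float(np.mean(ests))
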