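"""Cluster-separation diagnostics on a single principal-component axis.

Two clusters with centers of mass projected on a component at
mu_i = rho_i * sqrt(lambda) are compared through

* the linear (1-D Mahalanobis) distance  Delta_mu = |mu_2 - mu_1| / sigma,
  with sigma the pooled within-cluster standard deviation, and
* the MI-scaled distance, whose normalized square is
  (sigma^2/lambda) * Delta_mu_tilde^2
      = 1/4 * ( ln((1 - rho_2^2) / (1 - rho_1^2)) )^2
      = ( r(rho_2) - r(rho_1) )^2.

For nearby centers the difference linearizes to

  (sigma^2/lambda) (Delta_mu_tilde^2 - Delta_mu^2)
      ~ ( rho_1^2/(1 - rho_1^2)^2 - 1 ) (rho_2 - rho_1)^2,

whose leading coefficient changes sign at the critical correlation
rho* = sqrt((3 - sqrt(5))/2) ~ 0.618 (the inverse golden ratio): above it
the information scale *expands* cluster gaps.  A one-tailed Fisher-z test
gates whether a center-of-mass correlation credibly exceeds rho*.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .rescale import EmbeddingCoordinates

__all__ = [
    "SeparationReport",
    "linear_separation",
    "mi_separation_sq",
    "exact_normalized_difference",
    "linearized_difference",
    "critical_threshold",
    "CRITICAL_THRESHOLD_CLOSED_FORM",
    "gate_test",
    "compare_separations",
]

#: closed form sqrt((3 - sqrt(5))/2), the positive root of rho^2 = (1-rho^2)^2
CRITICAL_THRESHOLD_CLOSED_FORM = float(np.sqrt((3.0 - np.sqrt(5.0)) / 2.0))


@dataclass
class SeparationReport:
    """All separation quantities for one cluster pair on one axis."""

    label1: str
    label2: str
    axis: int
    rho1: float
    rho2: float
    lambda1: float
    pooled_sd: float
    delta_mu: float
    delta_mu_tilde_sq_scaled: float
    linearized_diff: float
    above_threshold: bool
    gate_p_value: float
    gate_n: int
    axis_reflected: bool = False

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


def linear_separation(mu1: float, mu2: float, pooled_sd: float) -> float:
    """1-D Mahalanobis distance |mu2 - mu1| / sigma of two projected centers."""
    if not pooled_sd > 0:
        raise ValueError(f"pooled_sd must be positive, got {pooled_sd}")
    return abs(mu2 - mu1) / pooled_sd


def _check_pos_rho(*rhos: float) -> None:
    for r in rhos:
        if not 0.0 < r < 1.0:
            raise ValueError(
                f"center-of-mass correlation {r} outside (0, 1); the comparison "
                "is stated for positive correlation coefficients"
            )


def mi_separation_sq(rho1: float, rho2: float) -> float:
    """Normalized squared MI-scaled distance (sigma^2/lambda) * Delta_mu_tilde^2.

    Equals 1/4 * (ln((1-rho2^2)/(1-rho1^2)))^2 and identically
    (r(rho2) - r(rho1))^2; symmetric under swapping the clusters.
    """
    _check_pos_rho(rho1, rho2)
    return 0.25 * float(np.log((1 - rho2 * rho2) / (1 - rho1 * rho1))) ** 2


def exact_normalized_difference(rho1: float, rho2: float) -> float:
    """Exact (sigma^2/lambda)-normalized Delta_mu_tilde^2 - Delta_mu^2.

    In these normalized units the linear squared distance is (rho2 - rho1)^2.
    """
    _check_pos_rho(rho1, rho2)
    return mi_separation_sq(rho1, rho2) - (rho2 - rho1) ** 2


def linearized_difference(rho1: float, rho2: float) -> float:
    """Leading-order expansion of the normalized distance difference.

    Returns (rho1^2/(1-rho1^2)^2 - 1) * (rho2 - rho1)^2; positive exactly
    when the MI scale separates the clusters more than the linear one, at
    leading order in rho2 - rho1.
    """
    _check_pos_rho(rho1, rho2)
    c = rho1 * rho1 / (1 - rho1 * rho1) ** 2 - 1.0
    return c * (rho2 - rho1) ** 2


def critical_threshold(tol: float = 1e-12) -> float:
    """Root rho* of rho^2/(1-rho^2)^2 = 1 on (0, 1), found by bisection.

    Equals sqrt((3 - sqrt(5))/2) = 0.6180339887... (the inverse golden
    ratio); the coefficient in the linearized comparison is negative below
    it and positive above it.
    """

    def f(r: float) -> float:
        return r * r - (1 - r * r) ** 2

    lo, hi = 0.0, 1.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if f(mid) > 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def gate_test(r: float, n: int, rho_null: float | None = None) -> float:
    """One-tailed test of H0: rho <= rho_null against H1: rho > rho_null.

    Uses the Fisher z-transform, z = (atanh(r) - atanh(rho_null)) * sqrt(n-3),
    referred to the standard normal; ``rho_null`` defaults to the critical
    threshold rho*.  ``n`` is the number of paired observations behind the
    sample correlation ``r``.
    """
    if n < 4:
        raise ValueError(f"need n >= 4 observations, got {n}")
    if rho_null is None:
        rho_null = critical_threshold()
    if not -1.0 < rho_null < 1.0:
        raise ValueError(f"|rho_null| must be < 1, got {rho_null}")
    if abs(r) >= 1.0:
        if abs(r) > 1.0:
            raise ValueError(f"sample correlation {r} outside [-1, 1]")
        warnings.warn("|r| = 1: degenerate correlation, p-value is 0 or 1", UserWarning)
        return 0.0 if r > 0 else 1.0
    z = (np.arctanh(r) - np.arctanh(rho_null)) * np.sqrt(n - 3)
    return float(norm.sf(z))


def compare_separations(
    cluster_labels,
    embedding: EmbeddingCoordinates,
    axis: int,
    *,
    standardized=None,
    decomposition=None,
) -> SeparationReport:
    """Assemble a :class:`SeparationReport` for two labelled clusters.

    ``cluster_labels`` maps each sample to one of exactly two labels (a dict
    keyed by sample id, or a sequence aligned with the embedding rows).

    The center-of-mass correlations rho_k are estimated, when the
    standardized matrix and decomposition are supplied, as the Pearson
    correlation between each cluster's mean standardized genotype row and
    the component score vector (n_loci observations) -- the estimator that
    can actually reach the high-correlation regime.  With only an embedding
    available, the mean of member loadings is used as a fallback; with m
    samples those loadings are O(1/sqrt(m)), so this route is meaningful
    only for small panels.

    The component's sign is a convention: if both center correlations are
    negative the axis is reflected; mixed signs raise, as the comparison is
    defined for positive correlations only.
    """
    if axis not in embedding.axes:
        raise ValueError(f"axis {axis} not among embedding axes {embedding.axes}")
    a = embedding.axes.index(axis)
    if isinstance(cluster_labels, dict):
        labels = [cluster_labels.get(s) for s in embedding.sample_ids]
        if any(lab is None for lab in labels):
            missing = [s for s, lab in zip(embedding.sample_ids, labels) if lab is None]
            raise ValueError(f"samples without a cluster label: {missing[:5]}")
    else:
        labels = list(cluster_labels)
        if len(labels) != len(embedding.sample_ids):
            raise ValueError("label count mismatch with embedding")
    uniq = sorted(set(labels))
    if len(uniq) != 2:
        raise ValueError(f"need exactly two cluster labels, got {uniq}")
    labels_arr = np.array(labels)
    members = [np.flatnonzero(labels_arr == u) for u in uniq]
    for u, mem in zip(uniq, members):
        if mem.size < 2:
            raise ValueError(f"cluster {u!r} has fewer than 2 members")

    lam = float(embedding.eigenvalues[a])
    if standardized is not None and decomposition is not None:
        Z = standardized.Z
        P_axis = decomposition.components(Z)[axis - 1]
        # the embedding may cover a subset of the cohort, so match by id
        sid_index = {s: i for i, s in enumerate(standardized.sample_ids)}
        try:
            rows = [
                np.array([sid_index[embedding.sample_ids[i]] for i in mem])
                for mem in members
            ]
        except KeyError as exc:
            raise ValueError(
                f"sample {exc.args[0]!r} not present in the standardized matrix"
            ) from None
        rhos = [float(np.corrcoef(Z[rw].mean(axis=0), P_axis)[0, 1]) for rw in rows]
        gate_n = Z.shape[1]
    else:
        rhos = [float(embedding.loadings[mem, a].mean()) for mem in members]
        gate_n = int(min(mem.size for mem in members))

    reflected = False
    if all(r < 0 for r in rhos):
        rhos = [-r for r in rhos]
        reflected = True

    lo = int(rhos[1] < rhos[0])  # index of the cluster with the smaller rho
    lab1, lab2 = uniq[lo], uniq[1 - lo]
    rho1, rho2 = rhos[lo], rhos[1 - lo]

    coord = embedding.conventional[:, a]
    mu = [float(coord[mem].mean()) for mem in members]
    var_within = [float(coord[mem].var(ddof=1)) for mem in members]
    n1, n2 = members[0].size, members[1].size
    pooled_sd = float(
        np.sqrt(((n1 - 1) * var_within[0] + (n2 - 1) * var_within[1]) / (n1 + n2 - 2))
    )
    if pooled_sd == 0:
        delta_mu = 0.0 if mu[0] == mu[1] else float("inf")
    else:
        delta_mu = linear_separation(mu[0], mu[1], pooled_sd)

    if rho1 == rho2:
        mi_sq, lin = 0.0, 0.0
    else:
        mi_sq = mi_separation_sq(rho1, rho2)
        lin = linearized_difference(rho1, rho2)
    rho_star = critical_threshold()
    above = rho1 > rho_star
    gate_p = gate_test(rho1, max(gate_n, 4), rho_star)

    return SeparationReport(
        label1=str(lab1),
        label2=str(lab2),
        axis=axis,
        rho1=rho1,
        rho2=rho2,
        lambda1=lam,
        pooled_sd=pooled_sd,
        delta_mu=delta_mu,
        delta_mu_tilde_sq_scaled=mi_sq,
        linearized_diff=lin,
        above_threshold=bool(above),
        gate_p_value=gate_p,
        gate_n=int(gate_n),
        axis_reflected=reflected,
    )
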