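"""Paired conventional and MI-rescaled map coordinates.

The conventional coordinate of sample i on component j is rho * sqrt(lambda_j)
with rho = U_ij; the information-rescaled coordinate replaces rho by
r(rho) = -sgn(rho) * 1/2 * log(1 - rho^2), applied entrywise (per sample),
so each axis is stretched monotonically: order along every axis is exactly
preserved while distances become information-valued.  Points closer to the
origin than the critical correlation are pulled together and points beyond
it pushed apart, which is what sharpens well-correlated clusters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mi import LogBase, signed_rescale_array
from .pca import PCADecomposition

__all__ = [
    "EmbeddingCoordinates",
    "rescale_loadings",
    "make_embedding",
    "write_embedding",
    "read_embedding",
    "plot_embedding",
]


@dataclass
class EmbeddingCoordinates:
    """Per-sample coordinates on chosen axes, in two parallel scales.

    ``conventional`` holds rho*sqrt(lambda); ``rescaled`` holds
    r(rho)*sqrt(lambda) in the declared information unit.  ``loadings``
    (the raw correlations rho = U entries) and the axis eigenvalues are
    retained so cluster diagnostics and round-trips stay lossless.
    """

    sample_ids: list[str]
    axes: list[int]
    conventional: np.ndarray
    rescaled: np.ndarray
    loadings: np.ndarray
    eigenvalues: np.ndarray
    base: LogBase = LogBase.nats
    population_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.base = LogBase(self.base)
        for name in ("conventional", "rescaled", "loadings"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape != (len(self.sample_ids), len(self.axes)):
                raise ValueError(f"{name} shape mismatch")

    def to_dataframe(self) -> pd.DataFrame:
        cols: dict[str, object] = {"sample_id": self.sample_ids}
        cols["population"] = (
            self.population_labels if self.population_labels is not None else [""] * len(self.sample_ids)
        )
        for a, ax in enumerate(self.axes):
            cols[f"PC{ax}_conv"] = self.conventional[:, a]
            cols[f"PC{ax}_mi"] = self.rescaled[:, a]
        return pd.DataFrame(cols)


def rescale_loadings(M: np.ndarray, base: str | LogBase = LogBase.nats) -> np.ndarray:
    """Entrywise signed rescaling of a correlation-loadings table M' = R(M)."""
    return signed_rescale_array(np.asarray(M, dtype=float), base)


def make_embedding(
    decomp: PCADecomposition,
    axes: list[int] | tuple[int, ...] = (1, 2),
    base: str | LogBase = LogBase.nats,
    *,
    population_labels: list[str] | None = None,
    weight: str = "sqrt_eigenvalue",
) -> EmbeddingCoordinates:
    """Build paired conventional / MI-rescaled coordinates on ``axes`` (1-based).

    ``weight='sqrt_eigenvalue'`` (default) multiplies both scales by
    sqrt(lambda_j); ``weight='none'`` leaves the rescaled coordinates as
    pure r(rho) in information units, comparable across axes.
    """
    axes = list(axes)
    if not axes:
        raise ValueError("empty axis list")
    if len(set(axes)) != len(axes):
        raise ValueError("duplicate axis indices")
    for a in axes:
        if not 1 <= a <= decomp.rank:
            raise ValueError(f"axis {a} out of range 1..{decomp.rank}")
    if weight not in ("sqrt_eigenvalue", "none"):
        raise ValueError("weight must be 'sqrt_eigenvalue' or 'none'")
    base = LogBase(base)
    j = np.array(axes, dtype=int) - 1
    lam = decomp.eigenvalues[j]
    U = decomp.U[:, j].copy()
    null = decomp.null_components[j]
    if np.any(null):
        warnings.warn(
            f"axes {[axes[i] for i in np.flatnonzero(null)]} have a null eigenvalue; "
            "their coordinates are set to 0",
            UserWarning,
        )
        U[:, null] = 0.0
    w = np.sqrt(lam) if weight == "sqrt_eigenvalue" else np.ones_like(lam)
    w = np.where(null, 0.0 if weight == "sqrt_eigenvalue" else 1.0, w)
    conventional = U * np.sqrt(np.where(null, 0.0, lam))[None, :]
    rescaled = signed_rescale_array(U, base) * w[None, :]
    if population_labels is not None and len(population_labels) != decomp.n_samples:
        raise ValueError("population label count mismatch")
    return EmbeddingCoordinates(
        sample_ids=list(decomp.sample_ids),
        axes=axes,
        conventional=conventional,
        rescaled=rescaled,
        loadings=U,
        eigenvalues=lam,
        base=base,
        population_labels=list(population_labels) if population_labels is not None else None,
    )


def write_embedding(coords: EmbeddingCoordinates, path: str) -> None:
    """Write the embedding TSV (lossless at 17 significant digits).

    Two comment lines carry the axis eigenvalues, raw loadings availability
    and the information unit so that :func:`read_embedding` round-trips.
    """
    if not coords.axes:
        raise ValueError("empty axis list")
    df = coords.to_dataframe()
    for a, ax in enumerate(coords.axes):
        df[f"PC{ax}_loading"] = coords.loadings[:, a]
    with open(path, "w") as fh:
        fh.write(f"# base={coords.base.value}\n")
        fh.write("# eigenvalues=" + ",".join(f"{v:.17g}" for v in coords.eigenvalues) + "\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def read_embedding(path: str) -> EmbeddingCoordinates:
    """Read an embedding TSV written by :func:`write_embedding`."""
    import io

    base = LogBase.nats
    eigenvalues = None
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("# base="):
            base = LogBase(line.strip().split("=", 1)[1])
        elif line.startswith("# eigenvalues="):
            eigenvalues = np.array(
                [float(v) for v in line.strip().split("=", 1)[1].split(",")]
            )
        elif not line.startswith("#"):
            body_start = i
            break
    df = pd.read_csv(
        io.StringIO("".join(lines[body_start:])),
        sep="\t",
        dtype={"sample_id": str, "population": str},
        float_precision="round_trip",
    )
    axes = [int(c[2:-5]) for c in df.columns if c.startswith("PC") and c.endswith("_conv")]
    if eigenvalues is None:
        raise ValueError(f"{path} lacks the eigenvalue header line")
    conventional = np.column_stack([df[f"PC{a}_conv"] for a in axes])
    rescaled = np.column_stack([df[f"PC{a}_mi"] for a in axes])
    if all(f"PC{a}_loading" in df.columns for a in axes):
        loadings = np.column_stack([df[f"PC{a}_loading"] for a in axes])
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            loadings = np.where(eigenvalues > 0, conventional / np.sqrt(eigenvalues), 0.0)
    pops = df["population"].fillna("").tolist() if "population" in df.columns else None
    if pops is not None and all(p == "" for p in pops):
        pops = None
    return EmbeddingCoordinates(
        sample_ids=df["sample_id"].tolist(),
        axes=axes,
        conventional=conventional,
        rescaled=rescaled,
        loadings=loadings,
        eigenvalues=eigenvalues,
        base=base,
        population_labels=pops,
    )


def plot_embedding(coords: EmbeddingCoordinates, path: str, axes_pair: tuple[int, int] | None = None) -> None:
    """Two-panel scatter (conventional vs rescaled), colored by population."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if axes_pair is None:
        if len(coords.axes) < 2:
            raise ValueError("need at least two axes to plot")
        axes_pair = (coords.axes[0], coords.axes[1])
    ix = [coords.axes.index(a) for a in axes_pair]
    pops = coords.population_labels or ["all"] * len(coords.sample_ids)
    uniq = sorted(set(pops))
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(11, 5))
    for pop in uniq:
        sel = np.array([p == pop for p in pops])
        ax1.scatter(coords.conventional[sel, ix[0]], coords.conventional[sel, ix[1]], s=12, label=pop)
        ax2.scatter(coords.rescaled[sel, ix[0]], coords.rescaled[sel, ix[1]], s=12, label=pop)
    ax1.set_title("conventional (rho * sqrt(lambda))")
    ax2.set_title(f"MI-rescaled (r(rho) * sqrt(lambda), {coords.base.value})")
    for ax in (ax1, ax2):
        ax.set_xlabel(f"PC{axes_pair[0]}")
        ax.set_ylabel(f"PC{axes_pair[1]}")
    ax1.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
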