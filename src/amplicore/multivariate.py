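"""Distance-based and constrained ordination of community tables.

Implements the multivariate toolkit used for soil-community comparisons:
Bray-Curtis dissimilarity, principal coordinates analysis (PCoA),
group-average (UPGMA) and Ward hierarchical clustering with newick export,
distance-based PERMANOVA, and canonical correspondence analysis (CCA)
relating taxon abundances to environmental drivers such as THg, MeHg and
soil nutrient pools.

PCoA, PERMANOVA and CCA are native implementations written against their
textbook definitions (Gower double-centering; pseudo-F over permuted
labels; chi-square-standardized taxon matrix projected by weighted least
squares onto the environment space).  The test suite cross-checks them
against scikit-bio's independent implementations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from scipy.stats import chi2_contingency

__all__ = [
    "DistanceMatrix",
    "OrdinationResult",
    "CCAResult",
    "PermanovaResult",
    "bray_curtis",
    "pcoa",
    "hcluster",
    "linkage_to_newick",
    "permanova",
    "cca_fit",
]


@dataclass
class DistanceMatrix:
    """Symmetric zero-diagonal dissimilarity matrix over named samples."""

    ids: list[str]
    data: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise ValueError("distance matrix must have a zero diagonal")
        self.data = d

    def condensed(self) -> np.ndarray:
        return squareform(self.data, checks=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.ids, columns=self.ids)


def bray_curtis(table: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between sample columns.

    ``d(i, j) = 1 - 2 * sum(min(x_i, x_j)) / sum(x_i + x_j)``, on the
    feature-by-sample abundance table (raw or normalized counts).
    """
    values = table.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("abundances must be non-negative")
    zero = values.sum(axis=0) == 0
    if zero.any():
        bad = [c for c, z in zip(table.columns, zero) if z]
        raise ValueError(f"all-zero sample(s): {bad}")
    d = squareform(pdist(values.T, metric="braycurtis"))
    return DistanceMatrix(list(table.columns), d)


@dataclass
class OrdinationResult:
    eigenvalues: np.ndarray  # positive eigenvalues, descending
    coordinates: pd.DataFrame  # samples x axes
    proportion_explained: np.ndarray
    n_negative_eigenvalues: int


def pcoa(dm: DistanceMatrix) -> OrdinationResult:
    """Principal coordinates analysis by Gower double-centering.

    Axes with negative eigenvalues (possible for semi-metric input such as
    Bray-Curtis) are dropped and counted rather than corrected, so the
    returned proportions are relative to the positive part of the spectrum.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("PCoA needs at least 3 samples")
    d2 = dm.data**2
    centering = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * centering @ d2 @ centering
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(1e-10, 1e-10 * abs(eigvals[0])) if eigvals.size else 0.0
    positive = eigvals > tol
    n_negative = int((eigvals < -tol).sum())
    lam = eigvals[positive]
    coords = eigvecs[:, positive] * np.sqrt(lam)
    frame = pd.DataFrame(
        coords, index=dm.ids, columns=[f"PCo{i + 1}" for i in range(coords.shape[1])]
    )
    return OrdinationResult(lam, frame, lam / lam.sum(), n_negative)


@dataclass
class DendrogramResult:
    linkage: np.ndarray
    newick: str
    ids: list[str]


def linkage_to_newick(z: np.ndarray, ids: list[str]) -> str:
    """Render a scipy linkage matrix as a newick string with branch lengths."""
    tree = hierarchy.to_tree(z)

    def _render(node, parent_height: float) -> str:
        length = parent_height - (node.dist if not node.is_leaf() else 0.0)
        if node.is_leaf():
            return f"{ids[node.id]}:{length:.10g}"
        left = _render(node.left, node.dist)
        right = _render(node.right, node.dist)
        return f"({left},{right}):{length:.10g}"

    return f"({_render(tree.left, tree.dist)},{_render(tree.right, tree.dist)});"


def hcluster(dm: DistanceMatrix, linkage: str = "group_average") -> DendrogramResult:
    """Agglomerative clustering of a distance matrix.

    ``group_average`` is UPGMA (ultrametric heights); ``ward`` uses the
    squared-distance update (ward.D2 convention).  Scipy's deterministic
    merge ordering provides tie-breaking.
    """
    if len(dm.ids) < 2:
        raise ValueError("clustering needs at least 2 samples")
    method = {"group_average": "average", "ward": "ward"}.get(linkage)
    if method is None:
        raise ValueError(f"unknown linkage {linkage!r}")
    z = hierarchy.linkage(dm.condensed(), method=method)
    return DendrogramResult(z, linkage_to_newick(z, dm.ids), dm.ids)


@dataclass
class PermanovaResult:
    pseudo_f: float
    p_value: float
    n_permutations: int
    ss_among: float
    ss_within: float


def _permanova_f(d2: np.ndarray, labels: np.ndarray) -> tuple[float, float, float]:
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    groups = np.unique(labels)
    for g in groups:
        idx = np.flatnonzero(labels == g)
        if idx.size > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(idx.size, 1)].sum() / idx.size
    ss_among = ss_total - ss_within
    df_among = len(groups) - 1
    df_within = n - len(groups)
    f = (ss_among / df_among) / (ss_within / df_within)
    return f, ss_among, ss_within


def permanova(
    dm: DistanceMatrix,
    labels,
    n_perm: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """Permutational multivariate ANOVA on a distance matrix.

    Pseudo-F is computed from among- and within-group sums of squared
    distances; the p-value is ``(1 + #(F_perm >= F_obs)) / (1 + n_perm)``
    under random relabelling, reproducible for a given seed and invariant
    to sample ordering.
    """
    labels = np.asarray(
        [labels[s] for s in dm.ids] if isinstance(labels, dict) else labels
    )
    if labels.shape[0] != len(dm.ids):
        raise ValueError("one label per sample required")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    if (counts == 0).any():
        raise ValueError("empty group")
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")

    # canonical sample order so that permuting the input leaves p unchanged
    order = np.argsort(np.asarray(dm.ids))
    d2 = dm.data[np.ix_(order, order)] ** 2
    labels = labels[order]

    f_obs, ss_among, ss_within = _permanova_f(d2, labels)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        f_perm, _, _ = _permanova_f(d2, perm)
        if f_perm >= f_obs:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return PermanovaResult(float(f_obs), float(p), n_perm, ss_among, ss_within)


@dataclass
class CCAResult:
    eigenvalues: np.ndarray  # constrained axes, descending
    site_scores: pd.DataFrame
    species_scores: pd.DataFrame
    biplot_scores: pd.DataFrame  # environment variables x axes
    total_inertia: float
    ca_eigenvalues: np.ndarray  # unconstrained correspondence-analysis spectrum


def cca_fit(
    taxa: pd.DataFrame,
    env: pd.DataFrame,
    pretransform_env: bool = True,
) -> CCAResult:
    """Canonical correspondence analysis of a community against environment.

    The taxon table (samples x taxa, non-negative) is chi-square
    standardized; the standardized matrix is projected by weighted least
    squares onto the span of the (optionally log(X+1)-transformed, then
    weighted-standardized) environment variables, and the projection is
    eigen-analyzed.  Scores follow the scaling-2 convention (taxon scores
    scaled by singular values).  Total inertia equals the table's
    chi-square statistic divided by its grand total.
    """
    if list(taxa.index) != list(env.index):
        raise ValueError("samples must be aligned between taxa and env tables")
    n, q = env.shape
    if n < q + 2:
        raise ValueError("need at least n_env + 2 samples")
    y = taxa.to_numpy(dtype=float)
    if (y < 0).any():
        raise ValueError("taxon abundances must be non-negative")
    if (y.sum(axis=1) == 0).any() or (y.sum(axis=0) == 0).any():
        raise ValueError("taxa table must have no all-zero rows or columns")

    x = env.to_numpy(dtype=float)
    if pretransform_env:
        if (x < 0).any():
            raise ValueError("log(X+1) pretransform requires non-negative env values")
        x = np.log1p(x)
    constant = np.ptp(x, axis=0) == 0
    if constant.any():
        bad = [c for c, flag in zip(env.columns, constant) if flag]
        raise ValueError(f"constant environment column(s): {bad}")

    total = y.sum()
    p = y / total
    r = p.sum(axis=1)
    c = p.sum(axis=0)
    qbar = (p - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    total_inertia = float((qbar**2).sum())

    # weighted centering + standardization of environment variables
    xc = x - r @ x
    wsd = np.sqrt(r @ (xc**2))
    xc = xc / wsd
    b = xc * np.sqrt(r)[:, None]
    btb = b.T @ b
    cond = np.linalg.cond(btb)
    if cond > 1e10:
        raise ValueError(
            f"collinear environment columns (condition number {cond:.3g})"
        )
    hat = b @ np.linalg.solve(btb, b.T)
    fitted = hat @ qbar

    u, s, vt = np.linalg.svd(fitted, full_matrices=False)
    keep = s**2 > 1e-12
    keep[min(q, keep.size):] = False
    u, s, vt = u[:, keep], s[keep], vt[keep]
    eig = s**2

    site = u / np.sqrt(r)[:, None]
    species = (vt.T / np.sqrt(c)[:, None]) * s
    biplot = b.T @ u  # weighted correlation of standardized env with axes

    axes = [f"CCA{i + 1}" for i in range(eig.size)]
    ca_s = np.linalg.svd(qbar, compute_uv=False)
    ca_eig = ca_s[ca_s**2 > 1e-12] ** 2

    return CCAResult(
        eigenvalues=eig,
        site_scores=pd.DataFrame(site, index=taxa.index, columns=axes),
        species_scores=pd.DataFrame(species, index=taxa.columns, columns=axes),
        biplot_scores=pd.DataFrame(biplot, index=env.columns, columns=axes),
        total_inertia=total_inertia,
        ca_eigenvalues=ca_eig,
    )


def chi_square_inertia(taxa: pd.DataFrame) -> float:
    """Independent route to total inertia: chi-square statistic / grand total."""
    stat = chi2_contingency(taxa.to_numpy(), correction=False)[0]
    return float(stat / taxa.to_numpy().sum())
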