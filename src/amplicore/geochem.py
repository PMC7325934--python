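"""Soil geochemistry statistics: correlations, MeHg fractions, contamination bins.

Works on the five-site table of nutrient and mercury measurements
(moisture, total C/N/P, loss on ignition, KCl-extractable NH4/NO3/PO4,
total mercury THg and monomethylmercury MeHg, both ng/g dry weight).
Below-detection ("b.d.") measurements are represented as an explicit mask
over a NaN-bearing numeric table: correlations drop them pairwise, while
cluster analysis imputes them at half the minimum observed value of that
variable.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from scipy.stats import pearsonr

from .multivariate import linkage_to_newick

__all__ = [
    "GeochemTable",
    "BinThresholds",
    "convert_units",
    "pearson_pairs",
    "mehg_fraction",
    "bin_and_cluster",
]

BD = "b.d."

VARIABLES = [
    "moisture_pct",
    "total_carbon_g_kg",
    "total_nitrogen_g_kg",
    "total_phosphorus_mg_kg",
    "loi_pct",
    "extractable_nh4_mg_kg",
    "extractable_no3_mg_kg",
    "extractable_po4_mg_kg",
    "thg_ng_g",
    "mehg_ng_g",
]

_FIXTURE_ROWS: dict[str, list[object]] = {
    # moisture, TC, TN, TP, LOI, NH4, NO3, PO4, THg, MeHg
    "H-02": [54.8, 2.868, 1.89, 308, 6.5, 32.13, 3.230, 0.096, 9.80, 0.27],
    "S1": [69.0, 5.997, 4.469, 1371, 20.0, 114.19, 0.623, 0.335, 788.28, 0.98],
    "S3": [50.5, 4.156, 2.245, 242, 8.0, 4.99, 0.250, BD, 26.19, 0.82],
    "R1": [32.8, 1.219, 0.628, 68.5, 2.4, 29.67, BD, BD, 13.64, 0.27],
    "B": [31.8, 0.951, 0.852, 495, 4.3, 61.81, 0.550, 0.027, 1688.31, 1.21],
}

#: Sites designated as uncontaminated controls in the study design.
REFERENCE_SITES = frozenset({"R1"})


@dataclass
class GeochemTable:
    """Numeric site-by-variable table with a below-detection mask."""

    values: pd.DataFrame  # sites x variables, NaN where below detection
    below_detection: pd.DataFrame  # same shape, bool

    def __post_init__(self) -> None:
        present = self.values.to_numpy()
        if np.nanmin(present) < 0:
            raise ValueError("geochemistry values must be non-negative")

    @property
    def sites(self) -> list[str]:
        return list(self.values.index)

    @classmethod
    def fixture(cls) -> "GeochemTable":
        raw = pd.DataFrame.from_dict(_FIXTURE_ROWS, orient="index", columns=VARIABLES)
        bd = raw.map(lambda v: v == BD)
        values = raw.where(~bd).astype(float)
        return cls(values, bd.astype(bool))

    @classmethod
    def from_csv(cls, text: str) -> "GeochemTable":
        raw = pd.read_csv(io.StringIO(text), index_col=0)
        bd = raw.map(lambda v: str(v).strip() == BD)
        values = raw.where(~bd)
        return cls(values.astype(float), bd.astype(bool))

    def to_csv(self) -> str:
        out = self.values.astype(object).copy()
        out[self.below_detection] = BD
        return out.to_csv()

    def imputed(self) -> pd.DataFrame:
        """Below-detection entries replaced by half the variable's minimum."""
        filled = self.values.copy()
        for col in filled.columns:
            if filled[col].isna().any():
                filled[col] = filled[col].fillna(filled[col].min() / 2.0)
        return filled


def convert_units(value: float, from_unit: str = "ng/g", to_unit: str = "ppm") -> float:
    """Convert mercury concentrations between ng/g (= ppb) and ppm."""
    if value < 0:
        raise ValueError("concentration must be non-negative")
    key = (from_unit, to_unit)
    if key == ("ng/g", "ppm"):
        return value / 1000.0
    if key == ("ppm", "ng/g"):
        return value * 1000.0
    if from_unit == to_unit:
        return value
    raise ValueError(f"unsupported conversion {from_unit} -> {to_unit}")


def pearson_pairs(table: GeochemTable, var_a: str, var_b: str) -> float:
    """Pearson correlation between two variables on raw values.

    Sites where either variable is below detection (or missing) are
    excluded pairwise; at least three complete pairs are required.
    """
    a = table.values[var_a]
    b = table.values[var_b]
    keep = a.notna() & b.notna()
    if keep.sum() < 3:
        raise ValueError("need at least 3 complete pairs")
    x, y = a[keep].to_numpy(), b[keep].to_numpy()
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    return float(pearsonr(x, y).statistic)


def mehg_fraction(table: GeochemTable, sites: list[str]) -> tuple[pd.Series, float]:
    """Per-site MeHg as a percentage of THg, and their unweighted mean."""
    thg = table.values.loc[sites, "thg_ng_g"]
    mehg = table.values.loc[sites, "mehg_ng_g"]
    if (thg <= 0).any() or thg.isna().any():
        raise ValueError("THg must be positive for all requested sites")
    pct = 100.0 * mehg / thg
    return pct, float(pct.mean())


@dataclass(frozen=True)
class BinThresholds:
    """THg cutoffs (ng/g) separating contamination levels."""

    high: float = 1000.0
    medium: float = 100.0


@dataclass
class BinAndClusterResult:
    bins: pd.Series  # site -> level
    site_newick: str
    variable_newick: str
    site_distances: pd.DataFrame


def bin_and_cluster(
    table: GeochemTable,
    thresholds: BinThresholds = BinThresholds(),
    reference_sites: frozenset[str] = REFERENCE_SITES,
) -> BinAndClusterResult:
    """Bin sites into contamination levels by THg and cluster the table.

    Levels: THg >= ``thresholds.high`` -> "high"; >= ``thresholds.medium``
    -> "medium"; otherwise "low", except sites designated as study
    references, which are labelled "reference" regardless.  Clustering uses
    log(X+1)-transformed variables (below-detection imputed at half the
    variable minimum), Bray-Curtis dissimilarity and group-average linkage,
    run both across sites (which variables drive site similarity) and
    across variables (which measurements co-vary over sites).
    """
    thg = table.values["thg_ng_g"]
    if thg.isna().any():
        raise ValueError("THg is required for every site")

    def _level(site: str, value: float) -> str:
        if site in reference_sites:
            return "reference"
        if value >= thresholds.high:
            return "high"
        if value >= thresholds.medium:
            return "medium"
        return "low"

    bins = pd.Series({s: _level(s, thg[s]) for s in table.sites}, name="level")

    logged = np.log1p(table.imputed())
    site_d = pdist(logged.to_numpy(), metric="braycurtis")
    var_d = pdist(logged.to_numpy().T, metric="braycurtis")
    site_Z = hierarchy.linkage(site_d, method="average")
    var_Z = hierarchy.linkage(var_d, method="average")
    from scipy.spatial.distance import squareform

    dm = pd.DataFrame(squareform(site_d), index=table.sites, columns=table.sites)
    return BinAndClusterResult(
        bins=bins,
        site_newick=linkage_to_newick(site_Z, table.sites),
        variable_newick=linkage_to_newick(var_Z, list(logged.columns)),
        site_distances=dm,
    )
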