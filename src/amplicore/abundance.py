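"""Normalization, filtering, core-microbiome and display transforms.

Conventions follow common microbiome-analysis practice: total sum scaling
(TSS) to relative abundances, a low-count prevalence filter followed by an
inter-quartile-range (IQR) low-variance filter, a prevalence x relative-
abundance core-microbiome rule (default: present at >= 0.01% relative
abundance in >= 20% of samples), bias-corrected Chao1 richness, and the
two display transforms used for heatmaps (log then per-feature z-score)
and stacked barplots (pool taxa under 1% mean abundance into "Other").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FilterConfig",
    "tss_normalize",
    "filter_features",
    "core_microbiome",
    "chao1",
    "display_transforms",
]


@dataclass(frozen=True)
class FilterConfig:
    prevalence_fraction: float = 0.20
    min_count: int = 4
    variance_quantile: float = 0.10
    core_abundance_threshold: float = 0.0001  # 0.01%; "strict" preset uses 0.002

    def __post_init__(self) -> None:
        for f in (self.prevalence_fraction, self.variance_quantile):
            if not (0.0 <= f <= 1.0):
                raise ValueError("fractions must be in [0, 1]")


def tss_normalize(table: pd.DataFrame) -> pd.DataFrame:
    """Total sum scaling: each sample column divided by its total."""
    totals = table.sum(axis=0)
    zero = totals == 0
    if zero.any():
        raise ValueError(f"all-zero sample(s): {list(totals.index[zero])}")
    return table / totals


def filter_features(
    table: pd.DataFrame, config: FilterConfig = FilterConfig()
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Low-count then low-variance (IQR) feature filtering.

    A feature survives the count filter when it reaches ``min_count`` in at
    least ``prevalence_fraction`` of samples; of the survivors, the
    ``variance_quantile`` fraction with the smallest IQR of relative
    abundance is removed.  Returns the filtered table and a removal report.
    """
    if table.empty:
        raise ValueError("empty table")
    n_samples = table.shape[1]
    needed = int(np.ceil(config.prevalence_fraction * n_samples))
    prevalent = (table >= config.min_count).sum(axis=1) >= needed
    removed_low_count = int((~prevalent).sum())
    kept = table.loc[prevalent]
    if kept.empty:
        raise ValueError("low-count filter removed all features")

    rel = tss_normalize(kept)
    iqr = rel.quantile(0.75, axis=1) - rel.quantile(0.25, axis=1)
    n_drop = int(np.floor(config.variance_quantile * kept.shape[0]))
    if n_drop > 0:
        drop_ids = iqr.sort_values(kind="stable").index[:n_drop]
        kept = kept.drop(index=drop_ids)
    if kept.empty:
        raise ValueError("variance filter removed all features")
    report = {
        "features_in": int(table.shape[0]),
        "removed_low_count": removed_low_count,
        "removed_low_variance": n_drop,
        "features_out": int(kept.shape[0]),
    }
    return kept, report


def core_microbiome(
    relative: pd.DataFrame, config: FilterConfig = FilterConfig()
) -> list[str]:
    """Taxa at or above the abundance threshold in enough samples."""
    needed = int(np.ceil(config.prevalence_fraction * relative.shape[1]))
    hits = (relative >= config.core_abundance_threshold).sum(axis=1)
    return list(relative.index[hits >= needed])


def chao1(counts, bias_corrected: bool = True) -> float:
    """Chao1 richness estimate from one sample's feature counts.

    Bias-corrected form: ``S_obs + F1*(F1-1) / (2*(F2+1))`` with F1/F2 the
    singleton and doubleton counts; the classic form ``S_obs + F1^2/(2*F2)``
    is available but undefined at F2 = 0.
    """
    c = np.asarray(counts)
    if np.any(c < 0) or not np.allclose(c, np.round(c)):
        raise ValueError("counts must be non-negative integers")
    c = c[c > 0]
    s_obs = c.size
    if s_obs == 0:
        return 0.0
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    if bias_corrected:
        return float(s_obs + f1 * (f1 - 1) / (2 * (f2 + 1)))
    if f2 == 0:
        raise ValueError("classic Chao1 undefined when there are no doubletons")
    return float(s_obs + f1**2 / (2 * f2))


def display_transforms(relative: pd.DataFrame, mode: str) -> pd.DataFrame:
    """Heatmap (log + per-feature z-score) or barplot (>1% pooling) transform.

    Heatmap mode adds a pseudocount of half the smallest nonzero value
    before the log; constant features get z = 0.  Barplot mode keeps taxa
    with mean relative abundance > 1% and pools the rest into "Other" so
    columns still sum to 1.
    """
    if mode == "heatmap":
        nonzero = relative.to_numpy()
        nonzero = nonzero[nonzero > 0]
        pseudo = nonzero.min() / 2.0 if nonzero.size else 1e-9
        logged = np.log(relative + pseudo)
        mu = logged.mean(axis=1)
        sd = logged.std(axis=1, ddof=0)
        z = logged.sub(mu, axis=0).div(sd.replace(0, np.nan), axis=0).fillna(0.0)
        return z
    if mode == "barplot":
        keep = relative.mean(axis=1) > 0.01
        top = relative.loc[keep]
        other = relative.loc[~keep].sum(axis=0)
        if (other > 0).any() or (~keep).any():
            top = pd.concat([top, other.rename("Other").to_frame().T])
        return top
    raise ValueError(f"unknown mode {mode!r}")
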