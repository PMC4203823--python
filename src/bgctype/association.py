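"""Spearman association between the community and chemicals matrices.

The Filtration step correlates every OTU's relative-abundance trajectory with
every chemical variable across the shared sampling points and keeps the OTUs
whose trajectory reaches |rho| >= 0.70 for at least one chemical variable.
Spearman's rho is the Pearson correlation of average (fractional) ranks, so
ties within a trajectory receive the mean of the ranks they span; a constant
trajectory has no ranking and its correlation is undefined (masked, never
counted as passing the threshold).

``stocsy_1d`` provides one-dimensional statistical total correlation
spectroscopy: the Pearson correlation (and covariance) of one spectral bin's
intensity vector against every bin, used to judge whether bins assigned to
the same compound co-vary.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from bgctype.ingest import FeatureTable, FusedDataset, block_of


@dataclass
class CorrelationMatrix:
    """OTU x chemical-variable Spearman correlation matrix.

    ``rho`` holds NaN where the correlation is undefined (either vector
    constant over the sampling points); ``undefined_mask`` marks those cells.
    """

    otu_ids: list[str]
    chem_ids: list[str]
    rho: np.ndarray
    n_samples: int
    undefined_mask: np.ndarray

    def __post_init__(self) -> None:
        self.rho = np.asarray(self.rho, dtype=float)
        self.undefined_mask = np.asarray(self.undefined_mask, dtype=bool)
        if self.rho.shape != (len(self.otu_ids), len(self.chem_ids)):
            raise ValueError("rho shape does not match id lists")
        if self.undefined_mask.shape != self.rho.shape:
            raise ValueError("undefined_mask shape does not match rho")
        defined = self.rho[~self.undefined_mask]
        if defined.size and (np.abs(defined) > 1 + 1e-9).any():
            raise ValueError("|rho| exceeds 1 on defined entries")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rho, index=self.otu_ids, columns=self.chem_ids)

    def counts_by_block(self) -> dict[str, int]:
        """Retained OTUs per source domain (from fused feature-id prefixes)."""
        return dict(Counter(block_of(o) for o in self.otu_ids))


def spearman_rho(x, y) -> float:
    """Spearman rank correlation of two equal-length vectors (n >= 3).

    Returns NaN when either vector is constant (no ranking exists).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or len(x) != len(y):
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if len(x) < 3:
        raise ValueError(f"need at least 3 observations, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


def _rank_standardise(m: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise average ranks, centred and L2-normalised; flags constant rows."""
    ranks = stats.rankdata(m, axis=1)
    ranks -= ranks.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(ranks, axis=1)
    constant = norms == 0
    norms[constant] = 1.0
    return ranks / norms[:, None], constant


def correlation_matrix(d: FusedDataset) -> CorrelationMatrix:
    """Spearman rho of every community row against every chemicals row."""
    n = len(d.sample_ids)
    if n < 3:
        raise ValueError(f"need at least 3 sampling points, got {n}")
    ru, const_u = _rank_standardise(d.community.values.astype(float))
    rc, const_c = _rank_standardise(d.chemicals.values.astype(float))
    rho = np.clip(ru @ rc.T, -1.0, 1.0)
    mask = const_u[:, None] | const_c[None, :]
    rho[mask] = np.nan
    return CorrelationMatrix(
        otu_ids=d.community.feature_ids,
        chem_ids=d.chemicals.feature_ids,
        rho=rho,
        n_samples=n,
        undefined_mask=mask,
    )


def filter_otus_by_max_abs_correlation(
    c: CorrelationMatrix, threshold: float = 0.70
) -> CorrelationMatrix:
    """Keep OTUs with at least one defined |rho| >= threshold (inclusive).

    All chemical columns are retained — sub-threshold correlations still
    contribute to the PCA and chemical profiles downstream.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    with np.errstate(invalid="ignore"):
        max_abs = np.nanmax(np.where(c.undefined_mask, -np.inf, np.abs(c.rho)), axis=1)
    keep = max_abs >= threshold
    return CorrelationMatrix(
        otu_ids=[o for o, k in zip(c.otu_ids, keep) if k],
        chem_ids=list(c.chem_ids),
        rho=c.rho[keep],
        n_samples=c.n_samples,
        undefined_mask=c.undefined_mask[keep],
    )


def stocsy_1d(spectra: FeatureTable, driver_id: str) -> pd.DataFrame:
    """1D-STOCSY: Pearson correlation/covariance of a driver bin vs all bins.

    Returns a DataFrame indexed by bin id with columns ``correlation`` and
    ``covariance`` (population covariance across sampling points).
    """
    if driver_id not in spectra.feature_ids:
        raise KeyError(f"driver bin {driver_id!r} not in table")
    vals = spectra.values.astype(float)
    n = vals.shape[1]
    if n < 3:
        raise ValueError(f"need at least 3 sampling points, got {n}")
    driver = vals[spectra.feature_ids.index(driver_id)]
    if np.ptp(driver) == 0:
        raise ValueError(f"driver bin {driver_id!r} is constant across sampling points")
    dc = driver - driver.mean()
    centred = vals - vals.mean(axis=1, keepdims=True)
    cov = centred @ dc / n
    denom = np.linalg.norm(centred, axis=1) * np.linalg.norm(dc)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, centred @ dc / denom, np.nan)
    return pd.DataFrame(
        {"correlation": np.clip(corr, -1, 1), "covariance": cov},
        index=pd.Index(spectra.feature_ids, name="bin"),
    )
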