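"""Description step: community distributions, taxonomy breakdowns and the
per-type chemical profile table.

For each BGC type the chemical profile is built from two curves over all
chemical variables: the type's average correlation (mean Spearman rho over
its member OTUs) and the loadings of the principal component that best
explains the type (largest absolute mean member score on PC1 vs PC2).  Both
curves are scaled to unit variance without centring — division by the
population root-mean-square — and compared variable by variable with the
population standard deviation of the pair, STDEVP(a, b) = |a - b| / 2.
Variables with STDEVP >= 0.20 whose raw average correlation is positive are
extracted as the type's chemical profile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from bgctype.association import CorrelationMatrix
from bgctype.clustering import TypingResult
from bgctype.ingest import FeatureTable, block_of

#: canonical rank order of a SILVA-style lineage
LINEAGE_RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")


def scale_unit_variance_nocenter(v) -> np.ndarray:
    """Divide a vector by its population root-mean-square, sqrt(mean(v^2)).

    The scaled vector has mean square exactly 1; no centring is applied, so
    the sign pattern and the zero point are preserved.
    """
    v = np.asarray(v, dtype=float)
    rms = float(np.sqrt(np.nanmean(v**2)))
    if rms == 0 or not np.isfinite(rms):
        raise ValueError("cannot scale a zero (or undefined) vector to unit variance")
    return v / rms


def scale_unit_variance_centered(v) -> np.ndarray:
    """Division by the centred population SD (sensitivity-analysis variant)."""
    v = np.asarray(v, dtype=float)
    sd = float(np.nanstd(v))
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("cannot scale a constant vector by its standard deviation")
    return v / sd


def pair_stdevp(a: float, b: float) -> float:
    """Population standard deviation of the two-element set {a, b}: |a - b| / 2."""
    return abs(a - b) / 2.0


def community_distribution(
    t: TypingResult, community: FeatureTable
) -> dict[int, pd.DataFrame]:
    """Per-type, per-domain sums of member relative abundances by sampling point.

    Returns ``{bgc_type: DataFrame(domains x sampling points)}``; a domain a
    type has no members in yields a zero row.
    """
    missing = set(t.labels) - set(community.feature_ids)
    if missing:
        raise KeyError(f"labelled OTU(s) missing from community table: {sorted(missing)[:5]}")
    domains = sorted({block_of(f) for f in t.labels}) or [""]
    out: dict[int, pd.DataFrame] = {}
    for bgc_type in range(1, t.k + 1):
        rows = {}
        members = set(t.members(bgc_type))
        for dom in domains:
            ids = [f for f in community.feature_ids if f in members and block_of(f) == dom]
            rows[dom] = (
                community.data.loc[ids].sum(axis=0)
                if ids
                else pd.Series(0.0, index=community.sample_ids)
            )
        out[bgc_type] = pd.DataFrame(rows).T
    return out


def _collapse_label(lineage: tuple[str, ...], level: str) -> str:
    """Collapse a lineage at the requested rank, or at the next divergence
    actually present when the lineage is truncated above that rank."""
    if not lineage:
        return "Unassigned"
    depth = LINEAGE_RANKS.index(level)
    return lineage[min(depth, len(lineage) - 1)]


def collapse_taxonomy(
    t: TypingResult,
    taxonomy: dict[str, tuple[str, ...]],
    community: FeatureTable,
    level: str = "class",
) -> dict[int, pd.Series]:
    """Abundance-weighted taxonomy breakdown per BGC type, as percentages.

    OTUs are collapsed to the requested rank (class by default); lineages
    truncated above that rank collapse at their deepest available rank, and
    empty lineages are grouped under ``Unassigned``.  Weights are each member
    OTU's summed relative abundance over the sampling points; each type's
    percentages sum to 100.
    """
    if level not in LINEAGE_RANKS:
        raise ValueError(f"unknown rank {level!r}")
    out: dict[int, pd.Series] = {}
    for bgc_type in range(1, t.k + 1):
        weights: dict[str, float] = {}
        for otu in t.members(bgc_type):
            lab = _collapse_label(taxonomy.get(otu, ()), level)
            w = float(community.data.loc[otu].sum()) if otu in community.data.index else 0.0
            weights[lab] = weights.get(lab, 0.0) + w
        series = pd.Series(weights, dtype=float).sort_values(ascending=False)
        total = series.sum()
        out[bgc_type] = (
            100.0 * series / total if total > 0 else series
        )
    return out


def select_explaining_pc(t: TypingResult) -> dict[int, int]:
    """Map each BGC type to the PC (1 or 2) that better explains it.

    The explaining component is the one with the larger absolute mean member
    score; an exact tie falls back to PC1 with a warning.
    """
    if t.pca.scores.shape[1] < 2:
        raise ValueError("need at least 2 principal components")
    otu_index = {o: i for i, o in enumerate(t.labels)}
    out: dict[int, int] = {}
    for bgc_type in range(1, t.k + 1):
        idx = [otu_index[o] for o in t.members(bgc_type)]
        if not idx:
            raise ValueError(f"BGC type {bgc_type} has no member OTUs")
        centroid = t.pca.scores[idx, :2].mean(axis=0)
        if abs(centroid[0]) == abs(centroid[1]):
            warnings.warn(
                f"BGC type {bgc_type}: |mean PC1 score| == |mean PC2 score|; using PC1",
                stacklevel=2,
            )
            out[bgc_type] = 1
        else:
            out[bgc_type] = 1 + int(np.argmax(np.abs(centroid)))
    return out


def extract_chemical_profile(
    c: CorrelationMatrix,
    t: TypingResult,
    cut: float = 0.20,
    scaling: str = "rms",
) -> dict[int, pd.DataFrame]:
    """Build the chemical-profile table for every BGC type.

    Per type and chemical variable the table holds the average correlation
    over member OTUs, the explaining PC's loading, both curves scaled to unit
    variance without centring, their pairwise STDEVP, and the extraction flag
    ``(STDEVP >= cut) AND (raw average correlation > 0)``.  The loading
    vector's sign is aligned to the average-correlation curve first: PCA
    components carry an arbitrary sign which would otherwise flip the
    extraction outcome arbitrarily.

    Returns ``{bgc_type: DataFrame}`` with rows ordered by chemical block
    (ICP-OES, FT-IR, NMR order of the fused chemicals matrix).
    """
    if set(t.labels) != set(c.otu_ids):
        raise ValueError("typing result and correlation matrix disagree on OTU ids")
    scale = {"rms": scale_unit_variance_nocenter, "sd": scale_unit_variance_centered}[scaling]
    explaining = select_explaining_pc(t)
    otu_index = {o: i for i, o in enumerate(c.otu_ids)}
    rho = np.where(c.undefined_mask, np.nan, c.rho)
    out: dict[int, pd.DataFrame] = {}
    for bgc_type in range(1, t.k + 1):
        members = t.members(bgc_type)
        if not members:
            raise ValueError(f"BGC type {bgc_type} has no member OTUs")
        idx = [otu_index[o] for o in members]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # all-NaN column -> NaN mean, handled below
            avg_rho = np.nanmean(rho[idx], axis=0)
        pc = explaining[bgc_type]
        loading = t.pca.loadings[:, pc - 1].copy()
        finite = np.isfinite(avg_rho)
        if np.dot(loading[finite], avg_rho[finite]) < 0:
            loading = -loading
        scaled_rho = scale(avg_rho)
        scaled_loading = scale(loading)
        stdevp = np.abs(scaled_rho - scaled_loading) / 2.0
        extracted = (stdevp >= cut) & (avg_rho > 0) & finite
        frame = pd.DataFrame(
            {
                "chem_block": [block_of(ch) for ch in c.chem_ids],
                "avg_correlation": avg_rho,
                "explaining_pc": pc,
                "loading": loading,
                "scaled_avg_correlation": scaled_rho,
                "scaled_loading": scaled_loading,
                "stdevp": stdevp,
                "extracted": extracted,
            },
            index=pd.Index(c.chem_ids, name="chemical_variable"),
        )
        out[bgc_type] = frame
    return out


def extracted_variables(profiles: dict[int, pd.DataFrame]) -> dict[int, list[str]]:
    """Convenience: the extracted chemical variables per BGC type, in table order."""
    return {
        bgc: list(frame.index[frame["extracted"]]) for bgc, frame in profiles.items()
    }
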