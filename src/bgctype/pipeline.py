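"""End-to-end BGC typing run with a machine-readable manifest.

``run_pipeline`` executes ingest -> association -> organization -> description
and returns every intermediate artifact plus a manifest recording the
configuration, seeds, input hashes and per-stage row/column counts, so the
headline numbers of a run (retained OTUs per domain, selected k, cluster
sizes) can be checked from the manifest alone.  ``write_reports`` serialises
the artifacts as TSV/JSON.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from bgctype import association, clustering, ingest, profiling
from bgctype.association import CorrelationMatrix
from bgctype.clustering import TypingResult, WCSSCurve
from bgctype.ingest import FeatureTable, FusedDataset

log = logging.getLogger("bgctype")

#: defaults are the method's stated parameters
DEFAULT_THRESHOLD = 0.70
DEFAULT_K_MAX = 15
DEFAULT_STDEVP_CUT = 0.20


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    ``community`` and ``chemicals`` map block labels (archaea/16S/18S and
    icp/ftir/nmr) to input paths; format is taken from the extension
    (``.biom`` -> BIOM 1.0 JSON, else TSV).  All analysis defaults equal the
    method's stated parameters: correlation threshold 0.70, k tested up to
    15, STDEVP cut 0.20.
    """

    community: dict[str, str] = field(default_factory=dict)
    chemicals: dict[str, str] = field(default_factory=dict)
    output_dir: str = "bgctype_out"
    threshold: float = DEFAULT_THRESHOLD
    k_max: int = DEFAULT_K_MAX
    k: int | None = None
    stdevp_cut: float = DEFAULT_STDEVP_CUT
    cluster_space: str = "corr_rows"
    centering: str = "mean"
    seed: int = 0
    n_init: int = 50
    include_ph: bool = False
    singleton_min_total: int = 2
    taxonomy_level: str = "class"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**doc)

    def params(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d.pop("community")
        d.pop("chemicals")
        d.pop("output_dir")
        return d


@dataclass
class RunResult:
    """All artifacts of a pipeline run."""

    dataset: FusedDataset
    correlations: CorrelationMatrix
    filtered: CorrelationMatrix
    curve: WCSSCurve
    typing: TypingResult
    distributions: dict[int, pd.DataFrame]
    taxonomy: dict[int, pd.Series]
    profiles: dict[int, pd.DataFrame]
    manifest: dict[str, Any]


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raise with stage context
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _table_digest(t: FeatureTable) -> str:
    h = hashlib.sha256()
    h.update("\t".join(t.feature_ids).encode())
    h.update("\t".join(t.sample_ids).encode())
    h.update(np.ascontiguousarray(t.values.astype(float)).tobytes())
    return h.hexdigest()


@_stage("ingest")
def _load_tables(paths: dict[str, str]) -> dict[str, FeatureTable]:
    out = {}
    for block, path in paths.items():
        fmt = "biom" if str(path).endswith(".biom") else "tsv"
        out[block] = ingest.read_feature_table(path, fmt=fmt, block=block)
    return out


def run_pipeline_from_tables(
    community_tables: dict[str, FeatureTable],
    chemical_tables: dict[str, FeatureTable],
    cfg: RunConfig | None = None,
) -> RunResult:
    """Run the three BGC-typing steps on already-loaded tables."""
    cfg = cfg or RunConfig()
    manifest: dict[str, Any] = {"config": cfg.params(), "stages": {}}

    # ---- Filtration: tables -> matrices -> correlations -------------------
    prepared = []
    counts_after_singleton = {}
    for block, t in community_tables.items():
        kept = ingest.filter_singleton_otus(t, cfg.singleton_min_total)
        counts_after_singleton[block] = kept.shape[0]
        prepared.append(ingest.to_relative_abundance(kept))
        log.info("%s: %d/%d OTUs after singleton filter", block, kept.shape[0], t.shape[0])
    chem_prepared = []
    for block, t in chemical_tables.items():
        if not cfg.include_ph and "pH" in t.feature_ids:
            t = t.drop_features(["pH"])
        chem_prepared.append(t)
    community = ingest.fuse_tables(prepared, "fused_community")
    chemicals = ingest.fuse_tables(chem_prepared, "fused_chemicals")
    dataset = FusedDataset(community, chemicals)
    manifest["stages"]["ingest"] = {
        "otus_after_singleton_filter": counts_after_singleton,
        "community_shape": list(community.shape),
        "chemicals_shape": list(chemicals.shape),
        "input_digests": {
            **{b: _table_digest(t) for b, t in community_tables.items()},
            **{b: _table_digest(t) for b, t in chemical_tables.items()},
        },
    }

    corr = _stage("association")(association.correlation_matrix)(dataset)
    filtered = _stage("association")(association.filter_otus_by_max_abs_correlation)(
        corr, cfg.threshold
    )
    retained = filtered.counts_by_block()
    log.info("retained OTUs at |rho|>=%.2f per domain: %s", cfg.threshold, retained)
    manifest["stages"]["association"] = {
        "threshold": cfg.threshold,
        "retained_otus_per_domain": retained,
        "retained_otus_total": len(filtered.otu_ids),
    }

    # ---- Organization ------------------------------------------------------
    k_max = min(cfg.k_max, len(filtered.otu_ids))
    curve = _stage("organization")(clustering.wcss_curve)(
        filtered, k_max=k_max, seed=cfg.seed, n_init=cfg.n_init
    )
    selected_k, profile = clustering.select_k_by_elbow(curve)
    k = cfg.k if cfg.k is not None else selected_k
    typing = _stage("organization")(clustering.cluster_bgc_types)(
        filtered,
        k,
        cluster_space=cfg.cluster_space,
        seed=cfg.seed,
        n_init=cfg.n_init,
        curve=curve,
        centering=cfg.centering,
    )
    sizes = {bgc: len(typing.members(bgc)) for bgc in range(1, typing.k + 1)}
    log.info("selected k=%d (elbow %d); cluster sizes %s", k, selected_k, sizes)
    manifest["stages"]["organization"] = {
        "wcss": {int(kk): float(w) for kk, w in zip(curve.k_values, curve.wcss)},
        "second_differences": profile,
        "elbow_k": selected_k,
        "k_used": k,
        "cluster_sizes": sizes,
        "cluster_space": cfg.cluster_space,
        "explained_variance_top5": [float(v) for v in typing.pca.explained_variance[:5]],
    }

    # ---- Description -------------------------------------------------------
    distributions = _stage("description")(profiling.community_distribution)(typing, community)
    taxonomy = _stage("description")(profiling.collapse_taxonomy)(
        typing, community.taxonomy or {}, community, cfg.taxonomy_level
    )
    profiles = _stage("description")(profiling.extract_chemical_profile)(
        filtered, typing, cut=cfg.stdevp_cut
    )
    manifest["stages"]["description"] = {
        "stdevp_cut": cfg.stdevp_cut,
        "explaining_pc": {
            bgc: int(frame["explaining_pc"].iloc[0]) for bgc, frame in profiles.items()
        },
        "extracted_per_type": {
            bgc: list(map(str, frame.index[frame["extracted"]]))
            for bgc, frame in profiles.items()
        },
    }
    return RunResult(
        dataset=dataset,
        correlations=corr,
        filtered=filtered,
        curve=curve,
        typing=typing,
        distributions=distributions,
        taxonomy=taxonomy,
        profiles=profiles,
        manifest=manifest,
    )


def run_pipeline(cfg: RunConfig) -> RunResult:
    """Load the configured input tables and run the full pipeline."""
    community_tables = _load_tables(cfg.community)
    chemical_tables = _load_tables(cfg.chemicals)
    result = run_pipeline_from_tables(community_tables, chemical_tables, cfg)
    result.manifest["inputs"] = {
        block: {"path": str(path), "sha256": _sha256(Path(path))}
        for block, path in {**cfg.community, **cfg.chemicals}.items()
    }
    return result


#: files write_reports produces
REPORT_FILES = (
    "labels.tsv",
    "wcss_curve.tsv",
    "pca_scores.tsv",
    "pca_loadings.tsv",
    "community_distribution.tsv",
    "taxonomy_breakdown.tsv",
    "chemical_profile_long.tsv",
    "chemical_profile_table.tsv",
    "manifest.json",
)


def write_reports(r: RunResult, outdir: str | Path, plots: bool = False) -> list[Path]:
    """Write all run artifacts as TSV plus the JSON manifest.

    ``plots=True`` additionally renders the WCSS curve, the PC1/PC2 scatter
    coloured by BGC type, and the distribution bars (requires matplotlib).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    labels = pd.DataFrame(
        {"bgc_type": pd.Series(r.typing.labels)},
    )
    labels.index.name = "otu_id"
    labels.to_csv(outdir / "labels.tsv", sep="\t")

    pd.DataFrame({"k": r.curve.k_values, "wcss": r.curve.wcss}).to_csv(
        outdir / "wcss_curve.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        r.typing.pca.scores,
        index=pd.Index(r.filtered.otu_ids, name="otu_id"),
        columns=[f"PC{i + 1}" for i in range(r.typing.pca.scores.shape[1])],
    ).to_csv(outdir / "pca_scores.tsv", sep="\t")
    pd.DataFrame(
        r.typing.pca.loadings,
        index=pd.Index(r.filtered.chem_ids, name="chemical_variable"),
        columns=[f"PC{i + 1}" for i in range(r.typing.pca.loadings.shape[1])],
    ).to_csv(outdir / "pca_loadings.tsv", sep="\t")

    dist_rows = []
    for bgc, frame in r.distributions.items():
        for dom, row in frame.iterrows():
            dist_rows.append({"bgc_type": bgc, "domain": dom, **row.to_dict()})
    pd.DataFrame(dist_rows).to_csv(outdir / "community_distribution.tsv", sep="\t", index=False)

    tax_rows = []
    for bgc, series in r.taxonomy.items():
        for taxon, pct in series.items():
            tax_rows.append({"bgc_type": bgc, "taxon": taxon, "percent_abundance": pct})
    pd.DataFrame(tax_rows).to_csv(outdir / "taxonomy_breakdown.tsv", sep="\t", index=False)

    long = pd.concat(
        {bgc: frame for bgc, frame in r.profiles.items()}, names=["bgc_type"]
    ).reset_index()
    long.to_csv(outdir / "chemical_profile_long.tsv", sep="\t", index=False)

    # Table-1 style: one column per BGC type, extracted variables grouped by block
    blocks = sorted({profiling.block_of(c) for c in r.filtered.chem_ids})
    cols = {
        f"BGC_type_{bgc}": [
            ", ".join(frame.index[(frame["chem_block"] == blk) & frame["extracted"]])
            for blk in blocks
        ]
        for bgc, frame in r.profiles.items()
    }
    pd.DataFrame(cols, index=pd.Index(blocks, name="chem_block")).to_csv(
        outdir / "chemical_profile_table.tsv", sep="\t"
    )

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(r.manifest, fh, indent=2, sort_keys=True, default=str)

    written = [outdir / name for name in REPORT_FILES]
    if plots:
        written += _render_plots(r, outdir)
    return written


def _render_plots(r: RunResult, outdir: Path) -> list[Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    paths = []
    fig, ax = plt.subplots()
    ax.plot(r.curve.k_values, r.curve.wcss, "o-")
    ax.set_xlabel("number of BGC types")
    ax.set_ylabel("within-cluster sum of squares")
    fig.savefig(outdir / "wcss_curve.png", dpi=120)
    plt.close(fig)
    paths.append(outdir / "wcss_curve.png")

    fig, ax = plt.subplots()
    labels = np.array([r.typing.labels[o] for o in r.filtered.otu_ids])
    sc = ax.scatter(
        r.typing.pca.scores[:, 0], r.typing.pca.scores[:, 1], c=labels, cmap="tab10", s=12
    )
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    fig.colorbar(sc, label="BGC type")
    fig.savefig(outdir / "pc_scores.png", dpi=120)
    plt.close(fig)
    paths.append(outdir / "pc_scores.png")
    return paths
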