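"""Synthetic multi-omics datasets with planted OTU-chemical association blocks.

The generator emulates the shape of a paddy-field style survey: ~14 sampling
points, three community domains (archaea / 16S / 18S rRNA), three chemical
blocks (element concentrations, FT-IR integrals, NMR bucket integrals), and a
handful of environmental gradients that drive both organisms and chemistry.

Each BGC type g owns a latent factor f_g over the sampling points; its member
OTUs' expected abundances and its chemical variables are monotone functions
of f_g plus Gaussian noise, so within-block Spearman correlations are high by
construction.  Types are arranged pairwise on shared axes: the two types of
an axis have factors with exact sample correlation -r (0 < r < 1, axes
mutually orthogonal).  This reproduces the cross-like score geometry of real
BGC typing — two types at opposite ends of PC1, two at opposite ends of PC2 —
while keeping each type's mean-correlation curve distinguishable from the PC
loading curve, which is what the STDEVP extraction rule detects.  With fully
independent factors (``factor_mode="independent"``, also available) chance
rank correlations of order 1/sqrt(n-1) blur both the geometry and the
extraction at realistic numbers of sampling points.

Counts are drawn multinomially per sampling point at a fixed sequencing
depth, so relative-abundance normalisation is meaningful.  Each domain also
carries a "background" taxon absorbing the remaining read mass, which keeps
every planted OTU's relative abundance monotone in its factor (total
expected weight per sampling point is constant by construction).  Null OTUs
and null chemical variables are independent noise; singleton OTUs carry
exactly one read in total and exist to be removed by the singleton filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from bgctype.ingest import BLOCK_SEP, FeatureTable

_DOMAINS = ("archaea", "16S", "18S")
_CHEM_BLOCKS = ("icp", "ftir", "nmr")
_DOMAIN_LINEAGE = {"archaea": "Archaea", "16S": "Bacteria", "18S": "Eukaryota"}


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic dataset.

    Defaults mirror the survey shape the pipeline targets: 14 sampling
    points, 4 BGC types of 25 OTUs and 5 chemical variables each, plus
    uncorrelated OTUs/chemicals, singletons, and measurement noise with
    standard deviation 0.1 on the latent (unit-variance) scale.
    """

    n_samples: int = 14
    n_types: int = 4
    otus_per_type: int = 25
    chems_per_type: int = 5
    n_null_otus: int = 20
    n_singleton_otus: int = 5
    n_null_chems: int = 6
    noise_sd: float = 0.1
    link: str = "linear"
    sequencing_depth: int = 50_000
    seed: int = 0
    factor_mode: str = "paired_axes"
    axis_anticorr: tuple[float, ...] = (0.45, 0.18)

    def __post_init__(self) -> None:
        for name in (
            "n_samples",
            "n_types",
            "otus_per_type",
            "chems_per_type",
            "n_null_otus",
            "n_singleton_otus",
            "n_null_chems",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_samples < 3:
            raise ValueError("need at least 3 sampling points")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.link not in ("linear", "monotone_nonlinear"):
            raise ValueError(f"unknown link {self.link!r}")
        if self.factor_mode not in ("paired_axes", "independent"):
            raise ValueError(f"unknown factor_mode {self.factor_mode!r}")
        if any(not 0 <= r < 1 for r in self.axis_anticorr):
            raise ValueError("axis anti-correlations must lie in [0, 1)")


@dataclass
class GroundTruth:
    """Planted memberships and latent factors of a synthetic dataset.

    Feature ids are in fused form (``block|feature``) so they can be compared
    directly with pipeline outputs.
    """

    otu_to_type: dict[str, int]
    chem_to_type: dict[str, int]
    factors: dict[int, np.ndarray] = field(repr=False)

    def typed_otus(self) -> list[str]:
        return sorted(self.otu_to_type)

    def chems_of_type(self, bgc_type: int) -> list[str]:
        return sorted(c for c, g in self.chem_to_type.items() if g == bgc_type)


def paper_shape_preset(seed: int = 0, **overrides) -> SyntheticSpec:
    """Survey-shaped preset: 14 sampling points, 4 BGC types arranged on two
    orthogonal axes, three community domains and three chemical blocks."""
    return SyntheticSpec(seed=seed, **overrides)


def _orthonormal_factors(rng: np.random.Generator, n_dirs: int, n_samples: int) -> np.ndarray:
    """Rows: n_dirs mutually orthogonal directions of unit RMS over samples."""
    if n_dirs > n_samples:
        raise ValueError(f"cannot place {n_dirs} orthogonal factors in {n_samples} samples")
    g = rng.standard_normal((n_samples, n_dirs))
    q, _ = np.linalg.qr(g)
    # fix a deterministic sign per column for reproducibility across BLAS builds
    signs = np.sign(q[np.argmax(np.abs(q), axis=0), np.arange(n_dirs)])
    signs[signs == 0] = 1.0
    return (q * signs).T * np.sqrt(n_samples)


def _spearman_pairs(factors: np.ndarray) -> np.ndarray:
    from scipy import stats

    ranks = stats.rankdata(factors, axis=1)
    ranks -= ranks.mean(axis=1, keepdims=True)
    ranks /= np.linalg.norm(ranks, axis=1, keepdims=True)
    return ranks @ ranks.T


def _type_factors(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Per-type latent factor over sampling points, shape (n_types, n_samples).

    In ``paired_axes`` mode (the default) types 2j-1 and 2j share axis j with
    exact sample correlation -r_j; the axes themselves are orthogonal.  With
    only ~14 sampling points a random draw carries chance rank correlations
    of order 1/sqrt(n-1) between axes, which would contaminate the planted
    block structure, so the draw is conditioned: candidates are redrawn until
    cross-axis Spearman correlations are near zero and within-pair Spearman
    correlations are near their -r_j targets (best candidate kept otherwise).
    """
    if spec.factor_mode == "independent":
        return _orthonormal_factors(rng, spec.n_types, spec.n_samples)
    n_axes = (spec.n_types + 1) // 2
    partner_r = {
        axis: spec.axis_anticorr[axis % len(spec.axis_anticorr)] for axis in range(n_axes)
    }
    best, best_score = None, np.inf
    for _ in range(50_000):
        base = _orthonormal_factors(rng, 2 * n_axes, spec.n_samples)
        factors = np.empty((spec.n_types, spec.n_samples))
        for axis in range(n_axes):
            g, h = base[2 * axis], base[2 * axis + 1]
            r = partner_r[axis]
            factors[2 * axis] = g
            if 2 * axis + 1 < spec.n_types:
                factors[2 * axis + 1] = -r * g + np.sqrt(1 - r**2) * h
        s = _spearman_pairs(factors)
        cross_err, pair_err = 0.0, 0.0
        for i in range(spec.n_types):
            for j in range(i + 1, spec.n_types):
                if i // 2 == j // 2:
                    pair_err = max(pair_err, abs(s[i, j] + partner_r[i // 2]))
                else:
                    cross_err = max(cross_err, abs(s[i, j]))
        score = max(cross_err / 0.025, pair_err / 0.05)
        if score < best_score:
            best, best_score = factors, score
        if score <= 1.0:
            break
    return best


def _null_latent(rng: np.random.Generator, factors: np.ndarray, cap: float = 0.15) -> np.ndarray:
    """Latent for an uncorrelated feature: redrawn until its chance Spearman
    association with every planted factor stays below ``cap``."""
    n = factors.shape[1]
    best, best_worst = None, np.inf
    for _ in range(200):
        x = rng.standard_normal(n)
        worst = max(
            abs(_spearman_pairs(np.vstack([x, f]))[0, 1]) for f in factors
        ) if len(factors) else 0.0
        if worst < best_worst:
            best, best_worst = x, worst
        if worst <= cap:
            break
    return best


def _link(spec: SyntheticSpec, x: np.ndarray) -> np.ndarray:
    """Monotone map from latent scale to a positive expected OTU weight."""
    if spec.link == "linear":
        return np.maximum(1.0 + 0.35 * x, 1e-3)
    return np.exp(0.5 * x)


def generate_dataset(
    spec: SyntheticSpec,
) -> tuple[dict[str, FeatureTable], dict[str, FeatureTable], GroundTruth]:
    """Generate per-domain OTU count tables, chemical tables and ground truth.

    Returns ``(community_tables, chemical_tables, truth)`` where the dicts
    are keyed by domain (archaea/16S/18S) and chemical block (icp/ftir/nmr).
    Deterministic for a fixed ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    samples = [f"sp{i + 1:02d}" for i in range(spec.n_samples)]
    factors = _type_factors(spec, rng)

    # ---- community: assign OTUs to domains round-robin --------------------
    otu_specs: list[tuple[str, str, int]] = []  # (otu_id, domain, planted type or 0)
    for g in range(1, spec.n_types + 1):
        for i in range(spec.otus_per_type):
            dom = _DOMAINS[len(otu_specs) % len(_DOMAINS)]
            otu_specs.append((f"OTU_t{g}_{i + 1:03d}", dom, g))
    for i in range(spec.n_null_otus):
        dom = _DOMAINS[len(otu_specs) % len(_DOMAINS)]
        otu_specs.append((f"OTU_null_{i + 1:03d}", dom, 0))
    singleton_specs: list[tuple[str, str]] = []
    for i in range(spec.n_singleton_otus):
        dom = _DOMAINS[(len(otu_specs) + i) % len(_DOMAINS)]
        singleton_specs.append((f"OTU_single_{i + 1:03d}", dom))

    max_dom_features = max(
        (
            sum(1 for _, d, _ in otu_specs if d == dom)
            + sum(1 for _, d in singleton_specs if d == dom)
            for dom in _DOMAINS
        ),
        default=0,
    )
    if spec.sequencing_depth < max(1, 4 * max_dom_features):
        raise ValueError(
            f"sequencing_depth={spec.sequencing_depth} too small to realise "
            f"singletons distinctly from sampled OTUs ({max_dom_features} features/domain)"
        )

    community: dict[str, FeatureTable] = {}
    otu_to_type: dict[str, int] = {}
    for dom in _DOMAINS:
        ids, weights, lineages = [], [], {}
        for otu_id, d, g in otu_specs:
            if d != dom:
                continue
            ids.append(otu_id)
            if g > 0:
                x = factors[g - 1] + spec.noise_sd * rng.standard_normal(spec.n_samples)
                otu_to_type[f"{dom}{BLOCK_SEP}{otu_id}"] = g
                lineages[otu_id] = (
                    _DOMAIN_LINEAGE[dom],
                    f"Phylum_ax{(g + 1) // 2}",
                    f"Class_t{g}",
                )
            else:
                x = _null_latent(rng, factors)
                # null OTUs: lineage truncated at phylum (tests the collapse fallback)
                lineages[otu_id] = (_DOMAIN_LINEAGE[dom], "Phylum_null")
            weights.append(_link(spec, x))
        w = np.array(weights) if weights else np.zeros((0, spec.n_samples))
        # background taxon keeps the per-point total weight constant, so every
        # planted OTU's relative abundance stays monotone in its factor
        total = w.sum(axis=0)
        background = np.full(spec.n_samples, 1.5 * total.max() if len(w) else 1.0) - total
        ids.append(f"OTU_bg_{dom}")
        lineages[f"OTU_bg_{dom}"] = (_DOMAIN_LINEAGE[dom], "Phylum_bg", "Class_bg")
        w = np.vstack([w, background]) if len(w) else background[None, :]
        probs = w / w.sum(axis=0)
        counts = np.stack(
            [rng.multinomial(spec.sequencing_depth, probs[:, s]) for s in range(spec.n_samples)],
            axis=1,
        )
        for otu_id, d in singleton_specs:
            if d != dom:
                continue
            row = np.zeros(spec.n_samples, dtype=np.int64)
            row[rng.integers(spec.n_samples)] = 1
            counts = np.vstack([counts, row])
            ids.append(otu_id)
            lineages[otu_id] = ()
        frame = pd.DataFrame(counts, index=ids, columns=samples)
        community[dom] = FeatureTable(frame, dom, "counts", lineages)

    # ---- chemistry: round-robin over icp / ftir / nmr ---------------------
    chem_scale = {"icp": 50.0, "ftir": 1.0, "nmr": 1.0}
    chem_rows: dict[str, dict[str, np.ndarray]] = {b: {} for b in _CHEM_BLOCKS}
    chem_to_type: dict[str, int] = {}
    counter = 0
    for g in range(1, spec.n_types + 1):
        for i in range(spec.chems_per_type):
            block = _CHEM_BLOCKS[counter % len(_CHEM_BLOCKS)]
            counter += 1
            cid = f"C_t{g}_{i + 1:02d}"
            x = factors[g - 1] + spec.noise_sd * rng.standard_normal(spec.n_samples)
            chem_rows[block][cid] = chem_scale[block] * np.exp(0.6 * x)
            chem_to_type[f"{block}{BLOCK_SEP}{cid}"] = g
    for i in range(spec.n_null_chems):
        block = _CHEM_BLOCKS[counter % len(_CHEM_BLOCKS)]
        counter += 1
        x = _null_latent(rng, factors)
        chem_rows[block][f"C_null_{i + 1:02d}"] = chem_scale[block] * np.exp(0.6 * x)

    chemicals: dict[str, FeatureTable] = {}
    for block in _CHEM_BLOCKS:
        rows = chem_rows[block]
        if not rows:
            continue
        frame = pd.DataFrame(np.array(list(rows.values())), index=list(rows), columns=samples)
        chemicals[block] = FeatureTable(
            frame, block, "concentration_ppm" if block == "icp" else "integral"
        )

    truth = GroundTruth(
        otu_to_type=otu_to_type,
        chem_to_type=chem_to_type,
        factors={g: factors[g - 1].copy() for g in range(1, spec.n_types + 1)},
    )
    return community, chemicals, truth
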