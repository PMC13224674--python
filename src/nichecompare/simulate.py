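"""Synthetic single-cell and spatial data emulating a four-group endometriosis study.

The generator reproduces the *statistical* structure the downstream analysis
assumes rather than any particular biology: four tissue groups (control
endometrium ``Ctrl``, patient eutopic endometrium ``EuE``, peritoneal lesions
``EcP``, ovarian lesions ``EcO``) with patient-level replication (3/9/8/4
patients), negative-binomial background counts, a handful of *sparse* genes
expressed in a small, group-shifted fraction of cells (a CCL19-like chemokine
among them), multiplicative gene programs (smooth muscle in EcO, immune
checkpoints and cytotoxicity in EcP), and a 60-segment spatial design
(30 + 30 segments over two tissues, three sorted compartments, three slides of
24/24/12 segments) in which a ligand-receptor pair is driven by a latent niche
factor plus an immune-content confounder.

Every simulation returns a :class:`TruthTable` holding the planted parameters
so recovery tests can compare estimates against ground truth.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse as sp
from scipy.optimize import brentq
from scipy.stats import norm as _norm

GROUPS = ("Ctrl", "EuE", "EcP", "EcO")

CELL_TYPES = (
    "T cells",
    "Macrophages",
    "B cells",
    "Epithelial cells",
    "Stromal cells",
    "Fibroblasts",
    "Endothelial cells",
    "Smooth muscle cells",
    "Pericytes",
)

#: Cell types counted toward the immune aggregate (NK included when labelled).
IMMUNE_CELL_TYPES = ("T cells", "Macrophages", "B cells", "NK cells")

DEFAULT_PATIENTS = {"Ctrl": 3, "EuE": 9, "EcP": 8, "EcO": 4}

#: Published per-group cell totals consistent with the positive-cell
#: denominators (they sum to 81,676).
REPORTED_GROUP_CELLS = {"Ctrl": 10351, "EuE": 24440, "EcP": 23251, "EcO": 23634}
#: Alternative EuE total printed in the same study's statistical summary;
#: exposed so either convention can be selected when scaling a simulation.
EUE_CELLS_ALTERNATIVE = 10806

# Per-group cell-type proportions chosen to reproduce the published immune
# aggregates (Ctrl 23.9%, EuE 33.9%, EcP 46.3%, EcO 15.3%), the within-immune
# T/macrophage splits, and the EcO smooth-muscle enrichment (39.8%).
DEFAULT_CELLTYPE_PROPORTIONS: dict[str, dict[str, float]] = {
    "Ctrl": {
        "T cells": 0.1245, "Macrophages": 0.1004, "B cells": 0.0141,
        "Epithelial cells": 0.2800, "Stromal cells": 0.2800,
        "Fibroblasts": 0.0800, "Endothelial cells": 0.0600,
        "Smooth muscle cells": 0.0300, "Pericytes": 0.0310,
    },
    "EuE": {
        "T cells": 0.2109, "Macrophages": 0.1085, "B cells": 0.0196,
        "Epithelial cells": 0.2200, "Stromal cells": 0.2200,
        "Fibroblasts": 0.0900, "Endothelial cells": 0.0600,
        "Smooth muscle cells": 0.0400, "Pericytes": 0.0310,
    },
    "EcP": {
        "T cells": 0.2116, "Macrophages": 0.2315, "B cells": 0.0199,
        "Epithelial cells": 0.1000, "Stromal cells": 0.2000,
        "Fibroblasts": 0.1000, "Endothelial cells": 0.0600,
        "Smooth muscle cells": 0.0470, "Pericytes": 0.0300,
    },
    "EcO": {
        "T cells": 0.0852, "Macrophages": 0.0623, "B cells": 0.0055,
        "Epithelial cells": 0.1000, "Stromal cells": 0.1800,
        "Fibroblasts": 0.1000, "Endothelial cells": 0.0400,
        "Smooth muscle cells": 0.3980, "Pericytes": 0.0290,
    },
}


@dataclass(frozen=True)
class SparseGeneSpec:
    """A gene expressed in a small fraction of cells.

    ``expressing_fraction`` and ``intensity`` are per-group maps; intensity is
    the geometric mean of counts among expressing cells (draws are lognormal
    with log-scale spread ``sigma``, then rounded up to stay positive).
    """

    gene: str
    expressing_fraction: dict[str, float]
    intensity: dict[str, float]
    sigma: float = 0.8


@dataclass(frozen=True)
class ProgramSpec:
    """A gene program shifted multiplicatively (2**log2_effect) in one group."""

    genes: tuple[str, ...]
    target_group: str
    log2_effect: float


@dataclass(frozen=True)
class LRPairSpec:
    """A ligand-receptor pair co-driven by a latent niche factor.

    ``latent_rho`` is the target Spearman correlation induced through a
    Gaussian copula; ``confounder_loading`` couples both genes to the shared
    immune-content factor that also drives the immune marker genes.
    """

    ligand: str
    receptor: str
    latent_rho: float
    confounder_loading: float = 0.0


@dataclass(frozen=True)
class SegmentDesign:
    n_segments_per_tissue: int = 30
    tissues: tuple[str, ...] = ("EuE", "EcP")
    compartments: tuple[str, ...] = ("Macrophages", "Epithelium", "Stroma")
    slide_sizes: dict[str, int] = field(
        default_factory=lambda: {"Slide_1": 24, "Slide_3": 24, "Slide_4": 12}
    )


def _default_sparse_specs() -> list[SparseGeneSpec]:
    return [
        # CCL19-like chemokine: rare, strongly enriched in EcP, with a 7.6x
        # intensity shift among expressors.
        SparseGeneSpec(
            "CCL19",
            {"Ctrl": 0.0025, "EuE": 0.0050, "EcP": 0.0161, "EcO": 0.0006},
            {"Ctrl": 2.0, "EuE": 3.0, "EcP": 15.2, "EcO": 2.0},
        ),
        SparseGeneSpec(
            "CCR7",
            {"Ctrl": 0.010, "EuE": 0.010, "EcP": 0.025, "EcO": 0.008},
            {"Ctrl": 2.0, "EuE": 2.0, "EcP": 4.6, "EcO": 2.0},
        ),
        # NNMT-like gene: broadly expressed, fractions comparable across groups.
        SparseGeneSpec(
            "NNMT",
            {"Ctrl": 0.290, "EuE": 0.205, "EcP": 0.239, "EcO": 0.246},
            {"Ctrl": 2.0, "EuE": 2.0, "EcP": 2.0, "EcO": 4.0},
        ),
    ]


def _default_program_specs() -> list[ProgramSpec]:
    return [
        ProgramSpec(("MYH11", "ACTA2", "DES", "TAGLN"), "EcO", 3.0),
        ProgramSpec(("CTLA4", "PDCD1", "LAG3", "HAVCR2", "TIGIT"), "EcP", 2.0),
        ProgramSpec(("GZMB", "PRF1", "GNLY"), "EcP", 2.0),
        # immune activity is lowest in the ovarian lesions: cytotoxicity and
        # checkpoint programs sit below the control baseline there
        ProgramSpec(("GZMB", "PRF1", "GNLY"), "EcO", -1.0),
        ProgramSpec(("CTLA4", "PDCD1", "LAG3", "HAVCR2", "TIGIT"), "EcO", -0.5),
        ProgramSpec(("ESR1", "PGR"), "EcP", -1.0),
        ProgramSpec(("ESR1", "PGR"), "EcO", -2.5),
        ProgramSpec(("COL1A1", "COL3A1", "FN1"), "EuE", 1.0),
        ProgramSpec(("CD68", "CD3D", "CD3E", "PTPRC", "CD4", "CD8A"), "EcP", 1.5),
    ]


def _default_lr_specs() -> list[LRPairSpec]:
    return [
        LRPairSpec("CCL19", "CCR7", latent_rho=0.87, confounder_loading=0.4),
        LRPairSpec("TGFB1", "TGFBR1", latent_rho=0.90, confounder_loading=0.0),
    ]


IMMUNE_MARKER_GENES = ("CD68", "CD3D", "CD3E", "PTPRC", "CD4", "CD8A")


class ConfigurationError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults describe the desk-scale study: 24 patients in the published
    3/9/8/4 split, 500 cells per patient, a 2,000-gene panel, shared NB
    dispersion 0.5, and the published 60-segment spatial design.
    """

    n_patients_per_group: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_PATIENTS)
    )
    cells_per_patient: int = 500
    n_genes: int = 2000
    celltype_proportions: dict[str, dict[str, float]] = field(
        default_factory=lambda: {g: dict(p) for g, p in DEFAULT_CELLTYPE_PROPORTIONS.items()}
    )
    sparse_gene_specs: list[SparseGeneSpec] = field(default_factory=_default_sparse_specs)
    program_specs: list[ProgramSpec] = field(default_factory=_default_program_specs)
    nb_dispersion: float = 0.5
    mean_range: tuple[float, float] = (0.05, 5.0)
    low_quality_fraction: float = 0.05
    segment_design: SegmentDesign = field(default_factory=SegmentDesign)
    lr_pair_specs: list[LRPairSpec] = field(default_factory=_default_lr_specs)
    segment_mean_range: tuple[float, float] = (5.0, 400.0)
    segment_signal_sd: float = 0.6
    seed: int = 0

    def validate(self) -> None:
        if self.cells_per_patient <= 0 or self.n_genes <= 0:
            raise ConfigurationError("cells_per_patient and n_genes must be positive")
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be positive")
        for group, props in self.celltype_proportions.items():
            total = sum(props.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"cell-type proportions for {group} sum to {total}, not 1"
                )
            if any(p < 0 for p in props.values()):
                raise ConfigurationError(f"negative proportion in group {group}")
        for spec in self.sparse_gene_specs:
            for g, f in spec.expressing_fraction.items():
                if not 0.0 <= f <= 1.0:
                    raise ConfigurationError(
                        f"expressing fraction {f} for {spec.gene}/{g} outside [0, 1]"
                    )
            if any(v <= 0 for v in spec.intensity.values()):
                raise ConfigurationError(f"non-positive intensity for {spec.gene}")
        for pair in self.lr_pair_specs:
            if not -1.0 < pair.latent_rho < 1.0:
                raise ConfigurationError(
                    f"latent correlation {pair.latent_rho} must lie in (-1, 1)"
                )
        design = self.segment_design
        total = design.n_segments_per_tissue * len(design.tissues)
        if sum(design.slide_sizes.values()) != total:
            raise ConfigurationError(
                "slide sizes must sum to the total number of segments"
            )


@dataclass
class TruthTable:
    """Planted parameters of a simulation, keyed by simulated gene names."""

    sparse_genes: dict[str, dict] = field(default_factory=dict)
    programs: list[dict] = field(default_factory=list)
    lr_pairs: list[dict] = field(default_factory=list)
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _ceil_lognormal_scale(target: float, sigma: float) -> float:
    """Lognormal scale whose ceil-discretized draws keep geometric mean ``target``.

    Expressor counts are ``ceil(LogNormal(ln s, sigma))``; rounding up inflates
    the geometric mean, most strongly near 1.  Solving
    ``E[ln ceil X] = ln target`` for ``s`` makes the planted intensity exact on
    the scale the geometric-mean statistic estimates.  Targets at or below
    ~1 are returned unadjusted (counts are bounded below by 1).
    """
    if target <= 1.05:
        return target

    def gap(ln_s: float) -> float:
        kmax = int(math.exp(ln_s + 5.0 * sigma)) + 2
        ks = np.arange(1, kmax + 1)
        upper = _norm.cdf((np.log(ks) - ln_s) / sigma)
        pk = np.diff(upper, prepend=0.0)
        pk[-1] += 1.0 - upper[-1]
        return float((np.log(ks) * pk).sum()) - math.log(target)

    try:
        return float(math.exp(brentq(gap, math.log(target) - 2.0, math.log(target) + 1.0)))
    except ValueError:
        return target


def _named_genes(config: SimConfig) -> list[str]:
    names: list[str] = []
    for spec in config.sparse_gene_specs:
        names.append(spec.gene)
    for prog in config.program_specs:
        names.extend(prog.genes)
    for pair in config.lr_pair_specs:
        names.extend([pair.ligand, pair.receptor])
    names.extend(IMMUNE_MARKER_GENES)
    seen: dict[str, None] = {}
    for n in names:
        seen.setdefault(n)
    return list(seen)


def gene_panel(config: SimConfig) -> list[str]:
    """Named genes first, then filler genes G0001... up to ``n_genes``."""
    named = _named_genes(config)
    if len(named) > config.n_genes:
        raise ConfigurationError(
            f"n_genes={config.n_genes} smaller than the {len(named)} named genes"
        )
    n_fill = config.n_genes - len(named)
    return named + [f"G{i + 1:04d}" for i in range(n_fill)]


def simulate_cells(config: SimConfig | None = None, seed: int | None = None):
    """Simulate a single-cell count matrix with per-cell metadata.

    Returns an :class:`anndata.AnnData` (cells x genes, raw integer counts in
    ``X``) and the :class:`TruthTable` of planted parameters.  Identical
    config + seed gives byte-identical output.
    """
    config = config or SimConfig()
    config.validate()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)

    groups_per_cell: list[str] = []
    patients: list[str] = []
    for group in GROUPS:
        n_pat = config.n_patients_per_group.get(group, 0)
        for p in range(n_pat):
            pid = f"{group}_P{p + 1:02d}"
            groups_per_cell.extend([group] * config.cells_per_patient)
            patients.extend([pid] * config.cells_per_patient)
    n_cells = len(groups_per_cell)
    if n_cells == 0:
        raise ConfigurationError("no patients configured")
    group_arr = np.asarray(groups_per_cell)

    cell_types = np.empty(n_cells, dtype=object)
    for group in GROUPS:
        idx = np.flatnonzero(group_arr == group)
        if idx.size == 0:
            continue
        props = config.celltype_proportions[group]
        labels = list(props)
        p = np.asarray([props[l] for l in labels], dtype=float)
        p = p / p.sum()
        cell_types[idx] = rng.choice(labels, size=idx.size, p=p)

    genes = gene_panel(config)
    sparse_names = {s.gene for s in config.sparse_gene_specs}
    n_genes = len(genes)

    # Background NB means, log-uniform across genes; sparse genes are handled
    # by their own expressor model and excluded from the background.
    lo, hi = config.mean_range
    base_mean = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_genes))

    # Per-gene multiplicative group effects from the program specs.
    group_factor = np.ones((n_genes, len(GROUPS)))
    gene_index = {g: i for i, g in enumerate(genes)}
    for prog in config.program_specs:
        for g in prog.genes:
            if g in sparse_names:
                continue
            group_factor[gene_index[g], GROUPS.index(prog.target_group)] *= (
                2.0 ** prog.log2_effect
            )

    code_of = {g: i for i, g in enumerate(GROUPS)}
    group_codes = np.asarray([code_of[g] for g in group_arr])

    alpha = config.nb_dispersion
    shape = 1.0 / alpha
    blocks = []
    block_size = 200
    for start in range(0, n_genes, block_size):
        stop = min(start + block_size, n_genes)
        mu = base_mean[start:stop, None] * group_factor[start:stop][:, group_codes]
        lam = rng.gamma(shape, mu * alpha)
        counts = rng.poisson(lam)
        for spec in config.sparse_gene_specs:
            gi = gene_index[spec.gene]
            if not start <= gi < stop:
                continue
            row = np.zeros(n_cells, dtype=np.int64)
            for group in GROUPS:
                idx = np.flatnonzero(group_arr == group)
                if idx.size == 0:
                    continue
                frac = spec.expressing_fraction.get(group, 0.0)
                expressed = idx[rng.random(idx.size) < frac]
                if expressed.size:
                    s = _ceil_lognormal_scale(spec.intensity[group], spec.sigma)
                    draws = rng.lognormal(math.log(s), spec.sigma, expressed.size)
                    row[expressed] = np.ceil(draws).astype(np.int64)
            counts[gi - start] = row
        blocks.append(sp.csr_matrix(counts.astype(np.int64)))
    X = sp.vstack(blocks).T.tocsr()  # cells x genes

    # Low-quality cells: heavily thinned counts and high mitochondrial load,
    # so the standard QC thresholds remove them.
    low_quality = rng.random(n_cells) < config.low_quality_fraction
    if low_quality.any():
        row_of_data = np.repeat(np.arange(n_cells), np.diff(X.indptr))
        sel = low_quality[row_of_data]
        X.data[sel] = rng.binomial(X.data[sel], 0.15)
    X.eliminate_zeros()

    mito = rng.beta(2.0, 18.0, size=n_cells)
    mito[low_quality] = rng.beta(7.0, 13.0, size=int(low_quality.sum()))

    n_umi = np.asarray(X.sum(axis=1)).ravel().astype(int)
    n_det = np.asarray((X > 0).sum(axis=1)).ravel().astype(int)

    obs = pd.DataFrame(
        {
            "group": pd.Categorical(group_arr, categories=list(GROUPS)),
            "patient": patients,
            "cell_type": cell_types.astype(str),
            "n_genes_detected": n_det,
            "n_umi": n_umi,
            "mito_fraction": mito,
        },
        index=[f"cell_{i:06d}" for i in range(n_cells)],
    )
    adata = ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=genes))

    truth = TruthTable(seed=seed)
    for spec in config.sparse_gene_specs:
        truth.sparse_genes[spec.gene] = {
            "expressing_fraction": dict(spec.expressing_fraction),
            "intensity": dict(spec.intensity),
            "sigma": spec.sigma,
        }
    for prog in config.program_specs:
        truth.programs.append(
            {
                "genes": list(prog.genes),
                "target_group": prog.target_group,
                "log2_effect": prog.log2_effect,
            }
        )
    return adata, truth


def _segment_layout(design: SegmentDesign) -> pd.DataFrame:
    rows = []
    comps = design.compartments
    for tissue in design.tissues:
        for i in range(design.n_segments_per_tissue):
            rows.append({"tissue": tissue, "compartment": comps[i % len(comps)]})
    meta = pd.DataFrame(rows)
    # Interleave tissues so each slide spans both, then fill slides in order.
    order = []
    per_tissue = design.n_segments_per_tissue
    for i in range(per_tissue):
        for t in range(len(design.tissues)):
            order.append(t * per_tissue + i)
    meta = meta.iloc[order].reset_index(drop=True)
    slides = []
    for slide, size in design.slide_sizes.items():
        slides.extend([slide] * size)
    meta["slide"] = slides
    meta.index = [f"segment_{i + 1:03d}" for i in range(len(meta))]
    return meta


def simulate_segments(config: SimConfig | None = None, seed: int | None = None):
    """Simulate a spatial segment count matrix (segments x genes).

    Ligand-receptor pairs follow a Gaussian copula with the configured latent
    Spearman correlation; an immune-content factor loads the immune marker
    genes and, via ``confounder_loading``, the LR pairs, making the
    partial-correlation adjustment testable.  Counts are Poisson around
    segment-level lognormal means, large enough that ranks are barely
    perturbed.
    """
    config = config or SimConfig()
    config.validate()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)

    meta = _segment_layout(config.segment_design)
    n_seg = len(meta)
    genes = gene_panel(config)
    gene_index = {g: i for i, g in enumerate(genes)}
    n_genes = len(genes)

    lo, hi = config.segment_mean_range
    log_base = rng.uniform(np.log(lo), np.log(hi), size=n_genes)

    tissues = meta["tissue"].to_numpy()
    comps = meta["compartment"].to_numpy()
    slides = meta["slide"].to_numpy()

    s = config.segment_signal_sd
    # Structured log-scale profiles: additive tissue + compartment effects,
    # a slide (batch) effect, and segment noise.
    tissue_levels = list(dict.fromkeys(tissues))
    comp_levels = list(dict.fromkeys(comps))
    slide_levels = list(dict.fromkeys(slides))
    log_mu = np.empty((n_seg, n_genes))
    for j in range(n_genes):
        t_eff = {t: rng.normal(0, 0.7) for t in tissue_levels}
        c_eff = {c: rng.normal(0, 0.7) for c in comp_levels}
        s_eff = {sl: rng.normal(0, 0.35) for sl in slide_levels}
        profile = (
            np.asarray([t_eff[t] for t in tissues])
            + np.asarray([c_eff[c] for c in comps])
            + np.asarray([s_eff[sl] for sl in slides])
            + rng.normal(0, 0.7, size=n_seg)
        )
        profile = (profile - profile.mean()) / profile.std()
        log_mu[:, j] = log_base[j] + s * profile

    # Immune-content factor and marker genes.
    immune_factor = rng.normal(0, 1, size=n_seg)
    for g in IMMUNE_MARKER_GENES:
        j = gene_index[g]
        prof = 1.0 * immune_factor + rng.normal(0, 0.3, size=n_seg)
        prof = prof - prof.mean()
        log_mu[:, j] = log_base[j] + 0.6 * prof / max(prof.std(), 1e-12)

    truth = TruthTable(seed=seed)
    for pair in config.lr_pair_specs:
        rho_s = pair.latent_rho
        rho_pearson = 2.0 * math.sin(math.pi * rho_s / 6.0)
        z_shared = rng.normal(0, 1, size=n_seg)
        e1 = rng.normal(0, 1, size=n_seg)
        e2 = rng.normal(0, 1, size=n_seg)
        a = math.sqrt(abs(rho_pearson))
        b = math.sqrt(1.0 - abs(rho_pearson))
        sign = 1.0 if rho_pearson >= 0 else -1.0
        z_l = a * z_shared + b * e1
        z_r = sign * a * z_shared + b * e2
        lam = pair.confounder_loading
        # LR genes sit at a fixed high abundance so Poisson noise barely
        # perturbs ranks and the counts' Spearman tracks the latent target.
        for g, z in ((pair.ligand, z_l), (pair.receptor, z_r)):
            j = gene_index[g]
            log_mu[:, j] = math.log(150.0) + 0.8 * z + lam * immune_factor
        truth.lr_pairs.append(
            {
                "ligand": pair.ligand,
                "receptor": pair.receptor,
                "latent_rho": pair.latent_rho,
                "confounder_loading": pair.confounder_loading,
            }
        )

    # Per-segment technical depth (library size) variation; this is exactly
    # the nuisance Q3 normalization is designed to remove.
    depth = rng.normal(0.0, 0.3, size=n_seg)
    counts = rng.poisson(np.exp(log_mu + depth[:, None])).astype(np.int64)
    detection = (counts > 0).mean(axis=1)
    obs = meta.copy()
    obs["detection_rate"] = detection
    adata = ad.AnnData(
        X=counts, obs=obs, var=pd.DataFrame(index=genes)
    )
    adata.uns["immune_factor"] = immune_factor  # planted; for diagnostics only
    return adata, truth


def planted_variance_segments(
    n_segments: int = 60,
    n_genes: int = 200,
    bio_frac: float = 0.609,
    batch_frac: float = 0.123,
    design: SegmentDesign | None = None,
    seed: int = 0,
) -> ad.AnnData:
    """Continuous segment profiles with an exact planted variance split.

    Each gene's profile is a sum of three mutually orthogonalized,
    unit-variance components — an additive tissue+compartment pattern, a
    slide pattern, and noise — weighted so the biological and batch variance
    shares equal ``bio_frac`` and ``batch_frac``.  Used to validate the
    variance-partitioning estimator against known ground truth.
    """
    if bio_frac < 0 or batch_frac < 0 or bio_frac + batch_frac > 1:
        raise ConfigurationError("variance fractions must be non-negative and sum <= 1")
    design = design or SegmentDesign()
    meta = _segment_layout(design)
    if len(meta) != n_segments:
        per_tissue = n_segments // len(design.tissues)
        design = SegmentDesign(
            n_segments_per_tissue=per_tissue,
            tissues=design.tissues,
            compartments=design.compartments,
            slide_sizes={"Slide_1": n_segments - n_segments // 2, "Slide_3": n_segments // 2},
        )
        meta = _segment_layout(design)
    rng = np.random.default_rng(seed)
    n = len(meta)

    d_bio = pd.get_dummies(meta[["tissue", "compartment"]], drop_first=False)
    d_bio = np.column_stack([np.ones(n), d_bio.to_numpy(dtype=float)])
    d_slide = pd.get_dummies(meta["slide"], drop_first=False)
    d_slide = np.column_stack([np.ones(n), d_slide.to_numpy(dtype=float)])

    def _project_out(v: np.ndarray, basis: np.ndarray) -> np.ndarray:
        coef, *_ = np.linalg.lstsq(basis, v, rcond=None)
        return v - basis @ coef

    def _standardize(v: np.ndarray) -> np.ndarray:
        v = v - v.mean()
        return v / max(v.std(), 1e-12)

    X = np.empty((n, n_genes))
    tissues = meta["tissue"].to_numpy()
    comps = meta["compartment"].to_numpy()
    slides = meta["slide"].to_numpy()
    for j in range(n_genes):
        t_eff = {t: rng.normal() for t in dict.fromkeys(tissues)}
        c_eff = {c: rng.normal() for c in dict.fromkeys(comps)}
        z_bio = _standardize(
            np.asarray([t_eff[t] for t in tissues])
            + np.asarray([c_eff[c] for c in comps])
        )
        s_eff = {sl: rng.normal() for sl in dict.fromkeys(slides)}
        z_slide = np.asarray([s_eff[sl] for sl in slides])
        z_slide = _standardize(_project_out(z_slide, d_bio))
        eps = rng.normal(size=n)
        eps = _standardize(_project_out(_project_out(eps, d_bio), d_slide))
        X[:, j] = (
            math.sqrt(bio_frac) * z_bio
            + math.sqrt(batch_frac) * z_slide
            + math.sqrt(1.0 - bio_frac - batch_frac) * eps
        )
    return ad.AnnData(X=X, obs=meta, var=pd.DataFrame(index=[f"V{j:04d}" for j in range(n_genes)]))
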