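"""Pathway networks, immune-hot/cold niche calls, and report bundles.

The hot/cold classifier operationalizes a qualitative dichotomy with explicit
stored thresholds: a lesion group is *immune-hot* when its immune cell
fraction is high and its checkpoint score exceeds the reference group's mean,
*immune-cold* when both are low, and *indeterminate* otherwise.  The rule and
its thresholds are this package's own construction, chosen to make the
dichotomy reproducible and testable.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .genescores import GeneSet


def pathway_network(
    scores: pd.DataFrame,
    groups,
    de: pd.DataFrame,
    sets: dict[str, GeneSet],
    edge_threshold: float = 0.5,
) -> nx.Graph:
    """Build a pathway-level signaling network.

    ``scores`` holds one column of per-unit activity scores per pathway.
    Node size is the mean |log2fc| over the pathway's genes present in the DE
    table (0, with a warning, when none is); node ``specificity`` is the
    group with the largest mean activity.  Edges connect pathway pairs whose
    score Spearman correlation exceeds ``edge_threshold``; the correlation is
    stored as the edge weight.
    """
    groups = pd.Series(np.asarray(groups))
    g = nx.Graph()
    names = sorted(sets)
    for name in names:
        gs = sets[name]
        present = [x for x in gs.genes if x in de.index]
        if present:
            size = float(de.loc[present, "log2fc"].abs().mean())
        else:
            warnings.warn(f"pathway {name!r} has no genes in the DE table; size 0")
            size = 0.0
        means = (
            pd.DataFrame({"s": scores[name].to_numpy(), "g": groups.to_numpy()})
            .groupby("g", observed=True)["s"]
            .mean()
        )
        g.add_node(name, size=size, specificity=str(means.idxmax()))
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            rho = stats.spearmanr(scores[a], scores[b]).statistic
            if np.isfinite(rho) and rho > edge_threshold:
                g.add_edge(a, b, weight=float(rho))
    return g


@dataclass
class NicheCall:
    group: str
    immune_fraction: float
    checkpoint_score: float
    chemokine_flag: bool
    call: str
    reason: str = ""


def classify_niche(
    immune_fractions: pd.Series,
    checkpoint_scores: pd.Series,
    reference_group: str = "Ctrl",
    hot_immune: float = 0.30,
    cold_immune: float = 0.20,
    chemokine_enriched: dict[str, bool] | None = None,
) -> pd.DataFrame:
    """Immune-hot / immune-cold calls per lesion group.

    ``immune_fractions`` and ``checkpoint_scores`` are per-group values (the
    checkpoint score being the group mean of an exhaustion/checkpoint gene-set
    score).  The call is a pure function of these inputs and the stored
    thresholds; missing inputs yield ``indeterminate`` with a reason.
    """
    chemokine_enriched = chemokine_enriched or {}
    if reference_group not in checkpoint_scores.index:
        raise ValueError(f"reference group {reference_group!r} missing from scores")
    ref = float(checkpoint_scores[reference_group])
    calls = []
    for group in immune_fractions.index:
        if group == reference_group:
            continue
        frac = immune_fractions.get(group, np.nan)
        score = checkpoint_scores.get(group, np.nan)
        flag = bool(chemokine_enriched.get(group, False))
        if not (np.isfinite(frac) and np.isfinite(score)):
            call, reason = "indeterminate", "missing inputs"
        elif frac >= hot_immune and score > ref:
            call, reason = "immune-hot", ""
        elif frac <= cold_immune and score <= ref:
            call, reason = "immune-cold", ""
        else:
            call, reason = "indeterminate", "between thresholds"
        calls.append(
            NicheCall(
                group=str(group),
                immune_fraction=float(frac),
                checkpoint_score=float(score),
                chemokine_flag=flag,
                call=call,
                reason=reason,
            )
        )
    df = pd.DataFrame([c.__dict__ for c in calls]).set_index("group")
    df.attrs["thresholds"] = {
        "hot_immune": hot_immune,
        "cold_immune": cold_immune,
        "reference_group": reference_group,
    }
    return df


_EXPECTED_SECTIONS = (
    "qc_report",
    "composition",
    "sparse_tests",
    "pseudobulk_de",
    "score_summaries",
    "lr_screen",
    "partial_correlation",
    "variance_partition",
    "niche_calls",
)


def _jsonable(obj):
    if isinstance(obj, pd.DataFrame):
        return json.loads(obj.to_json(orient="split"))
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_report(outdir, sections: dict, config: dict | None = None, seed: int | None = None) -> dict:
    """Write a report bundle: one CSV per tabular section plus summary.json.

    The summary records a manifest of present and missing sections, the seed,
    and a hash of the configuration, and is byte-stable given identical
    inputs.  Returns the summary dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    present, missing = [], []
    payload = {}
    for name in _EXPECTED_SECTIONS:
        if name in sections and sections[name] is not None:
            present.append(name)
            obj = sections[name]
            if isinstance(obj, pd.DataFrame):
                obj.to_csv(outdir / f"{name}.csv")
            payload[name] = _jsonable(obj)
        else:
            missing.append(name)
    extras = sorted(set(sections) - set(_EXPECTED_SECTIONS))
    for name in extras:
        payload[name] = _jsonable(sections[name])
        present.append(name)
    config_json = json.dumps(_jsonable(config or {}), sort_keys=True)
    summary = {
        "manifest": {"present": present, "missing": missing},
        "seed": seed,
        "config_hash": hashlib.sha256(config_json.encode()).hexdigest(),
        "sections": payload,
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary


def run_pipeline(config=None, seed: int = 0, outdir=None) -> dict:
    """End-to-end synthetic run: simulate, QC, test, score, screen, classify.

    Returns a dict with every headline table; writes a report bundle when
    ``outdir`` is given.
    """
    from . import genescores, pseudobulk, sc_core, sparse_test, spatial
    from .simulate import SimConfig, simulate_cells, simulate_segments

    config = config or SimConfig()
    cells_raw, truth = simulate_cells(config, seed=seed)
    cells_qc, qc_report = sc_core.qc_filter_cells(cells_raw)
    cells = sc_core.lognormalize(cells_qc)
    composition = sc_core.composition_table(cells)

    sparse_tab = sparse_test.sparse_test_table(
        cells,
        genes=[s.gene for s in config.sparse_gene_specs],
        comparisons=[("EcP", "Ctrl"), ("EcP", "EcO"), ("EcO", "Ctrl")],
    )

    pb = pseudobulk.aggregate_pseudobulk(cells_qc)
    pb = pseudobulk.filter_low_expression(pb)
    de = pseudobulk.nb_wald_de(pb, "EcP", "Ctrl")

    scores = {
        name: genescores.geneset_score(cells, gs)
        for name, gs in genescores.DEFAULT_PATHWAYS.items()
    }
    groups = cells.obs["group"].to_numpy()
    score_summaries = pd.concat(
        {name: genescores.group_score_summary(v, groups) for name, v in scores.items()},
        names=["pathway", "group"],
    )

    segs_raw, seg_truth = simulate_segments(config, seed=seed + 1)
    segs = spatial.qc_filter_segments(segs_raw)
    segs = spatial.q3_normalize(segs)
    segs_log = spatial.log_segments(segs)
    lr_pairs = [(p.ligand, p.receptor) for p in config.lr_pair_specs]
    lr_genes = sorted({g for pair in lr_pairs for g in pair})
    records = spatial.spearman_matrix(segs_log, lr_genes)
    screen = spatial.ligand_receptor_screen(records, lr_pairs)
    immune = spatial.immune_score_segments(segs_log)
    ligand, receptor = lr_pairs[0]
    lx = segs_log[:, ligand].X.ravel()
    rx = segs_log[:, receptor].X.ravel()
    partial_rho, partial_p = spatial.partial_spearman(lx, rx, immune)
    varpart = spatial.variance_partition(segs_log)

    checkpoint = pd.Series(
        genescores.group_score_summary(scores["exhaustion"], groups)["mean"]
    )
    niche = classify_niche(composition["immune"], checkpoint)

    results = {
        "qc_report": qc_report,
        "composition": composition,
        "sparse_tests": sparse_tab,
        "pseudobulk_de": de,
        "score_summaries": score_summaries,
        "lr_screen": screen,
        "partial_correlation": {"rho": partial_rho, "p": partial_p},
        "variance_partition": varpart,
        "niche_calls": niche,
        "truth": truth.to_dict(),
        "segment_truth": seg_truth.to_dict(),
    }
    if outdir is not None:
        write_report(outdir, results, config={"n_genes": config.n_genes}, seed=seed)
    return results
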