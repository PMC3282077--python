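"""End-to-end orchestration: preprocess -> noise -> DE -> downstream analyses.

:func:`analyze` runs the whole chain in memory and returns an
:class:`AnalysisBundle`; :func:`write_bundle` serialises the per-stage
tables plus a JSON summary and a run manifest. The command-line interface
in :mod:`txrev.cli` is a thin wrapper over these two functions.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .diffexp import DEFAULT_CONTRASTS, ComparisonResult, DEGeneSets, compare_conditions, to_gene_sets
from .enrichment import EnrichmentResult, enrich
from .io import (
    DesignTable,
    ExpressionMatrix,
    GeneSetCollection,
    ProbeAnnotation,
    signed_fold_change,
)
from .noise import IntensityNoiseModel, fit_noise_model
from .pca import SampleMap, pca, shift_metric
from .preprocess import AveragedData, GeneMatrix, average_replicates, collapse_to_genes, to_log2
from .reversal import ReversalReport, classify_reversal
from .setlogic import partition_de_results
from .signature import ConsensusSignature, build_consensus, intersect_with_de

log = logging.getLogger(__name__)

__all__ = ["PipelineParams", "AnalysisBundle", "analyze", "write_bundle"]


@dataclass
class PipelineParams:
    """All thresholds of the analysis, with the canonical defaults."""

    contrasts: tuple[tuple[str, str], ...] = DEFAULT_CONTRASTS
    expression_threshold: float = 4.0
    de_alpha: float = 0.05
    fc_min: float = 1.5
    noise_window: int = 500
    enrichment_fdr: float = 0.10
    enrichment_min_overlap: int = 5
    enrichment_min_size: int = 8
    enrichment_max_size: int = 500
    min_votes: int = 2
    n_components: int = 2
    reversal_primary: tuple[str, str] = ("C", "0")
    reversal_counter: tuple[str, str] = ("ZC", "C")
    venn_roles: tuple[str, str, str] = ("AZC-AC", "ZC-C", "A-0")

    def __post_init__(self) -> None:
        for name in ("de_alpha", "fc_min", "enrichment_fdr"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class AnalysisBundle:
    params: PipelineParams
    noise: IntensityNoiseModel
    averaged: AveragedData
    gene_matrix: GeneMatrix
    comparisons: dict[str, ComparisonResult]
    gene_sets: dict[str, DEGeneSets]
    reversal: ReversalReport | None
    clusters: dict[str, frozenset[str]] | None
    enrichment: dict[str, EnrichmentResult]
    sample_map: SampleMap
    shift_ratios: dict[str, float]
    consensus: ConsensusSignature | None = None
    consensus_overlap: tuple[set[str], set[str]] | None = None

    def summary(self) -> dict:
        out: dict = {
            "de_counts": {
                label: {"up": len(gs.up), "down": len(gs.down)}
                for label, gs in self.gene_sets.items()
            },
            "shift_ratios": self.shift_ratios,
            "explained_variance": [float(v) for v in self.sample_map.explained_variance_fractions],
        }
        if self.reversal is not None:
            out["reversal"] = self.reversal.summary_dict()
        if self.clusters is not None:
            out["cluster_sizes"] = {k: len(v) for k, v in self.clusters.items()}
        if self.enrichment:
            out["significant_sets"] = {
                q: list(res.significant["set_name"]) for q, res in self.enrichment.items()
            }
        if self.consensus is not None:
            out["consensus"] = {
                "up": len(self.consensus.up),
                "down": len(self.consensus.down),
                "conflicting": len(self.consensus.conflicting),
            }
            if self.consensus_overlap is not None:
                out["consensus"]["shared_up"] = len(self.consensus_overlap[0])
                out["consensus"]["shared_down"] = len(self.consensus_overlap[1])
        return out


def _gene_fc(gene_matrix: GeneMatrix, cond_a: str, cond_b: str) -> pd.Series:
    d = (
        gene_matrix.values[:, gene_matrix.condition_index(cond_a)]
        - gene_matrix.values[:, gene_matrix.condition_index(cond_b)]
    )
    return pd.Series(signed_fold_change(d), index=gene_matrix.gene_symbols)


def _reversal_from_calls(
    gene_matrix: GeneMatrix,
    de: DEGeneSets,
    primary: tuple[str, str],
    counter: tuple[str, str],
    fc_threshold: float,
) -> ReversalReport:
    """Classify zinc-rescue status of every gene called DE in the primary contrast."""
    from .reversal import STATUSES, ReversalReport

    fc_p = _gene_fc(gene_matrix, *primary)
    fc_c = _gene_fc(gene_matrix, *counter)
    rows = []
    counts = {d: {s: 0 for s in STATUSES} for d in ("up", "down")}
    for direction, members in (("up", de.up), ("down", de.down)):
        for gene in sorted(members):
            status = classify_reversal(float(fc_p[gene]), float(fc_c[gene]), fc_threshold)
            counts[direction][status] += 1
            rows.append((gene, direction, float(fc_p[gene]), float(fc_c[gene]), status))
    table = pd.DataFrame(
        rows, columns=["gene", "direction", "fc_primary", "fc_counter", "status"]
    )
    return ReversalReport(table, counts, fc_threshold)


def analyze(
    matrix: ExpressionMatrix,
    design: DesignTable,
    annotation: ProbeAnnotation,
    pathways: GeneSetCollection | None = None,
    study_up_sets: list[set[str]] | None = None,
    study_down_sets: list[set[str]] | None = None,
    params: PipelineParams | None = None,
) -> AnalysisBundle:
    """Run the full analysis chain on one dataset."""
    p = params or PipelineParams()
    if matrix.scale == "linear":
        matrix = to_log2(matrix)
    design.check_against(matrix)

    noise = fit_noise_model(matrix, design, window_size=p.noise_window)
    averaged = average_replicates(matrix, design)
    gene_matrix = collapse_to_genes(averaged, annotation)

    comparisons: dict[str, ComparisonResult] = {}
    gene_sets: dict[str, DEGeneSets] = {}
    known = set(design.conditions)
    for cond_a, cond_b in p.contrasts:
        if cond_a not in known or cond_b not in known:
            log.warning("skipping contrast %s-%s: condition absent", cond_a, cond_b)
            continue
        res = compare_conditions(
            matrix, design, cond_a, cond_b, noise,
            t=p.expression_threshold, alpha=p.de_alpha, fc_min=p.fc_min,
        )
        comparisons[res.label] = res
        gene_sets[res.label] = to_gene_sets(res, annotation, gene_matrix)

    primary_label = "-".join(p.reversal_primary)
    reversal = None
    if primary_label in gene_sets:
        reversal = _reversal_from_calls(
            gene_matrix, gene_sets[primary_label], p.reversal_primary,
            p.reversal_counter, p.fc_min,
        )

    clusters = None
    enrichment_results: dict[str, EnrichmentResult] = {}
    if all(label in gene_sets for label in p.venn_roles):
        a, b, c = (gene_sets[label] for label in p.venn_roles)
        clusters = partition_de_results(a, b, c)
        if pathways is not None:
            universe = set(gene_matrix.gene_symbols)
            queries = {
                "drug_response_restored": set(clusters["pink"]) | set(clusters["green"]),
                "zinc_response_shared": set(clusters["light_blue"]) | set(clusters["violet"]),
            }
            for name, query in queries.items():
                if query:
                    enrichment_results[name] = enrich(
                        query, pathways, universe,
                        fdr=p.enrichment_fdr,
                        min_overlap=p.enrichment_min_overlap,
                        min_size=p.enrichment_min_size,
                        max_size=p.enrichment_max_size,
                    )

    sample_map = pca(averaged, n_components=p.n_components)
    shift_ratios: dict[str, float] = {}
    for base, pert, resc in (("0", "C", "ZC"), ("A", "AC", "AZC")):
        if all(c in sample_map.condition_labels for c in (base, pert, resc)):
            shift_ratios[f"{base}:{pert}->{resc}"] = shift_metric(
                sample_map, base, pert, resc
            ).shift_ratio

    consensus = None
    overlap = None
    if study_up_sets is not None and study_down_sets is not None:
        consensus = build_consensus(study_up_sets, study_down_sets, min_votes=p.min_votes)
        if primary_label in gene_sets:
            overlap = intersect_with_de(consensus, gene_sets[primary_label])

    return AnalysisBundle(
        params=p,
        noise=noise,
        averaged=averaged,
        gene_matrix=gene_matrix,
        comparisons=comparisons,
        gene_sets=gene_sets,
        reversal=reversal,
        clusters=clusters,
        enrichment=enrichment_results,
        sample_map=sample_map,
        shift_ratios=shift_ratios,
        consensus=consensus,
        consensus_overlap=overlap,
    )


def write_bundle(bundle: AnalysisBundle, out_dir: str | Path, manifest_extra: dict | None = None) -> Path:
    """Write per-stage TSVs, the JSON summary and a reproducibility manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for label, res in bundle.comparisons.items():
        res.table.to_csv(out / f"de_{label}.tsv", sep="\t", index=False)
    if bundle.reversal is not None:
        bundle.reversal.table.to_csv(out / "reversal.tsv", sep="\t", index=False)
    if bundle.clusters is not None:
        rows = [(g, name) for name, members in bundle.clusters.items() for g in sorted(members)]
        pd.DataFrame(rows, columns=["gene", "cluster"]).to_csv(
            out / "clusters.tsv", sep="\t", index=False
        )
    for name, res in bundle.enrichment.items():
        res.table.to_csv(out / f"enrichment_{name}.tsv", sep="\t", index=False)
    coords = pd.DataFrame(
        bundle.sample_map.coordinates,
        index=bundle.sample_map.condition_labels,
        columns=[f"PC{i+1}" for i in range(bundle.sample_map.coordinates.shape[1])],
    )
    coords.index.name = "condition"
    coords.to_csv(out / "pca_coordinates.tsv", sep="\t")

    summary = bundle.summary()
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    manifest = {
        "txrev_version": __version__,
        "params": {
            **asdict(bundle.params),
            "contrasts": [list(c) for c in bundle.params.contrasts],
        },
    }
    if manifest_extra:
        manifest.update(manifest_extra)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return out / "summary.json"


def file_checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
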