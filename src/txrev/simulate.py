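"""Synthetic factorial expression data with planted, known structure.

The generator emulates the statistical structure the pipeline assumes: a
2x2x2 factorial of drug (A), zinc (Z) and cobalt (C) — eight conditions in
duplicate — with

* per-gene baseline log2 intensities,
* planted additive log2 effects for each single agent,
* a *reversal* interaction: for a configurable fraction of cobalt-affected
  genes, zinc cancels the cobalt effect whenever both agents are present
  (ZC, AZC),
* a *block* interaction: for a fraction of drug-affected genes, cobalt
  suppresses the drug effect (AC, AZC); zinc lifts the block in AZC for
  the same fraction of blocked genes as the reversal fraction,
* intensity-dependent replicate noise (SD linear in log2 intensity between
  two anchor points, clamped),
* several probes per gene with a fixed per-probe offset, a configurable
  fraction of probes left unannotated,
* a planted pathway enriched in zinc-reversed cobalt genes among random
  decoy sets, and
* multi-study up/down gene sets whose voting consensus is a known core.

Everything is driven by one integer seed; repeated calls are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .io import (
    CONDITIONS_8,
    DesignTable,
    ExpressionMatrix,
    GeneSetCollection,
    ProbeAnnotation,
)

__all__ = ["SimulationConfig", "SimulationTruth", "SimulationResult", "simulate", "evaluate"]


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults give a desk-scale but realistic array.

    Fractions are of ``n_genes``; effect magnitudes are absolute log2 fold
    changes (signs are drawn per gene). The drug effect is larger than the
    cobalt effect so that the leading principal component of the averaged
    conditions is the drug axis and the second the (zinc-reversible)
    cobalt axis.
    """

    n_probes: int = 10_000
    n_genes: int = 8_000
    n_replicates: int = 2
    baseline_mean: float = 8.0
    baseline_sd: float = 1.8
    probe_offset_sd: float = 0.25
    annotated_fraction: float = 0.95
    # replicate noise: SD linear in intensity between the two anchors, clamped
    noise_sd_low: float = 0.45
    noise_sd_high: float = 0.15
    noise_intensity_low: float = 4.0
    noise_intensity_high: float = 12.0
    # planted single-agent effects
    drug_fraction: float = 0.15
    drug_log2_effect: float = 2.0
    cobalt_fraction: float = 0.25
    cobalt_log2_effect: float = 1.5
    zinc_fraction: float = 0.05
    zinc_log2_effect: float = 1.0
    # interactions
    reversal_fraction: float = 0.8
    drug_block_fraction: float = 0.5
    # planted pathway collection
    pathway_size: int = 50
    pathway_from_reversed: int = 30
    n_decoy_sets: int = 49
    # multi-study signature inputs
    n_studies: int = 10
    signature_core_up: int = 150
    signature_core_down: int = 76
    study_private_genes: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("drug_fraction", "cobalt_fraction", "zinc_fraction",
                     "reversal_fraction", "drug_block_fraction", "annotated_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must lie in [0, 1]")
        for name in ("drug_log2_effect", "cobalt_log2_effect", "zinc_log2_effect"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0 (signs are drawn per gene)")
        if self.n_probes < self.n_genes:
            raise ValueError("need at least one probe per gene")
        if self.pathway_size > self.n_genes:
            raise ValueError("planted pathway larger than the gene universe")
        if self.pathway_from_reversed > self.pathway_size:
            raise ValueError("pathway_from_reversed exceeds pathway_size")


@dataclass
class SimulationTruth:
    """Ground truth of one simulation, gene-indexed."""

    gene_symbols: list[str]
    drug_effect: np.ndarray  # signed log2 effect, 0 where unaffected
    cobalt_effect: np.ndarray
    zinc_effect: np.ndarray
    reversed_by_zinc: np.ndarray  # bool, meaningful where cobalt_effect != 0
    drug_blocked: np.ndarray  # bool, meaningful where drug_effect != 0
    block_lifted_by_zinc: np.ndarray  # bool, meaningful where drug_blocked
    condition_means: np.ndarray  # genes x 8 conditions (log2)
    pathway_name: str
    pathway_members: frozenset[str]
    study_up_sets: list[set[str]]
    study_down_sets: list[set[str]]
    core_up: set[str]
    core_down: set[str]

    def cobalt_genes(self) -> np.ndarray:
        return self.cobalt_effect != 0


@dataclass
class SimulationResult:
    matrix: ExpressionMatrix
    design: DesignTable
    annotation: ProbeAnnotation
    pathways: GeneSetCollection
    truth: SimulationTruth
    config: SimulationConfig


def _noise_sd(cfg: SimulationConfig, intensity: np.ndarray) -> np.ndarray:
    x = np.clip(intensity, cfg.noise_intensity_low, cfg.noise_intensity_high)
    span = cfg.noise_intensity_high - cfg.noise_intensity_low
    frac = (x - cfg.noise_intensity_low) / span if span > 0 else 0.0
    return cfg.noise_sd_low + (cfg.noise_sd_high - cfg.noise_sd_low) * frac


def _condition_means(cfg: SimulationConfig, truth_arrays: dict, baseline: np.ndarray) -> np.ndarray:
    """Planted mean structure: baseline plus active effects per condition."""
    n = len(baseline)
    means = np.tile(baseline[:, None], (1, len(CONDITIONS_8)))
    for j, cond in enumerate(CONDITIONS_8):
        has_a, has_z, has_c = ("A" in cond), ("Z" in cond), ("C" in cond)
        if has_c:
            active = np.ones(n, dtype=bool)
            if has_z:  # zinc cancels cobalt for reversal-flagged genes
                active &= ~truth_arrays["reversed_by_zinc"]
            means[:, j] += truth_arrays["cobalt_effect"] * active
        if has_a:
            active = np.ones(n, dtype=bool)
            if has_c:  # cobalt blocks the drug effect for block-flagged genes
                blocked = truth_arrays["drug_blocked"].copy()
                if has_z:  # zinc lifts the block where flagged
                    blocked &= ~truth_arrays["block_lifted_by_zinc"]
                active &= ~blocked
            means[:, j] += truth_arrays["drug_effect"] * active
        if has_z:
            means[:, j] += truth_arrays["zinc_effect"]
    return means


def simulate(config: SimulationConfig | None = None, seed: int | None = None) -> SimulationResult:
    """Generate one dataset; ``seed`` overrides ``config.seed`` when given."""
    cfg = config or SimulationConfig()
    if seed is not None:
        cfg = SimulationConfig(**{**asdict(cfg), "seed": seed})
    rng = np.random.default_rng(cfg.seed)
    n_g, n_p = cfg.n_genes, cfg.n_probes

    genes = [f"G{i:06d}" for i in range(n_g)]
    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=n_g)

    def planted(fraction: float, magnitude: float) -> np.ndarray:
        effect = np.zeros(n_g)
        k = int(round(fraction * n_g))
        idx = rng.choice(n_g, size=k, replace=False)
        effect[idx] = magnitude * rng.choice([-1.0, 1.0], size=k)
        return effect

    drug = planted(cfg.drug_fraction, cfg.drug_log2_effect)
    cobalt = planted(cfg.cobalt_fraction, cfg.cobalt_log2_effect)
    zinc = planted(cfg.zinc_fraction, cfg.zinc_log2_effect)
    reversed_by_zinc = (cobalt != 0) & (rng.random(n_g) < cfg.reversal_fraction)
    drug_blocked = (drug != 0) & (rng.random(n_g) < cfg.drug_block_fraction)
    block_lifted = drug_blocked & (rng.random(n_g) < cfg.reversal_fraction)

    arrays = {
        "drug_effect": drug,
        "cobalt_effect": cobalt,
        "zinc_effect": zinc,
        "reversed_by_zinc": reversed_by_zinc,
        "drug_blocked": drug_blocked,
        "block_lifted_by_zinc": block_lifted,
    }
    means = _condition_means(cfg, arrays, baseline)

    # probes: one per gene guaranteed, surplus assigned at random
    probe_gene = np.concatenate([np.arange(n_g), rng.integers(0, n_g, size=n_p - n_g)])
    rng.shuffle(probe_gene)
    probes = [f"P{i:06d}_at" for i in range(n_p)]
    offsets = rng.normal(0.0, cfg.probe_offset_sd, size=n_p)

    sample_ids, assignments = [], {}
    for cond in CONDITIONS_8:
        for r in range(1, cfg.n_replicates + 1):
            sid = f"{cond}_r{r}"
            sample_ids.append(sid)
            assignments[sid] = (cond, r)
    design = DesignTable(assignments)

    probe_means = means[probe_gene] + offsets[:, None]  # probes x 8
    sd = _noise_sd(cfg, probe_means)  # probes x 8
    values = np.empty((n_p, len(sample_ids)))
    for s, sid in enumerate(sample_ids):
        j = CONDITIONS_8.index(assignments[sid][0])
        values[:, s] = probe_means[:, j] + rng.normal(0.0, 1.0, size=n_p) * sd[:, j]
    matrix = ExpressionMatrix(probes, sample_ids, values, scale="log2")

    annotated = rng.random(n_p) < cfg.annotated_fraction
    # keep >= 1 annotated probe per gene so the gene universe equals `genes`
    first_probe_of_gene: dict[int, int] = {}
    for i, g in enumerate(probe_gene):
        first_probe_of_gene.setdefault(int(g), i)
    annotated[list(first_probe_of_gene.values())] = True
    annotation = ProbeAnnotation(
        {probes[i]: genes[probe_gene[i]] for i in range(n_p) if annotated[i]}
    )

    pathways = _planted_pathways(cfg, rng, genes, cobalt, reversed_by_zinc)
    study_up, study_down, core_up, core_down = _study_sets(cfg, rng, genes, cobalt)

    truth = SimulationTruth(
        gene_symbols=genes,
        condition_means=means,
        pathway_name="PLANTED_REVERSAL_PATHWAY",
        pathway_members=pathways.sets["PLANTED_REVERSAL_PATHWAY"],
        study_up_sets=study_up,
        study_down_sets=study_down,
        core_up=core_up,
        core_down=core_down,
        **arrays,
    )
    return SimulationResult(matrix, design, annotation, pathways, truth, cfg)


def _planted_pathways(cfg, rng, genes, cobalt, reversed_by_zinc) -> GeneSetCollection:
    reversed_idx = np.flatnonzero(reversed_by_zinc)
    quiet_idx = np.flatnonzero(cobalt == 0)
    k_rev = min(cfg.pathway_from_reversed, len(reversed_idx))
    members = list(rng.choice(reversed_idx, size=k_rev, replace=False)) if k_rev else []
    filler = rng.choice(quiet_idx, size=cfg.pathway_size - k_rev, replace=False)
    members = sorted(int(i) for i in (*members, *filler))
    sets = {"PLANTED_REVERSAL_PATHWAY": frozenset(genes[i] for i in members)}
    for d in range(cfg.n_decoy_sets):
        idx = rng.choice(len(genes), size=cfg.pathway_size, replace=False)
        sets[f"DECOY_{d:03d}"] = frozenset(genes[int(i)] for i in idx)
    return GeneSetCollection(sets, {name: "canonical" for name in sets})


def _study_sets(cfg, rng, genes, cobalt):
    """Per-study up/down sets whose >=2-vote consensus is a planted core.

    Core genes are taken from cobalt-modulated genes of the matching sign
    where available (so the consensus intersects the cobalt DE calls, as a
    hypoxia signature would); each appears in 2..n_studies study sets.
    Private filler genes appear in exactly one study and never reach the
    vote threshold.
    """
    up_pool = list(np.flatnonzero(cobalt > 0))
    down_pool = list(np.flatnonzero(cobalt < 0))
    quiet = list(np.flatnonzero(cobalt == 0))
    rng.shuffle(quiet)

    def pick_core(pool: list[int], k: int) -> list[int]:
        take = min(k, len(pool))
        chosen = list(rng.choice(pool, size=take, replace=False))
        chosen += [quiet.pop() for _ in range(k - take)]
        return [int(i) for i in chosen]

    core_up_idx = pick_core(up_pool, cfg.signature_core_up)
    core_down_idx = pick_core(down_pool, cfg.signature_core_down)
    used = set(core_up_idx) | set(core_down_idx)
    private_pool = [i for i in quiet if i not in used]

    up_sets: list[set[str]] = [set() for _ in range(cfg.n_studies)]
    down_sets: list[set[str]] = [set() for _ in range(cfg.n_studies)]
    for sets, core_idx in ((up_sets, core_up_idx), (down_sets, core_down_idx)):
        for gi in core_idx:
            k = int(rng.integers(2, cfg.n_studies + 1))
            for s in rng.choice(cfg.n_studies, size=k, replace=False):
                sets[s].add(genes[gi])
        for s in range(cfg.n_studies):
            for _ in range(cfg.study_private_genes):
                if private_pool:
                    sets[s].add(genes[private_pool.pop()])
    core_up = {genes[i] for i in core_up_idx}
    core_down = {genes[i] for i in core_down_idx}
    return up_sets, down_sets, core_up, core_down


# ---------------------------------------------------------------------------
# truth-vs-output metrics


def evaluate(truth: SimulationTruth, de_up: set[str], de_down: set[str],
             effect: np.ndarray | None = None) -> dict[str, float]:
    """Sensitivity and observed false-discovery fraction of one DE call set.

    ``effect`` defaults to the cobalt effect (the C-0 contrast); pass
    ``truth.drug_effect`` to score an A-0 call set, etc.
    """
    eff = truth.cobalt_effect if effect is None else effect
    symbols = truth.gene_symbols
    if not set(de_up) <= set(symbols) or not set(de_down) <= set(symbols):
        raise ValueError("DE calls contain symbols outside the simulated universe")
    true_up = {s for s, e in zip(symbols, eff) if e > 0}
    true_down = {s for s, e in zip(symbols, eff) if e < 0}
    called = de_up | de_down
    correct = (de_up & true_up) | (de_down & true_down)
    n_affected = len(true_up) + len(true_down)
    sensitivity = len(correct) / n_affected if n_affected else float("nan")
    fdr = 1.0 - len(correct) / len(called) if called else 0.0
    return {
        "sensitivity": sensitivity,
        "observed_fdr": fdr,
        "n_called": float(len(called)),
        "n_affected": float(n_affected),
    }
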