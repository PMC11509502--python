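"""End-to-end orchestration of the paired proteome comparison.

Stages: binarize -> per-sample counts -> condition-unique detection ->
paired differential expression -> overabundance + PCA -> min-rank list ->
optional mHG enrichment.  All tables are written as TSV, plots as PNG, and
a machine-readable summary as JSON.  Runs are deterministic per seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

import proteopair
from proteopair.appearance import (
    AppearanceMatrix,
    binarize,
    detect_unique_proteins,
    per_sample_protein_counts,
)
from proteopair.enrichment_mhg import enrich_ranked_list
from proteopair.global_structure import fdr_at_threshold, overabundance, pca_binary
from proteopair.io import (
    GeneSetCollection,
    IntensityMatrix,
    PairedDesign,
    read_design,
    read_gene_sets,
    read_intensity_table,
    write_design,
    write_gene_sets,
    write_intensity_table,
    write_results_table,
)
from proteopair.paired_de import (
    DifferentialResultTable,
    min_rank_list,
    run_differential_expression,
    volcano_table,
)
from proteopair.synthetic_data import (
    GroundTruth,
    SyntheticConfig,
    generate_annotation_sets,
    generate_paired_proteome,
)

__all__ = ["RunConfig", "run_pipeline", "summarize"]

logger = logging.getLogger(__name__)

SUMMARY_ALPHAS = (0.01, 0.05)


@dataclass
class RunConfig:
    """Configuration of one pipeline run: real inputs or synthetic data."""

    out_dir: Path
    intensities: Path | None = None
    design: Path | None = None
    gmt: Path | None = None
    synthetic: bool = False
    synthetic_config: SyntheticConfig | None = None
    id_column: str = "Protein IDs"
    min_fraction: float = 0.4
    transform: str = "raw"
    make_plots: bool = True
    seed: int = 0
    extra_flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        has_real = self.intensities is not None or self.design is not None
        if self.synthetic and has_real:
            raise ValueError("give either real input paths or synthetic=True, not both")
        if not self.synthetic and (self.intensities is None or self.design is None):
            raise ValueError("real runs need both --intensities and --design")


def _setup_logging(out_dir: Path) -> None:
    handler = logging.FileHandler(out_dir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("proteopair")
    root.setLevel(logging.INFO)
    root.addHandler(handler)


def summarize(
    a: AppearanceMatrix,
    d: PairedDesign,
    unique_records,
    de: DifferentialResultTable,
    ranked: list[str],
    truth: GroundTruth | None = None,
) -> dict:
    """Machine-readable run summary mirroring the headline outputs."""
    w_p = de.table["w_p"].to_numpy()
    defined = w_p[~np.isnan(w_p)]
    fdr_block = {}
    for alpha in SUMMARY_ALPHAS:
        observed = int((defined <= alpha).sum())
        fdr = fdr_at_threshold(defined, alpha) if observed else None
        fdr_block[str(alpha)] = {"observed": observed, "fdr_estimate": fdr}
    unique_counts = {c: 0 for c in d.conditions}
    for r in unique_records:
        unique_counts[r.condition] += 1
    summary = {
        "n_proteins": a.n_proteins,
        "n_proteins_observed": int((a.bits.sum(axis=1) > 0).sum()),
        "n_subjects": d.n_subjects,
        "conditions": list(d.conditions),
        "unique_counts": unique_counts,
        "wilcoxon_discoveries": fdr_block,
        "top_min_rank": ranked[:10],
    }
    if truth is not None:
        found = {r.protein_id for r in unique_records}
        summary["planted_unique_recovered"] = {
            d.condition_a: sum(1 for p in truth.unique_a if p in found),
            d.condition_b: sum(1 for p in truth.unique_b if p in found),
        }
        summary["planted_unique_counts"] = {
            d.condition_a: len(truth.unique_a),
            d.condition_b: len(truth.unique_b),
        }
    return summary


def _plot_sample_counts(counts: dict[str, int], d: PairedDesign, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(8, 4))
    samples = d.all_samples()
    ax.bar(range(len(samples)), [counts[s] for s in samples])
    ax.set_xticks(range(len(samples)))
    ax.set_xticklabels(samples, rotation=90, fontsize=6)
    ax.set_ylabel("proteins observed")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def _plot_pca(emb, d: PairedDesign, path: Path) -> None:
    fig = plt.figure(figsize=(6, 5))
    ax = fig.add_subplot(projection="3d")
    cond_of = {d.pairs[s][c]: c for s in d.subjects for c in d.conditions}
    for cond, color in zip(d.conditions, ("tab:orange", "tab:blue")):
        idx = [i for i, s in enumerate(emb.sample_ids) if cond_of.get(s) == cond]
        ax.scatter(*emb.coordinates[idx, :3].T, label=cond, color=color)
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.set_zlabel("PC3")
    ax.legend()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def _plot_overabundance(curve, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve.thresholds, curve.observed, label="observed")
    ax.plot(curve.thresholds, curve.expected, label="expected", linestyle="--")
    ax.set_xscale("log")
    ax.set_xlabel("p-value threshold")
    ax.set_ylabel("proteins")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def _plot_volcano(vt: pd.DataFrame, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(vt["effect"], vt["neg_log10_p"], s=6, alpha=0.5)
    ax.set_xlabel("median paired difference")
    ax.set_ylabel("-log10 p")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def run_pipeline(c: RunConfig) -> dict:
    """Execute the full analysis; returns the run summary dict.

    Any stage failure is re-raised annotated with the stage name.
    """
    out = Path(c.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out)
    logger.info("proteopair %s  seed=%d  min_fraction=%g  transform=%s  flags=%s",
                proteopair.__version__, c.seed, c.min_fraction, c.transform, c.extra_flags)

    stage = "load"
    try:
        truth: GroundTruth | None = None
        gene_sets: GeneSetCollection | None = None
        if c.synthetic:
            sc = c.synthetic_config or SyntheticConfig(seed=c.seed)
            m, d, truth = generate_paired_proteome(sc)
            gene_sets = generate_annotation_sets(truth, sc)
            write_intensity_table(m, out / "intensities.tsv")
            write_design(d, out / "design.csv")
            write_gene_sets(gene_sets, out / "gene_sets.gmt")
            (out / "ground_truth.json").write_text(
                json.dumps(dataclasses.asdict(truth), indent=2)
            )
        else:
            m = read_intensity_table(c.intensities, id_column=c.id_column)
            d = read_design(c.design)
            if c.gmt is not None:
                gene_sets = read_gene_sets(c.gmt)

        stage = "binarize"
        a = binarize(m)
        counts = per_sample_protein_counts(a)
        write_results_table(
            [{"sample_id": s, "n_proteins": n} for s, n in counts.items()],
            out / "per_sample_counts.tsv",
        )

        stage = "unique_detection"
        unique = detect_unique_proteins(a, d, min_fraction=c.min_fraction)
        write_results_table(
            [
                {
                    "protein_id": r.protein_id,
                    "condition": r.condition,
                    "n_present": r.n_present,
                    "fraction": r.fraction,
                    "p_value": r.p_value,
                    "q_value": r.q_value,
                }
                for r in unique
            ],
            out / "unique_proteins.tsv",
            columns=["protein_id", "condition", "n_present", "fraction", "p_value", "q_value"],
        )

        stage = "differential_expression"
        de = run_differential_expression(m, d, transform=c.transform)
        write_results_table(de.table, out / "differential_expression.tsv")

        stage = "global_structure"
        w_p = de.table["w_p"].to_numpy()
        curve = overabundance(w_p[~np.isnan(w_p)])
        write_results_table(
            pd.DataFrame(
                {
                    "threshold": curve.thresholds,
                    "observed": curve.observed,
                    "expected": curve.expected,
                    "ratio": curve.ratio,
                    "fdr_estimate": curve.fdr_estimate,
                }
            ),
            out / "overabundance.tsv",
        )
        emb = pca_binary(a, n_components=3)
        write_results_table(
            pd.DataFrame(
                {
                    "sample_id": emb.sample_ids,
                    "pc1": emb.coordinates[:, 0],
                    "pc2": emb.coordinates[:, 1],
                    "pc3": emb.coordinates[:, 2],
                }
            ),
            out / "pca_embedding.tsv",
        )
        write_results_table(
            pd.DataFrame(
                {
                    "component": [1, 2, 3],
                    "explained_variance_fraction": emb.explained_variance_fractions,
                }
            ),
            out / "pca_explained_variance.tsv",
        )

        stage = "min_rank"
        ranked = min_rank_list(de)
        write_results_table(
            [{"rank": i + 1, "protein_id": p} for i, p in enumerate(ranked)],
            out / "ranked_proteins.tsv",
        )

        stage = "enrichment"
        if gene_sets is not None:
            results = enrich_ranked_list(ranked, gene_sets)
            write_results_table(
                [
                    {
                        "term_id": r.term_id,
                        "description": r.description,
                        "N": r.N,
                        "K": r.K,
                        "n_opt": r.n_opt,
                        "b_opt": r.b_opt,
                        "mhg_score": r.mhg_score,
                        "p_value": r.p_value,
                        "q_value": r.q_value,
                    }
                    for r in results
                ],
                out / "enrichment.tsv",
                columns=["term_id", "description", "N", "K", "n_opt", "b_opt",
                         "mhg_score", "p_value", "q_value"],
            )
        else:
            logger.info("no gene sets supplied; enrichment stage skipped")

        stage = "plots"
        if c.make_plots:
            _plot_sample_counts(counts, d, out / "per_sample_counts.png")
            _plot_pca(emb, d, out / "pca_3d.png")
            _plot_overabundance(curve, out / "overabundance.png")
            _plot_volcano(volcano_table(de, "wilcoxon"), out / "volcano_wilcoxon.png")

        stage = "summary"
        summary = summarize(a, d, unique, de, ranked, truth)
        summary["seed"] = c.seed
        summary["version"] = proteopair.__version__
        summary["min_fraction"] = c.min_fraction
        summary["transform"] = c.transform
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
        return summary
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
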