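"""End-to-end orchestration of the expression-signature and clonality
analyses, with deterministic manifests.

The expression chain runs differential selection -> cluster aggregation ->
cross-species signature -> LPS classification; the clonality chain runs
(read merging -> demultiplexing ->) clonotype aggregation -> top-clone
frequencies -> dominant isoform matching -> group comparison.  Every stage
writes its outputs into the configured directory and the manifest records
a content hash per file, so identical config + inputs + seed reproduce
identical manifests.

One global seed is fanned out to per-stage child seeds by fixed offsets.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import aggclust, clonality, diffexpr, synthio, wrightlps, xspecies
from .config import PipelineConfig
from .matrix import ExpressionMatrix

__all__ = ["run_expression_pipeline", "run_clonality_pipeline", "simulate_inputs"]

log = logging.getLogger(__name__)

# fixed per-stage seed offsets (children stay below 2**31)
SEED_KMEANS = 11
SEED_SIM_EXPR = 23
SEED_SIM_VALID = 37
SEED_SIM_REP = 41


def _child_seed(seed: int, offset: int) -> int:
    return (int(seed) * 1_000 + offset) % (2**31 - 1)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _manifest(outdir: Path, stage_files: dict[str, list[Path]], config: PipelineConfig) -> dict:
    manifest = {
        "stages": {
            stage: {p.name: _sha256(p) for p in files}
            for stage, files in stage_files.items()
        },
        "config": config.to_dict(),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _binary_positive(matrix: ExpressionMatrix, positive: str) -> ExpressionMatrix:
    """Relabel a multi-entity cohort as positive class vs pooled rest."""
    relabeled = {
        s: (positive if c == positive else "rest")
        for s, c in matrix.class_of_sample.items()
    }
    return ExpressionMatrix(matrix.values.copy(), matrix.species, relabeled)


def _contrast(matrix: ExpressionMatrix, a: str | None, b: str | None) -> tuple[str, str]:
    classes = matrix.classes()
    if len(classes) < 2:
        raise ValueError("matrix has fewer than 2 classes")
    return a or classes[0], b or classes[1]


def run_expression_pipeline(config: PipelineConfig, outdir: Path | str | None = None) -> dict:
    """Run DE -> aggregation -> signature -> LPS; return the manifest."""
    config.validate()
    p = config.paths
    for name in ("mouse_matrix", "mouse_annotations", "human_matrix", "human_annotations"):
        value = getattr(p, name)
        if value is None or not Path(value).exists():
            raise FileNotFoundError(f"paths.{name} missing or unreadable: {value}")
    if p.validation_matrix is not None and p.validation_annotations is None:
        raise FileNotFoundError("paths.validation_annotations required with validation_matrix")

    out = Path(outdir or p.outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.echo(out)
    stage_files: dict[str, list[Path]] = {}

    mouse = ExpressionMatrix.from_tsv(p.mouse_matrix, p.mouse_annotations)
    human = ExpressionMatrix.from_tsv(p.human_matrix, p.human_annotations)

    # --- stage 1: mouse differential expression -------------------------
    dx = config.diffexpr
    ga, gb = _contrast(mouse, dx.group_a, dx.group_b)
    log.info("[diffexpr] mouse contrast %s vs %s", ga, gb)
    mouse_de = diffexpr.differential_table(mouse, ga, gb, dx.prior_df, dx.prior_var)
    mouse_de = diffexpr.select_de(
        mouse_de, dx.fc_threshold, dx.alpha, dx.heterogeneity_quantile
    )
    de_path = out / "mouse_de.tsv"
    mouse_de.to_csv(de_path, sep="\t")
    stage_files["diffexpr"] = [de_path]
    selected = list(mouse_de.index[mouse_de["selected"]])
    log.info("[diffexpr] %d genes selected", len(selected))
    if len(selected) < 3:
        raise RuntimeError("diffexpr: fewer than 3 selected genes; aborting")

    # --- stage 2: cluster aggregation -----------------------------------
    ac = config.aggclust
    k_init = ac.k_init
    if len(selected) < k_init:
        k_init = max(2, len(selected) // 2)
        log.info("[aggclust] lowering k_init to %d (%d selected genes)", k_init, len(selected))
    state = aggclust.initial_kmeans(
        mouse.subset_genes(selected), k_init=k_init,
        seed=_child_seed(config.seed, SEED_KMEANS), restarts=ac.restarts,
    )
    state = aggclust.aggregate(
        state, reference_mode=ac.reference_mode, matrix=mouse, group_contrast=(ga, gb)
    )
    assign_path = out / "clusters.tsv"
    state.assignment.rename("cluster").to_frame().rename_axis("gene_id").to_csv(
        assign_path, sep="\t"
    )
    trace_path = out / "merge_trace.tsv"
    aggclust.trace_table(state).to_csv(trace_path, sep="\t", index=False)
    heatmap_path = out / "cluster_heatmap.png"
    aggclust.plot_cluster_heatmap(state, heatmap_path)
    stage_files["aggclust"] = [assign_path, trace_path]
    log.info("[aggclust] k_star = %s aggregated clusters", state.k_star)

    # --- stage 3: cross-species signature -------------------------------
    positive = config.lps.positive_class or human.classes()[1]
    human_bin = _binary_positive(human, positive)
    human_de = diffexpr.differential_table(
        human_bin, "rest", positive, dx.prior_df, dx.prior_var
    )
    human_de = diffexpr.select_de(
        human_de, dx.fc_threshold, dx.alpha, dx.heterogeneity_quantile
    )
    pairs = xspecies.map_orthologs(selected, list(human.gene_ids))
    signature = xspecies.coherent_signature(
        mouse_de.loc[selected], human_de, pairs
    )
    sig_path = out / "signature.tsv"
    signature.to_tsv(sig_path)
    overlap_path = out / "signature_overlap.json"
    xspecies.overlap_counts(signature, overlap_path)
    coherency = (
        xspecies.branch_coherency(mouse, human_bin, signature, (ga, gb), ("rest", positive))
        if len(signature) >= 4
        else float("nan")
    )
    stage_files["xspecies"] = [sig_path, overlap_path]
    log.info("[xspecies] signature size %d, branch coherency %.3f", len(signature), coherency)

    # --- stage 4: LPS classifier ----------------------------------------
    lc = config.lps
    labels = {s: c == positive for s, c in human.class_of_sample.items()}
    sig_genes = signature.human_genes()
    if len(sig_genes) < 2:
        raise RuntimeError("wrightlps: signature too small to fit a classifier")
    model = wrightlps.fit_lps(
        human, labels, sig_genes, p_hi=lc.p_hi, p_lo=lc.p_lo, positive_class=positive
    )
    if lc.max_genes is not None:
        sig_genes, model = wrightlps.refine_predictor(
            human, labels, sig_genes, max_genes=lc.max_genes, p_hi=lc.p_hi, p_lo=lc.p_lo
        )
    model_path = out / "lps_model.json"
    model.to_json(model_path)
    stage_files["wrightlps"] = [model_path]

    report = {
        "n_selected": len(selected),
        "k_star": state.k_star,
        "signature_size": len(signature),
        "signature_up": signature.n_up,
        "signature_down": signature.n_down,
        "branch_coherency": coherency,
        "lps_genes": len(sig_genes),
    }

    if p.validation_matrix is not None:
        validation = ExpressionMatrix.from_tsv(p.validation_matrix, p.validation_annotations)
        preds = wrightlps.predict_table(model, validation)
        preds["true_class"] = [
            validation.class_of_sample[s] for s in preds["sample_id"]
        ]
        pred_path = out / "validation_predictions.tsv"
        preds.to_csv(pred_path, sep="\t", index=False)
        stage_files["wrightlps"].append(pred_path)
        pos_mask = preds["true_class"] == positive
        if pos_mask.any():
            report["min_posterior_true_positive"] = float(
                preds.loc[pos_mask, "posterior"].min()
            )
            report["n_validation_positive_called"] = int(
                (preds.loc[pos_mask, "call"] == "WM").sum()
            )

    report_path = out / "expression_report.json"
    report_path.write_text(json.dumps(report, indent=1, sort_keys=True))
    stage_files["report"] = [report_path]
    return _manifest(out, stage_files, config)


def run_clonality_pipeline(config: PipelineConfig, outdir: Path | str | None = None) -> dict:
    """Run the repertoire clonality analysis; return the manifest."""
    config.validate()
    p = config.paths
    cc = config.clonality
    out = Path(outdir or p.outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.echo(out)
    stage_files: dict[str, list[Path]] = {}

    if p.airr_table is not None:
        log.info("[clonality] AIRR input; merging/demultiplexing skipped")
        airr = pd.read_csv(p.airr_table, sep="\t")
        if airr.empty:
            raise ValueError("empty AIRR table")
        table = clonality.build_clonotypes(airr)
    else:
        for name in ("fastq_r1", "fastq_r2", "barcode_table", "primer_table"):
            value = getattr(p, name)
            if value is None or not Path(value).exists():
                raise FileNotFoundError(f"paths.{name} missing or unreadable: {value}")
        merged = []
        for r1, r2 in clonality.read_fastq_pairs(p.fastq_r1, p.fastq_r2):
            m = clonality.merge_read_pair(
                r1, r2, min_overlap=cc.min_overlap,
                max_mismatch_density=cc.max_mismatch_density,
            )
            if m is not None:
                merged.append(m)
        annotated, tally = clonality.demultiplex(
            merged,
            clonality.load_barcode_table(p.barcode_table),
            clonality.load_primer_table(p.primer_table),
        )
        log.info("[clonality] demultiplex tally %s", tally)
        table = clonality.build_clonotypes(annotated)

    report = clonality.top_clone_frequencies(table, n_top=cc.n_top)
    table_path = out / "clonotypes.tsv"
    table.to_csv(table_path, sep="\t", index=False)
    top_path = out / "top_clones.tsv"
    report.to_frame().to_csv(top_path, sep="\t", index=False)
    stage_files["clonotypes"] = [table_path, top_path]

    samples = sorted(table["sample_id"].unique())
    chains = sorted(table["chain"].unique())
    matches = {}
    for sample in samples:
        for chain in chains:
            try:
                matches[f"{sample}|{chain}"] = clonality.dominant_isoform_match(
                    report, sample, chain
                )
            except KeyError:
                continue

    summary: dict = {"dominant_isoform_match": matches}
    if p.sample_groups is not None:
        groups = pd.read_csv(p.sample_groups, sep="\t")
        group_of = dict(zip(groups["sample_id"], groups["group"]))
        names = sorted(set(group_of.values()))
        if len(names) == 2:
            g0, g1 = names
            pvals = {}
            for chain in chains:
                for isoform in sorted(table["isoform"].unique()):
                    x, y = [], []
                    for (s, c, iso), lib in report.libraries.items():
                        if c != chain or iso != isoform:
                            continue
                        freq = lib["top_clones"][0][1]
                        (x if group_of.get(s) == g0 else y).append(freq)
                    if x and y:
                        pvals[f"{chain}|{isoform}"] = clonality.ranksum_exact(
                            x, y, "two-sided"
                        )
            summary["ranksum_p"] = pvals
            summary["groups"] = {"x": g0, "y": g1}
    summary_path = out / "clonality_summary.json"
    summary_path.write_text(json.dumps(summary, indent=1, sort_keys=True))
    stage_files["summary"] = [summary_path]
    return _manifest(out, stage_files, config)


# ---------------------------------------------------------------------------
# Synthetic input generation (study-shaped defaults)
# ---------------------------------------------------------------------------

MOUSE_CLASSES = [("WT", 3), ("MUT", 4)]
HUMAN_REFERENCE_CLASSES = [("NT", 4), ("WM", 7)]
VALIDATION_CLASSES = [
    ("CLL", 19), ("WM_L265P", 15), ("NMZL", 12), ("WM_WT", 5), ("FCL", 4), ("NT", 3)
]


def simulate_inputs(
    outdir: Path | str,
    seed: int = 0,
    signature_size: int = 300,
    n_background: int = 1700,
    discordance_rate: float = 0.05,
    effect: float = 2.0,
    noise_sd: float = 0.5,
    n_repertoire_reads: int = 2000,
    with_fastq: bool = False,
) -> dict[str, Path]:
    """Generate a full study-shaped synthetic input set on disk.

    Cohort shapes follow the emulated study: 3 + 4 mouse spleens, an
    11-sample human reference, a 58-sample multi-entity validation cohort,
    and 5 + 6 repertoire samples clonal in the mu chain only.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    mouse, human, truth = synthio.simulate_paired_species(
        signature_size, discordance_rate, MOUSE_CLASSES, HUMAN_REFERENCE_CLASSES,
        effect=effect, noise_sd=noise_sd, seed=_child_seed(seed, SEED_SIM_EXPR),
        n_background=n_background, human_positive_class="WM",
    )
    _, validation, _ = synthio.simulate_paired_species(
        signature_size, 0.0, MOUSE_CLASSES, VALIDATION_CLASSES,
        effect=effect, noise_sd=noise_sd, seed=_child_seed(seed, SEED_SIM_VALID),
        n_background=n_background, human_positive_class="WM_L265P",
    )
    paths = {}
    for name, matrix in (
        ("mouse", mouse), ("human", human), ("validation", validation)
    ):
        m = out / f"{name}_matrix.tsv"
        a = out / f"{name}_annotations.tsv"
        matrix.to_tsv(m, a)
        paths[f"{name}_matrix"], paths[f"{name}_annotations"] = m, a
    truth.to_json(out / "expression_truth.json")

    rng = np.random.default_rng(_child_seed(seed, SEED_SIM_REP))
    samples = [(f"ctrl_{i + 1}", False, 0.0) for i in range(5)] + [
        (f"tum_{i + 1}", True, float(rng.uniform(0.4, 0.8))) for i in range(6)
    ]
    rep_table, rep_truth = synthio.simulate_repertoire(
        samples, n_reads=n_repertoire_reads, seed=_child_seed(seed, SEED_SIM_REP),
        fastq_dir=out / "fastq" if with_fastq else None,
    )
    airr_path = out / "repertoire_airr.tsv"
    rep_table.to_csv(airr_path, sep="\t", index=False)
    paths["airr_table"] = airr_path
    rep_truth.to_json(out / "repertoire_truth.json")
    groups = pd.DataFrame(
        {
            "sample_id": [s for s, *_ in samples],
            "group": ["control"] * 5 + ["tumor"] * 6,
        }
    )
    groups_path = out / "sample_groups.tsv"
    groups.to_csv(groups_path, sep="\t", index=False)
    paths["sample_groups"] = groups_path
    return paths
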