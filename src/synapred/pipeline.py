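"""End-to-end orchestration: simulate -> preprocess -> train -> classify -> evaluate.

``run_all`` executes every stage in order, writes all artifacts under the
output directory, and returns a manifest with the gene accounting at each
stage (total -> expressed -> training / classified), cross-validation
reports, sweep counts, enrichment, tissue-specificity and homolog-overlap
results.  Every output file header carries the run seed and a hash of the
configuration, and a rerun with the same seed is byte-identical.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as sio
from .classifiers import ClassifierSpec, CVReport, MODELS, cross_validate, grid_search_svm, score_all
from .consensus import DEFAULT_THRESHOLDS, coincidence, consensus_catalogue, final_catalogue, sweep, threshold_catalogue
from .enrichment import enrich, enrichment_by_threshold
from .preprocess import filter_expressed, normalize
from .simulate import PLANTED_TERM, SyntheticConfig, generate_all
from .tissue_homology import gtsde, gtsde_proportions, random_list_null, synaptic_homolog_overlap
from .trainset import build_training_set

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration of a full run: either real-input paths or a synthetic config."""

    synthetic: SyntheticConfig | None = None
    expression_path: str | None = None
    positives_path: str | None = None
    tissue_path: str | None = None
    gmt_path: str | None = None
    homology_path: str | None = None
    human_synaptic_path: str | None = None
    synapse_terms_path: str | None = None
    spec: ClassifierSpec = field(default_factory=ClassifierSpec)
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    grid_search: bool = True
    ratio_max: float = 0.05
    fpkm_min: float = 25.0
    p_max: float = 1e-4
    q_max: float = 1e-3
    high_min: float = 4.0
    low_max: float = 1.0
    null_reps: int = 100
    seed: int = 0
    outdir: str = "synapred_out"

    def validate(self) -> "PipelineConfig":
        if self.synthetic is None and self.expression_path is None:
            raise ValueError(
                "either a synthetic config or real input paths must be provided"
            )
        if list(self.thresholds) != sorted(self.thresholds):
            raise ValueError("thresholds must be ascending")
        return self

    def hash(self) -> str:
        # scientific configuration only: where outputs land is not part of it
        payload = {
            k: (dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v)
            for k, v in dataclasses.asdict(self).items()
            if k != "outdir"
        }
        return hashlib.sha1(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        synth = raw.pop("synthetic", None)
        spec = raw.pop("spec", None)
        cfg = cls(**raw)
        if synth is not None:
            cfg.synthetic = SyntheticConfig(**synth) if isinstance(synth, dict) else SyntheticConfig()
        if spec is not None:
            cfg.spec = ClassifierSpec(**spec)
        if "thresholds" not in raw:
            cfg.thresholds = DEFAULT_THRESHOLDS
        cfg.thresholds = tuple(cfg.thresholds)
        return cfg


def _load_inputs(config: PipelineConfig, outdir: Path, meta: dict):
    """Either generate the synthetic inputs (writing them out) or read files."""
    if config.synthetic is not None:
        synth = dataclasses.replace(config.synthetic, seed=config.seed)
        data = generate_all(synth)
        sio.write_expression(data.expression, outdir / "expression.tsv", meta)
        sio.write_tissue_table(data.tissue, outdir / "tissue.tsv", meta)
        sio.write_gene_list(data.positives, outdir / "positives.txt", meta)
        sio.write_gmt(data.gene_sets, outdir / "annotations.gmt")
        sio.write_homology(data.homology, outdir / "homology.tsv", meta)
        sio.write_gene_list(data.human_synaptic, outdir / "human_synaptic.txt", meta)
        sio.write_gene_list(data.synapse_terms, outdir / "synapse_terms.txt", meta)
        data.truth.table.to_csv(outdir / "truth.tsv", sep="\t")
        return (
            data.expression,
            set(data.positives),
            data.tissue,
            data.gene_sets,
            data.homology,
            data.human_synaptic,
            data.synapse_terms,
        )
    expression = sio.read_expression(config.expression_path)
    positives = set(sio.read_gene_list(config.positives_path))
    tissue = sio.read_tissue_table(config.tissue_path)
    gene_sets = sio.read_gmt(config.gmt_path) if config.gmt_path else {}
    homology = sio.read_homology(config.homology_path) if config.homology_path else {}
    human_synaptic = (
        set(sio.read_gene_list(config.human_synaptic_path))
        if config.human_synaptic_path
        else set()
    )
    synapse_terms = (
        set(sio.read_gene_list(config.synapse_terms_path))
        if config.synapse_terms_path
        else {PLANTED_TERM}
    )
    return expression, positives, tissue, gene_sets, homology, human_synaptic, synapse_terms


def run_all(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns (and writes) the run manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {"seed": config.seed, "config_hash": config.hash()}

    (
        expression,
        positives,
        tissue,
        gene_sets,
        homology,
        human_synaptic,
        synapse_terms,
    ) = _load_inputs(config, outdir, meta)

    # preprocessing: drop adult-only / silent genes, normalize stage profiles
    expressed = filter_expressed(expression)
    profiles = normalize(expression, expressed)
    sio.write_tsv(profiles, outdir / "normalized_profiles.tsv", meta)

    # training set from the two biological criteria
    training, classification = build_training_set(
        positives, expression, tissue, expressed,
        ratio_max=config.ratio_max, fpkm_min=config.fpkm_min,
    )
    labels = training.labels()
    train_profiles = profiles.loc[labels.index]
    sio.write_gene_list(training.negatives, outdir / "negatives.txt", meta)

    # model tuning + 10-fold cross-validation
    spec = config.spec
    if config.grid_search:
        c_star, gamma_star, grid_err = grid_search_svm(
            train_profiles, labels,
            grid_c=spec.svm_grid_c, grid_gamma=spec.svm_grid_gamma,
            seed=config.seed,
        )
        spec = dataclasses.replace(spec, svm_c=c_star, svm_gamma=gamma_star)
        logger.info("SVM grid search: C=%g gamma=%g (CV error %.4f)", c_star, gamma_star, grid_err)
    cv_reports: dict[str, CVReport] = {
        m: cross_validate(m, train_profiles, labels, spec, seed=config.seed)
        for m in MODELS
    }

    # score the classification set
    class_profiles = profiles.loc[sorted(classification)]
    probs = score_all(train_profiles, labels, class_profiles, spec, seed=config.seed)
    sio.write_probabilities(probs, outdir / "probabilities.tsv", meta)

    # threshold sweep, consensus, final catalogue
    sweep_table = sweep(probs, config.thresholds)
    sio.write_tsv(sweep_table, outdir / "sweep.tsv", meta)
    top = config.thresholds[-1]
    consensus_top = consensus_catalogue(probs, top)
    final, excluded = final_catalogue(consensus_top, gene_sets, synapse_terms)
    for cat, name in ((consensus_top, "consensus"), (final, "final_catalogue")):
        sio.write_gene_list(
            cat.genes, outdir / f"{name}.txt",
            {**meta, "model": cat.model, "threshold": cat.threshold},
        )
    coincidences = {
        f"knn_vs_{m}": coincidence(probs, "knn", m, 0.5) for m in ("rf", "svm")
    }

    # enrichment of the top consensus catalogue against the classified universe
    background = set(probs.index)
    enrichment_table = enrich(
        consensus_top.genes, background, gene_sets,
        p_max=config.p_max, q_max=config.q_max, significant_only=False,
    ) if gene_sets else pd.DataFrame()
    if len(enrichment_table):
        sio.write_tsv(enrichment_table.set_index("term"), outdir / "enrichment.tsv", meta)
    planted_series = (
        enrichment_by_threshold(
            probs, config.thresholds, background, gene_sets, PLANTED_TERM
        )
        if PLANTED_TERM in gene_sets
        else None
    )

    # tissue-specific differential expression proportions per threshold
    lists = gtsde(tissue, high_min=config.high_min, low_max=config.low_max)
    gtsde_by_threshold = pd.DataFrame(
        {
            t: gtsde_proportions(consensus_catalogue(probs, t).genes, lists)
            for t in config.thresholds
        }
    )
    sio.write_tsv(gtsde_by_threshold, outdir / "gtsde_proportions.tsv", meta)

    # homolog overlap with resampling null (skipped without a homology map)
    homology_result = None
    if homology:
        count, overlap_table = synaptic_homolog_overlap(
            final.genes, homology, human_synaptic, probs
        )
        null = random_list_null(
            background, len(consensus_top.genes), homology, human_synaptic,
            gene_sets, synapse_terms, reps=config.null_reps, seed=config.seed,
        )
        sio.write_tsv(overlap_table.set_index("gene_id"), outdir / "homolog_overlap.tsv", meta)
        homology_result = {
            "observed": count,
            "null_mean": null.mean,
            "null_interval95": list(null.interval95),
            "null_p99": null.percentile(99),
            "reps": null.reps,
        }
    else:
        logger.info("no homology map supplied; homology stage skipped")

    manifest = {
        "seed": config.seed,
        "config_hash": meta["config_hash"],
        "counts": {
            "total": int(len(expression)),
            "excluded_no_stage_expression": int(len(expression) - len(expressed)),
            "expressed": int(len(expressed)),
            "positives": int(len(training.positives)),
            "negatives": int(len(training.negatives)),
            "training": int(len(training.genes)),
            "classified": int(len(classification)),
            "consensus_top": int(len(consensus_top.genes)),
            "final_catalogue": int(len(final.genes)),
            "excluded_annotated": int(len(excluded)),
        },
        "svm_params": {"C": spec.svm_c, "gamma": spec.svm_gamma},
        "cv": {m: r.to_dict() for m, r in cv_reports.items()},
        "coincidence_at_0.5": coincidences,
        "sweep": {str(t): sweep_table[t].to_dict() for t in sweep_table.columns},
        "planted_term_enrichment": (
            {str(k): (None if pd.isna(v) else float(v)) for k, v in planted_series.items()}
            if planted_series is not None
            else None
        ),
        "gtsde_cns_percent": {
            str(t): (None if pd.isna(v) else float(v))
            for t, v in gtsde_by_threshold.loc["cns"].items()
        },
        "homology": homology_result,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
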