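"""End-to-end pipeline: simulate/load → preprocess → train → perturb →
significance → class signatures → enrichment → figures, with a manifest
recording seeds, configuration and output hashes for reproducibility.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import engine, enrichment, gem_io, stats, synthetic
from .gem_io import ExpressionMatrix

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Configuration for one pipeline run.

    Either ``gem_path``/``labels_path`` point at input files, or
    ``cohort`` describes a synthetic cohort to generate.
    """

    seed: int
    output_dir: str
    target_class: str = "normal-gtex"
    gem_path: str | None = None
    labels_path: str | None = None
    mapping_path: str | None = None
    cohort: synthetic.CohortConfig | None = None
    n_heldout_per_class: int = 10
    sd_multiplier: float = 2.0
    p_cutoff: float = 0.01
    bonferroni_cutoff: float = 1e-5
    quantile_normalize: bool = False
    classifier: engine.ClassifierConfig = field(
        default_factory=engine.ClassifierConfig)
    generator: engine.GeneratorConfig = field(
        default_factory=engine.GeneratorConfig)
    n_terms: int = 50
    enriched_fraction: float = 1.0
    make_plots: bool = True

    def validate(self) -> None:
        if self.gem_path is None and self.cohort is None:
            raise ValueError("config needs either gem/labels paths or a "
                             "synthetic cohort config")
        if self.gem_path is not None and self.labels_path is None:
            raise ValueError("labels_path required with gem_path")


@dataclass
class PipelineResult:
    """In-memory handles to everything a run produced."""

    config: RunConfig
    classifier: engine.ClassifierModel
    generator: engine.GeneratorModel
    heldout_labels: pd.Series
    perturbation: engine.PerturbationResult
    calls: list[stats.SignificanceCall]
    signatures: list[stats.ClassSignature]
    classifier_test_accuracy: float
    perturbation_accuracy: float
    mu_t: pd.Series
    enriched: dict[tuple[str, str], list[enrichment.EnrichmentRecord]]
    truth: synthetic.CohortTruth | None
    manifest: dict


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute every stage; on error, re-raise annotated with the stage
    name, leaving the outputs written so far in place."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "outputs": {}}
    stage = "setup"

    def tick(name: str):
        nonlocal stage
        stage = name
        logger.info("stage %s", name)
        return time.perf_counter()

    try:
        t0 = tick("load")
        truth = None
        if config.cohort is not None:
            cohort_cfg = dataclasses.replace(config.cohort, seed=config.seed)
            gem, labels, truth = synthetic.generate_cohort(cohort_cfg)
            gem_io.write_gem(gem, out / "cohort.tsv")
            gem_io.write_labels(labels, out / "labels.tsv")
            (out / "truth.json").write_text(
                json.dumps(truth.to_dict(), indent=1))
        else:
            gem = gem_io.read_gem(config.gem_path)
            labels = gem_io.align_labels(
                gem_io.read_labels(config.labels_path), gem)
        manifest["stages"]["load"] = round(time.perf_counter() - t0, 3)

        t0 = tick("preprocess")
        if config.quantile_normalize:
            gem = gem_io.quantile_normalize(gem_io.log2_transform(gem))
        manifest["stages"]["preprocess"] = round(time.perf_counter() - t0, 3)

        t0 = tick("split")
        train_gem, train_labels, held_gem, held_labels = \
            engine.split_train_heldout(gem, labels,
                                       config.n_heldout_per_class,
                                       seed=config.seed)
        # minimum-value imputation: held-out filled with the TRAIN minimum
        train_imp = gem_io.impute_missing(train_gem, train_gem)
        held_imp = gem_io.impute_missing(held_gem, train_gem)
        manifest["stages"]["split"] = round(time.perf_counter() - t0, 3)

        t0 = tick("train_classifier")
        clf = engine.train_classifier(train_imp, train_labels,
                                      config.classifier, seed=config.seed)
        clf_acc = engine.classifier_accuracy(clf, held_imp, held_labels)
        engine.save_classifier(clf, out / "classifier.npz")
        manifest["stages"]["train_classifier"] = \
            round(time.perf_counter() - t0, 3)

        t0 = tick("train_generator")
        gen = engine.train_generator(clf, train_imp, train_labels,
                                     config.target_class, config.generator,
                                     seed=config.seed)
        engine.save_generator(gen, out / "generator.npz")
        manifest["stages"]["train_generator"] = \
            round(time.perf_counter() - t0, 3)

        t0 = tick("perturb")
        pert = engine.perturb(gen, held_imp)
        pert_acc = engine.perturbation_accuracy(clf, pert.perturbed,
                                                config.target_class)
        mu_t = engine.target_mean(train_imp, train_labels,
                                  config.target_class)
        gem_io.write_gem(pert.perturbations, out / "perturbations.tsv")
        gem_io.write_gem(pert.perturbed, out / "perturbed.tsv")
        mu_t.to_csv(out / "mu_T.tsv", sep="\t", header=False,
                    float_format="%.6g")
        manifest["stages"]["perturb"] = round(time.perf_counter() - t0, 3)

        t0 = tick("significance")
        calls = stats.call_all_samples(pert.perturbations, held_labels,
                                       config.sd_multiplier)
        lists_dir = out / "significant_genes"
        lists_dir.mkdir(exist_ok=True)
        for c in calls:
            (lists_dir / f"{c.sample_id}_up.txt").write_text(
                "\n".join(sorted(c.up_genes)) + "\n")
            (lists_dir / f"{c.sample_id}_down.txt").write_text(
                "\n".join(sorted(c.down_genes)) + "\n")
        by_class: dict[str, list[stats.SignificanceCall]] = {}
        for c in calls:
            by_class.setdefault(c.class_label, []).append(c)
        signatures = [stats.class_signature(cs, pert.perturbations)
                      for cs in by_class.values()]
        summary = stats.signature_table(signatures)
        summary.to_csv(out / "class_summary.tsv", sep="\t", index=False,
                       float_format="%.6g")
        manifest["stages"]["significance"] = \
            round(time.perf_counter() - t0, 3)

        t0 = tick("enrichment")
        background = gem.gene_ids
        if config.mapping_path is not None:
            mapping = pd.read_csv(config.mapping_path, sep="\t")
            if "gene" not in mapping.columns:
                mapping.columns = ["gene", "term"][:len(mapping.columns)]
        elif truth is not None:
            tm = synthetic.generate_term_mapping(
                truth, config.n_terms, config.enriched_fraction,
                background, seed=config.seed)
            mapping = tm.mapping
            mapping.to_csv(out / "term_mapping.tsv", sep="\t", index=False)
        else:
            mapping = None
        enriched: dict[tuple[str, str],
                       list[enrichment.EnrichmentRecord]] = {}
        if mapping is not None:
            queries = enrichment.build_query_lists(by_class)
            all_records = []
            for (label, direction), query in queries.items():
                recs = enrichment.fisher_enrichment(
                    query, background, mapping,
                    module_name=f"{label}:{direction}")
                kept = enrichment.filter_enriched(
                    recs, config.p_cutoff, config.bonferroni_cutoff)
                enriched[(label, direction)] = kept
                all_records.extend(kept)
            enrichment.records_table(all_records).to_csv(
                out / "enriched_terms.tsv", sep="\t", index=False)
        manifest["stages"]["enrichment"] = \
            round(time.perf_counter() - t0, 3)

        if config.make_plots:
            t0 = tick("plots")
            from . import plots
            sid = pert.sample_ids[0]
            plots.plot_sample_heatmap(
                held_imp.data[sid].rename(sid),
                pert.perturbations.data[sid],
                pert.perturbed.data[sid], mu_t,
                out / f"heatmap_{sid}.png")
            plots.plot_class_bars(summary, "avg_DIR_count",
                                  out / "fig_counts.png",
                                  "Significant genes per sample")
            plots.plot_class_bars(summary, "avg_shared_DIR",
                                  out / "fig_shared.png",
                                  "Shared significant genes per pair")
            plots.plot_class_bars(summary, "avg_jaccard_DIR",
                                  out / "fig_jaccard.png",
                                  "Jaccard proportion per pair")
            plots.plot_embedding(
                gem_io.impute_missing(gem, train_gem), labels,
                pert.perturbed, out / "fig_embedding.png",
                seed=config.seed)
            manifest["stages"]["plots"] = round(time.perf_counter() - t0, 3)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") \
            from exc

    manifest["classifier_test_accuracy"] = clf_acc
    manifest["perturbation_accuracy"] = pert_acc
    manifest["config"] = _config_dict(config)
    for f in sorted(out.rglob("*")):
        if f.is_file() and f.suffix in {".tsv", ".json", ".txt", ".npz"}:
            manifest["outputs"][str(f.relative_to(out))] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  sort_keys=True))

    return PipelineResult(
        config=config, classifier=clf, generator=gen,
        heldout_labels=held_labels, perturbation=pert, calls=calls,
        signatures=signatures, classifier_test_accuracy=clf_acc,
        perturbation_accuracy=pert_acc, mu_t=mu_t, enriched=enriched,
        truth=truth, manifest=manifest)


def _config_dict(config: RunConfig) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (list, tuple)):
            return [enc(v) for v in obj]
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        return obj
    return enc(config)
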