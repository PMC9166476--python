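"""Synthetic labeled expression cohorts with planted class signatures.

The generator emulates the structure of a merged tumor/normal thyroid
cohort: six classes (four tumor stages plus normal tissue from two
repositories), per-gene log2-scale baselines, signed effect genes that are
either shared by all tumor stages or specific to one stage, a batch offset
separating the two normal sources, Gaussian noise, and sporadic missing
values.  A ground-truth ledger records exactly which genes were planted
where, so downstream stages (perturbation, significance calling,
enrichment) can be tested for parameter recovery without external data.

Values are generated directly on the log2 scale, where all planted effects
are additive; :func:`linear_scale` exports 2**x matrices so the
preprocessing path (log2 + quantile normalization) can be exercised
end-to-end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gem_io import ExpressionMatrix

__all__ = [
    "TUMOR_CLASSES",
    "NORMAL_CLASSES",
    "DEFAULT_CLASSES",
    "CohortConfig",
    "ClassTruth",
    "CohortTruth",
    "generate_cohort",
    "generate_term_mapping",
    "TermMappingResult",
    "linear_scale",
]

TUMOR_CLASSES = ("tumor-s1", "tumor-s2", "tumor-s3", "tumor-s4")
NORMAL_CLASSES = ("normal-tcga", "normal-gtex")
DEFAULT_CLASSES = TUMOR_CLASSES + NORMAL_CLASSES


@dataclass(frozen=True)
class CohortConfig:
    """Generation parameters; defaults are the package's standard study
    conditions (desk-scale stand-in for a ~19k-gene tumor/normal cohort).

    All expression-scale parameters are in log2 units.
    """

    n_genes: int = 2000
    classes: tuple[str, ...] = DEFAULT_CLASSES
    n_train_per_class: int = 40
    n_heldout_per_class: int = 10
    baseline_log_mean_range: tuple[float, float] = (2.0, 10.0)
    effect_size: float = 2.0
    n_shared_effect_genes: int = 20
    n_stage_specific_genes: int = 20
    batch_offset: float = 0.5
    n_batch_genes: int = 100
    noise_sd: float = 0.7
    missing_rate: float = 0.001
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0 or self.n_train_per_class <= 0 \
                or self.n_heldout_per_class <= 0:
            raise ValueError("sizes must be positive")
        if self.effect_size < 0 or self.noise_sd <= 0:
            raise ValueError("effect_size must be >= 0 and noise_sd > 0")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be a probability < 1")
        n_tumor = sum(1 for c in self.classes if c.startswith("tumor"))
        planted = self.n_shared_effect_genes \
            + n_tumor * self.n_stage_specific_genes
        if planted >= self.n_genes / 4:
            raise ValueError(
                f"planted genes ({planted}) must be < n_genes/4 "
                f"({self.n_genes / 4:.0f})"
            )
        if planted + self.n_batch_genes > self.n_genes:
            raise ValueError("planted + batch genes exceed n_genes")

    @property
    def n_per_class(self) -> int:
        return self.n_train_per_class + self.n_heldout_per_class


@dataclass(frozen=True)
class ClassTruth:
    """Planted effects for one class: gene → signed log2 effect.

    ``up`` genes sit *above* normal in this class (positive effect), so
    restoring normal expression requires a negative perturbation; ``down``
    genes are the mirror case.
    """

    up: dict[str, float] = field(default_factory=dict)
    down: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class CohortTruth:
    """Ground-truth ledger for a generated cohort."""

    per_class: dict[str, ClassTruth]
    batch_genes: tuple[str, ...]
    shared_up: tuple[str, ...]
    shared_down: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "per_class": {
                c: {"up": t.up, "down": t.down}
                for c, t in self.per_class.items()
            },
            "batch_genes": list(self.batch_genes),
            "shared_up": list(self.shared_up),
            "shared_down": list(self.shared_down),
        }


def generate_cohort(config: CohortConfig
                    ) -> tuple[ExpressionMatrix, pd.Series, CohortTruth]:
    """Generate (expression matrix, labels, truth) for one synthetic cohort.

    Each sample value is ``baseline + class effect + batch offset + noise``
    with the class effect nonzero only on that class's planted genes.
    Deterministic for a fixed config (including seed).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    width = len(str(config.n_genes))
    genes = [f"G{i:0{width}d}" for i in range(1, config.n_genes + 1)]

    tumor_classes = [c for c in config.classes if c.startswith("tumor")]
    n_specific = config.n_stage_specific_genes
    n_planted = config.n_shared_effect_genes + len(tumor_classes) * n_specific
    picked = rng.choice(config.n_genes, size=n_planted + config.n_batch_genes,
                        replace=False)
    planted_idx = picked[:n_planted]
    batch_idx = picked[n_planted:]

    shared = planted_idx[:config.n_shared_effect_genes]
    half = config.n_shared_effect_genes // 2
    shared_up, shared_down = shared[:half], shared[half:]

    per_class: dict[str, ClassTruth] = {}
    offset = config.n_shared_effect_genes
    es = config.effect_size
    for c in config.classes:
        if c not in tumor_classes:
            per_class[c] = ClassTruth()
            continue
        spec = planted_idx[offset:offset + n_specific]
        offset += n_specific
        h = n_specific // 2
        up = {genes[i]: es for i in np.concatenate([shared_up, spec[:h]])}
        down = {genes[i]: -es for i in np.concatenate([shared_down, spec[h:]])}
        per_class[c] = ClassTruth(up=up, down=down)

    lo, hi = config.baseline_log_mean_range
    baseline = rng.uniform(lo, hi, size=config.n_genes)

    sample_ids: list[str] = []
    labels: list[str] = []
    columns = []
    effect_vec = {c: np.zeros(config.n_genes) for c in config.classes}
    gene_pos = {g: i for i, g in enumerate(genes)}
    for c, truth in per_class.items():
        for g, e in truth.up.items():
            effect_vec[c][gene_pos[g]] = e
        for g, e in truth.down.items():
            effect_vec[c][gene_pos[g]] = e
    batch_vec = np.zeros(config.n_genes)
    batch_vec[batch_idx] = config.batch_offset

    for c in config.classes:
        mean = baseline + effect_vec[c]
        if c == "normal-tcga":
            mean = mean + batch_vec
        for i in range(config.n_per_class):
            sid = f"{c}_{i + 1:03d}"
            x = mean + rng.normal(0.0, config.noise_sd, size=config.n_genes)
            sample_ids.append(sid)
            labels.append(c)
            columns.append(x)

    values = np.column_stack(columns)
    if config.missing_rate > 0:
        mask = rng.random(values.shape) < config.missing_rate
        values = np.where(mask, np.nan, values)

    gem = ExpressionMatrix(pd.DataFrame(values, index=genes,
                                        columns=sample_ids))
    label_s = pd.Series(labels, index=sample_ids, name="label")
    truth = CohortTruth(
        per_class=per_class,
        batch_genes=tuple(genes[i] for i in sorted(batch_idx)),
        shared_up=tuple(genes[i] for i in shared_up),
        shared_down=tuple(genes[i] for i in shared_down),
    )
    return gem, label_s, truth


@dataclass(frozen=True)
class TermMappingResult:
    """Gene→term annotation table plus the identity of the planted term."""

    mapping: pd.DataFrame  # columns: gene, term, vocabulary
    planted_term: str
    terms: pd.DataFrame    # columns: term, vocabulary, description


def generate_term_mapping(truth: CohortTruth, n_terms: int,
                          enriched_fraction: float,
                          background: list[str],
                          seed: int) -> TermMappingResult:
    """Build a gene→term table with one term planted on a truth gene set.

    The planted term covers ``enriched_fraction`` of the stage-shared
    tumor-up genes (shared by every tumor class, absent from normals) plus
    random background genes; the remaining terms annotate random background
    genes only.  Every term annotates at least two genes.
    """
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    if not 0.0 < enriched_fraction <= 1.0:
        raise ValueError("enriched_fraction must be in (0, 1]")
    bg = list(dict.fromkeys(background))
    bg_set = set(bg)
    truth_genes = {g for t in truth.per_class.values()
                   for g in (*t.up, *t.down)}
    if not truth_genes <= bg_set:
        raise ValueError("background must contain every truth gene")

    rng = np.random.default_rng(seed)
    rows: list[tuple[str, str, str]] = []

    planted_term = "CUST:0000001"
    target_set = list(truth.shared_up)
    n_cover = max(2, int(np.ceil(enriched_fraction * len(target_set))))
    covered = [target_set[i] for i in
               rng.choice(len(target_set), size=min(n_cover, len(target_set)),
                          replace=False)]
    n_extra = min(30, len(bg))
    extras = [bg[i] for i in rng.choice(len(bg), size=n_extra, replace=False)]
    for g in dict.fromkeys(covered + extras):
        rows.append((g, planted_term, "custom"))

    term_meta = [(planted_term, "custom", "planted tumor-up signature")]
    vocabs = ("GO", "KEGG", "IPR")
    for t in range(1, n_terms):
        acc = f"CUST:{t + 1:07d}"
        vocab = vocabs[t % 3]
        size = int(rng.integers(2, max(3, min(50, len(bg)))))
        members = [bg[i] for i in rng.choice(len(bg), size=size, replace=False)]
        for g in members:
            rows.append((g, acc, vocab))
        term_meta.append((acc, vocab, "random background term"))

    mapping = pd.DataFrame(rows, columns=["gene", "term", "vocabulary"])
    terms = pd.DataFrame(term_meta, columns=["term", "vocabulary",
                                             "description"])
    return TermMappingResult(mapping=mapping, planted_term=planted_term,
                             terms=terms)


def linear_scale(gem: ExpressionMatrix) -> ExpressionMatrix:
    """Export a log2-scale cohort back to the linear (FPKM-like) scale."""
    return ExpressionMatrix(pd.DataFrame(
        np.power(2.0, gem.values), index=gem.data.index,
        columns=gem.data.columns))
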