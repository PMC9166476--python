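"""Adversarial perturbation engine.

Two-phase training, mirroring the standard adversarial-perturbation
workflow for expression data:

1. a fully-connected classifier learns to predict each sample's class
   label from its (log2, normalized) expression vector;
2. with the classifier frozen, a generator network learns an additive
   perturbation ``P(x)`` such that ``x + P(x)`` is classified as a chosen
   *target* class, under a magnitude penalty that keeps perturbations
   minimal.

Sign convention (fixed across the package): a POSITIVE perturbation means
the gene must increase to reach the target (the source under-expresses
it — "tumor-downregulated"); a NEGATIVE perturbation marks a
tumor-upregulated gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gem_io import ExpressionMatrix, align_labels
from .nn import MLP, Adam, softmax, softmax_cross_entropy

__all__ = [
    "ClassifierConfig",
    "GeneratorConfig",
    "ClassifierModel",
    "GeneratorModel",
    "PerturbationResult",
    "split_train_heldout",
    "train_classifier",
    "classifier_accuracy",
    "train_generator",
    "perturb",
    "perturbation_accuracy",
    "target_mean",
    "save_classifier",
    "load_classifier",
    "save_generator",
    "load_generator",
]

_CHECKPOINT_VERSION = 1


@dataclass(frozen=True)
class ClassifierConfig:
    hidden_sizes: tuple[int, ...] = (512, 128)
    learning_rate: float = 1e-3
    epochs: int = 200
    # decoupled L2; keeps the net near the strong linear class boundaries
    # instead of memorising per-sample noise directions
    weight_decay: float = 10.0


@dataclass(frozen=True)
class GeneratorConfig:
    """Generator training hyperparameters.

    The loss is ``CE(classifier(x+P), target) + λ_magnitude·mean(P²)
    + λ_target·mean((x+P−μ_T)²)``.  The target-matching term anchors the
    perturbed profile to the target-class mean; without it the generator
    is free to fool the classifier along non-biological directions.
    ``weight_decay`` and ``input_jitter`` (SD of Gaussian noise added to
    the standardized net input each epoch) regularize the generator so it
    learns the class-level correction pattern rather than memorising
    per-sample noise — memorisation inflates the per-sample significance
    threshold and plants spurious genes shared across samples.
    """

    hidden_sizes: tuple[int, ...] = (512, 128, 512)
    learning_rate: float = 2e-3
    epochs: int = 800
    lambda_magnitude: float = 0.01
    lambda_target: float = 3.0
    weight_decay: float = 3.0
    input_jitter: float = 1.0


@dataclass
class ClassifierModel:
    """Frozen classifier: expression vector → class probability vector.

    Inputs are z-scored per gene with training-set statistics inside the
    model, so callers always pass raw log2-scale expression.
    """

    class_labels: list[str]
    gene_ids: list[str]
    net: MLP
    feature_mean: np.ndarray = None
    feature_scale: np.ndarray = None
    config: ClassifierConfig = field(default_factory=ClassifierConfig)
    seed: int = 0

    def _standardize(self, x: np.ndarray) -> np.ndarray:
        return (x - self.feature_mean) / self.feature_scale

    def predict_proba(self, gem: ExpressionMatrix) -> np.ndarray:
        x = self._standardize(_feature_matrix(self, gem))
        logits, _ = self.net.forward(x)
        return softmax(logits)

    def predict(self, gem: ExpressionMatrix) -> list[str]:
        proba = self.predict_proba(gem)
        return [self.class_labels[i] for i in proba.argmax(axis=1)]


@dataclass
class GeneratorModel:
    """Generator: expression vector → additive perturbation vector.

    The net consumes z-scored features (training statistics inherited
    from the classifier) but emits P directly in log2-expression units.
    """

    target_class: str
    gene_ids: list[str]
    net: MLP
    feature_mean: np.ndarray = None
    feature_scale: np.ndarray = None
    config: GeneratorConfig = field(default_factory=GeneratorConfig)
    seed: int = 0


@dataclass(frozen=True)
class PerturbationResult:
    """Perturbations P and the perturbed matrix X+P (genes × samples)."""

    perturbations: ExpressionMatrix
    perturbed: ExpressionMatrix

    @property
    def sample_ids(self) -> list[str]:
        return self.perturbations.sample_ids


def _require_finite(gem: ExpressionMatrix, what: str) -> np.ndarray:
    vals = gem.values
    if not np.isfinite(vals).all():
        raise ValueError(
            f"{what} contains missing/non-finite values; impute first")
    return vals


def _feature_matrix(model, gem: ExpressionMatrix) -> np.ndarray:
    if gem.gene_ids != model.gene_ids:
        raise ValueError("gene IDs/order do not match the trained model")
    return _require_finite(gem, "expression matrix").T  # samples × genes


def split_train_heldout(gem: ExpressionMatrix, labels: pd.Series,
                        n_heldout_per_class: int, seed: int
                        ) -> tuple[ExpressionMatrix, pd.Series,
                                   ExpressionMatrix, pd.Series]:
    """Randomly remove ``n_heldout_per_class`` samples of every class.

    Returns (train gem, train labels, heldout gem, heldout labels); the
    two sample sets partition the input.  Deterministic under ``seed``.
    """
    labels = align_labels(labels, gem)
    rng = np.random.default_rng(seed)
    heldout: list[str] = []
    for c in sorted(labels.unique()):
        members = [s for s in gem.sample_ids if labels[s] == c]
        if len(members) <= n_heldout_per_class:
            raise ValueError(
                f"class {c!r} has {len(members)} samples; needs more than "
                f"{n_heldout_per_class} to hold out")
        pick = rng.choice(len(members), size=n_heldout_per_class,
                          replace=False)
        heldout.extend(members[i] for i in sorted(pick))
    heldout_set = set(heldout)
    train_ids = [s for s in gem.sample_ids if s not in heldout_set]
    heldout_ids = [s for s in gem.sample_ids if s in heldout_set]
    return (gem.select_samples(train_ids), labels[train_ids],
            gem.select_samples(heldout_ids), labels[heldout_ids])


def train_classifier(gem: ExpressionMatrix, labels: pd.Series,
                     config: ClassifierConfig | None = None,
                     seed: int = 0) -> ClassifierModel:
    """Train the class-label classifier (full-batch Adam, fixed epochs)."""
    config = config or ClassifierConfig()
    labels = align_labels(labels, gem)
    class_labels = sorted(labels.unique())
    if len(class_labels) < 2:
        raise ValueError("training requires at least two classes")
    x_raw = _require_finite(gem, "training matrix").T
    y = np.array([class_labels.index(l) for l in labels])
    mu = x_raw.mean(axis=0)
    scale = x_raw.std(axis=0, ddof=0)
    scale[scale == 0.0] = 1.0  # zero-variance genes pass through centred
    x = (x_raw - mu) / scale

    rng = np.random.default_rng(seed)
    net = MLP((gem.n_genes, *config.hidden_sizes, len(class_labels)), rng)
    opt = Adam(net.params, lr=config.learning_rate,
               weight_decay=config.weight_decay)
    for _ in range(config.epochs):
        logits, caches = net.forward(x)
        _, d_logits = softmax_cross_entropy(logits, y)
        _, grads = net.backward(d_logits, caches)
        opt.step(grads)
    return ClassifierModel(class_labels=class_labels,
                           gene_ids=gem.gene_ids, net=net,
                           feature_mean=mu, feature_scale=scale,
                           config=config, seed=seed)


def classifier_accuracy(model: ClassifierModel, gem: ExpressionMatrix,
                        labels: pd.Series) -> float:
    """Fraction of samples whose argmax class equals the true label."""
    labels = align_labels(labels, gem)
    unknown = set(labels.unique()) - set(model.class_labels)
    if unknown:
        raise ValueError(f"unknown label(s): {sorted(unknown)}")
    pred = model.predict(gem)
    truth = list(labels)
    return float(np.mean([p == t for p, t in zip(pred, truth)]))


def train_generator(classifier: ClassifierModel, gem: ExpressionMatrix,
                    labels: pd.Series, target_class: str,
                    config: GeneratorConfig | None = None,
                    seed: int = 0) -> GeneratorModel:
    """Train the adversarial generator toward ``target_class``.

    Minimises ``CE(classifier(x+P), target) + λ_mag·mean(P²)``
    (optionally plus ``λ_target·mean((x+P−μ_T)²)``) over all training
    samples, with the classifier frozen.
    """
    config = config or GeneratorConfig()
    labels = align_labels(labels, gem)
    if target_class not in classifier.class_labels:
        raise ValueError(f"target class {target_class!r} unknown to classifier")
    if target_class not in set(labels.unique()):
        raise ValueError(f"target class {target_class!r} absent from training labels")
    x = _feature_matrix(classifier, gem)
    n, g = x.shape
    t_idx = classifier.class_labels.index(target_class)
    y_target = np.full(n, t_idx)
    mean, scale = classifier.feature_mean, classifier.feature_scale
    x_std = (x - mean) / scale

    mu_t = None
    if config.lambda_target > 0:
        mu_t = x[np.asarray(labels) == target_class].mean(axis=0)

    rng = np.random.default_rng(seed)
    gen = MLP((g, *config.hidden_sizes, g), rng)
    opt = Adam(gen.params, lr=config.learning_rate,
               weight_decay=config.weight_decay)
    clf_net = classifier.net

    for epoch in range(config.epochs):
        if config.input_jitter > 0:
            x_in = x_std + rng.normal(0.0, config.input_jitter, x_std.shape)
        else:
            x_in = x_std
        p, g_caches = gen.forward(x_in)
        z = x + p
        logits, c_caches = clf_net.forward((z - mean) / scale)
        _, d_logits = softmax_cross_entropy(logits, y_target)
        d_z_std, _ = clf_net.backward(d_logits, c_caches)  # classifier frozen
        d_p = d_z_std / scale + 2.0 * config.lambda_magnitude * p / p.size
        if mu_t is not None:
            d_p = d_p + 2.0 * config.lambda_target * (z - mu_t) / p.size
        _, grads = gen.backward(d_p, g_caches)
        # cosine decay settles the weights instead of leaving them at a
        # random point of the late-training oscillation
        lr_scale = 0.5 * (1.0 + np.cos(np.pi * epoch / config.epochs))
        opt.step(grads, lr_scale=max(lr_scale, 0.02))

    return GeneratorModel(target_class=target_class,
                          gene_ids=classifier.gene_ids, net=gen,
                          feature_mean=mean, feature_scale=scale,
                          config=config, seed=seed)


def perturb(generator: GeneratorModel,
            gem: ExpressionMatrix) -> PerturbationResult:
    """Apply the trained generator to each sample column of ``gem``."""
    x = _feature_matrix(generator, gem)
    x_std = (x - generator.feature_mean) / generator.feature_scale
    p, _ = generator.net.forward(x_std)
    p_df = pd.DataFrame(p.T, index=gem.data.index, columns=gem.data.columns)
    return PerturbationResult(
        perturbations=ExpressionMatrix(p_df),
        perturbed=ExpressionMatrix(gem.data + p_df),
    )


def perturbation_accuracy(classifier: ClassifierModel,
                          perturbed: ExpressionMatrix,
                          target_class: str) -> float:
    """Fraction of perturbed samples the classifier assigns to the target."""
    if perturbed.n_samples == 0:
        raise ValueError("no samples to evaluate")
    if target_class not in classifier.class_labels:
        raise ValueError(f"unknown target class {target_class!r}")
    pred = classifier.predict(perturbed)
    return float(np.mean([p == target_class for p in pred]))


def target_mean(gem: ExpressionMatrix, labels: pd.Series,
                target_class: str) -> pd.Series:
    """Per-gene mean over the target class's training samples (μ_T).

    Missing values are excluded gene-wise rather than imputed.
    """
    labels = align_labels(labels, gem)
    members = [s for s in gem.sample_ids if labels[s] == target_class]
    if not members:
        raise ValueError(f"target class {target_class!r} has no samples")
    mu = gem.data[members].mean(axis=1, skipna=True)
    mu.name = "mu_T"
    return mu


def save_classifier(model: ClassifierModel, path) -> None:
    np.savez(path, version=_CHECKPOINT_VERSION, kind="classifier",
             class_labels=np.asarray(model.class_labels),
             gene_ids=np.asarray(model.gene_ids), seed=model.seed,
             feature_mean=model.feature_mean,
             feature_scale=model.feature_scale,
             **model.net.state_dict())


def load_classifier(path) -> ClassifierModel:
    with np.load(path, allow_pickle=False) as data:
        _check_kind(data, "classifier")
        return ClassifierModel(
            class_labels=[str(c) for c in data["class_labels"]],
            gene_ids=[str(g) for g in data["gene_ids"]],
            net=MLP.from_state(data),
            feature_mean=np.asarray(data["feature_mean"], dtype=float),
            feature_scale=np.asarray(data["feature_scale"], dtype=float),
            seed=int(data["seed"]))


def save_generator(model: GeneratorModel, path) -> None:
    np.savez(path, version=_CHECKPOINT_VERSION, kind="generator",
             target_class=model.target_class,
             gene_ids=np.asarray(model.gene_ids), seed=model.seed,
             feature_mean=model.feature_mean,
             feature_scale=model.feature_scale,
             **model.net.state_dict())


def load_generator(path) -> GeneratorModel:
    with np.load(path, allow_pickle=False) as data:
        _check_kind(data, "generator")
        return GeneratorModel(
            target_class=str(data["target_class"]),
            gene_ids=[str(g) for g in data["gene_ids"]],
            net=MLP.from_state(data),
            feature_mean=np.asarray(data["feature_mean"], dtype=float),
            feature_scale=np.asarray(data["feature_scale"], dtype=float),
            seed=int(data["seed"]))


def _check_kind(data, expected: str) -> None:
    if str(data["kind"]) != expected or int(data["version"]) != _CHECKPOINT_VERSION:
        raise ValueError(f"not a version-{_CHECKPOINT_VERSION} {expected} checkpoint")
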