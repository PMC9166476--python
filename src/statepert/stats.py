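"""Per-sample significance calling and per-class perturbation signatures.

Given a perturbation matrix (genes × perturbed samples), each sample's
significantly perturbed genes are those whose perturbation lies more than
``k`` standard deviations (default 2) from the mean of all perturbation
values for that sample.  Per class, the package then reports:

* commonly perturbed genes — significant in the same direction in every
  sample of the class;
* the average per-sample count of significant genes, with standard error;
* the average number, and Jaccard proportion, of significant genes shared
  between two samples of the same class, over unordered pairs.

Direction naming follows the restore-to-normal convention: a NEGATIVE
perturbation marks a tumor-UPregulated gene (expression must fall to
reach normal); a POSITIVE perturbation marks a tumor-DOWNregulated gene.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gem_io import ExpressionMatrix

__all__ = [
    "SignificanceCall",
    "ClassSignature",
    "call_significant",
    "call_all_samples",
    "commonly_perturbed",
    "class_count_summary",
    "pairwise_shared",
    "shared_proportion",
    "significant_perturbation_stats",
    "class_signature",
    "signature_table",
]

logger = logging.getLogger(__name__)

_DIRECTIONS = ("up", "down")


@dataclass(frozen=True)
class SignificanceCall:
    """One sample's significantly perturbed gene sets.

    ``up_genes``: tumor-upregulated (perturbation < mean − k·SD);
    ``down_genes``: tumor-downregulated (perturbation > mean + k·SD).
    """

    sample_id: str
    class_label: str
    up_genes: frozenset[str]
    down_genes: frozenset[str]
    sample_mean: float
    sample_sd: float

    def genes(self, direction: str) -> frozenset[str]:
        _check_direction(direction)
        return self.up_genes if direction == "up" else self.down_genes


def _check_direction(direction: str) -> None:
    if direction not in _DIRECTIONS:
        raise ValueError(f"direction must be one of {_DIRECTIONS}")


def call_significant(perturbation: pd.Series, sample_id: str,
                     class_label: str,
                     sd_multiplier: float = 2.0) -> SignificanceCall:
    """Flag genes beyond ``sd_multiplier`` population SDs from the sample
    mean, with strict inequalities at the threshold.

    A zero-SD (constant) perturbation vector yields empty sets with a
    logged warning rather than an error.
    """
    vals = perturbation.to_numpy(dtype=float)
    finite = np.isfinite(vals)
    if finite.sum() < 2:
        raise ValueError("perturbation vector needs at least 2 finite values")
    mean = float(vals[finite].mean())
    sd = float(vals[finite].std(ddof=0))
    if sd == 0.0:
        logger.warning("sample %s: zero perturbation SD, no significant genes",
                       sample_id)
        up: frozenset[str] = frozenset()
        down: frozenset[str] = frozenset()
    else:
        hi = mean + sd_multiplier * sd
        lo = mean - sd_multiplier * sd
        genes = perturbation.index.to_numpy()
        down = frozenset(genes[finite & (vals > hi)])
        up = frozenset(genes[finite & (vals < lo)])
    return SignificanceCall(sample_id=sample_id, class_label=class_label,
                            up_genes=up, down_genes=down,
                            sample_mean=mean, sample_sd=sd)


def call_all_samples(perturbations: ExpressionMatrix, labels: pd.Series,
                     sd_multiplier: float = 2.0) -> list[SignificanceCall]:
    """Run :func:`call_significant` on every sample column."""
    calls = []
    for sid in perturbations.sample_ids:
        calls.append(call_significant(perturbations.data[sid], sid,
                                      str(labels[sid]), sd_multiplier))
    return calls


def _one_class(calls: list[SignificanceCall]) -> str:
    if not calls:
        raise ValueError("no significance calls supplied")
    classes = {c.class_label for c in calls}
    if len(classes) > 1:
        raise ValueError(f"calls span multiple classes: {sorted(classes)}")
    return calls[0].class_label


def commonly_perturbed(calls: list[SignificanceCall]
                       ) -> tuple[frozenset[str], frozenset[str]]:
    """Genes significant in the same direction in EVERY sample of a class."""
    _one_class(calls)
    common_up = frozenset.intersection(*(c.up_genes for c in calls))
    common_down = frozenset.intersection(*(c.down_genes for c in calls))
    return common_up, common_down


def _mean_se(values: np.ndarray) -> tuple[float, float]:
    mean = float(values.mean())
    se = float(values.std(ddof=1) / np.sqrt(len(values))) \
        if len(values) > 1 else float("nan")
    return mean, se


def class_count_summary(calls: list[SignificanceCall]
                        ) -> dict[str, float]:
    """Mean and SE of per-sample significant-gene counts, per direction."""
    _one_class(calls)
    if len(calls) < 2:
        raise ValueError("need at least 2 calls for a standard error")
    up = np.array([len(c.up_genes) for c in calls], dtype=float)
    down = np.array([len(c.down_genes) for c in calls], dtype=float)
    avg_up, se_up = _mean_se(up)
    avg_down, se_down = _mean_se(down)
    return {"avg_up_count": avg_up, "se_up_count": se_up,
            "avg_down_count": avg_down, "se_down_count": se_down}


def pairwise_shared(calls: list[SignificanceCall],
                    direction: str) -> tuple[float, float]:
    """Average |A∩B| over unordered within-class sample pairs, with SE."""
    _check_direction(direction)
    _one_class(calls)
    if len(calls) < 2:
        raise ValueError("need at least 2 calls for pairwise statistics")
    sets = [c.genes(direction) for c in calls]
    counts = np.array([len(a & b) for a, b in itertools.combinations(sets, 2)],
                      dtype=float)
    return _mean_se(counts)


def shared_proportion(calls: list[SignificanceCall],
                      direction: str) -> tuple[float, float]:
    """Average Jaccard |A∩B|/|A∪B| over unordered pairs, with SE.

    A pair whose union is empty contributes 0 (logged).
    """
    _check_direction(direction)
    _one_class(calls)
    if len(calls) < 2:
        raise ValueError("need at least 2 calls for pairwise statistics")
    sets = [c.genes(direction) for c in calls]
    props = []
    for a, b in itertools.combinations(sets, 2):
        union = a | b
        if not union:
            logger.info("empty-set pair contributes Jaccard 0")
            props.append(0.0)
        else:
            props.append(len(a & b) / len(union))
    return _mean_se(np.asarray(props))


def significant_perturbation_stats(calls: list[SignificanceCall],
                                   perturbations: ExpressionMatrix,
                                   direction: str) -> tuple[float, float]:
    """Pooled mean and population SD of the perturbation values of all
    (sample, gene) pairs flagged significant in the given direction."""
    _check_direction(direction)
    _one_class(calls)
    pool: list[float] = []
    for c in calls:
        col = perturbations.data[c.sample_id]
        pool.extend(float(col[g]) for g in sorted(c.genes(direction)))
    if not pool:
        logger.warning("no significant genes pooled for direction %s",
                       direction)
        return float("nan"), float("nan")
    arr = np.asarray(pool)
    return float(arr.mean()), float(arr.std(ddof=0))


@dataclass(frozen=True)
class ClassSignature:
    """All per-class summary quantities derived from significance calls."""

    class_label: str
    n_samples: int
    common_up: frozenset[str]
    common_down: frozenset[str]
    avg_up_count: float
    se_up_count: float
    avg_down_count: float
    se_down_count: float
    avg_shared_up: float
    se_shared_up: float
    avg_shared_down: float
    se_shared_down: float
    avg_jaccard_up: float
    se_jaccard_up: float
    avg_jaccard_down: float
    se_jaccard_down: float
    mean_perturbation_up: float
    sd_perturbation_up: float
    mean_perturbation_down: float
    sd_perturbation_down: float


def class_signature(calls: list[SignificanceCall],
                    perturbations: ExpressionMatrix) -> ClassSignature:
    """Assemble every per-class summary for one class's calls."""
    label = _one_class(calls)
    common_up, common_down = commonly_perturbed(calls)
    counts = class_count_summary(calls)
    sh_up = pairwise_shared(calls, "up")
    sh_down = pairwise_shared(calls, "down")
    j_up = shared_proportion(calls, "up")
    j_down = shared_proportion(calls, "down")
    p_up = significant_perturbation_stats(calls, perturbations, "up")
    p_down = significant_perturbation_stats(calls, perturbations, "down")
    return ClassSignature(
        class_label=label, n_samples=len(calls),
        common_up=common_up, common_down=common_down,
        avg_up_count=counts["avg_up_count"],
        se_up_count=counts["se_up_count"],
        avg_down_count=counts["avg_down_count"],
        se_down_count=counts["se_down_count"],
        avg_shared_up=sh_up[0], se_shared_up=sh_up[1],
        avg_shared_down=sh_down[0], se_shared_down=sh_down[1],
        avg_jaccard_up=j_up[0], se_jaccard_up=j_up[1],
        avg_jaccard_down=j_down[0], se_jaccard_down=j_down[1],
        mean_perturbation_up=p_up[0], sd_perturbation_up=p_up[1],
        mean_perturbation_down=p_down[0], sd_perturbation_down=p_down[1],
    )


def signature_table(signatures: list[ClassSignature]) -> pd.DataFrame:
    """Flatten class signatures into one summary row per class."""
    rows = []
    for s in signatures:
        rows.append({
            "class": s.class_label, "n_samples": s.n_samples,
            "n_common_up": len(s.common_up),
            "n_common_down": len(s.common_down),
            "common_up": ",".join(sorted(s.common_up)),
            "common_down": ",".join(sorted(s.common_down)),
            "avg_up_count": s.avg_up_count, "se_up_count": s.se_up_count,
            "avg_down_count": s.avg_down_count,
            "se_down_count": s.se_down_count,
            "avg_shared_up": s.avg_shared_up,
            "se_shared_up": s.se_shared_up,
            "avg_shared_down": s.avg_shared_down,
            "se_shared_down": s.se_shared_down,
            "avg_jaccard_up": s.avg_jaccard_up,
            "se_jaccard_up": s.se_jaccard_up,
            "avg_jaccard_down": s.avg_jaccard_down,
            "se_jaccard_down": s.se_jaccard_down,
            "mean_perturbation_up": s.mean_perturbation_up,
            "sd_perturbation_up": s.sd_perturbation_up,
            "mean_perturbation_down": s.mean_perturbation_down,
            "sd_perturbation_down": s.sd_perturbation_down,
        })
    return pd.DataFrame(rows)
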