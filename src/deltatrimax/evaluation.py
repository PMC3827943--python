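"""Quality measures for tricluster sets.

* affirmation score — Prelic-style average best-match similarity between an
  implanted (ground-truth) set and a recovered set, per mode and combined;
* coverage — percentage of the gene x sample x time index space touched by
  the union of reported triclusters;
* TQI — per-cluster MSR divided by volume (lower is better);
* SDB — each cluster's MSR relative to the excess MSR of size-matched random
  triclusters (lower means stronger departure from background).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .tensor import ExpressionTensor, Tricluster, residue_array

__all__ = [
    "AffirmationResult",
    "QualityReport",
    "EvaluationError",
    "affirmation_score",
    "coverage",
    "tqi",
    "sdb",
    "quality_report",
]

COMBINE_RULES = ("product", "cube_root")


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class AffirmationResult:
    """Per-mode and overall affirmation scores, all in [0, 1]."""

    gene_score: float
    sample_score: float
    time_score: float
    overall: float
    combine_rule: str


@dataclass
class QualityReport:
    coverage: float
    tqi_per_cluster: list[float]
    average_tqi: float
    sdb: float
    r_random: int
    sdb_flags: list[int] = field(default_factory=list)  # nonpositive denominators


def _jaccard(a: Sequence[int], b: Sequence[int]) -> float:
    sa, sb = set(a), set(b)
    return len(sa & sb) / len(sa | sb)


def _mode_score(t1: Sequence[Tricluster], t2: Sequence[Tricluster],
                attr: str) -> float:
    total = 0.0
    for a in t1:
        total += max(_jaccard(getattr(a, attr), getattr(b, attr)) for b in t2)
    return total / len(t1)


def affirmation_score(implanted: Sequence[Tricluster],
                      found: Sequence[Tricluster],
                      combine_rule: str = "product") -> AffirmationResult:
    """Average best-match similarity of ``implanted`` against ``found``.

    Per mode, each implanted tricluster is matched with the found tricluster
    maximizing the Jaccard index of that mode's index sets, and the matches
    are averaged.  The overall score is the product of the three mode scores
    (``combine_rule="product"``, the printed definition) or its cube root
    (``"cube_root"``, the geometric-mean variant).  Equals 1 when the two
    sets coincide.
    """
    if combine_rule not in COMBINE_RULES:
        raise EvaluationError(f"combine_rule must be one of {COMBINE_RULES}")
    if not implanted:
        raise EvaluationError("affirmation score undefined for an empty "
                              "reference set")
    if not found:
        return AffirmationResult(0.0, 0.0, 0.0, 0.0, combine_rule)
    g = _mode_score(implanted, found, "gene_idx")
    c = _mode_score(implanted, found, "sample_idx")
    t = _mode_score(implanted, found, "time_idx")
    overall = g * c * t
    if combine_rule == "cube_root":
        overall = overall ** (1.0 / 3.0)
    return AffirmationResult(g, c, t, overall, combine_rule)


def coverage(found: Sequence[Tricluster],
             tensor_dims: tuple[int, int, int]) -> float:
    """Percent of the index space spanned by the unions of each mode."""
    G, C, T = tensor_dims
    if min(G, C, T) < 1:
        raise EvaluationError("tensor dims must be positive")
    if not found:
        return 0.0
    g = len(set().union(*(tc.gene_idx for tc in found)))
    c = len(set().union(*(tc.sample_idx for tc in found)))
    t = len(set().union(*(tc.time_idx for tc in found)))
    return 100.0 * (g * c * t) / (G * C * T)


def tqi(found: Sequence[Tricluster]) -> tuple[list[float], float]:
    """Per-cluster MSR/volume and its arithmetic mean (lower is better)."""
    per = []
    for tc in found:
        if tc.msr is None:
            raise EvaluationError("tricluster has no recorded MSR")
        per.append(tc.msr / tc.volume)
    return per, float(np.mean(per)) if per else 0.0


def _random_msr(values: np.ndarray, shape: tuple[int, int, int],
                rng: np.random.Generator) -> float:
    G, C, T = values.shape
    I = rng.choice(G, size=shape[0], replace=False)
    J = rng.choice(C, size=shape[1], replace=False)
    K = rng.choice(T, size=shape[2], replace=False)
    sub = values[np.ix_(I, J, K)]
    return float((residue_array(sub) ** 2).mean())


def sdb(found: Sequence[Tricluster], tensor: ExpressionTensor,
        r: int = 100, seed: int = 0) -> float:
    """Statistical difference from background.

    For each found tricluster, ``r`` random triclusters with the same mode
    cardinalities are drawn from the tensor and the term
    ``MSR_i / (mean RMSR - MSR_i)`` accumulated; the mean over clusters is
    returned.  A nonpositive denominator (cluster no better than background)
    triggers a warning and the term is reported as computed.
    """
    if r < 1:
        raise EvaluationError("r must be >= 1")
    if not found:
        raise EvaluationError("no triclusters to score")
    rng = np.random.default_rng(seed)
    terms = []
    for i, tc in enumerate(found):
        if tc.msr is None:
            raise EvaluationError("tricluster has no recorded MSR")
        rmsr = np.mean([_random_msr(tensor.values, tc.shape, rng)
                        for _ in range(r)])
        denom = rmsr - tc.msr
        if denom <= 0:
            warnings.warn(f"tricluster {i}: mean random MSR {rmsr:.4g} does "
                          f"not exceed cluster MSR {tc.msr:.4g}; SDB term is "
                          "unreliable", stacklevel=2)
        terms.append(_sdb_term(tc.msr, denom))
    return float(np.mean(terms))


def _sdb_term(msr_i: float, denom: float) -> float:
    if msr_i == 0:
        return 0.0
    if denom == 0:
        return float("inf")
    return msr_i / denom


def quality_report(found: Sequence[Tricluster], tensor: ExpressionTensor,
                   r: int = 100, seed: int = 0) -> QualityReport:
    """Coverage, TQI and SDB of a result set in one report."""
    per, avg = tqi(found)
    rng = np.random.default_rng(seed)
    terms, flags = [], []
    for i, tc in enumerate(found):
        rmsr = np.mean([_random_msr(tensor.values, tc.shape, rng)
                        for _ in range(r)])
        denom = rmsr - tc.msr
        if denom <= 0:
            flags.append(i)
        terms.append(_sdb_term(tc.msr, denom))
    return QualityReport(
        coverage=coverage(found, tensor.shape),
        tqi_per_cluster=per,
        average_tqi=avg,
        sdb=float(np.mean(terms)) if terms else 0.0,
        r_random=r,
        sdb_flags=flags,
    )
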