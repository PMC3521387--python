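"""Scoring of ranked-pair output against simulation truth, and ROC curves.

Three per-dataset correctness rules cover the validation scenarios:

* single interacting pair — the true pair must be ranked first;
* multiple independent pairs — every disease SNP must appear somewhere in
  the top five ranked pairs;
* higher-order network — take the maximal prefix of the ranking in which
  every pair contains at least one disease SNP (the "top block"); correct
  iff that prefix covers every disease SNP.  This is the strictest reading
  of "all consecutive top pairs": a single interleaved background pair
  terminates the block.

Accuracy over replicates is the percentage of datasets judged correct.
ROC curves sweep a rho_diff threshold t: sensitivity is the fraction of
true interacting pairs scoring >= t, specificity the fraction of all other
(valid) pairs scoring < t; pairs joining a disease SNP with a background
SNP count as negatives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .prioritize import RankedPairs

__all__ = [
    "TruthRecord",
    "AccuracyResult",
    "RocResult",
    "truth_from_record",
    "correct_single_pair",
    "correct_multi_pair",
    "correct_higher_order",
    "is_correct",
    "accuracy_over_replicates",
    "roc_curve",
]

SCENARIOS = ("single_pair", "single_pair_marginal", "multi_pair", "higher_order")


@dataclass
class TruthRecord:
    """Ground truth of one simulated dataset."""

    disease_snp_indices: frozenset[int]
    true_pairs: frozenset[tuple[int, int]]  # each stored sorted (i < j)
    scenario: str

    def __post_init__(self) -> None:
        self.disease_snp_indices = frozenset(self.disease_snp_indices)
        self.true_pairs = frozenset(tuple(sorted(p)) for p in self.true_pairs)
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        for a, b in self.true_pairs:
            if a not in self.disease_snp_indices or b not in self.disease_snp_indices:
                raise ValueError(f"pair ({a},{b}) endpoint not a disease SNP")


def truth_from_record(truth: dict) -> TruthRecord:
    """Build a TruthRecord from a simulator truth dict (or loaded JSON)."""
    return TruthRecord(
        disease_snp_indices=frozenset(truth["disease_snp_indices"]),
        true_pairs=frozenset(tuple(p) for p in truth["true_pairs"]),
        scenario=truth["scenario"],
    )


def correct_single_pair(ranked: RankedPairs, truth: TruthRecord) -> bool:
    """True iff the rank-1 pair is exactly the (unordered) true pair."""
    if not ranked.entries:
        raise ValueError("empty ranking")
    if len(truth.true_pairs) != 1:
        raise ValueError("single-pair rule needs exactly one true pair")
    (true_pair,) = truth.true_pairs
    top = tuple(sorted(ranked.pairs[0]))
    return top == true_pair


def correct_multi_pair(ranked: RankedPairs, truth: TruthRecord) -> bool:
    """True iff every disease SNP appears in at least one of the top 5 pairs."""
    if len(ranked.entries) < 5:
        raise ValueError("multi-pair rule needs at least 5 ranked pairs")
    seen: set[int] = set()
    for i, j in ranked.pairs[:5]:
        seen.update((i, j))
    return truth.disease_snp_indices <= seen


def correct_higher_order(ranked: RankedPairs, truth: TruthRecord) -> bool:
    """True iff the maximal all-disease-SNP prefix covers every disease SNP."""
    if not ranked.entries:
        raise ValueError("empty ranking")
    covered: set[int] = set()
    for i, j in ranked.pairs:
        if i not in truth.disease_snp_indices and j not in truth.disease_snp_indices:
            break
        covered.update((i, j))
    return truth.disease_snp_indices <= covered


_RULES = {
    "single_pair": correct_single_pair,
    "single_pair_marginal": correct_single_pair,
    "multi_pair": correct_multi_pair,
    "higher_order": correct_higher_order,
}


def is_correct(ranked: RankedPairs, truth: TruthRecord) -> bool:
    """Apply the scenario-appropriate correctness rule."""
    return _RULES[truth.scenario](ranked, truth)


@dataclass
class AccuracyResult:
    n_datasets: int
    n_correct: int

    @property
    def accuracy_pct(self) -> float:
        return 100.0 * self.n_correct / self.n_datasets


def accuracy_over_replicates(
    datasets: list[tuple[RankedPairs, TruthRecord]]
) -> AccuracyResult:
    """Percentage of replicate datasets judged correct under their scenario rule."""
    if not datasets:
        raise ValueError("need at least one dataset")
    scenarios = {t.scenario for _, t in datasets}
    if len(scenarios) > 1:
        raise ValueError(f"mixed scenarios: {sorted(scenarios)}")
    n_correct = sum(is_correct(r, t) for r, t in datasets)
    return AccuracyResult(n_datasets=len(datasets), n_correct=n_correct)


@dataclass
class RocResult:
    """Empirical ROC over rho_diff thresholds.

    ``points`` is a list of (threshold, sensitivity, specificity);
    ``min_threshold_full_sensitivity`` is the smallest observed rho_diff
    attaining sensitivity 1 (the minimum score among the true pairs).
    """

    points: list[tuple[float, float, float]] = field(default_factory=list)
    min_threshold_full_sensitivity: float = float("nan")


def roc_curve(scores, truth: TruthRecord, thresholds=None) -> RocResult:
    """Sweep rho_diff thresholds over all scored pairs.

    ``scores`` is an iterable of PairScore (or the scan's record array).
    Invalid pairs are excluded.  Default threshold grid is the sorted set
    of observed rho_diff values — the exact empirical ROC.
    """
    if not truth.true_pairs:
        raise ValueError("truth has no true pairs")
    if isinstance(scores, np.ndarray) and scores.dtype.names:
        items = [
            (tuple(sorted((int(r["i"]), int(r["j"])))), float(r["rho_diff"]))
            for r in scores
            if bool(r["valid"])
        ]
    else:
        items = [(tuple(sorted(s.pair)), s.rho_diff) for s in scores if s.valid]
    pos = np.array([d for p, d in items if p in truth.true_pairs])
    neg = np.array([d for p, d in items if p not in truth.true_pairs])
    if pos.size == 0:
        raise ValueError("no valid scored pair matches the truth pairs")
    if thresholds is None:
        thresholds = np.unique([d for _, d in items])
    points = []
    for t in thresholds:
        sens = float((pos >= t).mean())
        spec = float((neg < t).mean()) if neg.size else 1.0
        points.append((float(t), sens, spec))
    return RocResult(
        points=points,
        min_threshold_full_sensitivity=float(pos.min()),
    )
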