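"""Stability indices for feature rankings and importance scores.

Four pairwise indices quantify how consistent two VIM runs are:

* Spearman rank correlation of the two feature orderings (1 identical,
  -1 exactly inverse);
* an averaged Jaccard index: the top-j set overlap |A_j ∩ B_j| / |A_j ∪ B_j|
  averaged over prefix lengths j = 1..d-1;
* the Kuncheva index: the same prefix overlaps corrected for the overlap
  expected by chance, (r_j - j²/d) / (j - j²/d), averaged over j;
* MARD, the mean absolute relative difference of the raw importance scores.

When the feature set is larger than ``cap`` (default 100) only the top-cap
features of each ranking enter the evaluation.  For the set-overlap indices
this truncates the prefix sums at cap; for Spearman and MARD, whose formulas
need a common feature set, the union of the two top-cap sets is used (an
intersection mode is available for Spearman).  The Kuncheva chance term
keeps the *full* dimensionality d by default, since the probability of
chance overlap is governed by the whole feature pool.

k-run stability is the mean of the index over all k(k-1)/2 unordered pairs,
reported with its sample variance.
"""

from __future__ import annotations

import itertools
import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .forest_vim import FeatureRanking, ImportanceScores, rank_features

__all__ = [
    "PairwiseStability",
    "StabilityResult",
    "BoxSummary",
    "truncate",
    "spearman_stability",
    "jaccard_stability",
    "kuncheva_stability",
    "mard",
    "pairwise_stability",
    "kway_stability",
    "boxplot_summary",
    "INDEX_NAMES",
]

INDEX_NAMES = ("spearman", "jaccard", "kuncheva", "mard")


@dataclass(frozen=True)
class PairwiseStability:
    spearman: float
    jaccard: float
    kuncheva: float
    mard: float
    top: int


@dataclass
class StabilityResult:
    """All pairwise index values from one k-run experiment, with summary stats."""

    index: str
    values: list
    k: int
    metadata: dict = field(default_factory=dict)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def variance(self) -> float:
        """Sample variance (n-1 denominator) of the pairwise values."""
        if len(self.values) < 2:
            return 0.0
        return float(np.var(self.values, ddof=1))

    def __post_init__(self):
        expected = self.k * (self.k - 1) // 2
        if len(self.values) != expected:
            raise ValueError(
                f"{len(self.values)} pairwise values for k={self.k}; expected {expected}"
            )

    def to_dict(self) -> dict:
        return {
            "index": self.index,
            "k": self.k,
            "values": [float(v) for v in self.values],
            "mean": self.mean,
            "variance": self.variance,
            "metadata": self.metadata,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StabilityResult":
        return cls(index=d["index"], values=list(d["values"]), k=d["k"],
                   metadata=dict(d.get("metadata", {})))

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


def _check_pair(g: FeatureRanking, h: FeatureRanking) -> int:
    if set(g.order.tolist()) != set(h.order.tolist()):
        raise ValueError("rankings are over different feature sets")
    return len(g.order)


def truncate(ranking: FeatureRanking, cap: int = 100) -> np.ndarray:
    """First min(cap, d) feature ids of the ranking, order preserved."""
    if cap < 1:
        raise ValueError("cap must be >= 1")
    return ranking.order[: min(cap, len(ranking.order))]


def _spearman_from_positions(pg: np.ndarray, ph: np.ndarray) -> float:
    d = len(pg)
    s = float(np.sum((pg - ph) ** 2))
    return 1.0 - 6.0 * s / (d * (d * d - 1.0))


def spearman_stability(
    g: FeatureRanking, h: FeatureRanking, cap: int = 100, truncation: str = "union"
) -> float:
    """Spearman rank correlation between two feature rankings.

    With d <= cap the classical formula 1 - 6 Σ (p_g - p_h)² / (d(d²-1)) is
    applied to the full rankings.  With d > cap the two top-cap sets are
    combined (union by default, intersection optionally), each ranking is
    densely re-ranked within that common set, and the same formula is applied
    with d replaced by the common-set size.
    """
    d = _check_pair(g, h)
    if d == 1:
        raise ValueError("Spearman stability undefined for a single feature")
    if d <= cap:
        pg = np.array([g.position[int(f)] for f in g.order], dtype=float)
        ph = np.array([h.position[int(f)] for f in g.order], dtype=float)
        return _spearman_from_positions(pg, ph)
    tg, th = set(truncate(g, cap).tolist()), set(truncate(h, cap).tolist())
    if truncation == "union":
        common = tg | th
    elif truncation == "intersection":
        common = tg & th
    else:
        raise ValueError(f"unknown truncation mode {truncation!r}")
    if len(common) < 2:
        raise ValueError("fewer than 2 features in the common top set")
    feats = sorted(common)
    # dense re-rank: order the common set by each ranking's original positions
    pg = _dense_ranks(feats, g)
    ph = _dense_ranks(feats, h)
    return _spearman_from_positions(pg, ph)


def _dense_ranks(feats: list, ranking: FeatureRanking) -> np.ndarray:
    pos = np.array([ranking.position[int(f)] for f in feats], dtype=float)
    out = np.empty_like(pos)
    out[np.argsort(pos, kind="stable")] = np.arange(1, len(feats) + 1)
    return out


def _prefix_intersections(og: np.ndarray, oh: np.ndarray, d_eff: int) -> np.ndarray:
    """r_j = |top-j(g) ∩ top-j(h)| for j = 1..d_eff, computed incrementally."""
    seen_g, seen_h = set(), set()
    r = 0
    out = np.empty(d_eff, dtype=float)
    for j in range(d_eff):
        a, b = int(og[j]), int(oh[j])
        if a == b:
            r += 1
        else:
            if a in seen_h:
                r += 1
            if b in seen_g:
                r += 1
        seen_g.add(a)
        seen_h.add(b)
        out[j] = r
    return out


def jaccard_stability(g: FeatureRanking, h: FeatureRanking, cap: int = 100) -> float:
    """Prefix-averaged Jaccard overlap of the two rankings' top-j sets."""
    d = _check_pair(g, h)
    d_eff = min(d, cap)
    if d_eff == 1:
        raise ValueError("Jaccard stability undefined for a single feature")
    r = _prefix_intersections(g.order, h.order, d_eff - 1)
    j = np.arange(1, d_eff, dtype=float)
    return float(np.mean(r / (2.0 * j - r)))


def kuncheva_stability(
    g: FeatureRanking, h: FeatureRanking, cap: int = 100, chance_d: int | None = None
) -> float:
    """Prefix-averaged Kuncheva index (chance-corrected top-j overlap).

    ``chance_d`` is the feature-pool size used in the chance-correction term
    j²/d; it defaults to the full dimensionality even when the evaluation is
    truncated at ``cap``.
    """
    d = _check_pair(g, h)
    d_eff = min(d, cap)
    if d_eff == 1:
        raise ValueError("Kuncheva stability undefined for a single feature")
    D = float(d if chance_d is None else chance_d)
    r = _prefix_intersections(g.order, h.order, d_eff - 1)
    j = np.arange(1, d_eff, dtype=float)
    return float(np.mean((r - j * j / D) / (j - j * j / D)))


def mard(g: ImportanceScores, h: ImportanceScores, cap: int = 100) -> float:
    """Mean absolute relative difference of two importance-score runs.

    Each feature contributes |s_g - s_h| / (|s_g + s_h| / 2); features whose
    scores sum to zero contribute 0 (with a warning if their scores differ,
    which can happen for MDA).  When d > cap the feature set is the union of
    the two runs' top-cap features, so between cap and 2·cap features enter.
    """
    if g.method != h.method:
        raise ValueError("cannot compare scores from different VIM methods")
    gd, hd = g.as_dict(), h.as_dict()
    if set(gd) != set(hd):
        raise ValueError("score runs are over different feature sets")
    d = len(gd)
    if d > cap:
        feats = set(truncate(rank_features(g), cap).tolist()) | set(
            truncate(rank_features(h), cap).tolist()
        )
    else:
        feats = set(gd)
    if not feats:
        raise ValueError("empty feature set for MARD")
    total, n_zero_diff = 0.0, 0
    for f in feats:
        sg, sh = gd[f], hd[f]
        denom = abs(sg + sh) / 2.0
        if denom == 0.0:
            if sg != sh:
                n_zero_diff += 1
            continue
        total += abs(sg - sh) / denom
    if n_zero_diff:
        warnings.warn(
            f"{n_zero_diff} feature(s) with zero score sum but unequal scores "
            "contributed 0 to MARD",
            RuntimeWarning,
            stacklevel=2,
        )
    return total / len(feats)


def pairwise_stability(
    g: ImportanceScores, h: ImportanceScores, cap: int = 100
) -> PairwiseStability:
    """All four indices for one pair of VIM runs."""
    rg, rh = rank_features(g), rank_features(h)
    return PairwiseStability(
        spearman=spearman_stability(rg, rh, cap),
        jaccard=jaccard_stability(rg, rh, cap),
        kuncheva=kuncheva_stability(rg, rh, cap),
        mard=mard(g, h, cap),
        top=min(cap, len(rg.order)),
    )


def kway_stability(
    runs: list,
    index: str,
    cap: int = 100,
    metadata: dict | None = None,
) -> StabilityResult:
    """Average a pairwise index over all k(k-1)/2 unordered pairs of runs."""
    if index not in INDEX_NAMES:
        raise ValueError(f"unknown index {index!r}; choose from {INDEX_NAMES}")
    k = len(runs)
    if k < 2:
        raise ValueError("k-way stability needs at least 2 runs")
    rankings = [rank_features(r) for r in runs] if index != "mard" else None
    values = []
    for a, b in itertools.combinations(range(k), 2):
        if index == "spearman":
            values.append(spearman_stability(rankings[a], rankings[b], cap))
        elif index == "jaccard":
            values.append(jaccard_stability(rankings[a], rankings[b], cap))
        elif index == "kuncheva":
            values.append(kuncheva_stability(rankings[a], rankings[b], cap))
        else:
            values.append(mard(runs[a], runs[b], cap))
    return StabilityResult(index=index, values=values, k=k, metadata=metadata or {})


@dataclass(frozen=True)
class BoxSummary:
    """Notched box-plot summary statistics for a list of index values.

    The notch half-width is (3.14/2) · IQR / √n, i.e. the conventional
    notched-box rule for an approximate median comparison interval; whiskers
    extend to the most extreme values within 1.5·IQR of the hinges.
    """

    n: int
    median: float
    q1: float
    q3: float
    iqr: float
    whisker_low: float
    whisker_high: float
    outliers: tuple
    notch_halfwidth: float

    @property
    def notch_height(self) -> float:
        return 2.0 * self.notch_halfwidth


def boxplot_summary(values) -> BoxSummary:
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot summarize an empty list")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    return BoxSummary(
        n=int(v.size),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        iqr=float(iqr),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        outliers=tuple(float(x) for x in v[(v < lo_fence) | (v > hi_fence)]),
        notch_halfwidth=(3.14 / 2.0) * float(iqr) / math.sqrt(v.size),
    )
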