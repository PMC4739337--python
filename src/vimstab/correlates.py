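"""Dataset indicators and their association with intrinsic stability.

Four indicators summarize how hard a dataset is for VIM stability: the
feature count, the sample count, the class count, the forest's OOB accuracy
(a proxy for data complexity), and the composite ratio #feature/#sample —
the degree to which a dataset is high-dimensional with a small sample.

``correlation_test`` measures monotonic (Spearman, average-rank ties) or
linear (Pearson) association, with a two-sided p-value from the
t-approximation on n-2 degrees of freedom; an exact Monte-Carlo permutation
option is provided for very small n.  Significance is flagged at the 95%
confidence level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .forest_vim import Dataset, ForestModel, oob_accuracy

__all__ = [
    "DatasetIndicators",
    "CorrelationTest",
    "compute_indicators",
    "correlation_test",
    "correlate_stability",
    "benchmark_characteristics",
    "INDICATOR_NAMES",
]

INDICATOR_NAMES = ("n_feature", "n_sample", "n_class", "oob_accuracy", "ratio")


@dataclass(frozen=True)
class DatasetIndicators:
    name: str
    n_feature: int
    n_sample: int
    n_class: int
    oob_accuracy: float
    ratio: float

    def __post_init__(self):
        if min(self.n_feature, self.n_sample, self.n_class) <= 0:
            raise ValueError("counts must be positive")
        if abs(self.ratio - self.n_feature / self.n_sample) > 1e-9:
            raise ValueError("ratio inconsistent with n_feature/n_sample")

    def value(self, which: str) -> float:
        if which not in INDICATOR_NAMES:
            raise ValueError(f"unknown indicator {which!r}")
        return float(getattr(self, which))


@dataclass(frozen=True)
class CorrelationTest:
    coefficient: str  # "spearman" or "pearson"
    estimate: float
    p_value: float
    n: int

    @property
    def significant(self) -> bool:
        """True when the association is significant at 95% confidence."""
        return self.p_value < 0.05


def compute_indicators(data: Dataset, model: ForestModel) -> DatasetIndicators:
    """Read the count indicators from the data and OOB accuracy from the model."""
    return DatasetIndicators(
        name=data.name,
        n_feature=data.n_feature,
        n_sample=data.n_sample,
        n_class=data.n_class,
        oob_accuracy=oob_accuracy(model, data),
        ratio=data.n_feature / data.n_sample,
    )


def correlation_test(
    x,
    y,
    coefficient: str = "spearman",
    method: str = "t",
    n_permutations: int = 10000,
    seed: int = 0,
) -> CorrelationTest:
    """Spearman or Pearson correlation with a two-sided p-value.

    The default p-value uses the t-approximation t = r sqrt((n-2)/(1-r²))
    on n-2 degrees of freedom; ``method='permutation'`` replaces it with a
    Monte-Carlo permutation p-value (recommended below n ~ 10).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero-variance input: correlation undefined")

    def _estimate(a, b):
        if coefficient == "spearman":
            return float(stats.spearmanr(a, b).statistic)
        if coefficient == "pearson":
            return float(stats.pearsonr(a, b).statistic)
        raise ValueError(f"unknown coefficient {coefficient!r}")

    r = _estimate(x, y)
    if method == "t":
        if abs(r) >= 1.0:
            p = np.finfo(float).tiny  # degenerate perfect correlation
        else:
            t = r * np.sqrt((n - 2) / (1.0 - r * r))
            p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        hits = sum(
            abs(_estimate(x, y[rng.permutation(n)])) >= abs(r) - 1e-12
            for _ in range(n_permutations)
        )
        p = (hits + 1) / (n_permutations + 1)
    else:
        raise ValueError(f"unknown method {method!r}")
    return CorrelationTest(coefficient=coefficient, estimate=r, p_value=float(p), n=n)


def correlate_stability(
    indicator_table,
    stability_means,
    which_indicator: str,
    coefficient: str = "spearman",
    subgroup=None,
    **kwargs,
) -> CorrelationTest:
    """Correlate one dataset indicator with per-dataset stability means.

    ``indicator_table`` is a list of :class:`DatasetIndicators` aligned
    one-to-one with ``stability_means`` (a list of floats, e.g. the mean
    Spearman-index intrinsic stability of each dataset).  ``subgroup``
    optionally selects a boolean mask / index list (e.g. the low-dimensional
    datasets only).
    """
    if len(indicator_table) != len(stability_means):
        raise ValueError(
            f"misaligned tables: {len(indicator_table)} indicator rows vs "
            f"{len(stability_means)} stability means"
        )
    x = np.array([ind.value(which_indicator) for ind in indicator_table])
    y = np.asarray(stability_means, dtype=float)
    if subgroup is not None:
        sel = np.asarray(subgroup)
        x, y = x[sel], y[sel]
    return correlation_test(x, y, coefficient=coefficient, **kwargs)


#: published shape characteristics (domain, #feature, #sample, #class, forest
#: OOB accuracy) of 19 UCI / GEMS benchmark datasets widely used in
#: variable-importance stability studies.  The first 9 are low-dimensional
#: with large samples, the last 10 high-dimensional with small samples.
_BENCHMARKS = [
    ("yeast", "biology", 8, 1484, 10, 0.98),
    ("glass", "physical", 9, 240, 6, 0.79),
    ("vote", "social", 16, 232, 2, 0.97),
    ("segment", "image", 19, 2310, 7, 0.98),
    ("mushroom", "biology", 20, 8124, 2, 1.00),
    ("soybean", "biology", 35, 307, 19, 0.93),
    ("splice", "biology", 60, 3175, 4, 0.43),
    ("sonar", "physical", 60, 208, 2, 0.85),
    ("madelon", "artificial", 500, 2600, 2, 0.73),
    ("SRBCT", "biology", 2308, 83, 4, 1.00),
    ("Leukemia1", "biology", 5327, 72, 3, 0.94),
    ("DLBCL", "biology", 5469, 77, 2, 0.83),
    ("Tumors_9", "biology", 5726, 60, 9, 0.51),
    ("Brain_Tumor1", "biology", 5920, 90, 5, 0.83),
    ("Arcene", "biology", 10000, 100, 2, 0.79),
    ("Brain_Tumor2", "biology", 10367, 50, 4, 0.74),
    ("Prostate_Tumor", "biology", 10509, 102, 2, 0.92),
    ("Tumors_11", "biology", 12533, 174, 11, 0.88),
    ("Lung_Cancer", "biology", 12600, 203, 5, 0.92),
]


def benchmark_characteristics() -> pd.DataFrame:
    """The 19-benchmark characteristics table as a DataFrame.

    Columns: name, domain, n_feature, n_sample, n_class, oob_accuracy, ratio.
    Useful as a reference input for indicator-correlation analyses (e.g. the
    #feature vs #sample dependence across benchmarks).
    """
    df = pd.DataFrame(
        _BENCHMARKS,
        columns=["name", "domain", "n_feature", "n_sample", "n_class", "oob_accuracy"],
    )
    df["ratio"] = df["n_feature"] / df["n_sample"]
    return df
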