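"""Synthetic classification datasets for stability experiments.

The generator emulates the two regimes in which VIM stability is usually
studied: low-dimensional / large-sample tabular data (p ~ 10-60,
n ~ 200-8000) and high-dimensional / small-sample gene-expression-like data
(p in the thousands, n in the tens, few informative features, redundant
correlated copies, many pure-noise features).

Structure of a generated dataset:

* balanced class labels (counts within +/-1 of each other);
* ``n_informative`` Gaussian features whose class-conditional means are
  drawn at random and rescaled so the *minimum* pairwise distance between
  class means equals ``class_separation`` (in units of ``noise_sd``, so
  e.g. separation 4 makes even the closest class pair nearly separable);
* optionally, each informative feature has ``correlated_blocks`` redundant
  copies: the parent column plus Gaussian noise calibrated to a target
  within-block correlation ``block_rho``;
* all remaining features are pure N(0, noise_sd²) noise.

``strength_decay`` scales informative feature i's class-mean column by
decay^i, giving features a well-ordered importance profile (real data sets
have heterogeneous effect sizes; a strict ordering also makes ranking
convergence observable).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .forest_vim import Dataset

__all__ = ["SynthSpec", "generate", "regime_suite", "ratio_sweep_suite", "FIXTURES", "fixture"]


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of one synthetic dataset."""

    n_sample: int
    n_feature: int
    n_class: int = 2
    n_informative: int = 1
    class_separation: float = 3.0
    correlated_blocks: int = 0
    block_rho: float = 0.7
    noise_sd: float = 1.0
    strength_decay: float = 1.0
    seed: int = 0
    name: str = ""

    def __post_init__(self):
        if self.n_class < 2:
            raise ValueError("need at least 2 classes")
        if self.n_sample < 2 * self.n_class:
            raise ValueError("need at least 2 samples per class")
        if not (0 <= self.n_informative <= self.n_feature):
            raise ValueError("n_informative must lie in [0, n_feature]")
        if self.n_informative * (1 + self.correlated_blocks) > self.n_feature:
            raise ValueError("informative + redundant features exceed n_feature")
        if self.class_separation < 0 or self.noise_sd <= 0:
            raise ValueError("class_separation >= 0 and noise_sd > 0 required")
        if not (0 < self.block_rho < 1):
            raise ValueError("block_rho must lie in (0, 1)")


def generate(spec: SynthSpec) -> Dataset:
    """Generate one dataset from ``spec``; bit-reproducible from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    n, p, C = spec.n_sample, spec.n_feature, spec.n_class
    k = spec.n_informative

    # balanced labels (+/-1), shuffled row order
    base, rem = divmod(n, C)
    counts = [base + (1 if c < rem else 0) for c in range(C)]
    y = np.repeat(np.arange(C), counts)
    rng.shuffle(y)

    X = rng.normal(scale=spec.noise_sd, size=(n, p))
    informative = list(range(k))
    redundant = []
    if k > 0 and spec.class_separation > 0:
        mu = rng.normal(size=(C, k))
        # every informative column gets unit across-class spread before the
        # decay profile, so each one carries real signal with ordered strength
        mu -= mu.mean(axis=0)
        sd = mu.std(axis=0)
        sd[sd == 0] = 1.0
        mu = mu / sd * spec.strength_decay ** np.arange(k)
        dists = np.linalg.norm(mu[:, None, :] - mu[None, :, :], axis=-1)
        min_dist = dists[np.triu_indices(C, k=1)].min()
        if min_dist == 0:  # astronomically unlikely; redraw deterministically
            mu += rng.normal(scale=1e-6, size=mu.shape)
            dists = np.linalg.norm(mu[:, None, :] - mu[None, :, :], axis=-1)
            min_dist = dists[np.triu_indices(C, k=1)].min()
        mu *= spec.class_separation * spec.noise_sd / min_dist
        X[:, :k] += mu[y]

    for b in range(spec.correlated_blocks):
        for i in range(k):
            col = k + b * k + i
            parent = X[:, i]
            sd_p = parent.std()
            rho = spec.block_rho
            eps_sd = sd_p * math.sqrt(1.0 / rho**2 - 1.0) if sd_p > 0 else spec.noise_sd
            X[:, col] = parent + rng.normal(scale=eps_sd, size=n)
            redundant.append(col)

    feature_ids = np.arange(1, p + 1)
    meta = {
        "informative_ids": [i + 1 for i in informative],
        "redundant_ids": [c + 1 for c in redundant],
        "noise_ids": [
            i + 1 for i in range(p) if i not in set(informative) and i not in set(redundant)
        ],
        "spec": spec,
    }
    name = spec.name or f"synth_p{p}_n{n}_c{C}"
    return Dataset(X=X, y=y, feature_ids=feature_ids, name=name, meta=meta)


def _geom(lo: float, hi: float, size: int) -> np.ndarray:
    if size == 1:
        return np.array([lo], dtype=float)
    return np.geomspace(lo, hi, size)


def regime_suite(regime: str, size: int, seed: int) -> list:
    """A family of datasets spanning one study regime, varying p and n (hence
    the #feature/#sample ratio) while holding the class separation fixed.

    ``low_dim_large_n``: p 8..60, n 8000..200.  ``high_dim_small_n``:
    p 2000..12600, n 203..30.  Reproducible from ``seed``.
    """
    if size < 1:
        raise ValueError("size must be >= 1")
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0]) for s in ss.spawn(size)]
    out = []
    if regime == "low_dim_large_n":
        ps = np.round(_geom(8, 60, size)).astype(int)
        ns = np.round(_geom(8000, 200, size)).astype(int)
        cs = [(2, 3, 4, 6)[i % 4] for i in range(size)]
        for i in range(size):
            out.append(
                generate(
                    SynthSpec(
                        n_sample=int(ns[i]),
                        n_feature=int(ps[i]),
                        n_class=cs[i],
                        n_informative=max(2, int(ps[i]) // 2),
                        class_separation=3.0,
                        strength_decay=0.9,
                        seed=seeds[i],
                        name=f"low_dim_{i}",
                    )
                )
            )
    elif regime == "high_dim_small_n":
        ps = np.round(_geom(2000, 12600, size)).astype(int)
        ns = np.round(_geom(203, 30, size)).astype(int)
        cs = [(2, 3, 4, 9)[i % 4] for i in range(size)]
        for i in range(size):
            out.append(
                generate(
                    SynthSpec(
                        n_sample=int(ns[i]),
                        n_feature=int(ps[i]),
                        n_class=cs[i],
                        n_informative=10,
                        class_separation=3.0,
                        correlated_blocks=1,
                        strength_decay=0.9,
                        seed=seeds[i],
                        name=f"high_dim_{i}",
                    )
                )
            )
    else:
        raise ValueError(f"unknown regime {regime!r}")
    return out


def ratio_sweep_suite(
    size: int,
    seed: int,
    p_range: tuple = (10, 1500),
    n_range: tuple = (600, 30),
    n_class: int = 3,
) -> list:
    """A suite sweeping the #feature/#sample ratio across both regimes at a
    scale suitable for correlation experiments, all else held fixed.

    p rises and n falls geometrically across the suite so the ratio spans
    roughly p_range[0]/n_range[0] .. p_range[1]/n_range[1].
    """
    if size < 2:
        raise ValueError("a ratio sweep needs at least 2 datasets")
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0]) for s in ss.spawn(size)]
    ps = np.round(_geom(p_range[0], p_range[1], size)).astype(int)
    ns = np.round(_geom(n_range[0], n_range[1], size)).astype(int)
    out = []
    for i in range(size):
        p = int(ps[i])
        out.append(
            generate(
                SynthSpec(
                    n_sample=int(ns[i]),
                    n_feature=p,
                    n_class=n_class,
                    n_informative=min(5, max(2, p // 3)),
                    class_separation=3.0,
                    correlated_blocks=1 if p >= 15 else 0,
                    strength_decay=0.9,
                    seed=seeds[i],
                    name=f"ratio_sweep_{i}",
                )
            )
        )
    return out


#: named fixtures mirroring the shapes of widely used benchmark datasets
FIXTURES = {
    "yeast_like": SynthSpec(
        n_sample=1484, n_feature=8, n_class=10, n_informative=8,
        class_separation=4.0, strength_decay=0.8, name="yeast_like",
    ),
    "glass_like": SynthSpec(
        n_sample=240, n_feature=9, n_class=6, n_informative=6,
        class_separation=3.0, strength_decay=0.85, name="glass_like",
    ),
    "sonar_like": SynthSpec(
        n_sample=208, n_feature=60, n_class=2, n_informative=10,
        class_separation=2.5, correlated_blocks=1, strength_decay=0.9, name="sonar_like",
    ),
    "madelon_like": SynthSpec(
        n_sample=2600, n_feature=500, n_class=2, n_informative=5,
        class_separation=2.0, correlated_blocks=3, strength_decay=0.9, name="madelon_like",
    ),
    "srbct_like": SynthSpec(
        n_sample=83, n_feature=2308, n_class=4, n_informative=20,
        class_separation=3.5, correlated_blocks=2, strength_decay=0.9, name="srbct_like",
    ),
}


def fixture(name: str, seed: int = 0) -> Dataset:
    """Generate a registered fixture dataset with the given seed."""
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; choose from {sorted(FIXTURES)}")
    return generate(replace(FIXTURES[name], seed=seed))
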