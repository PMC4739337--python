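"""Experiment protocols: intrinsic, data-perturbation and parameter-variation
stability.

*Intrinsic* stability is the self-consistence of a VIM across ``k_runs``
repeated runs on identical data and identical hyper-parameters — only the
internal randomness (bagging, per-node feature sampling, and for MDA the
OOB permutations) differs between runs.

*Data-perturbation* stability perturbs the data instead: the samples are
partitioned into ``folds`` equal parts and one VIM run is executed on each
fold-complement training set; the index is averaged over all pairs of
training sets.  A nested intrinsic arm repeats ``k_runs`` runs on each
training set, computes per-training-set intrinsic stability, and averages
the means over the folds — so both arms are measured on the same data.

*Parameter-variation* stability varies ntree (or mtry) over a grid with one
run per grid point, again with a nested per-grid-point intrinsic arm.

All randomness flows from ``master_seed`` through a deterministic seed tree
(protocol → arm → run), recorded in each result's provenance so any number
can be replayed bit-exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .forest_vim import (
    Dataset,
    ForestConfig,
    ImportanceScores,
    fit_forest,
    mda_importance,
    mdg_importance,
)
from .stability import INDEX_NAMES, StabilityResult, kway_stability

__all__ = [
    "ProtocolSpec",
    "IntrinsicResult",
    "PairedStability",
    "ExperimentReport",
    "resolve_mtry",
    "derive_seed",
    "vim_run",
    "run_intrinsic",
    "run_perturbation",
    "run_ntree_variation",
    "run_mtry_variation",
]

DEFAULT_NTREE_GRID = (50, 100, 200, 500, 1000, 2000, 5000, 10000, 20000, 50000)
DEFAULT_MTRY_GRID = ("one", "dwdef", "def", "updef")


@dataclass(frozen=True)
class ProtocolSpec:
    """Configuration shared by all protocols.

    ``base_config`` carries the default ntree/mtry (ntree 20000 with
    mtry="def" matches common practice for converged importance estimates;
    experiments routinely scale it down).  ``mtry`` may be an integer or one
    of the symbols one/dwdef/def/updef resolved against the feature count.
    """

    method: str  # "MDA" or "MDG"
    base_config: ForestConfig
    k_runs: int = 10
    folds: int = 10
    ntree_grid: tuple = DEFAULT_NTREE_GRID
    mtry_grid: tuple = DEFAULT_MTRY_GRID
    master_seed: int = 0
    cap: int = 100
    stratified: bool = False

    def __post_init__(self):
        if self.method not in ("MDA", "MDG"):
            raise ValueError("method must be 'MDA' or 'MDG'")
        if self.k_runs < 2:
            raise ValueError("k_runs must be >= 2")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if not self.ntree_grid or not self.mtry_grid:
            raise ValueError("parameter grids must be non-empty")


@dataclass
class IntrinsicResult:
    """k-run intrinsic stability of one VIM on one dataset."""

    results: dict  # index name -> StabilityResult
    runs: list  # the k ImportanceScores
    provenance: dict

    def mean(self, index: str) -> float:
        return self.results[index].mean


@dataclass
class PairedStability:
    """A variation arm (perturbation or parameter grid) paired with the nested
    intrinsic arm measured on the same training sets / grid points."""

    arm: str
    variation: dict  # index -> StabilityResult across folds/grid points
    intrinsic_per_point: list  # one {index -> StabilityResult} per fold/point
    provenance: dict

    def intrinsic_mean(self, index: str) -> float:
        """Average of per-point intrinsic means (average-of-averages)."""
        return float(np.mean([r[index].mean for r in self.intrinsic_per_point]))

    def intrinsic_values(self, index: str) -> list:
        """All nested intrinsic pairwise values, pooled across points."""
        out = []
        for r in self.intrinsic_per_point:
            out.extend(r[index].values)
        return out


@dataclass
class ExperimentReport:
    """Serializable record of one protocol execution."""

    protocol: str
    method: str
    dataset_name: str
    cap: int
    stability_sets: dict  # arm name -> {index -> StabilityResult}
    scalars: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)


def resolve_mtry(symbol, d: int) -> int:
    """Resolve a symbolic mtry against d features.

    def = round(sqrt(d)) clamped to [1, d]; one = 1; dwdef = max(1, round(def/2));
    updef = min(d, round(1.5 * def)).  Integers pass through (clamped).
    """
    if d < 1:
        raise ValueError("d must be >= 1")
    if isinstance(symbol, (int, np.integer)):
        return int(min(max(1, int(symbol)), d))
    dflt = min(max(1, round(math.sqrt(d))), d)
    if symbol == "def":
        return dflt
    if symbol == "one":
        return 1
    if symbol == "dwdef":
        return max(1, round(dflt / 2))
    if symbol == "updef":
        return min(d, round(1.5 * dflt))
    raise ValueError(f"unknown mtry symbol {symbol!r}")


def derive_seed(master_seed: int, *path) -> int:
    """Deterministic child seed from a master seed and a (protocol, arm, run)
    path; components may be strings or integers."""
    key = tuple(
        int.from_bytes(str(p).encode(), "little") % (2**31) if isinstance(p, str) else int(p)
        for p in path
    )
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=key)
    return int(ss.generate_state(1)[0])


def vim_run(data: Dataset, config: ForestConfig, method: str, run_seed: int) -> ImportanceScores:
    """One complete VIM run: fit a forest and score every feature.

    ``run_seed`` drives both the forest (bagging + randomization) and, for
    MDA, the permutation stream, through two fixed sub-streams.
    """
    fit_seed = derive_seed(run_seed, 0)
    model = fit_forest(data, config.with_seed(fit_seed))
    if method == "MDA":
        return mda_importance(model, data, seed=derive_seed(run_seed, 1))
    if method == "MDG":
        return mdg_importance(model)
    raise ValueError(f"unknown VIM method {method!r}")


def _resolve_config(spec: ProtocolSpec, d: int, ntree=None, mtry=None) -> ForestConfig:
    cfg = spec.base_config
    return ForestConfig(
        ntree=int(ntree if ntree is not None else cfg.ntree),
        mtry=resolve_mtry(mtry if mtry is not None else cfg.mtry, d),
        seed=cfg.seed,
    )


def _kway_all(runs, cap, metadata) -> dict:
    return {idx: kway_stability(runs, idx, cap, metadata=dict(metadata)) for idx in INDEX_NAMES}


def run_intrinsic(
    data: Dataset,
    spec: ProtocolSpec,
    config: ForestConfig | None = None,
    seed_path: tuple = ("intrinsic",),
) -> IntrinsicResult:
    """k_runs repeated VIM runs on the same data and config; k-way stability
    of the resulting rankings (Spearman/Jaccard/Kuncheva) and scores (MARD)."""
    cfg = config if config is not None else _resolve_config(spec, data.n_feature)
    run_seeds = [derive_seed(spec.master_seed, *seed_path, r) for r in range(spec.k_runs)]
    runs = [vim_run(data, cfg, spec.method, s) for s in run_seeds]
    meta = {
        "protocol": "intrinsic",
        "method": spec.method,
        "dataset": data.name,
        "ntree": cfg.ntree,
        "mtry": cfg.mtry,
    }
    return IntrinsicResult(
        results=_kway_all(runs, spec.cap, meta),
        runs=runs,
        provenance={"master_seed": spec.master_seed, "seed_path": list(seed_path),
                    "run_seeds": run_seeds, "ntree": cfg.ntree, "mtry": cfg.mtry},
    )


def _partition(data: Dataset, spec: ProtocolSpec, rng: np.random.Generator) -> list:
    """Random partition into ``folds`` near-equal parts (optionally stratified)."""
    n = data.n_sample
    if spec.stratified:
        folds = [[] for _ in range(spec.folds)]
        for cls in data.classes:
            idx = np.flatnonzero(data.y == cls)
            rng.shuffle(idx)
            for i, part in enumerate(np.array_split(idx, spec.folds)):
                folds[(i + rng.integers(spec.folds)) % spec.folds].extend(part.tolist())
        return [np.sort(np.array(f, dtype=int)) for f in folds]
    perm = rng.permutation(n)
    return [np.sort(part) for part in np.array_split(perm, spec.folds)]


def run_perturbation(data: Dataset, spec: ProtocolSpec) -> PairedStability:
    """Data-perturbation stability via ``folds``-fold partition, paired with a
    nested intrinsic arm on each training set."""
    if data.n_sample < spec.folds:
        raise ValueError("fewer samples than folds")
    d = data.n_feature
    cfg = _resolve_config(spec, d)
    rng = np.random.default_rng(derive_seed(spec.master_seed, "perturbation", "partition"))
    parts = _partition(data, spec, rng)
    all_idx = np.arange(data.n_sample)

    train_sets = []
    for f, part in enumerate(parts):
        train = np.setdiff1d(all_idx, part)
        sub = data.subset(train, name=f"{data.name}/fold{f}")
        if len(np.unique(sub.y)) < data.n_class:
            raise ValueError(f"training set for fold {f} lost a class entirely")
        train_sets.append(sub)

    # perturbation arm: one run per training set
    pert_runs = [
        vim_run(sub, cfg, spec.method, derive_seed(spec.master_seed, "perturbation", "arm", f))
        for f, sub in enumerate(train_sets)
    ]
    meta = {"protocol": "perturbation", "method": spec.method, "dataset": data.name,
            "ntree": cfg.ntree, "mtry": cfg.mtry}
    variation = _kway_all(pert_runs, spec.cap, meta)

    # nested intrinsic arm: k_runs repeated runs on each training set
    intrinsic_per_fold = []
    for f, sub in enumerate(train_sets):
        res = run_intrinsic(sub, spec, config=cfg,
                            seed_path=("perturbation", "intrinsic", f))
        intrinsic_per_fold.append(res.results)

    return PairedStability(
        arm="perturbation",
        variation=variation,
        intrinsic_per_point=intrinsic_per_fold,
        provenance={"master_seed": spec.master_seed, "folds": spec.folds,
                    "fold_sizes": [len(p) for p in parts],
                    "ntree": cfg.ntree, "mtry": cfg.mtry},
    )


def _run_grid_variation(
    data: Dataset, spec: ProtocolSpec, arm: str, grid, configs
) -> PairedStability:
    var_runs = [
        vim_run(data, cfg, spec.method, derive_seed(spec.master_seed, arm, "arm", g))
        for g, cfg in enumerate(configs)
    ]
    meta = {"protocol": arm, "method": spec.method, "dataset": data.name,
            "grid": list(map(str, grid))}
    variation = _kway_all(var_runs, spec.cap, meta)
    intrinsic_per_point = []
    for g, cfg in enumerate(configs):
        res = run_intrinsic(data, spec, config=cfg, seed_path=(arm, "intrinsic", g))
        intrinsic_per_point.append(res.results)
    return PairedStability(
        arm=arm,
        variation=variation,
        intrinsic_per_point=intrinsic_per_point,
        provenance={"master_seed": spec.master_seed, "grid": list(map(str, grid)),
                    "configs": [(c.ntree, c.mtry) for c in configs]},
    )


def run_ntree_variation(data: Dataset, spec: ProtocolSpec) -> PairedStability:
    """Vary ntree over ``spec.ntree_grid`` (mtry held at its default), one VIM
    run per grid point, paired with per-point intrinsic arms."""
    d = data.n_feature
    configs = [_resolve_config(spec, d, ntree=nt, mtry="def") for nt in spec.ntree_grid]
    return _run_grid_variation(data, spec, "ntree_variation", spec.ntree_grid, configs)


def run_mtry_variation(data: Dataset, spec: ProtocolSpec) -> PairedStability:
    """Vary mtry over ``spec.mtry_grid`` at fixed ntree, one VIM run per grid
    point, paired with per-point intrinsic arms."""
    d = data.n_feature
    configs = [_resolve_config(spec, d, mtry=sym) for sym in spec.mtry_grid]
    return _run_grid_variation(data, spec, "mtry_variation", spec.mtry_grid, configs)
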