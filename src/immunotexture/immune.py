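"""Clonal-selection optimizer for joint feature screening and SVM tuning.

Candidate solutions (antibodies) are binary chromosomes of 32 equal-width
fields, ``n`` bits each (default 8, so 256 bits): fields 1-2 decode to the
RBF-SVM parameters C and r on a log2 scale, fields 3-32 are feature screens —
a feature enters the model iff its field decodes above the field midpoint.
Affinity of an antibody against the antigen (the classification problem) is
the five-fold cross-validated accuracy of the RBF-SVM it encodes.

One cycle: evaluate every antibody; clone the best one ``clone_best`` times
and every other ``clone_general`` times (default 30x / 10x, population 5);
mutate clones by independent per-bit flips at rate ``1/n`` (mutation
probability shrinks as field coding length grows); then each lineage keeps
the fittest of the parent and its clones, so the best affinity never
decreases.  Cycles repeat until a target affinity or the generation cap
(default 500) is reached.

Binary fields decode to reals on ``[d, u]`` by

    x = d + (u - d) / (2^l - 1) * sum_j a_j 2^(j-1),   j = 1 is the first bit,

a bijection between bit patterns and a uniform grid of ``2^l`` values.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .classifiers import C_BOUNDS_LOG2, N_FOLDS, R_BOUNDS_LOG2, EvalReport, LabeledDataset, five_fold_rotation, make_rbf_svm
from .errors import ParameterError, StateError

N_FIELDS = 32
N_FEATURES = 30


@dataclass(frozen=True)
class IaConfig:
    """Optimizer parameters; defaults follow the study protocol
    (5 antibody groups, 10x/30x clone rates, 500 cycles)."""

    n_groups: int = 5
    bits_per_field: int = 8
    clone_general: int = 10
    clone_best: int = 30
    max_generations: int = 500
    target_affinity: float = 1.0
    seed: int = 0
    c_bounds_log2: tuple[float, float] = C_BOUNDS_LOG2
    r_bounds_log2: tuple[float, float] = R_BOUNDS_LOG2
    mutation_rate: float | None = None  # default 1 / bits_per_field

    def __post_init__(self) -> None:
        if not (self.clone_best > self.clone_general >= 1):
            raise ParameterError("require clone_best > clone_general >= 1")
        if not (0 < self.target_affinity <= 1):
            raise ParameterError("target_affinity must be in (0, 1]")
        if self.bits_per_field < 1 or self.n_groups < 1 or self.max_generations < 1:
            raise ParameterError("n_groups, bits_per_field, max_generations must be >= 1")

    @property
    def n_bits(self) -> int:
        return N_FIELDS * self.bits_per_field

    @property
    def per_bit_mutation(self) -> float:
        return self.mutation_rate if self.mutation_rate is not None else 1.0 / self.bits_per_field


@dataclass
class Antibody:
    """Binary chromosome with its decoded phenotype and cached affinity."""

    bits: np.ndarray  # uint8 array of 0/1, length 32 * n
    c: float
    r: float
    feature_mask: np.ndarray  # 30 booleans, at least one True
    affinity: float | None = None
    parent_index: int | None = None

    def key(self) -> bytes:
        return self.bits.tobytes()


def decode_field(bits: np.ndarray, lower: float, upper: float) -> float:
    """Decode one binary field to a real on ``[lower, upper]``.

    The first bit of the field is the least significant; all-zero decodes to
    ``lower`` and all-one to ``upper`` exactly.
    """
    if upper <= lower:
        raise ParameterError(f"require upper > lower, got ({lower}, {upper})")
    bits = np.asarray(bits)
    l = bits.size
    if l < 1:
        raise ParameterError("field must have at least 1 bit")
    total = int((bits.astype(np.int64) << np.arange(l)).sum())
    return lower + (upper - lower) * total / (2**l - 1)


def encode_field(value: float, lower: float, upper: float, n_bits: int) -> np.ndarray:
    """Inverse of :func:`decode_field` onto the nearest grid point."""
    if upper <= lower:
        raise ParameterError(f"require upper > lower, got ({lower}, {upper})")
    k = int(round((value - lower) / (upper - lower) * (2**n_bits - 1)))
    k = min(max(k, 0), 2**n_bits - 1)
    return ((k >> np.arange(n_bits)) & 1).astype(np.uint8)


def _fields(bits: np.ndarray, n: int) -> np.ndarray:
    return bits.reshape(N_FIELDS, n)


def make_antibody(bits: np.ndarray, cfg: IaConfig, rng: np.random.Generator | None = None) -> Antibody:
    """Decode a chromosome; repairs an empty feature mask by switching one
    random feature field fully on."""
    bits = np.asarray(bits, dtype=np.uint8).copy()
    if bits.size != cfg.n_bits:
        raise ParameterError(f"chromosome must have {cfg.n_bits} bits, got {bits.size}")
    n = cfg.bits_per_field
    fields = _fields(bits, n)
    # feature screen: field value on [0, 1], selected iff >= midpoint
    vals = np.array([decode_field(fields[2 + i], 0.0, 1.0) for i in range(N_FEATURES)])
    mask = vals >= 0.5
    if not mask.any():
        rng = rng or np.random.default_rng(0)
        j = int(rng.integers(N_FEATURES))
        fields[2 + j] = 1
        mask[j] = True
    c = 2.0 ** decode_field(fields[0], *cfg.c_bounds_log2)
    r = 2.0 ** decode_field(fields[1], *cfg.r_bounds_log2)
    return Antibody(bits=bits, c=c, r=r, feature_mask=mask)


def init_population(cfg: IaConfig, rng: np.random.Generator) -> list[Antibody]:
    """``n_groups`` antibodies with i.i.d. fair-coin bits (repaired)."""
    return [
        make_antibody(rng.integers(0, 2, size=cfg.n_bits, dtype=np.uint8), cfg, rng)
        for _ in range(cfg.n_groups)
    ]


class SvmAffinityEvaluator:
    """Affinity = five-fold cross-validated RBF-SVM accuracy.

    Standardization is fitted per training fold.  Identical chromosomes are
    cached; ``n_fits`` counts actual SVM trainings (5 per cache miss), the
    execution-count unit shared with the baselines.
    """

    def __init__(self, data: LabeledDataset):
        if data.n_classes < 2:
            raise ParameterError("dataset must contain at least 2 classes")
        self.data = data
        self._x = data.x
        self._cache: dict[bytes, float] = {}
        self.n_fits = 0

    def __call__(self, ab: Antibody) -> float:
        key = ab.key()
        if key in self._cache:
            ab.affinity = self._cache[key]
            return ab.affinity
        x = self._x[:, ab.feature_mask]
        y = self.data.labels
        accs = []
        for f in range(N_FOLDS):
            train, test = self.data.fold_id != f, self.data.fold_id == f
            scaler = StandardScaler().fit(x[train])
            model = SVC(C=ab.c, gamma=ab.r, kernel="rbf")
            model.fit(scaler.transform(x[train]), y[train])
            accs.append(float(np.mean(model.predict(scaler.transform(x[test])) == y[test])))
            self.n_fits += 1
        value = float(np.mean(accs))
        self._cache[key] = value
        ab.affinity = value
        return value


def affinity(ab: Antibody, data: LabeledDataset) -> float:
    """Convenience single-antibody evaluation (see :class:`SvmAffinityEvaluator`)."""
    return SvmAffinityEvaluator(data)(ab)


def clone_and_mutate(pop: list[Antibody], cfg: IaConfig, rng: np.random.Generator) -> list[Antibody]:
    """Clonal expansion: best parent cloned ``clone_best`` times, others
    ``clone_general``; clones get independent per-bit flips at ``1/n``.

    Parents are left untouched; each clone records its parent's index.
    """
    if any(ab.affinity is None for ab in pop):
        raise StateError("all antibodies must be evaluated before cloning")
    best_idx = int(np.argmax([ab.affinity for ab in pop]))
    p = cfg.per_bit_mutation
    clones: list[Antibody] = []
    for i, parent in enumerate(pop):
        n_clones = cfg.clone_best if i == best_idx else cfg.clone_general
        for _ in range(n_clones):
            bits = parent.bits.copy()
            flips = rng.random(bits.size) < p
            bits[flips] ^= 1
            clone = make_antibody(bits, cfg, rng)
            clone.parent_index = i
            clones.append(clone)
    return clones


def select_next_generation(parents: list[Antibody], clones: list[Antibody], cfg: IaConfig) -> list[Antibody]:
    """Per-lineage elitism: each parent is replaced by its best clone only if
    the clone's affinity is strictly higher; population size is restored to
    ``n_groups`` and the global best is never lost."""
    survivors = []
    for i, parent in enumerate(parents):
        lineage = [c for c in clones if c.parent_index == i]
        best = parent
        for c in lineage:
            if c.affinity is not None and (best.affinity is None or c.affinity > best.affinity):
                best = c
        survivors.append(best)
    return survivors[: cfg.n_groups]


@dataclass
class RunHistory:
    """Per-generation record of the optimization run."""

    generation: list[int] = dc_field(default_factory=list)
    best_affinity: list[float] = dc_field(default_factory=list)
    mean_affinity: list[float] = dc_field(default_factory=list)
    best_snapshot: list[Antibody] = dc_field(default_factory=list)

    def append(self, gen: int, pop: list[Antibody]) -> None:
        affs = [ab.affinity for ab in pop]
        best = pop[int(np.argmax(affs))]
        self.generation.append(gen)
        self.best_affinity.append(float(max(affs)))
        self.mean_affinity.append(float(np.mean(affs)))
        self.best_snapshot.append(best)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "generation": self.generation,
                "best_affinity": self.best_affinity,
                "mean_affinity": self.mean_affinity,
            }
        )
        # the convergence plots track the objective 1 - best accuracy, the
        # quantity that decreases toward the optimum
        df["objective"] = 1.0 - df["best_affinity"]
        return df


def run_optimization(
    data: LabeledDataset | None,
    cfg: IaConfig,
    affinity_fn=None,
    return_report: bool = False,
):
    """Full clonal-selection loop: init, evaluate, clone/mutate, select.

    Stops when the best affinity reaches ``cfg.target_affinity`` or after
    ``cfg.max_generations`` cycles; fully reproducible from ``cfg.seed``.
    ``affinity_fn`` may replace the SVM evaluator (e.g. an analytic surrogate
    for optimizer studies).  With ``return_report=True`` an :class:`EvalReport`
    for the best antibody is appended (SVM affinity only).
    """
    evaluator = None
    if affinity_fn is None:
        if data is None:
            raise ParameterError("either data or affinity_fn is required")
        evaluator = SvmAffinityEvaluator(data)
        affinity_fn = evaluator
    rng = np.random.default_rng(cfg.seed)
    pop = init_population(cfg, rng)
    history = RunHistory()
    for ab in pop:
        affinity_fn(ab)
    for gen in range(1, cfg.max_generations + 1):
        history.append(gen, pop)
        if max(ab.affinity for ab in pop) >= cfg.target_affinity:
            break
        if gen == cfg.max_generations:
            break
        clones = clone_and_mutate(pop, cfg, rng)
        for c in clones:
            affinity_fn(c)
        pop = select_next_generation(pop, clones, cfg)
    best = history.best_snapshot[int(np.argmax(history.best_affinity))]
    if not return_report:
        return best, history
    if evaluator is None:
        raise ParameterError("return_report requires the SVM affinity evaluator")
    rotation = five_fold_rotation(
        data,
        lambda: make_rbf_svm(best.c, best.r),
        columns=best.feature_mask,
    )
    report = EvalReport(
        accuracy=rotation.accuracy,
        per_class=rotation.per_class,
        n_executions=evaluator.n_fits,
        confusion=rotation.confusion,
    )
    return best, history, report
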