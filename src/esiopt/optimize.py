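"""NSGA-II selection of EEG channel subsets for source imaging.

Channel selection is cast as a two-objective minimization over binary
chromosomes of length g (one gene per candidate electrode): the mean
localization error across ALL epochs of the benchmark dataset, and the number
of selected channels.  A single channel combination is optimized for the whole
epoch set (rather than one combination per epoch).  Supported placement
constraints: restriction to an allowed label set (e.g. the 10-10 system), a
hemispheric symmetry constraint (equal channel counts left/right, midline
exempt), and cascade search (each smaller subset restricted to the previously
found larger one).

The genetic loop is elitist NSGA-II: fast non-dominated sorting with crowding
distance, binary-tournament parent selection, uniform crossover and per-gene
bit-flip mutation; offspring violating a constraint are rejected and redrawn.
Every evaluated individual is archived, so the best combination per channel
count and the overall Pareto front can be extracted afterwards.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .headmodel import LeadField, Montage, label_side, mirror_label
from .inverse import apply_inverse, localization_error, make_inverse
from .simulate import EpochSet

__all__ = [
    "ChannelMask",
    "ConstraintSpec",
    "ParetoRecord",
    "GaConfig",
    "evaluate_mask",
    "check_constraints",
    "nondominated_sort",
    "crowding_distance",
    "run_nsga2",
    "run_cascade",
    "mirror_expand",
    "Nsga2Result",
]

_MAX_CONSECUTIVE_REJECTIONS = 10_000


class ConstraintViolation(ValueError):
    pass


@dataclass(frozen=True)
class ChannelMask:
    """Binary chromosome over the candidate electrode positions."""

    bits: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "bits", np.asarray(self.bits, bool))

    @classmethod
    def from_labels(cls, labels, montage: Montage) -> "ChannelMask":
        bits = np.zeros(len(montage), bool)
        for l in labels:
            bits[montage.index_of(l)] = True
        return cls(bits)

    def labels(self, montage: Montage) -> list[str]:
        return [montage.labels[i] for i in np.flatnonzero(self.bits)]

    @property
    def n_channels(self) -> int:
        return int(self.bits.sum())

    def key(self) -> bytes:
        return np.packbits(self.bits).tobytes()

    def __len__(self) -> int:
        return self.bits.size


@dataclass(frozen=True)
class ConstraintSpec:
    """Active placement constraints for the search."""

    allowed_labels: frozenset | None = None
    symmetric: bool = False
    parent_mask: ChannelMask | None = None
    target_counts: tuple[int, ...] | None = None


@dataclass(frozen=True)
class ParetoRecord:
    mask: ChannelMask
    mean_loc_error: float  # mm
    n_channels: int
    generation_found: int = 0

    def __post_init__(self):
        if self.mean_loc_error < 0:
            raise ValueError("mean localization error must be non-negative")

    def dominates(self, other: "ParetoRecord") -> bool:
        no_worse = (
            self.mean_loc_error <= other.mean_loc_error
            and self.n_channels <= other.n_channels
        )
        better = (
            self.mean_loc_error < other.mean_loc_error
            or self.n_channels < other.n_channels
        )
        return no_worse and better


@dataclass(frozen=True)
class GaConfig:
    population_size: int = 100
    n_generations: int = 100
    crossover_rate: float = 0.9
    mutation_rate: float | None = None  # per gene; None -> 1/g
    seed: int = 0
    esi_method: str = "sloreta"
    lambda2: float = 0.0

    def __post_init__(self):
        if self.population_size < 2 or self.population_size % 2:
            raise ValueError("population_size must be even and >= 2")
        if not 0.0 <= self.crossover_rate <= 1.0:
            raise ValueError("crossover_rate must be in [0, 1]")
        if self.mutation_rate is not None and not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must be in [0, 1]")


def evaluate_mask(
    mask: ChannelMask,
    lf: LeadField,
    epochs: EpochSet,
    truth=None,
    esi_method: str = "sloreta",
    lambda2: float = 0.0,
) -> tuple[float, int]:
    """(mean localization error over all epochs in mm, channel count).

    One inverse operator is built per mask and applied to every epoch; the
    error of each epoch's power peak against its ground-truth source is
    averaged over the whole set.
    """
    if mask.n_channels == 0:
        raise ConstraintViolation("empty channel mask")
    truth = epochs.truth if truth is None else np.asarray(truth, int)
    op = make_inverse(esi_method, lf, lambda2, mask.bits)
    src = lf.source_space
    errors = [
        localization_error(est, t, src)
        for est, t in zip(apply_inverse(op, epochs), truth)
    ]
    return float(np.mean(errors)), mask.n_channels


def check_constraints(mask: ChannelMask, spec: ConstraintSpec, montage: Montage) -> bool:
    """True iff every active constraint holds for ``mask``.

    Symmetry means equal numbers of selected left- and right-hemisphere
    channels; midline (z-suffix) electrodes are exempt from the balance.
    """
    idx = np.flatnonzero(mask.bits)
    labels = [montage.labels[i] for i in idx]
    if spec.allowed_labels is not None and not set(labels) <= set(spec.allowed_labels):
        return False
    if spec.symmetric:
        sides = [label_side(l) for l in labels]
        if sides.count("L") != sides.count("R"):
            return False
    if spec.parent_mask is not None:
        if np.any(mask.bits & ~spec.parent_mask.bits):
            return False
    return True


def nondominated_sort(records: list[ParetoRecord]) -> list[list[int]]:
    """Fast non-dominated sorting; returns index fronts, best first."""
    n = len(records)
    dominated_by: list[list[int]] = [[] for _ in range(n)]
    n_dominating = np.zeros(n, dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            if records[i].dominates(records[j]):
                dominated_by[i].append(j)
                n_dominating[j] += 1
            elif records[j].dominates(records[i]):
                dominated_by[j].append(i)
                n_dominating[i] += 1
    fronts: list[list[int]] = []
    current = [i for i in range(n) if n_dominating[i] == 0]
    while current:
        fronts.append(current)
        nxt: list[int] = []
        for i in current:
            for j in dominated_by[i]:
                n_dominating[j] -= 1
                if n_dominating[j] == 0:
                    nxt.append(j)
        current = nxt
    return fronts


def crowding_distance(records: list[ParetoRecord], front: list[int]) -> np.ndarray:
    """NSGA-II crowding distance of the members of one front."""
    m = len(front)
    dist = np.zeros(m)
    if m <= 2:
        dist[:] = np.inf
        return dist
    for objective in (
        lambda r: r.mean_loc_error,
        lambda r: float(r.n_channels),
    ):
        vals = np.array([objective(records[i]) for i in front])
        order = np.argsort(vals, kind="stable")
        dist[order[0]] = dist[order[-1]] = np.inf
        span = vals[order[-1]] - vals[order[0]]
        if span <= 0:
            continue
        dist[order[1:-1]] += (vals[order[2:]] - vals[order[:-2]]) / span
    return dist


@dataclass
class Nsga2Result:
    archive: list[ParetoRecord]
    population: list[ParetoRecord]
    config: GaConfig

    def pareto_front(self) -> list[ParetoRecord]:
        """Mutually non-dominating archive members, sorted by channel count."""
        fronts = nondominated_sort(self.archive)
        best = [self.archive[i] for i in fronts[0]] if fronts else []
        return sorted(best, key=lambda r: (r.n_channels, r.mean_loc_error))

    def best_per_count(self) -> dict[int, ParetoRecord]:
        """Lowest-error archive member for each channel count."""
        best: dict[int, ParetoRecord] = {}
        for rec in self.archive:
            cur = best.get(rec.n_channels)
            if cur is None or rec.mean_loc_error < cur.mean_loc_error:
                best[rec.n_channels] = rec
        return dict(sorted(best.items()))


def _candidate_indices(spec: ConstraintSpec, montage: Montage) -> np.ndarray:
    """Genes allowed to be set: the search-space and cascade constraints are
    enforced structurally, only symmetry is handled by rejection."""
    ok = np.ones(len(montage), bool)
    if spec.allowed_labels is not None:
        allowed = set(spec.allowed_labels)
        ok &= np.array([l in allowed for l in montage.labels])
    if spec.parent_mask is not None:
        ok &= spec.parent_mask.bits
    if not ok.any():
        raise ConstraintViolation("constraint set admits no channels")
    return np.flatnonzero(ok)


def _random_mask(rng, g: int, candidates: np.ndarray, lo: int, hi: int) -> ChannelMask:
    count = int(rng.integers(lo, hi + 1))
    count = min(count, candidates.size)
    chosen = rng.choice(candidates, size=count, replace=False)
    bits = np.zeros(g, bool)
    bits[chosen] = True
    return ChannelMask(bits)


def run_nsga2(
    lf: LeadField,
    epochs: EpochSet,
    truth=None,
    spec: ConstraintSpec = ConstraintSpec(),
    cfg: GaConfig = GaConfig(),
) -> Nsga2Result:
    """Seeded NSGA-II over channel masks; returns the full evaluation archive.

    Initial masks draw their channel count uniformly in [4, g/2] (clipped to
    the candidate-set size) to seed the whole range of the front.  Evaluations
    are memoized by mask, duplicates are archived once.
    """
    montage = lf.montage
    g = len(montage)
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    candidates = _candidate_indices(spec, montage)
    mut_rate = cfg.mutation_rate if cfg.mutation_rate is not None else 1.0 / g
    lo = min(4, max(1, candidates.size // 2))
    hi = max(lo, candidates.size // 2)
    if spec.target_counts:
        hi = max(hi, min(candidates.size, max(spec.target_counts)))

    cache: dict[bytes, tuple[float, int]] = {}
    archive: dict[bytes, ParetoRecord] = {}

    def evaluate(mask: ChannelMask, generation: int) -> ParetoRecord:
        key = mask.key()
        if key not in cache:
            cache[key] = evaluate_mask(
                mask, lf, epochs, truth, cfg.esi_method, cfg.lambda2
            )
        err, count = cache[key]
        rec = ParetoRecord(mask, err, count, generation)
        if key not in archive:
            archive[key] = rec
        return rec

    def draw_valid(make, what: str) -> ChannelMask:
        for _ in range(_MAX_CONSECUTIVE_REJECTIONS):
            mask = make()
            if mask.n_channels >= 1 and check_constraints(mask, spec, montage):
                return mask
        raise ConstraintViolation(
            f"{what}: {_MAX_CONSECUTIVE_REJECTIONS} consecutive constraint rejections"
        )

    population = [
        evaluate(draw_valid(lambda: _random_mask(rng, g, candidates, lo, hi), "init"), 0)
        for _ in range(cfg.population_size)
    ]

    def tournament(ranks: np.ndarray, crowd: np.ndarray) -> int:
        a, b = rng.integers(0, len(population), size=2)
        if ranks[a] != ranks[b]:
            return a if ranks[a] < ranks[b] else b
        return a if crowd[a] >= crowd[b] else b

    def make_child(pa: ChannelMask, pb: ChannelMask) -> ChannelMask:
        if rng.random() < cfg.crossover_rate:
            take_a = rng.random(g) < 0.5
            bits = np.where(take_a, pa.bits, pb.bits)
        else:
            bits = pa.bits.copy()
        flip = np.zeros(g, bool)
        flip[candidates] = rng.random(candidates.size) < mut_rate
        return ChannelMask(bits ^ flip)

    for generation in range(1, cfg.n_generations + 1):
        ranks = np.empty(len(population), int)
        crowd = np.empty(len(population))
        for rank, front in enumerate(nondominated_sort(population)):
            ranks[front] = rank
            crowd[front] = crowding_distance(population, front)
        offspring = []
        while len(offspring) < cfg.population_size:
            pa = population[tournament(ranks, crowd)].mask
            pb = population[tournament(ranks, crowd)].mask
            child = draw_valid(lambda: make_child(pa, pb), f"generation {generation}")
            offspring.append(evaluate(child, generation))
        # elitist environmental selection on parents + offspring
        combined = population + offspring
        selected: list[ParetoRecord] = []
        for front in nondominated_sort(combined):
            if len(selected) + len(front) <= cfg.population_size:
                selected.extend(combined[i] for i in front)
            else:
                cd = crowding_distance(combined, front)
                order = np.argsort(-cd, kind="stable")
                room = cfg.population_size - len(selected)
                selected.extend(combined[front[i]] for i in order[:room])
                break
        population = selected

    return Nsga2Result(list(archive.values()), population, cfg)


def run_cascade(
    lf: LeadField,
    epochs: EpochSet,
    truth=None,
    counts=(32, 16, 8),
    spec: ConstraintSpec = ConstraintSpec(),
    cfg: GaConfig = GaConfig(),
) -> dict[int, tuple[ParetoRecord, Nsga2Result]]:
    """Nested optimizations for decreasing channel counts.

    Each stage after the first restricts its search space to the best mask the
    previous stage found at its target count.  If a stage's archive holds no
    mask at exactly the target count, the nearest available count is used with
    a warning.
    """
    counts = list(counts)
    if any(b >= a for a, b in zip(counts, counts[1:])):
        raise ValueError("counts must be strictly decreasing")
    results: dict[int, tuple[ParetoRecord, Nsga2Result]] = {}
    stage_spec = replace(spec, target_counts=tuple(counts))
    for i, target in enumerate(counts):
        if stage_spec.parent_mask is not None and stage_spec.parent_mask.n_channels < target:
            raise ConstraintViolation(
                f"cascade parent has fewer channels than target {target}"
            )
        res = run_nsga2(lf, epochs, truth, stage_spec, replace(cfg, seed=cfg.seed + i))
        per_count = res.best_per_count()
        if target in per_count:
            best = per_count[target]
        else:
            available = np.array(sorted(per_count))
            nearest = int(available[np.argmin(np.abs(available - target))])
            warnings.warn(
                f"no mask with exactly {target} channels; using nearest count {nearest}"
            )
            best = per_count[nearest]
        results[target] = (best, res)
        stage_spec = replace(stage_spec, parent_mask=best.mask)
    return results


def mirror_expand(mask: ChannelMask, montage: Montage) -> ChannelMask:
    """Add each selected channel's opposite-hemisphere partner.

    Midline channels are fixed points; a missing mirror label raises a warning
    and the channel is kept unpaired.
    """
    bits = mask.bits.copy()
    for i in np.flatnonzero(mask.bits):
        label = montage.labels[i]
        partner = mirror_label(label)
        if partner == label:
            continue
        try:
            bits[montage.index_of(partner)] = True
        except ValueError:
            warnings.warn(f"mirror label {partner!r} not in montage; skipping {label}")
    return ChannelMask(bits)
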