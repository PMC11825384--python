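"""Candidate enumeration, shape-distance metrics, ranking, Pareto front.

Given a wild-type sequence and a set of mutable positions (at most 7), the
engine enumerates the full 4^m Cartesian product of bases at those
positions — up to 4^7 = 16384 candidates, the wild type included and
flagged — predicts a shape profile for every candidate, and scores each
against the wild type along two axes:

* base-readout distance (physicochemical functional-group, one-hot, or
  Levenshtein; see :mod:`shapemut.seq_encoding`), and
* shape-readout distance over a user-selected feature subset, either
  Euclidean (default; absolute profile change) or Pearson (1 - r per
  feature; pattern change, insensitive to constant offsets).

Shape distances may be restricted to *focal* positions — e.g. the spacer
between cooperative binding sites — so that only shape change in the region
of interest counts.  Because a point mutation perturbs shape only within
the predictor's window reach, candidates mutated far from every focal
point score zero shape change under focal restriction.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .errors import (
    CoordinateError,
    DegenerateCorrelationError,
    EmptyFocalError,
    InsufficientFocalError,
    LengthMismatchError,
    PositionLimitError,
)
from .seq_encoding import (
    ALPHABET,
    NucleotideSequence,
    levenshtein_distance,
    onehot_distance,
    physchem_distance,
)
from .shape_engine import (
    FeatureClass,
    ShapeProfile,
    feature_by_name,
)

#: Combinatorial budget: at most 4^7 = 16384 candidates per run.
MAX_POSITIONS = 7

BASE_METRICS = {
    "physchem": physchem_distance,
    "onehot": onehot_distance,
    "levenshtein": levenshtein_distance,
}
SHAPE_METRICS = ("euclidean", "pearson")


@dataclass(frozen=True)
class MutationSpec:
    """Set of 1-based mutable positions, at most :data:`MAX_POSITIONS`."""

    positions: Tuple[int, ...]

    def __init__(self, positions: Iterable[int]):
        pos = tuple(sorted(int(p) for p in positions))
        if len(set(pos)) != len(pos):
            raise CoordinateError(f"duplicate mutation positions in {pos}")
        if len(pos) > MAX_POSITIONS:
            raise PositionLimitError(
                f"{len(pos)} mutable positions requested; at most "
                f"{MAX_POSITIONS} are supported (4^{MAX_POSITIONS} = "
                f"{4 ** MAX_POSITIONS} candidates)"
            )
        if not pos:
            raise CoordinateError("need at least one mutation position")
        object.__setattr__(self, "positions", pos)

    def validate(self, n: int) -> None:
        for p in self.positions:
            if not 1 <= p <= n:
                raise CoordinateError(
                    f"mutation position {p} outside sequence of length {n}"
                )


@dataclass(frozen=True)
class FocalRegion:
    """1-based positions over which shape distances are computed."""

    positions: Tuple[int, ...]

    def __init__(self, positions: Iterable[int]):
        pos = tuple(sorted(set(int(p) for p in positions)))
        if not pos:
            raise EmptyFocalError("focal region must contain at least one position")
        object.__setattr__(self, "positions", pos)

    @classmethod
    def full(cls, n: int) -> "FocalRegion":
        return cls(range(1, n + 1))

    def validate(self, n: int) -> None:
        for p in self.positions:
            if not 1 <= p <= n:
                raise CoordinateError(
                    f"focal position {p} outside sequence of length {n}"
                )


@dataclass
class DistanceConfig:
    """How base and shape distances are computed.

    ``normalize=None`` (auto) z-scores feature values, pooled over the
    candidate ensemble, when two or more features are selected — features
    carry incommensurate units (Angstrom vs degrees) — and leaves a single
    feature unscaled.  ``norm_stats`` is filled in by :func:`run_design`
    when normalization is active.
    """

    features: Tuple[str, ...] = ("MGW",)
    shape_metric: str = "euclidean"
    base_metric: str = "physchem"
    focal: Optional[FocalRegion] = None
    normalize: Optional[bool] = None
    norm_stats: Optional[Dict[str, Tuple[float, float]]] = field(
        default=None, repr=False
    )

    def __post_init__(self):
        if self.shape_metric not in SHAPE_METRICS:
            raise ValueError(
                f"shape_metric must be one of {SHAPE_METRICS}, "
                f"got {self.shape_metric!r}"
            )
        if self.base_metric not in BASE_METRICS:
            raise ValueError(
                f"base_metric must be one of {tuple(BASE_METRICS)}, "
                f"got {self.base_metric!r}"
            )
        feats = tuple(self.features)
        if not feats:
            raise ValueError("at least one shape feature must be selected")
        for f in feats:
            feature_by_name(f)
        self.features = feats

    @property
    def normalize_effective(self) -> bool:
        if self.normalize is None:
            return len(self.features) >= 2
        return bool(self.normalize)


@dataclass
class CandidateResult:
    """One scored mutation candidate."""

    sequence: str
    substitutions: Tuple[Tuple[int, str, str], ...]  # (1-based pos, wt, mut)
    base_distance: float
    shape_distance: float
    feature_distances: Dict[str, float]
    is_wildtype: bool
    rank: int = 0


def enumerate_candidates(wt, spec: MutationSpec) -> List[NucleotideSequence]:
    """All 4^m substitution candidates at the spec's positions.

    The full Cartesian product of {A, C, G, T} over the (sorted) mutable
    positions, every other position fixed; generation order is
    lexicographic in the substituted bases, and the wild type itself is
    among the candidates.
    """
    wt = NucleotideSequence(wt)
    spec.validate(len(wt))
    chars = list(wt)
    out: List[NucleotideSequence] = []
    for combo in itertools.product(ALPHABET, repeat=len(spec.positions)):
        c = chars.copy()
        for p, b in zip(spec.positions, combo):
            c[p - 1] = b
        out.append(NucleotideSequence("".join(c)))
    return out


def substitutions_of(wt, candidate) -> Tuple[Tuple[int, str, str], ...]:
    """(1-based position, wt base, candidate base) for every difference."""
    wt, candidate = NucleotideSequence(wt), NucleotideSequence(candidate)
    if len(wt) != len(candidate):
        raise LengthMismatchError("candidate and wild type differ in length")
    return tuple(
        (i, a, b) for i, (a, b) in enumerate(zip(wt, candidate), start=1) if a != b
    )


def focal_indices(
    focal: FocalRegion, feature_klass: FeatureClass, n: int
) -> np.ndarray:
    """1-based profile indices selected by a focal region.

    Per-base-pair features use the focal positions directly.  For step
    features, a step is included when at least one of its two endpoint
    positions is focal: step j (1-based, between positions j and j+1) is
    selected iff j or j+1 is focal.
    """
    focal.validate(n)
    if feature_klass is FeatureClass.INTER_BP:
        steps = set()
        for p in focal.positions:
            if p - 1 >= 1:
                steps.add(p - 1)
            if p <= n - 1:
                steps.add(p)
        return np.array(sorted(steps), dtype=np.int64)
    return np.array(focal.positions, dtype=np.int64)


def _restricted(
    profile: ShapeProfile, feature: str, focal: Optional[FocalRegion]
) -> np.ndarray:
    feat = feature_by_name(feature)
    vec = profile[feature]
    if focal is None:
        return vec
    idx = focal_indices(focal, feat.klass, profile.n)
    idx = idx[idx <= len(vec)]  # step indices clipped to n-1
    if idx.size == 0:
        raise EmptyFocalError(
            f"focal region selects no indices for feature {feature!r}"
        )
    return vec[idx - 1]


def shape_distance_euclidean(
    wt_profile: ShapeProfile,
    cand_profile: ShapeProfile,
    cfg: DistanceConfig,
) -> Tuple[float, Dict[str, float]]:
    """Euclidean shape distance restricted to the focal region.

    Returns ``(overall, per_feature)`` where overall is the single square
    root of the sum of squared differences pooled over all selected
    features and focal indices, and per_feature holds each feature's own
    root-sum-of-squares contribution.  When ``cfg.norm_stats`` is set,
    values are z-scored per feature first.
    """
    if wt_profile.n != cand_profile.n:
        raise LengthMismatchError("profiles come from sequences of unequal length")
    total = 0.0
    per_feature: Dict[str, float] = {}
    for name in cfg.features:
        a = _restricted(wt_profile, name, cfg.focal).astype(float)
        b = _restricted(cand_profile, name, cfg.focal).astype(float)
        if cfg.norm_stats and name in cfg.norm_stats:
            mu, sd = cfg.norm_stats[name]
            a = (a - mu) / sd
            b = (b - mu) / sd
        ss = float(np.sum((a - b) ** 2))
        per_feature[name] = math.sqrt(ss)
        total += ss
    return math.sqrt(total), per_feature


def shape_distance_pearson(
    wt_profile: ShapeProfile,
    cand_profile: ShapeProfile,
    cfg: DistanceConfig,
) -> Tuple[float, Dict[str, float]]:
    """Correlation shape distance: per feature 1 - r over focal indices.

    The overall distance is the unweighted mean of the per-feature values
    and lies in [0, 2]; identical patterns score 0 regardless of constant
    offsets, anticorrelated patterns score 2.  Requires at least three
    usable focal values and nonzero variance in both restricted vectors
    (a constant profile has no pattern to correlate — this raises rather
    than silently returning 0).
    """
    if wt_profile.n != cand_profile.n:
        raise LengthMismatchError("profiles come from sequences of unequal length")
    per_feature: Dict[str, float] = {}
    for name in cfg.features:
        a = _restricted(wt_profile, name, cfg.focal).astype(float)
        b = _restricted(cand_profile, name, cfg.focal).astype(float)
        if a.size < 3:
            raise InsufficientFocalError(
                f"feature {name!r}: Pearson distance needs >= 3 focal values, "
                f"got {a.size}"
            )
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            raise DegenerateCorrelationError(
                f"feature {name!r}: zero variance in restricted profile; "
                "Pearson distance is undefined"
            )
        r = float(np.corrcoef(a, b)[0, 1])
        per_feature[name] = 1.0 - r
    overall = float(np.mean(list(per_feature.values())))
    return overall, per_feature


def _pooled_norm_stats(
    profiles: Sequence[ShapeProfile], cfg: DistanceConfig
) -> Dict[str, Tuple[float, float]]:
    """Per-feature mean/SD of focal values pooled over the whole ensemble.

    A zero pooled SD (feature untouched by any candidate) falls back to 1
    so the feature contributes raw differences of zero rather than NaN.
    """
    stats: Dict[str, Tuple[float, float]] = {}
    for name in cfg.features:
        pooled = np.concatenate(
            [_restricted(p, name, cfg.focal).astype(float) for p in profiles]
        )
        sd = float(np.std(pooled))
        stats[name] = (float(np.mean(pooled)), sd if sd > 0 else 1.0)
    return stats


def run_design(
    wt,
    spec: MutationSpec,
    cfg: DistanceConfig,
    predictor,
    objective: str = "max",
) -> List[CandidateResult]:
    """Enumerate, score and rank all mutation candidates against the wild type.

    ``objective`` sets the ranking direction for the shape distance:
    ``"max"`` puts the largest shape change first (shape-perturbing
    design), ``"min"`` the smallest (shape-preserving design).  Ties are
    broken by ascending base distance, then lexicographic sequence, so the
    output order is fully deterministic.
    """
    if objective not in ("max", "min"):
        raise ValueError(f"objective must be 'max' or 'min', got {objective!r}")
    wt = NucleotideSequence(wt)
    spec.validate(len(wt))
    if cfg.focal is not None:
        cfg.focal.validate(len(wt))
    candidates = enumerate_candidates(wt, spec)
    profiles = [predictor.predict(c, features=cfg.features) for c in candidates]
    wt_index = candidates.index(wt)
    wt_profile = profiles[wt_index]

    eff_cfg = cfg
    if cfg.shape_metric == "euclidean" and cfg.normalize_effective:
        eff_cfg = DistanceConfig(
            features=cfg.features,
            shape_metric=cfg.shape_metric,
            base_metric=cfg.base_metric,
            focal=cfg.focal,
            normalize=cfg.normalize,
            norm_stats=_pooled_norm_stats(profiles, cfg),
        )

    base_fn = BASE_METRICS[cfg.base_metric]
    shape_fn = (
        shape_distance_euclidean
        if cfg.shape_metric == "euclidean"
        else shape_distance_pearson
    )
    results: List[CandidateResult] = []
    for cand, prof in zip(candidates, profiles):
        overall, per_feature = shape_fn(wt_profile, prof, eff_cfg)
        results.append(
            CandidateResult(
                sequence=str(cand),
                substitutions=substitutions_of(wt, cand),
                base_distance=float(base_fn(wt, cand)),
                shape_distance=overall,
                feature_distances=per_feature,
                is_wildtype=(cand == wt),
            )
        )
    sign = -1.0 if objective == "max" else 1.0
    results.sort(key=lambda r: (sign * r.shape_distance, r.base_distance, r.sequence))
    for i, r in enumerate(results, start=1):
        r.rank = i
    return results


def pareto_front(
    results: Sequence[CandidateResult], objective: str = "max"
) -> List[CandidateResult]:
    """Non-dominated candidates in the (base distance, shape distance) plane.

    Base distance is always minimized; ``objective`` sets the direction for
    shape distance.  A candidate is dominated when another is at least as
    good on both axes and strictly better on one.  Under ``"max"`` the
    wild type (zero edits, zero shape change) is excluded — it is trivially
    non-dominated but never a useful design.
    """
    if not results:
        raise ValueError("pareto_front needs at least one candidate")
    if objective not in ("max", "min"):
        raise ValueError(f"objective must be 'max' or 'min', got {objective!r}")
    pool = [r for r in results if not (objective == "max" and r.is_wildtype)]
    better = max if objective == "max" else min
    # sweep base-distance groups in ascending order; a point survives iff its
    # shape value is the group's best AND strictly better than every
    # strictly-cheaper group's best
    pool_sorted = sorted(pool, key=lambda r: r.base_distance)
    front: List[CandidateResult] = []
    best_cheaper: Optional[float] = None
    i = 0
    while i < len(pool_sorted):
        j = i
        while (
            j < len(pool_sorted)
            and pool_sorted[j].base_distance == pool_sorted[i].base_distance
        ):
            j += 1
        group = pool_sorted[i:j]
        group_best = better(r.shape_distance for r in group)
        improves = best_cheaper is None or (
            group_best > best_cheaper
            if objective == "max"
            else group_best < best_cheaper
        )
        if improves:
            front.extend(r for r in group if r.shape_distance == group_best)
            best_cheaper = group_best
        else:
            best_cheaper = better(best_cheaper, group_best)
        i = j
    front.sort(key=lambda r: r.rank)
    return front
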