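"""Piecewise logistic feature scoring.

Every primer/pair feature is mapped to a score by the same curve family: a
plateau of 1 over the feature's optimal range, flanked by two logistic
(sigmoid) tails.  A parameter set is six numbers, written in configuration
order ``(MinO, MaxO, Min, Max, MinL, MaxL)``:

* ``[MinO, MaxO]`` -- the optimal range, score 1 (the full score);
* ``Min`` / ``Max`` -- the points where the score crosses 0;
* ``MinL`` / ``MaxL`` -- the saturation limits where the score approaches its
  (usually negative) minimum.

The left tail for ``x <= MinO`` is ``L/(1+e^{-k(x-x0)}) - y0`` with
``k = 10/(MinO-MinL)``, ``x0 = (MinO+MinL)/2``, ``y0 = e^{k(Min-x0)}`` and
``L = 1+y0``; the right tail mirrors it.  ``f(Min) = 0`` and ``f(Max) = 0``
hold algebraically for every valid parameter set.  A branch with
``MinO == MinL`` (or ``MaxO == MaxL``) would divide by zero; such a branch is
*disabled* and scores 1 on that whole side -- the convention used by several
built-in feature models ("large enough" limits) to mean "no penalty in that
direction".

Composite penalties for variant (SNP) and homopolymer (poly) annotations and
the weighted-sum aggregation that turns per-feature scores into a 0-100
primer or pair score also live here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping, Sequence


class ScoreModelError(ValueError):
    """Invalid model parameters, weights or penalty annotations."""


@dataclass(frozen=True)
class ModelParams:
    """One piecewise logistic parameter set.

    Constructor argument order follows the configuration convention
    ``(MinO, MaxO, Min, Max, MinL, MaxL)``.
    """

    opt_min: float
    opt_max: float
    zero_min: float
    zero_max: float
    lim_min: float
    lim_max: float

    def __post_init__(self) -> None:
        vals = (self.opt_min, self.opt_max, self.zero_min, self.zero_max,
                self.lim_min, self.lim_max)
        if not all(math.isfinite(v) for v in vals):
            raise ScoreModelError(f"non-finite model parameters: {vals}")
        if not (self.lim_min <= self.zero_min <= self.opt_min
                <= self.opt_max <= self.zero_max <= self.lim_max):
            raise ScoreModelError(
                "model parameters must satisfy "
                "MinL <= Min <= MinO <= MaxO <= Max <= MaxL, got "
                f"({self.opt_min}, {self.opt_max}, {self.zero_min}, "
                f"{self.zero_max}, {self.lim_min}, {self.lim_max})")

    @property
    def left_disabled(self) -> bool:
        return self.opt_min == self.lim_min

    @property
    def right_disabled(self) -> bool:
        return self.opt_max == self.lim_max

    @classmethod
    def from_sequence(cls, values: Sequence[float] | str) -> "ModelParams":
        """Parse six numbers in order (MinO, MaxO, Min, Max, MinL, MaxL).

        Accepts a comma-separated string, the configuration-file syntax.
        """
        if isinstance(values, str):
            values = [float(v) for v in values.split(",")]
        values = list(values)
        if len(values) != 6:
            raise ScoreModelError(
                f"expected 6 model parameters, got {len(values)}")
        return cls(*(float(v) for v in values))

    def as_tuple(self) -> tuple[float, ...]:
        return (self.opt_min, self.opt_max, self.zero_min, self.zero_max,
                self.lim_min, self.lim_max)


@dataclass(frozen=True)
class BranchConstants:
    """Logistic constants of one tail: k, x0, y0 and L = 1 + y0."""

    k: float
    x0: float
    y0: float
    l: float


@dataclass(frozen=True)
class LogisticConstants:
    """Constants of both tails; a disabled branch is ``None``."""

    left: BranchConstants | None
    right: BranchConstants | None


def _branch(opt: float, zero: float, lim: float) -> BranchConstants:
    k = 10.0 / (opt - lim)
    x0 = (opt + lim) / 2.0
    y0 = math.exp(k * (zero - x0))
    return BranchConstants(k=k, x0=x0, y0=y0, l=1.0 + y0)


@lru_cache(maxsize=None)
def logistic_constants(params: ModelParams) -> LogisticConstants:
    """Derive the tail constants of a parameter set.

    ``k = 10/(MinO−MinL)``, ``x0 = (MinO+MinL)/2``, ``y0 = e^{k(Min−x0)}``,
    ``L = 1+y0`` on the left, mirrored on the right (where ``k`` comes out
    negative because MaxL > MaxO).
    """
    left = None if params.left_disabled else _branch(
        params.opt_min, params.zero_min, params.lim_min)
    right = None if params.right_disabled else _branch(
        params.opt_max, params.zero_max, params.lim_max)
    return LogisticConstants(left=left, right=right)


def piecewise_score(x: float, params: ModelParams) -> float:
    """Score a feature value.

    Left logistic for ``x <= MinO``, exactly 1 on ``(MinO, MaxO]``, right
    logistic for ``x > MaxO``.  A disabled branch scores 1 on its side.  No
    clamping is applied beyond the limits: the logistic is already monotone
    and bounded by ``-y0`` asymptotically.
    """
    if not math.isfinite(x):
        raise ScoreModelError(f"non-finite feature value: {x}")
    c = logistic_constants(params)
    if x <= params.opt_min:
        # a single-point optimal range (MinO == MaxO, e.g. the EndA
        # optimum at exactly one 3' adenine) is attainable and scores 1;
        # a non-degenerate range evaluates the left logistic at MinO as
        # the model is written
        if x == params.opt_min and params.opt_min == params.opt_max:
            return 1.0
        b = c.left
    elif x <= params.opt_max:
        return 1.0
    else:
        b = c.right
    if b is None:
        return 1.0
    exponent = -b.k * (x - b.x0)
    if exponent > 700.0:  # tail saturated at its asymptote -y0
        return -b.y0
    return b.l / (1.0 + math.exp(exponent)) - b.y0


@dataclass(frozen=True)
class SiteAnnotation:
    """A SNP or homopolymer inside a primer.

    ``dist3`` is the distance from the primer 3' end in bases (0 for the
    3'-terminal base -- the position where a variant hurts most);  ``length``
    is the variant/run length in bases.
    """

    dist3: int
    length: int

    def __post_init__(self) -> None:
        if self.dist3 < 0:
            raise ScoreModelError(f"negative dist3: {self.dist3}")
        if self.length < 1:
            raise ScoreModelError(f"length must be >= 1: {self.length}")


# Penalty constants: score = 1 - sum_j a * [f(p_j) + b] * f(l_j).
# a scales the whole penalty, b is the floor paid per site regardless of its
# distance to the 3' end.
_PENALTY_CONSTANTS = {"snp": (4.0, 0.2), "poly": (2.0, 2.0)}


def site_penalty_score(
    sites: Iterable[SiteAnnotation],
    kind: str,
    models: Mapping[str, ModelParams] | None = None,
) -> float:
    """Composite SNP/poly score: ``1 - sum a*[f(p_j)+b]*f(l_j)``.

    Empty input returns exactly 1; the result is unclamped and may go
    negative for severe inputs (e.g. a long 3'-terminal homopolymer).
    """
    kind = kind.lower()
    if kind not in _PENALTY_CONSTANTS:
        raise ScoreModelError(f"kind must be 'snp' or 'poly', got {kind!r}")
    if models is None:
        models = DEFAULT_MODELS
    a, b = _PENALTY_CONSTANTS[kind]
    pos_model = models[f"{kind}_pos"]
    len_model = models[f"{kind}_len"]
    penalty = 0.0
    for site in sites:
        penalty += a * (piecewise_score(site.dist3, pos_model) + b) \
            * piecewise_score(site.length, len_model)
    return 1.0 - penalty


class FeatureWeights(Mapping[str, float]):
    """Immutable feature -> weight table; weights are >= 0 and sum to 100."""

    def __init__(self, weights: Mapping[str, float]):
        table = {str(k): float(v) for k, v in weights.items()}
        if any(v < 0 for v in table.values()):
            raise ScoreModelError(f"negative weight in {table}")
        total = sum(table.values())
        if not math.isclose(total, 100.0, rel_tol=0, abs_tol=1e-9):
            raise ScoreModelError(
                f"weights must sum to 100, got {total} in {table}")
        self._table = table

    def __getitem__(self, key: str) -> float:
        return self._table[key]

    def __iter__(self):
        return iter(self._table)

    def __len__(self) -> int:
        return len(self._table)

    def __repr__(self) -> str:
        return f"FeatureWeights({self._table})"

    def drop(self, feature: str) -> "FeatureWeights":
        """Remove a feature, redistributing its weight proportionally."""
        if feature not in self._table:
            return self
        rest = {k: v for k, v in self._table.items() if k != feature}
        remaining = sum(rest.values())
        if remaining <= 0:
            raise ScoreModelError(
                f"cannot drop {feature!r}: no weight left to redistribute")
        scale = 100.0 / remaining
        return FeatureWeights({k: v * scale for k, v in rest.items()})


def weighted_total(
    scores: Mapping[str, float],
    weights: FeatureWeights,
) -> float:
    """Weighted sum of per-feature scores on the 0-100 scale.

    Weights are on the 0-100 scale and scores on the <=1 scale, so an
    all-optimal input totals exactly 100.
    """
    missing = [k for k in weights if k not in scores]
    if missing:
        raise ScoreModelError(f"missing feature scores: {missing}")
    return sum(w * scores[name] for name, w in weights.items())


def tm_model(opt_tm: float) -> ModelParams:
    """f(Tm) parameter set (T, T+1, T-2, T+5, T-5, T+10) around the
    user-chosen optimal melting temperature T (degrees C)."""
    t = float(opt_tm)
    return ModelParams(t, t + 1, t - 2, t + 5, t - 5, t + 10)


#: Built-in parameter sets, keyed by feature name.  Order within each tuple
#: is (MinO, MaxO, Min, Max, MinL, MaxL).  "Tm" is instantiated at run time
#: from the user's optimal Tm via :func:`tm_model`.
DEFAULT_MODELS: dict[str, ModelParams] = {
    # single-primer features
    "GC": ModelParams(0.55, 0.6, 0.45, 0.65, 0.3, 0.7),
    "Self": ModelParams(-50, 45, -50, 50, -50, 55),
    "EndA": ModelParams(1, 1, 0, 4, -1, 7),
    "EnddG": ModelParams(-9, -7, -12, -6, -14, -5),
    # SNP/poly penalty components (position = distance to 3' end)
    "snp_pos": ModelParams(0, 0, 0, 10, 0, 10),
    "poly_pos": ModelParams(0, 0, 0, 10, 0, 10),
    "snp_len": ModelParams(15, 100, -15, 100, -15, 100),
    "poly_len": ModelParams(15, 100, 0, 100, 0, 100),
    # binding/product efficiency components
    "btm": ModelParams(60, 100, 45, 100, 45, 100),
    "mismatch_pos": ModelParams(25, 100, 0.95, 100, 0.95, 100),
    # pair relation features
    "Tmdiff": ModelParams(0, 1, 0, 4, 0, 8),
    "Lendiff": ModelParams(0, 2, 0, 6, 0, 10),
    "Pos": ModelParams(10, 20, 5, 45, 5, 45),
    "Dis": ModelParams(120, 160, 100, 180, 80, 200),
    "oEff": ModelParams(0, 0, 0, 0.02, 0, 0.1),
}


def default_models(
    opt_tm: float | None = None,
    overrides: Mapping[str, ModelParams] | None = None,
) -> dict[str, ModelParams]:
    """Copy of the registry, with f(Tm) instantiated and overrides applied."""
    models = dict(DEFAULT_MODELS)
    if opt_tm is not None:
        models["Tm"] = tm_model(opt_tm)
    if overrides:
        models.update(overrides)
    return models


# Default weight tables.  The published constraint is only that each table
# sums to 100; the split below gives the most weight to the features with a
# major effect on amplification (Tm, GC, specificity, product size) and
# little to EndA/Tmdiff/Lendiff.
DEFAULT_PRIMER_WEIGHTS = FeatureWeights({
    "Tm": 30, "GC": 15, "Self": 15, "EnddG": 15, "SNP": 15,
    "poly": 7, "EndA": 3,
})
DEFAULT_RELATION_WEIGHTS = FeatureWeights({
    "oEff": 50, "Dis": 25, "Pos": 15, "Tmdiff": 6, "Lendiff": 4,
})
DEFAULT_PAIR_WEIGHTS = FeatureWeights({
    "Primer1": 25, "Primer2": 25, "relation": 50,
})
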