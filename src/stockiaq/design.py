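"""Latin Hypercube training designs over building/physics parameters.

The surrogate is trained on simulator runs at parameter points placed by a
Latin Hypercube design: each continuous dimension is stratified into n
equal-probability bins with exactly one sample per bin, giving much better
marginal coverage than i.i.d. sampling at small n. Emission rates are drawn
through a truncated power-law (Pareto) inverse CDF, reflecting the
heavy-tailed distribution of domestic CO source strengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import qmc


@dataclass
class ParameterSpec:
    """One design dimension.

    families: ``uniform`` (bounds), ``truncnorm`` (bounds + loc/scale),
    ``powerlaw`` (bounds + exponent > 1), ``categorical`` (levels [+ probs]).
    """

    name: str
    family: str
    bounds: tuple[float, float] | None = None
    loc: float = 0.0
    scale: float = 1.0
    exponent: float = 2.0
    levels: Sequence | None = None
    probs: Sequence[float] | None = None
    units: str = ""

    def __post_init__(self) -> None:
        if self.family == "categorical":
            if not self.levels:
                raise ValueError(f"{self.name}: categorical needs levels")
        else:
            if self.bounds is None or not self.bounds[0] < self.bounds[1]:
                raise ValueError(f"{self.name}: bounds must be ordered")
            if self.family == "powerlaw":
                if self.bounds[0] <= 0:
                    raise ValueError(f"{self.name}: power-law lower bound must be > 0")
                if self.exponent <= 1:
                    raise ValueError(f"{self.name}: power-law exponent must be > 1")


@dataclass
class ParameterSpace:
    """Ordered list of design dimensions with unique names."""

    params: list[ParameterSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [p.name for p in self.params]
        if len(set(names)) != len(names):
            raise ValueError("parameter names must be unique")

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.params]


def power_law_sample(x_min: float, x_max: float, exponent: float, u):
    """Inverse-CDF transform of the truncated Pareto density p(x) ∝ x^−a.

    u = 0 maps to x_min, u = 1 to x_max. For a = 2 this reduces to
    x = x_min / (1 − u·(1 − x_min/x_max)).
    """
    if not 0 < x_min < x_max:
        raise ValueError("need 0 < x_min < x_max")
    if exponent <= 1:
        raise ValueError("exponent must be > 1")
    u = np.asarray(u, dtype=float)
    if np.any(u < 0) or np.any(u > 1):
        raise ValueError("u must lie in [0, 1]")
    g = exponent - 1.0
    r = (x_min / x_max) ** g
    x = x_min * (1.0 - u * (1.0 - r)) ** (-1.0 / g)
    return float(x) if x.ndim == 0 else x


def _transform(spec: ParameterSpec, u: np.ndarray):
    if spec.family == "uniform":
        lo, hi = spec.bounds
        return lo + u * (hi - lo)
    if spec.family == "truncnorm":
        lo, hi = spec.bounds
        a = (lo - spec.loc) / spec.scale
        b = (hi - spec.loc) / spec.scale
        return stats.truncnorm.ppf(np.clip(u, 1e-12, 1 - 1e-12),
                                   a, b, loc=spec.loc, scale=spec.scale)
    if spec.family == "powerlaw":
        return power_law_sample(spec.bounds[0], spec.bounds[1], spec.exponent, u)
    if spec.family == "categorical":
        probs = (np.asarray(spec.probs, dtype=float) if spec.probs is not None
                 else np.full(len(spec.levels), 1.0 / len(spec.levels)))
        edges = np.cumsum(probs) / probs.sum()
        idx = np.searchsorted(edges, u, side="right").clip(0, len(spec.levels) - 1)
        return np.asarray(spec.levels, dtype=object)[idx]
    raise ValueError(f"unknown family {spec.family!r}")


def latin_hypercube(space: ParameterSpace, n: int, seed: int = 0) -> pd.DataFrame:
    """n-point Latin Hypercube design over the parameter space.

    Each continuous dimension has exactly one sample in each of n
    equal-probability strata; categorical dimensions are sampled
    proportionally through the same stratified uniforms. Deterministic for
    a given seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    sampler = qmc.LatinHypercube(d=len(space.params), seed=seed)
    u = sampler.random(n)
    cols = {p.name: _transform(p, u[:, j]) for j, p in enumerate(space.params)}
    return pd.DataFrame(cols)
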