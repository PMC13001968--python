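"""Synthetic Likert cohorts, noisy model trajectories, and the bundled
dental-cohort entropy fixture.

The cohort generator emulates the statistical texture of a multi-wave
aging survey on 5-category Likert items: per-item entropies starting in
the 1.9-2.25 bit range with gradual declines of 0.05-0.15 bits over the
study span, and respondent attrition shrinking the cohort to roughly a
third of its initial size when requested.  Counts are multinomial draws
from a category distribution matched exactly to a target entropy via a
one-parameter exponential tilt.

The trajectory generator produces observations of the ODE model itself
(truth plus i.i.d. Gaussian noise on the normalized scale), for
parameter-recovery and structural-contrast experiments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import brentq

from .dynamics import CoupledTraitParams, InitialCondition, simulate
from .entropy import EntropySeries, LikertWaveTable, shannon_entropy_bits
from .errors import InvalidInputError
from .estimation import ObservedTrajectories

__all__ = [
    "CohortSimSpec",
    "TrajectorySimSpec",
    "entropy_matched_distribution",
    "default_entropy_paths",
    "generate_likert_waves",
    "generate_trajectory_data",
    "dental_fixture",
    "dental_observed",
    "DENTAL_SUPP_BITS",
    "DENTAL_TIME_BITS",
]

#: entropy trajectories of the two dental-cohort items (bits), one value
#: per academic stage D1-D4: perceived support and perceived time pressure
DENTAL_SUPP_BITS = (1.7278, 1.7198, 1.7755, 1.8126)
DENTAL_TIME_BITS = (1.4530, 1.6855, 1.8210, 1.7319)


def entropy_matched_distribution(target_h: float, n_categories: int) -> np.ndarray:
    """A categorical distribution of given Shannon entropy (bits).

    Uses the exponential-tilt family ``p_i(lam) ~ exp(-lam * i)`` over
    linear category scores ``i = 0..n-1``: entropy is log2(n) at
    ``lam = 0`` and decreases strictly monotonically to 0 as
    ``lam -> inf``, so root bracketing on the tilt always converges.
    The returned distribution's entropy matches ``target_h`` within
    1e-6 bits.
    """
    if n_categories < 2:
        raise InvalidInputError(f"n_categories must be >= 2, got {n_categories}")
    hmax = math.log2(n_categories)
    if not (0.0 < target_h <= hmax + 1e-12):
        raise InvalidInputError(
            f"target entropy {target_h} outside (0, log2({n_categories})={hmax:.6f}]"
        )
    scores = np.arange(n_categories, dtype=float)

    def dist(lam: float) -> np.ndarray:
        w = np.exp(-lam * scores)
        return w / w.sum()

    if target_h >= hmax - 1e-12:
        return np.full(n_categories, 1.0 / n_categories)

    def gap(lam: float) -> float:
        return shannon_entropy_bits(dist(lam)) - target_h

    hi = 1.0
    while gap(hi) > 0:
        hi *= 2.0
        if hi > 1e6:  # pragma: no cover - unreachable for valid targets
            raise InvalidInputError(f"could not bracket tilt for target {target_h}")
    lam = brentq(gap, 0.0, hi, xtol=1e-12, rtol=8.9e-16)
    return dist(lam)


@dataclass(frozen=True)
class CohortSimSpec:
    """Specification of a synthetic Likert cohort.

    ``entropy_paths`` holds one target entropy trajectory (bits) per
    item, shape ``(n_items, n_waves)``; when omitted,
    :func:`default_entropy_paths` draws gently declining paths.
    ``total_attrition`` is the fraction of the initial cohort lost by
    the final wave (0.66 leaves roughly one-third responding);
    respondent totals decline geometrically between waves.
    """

    n_items: int
    wave_times: Sequence[float]
    n_categories: int = 5
    n_respondents: int = 1700
    total_attrition: float = 0.0
    entropy_paths: Optional[np.ndarray] = None
    seed: int = 0

    def __post_init__(self):
        times = np.asarray(self.wave_times, float)
        object.__setattr__(self, "wave_times", times)
        if self.n_items < 1 or times.size < 1:
            raise InvalidInputError("need at least one item and one wave")
        if np.any(np.diff(times) <= 0):
            raise InvalidInputError("wave_times must be strictly increasing")
        if not (0.0 <= self.total_attrition < 1.0):
            raise InvalidInputError("total_attrition must be in [0, 1)")
        if self.n_respondents < 1:
            raise InvalidInputError("n_respondents must be positive")
        if self.entropy_paths is not None:
            paths = np.asarray(self.entropy_paths, float)
            if paths.shape != (self.n_items, times.size):
                raise InvalidInputError(
                    f"entropy_paths shape {paths.shape} != "
                    f"({self.n_items}, {times.size})"
                )
            hmax = math.log2(self.n_categories)
            if np.any(paths <= 0) or np.any(paths > hmax + 1e-12):
                raise InvalidInputError(
                    f"target entropies must lie in (0, log2({self.n_categories})]"
                )
            object.__setattr__(self, "entropy_paths", paths)

    @property
    def respondents_per_wave(self) -> np.ndarray:
        """Respondent totals per wave under geometric attrition."""
        w = self.wave_times.size
        if w == 1 or self.total_attrition == 0.0:
            counts = np.full(w, self.n_respondents)
        else:
            frac = (1.0 - self.total_attrition) ** (np.arange(w) / (w - 1))
            counts = np.rint(self.n_respondents * frac).astype(int)
        if np.any(counts < 1):
            raise InvalidInputError("attrition leaves a wave with zero respondents")
        return counts


def default_entropy_paths(
    n_items: int, n_waves: int, n_categories: int, rng: np.random.Generator
) -> np.ndarray:
    """Linearly declining per-item entropy targets: start uniform in
    [1.9, 2.25] bits, total decline uniform in [0.05, 0.15] bits."""
    hmax = math.log2(n_categories)
    start = rng.uniform(1.9, min(2.25, hmax - 1e-6), size=n_items)
    decline = rng.uniform(0.05, 0.15, size=n_items)
    frac = np.linspace(0.0, 1.0, n_waves)
    return start[:, None] - decline[:, None] * frac[None, :]


def generate_likert_waves(spec: CohortSimSpec) -> List[LikertWaveTable]:
    """Draw multinomial Likert count tables for every item x wave."""
    rng = np.random.default_rng(spec.seed)
    paths = spec.entropy_paths
    if paths is None:
        paths = default_entropy_paths(
            spec.n_items, spec.wave_times.size, spec.n_categories, rng
        )
    totals = spec.respondents_per_wave
    tables: List[LikertWaveTable] = []
    for j in range(spec.n_items):
        for w, t in enumerate(spec.wave_times):
            probs = entropy_matched_distribution(paths[j, w], spec.n_categories)
            counts = rng.multinomial(totals[w], probs)
            if counts.sum() == 0:  # pragma: no cover - totals >= 1
                raise InvalidInputError(f"zero respondents at wave {w}")
            tables.append(
                LikertWaveTable(
                    item_id=f"item_{j:02d}",
                    wave_label=f"wave_{w}",
                    wave_time=float(t),
                    counts=counts,
                )
            )
    return tables


@dataclass(frozen=True)
class TrajectorySimSpec:
    """Specification of noisy observations of the ODE model itself."""

    params: CoupledTraitParams
    init: InitialCondition
    wave_times: Sequence[float]
    noise_sd: float = 0.005
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "wave_times", np.asarray(self.wave_times, float))
        if self.noise_sd < 0:
            raise InvalidInputError("noise_sd must be >= 0")


def generate_trajectory_data(spec: TrajectorySimSpec) -> ObservedTrajectories:
    """Simulate the true model at the wave times and add i.i.d. Gaussian
    observation noise (sd on the normalized scale) to both traits."""
    traj = simulate(spec.params, spec.init, spec.wave_times)
    rng = np.random.default_rng(spec.seed)
    n = traj.N + rng.normal(0.0, spec.noise_sd, traj.N.size)
    p = traj.P + rng.normal(0.0, spec.noise_sd, traj.P.size)
    return ObservedTrajectories(spec.wave_times, n, p)


def dental_fixture(
    n_categories: int = 5, wave_times: Sequence[float] = (0.0, 1.0, 2.0, 3.0)
) -> Tuple[EntropySeries, EntropySeries]:
    """The dental-student cohort entropy fixture.

    Two items measured over four academic stages (D1-D4, spaced one
    year apart by convention): perceived support (``supp``, mapped to
    N) and perceived time pressure (``time``, mapped to P).  Entropies
    are in bits; the items' true category count is not part of the
    record, so it is explicit, overridable metadata (default 5, under
    which all normalized values fall inside (0, 1)).
    """
    times = np.asarray(wave_times, float)
    if times.size != 4:
        raise InvalidInputError("the dental fixture has exactly 4 waves")
    hmax = math.log2(n_categories)
    out = []
    for item, bits in (("supp", DENTAL_SUPP_BITS), ("time", DENTAL_TIME_BITS)):
        bits = np.asarray(bits, float)
        out.append(
            EntropySeries(
                item_id=item,
                wave_times=times,
                entropy_bits=bits,
                entropy_norm=bits / hmax,
                n_categories=n_categories,
            )
        )
    return out[0], out[1]


def dental_observed(scale: str = "norm", n_categories: int = 5) -> ObservedTrajectories:
    """Dental fixture packaged for fitting: supp -> N, time -> P."""
    supp, time = dental_fixture(n_categories=n_categories)
    if scale == "norm":
        return ObservedTrajectories(supp.wave_times, supp.entropy_norm,
                                    time.entropy_norm)
    if scale == "bits":
        return ObservedTrajectories(supp.wave_times, supp.entropy_bits,
                                    time.entropy_bits)
    raise InvalidInputError(f"scale must be 'norm' or 'bits', got {scale!r}")
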