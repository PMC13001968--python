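"""Shannon-entropy summarization of Likert-scale survey waves.

Each questionnaire item at each survey wave yields a vector of category
counts.  Counts are turned into a categorical probability distribution,
summarized by Shannon entropy in bits, normalized by the theoretical
maximum ``log2(n_categories)`` so that items with different category
counts are comparable, and finally averaged across items into a pooled
cohort heterogeneity index ``H*(t)`` on the unit interval.

The entropy is a cross-sectional dispersion summary of the cohort at one
measurement occasion; it says nothing about within-person variability.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import entropy as _scipy_entropy

from .errors import AlignmentError, InvalidInputError

__all__ = [
    "LikertWaveTable",
    "EntropySeries",
    "PooledEntropyIndex",
    "counts_to_probabilities",
    "shannon_entropy_bits",
    "normalize_entropy",
    "entropy_series",
    "pooled_entropy_index",
]

#: tolerance for a probability vector summing to one; counts-derived
#: probabilities are exact, this only guards float round-trip
PROB_SUM_TOL = 1e-9


@dataclass(frozen=True)
class LikertWaveTable:
    """Category counts for one item at one survey wave.

    Parameters
    ----------
    item_id : str
        Identifier of the questionnaire item.
    wave_label : str
        Human-readable wave label (e.g. a survey year or stage name).
    wave_time : float
        Wave time in years (any consistent origin).
    counts : numpy.ndarray
        Nonnegative integer counts, one per response category.
    """

    item_id: str
    wave_label: str
    wave_time: float
    counts: np.ndarray

    def __post_init__(self):
        counts = np.asarray(self.counts)
        if counts.ndim != 1 or counts.size < 2:
            raise InvalidInputError(
                f"item {self.item_id!r}, wave {self.wave_label!r}: "
                "counts must be a vector with at least 2 categories"
            )
        if np.any(counts < 0):
            raise InvalidInputError(
                f"item {self.item_id!r}, wave {self.wave_label!r}: negative count"
            )
        if counts.sum() <= 0:
            raise InvalidInputError(
                f"item {self.item_id!r}, wave {self.wave_label!r}: all counts are zero"
            )
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @property
    def n_categories(self) -> int:
        return int(self.counts.size)

    @property
    def n_respondents(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class EntropySeries:
    """Per-item entropy trajectory across waves (bits and normalized)."""

    item_id: str
    wave_times: np.ndarray
    entropy_bits: np.ndarray
    entropy_norm: np.ndarray
    n_categories: int

    def __post_init__(self):
        object.__setattr__(self, "wave_times", np.asarray(self.wave_times, float))
        object.__setattr__(self, "entropy_bits", np.asarray(self.entropy_bits, float))
        object.__setattr__(self, "entropy_norm", np.asarray(self.entropy_norm, float))


@dataclass(frozen=True)
class PooledEntropyIndex:
    """Cohort-level pooled entropy index H*(t): the unweighted mean of
    normalized item entropies at each wave."""

    wave_times: np.ndarray
    h_star: np.ndarray
    n_items: int

    def __post_init__(self):
        object.__setattr__(self, "wave_times", np.asarray(self.wave_times, float))
        object.__setattr__(self, "h_star", np.asarray(self.h_star, float))


def counts_to_probabilities(counts, *, item_id=None, wave_label=None) -> np.ndarray:
    """Convert category counts into a probability vector.

    Raises :class:`InvalidInputError` for negative or all-zero counts,
    naming the offending (item, wave) when provided.
    """
    counts = np.asarray(counts, dtype=float)
    where = ""
    if item_id is not None or wave_label is not None:
        where = f" (item {item_id!r}, wave {wave_label!r})"
    if counts.ndim != 1 or counts.size == 0:
        raise InvalidInputError(f"counts must be a nonempty vector{where}")
    if np.any(counts < 0):
        raise InvalidInputError(f"negative category count{where}")
    total = counts.sum()
    if total <= 0:
        raise InvalidInputError(f"all category counts are zero{where}")
    return counts / total


def shannon_entropy_bits(probs) -> float:
    """Shannon entropy H = -sum p_i log2 p_i of a probability vector, in bits.

    Zero-probability categories contribute nothing.  The vector must sum
    to one within :data:`PROB_SUM_TOL`.
    """
    probs = np.asarray(probs, dtype=float)
    if np.any(probs < 0):
        raise InvalidInputError("probabilities must be nonnegative")
    if abs(probs.sum() - 1.0) > PROB_SUM_TOL:
        raise InvalidInputError(
            f"probabilities sum to {probs.sum():.12g}, not 1 within {PROB_SUM_TOL}"
        )
    return float(_scipy_entropy(probs, base=2))


def normalize_entropy(h: float, n_categories: int) -> float:
    """Divide an entropy in bits by its theoretical maximum log2(n)."""
    if n_categories < 2:
        raise InvalidInputError(f"n_categories must be >= 2, got {n_categories}")
    hmax = np.log2(n_categories)
    if h < -1e-12 or h > hmax + 1e-9:
        raise InvalidInputError(
            f"entropy {h} outside [0, log2({n_categories})={hmax:.6f}]"
        )
    return float(np.clip(h / hmax, 0.0, 1.0))


def entropy_series(tables: Iterable[LikertWaveTable]) -> EntropySeries:
    """Build an :class:`EntropySeries` from the wave tables of one item.

    Wave times must be strictly increasing; all waves of an item must
    share the same number of categories.
    """
    tables = sorted(tables, key=lambda t: t.wave_time)
    if not tables:
        raise InvalidInputError("no wave tables supplied")
    item_ids = {t.item_id for t in tables}
    if len(item_ids) != 1:
        raise InvalidInputError(f"tables span multiple items: {sorted(item_ids)}")
    n_cats = {t.n_categories for t in tables}
    if len(n_cats) != 1:
        raise InvalidInputError(
            f"item {tables[0].item_id!r}: inconsistent category counts {sorted(n_cats)}"
        )
    times = np.array([t.wave_time for t in tables], float)
    if np.any(np.diff(times) <= 0):
        raise InvalidInputError(
            f"item {tables[0].item_id!r}: wave times not strictly increasing"
        )
    n = tables[0].n_categories
    bits = np.array(
        [
            shannon_entropy_bits(
                counts_to_probabilities(
                    t.counts, item_id=t.item_id, wave_label=t.wave_label
                )
            )
            for t in tables
        ]
    )
    norm = np.array([normalize_entropy(h, n) for h in bits])
    return EntropySeries(
        item_id=tables[0].item_id,
        wave_times=times,
        entropy_bits=bits,
        entropy_norm=norm,
        n_categories=n,
    )


def pooled_entropy_index(series: Sequence[EntropySeries]) -> PooledEntropyIndex:
    """Average normalized item entropies across items into H*(t).

    All series must share an identical wave grid; the unweighted
    arithmetic mean is used (no respondent-count weighting).
    """
    if len(series) < 1:
        raise InvalidInputError("need at least one entropy series to pool")
    ref = series[0].wave_times
    offending = [
        s.item_id for s in series if not np.array_equal(s.wave_times, ref)
    ]
    if offending:
        raise AlignmentError(
            "wave grids differ from item "
            f"{series[0].item_id!r} for items: {offending}"
        )
    stacked = np.vstack([s.entropy_norm for s in series])
    return PooledEntropyIndex(
        wave_times=ref.copy(), h_star=stacked.mean(axis=0), n_items=len(series)
    )
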