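"""Raw cleavage intensities to normalized reactivities.

Implements the standard quantification of capillary-electrophoresis
hydroxyl radical data: background subtraction of the (-)-catalyst channel,
normalization to a 0-to-~1.5 scale where 1.0 is the mean intensity of the
highly reactive nucleotides (the 8% most reactive after excluding the top
2%), optional three-nucleotide smoothing for display, and classification of
solvent-inaccessible nucleotides (reactivity at or below one-half the
reference mean).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from math import ceil

import numpy as np

__all__ = [
    "CleavageProfile",
    "ReactivityProfile",
    "NormalizationRule",
    "subtract_background",
    "normalize_reactivity",
    "smooth",
    "classify_inaccessible",
]


@dataclass
class CleavageProfile:
    """Two-channel raw intensities per nucleotide (1-based positions)."""

    positions: np.ndarray
    plus_intensity: np.ndarray
    minus_intensity: np.ndarray
    nodata_mask: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=int)
        self.plus_intensity = np.asarray(self.plus_intensity, dtype=float)
        self.minus_intensity = np.asarray(self.minus_intensity, dtype=float)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        n = len(self.positions)
        for nm in ("plus_intensity", "minus_intensity", "nodata_mask"):
            if len(getattr(self, nm)) != n:
                raise ValueError("all arrays must have equal length")
        ok = ~self.nodata_mask
        if np.any(self.plus_intensity[ok] < 0) or np.any(self.minus_intensity[ok] < 0):
            raise ValueError("unmasked intensities must be >= 0")


@dataclass
class ReactivityProfile:
    """Normalized reactivities on the 0-to-~1.5 scale.

    ``normalization_factor`` is the raw-intensity mean of the reference set
    (8% most reactive after excluding the top 2%); dividing by it defines
    reactivity 1.0.  ``reference_positions`` records which nucleotides formed
    that set.  ``smoothed`` marks profiles averaged for display; statistics
    are computed on unsmoothed profiles.
    """

    positions: np.ndarray
    reactivity: np.ndarray
    nodata_mask: np.ndarray
    normalization_factor: float
    smoothed: bool = False
    reference_positions: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=int)
        self.reactivity = np.asarray(self.reactivity, dtype=float)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        self.reference_positions = np.asarray(self.reference_positions, dtype=int)
        if not len(self.positions) == len(self.reactivity) == len(self.nodata_mask):
            raise ValueError("all arrays must have equal length")
        if not self.normalization_factor > 0:
            raise ValueError("normalization_factor must be > 0")


@dataclass(frozen=True)
class NormalizationRule:
    """The 8%-after-top-2% normalization rule with its companion settings."""

    exclude_top_fraction: float = 0.02
    reference_fraction: float = 0.08
    smoothing_window: int = 3
    inaccessible_cutoff: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.exclude_top_fraction < 1:
            raise ValueError("exclude_top_fraction must lie in (0, 1)")
        if not 0 < self.reference_fraction < 1:
            raise ValueError("reference_fraction must lie in (0, 1)")
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ValueError("smoothing_window must be odd and >= 1")


def subtract_background(
    profile: CleavageProfile,
    channel_scale: float = 1.0,
    saturation_level: float | None = None,
) -> CleavageProfile:
    """Subtract the (-)-catalyst channel from the (+)-catalyst channel.

    Net intensity is ``max(plus - channel_scale * minus, 0)``.  Positions
    where the (-) channel saturates (at or above ``saturation_level``, if
    given) are masked: their background is unquantifiable.
    """
    net = np.clip(profile.plus_intensity - channel_scale * profile.minus_intensity, 0.0, None)
    mask = profile.nodata_mask.copy()
    if saturation_level is not None:
        mask |= profile.minus_intensity >= saturation_level
    return CleavageProfile(
        positions=profile.positions.copy(),
        plus_intensity=net,
        minus_intensity=np.zeros_like(net),
        nodata_mask=mask,
    )


MIN_UNMASKED_FOR_NORMALIZATION = 25


def normalization_factor(values: np.ndarray, rule: NormalizationRule):
    """Reference-set mean of an unmasked intensity vector.

    Values are sorted descending (stable, ties by position order); the top
    ``ceil(exclude_top_fraction * N)`` are discarded and the mean of the next
    ``ceil(reference_fraction * N)`` is returned along with the indices (into
    ``values``) of that reference set.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    order = np.argsort(-values, kind="stable")
    n_excl = ceil(rule.exclude_top_fraction * n)
    n_ref = ceil(rule.reference_fraction * n)
    ref_idx = order[n_excl : n_excl + n_ref]
    if len(ref_idx) == 0:
        raise ValueError("reference set is empty; profile too short")
    factor = float(np.mean(values[ref_idx]))
    return factor, ref_idx


def normalize_reactivity(
    profile: CleavageProfile, rule: NormalizationRule | None = None
) -> ReactivityProfile:
    """Normalize a background-subtracted profile to the 0-to-~1.5 scale.

    Divides every intensity by the mean of the 8% most reactive nucleotides
    after first excluding the top 2% of reactivities, so the reference set's
    mean reactivity is exactly 1.0.
    """
    rule = rule or NormalizationRule()
    ok = ~profile.nodata_mask
    n_ok = int(np.sum(ok))
    if n_ok < MIN_UNMASKED_FOR_NORMALIZATION:
        raise ValueError(
            f"only {n_ok} unmasked positions; need >= {MIN_UNMASKED_FOR_NORMALIZATION} "
            "for a non-empty reference set"
        )
    values = profile.plus_intensity[ok]
    factor, ref_idx = normalization_factor(values, rule)
    if factor <= 0:
        raise ValueError("normalization factor is zero (all-zero profile)")
    reactivity = np.full(len(profile.positions), np.nan)
    reactivity[ok] = values / factor
    return ReactivityProfile(
        positions=profile.positions.copy(),
        reactivity=reactivity,
        nodata_mask=profile.nodata_mask.copy(),
        normalization_factor=factor,
        smoothed=False,
        reference_positions=profile.positions[ok][ref_idx],
    )


def smooth(profile: ReactivityProfile, window: int | None = None) -> ReactivityProfile:
    """Centered moving average for display.

    The window shrinks at the sequence ends to the available neighbors, and
    masked positions are excluded from each window's mean.  Positions that
    are themselves masked stay masked.
    """
    if window is None:
        window = NormalizationRule().smoothing_window
    if window < 1 or window % 2 == 0:
        raise ValueError("smoothing window must be odd and >= 1")
    half = window // 2
    ok = ~profile.nodata_mask
    vals = np.where(ok, np.nan_to_num(profile.reactivity), 0.0)
    kernel = np.ones(window)
    num = np.convolve(vals, kernel, mode="same")
    den = np.convolve(ok.astype(float), kernel, mode="same")
    with np.errstate(invalid="ignore"):
        out = np.where(den > 0, num / den, np.nan)
    out = np.where(ok, out, np.nan)
    return ReactivityProfile(
        positions=profile.positions.copy(),
        reactivity=out,
        nodata_mask=profile.nodata_mask.copy(),
        normalization_factor=profile.normalization_factor,
        smoothed=True,
        reference_positions=profile.reference_positions.copy(),
    )


def classify_inaccessible(
    profile: ReactivityProfile, cutoff: float | None = None
) -> np.ndarray:
    """Boolean mask of solvent-inaccessible nucleotides.

    A nucleotide is inaccessible when its reactivity is at or below
    ``cutoff`` (default 0.5, one-half the 1.0 reference mean); the rule is
    inclusive.  Masked positions are never flagged.
    """
    if cutoff is None:
        cutoff = NormalizationRule().inaccessible_cutoff
    ok = ~profile.nodata_mask
    out = np.zeros(len(profile.positions), dtype=bool)
    out[ok] = profile.reactivity[ok] <= cutoff
    return out
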