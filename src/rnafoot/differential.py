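"""Bound-minus-free difference profiles and protection/enhancement calls.

A difference plot is a model-free view of ligand-induced structural change:
protections (reactivity losses at sites the protein occludes) appear as
negative deltas and enhancements as positive ones.  Significant changes are
those with an absolute reactivity difference of 0.2 or more — two-fold above
the typical mean background difference — an inclusive effect-size rule, not
a p-value procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .reactivity import ReactivityProfile

__all__ = [
    "DifferenceProfile",
    "ChangeCall",
    "CallThreshold",
    "Region",
    "difference_profile",
    "estimate_threshold",
    "call_changes",
    "segment_regions",
    "PROTECTION",
    "ENHANCEMENT",
]

PROTECTION = "protection"
ENHANCEMENT = "enhancement"


@dataclass
class DifferenceProfile:
    """Per-nucleotide bound-minus-free reactivity differences."""

    positions: np.ndarray
    delta: np.ndarray
    nodata_mask: np.ndarray
    smoothed: bool = False

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=int)
        self.delta = np.asarray(self.delta, dtype=float)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if not len(self.positions) == len(self.delta) == len(self.nodata_mask):
            raise ValueError("all arrays must have equal length")


@dataclass(frozen=True)
class ChangeCall:
    """A significant reactivity change at one nucleotide."""

    position: int
    direction: str  # protection | enhancement
    magnitude: float  # |delta|
    region_id: int | None = None

    def __post_init__(self) -> None:
        if self.direction not in (PROTECTION, ENHANCEMENT):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.magnitude < 0:
            raise ValueError("magnitude must be >= 0")


@dataclass(frozen=True)
class CallThreshold:
    """Significance rule: call |delta| >= min_abs_delta (inclusive)."""

    min_abs_delta: float = 0.2
    background_multiplier: float = 2.0

    def __post_init__(self) -> None:
        if not self.min_abs_delta >= 0:
            raise ValueError("min_abs_delta must be >= 0")


@dataclass(frozen=True)
class Region:
    """A contiguous run of same-direction calls (1-based inclusive span)."""

    region_id: int
    direction: str
    start: int
    end: int
    n_calls: int
    mean_magnitude: float


def difference_profile(
    bound: ReactivityProfile, free: ReactivityProfile
) -> DifferenceProfile:
    """delta(i) = bound reactivity - free reactivity; masks are unioned.

    Both profiles must cover the same positions and share a smoothing state
    (comparing a smoothed with an unsmoothed profile is meaningless).
    """
    if len(bound.positions) != len(free.positions) or np.any(
        bound.positions != free.positions
    ):
        raise ValueError("profiles cover different positions")
    if bound.smoothed != free.smoothed:
        raise ValueError("mixed smoothing states: smooth both profiles or neither")
    mask = bound.nodata_mask | free.nodata_mask
    delta = np.where(mask, np.nan, bound.reactivity - free.reactivity)
    return DifferenceProfile(
        positions=bound.positions.copy(),
        delta=delta,
        nodata_mask=mask,
        smoothed=bound.smoothed,
    )


def estimate_threshold(
    replicate_deltas: list[DifferenceProfile],
    multiplier: float = 2.0,
    strict: bool = False,
) -> CallThreshold:
    """Derive the significance threshold from no-change replicate differences.

    threshold = multiplier x mean |delta| over all unmasked positions of
    free-vs-free (or otherwise unchanged-condition) difference profiles.
    With no replicates, falls back to the default 0.2 unless ``strict``.
    """
    if not replicate_deltas:
        if strict:
            raise ValueError("no replicate difference profiles supplied (strict mode)")
        return CallThreshold(min_abs_delta=0.2, background_multiplier=multiplier)
    pooled = np.concatenate(
        [np.abs(d.delta[~d.nodata_mask]) for d in replicate_deltas]
    )
    if pooled.size == 0:
        raise ValueError("replicate difference profiles are fully masked")
    return CallThreshold(
        min_abs_delta=float(multiplier * pooled.mean()),
        background_multiplier=multiplier,
    )


def call_changes(
    diff: DifferenceProfile, threshold: CallThreshold | None = None
) -> list[ChangeCall]:
    """Call every unmasked position with |delta| >= min_abs_delta.

    The rule is inclusive: a difference of exactly the threshold is
    significant.  Direction follows the sign of delta.
    """
    threshold = threshold or CallThreshold()
    if threshold.min_abs_delta <= 0:
        raise ValueError("threshold must be positive for calling")
    calls: list[ChangeCall] = []
    ok = ~diff.nodata_mask
    for pos, d in zip(diff.positions[ok], diff.delta[ok]):
        if abs(d) >= threshold.min_abs_delta:
            calls.append(
                ChangeCall(
                    position=int(pos),
                    direction=PROTECTION if d < 0 else ENHANCEMENT,
                    magnitude=float(abs(d)),
                )
            )
    return calls


def segment_regions(calls: list[ChangeCall], max_gap: int = 1) -> list[Region]:
    """Group same-direction calls into contiguous regions.

    Two consecutive calls share a region when they have the same direction
    and at most ``max_gap`` positions lie between them (default 1, so a
    single masked or no-data site does not split a footprint).
    """
    if any(
        calls[k].position >= calls[k + 1].position for k in range(len(calls) - 1)
    ):
        raise ValueError("calls must be sorted by position")
    regions: list[Region] = []
    run: list[ChangeCall] = []

    def flush() -> None:
        if run:
            regions.append(
                Region(
                    region_id=len(regions),
                    direction=run[0].direction,
                    start=run[0].position,
                    end=run[-1].position,
                    n_calls=len(run),
                    mean_magnitude=float(np.mean([c.magnitude for c in run])),
                )
            )

    for call in calls:
        if run and (
            call.direction != run[-1].direction
            or call.position - run[-1].position - 1 > max_gap
        ):
            flush()
            run = []
        run.append(call)
    flush()
    return regions
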