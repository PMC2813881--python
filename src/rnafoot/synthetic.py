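"""Synthetic data generators for hydroxyl radical footprinting experiments.

Everything downstream of the wet lab is testable against these generators:
they produce RNA structure models with annotated GNRA tetraloop-receptor
motifs, two-channel cleavage profiles whose (+)-catalyst intensities are
proportional to per-nucleotide solvent accessibility, electropherogram-like
Gaussian peak trains with exponential signal decay, and cooperative Hill
binding curves.

Coordinates are 1-based throughout, matching standard nucleotide numbering
in chemical probing work.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .reactivity import CleavageProfile
from .binding import BindingDataset

__all__ = [
    "Element",
    "TertiaryContact",
    "RnaStructureModel",
    "SimulationConfig",
    "Trace",
    "build_toy_structure",
    "simulate_cleavage",
    "simulate_trace",
    "simulate_binding_curve",
]

_BASES = "ACGU"
_COMPLEMENT = {"A": "U", "U": "A", "C": "G", "G": "C"}

MIN_TOY_LENGTH = 80
_STEM_LEN = 6
_LOOP_LEN = 4
_CONTACT_BP = 3  # base pairs of the receptor helix forming the docking site


@dataclass(frozen=True)
class Element:
    """A named secondary-structure element (1-based positions)."""

    label: str
    kind: str  # helix | loop | junction | exon
    positions: tuple[int, ...]


@dataclass(frozen=True)
class TertiaryContact:
    """A GNRA tetraloop docked against a distal receptor helix."""

    loop_label: str
    receptor_label: str
    loop_positions: tuple[int, ...]
    receptor_positions: tuple[int, ...]  # the docking face of the receptor

    @property
    def motif_id(self) -> str:
        return f"{self.loop_label}:{self.receptor_label}"


@dataclass
class RnaStructureModel:
    """RNA sequence, pairing, named elements, tertiary contacts and
    per-state ground-truth solvent accessibility.

    ``accessibility_free`` / ``accessibility_bound`` hold values in [0, 1]
    (1 = fully solvent exposed); they may be ``None`` for models parsed
    from structure files, where no ground truth exists.
    """

    name: str
    sequence: str
    pairs: frozenset[tuple[int, int]]
    elements: tuple[Element, ...] = ()
    tertiary_contacts: tuple[TertiaryContact, ...] = ()
    accessibility_free: np.ndarray | None = None
    accessibility_bound: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.validate()

    @property
    def length(self) -> int:
        return len(self.sequence)

    def validate(self) -> None:
        L = self.length
        if any(b not in _BASES for b in self.sequence):
            raise ValueError("sequence must contain only A/C/G/U")
        seen: set[int] = set()
        for i, j in self.pairs:
            if not (1 <= i < j <= L):
                raise ValueError(f"invalid pair ({i},{j}) for length {L}")
            if i in seen or j in seen:
                raise ValueError(f"position paired more than once in ({i},{j})")
            seen.update((i, j))
        covered: set[int] = set()
        for el in self.elements:
            if el.kind in ("helix", "loop"):
                overlap = covered.intersection(el.positions)
                if overlap:
                    raise ValueError(
                        f"position(s) {sorted(overlap)} in more than one helix/loop element"
                    )
                covered.update(el.positions)
            if any(not 1 <= p <= L for p in el.positions):
                raise ValueError(f"element {el.label} has out-of-range positions")
        labels = {el.label for el in self.elements}
        for tc in self.tertiary_contacts:
            for lab in (tc.loop_label, tc.receptor_label):
                if lab not in labels:
                    raise ValueError(f"tertiary contact references unknown element {lab!r}")
        for arr, nm in (
            (self.accessibility_free, "accessibility_free"),
            (self.accessibility_bound, "accessibility_bound"),
        ):
            if arr is None:
                continue
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (L,):
                raise ValueError(f"{nm} must have length {L}")
            if np.any(arr < 0) or np.any(arr > 1):
                raise ValueError(f"{nm} values must lie in [0, 1]")

    # -- helpers -------------------------------------------------------

    def partner(self) -> np.ndarray:
        """0 = unpaired; otherwise the 1-based pairing partner, indexed 1..L."""
        out = np.zeros(self.length + 1, dtype=int)
        for i, j in self.pairs:
            out[i] = j
            out[j] = i
        return out

    def element_by_label(self, label: str) -> Element:
        for el in self.elements:
            if el.label == label:
                return el
        raise KeyError(label)

    def accessibility(self, state: str) -> np.ndarray:
        if state == "free":
            arr = self.accessibility_free
        elif state == "bound":
            arr = self.accessibility_bound
        else:
            raise ValueError(f"unknown state {state!r}; expected 'free' or 'bound'")
        if arr is None:
            raise ValueError(f"model {self.name!r} has no accessibility for state {state!r}")
        return np.asarray(arr, dtype=float)

    def receptor_extension(self, contact: TertiaryContact) -> tuple[int, ...]:
        """Receptor-helix positions outside the docking face: the half of the
        helix extending toward the molecular exterior."""
        helix = self.element_by_label(contact.receptor_label)
        return tuple(sorted(set(helix.positions) - set(contact.receptor_positions)))

    def footprint_positions(self) -> tuple[int, ...]:
        """All positions a bound protein occludes: each tetraloop plus the
        full receptor helix (docking face and exterior extension)."""
        pos: set[int] = set()
        for tc in self.tertiary_contacts:
            pos.update(tc.loop_positions)
            pos.update(self.element_by_label(tc.receptor_label).positions)
        return tuple(sorted(pos))


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the generative cleavage model.

    intensity_scale : arbitrary fluorescence units of a fully exposed
        nucleotide's mean (+)-catalyst signal.
    noise_cv : coefficient of variation of the multiplicative lognormal
        noise on each cleavage intensity.
    background_rate : fraction of full-scale signal present in the
        (-)-catalyst channel (reverse-transcription stops, not cleavage).
    footprint_depth : fractional accessibility reduction at protein-contact
        sites in the bound state.
    """

    length: int = 540
    intensity_scale: float = 1000.0
    noise_cv: float = 0.05
    background_rate: float = 0.1
    footprint_depth: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if not 0 <= self.background_rate < 1:
            raise ValueError("background_rate must lie in [0, 1)")
        if not 0 < self.footprint_depth <= 1:
            raise ValueError("footprint_depth must lie in (0, 1]")


@dataclass
class Trace:
    """Electropherogram-like readout: intensity versus elution index for the
    (+)-catalyst, (-)-catalyst and sequencing-ladder channels, sharing one
    elution axis, plus the expected elution position of each nucleotide."""

    channels: dict[str, np.ndarray]
    peak_positions: np.ndarray  # expected elution index per nucleotide

    def __post_init__(self) -> None:
        self.peak_positions = np.asarray(self.peak_positions, dtype=float)
        if np.any(np.diff(self.peak_positions) <= 0):
            raise ValueError("peak_positions must be strictly increasing")
        n = {len(v) for v in self.channels.values()}
        if len(n) > 1:
            raise ValueError("all channels must share one elution axis")
        for name, v in self.channels.items():
            if np.any(np.asarray(v) < 0):
                raise ValueError(f"channel {name!r} has negative intensities")


# ---------------------------------------------------------------------------
# structure generator
# ---------------------------------------------------------------------------


def _hairpin(start: int, loop_seq: str, rng: np.random.Generator):
    """Sequence, pairs and (stem5, loop, stem3) position blocks of a hairpin
    starting at 1-based position ``start``."""
    stem5 = list(range(start, start + _STEM_LEN))
    loop = list(range(start + _STEM_LEN, start + _STEM_LEN + _LOOP_LEN))
    stem3 = list(range(loop[-1] + 1, loop[-1] + 1 + _STEM_LEN))
    seq5 = "".join(rng.choice(list(_BASES), size=_STEM_LEN))
    seq3 = "".join(_COMPLEMENT[b] for b in reversed(seq5))
    pairs = {(stem5[t], stem3[_STEM_LEN - 1 - t]) for t in range(_STEM_LEN)}
    return seq5 + loop_seq + seq3, pairs, stem5, loop, stem3


def build_toy_structure(
    length: int,
    seed: int = 0,
    footprint_depth: float = 0.6,
    buried_fraction: float = 0.20,
) -> RnaStructureModel:
    """Build a group-I-intron-like toy model with two GNRA tetraloop-receptor
    motifs: the L2 tetraloop docks against the P8 helix and the L9 tetraloop
    against the P5 helix.

    The free state is largely solvent exposed (the motif elements fully so),
    with ``buried_fraction`` of the remaining positions buried, emulating a
    partly structured but not natively folded RNA.  The bound state reduces
    accessibility by ``footprint_depth`` over each tetraloop and over the
    whole of each receptor helix (docking face plus exterior extension),
    producing the three-part protection signature of a bound protein.
    Deterministic for a fixed seed.
    """
    if length < MIN_TOY_LENGTH:
        raise ValueError(
            f"length {length} too small to place two tetraloop-receptor motifs; "
            f"minimum is {MIN_TOY_LENGTH} nt"
        )
    if not 0 < footprint_depth <= 1:
        raise ValueError("footprint_depth must lie in (0, 1]")
    rng = np.random.default_rng(seed)

    hairpin_nt = 2 * _STEM_LEN + _LOOP_LEN
    n_fill = length - 4 * hairpin_nt
    base, rem = divmod(n_fill, 5)
    fill_sizes = [base + (1 if k < rem else 0) for k in range(5)]

    seq_parts: list[str] = []
    pairs: set[tuple[int, int]] = set()
    elements: list[Element] = []
    cursor = 1

    def add_filler(label: str, kind: str, size: int) -> None:
        nonlocal cursor
        seq_parts.append("".join(rng.choice(list(_BASES), size=size)))
        elements.append(Element(label, kind, tuple(range(cursor, cursor + size))))
        cursor += size

    hairpins: dict[str, tuple[list[int], list[int], list[int]]] = {}

    def add_hairpin(hlabel: str, llabel: str, loop_seq: str) -> None:
        nonlocal cursor
        seq, hp_pairs, s5, lp, s3 = _hairpin(cursor, loop_seq, rng)
        seq_parts.append(seq)
        pairs.update(hp_pairs)
        elements.append(Element(hlabel, "helix", tuple(s5 + s3)))
        elements.append(Element(llabel, "loop", tuple(lp)))
        hairpins[hlabel] = (s5, lp, s3)
        cursor += hairpin_nt

    add_filler("EX5", "exon", fill_sizes[0])
    add_hairpin("P2", "L2", "GAAA")
    add_filler("J2/5", "junction", fill_sizes[1])
    add_hairpin("P5", "L5", "UUCG")
    add_filler("J5/8", "junction", fill_sizes[2])
    add_hairpin("P8", "L8", "UUCG")
    add_filler("J8/9", "junction", fill_sizes[3])
    add_hairpin("P9", "L9", "GAAA")
    add_filler("EX3", "exon", fill_sizes[4])

    sequence = "".join(seq_parts)
    assert len(sequence) == length

    def docking_face(hlabel: str) -> tuple[int, ...]:
        s5, _, s3 = hairpins[hlabel]
        return tuple(s5[-_CONTACT_BP:] + s3[:_CONTACT_BP])  # bp nearest the loop

    contacts = (
        TertiaryContact("L2", "P8", tuple(hairpins["P2"][1]), docking_face("P8")),
        TertiaryContact("L9", "P5", tuple(hairpins["P9"][1]), docking_face("P5")),
    )

    # ground-truth accessibility: motif elements fully reactive in the free
    # state; a fixed fraction of the remaining RNA buried
    acc_free = rng.uniform(0.7, 1.0, size=length)
    motif_pos: set[int] = set()
    for tc in contacts:
        motif_pos.update(tc.loop_positions)
        for hl in (tc.receptor_label,):
            s5, _, s3 = hairpins[hl]
            motif_pos.update(s5 + s3)
    # keep a 2-nt buffer reactive so smoothing never drags motif edges down
    buffered = set()
    for p in motif_pos:
        buffered.update(range(max(1, p - 2), min(length, p + 2) + 1))
    pool = np.array(sorted(set(range(1, length + 1)) - buffered), dtype=int)
    n_buried = int(round(buried_fraction * length))
    if n_buried > len(pool):
        raise ValueError("buried_fraction too large for this length")
    buried = rng.choice(pool, size=n_buried, replace=False)
    acc_free[buried - 1] = rng.uniform(0.05, 0.2, size=n_buried)

    acc_bound = acc_free.copy()
    fp = np.array(sorted(motif_pos), dtype=int)
    acc_bound[fp - 1] *= 1.0 - footprint_depth

    return RnaStructureModel(
        name=f"toy_bI3_like_L{length}_s{seed}",
        sequence=sequence,
        pairs=frozenset(pairs),
        elements=tuple(elements),
        tertiary_contacts=contacts,
        accessibility_free=acc_free,
        accessibility_bound=acc_bound,
    )


# ---------------------------------------------------------------------------
# cleavage / trace / binding generators
# ---------------------------------------------------------------------------


def _lognormal_noise(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Unit-mean multiplicative lognormal noise with the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def simulate_cleavage(
    model: RnaStructureModel, state: str, config: SimulationConfig
) -> CleavageProfile:
    """Draw a two-channel cleavage profile for the given state.

    (+)-catalyst intensity at position i is
    ``intensity_scale * accessibility(i) * lognormal(cv)`` plus an
    independent background term; the (-)-catalyst channel is a
    background-only draw (it measures reverse-transcription stops, which
    are independent of radical cleavage).
    """
    acc = model.accessibility(state)
    L = len(acc)
    rng = np.random.default_rng(config.seed)
    signal = config.intensity_scale * acc * _lognormal_noise(rng, config.noise_cv, L)
    bg_level = config.background_rate * config.intensity_scale
    bg_plus = bg_level * _lognormal_noise(rng, config.noise_cv, L) if bg_level else np.zeros(L)
    bg_minus = bg_level * _lognormal_noise(rng, config.noise_cv, L) if bg_level else np.zeros(L)
    return CleavageProfile(
        positions=np.arange(1, L + 1),
        plus_intensity=signal + bg_plus,
        minus_intensity=bg_minus,
        nodata_mask=np.zeros(L, dtype=bool),
    )


def simulate_trace(
    profile: CleavageProfile,
    peak_spacing: float = 10.0,
    peak_width: float = 1.5,
    decay_rate: float = 1.0,
    seed: int = 0,
    baseline_sd: float = 0.0,
) -> Trace:
    """Render a cleavage profile as a Gaussian peak train.

    Nucleotide i (0-based index k) contributes one Gaussian of area
    ``intensity * decay_rate**k`` centred at ``(k + 1) * peak_spacing``,
    emulating the exponential signal decay of primer extension along the
    template.  The ladder channel carries uniform-area anchor peaks.
    """
    if peak_width >= peak_spacing:
        raise ValueError(
            f"peak_width ({peak_width}) must be smaller than peak_spacing ({peak_spacing})"
        )
    if not 0 < decay_rate <= 1:
        raise ValueError("decay_rate must lie in (0, 1]")
    L = len(profile.positions)
    centers = (np.arange(L) + 1.0) * peak_spacing
    axis = np.arange(int(np.ceil((L + 2) * peak_spacing)))
    decay = decay_rate ** np.arange(L)
    ladder_area = np.full(L, 0.5 * float(np.median(profile.plus_intensity)))

    def render(areas: np.ndarray) -> np.ndarray:
        y = np.zeros(len(axis))
        halfwin = int(np.ceil(6 * peak_width))
        norm = 1.0 / (peak_width * np.sqrt(2 * np.pi))
        for k in range(L):
            c = centers[k]
            lo = max(0, int(c) - halfwin)
            hi = min(len(axis), int(c) + halfwin + 1)
            x = axis[lo:hi]
            y[lo:hi] += areas[k] * norm * np.exp(-0.5 * ((x - c) / peak_width) ** 2)
        return y

    channels = {
        "plus_catalyst": render(profile.plus_intensity * decay),
        "minus_catalyst": render(profile.minus_intensity * decay),
        "ladder": render(ladder_area * decay),
    }
    if baseline_sd > 0:
        rng = np.random.default_rng(seed)
        for name in channels:
            channels[name] = np.clip(
                channels[name] + rng.normal(0, baseline_sd, size=len(axis)), 0, None
            )
    return Trace(channels=channels, peak_positions=centers)


def simulate_binding_curve(
    A: float,
    n: float,
    k_half: float,
    concentrations,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> BindingDataset:
    """Draw a filter-partitioning binding curve from the cooperative Hill
    model: fraction bound = A[P]^n / ([P]^n + K½^n) plus Gaussian noise,
    clipped to [0, 1.05] (real filter data can slightly overshoot 1)."""
    conc = np.asarray(list(concentrations), dtype=float)
    if conc.size == 0:
        raise ValueError("concentration list is empty")
    if np.any(conc <= 0):
        raise ValueError("concentrations must be strictly positive")
    if not 0 < A <= 1:
        raise ValueError("A must lie in (0, 1]")
    order = np.argsort(conc)
    conc = conc[order]
    f = A * conc**n / (conc**n + k_half**n)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        f = f + rng.normal(0, noise_sd, size=conc.size)
    f = np.clip(f, 0.0, 1.05)
    return BindingDataset(protein_concentration=conc, fraction_bound=f)
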