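"""Readers and writers for the plain-text formats used across the pipeline.

Formats: CT connectivity tables and dot-bracket strings for secondary
structure (with optional element / tertiary-contact side-car tables),
SHAPE-style two-column reactivity files (-999 sentinel for no-data),
tab-delimited cleavage profiles and peak tables, per-channel trace files,
difference/region tables, and binding CSV / fit JSON.

All positional outputs are 1-based inclusive and say so in their headers
(CT and probing-file convention; a 0-based BED-style export is available
behind a flag on region output).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .binding import BindingDataset, HillFit
from .differential import DifferenceProfile, Region
from .reactivity import CleavageProfile, ReactivityProfile
from .synthetic import Element, RnaStructureModel, TertiaryContact, Trace
from .traces import PeakTable

__all__ = [
    "NODATA_SENTINEL",
    "read_structure",
    "write_ct",
    "read_ct",
    "write_dot_bracket",
    "read_dot_bracket",
    "dot_bracket_string",
    "write_annotations",
    "read_annotations",
    "write_cleavage_profile",
    "read_cleavage_profile",
    "write_reactivity",
    "read_reactivity",
    "write_peak_table",
    "read_peak_table",
    "write_trace",
    "read_trace",
    "write_difference",
    "read_difference",
    "write_regions",
    "write_binding_csv",
    "read_binding_csv",
    "write_fit_json",
    "write_fitted_curve",
]

NODATA_SENTINEL = -999.0


class StructureParseError(ValueError):
    """Raised on malformed or inconsistent structure files."""


# ---------------------------------------------------------------------------
# secondary structure
# ---------------------------------------------------------------------------


def write_ct(model: RnaStructureModel, path) -> None:
    partner = model.partner()
    lines = [f"{model.length} {model.name}"]
    for i in range(1, model.length + 1):
        lines.append(
            f"{i} {model.sequence[i - 1]} {i - 1} "
            f"{i + 1 if i < model.length else 0} {partner[i]} {i}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_ct(path) -> RnaStructureModel:
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise StructureParseError(f"{path}: empty CT file")
    try:
        length = int(lines[0].split()[0])
    except (IndexError, ValueError) as exc:
        raise StructureParseError(f"{path}:1: bad CT header") from exc
    name = " ".join(lines[0].split()[1:]) or Path(path).stem
    seq: list[str] = []
    partner = np.zeros(length + 1, dtype=int)
    for row, line in enumerate(lines[1 : length + 1], start=2):
        fields = line.split()
        if len(fields) < 6:
            raise StructureParseError(f"{path}:{row}: malformed CT row (need 6 columns)")
        try:
            i, base, pair = int(fields[0]), fields[1], int(fields[4])
        except ValueError as exc:
            raise StructureParseError(f"{path}:{row}: non-numeric CT field") from exc
        if i != row - 1:
            raise StructureParseError(f"{path}:{row}: CT rows out of order")
        seq.append(base.upper().replace("T", "U"))
        partner[i] = pair
    if len(seq) != length:
        raise StructureParseError(f"{path}: expected {length} rows, found {len(seq)}")
    pairs: set[tuple[int, int]] = set()
    for i in range(1, length + 1):
        j = partner[i]
        if j == 0:
            continue
        if not 1 <= j <= length or partner[j] != i:
            raise StructureParseError(
                f"{path}:{i + 1}: inconsistent pairing {i}->{j} but {j}->{partner[j] if 1 <= j <= length else '?'}"
            )
        if i < j:
            pairs.add((i, j))
    return RnaStructureModel(name=name, sequence="".join(seq), pairs=frozenset(pairs))


def dot_bracket_string(model: RnaStructureModel) -> str:
    s = ["."] * model.length
    for i, j in model.pairs:
        s[i - 1], s[j - 1] = "(", ")"
    return "".join(s)


def write_dot_bracket(model: RnaStructureModel, path) -> None:
    Path(path).write_text(f">{model.name}\n{model.sequence}\n{dot_bracket_string(model)}\n")


def parse_dot_bracket(name: str, sequence: str, structure: str) -> RnaStructureModel:
    if len(sequence) != len(structure):
        raise StructureParseError("sequence and structure lengths differ")
    stack: list[int] = []
    pairs: set[tuple[int, int]] = set()
    for k, ch in enumerate(structure, start=1):
        if ch == "(":
            stack.append(k)
        elif ch == ")":
            if not stack:
                raise StructureParseError(f"unbalanced ')' at position {k}")
            pairs.add((stack.pop(), k))
        elif ch != ".":
            raise StructureParseError(f"unsupported character {ch!r} at position {k}")
    if stack:
        raise StructureParseError(f"unclosed '(' at position {stack[-1]}")
    return RnaStructureModel(
        name=name,
        sequence=sequence.upper().replace("T", "U"),
        pairs=frozenset(pairs),
    )


def read_dot_bracket(path) -> RnaStructureModel:
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if lines and lines[0].startswith(">"):
        name, lines = lines[0][1:].strip(), lines[1:]
    else:
        name = Path(path).stem
    if len(lines) < 2:
        raise StructureParseError(f"{path}: need sequence and structure lines")
    return parse_dot_bracket(name, lines[0], lines[1])


def write_annotations(model: RnaStructureModel, elements_path, contacts_path) -> None:
    """Side-car tables: elements (label, kind, comma-joined 1-based positions)
    and tetraloop-receptor contacts."""
    el = pd.DataFrame(
        {
            "label": [e.label for e in model.elements],
            "kind": [e.kind for e in model.elements],
            "positions": [",".join(map(str, e.positions)) for e in model.elements],
        }
    )
    el.to_csv(elements_path, sep="\t", index=False)
    tc = pd.DataFrame(
        {
            "loop_label": [t.loop_label for t in model.tertiary_contacts],
            "receptor_label": [t.receptor_label for t in model.tertiary_contacts],
            "loop_positions": [",".join(map(str, t.loop_positions)) for t in model.tertiary_contacts],
            "receptor_positions": [
                ",".join(map(str, t.receptor_positions)) for t in model.tertiary_contacts
            ],
        }
    )
    tc.to_csv(contacts_path, sep="\t", index=False)


def read_annotations(elements_path, contacts_path=None):
    el = pd.read_csv(elements_path, sep="\t", dtype=str)
    elements = tuple(
        Element(r.label, r.kind, tuple(int(x) for x in r.positions.split(",")))
        for r in el.itertuples()
    )
    contacts: tuple[TertiaryContact, ...] = ()
    if contacts_path is not None and Path(contacts_path).exists():
        tc = pd.read_csv(contacts_path, sep="\t", dtype=str)
        contacts = tuple(
            TertiaryContact(
                r.loop_label,
                r.receptor_label,
                tuple(int(x) for x in r.loop_positions.split(",")),
                tuple(int(x) for x in r.receptor_positions.split(",")),
            )
            for r in tc.itertuples()
        )
    return elements, contacts


def read_structure(path, elements_path=None, contacts_path=None) -> RnaStructureModel:
    """Read CT (.ct) or dot-bracket (anything else) structure, attaching
    element and contact annotations from side-car tables when given."""
    path = Path(path)
    model = read_ct(path) if path.suffix.lower() == ".ct" else read_dot_bracket(path)
    if elements_path is not None:
        elements, contacts = read_annotations(elements_path, contacts_path)
        model = RnaStructureModel(
            name=model.name,
            sequence=model.sequence,
            pairs=model.pairs,
            elements=elements,
            tertiary_contacts=contacts,
        )
    return model


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------


def write_cleavage_profile(profile: CleavageProfile, path) -> None:
    plus = np.where(profile.nodata_mask, NODATA_SENTINEL, profile.plus_intensity)
    minus = np.where(profile.nodata_mask, NODATA_SENTINEL, profile.minus_intensity)
    df = pd.DataFrame({"position": profile.positions, "plus": plus, "minus": minus})
    with open(path, "w") as fh:
        fh.write("# 1-based positions; -999 = no data\n")
        df.to_csv(fh, sep="\t", index=False)


def read_cleavage_profile(path) -> CleavageProfile:
    df = pd.read_csv(path, sep="\t", comment="#")
    mask = (df["plus"] == NODATA_SENTINEL) | (df["minus"] == NODATA_SENTINEL)
    return CleavageProfile(
        positions=df["position"].to_numpy(),
        plus_intensity=np.where(mask, 0.0, df["plus"].to_numpy()),
        minus_intensity=np.where(mask, 0.0, df["minus"].to_numpy()),
        nodata_mask=mask.to_numpy(),
    )


def write_reactivity(profile: ReactivityProfile, path) -> None:
    vals = np.where(profile.nodata_mask, NODATA_SENTINEL, profile.reactivity)
    df = pd.DataFrame({"position": profile.positions, "reactivity": vals})
    with open(path, "w") as fh:
        fh.write(
            "# 1-based positions; -999 = no data; "
            f"normalization_factor={profile.normalization_factor!r}; "
            f"smoothed={profile.smoothed}\n"
        )
        df.to_csv(fh, sep="\t", index=False)


def read_reactivity(path) -> ReactivityProfile:
    header = Path(path).read_text().splitlines()[0]
    factor, smoothed = 1.0, False
    for token in header.lstrip("# ").split(";"):
        token = token.strip()
        if token.startswith("normalization_factor="):
            factor = float(token.split("=", 1)[1])
        elif token.startswith("smoothed="):
            smoothed = token.split("=", 1)[1] == "True"
    df = pd.read_csv(path, sep="\t", comment="#")
    mask = df["reactivity"] == NODATA_SENTINEL
    return ReactivityProfile(
        positions=df["position"].to_numpy(),
        reactivity=np.where(mask, np.nan, df["reactivity"].to_numpy()),
        nodata_mask=mask.to_numpy(),
        normalization_factor=factor,
        smoothed=smoothed,
    )


def write_peak_table(table: PeakTable, path) -> None:
    df = pd.DataFrame(
        {
            "position": table.position,
            "elution": table.elution,
            "width": table.width,
            "area_plus": table.area_plus,
            "area_minus": table.area_minus,
            "flag": table.flag,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_peak_table(path) -> PeakTable:
    df = pd.read_csv(path, sep="\t")
    return PeakTable(
        position=df["position"].to_numpy(),
        elution=df["elution"].to_numpy(),
        width=df["width"].to_numpy(),
        area_plus=df["area_plus"].to_numpy(),
        area_minus=df["area_minus"].to_numpy(),
        flag=df["flag"].to_numpy(dtype=object),
    )


def write_trace(trace: Trace, prefix) -> None:
    """Per-channel two-column text (elution index, intensity) plus a peak
    position file, under ``<prefix>.<channel>.txt``."""
    prefix = Path(prefix)
    for name, values in trace.channels.items():
        df = pd.DataFrame({"elution": np.arange(len(values)), "intensity": values})
        df.to_csv(f"{prefix}.{name}.txt", sep="\t", index=False)
    pd.DataFrame({"position": np.arange(1, len(trace.peak_positions) + 1),
                  "elution": trace.peak_positions}).to_csv(
        f"{prefix}.peaks.txt", sep="\t", index=False
    )


def read_trace(prefix, channels=("plus_catalyst", "minus_catalyst", "ladder")) -> Trace:
    prefix = Path(prefix)
    chan = {
        name: pd.read_csv(f"{prefix}.{name}.txt", sep="\t")["intensity"].to_numpy()
        for name in channels
    }
    peaks = pd.read_csv(f"{prefix}.peaks.txt", sep="\t")["elution"].to_numpy()
    return Trace(channels=chan, peak_positions=peaks)


# ---------------------------------------------------------------------------
# differences, regions, binding
# ---------------------------------------------------------------------------


def write_difference(diff: DifferenceProfile, calls, path) -> None:
    called = {c.position: c.direction for c in calls}
    vals = np.where(diff.nodata_mask, NODATA_SENTINEL, diff.delta)
    df = pd.DataFrame(
        {
            "position": diff.positions,
            "delta": vals,
            "call": [called.get(int(p), ".") for p in diff.positions],
        }
    )
    with open(path, "w") as fh:
        fh.write(f"# 1-based positions; -999 = no data; smoothed={diff.smoothed}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_difference(path) -> DifferenceProfile:
    header = Path(path).read_text().splitlines()[0]
    smoothed = "smoothed=True" in header
    df = pd.read_csv(path, sep="\t", comment="#")
    mask = df["delta"] == NODATA_SENTINEL
    return DifferenceProfile(
        positions=df["position"].to_numpy(),
        delta=np.where(mask, np.nan, df["delta"].to_numpy()),
        nodata_mask=mask.to_numpy(),
        smoothed=smoothed,
    )


def write_regions(regions: list[Region], path, zero_based: bool = False) -> None:
    """Region table; 1-based inclusive spans by default (probing convention),
    0-based half-open BED-style spans behind ``zero_based``."""
    rows = []
    for r in regions:
        start = r.start - 1 if zero_based else r.start
        rows.append(
            {
                "region_id": r.region_id,
                "direction": r.direction,
                "start": start,
                "end": r.end,
                "n_calls": r.n_calls,
                "mean_magnitude": r.mean_magnitude,
            }
        )
    with open(path, "w") as fh:
        fh.write(
            "# spans are 0-based half-open (BED-style)\n"
            if zero_based
            else "# spans are 1-based inclusive (not BED)\n"
        )
        pd.DataFrame(
            rows, columns=["region_id", "direction", "start", "end", "n_calls", "mean_magnitude"]
        ).to_csv(fh, sep="\t", index=False)


def write_binding_csv(data: BindingDataset, path) -> None:
    pd.DataFrame(
        {
            "concentration_nM": data.protein_concentration,
            "fraction_bound": data.fraction_bound,
            "replicate": data.replicate or "1",
        }
    ).to_csv(path, index=False)


def read_binding_csv(path) -> BindingDataset:
    df = pd.read_csv(path)
    df = df.sort_values("concentration_nM", kind="stable")
    rep = str(df["replicate"].iloc[0]) if "replicate" in df else None
    return BindingDataset(
        protein_concentration=df["concentration_nM"].to_numpy(),
        fraction_bound=df["fraction_bound"].to_numpy(),
        replicate=rep,
    )


def write_fit_json(fit: HillFit, path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "A": fit.A,
                "n": fit.n,
                "k_half_nM": fit.k_half,
                "r_squared": fit.r_squared,
                "converged": fit.converged,
            },
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )


def write_fitted_curve(fit: HillFit, data: BindingDataset, path, n_points: int = 200) -> None:
    from .binding import hill_fraction_bound

    p = np.geomspace(data.protein_concentration.min(), data.protein_concentration.max(), n_points)
    pd.DataFrame({"concentration_nM": p, "fraction_bound": hill_fraction_bound(p, fit)}).to_csv(
        path, index=False
    )
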