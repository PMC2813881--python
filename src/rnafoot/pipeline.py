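"""End-to-end analysis: cleavage profiles to motif-level footprint reports.

Stages: background subtraction -> normalization -> smoothing -> bound-minus-
free difference -> significance calls -> region segmentation -> structural
assignment -> motif coverage and three-part signature (+ optional Hill
binding fits).  Runs either on files or fully synthetically; every seed and
threshold used is recorded in the machine-readable summary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import fileio
from .binding import fit_hill, goodness_of_fit
from .differential import CallThreshold, call_changes, difference_profile, segment_regions
from .motifs import assign_calls, find_gnra_tetraloops, motif_coverage, signature_check
from .reactivity import NormalizationRule, classify_inaccessible, normalize_reactivity, smooth, subtract_background
from .synthetic import SimulationConfig, build_toy_structure, simulate_cleavage

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of one analysis run.

    With no input paths the run is synthetic: a toy two-motif model of
    ``length`` nucleotides is built and free/bound profiles are simulated
    from it.  Given profile paths (and a structure with annotation
    side-cars), the same stages run on files instead.
    """

    # synthetic mode
    length: int = 540
    seed: int = 1
    intensity_scale: float = 1000.0
    noise_cv: float = 0.05
    background_rate: float = 0.1
    footprint_depth: float = 0.6

    # file mode (all-or-nothing for profiles)
    structure_path: str | None = None
    elements_path: str | None = None
    contacts_path: str | None = None
    free_profile_path: str | None = None
    bound_profile_path: str | None = None
    binding_csv_path: str | None = None

    # analysis parameters
    normalization: NormalizationRule = field(default_factory=NormalizationRule)
    min_abs_delta: float = 0.2
    adjacency_k: int = 2
    diff_on_smoothed: bool = True

    output_dir: str | None = None
    verbosity: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        norm = raw.pop("normalization", None)
        cfg = cls(**raw)
        if norm:
            cfg.normalization = NormalizationRule(**norm)
        return cfg


def _derived_seeds(seed: int) -> tuple[int, int]:
    rng = np.random.default_rng(seed)
    free, bound = (int(s) for s in rng.integers(0, 2**31 - 1, size=2))
    return free, bound


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and return a JSON-serializable summary.

    Raises with the failing stage's name in the message; when an output
    directory is configured, all intermediate artifacts are written there in
    the package's own re-readable formats.
    """
    out = Path(config.output_dir) if config.output_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    stage = "inputs"
    try:
        if config.free_profile_path and config.bound_profile_path:
            free_raw = fileio.read_cleavage_profile(config.free_profile_path)
            bound_raw = fileio.read_cleavage_profile(config.bound_profile_path)
            model = (
                fileio.read_structure(
                    config.structure_path, config.elements_path, config.contacts_path
                )
                if config.structure_path
                else None
            )
            seeds = {}
        else:
            model = build_toy_structure(
                config.length, config.seed, footprint_depth=config.footprint_depth
            )
            free_seed, bound_seed = _derived_seeds(config.seed)
            base = dict(
                length=config.length,
                intensity_scale=config.intensity_scale,
                noise_cv=config.noise_cv,
                background_rate=config.background_rate,
                footprint_depth=config.footprint_depth,
            )
            free_raw = simulate_cleavage(model, "free", SimulationConfig(seed=free_seed, **base))
            bound_raw = simulate_cleavage(model, "bound", SimulationConfig(seed=bound_seed, **base))
            seeds = {"master": config.seed, "free": free_seed, "bound": bound_seed}

        stage = "subtract_background"
        free_net = subtract_background(free_raw)
        bound_net = subtract_background(bound_raw)

        stage = "normalize"
        free_react = normalize_reactivity(free_net, config.normalization)
        bound_react = normalize_reactivity(bound_net, config.normalization)

        stage = "smooth"
        window = config.normalization.smoothing_window
        free_s = smooth(free_react, window)
        bound_s = smooth(bound_react, window)

        stage = "difference"
        if config.diff_on_smoothed:
            diff = difference_profile(bound_s, free_s)
        else:
            diff = difference_profile(bound_react, free_react)

        stage = "call_changes"
        threshold = CallThreshold(min_abs_delta=config.min_abs_delta)
        calls = call_changes(diff, threshold)

        stage = "segment_regions"
        regions = segment_regions(calls)

        stage = "assign"
        summaries = coverage = signatures = None
        gnra = []
        if model is not None and model.elements:
            summaries = assign_calls(calls, model, config.adjacency_k)
            coverage = motif_coverage(summaries)
            signatures = signature_check(calls, model)
            gnra = find_gnra_tetraloops(model)

        stage = "classify_inaccessible"
        inaccessible = classify_inaccessible(free_react, config.normalization.inaccessible_cutoff)

        stage = "binding"
        binding_fit = None
        if config.binding_csv_path:
            data = fileio.read_binding_csv(config.binding_csv_path)
            binding_fit = fit_hill(data)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    n_prot = sum(1 for c in calls if c.direction == "protection")
    summary = {
        "seeds": seeds,
        "normalization": {
            "factor_free": free_react.normalization_factor,
            "factor_bound": bound_react.normalization_factor,
            "exclude_top_fraction": config.normalization.exclude_top_fraction,
            "reference_fraction": config.normalization.reference_fraction,
        },
        "threshold": {
            "min_abs_delta": threshold.min_abs_delta,
            "background_multiplier": threshold.background_multiplier,
        },
        "smoothing_window": window,
        "diff_on_smoothed": config.diff_on_smoothed,
        "adjacency_k": config.adjacency_k,
        "n_calls": len(calls),
        "n_protections": n_prot,
        "n_enhancements": len(calls) - n_prot,
        "n_regions": len(regions),
        "fraction_inaccessible_free": float(np.mean(inaccessible)),
        "gnra_tetraloops": gnra,
        "motif_coverage": coverage,
        "signatures": [
            {
                "motif": s.motif_id,
                "loop": s.loop_protected,
                "receptor_contact": s.receptor_contact_protected,
                "receptor_extension": s.receptor_extension_protected,
                "complete": s.complete,
            }
            for s in signatures
        ]
        if signatures is not None
        else None,
        "binding_fit": (
            {
                "A": binding_fit.A,
                "n": binding_fit.n,
                "k_half_nM": binding_fit.k_half,
                "r_squared": goodness_of_fit(binding_fit, data),
                "converged": binding_fit.converged,
            }
            if binding_fit is not None
            else None
        ),
    }

    if out:
        if model is not None:
            fileio.write_ct(model, out / "structure.ct")
            fileio.write_annotations(model, out / "elements.tsv", out / "contacts.tsv")
        fileio.write_cleavage_profile(free_raw, out / "free_raw.tsv")
        fileio.write_cleavage_profile(bound_raw, out / "bound_raw.tsv")
        fileio.write_reactivity(free_react, out / "free_reactivity.tsv")
        fileio.write_reactivity(bound_react, out / "bound_reactivity.tsv")
        fileio.write_reactivity(free_s, out / "free_reactivity_smoothed.tsv")
        fileio.write_reactivity(bound_s, out / "bound_reactivity_smoothed.tsv")
        fileio.write_difference(diff, calls, out / "difference.tsv")
        fileio.write_regions(regions, out / "regions.tsv")
        if summaries is not None:
            pd.DataFrame(
                [
                    {
                        "label": s.label,
                        "kind": s.kind,
                        "adjacency": s.adjacency,
                        "n_positions": s.n_positions,
                        "n_protected": s.n_protected,
                        "n_enhanced": s.n_enhanced,
                        "in_tetraloop_receptor": s.in_tetraloop_receptor,
                    }
                    for s in summaries
                ]
            ).to_csv(out / "element_summary.tsv", sep="\t", index=False)
        if binding_fit is not None:
            fileio.write_fit_json(binding_fit, out / "binding_fit.json")
        (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")

    return summary
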