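# rnafoot

Quantification of hydroxyl radical footprinting experiments on RNA, and
cooperative Hill analysis of protein-RNA binding curves.

Hydroxyl radicals cleave the RNA backbone roughly in proportion to each
nucleotide's solvent accessibility, so a capillary-electrophoresis readout
of cleavage positions is a single-nucleotide-resolution map of an RNA's
tertiary fold — and a protein bound to the RNA leaves a footprint of
reduced cleavage at its contact surface. `rnafoot` is for structural RNA
biochemists who run such experiments (or want to reason quantitatively
about them): it turns raw two-channel intensity data into normalized
reactivities, maps protein-induced protections and enhancements onto
annotated secondary structure — in particular onto GNRA tetraloop-receptor
tertiary motifs — and fits filter-partitioning binding data to the
cooperative Hill model.

## What it computes

**Reactivity scale.** Net intensities (after subtracting the (−)-catalyst
background channel) are normalized to a 0-to-~1.5 scale by dividing by the
mean of the 8% most reactive nucleotides, after first excluding the top 2%
as outliers. On this scale 1.0 is by definition the mean intensity of
highly reactive (solvent-exposed) nucleotides, and nucleotides at or below
0.5 — one-half that mean — are classified solvent inaccessible.

**Footprints.** Bound-minus-free difference profiles,
Δ(i) = R_bound(i) − R_free(i), with protections negative and enhancements
positive. Changes with |Δ| ≥ 0.2 (two-fold above typical background; the
rule is inclusive) are significant; calls are segmented into regions,
assigned to structural elements, and classified as within / adjacent to /
distal from annotated tetraloop-receptor motifs. A per-motif check reports
the three-part signature of a protein-stabilized tetraloop-receptor
interaction: protection of (i) the tetraloop, (ii) the receptor docking
face, and (iii) the receptor helix extending toward the exterior.

**Binding.** Filter-partitioning titrations are fit by nonlinear least
squares to

    fraction bound = A·[P]ⁿ / ([P]ⁿ + K½ⁿ)

giving the bindable fraction A, apparent Hill coefficient n, half-saturation
concentration K½, and R².

A seeded synthetic-data module generates structure models with planted
tetraloop-receptor footprints, two-channel cleavage profiles,
electropherogram-like peak trains with signal decay, and noisy Hill curves,
so the entire pipeline is testable end-to-end without instrument data.

## Worked example

Fit a synthetic bI3-like titration (12 log-spaced concentrations,
0.1–3000 nM, noise sd 0.02, generated with A=0.95, n=2.2, K½=9.7 nM):

```sh
$ rnafoot fit-binding --csv bI3.csv --out fit.json
A=0.957 n=2.09 K1/2=9.6 nM R^2=0.999
```

The fit recovers the generating parameters within noise: ~96% of the RNA is
bindable, half-saturation near 9.7 nM, and a Hill coefficient near 2 —
consistent with cooperative binding by two protein dimers.

Run the full footprinting analysis on a seeded 540-nt synthetic experiment:

```sh
$ rnafoot run-all --seed 1
```

Key fields of the printed summary:

```json
{
  "n_protections": 34,
  "n_enhancements": 0,
  "n_regions": 6,
  "motif_coverage": 1.0,
  "fraction_inaccessible_free": 0.2,
  "gnra_tetraloops": ["L2", "L9"],
  "signatures": [
    {"motif": "L2:P8", "loop": true, "receptor_contact": true,
     "receptor_extension": true, "complete": true},
    {"motif": "L9:P5", "loop": true, "receptor_contact": true,
     "receptor_extension": true, "complete": true}
  ]
}
```

Read: 20% of the free RNA is solvent-inaccessible; upon binding, 34
nucleotides become significantly protected, every one of them within or
immediately adjacent to the two GNRA tetraloop-receptor motifs (L2 docked
on P8, L9 docked on P5), and both motifs show the complete three-part
protection signature. The summary also records the exact normalization
factors, threshold, adjacency parameter and seeds used.

The other subcommands (`simulate`, `integrate`, `normalize`, `diff`,
`annotate`) expose the individual stages; `rnafoot run-all --config cfg.yaml`
drives everything from a YAML config. All of this is equally available as a
library (`import rnafoot`).

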