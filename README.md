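# phytomotion

Structural and sequence analysis of histidine acid phytases (clade 2
histidine phosphatases, Pfam His_Phos_2), built around the questions a
U-loop-bearing multiple inositol polyphosphate phosphatase (MINPP)
raises: how far does the molecular lid rotate between catalytic-cycle
snapshots, which residues form the hinge, which residues populate the six
phytate specificity pockets around a bound inositol hexakissulfate
analog, and which family members carry a U-loop insertion, of which type?

It is aimed at structural biologists and enzyme engineers working with
phytases and related two-domain acid phosphatases who want these
quantities computed reproducibly from deposited coordinates and
sequences, with every number traceable to inputs, parameters and
checksums.

## What it computes

**Domain motion.** Two snapshots of the same protein are compared by the
sliding-window rotation-vector method: each residue's local C-alpha
window is superposed across the states, the resulting axis-angle vectors
are clustered into quasi-rigid domains, and the moving domain's residual
motion after a fixed-domain fit is decomposed into a screw — rotation
angle θ about a hinge axis **n** with pitch translation along it.  The
reported *percent closure* is 100·sin²γ, where γ is the angle between
**n** and the line joining the domain centroids: 100% is a pure
book-closing motion, 0% a pure twist.  Hinge residues are the junction
segments between domains plus residues whose C-alpha lies within 5.5 Å
of the screw axis.

**Active site.** Specificity subsites A–F are mapped with the 6 Å rule:
pocket A holds the substituent nearest the catalytic histidine (the
scissile-phosphate analog) and B–F follow in cyclically decreasing
ring-position order; each pocket's contacts are the residues with any
heavy atom within the cutoff of the substituent group.  Disulfides
(SG–SG ≤ 2.3 Å), polar contacts (N/O…N/O ≤ 3.5 Å), minimum distances and
per-residue displacement classes (< 2, 2–4, > 4 Å after a fixed-domain
fit) complete the contact analytics.

**Sequences.** A scanner for the family signature motifs — RHGXRXh with
the nucleophilic histidine, the HD / HAE proton-donor motifs, GXLTXXG,
DAAM, and the extended consensus RHGXRXL(S/T)SXK — plus U-loop detection
against a non-loop reference alignment and classification into types A
(long, two cysteines), B (medium) and C (short).

**Synthetic ground truth.** Seeded generators produce two-body hinge
structures with a known screw, toy ligand sites with planted contacts at
exact distances, and sequence families with planted motifs and loops, so
every stage of the pipeline is testable without downloads.

See `docs/methods.md` for the model details, parameter defaults and
limitations.

## Worked example

Generate a synthetic hinge pair with a known 18° screw and analyse it:

```
$ phytomotion simulate motion --spec spec.json --out sim/   # {"angle": 18.0, "seed": 4}
$ phytomotion motion sim/state_a.pdb sim/state_b.pdb
analysing chain A: state_a -> state_b
{
  "fixed_domain_rmsd": 0.0,
  "hinge_segments": [
    {"chain": "A", "end": 124, "start": 119}, ...
  ],
  "moving_domain_fraction": 0.427,
  "n_domains": 2,
  "percent_closure": 86.1,
  "rotation_angle": 18.0,
  ...
}
```

The pipeline found two rigid domains, recovered the applied rotation
exactly (18.0°), and placed the hinge segments at the junction between
the bodies (the generator's hinge sits between residues 120 and 121).
The closure value says this particular random axis is 86% book-closing,
14% twist.  `--json report.json --tsv per_residue.tsv` writes the full
report (with input checksums and the complete configuration) and a
per-residue table of rotation-vector magnitude, domain label and
displacement.

Other subcommands: `phytomotion subsites` (A–F mapping around a bound
ligand), `phytomotion contacts` (disulfide / polar / minimum-distance),
`phytomotion uloop` (motif scan + loop classification), and
`phytomotion snapshot-cycle`, which runs the whole workflow over four
snapshots (apo, substrate-analog complex, covalent intermediate, product
complex) and emits one consolidated report.

The numbered scripts under `analysis/` run the synthetic study end to
end (screw recovery, closure geometry, subsite mapping, sequence screen)
and write their tables under `results/`.  For example:

```
$ python analysis/02_closure_geometry.py
 axis_angle_deg  expected_closure_pct  reported_closure_pct  deviation_pct
              0                   0.0                  0.00          0.002
             45                  50.0                 50.00          0.004
             90                 100.0                100.00         -0.000
largest deviation from the sin^2 law: 0.006 points
```

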