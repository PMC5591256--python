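# Methods

This note documents the models and numerical conventions behind
`triplexkit`: what each stage computes, which knobs matter, what the
synthetic trajectories do and do not emulate, and where the design was
genuinely open.

## Scope and the shape of the problem

The package analyses the structural behaviour of locked-nucleic-acid
(LNA)-modified oligonucleotides bound to double-stranded DNA.  A
pyrimidine-motif triplex-forming oligonucleotide (TFO) lies in the major
groove of a purine·pyrimidine duplex, parallel to the purine strand, and
reads it through Hoogsteen pairs: T•A, and C+•G in which the TFO cytosine
is N3-protonated.  LNA monomers carry a 2′-O,4′-C methylene bridge that
locks the furanose in the north (C3′-endo) pucker; mixing them with DNA
("mixmers") pre-organizes a single strand toward the conformation it
adopts inside a triplex.  The analyses here are the standard readouts of
that system: sugar pseudorotation, glycosidic torsion, per-pair
hydrogen-bond persistence over a trajectory, and base-pair-step helical
parameters of the duplex.

## Sequence model

The mixmer dialect is parsed literally: lowercase = DNA, uppercase = LNA,
`**P**` (or bare `P`) = TINA, an intercalating base-free monomer that is
not counted as a nucleotide; `-` separates segments (bisLNA arm/linker/
arm); `Cy3`/`Cy5` at an end is a fluorophore label; `5'-`/`-3'`
decorations and 3′→5′ printing are normalised (unicode primes accepted).
Bold spans longer than one character are kept as binding-site highlights.
Complement operations: the Watson-Crick complement is antiparallel
(A↔T, G↔C, returned 5′→3′); the parallel Hoogsteen complement is
position-wise, maps A→T and G→C+, and is only defined on purine tracts.
Binding-site search requires an exact Hoogsteen-complement match — the
studied TFOs are fully matched, and mismatch-tolerant search is out of
scope.  One consequence is documented behaviour rather than a defect: the
ON3 "c > t" variants (terminal cytosines replaced by thymine, originally
to avoid a fixed-protonation artifact at a fraying end) place T over G at
the ends and therefore have no exact site; they parse and count like any
other entry but cannot seed a built triplex.

The printed 10-nt partial WC complementarity of WC29 to the TFO binding
site depends on an unstated alignment rule; no such rule is hard-coded.

## Fiber models

Idealized structures are generated from fixed per-step helical
parameters, not refined coordinates.  Pair *i* of an *n*-bp duplex sits at
rotation `i·Ω` about and translation `i·h` along the global z axis, with
an optional lateral x-displacement of each pair origin and an optional
inclination of the pair frame.  Defaults: B form Ω = 36.0°, h = 3.38 Å,
x-disp 0, C2′-endo sugars (P = 162°, τm = 38°); A form Ω = 32.7°,
h = 2.81 Å, x-disp −4.1 Å, C3′-endo sugars (P = 18°, τm = 40°) — standard
fiber values.  The A-form default keeps inclination at 0° so the
builder↔analyzer step-twist round trip is exact to numerical precision;
users wanting an inclined A-like start can set the field explicitly.

Bases are rigid planar templates in the standard nucleic-acid reference
frame (origin on the pairing pseudo-dyad, x toward the major groove); the
strand-II base of a WC pair is the complement's template rotated 180°
about x.  The third strand is placed from a computed Hoogsteen transform:
the TFO pyrimidine's N3 is put 2.9 Å from the purine's N7 along the
in-plane N7 exit direction, with the second contact (O4→N6 for T•A,
N4→O6 for C+•G) aligned.  The exact triad template used originally is
unrecoverable; the contract here is geometric — every built Hoogsteen
N7–N3 distance is 2.9 Å, comfortably below the 3.5 Å pairing criterion —
not any specific deposited coordinates.  TFO cytosines are flagged
protonated at build time.  TINA monomers get no 3D representation
(explicit intercalator geometry is out of scope); TFO residues are
numbered by nucleotide index.

Sugars are built by an exact pseudorotation solver.  Given a target
(P, τm), the cosine-law torsions νⱼ = τm·cos(P + (j−2)·144°) are imposed
for ν1, ν2 while three ring bond angles are solved (square Newton system)
to close the ring on the fixed bond lengths, and an outer fixed-point
iteration adjusts the targets until the *measured* Altona–Sundaralingam
phase and amplitude equal the request to < 1e-6°.  The AS inversion used
throughout is

    tan P = ((ν4 + ν1) − (ν3 + ν0)) / (2 ν2 (sin 36° + sin 72°)),

with amplitude computed by the hypot form so P = ±90° (ν2 = 0) is exact;
"undefined pucker" is raised only for genuinely planar rings
(max |νⱼ| < 1e-6°).  χ is set by spinning the ring about the glycosidic
bond; B-form DNA residues are built at χ = 262° (upper anti), north
sugars (LNA and A-form) at χ = 203° (low anti), matching the low-anti /
north coupling seen for triplex-bound TFOs.  LNA rings are fixed at
P = 17°, τm = 48°; the methylene bridge atoms themselves are not placed,
because no analysis here consumes them, and south targets on LNA raise an
error.  Phosphates are attached by template torsions adequate for
groove-width trends; backbone torsional realism beyond the ring is
explicitly not guaranteed.

## Conformational analysis

χ is the dihedral O4′-C1′-N1-C2 (pyrimidines) / O4′-C1′-N9-C4 (purines),
reported in [0°, 360°) so the conventional bins read literally:
anti 170° < χ < 320°, low anti below 220°, high anti above 270° (the
unnamed 220–270° middle is labelled `mid_anti` for complete reporting),
syn 30° < χ < 90°, everything else `other`.  P is reported in
(−90°, 270°] so north (−90° < P ≤ 90°) and south (90° < P ≤ 270°)
partition the circle; 90° is north.  These output-range conventions are
forced by the bin arithmetic and are deliberately surfaced here.
Profiles are per-residue class fractions and 5°-binned histograms
(width configurable); by default the last two nucleotides of each strand
end are excluded, the usual guard against end fraying, with
`exclude_ends=0` available.

## Pairing persistence

One heavy-atom distance per pair is monitored: N1–N3 for WC, N7–N3 for
Hoogsteen; a distance under 3.5 Å counts as hydrogen-bonded in that
frame.  No hydrogen positions, angle terms or smoothing are involved.  A
pair is called *lost* when its unpaired fraction over the final third of
the trajectory exceeds one half — persistence plots of destabilized
triplexes end in blank space, and this window criterion is a stated,
reproducible version of reading them; both knobs are configurable.  Lost
pairs are annotated by 5′/3′ proximity along their strand.  Spontaneous
terminal openings are reported, not suppressed; use exclude-ends
reporting where terminal restraint-like behaviour is wanted.

## Helical parameters and the LirA call

Base reference frames come from least-squares fits of the observed base
atoms to the planar templates (fit RMSD > 0.5 Å is an error).  Step
parameters (twist, roll, tilt, shift, slide, rise) follow the symmetric
mid-frame (CEHS-style, 3DNA-compatible) convention.  The helical
decomposition of each step — x-displacement and inclination — uses the
local helical axis of the step rotation and expresses the displacement in
the 5′-pair frame; this makes the builder round trip exact (a fiber built
at x-disp −4.3 Å measures −4.3 Å).  Curvilinear-axis (Curves+-style)
values can differ from the mid-frame scheme by a few tenths of an
Å/degree, and that scheme also attributes x-displacement per base pair
rather than per step; the convention difference is intentional and
documented.  Groove widths are cross-strand P–P closest approaches per
base-pair level minus 5.8 Å for the phosphate radii, with the major
groove taken as the closest approach on the opposite side of the pairing
register — a simple El Hassan–Calladine-style recipe adequate for the
qualitative groove statements made here.

The duplex-form classifier takes mean interior-step values and returns
exactly one of B, A, LirA, intermediate.  Defaults: B when
x ≥ −1.5 Å and twist ≥ 34°; candidate-A when x ≤ −3.0 Å, slide ≤ −1.0 Å
and twist ≤ 32°; within candidate-A, A when inclination ≥ 12° or
roll ≥ 8°, LirA ("Low Inclination & Roll A-DNA") when both inclination
and roll are below 8°, otherwise intermediate.  These thresholds bracket
the reference mean tuples for the two regimes — (−0.8 Å, 0 Å, 36°) for
the unmodified duplex and (−4.3 Å, −1.6 Å, 30°) for the LNA/DNA
hetero-duplex — and every threshold is configurable.

## Synthetic trajectories

MD output is emulated, not simulated.  On top of a built model the
generator applies, per 40 ps frame:

* **Sugar repuckering** — each residue follows a stationary two-state
  Markov chain over {north, south}; DNA defaults to a north fraction of
  0.30 (the paper-level statement is only that DNA prefers south; 0.30 is
  a fixed, configurable choice of "south-preferring"), LNA is locked at
  1.  The ring is rebuilt each frame at P ~ N(17°, 5°) (north) or
  N(162°, 8°) (south), truncated to the bin and quantized to 0.25° so
  exact ring solutions can be cached per residue.
* **Hoogsteen opening** — each HG pair follows a two-state chain with
  stationary open probability (baseline 0.02) and per-pair overrides; an
  open pair's TFO nucleotide is displaced rigidly 3 Å along the radial
  groove-exit direction, carrying N7–N3 from 2.9 Å to ≈ 5.9 Å.  Opening
  is a displacement, not a torsional flip: the monitored observable is a
  single distance and this is the simplest sufficient mechanism.
* **Noise** — isotropic Gaussian positional noise, σ = 0.15 Å, on every
  atom.

The realized state series are returned as ground truth, and the emitted
coordinates are reconciled with it: after noise, any monitored pair
distance on the wrong side of the 3.5 Å cutoff, and any ring whose
measured pucker class contradicts its latent state, has its noise
redrawn.  This makes the persistence matrix and the per-frame pucker
classes equal the ground truth exactly, so recovery tests are exact where
they can be and statistical only where they must be.  Transition rates
default to 0.05/frame; they are a contract about occupancies, not
kinetics — where a test asserts a binomial error bar the rate is set to 1
(i.i.d. draws), since the slow-mixing default inflates the variance of a
2000-frame occupancy by roughly (1+ρ)/(1−ρ) ≈ 39.

What the generator does *not* emulate: force-field energetics, correlated
inter-residue motion, backbone torsional dynamics, χ dynamics coupled to
repuckering, base-pair breathing of the WC duplex, or the specific
lost-pair counts of particular simulated systems.  Passing tests
demonstrate that the analysis stack measures what the generator planted
at the stated statistical power — not that real MD data would show those
values.

Presets reproduce qualitative signatures at desk scale: the
`3prime-reduced` / `5prime-reduced` pair raise the opening probability on
the terminal DNA-only run of the respective TFO (0.85 on the 3′ run,
0.30 on the 5′ run: destabilization concentrated at, and only lasting at,
the 3′ end), `lna-tfo` forces the bound TFO fully north while duplex DNA
stays mixed, and `hetero-duplex` starts the LNA/DNA duplex from an A-like
low-inclination/low-roll spec (twist 30°, x-disp −4.3 Å) that the
classifier calls LirA.

## Reproducibility and problem sizes

All randomness flows from a single integer seed; equal seeds give
bit-identical trajectories and, with fixed-precision TSV output, byte-
identical analysis artifacts (the `demo` subcommand is tested against
committed golden files).  Default test and demo problem sizes are the
19-bp c-MYC duplex and its 13–15-nt TFOs — the same systems the analyses
were designed around — with trajectories of 20–2000 frames; a 2000-frame
triplex trajectory generates in well under a minute on one core.

## Known limitations

* Fiber models are idealized: no sequence-dependent geometry, no
  minimization, no solvent; triplex sterics beyond the Hoogsteen-distance
  contract are not validated.
* Groove widths use raw P–P minima, not spline-refined curves; values are
  for trends, not absolute comparison with refined structures.
* The helical decomposition convention differs from curvilinear-axis
  tools by design (see above).
* Mismatched (e.g. T·G) triads are not modelled anywhere in the pipeline.
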