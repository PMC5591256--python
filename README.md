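# triplexkit

Structural analysis of LNA-modified DNA duplexes and parallel Hoogsteen
triplexes: mixmer sequence modelling, fiber-model structure building,
sugar-pucker and glycosidic-torsion classification, hydrogen-bond
persistence over trajectories, and base-pair-step helical
characterization including the LirA ("Low Inclination & Roll A-DNA")
duplex-form call.

## Who this is for

Nucleic-acid structural biologists and oligonucleotide chemists working
with triplex-forming oligonucleotides (TFOs) that mix DNA with locked
nucleic acid (LNA).  A pyrimidine TFO binds the polypurine strand of
duplex DNA in the major groove, parallel to it, through Hoogsteen pairs
(T•A and C+•G with a protonated cytosine); LNA's 2′-O,4′-C bridge locks
its sugar in the north (C3′-endo) pucker and pre-organizes the strand for
binding.  `triplexkit` provides the full analysis stack around that
system, plus a seeded synthetic-trajectory generator that emulates the
statistical structure of MD snapshot series so every analysis stage can
be tested against known ground truth.

## The quantities at the core

* **Sugar pucker** — Altona–Sundaralingam pseudorotation from the five
  endocyclic torsions ν0..ν4 (ν2 = C1′-C2′-C3′-C4′ = τm·cos P):

  tan P = ((ν4+ν1) − (ν3+ν0)) / (2 ν2 (sin 36° + sin 72°)),

  binned *north* (−90° < P ≤ 90°) / *south* (90° < P ≤ 270°).
* **Glycosidic torsion** — χ = O4′-C1′-N1-C2 (pyrimidines) /
  O4′-C1′-N9-C4 (purines), in [0°, 360°); *anti* 170–320° with low/high
  anti below 220° / above 270°, *syn* 30–90°.
* **Pair persistence** — N1–N3 (WC) and N7–N3 (Hoogsteen) heavy-atom
  distances per frame; < 3.5 Å counts as hydrogen-bonded; a pair is
  "lost" when mostly open over the final third of a run.
* **Helical parameters** — mid-frame (CEHS/3DNA-style) twist, roll,
  tilt, shift, slide, rise per base-pair step, plus x-displacement and
  inclination from the local helical axis; mean interior values feed a
  B / A / LirA / intermediate classifier.

## Worked example

```python
from triplexkit import (
    get_duplex, get_oligo, count_lna, find_tfo_binding_site,
    build_triplex, TrajSpec, generate, persistence_matrix,
    step_parameters, mean_step_parameters, classify_helix,
)

on2 = get_oligo("ON2")                      # 5'-CcTtTtCtTtTtTcT-3'
print(len(on2), count_lna(on2))             # -> 15 8

duplex = get_duplex("c-MYC_DS19")
tfo = get_oligo("ON2-5'DNA")
print(find_tfo_binding_site(duplex, tfo))   # -> (3, 17)

model = build_triplex(duplex, tfo)          # B-form fiber, 3 chains
traj, truth = generate(model, TrajSpec(n_frames=200, seed=7))

pp = persistence_matrix(traj)               # 19 WC + 15 HG pairs
hg = [i for i, p in enumerate(pp.pairs) if p.kind == "HG"]
print(round(pp.fraction_paired()[hg].mean(), 3))   # -> 0.991

means = mean_step_parameters(step_parameters(model))
print(round(means["twist"], 2), classify_helix(means).label)  # -> 36.0 B
```

The 15-mer ON2 carries 8 LNAs; its DNA-end variant ON2-5'DNA binds the
19-bp c-MYC target at purine positions 3–17, giving 15 Hoogsteen pairs on
top of the 19 Watson-Crick pairs.  At the default 2% stationary opening
probability the mean Hoogsteen occupancy over 200 frames comes out 0.991,
and the built fiber measures back its own 36.0° twist, classifying as
B-form.  The `truth` object holds the generator's realized open/closed
and north/south series; the persistence matrix equals it exactly by the
generator's consistency contract.

The same pipeline from the shell:

```sh
triplexkit fixtures                       # list the shipped sequences
triplexkit build --duplex c-MYC_DS19 --tfo ON2-5'DNA -o triplex.pdb
triplexkit synth --preset 3prime-reduced --frames 500 --seed 1 -o traj.pdb
triplexkit analyze traj.pdb --outdir results/
triplexkit demo --outdir demo/            # seeded end-to-end run
```

`analyze` writes per-residue conformation tables, the pair×time
persistence table and text mosaic, per-step helical parameters and a
summary with the helix call; every run dumps its effective `config.txt`
and replaying from it reproduces the outputs byte for byte.

## Layout

| module | contents |
| --- | --- |
| `triplexkit.oligo` | mixmer notation, WC/Hoogsteen complements, binding sites, ratios, sequence catalog, FASTA |
| `triplexkit.structure` | Structure/Trajectory containers, PDB I/O |
| `triplexkit.builder` | B/A fiber duplexes, parallel triplexes, exact sugar-pucker construction |
| `triplexkit.conformation` | dihedrals, χ, pseudorotation, bins, per-residue profiles |
| `triplexkit.pairing` | WC/HG pair registry, persistence matrix, lost-pair calls |
| `triplexkit.helical` | base frames, step parameters, grooves, B/A/LirA classifier |
| `triplexkit.synth` | seeded synthetic trajectories with ground truth; presets |
| `triplexkit.cli` | `triplexkit` command: build / synth / analyze / demo / fixtures |

See `docs/methods.md` for the models, conventions and limitations in
detail.
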