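# memwire

Trajectory post-processing for membrane-transporter MD: **water-wire
detection by the minimum-spanning-tree minimax-gap method**, geometric
**fatty-acid / lipid binding classification** at interhelical sites,
**leaflet-resolved radial lipid enrichment**, and **reciprocal-space (PME)
electrostatic potential profiles** along detected wires.

The package targets the analysis of SLC25-family mitochondrial carriers —
the ADP/ATP carrier (AAC1) and uncoupling protein 1 (UCP1) — where
deprotonated long-chain fatty acids such as arachidonate (AA) activate a
proton leak across the inner membrane.  Transient chains of water molecules
("water wires") bridging the intermembrane-space (C) and matrix (M) sides
are candidate Grotthuss proton pathways; the analyses here quantify how
often such wires form, where fatty acids bind, how strongly they accumulate
near the protein, and what electrostatic barrier a proton on a wire would
face.  All algorithms are protein-agnostic: any structure + trajectory with
helix annotations and per-atom charges can be analyzed.

## The methods in brief

**Water wires (minimax gap).** Per frame, the oxygens of waters inside a
cylinder around the protein (optionally plus AA carboxylate oxygens) form a
graph whose edges are minimum-image O–O distances up to 1 nm.  For bulk
endpoint waters *s*, *t* on opposite sides, the path through a minimum
spanning tree realizes

    max_gap(s,t) = min over paths P of max over edges e in P of d(e),

the smallest achievable largest O–O hop.  A wire is *formed* when
`max_gap <= 0.33 nm`.  Formation frequency, lifetime histograms, and
assignment of each wire to a pseudosymmetric unit (the nearest helix pair:
TM2/TM3, TM4/TM5, TM6/TM1, …) are reported per trajectory.

**Binding.** A lipid probe is *bound* at an interhelical site when its tail
crosses a two-triangle surface spanning the helix gap while contacting heavy
atoms of both helices within 0.5 nm; *deep* when its head group (AA
carboxylate / POPC phosphate) is within 1.3 nm of the protein center of
mass; *cavity-bound* when every heavy atom is inside the central cavity.
Maximal deep runs become events with residence times; per-residue contact
frequencies are normalized by the bound-frame count.

**Enrichment.** With the protein approximated as a cylinder (C-leaflet
radius from the C-side helix ends, M-leaflet radius fixed at 2 nm), the AA
mole fraction `AA/(AA+POPC)` is pooled over frames in annuli of distance
from the protein surface; the enrichment ratio compares the 0–1 nm ring to
the bulk membrane.

**Electrostatics.** The smooth (reciprocal) component of the particle-mesh
Ewald potential — 4th-order B-spline charge spreading, FFT Poisson solve
with Gaussian smearing `exp(-k²/4β²)/k²`, k=0 excluded — is evaluated at
wire-node oxygens, referenced to bulk water, and binned along the membrane
normal in kT/e (convertible to volts).  Short-range terms are deliberately
omitted, as in grid-based potential estimators of this kind.

**Synthetic systems.** A seeded generator builds a 6-helix pseudo-protein in
a two-leaflet bead membrane (POPC-like lipids, charge −1 AA chains, water
slabs, counter-ions; always electroneutral) and can *plant* wire schedules,
binding events, and radial enrichment with known ground truth, emitted as a
sidecar JSON.  Every detector has recovery tests driven from this ground
truth.

## Worked example

```python
from memwire import (SyntheticSpec, generate_system, plant_wire_schedule,
                     PlantedWireSchedule, classify_and_summarize)

sysd = generate_system(SyntheticSpec(seed=1, n_frames=100))
schedule = PlantedWireSchedule.bernoulli(100, 0.4, seed=2)
traj, record = plant_wire_schedule(sysd, schedule)   # thread waters through TM4/TM5
stats = classify_and_summarize(traj)
print(f"planted wire fraction   : {record['realized_fraction']:.2f}")
print(f"recovered frequency     : {stats.formation_frequency:.2f}")
print(f"longest wire lifetime   : {stats.lifetimes_ns.max():.1f} ns")
print(f"wires per unit          : {stats.unit_counts}")
```

prints

```
planted wire fraction   : 0.40
recovered frequency     : 0.40
longest wire lifetime   : 0.8 ns
wires per unit          : {'TM4/TM5': 40}
```

The detector recovers the planted formation frequency exactly: wires exist
precisely in the frames where the generator placed a complete chain
(O–O spacing ≤ 0.30 nm), and the longest run of formed frames (4 frames ×
200 ps) gives the 0.8 ns lifetime.  The constriction of every wire lies in
the planted TM4/TM5 channel, so all 40 formed frames are assigned to that
unit.

The same workflow runs from the shell:

```
memwire generate --seed 1 --n-frames 100 --out traj.gro --ground-truth gt.json
memwire wires traj.gro                # wires_series.csv + wires_summary.json
memwire check                         # audit the packaged run-metadata tables
memwire run --config run.yaml         # full multi-stage pipeline
```

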