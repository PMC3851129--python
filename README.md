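# glusim

Dynamic kinetic simulation and gene-dosage sensitivity analysis of
L-glutamate fermentation in an *E. coli* ΔsucA central-metabolism model.

The package provides:

* **model_core** — species / Michaelis–Menten rate laws / reactions /
  covalent-modification cycles (the isocitrate-dehydrogenase
  phosphorylation cycle with 3-phosphoglycerate inhibition of the
  bifunctional kinase/phosphatase) and network assembly with a
  stoichiometric matrix.
* **gene_expression** — operon-level transcription/translation units with
  a dosage (copy-factor) multiplier, TF regulation, and RNAP/ribosome
  levels driven by the specific growth rate.
* **biomass_model** — summation biomass model: precursor composition table
  (positive OAA/FUM coefficients enforced, branch-point key substances
  required), growth-proportional drains, minimum-norm (pseudoinverse)
  combination of branch-point routes, and the fixed revised side reactions
  (arginine route, purine route, glycogen synthesis).
* **simulation_engine** — stiff ODE integration (BDF, generated right-hand
  side, colored finite-difference Jacobian) over a prescribed fed-batch
  growth profile; knockout and copy-factor perturbation operators; molar
  glutamate-per-glucose yield metric.
* **sensitivity** — exponential copy-number sweeps (0.001–1000), maximum
  sensitivity max (Y−Y0)/Y0 and scale factor X/X0, ranking tables,
  dose–response and end-point snapshot reports.
* **reference_model** — a fully parameterised reduced ΔsucA model
  (PTS uptake, glycolysis with explicit PGK/GpmA/Eno, pentose-phosphate
  branch, TCA truncated at α-ketoglutarate, glyoxylate shunt under IclR,
  ICD phosphorylation cycle, glutamate export, 16 perturbable gene units,
  logistic growth profile) plus parameter jitter and the expected
  dosage-direction panel.
* **modelio / sbml / cli** — text model-definition format, TSV time
  courses and growth profiles, SBML L3 export, and the `glusim` CLI.

## CLI

```sh
glusim make-ref --out-dir ref/                 # write the reference model
glusim validate --model ref/model.txt
glusim simulate --model ref/model.txt --profile ref/growth_profile.tsv \
    --t-end 840 --interval 5 --out tc.tsv
glusim sweep --model ref/model.txt --profile ref/growth_profile.tsv \
    --all --points 61 --consumption-species GLC_used --out ranking.tsv
glusim perturb --model ref/model.txt --profile ref/growth_profile.tsv \
    --gene epd-pgk --factor 100 --out snapshot.tsv
glusim export-sbml --model ref/model.txt --out model.xml
```

Every command writes a `<out>.manifest.json` (command, inputs, model
checksum, seed, version, timestamp). For sweeps against the bundled
reference model pass `--consumption-species GLC_used` (the clamped-feed
uptake counter) or use the library-level
`glusim.reference_model.reference_config()`.

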