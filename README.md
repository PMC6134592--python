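# exocube

An offline toolkit for curated **exometabolomics assertion datacubes**:
qualitative observations of how microorganisms transform the metabolite
pool of an environment, organised along three dimensions — metabolites,
organisms and environments — and scored for metabolite competition and
exchange between organisms.

Exometabolomics ("metabolite footprinting") compares the extracellular
metabolite composition of a medium before and after microbial growth.
Each (metabolite, organism, environment) triple gets one *assertion*:
`increase`, `decrease`, `no change` or `not investigated`, while the
untransformed control pool — modelled as the reserved pseudo-organism
`The Environment` — records `detected` / `not detected`. The package is
aimed at microbiologists designing synthetic media and microbial
consortia, and at anyone who needs these assertion tables as computable,
diffable artifacts rather than a website.

## What it does

* **Datacube model and I/O** — validated in-memory datacube; a
  tab-delimited upload dialect (columns `metabolites | organisms |
  environments | action assertions | log2fc | confidence | p_value |
  project`, CSV behind a flag, putative identifications in parentheses);
  a single-file relational SQLite store.
* **Assertion engine** — converts replicate control-vs-spent relative
  abundances into assertions: detection thresholding, a two-sided test
  (Welch's *t* or Mann–Whitney *U*), optional Benjamini–Hochberg
  correction per experiment, and confidence = min(|log2 FC|, 5) for cell
  shading. A metabolite detected on only one side gets the cap (5)
  exactly, since a fold change against zero is undefined.
* **Compatibility scores** — for organisms sharing one environment, with
  `D_o` / `I_o` the metabolite sets organism *o* decreases / increases
  and `P` the control pool:

  * Environmental Uptake Score: `EUS = |D_scored ∩ P| / |P|`
  * Fraction of Metabolites under Competition:
    `OCS-FMC = |D_scored ∩ D_reference| / |D_scored|`
  * Fraction of Metabolites for potential Exchange:
    `OCS-FME = |D_scored ∩ I_reference| / |D_scored|`

  plus per-cell competition/exchange marks. Low FMC and high FME suggest
  a compatible pairing.
* **Views** — One Environment / One Organism / One Metabolite slice
  tables with the tan/gray/red/blue/white/checkered encoding, and the
  bipartite organism–metabolite web (node-link JSON or GraphML).
* **Simulation** — seeded random datacubes, ground-truth spike-in
  replicate experiments, and a fixed two-isolate fixture whose set sizes
  are back-solved from a published compatibility-score walkthrough.

## Worked example

Two soil isolates cultured in R2A broth: *Phenylobacterium* sp.
GW123-8A04 and *Pseudomonas* sp. FW300-N2A2. Build the fixture and score
GW123-8A04 against FW300-N2A2 as the reference column:

```sh
$ exocube simulate worked-example --out worked.tsv
$ exocube score worked.tsv -e R2A -r FW300-N2A2
kind    scored      reference   numerator   denominator value
FMC     GW123-8A04  FW300-N2A2  25          50          0.5
FME     GW123-8A04  FW300-N2A2  8           50          0.16
```

Reading: the two isolates decrease 25 of the same metabolites, which is
half of everything GW123-8A04 consumes (FMC = 0.5) — substantial
potential competition. FW300-N2A2 increases 8 metabolites that
GW123-8A04 decreases (FME = 0.16), so GW123-8A04 could benefit from the
pairing. Selecting the control as reference yields uptake scores:

```sh
$ exocube score worked.tsv -e R2A
kind    scored      reference        numerator  denominator value
EUS     FW300-N2A2  The Environment  26         100         0.26
EUS     GW123-8A04  The Environment  50         100         0.5
```

GW123-8A04 draws on half of the 100-metabolite starting pool, roughly
twice the footprint of FW300-N2A2. The same objects are available from
Python (`exocube.worked_example_fixture()`, `exocube.fmc(...)`, ...),
and `exocube view` / `exocube web` export the slice tables and the
interaction web for any datacube.

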