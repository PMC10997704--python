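# dermocybe

Integrative chemotaxonomy toolkit for dermocyboid *Cortinarius* (subgenus
*Dermocybe*) — the brightly coloured, anthraquinone-pigmented webcaps of
European coniferous forests.

Species delimitation in this group is notoriously hard: rDNA ITS divergence
between sister species can be a handful of bases, and macroscopic characters
overlap.  Pigment chemistry helps: each species carries a reproducible
semi-quantitative profile of 15 annotated anthraquinones (emodin,
dermocybin, dermolutein, flavomannin-6,6'-dimethyl-ether (FDM),
7,7'-biphyscion, their glycosides, …), measurable by HPLC-DAD even from
decades-old herbarium material.  This package implements that workflow as a
reusable, tested library for mycologists and natural-product chemists:

- **`dermocybe.chromatograms`** — HPLC-DAD processing: the three detector
  channels (428/478/519 nm) are summed, peaks called against a 5% threshold,
  expressed relative to the tallest peak (= 100%), classified as *trace*
  (< 10%) or *main* (≥ 10%) pigments, and annotated by retention time.
- **`dermocybe.pigments`** — the 15-compound reference library, 15 encoded
  species profiles, and the four pigment groups (Croceus, Malicorius,
  Ominosus, Sanguineus) with a rule-plus-centroid assignment engine and
  Bray-Curtis species matching for re-identifying unknown material.
- **`dermocybe.morphometrics`** — basidiospore summaries in the
  (min) MV ± sd (max) scheme, the per-spore length/width ratio
  Q = mean ± sd, Bonferroni-corrected Welch t-tests, 95% coverage ellipses
  (χ²(2) quantile 5.991), and an internal-consistency checker for printed
  spore tables.
- **`dermocybe.congruence`** — chemo-phylogenetic congruence from scratch:
  Bray-Curtis matrices (BC = 1 − 2Σmin/Σsum) for pigment tables and for
  alignments via five-state one-hot encoding (= p-distance with gap as a
  state), Ward.D hierarchical clustering (Lance-Williams on unsquared
  dissimilarities), cophenetic matrices, tanglegram entanglement in [0, 1],
  and a one-sided Mantel permutation test (999 permutations).
- **`dermocybe.idkey`** — the dichotomous identification key for Central
  European coniferous-forest *Dermocybe* as machine-readable data: 28
  couplets, 28 terminal leads, 26 taxa, with validation, candidate-set
  traversal under partial observations, and per-pair distinguishing
  characters.
- **`dermocybe.simulate`** — seeded generators for spore measurement sets
  (bivariate normal at the published per-species moments), chromatograms
  (Gaussian peaks from encoded profiles), and coupled alignment +
  pigment-profile data sets with tunable clade/chemistry coupling.

## Worked example

Simulate a noiseless chromatogram for *C. vitiosus* from its encoded profile,
rebuild the profile from the raw trace, and classify it:

```sh
$ dermocybe simulate chromatogram --species "Cortinarius vitiosus" --seed 3 --out vit.csv
$ dermocybe profile build --chromatogram vit.csv --out vit.json
wrote profile with 8 pigments to vit.json
$ dermocybe profile group --profile vit.json
{"group": "Sanguineus", "centroid_distance": 0.18042813455657492}
$ dermocybe profile match --profile vit.json | head -8
[
  {
    "species": "Cortinarius vitiosus",
    "distance": 0.0
  },
  {
    "species": "Cortinarius cistoadelphus",
    "distance": 0.15662650602409633
```

The round trip recovers the encoded profile exactly (distance 0 to
*C. vitiosus*), and the group engine places it in the Sanguineus pigment
group — red species whose colour comes mainly from dermocybin (13) with
dermocybin-1-glycoside (7) characteristic.

Spore morphometrics, from simulation to the standard textual scheme:

```sh
$ dermocybe simulate spores --species "Cortinarius ominosus" --n 30 --seed 5 --out omi.tsv
$ dermocybe spores summarize --measurements omi.tsv
Cortinarius ominosus: (6.8) 7.4 ± 0.34 (8.3) x (3.6) 4.0 ± 0.23 (4.5) µm; Q = 1.84 ± 0.13 (n = 30)
```

i.e. 30 simulated spores with mean length 7.4 µm, mean width 4.0 µm and mean
per-spore length/width ratio Q = 1.84 — within sampling error of the
generating parameters (7.47 × 4.12 µm, Q 1.82) at n = 30.

Identify a field collection from partial characters (unknown characters keep
all compatible leads open):

```sh
$ cat record.yaml
lamellae_colour_young: red
pileus_colour: red
pileus_brownish_tint: present
spore_width_mean: 4.0
$ dermocybe key identify --record record.yaml
{ "candidates": ["Cortinarius vitiosus"], ... }
```

Library use mirrors the CLI; see the docstrings in each module and
`docs/methods.md` for the models, conventions and their rationale.

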