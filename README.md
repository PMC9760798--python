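# boolfate

Synchronous Boolean network dynamics for cell-fate analysis: attractor
enumeration (fixed points and cycles), macrophage-style phenotype
annotation, persistent clamp-perturbation fate maps, and 2-D t-SNE
embeddings of binary attractor states.

## What it does

- **`boolfate.network`** — Boolean networks with named nodes and
  NOT/AND/OR rules (or explicit truth tables). Reads and writes BoolNet-style
  `targets, factors` text and a JSON dialect with an input-node policy.
  Deterministic synchronous updates; integer state codecs (node 0 = least
  significant bit); persistent node clamps.
- **`boolfate.attractors`** — exhaustive attractor enumeration via
  successor-table traversal with path memoization (exact basin sizes, default
  ceiling n = 22) or seeded sampling (basin fractions, subset of the
  exhaustive census). Cycles are canonicalized with the smallest state code
  first.
- **`boolfate.phenotype`** — declarative phenotype schemes (labels, marker
  conditions, fallback, tumor-promoting / tumor-eliminating / neutral outcome
  classes). Attractors classify as pure fixed point, hybrid fixed point, or
  cycle. The bundled default scheme maps M1 ⇔ STAT1∨NFKB, M2a ⇔ STAT6,
  M2b ⇔ AP1, M2c ⇔ STAT3, M2d ⇔ HIF1A, with M0 fallback.
- **`boolfate.fatemap`** — cell-fate maps: for every attractor and node,
  clamp the node to the opposite value (both values when it varies across a
  cycle) and resolve the destination attractor(s) in the clamped network.
  Sign convention: `+` turns an off node on, `-` turns an on node off.
  Exports TSV, GraphML and DOT. A transient (one-step flip) variant is
  available for comparison.
- **`boolfate.embedding`** — t-SNE maps of attractor states from their 0/1
  vectors (one point per cycle state), deterministic for a fixed seed;
  duplicate rows are collapsed for the embedding and re-expanded with a small
  seeded jitter.
- **`boolfate.synthetic`** — random N-K networks (seeded truth tables with
  output bias), analytic fixtures with known censuses (`identity_<n>`,
  `toggle`, `negation_ring_3`, `and_chain_4`), and a curated 17-node
  macrophage polarization fixture whose exhaustive census is frozen as a
  regression snapshot.

## CLI

```sh
# enumerate + annotate attractors
boolfate attractors --network net.bnet --out-json attractors.json \
    --scheme scheme.json --out-tsv annotated.tsv

# perturbation fate map (TSV + GraphML + DOT)
boolfate fatemap --network net.bnet --scheme scheme.json \
    --nodes all --mode clamp --out-prefix map

# 2-D embedding of attractor states
boolfate embed --network net.bnet --seed 1 --out coords.csv --plot map.png

# generators
boolfate synth random --n 10 --k 2 --bias 0.5 --seed 1 --out net.json
boolfate synth fixture --name macrophage --out macro.bnet
```

Networks ending in `.json` are read in the JSON dialect; anything else as
BoolNet text.

## Data files

- `src/boolfate/data/macrophage.bnet` — the curated fixture network
  (environmental cytokines as identity-rule inputs).
- `src/boolfate/data/phenotype_scheme.json` — the default phenotype scheme.
- `src/boolfate/data/macrophage_census.json` — frozen census / fate-map
  regression snapshot; regenerate only via
  `boolfate.synthetic.regenerate_macrophage_snapshot(path, i_know_what_i_am_doing=True)`.
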