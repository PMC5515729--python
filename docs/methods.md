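# Methods

## The model

`somrx` predicts sites of metabolism (SOMs) and metabolite structures for
drug-like molecules by data mining a corpus of curated metabolic reactions.
The core assumption is statistical: an atom whose local topological
environment frequently appears as a reaction center in known
biotransformations is itself likely to be metabolized. The method therefore
needs (a) a per-atom descriptor of local environment, (b) a similarity
decision between descriptors, (c) occurrence statistics over two reference
databases, and (d) a chemistry-aware correction that removes spurious
statistical hits.

### Layered atom-environment fingerprints

Every heavy atom is described by a 6 × 44 count matrix `F[j, n]`: row *j*
(layer) counts the heavy atoms at bond-graph shortest-path distance exactly
*j* from the root, broken down by atom type *n*. Layer 0 is the root atom
itself, so row 0 always sums to one. The atom-type alphabet is the SYBYL/
Tripos mol2 vocabulary — 33 base types (C.3, C.2, C.1, C.ar, C.cat, 7 N
types, O.3/O.2/O.co2, 4 S types, P.3, halogens, common metals) — extended by
ten elements that occur in metabolic corpora (As, Pt, Co, Mn, Zn, Se, Ge,
Sn, Gd, B) and one reserved padding pseudo-type. A layer beyond the
molecule's radius holds a single padding count, so no row is ever all-zero
and the similarity formulas below are always well defined. Hydrogens are
implicit and never counted; ring atoms contribute once, at their minimal
distance.

### Similarity decision

Two fingerprints are compared in three steps:

1. **Exact-match prefix.** The top `exact_depth` layers (default 3,
   counting the root layer as the first) must be identical. This enforces a
   small identical core environment and allows indexed retrieval.
2. **Per-layer metrics.** For each layer *j*, the Soergel dissimilarity
   (complement of the count-form Tanimoto coefficient, in [0, 1]) and the
   count-form Hamming distance (sum of absolute differences) are computed
   over the full 44-column width.
3. **Weighted total.**
   `d_total = Σ_j Δλ_{j+1} · d_j · d_Ham,j` with
   `Δλ = (2/λ_total)[λ/e^(λ−1) + (λ_total−1)/(2λ)]`, λ = j + 1,
   λ_total = 6. The weight decreases strictly with depth (7/6 at the root
   layer down to ≈ 0.152 at layer six), so near environments dominate.
   A pair is *similar* when the prefix matches and `d_total ≤ 3.5`
   (inclusive). `d_total` is 0 for identical matrices and unbounded above.

Parameter defaults (`exact_depth = 3`, `threshold = 3.5`, 6 layers) are the
method's published operating point and are exposed on the CLI and
`SimilarityParams`.

### The two databases

From the curated corpus two keyed collections are built: every heavy atom
of every substrate increments the **substrate database**; every annotated
SOM atom increments the **reaction-center database** under the record's
reaction-pattern id. Counts are occurrence-weighted multisets. Since every
center is a substrate atom, center counts are dominated key-by-key by
substrate counts, guaranteeing `n ≤ m` for any query. Retrieval buckets
keys by their layer-0..2 serialization; when `exact_depth ≥ 3` only the
query's bucket is scanned, with results provably identical to a linear scan
(enforced by test). Persistence is sorted JSON-lines plus a manifest with a
SHA-256 content hash, which also makes database builds order-independent
and byte-reproducible.

### SOM annotation of the corpus

Reaction records rarely label their centers, so labels are derived:

- **Structure diff (simple reactions).** The maximum common substructure
  (connected, element-exact, bond-order-exact, ring bonds matching ring
  bonds) maps substrate onto product; substrate atoms outside the mapping,
  or mapped atoms whose heavy degree or hydrogen count changes, are the raw
  centers. The *heteroatom convention* collapses a {heteroatom, leaving
  alkyl carbon} diff onto the heteroatom, so O/N/S-dealkylations are
  centered on the heteroatom.
- **Pattern mapping (complex reactions).** For ring reactions the record's
  reaction SMARTS is matched onto the substrate and the pattern's
  designated reaction-center map atom defines the SOM. The center defaults
  to the first mapped atom whose in-pattern bonding differs between the two
  sides and can be overridden per pattern (the ring-opening rule, for
  instance, designates the carbon that becomes the carboxylic acid).
- Explicitly provided labels take precedence over both.

### Scoring, correction, and metabolite generation

For each query atom *i*: `m` = occurrence-weighted similar hits in the
substrate database, `n` = similar hits in the center database. Each center
hit carries pattern ids; the hit is re-classified as dissimilar when *none*
of its patterns can be applied with its reaction center anchored at atom
*i* and at least one sanitizable product. The corrected count is `x`, and

    r_i = (n − x) / (m − x)        (r_i = 0 when m = 0 or m = x)
    p_i = r_i / max_i(r_i)         (p_i = 0 when all r are 0)

`p` is the per-site metabolic probability; the best evidenced site of any
molecule with hits scores exactly 1.0. Sites are binned: very unlikely
[0, 0.15), unlikely [0.15, 0.33), likely [0.33, 0.66), very likely
[0.66, 1.0]. The printed upper bin excludes 1.00 in its source, but
normalization forces the top site to 1.00, so the interval is closed here.
Ranking is by descending `p`, ties broken by atom index. Metabolites are
the sanitized products of the applicable patterns at sites ranked within
top-k with `p > 0`, deduplicated by canonical SMILES, ordered by site rank,
then support (occurrence count of the generating center entries), then
SMILES. Unpatterned center records (MCS-annotated) cannot be
applicability-checked; they keep their statistical weight and generate no
structures.

## Corpus curation

Five filters mirror standard reaction-database hygiene: duplicate reactions
(canonical reaction SMILES identity: each side canonicalized, sorted,
dot-joined), R-group dummies or radicals, unparseable structures, ambiguous
centers (no pattern and an empty structure diff — e.g. chelation), and
single-element reactants/products. Curation is idempotent. For
multi-reactant records the largest reactant by heavy-atom count is "the
substrate"; cofactors stay on the pattern side.

## The synthetic corpus

Licensed metabolic corpora cannot ship, so `somrx.fixtures` generates a
labelled stand-in: eight reaction classes (O/N/S-demethylation, aromatic
hydroxylation, phenol O-glucuronidation, methyl-ester hydrolysis,
cyclization of 4-aminobutanoic-acid analogs to lactams, ring opening of
N-alkylpiperidines), ten records per class by default, each substrate a
scaffold template decorated with benign substituents from a fixed list
under a seeded generator. Products and SOM labels come from applying the
class's reaction SMARTS at its designated center, making every record
self-consistent by construction. 20 % of records per class are held out;
unreactive decoy molecules are emitted alongside. Substituent decoration
(rather than random graph generation) is deliberate: the similarity model
only produces hits when atom environments recur across records, which is
exactly the redundancy real corpora have.

What the generator does *not* emulate: the class imbalance, structural
diversity, noise and multi-step records of real corpora, secondary-amine
chemistry (the cyclization rule requires a primary amine, a documented
specificity of the printed pattern), and competing reactions at one site.
Passing the holdout-recovery tests therefore demonstrates that the
machinery is self-consistent and discriminates recurring reactive
environments from inert ones — not that real-world accuracy matches any
published benchmark.

## Evaluation protocol

- **Top-k SOM accuracy**: fraction of molecules with a true SOM among the k
  best-ranked sites; credit is symmetry-aware (an atom in the same
  graph-automorphism class as a true SOM counts).
- **Atom-level ROC/AUC**: pooled over all atoms, and mean/median of
  per-molecule AUCs; single-class molecules are excluded from the
  per-molecule statistics.
- **Metabolite recall/precision/F1/FP**: micro-averaged over molecules;
  structure identity is stereo-stripped canonical SMILES equality;
  molecules without experimental metabolites leave the recall denominator.
- **Depth sweep**: the whole site-prediction pass rerun at exact-match
  depths 1–6; deeper prefixes return fewer similar environments, degrading
  coverage — the shipped default of three layers is the published optimum.

Problem sizes used by the shipped tests and the acceptance script: 8
classes × 10 records (64 training / 16 holdout), ten generator seeds for
the across-seed AUC check. On this corpus holdout top-3 accuracy is 1.0
and pooled AUC ≈ 0.99 (seed 7); the across-seed minimum pooled AUC stays
above 0.9.

## Numerical and degenerate-input choices

- Soergel denominator of two all-zero rows would be 0/0; the padding column
  prevents it, and the implementation returns 0 (equal-empty) defensively.
- `r` conventions: `m = 0` or `m = x` give `r = 0` (no usable evidence).
- Threshold comparison is inclusive (`≤ 3.5`), prefix equality is integer
  array equality, and all tie-breaks (site rank, metabolite order, database
  serialization) are total orders, so every output is bit-reproducible for
  fixed inputs regardless of record order.
- Fingerprint serialization (`layer:column=count;…` joined by `|`) is the
  database key and is stable across runs and platforms.

## Known limitations

- Single transformation step only; no metabolism trees.
- No isoform-specific enzyme models and no mechanistic (H-abstraction
  energy) reasoning; dealkylations are centered on the heteroatom by
  convention, which differs from mechanism-based tools that flag the
  carbon.
- Atom environments absent from the database yield `p = 0` and can push
  genuinely reactive novel sites below inert but familiar ones.
- The SYBYL typer covers the 44-type alphabet only; exotic elements raise
  an explicit error rather than guessing.
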