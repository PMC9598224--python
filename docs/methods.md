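# Methods

This note documents the models, rules and numerical choices behind
`trnadyn`, and what the synthetic-data tests do and do not demonstrate.

## Cloverleaf annotation

Every tRNA position carries exactly one structural-domain label; the labels
tile the sequence.  The canonical layout is

```
A-stem5' (7) · CC (2) · D-stem5' (d) · D-loop · D-stem3' (d) · CC (1) ·
An-stem5' (5) · An-loop (7) · An-stem3' (5) · V-loop ·
T-stem5' (5) · T-loop · T-stem3' (5) · A-stem3' (7) · discriminator (1)
```

with d ∈ {3, 4}, D-loop 3–10 nt, V-loop 4–6 nt, T-loop 7–9 nt.  The
D-armless isotype (trnS-GCU) replaces the D-arm with a longer CC connector.
The CC label is deliberately allowed to occupy two physical segments; a
single contiguous "central connector" cannot tile a real cloverleaf.  For
per-domain tallies the position labels collapse to nine groups (A-stem,
D-stem, D-loop, An-stem, An-loop, V-loop, T-stem, T-loop, CC-loop); the
discriminator is grouped with the acceptor stem because the reporting
scheme has no separate discriminator category.

**Structure mode** takes a balanced dot-bracket string, groups stacked base
pairs into helices (three or four expected), assigns arms in 5'→3' order
and labels each unpaired run from its flanking stems.  **Template mode**
enumerates every layout consistent with the sequence length and with the
anticodon centered in a 7-nt anticodon loop, and scores each layout's stem
pairs: Watson–Crick +3, G·T wobble +2, non-complementary −2.  The
highest-scoring layout wins; ties prefer the cloverleaf over the armless
form, then the longer D-stem, then shorter D-, V- and T-loops.  The
mismatch penalty (rather than a plain count of complementary pairs) is what
makes the search decisive: a layout that closes its stems cleanly always
beats a rival that buys one extra chance pair at the cost of a mispair.
A sequence admitting no layout raises `unfoldable`.  Encoded CCA is assumed
absent (mitochondrial genes); an unpairable trailing CCA is treated as a 3'
extension with a warning.

Stem pairs that are neither Watson–Crick nor wobble are reported as
mismatches; G·T/T·G pairs are reported separately with a `wobble` flag, so
either convention (wobble as valid pairing or as mismatch) can be
recovered downstream.

## Domain-preserving alignment and consensus

Per gene, homologous domain blocks (delimited by the annotations) are
aligned independently and concatenated, so no gap column ever spans a
domain boundary — the computational analogue of manual structure-aware tRNA
alignment.  Within a block a center-star strategy is used: the center is
the sequence minimizing the summed edit distance (edlib) to all others,
every sequence is aligned to it by Needleman–Wunsch (match +2, mismatch −1,
gap −2, configurable) and center gap patterns are merged slot-wise.  This
is exact for pairs and a standard 2-approximation heuristic for more
sequences; at tRNA scale (~70 nt, blocks of 3–25 nt) it is both fast and
adequate.  Mixed armless/cloverleaf inputs are rejected because their
columns have no domain-wise homology.

The consensus caller emits, per column, the majority base when its
frequency among non-gap rows reaches the threshold (default 0.95; 0.5
reproduces a plain majority rule) and otherwise the minimal IUPAC code
covering the bases tied for the maximal count.  Columns with gap frequency
above 0.5 are omitted from the consensus but kept in the alignment, where
the indel scoring needs them.

## Substitution quantification

Each column is an independent locus.  The most frequent base is the
dominant, conserved state; ties produce a degenerate dominant (e.g. A/G →
R), in which case exactly one tie member — the earliest in A<C<G<T order —
is the conserved designate and the other members are scored as
substitutions relative to it.  Substitutions are transitions (same
purine/pyrimidine class as the designate) or transversions (cross-class).
Columns containing gaps are indel loci: an **insertion** locus when gaps
outnumber every base (the dominant state is then the gap and base carriers
are labeled I), a **deletion** locus otherwise (gap carriers labeled D),
with equality resolving to deletion.  This "gaps versus the dominant base"
comparison is the one deterministic reading that never calls a
three-quarters-conserved column an insertion site.

Category totals map to weights from the fixed ladder 0.00/0.25/0.50/0.75/
1.00: categories are ranked by descending total (ties broken in the fixed
order C, V, S, D, I) and the most frequent category receives the smallest
weight.  When the observed mutation categories are substitutions only, the
fixed weights S=0.25, V=0.50 (C=0.00) apply instead.  Weights can be
derived once from the pooled totals of all tRNAs (`global`, the default,
matching family-average reporting) or per gene (`per-gene`).

Per-tRNA weighted totals (divided by cohort size, so nested cohorts of
different sizes are comparable) are z-scored across the 22 tRNAs within
each cohort: z = (x − mean)/SD with the population SD, so the z-vector has
mean 0 and SD 1 exactly.  Category 1–4 assignment uses the z signs
(z ≥ 0 = hyper-variable); |z| ≥ 1 additionally flags a gene extreme.  Sign
and the ±1 limit are kept separate because more genes belong to each
category than cross the ±1 lines.

## Evolutionary statistics

**Tajima's D** uses the standard coefficient chain (a1 = Σ 1/i, a2 = Σ 1/i²,
b1, b2, c1, c2, e1, e2), π from mean pairwise differences and θ_W = S/a1.
Gap-containing columns are removed entirely (complete deletion) so S, π and
θ_W are computed on one common site set — mixing pairwise-complete π with a
complete-deletion S would make the variance chain internally inconsistent.
D is undefined (None) at S = 0.  Two-tailed significance comes from the
beta approximation of D's null distribution over its attainable range
[D_min, D_max] with mean 0 and variance 1, evaluated at the 0.05 level.

**Transition/transversion bias** follows the Tamura–Nei (1993) closed
forms.  After a partial-deletion filter (columns with ≥95% site coverage by
default), mismatch proportions P1 (A↔G), P2 (C↔T) and Q (transversions) are
pooled site-weighted over all sequence pairs; saturated pairs (a log
argument ≤ 0) are skipped with a warning.  With L1, L2, L3 the TN93 log
terms and g the observed base frequencies (g_R = g_A+g_G, g_Y = g_C+g_T):

```
k1 = (L1 − g_Y·L3)/(g_R·L3)     k2 = (L2 − g_R·L3)/(g_Y·L3)
R  = (g_A g_G k1 + g_C g_T k2)/(g_R g_Y)
```

Pooling over pairs is a composite (not a joint-likelihood) estimate; the
parameter-recovery test shows it recovers a known bias within a few
percent at 1000 sites.  Distances use the three-term TN93 formula with
pairwise-complete sites; saturated pairs fall back to 1.5× the largest
finite distance with a warning.  Trees are neighbor-joining (scikit-bio)
— exact on additive matrices — and the NJ leaf order doubles as the
clustering order for heatmap-style matrix export.  Trees are left unrooted
(or midpoint-rooted by the caller); no outgroup logic is built in.

## Codon-level accounting

Translation uses the vertebrate mitochondrial code (TGA=Trp, AGA/AGG=stop,
ATA=Met).  Aligned ref/alt codons classify as synonymous, nonsynonymous,
truncation (substitution to a stop), deletion (gap length a multiple of 3)
or frameshift (any other gap length); the classification is total over
codon pairs.  Incomplete terminal stops (T·· / TA·, completed by
polyadenylation in mitochondrial mRNAs) are treated as complete stops and
skipped when unchanged, logged otherwise.  Nonsynonymous changes X→Y
increment a 20×20 matrix whose column sums are forward counts (changes
toward an amino acid) and row sums backward counts (changes away from it);
stop-loss events carry no amino-acid pair and are excluded from the
matrix, so Σ forward = Σ backward holds for every input.

The partial Mantel test uses the residual-permutation method: lower
triangles of A and B are residualized on C by OLS, the statistic is the
Pearson correlation of residuals, and the null is built by jointly
permuting rows/columns of A's residual matrix (999 permutations by
default, seeded; two-tailed p with the +1 correction).  The correlation
battery reports Benjamini–Hochberg q-values alongside raw p.

## Synthetic cohorts

The generator emulates a family-level mitogenome survey at desk scale:

- **Cohort**: 30 species by default, 9 of them forming a nested sublineage
  clade (mirroring three genera sampled in triplicate); random coalescent
  subtrees for sublineage and remainder joined at the root, depth
  normalized to 1.
- **tRNAs**: 22 isotypes with randomized layouts inside the structural
  ranges, one D-armless gene, eight reverse-strand genes.  Substitutions
  follow a K80-style kernel with kappa = 2.3 (between the purine and
  pyrimidine transition/transversion rate ratios reported for such data);
  the base rate 0.10 substitutions/site over unit depth yields ≈50%
  polymorphic columns and, with the indel rate 0.15 events/loop-site,
  ≈8% gap-bearing columns — the site-class mix a family-scale tRNA survey
  shows.  Stem substitutions are compensated on the partner strand
  (covariation), occasionally leaving a G·T wobble (5%); the anticodon is
  invariant.  Indels are whole-column events confined to loops, with
  D-loop and V-loop odds elevated and An-/T-loop odds near zero, and loop
  lengths clamped to the structural ranges.
- **Identifiability by construction**: root sequences are resampled until
  the true layout beats every rival template layout by a fold-score margin
  ≥ 3, a 3-bp D-stem is only emitted with a 3–4 nt D-loop (so no 4-bp
  rival layout fits the constraints) and the armless connector is kept at
  10–11 nt (so no cloverleaf rival fits).  This is what makes "template
  annotation recovers the generator's truth exactly" a theorem about the
  emitted data rather than a statistical tendency — and it is also the
  main idealization: real tRNAs carry uncompensated stem mispairs that can
  make the fold genuinely ambiguous, so exact recovery on synthetic data
  does not promise exact recovery on real genes.
- **Per-gene contrast**: default rate multipliers make trnC/trnY/trnP/
  trnG/trnI/trnH hyper-variable and trnA/trnE/trnF/trnK/trnN/trnQ/trnW/
  trnD hypo-variable family-wide, with sublineage-only factors flipping
  trnH down (category 3) and trnD up (category 4), reproducing the
  qualitative four-category pattern such surveys report.  The truth table
  records multipliers, true categories, the tree and all domain labels.
- **CDS**: 13 genes with realistic lengths (~11.4 kb total) evolved at the
  codon level; each substitution event is nonsynonymous with probability
  0.11 (the nonsynonymous share of observed coding changes in such data),
  never creates an internal stop, and rare structural events add in-frame
  deletions, frameshifts and truncations at per-gene-per-branch
  probabilities of 0.005/0.003/0.003.

What the generator does **not** emulate: realistic base composition beyond
uniform (no GC skew), rate variation among sites within a domain,
recombination or heteroplasmy artifacts, annotation errors, or sequencing
noise.  Tests passing on this generator therefore validate the pipeline's
logic and statistics, not its robustness to dirty real-world records (the
QC filters address only the gross cases: missing isotypes, outlier lengths,
ambiguous bases).

The two `worked_example` fixtures rebuild a published three-species trnC
(66 nt, seven transition polymorphisms, four minority alleles from one
species, wobble pairs T5·G61 and G10·T20, 3-nt D-loop) and trnD (73 nt,
nine variable sites in the D- and T-loops, one three-variant site, one
C50·A64 mispair) comparison.  Only the printed constraints are meaningful;
the monomorphic background is generated from a fixed seed and is arbitrary.
The trnC fixture's variable loop is 3 nt — one below the family-range
minimum — because a 66-nt gene with a 3-nt D-loop cannot otherwise satisfy
the fixed stem lengths; its annotation is therefore constructed directly
rather than via template search.

## Problem sizes

Defaults were chosen so the whole suite runs in well under a minute of
simulation time per property: cohorts of 30 species for the end-to-end
category-recovery check (20 seeds), 12 species for NJ clade recovery
(20 seeds), 20-sequence coalescent replicates (100) for the Tajima null,
1000 sites for Tamura–Nei parameter recovery, and 200 seeded runs of 99
permutations for the Mantel type-I calibration.

## Known limitations

- Center-star alignment is heuristic beyond pairwise; pathological gap
  placements are possible in highly diverged loops.
- The TN93 composite pooling assumes shared base composition across pairs.
- Tajima significance uses the beta approximation, which is conservative
  at small S.
- Template annotation requires the anticodon to sit at the center of a
  7-nt anticodon loop; genes with 8–9 nt anticodon loops would need a
  dot-bracket structure as input.
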