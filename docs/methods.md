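# Methods

## The model

The pipeline treats co-expression as a bipartite occurrence structure rather
than a gene–gene graph. An edge candidate is one observation
(gene *g*, subunit member *m*, stress *s*) with a Pearson correlation score
in [−1, 1]. After thresholding, genes connect only to **stress-unit nodes**
SU<sub>s,m</sub> — never to each other — so the graph is bipartite by
construction, and closeness centrality of a gene measures how broadly it
occurs across (stress, member) contexts rather than direct co-expression
with other genes. Two genes attached to identical stress-unit sets receive
identical centrality; this degeneracy is intrinsic to the model, not a bug.

### Thresholding

Records survive when score ≥ mean (inclusive; ties at the mean are kept).
The default pools all of a subunit's records into one mean because the
per-stress networks are merged into a single per-subunit network before
analysis; a `per_stress` mode (one mean per stress) exists for sensitivity
analysis, as does an `absolute` flag that thresholds |score| and therefore
retains strong negative correlations. The default operates on raw signed
scores: an above-mean rule on signed values effectively discards negative
correlations, which is the intended behaviour.

### Closeness centrality

C<sub>x</sub> = n / Σ<sub>y</sub> d(x, y), with d the unweighted
shortest-path hop count within x's connected component. The normalising *n*
admits two standard readings, both implemented:

* `reachable_count` (default): *n* = number of nodes reachable from x.
  Scores fall in (0, 1] on non-singleton components; a star centre scores
  exactly 1; isolated nodes score 0.
* `classic_n`: the above multiplied by the Wasserman–Faust factor
  reachable/(N − 1), which down-weights small components.

Distances never cross components (no infinite terms enter the sum).

### High-CCS selection and hubs

The per-subunit "high centrality" cut is made at the **largest gap**: sort
the *unique* gene scores descending, cut where consecutive values drop the
most, keep everything at or above the cut. Operating on unique values keeps
massive ties from fragmenting the gap structure; when several gaps tie for
largest, the highest one is used (the smallest, most conservative
selection); with a single unique value everyone is selected. An absolute
threshold mode (inclusive ≥) is also available. This reconstruction
formalises the informal "cut at the significant decline" rule; the numeric
cutoffs behind any particular real dataset are not recoverable, so the gap
rule is the package's own operationalisation. Hub genes are the
intersection of the per-subunit selections.

### Venn membership

`venn_regions` assigns every gene of the union to its *exact*-membership
signature (in these sets and no others); all 2<sup>n</sup> − 1 signatures
are reported, empty or not, sorted by popcount then set order for
diff-stable output. "At-least" intersections (|A ∩ B| regardless of other
sets) are sums of regions via `VennReport.at_least`. The computation is
general; the 7-set cap is a readability bound of downstream rendering.

### Clustering

Each surviving record becomes a point ⟨stress code, CCS, score⟩. Stress is
an ordinal integer code 1..7 (Cold, Heat, Genotoxic, Drought, Salt,
Osmotic, Wounding) — a deliberate modelling artefact, kept because the
stress axis then spans 1–7 while the other two axes span at most 1, making
stress the dominant feature in dense subunits. Features are clustered raw
by default; a z-score flag exists for sensitivity analysis. K-means uses
k-means++ initialisation, 10 restarts, 300 max iterations and tolerance
1e-4, deterministic per seed. K ∈ {2..9} is scored by the mean silhouette
over all points, and the chosen K is the *smallest* within 0.01 of the
maximum — preferring parsimony when larger K fluctuates around the same
score. Silhouette is computed on the full point set by default with an
optional subsample cap for very large tables (the fit always uses all
points). If fewer points than the top of the range are available the range
shrinks with a warning; fewer than 3 points is an error.

### Motif scanning

Patterns are IUPAC strings; every start position is tested, so overlapping
matches all count (short 4-mer elements make any non-overlapping convention
severely undercount). A sequence `N` matches only a pattern `N` — unknown
bases never inflate counts. Default strand mode is `both`: the reverse
complement of the pattern is additionally tested against the supplied
strand and reported as strand `−`, except that self-complementary patterns
(e.g. CACGTG) would duplicate every forward hit and are therefore reported
once with strand `+`. Forward-only mode is available since strand handling
conventions differ between scanners. "Clubbing" groups one gene's hits by
(motif name, pattern, strand); the group frequency is its number of
distinct starts. Coordinates are 1-based on the supplied sequence; the hits
table adds a TSS-relative offset column (position 1 of a full 1-kb promoter
is −1000).

The built-in library holds the 16 stress-associated cis-regulatory
elements used throughout, two pairs of which intentionally share a pattern
under different names (EBOXBNNAPA/MYCCONSENSUSAT = CANNTG,
NODCON2GM/OSE2ROOTNODULE = CTCTT).

## The synthetic-data generator

`generate_coexpression` emulates the structure of microarray-derived
co-expression score tables:

* Background scores ~ truncated normal on [−1, 1], one (location, scale)
  per (subunit, stress). Defaults: locations 0.15 / 0.25 / 0.35 for A / B /
  C — reproducing the observed ordering in which the catalytic subunit's
  scores sit highest — and a common scale of 0.2. A truncated normal is the
  simplest bounded unimodal family matching the box-plot shape of real
  per-stress distributions; all parameters are exposed.
* `coverage` (default 0.8) is the probability that a background
  (gene, member, stress) record exists at all, emulating genes that simply
  do not appear in some stress experiments.
* Planted hubs receive a deterministic score of location + `hub_offset`
  (default 0.6 = 3× the default scale), clipped to 1, in **every**
  (subunit, member, stress) slot — guaranteeing they survive any mean
  threshold and dominate closeness.

`generate_promoters` writes i.i.d. background at a requested GC (default
0.36, typical of plant upstream regions) and realises planted IUPAC
instances at non-overlapping positions, resolving each ambiguity code
uniformly. With `avoid_background`, background is rejection-sampled (whole
sequence first, then per-window repair of offending positions) until no
match of any planted pattern — on either strand, in *any* promoter of the
set — exists outside the planted forward-strand sites. This makes the
planted counts exactly what a both-strand scanner reports, which is the
point: exact ground truth for the scanning stage.

What the generator does **not** emulate: correlated scores across members
or stresses (records are independent), probe-level noise or missingness
structure, realistic gene-count scales (tens of genes, not tens of
thousands), promoter composition beyond uniform GC (no CpG structure, no
TATA geometry), and real co-occurrence statistics of motifs. Passing the
planted-recovery tests therefore demonstrates correctness of the machinery,
not statistical performance on real microarray data.

## Numerical and degenerate-input choices

* Thresholds and selections use inclusive ≥ throughout.
* The pooled mean is an ordinary float mean (numpy); tests compare it to
  compensated summation at 1e-12.
* Empty filtered tables build empty networks (not an error); an empty
  intersection of hub selections is a valid result; `club_hits` of an empty
  list is empty.
* GEXF export rounds edge weights to 6 decimal places — the round-trip
  precision contract; stress-unit node identity is serialised as
  `SU|<stress>|<member>`.
* K-means is deterministic given a seed; `fit_kmeans` refuses K larger than
  the number of distinct points.
* Reproducibility contract for generators: same seed + same version ⇒
  identical output; cross-platform bit stability is not promised.

## Problem sizes

The analysis drivers and the reference-quantity script run on synthetic
tables of 20–40 genes × 17 members × 7 stresses (a few thousand records)
with 3 planted hubs, and 1-kb promoters — sizes at which every stage,
including 100-graph centrality oracles and 500-sequence scanner oracles in
the test suite, completes in seconds while still exercising full coverage
(35/70/14 stress-unit nodes) and non-trivial Venn/cluster structure.

## Known limitations

* Closeness on the bipartite occurrence graph compresses into few distinct
  values when coverage is high; the largest-gap rule is then sensitive to
  the background coverage distribution. The hub *intersection* across
  subunits is what makes recovery robust.
* Stress as an ordinal code makes cluster structure rotation-variant in
  that axis; conclusions about "stress-dominated" clusters are conditional
  on this encoding.
* The scanner is exact but naive (O(len × |pattern|) per motif); it is
  ample for kb-scale promoters and would need automaton-based matching for
  genome-scale scans.
* `avoid_background` can fail (with a clear error) when planted patterns
  are so dense that stray matches fall entirely inside planted sites, e.g.
  when planting a pattern and its reverse complement as separate motifs.
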