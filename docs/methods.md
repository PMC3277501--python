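# Methods

This note documents the models and procedures `proteotherm` implements,
the parameters that matter, what the synthetic-data generators do and do
not emulate, and the numerical and design choices made where the design
was open.

## Sequence handling

All sequence statistics operate on codon alignments: equal-length,
in-frame nucleotide records with a boolean mask over codon columns.
Coordinates are 0-based half-open internally; every user-facing report is
1-based. Masking works at the codon-column level (the analyses live in
codon space): a column is dropped when *any* record carries a gap or an
ambiguity (`-`, `N`) anywhere in the codon. This deterministic rule stands
in for the manual curation step ("checked by eye") that alignment
pipelines otherwise rely on; it is intentionally conservative and
idempotent. Translation uses the universal genetic code (NCBI table 1,
via Biopython); a stop codon in a retained column is an error, a stop in
a masked column translates to `X` so that column indices stay aligned.
PHYLIP I/O uses the relaxed dialect (whitespace-delimited names), since
strict 10-character names truncate species tags.

## Composition indices

Residue frequencies exclude `X` and gaps from both numerator and
denominator. The hydrophobic index *W* is the frequency-weighted mean of
the Sweet–Eisenberg OMH scale (D −1.31 … F +1.92, unitless); it is bounded
by the scale's extremes and depends only on the profile, not the residue
order. Category fractions are sums of frequencies over named residue
sets. The charged/polar/hydrophobic partition is configurable because no
single convention exists (is His charged? is Gly polar?); the default
puts His with the charged residues ({D,E,K,R,H}) and Gly with the polars
({S,T,N,Q,Y,C,W,G}), leaving {A,V,L,I,M,F,P} hydrophobic. GARP and
FYMINK are fixed by codon GC content and are not configurable. The
E+K/Q+H ratio is reported as *undefined* (an exception, never infinity)
when the gene set contains no Gln or His.

GC3 and GC1+2 are computed over all sense codons — Met and Trp included,
stop codons excluded — with ambiguous bases removed from numerator and
denominator position-wise. Including the non-degenerate codons is the
simplest reproducible rule and only dampens GC3 contrasts slightly.

Bootstrap standard deviations resample codon columns (not residues) with
replacement, alignment-wide, so all taxa share each replicate's column
draw and nucleotide- and protein-level statistics come from the same
replicate. Default 100 replicates; a fixed seed makes the SDs exactly
reproducible. Replicates on which a statistic fails (e.g. an undefined
ratio) are skipped and counted; more than 10 % skipped is an error.

## GC-bias regressions

Ordinary least squares (statsmodels) with an F test on (1, n−2) df and
two-sided p-values. The outlier rule flags a taxon whose y lies outside
the pointwise confidence band *of the mean response* at its x, at the
fit's CI level (default 99 %). The fit includes all taxa by default, with
a leave-one-out refit option for flagged taxa, because a strong outlier
drags the band toward itself. The mean-response band is deliberately
narrow — it asks whether a taxon departs from the fitted *trend*, not
whether it is predictable — so with many taxa and small sampling noise an
occasional unplanted taxon can fall outside it; the planted-outlier tests
therefore assert that the planted taxon is flagged and is the largest
standardized departure, not that it is the only flag.

## Codon-usage bias

Codon counting excludes a terminal stop codon and skips (with a per-gene
warning) internal stops and ambiguous codons. RSCU is count × family
size / family total, undefined (NaN) for unused families.

Wright's Nc uses the homozygosity estimator F̂ = (nΣp²−1)/(n−1) per
synonymous family; families with n < 2 or F̂ ≤ 0 are unusable and
replaced by their degeneracy-class mean, and Nc = 2 + 9/F̄₂ + 1/F̄₃ +
5/F̄₄ + 3/F̄₆, capped at 62. When a whole degeneracy class lacks a usable
family the gene's Nc is undefined rather than patched; note this differs
from CodonW, which substitutes (F̄₂+F̄₄)/2 for a missing 3-fold class
(Ile), so very short or Ile-free genes that CodonW scores come back
undefined here. The null curve against GC3 is
Nc\* = 2 + s + 29/(s²+(1−s)²); the linear term makes it slightly
asymmetric about s = 0.5 (Nc\*(1−s) − Nc\*(s) = 1 − 2s), which is a
property of the formula, not an implementation artifact.

Correspondence analysis runs on relative codon frequencies over the 59
synonymously variable sense codons (Met, Trp and stops excluded — the
CodonW convention), via SVD of the standardized residual matrix of the
relative-frequency table; genes and codons are placed in symmetric
principal coordinates. Axis 1 is oriented so gene coordinates correlate
positively with gene GC3, which also fixes the preferred-codon scan
against sign flips. Each species is analysed in its own CA run by
default; a joint run is a matter of passing a combined table.

Preferred (Fop) codons compare pooled codon usage between the genes in
the top and bottom 10 % of axis 1 (ties at the boundary broken by gene
id), per codon, with a 2×2 chi-square of codon-vs-rest-of-family counts;
a codon is preferred when enriched in the high-bias (high-GC3) set at
p < 0.01. The 10 %/0.01 convention is configurable; the detected count is
sensitive to it, which is why the GC-ended *character* of the detected
set, not its size, is the robust readout.

## Directional substitution tests

The oriented table M[i,j] counts positions where the donor species shows
residue i and the focal species residue j, pooled over ortholog pairs;
gap/`X` positions are excluded from the site count. Swapping the species
transposes M. Protein divergence is 100·ΣM/n_sites.

The binomial test treats each substitution touching residue a as a gain
or a loss with probability ½ under no directional replacement, and is
one-tailed in the direction of the observed excess. Because the
direction is chosen from the data, the procedure's exact size at nominal
α is close to 2α (minus discreteness) — the calibration tests compare
its realized error rate against that exact size, computed from the
binomial pmf, rather than against α.

The neutral expectation weights each directed cell by
w(i→j) = π_i·S[i,j]·π_j, with S the published WAG exchangeability matrix
(bundled) and π the unweighted mean of the two species' observed residue
frequencies over the analysed sites, scaled so that ΣE equals the
observed number of replacements. The null is symmetric by construction,
so any directional asymmetry is signal. Outliers are cells whose
difference d = obs − exp, standardized by the empirical mean and SD of
the 380 directed differences, exceeds |z| > 1.96 (5 % two-sided); an
unordered 190-cell mode is available. The global chi-square pools cells
with expected < 1 into a remainder cell and uses pooled-cells − 1 df;
without pooling the statistic is invalid for rare replacement classes.

## Structural effect classification

ASA uses Shrake–Rupley sphere-point sampling: each atom's solvent sphere
(van der Waals radius + 1.4 Å probe) is sampled on a deterministic
Fibonacci spiral lattice (default 960 points), a point being accessible
when outside every neighbour's solvent sphere. The fixed point set makes
ASA bit-reproducible; under rigid rotation values move by at most a few
Å² (the lattice is not rotation-invariant), which is the tolerance the
invariance tests use. Element radii: C 1.70, N 1.55, O 1.52, S 1.80,
H 1.20, P 1.80 Å, default 1.70. Burial classes: buried < 20 Å²,
intermediate 20–60 Å², exposed ≥ 60 Å² (boundaries going up).

Residue volumes come from a bundled standard table (Zamyatnin); the
volume-neutrality threshold for conservative apolar replacements defaults
to 26 Å³ — a glycine-sized yardstick — and is configurable, since
standard volume tables would put glycine itself nearer 60 Å³. Hydrogen
bonds are counted as side-chain N/O heavy atoms within 3.5 Å of another
residue's N/O; salt bridges as opposite formal-charge side-chain atoms
within 4.0 Å; both cutoffs are conventional and configurable. Secondary
structure is read from PDB HELIX/SHEET records (or a user column), never
computed.

The rule cascade: same-category replacements are conservative — apolar
pairs scored by the sign of the volume change (neutral within the
threshold), polar/charged pairs by the bond-count change (neutral at
zero or unknown). Cross-category replacements are scored by burial: a
hydrophobic residue introduced at a buried position, or a hydrophilic one
at an exposed position, or a charge introduced at an exposed position, is
positive; the reverse placements are negative — except that a buried
polar/charged residue forming a new bond is rescued to positive.
Intermediate burial without bond information is neutral under its own
rule id. Exactly one rule fires per record and its id is recorded, so
every classification is auditable. When the two species' models disagree
on burial, the donor model's class is used and both are reported.

## Synthetic data: what it emulates, and what it does not

The ortholog-pair generator draws an ancestor from the WAG equilibrium
frequencies, evolves two descendant amino-acid sequences independently
(at most one substitution per site and lineage), and back-assigns codons
so that third positions hit a target GC3 (Met/Trp pull realized GC3 up
by ≲ 2 points); unchanged sites share the ancestral codon. The focal
lineage's i→j rate is multiplied by β[i,j], with the site's total
substitution probability scaled accordingly, so β = 5 means a five-fold
i→j flux on that lineage and nothing else. The recorded truth is the
realized donor→focal difference table, which the extraction stage must
recover exactly (a closed loop the tests assert). Defaults are the study
scale: 335 genes, 40 338 codons, and a per-lineage substitution
probability of 0.036 per site, calibrated to give the observed
inter-species protein divergence of about 7 %.

The taxon-composition generator places taxa evenly along a GC3 gradient
(default 11 taxa, 5 991 codons, GC3 0.25–0.75) and scales GARP residues
up and FYMINK residues down linearly in GC3 around the WAG equilibrium
(trade strength 0.8), with an optional outlier taxon at mid-GC3 whose
Arg and Pro frequencies are multiplied by 1.6. The helix builder places
backbone atoms by internal coordinates at φ = −57°, ψ = −47°, ω = 180°.

None of these emulate real data's gene-family structure, rate
heterogeneity across sites or genes, indels, codon-level selection, or
phylogenies beyond a two-taxon split. Passing tests therefore show that
the statistics recover what the generators plant at realistic scale and
stay calibrated under the null — not that any particular real species
pair shows the thermophile signature.

## Problem sizes and calibration findings

The calibration tests run 200 null replicates and 100 planted-bias
replicates at 40 000 sites each; the full suite completes in well under
a minute of simulation time. Two findings worth knowing:

* The null outlier-flag rate of the z-scan sits near 6 % rather than
  exactly 5 %, because the 380 differences are mildly skewed
  (Poisson-like counts); the calibration test accepts 2–9 %.
* At the study-scale divergence, a planted β[V→A] = 5 is recovered by
  the outlier scan in ~100 % of replicates, while the Ala binomial
  excess reaches significance in only ~85 % (the planted flux adds
  roughly +40 net Ala gains against a background of ~600 Ala-touching
  events, a mean excess z near 2.8). Joint recovery by both detectors
  at ≥ 95 % would need either a stronger bias (β ≈ 7) or roughly
  double the divergence; the corresponding acceptance check documents
  this honestly rather than inflating the generator's rate.

## Known limitations

* The masking rule is stricter than manual curation; column counts on
  real alignments will differ from hand-curated ones.
* Nc is undefined for genes missing a whole degeneracy class (see
  above) — short genes are the common case.
* The CA codon set and Fop conventions follow CodonW defaults; other
  choices change the detected Fop count (not its GC-ended character in
  the regimes tested).
* The bond-count deltas are geometric contact counts, not an energy
  model; dN/dS-based selection inference and homology modelling are out
  of scope — the structure stage consumes already-built coordinate
  models.
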