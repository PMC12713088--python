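# Methods

## Scope and data model

All coordinates are 0-based half-open throughout (BED-native); the gene
table uses the same convention and says so in its header. The pipeline
starts from processed artifacts: peak intervals, gene models, gene ×
sample count matrices (raw counts plus per-sample genome-wide library
sizes) and genome FASTA. Read alignment, peak calling and de novo motif
discovery are out of scope.

## Peak-to-gene assignment

A peak is assigned to every gene whose body, extended `upstream_window`
bp upstream of the TSS (default 1000, strand-aware), it overlaps under
half-open interval logic. There is no nearest-gene tie-break: a peak that
spans two promoter-extended genes counts for both, which matches the
set-based definition of targets (a gene is "bound" by a factor iff it has
≥ 1 assigned peak). The window default reflects TSS-proximal binding; it
is a flag because annotation conventions differ and the choice measurably
shifts target-set sizes.

## Overlap statistics

For sets of sizes K and n in a universe of N with overlap k:
expected = Kn/N, RF = k/expected, and p-values come from the
hypergeometric distribution of k computed in log space. The two-tailed
convention is genuinely ambiguous in the field, so both are implemented:
minimum-likelihood (default; sums probabilities of all outcomes no more
likely than the observed one) and doubling of the smaller one-sided tail,
capped at 1. Every serialized result carries its convention. The universe
defaults to all genes in the gene table.

## Differential calling

Counts are first scaled to the geometric-mean library size (rounded), so
replicates are exchangeable under the null, then pooled within condition.
For a gene with pooled counts S_wt and S_mut, the test conditions on
T = S_wt + S_mut: with n replicates per condition iid NB(μ, φ), the
conditional law of S_mut given T is free of the library scale and, with
μ̂ = T/(n_wt + n_mut) plugged in, P(S = s | T) ∝ f_mut(s)·f_wt(T − s)
where f_c is NB with mean n_c·μ̂ and dispersion φ/n_c. Two-sided p-values
sum the conditional probabilities of all splits no more likely than the
observed one (minimum-likelihood); at φ = 0 this reduces exactly to the
conditional binomial test. The implementation vectorizes over genes and
enumerates the full conditional support, so p-values are exact, not
asymptotic.

The common dispersion is estimated by conditional maximum likelihood:
within a condition the replicates share a mean, and conditioning each
gene's replicate vector on its total removes that mean entirely —
P(y₁..yₙ | Σy = z) = ∏C(yᵢ+r−1, yᵢ)/C(z+nr−1, z) with r = 1/φ — so one
φ maximizes the summed conditional log-likelihood over genes and both
conditions. Moment matching was tried first and rejected: with two
replicates it is noisy and biased low, which inflated the empirical FDR
to ~0.15–0.22 in simulations; the CML estimate recovers a planted
φ = 0.1 to within a few percent and brings the empirical FDR back to
~0.05–0.06.

Fold changes are log₂ of library-normalized (counts per million)
replicate means with a pseudocount of 0.5 in numerator and denominator,
which keeps log2fc finite at zero counts. Status is a pure function of
(log2fc, q, thresholds): `up` requires q < FDR *and* fold change above
the up cutoff; `down` symmetric; otherwise `unchanged`. Presets:
transcripts |log₂FC| > 0.5, marks linear FC > 1.2 or < 0.8, both at
FDR < 0.05 (Benjamini–Hochberg step-up, via statsmodels). Peak-level
enrichment changes use a separate threshold rule (default FC 1.5,
strict inequalities, ties `unchanged`).

**Power ceiling (important).** The variance of the estimated log
fold-change is bounded below by φ·(1/n_wt + 1/n_mut) regardless of
sequencing depth. At the generator defaults (φ = 0.1, 2 + 2 replicates)
that is SD ≈ 0.32 natural-log units, so a planted FC = 3 effect sits at
≈ 3.4σ and the power of any FDR-controlling caller at q < 0.05 is
~0.3–0.5. Recovered per-subclass dependence fractions are therefore a
roughly uniform under-count of the planted fractions: their *ordering*
is recovered reliably at deep counts, their absolute values are not.
This is an information limit of the simulated design, not an
implementation artifact.

## Subclasses, dependence ratios, deciles

Subclasses of the common target set T against PEAT and PRC2 are
non-exclusive — `peat_shared` = T∩PEAT and `prc2_shared` = T∩PRC2 may
overlap — and the dual overlap is reported explicitly so the identity
|specific| = |T| − |T∩PEAT| − |T∩PRC2| + |both| is always checkable
(with the study-scale printed counts it implies 196 dual-shared genes).
The dependence ratio of a subclass is |subclass ∩ affected|/|subclass|,
where `affected` defaults to the genes whose H3K4me3 is called `up` in
the mutant under the mark preset.

Deciles are assigned over the whole universe sorted ascending by a
per-gene signal (default: wild-type H3K4me3 RPKM averaged over
replicates; the metric is a flag since no single canonical choice
exists). Ties break by gene id, making the assignment a total order and
input-order invariant. With n = 10q + r genes, deciles 1..r take q+1
genes and the rest q, so n = 32,548 yields sizes {3255×8, 3254×2} with
the lowest-signal genes in decile 1.

## Motif analysis

PWMs are 4 × L probability matrices (rows A,C,G,T; columns sum to 1)
with a uniform background and pseudocount 0.001; scanning scores each
window by Σ log₂((p+pc)/(bg+pc)) on both strands, and a window is a hit
at ≥ `threshold` × the maximum attainable score (default 0.8; planting
tests use 0.95 to keep background hits negligible). Windows containing N
never score. Minus-strand hits are reported at the forward-coordinate
left edge of the window.

The co-occurrence test classifies peaks four ways by the presence of two
motifs and compares the both-fraction with p̂_A·p̂_B. The headline
p-value conditions on the observed margins (one-tailed hypergeometric,
i.e. Fisher's exact enrichment tail): the plug-in binomial tail
P(X ≥ n_both; n, p̂_A·p̂_B) — also reported — is markedly conservative
because the expectation is estimated from the same peaks (measured
rejection ~0.008 at α = 0.05 under independence, vs ~0.045 for the
margin-conditioned test). A label-permutation p (≥ 1000 shuffles,
seeded, add-one corrected) is available as a third route.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
not sequencing mechanics (no reads, fragments or peak-caller behavior;
H3K27me3/H4K5ac/H2Aub dynamics beyond static subclass baselines are out
of scope).

* **Genome.** Genes (default 6000, lengths U[1000, 3000] bp) are laid
  out without overlap on 2 chromosomes, random strands, gaps
  U[1500, 3000] bp, ≥ 2 kb clear flanks; sequence is i.i.d. uniform
  A/C/G/T. The minimum gap exceeds the promoter window plus the maximum
  upstream peak extent, so with perfect detection peak-to-gene
  assignment is unambiguous and planted target sets are recoverable
  exactly. An optional per-chromosome length cap turns impossible
  packings into a sizing error naming the chromosome.
* **Occupancy.** Genes carry latent occupancy by TRHT/TRHD (p = 0.245),
  PEAT (p = 0.249) and PRC2 (p = 0.162) — genome fractions at the scale
  of the Arabidopsis regulons. PEAT is enriched 1.8-fold on TRHT/TRHD
  genes with the marginal preserved; PRC2 genes are drawn by weighted
  sampling that down-weights PEAT genes 5-fold, so PEAT and PRC2 targets
  are strongly depleted of each other while PRC2 stays calibrated to its
  marginal.
* **Binding.** Each factor of an occupied complex (TRB1/ICU11/HTH1/ZDP2;
  EPCR2/UBP5/PWWP1; LHP1) emits a TSS-proximal peak with probability
  `factor_detection_prob` (default 0.9) and NB gene-level counts whose
  mean shares a per-gene per-complex lognormal strength — that shared
  strength is what makes within-complex sample correlations exceed
  cross-complex ones.
* **Marks and expression.** Wild-type H3K4me3 baselines are ordered
  peat_shared (30 RPKM) > nontarget (12) > specific (10) > prc2_shared
  (3), encoding the intermediate chromatin state of complex-specific
  targets; genes in both shared sets take the PRC2-shared baseline
  (Polycomb dominates). Per mutant genotype (default: one demethylase
  mutant), each target gene gains a planted FC-3 mark increase with
  subclass probability (peat_shared 0.05, specific 0.17, prc2_shared
  0.29); a planted mark gain is accompanied by a planted FC-3 expression
  gain with probability 0.6, and a 1% background of random
  expression changes (half up, half down) provides non-target DEGs.
  Counts are NB with dispersion 0.1 (so the differential stage's
  dispersion handling is genuinely exercised), 2 replicates per
  genotype, 2×10⁶ mapped reads per sample.
* **Motifs.** Two illustrative near-consensus PWMs ship with the
  package — telobox-like (AAACCCTA) and NAC-binding-like (TTGCGTGT),
  0.91 consensus probability per column; they are constructions, not
  matrices fitted to ChIP data. Per peak, presence of each motif follows
  a joint law with configurable marginals (0.4, 0.3) and co-occurrence
  excess P(both)/(P(A)P(B)) (default 2.0); feasibility
  (P(both) ≤ min marginal, P(neither) ≥ 0) is validated. Planted
  instances write the consensus at a uniform offset/strand inside the
  peak; two motifs in one peak never overlap.
* **Determinism.** One master seed feeds named substreams (genome,
  binding, marks, motifs), so identical configs give byte-identical
  outputs and stages can be regenerated independently.

What passing synthetic tests do *not* show: real ChIP/RNA data have
gene-specific dispersions, GC and mappability biases, correlated
replicates, fuzzy peak boundaries, and motif instances that diverge from
consensus — none of which the generator produces. Recovery results here
validate the statistical logic, not robustness to those artifacts.

## Problem sizes in tests and the acceptance script

Unit and property tests run on universes of ≤ 6000 genes. Calibration
uses 50 null studies of 2000 genes and 1000 independent peak sets of
2000 peaks; structure recovery uses 20 studies of 6000 genes at 2×10⁷
reads ("deep counts", where detection power is uniform across
subclasses). The acceptance script uses 6 recovery seeds, 10 null seeds
and one 4000-gene study for the motif chain — sizes chosen so the whole
chain re-runs in well under a minute on one core while keeping Monte
Carlo error small relative to the asserted margins.

## Known limitations

* Pooling replicates discards per-replicate identity; a replicate-aware
  GLM (edgeR/DESeq2-style) is the natural extension point and would give
  slightly better power at unequal library sizes.
* The common-dispersion model is exactly the generator's regime; on real
  data with dispersion trends the single φ is a compromise.
* The exact conditional test enumerates the support, so runtime grows
  with pooled counts (~10⁴ per gene remains comfortably fast).
* "Paired Mann–Whitney" requests are served as Wilcoxon signed-rank —
  the rank test actually defined for paired data — and flagged as such.
* The library-scaling step rounds scaled counts; for library ratios far
  from 1 this is an approximation (exchangeability is restored only
  approximately).
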