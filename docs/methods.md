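# Methods

`regulonkit` reconstructs the regulons of bacterial transcription factors
(TFs) that bind palindromic DNA motifs — the situation typified by the LacI
family, whose homodimeric regulators recognize inverted repeats with a
central CG pair, mostly 16–22 bp wide, concentrated 140–30 bp upstream of
the start codons of the operons they control.  The package implements the
comparative-genomics workflow for this setting and validates it end to end
on synthetic pangenomes with planted ground truth.

## The reconstruction model

**Promoters.**  Every operon's regulatory window spans −400 to +100 bp
around the translational start of its first gene, oriented 5'→3' with
respect to that gene.  Windows are clipped only at contig boundaries, never
at upstream genes: binding sites inside coding sequence are rare but real,
so coding overlap is allowed.  The alternative (clipping at the nearest
upstream gene) would silently remove the far-upstream site class; we
document it as an option not taken.

**Binding model.**  A position weight matrix (PWM) over A/C/G/T with
log-odds in bits against an explicit background (uniform by default,
per-genome mononucleotide by flag).  Frequencies use a pseudocount
(default 0.5) to avoid −∞ log-odds from small training sets.  Because the
TFs are homodimers, count matrices are symmetrized,
`C ← (C + revcomp(C))/2`, which makes every window score exactly
strand-flip invariant; one strand is scanned and strands are reported on
the anchor's coding strand.  Windows containing N are skipped, not scored.

**Detection threshold.**  The threshold is always the minimum score over
the training sites.  This makes the bit scale self-calibrating:
no externally tuned cutoff exists anywhere in the pipeline.  "Score at
least the threshold" is read as ≥, so training sites always pass their own
threshold.

**Motif discovery.**  A zero-or-one-occurrence-per-sequence (ZOOPS)
expectation–maximization over each candidate width in 14–24 bp, with the
count matrix re-symmetrized every iteration (simple, and it preserves the
palindromic invariant exactly, unlike constrained optimization).  Restarts
are seeded from the most self-complementary windows in the promoter set;
near-palindromic real sites rank far above background windows on that
statistic, and random-window initialization demonstrably converges to
degenerate weak-palindrome optima.  The width is chosen by total
information content after subtracting the per-column small-sample
expectation under background (≈ 3/(2·ln2·n) bits for n effective sites),
then uninformative flanks (< 0.3 bits/column) are trimmed symmetrically —
without the penalty and the trim, the widest window wins on accumulated
noise.  Harvested training sites (posterior > 0.5) pass a coherence cut:
windows scoring below half the median of the harvested set are rejected,
because in the ZOOPS model promoters that genuinely lack a site still
nominate their best background window, and one such window would wreck the
minimum-score threshold.  A mean information content below 0.5 bits/column
flags the motif as low-confidence (background-like).

**Operons.**  Maximal runs of adjacent co-directional genes with
intergenic distance ≤ 100 bp (inclusive — the boundary is covered by
tests) and no predicted TF site centered in an internal gap.  Overlapping
same-strand genes always merge.  The internal-site rule and scanning are
mutually dependent, so operons are predicted in two passes: layout only,
scan, then re-split at internal sites and re-scan.  Cross-genome
conservation of gene adjacencies is scored (support = number of genomes
where the ordered ortholog-group pair is co-operonic) and can optionally
cut unsupported adjacencies; scoring-only is the default.

**Orthology.**  Bidirectional best hits (BBH) over all genome pairs, with
ortholog groups as connected components of the BBH graph.  Similarity is a
normalized shared k-mer count (k = 4) by default, with Smith–Waterman
local alignment (BLOSUM62, gap open −11 / extend −1) by flag; ties are
broken lexicographically and flagged.  TF groups are additionally split by
binding-motif similarity — single linkage at τ = 0.8 mean best-aligned
per-column Pearson correlation of frequency columns.  τ is a free
parameter of our making (the notion "highly similar motifs" is inherently
operational); it cleanly separates identical (1.0) from unrelated (~0.25)
motifs.  Effector specificity is not computable from sequence and is
carried as a free-text annotation only.

**Regulon assembly and the consistency check.**  Every operon whose
promoter window contains a hit at or above the threshold is a candidate
member.  A site falling inside two overlapping windows of divergently
transcribed operons counts for both (the divergon convention).  The
cross-genome consistency filter then keeps a candidate iff operons sharing
its first gene's ortholog group carry above-threshold sites in at least
`min_genomes` genomes (default 2, counting itself); regulation is conserved
across a clade, spurious matches are genome-private.  The operon's
signature is its first gene's group because promoter identity follows the
first gene.

**Footprint completion (refinement).**  Discovery runs on the TF's own
orthologous promoters (autoregulation seeds the training set — ~72% of
these TFs autoregulate).  A minimum over that small training set cannot
relax, so a single round of scanning would permanently miss weaker
orthologous sites.  The pipeline therefore refines (default 2 rounds):
every consistency-retained ortholog-operon contributes its best-scoring
promoter window in *every* genome where the operon exists, accepted when
the score clears a detection floor computed from the PWM's exact null
score distribution (per-column convolution, the standard PWM p-value DP)
at an expected ≤ 1 false window per clade scan.  The enlarged training set
rebuilds the PWM, and the threshold remains the minimum over the training
set — the same rule as before, now applied to a training set that spans
the regulon.

**Classification and regulogs.**  A regulon is global iff it has more than
15 target genes in at least 7 operons spanning ≥ 2 distinct non-empty
pathway labels (the pathway judgment is operationalized through the
annotation labels); otherwise local.  Autoregulation is operon-level
membership of the TF's own operon.  A regulog aggregates the genome-level
regulons of one TF ortholog group; its merged motif is rebuilt from the
union of member sites.  Genomes whose regulon retained no members are
reported but excluded from regulog counts.

## The synthetic pangenome

The simulator emulates a clade of N related genomes (default 10) sharing
an orthologous gene complement with gene-loss noise, one TF gene per
genome, and a planted palindromic motif.  Defaults are the study
conditions; they are not tuned per experiment:

| parameter | default | why |
|---|---|---|
| genomes / genes | 10 / 60 | desk-scale clade, ~25 operons per genome |
| gene length | ~750 bp (±200) | typical bacterial CDS |
| intra-operon gaps | U(20, 80) bp | below the 100-bp operon rule |
| inter-operon gaps | U(260, 450) bp | room for promoters and planted sites |
| upstream gaps of site-bearing operons | U(660, 900) bp | see below |
| motif width / center | 18 / CG | modal class of even palindromes |
| site corruption | 0.10 per position | conserved but imperfect sites |
| site centers | 75% in [−140, −30] | observed positional concentration |
| off-core offsets | U(−220, −141) ∪ U(−29, −15) | far-upstream and proximal tails |
| tandem spacing | off (22/32 bp when on) | helical-period double sites |
| autoregulation | 0.72 per TF | observed autoregulation rate |
| gene loss | 0.05 per gene per genome | mild complement divergence |
| decoys | Poisson(2) per genome | near-threshold palindromic look-alikes |
| protein substitution | 0.10 per residue | BBH nontrivial but solvable |
| GC content | 0.50 | neutral background |

Two deliberate departures from naive uniformity keep the planted truth
well-posed at desk scale:

* **Site-bearing operons get wider upstream gaps (660–900 bp).**  Promoter
  windows reach 400 bp beyond a divergent neighbor's start codon.  With
  ordinary ~300-bp gaps, most planted sites would lie inside *two* windows
  and the divergon convention would attribute them to both operons — not a
  method error but an ambiguity of the data, which would make planted-truth
  precision unmeasurable.  Divergon sharing is exercised by dedicated
  fixtures instead of the default clade.
* **Decoy anchors are never reused across genomes** (nor are their layout
  neighbors, since a decoy in a shared gap attributes to both flanks).
  Decoys model genome-private false motif look-alikes; with only ~19
  candidate anchor operons, independent placement would collide across
  genomes by the birthday effect and defeat the consistency filter by
  construction, a coincidence that is negligible at real genome scale
  (thousands of operons).

Decoys are random palindromic strings walked down from the consensus until
they score within 1 bit of the ground-truth threshold (the minimum planted
site score under the PWM of the planted sites) — adversarial inputs for the
consistency filter.  Background sequence is i.i.d. at the configured GC;
orthologous proteins are substitution-mutated copies of a per-group random
ancestor.

**What the simulator does not model** — and hence what passing tests do not
show about real data: higher-order background composition (real genomes
have skews and repeats that inflate false positives), indels in sites or
proteins, horizontal transfer, variable motif spacing within a TF group,
operon rearrangement, and any correlation between regulation and gene
content.  The recovery rates reported here are upper bounds specific to
these idealizations.

## Recovery metrics

A planted site counts as recovered when a predicted site center in the
same genome lies within 3 bp of its center.  Operon membership is matched
by the anchoring first gene.  Precision is null (not 0) when nothing was
predicted.  Consensus distance is the best-alignment mismatch count over
both orientations, with width differences counted as mismatches.

## Numerical choices and degenerate inputs

* EM: γ (site prior) clipped to [0.05, 0.99]; convergence at |Δ log L| <
  0.01; 60 iterations cap; 2 restarts per width.
* Null-distribution DP: 0.05-bit score bins.
* Empty regulons are valid outputs, reported with null metrics; empty
  reconstructions yield null precision; promoters shorter than the maximum
  width are a named hard error.
* Best-hit and best-window ties break lexicographically; every output
  table is explicitly sorted, so fixed config + seed reproduces results
  byte-identically.

## Problem sizes of the bundled benchmarks

The validation studies run at: 50 replicates for motif recovery (10
genomes × 8 regulated operons each), 25 replicates for end-to-end recovery
plus a 10-replicate no-filter control arm, and ~10,000 planted sites
(10 clades of 25 genomes × 40 operons) for the positional statistics —
sizes at which the sampling error of each reported rate is well below the
margins being tested.
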