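# Methods

## The system being modelled

Organellar group II introns are mobile catalytic RNAs. Each intron folds
into six domains (DI–DVI) around a central wheel. DI scaffolds folding and
presents three exon-binding loops (EBS1, EBS2, EBS3) whose reverse-complement
partners (IBS1 = upstream-exon positions −6…−1, IBS2 = −12…−7, IBS3 = the
first downstream-exon base) define the splice site and the retrohoming
target. DV is the catalytic core, strongly conserved at ~34 nt. DVI carries
a bulged adenosine, the lariat branch point, a few nucleotides in from the
3′ end. The termini carry a conserved 5′ hexamer (GUGCGA) and a 3′ AY
dinucleotide. Many introns encode a protein in a DIV loop: a reverse
transcriptase/maturase (RT/M) or, in some lineages, a LAGLIDADG homing
endonuclease (LHE). Families are recognized by their insertion site
(`gene-site`) plus sequence homology, and subgroups by junction motifs:
the four unpaired nucleotides between DII and DIII (BVGA → IIA1, RRGA →
IIA2) and the two unpaired nucleotides before DV (YW → IIB1, RG → IIB2);
a short, IEP-less, heavily degenerated scaffold is "IIB-like".

## Synthetic cohort generator

The generator produces cohorts with complete ground truth so that every
downstream stage is testable without external data.

**Templates as labelled segments.** An intron template is an ordered list of
sequence segments, each with a fixed dot-bracket: terminal motifs, DI outer
stem and its child hairpins (EBS1/EBS2/EBS3 helices, the accessory elements
Ia, IC2, ID2, ID2a, IE, and an optional padding hairpin for long-scaffold
experiments), DII, the diagnostic DII–DIII tetramer, DIII (plus DIIIa when
flagged), DIV with an embedded ORF, the diagnostic DIV–DV dimer, the fixed
34-nt DV, and a 19-nt DVI whose bulge is the branch-point adenosine 8 nt
from the intron's 3′ end. Accessory sub-helices have distinct
(stem, loop) sizes so a size-fingerprint heuristic can label them; the
structure is bookkeeping truth, not a thermodynamic prediction (folding is
out of scope by design).

**Between-family signal.** Family templates are not drawn independently:
every shared segment descends from an ancestral sequence evolved along a
fixed family guide tree whose topology mirrors the subgroup structure
(IIB-like, (IIA1, IIA2), ((IIB1-RT/M, IIB1-LHE), (IIB2-RT/M, IIB2-LHE))),
with equal edge lengths scaled so the deepest leaf sits `family_divergence`
(default 0.2) substitutions/site from the root. DIIIa-carrying IIA1
families form their own subclade. This is what makes family-level RNA trees,
RT/M protein trees and LHE protein trees meaningful: the RT/M ORF is one
ancestral sequence evolved along the same tree (coevolution), while each
LHE invasion event draws an independent ancestral LHE, so LHE-carrying
families form per-event clades that are jointly non-monophyletic on the RNA
tree (the dual-origin signature). Invasion events are the connected
components of the `invasion_donor` links among LHE families.

**Family-specific overrides.** At each leaf the diagnostic junctions are
drawn from their IUPAC patterns (kept unambiguous between BVGA and RRGA,
and non-matching for IIB), EBS loops are set to the reverse complements of
the reference-gene IBS windows at the family's insertion site, and
degeneration flags are applied: a 2–10-nt 5′ linker (always together with
branch-point loss, mirroring their observed coupling), deletion of the DVI
bulge, removal of IC2/ID2, insertion of ID2a/IE/DIIIa, premature-stop or
absent ORFs. For `lose_EBS2` the EBS2 loop is rejection-resampled until the
package's own detector scores the site as lost; ground truth for all EBS
fields is then recorded from a detector run on the finished template, so
truth always describes the emitted object. The IIB-like lineage never
carries the padding hairpin — its defining property is a reduced scaffold
(< 800 nt).

**Evolution.** Species trees are pure-birth (Yule) trees with leaf depth
normalized to 1.0, so substitution rates are expected substitutions/site
across the whole tree depth. Substitution is a single-parameter equal-rate
(JC-like) process applied hierarchically along branches, with separate
rates for scaffold and ORF positions. Selection is modelled only as
invariance: the 5′ hexamer, DV, DVI loop + branch point, diagnostic
junctions, ORF start/stop and the diagnostic protein motifs do not mutate
within a family, and nonsense mutations the template did not carry are
reverted (purifying selection on the IEP). Presence/absence of each family
in each species is an independent Bernoulli draw — occurrence frequency is
treated as a marginal summary, not a tree-aware gain/loss process. Emission
writes plain-text files (FASTA genomes/introns, GFF3 gene models 1-based
inclusive, 3-line dot-bracket records, a truth TSV, Newick trees) and is
byte-deterministic for a fixed configuration.

**Default conditions.** The clean roster holds 12 families (IIA1/IIA2/
IIB1/IIB2, RT/M and LHE, no degenerations) with presence 1.0 — the
round-trip condition. The rich roster holds 15 mitochondrial-flavoured
families exercising every degeneration plus two LHE invasion events; its
presence probabilities follow reported occurrence frequencies for the
corresponding real families (0.523/0.489-class values down to 0.045). The
worked cohort in `analysis/` uses 44 genomes, scaffold divergence 0.04 and
ORF divergence 0.06, and `scaffold_extra = 1800` nt of DI padding so that
tree-building operates on ~2000 scaffold columns.

## Annotation rules

* **Domains**: top-level helices of the dot-bracket, 5′→3′. Six helices map
  to DI–DVI; seven map the extra helix between the third and fourth to
  DIIIa; five or eight are handled positionally with a warning; anything
  else is a layout error. The unpaired prefix before DI, minus the 6-nt
  terminal motif, is the linker.
* **Terminal motifs**: GUGCGA searched in the first 15 nt (≤1 mismatch →
  "variant"); the 3′ end must match A followed by a pyrimidine.
* **Branch point**: an unpaired A inside DVI, 6–10 nt from the intron 3′
  end.
* **EBS/IBS**: single-stranded stretches of DI are scanned for the best
  reverse-complement window of each IBS; EBS1 needs ≥5/6 complementary
  pairs, EBS2 ≥4/6 (excluding the EBS1 window), EBS3 one exact pair (the
  most 3′ match, where it sits in real introns); G·U pairs count only when
  wobble is enabled. Thresholds are package choices — the source analyses
  report presence/loss qualitatively.
* **Accessories**: with no user labels, DI child helices are fingerprinted
  by exact (stem, loop) size in canonical order after anchoring the EBS
  helices — documented as approximate, exact on generator output.
* **Subgroup**: tetramer first (both patterns matching → "ambiguous-IIA",
  resolvable by a caller-supplied clade prior), then dimer, then the
  IIB-like rule (no IEP, < 800 nt, ≥ 2 core features absent among 5′ motif,
  branch point, EBS1, EBS2), else unclassified.
* **IEP**: stop-to-stop ORFs ≥ 100 codons in the three forward frames of
  DIV (IEPs are sense-encoded; reverse frames are not searched). LHE = two
  LAGLIDADG copies (≤3 mismatches each) 80–150 aa apart; RT/M = [YF]xDD
  plus ≥1 [LIV]PQG RT block. Intact requires a single ORF covering the
  motif-anchored core ±20 aa; motif evidence without such an ORF is
  degenerated; sub-threshold motif hits are reported as remnant candidates
  without judgement. Translation table defaults to 1 and is configurable —
  the genetic code for organellar ORFs is deliberately a parameter.

## Families and occurrence

Insertion sites are mapped by local alignment (match +2, mismatch −3, gap
open −5, extend −2) of the ≤20-nt upstream exon flank onto the reference
host gene; the site is the reference coordinate of the last aligned flank
base, advanced past any unaligned flank suffix so a mutated terminal base
cannot shift the site (identity < 60% → unmappable). Families are
single-linkage clusters within a (gene, site) group under global identity
≥ 60% over ≥ 50% of the shorter sequence, with identity counted over all
alignment columns including gaps (unrelated sequences then score ~0.5,
well below threshold); co-sited non-homologous clusters get `.2`, `.3`
suffixes. Member search runs the installed NCBI `blastn` (word size 11) and
preserves the cutoff semantics E ≤ 1e−5, query coverage ≥ 30%; bit-level
parity with any particular BLAST build is explicitly not promised.
Occurrence frequency is computed per organelle compartment; classes use the
unrounded frequency (> 0.40 broad, < 0.15 narrow) while percentages print
with one decimal.

## Phylogenetics

Maximum-likelihood inference with model selection is out of scope: the
questions asked of the trees are topological (clade membership, congruence),
and neighbor joining on p or JC69 distances (pairwise deletion; JC69
undefined at p ≥ 0.75 and flagged infinite) answers them deterministically.
NJ uses the Saitou–Nei Q criterion with ties broken toward the
lexicographically smallest cluster-label pair and negative branch lengths
clamped to zero; the implementation is cross-checked against an independent
NJ in the test suite. Support comes from a classical column bootstrap
(seeded, deterministic), mapped only onto bipartitions of the point-estimate
tree. Congruence is the Robinson–Foulds distance (symmetric difference of
non-trivial bipartitions); monophyly is assessed after rooting on a named
outgroup leaf. Hotspot masking removes labelled column intervals (accessory
elements, padding, diagnostic junctions in the synthetic coordinate system)
before distance computation; note that removing invariant columns preserves
mismatch counts and topology but necessarily rescales per-site distances.
A center-star progressive aligner (affine gaps) is provided for
high-identity family representatives; pre-aligned input passes through
unchanged. On synthetic cohorts the scaffold "alignment" is exact by
construction: the generator's shared segments are positionally homologous,
and segments absent from any selected family (ORFs, linkers, family-specific
variants) drop out of the common coordinate system automatically.

## Statistics

Length and GC are compared across lineage × organelle with a two-way
fixed-effects ANOVA using Type-II sums of squares (cohorts are unbalanced);
a single-level factor reduces to one-way with a warning. Post hoc contrasts
use Tukey–Kramer HSD on the crossed cells via statsmodels (exact for
unequal n). Null calibration (normal noise, 2×2, 1000 replicates) puts each
effect's type-I error within 0.05 ± 0.015. Sequence logos use information
content 2 − H (log2) per position over {A,C,G,U}; the small-sample
correction 3/(2·ln2·n) is off by default so the 0-bit/2-bit bounds are
exact, and can be enabled by flag. The bubble matrix reports, per family ×
feature, the percentage of members carrying the feature to one decimal,
with not-assessable members excluded from (and reported next to) each
denominator. GC-vs-host comparisons offer a one-sample t-test with a
Wilcoxon signed-rank fallback at small n, in both per-intron and per-family
modes.

## What the generator does and does not emulate

It emulates the structural grammar (domains, motifs, EBS/IBS pairing,
accessory gain/loss), family/subgroup organisation, IEP content and decay,
presence/absence breadth, and coupled RNA/protein divergence with
independent LHE invasions. It does **not** emulate thermodynamic folding,
realistic codon usage or base composition (all segments are drawn uniformly,
so lineage GC contrasts are not built in and the GC machinery is exercised
rather than validated against a planted effect), indels within families
(within-family alignments are trivial), recombination, or tree-aware
gain/loss dynamics. Tests passing on synthetic cohorts therefore establish
that the rules and estimators are implemented correctly and are robust to
substitutional noise — not that they would be equally accurate on real
genomes, where structure must be supplied or predicted externally and
alignment is non-trivial.

## Numerical and interface choices

Coordinates are 1-based inclusive throughout (GFF3 convention); insertion
site `s` means "between reference positions s and s+1", and gene names with
hyphens split on the last hyphen. Introns are RNA internally (T→U on load),
genomes DNA; minus-strand introns are reverse-complemented by the loader.
Consensus building treats the gap as a symbol, drops gap-majority columns,
and breaks nucleotide ties alphabetically (A<C<G<U) while recording tied
columns. All stochastic components take explicit seeds and are reproducible
to the byte. The analysis entry points are the numbered scripts under
`analysis/` plus the library API — the package intentionally ships no
console-script wrapper, since every step is a one-line function call and
the scripts document the workflow end to end.

## Problem sizes

The default verification conditions are: 12 families × 20 species for the
zero-mutation round trip; 20 seeded cohorts (~2000 scaffold columns, 10
RT/M families) for coevolution congruence and 10 seeded cohorts for the
dual-origin pattern; 100 random 6–10-taxon trees for NJ consistency; 1000
null replicates for ANOVA calibration; 1000 random alignments for the
consensus oracle; and a 44-genome, 15-family cohort for the worked
analysis. These sizes give stable, reproducible statistics while keeping
any single run in the seconds-to-a-minute range.

## Known limitations

Accessory labelling beyond the generator's vocabulary (Ia-like, ICa, ICb,
IDa distinctions) is pass-through only; de novo discovery inside DI is a
size heuristic. The BLASTN-based search assists presence calls on annotated
cohorts and is not a de novo intron discoverer. JC69 distances saturate at
high divergence, so between-event LHE branch lengths are qualitative.
Real-data ingestion expects annotated GFF3 plus user-supplied dot-bracket
structures; GenBank flat-file parsing is intentionally not included.
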