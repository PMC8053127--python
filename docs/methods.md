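# Methods

## Cleavage-end counting

A RiboMeth-seq fragment is one alkaline-hydrolysis product, represented by
the outermost coordinates of a properly paired read pair (secondary and
supplementary alignments are ignored; a pair is counted once, via read 1;
the default MAPQ filter is 0). Every cut between nucleotides *i* and *i*+1
leaves a 3′ end at *i* and a 5′ end at *i*+1, so the 5′-end count is shifted
one position upstream and added to the 3′-end count, giving the combined
per-bond track n_i for i = 1..L−1. Cuts at the molecule termini fall off the
track by construction. The average end count AEC = fragments / RNA length
(in nt) is the coverage statistic used throughout; because each interior cut
contributes two ends, the combined track averages about 2×AEC per bond.

## MethScore

S_i = 1 − n_i / (0.5·(L_i + R_i)), with L_i and R_i weighted means of the
counts over the `flank` = 6 positions on each side. The neighbor taper is
the method's main free parameter; we use w = (1.0, 0.9, 0.8, 0.7, 0.6, 0.5)
(nearest first) and expose it in `ScoreConfig`. Design choices:

- **End exclusion.** Twenty nucleotides at each terminus are masked
  (`end_region`): library end effects distort counts there. Neighbor
  windows do not borrow across this boundary by default; truncated windows
  renormalize their weights over the available positions
  (`borrow_into_ends=True` restores borrowing). A position whose side has no
  usable neighbor at all is masked `undefined`.
- **Coverage floor.** Positions with 0.5·(L+R) < 10 counts are masked
  `low_coverage`; a zero denominator is `undefined`. This automates the
  manual removal of spurious high scores at low or uneven coverage.
- **Negative scores are retained.** They indicate a locally elevated
  intrinsic hydrolysis rate and are required for correct score differences
  between samples and for the methylation level
  (S_mod − S_unmod)/(1 − S_unmod).
- Scores are indexed by the nucleotide 5′ of the bond (the methylated
  residue protects the bond to its 3′ neighbor).

Between-sample comparison (`score_delta`) reports per-site ΔS = S_a − S_b
(positive when a is more methylated), the mean ΔS, and a one-tailed paired
t-test for mean ΔS > 0.

## Nm calling and reliability

Calls use a fixed threshold S ≥ 0.8. Scores in [0.5, 0.8) are *rescued* only
with independent evidence: an assigned guide snoRNA and a score drop of at
least 0.1 in a perturbation sample (e.g. a methyltransferase mutant);
otherwise they are rejected with reasons. Candidates whose ±6 end-count
coefficient of variation exceeds 3.0 are flagged as likely unevenness
artifacts — flagged, never silently deleted. The rescue delta default (0.1)
sits well above the global mean score changes such mutants produce, so it
selects sites with a clearly genuine response; all four thresholds are
plain `CallConfig` fields.

Reliability is estimated by drawing fragments without replacement to a grid
of target AECs, rebuilding and rescoring the track, and calling at the
threshold: discovery rate = TP/True and precision = TP/Positive, averaged
over replicates (0/0 is reported as undefined, never as 0 or 1). The
subsampling scorer deliberately drops the coverage floor — the curve exists
to expose the low-coverage failure mode (spurious high scores) that the
floor is designed to hide. On the synthetic reference condition (2-kb RNA,
20 fully methylated sites, p0 = 0.02, full coverage AEC 60, grid
2–50, 20 scenes × 3 replicates) precision collapses below AEC ≈ 10–15 while
discovery stays flat, and the smallest grid AEC with precision ≥ 0.9 has a
median of ~10; we document [5, 30] as the expected band for this statistic
around the field's rule of thumb of 15.

## Guide assignment

Box location: box D is the 3′-most CUGA ending within 10 nt of the 3′ end;
box C the 5′-most RUGAUGA within nt 2–12; every internal NNGA whose GA is
exact is kept as a box D′ candidate (degenerate D′ boxes are common, so no
stronger motif is required; ties among candidates are not broken — all that
yield a valid duplex are reported). Box C′ is located for annotation only
and is never required for D′-guide validity. Catalog coordinates override
motif search.

The duplex search replaces heuristic short-read alignment with exact
enumeration of ungapped antiparallel Watson–Crick duplexes — at these
scales it is faster and strictly complete. A primary duplex anchors the
methylation site to guide position 5 (counted upstream of the box's first
base), takes the maximal WC run through the anchor within a ±100-nt
substrate window (clipped at sequence ends, never wrapped), and must have
≥7 WC pairs, ≥2 substrate pairs 5′ and ≥3 pairs 3′ of the site. Accepted
duplexes are extended stepwise through G:U wobble pairs at both ends;
extension stops at the first non-pair and never pairs box nucleotides.
Sites guided by multiple snoRNAs keep all records (no best-hit collapsing).

Extra (secondary) pairs are enumerated the same way over the whole snoRNA,
kept at 7–15 bp after GU extension, and discarded when they overlap box
motifs or the primary pair (on either molecule) by more than 2 nt —
"significant overlap" is not defined sharply anywhere, so the 2-nt bound is
a configurable choice. Each extra pair is annotated with its side and
distance relative to the primary pair on both molecules.

Non-canonical multi-specificity: an unassigned site 1 nt (guide position 6)
or 2 nt (position 7) 3′ of a site assigned through a D′ guide inherits that
guide; the +5/+6 tandem is the experimentally validated pattern, +5/+7 is
flagged as predicted. A relaxed rescue mode (off by default) permits one
internal mismatch with a 12-bp minimum for still-unassigned sites and labels
its records `relaxed`; it approximates, but does not reproduce, the more
mismatch-tolerant probabilistic searches sometimes used for such rescues.

## Abundance

Reads (fragments) per RNA divided by length in kb gives RPK; dividing by
the 18S rRNA RPK and scaling by 1e6 gives normalized TPM — molecules per
million 18S molecules, comparable across samples because cytoplasmic rRNA
levels are stable. Condition comparisons report the fraction change
(TPM_wt − TPM_mut)/TPM_wt per RNA and, per class, both the change of summed
TPM and the mean of per-RNA changes (the two differ under heterogeneous
abundance; which one a summary statistic means is often ambiguous, so both
are emitted). For a site's cumulative guide change, all assigned guide
variants are summed per condition before the change is taken.

## The synthetic-data generator

`simdata` emulates the measurement chain: random references at a set GC
content; planted sites with stoichiometry f; snoRNAs assembled as
pad–RUGAUGA–spacer–[D′ guide]–NNGA–spacer–[D guide]–CUGA–pad with the guide
element the exact antiparallel complement of the substrate window placing
the site at the planted offset (5, 6 or 7); optional extra-pair elements
and guide degradation (point mutations or scrambling).

Fragmentation: methylation is drawn per molecule and site as Bernoulli(f) —
stoichiometry is a property of the molecule population, not of individual
bonds; both conventions give the same mean protection but different
variance — and each unprotected bond is cut independently with probability
p0 = 0.02 per molecule (a free parameter: no quantitative hydrolysis rate
is established; 0.02/bond makes a 2-kb RNA yield library-sized fragments).
A methylated nucleotide protects its 3′ bond completely. Fragments between
consecutive cuts (and termini) are retained when their length lies in
[20, 200] nt — a hard window approximating a gel cut of 170–350 bp minus
~150 bp of adapters; a real gel has soft edges, which this deliberately
does not model. Molecules are generated until the per-RNA fragment target
is met. Identical config and seed give byte-identical output.

What the generator does **not** emulate: sequencing errors, PCR duplicates
and barcodes, ligation and coverage biases, multi-mapping between similar
references, and the soft insert-size distribution. Passing tests therefore
demonstrate the correctness of the counting, scoring, calling and
assignment logic under the stated stochastic model — not robustness to
platform artifacts in real libraries.

Condition pairs scale selected snoRNA copy numbers and/or site
stoichiometries; snoRNA read counts are Poisson draws proportional to copy
number × length, anchored by a stable 18S reference, and `couple_sites`
ties each site's mutant stoichiometry to its guide's abundance factor.

## Problem sizes and numerical checks

The test and acceptance workloads use: stoichiometry recovery on a 600-nt
RNA with one isolated site at AEC 100 over 20 seeds per f ∈ {0.25, 0.5,
0.75, 1.0} (mean |S − f| stays within 0.05); guide recovery on a 2-kb scene
with 30 planted guides; reliability on 2-kb scenes with 20 sites and 120k
fragments; condition comparison with a 0.46× class knockdown (read out as
≈54% loss of summed TPM) and a planted f drop 0.9→0.6 (read out as ΔS ≈
0.3). These sizes keep every experiment's Monte-Carlo error comfortably
below the tolerances being checked. The production scorer is verified
against a naive direct-summation implementation to 1e-12, and the duplex
search against a brute-force enumeration oracle on random small instances.

## Known limitations

- The neighbor-weight taper is a convention, not a fitted quantity;
  published per-site scores can only be reproduced exactly with the
  original weights and raw data.
- The flatness of simulated end counts holds for the raw 3′-end counts; the
  combined track double-counts each cut (one 3′ end plus one shifted 5′
  end) and is overdispersed relative to Poisson by construction.
- The CV-based unevenness flag is a blunt automation of what is ultimately
  a visual-inspection judgement; it annotates rather than filters.
- Cross-species conservation intersection requires an externally supplied
  coordinate equivalence map; unmapped positions are conservatively counted
  as species-specific.
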