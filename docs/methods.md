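# Methods

This note records the models, parameter choices and numerical conventions
behind `alomine`, and what the synthetic benchmark does and does not
establish.

## Coordinates, translation, formats

Internal coordinates are 0-based half-open on the forward strand; GFF3
output is 1-based inclusive. Translation uses the bacterial/archaeal code
(table 11); ATG, GTG and TTG are accepted initiators and emit M at ORF
starts. Ambiguity codes other than N are rejected so ORF arithmetic stays
exact. FASTA I/O is delegated to Biopython; GFF3 is a minimal 9-column
reader/writer (features are flat lists here, so a database-backed parser
would add nothing), property-tested for round-trip bijectivity.

## ORF and cognate-peptide search

ORFs run from the first initiator after the previous in-frame stop to the
next stop (stop codon included in the interval); an all-starts mode exists
because real annotations mix conventions. The cognate-peptide window for a
receptor `[s, e)` on `+` is `[e − 100, e + 200)` (strand-mirrored on `−`,
clipped at contig edges): the published search region covering the
receptor's last 100 nt and the 200 nt downstream. A peptide qualifies when
its start codon lies in the window — the window bounds the search, not the
ORF — its length is 30–50 aa (the executed-procedure band; a 32–50 aa
variant appears elsewhere and is configurable), and it lies on the
receptor's strand (a flag relaxes this; "encoded immediately downstream"
implies but does not state same-strandedness).

## TPR-like repeat detection

The scan is a 34 × 20 log₂-odds profile (pseudocount 1, Robinson–Robinson
background, clipped to ±10) built from a bundled synthetic seed alignment
of 16 repeat units derived from the classical TPR consensus (conserved
small/large hydrophobic positions 4, 7, 8, 11, 20, 24, 27, 32). Windows are
scored at every offset; non-overlapping windows with positive score are
accepted greedily in descending score order (ties to the smaller offset).

The calibration statistic is the summed accepted score or, when no window
is positive, the best single-window score. The fallback matters: the
profile is discriminative enough that out-of-register windows essentially
never score positive, so the greedy sum alone is identically zero off
target and carries no null variance. Null proteins are drawn i.i.d. from
the profile's average column composition — a true repeat array with its
positional register destroyed — which makes the null conservative: plain
background proteins fall below it. The logistic map `P = 1/(1 + e^{−(a+bz)})`
uses slope `b = 1.5` and anchors `P = 0.5` at the null 99th percentile.
`P` is a calibrated surrogate for an external repeat-probability score, and
the conventional 0.75 seed threshold is applied to it; sensitivity on real
genomes therefore need not match the original tool, which is why seed-stage
recall is buffered by the homology expansion.

## Homology search and families

Alignment is exact Smith–Waterman (Biopython `PairwiseAligner`), BLOSUM62,
BLAST-style affine gaps (length-k gap costs 11 + k). Input sets are small
after the length/TPR pre-filters, so O(mn) is affordable. Significance uses
Karlin–Altschul `E = K·m·n·e^{−λS}` with the published gapped BLOSUM62 11/1
constants (K = 0.041, λ = 0.267); applying them to gapped scores is an
approximation, declared rather than fitted. Thresholds: E ≤ 1e−5 within a
genome, E ≤ 1e−10 across genomes; subjects < 250 aa, or on scaffolds
< 2,500 nt when contig information is present, are discarded. Iterative
profile search is replaced by a two-round transitive expansion (hits of
hits re-searched once), which captures the intent of multi-iteration
searches at desk scale. Families are single-linkage connected components of
the passing-hit graph; representatives are the longest member (ties
lexicographic), ids assigned in sorted-representative order for
determinism.

## Signal prediction and rescue

A signal call requires an 8-residue Kyte–Doolittle window with mean ≥ 1.6
within the first 30 residues and at least one K/R before that window.
These are standard Sec-signal heuristics standing in for an HMM-based
predictor; all four numbers are configuration values. The published manual
rescue ("near-threshold calls inferred by homology to family members") is
mechanized as: a negative call with relative margin ≥ −0.15 flips to
positive iff > 50 % of its family's calls are positive, evaluated on the
pre-rescue state so the result is order-independent; rescued calls are
flagged. The margin band is a documented default, not an inference about
the original tool's cutoff.

## Locus assembly

Receptor candidates are TPR seeds (P ≥ 0.75, ≥ 250 aa) plus homology
expansion. Receptors with no qualifying downstream ORF — or whose peptides
are all signal-negative and unrescued — are kept as orphan loci; degenerate
peptides are retained with their flags rather than dropped. The spo0E flag
is set when the next same-strand gene downstream of the locus lies within
200 nt (reusing the forward window span; the source description says only
"directly downstream") and either its annotated product matches /spo0E/i or
it hits a supplied reference protein at E ≤ 1e−5. The HTH domain is
asserted by the biology but never operationalized as a filter; the field is
advisory.

## MS fragment mapping and processing inference

Fragments are matched as exact substrings (MaxQuant emits residue
sequences); an I/L-collapse flag exists since MS cannot distinguish them.
Fragments outside 5–35 aa are discarded (the detectable band), and with
unique-only mapping a fragment matching more than one pro-peptide is
dropped. Inference: cleavage positions are distinct placement starts > 0;
the candidate cut is the internal placement end maximizing summed spectral
support among ends whose missing suffix is 5–10 aa (ties to the shortest
suffix, since heavier support and shorter mature peptides are the expected
signature); if every internal end leaves a longer suffix the call is
`longer_mature`; if all placements reach the C terminus, `no_internal_cut`;
no placements, `undetected`. Spectral counts from different samples are
pooled, mirroring cumulative-count reporting.

## Synthetic benchmark

The generator plants the exact anatomy the miner targets, with defaults at
the stated mining bounds: receptors = M + 50–60 aa HTH-like block +
10–20 aa linker + 6–8 profile-sampled TPR units (≥ 250 aa total); peptides
= M + 1–2 K/R + 8–12 hydrophobic residues (L-weighted pool) + ≥ 2-residue
polar linker + 5–10 aa mature segment drawn from a small/polar pool (so it
cannot mimic an h-region); intergenic sequence at GC 0.42. An in-frame TAA
is planted immediately upstream of every gene so ORF calls coincide with
the plant. Decoys implement their own definitions as generative guarantees:
TPR-no-peptide decoys get a downstream window scrubbed of same-strand
initiator codons (the planted truth really lacks a cognate ORF), and
signal-less short-ORF decoys cap strongly hydrophobic residues at 4 per
8-residue window so no h-region can assemble by chance. 30 % of loci get a
downstream spo0E-annotated gene within 200 nt.

Fragment simulation: per pro-peptide, 1–3 distinct cleavage sites in the
last 5 residues of the signal region; each fragment ends at the mature cut
with probability `mature_release_prob` (default 0.5) or at the C terminus;
spectral counts are geometric (mean ≈ 8); noise fragments are substrings of
non-peptide proteins. Cuts are clamped into the 5–35 aa detectable band
(the model emulates the set of *detectable* fragments); when no detectable
mature-ending fragment is emitted the truth marks the peptide
mature-undetectable, which mirrors real partial detection.

What a green benchmark establishes: the pipeline's logic — windowing,
strand handling, scoring, expansion, orphan/spo0E classification, cleavage
inference — is correct on data matching its generative assumptions. What it
does not establish: sensitivity on real genomes (real TPR arrays are more
divergent than profile-sampled units; real signal peptides vary more than
the planted architecture; real MS data carry identification noise the
simulator omits). Accuracy of mature calls is scored as correctness of
issued calls plus recovery of every peptide whose fragment set contains a
mature-ending fragment; peptides whose fragments all reach the C terminus
are *correctly* labelled `no_internal_cut` and are not counted as errors —
under the mixed cleavage model a substantial fraction of peptides is
undetectable by construction, just as real secretomes yield detection for
only a subset of predicted peptides.

## Determinism and limitations

All randomness (calibration shuffles, simulation, fragment sampling) flows
from explicit integer seeds; reruns are byte-identical on the data outputs
(the run manifest carries a wall-clock timestamp). Known limitations: the
repeat-probability calibration is a surrogate, so absolute seed-stage
sensitivity on real proteomes is untested; Karlin–Altschul constants are
applied to gapped scores; the GFF3 reader handles only the subset the
package writes; genomes are processed in memory (no streaming).
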