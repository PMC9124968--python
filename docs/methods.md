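# Methods

## Scope and model

`igjunction` annotates expressed immunoglobulin (Ig) reads — 5'-RACE
amplicons covering the whole variable region — against a germline segment
set for one locus (IGH, IGK or IGL), and provides a generative simulator of
the same process so every stage can be validated against known truth.

The underlying biological model is standard V(D)J recombination followed by
somatic hypermutation (SHM):

1. one germline V, (D — heavy chain only,) and J segment are joined;
2. exonucleolytic trimming removes 0–n nucleotides from the V 3' end, the
   J 5' end and (IGH) both D ends;
3. palindromic **P nucleotides** — the reverse complement of the terminal
   retained bases — can appear at a coding end *only if that end was not
   trimmed* (they arise from asymmetric hairpin opening);
4. non-templated **N nucleotides** are inserted by TdT;
5. AID-driven SHM substitutes bases across the V region, transition-biased
   and enriched at WRCY/RGYW hotspots (W=A/T, R=A/G, Y=C/T) and in the
   CDRs.

## Germline classification

V functionality follows the IMGT-style rules, computed from the per-gene
region annotations (FR1…FR3, 0-based half-open intervals):

* **pseudogene** — stop codon in the FR1→FR3 frame, or a region length that
  is not a multiple of 3 (frameshift);
* **ORF** — intact frame but a conserved-residue or regulatory violation:
  Cys-23 or Cys-104 absent, a leader without ATG, or (optionally) a missing
  downstream RSS;
* **incomplete** — FR1–FR3 annotation absent or truncated;
* **functional** otherwise.

The conserved cysteines are located positionally from the annotation:
Cys-104 is the final FR3 codon (FR3 ends at IMGT position 104) and Cys-23
the 4th codon from the FR1 end (FR1 spans IMGT 1–26). End-anchoring keeps
both positions correct for 5'-truncated annotations without requiring an
alignment to an external numbering template.

J genes are **functional** iff some reading frame is open through a
W-G-X-G (IGH) or F-G-X-G (light chain) motif; the FR4-terminal TVSS motif
is reported as an advisory flag only. D genes report their stop-free
reading frames.

RSS scanning matches heptamer CACAGTG and nonamer ACAAAAACC within
configurable mismatch budgets (defaults 1 and 2; the CAC core can be held
exact) and a 12±1 or 23±1 spacer, on both strands; minus-strand hits are
mirrored onto the plus axis. V clans are single-linkage clusters of FR1–FR3
nucleotide identity at a default threshold of 0.75 (the classic V-family
convention), labelled by descending size with lexicographic tie-break so
the labelling is input-order invariant.

## Assignment and anchoring

Each candidate germline window (V: FR1–FR3; J: the never-trimmed conserved
anchor codon onward; the trimmable J 5' part is attributed later by the
junction decomposition) is infix-aligned into the read. Scoring is match
+1, mismatch −1, gap open −4, gap extend −1. Alignment paths come from
edlib (banded edit distance) and are rescored under this scheme; because
edit distance scores a terminal substitution and a terminal gap equally, a
gapless alignment is substituted whenever it scores at least as high —
under the affine scheme substitutions always beat gaps, which keeps segment
boundaries stable on SHM-bearing reads. Exact score ties collapse to a
clan-level call with an explicit ambiguity flag; ambiguous reads are
excluded from SHM statistics by default because their mutation sets depend
on the chosen template. Only substitutions are recorded as mutated
positions; indels are excluded from SHM accounting. D genes are called by
the longest exact substring match (≥5 nt by default) inside the V–J
junction window.

The CDR3 is the read segment *strictly between* the Cys-104 codon and the
J anchor codon (W/F), both placed by projecting the germline anchor
positions through the alignments. Projection is deliberately primary: a
mutated anchor codon does not move the anchor (it increments
`anchor_mismatches`). A motif scan in the aligned frame (YYC / WGXG / FGXG
with ≤1 mismatch at non-critical residues) is the fallback when projection
is impossible.

## Junction decomposition

The junction window between the V and J alignments is attributed by these
ordered rules:

1. **Maximal templated attribution** — extend the V rightward by the
   longest exact match to the germline V 3' continuation, then the J
   leftward likewise; bases claimable by both sides go to V (left
   precedence). Matching is exact: a mutated junction base ends the
   extension, so SHM inside the junction is conservatively classified as N.
2. Deletions are the germline nucleotides beyond the retained ends.
3. **P before N** — at each untrimmed end, the longest insert prefix/suffix
   equal to the reverse complement of the terminal retained bases (capped
   at `max_p_len = 4`) is P; the cap prevents spuriously long palindromes.
4. (IGH) the best exact D match ≥ `min_d_match` inside the remaining insert
   receives its own deletions and P rules; everything left is N.
5. The concatenation retained_V · P · N · (P·D·P · N) · P · retained_J must
   reproduce the junction byte-exactly; a violation raises immediately.

An instance is flagged *ambiguous* when the maximal V and J extensions
overlap (several attributions tie for maximal templated length); the
V-precedence pick is then one of several defensible answers. An exhaustive
enumeration oracle over a toy V/J grid verifies both the chosen convention
and the ambiguity set.

Two consequences worth knowing: (a) recovered deletions are *lower bounds*
— an N base that coincidentally continues the germline inflates the
retained length, so the recovered deletion distribution is shifted slightly
toward 0 relative to the generative one (exact on junctions whose inserts
do not extend a germline match); (b) P/N boundaries inherit the same
convention dependence, documented rather than hidden.

## SHM analytics

SHM frequency = observed mutant bases / aligned (non-gap, non-N) bases,
reported as a percentage, overall and per germline V. Per-site profiles
count coverage and mutations per germline FR1–FR3 position; the 12-class
substitution spectrum normalizes counts by total mutant bases. Hotspot
analysis scans each germline V for WRCY (mutable C, motif position 3) and
RGYW (mutable G, position 2) — DGYW/WRCH available by configuration — and
compares the mutation frequency at hotspot C/G positions against all
non-hotspot C/G positions; enrichment is the ratio of those frequencies
(NaN when the baseline is empty). Sequencing error is *not* separated from
SHM; on real data the reported rates are SHM + residual error.

## Simulator

The generator draws, per read: segments by configurable usage weights
(J heavily biased, default 0.95/0.04/0.01, as observed in bovid
repertoires), trims from discrete empirical tables, P lengths (only at
untrimmed ends; the P string is then determined by the germline), N
inserts of uniform base composition, and SHM over FR1–FR3. Default tables
encode the qualitative repertoire structure the pipeline targets: V 3'
deletions concentrated at 0/2/3 bp with a maximum of 8; J 5' deletions at
0/3/6 bp (secondary 4 bp) with a maximum of 12; N and P lengths 0–1 bp for
κ, 0–2 bp for λ, and a longer N tail for the heavy chain (whose true N/P
length distribution is not separately specified; the λ shape with a wider
tail is an explicit assumption). Default per-locus SHM rates are 8.2%
(IGH), 2.4% (IGK) and 7.6% (IGL) with a transition-biased spectrum
(A↔G 0.17 each, C↔T 0.12 each, remainder uniform), CDR multiplier 3 and
hotspot multiplier 5. An ultra-long CDR3H mode (default 5% of heavy-chain
reads) rearranges a 90 nt (TATGGT)ₙ — i.e. (YG)ₙ — D template with ≤2 bp
trims, yielding CDR3s of ~40+ codons.

SHM is generated by drawing the read's mutation count from
Binomial(L, rate), then for each event a substitution class from the
12-class weights and a site among matching origin bases, weighted by the
CDR and hotspot multipliers. This construction makes the realized spectrum
equal the configured weights irrespective of base composition, keeps the
overall per-base rate at its nominal value, and makes the hotspot
enrichment ratio equal the multiplier in expectation — the three properties
the recovery tests check.

Ground truth records every draw; replaying the truth against the germline
set must reproduce each read byte-exactly (tested). The toy germline set is
deterministic in its seed: 6 functional V in two clans (~98% within-clan
identity), plus one ORF (Cys-104→Ser), one pseudogene (stop in FR2), one
truncated V, 4 D including the ultra-long template, 3 functional J + 1
lacking the anchor motif, and a constant-region stub; reads are decorated
with the 5'-RACE forward primer and the reverse complement of the
locus-specific reverse primer.

What the simulator does **not** emulate — and what passing tests therefore
do not show about real data: sequencing error as a separate channel
(modellable via `error_rate`, default 0), indels (SHM is substitution-only
here), D–D fusion, gene conversion, class switching, clonal lineage
structure (reads are independent), primer/adapter artefacts, and germline
polymorphism beyond the supplied set.

## Numerical and procedural choices

* Coordinates are 0-based half-open throughout; strand − RSS positions are
  mirrored to the + axis.
* "Between YYC and WGXG" is read as exclusive of both anchor codons; the
  convention is fixed and exported.
* Usage statistics count every read (no clonotype deduplication, matching
  the analysis the pipeline reproduces); `dedup` is available but off.
* Percentages are over assigned reads, with unassigned counts reported
  alongside rather than dropped.
* Population SD (denominator n) is used for junction length summaries.
* Reads failing primer screening are attributed to the primer rule before
  the length rule, so QC counts partition the input.
* Determinism: a fixed seed makes simulation byte-identical; the analysis
  pipeline itself is deterministic (canonical gene-id tie-breaking,
  order-independent clustering), verified by output hashing.

## Validation problem sizes

The test suite and acceptance script use: the exhaustive junction
micro-grid (20 nt V/J, trims 0–4², all inserts ≤3 nt; 2,125 instances);
n = 300 shared annotated runs per locus for invariants; n = 2,000 reads for
usage/SHM-rate/spectrum recovery; n = 5,000 for hotspot enrichment;
n = 10,000 (truth level) for trimming pmfs; n = 1,000 for CDR3 anchoring;
100 random sequences for the RSS oracle. These sizes give 3-SE recovery
bands of a fraction of a percentage point for the dominant parameters while
keeping the whole suite under a minute of compute.
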