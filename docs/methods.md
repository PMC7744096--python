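# Methods

## The assay model

A tRNA molecule is aminoacylated ("charged") when its 3′-terminal adenosine
carries an esterified amino acid. Periodate oxidation opens the 2′,3′-diol
of a free 3′ ribose; a charged tRNA is protected. After a pH-9 deacylation
step removes the amino acid from the surviving molecules, only tRNAs that
were charged at harvest present a ligatable 3′ end. The package collapses
the intervening chemistry (glucose quench, deacylation) into the assay's
operative rule:

- an **oxidized** library samples the charged pool — each gene's ligatable
  weight is abundance × charge fraction;
- a **control** (salt-treated) library samples the total pool — weight is
  abundance alone;
- the **spike-in** (a foreign yeast tRNA-Phe standing far from every
  cellular sequence) is added after oxidation at a fixed mass per sample,
  so its ligatable weight is the same in both treatments.

Because oxidation shrinks the cellular pool but not the spike, the spike's
share of an oxidized library rises as charging falls; this is what lets
the spike-normalized ratio of oxidized to control counts converge to the
true charged fraction. The simulator's `spike_in_fraction` is therefore
defined against the pre-treatment pool (default 0.05, i.e. the spike is 5%
of input molecules), a free parameter of the protocol since the actual
spike mass per 2 µg RNA is an experimental choice.

## Simulator

Each emitted read pair derives from exactly one ligated molecule; there is
no PCR-duplication model, matching a protocol with few (eight) PCR cycles
and no duplicate collapsing. Molecules are drawn multinomially from the
ligatable-weight distribution (genes uniform within an isodecoder), so a
truth table of ligated molecules per isodecoder accompanies every library
and totals exactly `n_read_pairs`.

The amplicon is the mature (CCA-ended) sequence with the two library
adaptors; mate 1 reads the insert 5′→3′ into the 3′ adaptor
(`TGGAATTCTCGGGTGCCAAGG`), mate 2 reads the reverse complement into the RT
adaptor (`AGATCGGAAGAGCGTCGTGTAGGGA`); both are 75 nt with constant Q40
qualities. Reverse-transcriptase misincorporation at methylated adenines
(the m1A58 artifact) is modeled as a substitution applied to the molecule
before both mates are taken: by default one site per gene, the 3′-most A
in the 55–60 nt window of the mature sequence, mutated with probability
`misincorporation_rate` (0.05 in the study conditions). Sequencing errors
beyond these designated sites, quality-score realism and RT truncation are
deliberately not modeled (a truncation-rate parameter exists, default 0);
consequently the preprocessing and alignment results on synthetic data are
cleaner than on real libraries, and passing tests demonstrate estimator
correctness under the assay's operative logic, not robustness to
instrument noise.

The synthetic reference generator emits 20 isodecoders (including
Gln-CTG, Gln-TTG and distinct iMet-CAT / Met-CAT groups) of random
tRNA-length sequences (72–90 nt) carrying their anticodon at positions
35–37, pairwise separated by ≥5 mismatches over the 3′-anchored overlap so
that one-mismatch alignment cannot cross isodecoders; within an
isodecoder, one gene copy is an exact duplicate or a 1-substitution
variant, exercising deduplication and within-isodecoder multimapping.
Real tRNA families are not this well separated everywhere; ambiguous
cross-isodecoder reads on real data would be set aside (see below), which
the conservative discard policy anticipates.

The study profile used for recovery runs sets the two glutamine
isodecoders to charge fraction 0.05 — the selective-uncharging condition —
with the others cycling 0.25/0.50/0.75/0.95, so the grid spans 0.05–0.95;
abundances are uneven (≈0.5–9% of the pool), with two isodecoders
deliberately below 1% to exercise low-abundance reporting.

qPCR simulation: Ct = baseline − log_base(template) + N(0, ct_noise_sd),
with template ∝ abundance (non-oxidized) or abundance × fraction
(oxidized) and the spike Ct at baseline + noise. Zero template reports the
Ct ceiling (default 40 cycles) with a flag, never infinity.

## Read processing and alignment

3′ adaptors are trimmed from each mate where a prefix of the adaptor (≥8
nt, ≤1 mismatch) matches; pairs whose mate 1 falls under 20 nt are
discarded as `too_short`. Mates merge when they overlap by ≥15 nt with ≤2
disagreements, resolved toward the higher-quality call; adaptor remnants
shorter than the 8 nt trim minimum are removed by the merge itself, since
mate-1 bases past the mate-2 end (and mate-2 bases before the mate-1
start) can only be read-through. Non-overlapping pairs fall back to
mate 1.

Because ligation fixes the 3′ end, alignment is an ungapped 3′-anchored
Hamming comparison against every mature reference sequence, allowing 5′
truncation of the read, overlap ≥20 nt and at most one mismatch (N counts
as a mismatch). This deterministic matcher replaces a general-purpose
aligner: tRNA+CCA amplicons are short, the anchor removes placement
ambiguity, and exactness permits oracle testing (the suite checks it
against an exhaustive scan on tens of thousands of reads). Ties at the
best (mismatches, overlap) spanning only one isodecoder's genes count for
that isodecoder; ties spanning several isodecoders are tallied as
ambiguous and excluded from counts — a conservative, integral-count policy
chosen over fractional splitting. Status tallies always sum to the library
size.

## Quantification

Charge ratio: each isodecoder count is divided by its own library's
spike-in count; the oxidized-over-control quotient of these normalized
abundances is the estimator. The spike-in is a per-sample internal
standard, so this single factor absorbs depth and ligation-efficiency
differences; library size is retained as a QC covariate, with a warning
when the spike and library-size scale factors disagree more than 3-fold.
Ratios are clamped to [0, 1] (raw values preserved with a `clamped` flag).
Isodecoders with fewer than `min_control_reads` (default 100) control
reads are reported absent with a `low_coverage` flag — the rule that
excludes poorly covered isodecoders from whole-compartment profiling
rather than reporting unstable ratios. A spike-in count below
`spike_floor` (default 100) in either library aborts normalization.

qPCR: fractions are base^(ΔCt_nonox − ΔCt_ox) with the spike ΔCt
subtraction performed within-sample before the cross-treatment
difference; the amplification base defaults to 2 (100% efficiency, with a
per-call override). Oxidized-arm Cts at the ceiling report fraction 0
with a `ceiling` flag; positive exponents clamp to 1.

Group comparisons mirror the two designs used with such measurements: a
paired two-sided t test, and one-way ANOVA followed by pairwise
comparisons adjusted by the Holm–Šídák step-down (i-th smallest of m raw
p values → 1 − (1 − p)^(m − i + 1), monotone). All-zero paired
differences report t = 0, p = 1; a zero-variance nonzero difference is
flagged `degenerate` with p reported as 0, i.e. below machine resolution.

## PolyQ tools and reporter constructs

`scan_polyq` returns all maximal glutamine runs ≥ `min_len` (default 10,
the census criterion) with 1-based starts; X breaks runs. The census
counts each protein once and reports the overall glutamine residue
fraction; its headline numbers depend entirely on the proteome release
supplied, so the package reports its input set rather than shipping one.

The reporter constructs are synthetic stand-ins, generated
deterministically from a fixed seed, for sequences that are not bundled
(HTT exon 1, GFP, Renilla luciferase): what carries the logic is
structure, not identity. `polyq_gfp` is ATG + an HTT-exon-1-like flank +
(CAG)n (n = 36 by default, a mildly pathogenic length) + a proline-rich
flank + a GGGGSGGGGS linker + an ATG-less marker ORF ending in the GFP
C-terminal signature DELYK, all in frame 0. The `*_minus1` variants
delete one nucleotide at the insert's 3′ end — downstream of the tract,
upstream of the linker — so the marker is reached only when the ribosome
slips one nucleotide backward within the tract, re-entering the (GCA)n
alanine frame; the luciferase-like control of equal insert length has no
tract and its −1 frame is engineered stop-free so a slip anywhere can
reach the marker. Frame analysis translates from the start codon with the
shift applied at the tract (or slip-region) 5′ boundary and reports which
of {0, −1, +1} reach the marker's end stop-free, plus the tract peptide
per frame (polyQ in frame 0, polyA in −1).

Two numerical details of the stand-in generator are worth recording.
First, a codon followed by an A-initial codon after methionine always
creates a −1-frame TGA (ATG + A··), so Met cannot precede K/N/I/T/M in
any peptide that must stay stop-free in the −1 frame; the stand-in
peptides avoid those digrams, and codon selection is a seeded
backtracking search rather than a greedy draw. Second, the marker ORF
carries explicitly engineered stop codons in its −1 and +1 internal
readings (CTT·AAA and GTA·AAA junctions), making the blocked frames a
designed property instead of a statistical accident of codon choice.

## Media helper

Concentrations for fractional DMEM formulations are recomputed from the
standard high-glucose DMEM amino-acid table (mg/L and the molar mass of
the supplied salt form): 5% of formulation gives 199.8 µM glutamine and
10.05 µM methionine, quoted as 200 and 10 µM.

## Problem sizes and defaults

Recovery runs use two libraries of 200,000 pairs (spike fraction 0.05,
misincorporation 0.05) on the 20-isodecoder reference; the qualitative
selective-uncharging ranking is also checked at 40,000 pairs, and the
monotonicity property averages 10 seeds of 4,000-pair libraries on a
6-isodecoder reference. At these sizes the maximum charge-ratio error at
abundance ≥1% is ≈0.02–0.03, dominated by binomial noise on the rarest
included isodecoders; it scales as n^(−1/2).

## Known limitations

- No gapped alignment or quality-aware scoring; RT truncations and
  general sequencing errors are outside the model.
- Cross-isodecoder multimappers are discarded, not fractionally assigned;
  on references with near-identical isodecoders this undercounts both
  libraries equally, leaving ratios unbiased but reducing coverage.
- Wobble decoding is not modeled: anticodon→codon is strict reverse
  complement.
- The polyQ census and the 5% DMEM helper reproduce published summary
  figures only against the corresponding proteome release / formulation.
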