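# Methods

`ribostruct` re-implements, as a tested pipeline on synthetic data with known
ground truth, the computational analysis linking in vivo RNA structure
(SHAPE-Structure-seq) to translation efficiency and subgenome asymmetry in an
allotetraploid transcriptome, through riboSNitch identification and
population-level selection statistics. This note documents the models, the
defaults and why they were chosen, the numerical conventions, and what the
synthetic data do and do not establish about real data.

## SHAPE reactivity from RT-stop counts

Per transcript, channel (±reagent) and replicate, the per-nucleotide stop
rate is `stops[i] / coverage[i]`; positions with coverage below
`min_coverage` (default 50) are missing. Raw reactivity is the
background-subtracted excess `max(0, plus_rate − minus_rate)`, missing
wherever either channel is missing. The plain stop-rate estimator is used
rather than a log-ratio (drop-off) estimator; the two agree when per-position
stop probabilities are small and independent, which is also the regime the
simulator generates.

**2–8 % normalization.** Within a transcript, the top 2 % of defined raw
values (count `ceil(0.02·n)`) are excluded as outliers and all values are
divided by the mean of the next 8 % (count `round-half-up(0.08·n)`). Ties are
broken by value then position so results are bit-reproducible. Transcripts
with fewer than 20 defined positions or a zero divisor are dropped with a
warning. Worked example: raw values 0…99 exclude {99, 98} and divide by
mean(90…97) = 93.5.

Replicates are normalized independently and merged position-wise by the mean
of defined values; a position missing in one replicate takes the other's
value. The mean pairwise Pearson correlation between replicates is reported
per transcript as a reproducibility QC. Missingness only propagates forward:
no stage re-defines a masked position.

## Secondary-structure model and folding engine

The ensemble is the set of pseudoknot-free structures over canonical pairs
{GC, AU, GU} with hairpin loops of at least 3 nt. The energy of a structure
is pair-additive:

    E(s) = Σ_pairs e(type) + Σ_{i paired} g(i),
    e(GC) = −3, e(AU) = −2, e(GU) = −1 (configurable),
    g(i) = m·ln(reactivity(i) + 1) + b  (Deigan form; m = 1.8, b = −0.6,
                                         0 where reactivity is missing).

Boltzmann weights use `exp(−E/kT)` with `kT = 0.6`, a free scale parameter.
This simplified model — not the full nearest-neighbour parameterization — is
deliberate: it makes the exhaustive-enumeration oracle exact and
desk-runnable, and the analyses built on top (BPP comparisons, PPV,
riboSNitch calling) are engine-agnostic. The energy model is a plug-in
dataclass, so a richer model can be substituted without touching the DP.

**Dynamic programmes.** The MFE structure uses the leftmost-base
decomposition with a deterministic traceback (prefer unpaired, then the
smallest pairing partner; ties at 1e−9). Base-pairing probabilities come
from an exact inside–outside algorithm over the same unambiguous grammar
(`Z(i,j) = Z(i+1,j) + Σ_k q(i,k)·Z(i+1,k−1)·Z(k+1,j)`), O(n³) time. Weights
are rescaled per base, anchored at the MFE, so partition values stay inside
double range for window-sized inputs; probabilities are scale-invariant.
`bpp[i]` is the probability that nucleotide *i* is paired to any partner
(the complement of single-strandedness). The test suite checks the DP
against full enumeration to 1e−9 on hundreds of random sequences up to 18 nt
and cross-checks pairedness classification against ViennaRNA on hairpin
fixtures.

**Windowing.** Transcripts longer than `fold_window` (default 300 nt) are
folded in sliding windows with step 150; per-nucleotide BPP is averaged over
covering windows. The MFE dot-bracket of a long transcript is assembled from
non-overlapping 300-nt blocks so the pair set stays nested. Long-range pairs
across block boundaries are therefore invisible — a documented limitation
shared with any windowed fold.

**Probing truth.** The simulator modifies nucleotides according to
ensemble-majority pairedness (`bpp > 0.5`) of the structure used as truth,
not the single MFE structure, because the chemical probe sees the Boltzmann
ensemble. Coverage is Poisson; (+) stops are Binomial(coverage,
background + mod_rate by paired status), (−) stops Binomial(coverage,
background); stops are independent per position (no reverse-transcriptase
drop-off cascade) — matching the reactivity estimator's assumptions, and a
known simplification relative to real libraries.

## Translation efficiency and codon metrics

Counts are length-normalized to a per-million scale per replicate
(TPM-style; a non-length-normalized mode exists since within-pair ratios are
length-robust). TE is polysome abundance over RNA abundance per replicate;
the per-transcript point estimate is the mean of replicate TEs and is
missing if RNA abundance is zero in any replicate. Differential TE between
homoeologs is a two-sample Student t test on per-replicate log2 TEs followed
by Benjamini–Hochberg correction across pairs; the log2 TE ratio estimate is
the difference of mean log2 TEs (the log scale is also what the recovery
benchmark measures, since TE is a ratio quantity). Covariate correlations
(GC content, CAI, tAI, RNA abundance) are Pearson correlations against
log2 TE on pairwise-complete observations.

CAI is the geometric mean of relative adaptiveness `r_i = f_i / max(f_j)`
over synonymous codons; tAI the geometric mean of codon weights `w_k`
normalized to max 1. Both are computed in log space; stop codons are
excluded and N-containing codons skipped with `n` decremented.

The metagene profile rescales each transcript's 5′UTR/CDS/3′UTR to fixed
bins (50/100/50) and averages the top and bottom TE decile position-wise;
bins narrower than the region sample the nearest position. The 3-nt
periodicity score is the magnitude of the discrete Fourier component at
period 3 of the CDS-restricted profile, normalized by the signal sum; it is
1 for a pure codon-phase signal, 0 for a flat one, and codons containing a
missing position are dropped whole so the reading frame is preserved.

## Homoeolog asymmetry

Per pair, structural asymmetry is a two-sample Wilcoxon rank-sum test on the
per-nucleotide BPP vectors of the two homoeologs (chosen because homoeolog
lengths differ), with direction from the mean difference and pairs under 20
defined positions excluded. Treating nucleotides as exchangeable units
ignores the strong positional autocorrelation of BPP along a transcript, so
the per-pair p-values are approximate; a per-transcript-mean mode is
provided for a caveat-free direction call. Structure–translation coupling is
the Pearson correlation of |Δ mean BPP| against |Δ log2 TE| across pairs,
globally, per region, and per user-supplied functional group (groups under
10 pairs excluded; per-group significance after BH).

## SNVs, eSDC and riboSNitch calling

Homoeolog pairs are aligned globally with affine gaps (match +1, mismatch
−1, first gap column −4, each additional −1) through Biopython's pairwise
aligner, which is deterministic and matches an exhaustive-alignment oracle
on small inputs. SNVs are aligned mismatch columns with both bases in ACGU
(columns containing N are dropped); indels are maximal gap runs; transitions
are A↔G and C↔U. Genic region is assigned from the A-subgenome annotation;
disagreement with the B annotation is recorded and flagged.

eSDC = (1 − Pearson r) · √L over the L alignment columns where both
reactivity profiles are defined (≥ 20 required; exponent configurable). It
inherits Pearson's invariance to shifting and rescaling either profile.

**riboSNitch test.** For each SNV (SNVs closer than window/2 are clustered,
tested jointly at the cluster centre and flagged non-isolated), the
absolute A−B differences of BPP and of reactivity inside a ±50-column
window are each compared against the same pair's outside-window differences
with a one-sided Wilcoxon rank-sum ("is the local disruption larger than
this pair's own noise floor?"). A paired signed-rank test on the raw
differences was rejected during design: a helix relocation moves BPP up at
the new stem and down at the displaced one, so signed differences cancel
even when the structure change is large. The call requires both signals
significant at α = 0.05 **and** both effect sizes (mean |difference| inside
minus outside) ≥ 0.1; mean rather than median, because a flip that
rearranges a third of the window must still register against an unchanged
majority. BH-adjusted mode is available by flag. SNVs with fewer than 20
defined columns inside or outside the window stay untested and are excluded
from riboSNitch ratios (a strict mode keeps them in the denominator).

**Constructed flip fixtures.** The power benchmark uses a bistable switch:
a G-run (P1), U-run (P2), C-run (P3) and A-run (P4) arranged so stem S1
(P1–P3) and stem S2 (P2–P4) mutually cross, and are therefore strictly
exclusive in a pseudoknot-free ensemble — in a pair-additive model this
geometric exclusion is the only way to prevent the ensemble from "splitting"
a switch between both helices. Filler is N, which never pairs. Allele A
favours S1; a single G→A substitution in P1 removes one GC pair and tips the
ensemble to S2, flipping the paired status of ~38 positions. Each fixture is
verified through the folding engine (|ΔBPP| ≥ 0.5 at ≥ 10 positions) before
it enters the power denominator. Null fixtures are a single G/C hairpin with
an A→U substitution in the N-filler tail, which has no pairing partner by
construction.

## Population genetics

Allele frequencies are `f_i = c(i)/Σc(i)` per subpopulation, with diploid
genotypes contributing two counts and ties for the major allele broken
alphabetically (A<C<G<U). F_ST = σ²_π / (π̄(1−π̄)) where π̄ and σ²_π are the
mean and **population** variance (divide by the number of subpopulations; a
sample-variance mode exists) of the tracked allele's frequency — the global
major allele's, an arbitrary choice for biallelic sites since F_ST is
symmetric under allele swap (asserted by test). F_ST is clipped to [0, 1]
and missing when π̄ ∈ {0, 1}. The conservation ratio of an SNV class on a
transcript is c(major)/c(total): the fraction of that class's SNVs whose
reference-pair allele equals the major allele of the reference
subpopulation. Class contrasts use Student's t or Wilcoxon rank-sum with ≥ 3
values per class.

The population simulator draws diploid genotypes binomially. riboSNitch
sites get divergent reference-allele frequencies (0.95 / 0.28 / 0.05 across
the three subpopulations, mirroring a domestication sweep in a cultivated
group, its domesticated wild relative and the wild group); other sites share
one near-fixation frequency drawn from Beta(18, 2) — subgenome-diagnostic
variants are expected to be close to fixed within a subspecies. Frequency
recovery is reported as per-subpopulation RMSE across sites with a 0.05
bound at 50 accessions per subpopulation: 0.05 = √(0.25/100) is the
worst-case binomial standard error at 100 chromosomes, so it bounds the RMSE
but not the per-site maximum (which grows with the number of sites under any
correct implementation).

## Synthetic study conditions

The generator defaults define the study conditions: 4.58 % substitution rate
between subgenomes with a 2:1 transition:transversion weight; 1–3 nt indels
at rate 0.002/nt placed ≥ 10 nt from region boundaries (CDS length stays a
multiple of 3); per-pair log2 TE differences ~ N(0, 1) (translation
asymmetry in the motivating system is large — roughly half of pairs differ
significantly); negative-binomial counts with dispersion 0.05 over three
replicates (typical bulk-RNA biological replication); modification rates
0.10 (unpaired) vs 0.01 (paired) over a 0.02 background at Poisson coverage
200 with two probing replicates; subpopulation sizes 13/29/28 accessions.
Every generator draws from its own `numpy` Generator seeded with
`[stream_id, seed]`, so runs are fully deterministic and stages independent.

Problem sizes used by the shipped benchmarks and the acceptance script — 50
pairs for TE recovery, ≥ 5000 positions for reactivity AUC, 20 flip and 40
null fixtures for riboSNitch power/FPR, 40 sites × 50 accessions/pop for
frequency recovery, 1000 pairs for the TE null, 12-pair / 150-nt transcripts
for the end-to-end fixture — are the package's choice of a desk-scale
design; all statistics scale with the usual √n behaviour.

**What passing these benchmarks does not show.** The simulator omits
sequencing error, alignment ambiguity, RT drop-off cascades, isoform
mixtures, adduct-context bias, and the full thermodynamics of real RNA; the
energy model is pair-additive. Recovery on this synthetic data demonstrates
that the estimators and tests are implemented correctly and calibrated under
their own assumptions — not that those assumptions hold for any particular
real library.

## Numerical conventions

Internal coordinates are 0-based half-open everywhere; GFF3, CT and VCF are
converted at the format boundary. All tie-breaks are deterministic (value
then position in normalization; unpaired-then-smallest-partner in traceback;
alphabetical major allele). Degenerate inputs return missing values rather
than raising wherever the quantity is a statistic (empty regions, zero
variance, monomorphic F_ST); contract violations (stops > coverage,
unbalanced dot-brackets, unknown config keys) raise with the offending
file/line/field. Two pipeline runs with the same config produce
byte-identical outputs.
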