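# Methods

This note documents the models, rules and numerical choices behind
`knobminer`, and what the synthetic data generator does and does not
emulate.

## The biological setting

Cattle have a small heavy-chain gene-segment repertoire (≈10 V, 10 D, 4 J;
the plain combinatorial product is 400, although the literature quotes a
theoretical diversity of ≈4,000 for cattle — the package implements the
arithmetic and documents the discrepancy rather than resolving it; for the
human counts 55×23×6 the product is 7,590). Diversity is recovered through
heavy somatic hypermutation (SHM) and, in a subset of rearrangements,
through an ultralong CDRH3: a β-ribbon stalk presenting a disulphide-rich
knob domain encoded by IGHD8-2. The germline knob core carries four
cysteines and is rich in glycine, tyrosine and serine whose codons are one
substitution away from TGT/TGC, so SHM preferentially creates additional
cysteines; even cysteine counts are favoured because cysteines function in
disulphide pairs.

## Synthetic repertoire generator

No raw reads are deposited for this kind of experiment, so the generator is
a first-class module that emulates the statistical structure the pipeline
assumes and plants per-clone ground truth.

**Germline stand-in.** The bundled `GermlineSet` is synthetic (10 V, 10 D,
4 J, matching the approximate bovine counts) and explicitly labelled as a
stand-in; real germlines can be loaded from FASTA. The ultralong V
contributes a 12-residue ascending stalk containing two tandem copies of a
12-nt probe standing in for the duplicated IGHV1-7 portion that marks
ultralong rearrangements; the IGHD8-2 stand-in is a 50-residue G/Y/S-rich
core with exactly four cysteines ending in the knob C-terminal anchor
`...CVA`; the ultralong J contributes the descending stalk `YIYAYEW`, whose
aromatic/aliphatic alternation drives the boundary rule. Gly/Tyr/Ser are
encoded with codons one substitution from TGT, mirroring the codon bias of
the real segment.

**Amplicon anatomy.** Each read is
`adaptor + 8-nt barcode + framework-3 primer region + CDRH3 + framework-4
region`. The printed forward primer ends two nucleotides into the conserved
framework-3 cysteine codon; the generator embeds the primer region up to
the `...TAYTAC` codon boundary so that the translated anchors (`DSATYY`
upstream, `LL[V/I]TVSS` downstream — a template leucine codon plus the
reverse-complemented reverse primer) bound *exactly* the planted CDRH3.
This keeps the strictly-between-motifs extraction contract and the planted
truth consistent; the conserved junction cysteine is treated as the first
CDRH3 residue. IUPAC degeneracies (M, Y, R) are expanded uniformly at
random per read, since primer pools are mixtures.

**Clonal structure.** Defaults are the study conditions the pipeline
targets: 3,559 unique CDRH3; ultralong fraction 0.043; the ultralong
compartment organised into 20 clonal families holding half of its members
(family sizes ≥2, remainder singleton lineages). Every lineage founder
diverges from the germline core at a fixed count of
`round(0.35 × 44)` = 15 of the 44 mutable core sites (the four cysteines
and the `VA` anchor are preserved), replacing residues with draws from a
cysteine-free alphabet. The deterministic mutation count keeps
between-lineage identity narrowly distributed (~60 ± 3 %), comfortably
below the 75 % clonotype threshold, while retaining enough germline core
for cysteine mapping (score floor: half the core self-score). Cysteine
gains are applied **in pairs** (disulphide partners): the number of extra
pairs is Binomial(2, min(0.85, 0.15·(cys_bias−1))) per founder, which
produces the observed preference for even knob cysteine counts.

**SHM.** Members of a lineage apply independent per-site substitutions at
`shm_rate` (default 0.01/nt), with the substitution that converts a
Gly/Tyr/Ser codon to a cysteine codon weighted by `cys_bias` (default 5).
Mutations creating stop codons are redrawn — nonsense variants are neither
expressed nor selected, and stop-containing reads would be discarded by the
extraction stage anyway. The descending stalk and the knob C-terminal
anchor are SHM-cold, reflecting the structural conservation of the stalk;
this is what makes planted knob spans recoverable at ≥99 %. With
`shm_rate = 0` all somatic change (including lineage divergence) is
switched off and every sequence is an exact germline V-D-J concatenation.
When SHM is active, records are forced to be unique nucleotide sequences —
the unit of the repertoire is the unique CDRH3, with read depth supplying
multiplicity via a geometric(0.3) copy-number law.

**Error channel.** Substitutions and indels are injected per base at the
configured rates; positions inside homopolymer runs of length ≥3 receive a
5× indel multiplier (Ion-Torrent-like profile; the magnitude is a package
choice). Qualities are constant Q30 placeholders — the processing chain
never uses them.

**What the generator does not emulate:** junctional trimming/N-additions
(ultralong clones share one length; regular diversity comes from segment
choice and SHM), PCR chimeras, length-biased amplification (recognised as a
real phenomenon, deliberately off by default), paired-end structure. A pass
on synthetic data therefore demonstrates the correctness of the processing
logic under the stated statistical assumptions, not performance on real
Ion-Torrent data.

## Read processing

Extraction translates each read in all three frames and searches all of
them jointly; a frame qualifies if it yields a motif-bounded, stop-free
region. The CDRH3 is the span strictly between `DSATYY` and the earliest of
the two literal downstream motifs `LLVTVSS`/`LLITVSS` (the degenerate
bracket expands to exactly these two strings). Anchors are primer-encoded,
not somatic, so they are excluded; by convention the extracted region is
reported as Kabat H93–H102. Reads qualifying in multiple frames are
discarded with a reason code (truth is unknowable), as are reads with an
ambiguous base inside the CDRH3 span. Deduplication is exact at the
nucleotide level per sample, sorted by copy number then sequence.
Coordinates are 0-based half-open everywhere.

Demultiplexing reads the barcode at the fixed offset after the adaptor and
validates that barcodes are mutually separated by more than twice the
allowed mismatch count, so assignment is unambiguous.

## Ultralong classification

The length criterion is strict (`> 90` bp) and is measured on the
motif-bounded CDRH3 nucleotide span (the threshold's reference interval is
not stated more precisely anywhere; this is the package's reading).
Duplication evidence — two non-overlapping matches of the IGHV1-7-portion
probe with at most one mismatch each (SHM can hit the probe) — is optional
because length alone is described as sufficient for identification. The
probe itself is a required configuration value with a bundled synthetic
default, because the real duplicated sequence is not published in a usable
form.

## Clonotyping

Identity comes from one optimal global alignment with match +1, mismatch 0,
gap open −10, gap extension −1; identity = 100 × matches / alignment
columns, so gaps count against identity — length differences between
clonally related sequences must penalise. Clusters are single-linkage
(connected components of the threshold graph): no algorithmic arbitrariness
and invariance to input order. The threshold defaults to ≥75 % (`geq`),
with a `gt` mode available because the two natural readings ("≥75 %
homology" vs "greater than 75 % identity") differ exactly at the boundary.
Clonotype counting treats clusters of size ≥2 as clonotypes and the rest as
singletons. Clustering operates on the full CDRH3 by default with a
knob-only option.

## Knob boundaries

Knob start: the residue immediately preceding the first germline cysteine
(read as "the single preceding residue"). Germline cysteines are located by
locally aligning the IGHD8-2 core to the CDRH3 (same scoring as above);
positions aligned to core cysteines are reported even when mutated away
from cysteine (with a flag), and an alignment scoring below half the core's
self-score raises a "core not found" error. Knob end: scanning after the
*last* germline cysteine (to avoid matching intra-knob aromatics), find the
first aromatic-led run of ≥3 residues alternating between the aromatic
{F, W, Y} and aliphatic {A, V, L, I} classes; the knob ends after the last
aliphatic residue preceding that run. Histidine and methionine belong to
neither class; the classes and the run length are configurable because no
formal definition exists — three alternating residues is the shortest
unambiguous pattern, and requiring the run to begin with an aromatic
residue prevents a trailing knob aliphatic from being absorbed into the
stalk. Without any such run the knob extends to the CDRH3 end (descending
stalk empty) with a warning rather than an error.

## Constructs and digestion

CDRH3–ScFc: `leader + CDRH3 + template`, where the template must contain a
TEV site and a poly-His tract; the bundled template is a labelled synthetic
stub (the real ScFc tag sequence is supplementary-only and can be passed
in). Fab–knob: `acceptor[:i] + ENLYFQG + knob + ENLYFQG + acceptor[i:]`.
TEV cleaves after the Q of every `ENLYFQ` followed by G or S; fragments
concatenate exactly to the input, and the released knob fragment carries
the G/S remnant at its N-terminus and `ENLYFQ` at its C-terminus — remnant
bookkeeping is explicit in the fragment strings rather than assuming how
many residues the excised peptide retains.

## Mass prediction

Formulas are residue sums plus one water (via pyteomics' standard residue
table); each disulphide removes two hydrogens, i.e. −2 × 1.00782503 Da,
linear in the bond count and independent of where the bonds form. By
default all cysteines are assumed oxidised in pairs
(`n = floor(nCys/2)`), overridable. m/z = (M + z·1.00727646)/z. Isotope
envelopes are computed by convolving per-element isotope distributions on
the nucleon grid (binary exponentiation with pruning at 1e-12), peaks
spaced one neutron mass (1.00866491588 Da)/z above the monoisotopic peak,
normalised to a maximum of 1 and truncated at relative abundance 1e-4.
Constants are pinned explicitly because vendor software normally hides
them. Chromatographic retention, MS/MS fragments and raw-spectrum
deconvolution are out of scope.

## Binding analytics

The single-cycle protocol defaults to seven 3-fold dilutions from 1 µM
(lowest 1.37 nM), 230 s contact, and 1,800 s (peptides) or 10,000 s
(fusions) final dissociation, 1 Hz sampling, no inter-injection gap
(instrument-specific and unpublished; configurable). The sensorgram is the
closed-form piecewise 1:1 Langmuir solution — exact and fast; an
ODE-integrator cross-check lives in the tests only. Simulated data is
already reference-subtracted; bulk-shift and mass-transport terms are out
of model.

Fitting runs Levenberg–Marquardt in log10-parameter space from a 3×3 grid
of starts (log kon ∈ {3, 5, 7}, log koff ∈ {−5, −3, −1}, Rmax started at
the signal maximum), keeping the lowest residual (ties: lowest koff), with
a global Rmax. Standard errors come from the Gauss–Newton covariance by the
delta method. Fitted koff below 1.0e-5 s⁻¹ sets a determination-limit flag
rather than being truncated. On noiseless simulations the generating
parameters are recovered to better than 0.1 % relative; at 1 RU Gaussian
noise the median relative KD error over 50 replicates is well under 10 %
(both recomputed by `scripts/acceptance.py`).

The 4PL model `y = bottom + (top−bottom)/(1 + (x/midpoint)^(−hill))` is
fitted with the midpoint in log space and both Hill-sign starts, covering
saturation (hill > 0) and inhibition (hill < 0) in one form; |hill| within
[0.5, 2] sets an in-range flag. A background-subtraction helper removes the
mean of designated background wells. Cheng–Prusoff:
`Ki = IC50/(1 + [R]/KDapp)`; an assay run at `[R] = KDapp` halves the IC50,
and Ki → IC50 as [R] → 0.

## Pipeline sizes and determinism

The default end-to-end run (3,559 unique clones, ≈12k noiseless reads,
~150 ultralong, ~11k pairwise alignments for clonotyping) completes in
seconds; the acceptance script, including the 50-replicate kinetics
recovery study, in well under a minute. These sizes were chosen so the full
repertoire-scale behaviour (unique counts, ultralong percentage, 20
clonotypes, ~50 % singleton fraction) is exercised at desk scale. All
randomness flows through explicit integer seeds
(`numpy.random.default_rng`); identical configurations give byte-identical
outputs apart from manifest timestamps.

## Known limitations

- The clonotype-count behaviour is demonstrated on the synthetic cohort;
  the real 154-sequence cohort is not redistributable, so agreement with
  the published clonotype partition cannot be checked directly.
- Fixed ultralong length (no junctional indel model) makes the ultralong
  length distribution degenerate; the >90 bp classifier is therefore
  trivially satisfied on synthetic data and its edge behaviour is tested
  with constructed sequences instead.
- The identity denominator uses one optimal alignment; co-optimal
  alignments with different column counts could in principle give slightly
  different identities for near-threshold pairs.
- The SCK fitter assumes the 1:1 model that generated the data;
  heterogeneous-ligand and mass-transport-limited regimes are out of scope.
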