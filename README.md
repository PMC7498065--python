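# knobminer

Bovine antibodies include a unique structural class in which the heavy-chain
CDR3 (CDRH3) is *ultralong*: an anti-parallel β-ribbon stalk presenting a
small (3–6 kDa), disulphide-stapled **knob domain** encoded by the IGHD8-2
germline segment. Isolated knob domains can bind antigen autonomously, which
makes them attractive peptide-sized binders that can be discovered by cow
immunisation, targeted CDRH3 amplicon sequencing and fusion-protein
screening.

`knobminer` implements the computational side of that discovery workflow as
a tested, reusable Python package:

1. **Synthetic repertoire generation** — ground-truthed CDRH3 repertoires
   (regular + ultralong clones, clonal families, cysteine-biased somatic
   hypermutation) and Ion-Torrent-style barcoded amplicon reads, so every
   downstream stage is testable without any sequencing data.
2. **Read processing** — FASTQ→FASTA, barcode demultiplexing, three-frame
   translation and extraction of the CDRH3 as the residues strictly between
   the translated primer motifs `DSATYY` and `LL[V/I]TVSS`, followed by
   exact nucleotide-level deduplication with copy numbers.
3. **Ultralong classification** — length criterion (>90 bp, strict) with an
   optional check for the characteristic tandem duplication of an IGHV1-7
   portion, plus cysteine profiling (`C-x3-C-x7-C…` patterns, parity).
4. **Clonotyping** — percent identity from one optimal global alignment
   (match +1, mismatch 0, gap open −10, extend −1; identity =
   100·matches/columns) and single-linkage clustering at ≥75 % identity.
5. **Knob annotation & construct design** — knob N-terminus = the residue
   immediately preceding the first germline cysteine; C-terminus = the final
   aliphatic residue before the alternating aromatic/aliphatic motif of the
   descending stalk; CDRH3–ScFc and Fab–knob fusion ORFs flanked by TEV
   sites (`ENLYFQ↓G/S`), with in-silico TEV digestion.
6. **Mass prediction** — elemental formulas, disulphide correction
   (−2 × 1.00782503 Da per bond, all cysteines paired by default), charge
   state m/z `(M + z·1.00727646)/z` and isotope envelopes by per-element
   convolution.
7. **Binding analytics** — single-cycle kinetics under the 1:1 Langmuir
   model `R(t) = Req + (R0 − Req)·e^{−(kon·C+koff)t}` with
   `Req = kon·C·Rmax/(kon·C + koff)` (seven 3-fold dilutions from 1 µM down
   to 1.37 nM, 230 s contact, 1 800 s/10 000 s dissociation), multi-start
   least-squares fitting with a `koff < 1e-5 s⁻¹` determination-limit flag,
   4-parameter-logistic FRET fits with a Hill-slope range check (0.5–2),
   and Cheng–Prusoff conversion `Ki = IC50 / (1 + [R]/KD)`.

## Worked example

```python
from Bio.Seq import Seq
from knobminer import (RepertoireConfig, builtin_germlines, simulate_repertoire,
                       emit_reads, demultiplex, process_sample, DEFAULT_BARCODES,
                       is_ultralong, cluster_clonotypes, annotate_knob,
                       MassPrediction, summary_report)

germlines = builtin_germlines()
records = simulate_repertoire(
    germlines, RepertoireConfig(n_clones=500, ultralong_fraction=0.1, seed=7))
reads = emit_reads(records, DEFAULT_BARCODES, seed=7)     # noiseless channel

bins = demultiplex(reads, list(DEFAULT_BARCODES), max_mismatch=1)
cdrs = [c for bc in DEFAULT_BARCODES for c in process_sample(bins[bc], bc)]
annotations = [is_ultralong(c) for c in cdrs]
ultralong = [c for c, a in zip(cdrs, annotations) if a.is_ultralong]

core_aa = str(Seq(germlines.ighd82_core.seq).translate())
knobs = {c.cdrh3_aa: annotate_knob(c.cdrh3_aa, core_aa) for c in ultralong}
clusters = cluster_clonotypes([c.cdrh3_aa for c in ultralong])
print(summary_report(cdrs, annotations, clusters, knobs))

knob = knobs[ultralong[0].cdrh3_aa]
pred = MassPrediction.predict(knob.knob)
print(knob.knob, pred.monoisotopic_mass, dict(pred.charge_states)[4])
```

prints

```
{'n_total_unique': 500, 'n_ultralong': 57, 'ultralong_pct': 11.4,
 'n_clonotypes': 14, 'n_singletons': 29,
 'fraction_in_clonotypes': 0.491..., 'ultralong_cys_parity': {'even': 39, 'odd': 18}}
SCPWGYQCFYASGYVSCQGYDTNCSLISGYMYDCVFYDGQSEGGYCVA 5303.0145 1326.7609
```

i.e. all 500 planted unique CDRH3 are recovered from the 1 795 noiseless
reads, 57 (11.4 %) are ultralong, they fall into 14 clonotypes at ≥75 %
identity with roughly half the sequences in multi-member clusters, knob
cysteine counts are predominantly even, and the first excised knob peptide
(6 cysteines → 3 disulphides) has a predicted monoisotopic mass of
5303.0145 Da, observed at m/z 1326.7609 in the 4+ charge state.

The same stages are available as a CLI
(`knobminer run|simulate|extract|classify|clonotype|mass|sck-sim|sck-fit|fret-fit|ki`),
driven by a declarative YAML configuration and emitting a `manifest.json`
with per-stage record counts and a configuration hash.

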