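"""Ground-truthed synthetic bovine CDRH3 repertoires and barcoded amplicon reads.

Bovine antibodies compensate for a small V/D/J gene-segment repertoire with
heavy somatic hypermutation (SHM) and, in a subset of rearrangements, an
ultralong CDRH3: an anti-parallel beta-ribbon stalk presenting a small,
disulphide-stapled "knob" domain encoded by the IGHD8-2 germline segment.
The germline knob core carries four cysteines and is rich in glycine,
tyrosine and serine codons that are a single nucleotide away from TGT/TGC,
so SHM readily adds further cysteine pairs.

This module simulates that repertoire structure, plants per-clone ground
truth (sequence, ultralong flag, knob span, copy number, sample barcode),
and emits Ion-Torrent-style barcoded amplicon reads so that every
downstream stage of the pipeline can be tested without external data.
No real raw reads are deposited for this kind of experiment; the bundled
germline set is a synthetic stand-in with the documented statistical
properties, loadable from FASTA so real germlines can be substituted.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class ConfigurationError(ValueError):
    """Raised when a simulation or processing configuration is invalid."""


# --------------------------------------------------------------------------
# Amplicon anatomy (Ion-Torrent barcoding PCR)
#
# read = adaptor + 8-nt barcode + framework-3 primer region + CDRH3 +
#        framework-4 region.  The forward primer region is embedded up to the
# ...TAYTAC codon boundary (the printed primer continues two nucleotides into
# the conserved FR3 cysteine codon); the framework-4 region is a template Leu
# codon followed by the reverse complement of the reverse primer, so the
# translated anchors are exactly DSATYY and LL[V/I]TVSS.
# --------------------------------------------------------------------------

ADAPTOR = "CCATCTCATCCCTGCGTGTCTCCGACTCAG"
BARCODE_LENGTH = 8
#: forward primer region with IUPAC degeneracy (M = A/C, Y = C/T)
FR3_PRIMER_REGION = "CGGACTCGGCCACMTAYTAC"
#: framework-4: template Leu + revcomp of reverse primer (R = A/G -> Val/Ile)
FR4_REGION = "CTGCTGRTCACCGTCTCGAGC"

DEFAULT_BARCODES = ("AAGGTTCC", "CCTTAAGG")

IUPAC_EXPANSION = {"M": "AC", "Y": "CT", "R": "AG"}

# One codon per amino acid; Gly/Tyr/Ser use codons one substitution away from
# TGT (cysteine), mirroring the codon bias of IGHD8-2.
AA_TO_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAG", "R": "CGT",
    "S": "AGT", "T": "ACT", "V": "GTG", "W": "TGG", "Y": "TAT",
}

STOP_CODONS = {"TAA", "TAG", "TGA"}
CYS_CODONS = ("TGT", "TGC")


def encode_peptide(aa: str) -> str:
    """Reverse-translate a peptide with the module's fixed codon table."""
    try:
        return "".join(AA_TO_CODON[a] for a in aa)
    except KeyError as exc:  # pragma: no cover - construction-time guard
        raise ValueError(f"cannot encode residue {exc}") from exc


def _cys_route(codon: str) -> tuple[int, str] | None:
    """Return (position, base) of the single substitution turning *codon*
    into a cysteine codon, or None if no such route exists."""
    for target in CYS_CODONS:
        diff = [i for i in range(3) if codon[i] != target[i]]
        if len(diff) == 1:
            return diff[0], target[diff[0]]
    return None


# --------------------------------------------------------------------------
# Germline set
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GermlineSegment:
    name: str
    seq: str
    role: str            # "V" | "D" | "J"
    tag: str = "regular"  # "regular" | "ultralong" | "IGHD8-2"


@dataclass
class GermlineSet:
    """V/D/J segments contributing to the CDRH3, plus the IGHV1-7-style
    duplication probe that marks ultralong rearrangements.

    Segment sequences here are the CDRH3-contributing portions only; the
    amplicon framework regions are fixed by the primers.
    """

    v_segments: list[GermlineSegment]
    d_segments: list[GermlineSegment]
    j_segments: list[GermlineSegment]
    ighv17_tail: str

    def __post_init__(self) -> None:
        for group, role in ((self.v_segments, "V"), (self.d_segments, "D"),
                            (self.j_segments, "J")):
            if not group:
                raise ConfigurationError(f"empty germline {role}-segment list")
            for seg in group:
                if set(seg.seq) - set("ACGT"):
                    raise ConfigurationError(
                        f"segment {seg.name} not over ACGT")
        core = self.ighd82_core
        n_cys = str(Seq(core.seq).translate()).count("C")
        if n_cys != 4:
            raise ConfigurationError(
                f"IGHD8-2-role segment must encode exactly 4 cysteines, "
                f"found {n_cys}")

    @property
    def ighd82_core(self) -> GermlineSegment:
        for seg in self.d_segments:
            if seg.tag == "IGHD8-2":
                return seg
        raise ConfigurationError("no D segment tagged IGHD8-2")

    @property
    def ultralong_v(self) -> GermlineSegment:
        for seg in self.v_segments:
            if seg.tag == "ultralong":
                return seg
        raise ConfigurationError("no V segment tagged ultralong")

    @property
    def ultralong_j(self) -> GermlineSegment:
        for seg in self.j_segments:
            if seg.tag == "ultralong":
                return seg
        raise ConfigurationError("no J segment tagged ultralong")

    def regular(self, role: str) -> list[GermlineSegment]:
        group = {"V": self.v_segments, "D": self.d_segments,
                 "J": self.j_segments}[role]
        return [s for s in group if s.tag == "regular"]

    # -- FASTA round trip ---------------------------------------------------
    def to_fasta(self, handle) -> None:
        close = False
        if isinstance(handle, str):
            handle, close = open(handle, "w"), True
        try:
            records = []
            for seg in (*self.v_segments, *self.d_segments, *self.j_segments):
                records.append(SeqRecord(
                    Seq(seg.seq), id=seg.name, description=f"role={seg.role} tag={seg.tag}"))
            records.append(SeqRecord(
                Seq(self.ighv17_tail), id="IGHV1-7-tail",
                description="role=probe tag=duplication"))
            SeqIO.write(records, handle, "fasta")
        finally:
            if close:
                handle.close()

    @classmethod
    def from_fasta(cls, handle) -> "GermlineSet":
        close = False
        if isinstance(handle, str):
            handle, close = open(handle), True
        try:
            vs, ds, js, probe = [], [], [], None
            for rec in SeqIO.parse(handle, "fasta"):
                fields = dict(f.split("=", 1) for f in rec.description.split()
                              if "=" in f)
                role, tag = fields.get("role", ""), fields.get("tag", "regular")
                if role == "probe":
                    probe = str(rec.seq)
                elif role == "V":
                    vs.append(GermlineSegment(rec.id, str(rec.seq), "V", tag))
                elif role == "D":
                    ds.append(GermlineSegment(rec.id, str(rec.seq), "D", tag))
                elif role == "J":
                    js.append(GermlineSegment(rec.id, str(rec.seq), "J", tag))
            if probe is None:
                raise ConfigurationError("germline FASTA lacks a probe record")
            return cls(vs, ds, js, probe)
        finally:
            if close:
                handle.close()


#: 12-nt IGHV1-7-tail stand-in; its tandem duplication marks ultralong
#: rearrangements (encodes the stalk repeat TSVH).
DUPLICATION_PROBE = "ACTAGCGTGCAC"

_UL_V_AA = "C" + "TSVH" + "TSVH" + "QKT"            # 12 aa ascending stalk
#: synthetic IGHD8-2 core: 50 aa, exactly 4 Cys, G/Y/S-rich, ends with the
#: knob C-terminal anchor ...CVA (final aliphatic before the descending stalk)
_CORE_AA = ("GYS" + "C" + "PDGYSYGYDSGYGS" + "C" + "SGYDTYGSYRSGYGYD" + "C"
            + "SGYDGYSNGRY" + "CVA")
_UL_J_AA = "YIYAYEW"                                 # descending stalk

assert len(_CORE_AA) == 50 and _CORE_AA.count("C") == 4

_REGULAR_V_AA = ["CAR", "CAK", "CTR", "CVR", "CGL", "CAH", "CSR", "CAN", "CLR"]
_REGULAR_D_AA = ["GYSSGY", "DTAMVG", "GSCYDC", "RGYYGD", "SSGWYG",
                 "DGYNYG", "GITGTT", "VDTAMY", "SGYDLY"]
_REGULAR_J_AA = ["YFDY", "AFDI", "GMDV"]


def builtin_germlines() -> GermlineSet:
    """The bundled synthetic stand-in germline set (10 V, 10 D, 4 J —
    matching the approximate bovine segment counts)."""
    vs = [GermlineSegment("IGHV1-7.syn",
                          "TGT" + DUPLICATION_PROBE + DUPLICATION_PROBE
                          + encode_peptide("QKT"), "V", "ultralong")]
    vs += [GermlineSegment(f"IGHV-R{i+1}.syn", encode_peptide(aa), "V")
           for i, aa in enumerate(_REGULAR_V_AA)]
    ds = [GermlineSegment("IGHD8-2.syn", encode_peptide(_CORE_AA), "D",
                          "IGHD8-2")]
    ds += [GermlineSegment(f"IGHD-R{i+1}.syn", encode_peptide(aa), "D")
           for i, aa in enumerate(_REGULAR_D_AA)]
    js = [GermlineSegment("IGHJ2-1.syn", encode_peptide(_UL_J_AA), "J",
                          "ultralong")]
    js += [GermlineSegment(f"IGHJ-R{i+1}.syn", encode_peptide(aa), "J")
           for i, aa in enumerate(_REGULAR_J_AA)]
    return GermlineSet(vs, ds, js, DUPLICATION_PROBE)


# --------------------------------------------------------------------------
# Repertoire configuration and truth records
# --------------------------------------------------------------------------

@dataclass
class RepertoireConfig:
    """Study conditions for the simulated repertoire.

    Defaults emulate the antigen-enriched bovine pool this pipeline targets:
    3,559 unique CDRH3 of which ~4.3% are ultralong, the ultralong
    compartment organised into 20 clonal families holding about half of its
    members (the remainder singleton lineages).
    """

    n_clones: int = 3559
    ultralong_fraction: float = 0.043
    shm_rate: float = 0.01
    cys_bias: float = 5.0
    clone_size_distribution: tuple = ("geometric", 0.3)
    seed: int = 0
    # clonal structure of the ultralong compartment
    n_families: int = 20
    family_fraction: float = 0.5
    #: fraction of mutable knob-core sites replaced in each lineage founder
    lineage_divergence: float = 0.35

    def validate(self) -> None:
        for name in ("ultralong_fraction", "family_fraction"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name}={p} outside [0, 1]")
        if not 0.0 <= self.shm_rate < 1.0:
            raise ConfigurationError(f"shm_rate={self.shm_rate} invalid")
        if self.n_clones < 1:
            raise ConfigurationError("n_clones must be >= 1")
        if self.cys_bias < 1.0:
            raise ConfigurationError("cys_bias must be >= 1")
        kind, *params = self.clone_size_distribution
        if kind != "geometric" or not 0 < params[0] <= 1:
            raise ConfigurationError(
                f"unsupported clone_size_distribution {self.clone_size_distribution}")


@dataclass
class TruthRecord:
    clone_id: str
    lineage_id: str
    cdrh3_nt: str
    cdrh3_aa: str
    is_ultralong: bool
    knob_span: tuple[int, int] | None
    sample_barcode: str
    copy_number: int


def truth_table(records: Sequence[TruthRecord]) -> "pandas.DataFrame":
    """Truth records as a DataFrame (column order is part of the contract)."""
    import pandas as pd

    rows = [{
        "clone_id": r.clone_id, "lineage_id": r.lineage_id,
        "sample_barcode": r.sample_barcode, "cdrh3_nt": r.cdrh3_nt,
        "cdrh3_aa": r.cdrh3_aa, "is_ultralong": r.is_ultralong,
        "knob_start": r.knob_span[0] if r.knob_span else -1,
        "knob_end": r.knob_span[1] if r.knob_span else -1,
        "copy_number": r.copy_number,
    } for r in records]
    return pd.DataFrame(rows, columns=[
        "clone_id", "lineage_id", "sample_barcode", "cdrh3_nt", "cdrh3_aa",
        "is_ultralong", "knob_start", "knob_end", "copy_number"])


# --------------------------------------------------------------------------
# Somatic hypermutation
# --------------------------------------------------------------------------

_FOUNDER_ALPHABET = "ADEFGHIKLMNPQRSTVWY"  # no Cys: cysteine gains are paired


def _mutate_sites(nt: list[str], rate: float, cys_bias: float,
                  rng: np.random.Generator, start: int, stop: int) -> None:
    """Independent per-site substitutions on nt[start:stop] (codon-aligned
    region assumed to begin at a codon boundary at index 0 of *nt*).

    The substitution creating TGT/TGC from a Gly/Tyr/Ser codon is weighted by
    *cys_bias*; codon changes that would introduce a stop are redrawn.
    """
    if rate <= 0:
        return
    for ci in range(0, len(nt) - 2, 3):
        if ci + 3 <= start or ci >= stop:
            continue
        codon = "".join(nt[ci:ci + 3])
        route = _cys_route(codon) if str(Seq(codon).translate()) in "GYS" else None
        for attempt in range(8):
            new = list(codon)
            changed = False
            for k in range(3):
                pos = ci + k
                if pos < start or pos >= stop:
                    continue
                base = new[k]
                weights = []
                alts = [b for b in "ACGT" if b != base]
                for b in alts:
                    w = rate / 3.0
                    if route is not None and route == (k, b):
                        w *= cys_bias
                    weights.append(min(w, 0.3))
                u = rng.random()
                acc = 0.0
                for b, w in zip(alts, weights):
                    acc += w
                    if u < acc:
                        new[k] = b
                        changed = True
                        break
            if not changed or "".join(new) not in STOP_CODONS:
                if changed:
                    nt[ci:ci + 3] = new
                break


def _shm(nt: str, rate: float, cys_bias: float, rng: np.random.Generator,
         stop_nt: int | None = None) -> str:
    """Apply SHM to nt[0:stop_nt] (default: whole sequence)."""
    sites = list(nt)
    _mutate_sites(sites, rate, cys_bias, rng, 0, stop_nt if stop_nt is not None else len(nt))
    return "".join(sites)


# --------------------------------------------------------------------------
# Repertoire simulation
# --------------------------------------------------------------------------

def _found_lineage(germlines: GermlineSet, config: RepertoireConfig,
                   rng: np.random.Generator) -> str:
    """Create an ultralong lineage founder nucleotide sequence.

    The knob core diverges from the germline IGHD8-2 at a fixed number of
    mutable sites (cysteines and the C-terminal VA anchor are preserved);
    additional cysteines are introduced in pairs, modelling disulphide
    partners; the stalks are left germline.
    """
    v = germlines.ultralong_v.seq
    j = germlines.ultralong_j.seq
    core = list(germlines.ighd82_core.seq)
    core_aa = str(Seq("".join(core)).translate())
    cys_idx = [i for i, a in enumerate(core_aa) if a == "C"]
    protected = set(cys_idx) | {len(core_aa) - 2, len(core_aa) - 1}
    eligible = [i for i in range(len(core_aa)) if i not in protected]

    n_mut = max(1, round(config.lineage_divergence * len(eligible)))
    for i in rng.choice(len(eligible), size=min(n_mut, len(eligible)),
                        replace=False):
        aa = _FOUNDER_ALPHABET[rng.integers(len(_FOUNDER_ALPHABET))]
        site = eligible[i]
        core[3 * site:3 * site + 3] = AA_TO_CODON[aa]

    if config.cys_bias > 1.0:
        p_pair = min(0.85, 0.15 * (config.cys_bias - 1.0))
        n_pairs = rng.binomial(2, p_pair)
        if n_pairs:
            routes = []
            for site in eligible:
                codon = "".join(core[3 * site:3 * site + 3])
                if str(Seq(codon).translate()) in "GYS":
                    r = _cys_route(codon)
                    if r is not None:
                        routes.append((site, r))
            rng.shuffle(routes)
            for site, (k, b) in routes[:2 * n_pairs]:
                core[3 * site + k] = b
    return v + "".join(core) + j


def _knob_span(germlines: GermlineSet) -> tuple[int, int]:
    v_len = len(germlines.ultralong_v.seq) // 3
    core_aa = str(Seq(germlines.ighd82_core.seq).translate())
    first_cys = core_aa.index("C")
    return (v_len + first_cys - 1, v_len + len(core_aa))


def simulate_repertoire(germlines: GermlineSet, config: RepertoireConfig,
                        barcodes: Sequence[str] = DEFAULT_BARCODES,
                        ) -> list[TruthRecord]:
    """Draw a ground-truthed repertoire of unique CDRH3 clones.

    Each clone is either a regular V-D-J rearrangement or a member of an
    ultralong lineage; per-clone copy numbers follow the configured
    clone-size law.  With ``shm_rate == 0`` no somatic change of any kind is
    applied and every sequence is an exact germline concatenation.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_ul = int(rng.binomial(config.n_clones, config.ultralong_fraction))
    n_regular = config.n_clones - n_ul

    # lineage plan for the ultralong compartment
    founders: list[str] = []
    membership: list[int] = []
    if n_ul:
        n_in_family = round(config.family_fraction * n_ul)
        n_fam = min(config.n_families, n_in_family // 2)
        sizes = [2] * n_fam
        extra = n_in_family - 2 * n_fam
        for _ in range(max(extra, 0)):
            sizes[rng.integers(n_fam)] += 1
        n_singletons = n_ul - sum(sizes)
        sizes += [1] * n_singletons
        divergence = config if config.shm_rate > 0 else dataclasses.replace(
            config, lineage_divergence=0.0, cys_bias=1.0)
        for li, size in enumerate(sizes):
            if config.shm_rate > 0:
                founders.append(_found_lineage(germlines, divergence, rng))
            else:
                founders.append(germlines.ultralong_v.seq
                                + germlines.ighd82_core.seq
                                + germlines.ultralong_j.seq)
            membership += [li] * size

    span = _knob_span(germlines)
    stalk_start_nt = 3 * (span[1] - 2)  # keep VA anchor + descending stalk cold
    records: list[TruthRecord] = []
    seen: set[str] = set()
    kind, p_geom = config.clone_size_distribution[0], config.clone_size_distribution[1]

    def draw_copies() -> int:
        return int(rng.geometric(p_geom))

    for ci, lineage in enumerate(membership):
        founder = founders[lineage]
        for _ in range(200):
            nt = _shm(founder, config.shm_rate, config.cys_bias, rng,
                      stop_nt=stalk_start_nt)
            if config.shm_rate == 0 or nt not in seen:
                break
        seen.add(nt)
        aa = str(Seq(nt).translate())
        records.append(TruthRecord(
            clone_id=f"UL{ci:05d}", lineage_id=f"L{lineage:04d}",
            cdrh3_nt=nt, cdrh3_aa=aa, is_ultralong=True, knob_span=span,
            sample_barcode=barcodes[int(rng.integers(len(barcodes)))],
            copy_number=draw_copies()))

    reg_v = germlines.regular("V")
    reg_d = germlines.regular("D")
    reg_j = germlines.regular("J")
    for ci in range(n_regular):
        for _ in range(200):
            v = reg_v[int(rng.integers(len(reg_v)))]
            d = reg_d[int(rng.integers(len(reg_d)))]
            j = reg_j[int(rng.integers(len(reg_j)))]
            nt = _shm(v.seq + d.seq + j.seq, config.shm_rate, config.cys_bias,
                      rng)
            if config.shm_rate == 0 or nt not in seen:
                break
        seen.add(nt)
        records.append(TruthRecord(
            clone_id=f"RG{ci:05d}", lineage_id=f"R{ci:05d}",
            cdrh3_nt=nt, cdrh3_aa=str(Seq(nt).translate()),
            is_ultralong=False, knob_span=None,
            sample_barcode=barcodes[int(rng.integers(len(barcodes)))],
            copy_number=draw_copies()))
    return records


# --------------------------------------------------------------------------
# Read emission
# --------------------------------------------------------------------------

def _expand_iupac(template: str, rng: np.random.Generator) -> str:
    out = []
    for b in template:
        choices = IUPAC_EXPANSION.get(b)
        out.append(b if choices is None else choices[int(rng.integers(len(choices)))])
    return "".join(out)


def _error_channel(nt: str, sub_rate: float, indel_rate: float,
                   homopolymer_multiplier: float,
                   rng: np.random.Generator) -> str:
    if sub_rate == 0 and indel_rate == 0:
        return nt
    # per-position homopolymer run length
    runs = np.ones(len(nt), dtype=int)
    i = 0
    while i < len(nt):
        j = i
        while j < len(nt) and nt[j] == nt[i]:
            j += 1
        runs[i:j] = j - i
        i = j
    out: list[str] = []
    for i, base in enumerate(nt):
        p_indel = indel_rate * (homopolymer_multiplier if runs[i] >= 3 else 1.0)
        if indel_rate and rng.random() < p_indel:
            if rng.random() < 0.5:
                continue                      # deletion
            out.append(base)                  # insertion: duplicate the base
            out.append(base)
            continue
        if sub_rate and rng.random() < sub_rate:
            alts = [b for b in "ACGT" if b != base]
            base = alts[int(rng.integers(3))]
        out.append(base)
    return "".join(out)


def emit_reads(records: Sequence[TruthRecord], barcodes: Sequence[str],
               sub_rate: float = 0.0, indel_rate: float = 0.0, seed: int = 0,
               depth: int | None = None, homopolymer_multiplier: float = 5.0,
               quality: int = 30) -> list[SeqRecord]:
    """Emit barcoded amplicon reads (one FASTQ record per sequenced copy).

    ``depth`` overrides the planted per-clone copy numbers.  Qualities are a
    constant Phred placeholder; the processing chain never uses them.
    """
    if sub_rate < 0 or indel_rate < 0:
        raise ConfigurationError("error rates must be non-negative")
    if len(set(barcodes)) != len(barcodes):
        raise ConfigurationError("barcode collision in barcode list")
    for bc in barcodes:
        if len(bc) != BARCODE_LENGTH or set(bc) - set("ACGT"):
            raise ConfigurationError(f"invalid barcode {bc!r}")
    known = set(barcodes)
    rng = np.random.default_rng(seed)
    reads: list[SeqRecord] = []
    for rec in records:
        if rec.sample_barcode not in known:
            raise ConfigurationError(
                f"record {rec.clone_id} barcode {rec.sample_barcode} not in "
                "barcode list")
        n = depth if depth is not None else rec.copy_number
        for copy in range(n):
            fr3 = _expand_iupac(FR3_PRIMER_REGION, rng)
            fr4 = _expand_iupac(FR4_REGION, rng)
            nt = ADAPTOR + rec.sample_barcode + fr3 + rec.cdrh3_nt + fr4
            nt = _error_channel(nt, sub_rate, indel_rate,
                                homopolymer_multiplier, rng)
            sr = SeqRecord(Seq(nt), id=f"{rec.clone_id}_r{copy}",
                           description="")
            sr.letter_annotations["phred_quality"] = [quality] * len(nt)
            reads.append(sr)
    return reads


def write_fastq(reads: Iterable[SeqRecord], handle) -> None:
    close = False
    if isinstance(handle, str):
        handle, close = open(handle, "w"), True
    try:
        SeqIO.write(reads, handle, "fastq")
    finally:
        if close:
            handle.close()


def reads_to_fastq_str(reads: Iterable[SeqRecord]) -> str:
    buf = io.StringIO()
    SeqIO.write(reads, buf, "fastq")
    return buf.getvalue()
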