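"""From raw barcoded amplicon reads to a deduplicated per-sample CDRH3 table.

The processing chain mirrors the deep-sequencing workflow for CDRH3
amplicon libraries: FASTQ -> FASTA, demultiplexing on the 8-nt barcode that
follows the sequencing adaptor, translation of each read in all three
frames, and extraction of the CDRH3 as the residues strictly between the
translated framework-3 and framework-4 primer motifs (DSATYY and
LL[V/I]TVSS).  Anchors are primer-encoded, not somatic, so they are not
part of the reported CDRH3; the extracted region corresponds to Kabat
H93-H102 by convention.  Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

from .synthetic_repertoire import ADAPTOR, BARCODE_LENGTH, ConfigurationError

logger = logging.getLogger(__name__)

UPSTREAM_MOTIF = "DSATYY"
#: the degenerate downstream anchor is exactly these two literal strings
DOWNSTREAM_MOTIFS = ("LLVTVSS", "LLITVSS")

# discard/skip reason codes
REASON_NO_UPSTREAM = "no_upstream_motif"
REASON_NO_DOWNSTREAM = "no_downstream_motif"
REASON_EMPTY_SPAN = "empty_span"
REASON_STOP_IN_CDR = "stop_in_cdrh3"
REASON_MULTI_FRAME = "multiple_qualifying_frames"
REASON_NO_FRAME = "no_qualifying_frame"
REASON_N_IN_CDR = "ambiguous_base_in_cdrh3"


@dataclass(frozen=True)
class CdrSequence:
    """A (deduplicated) CDRH3 observation within one sample."""

    sample_barcode: str
    cdrh3_nt: str
    cdrh3_aa: str
    frame: int
    copy_number: int = 1

    def __post_init__(self):
        if self.copy_number < 1:
            raise ValueError("copy_number must be >= 1")


# --------------------------------------------------------------------------
# FASTQ -> FASTA
# --------------------------------------------------------------------------

def fastq_to_fasta(in_handle, out_handle) -> int:
    """Convert FASTQ to FASTA, order-preserving, qualities dropped.

    Returns the number of records written.  A malformed 4-line block raises
    a parse error naming the record index.
    """
    close_in = close_out = False
    if isinstance(in_handle, str):
        in_handle, close_in = open(in_handle), True
    if isinstance(out_handle, str):
        out_handle, close_out = open(out_handle, "w"), True
    n = 0
    try:
        try:
            for rec in SeqIO.parse(in_handle, "fastq"):
                out_handle.write(f">{rec.id}\n{rec.seq}\n")
                n += 1
        except ValueError as exc:
            raise ValueError(f"malformed FASTQ at record {n}: {exc}") from exc
    finally:
        if close_in:
            in_handle.close()
        if close_out:
            out_handle.close()
    return n


# --------------------------------------------------------------------------
# Demultiplexing
# --------------------------------------------------------------------------

def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def validate_barcode_set(barcodes: Sequence[str], max_mismatch: int) -> None:
    if len(set(barcodes)) != len(barcodes):
        raise ConfigurationError("duplicate barcodes")
    for bc in barcodes:
        if len(bc) != BARCODE_LENGTH or set(bc) - set("ACGT"):
            raise ConfigurationError(f"invalid barcode {bc!r}")
    for i, a in enumerate(barcodes):
        for b in barcodes[i + 1:]:
            if _hamming(a, b) <= 2 * max_mismatch:
                raise ConfigurationError(
                    f"ambiguous barcode set: {a} and {b} are within "
                    f"2*max_mismatch={2 * max_mismatch}")


def demultiplex(reads: Iterable, barcodes: Sequence[str],
                max_mismatch: int = 1, adaptor: str = ADAPTOR) -> dict:
    """Partition reads into per-barcode bins plus an ``undetermined`` bin.

    The barcode is read at the fixed offset immediately after the adaptor.
    Accepts Bio.SeqRecord objects or (id, sequence) pairs.
    """
    validate_barcode_set(barcodes, max_mismatch)
    offset = len(adaptor)
    bins: dict = {bc: [] for bc in barcodes}
    bins["undetermined"] = []
    for read in reads:
        seq = str(read.seq) if hasattr(read, "seq") else read[1]
        observed = seq[offset:offset + BARCODE_LENGTH]
        best, best_d = None, max_mismatch + 1
        for bc in barcodes:
            d = _hamming(observed, bc)
            if d < best_d:
                best, best_d = bc, d
        bins[best if best is not None else "undetermined"].append(read)
    return bins


# --------------------------------------------------------------------------
# Translation and CDRH3 extraction
# --------------------------------------------------------------------------

def translate_three_frames(nt: str) -> tuple[str, str, str]:
    """Translate in frames 0/1/2 (standard table, stops rendered '*',
    trailing partial codons dropped)."""
    out = []
    for f in range(3):
        sub = nt[f:]
        sub = sub[:len(sub) - len(sub) % 3]
        out.append(str(Seq(sub).translate()) if sub else "")
    return tuple(out)


def extract_cdrh3(aa: str, upstream_motif: str = UPSTREAM_MOTIF,
                  downstream_motifs: Sequence[str] = DOWNSTREAM_MOTIFS,
                  ) -> tuple[tuple[str, tuple[int, int]] | None, str | None]:
    """Extract the CDRH3 from a translated read.

    Returns ``((cdrh3_aa, (start, end)), None)`` on success, where the span
    is 0-based half-open over *aa* and covers the residues strictly between
    the end of the upstream motif and the start of the earliest downstream
    motif; otherwise ``(None, reason)``.
    """
    if not upstream_motif or not all(downstream_motifs):
        raise ConfigurationError("motifs must be non-empty")
    up = aa.find(upstream_motif)
    if up < 0:
        return None, REASON_NO_UPSTREAM
    start = up + len(upstream_motif)
    down = min((p for p in (aa.find(m, start) for m in downstream_motifs)
                if p >= 0), default=-1)
    if down < 0:
        return None, REASON_NO_DOWNSTREAM
    if down <= start:
        return None, REASON_EMPTY_SPAN
    region = aa[start:down]
    if "*" in region:
        return None, REASON_STOP_IN_CDR
    return (region, (start, down)), None


def select_frame_and_collect(nt: str, sample_barcode: str = "",
                             ) -> tuple[CdrSequence | None, str | None]:
    """Search all three frames jointly and keep the unique qualifying one.

    A frame qualifies when it yields a motif-bounded, stop-free CDRH3.
    Reads qualifying in several frames are discarded (truth unknowable), as
    are reads with an ambiguous base inside the CDRH3 nucleotide span.
    """
    hits = []
    for f, aa in enumerate(translate_three_frames(nt)):
        result, _ = extract_cdrh3(aa)
        if result is not None:
            hits.append((f, result))
    if not hits:
        return None, REASON_NO_FRAME
    if len(hits) > 1:
        logger.debug("read discarded: %s", REASON_MULTI_FRAME)
        return None, REASON_MULTI_FRAME
    f, (region, (a_start, a_end)) = hits[0]
    nt_span = nt[f + 3 * a_start:f + 3 * a_end]
    if "N" in nt_span:
        return None, REASON_N_IN_CDR
    return CdrSequence(sample_barcode=sample_barcode, cdrh3_nt=nt_span,
                       cdrh3_aa=region, frame=f), None


def dedupe_and_count(cdrs: Sequence[CdrSequence]) -> list[CdrSequence]:
    """Exact nucleotide-level deduplication within one sample.

    Output is sorted by descending copy number, then lexicographic
    nucleotide sequence.
    """
    if not cdrs:
        return []
    barcodes = {c.sample_barcode for c in cdrs}
    if len(barcodes) != 1:
        raise ValueError(f"mixed sample barcodes in dedupe input: {barcodes}")
    counts: dict[str, list] = {}
    for c in cdrs:
        if c.cdrh3_nt in counts:
            counts[c.cdrh3_nt][1] += c.copy_number
        else:
            counts[c.cdrh3_nt] = [c, c.copy_number]
    out = [replace(c, copy_number=n) for c, n in counts.values()]
    out.sort(key=lambda c: (-c.copy_number, c.cdrh3_nt))
    return out


def process_sample(reads: Iterable, sample_barcode: str) -> list[CdrSequence]:
    """Extract + dedupe one demultiplexed bin."""
    collected = []
    for read in reads:
        seq = str(read.seq) if hasattr(read, "seq") else read[1]
        cdr, _ = select_frame_and_collect(seq, sample_barcode)
        if cdr is not None:
            collected.append(cdr)
    return dedupe_and_count(collected)


# --------------------------------------------------------------------------
# Combinatorial diversity
# --------------------------------------------------------------------------

def theoretical_diversity(v: int, d: int, j: int) -> int:
    """Theoretical V x D x J combinatorial diversity.

    For the human segment counts (55, 23, 6) this is 7,590.  Note that for
    cattle (~10 V, ~10 D, 4 J) the product is 400, while the literature
    quotes a diversity of approximately 4,000 for the bovine heavy-chain
    repertoire; the arithmetic here is the plain product and the
    discrepancy is documented rather than resolved.
    """
    if v < 1 or d < 1 or j < 1:
        raise ValueError("segment counts must be positive")
    return v * d * j
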