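"""Knob/stalk partition of ultralong CDRH3 and cleavable fusion design.

An ultralong CDRH3 comprises an ascending beta-strand, a disulphide-rich
knob domain derived from the IGHD8-2 germline segment, and a descending
strand with a characteristic alternating aromatic/aliphatic pattern.  The
knob N-terminus is the residue immediately preceding the first germline
cysteine; the C-terminus is the final aliphatic residue preceding the
alternating aromatic-aliphatic motif of the descending stalk.

For screening and excision, knob domains are carried on fusion constructs:
the whole CDRH3 fused to a TEV-cleavable poly-His single-chain Fc, or the
isolated knob spliced into an acceptor Fab CDRH3 between two TEV sites.
TEV protease cleaves ENLYFQ | (G/S).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Sequence

from Bio import Align

logger = logging.getLogger(__name__)

#: Mus musculus immunoglobulin heavy-chain leader used for all expressions
LEADER_AA = "MEWSWVFLFFLSVTTGVHS"
TEV_RECOGNITION = "ENLYFQ"          # cleaved before a G or S remnant
TEV_SITE_AA = "ENLYFQG"

AROMATIC = frozenset("FWY")
ALIPHATIC = frozenset("AVLI")

#: synthetic stand-in for the TEV-cleavable poly-His ScFc expression tag
#: (linker + TEV site + abbreviated Fc body + His10); not the real construct
SCFC_TEMPLATE_SYNTHETIC = ("SGENLYFQG"
                           + "ASTKGPSVLAPSSKSTSGGTAALGDKTHTSPPSP"
                           + "HHHHHHHHHH")


class CoreNotFoundError(ValueError):
    """The IGHD8-2 core could not be located in the CDRH3."""


@dataclass(frozen=True)
class CysMapping:
    index: int          # position in the CDRH3
    mutated: bool       # residue is no longer cysteine


@dataclass(frozen=True)
class KnobAnnotation:
    cdrh3_aa: str
    knob_span: tuple[int, int]
    germline_cys_indices: tuple[int, ...]
    descending_stalk_missing: bool = False

    @property
    def ascending_stalk(self) -> str:
        return self.cdrh3_aa[:self.knob_span[0]]

    @property
    def knob(self) -> str:
        return self.cdrh3_aa[self.knob_span[0]:self.knob_span[1]]

    @property
    def descending_stalk(self) -> str:
        return self.cdrh3_aa[self.knob_span[1]:]


@dataclass(frozen=True)
class FusionConstruct:
    construct_type: str                 # "cdrh3_scfc" | "fab_knob"
    orf_aa: str
    leader_aa: str
    tev_sites: tuple[int, ...]
    insert_span: tuple[int, int]


_LOCAL = Align.PairwiseAligner(mode="local", match_score=1, mismatch_score=0,
                               open_gap_score=-10, extend_gap_score=-1)


def map_germline_cysteines(cdrh3_aa: str, ighd82_core_aa: str,
                           ) -> list[CysMapping]:
    """Locate the germline core cysteine positions within a CDRH3.

    The core is locally aligned to the CDRH3 (same scoring as clonotype
    identity); positions aligned to core cysteines are returned in order,
    flagged ``mutated`` when the CDRH3 residue is no longer cysteine.
    Raises :class:`CoreNotFoundError` when the best alignment scores below
    half the core's self-alignment score.
    """
    if "C" not in ighd82_core_aa:
        raise ValueError("core peptide contains no cysteine")
    aln = _LOCAL.align(cdrh3_aa, ighd82_core_aa)
    best = aln[0]
    if best.score < 0.5 * len(ighd82_core_aa):
        raise CoreNotFoundError(
            f"core not found: alignment score {best.score} below floor "
            f"{0.5 * len(ighd82_core_aa)}")
    target_blocks, query_blocks = best.aligned
    mappings = []
    core_cys = [i for i, a in enumerate(ighd82_core_aa) if a == "C"]
    for q in core_cys:
        for (ts, _te), (qs, qe) in zip(target_blocks, query_blocks):
            if qs <= q < qe:
                t = ts + (q - qs)
                mappings.append(CysMapping(index=t,
                                           mutated=cdrh3_aa[t] != "C"))
                break
    return mappings


def _first_alternating_run(aa: str, start: int, aromatic: frozenset,
                           aliphatic: frozenset, min_alternation: int,
                           ) -> int | None:
    """Smallest index >= start where an aromatic-led run of
    *min_alternation* residues alternates between the aromatic and
    aliphatic classes."""
    def cls(res: str) -> str | None:
        if res in aromatic:
            return "ar"
        if res in aliphatic:
            return "al"
        return None

    for t in range(start, len(aa) - min_alternation + 1):
        if cls(aa[t]) != "ar":
            continue
        ok = True
        prev = "ar"
        for k in range(1, min_alternation):
            c = cls(aa[t + k])
            if c is None or c == prev:
                ok = False
                break
            prev = c
        if ok:
            return t
    return None


def call_knob_boundaries(cdrh3_aa: str,
                         germline_cys_indices: Sequence[int],
                         aromatic_set: frozenset = AROMATIC,
                         aliphatic_set: frozenset = ALIPHATIC,
                         min_alternation: int = 3) -> KnobAnnotation:
    """Partition an ultralong CDRH3 into stalk / knob / stalk.

    Knob start: the residue immediately preceding the first germline
    cysteine.  Knob end: the position after the last aliphatic residue that
    precedes the first aromatic-led run of >= *min_alternation* residues
    alternating between the aromatic and aliphatic classes, scanning after
    the last germline cysteine.  Without such a run the knob extends to the
    end of the CDRH3 (empty descending stalk, with a warning).
    """
    if not germline_cys_indices:
        raise ValueError("no germline cysteine indices")
    cys = sorted(germline_cys_indices)
    if cys[0] == 0:
        raise ValueError("first germline cysteine at index 0: no preceding "
                         "residue to start the knob")
    start = cys[0] - 1
    run = _first_alternating_run(cdrh3_aa, cys[-1] + 1, aromatic_set,
                                 aliphatic_set, min_alternation)
    missing = run is None
    if run is None:
        end = len(cdrh3_aa)
        logger.warning("no descending-stalk alternation found; knob extends "
                       "to the CDRH3 end")
    else:
        aliphatics = [i for i in range(cys[-1] + 1, run)
                      if cdrh3_aa[i] in aliphatic_set]
        end = (aliphatics[-1] + 1) if aliphatics else run
    return KnobAnnotation(cdrh3_aa=cdrh3_aa, knob_span=(start, end),
                          germline_cys_indices=tuple(cys),
                          descending_stalk_missing=missing)


def annotate_knob(cdrh3_aa: str, ighd82_core_aa: str,
                  **kwargs) -> KnobAnnotation:
    """Map germline cysteines then call boundaries in one step."""
    mapping = map_germline_cysteines(cdrh3_aa, ighd82_core_aa)
    return call_knob_boundaries(cdrh3_aa, [m.index for m in mapping],
                                **kwargs)


# --------------------------------------------------------------------------
# Fusion constructs and TEV digestion
# --------------------------------------------------------------------------

def _tev_sites(orf: str) -> tuple[int, ...]:
    return tuple(m.start() for m in re.finditer("ENLYFQ(?=[GS])", orf))


def build_cdrh3_scfc(cdrh3_aa: str, scfc_template_aa: str = SCFC_TEMPLATE_SYNTHETIC,
                     leader_aa: str = LEADER_AA) -> FusionConstruct:
    """Whole CDRH3 fused N-terminally of a TEV-cleavable poly-His ScFc."""
    if not cdrh3_aa:
        raise ValueError("empty CDRH3")
    if not _tev_sites(scfc_template_aa):
        raise ValueError("ScFc template lacks a TEV recognition site")
    if "HHHHHH" not in scfc_template_aa:
        raise ValueError("ScFc template lacks a poly-His tract")
    orf = leader_aa + cdrh3_aa + scfc_template_aa
    return FusionConstruct(
        construct_type="cdrh3_scfc", orf_aa=orf, leader_aa=leader_aa,
        tev_sites=_tev_sites(orf),
        insert_span=(len(leader_aa), len(leader_aa) + len(cdrh3_aa)))


def build_fab_knob_fusion(knob_aa: str, acceptor_heavy_aa: str,
                          insertion_point: int,
                          tev_site_aa: str = TEV_SITE_AA) -> FusionConstruct:
    """Splice a knob into an acceptor heavy chain between two TEV sites."""
    if not knob_aa:
        raise ValueError("empty knob")
    if not 0 <= insertion_point <= len(acceptor_heavy_aa):
        raise ValueError("insertion point outside acceptor sequence")
    orf = (acceptor_heavy_aa[:insertion_point] + tev_site_aa + knob_aa
           + tev_site_aa + acceptor_heavy_aa[insertion_point:])
    start = insertion_point + len(tev_site_aa)
    return FusionConstruct(
        construct_type="fab_knob", orf_aa=orf, leader_aa="",
        tev_sites=_tev_sites(orf),
        insert_span=(start, start + len(knob_aa)))


def tev_digest(orf_aa: str) -> list[str]:
    """Cleave after the Q of every ENLYFQ followed by G or S.

    Fragments concatenate to the input; for a doubly flanked knob the
    released middle fragment is the G/S remnant + knob + ENLYFQ (remnant
    bookkeeping is explicit in the fragment strings).
    """
    cuts = [m.start() + len(TEV_RECOGNITION)
            for m in re.finditer("ENLYFQ(?=[GS])", orf_aa)]
    fragments = []
    prev = 0
    for c in cuts:
        fragments.append(orf_aa[prev:c])
        prev = c
    fragments.append(orf_aa[prev:])
    return [f for f in fragments if f] or [""]
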