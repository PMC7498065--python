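"""Classification of CDRH3 sequences as ultralong and cysteine profiling.

Ultralong bovine CDRH3 are identified by nucleotide length (>90 bp, strict)
and, optionally, by the characteristic tandem duplication of a portion of
the IGHV1-7 gene segment near the V/CDRH3 junction.  The knob region of an
ultralong CDRH3 carries a variable number of cysteines, with even counts
preferred (consistent with full disulphide pairing).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .read_processing import CdrSequence
from .synthetic_repertoire import ConfigurationError

DEFAULT_LENGTH_THRESHOLD_NT = 90


@dataclass(frozen=True)
class UltralongAnnotation:
    is_ultralong: bool
    length_nt: int
    duplication_found: bool
    duplication_offsets: tuple[int, int] | None
    cys_count: int
    cys_positions: tuple[int, ...]
    cys_pattern: str


def _near_matches(seq: str, probe: str, max_mismatch: int = 1) -> list[int]:
    hits = []
    for i in range(len(seq) - len(probe) + 1):
        if sum(a != b for a, b in zip(seq[i:i + len(probe)], probe)) <= max_mismatch:
            hits.append(i)
    return hits


def find_duplication(nt: str, probe: str,
                     max_mismatch: int = 1) -> tuple[int, int] | None:
    """Two non-overlapping exact-or-near (<= *max_mismatch*) probe matches."""
    hits = _near_matches(nt, probe, max_mismatch)
    for i, a in enumerate(hits):
        for b in hits[i + 1:]:
            if b >= a + len(probe):
                return (a, b)
    return None


def cysteine_profile(aa: str) -> tuple[int, tuple[int, ...], str, str]:
    """Return (count, 0-based positions, spacing pattern, parity).

    The pattern string lists inter-cysteine gaps, e.g. ``C-x3-C-x7-C``;
    a cysteine-free sequence has an empty pattern and even parity.
    """
    if not aa:
        raise ValueError("empty amino-acid sequence")
    positions = tuple(i for i, a in enumerate(aa) if a == "C")
    parts = []
    for i, p in enumerate(positions):
        if i:
            parts.append(f"x{p - positions[i - 1] - 1}")
        parts.append("C")
    pattern = "-".join(parts)
    parity = "even" if len(positions) % 2 == 0 else "odd"
    return len(positions), positions, pattern, parity


def positions_from_pattern(pattern: str, first_position: int = 0,
                           ) -> tuple[int, ...]:
    """Reconstruct cysteine positions from a spacing pattern (round trip of
    :func:`cysteine_profile` up to the position of the first cysteine)."""
    if not pattern:
        return ()
    positions = [first_position]
    for gap in re.findall(r"x(\d+)", pattern):
        positions.append(positions[-1] + int(gap) + 1)
    return tuple(positions)


def is_ultralong(cdr: CdrSequence,
                 length_threshold_nt: int = DEFAULT_LENGTH_THRESHOLD_NT,
                 require_duplication: bool = False,
                 duplication_probe: str | None = None,
                 probe_max_mismatch: int = 1) -> UltralongAnnotation:
    """Annotate one CDRH3.

    The length criterion is strict (``> length_threshold_nt``), measured on
    the motif-bounded CDRH3 nucleotide span.  When *require_duplication* is
    set, the IGHV1-7 duplication must also be present (two non-overlapping
    near-matches of the probe); by default length alone decides.
    """
    if require_duplication and not duplication_probe:
        raise ConfigurationError(
            "require_duplication needs a non-empty duplication probe")
    length_nt = len(cdr.cdrh3_nt)
    long_enough = length_nt > length_threshold_nt
    offsets = None
    found = False
    if duplication_probe:
        offsets = find_duplication(cdr.cdrh3_nt, duplication_probe,
                                   probe_max_mismatch)
        found = offsets is not None
    ultralong = long_enough and (found or not require_duplication)
    count, positions, pattern, _ = cysteine_profile(cdr.cdrh3_aa)
    return UltralongAnnotation(
        is_ultralong=ultralong, length_nt=length_nt,
        duplication_found=found, duplication_offsets=offsets,
        cys_count=count, cys_positions=positions, cys_pattern=pattern)


def annotate_cohort(cdrs: Sequence[CdrSequence],
                    **kwargs) -> list[UltralongAnnotation]:
    return [is_ultralong(c, **kwargs) for c in cdrs]


def cohort_summary(annotations: Sequence[UltralongAnnotation]) -> pd.DataFrame:
    """Counts by (length class, cysteine count, parity); marginal totals
    equal the input size."""
    if not annotations:
        raise ValueError("empty annotation list")
    rows = [{
        "length_class": "ultralong" if a.is_ultralong else "regular",
        "cys_count": a.cys_count,
        "parity": "even" if a.cys_count % 2 == 0 else "odd",
    } for a in annotations]
    df = pd.DataFrame(rows)
    out = (df.value_counts(["length_class", "cys_count", "parity"])
             .rename("n").reset_index()
             .sort_values(["length_class", "cys_count"])
             .reset_index(drop=True))
    return out
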