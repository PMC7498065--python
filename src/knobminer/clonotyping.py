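"""Clonotype clustering of CDRH3 amino-acid sequences by percent identity.

A clonotype groups sequences that plausibly share a clonal lineage.
Identity is computed from one optimal global alignment (match +1,
mismatch 0, gap open -10, gap extend -1) as 100 x matches / alignment
columns, so length differences between clonally related sequences count
against identity.  Clusters are single-linkage: connected components of
the graph whose edges join pairs meeting the identity threshold (default
>= 75%), which makes the partition independent of input order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx
from Bio import Align


@dataclass(frozen=True)
class Clonotype:
    clonotype_id: str
    members: tuple[str, ...]
    representative: str
    size: int


def _make_aligner(mode: str = "global") -> Align.PairwiseAligner:
    return Align.PairwiseAligner(mode=mode, match_score=1, mismatch_score=0,
                                 open_gap_score=-10, extend_gap_score=-1)


_GLOBAL = _make_aligner()


def pairwise_identity(a: str, b: str) -> float:
    """Percent identity in [0, 100] from one optimal global alignment.

    Symmetric by construction: arguments are ordered canonically before
    aligning.
    """
    if not a or not b:
        raise ValueError("empty sequence")
    x, y = sorted((a, b))
    aln = _GLOBAL.align(x, y)[0]
    counts = aln.counts()
    columns = aln.length
    return 100.0 * counts.identities / columns


def cluster_clonotypes(seqs: Sequence[str], threshold_pct: float = 75.0,
                       mode: str = "geq",
                       copy_numbers: Sequence[int] | None = None,
                       ) -> list[Clonotype]:
    """Single-linkage clusters at the identity threshold.

    *mode* is ``"geq"`` (identity >= threshold, the S1-caption reading) or
    ``"gt"`` (strictly greater, the Results-text reading).  The
    representative of a cluster is its highest-copy member (ties broken by
    lexicographic order); output is ordered by size descending, then
    representative.
    """
    if not 0 < threshold_pct <= 100:
        raise ValueError("threshold must be in (0, 100]")
    if mode not in ("geq", "gt"):
        raise ValueError(f"unknown threshold mode {mode!r}")
    if not seqs:
        return []
    copies = list(copy_numbers) if copy_numbers is not None else [1] * len(seqs)
    g = nx.Graph()
    g.add_nodes_from(range(len(seqs)))
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            ident = pairwise_identity(seqs[i], seqs[j])
            if (ident >= threshold_pct) if mode == "geq" else (ident > threshold_pct):
                g.add_edge(i, j)
    clusters = []
    for comp in nx.connected_components(g):
        members = tuple(sorted(seqs[i] for i in comp))
        rep = min(comp, key=lambda i: (-copies[i], seqs[i]))
        clusters.append((members, seqs[rep]))
    clusters.sort(key=lambda c: (-len(c[0]), c[1]))
    return [Clonotype(clonotype_id=f"CT{k:04d}", members=m, representative=r,
                      size=len(m))
            for k, (m, r) in enumerate(clusters)]


def clonotype_summary(clusters: Sequence[Clonotype],
                      min_members_for_clonotype: int = 2,
                      ) -> tuple[int, int, float]:
    """(n_clonotypes, n_singletons, fraction_in_clonotypes).

    A cluster counts as a clonotype when it has at least
    *min_members_for_clonotype* members; the fraction is the share of all
    sequences that fall in such clusters.
    """
    total = sum(c.size for c in clusters)
    n_clonotypes = sum(1 for c in clusters
                       if c.size >= min_members_for_clonotype)
    n_singletons = sum(1 for c in clusters if c.size == 1)
    in_clonotypes = sum(c.size for c in clusters
                        if c.size >= min_members_for_clonotype)
    fraction = in_clonotypes / total if total else 0.0
    return n_clonotypes, n_singletons, fraction
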