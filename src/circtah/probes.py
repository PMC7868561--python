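"""Back-splice junction library construction and microarray probe
re-annotation.

The junction library holds, per circRNA, the sequence context of the
back-splice junction: up to 45 nt from the 3' end ("tail") joined to up to
45 nt from the 5' end ("head") of the circle, in transcript orientation
(reverse-complemented for minus-strand circles).  Probes are re-annotated
by exact full-length occurrence in a junction sequence, in either
orientation, with the extra requirement that the match span crosses the
junction midpoint — a probe lying wholly inside one flank is not
junction-specific.  Two filtering rules then apply: a probe hitting more
than one circRNA is discarded, and a circRNA is retained only when at
least one exact-match probe remains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .io import CircRNA, Gene

JUNCTION_FLANK = 45


@dataclass(frozen=True)
class JunctionSeq:
    circ_id: str
    sequence: str
    #: index of the first base of the head flank (the junction point)
    junction_offset: int


@dataclass
class ProbeMatch:
    probe_id: str
    circ_id: str
    offset: int
    reverse_complement: bool
    passes_uniqueness: bool = True
    passes_perfection: bool = True


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def circ_sequence(
    circ: CircRNA,
    genome: dict[str, str],
    exons: tuple[tuple[int, int], ...] | None = None,
) -> str:
    """Transcript-orientation sequence of a circRNA.

    With ``exons`` (host exon blocks), the spliced sequence is the
    concatenation of the exon pieces intersecting the circle's span;
    otherwise the contiguous genomic span is used.  Minus-strand circles
    are reverse-complemented.
    """
    chrom_seq = genome.get(circ.chrom)
    if chrom_seq is None or circ.end > len(chrom_seq):
        raise ValueError(f"circRNA {circ.id} span not covered by genome")
    if exons:
        pieces = [
            chrom_seq[max(a, circ.start) : min(b, circ.end)]
            for a, b in sorted(exons)
            if a < circ.end and circ.start < b
        ]
        seq = "".join(pieces) if pieces else chrom_seq[circ.start : circ.end]
    else:
        seq = chrom_seq[circ.start : circ.end]
    return _revcomp(seq) if circ.strand == "-" else seq.upper()


def build_junction_library(
    circs: list[CircRNA],
    genome: dict[str, str],
    genes: list[Gene] | None = None,
    flank: int = JUNCTION_FLANK,
    spliced: bool = True,
) -> list[JunctionSeq]:
    """Per-circRNA back-splice junction sequences (tail + head flanks).

    For circles shorter than ``2*flank`` the flanks are truncated to
    ⌊L/2⌋ each so the junction stays centred.  ``spliced`` selects exonic
    splicing when the host's exon blocks are available.
    """
    exon_map = {g.id: g.exons for g in genes} if genes else {}
    library = []
    for c in circs:
        exons = exon_map.get(c.host_gene) if spliced else None
        seq = circ_sequence(c, genome, exons)
        f = min(flank, len(seq) // 2)
        tail = seq[-f:] if f > 0 else ""
        head = seq[:f]
        library.append(JunctionSeq(c.id, (tail + head).upper(), len(tail)))
    return library


def _find_junction_hits(
    probe: str, junction: JunctionSeq, require_crossing: bool = True
) -> list[int]:
    """Offsets of full-length probe occurrences crossing the junction point."""
    hits = []
    seq, mid = junction.sequence, junction.junction_offset
    start = 0
    while True:
        i = seq.find(probe, start)
        if i < 0:
            break
        if not require_crossing or (i < mid < i + len(probe)):
            hits.append(i)
        start = i + 1
    return hits


def match_probes(
    probes: dict[str, str],
    library: list[JunctionSeq],
    require_crossing: bool = True,
) -> tuple[list[ProbeMatch], set[str]]:
    """Re-annotate probes against the junction library.

    A hit is a full-length exact occurrence of the probe (either
    orientation) in a junction sequence, spanning the junction midpoint.
    Probes hitting > 1 circRNA are discarded (uniqueness rule); the
    returned circRNA set keeps only circles with >= 1 retained exact-match
    probe (perfection rule).  Returns (retained matches, re-annotated
    circRNA ids).
    """
    if not library:
        raise ValueError("empty junction library")
    matches: list[ProbeMatch] = []
    for pid, pseq in probes.items():
        pseq = pseq.upper()
        hits: list[ProbeMatch] = []
        for junc in library:
            for rc, query in ((False, pseq), (True, _revcomp(pseq))):
                offs = _find_junction_hits(query, junc, require_crossing)
                if offs:
                    hits.append(ProbeMatch(pid, junc.circ_id, offs[0], rc))
                    break  # one hit per junction is enough
        circ_ids = {h.circ_id for h in hits}
        if len(circ_ids) == 1:
            matches.append(hits[0])
        elif len(circ_ids) > 1:
            for h in hits:
                h.passes_uniqueness = False
    reannotated = {m.circ_id for m in matches}
    return matches, reannotated


def collapse_intensities(
    intensities: pd.DataFrame, matches: list[ProbeMatch]
) -> pd.DataFrame:
    """Per-circRNA expression: mean of its retained probes, per sample.

    ``intensities`` is probes × samples with the probe id as index.
    CircRNAs whose probes are all absent from the table are dropped.
    """
    probe_map: dict[str, list[str]] = {}
    for m in matches:
        probe_map.setdefault(m.circ_id, []).append(m.probe_id)
    rows = {}
    for circ_id, pids in sorted(probe_map.items()):
        present = [p for p in pids if p in intensities.index]
        if not present:
            import logging

            logging.getLogger(__name__).warning(
                "circRNA %s: no probes present in intensity table; dropped",
                circ_id,
            )
            continue
        rows[circ_id] = intensities.loc[present].mean(axis=0)
    return pd.DataFrame.from_dict(rows, orient="index")
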