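"""ChIA-PET style contact calling between circRNA TSS windows and distal
cis-regulatory regions.

A contact is supported when one anchor of a pair overlaps the circRNA's
−2 kb/+1 kb TSS window, the partner anchor overlaps a regulatory region
(H3K27ac peaks by default), and the anchor midpoints are at least
``min_distance`` apart (default 10 kb: the "distal" requirement).  Pairs
are unordered: swapping anchors changes nothing.  3C/5C/Hi-C pairs are
treated identically to ChIA-PET pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .classify import proximal_region
from .io import CircRNA, GenomicInterval, InteractionPair, PeakSet

MIN_DISTAL_BP = 10_000


@dataclass
class ContactCall:
    circ_id: str
    n_pairs: int = 0
    contacted: list[GenomicInterval] = field(default_factory=list)

    @property
    def has_contact(self) -> bool:
        return self.n_pairs >= 1


def _overlaps_any(iv: GenomicInterval, peaks_by_chrom) -> list[GenomicInterval]:
    out = []
    for p in peaks_by_chrom.get(iv.chrom, ()):
        if p.start < iv.end and iv.start < p.end:
            out.append(p)
    return out


def tss_contacts(
    pairs: list[InteractionPair],
    circs: list[CircRNA],
    regulatory: PeakSet,
    min_distance: int = MIN_DISTAL_BP,
    convention: str = "tf_window",
) -> list[ContactCall]:
    """Call distal regulatory contacts for every circRNA TSS."""
    peaks_by_chrom = regulatory.by_chrom()
    calls = []
    for c in circs:
        window = proximal_region(c.chrom, c.tss, c.strand, convention)
        call = ContactCall(c.id)
        for pair in pairs:
            for tss_anchor, reg_anchor in (
                (pair.anchor1, pair.anchor2),
                (pair.anchor2, pair.anchor1),
            ):
                if not tss_anchor.overlaps(window):
                    continue
                if abs(tss_anchor.midpoint() - reg_anchor.midpoint()) < min_distance:
                    continue
                hit = _overlaps_any(reg_anchor, peaks_by_chrom)
                if hit:
                    call.n_pairs += 1
                    call.contacted.extend(hit)
                    break  # count each pair at most once per circRNA
        calls.append(call)
    return calls


def contact_fraction(calls: list[ContactCall], tah_ids) -> dict:
    """Fraction of TSSs with >= 1 distal contact, in the TAH and non-TAH
    classes, plus their difference."""
    tah_ids = set(tah_ids)
    tah = [c for c in calls if c.circ_id in tah_ids]
    other = [c for c in calls if c.circ_id not in tah_ids]
    out = {"n_tah": len(tah), "n_other": len(other)}
    out["fraction_tah"] = (
        sum(c.has_contact for c in tah) / len(tah) if tah else float("nan")
    )
    out["fraction_other"] = (
        sum(c.has_contact for c in other) / len(other) if other else float("nan")
    )
    out["difference"] = out["fraction_tah"] - out["fraction_other"]
    return out


def calls_to_frame(calls: list[ContactCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "circ_id": [c.circ_id for c in calls],
            "has_contact": [c.has_contact for c in calls],
            "n_pairs": [c.n_pairs for c in calls],
        }
    )
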