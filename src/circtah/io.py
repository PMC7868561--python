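"""Readers and writers for the on-disk formats the pipeline consumes.

All coordinates are held internally as 0-based half-open intervals (BED
convention).  Catalog tables exported by circBase-style databases are BED-like
and are ingested as-is by default; a ``one_based`` flag on :func:`read_catalog`
shifts 1-based inclusive tables on ingest.  Chromosome names are taken
verbatim — no ``chr`` prefix normalisation is attempted, so naming mismatches
between inputs surface downstream as zero-overlap results.

Formats covered: BED3/BED6, narrowPeak, bedGraph, BEDPE, FASTA (via
Biopython) and the tab-separated circRNA / gene catalog tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

STRANDS = ("+", "-", ".")


class FormatError(ValueError):
    """A malformed record in an on-disk file."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


@dataclass(frozen=True)
class CircRNA:
    """A back-splice circle: its genomic span and host-gene linkage."""

    id: str
    chrom: str
    start: int
    end: int
    strand: str
    host_gene: str | None = None

    @property
    def tss(self) -> int:
        """5' end of the back-splice span by strand."""
        return self.start if self.strand == "+" else self.end

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)


@dataclass(frozen=True)
class Gene:
    """A linear gene with exon block structure."""

    id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...] = ()

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)


@dataclass
class PeakSet:
    """A set of called peaks (e.g. MACS narrowPeak output)."""

    intervals: list[GenomicInterval] = field(default_factory=list)
    scores: list[float] | None = None

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def sorted(self) -> "PeakSet":
        order = sorted(
            range(len(self.intervals)),
            key=lambda i: (self.intervals[i].chrom, self.intervals[i].start),
        )
        return PeakSet(
            [self.intervals[i] for i in order],
            None if self.scores is None else [self.scores[i] for i in order],
        )

    def by_chrom(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        for ivs in out.values():
            ivs.sort(key=lambda iv: iv.start)
        return out


@dataclass(frozen=True)
class InteractionPair:
    """An unordered pair of contact anchors (one BEDPE record)."""

    anchor1: GenomicInterval
    anchor2: GenomicInterval

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InteractionPair):
            return NotImplemented
        a = (self.anchor1, self.anchor2)
        b = (other.anchor1, other.anchor2)
        return a == b or a == b[::-1]

    def __hash__(self) -> int:
        return hash(frozenset((self.anchor1, self.anchor2)))


class SignalTrack:
    """Piecewise-constant read coverage (or score) per chromosome.

    Stored as sorted non-overlapping runs ``(starts, ends, values)`` per
    chromosome, plus the library size ``total_reads`` (the N of the
    RPKM-style denominators).  Positions outside any run have value 0.
    """

    def __init__(
        self,
        runs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
        total_reads: float = 1.0,
    ) -> None:
        if total_reads <= 0:
            raise ValueError("total_reads must be > 0")
        self.total_reads = float(total_reads)
        self._runs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, (s, e, v) in runs.items():
            s = np.asarray(s, dtype=np.int64)
            e = np.asarray(e, dtype=np.int64)
            v = np.asarray(v, dtype=float)
            order = np.argsort(s, kind="stable")
            s, e, v = s[order], e[order], v[order]
            if np.any(v < 0):
                raise ValueError(f"negative coverage on {chrom}")
            if len(s) > 1 and np.any(s[1:] < e[:-1]):
                bad = int(np.argmax(s[1:] < e[:-1]))
                if v[bad] != v[bad + 1]:
                    raise FormatError(
                        f"overlapping records with conflicting values on "
                        f"{chrom} near position {s[bad + 1]}"
                    )
                raise FormatError(f"overlapping records on {chrom} near {s[bad + 1]}")
            self._runs[chrom] = (s, e, v)

    @classmethod
    def from_records(
        cls,
        records: list[tuple[str, int, int, float]],
        total_reads: float = 1.0,
    ) -> "SignalTrack":
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in records:
            by_chrom.setdefault(chrom, []).append((start, end, value))
        runs = {}
        for chrom, recs in by_chrom.items():
            s, e, v = zip(*recs)
            runs[chrom] = (np.array(s), np.array(e), np.array(v))
        return cls(runs, total_reads)

    @property
    def chroms(self) -> list[str]:
        return list(self._runs)

    def value_at(self, chrom: str, pos: int) -> float:
        """Coverage value at a single bp; 0 when uncovered."""
        if chrom not in self._runs:
            return 0.0
        s, e, v = self._runs[chrom]
        i = int(np.searchsorted(s, pos, side="right")) - 1
        if i >= 0 and pos < e[i]:
            return float(v[i])
        return 0.0

    def interval_sum(self, chrom: str, start: int, end: int) -> float:
        """Sum of per-bp values over [start, end); uncovered bp contribute 0."""
        if end <= start or chrom not in self._runs:
            return 0.0
        s, e, v = self._runs[chrom]
        lo = int(np.searchsorted(e, start, side="right"))
        hi = int(np.searchsorted(s, end, side="left"))
        if hi <= lo:
            return 0.0
        ov = np.minimum(e[lo:hi], end) - np.maximum(s[lo:hi], start)
        return float(np.sum(ov * v[lo:hi]))

    def interval_values(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-bp values over [start, end) as a dense array (0 when uncovered)."""
        out = np.zeros(end - start, dtype=float)
        if chrom not in self._runs:
            return out
        s, e, v = self._runs[chrom]
        lo = int(np.searchsorted(e, start, side="right"))
        hi = int(np.searchsorted(s, end, side="left"))
        for i in range(lo, hi):
            a = max(int(s[i]), start) - start
            b = min(int(e[i]), end) - start
            out[a:b] = v[i]
        return out

    def records(self) -> list[tuple[str, int, int, float]]:
        out = []
        for chrom in sorted(self._runs):
            s, e, v = self._runs[chrom]
            out.extend(
                (chrom, int(a), int(b), float(c)) for a, b, c in zip(s, e, v)
            )
        return out


# ---------------------------------------------------------------------------
# BED / narrowPeak


def read_bed(path) -> PeakSet:
    """Read a BED3+ (incl. narrowPeak) file into a :class:`PeakSet`.

    Column 5 (BED score) or column 7 (narrowPeak signalValue) populates the
    peak scores when present.
    """
    intervals: list[GenomicInterval] = []
    scores: list[float] = []
    have_scores = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 columns")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            strand = fields[5] if len(fields) > 5 and fields[5] in STRANDS else "."
            try:
                intervals.append(GenomicInterval(chrom, start, end, strand))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            if len(fields) > 6:  # narrowPeak signalValue
                scores.append(float(fields[6]))
                have_scores = True
            elif len(fields) > 4:
                scores.append(float(fields[4]))
                have_scores = True
            else:
                scores.append(0.0)
    return PeakSet(intervals, scores if have_scores else None)


def write_bed(peaks: PeakSet, path, names: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(peaks.intervals):
            name = names[i] if names is not None else f"peak_{i}"
            score = peaks.scores[i] if peaks.scores is not None else 0.0
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score:g}\t{iv.strand}\n"
            )


# ---------------------------------------------------------------------------
# bedGraph


def read_bedgraph(path, total_reads: float = 1.0) -> SignalTrack:
    """Read a 4-column bedGraph into a :class:`SignalTrack`.

    ``total_reads`` is the sequencing library size N; bedGraph itself does
    not carry it, so it must be supplied (the synthetic writer emits a
    ``<name>.total`` sidecar which callers may read).
    """
    records: list[tuple[str, int, int, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns")
            try:
                records.append(
                    (fields[0], int(fields[1]), int(fields[2]), float(fields[3]))
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
    return SignalTrack.from_records(records, total_reads)


def write_bedgraph(track: SignalTrack, path, write_total_sidecar: bool = True) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, value in track.records():
            fh.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")
    if write_total_sidecar:
        with open(f"{path}.total", "w") as fh:
            fh.write(f"{track.total_reads:g}\n")


# ---------------------------------------------------------------------------
# BEDPE


def read_bedpe(path) -> list[InteractionPair]:
    """Read a BEDPE file (>=6 columns) into interaction pairs."""
    pairs: list[InteractionPair] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(f"{path}:{lineno}: expected >=6 columns")
            try:
                a1 = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
                a2 = GenomicInterval(fields[3], int(fields[4]), int(fields[5]))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            pairs.append(InteractionPair(a1, a2))
    return pairs


def write_bedpe(pairs: list[InteractionPair], path) -> None:
    with open(path, "w") as fh:
        for p in pairs:
            a, b = p.anchor1, p.anchor2
            fh.write(
                f"{a.chrom}\t{a.start}\t{a.end}\t{b.chrom}\t{b.start}\t{b.end}\n"
            )


# ---------------------------------------------------------------------------
# catalogs

_CIRC_COLS = ["id", "chrom", "start", "end", "strand", "host_gene"]
_GENE_COLS = ["id", "chrom", "start", "end", "strand", "exons"]


def _parse_exons(blob: str) -> tuple[tuple[int, int], ...]:
    """Parse 'start-end,start-end,...' exon blocks."""
    if not blob or blob == ".":
        return ()
    out = []
    for block in blob.split(","):
        a, b = block.split("-")
        out.append((int(a), int(b)))
    return tuple(out)


def read_circ_catalog(
    path, genes: list[Gene] | None = None, one_based: bool = False
) -> list[CircRNA]:
    """Read a circBase-style circRNA catalog (TSV with header).

    When ``genes`` is given, circRNAs naming an absent host gene trigger a
    warning and are retained with ``host_gene=None``.  ``one_based`` shifts
    1-based inclusive coordinates to the internal 0-based half-open
    convention on ingest.
    """
    gene_ids = {g.id for g in genes} if genes is not None else None
    circs: list[CircRNA] = []
    seen: set[str] = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[: len(_CIRC_COLS)] != _CIRC_COLS:
            raise FormatError(f"{path}: expected header {_CIRC_COLS}, got {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            cid, chrom = fields[0], fields[1]
            start, end = int(fields[2]), int(fields[3])
            if one_based:
                start -= 1
            if cid in seen:
                raise FormatError(f"{path}:{lineno}: duplicate id {cid!r}")
            seen.add(cid)
            host: str | None = fields[5] if fields[5] not in ("", ".") else None
            if host is not None and gene_ids is not None and host not in gene_ids:
                warnings.warn(
                    f"{path}:{lineno}: circRNA {cid} references absent host "
                    f"gene {host!r}; retained with null host"
                )
                host = None
            if start < 0 or start >= end:
                raise FormatError(
                    f"{path}:{lineno}: invalid span {start}-{end} for {cid}"
                )
            circs.append(CircRNA(cid, chrom, start, end, fields[4], host))
    return circs


def read_gene_catalog(path, one_based: bool = False) -> list[Gene]:
    """Read a gene catalog (TSV with header) incl. exon blocks."""
    genes: list[Gene] = []
    seen: set[str] = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[: len(_GENE_COLS)] != _GENE_COLS:
            raise FormatError(f"{path}: expected header {_GENE_COLS}, got {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            gid = fields[0]
            if gid in seen:
                raise FormatError(f"{path}:{lineno}: duplicate id {gid!r}")
            seen.add(gid)
            start, end = int(fields[2]), int(fields[3])
            exons = _parse_exons(fields[5]) if len(fields) > 5 else ()
            if one_based:
                start -= 1
                exons = tuple((a - 1, b) for a, b in exons)
            if start < 0 or start >= end:
                raise FormatError(
                    f"{path}:{lineno}: invalid span {start}-{end} for {gid}"
                )
            genes.append(Gene(gid, fields[1], start, end, fields[4], exons))
    return genes


def write_circ_catalog(circs: list[CircRNA], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_CIRC_COLS) + "\n")
        for c in circs:
            host = c.host_gene if c.host_gene is not None else "."
            fh.write(f"{c.id}\t{c.chrom}\t{c.start}\t{c.end}\t{c.strand}\t{host}\n")


def write_gene_catalog(genes: list[Gene], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_GENE_COLS) + "\n")
        for g in genes:
            blocks = ",".join(f"{a}-{b}" for a, b in g.exons) or "."
            fh.write(f"{g.id}\t{g.chrom}\t{g.start}\t{g.end}\t{g.strand}\t{blocks}\n")


# ---------------------------------------------------------------------------
# FASTA (delegated to Biopython)


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
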