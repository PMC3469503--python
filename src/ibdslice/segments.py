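"""Pairwise IBD segments, segment sets, and the tab-delimited match format.

The match format is one line per segment with 11 tab-separated fields::

    sample_i  sample_j  chrom  a_bp  b_bp  a_cm  b_cm  len_cm  n_sites  metric  source

``len_cm`` is written with 4 decimals; ``a_cm``/``b_cm`` carry full float
precision so that write -> read round-trips losslessly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Iterator

__all__ = ["IBDSegment", "SegmentSet", "write_match", "read_match"]

METRICS = ("genotype", "haplotype", "haploid")
SOURCES = ("array", "exome", "truth")


@dataclass(frozen=True)
class IBDSegment:
    """One shared segment between a sample pair on one chromosome.

    ``(a_bp, b_bp)`` are the physical positions of the first and last
    marker inside the segment (closed interval, 1-based as in VCF);
    ``(a_cm, b_cm)`` are the corresponding genetic positions.
    """

    sample_i: str
    sample_j: str
    chrom: str
    a_bp: int
    b_bp: int
    a_cm: float
    b_cm: float
    n_sites: int
    metric: str = "haplotype"
    source: str = "exome"

    def __post_init__(self) -> None:
        if self.a_bp >= self.b_bp:
            raise ValueError(f"segment requires a_bp < b_bp, got {self.a_bp}..{self.b_bp}")
        if self.a_cm > self.b_cm:
            raise ValueError("segment requires a_cm <= b_cm")
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r}")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.sample_i, self.sample_j)

    @property
    def len_cm(self) -> float:
        return self.b_cm - self.a_cm

    @property
    def len_bp(self) -> int:
        return self.b_bp - self.a_bp

    @property
    def density(self) -> float:
        """Marker density in sites/cM; infinite for zero-cM segments."""
        if self.len_cm == 0:
            return float("inf")
        return self.n_sites / self.len_cm


def _norm_pair(i: str, j: str) -> tuple[str, str]:
    return (i, j) if i <= j else (j, i)


class SegmentSet:
    """Mapping from unordered sample pair to its list of IBD segments."""

    def __init__(self, segments: Iterable[IBDSegment] = ()):
        self._by_pair: dict[tuple[str, str], list[IBDSegment]] = {}
        for seg in segments:
            self.add(seg)

    def add(self, seg: IBDSegment) -> None:
        pair = _norm_pair(seg.sample_i, seg.sample_j)
        if pair != (seg.sample_i, seg.sample_j):
            seg = replace(seg, sample_i=pair[0], sample_j=pair[1])
        self._by_pair.setdefault(pair, []).append(seg)

    def pairs(self) -> list[tuple[str, str]]:
        return sorted(self._by_pair)

    def get(self, i: str, j: str) -> list[IBDSegment]:
        return list(self._by_pair.get(_norm_pair(i, j), []))

    def samples(self) -> set[str]:
        out: set[str] = set()
        for i, j in self._by_pair:
            out.add(i)
            out.add(j)
        return out

    def __iter__(self) -> Iterator[IBDSegment]:
        for pair in self.pairs():
            yield from sorted(
                self._by_pair[pair], key=lambda s: (s.chrom, s.a_bp, s.b_bp, s.metric)
            )

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_pair.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SegmentSet):
            return NotImplemented
        return sorted(self, key=repr) == sorted(other, key=repr)

    def total_len_cm(self) -> float:
        return sum(s.len_cm for s in self)

    def filter(self, predicate) -> "SegmentSet":
        return SegmentSet(s for s in self if predicate(s))


def write_match(segments: SegmentSet, path) -> None:
    """Write a SegmentSet in the tab-delimited match format (see module doc)."""
    with open(path, "w") as fh:
        for s in segments:
            fh.write(
                f"{s.sample_i}\t{s.sample_j}\t{s.chrom}\t{s.a_bp}\t{s.b_bp}\t"
                f"{s.a_cm!r}\t{s.b_cm!r}\t{s.len_cm:.4f}\t{s.n_sites}\t"
                f"{s.metric}\t{s.source}\n"
            )


def read_match(path) -> SegmentSet:
    """Read a match file written by :func:`write_match`."""
    out = SegmentSet()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 11:
                raise ValueError(
                    f"{path}:{lineno}: expected 11 tab-separated fields, "
                    f"got {len(fields)}"
                )
            out.add(
                IBDSegment(
                    sample_i=fields[0],
                    sample_j=fields[1],
                    chrom=fields[2],
                    a_bp=int(fields[3]),
                    b_bp=int(fields[4]),
                    a_cm=float(fields[5]),
                    b_cm=float(fields[6]),
                    n_sites=int(fields[8]),
                    metric=fields[9],
                    source=fields[10],
                )
            )
    return out
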