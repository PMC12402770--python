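"""Genome interval sets with BED semantics (0-based, half-open).

The pipeline needs only a handful of interval operations — normalization,
intersection, union length, and per-region overlap — but it needs them with
exact, auditable semantics because TMB denominators and CNV blacklist
filters are defined directly on them. The representation is a per-chromosome
sorted list of non-overlapping ``(start, end)`` half-open pairs.

Coordinates convert at type boundaries only: variants and segments are
1-based inclusive (MAF/SEG convention); anything entering this class is
0-based half-open (BED convention).
"""

from __future__ import annotations

from typing import Dict, Iterable, Iterator, List, Tuple

Interval = Tuple[int, int]


def _normalize(pairs: Iterable[Interval]) -> List[Interval]:
    """Sort and merge overlapping or abutting half-open intervals."""
    out: List[Interval] = []
    for start, end in sorted(pairs):
        if out and start <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], end))
        else:
            out.append((start, end))
    return out


class GenomeIntervals:
    """An immutable, normalized set of genomic intervals.

    Parameters
    ----------
    intervals : iterable of (chrom, start, end)
        0-based half-open records. Negative coordinates or start > end are
        rejected; start == end (empty interval) is dropped.
    name : str
        Label for provenance (e.g. ``surveyed_strelka``, ``CDS``).
    """

    def __init__(self, intervals: Iterable[Tuple[str, int, int]] = (), name: str = ""):
        self.name = name
        by_chrom: Dict[str, List[Interval]] = {}
        for chrom, start, end in intervals:
            if start < 0 or end < 0:
                raise ValueError(f"negative coordinate in interval {chrom}:{start}-{end}")
            if start > end:
                raise ValueError(f"start > end in interval {chrom}:{start}-{end}")
            if start == end:
                continue
            by_chrom.setdefault(normalize_chrom(chrom), []).append((start, end))
        self._by_chrom: Dict[str, List[Interval]] = {
            c: _normalize(ivs) for c, ivs in by_chrom.items()
        }

    # -- container protocol -------------------------------------------------
    def __iter__(self) -> Iterator[Tuple[str, int, int]]:
        for chrom in sorted(self._by_chrom):
            for start, end in self._by_chrom[chrom]:
                yield chrom, start, end

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_chrom.values())

    def __eq__(self, other) -> bool:
        if not isinstance(other, GenomeIntervals):
            return NotImplemented
        return self._by_chrom == other._by_chrom

    def __repr__(self) -> str:
        return f"GenomeIntervals(name={self.name!r}, n={len(self)}, bp={self.total_length()})"

    # -- arithmetic ----------------------------------------------------------
    def total_length(self) -> int:
        """Total covered bases."""
        return sum(e - s for ivs in self._by_chrom.values() for s, e in ivs)

    def intersect(self, other: "GenomeIntervals") -> "GenomeIntervals":
        """Set intersection by linear sweep over the sorted interval lists."""
        out = []
        for chrom in self._by_chrom.keys() & other._by_chrom.keys():
            a, b = self._by_chrom[chrom], other._by_chrom[chrom]
            i = j = 0
            while i < len(a) and j < len(b):
                lo = max(a[i][0], b[j][0])
                hi = min(a[i][1], b[j][1])
                if lo < hi:
                    out.append((chrom, lo, hi))
                if a[i][1] < b[j][1]:
                    i += 1
                else:
                    j += 1
        return GenomeIntervals(out, name=f"({self.name})&({other.name})")

    def union(self, other: "GenomeIntervals") -> "GenomeIntervals":
        return GenomeIntervals(list(self) + list(other), name=f"({self.name})|({other.name})")

    def overlap_bp(self, chrom: str, start: int, end: int) -> int:
        """Bases of the half-open query covered by this set."""
        chrom = normalize_chrom(chrom)
        total = 0
        for s, e in self._by_chrom.get(chrom, ()):
            if e <= start:
                continue
            if s >= end:
                break
            total += min(e, end) - max(s, start)
        return total

    def contains_point(self, chrom: str, pos0: int) -> bool:
        """True if the 0-based position lies inside the set."""
        return self.overlap_bp(chrom, pos0, pos0 + 1) == 1


def normalize_chrom(chrom: str) -> str:
    """Normalize chromosome naming to the ``chr``-prefixed form."""
    chrom = str(chrom).strip()
    if chrom.upper() in {"MT", "CHRMT", "CHRM", "M"}:
        return "chrM"
    if chrom.lower().startswith("chr"):
        return "chr" + chrom[3:]
    return "chr" + chrom
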