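"""Core genomic-interval data model, interval algebra, and flat-file IO.

Coordinates are 0-based, half-open everywhere (BED convention).  GTF's
1-based inclusive coordinates are converted on read.
"""

from __future__ import annotations

import re
from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

__all__ = [
    "GenomicRegion",
    "RegionSet",
    "GeneModel",
    "read_regions",
    "write_bed",
    "read_gtf_genes",
    "read_fasta",
    "write_fasta",
    "read_chrom_sizes",
    "filter_assembly",
    "overlap_partition",
    "merge_regions",
    "name_regions",
    "nearest_feature",
]


@dataclass
class GenomicRegion:
    """A half-open genomic interval ``[start, end)`` with optional summit.

    Parameters
    ----------
    chrom : str
        Chromosome identifier.
    start, end : int
        0-based half-open coordinates, ``0 <= start < end``.
    summit : int, optional
        0-based position of maximal occupancy, ``start <= summit < end``.
    name : str, optional
        Free-text label.
    score : float, optional
    summit_imputed : bool
        True when the summit was imputed (e.g. midpoint fallback for
        narrowPeak records with summit offset -1).
    """

    chrom: str
    start: int
    end: int
    summit: int | None = None
    name: str | None = None
    score: float | None = None
    summit_imputed: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:[{self.start},{self.end})"
            )
        if self.summit is not None and not (self.start <= self.summit < self.end):
            raise ValueError(
                f"summit {self.summit} outside {self.chrom}:[{self.start},{self.end})"
            )

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicRegion") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def key(self) -> tuple:
        return (self.chrom, self.start, self.end, self.name)


class RegionSet:
    """An ordered collection of :class:`GenomicRegion`.

    Canonicalizing operations keep regions sorted by ``(chrom, start, end)``
    and drop exact ``(chrom, start, end, name)`` duplicates.
    """

    def __init__(
        self,
        regions: Iterable[GenomicRegion] = (),
        genome_id: str = "",
        provenance: str = "",
    ) -> None:
        self.regions: list[GenomicRegion] = list(regions)
        self.genome_id = genome_id
        self.provenance = provenance

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self) -> Iterator[GenomicRegion]:
        return iter(self.regions)

    def __getitem__(self, i):
        return self.regions[i]

    def canonicalize(self) -> "RegionSet":
        """Return a sorted, duplicate-free copy."""
        seen: set[tuple] = set()
        out = []
        for r in sorted(self.regions, key=lambda r: (r.chrom, r.start, r.end)):
            k = r.key()
            if k not in seen:
                seen.add(k)
                out.append(r)
        return RegionSet(out, self.genome_id, self.provenance)

    def by_chrom(self) -> dict[str, list[GenomicRegion]]:
        d: dict[str, list[GenomicRegion]] = {}
        for r in self.regions:
            d.setdefault(r.chrom, []).append(r)
        return d


@dataclass
class GeneModel:
    """A gene with a strand-aware transcription start site."""

    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    tss: int
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_DIALECTS = ("bed", "summit_bed", "narrowpeak")


def read_regions(path: str, dialect: str = "bed") -> RegionSet:
    """Read a BED-family file into a :class:`RegionSet`.

    ``dialect`` selects parsing rules:

    - ``bed``: columns chrom/start/end[/name[/score]].
    - ``summit_bed``: MACS2 ``*_summits.bed``; each record is a 1-bp
      interval whose start is taken as the summit.
    - ``narrowpeak``: ENCODE narrowPeak; column 10 is the summit offset
      from start, with -1 meaning "no summit called", imputed as the
      region midpoint and flagged.
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")
    regions = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                regions.append(_parse_record(fields, dialect))
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed record: {exc}") from exc
    return RegionSet(regions, provenance=f"read_regions({path}, {dialect})")


def _parse_record(fields: Sequence[str], dialect: str) -> GenomicRegion:
    chrom, start, end = fields[0], int(fields[1]), int(fields[2])
    if end <= start:
        raise ValueError(f"end {end} <= start {start}")
    name = fields[3] if len(fields) > 3 and fields[3] not in (".", "") else None
    score = None
    if len(fields) > 4 and fields[4] not in (".", ""):
        score = float(fields[4])
    if dialect == "bed":
        return GenomicRegion(chrom, start, end, name=name, score=score)
    if dialect == "summit_bed":
        return GenomicRegion(chrom, start, end, summit=start, name=name, score=score)
    # narrowpeak
    offset = int(fields[9])
    if offset == -1:
        summit = (start + end) // 2
        imputed = True
    else:
        summit = start + offset
        imputed = False
    score = float(fields[6]) if len(fields) > 6 and fields[6] != "." else score
    return GenomicRegion(
        chrom, start, end, summit=summit, name=name, score=score,
        summit_imputed=imputed,
    )


def write_bed(rs: RegionSet, path: str) -> None:
    """Write chrom/start/end[/name[/score]] records, tab-separated."""
    with open(path, "w") as fh:
        for r in rs:
            cols = [r.chrom, str(r.start), str(r.end)]
            if r.name is not None or r.score is not None:
                cols.append(r.name if r.name is not None else ".")
            if r.score is not None:
                cols.append(_fmt_score(r.score))
            fh.write("\t".join(cols) + "\n")


def _fmt_score(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(x)


_GTF_ATTR = re.compile(r'(\w+) "([^"]*)"')


def read_gtf_genes(path: str) -> list[GeneModel]:
    """Extract gene models from ``gene`` feature lines of a GTF file.

    Requires the ``gene_id`` attribute; ``gene_name`` falls back to the id
    and ``gene_biotype`` to ``protein_coding``.  TSS is the 0-based gene
    start on ``+`` and end-1 on ``-``.
    """
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GTF columns")
            if fields[2] != "gene":
                continue
            chrom, start1, end1, strand = fields[0], int(fields[3]), int(fields[4]), fields[6]
            attrs = dict(_GTF_ATTR.findall(fields[8]))
            if "gene_id" not in attrs:
                raise ValueError(f"{path}:{lineno}: gene line lacks gene_id")
            start0 = start1 - 1  # GTF is 1-based inclusive
            tss = start0 if strand == "+" else end1 - 1
            genes.append(
                GeneModel(
                    gene_id=attrs["gene_id"],
                    gene_name=attrs.get("gene_name", attrs["gene_id"]),
                    chrom=chrom,
                    strand=strand,
                    tss=tss,
                    biotype=attrs.get("gene_biotype", "protein_coding"),
                )
            )
    return genes


def read_fasta(path: str) -> dict[str, str]:
    """Read a FASTA file into an ordered name -> uppercase sequence dict."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fasta(seqs: dict[str, str], path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_chrom_sizes(path: str) -> dict[str, int]:
    """Read a two-column ``<chrom>\\t<length>`` table (.fai-style prefix)."""
    sizes = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            fields = line.split("\t")
            sizes[fields[0]] = int(fields[1])
    return sizes


# ---------------------------------------------------------------------------
# interval algebra
# ---------------------------------------------------------------------------


def filter_assembly(
    rs: RegionSet,
    allowed_chroms: str | Sequence[str] | None = None,
    blacklist: RegionSet | None = None,
) -> RegionSet:
    """Drop regions on disallowed chromosomes or overlapping a blacklist.

    ``allowed_chroms`` is either an explicit list of chromosome names or a
    regex matched against the start of the name (e.g. ``"NC"`` keeps only
    complete-assembly accessions).  Blacklist removal uses >=1 bp overlap.
    Input order is preserved.
    """
    regions = list(rs.regions)
    if allowed_chroms is not None:
        if isinstance(allowed_chroms, str):
            pat = re.compile(allowed_chroms)
            regions = [r for r in regions if pat.match(r.chrom)]
        else:
            allowed = set(allowed_chroms)
            if not allowed:
                raise ValueError("allowed_chroms list is empty")
            regions = [r for r in regions if r.chrom in allowed]
    if blacklist is not None and len(blacklist):
        index = _OverlapIndex(blacklist)
        regions = [r for r in regions if not index.overlaps(r)]
    return RegionSet(regions, rs.genome_id, rs.provenance)


class _OverlapIndex:
    """Sorted-interval index answering any-overlap queries in O(log n)."""

    def __init__(self, rs: RegionSet) -> None:
        self._starts: dict[str, list[int]] = {}
        self._prefmax_end: dict[str, list[int]] = {}
        for chrom, regs in rs.by_chrom().items():
            regs = sorted(regs, key=lambda r: r.start)
            starts = [r.start for r in regs]
            prefmax = []
            m = 0
            for r in regs:
                m = max(m, r.end)
                prefmax.append(m)
            self._starts[chrom] = starts
            self._prefmax_end[chrom] = prefmax

    def overlaps(self, r: GenomicRegion) -> bool:
        starts = self._starts.get(r.chrom)
        if not starts:
            return False
        # candidates have start < r.end; overlap iff the max end among them > r.start
        i = bisect_left(starts, r.end)
        return i > 0 and self._prefmax_end[r.chrom][i - 1] > r.start


def overlap_partition(
    a: RegionSet, b: RegionSet
) -> tuple[RegionSet, RegionSet, RegionSet, RegionSet]:
    """Partition each set by >=1 bp overlap with the other.

    Returns ``(a_only, a_overlapping, b_only, b_overlapping)``.  Counts are
    per input region: a region of ``a`` spanning two regions of ``b``
    contributes once to ``a_overlapping`` (and both spanned regions appear
    in ``b_overlapping``).
    """
    ib = _OverlapIndex(b)
    ia = _OverlapIndex(a)
    a_only, a_over = [], []
    for r in a:
        (a_over if ib.overlaps(r) else a_only).append(r)
    b_only, b_over = [], []
    for r in b:
        (b_over if ia.overlaps(r) else b_only).append(r)
    return (
        RegionSet(a_only, a.genome_id, "a_only"),
        RegionSet(a_over, a.genome_id, "a_overlapping"),
        RegionSet(b_only, b.genome_id, "b_only"),
        RegionSet(b_over, b.genome_id, "b_overlapping"),
    )


def merge_regions(rs: RegionSet) -> RegionSet:
    """Collapse every chain of >=1 bp-overlapping regions to its envelope.

    Output is sorted and non-overlapping; each merged region's name lists
    the member region names (comma-separated) as provenance.
    """
    out = []
    for chrom in sorted(rs.by_chrom()):
        regs = sorted(rs.by_chrom()[chrom], key=lambda r: (r.start, r.end))
        cur_start, cur_end = regs[0].start, regs[0].end
        members = [regs[0]]
        for r in regs[1:]:
            if r.start < cur_end:  # overlap: chain continues
                cur_end = max(cur_end, r.end)
                members.append(r)
            else:
                out.append(_envelope(chrom, cur_start, cur_end, members))
                cur_start, cur_end, members = r.start, r.end, [r]
        out.append(_envelope(chrom, cur_start, cur_end, members))
    return RegionSet(out, rs.genome_id, f"merge({rs.provenance})")


def _envelope(chrom: str, start: int, end: int, members: list[GenomicRegion]) -> GenomicRegion:
    names = [m.name for m in members if m.name]
    return GenomicRegion(chrom, start, end, name=",".join(names) if names else None)


def name_regions(rs: RegionSet, prefix: str) -> RegionSet:
    """Assign sequential names ``<prefix><i>`` (existing names are replaced;
    originals survive as provenance where merge ops put them)."""
    out = [
        GenomicRegion(r.chrom, r.start, r.end, summit=r.summit,
                      name=f"{prefix}{i}", score=r.score,
                      summit_imputed=r.summit_imputed)
        for i, r in enumerate(rs)
    ]
    return RegionSet(out, rs.genome_id, rs.provenance)


def nearest_feature(
    rs: RegionSet, genes: Sequence[GeneModel]
) -> list[tuple[str | None, int | None]]:
    """Annotate each region with the gene whose TSS is nearest its center.

    Distance is measured region center -> TSS; the sign follows the gene
    strand, negative meaning the region lies upstream of the TSS.  Ties on
    absolute distance break toward the lexicographically smaller gene_id.
    Regions on chromosomes without genes get ``(None, None)``.
    """
    if not genes:
        raise ValueError("gene collection is empty")
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom in by_chrom:
        by_chrom[chrom].sort(key=lambda g: (g.tss, g.gene_id))
    tss_sorted = {c: [g.tss for g in gs] for c, gs in by_chrom.items()}

    out: list[tuple[str | None, int | None]] = []
    for r in rs:
        gs = by_chrom.get(r.chrom)
        if not gs:
            out.append((None, None))
            continue
        center = r.center
        tss_list = tss_sorted[r.chrom]
        i = bisect_left(tss_list, center)
        best_abs = min(
            abs(tss_list[j] - center) for j in (i - 1, i) if 0 <= j < len(gs)
        )
        # all genes at exactly best_abs (TSS == center +/- best_abs), then tie-break
        cands: list[GeneModel] = []
        for t in {center - best_abs, center + best_abs}:
            lo = bisect_left(tss_list, t)
            hi = bisect_right(tss_list, t)
            cands.extend(gs[lo:hi])
        best = min(cands, key=lambda g: g.gene_id)
        signed = center - best.tss if best.strand == "+" else best.tss - center
        out.append((best.gene_id, signed))
    return out
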