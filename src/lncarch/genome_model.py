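"""Gene-annotation domain model and annotation-format I/O.

Internal coordinates are 0-based half-open on the forward strand
throughout the package; conversion to/from the 1-based closed GFF3
convention happens only at the I/O edges.  Genes are collapsed to one
representative per locus: the span and exon set are the unions over all
transcripts of the gene.
"""

from __future__ import annotations

import logging
from bisect import insort
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Sequence, Tuple

log = logging.getLogger(__name__)

LNCRNA = "lncRNA"
PROTEIN_CODING = "protein_coding"

#: GFF3 attribute keys probed, in order, to discover a gene's biotype.
BIOTYPE_KEYS = ("gene_biotype", "gene_type", "biotype")


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent annotation input."""


def merge_intervals(intervals: Iterable[Tuple[int, int]]) -> List[Tuple[int, int]]:
    """Merge overlapping/adjacent half-open intervals into a sorted disjoint list."""
    ivs = sorted(intervals)
    merged: List[Tuple[int, int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene locus: span, strand, exon structure and biotype.

    Parameters
    ----------
    gene_id : str
        Unique identifier within an annotation set.
    chrom : str
        Chromosome / contig name.
    start, end : int
        0-based half-open genomic span, ``0 <= start < end``.
    strand : str
        ``"+"`` or ``"-"``.
    exons : tuple of (int, int)
        Sorted, disjoint half-open exon intervals contained in
        ``[start, end)``; at least one.
    biotype : str
        ``"lncRNA"``, ``"protein_coding"``, or any other label (genes with
        other labels are retained but belong to neither analysis set).
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: Tuple[Tuple[int, int], ...]
    biotype: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise AnnotationError(
                f"{self.gene_id}: invalid span [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"{self.gene_id}: strand required, got {self.strand!r}")
        if not self.exons:
            raise AnnotationError(f"{self.gene_id}: at least one exon required")
        prev_end = None
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                raise AnnotationError(
                    f"{self.gene_id}: exon ({s}, {e}) outside span "
                    f"[{self.start}, {self.end})"
                )
            if prev_end is not None and s < prev_end:
                raise AnnotationError(f"{self.gene_id}: exons overlap or unsorted")
            prev_end = e

    # -- derived geometry ------------------------------------------------

    @property
    def tss(self) -> int:
        """Transcription start site coordinate (5' end on the gene's strand)."""
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        """Transcription end site coordinate (3' end on the gene's strand)."""
        return self.end if self.strand == "+" else self.start

    @property
    def introns(self) -> Tuple[Tuple[int, int], ...]:
        """Half-open intervals between consecutive exons."""
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
            if self.exons[i][1] < self.exons[i + 1][0]
        )

    @property
    def is_lncrna(self) -> bool:
        return self.biotype == LNCRNA

    @property
    def is_protein_coding(self) -> bool:
        return self.biotype == PROTEIN_CODING

    def overlaps(self, other: "GeneAnnotation") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


class GenomeAnnotationSet:
    """Collection of :class:`GeneAnnotation` with a per-chromosome sorted index."""

    def __init__(self, genes: Iterable[GeneAnnotation] = ()) -> None:
        self._genes: Dict[str, GeneAnnotation] = {}
        # chrom -> list of (start, end, gene_id) sorted by (start, end, gene_id)
        self._index: Dict[str, List[Tuple[int, int, str]]] = {}
        for g in genes:
            self.add(g)

    def add(self, gene: GeneAnnotation) -> None:
        if gene.gene_id in self._genes:
            raise AnnotationError(f"duplicate identifier: {gene.gene_id}")
        self._genes[gene.gene_id] = gene
        insort(self._index.setdefault(gene.chrom, []), (gene.start, gene.end, gene.gene_id))

    def __len__(self) -> int:
        return len(self._genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._genes

    def __getitem__(self, gene_id: str) -> GeneAnnotation:
        return self._genes[gene_id]

    def __iter__(self) -> Iterator[GeneAnnotation]:
        """Iterate genes in deterministic coordinate order (chrom, start, end, id)."""
        for chrom in sorted(self._index):
            for _, _, gid in self._index[chrom]:
                yield self._genes[gid]

    @property
    def chromosomes(self) -> List[str]:
        return sorted(self._index)

    def on_chrom(self, chrom: str) -> List[GeneAnnotation]:
        """Genes on one chromosome, sorted by start."""
        return [self._genes[gid] for _, _, gid in self._index.get(chrom, [])]

    def subset_biotype(self, biotype: str) -> "GenomeAnnotationSet":
        return GenomeAnnotationSet(g for g in self if g.biotype == biotype)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def _prescan_gff3(path: Path) -> None:
    """Validate basic GFF3 line structure, reporting 1-based line numbers."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise AnnotationError(
                    f"{path}: malformed GFF3 line {lineno}: expected 9 "
                    f"tab-separated fields, got {len(fields)}"
                )
            try:
                int(fields[3]), int(fields[4])
            except ValueError:
                raise AnnotationError(
                    f"{path}: malformed GFF3 line {lineno}: non-integer coordinates"
                ) from None


def read_gff3(path, biotype_keys: Sequence[str] = BIOTYPE_KEYS) -> GenomeAnnotationSet:
    """Read a GFF3 file into a :class:`GenomeAnnotationSet`.

    Gene features are collapsed to one record per gene: the exon set is the
    union of all descendant exons (across transcripts), merged where
    overlapping.  GFF3 1-based closed coordinates are converted to the
    internal 0-based half-open convention (``start - 1``, ``end``).  The
    biotype is taken from the first attribute key present among
    ``biotype_keys``; genes with no or unrecognized biotype are retained
    with that label as-is (they are neither lncRNA nor protein-coding).

    A gene without exon descendants gets its full span as a single exon
    (with a logged warning).
    """
    import gffutils

    path = Path(path)
    _prescan_gff3(path)
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="error",
        )
    except Exception as exc:  # gffutils raises ValueError on ID clashes
        if "duplicate" in str(exc).lower() or "already" in str(exc).lower():
            raise AnnotationError(f"{path}: duplicate identifier ({exc})") from exc
        raise AnnotationError(f"{path}: GFF3 parse error: {exc}") from exc

    aset = GenomeAnnotationSet()
    for gene in db.features_of_type("gene"):
        start0, end0 = gene.start - 1, gene.end
        exons = [
            (ex.start - 1, ex.end)
            for ex in db.children(gene.id, featuretype="exon")
        ]
        if exons:
            exons = merge_intervals(exons)
            start0 = min(start0, exons[0][0])
            end0 = max(end0, exons[-1][1])
        else:
            log.warning("gene %s has no exons; using gene span as single exon", gene.id)
            exons = [(start0, end0)]
        biotype = "unknown"
        for key in biotype_keys:
            if key in gene.attributes:
                biotype = gene.attributes[key][0]
                break
        aset.add(
            GeneAnnotation(
                gene_id=gene.id,
                chrom=gene.seqid,
                start=start0,
                end=end0,
                strand=gene.strand,
                exons=tuple(exons),
                biotype=biotype,
            )
        )
    return aset


def write_gff3(aset: GenomeAnnotationSet, path) -> None:
    """Write an annotation set as GFF3 (gene + exon features, 1-based closed)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in aset:
            attrs = f"ID={g.gene_id};gene_biotype={g.biotype}"
            fh.write(
                f"{g.chrom}\tlncarch\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for i, (s, e) in enumerate(g.exons, start=1):
                fh.write(
                    f"{g.chrom}\tlncarch\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                )


# ---------------------------------------------------------------------------
# BED12
# ---------------------------------------------------------------------------

def read_bed12(path, biotype: str) -> GenomeAnnotationSet:
    """Read a BED12 file; blocks become exons; all records get ``biotype``.

    BED coordinates are natively 0-based half-open and are kept as-is.
    """
    path = Path(path)
    aset = GenomeAnnotationSet()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise AnnotationError(
                    f"{path}: line {lineno}: BED12 requires 12 fields, got {len(f)}"
                )
            chrom, start, end, name, _score, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
            if strand not in ("+", "-"):
                raise AnnotationError(f"{path}: line {lineno}: strand required")
            n_blocks = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",") if x != ""]
            offsets = [int(x) for x in f[11].rstrip(",").split(",") if x != ""]
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise AnnotationError(
                    f"{path}: line {lineno}: blockCount={n_blocks} does not match "
                    f"blockSizes/blockStarts arity ({len(sizes)}/{len(offsets)})"
                )
            exons = tuple((start + o, start + o + s) for o, s in zip(offsets, sizes))
            aset.add(
                GeneAnnotation(
                    gene_id=name,
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    exons=exons,
                    biotype=biotype,
                )
            )
    return aset


def write_bed12(aset: GenomeAnnotationSet, path) -> None:
    """Write an annotation set as BED12 (exons as blocks), coordinate-sorted."""
    with open(path, "w") as fh:
        for g in aset:
            sizes = ",".join(str(e - s) for s, e in g.exons)
            offsets = ",".join(str(s - g.start) for s, _ in g.exons)
            fh.write(
                "\t".join(
                    [
                        g.chrom,
                        str(g.start),
                        str(g.end),
                        g.gene_id,
                        "0",
                        g.strand,
                        str(g.start),
                        str(g.end),
                        "0",
                        str(len(g.exons)),
                        sizes,
                        offsets,
                    ]
                )
                + "\n"
            )


def write_pairs_bed(pairs, path) -> None:
    """Write classified pairs as BED6+3.

    Columns: chrom, lnc start, lnc end, lncRNA id, 0, lnc strand,
    partner id, GA class, super-class.  Deterministically ordered by
    coordinate (then id).
    """
    rows = sorted(
        pairs, key=lambda p: (p.chrom, p.lnc_start, p.lnc_end, p.lncrna_id)
    )
    with open(path, "w") as fh:
        for p in rows:
            fh.write(
                "\t".join(
                    [
                        p.chrom,
                        str(p.lnc_start),
                        str(p.lnc_end),
                        p.lncrna_id,
                        "0",
                        p.lnc_strand,
                        p.partner_id,
                        p.ga.name,
                        p.ga.superclass,
                    ]
                )
                + "\n"
            )
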