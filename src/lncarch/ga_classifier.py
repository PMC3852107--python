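"""Genomic-architecture (GA) classification of lncRNA / protein-coding gene pairs.

Each lncRNA gene is paired with the closest protein-coding gene on the same
chromosome within an association radius (default 10 kbp; overlap counts as
distance 0), and the pair is assigned exactly one of 19 positional
architecture classes, which collapse onto 5 super-classes (antisense,
intronic, intergenic, bidirectional, promoter-associated).

Class definitions (first matching rule wins; all coordinates 0-based
half-open; "upstream"/"downstream" are relative to the protein-coding
gene's strand):

Overlapping pairs (span overlap > 0)
  intronic_{sense,antisense}
      lncRNA wholly inside one intron of the protein.
  exonic_{sense,antisense}
      lncRNA span contained in the protein span with the overlap restricted
      to exonic sequence.
  embedding_{sense,antisense}
      one gene's span contains the other's and the overlap touches both
      exonic and intronic sequence of the protein.
  head_to_head
      residual partial antisense overlap covering the protein's 5' end
      (divergent 5'-5' overlap).
  tail_to_tail
      residual partial antisense overlap covering the protein's 3' end
      (convergent 3'-3' overlap).
  (Residual *same-strand* partial overlaps resolve to exonic_sense if the
  overlap is purely exonic, else embedding_sense, keeping the rule total.)

Non-overlapping pairs
  promoter_associated_{sense,antisense}
      lncRNA lying entirely inside the 1 kbp window immediately upstream
      of the protein TSS (a short promoter-resident RNA), same / opposite
      strand.
  bidirectional_promoter_{1,5,10}kbp
      divergent pair (opposite strands, lncRNA on the protein's 5' side,
      transcription pointing apart) not contained in the promoter window;
      binned by TSS-to-TSS distance: (0,1000], (1000,5000], (5000,10000].
  intergenic_upstream_{1,5,10}kbp
      non-divergent (same-strand) lncRNA on the protein's 5' side, binned
      by closest-edge distance.
  intergenic_downstream_{1,5,10}kbp
      lncRNA on the protein's 3' side (either strand), binned by
      closest-edge distance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Tuple

from .genome_model import GeneAnnotation, GenomeAnnotationSet

#: Association radius in bp: a lncRNA with no protein-coding gene within
#: this edge distance is unassociated.
DEFAULT_RADIUS = 10_000

#: Width of the promoter window immediately upstream of the protein TSS.
DEFAULT_PROMOTER_WINDOW = 1_000

#: Distance bins, bp, half-open on the left: (0,1000], (1000,5000], (5000,10000].
DEFAULT_BIN_EDGES = (1_000, 5_000, 10_000)

SUPERCLASSES = (
    "antisense",
    "intronic",
    "intergenic",
    "bidirectional",
    "promoter_associated",
)

#: The 19 class labels in rule-priority / enumeration order.
GA_CLASS_NAMES = (
    "intronic_sense",
    "intronic_antisense",
    "exonic_sense",
    "exonic_antisense",
    "embedding_sense",
    "embedding_antisense",
    "head_to_head",
    "tail_to_tail",
    "promoter_associated_sense",
    "promoter_associated_antisense",
    "bidirectional_promoter_1kbp",
    "bidirectional_promoter_5kbp",
    "bidirectional_promoter_10kbp",
    "intergenic_upstream_1kbp",
    "intergenic_upstream_5kbp",
    "intergenic_upstream_10kbp",
    "intergenic_downstream_1kbp",
    "intergenic_downstream_5kbp",
    "intergenic_downstream_10kbp",
)

# Super-class mapping: the embedding/exonic/head-to-head/tail-to-tail overlap
# architectures form the antisense super-class (sense subtypes included — the
# group describes overlap topology; orientation is tracked separately);
# intronic is its own group; distance classes map by name.
_SUPERCLASS_OF: Dict[str, str] = {
    "intronic_sense": "intronic",
    "intronic_antisense": "intronic",
    "exonic_sense": "antisense",
    "exonic_antisense": "antisense",
    "embedding_sense": "antisense",
    "embedding_antisense": "antisense",
    "head_to_head": "antisense",
    "tail_to_tail": "antisense",
    "promoter_associated_sense": "promoter_associated",
    "promoter_associated_antisense": "promoter_associated",
    "bidirectional_promoter_1kbp": "bidirectional",
    "bidirectional_promoter_5kbp": "bidirectional",
    "bidirectional_promoter_10kbp": "bidirectional",
    "intergenic_upstream_1kbp": "intergenic",
    "intergenic_upstream_5kbp": "intergenic",
    "intergenic_upstream_10kbp": "intergenic",
    "intergenic_downstream_1kbp": "intergenic",
    "intergenic_downstream_5kbp": "intergenic",
    "intergenic_downstream_10kbp": "intergenic",
}

_PRIORITY = {name: i for i, name in enumerate(GA_CLASS_NAMES)}

_BIN_LABELS = ("1kbp", "5kbp", "10kbp")


@dataclass(frozen=True)
class GAClass:
    """One of the 19 architecture classes.

    ``distance_bin`` is ``"none"`` except for the intergenic and
    bidirectional classes; ``orientation`` records the strand relation of
    the pair (``"n/a"`` for the distance-binned classes whose definition
    fixes or ignores it).
    """

    name: str
    superclass: str
    distance_bin: str = "none"
    orientation: str = "n/a"

    def __post_init__(self) -> None:
        if self.name not in _PRIORITY:
            raise ValueError(f"unknown GA class: {self.name}")
        if self.superclass != _SUPERCLASS_OF[self.name]:
            raise ValueError(f"{self.name} is not a {self.superclass} class")

    @property
    def priority(self) -> int:
        """Rank in the rule order; smaller = more specific."""
        return _PRIORITY[self.name]


def make_ga_class(name: str, orientation: str = "n/a") -> GAClass:
    bin_label = "none"
    for lbl in _BIN_LABELS:
        if name.endswith("_" + lbl):
            bin_label = lbl
    return GAClass(
        name=name,
        superclass=_SUPERCLASS_OF[name],
        distance_bin=bin_label,
        orientation=orientation,
    )


def superclass_of(ga) -> str:
    """Map a GA class (or its name) to its super-class label."""
    name = ga.name if isinstance(ga, GAClass) else str(ga)
    try:
        return _SUPERCLASS_OF[name]
    except KeyError:
        raise ValueError(f"unknown GA class: {name}") from None


@dataclass(frozen=True)
class ArchitecturePair:
    """A classified lncRNA / protein-coding gene pair."""

    lncrna_id: str
    partner_id: str
    ga: GAClass
    edge_distance: int
    tss_distance: int
    overlap_bp: int
    # lncRNA coordinates, carried for deterministic output ordering / BED.
    chrom: str = ""
    lnc_start: int = 0
    lnc_end: int = 0
    lnc_strand: str = "+"


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def edge_distance(a: GeneAnnotation, b: GeneAnnotation) -> int:
    """Distance in bp between closest gene boundaries; 0 if they overlap."""
    if a.chrom != b.chrom:
        raise ValueError("edge_distance requires genes on the same chromosome")
    return max(0, a.start - b.end, b.start - a.end)


def _overlap_interval(a: GeneAnnotation, b: GeneAnnotation) -> Optional[Tuple[int, int]]:
    s, e = max(a.start, b.start), min(a.end, b.end)
    return (s, e) if s < e else None


def _interval_intersection_len(
    iv: Tuple[int, int], pieces: Iterable[Tuple[int, int]]
) -> int:
    s0, e0 = iv
    return sum(max(0, min(e0, e) - max(s0, s)) for s, e in pieces)


def _promoter_window(prot: GeneAnnotation, width: int) -> Tuple[int, int]:
    """Half-open window of ``width`` bp immediately upstream of the TSS."""
    if prot.strand == "+":
        return (prot.start - width, prot.start)
    return (prot.end, prot.end + width)


def _is_upstream(lnc: GeneAnnotation, prot: GeneAnnotation) -> bool:
    """True iff the (non-overlapping) lncRNA lies beyond the protein's 5' end."""
    if prot.strand == "+":
        return lnc.end <= prot.start
    return lnc.start >= prot.end


def _bin_label(distance: int, bin_edges: Tuple[int, int, int]) -> Optional[str]:
    for edge, lbl in zip(bin_edges, _BIN_LABELS):
        if distance <= edge:
            return lbl
    return None


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_pair(
    lnc: GeneAnnotation,
    prot: GeneAnnotation,
    *,
    promoter_window: int = DEFAULT_PROMOTER_WINDOW,
    bin_edges: Tuple[int, int, int] = DEFAULT_BIN_EDGES,
) -> GAClass:
    """Assign the GA class of one lncRNA / protein-coding gene pair.

    The pair is assumed associated (within the radius used by
    :func:`find_partner`); the rules are total over such pairs, so exactly
    one of the 19 labels is returned.
    """
    if lnc.chrom != prot.chrom:
        raise ValueError("classify_pair requires genes on the same chromosome")

    same_strand = lnc.strand == prot.strand
    orientation = "sense" if same_strand else "antisense"
    suffix = "_sense" if same_strand else "_antisense"
    ov = _overlap_interval(lnc, prot)

    if ov is not None:
        # lncRNA wholly inside one intron of the protein
        for istart, iend in prot.introns:
            if istart <= lnc.start and lnc.end <= iend:
                return make_ga_class("intronic" + suffix, orientation)
        exonic_ov = _interval_intersection_len(ov, prot.exons)
        purely_exonic = exonic_ov == (ov[1] - ov[0])
        lnc_in_prot = prot.start <= lnc.start and lnc.end <= prot.end
        prot_in_lnc = lnc.start <= prot.start and prot.end <= lnc.end
        if lnc_in_prot or prot_in_lnc:
            if purely_exonic:
                return make_ga_class("exonic" + suffix, orientation)
            return make_ga_class("embedding" + suffix, orientation)
        # residual partial overlap: exactly one gene end of the protein is covered
        if same_strand:
            name = "exonic_sense" if purely_exonic else "embedding_sense"
            return make_ga_class(name, orientation)
        covers_prot_left = lnc.start < prot.start
        covers_prot_5p = covers_prot_left == (prot.strand == "+")
        return make_ga_class("head_to_head" if covers_prot_5p else "tail_to_tail", orientation)

    # non-overlapping
    wstart, wend = _promoter_window(prot, promoter_window)
    if wstart <= lnc.start and lnc.end <= wend:
        return make_ga_class("promoter_associated" + suffix, orientation)

    upstream = _is_upstream(lnc, prot)
    if upstream and not same_strand:
        # divergent: both TSSs face the shared intergenic gap
        tdist = abs(lnc.tss - prot.tss)
        lbl = _bin_label(tdist, bin_edges)
        if lbl is not None:
            return make_ga_class(f"bidirectional_promoter_{lbl}", orientation)
        # TSS distance beyond the last bin (long divergent lncRNA whose far
        # TSS exceeds the radius): fall back to edge-binned intergenic.
    side = "upstream" if upstream else "downstream"
    dist = edge_distance(lnc, prot)
    lbl = _bin_label(max(dist, 1), bin_edges)
    if lbl is None:
        raise ValueError(
            f"pair {lnc.gene_id}/{prot.gene_id} at edge distance {dist} is "
            f"outside the association bins"
        )
    return make_ga_class(f"intergenic_{side}_{lbl}", orientation)


def find_partner(
    lnc: GeneAnnotation,
    proteins: GenomeAnnotationSet,
    radius: int = DEFAULT_RADIUS,
) -> Optional[str]:
    """Closest protein-coding gene id within ``radius`` bp, or None.

    Overlap counts as distance 0.  Ties on edge distance are broken by the
    higher-priority (more specific) GA class of the resulting pair, then
    lexicographically smaller gene_id.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    best: Optional[Tuple[int, int, str]] = None
    for prot in proteins.on_chrom(lnc.chrom):
        if not prot.is_protein_coding:
            continue
        if prot.start > lnc.end + radius:
            break
        d = edge_distance(lnc, prot)
        if d > radius:
            continue
        prio = classify_pair(lnc, prot).priority
        key = (d, prio, prot.gene_id)
        if best is None or key < best:
            best = key
    return best[2] if best else None


def classify_all(
    lncs: GenomeAnnotationSet,
    proteins: GenomeAnnotationSet,
    radius: int = DEFAULT_RADIUS,
    *,
    promoter_window: int = DEFAULT_PROMOTER_WINDOW,
    bin_edges: Tuple[int, int, int] = DEFAULT_BIN_EDGES,
) -> Tuple[List[ArchitecturePair], List[str]]:
    """Pair and classify every lncRNA.

    Returns ``(pairs, unassociated)``: one :class:`ArchitecturePair` per
    lncRNA with a partner within ``radius``, in deterministic coordinate
    order, plus the ids of lncRNAs with no partner.
    """
    pairs: List[ArchitecturePair] = []
    orphans: List[str] = []
    for lnc in lncs:
        if not lnc.is_lncrna:
            continue
        pid = find_partner(lnc, proteins, radius)
        if pid is None:
            orphans.append(lnc.gene_id)
            continue
        prot = proteins[pid]
        ga = classify_pair(lnc, prot, promoter_window=promoter_window, bin_edges=bin_edges)
        ov = _overlap_interval(lnc, prot)
        pairs.append(
            ArchitecturePair(
                lncrna_id=lnc.gene_id,
                partner_id=pid,
                ga=ga,
                edge_distance=edge_distance(lnc, prot),
                tss_distance=abs(lnc.tss - prot.tss),
                overlap_bp=(ov[1] - ov[0]) if ov else 0,
                chrom=lnc.chrom,
                lnc_start=lnc.start,
                lnc_end=lnc.end,
                lnc_strand=lnc.strand,
            )
        )
    return pairs, orphans


def pairs_to_frame(pairs: List[ArchitecturePair]):
    """Tabulate classified pairs as a pandas DataFrame (stable column order)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "lncrna_id": p.lncrna_id,
                "partner_id": p.partner_id,
                "ga_class": p.ga.name,
                "superclass": p.ga.superclass,
                "edge_distance": p.edge_distance,
                "tss_distance": p.tss_distance,
                "overlap_bp": p.overlap_bp,
            }
            for p in pairs
        ],
        columns=[
            "lncrna_id",
            "partner_id",
            "ga_class",
            "superclass",
            "edge_distance",
            "tss_distance",
            "overlap_bp",
        ],
    )
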