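"""Synthetic annotation sets and timecourses with planted ground truth.

The generator emulates the study design the pipeline targets: lncRNA /
protein-coding gene pairs laid out on one synthetic chromosome, one
geometry per requested architecture class, and replicated 4-point
timecourses (two biological replicates at 0/6/24/120 h by default) built
from dynamic-mode templates plus Gaussian noise, with a planted positive /
negative / absent lncRNA-protein correlation per pair.

Geometries are constructed by direct placement arithmetic from the class
definitions (distances sampled inside the correct bin, overlaps built per
class), independently of the classifier's predicate code, so
classifier round-trip tests are a genuine two-implementation check.
Pair groups are separated by more than the association radius, making
partner-finding unambiguous.  All randomness flows from ``spec.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .genome_model import (
    LNCRNA,
    PROTEIN_CODING,
    GeneAnnotation,
    GenomeAnnotationSet,
    write_bed12,
    write_gff3,
)
from .ga_classifier import DEFAULT_RADIUS, GA_CLASS_NAMES
from .expression import (
    DEFAULT_TIMEPOINTS,
    ExpressionTimecourse,
    kendall_tau,
    write_expression_tsv,
)
from . import dynamic_modes as dm

CHROM = "chrS"

#: Reference protein-coding gene in the local construction frame
#: (protein on '+', TSS at 0): 8 kbp span, three exons.
_PROT_SPAN = (0, 8000)
_PROT_EXONS = ((0, 1000), (3000, 4500), (7000, 8000))


@dataclass(frozen=True)
class SimulationSpec:
    """Study-condition parameters of the synthetic dataset.

    Defaults mirror the emulated design: two biological replicates at
    0/6/24/120 h, linear-scale intensities with baseline 100 and a 10x
    dynamic range, Gaussian noise sigma 0.2 on unit-range templates, and
    one pair per architecture class.
    """

    seed: int = 0
    n_pairs_per_class: Mapping[str, int] = field(
        default_factory=lambda: {name: 1 for name in GA_CLASS_NAMES}
    )
    chrom_length: Optional[int] = None
    spacing: int = 25_000
    noise_sigma: float = 0.2
    mode_family: str = dm.RATE
    mode_mix: Optional[Mapping[str, float]] = None
    corr_probs: Mapping[str, float] = field(
        default_factory=lambda: {"+": 0.4, "-": 0.4, "none": 0.2}
    )
    corr_plan: Optional[Sequence[str]] = None
    n_replicates: int = 2
    timepoints: Tuple[int, ...] = DEFAULT_TIMEPOINTS
    baseline: float = 100.0
    dyn_range: float = 10.0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if any(c < 0 for c in self.n_pairs_per_class.values()):
            raise ValueError("pair counts must be >= 0")
        if self.mode_mix is not None and abs(sum(self.mode_mix.values()) - 1) > 1e-9:
            raise ValueError("mode_mix probabilities must sum to 1")
        if abs(sum(self.corr_probs.values()) - 1) > 1e-9:
            raise ValueError("corr_probs must sum to 1")
        if self.n_replicates < 2:
            raise ValueError("at least 2 replicates")
        unknown = set(self.n_pairs_per_class) - set(GA_CLASS_NAMES)
        if unknown:
            raise ValueError(f"unknown GA classes in spec: {sorted(unknown)}")


# ---------------------------------------------------------------------------
# geometry construction
# ---------------------------------------------------------------------------

def _sample_gap(rng: np.random.Generator, bin_label: str) -> int:
    """An intergenic gap strictly inside one distance bin (margin kept)."""
    lo, hi = {"1kbp": (200, 1000), "5kbp": (1100, 5000), "10kbp": (5100, 9800)}[bin_label]
    return int(rng.integers(lo, hi + 1))


def _lnc_local_geometry(
    name: str, rng: np.random.Generator
) -> Tuple[int, int, bool]:
    """(start, end, same_strand) of the lncRNA in the protein's local frame.

    Protein occupies ``_PROT_SPAN`` on '+' with exons ``_PROT_EXONS``;
    coordinates may be negative (upstream of the TSS at 0).
    """
    if name.startswith("intronic"):
        # inside the (1000, 3000) intron, jittered
        s = int(rng.integers(1100, 2200))
        return s, int(rng.integers(s + 200, 2950)), not name.endswith("antisense")
    if name.startswith("exonic"):
        # inside the (3000, 4500) exon
        s = int(rng.integers(3050, 3900))
        return s, int(rng.integers(s + 100, 4480)), not name.endswith("antisense")
    if name.startswith("embedding"):
        # spans exon1/intron1/exon2 junctions, contained in the protein
        return int(rng.integers(200, 900)), int(rng.integers(3100, 4400)), not name.endswith("antisense")
    if name == "head_to_head":
        # pokes out past the protein 5' end, overlap inside exon1
        return -int(rng.integers(500, 2500)), int(rng.integers(100, 950)), False
    if name == "tail_to_tail":
        # pokes out past the protein 3' end, overlap inside exon3
        return int(rng.integers(7050, 7900)), 8000 + int(rng.integers(500, 2500)), False
    if name.startswith("promoter_associated"):
        # entirely within the 1 kbp upstream window (-1000, 0)
        length = int(rng.integers(200, 700))
        start = -1000 + int(rng.integers(0, 1000 - length + 1))
        return start, start + length, not name.endswith("antisense")
    if name.startswith("bidirectional_promoter") or name.startswith("intergenic_upstream"):
        gap = _sample_gap(rng, name.rsplit("_", 1)[1])
        length = int(rng.integers(1100, 2500))  # > window, never promoter-resident
        return -gap - length, -gap, name.startswith("intergenic")
    if name.startswith("intergenic_downstream"):
        gap = _sample_gap(rng, name.rsplit("_", 1)[1])
        length = int(rng.integers(1100, 2500))
        return 8000 + gap, 8000 + gap + length, True
    raise ValueError(f"unknown GA class: {name}")


def _place_pair(
    name: str,
    index: int,
    cursor: int,
    prot_plus: bool,
    rng: np.random.Generator,
) -> Tuple[GeneAnnotation, GeneAnnotation, int]:
    """Materialize one pair at ``cursor``; returns (lnc, prot, next free coord)."""
    ls, le, same = _lnc_local_geometry(name, rng)
    ps, pe = _PROT_SPAN
    exons = list(_PROT_EXONS)
    lnc_strand_plus = same

    if not prot_plus:
        # reflect the local frame: x -> -x, strands flip
        ls, le = -le, -ls
        ps, pe = -pe, -ps
        exons = sorted((-e, -s) for s, e in exons)
        lnc_strand_plus = not same

    lo = min(ls, ps)
    shift = cursor - lo
    lnc = GeneAnnotation(
        gene_id=f"lnc_{name}_{index:03d}",
        chrom=CHROM,
        start=ls + shift,
        end=le + shift,
        strand="+" if lnc_strand_plus else "-",
        exons=((ls + shift, le + shift),),
        biotype=LNCRNA,
    )
    prot = GeneAnnotation(
        gene_id=f"prot_{name}_{index:03d}",
        chrom=CHROM,
        start=ps + shift,
        end=pe + shift,
        strand="+" if prot_plus else "-",
        exons=tuple((s + shift, e + shift) for s, e in exons),
        biotype=PROTEIN_CODING,
    )
    return lnc, prot, max(le, pe) + shift


def simulate_annotations(spec: SimulationSpec) -> Tuple[GenomeAnnotationSet, pd.DataFrame]:
    """Construct the planted annotation set and its truth table.

    Returns the combined :class:`GenomeAnnotationSet` (lncRNAs and
    protein-coding genes) and a truth DataFrame with columns
    ``lncrna_id``, ``partner_id``, ``ga_class``.
    """
    rng = np.random.default_rng([spec.seed, 11])
    cursor = 1000
    genes: List[GeneAnnotation] = []
    truth_rows = []
    for name in GA_CLASS_NAMES:  # fixed order: determinism
        for i in range(spec.n_pairs_per_class.get(name, 0)):
            prot_plus = bool(rng.integers(0, 2))
            lnc, prot, top = _place_pair(name, i, cursor, prot_plus, rng)
            genes.extend([lnc, prot])
            truth_rows.append(
                {"lncrna_id": lnc.gene_id, "partner_id": prot.gene_id, "ga_class": name}
            )
            cursor = top + DEFAULT_RADIUS + spec.spacing
    required = cursor + 1000
    if spec.chrom_length is not None and spec.chrom_length < required:
        raise ValueError(
            f"chromosome too short: need at least {required} bp for this spec"
        )
    truth = pd.DataFrame(truth_rows, columns=["lncrna_id", "partner_id", "ga_class"])
    return GenomeAnnotationSet(genes), truth


# ---------------------------------------------------------------------------
# timecourse construction
# ---------------------------------------------------------------------------

def _unit(template: Sequence[float]) -> np.ndarray:
    t = np.asarray(template, dtype=float)
    return (t - t.min()) / (t.max() - t.min())


def _complement_mode(mode: dm.DynamicMode, modes: Sequence[dm.DynamicMode]) -> dm.DynamicMode:
    """The mode whose unit template is 1 - unit(template) of ``mode``.

    For rate modes this is the all-signs-flipped triple; for magnitude
    modes the 0/1 complement.  Both families are closed under it.
    """
    if mode.family == dm.RATE:
        sig = tuple("-" if s == "+" else "+" for s in mode.signature)
    else:
        sig = tuple(1 - v for v in mode.signature)
    for m in modes:
        if m.signature == sig:
            return m
    raise AssertionError(f"mode family not closed under complement at {mode.name}")


def _intensity(
    unit_profile: np.ndarray,
    spec: SimulationSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """Replicate x timepoint intensities: noisy unit template, linear scale.

    Gaussian noise (sd ``spec.noise_sigma``) is added on the unit-range
    scale per replicate and cell, truncated at 0 so intensities stay at or
    above baseline.
    """
    noisy = unit_profile[None, :] + rng.normal(
        0.0, spec.noise_sigma, size=(spec.n_replicates, len(unit_profile))
    )
    noisy = np.clip(noisy, 0.0, None)
    return spec.baseline * (1.0 + (spec.dyn_range - 1.0) * noisy)


def simulate_timecourses(
    spec: SimulationSpec, truth: pd.DataFrame
) -> Tuple[Dict[str, ExpressionTimecourse], pd.DataFrame]:
    """Plant modes and correlation signs; emit timecourses for every gene.

    The protein profile follows a mode template drawn from
    ``spec.mode_mix`` (uniform over the family by default).  The lncRNA
    follows the same template (planted sign "+"), its complement ("-"),
    or an independent low-|tau| decoy template ("none"), each with
    per-replicate Gaussian noise.  Returns the expression collection and
    the truth table extended with ``mode``, ``lnc_mode``, ``corr_sign``.
    """
    rng = np.random.default_rng([spec.seed, 23])
    modes = dm.enumerate_modes(spec.mode_family, len(spec.timepoints))
    by_name = {m.name: m for m in modes}
    if spec.mode_mix is not None:
        names = sorted(spec.mode_mix)
        probs = np.array([spec.mode_mix[n] for n in names])
    else:
        names = [m.name for m in modes]
        probs = np.full(len(modes), 1.0 / len(modes))
    if spec.corr_plan is not None and len(spec.corr_plan) != len(truth):
        raise ValueError("corr_plan length must match the number of pairs")

    expr: Dict[str, ExpressionTimecourse] = {}
    out_rows = []
    for i, row in enumerate(truth.itertuples(index=False)):
        mode = by_name[names[int(rng.choice(len(names), p=probs))]]
        sign = (
            spec.corr_plan[i]
            if spec.corr_plan is not None
            else str(rng.choice(list(spec.corr_probs), p=list(spec.corr_probs.values())))
        )
        prot_unit = _unit(mode.template)
        if sign == "+":
            lnc_mode = mode
            lnc_unit = prot_unit
        elif sign == "-":
            lnc_mode = _complement_mode(mode, modes)
            lnc_unit = 1.0 - prot_unit
        elif sign == "none":
            decoys = [
                m
                for m in modes
                if abs(kendall_tau(_unit(m.template), prot_unit)) < 0.6
            ]
            lnc_mode = decoys[int(rng.choice(len(decoys)))]
            lnc_unit = _unit(lnc_mode.template)
        else:
            raise ValueError(f"invalid planted correlation sign {sign!r}")

        expr[row.partner_id] = ExpressionTimecourse(
            gene_id=row.partner_id,
            timepoints=spec.timepoints,
            values=_intensity(prot_unit, spec, rng),
        )
        expr[row.lncrna_id] = ExpressionTimecourse(
            gene_id=row.lncrna_id,
            timepoints=spec.timepoints,
            values=_intensity(lnc_unit, spec, rng),
        )
        out_rows.append(
            {
                "lncrna_id": row.lncrna_id,
                "partner_id": row.partner_id,
                "ga_class": row.ga_class,
                "mode": mode.name,
                "lnc_mode": lnc_mode.name,
                "corr_sign": sign,
            }
        )
    out = pd.DataFrame(
        out_rows,
        columns=["lncrna_id", "partner_id", "ga_class", "mode", "lnc_mode", "corr_sign"],
    )
    return expr, out


@dataclass
class SimulatedDataset:
    annotations: GenomeAnnotationSet
    expression: Dict[str, ExpressionTimecourse]
    truth: pd.DataFrame


def simulate_dataset(spec: SimulationSpec) -> SimulatedDataset:
    """Compose annotation and timecourse generation with consistent ids."""
    annotations, truth = simulate_annotations(spec)
    expr, truth = simulate_timecourses(spec, truth)
    return SimulatedDataset(annotations=annotations, expression=expr, truth=truth)


def write_dataset(ds: SimulatedDataset, outdir) -> Dict[str, Path]:
    """Write GFF3 + per-biotype BED12 + expression TSV + truth TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "gff3": outdir / "annotations.gff3",
        "lnc_bed12": outdir / "lncrna.bed12",
        "prot_bed12": outdir / "protein.bed12",
        "expression": outdir / "expression.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_gff3(ds.annotations, paths["gff3"])
    write_bed12(ds.annotations.subset_biotype(LNCRNA), paths["lnc_bed12"])
    write_bed12(ds.annotations.subset_biotype(PROTEIN_CODING), paths["prot_bed12"])
    write_expression_tsv(ds.expression, paths["expression"])
    ds.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths


def spec_from_yaml(path) -> SimulationSpec:
    """Load a :class:`SimulationSpec` from a YAML mapping."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a YAML mapping of spec fields")
    if "timepoints" in raw:
        raw["timepoints"] = tuple(raw["timepoints"])
    return SimulationSpec(**raw)
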