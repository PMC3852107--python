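"""Expression timecourses, the differential-expression rule, pair
correlation, and the five-step filtration cascade.

The experimental design emulated here is a replicated 4-point timecourse
(0, 6, 24, 120 h; two biological replicates) of array intensities.  A gene
is differentially expressed (DE) when

* its replicates are rank-concordant on some 3-subset of the timepoints
  (Kendall's tau > 0.6 — on 3 untied points tau is ±1 or ±1/3, so this is
  perfect rank agreement on that subset), and
* the fold change between the first and last timepoint (replicate means,
  direction-symmetric) is at least 1.5.

lncRNA-protein pair correlation is Kendall's tau between the two
replicate-mean 4-point profiles; |tau| >= 0.6 calls a signed correlation
(on 4 untied points that admits exactly |tau| in {2/3, 1}).

The filtration cascade nests five memberships: (1) on the array, (2) DE,
(3) protein-associated, (4) partner also DE, (5) sign-correlated with the
partner; per-step frequency tables of architecture classes and dynamic
modes feed the enrichment module.

No normalization is applied anywhere; ``read_expression_tsv`` accepts a
pass-through ``normalizer`` hook for callers who need one.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Callable, Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

#: Hours of the emulated differentiation timecourse.
DEFAULT_TIMEPOINTS = (0, 6, 24, 120)


@dataclass(frozen=True)
class ExpressionTimecourse:
    """Replicate x timepoint intensity matrix for one gene."""

    gene_id: str
    timepoints: Tuple[int, ...]
    values: np.ndarray  # shape (n_replicates, n_timepoints), non-negative

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2 or v.shape[1] != len(self.timepoints):
            raise ValueError(f"{self.gene_id}: values must be replicates x timepoints")
        if v.shape[0] < 2:
            raise ValueError(f"{self.gene_id}: at least 2 replicates required")
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise ValueError(f"{self.gene_id}: intensities must be finite and non-negative")
        if np.any(np.diff(self.timepoints) <= 0):
            raise ValueError(f"{self.gene_id}: timepoints must be strictly increasing")

    @property
    def n_replicates(self) -> int:
        return self.values.shape[0]

    @property
    def means(self) -> np.ndarray:
        """Per-timepoint mean across replicates."""
        return self.values.mean(axis=0)

    @property
    def medians(self) -> np.ndarray:
        """Per-timepoint median across replicates."""
        return np.median(self.values, axis=0)


@dataclass(frozen=True)
class AnalysisConfig:
    """Thresholds of the expression analysis.

    tau_threshold
        Replicate-concordance cutoff for the DE rule (strict: tau must
        exceed it).
    fc_threshold
        Minimal first-to-last fold change (inclusive).
    subset_size
        Length of the timepoint subsets on which concordance is checked
        ("any three of the four").
    corr_threshold
        |tau| cutoff (inclusive) for calling a signed lncRNA-protein
        correlation.
    """

    tau_threshold: float = 0.6
    fc_threshold: float = 1.5
    subset_size: int = 3
    corr_threshold: float = 0.6

    def __post_init__(self) -> None:
        if min(self.tau_threshold, self.fc_threshold, self.corr_threshold) <= 0:
            raise ValueError("thresholds must be positive")
        if self.subset_size < 2:
            raise ValueError("subset_size must be at least 2")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_expression_tsv(
    path,
    normalizer: Optional[Callable[[pd.DataFrame], pd.DataFrame]] = None,
) -> Dict[str, ExpressionTimecourse]:
    """Read a replicated expression matrix.

    Expected layout: first column ``gene_id``; remaining column names
    ``r<replicate>_t<hours>`` (any order — the header drives assembly).
    ``normalizer``, if given, receives and returns the raw wide DataFrame
    before timecourse assembly (no normalization is applied by default).
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    df = df.set_index(df.columns[0])
    if normalizer is not None:
        df = normalizer(df)

    layout: List[Tuple[int, int, str]] = []
    for col in df.columns:
        m = _parse_column(col)
        if m is None:
            raise ValueError(f"{path}: unrecognized column header {col!r} (expected r<rep>_t<hours>)")
        layout.append((*m, col))
    reps = sorted({r for r, _, _ in layout})
    tps = sorted({t for _, t, _ in layout})
    want = {(r, t) for r in reps for t in tps}
    have = {(r, t) for r, t, _ in layout}
    if want != have:
        raise ValueError(f"{path}: incomplete replicate x timepoint grid: missing {sorted(want - have)}")
    colmap = {(r, t): c for r, t, c in layout}

    out: Dict[str, ExpressionTimecourse] = {}
    for gene_id, row in df.iterrows():
        if row.isna().any():
            missing = row.index[row.isna()][0]
            raise ValueError(f"{path}: missing value for gene {gene_id}, column {missing}")
        values = np.array([[float(row[colmap[(r, t)]]) for t in tps] for r in reps])
        if np.any(values < 0):
            raise ValueError(f"{path}: negative intensity for gene {gene_id}")
        out[str(gene_id)] = ExpressionTimecourse(
            gene_id=str(gene_id), timepoints=tuple(tps), values=values
        )
    return out


def _parse_column(col: str) -> Optional[Tuple[int, int]]:
    import re

    m = re.fullmatch(r"r(\d+)_t(\d+)", col.strip())
    return (int(m.group(1)), int(m.group(2))) if m else None


def write_expression_tsv(timecourses: Mapping[str, ExpressionTimecourse], path) -> None:
    """Inverse of :func:`read_expression_tsv` (columns sorted by rep, then hour)."""
    rows = []
    for gid in timecourses:
        tc = timecourses[gid]
        row = {"gene_id": gid}
        for ri in range(tc.n_replicates):
            for ti, t in enumerate(tc.timepoints):
                row[f"r{ri + 1}_t{t}"] = tc.values[ri, ti]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def kendall_tau(x: Sequence[float], y: Sequence[float]) -> float:
    """Kendall's rank correlation (tau-b tie correction).

    (concordant - discordant) / number of pairs for untied data; with ties
    the denominator is the tau-b geometric correction.  NaN if either
    vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("kendall_tau requires two equal-length vectors of length >= 2")
    return float(stats.kendalltau(x, y, variant="b").statistic)


def fold_change(tc: ExpressionTimecourse) -> float:
    """Direction-symmetric first/last fold change of the replicate means (>= 1)."""
    m_first, m_last = tc.means[0], tc.means[-1]
    lo, hi = min(m_first, m_last), max(m_first, m_last)
    if lo <= 0:
        raise ValueError(f"{tc.gene_id}: zero endpoint intensity, fold change undefined")
    return float(hi / lo)


@dataclass(frozen=True)
class DEResult:
    """DE verdict with the evidence behind it."""

    gene_id: str
    is_de: bool
    fold_change: float
    concordant: bool
    #: timepoint-index subsets on which every replicate pair exceeded tau.
    qualifying_subsets: Tuple[Tuple[int, ...], ...] = ()

    def __bool__(self) -> bool:
        return self.is_de


def is_differentially_expressed(tc: ExpressionTimecourse, cfg: AnalysisConfig = AnalysisConfig()) -> DEResult:
    """The DE rule: replicate concordance on some timepoint subset + fold change.

    For each replicate pair, concordance requires *some* subset of
    ``cfg.subset_size`` timepoints with ``kendall_tau > cfg.tau_threshold``
    on the two replicate profiles restricted to it; every replicate pair
    must have at least one such subset.  Fold change must be >=
    ``cfg.fc_threshold``.  Diagnostics list the subsets qualifying for all
    replicate pairs simultaneously.
    """
    n_t = len(tc.timepoints)
    if cfg.subset_size > n_t:
        raise ValueError("subset_size exceeds number of timepoints")
    subsets = list(itertools.combinations(range(n_t), cfg.subset_size))
    rep_pairs = list(itertools.combinations(range(tc.n_replicates), 2))

    per_pair_ok: List[set] = []
    for i, j in rep_pairs:
        ok = set()
        for sub in subsets:
            idx = list(sub)
            tau = stats.kendalltau(tc.values[i, idx], tc.values[j, idx], variant="b").statistic
            if np.isfinite(tau) and tau > cfg.tau_threshold:
                ok.add(sub)
        per_pair_ok.append(ok)

    concordant = all(ok for ok in per_pair_ok)
    common = set.intersection(*per_pair_ok) if per_pair_ok else set()
    fc = fold_change(tc)
    return DEResult(
        gene_id=tc.gene_id,
        is_de=bool(concordant and fc >= cfg.fc_threshold),
        fold_change=fc,
        concordant=concordant,
        qualifying_subsets=tuple(sorted(common)),
    )


@dataclass(frozen=True)
class PairCorrelation:
    lncrna_id: str
    partner_id: str
    tau: float
    sign: str  # "+", "-" or "none"


def correlate_pair(
    lnc_tc: ExpressionTimecourse,
    prot_tc: ExpressionTimecourse,
    cfg: AnalysisConfig = AnalysisConfig(),
) -> PairCorrelation:
    """Signed Kendall correlation between two replicate-mean profiles.

    "+" if tau >= cfg.corr_threshold, "-" if tau <= -cfg.corr_threshold,
    else "none".  On 4 untied points tau takes values in {0, ±1/3, ±2/3,
    ±1}, so the 0.6 cutoff admits exactly |tau| in {2/3, 1}.
    """
    if lnc_tc.timepoints != prot_tc.timepoints:
        raise ValueError("correlate_pair requires matching timepoints")
    tau = kendall_tau(lnc_tc.means, prot_tc.means)
    if np.isfinite(tau) and tau >= cfg.corr_threshold:
        sign = "+"
    elif np.isfinite(tau) and tau <= -cfg.corr_threshold:
        sign = "-"
    else:
        sign = "none"
    return PairCorrelation(
        lncrna_id=lnc_tc.gene_id, partner_id=prot_tc.gene_id, tau=tau, sign=sign
    )


# ---------------------------------------------------------------------------
# filtration cascade
# ---------------------------------------------------------------------------

#: Cascade step labels, in order.
CASCADE_STEPS = (
    "on_array",
    "differentially_expressed",
    "protein_associated",
    "partner_differentially_expressed",
    "correlated",
)


@dataclass
class CascadeResult:
    """Nested memberships and per-step frequency tables.

    ``flags`` is a per-lncRNA DataFrame with one boolean column per step
    plus ``correlation_sign`` and ``ga_class``/``superclass`` (``(none)``
    for unassociated lncRNAs); ``tables[step][kind]`` are value counts
    over the step's member set (kinds: ``ga_class``, ``superclass``, and
    one per supplied mode family).
    """

    flags: pd.DataFrame
    tables: Dict[str, Dict[str, pd.Series]]
    dropped: Tuple[str, ...] = ()

    def members(self, step: str) -> List[str]:
        return list(self.flags.index[self.flags[step]])

    def step_sizes(self) -> Dict[str, int]:
        return {s: int(self.flags[s].sum()) for s in CASCADE_STEPS}


def run_filtration_cascade(
    pairs: Sequence,
    expr: Mapping[str, ExpressionTimecourse],
    cfg: AnalysisConfig = AnalysisConfig(),
    lnc_ids: Optional[Iterable[str]] = None,
    mode_assignments: Optional[Mapping[str, Mapping[str, str]]] = None,
) -> CascadeResult:
    """Run the five filtration steps over a cohort of lncRNAs.

    Parameters
    ----------
    pairs
        Classified :class:`~lncarch.ga_classifier.ArchitecturePair` list
        (the protein-associated lncRNAs and their partners).
    expr
        Expression collection covering lncRNAs and partners; lncRNAs
        without an expression row are dropped with a warning count.
    cfg
        Thresholds.
    lnc_ids
        Full cohort of lncRNA ids ("on the array").  Defaults to the
        lncRNAs appearing in ``pairs``.
    mode_assignments
        Optional ``{family: {gene_id: mode_name}}`` used for per-step mode
        frequency tables.

    Memberships are nested by construction: each step's set is a subset of
    the previous one.
    """
    import logging

    log = logging.getLogger(__name__)

    pair_by_lnc = {p.lncrna_id: p for p in pairs}
    if lnc_ids is None:
        cohort = sorted(pair_by_lnc)
    else:
        cohort = sorted(set(lnc_ids))

    dropped = tuple(g for g in cohort if g not in expr)
    if dropped:
        log.warning("dropping %d lncRNAs with no expression row", len(dropped))
    cohort = [g for g in cohort if g in expr]

    rows = []
    for gid in cohort:
        p = pair_by_lnc.get(gid)
        on_array = True
        de = bool(is_differentially_expressed(expr[gid], cfg))
        associated = de and p is not None
        partner_de = bool(
            associated
            and p.partner_id in expr
            and is_differentially_expressed(expr[p.partner_id], cfg)
        )
        sign = "none"
        if partner_de:
            sign = correlate_pair(expr[gid], expr[p.partner_id], cfg).sign
        rows.append(
            {
                "lncrna_id": gid,
                "on_array": on_array,
                "differentially_expressed": de,
                "protein_associated": associated,
                "partner_differentially_expressed": partner_de,
                "correlated": sign != "none",
                "correlation_sign": sign,
                "ga_class": p.ga.name if p is not None else "(none)",
                "superclass": p.ga.superclass if p is not None else "(none)",
            }
        )
        if mode_assignments:
            for family, mapping in mode_assignments.items():
                rows[-1][f"mode_{family}"] = mapping.get(gid, "(unassigned)")
    mode_cols = [f"mode_{f}" for f in (mode_assignments or {})]
    flags = pd.DataFrame(
        rows,
        columns=[
            "lncrna_id",
            *CASCADE_STEPS,
            "correlation_sign",
            "ga_class",
            "superclass",
            *mode_cols,
        ],
    ).set_index("lncrna_id")

    tables: Dict[str, Dict[str, pd.Series]] = {}
    for step in CASCADE_STEPS:
        members = flags[flags[step]]
        kinds = {
            col: members[col].value_counts().sort_index()
            for col in ("ga_class", "superclass", *mode_cols)
        }
        tables[step] = kinds
    return CascadeResult(flags=flags, tables=tables, dropped=dropped)
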