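"""Temporal dynamic-mode templates and template-matching mode assignment.

Two families of eight modes describe a 4-point expression timecourse
(0, 6, 24, 120 h):

* **rate** modes — the sign pattern of expression change between
  consecutive timepoints; the eight modes are all 2**3 sign triples.  The
  numeric template of a sign triple is its cumulative sign path anchored
  at 0 (e.g. ``(+,+,-) -> (0, 1, 2, 1)``).
* **magnitude** modes — low/high (0/1) level patterns over the four
  timepoints: the three up-steps, the up-pulse, and their complements
  (constant patterns are excluded: Pearson correlation against them is
  undefined).

A gene's profile (replicate means by default, medians optionally) is
assigned the mode whose template has the highest Pearson correlation with
it.  Templates are indexed by timepoint *rank*, not by hours, so the
uneven 0/6/24/120 h spacing does not reweight late intervals: the modes
are ordinal patterns.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .expression import ExpressionTimecourse

RATE = "rate"
MAGNITUDE = "magnitude"

#: Rate-mode names, keyed by sign triple over the three intervals.
RATE_MODE_NAMES = {
    ("+", "+", "+"): "permanently_activated_by_6h",
    ("+", "+", "-"): "repressed_by_120h",
    ("+", "-", "-"): "transiently_activated_at_6h",
    ("+", "-", "+"): "transient_6h_spike_late_recovery",
    ("-", "+", "+"): "activated_by_24h",
    ("-", "+", "-"): "transiently_activated_at_24h",
    ("-", "-", "+"): "activated_by_120h",
    ("-", "-", "-"): "permanently_repressed_by_6h",
}

#: Magnitude-mode names keyed by 0/1 level signature over the 4 timepoints.
MAGNITUDE_MODE_NAMES = {
    (0, 1, 1, 1): "increased_by_6h",
    (0, 0, 1, 1): "increased_by_24h",
    (0, 0, 0, 1): "increased_by_120h",
    (0, 1, 1, 0): "transiently_increased_6_24h",
    (1, 0, 0, 0): "decreased_by_6h",
    (1, 1, 0, 0): "decreased_by_24h",
    (1, 1, 1, 0): "decreased_by_120h",
    (1, 0, 0, 1): "transiently_decreased_6_24h",
}


@dataclass(frozen=True)
class DynamicMode:
    """One template: family, name, signature and numeric 4-vector."""

    family: str
    name: str
    signature: Tuple
    template: Tuple[float, ...]

    def __post_init__(self) -> None:
        if len(set(self.template)) < 2:
            raise ValueError(f"constant template for mode {self.name}")


@dataclass(frozen=True)
class ModeAssignment:
    """Best-matching mode for one gene's profile.

    ``mode`` is None for an unassignable (zero-variance) profile.
    """

    gene_id: str
    family: str
    mode: Optional[str]
    pearson_r: float
    runner_up: Optional[str]
    runner_up_r: float
    tie: bool = False

    @property
    def assignable(self) -> bool:
        return self.mode is not None


def _rate_template(signs: Tuple[str, ...]) -> Tuple[float, ...]:
    """Cumulative sign path anchored at 0: (+,+,-) -> (0, 1, 2, 1)."""
    path = [0.0]
    for s in signs:
        path.append(path[-1] + (1.0 if s == "+" else -1.0))
    return tuple(path)


def enumerate_modes(family: str, n_timepoints: int = 4) -> List[DynamicMode]:
    """The eight modes of a family, in deterministic catalog order.

    Rate modes generalize to ``2**(n_timepoints-1)`` sign patterns for
    other timecourse lengths; the magnitude set is fixed for 4 timepoints.
    """
    if family == RATE:
        modes = []
        n = n_timepoints - 1
        for i in range(2**n):
            signs = tuple("+" if (i >> (n - 1 - j)) & 1 == 0 else "-" for j in range(n))
            name = RATE_MODE_NAMES.get(signs, "rate_" + "".join(signs))
            modes.append(
                DynamicMode(family=RATE, name=name, signature=signs, template=_rate_template(signs))
            )
        return modes
    if family == MAGNITUDE:
        if n_timepoints != 4:
            raise ValueError("magnitude modes are defined for 4 timepoints")
        return [
            DynamicMode(
                family=MAGNITUDE,
                name=name,
                signature=sig,
                template=tuple(float(v) for v in sig),
            )
            for sig, name in MAGNITUDE_MODE_NAMES.items()
        ]
    raise ValueError(f"unknown mode family: {family!r}")


def mode_catalog_frame(n_timepoints: int = 4):
    """Both mode families as a tidy DataFrame (for documentation dumps)."""
    import pandas as pd

    rows = []
    for family in (RATE, MAGNITUDE):
        for m in enumerate_modes(family, n_timepoints):
            rows.append(
                {
                    "family": m.family,
                    "name": m.name,
                    "signature": "".join(str(s) for s in m.signature),
                    "template": ",".join(f"{v:g}" for v in m.template),
                }
            )
    return pd.DataFrame(rows, columns=["family", "name", "signature", "template"])


def rate_signs(tc: ExpressionTimecourse, zero_sign: str = "-") -> Tuple[str, ...]:
    """Sign triple of consecutive differences of the per-timepoint medians.

    Zero differences map to ``zero_sign`` (default ``"-"``): a two-letter
    sign alphabet is required for the eight rate combinations.
    """
    med = tc.medians
    return tuple(
        "+" if d > 0 else ("-" if d < 0 else zero_sign) for d in np.diff(med)
    )


def _pearson_matrix(profiles: np.ndarray, templates: np.ndarray) -> np.ndarray:
    """Pearson r between each profile row and each template row.

    Rows with zero variance yield NaN correlations.
    """
    p = profiles - profiles.mean(axis=1, keepdims=True)
    t = templates - templates.mean(axis=1, keepdims=True)
    psd = np.sqrt((p**2).sum(axis=1))
    tsd = np.sqrt((t**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (p @ t.T) / np.outer(psd, tsd)
    return r


def score_profiles(profiles: np.ndarray, family: str) -> Tuple[np.ndarray, List[DynamicMode]]:
    """Pearson r of each profile (rows) against all 8 templates of a family."""
    profiles = np.asarray(profiles, dtype=float)
    if profiles.ndim == 1:
        profiles = profiles[None, :]
    modes = enumerate_modes(family, profiles.shape[1])
    templates = np.array([m.template for m in modes], dtype=float)
    return _pearson_matrix(profiles, templates), modes


def assign_mode(
    tc: ExpressionTimecourse, family: str, use_median: bool = False
) -> ModeAssignment:
    """Assign the best-correlating mode of a family to one timecourse.

    The profile is the per-timepoint replicate mean (median if
    ``use_median``).  Ties on Pearson r are broken by catalog order with
    the tie flag set.  A constant profile is unassignable, not an error.
    """
    profile = tc.medians if use_median else tc.means
    if np.ptp(profile) == 0:
        return ModeAssignment(
            gene_id=tc.gene_id,
            family=family,
            mode=None,
            pearson_r=float("nan"),
            runner_up=None,
            runner_up_r=float("nan"),
        )
    r, modes = score_profiles(profile, family)
    r = r[0]
    order = np.argsort(-r, kind="stable")
    best, second = int(order[0]), int(order[1])
    return ModeAssignment(
        gene_id=tc.gene_id,
        family=family,
        mode=modes[best].name,
        pearson_r=float(r[best]),
        runner_up=modes[second].name,
        runner_up_r=float(r[second]),
        tie=bool(np.isclose(r[best], r[second])),
    )


def assign_modes(
    timecourses: Sequence[ExpressionTimecourse], family: str, use_median: bool = False
) -> List[ModeAssignment]:
    """Vectorized :func:`assign_mode` over many timecourses."""
    return [assign_mode(tc, family, use_median) for tc in timecourses]


def assignments_to_frame(assignments: Sequence[ModeAssignment]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "gene_id": a.gene_id,
                "family": a.family,
                "mode": a.mode if a.mode is not None else "(unassignable)",
                "pearson_r": a.pearson_r,
                "runner_up": a.runner_up,
                "runner_up_r": a.runner_up_r,
                "tie": a.tie,
            }
            for a in assignments
        ],
        columns=["gene_id", "family", "mode", "pearson_r", "runner_up", "runner_up_r", "tie"],
    )
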