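"""Goodness-of-fit scoring, the deformation sweep, and tissue displacement.

Three area percentages summarize how a respirator's internal surface
sits on a face: *gap* (signed distance > 0 mm, air leakage paths),
*indentation* (< -3 mm, enough soft-tissue compression to put skin at
risk), and *adequate seal* (-3..0 mm, contact the soft tissues can
accommodate). A fourth, *conformity*, is the area within +/-1 mm of the
face and drives the choice of deformation level: sweep the ladder, then
pick the level combining high conformity with a narrow central-95%
distance interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .deform import DeformationLevel, nonrigid_icp
from .distances import (
    SignedDistanceMap,
    DistanceSummary,
    signed_distances,
    summarize_distances,
)
from .mesh import SurfaceMesh, apply_transform
from .rigid import ICPSettings, icp_align

__all__ = [
    "GoFThresholds",
    "GoFReport",
    "DeltaSweepResult",
    "gof_metrics",
    "select_delta_optimum",
    "run_delta_sweep",
    "tissue_displacement",
    "predict_fit",
]

#: Conformity ties closer than this (percentage points) fall through to
#: the CI-width tie-break.
CONFORMITY_TIE_TOL = 0.05


@dataclass(frozen=True)
class GoFThresholds:
    """Signed-distance band boundaries (mm).

    gap_min : distances strictly above this are gaps (default 0).
    indent_max : distances strictly below this are substantial
        indentation (default -3; beyond what facial soft tissue absorbs
        safely).
    conform_band : half-width of the conformity band (default 1).

    Band conventions mirror the strict gap/indent inequalities and the
    closed seal range: d = 0 and d = indent_max both count as seal, and
    the conformity band is inclusive on both ends.
    """

    gap_min: float = 0.0
    indent_max: float = -3.0
    conform_band: float = 1.0

    def __post_init__(self) -> None:
        if not self.indent_max < self.gap_min:
            raise ValueError("indent_max must be below gap_min")
        if self.conform_band <= 0:
            raise ValueError("conform_band must be positive")


@dataclass
class GoFReport:
    """Area percentages of the distance bands for one registration."""

    pct_gap: float
    pct_indent: float
    pct_seal: float
    pct_conform: float
    thresholds: GoFThresholds
    summary: DistanceSummary

    def as_dict(self) -> dict:
        return {
            "pct_gap": self.pct_gap,
            "pct_indent": self.pct_indent,
            "pct_seal": self.pct_seal,
            "pct_conform": self.pct_conform,
            "ci_width": self.summary.ci_width,
            "p_low": self.summary.p_low,
            "p_high": self.summary.p_high,
        }


def gof_metrics(
    dmap: SignedDistanceMap, thresholds: GoFThresholds | None = None
) -> GoFReport:
    """Band the signed distances and report area-weighted percentages.

    gap: d > gap_min; indentation: d < indent_max; seal: the closed
    remainder. The three always partition to 100%. Conformity
    (|d| <= conform_band) overlaps the others and is reported alongside.
    """
    thresholds = thresholds or GoFThresholds()
    d, w = dmap.distances, dmap.weights
    total = w.sum()
    if total <= 0 or len(d) == 0:
        raise ValueError("empty distance map")
    pct = lambda mask: float(100.0 * w[mask].sum() / total)  # noqa: E731
    report = GoFReport(
        pct_gap=pct(d > thresholds.gap_min),
        pct_indent=pct(d < thresholds.indent_max),
        pct_seal=pct((d >= thresholds.indent_max) & (d <= thresholds.gap_min)),
        pct_conform=pct(np.abs(d) <= thresholds.conform_band),
        thresholds=thresholds,
        summary=summarize_distances(dmap),
    )
    return report


def select_delta_optimum(
    conformities,
    ci_widths=None,
    levels: list[DeformationLevel] | None = None,
) -> tuple[DeformationLevel, float]:
    """Pick the optimum deformation level from a sweep.

    Primary criterion: maximum conformity percentage. Conformities tied
    within 0.05 percentage points fall through to the smaller central-95%
    width (when ``ci_widths`` is given), and any remaining tie goes to
    the stiffer level. Returns ``(level, conformity_at_level)``.

    When ``levels`` is omitted, nine values are taken as
    delta_1..delta_8 followed by rigid, and n values as delta_1..delta_n.
    """
    conformities = np.asarray(conformities, dtype=np.float64)
    n = len(conformities)
    if n == 0:
        raise ValueError("no levels to select from")
    if levels is None:
        if n == 9:
            levels = DeformationLevel.ladder(include_rigid=True)
        else:
            levels = [DeformationLevel.from_index(k) for k in range(1, n + 1)]
    if len(levels) != n:
        raise ValueError("levels and conformities must have equal length")
    if ci_widths is not None:
        ci_widths = np.asarray(ci_widths, dtype=np.float64)
        if len(ci_widths) != n:
            raise ValueError("ci_widths and conformities must have equal length")
    best = conformities.max()
    tied = np.flatnonzero(conformities >= best - CONFORMITY_TIE_TOL)
    if ci_widths is not None and len(tied) > 1:
        narrowest = ci_widths[tied].min()
        tied = tied[ci_widths[tied] <= narrowest]
    # remaining tie: stiffer level wins (RIGID counts as stiffest)
    pick = max(tied, key=lambda i: (levels[i]._sort_key(), -i))
    return levels[pick], float(conformities[pick])


@dataclass
class DeltaSweepResult:
    """Per-level fit reports and the selected optimum."""

    levels: list[DeformationLevel]
    reports: list[GoFReport]
    maps: list[SignedDistanceMap]
    optimum: DeformationLevel
    optimum_conformity: float
    selection_trace: dict = field(default_factory=dict)

    def report_for(self, level: DeformationLevel) -> GoFReport:
        return self.reports[self.levels.index(level)]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for level, report in zip(self.levels, self.reports):
            rows.append(
                {
                    "level": level.label,
                    "stiffness": (
                        np.nan if level.is_rigid else level.stiffness
                    ),
                    **report.as_dict(),
                    "is_optimum": level == self.optimum,
                }
            )
        return pd.DataFrame(rows)


def run_delta_sweep(
    respirator_internal: SurfaceMesh,
    unloaded_face: SurfaceMesh,
    loaded_face: SurfaceMesh,
    levels: list[DeformationLevel] | None = None,
    settings: ICPSettings | None = None,
    thresholds: GoFThresholds | None = None,
    weighting: str = "area",
) -> DeltaSweepResult:
    """Sweep the deformation ladder and score fit against the loaded face.

    For each level the respirator's internal surface is aligned and
    deformed toward the *unloaded* face, the (deformed or rigid) result
    is rigidly registered onto the *loaded* face, and the signed-distance
    distribution is banded into the GoF percentages. Inputs are expected
    in a common frame (see ``align_cascade``).

    The registration onto the loaded face trims the worst 20% of
    correspondences per round unless explicit settings are passed: the
    loaded face deviates from the deformed respirator exactly where the
    tissue moved, and those regions are what is being measured, so they
    must not steer the alignment.
    """
    levels = levels or DeformationLevel.ladder(include_rigid=True)
    if len(levels) == 0:
        raise ValueError("levels must be non-empty")
    loaded_settings = settings or ICPSettings(correspondence_trim_fraction=0.2)
    reports: list[GoFReport] = []
    maps: list[SignedDistanceMap] = []
    for level in levels:
        deformed, _, _ = nonrigid_icp(
            respirator_internal, unloaded_face, level, settings
        )
        onto_loaded = icp_align(deformed, loaded_face, loaded_settings)
        registered = apply_transform(deformed, onto_loaded.transform)
        dmap = signed_distances(registered, loaded_face, weighting=weighting)
        reports.append(gof_metrics(dmap, thresholds))
        maps.append(dmap)
    conformities = [r.pct_conform for r in reports]
    ci_widths = [r.summary.ci_width for r in reports]
    optimum, opt_conf = select_delta_optimum(conformities, ci_widths, levels)
    return DeltaSweepResult(
        levels=levels,
        reports=reports,
        maps=maps,
        optimum=optimum,
        optimum_conformity=opt_conf,
        selection_trace={
            "conformities": conformities,
            "ci_widths": ci_widths,
        },
    )


def tissue_displacement(
    unloaded_face: SurfaceMesh,
    loaded_face: SurfaceMesh,
    settings: ICPSettings | None = None,
    weighting: str = "area",
) -> tuple[SignedDistanceMap, DistanceSummary]:
    """Quantify facial soft-tissue displacement from the two facial scans.

    The loaded face (respirator in situ) is rigidly registered onto the
    unloaded face; signed distances of the loaded vertices against the
    unloaded surface are negative where tissue is pressed inward and
    positive where it bulges out. The summary's 2.5th / 97.5th
    percentiles are reported as the negative / positive soft-tissue
    displacements produced by donning the respirator.

    By default the alignment trims the worst 20% of correspondences each
    round: the two scans genuinely differ wherever the respirator pressed
    the tissue, and those regions must not drag the rigid alignment that
    is supposed to be anchored on unchanged tissue.
    """
    if settings is None:
        settings = ICPSettings(correspondence_trim_fraction=0.2)
    result = icp_align(loaded_face, unloaded_face, settings)
    registered = apply_transform(loaded_face, result.transform)
    dmap = signed_distances(registered, unloaded_face, weighting=weighting)
    return dmap, summarize_distances(dmap)


def predict_fit(
    unloaded_face: SurfaceMesh,
    respirator_internal: SurfaceMesh,
    optimum: DeformationLevel,
    settings: ICPSettings | None = None,
    thresholds: GoFThresholds | None = None,
    weighting: str = "area",
) -> GoFReport:
    """Final fit prediction: deform at the optimum level onto the
    unloaded face and band the resulting signed distances."""
    deformed, _, _ = nonrigid_icp(
        respirator_internal, unloaded_face, optimum, settings
    )
    dmap = signed_distances(deformed, unloaded_face, weighting=weighting)
    return gof_metrics(dmap, thresholds)
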