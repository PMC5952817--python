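"""Patient-level ischemic burden from per-segment perfusion assessments.

Each of the 16 AHA segments (apical cap excluded) is split into an
endocardial and an epicardial half, giving 32 sub-segments per patient, each
carrying a fraction of total left-ventricular mass. A sub-segment is ischemic
when its myocardial perfusion reserve (MPR) falls below 1.5; sub-segments
with late gadolinium enhancement (LGE, scar) are excluded from ischemia
assessment. Ischemic burden is the mass fraction of myocardium classified
ischemic; the dichotomized test results use the consensus thresholds of
>= 2 visually ischemic AHA segments and >= 10% MPR-ischemic myocardium.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

__all__ = [
    "SegmentStatus",
    "BurdenResult",
    "MPR_ISCHEMIA_THRESHOLD",
    "VISUAL_SEGMENT_THRESHOLD",
    "MPR_BURDEN_THRESHOLD",
    "subdivide_segments",
    "classify_segment_ischemia",
    "compute_ischemic_burden",
    "dichotomize",
    "burden_table",
]

#: MPR below this value defines an ischemic segment.
MPR_ISCHEMIA_THRESHOLD = 1.5
#: Visually positive test: at least this many ischemic AHA segments.
VISUAL_SEGMENT_THRESHOLD = 2
#: Quantitatively positive test: at least this fraction of myocardium ischemic.
MPR_BURDEN_THRESHOLD = 0.10

N_AHA_SEGMENTS = 16
N_SUB_SEGMENTS = 32
MASS_TOL = 1e-9


class SegmentStatus(str, Enum):
    ISCHEMIC = "ischemic"
    NORMAL = "normal"
    EXCLUDED_LGE = "excluded_lge"
    NON_ANALYZABLE = "non_analyzable"


@dataclass(frozen=True)
class BurdenResult:
    """Patient-level burden summary and dichotomized test results."""

    visual_burden: float
    mpr_burden: float
    visual_positive: bool
    mpr_positive: bool
    n_visual_segments: int


def subdivide_segments(
    aha_model: pd.DataFrame, endo_mass_share: float = 0.5
) -> pd.DataFrame:
    """Split a 16-segment AHA map into 32 endo/epi sub-segment records.

    ``aha_model`` needs columns ``aha_segment`` (1..16, each exactly once)
    and ``mass_fraction``; any other columns are copied onto both halves.
    Mass is conserved: each segment's fraction is split ``endo_mass_share`` /
    ``1 - endo_mass_share`` (default 50/50).
    """
    segs = set(aha_model["aha_segment"])
    if segs != set(range(1, N_AHA_SEGMENTS + 1)) or len(aha_model) != N_AHA_SEGMENTS:
        raise ValueError("aha_model must contain each AHA segment 1-16 exactly once")
    if not 0.0 < endo_mass_share < 1.0:
        raise ValueError("endo_mass_share must lie strictly between 0 and 1")
    halves = []
    for half, share in (("endo", endo_mass_share), ("epi", 1.0 - endo_mass_share)):
        part = aha_model.copy()
        part["half"] = half
        part["mass_fraction"] = part["mass_fraction"] * share
        halves.append(part)
    out = pd.concat(halves, ignore_index=True)
    return out.sort_values(["aha_segment", "half"], ignore_index=True)


def classify_segment_ischemia(
    mpr: float, lge: bool, mpr_threshold: float = MPR_ISCHEMIA_THRESHOLD
) -> SegmentStatus:
    """Status of one sub-segment: scar excludes it from ischemia assessment
    regardless of MPR; otherwise MPR < threshold (strict) is ischemic, a
    missing MPR is non-analyzable."""
    if lge:
        return SegmentStatus.EXCLUDED_LGE
    if mpr is None or not np.isfinite(mpr):
        return SegmentStatus.NON_ANALYZABLE
    return SegmentStatus.ISCHEMIC if mpr < mpr_threshold else SegmentStatus.NORMAL


def compute_ischemic_burden(
    segments: pd.DataFrame,
    mode: str = "mpr",
    mpr_threshold: float = MPR_ISCHEMIA_THRESHOLD,
    renormalize_lge: bool = False,
) -> float:
    """Mass fraction of myocardium classified ischemic for one patient.

    ``segments`` holds the patient's 32 sub-segment records with columns
    ``mass_fraction``, ``lge`` and, depending on ``mode``, ``mpr`` or
    ``visual_ischemic``. LGE sub-segments contribute nothing to the
    numerator; by default the denominator remains total LV mass (1.0), with
    ``renormalize_lge=True`` restricting it to scar-free mass instead.
    """
    if len(segments) != N_SUB_SEGMENTS:
        raise ValueError(f"expected {N_SUB_SEGMENTS} sub-segment records, got {len(segments)}")
    total = float(segments["mass_fraction"].sum())
    if abs(total - 1.0) > MASS_TOL:
        raise ValueError(f"mass fractions must sum to 1, got {total!r}")
    if mode not in ("mpr", "visual"):
        raise ValueError("mode must be 'mpr' or 'visual'")

    lge = segments["lge"].astype(bool).to_numpy()
    if mode == "mpr":
        status = [
            classify_segment_ischemia(m, g, mpr_threshold)
            for m, g in zip(segments["mpr"], lge)
        ]
        ischemic = np.array([s is SegmentStatus.ISCHEMIC for s in status])
    else:
        ischemic = segments["visual_ischemic"].astype(bool).to_numpy() & ~lge

    mass = segments["mass_fraction"].to_numpy(dtype=float)
    numerator = float(mass[ischemic].sum())
    denom = float(mass[~lge].sum()) if renormalize_lge else 1.0
    return numerator / denom if denom > 0 else 0.0


def dichotomize(
    segments: pd.DataFrame,
    visual_burden: float,
    mpr_burden: float,
    visual_segment_threshold: int = VISUAL_SEGMENT_THRESHOLD,
    mpr_burden_threshold: float = MPR_BURDEN_THRESHOLD,
) -> BurdenResult:
    """Apply the consensus positivity thresholds to one patient.

    The visual rule counts ischemic AHA segments at the 16-segment level — a
    segment counts once if either of its halves is flagged and it is free of
    scar — and is positive at >= ``visual_segment_threshold`` segments
    (inclusive). The quantitative rule is positive at
    ``mpr_burden >= mpr_burden_threshold`` (inclusive).
    """
    if visual_segment_threshold <= 0 or mpr_burden_threshold <= 0:
        raise ValueError("thresholds must be positive")
    flagged = segments[
        segments["visual_ischemic"].astype(bool) & ~segments["lge"].astype(bool)
    ]
    n_visual = int(flagged["aha_segment"].nunique())
    return BurdenResult(
        visual_burden=float(visual_burden),
        mpr_burden=float(mpr_burden),
        visual_positive=n_visual >= visual_segment_threshold,
        mpr_positive=mpr_burden >= mpr_burden_threshold,
        n_visual_segments=n_visual,
    )


def burden_table(
    segments: pd.DataFrame, mpr: pd.DataFrame | None = None, **kwargs
) -> pd.DataFrame:
    """Per-patient burden table from a multi-patient segment table.

    ``segments`` follows the synthetic segment-table layout (patient_id,
    aha_segment, half, mass_fraction, lge, visual_ischemic); ``mpr``
    optionally supplies measured MPR per (patient_id, aha_segment, half),
    otherwise a ``mpr`` or ``mpr_true`` column on ``segments`` is used.
    Returns patient_id, visual_burden, mpr_burden, visual_positive,
    mpr_positive, n_visual_segments.
    """
    df = segments.copy()
    if mpr is not None:
        df = df.merge(
            mpr[["patient_id", "aha_segment", "half", "mpr"]],
            on=["patient_id", "aha_segment", "half"],
            how="left",
        )
    elif "mpr" not in df.columns:
        if "mpr_true" not in df.columns:
            raise ValueError("no MPR values available: pass an mpr table or column")
        df["mpr"] = df["mpr_true"]

    rows = []
    for pid, grp in df.groupby("patient_id", sort=True):
        vis = compute_ischemic_burden(grp, mode="visual", **kwargs)
        qnt = compute_ischemic_burden(grp, mode="mpr", **kwargs)
        res = dichotomize(grp, vis, qnt)
        rows.append(
            dict(
                patient_id=pid,
                visual_burden=res.visual_burden,
                mpr_burden=res.mpr_burden,
                visual_positive=res.visual_positive,
                mpr_positive=res.mpr_positive,
                n_visual_segments=res.n_visual_segments,
            )
        )
    return pd.DataFrame(rows)
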