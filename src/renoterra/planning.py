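"""Surgical-planning quantities: total volumes, KVLS and PKVL.

KVLS (kidney volume loss at surgery) is the actual loss measured across scans:
``Vol_Tot_pre - Vol_Tot_post`` in cm3.  PKVL (predicted kidney volume loss) is
the preoperative prediction: the summed territory volumes of every endpoint
planned (or observed) to be lost.  Both are reported as absolute volumes and
as percentages of the preoperative total — the preoperative volume is the sole
percentage denominator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .errors import DegenerateInputError, ValidationError
from .image_io import FiducialSet, ParenchymaMask
from .territory import TerritoryTable

PHASE_PRE = "pre"
PHASE_POST = "post"


@dataclass
class VolumeSummary:
    """Total segmented parenchyma volume of one scan phase."""

    scan_phase: str
    vol_tot_cm3: float

    def __post_init__(self) -> None:
        if self.scan_phase not in (PHASE_PRE, PHASE_POST):
            raise ValidationError(f"scan_phase must be 'pre' or 'post', got {self.scan_phase!r}")
        if not self.vol_tot_cm3 > 0:
            raise ValidationError(f"vol_tot_cm3 must be positive, got {self.vol_tot_cm3}")


@dataclass
class PlanResult:
    """KVLS/PKVL figures for one pre/post pair (or a prospective plan).

    KVLS fields are ``None`` for prospective plans with no postoperative scan.
    """

    pkvl_cm3: float
    pkvl_pct: float
    lost_endpoint_names: list[str] = field(default_factory=list)
    kvls_cm3: float | None = None
    kvls_pct: float | None = None

    def to_dict(self) -> dict:
        return {
            "kvls_cm3": self.kvls_cm3,
            "kvls_pct": self.kvls_pct,
            "pkvl_cm3": self.pkvl_cm3,
            "pkvl_pct": self.pkvl_pct,
            "lost_endpoint_names": list(self.lost_endpoint_names),
        }


def total_volume(mask: ParenchymaMask, scan_phase: str = PHASE_PRE) -> VolumeSummary:
    """Total parenchyma volume in cm3 (voxel count x voxel volume / 1000)."""
    if not mask.occupancy.any():  # ParenchymaMask already guards; belt and braces
        raise DegenerateInputError("mask has no foreground voxels")
    return VolumeSummary(scan_phase=scan_phase, vol_tot_cm3=mask.volume_cm3)


def compute_kvls(pre: VolumeSummary, post: VolumeSummary) -> tuple[float, float]:
    """Actual kidney volume loss at surgery, as (cm3, % of preoperative).

    Negative values (postoperative volume above preoperative) are allowed but
    flagged with a warning — small cross-scan measurement noise is plausible.
    """
    if pre.scan_phase != PHASE_PRE or post.scan_phase != PHASE_POST:
        raise ValidationError(
            f"expected (pre, post) summaries, got ({pre.scan_phase!r}, {post.scan_phase!r})"
        )
    if not pre.vol_tot_cm3 > 0:
        raise ValidationError("preoperative volume must be positive")
    kvls_cm3 = pre.vol_tot_cm3 - post.vol_tot_cm3
    if kvls_cm3 < 0:
        warnings.warn(
            f"negative KVLS ({kvls_cm3:.1f} cm3): postoperative volume exceeds preoperative",
            stacklevel=2,
        )
    return kvls_cm3, 100.0 * kvls_cm3 / pre.vol_tot_cm3


def match_endpoints(pre: FiducialSet, post: FiducialSet) -> list[str]:
    """Endpoint names present preoperatively but absent (by exact name) after
    surgery — the 'no longer visible' endings whose territories count as lost.

    Order follows the preoperative file.  A postoperative endpoint name with no
    preoperative counterpart triggers a warning (new or renamed ending), not an
    error.
    """
    pre_names = pre.endpoint_names()
    post_names = set(post.endpoint_names())
    new = sorted(post_names - set(pre_names))
    if new:
        warnings.warn(
            f"postoperative endpoints with no preoperative counterpart: {new}", stacklevel=2
        )
    return [n for n in pre_names if n not in post_names]


def compute_pkvl(pre_table: TerritoryTable, lost: list[str]) -> tuple[float, float]:
    """Predicted kidney volume loss, as (cm3, % of preoperative total).

    The prediction assumes an ending that disappears takes its whole territory
    with it, so PKVL is the sum of the lost endpoints' preoperative territory
    volumes.
    """
    known = set(pre_table.endpoints["name"])
    unknown = [n for n in lost if n not in known]
    if unknown:
        raise ValidationError(f"lost endpoints not in preoperative table: {unknown}")
    pkvl_cm3 = float(sum(pre_table.volume_of(n) for n in lost))
    return pkvl_cm3, 100.0 * pkvl_cm3 / pre_table.total_volume_cm3


def make_plan(
    pre_table: TerritoryTable,
    lost: list[str],
    pre: VolumeSummary | None = None,
    post: VolumeSummary | None = None,
) -> PlanResult:
    """Assemble a :class:`PlanResult`; KVLS is filled only when both scan
    summaries are given (retrospective validation)."""
    pkvl_cm3, pkvl_pct = compute_pkvl(pre_table, lost)
    result = PlanResult(pkvl_cm3=pkvl_cm3, pkvl_pct=pkvl_pct, lost_endpoint_names=list(lost))
    if pre is not None and post is not None:
        result.kvls_cm3, result.kvls_pct = compute_kvls(pre, post)
    return result
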