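"""Per-patient comparison of electrical synchrony across pacing settings.

A pacing session holds one set of chamber metrics per programmed setting
(intrinsic rhythm plus up to four paced configurations).  The
configuration table — the data behind a "pacing configuration plot" —
shows how LV80 and RV80 shorten or lengthen under each setting relative to
the intrinsic rhythm, and how similar they are to each other (|LVRVDIFF|,
the interventricular electrical synchrony score).  The recommendation rule
operationalises the visual reading of such plots: prefer the paced setting
with the smallest |LVRVDIFF|, since interventricular synchrony is the
electrical quantity tied to LV functional response.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .geometry import PACED_SETTINGS, PacingSetting
from .metrics import ChamberMetrics


class SessionError(ValueError):
    """A pacing session is structurally invalid for the requested operation."""


#: fixed tie-break order after |LVRVDIFF| and BIV80
_TIE_ORDER = (
    PacingSetting.BIVP,
    PacingSetting.BIVP_LV30,
    PacingSetting.LVP,
    PacingSetting.RVP,
)


@dataclass(frozen=True)
class PacingSession:
    """Chamber metrics for one patient across available pacing settings.

    The intrinsic rhythm must be present — it is the reference state all
    deltas are computed against.
    """

    patient_id: str
    metrics: dict

    def __post_init__(self) -> None:
        normalized = {PacingSetting(k): v for k, v in self.metrics.items()}
        if len(normalized) != len(self.metrics):
            raise SessionError("duplicate pacing settings in session")
        if PacingSetting.INTRINSIC not in normalized:
            raise SessionError("session lacks the INTRINSIC reference setting")
        object.__setattr__(self, "metrics", normalized)

    @property
    def paced(self) -> dict:
        return {
            s: m for s, m in self.metrics.items() if s is not PacingSetting.INTRINSIC
        }


def config_table(session: PacingSession, f: float = 0.8) -> pd.DataFrame:
    """One row per setting: LV/RV/BIV times at ``f``, |LVRVDIFF| and deltas.

    Deltas are setting value minus intrinsic value, so the intrinsic row is
    identically zero and ``value = intrinsic + delta`` holds exactly.
    """
    intrinsic = session.metrics[PacingSetting.INTRINSIC]
    rows = []
    for setting in PacingSetting:
        if setting not in session.metrics:
            continue
        m: ChamberMetrics = session.metrics[setting]
        rows.append(
            {
                "setting": setting.value,
                "lv": m.time("LV", f),
                "rv": m.time("RV", f),
                "biv": m.time("BIV", f),
                "lvrvdiff": abs(m.time("LV", f) - m.time("RV", f)),
                "d_lv": m.time("LV", f) - intrinsic.time("LV", f),
                "d_rv": m.time("RV", f) - intrinsic.time("RV", f),
                "d_biv": m.time("BIV", f) - intrinsic.time("BIV", f),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class Recommendation:
    """A recommended pacing setting with the values that justified it."""

    setting: PacingSetting
    rationale: pd.DataFrame = field(compare=False)


def recommend_setting(session: PacingSession, f: float = 0.8) -> Recommendation:
    """Pick the paced setting minimising |LVRVDIFF| at the given fraction.

    Ties are broken by the smaller BIV time at ``f``, then by the fixed
    order BIVP, BIVP_LV30, LVP, RVP.  The rationale table lists every
    candidate's |LVRVDIFF| and BIV time.
    """
    paced = session.paced
    if len(paced) < 2:
        raise SessionError(
            f"recommendation needs >= 2 paced settings, session has {len(paced)}"
        )
    rows = []
    for setting, m in paced.items():
        rows.append(
            {
                "setting": setting,
                "lvrvdiff": abs(m.time("LV", f) - m.time("RV", f)),
                "biv": m.time("BIV", f),
                "tie_rank": _TIE_ORDER.index(setting),
            }
        )
    best = min(rows, key=lambda r: (r["lvrvdiff"], r["biv"], r["tie_rank"]))
    rationale = (
        pd.DataFrame(rows)
        .assign(setting=lambda d: d["setting"].map(lambda s: s.value))
        .sort_values(["lvrvdiff", "biv", "tie_rank"])
        .drop(columns="tie_rank")
        .reset_index(drop=True)
    )
    return Recommendation(setting=best["setting"], rationale=rationale)


@dataclass(frozen=True)
class ResponseFlags:
    """Responder flags; ``None`` when the underlying outcome is absent."""

    lvesv_responder: bool | None = None
    vo2_responder: bool | None = None


def classify_response(
    lvesvi_fc: float | None = None, delta_peak_vo2: float | None = None
) -> ResponseFlags:
    """Classify CRT response from outcome values.

    LVESV response means at least a 5% reduction in end-systolic volume —
    fractional change ≤ −0.05 — and functional response means an
    improvement in peak VO₂ of at least 1 mL/kg/min (both boundaries
    inclusive).  A missing outcome yields a missing flag, never False.
    """
    lvesv = None if lvesvi_fc is None else bool(lvesvi_fc <= -0.05)
    vo2 = None if delta_peak_vo2 is None else bool(delta_peak_vo2 >= 1.0)
    return ResponseFlags(lvesv_responder=lvesv, vo2_responder=vo2)
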