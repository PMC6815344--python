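"""Circumferential (limbal) mapping and quadrant statistics.

Positions along the limbus are indexed by angle on a 15-degree grid
(24 positions, 0-345).  Angles increase counter-clockwise with 270 degrees at
the inferior pole; the inferior quadrant is the closed arc 225-315 degrees
(both endpoints counted inferior), which yields exactly 7 inferior and 17
other positions per eye.  The headline comparison pools eyes and tests
inferior vs all other positions with a two-tailed two-sample t-test
(Welch by default; pooled-variance available).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LIMBAL_ANGLES_DEG",
    "INFERIOR_ARC_DEG",
    "LimbalSample",
    "QuadrantComparison",
    "InsufficientGroupError",
    "assign_quadrant",
    "compare_inferior_vs_rest",
    "diameter_by_angle",
    "cluster_span",
]

#: The 24-point acquisition grid, degrees.
LIMBAL_ANGLES_DEG = tuple(float(a) for a in range(0, 360, 15))

#: Closed arc defining the inferior quadrant, degrees.
INFERIOR_ARC_DEG = (225.0, 315.0)


class InsufficientGroupError(ValueError):
    """Raised when a comparison group has fewer than 2 samples."""


@dataclass
class LimbalSample:
    """Per-angle summary for one eye: ROI total fluorescence (au) and the
    per-segment median vessel diameters found at that position."""

    eye_id: str
    angle_deg: float
    total_au: float
    diameters_um: list = field(default_factory=list)
    quadrant: str = ""

    def __post_init__(self) -> None:
        if self.angle_deg % 15.0 != 0.0:
            raise ValueError(f"angle {self.angle_deg} not on the 15-degree grid")
        if self.total_au < 0:
            raise ValueError("total_au must be >= 0")
        if not self.quadrant:
            self.quadrant = assign_quadrant(self.angle_deg)


@dataclass
class QuadrantComparison:
    """Inferior-vs-rest group comparison (mean +/- SEM convention)."""

    group_means_au: dict
    group_sems_au: dict
    n_per_group: dict
    t_stat: float
    df: float
    p_value: float
    test_variant: str
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha

    def to_dict(self) -> dict:
        return {
            "group_means_au": self.group_means_au,
            "group_sems_au": self.group_sems_au,
            "n_per_group": self.n_per_group,
            "t_stat": self.t_stat,
            "df": self.df,
            "p_value": self.p_value,
            "test_variant": self.test_variant,
            "alpha": self.alpha,
            "inferior_arc_deg": list(INFERIOR_ARC_DEG),
            "arc_endpoints": "inclusive",
        }


def assign_quadrant(angle_deg: float) -> str:
    """Label an angle ``"inferior"`` iff it lies in the closed arc 225-315
    degrees, else ``"other"``.  Angles outside [0, 360) are normalized
    modulo 360 first."""
    a = float(angle_deg) % 360.0
    lo, hi = INFERIOR_ARC_DEG
    return "inferior" if lo <= a <= hi else "other"


def _sem(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1) / np.sqrt(x.size))


def compare_inferior_vs_rest(samples: list[LimbalSample],
                             variant: str = "welch",
                             alpha: float = 0.05) -> QuadrantComparison:
    """Two-tailed two-sample t-test of total fluorescence, inferior vs rest.

    Eyes are pooled.  ``variant`` is ``"welch"`` (unequal variance, default)
    or ``"pooled"``.  Raises :class:`InsufficientGroupError` if either group
    has fewer than 2 samples.
    """
    if variant not in ("welch", "pooled"):
        raise ValueError(f"unknown t-test variant: {variant!r}")
    inf = np.array([s.total_au for s in samples
                    if assign_quadrant(s.angle_deg) == "inferior"], dtype=float)
    oth = np.array([s.total_au for s in samples
                    if assign_quadrant(s.angle_deg) == "other"], dtype=float)
    if inf.size < 2 or oth.size < 2:
        raise InsufficientGroupError(
            f"need >= 2 samples per group, got {inf.size} inferior / {oth.size} other")
    equal_var = variant == "pooled"
    if np.ptp(inf) == 0.0 and np.ptp(oth) == 0.0 and inf[0] == oth[0]:
        # identical constant groups: zero difference, zero spread
        df = float(inf.size + oth.size - 2)
        return QuadrantComparison(
            group_means_au={"inferior": float(inf[0]), "other": float(oth[0])},
            group_sems_au={"inferior": 0.0, "other": 0.0},
            n_per_group={"inferior": int(inf.size), "other": int(oth.size)},
            t_stat=0.0, df=df, p_value=1.0, test_variant=variant, alpha=alpha)
    res = stats.ttest_ind(inf, oth, equal_var=equal_var)
    if equal_var:
        df = float(inf.size + oth.size - 2)
    else:
        df = float(res.df)  # Welch-Satterthwaite
    return QuadrantComparison(
        group_means_au={"inferior": float(inf.mean()), "other": float(oth.mean())},
        group_sems_au={"inferior": _sem(inf), "other": _sem(oth)},
        n_per_group={"inferior": int(inf.size), "other": int(oth.size)},
        t_stat=float(res.statistic),
        df=df,
        p_value=float(res.pvalue),
        test_variant=variant,
        alpha=alpha,
    )


def stratified_by_eye(samples: list[LimbalSample], variant: str = "welch"
                      ) -> dict[str, QuadrantComparison]:
    """Per-eye comparisons alongside the pooled headline test."""
    out = {}
    for eye in sorted({s.eye_id for s in samples}):
        out[eye] = compare_inferior_vs_rest(
            [s for s in samples if s.eye_id == eye], variant=variant)
    return out


def diameter_by_angle(samples: list[LimbalSample]) -> pd.DataFrame:
    """Per-angle diameter summary over the full 24-angle grid, ordered by angle.

    Angles with no sample (e.g. a failed frame) keep their row with NaN
    diameter fields and ``missing=True``.
    """
    rows = []
    by_angle: dict[float, list[float]] = {a: [] for a in LIMBAL_ANGLES_DEG}
    seen: set = set()
    for s in samples:
        a = s.angle_deg % 360.0
        by_angle.setdefault(a, []).extend(s.diameters_um)
        seen.add(a)
    for a in LIMBAL_ANGLES_DEG:
        d = by_angle[a]
        missing = a not in seen
        rows.append({
            "angle_deg": a,
            "quadrant": assign_quadrant(a),
            "n_segments": len(d),
            "max_diameter_um": float(np.max(d)) if d else np.nan,
            "median_diameter_um": float(np.median(d)) if d else np.nan,
            "missing": missing,
        })
    return pd.DataFrame(rows).sort_values("angle_deg").reset_index(drop=True)


def cluster_span(table: pd.DataFrame, high_threshold_um: float
                 ) -> list[tuple[float, float, float]]:
    """Maximal circular runs of consecutive grid angles whose max diameter
    meets ``high_threshold_um``.

    Returns ``(start_deg, end_deg, span_deg)`` triples with
    ``span = 15 deg * run length``; runs wrap across 345 -> 0.  A run covering
    all 24 angles is reported once as ``(0, 345, 360)``.
    """
    t = table.sort_values("angle_deg")
    angles = t["angle_deg"].to_numpy(dtype=float)
    if angles.size != len(LIMBAL_ANGLES_DEG) or np.any(angles != np.array(LIMBAL_ANGLES_DEG)):
        raise ValueError("table must cover the full 24-angle grid")
    above = (t["max_diameter_um"].to_numpy(dtype=float) >= high_threshold_um)
    above = np.nan_to_num(above, nan=False).astype(bool)
    k = angles.size
    if not above.any():
        return []
    if above.all():
        return [(0.0, 345.0, 360.0)]
    runs = []
    # find run starts: above[i] and not above[i-1] (circular)
    starts = [i for i in range(k) if above[i] and not above[(i - 1) % k]]
    for s in starts:
        length = 0
        while above[(s + length) % k]:
            length += 1
        runs.append((angles[s], angles[(s + length - 1) % k], 15.0 * length))
    runs.sort(key=lambda r: r[0])
    return runs
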