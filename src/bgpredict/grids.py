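"""Clarke and Parkes (consensus) error-grid analyses.

Both grids assign a (reference, predicted) glucose pair to a clinical-risk
zone A-E.  Zone A holds clinically accurate predictions (for Clarke, within
20% of the reference or jointly below 70 mg/dL); the later zones carry
increasing risk of a wrong treatment decision.

The Clarke grid is implemented as the published 1987 inequality rule set.
The Parkes grid for type-1 diabetes is implemented from the published
consensus boundary-vertex table (the 2013 technical-specification
coordinates); zone boundaries are polylines in the (reference, predicted)
plane, extended beyond their last vertex with the final segment's slope.
Points exactly on a boundary are assigned to the lower-risk side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

ZONES = ("A", "B", "C", "D", "E")


@dataclass
class ErrorGridResult:
    grid: str                 # "clarke" or "parkes-type1"
    zone_counts: dict
    zone_percent: dict

    @property
    def n(self) -> int:
        return sum(self.zone_counts.values())


def _as_result(grid: str, zones: np.ndarray) -> ErrorGridResult:
    n = len(zones)
    counts = {z: int(np.sum(zones == i)) for i, z in enumerate(ZONES)}
    percent = {z: 100.0 * c / n for z, c in counts.items()}
    return ErrorGridResult(grid=grid, zone_counts=counts, zone_percent=percent)


# ---------------------------------------------------------------------------
# Clarke error grid (1987 rule set)

def clarke_zones(ref, pred) -> np.ndarray:
    """Vectorized Clarke zone classification; returns indices into ZONES.

    Rules follow the published grid.  Zone A is checked first (within 20% of
    reference, or both values in the hypoglycemic range below 70 mg/dL), then
    E, C and D; everything else is the clinically benign zone B.  Boundary
    equalities in the C/D rules are strict so edge points fall into B.
    """
    ref = np.asarray(ref, float)
    pred = np.asarray(pred, float)
    if np.any(ref < 0) or np.any(pred < 0):
        raise ValueError("glucose values must be non-negative")
    zone = np.full(ref.shape, 1, dtype=int)  # default B

    a = (np.abs(pred - ref) <= 0.2 * ref) | ((ref < 70) & (pred < 70))
    e = ((ref <= 70) & (pred >= 180)) | ((ref >= 180) & (pred <= 70))
    c = (((70 <= ref) & (ref <= 290)) & (pred > ref + 110)) \
        | (((130 <= ref) & (ref <= 180)) & (pred < (7.0 / 5.0) * ref - 182))
    d = ((ref >= 240) & ((70 <= pred) & (pred <= 180))) \
        | ((ref <= 175.0 / 3.0) & (pred <= 180) & (pred >= 70)) \
        | ((((175.0 / 3.0) <= ref) & (ref <= 70)) & (pred >= (6.0 / 5.0) * ref))

    zone[d] = 3
    zone[c] = 2
    zone[e] = 4
    zone[a] = 0
    return zone


def clarke_zone(ref: float, pred: float) -> str:
    """Clarke zone letter for a single (reference, predicted) pair."""
    return ZONES[int(clarke_zones([ref], [pred])[0])]


def clarke_grid(y_true, y_pred) -> ErrorGridResult:
    return _as_result("clarke", clarke_zones(y_true, y_pred))


# ---------------------------------------------------------------------------
# Parkes consensus error grid, type 1 diabetes

#: Published boundary polylines (reference, predicted), type-1 grid.
#: "upper" boundaries separate zones above the identity line, "lower" below.
PARKES_T1_BOUNDARIES = {
    "B_upper": ((0, 50), (30, 50), (140, 170), (280, 380), (430, 550)),
    "B_lower": ((50, 0), (50, 30), (170, 145), (385, 300), (550, 450)),
    "C_upper": ((0, 60), (30, 60), (50, 80), (70, 110), (260, 550)),
    "C_lower": ((120, 0), (120, 30), (260, 130), (550, 250)),
    "D_upper": ((0, 100), (25, 100), (50, 125), (80, 215), (125, 550)),
    "D_lower": ((250, 0), (250, 40), (550, 150)),
    "E_upper": ((0, 150), (35, 155), (50, 550)),
}

PARKES_DOMAIN = (0.0, 550.0)


def _boundary_y(name: str, x: np.ndarray) -> np.ndarray:
    """Boundary polyline height at reference x, extended with the end slope."""
    pts = np.asarray(PARKES_T1_BOUNDARIES[name], float)
    xs, ys = pts[:, 0], pts[:, 1]
    y = np.interp(x, xs, ys)
    beyond = x > xs[-1]
    if np.any(beyond):
        slope = (ys[-1] - ys[-2]) / (xs[-1] - xs[-2])
        y = np.where(beyond, ys[-1] + slope * (x - xs[-1]), y)
    return y


def parkes_zones_type1(ref, pred, clamp: bool = True) -> np.ndarray:
    """Vectorized Parkes type-1 zone classification; indices into ZONES.

    A point above the identity line is compared against the upper boundary
    polylines from the outermost (E) inward; below the identity line against
    the lower ones (the type-1 grid has no lower E region).  A point exactly
    on a boundary goes to the lower-risk zone.  Out-of-domain inputs are
    clamped to [0, 550] with a warning (or rejected when ``clamp=False``).
    """
    ref = np.asarray(ref, float)
    pred = np.asarray(pred, float)
    lo, hi = PARKES_DOMAIN
    if np.any(ref < lo) or np.any(ref > hi) or np.any(pred < lo) or np.any(pred > hi):
        if not clamp:
            raise ValueError("values outside the Parkes grid domain [0, 550]")
        import warnings
        warnings.warn("values outside [0, 550] mg/dL clamped to the Parkes domain")
        ref = np.clip(ref, lo, hi)
        pred = np.clip(pred, lo, hi)

    zone = np.zeros(ref.shape, dtype=int)  # default A
    upper = pred >= ref
    # above the identity line: E > D > C > B, strict so boundaries fall inward
    for name, idx in (("B_upper", 1), ("C_upper", 2), ("D_upper", 3),
                      ("E_upper", 4)):
        outside = upper & (pred > _boundary_y(name, ref))
        zone[outside] = idx
    lower = ~upper
    for name, idx in (("B_lower", 1), ("C_lower", 2), ("D_lower", 3)):
        outside = lower & (pred < _boundary_y(name, ref))
        zone[outside] = idx
    return zone


def parkes_zone_type1(ref: float, pred: float) -> str:
    return ZONES[int(parkes_zones_type1([ref], [pred])[0])]


def parkes_grid(y_true, y_pred) -> ErrorGridResult:
    return _as_result("parkes-type1", parkes_zones_type1(y_true, y_pred))


def parkes_zone_polygons() -> dict:
    """Zone regions as closed polygons (for plotting and cross-checks).

    Each zone's polygon is built from its inner and outer boundary polylines
    clipped to the square domain; zone A is the band between the two B
    boundaries.
    """
    lo, hi = PARKES_DOMAIN

    def polyline_pts(name):
        pts = np.asarray(PARKES_T1_BOUNDARIES[name], float)
        if pts[-1, 0] < hi:  # extend to the domain edge with the final slope
            slope = (pts[-1, 1] - pts[-2, 1]) / (pts[-1, 0] - pts[-2, 0])
            y_end = pts[-1, 1] + slope * (hi - pts[-1, 0])
            if y_end > hi:   # leaves through the top: stop at y = hi
                x_top = pts[-1, 0] + (hi - pts[-1, 1]) / slope
                pts = np.vstack([pts, [x_top, hi]])
            else:
                pts = np.vstack([pts, [hi, y_end]])
        return pts

    bu, bl = polyline_pts("B_upper"), polyline_pts("B_lower")
    cu, cl = polyline_pts("C_upper"), polyline_pts("C_lower")
    du, dl = polyline_pts("D_upper"), polyline_pts("D_lower")
    eu = polyline_pts("E_upper")
    top_left = np.array([[lo, hi]])
    bottom_right = np.array([[hi, lo]])

    def band(outer, inner, corner):
        # region between two same-side boundaries, closed through the corner
        return np.vstack([inner, corner, outer[::-1]])

    polys = {
        "A": np.vstack([bu, bl[::-1]]),
        "B_upper": band(cu, bu, top_left), "B_lower": band(cl, bl, bottom_right),
        "C_upper": band(du, cu, top_left), "C_lower": band(dl, cl, bottom_right),
        "D_upper": band(eu, du, top_left), "D_lower": band(np.array([[hi, lo]]), dl, bottom_right),
        "E_upper": np.vstack([eu, top_left]),
    }
    return polys
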