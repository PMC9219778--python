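"""Risk metrics derived from converged fields.

Turns transported-species fields into the reported hemocompatibility
quantities: the flux-weighted activated-platelet percentage at the outlet,
volume-averaged clot burden, per-region clot amounts normalized by max-min
scaling, and the high-shear (HSSS) / long-residence-time (LRT) hotspot masks
whose co-location flags thrombosis-prone regions.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .closures import Thresholds
from .errors import (
    DegenerateNormalizationError,
    InvalidInputError,
    UndefinedMetricError,
)
from .flow_fields import FlowField
from .grid import CellKind, StructuredGrid2D

__all__ = [
    "RiskReport",
    "outlet_ap_percent",
    "normalize_risk",
    "hotspot_masks",
    "downstream_of",
    "region_report",
]

#: display-band fractions of the thresholds used for hotspot maps:
#: shear stress above 15/35 of NPSS0 and residence time above 0.35 of RT0.
DEFAULT_DISPLAY_FRACTIONS = (15.0 / 35.0, 0.35)


@dataclass
class RiskReport:
    """Summary metrics of one converged run."""

    outlet_ap_percent: float
    outlet_ap_percent_area: float
    volume_avg_tcs: float
    region_tcs: dict
    region_risk_normalized: dict | None
    hotspot_masks: dict

    def to_json_dict(self) -> dict:
        return {
            "outlet_ap_percent": self.outlet_ap_percent,
            "outlet_ap_percent_area": self.outlet_ap_percent_area,
            "volume_avg_tcs": self.volume_avg_tcs,
            "region_tcs": {str(k): v for k, v in self.region_tcs.items()},
            "region_risk_normalized": None
            if self.region_risk_normalized is None
            else {str(k): v for k, v in self.region_risk_normalized.items()},
            "hotspot_cell_counts": {
                k: int(np.count_nonzero(v)) for k, v in self.hotspot_masks.items()
            },
        }

    def region_frame(self) -> pd.DataFrame:
        rows = []
        for label, amount in sorted(self.region_tcs.items()):
            rows.append(
                {
                    "region": label,
                    "tcs_amount": amount,
                    "risk_normalized": None
                    if self.region_risk_normalized is None
                    else self.region_risk_normalized.get(label),
                }
            )
        return pd.DataFrame(rows)


def _outlet_faces(grid: StructuredGrid2D, flow: FlowField):
    """(fluid cell, outward flux) pairs over fluid/outlet interfaces."""
    kind = grid.cell_kind
    pairs = []
    for dj, di, flux, fj, fi in (
        (0, 1, flow.flux_x, 0, 1),   # east face
        (0, -1, flow.flux_x, 0, 0),  # west face
        (1, 0, flow.flux_y, 1, 0),   # north face
        (-1, 0, flow.flux_y, 0, 0),  # south face
    ):
        jj, ii = np.nonzero(kind == CellKind.FLUID)
        jn, inn = jj + dj, ii + di
        ok = (jn >= 0) & (jn < grid.ny) & (inn >= 0) & (inn < grid.nx)
        jj, ii, jn, inn = jj[ok], ii[ok], jn[ok], inn[ok]
        sel = kind[jn, inn] == CellKind.OUTLET
        jj, ii = jj[sel], ii[sel]
        sign = 1.0 if (dj + di) > 0 else -1.0
        q = sign * flux[jj + fj * dj, ii + fi * di]
        for a, b, qq in zip(jj, ii, q):
            pairs.append((a, b, qq))
    return pairs


def outlet_ap_percent(
    state, flow: FlowField, grid: StructuredGrid2D
) -> tuple[float, float]:
    """Outlet activated-platelet percentage, flux- and area-weighted.

    The flux-weighted mean of ``100 * APs / (APs + RPs)`` over the outlet
    faces is the transported (physically meaningful) average; the
    area-weighted variant is returned alongside and coincides with it for
    plug outflow.
    """
    pairs = _outlet_faces(grid, flow)
    if not pairs:
        raise UndefinedMetricError("grid has no fluid/outlet interfaces")
    q = np.array([max(qq, 0.0) for _, _, qq in pairs])
    frac = np.array(
        [
            100.0 * state.APs[j, i] / max(state.APs[j, i] + state.RPs[j, i], 1e-300)
            for j, i, _ in pairs
        ]
    )
    qsum = q.sum()
    if qsum <= 0:
        raise UndefinedMetricError("zero outward flux through the outlet")
    return float(np.sum(q * frac) / qsum), float(np.mean(frac))


def normalize_risk(values) -> np.ndarray:
    """Max-min normalization ``(x - min) / (max - min)`` onto [0, 1]."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise InvalidInputError("normalize_risk needs >= 2 values")
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        raise DegenerateNormalizationError(
            f"all {len(x)} values equal {lo!r}; max-min normalization undefined"
        )
    return (x - lo) / (hi - lo)


def hotspot_masks(
    sss_field,
    rt_field,
    thresholds: Thresholds | None = None,
    display_fractions=DEFAULT_DISPLAY_FRACTIONS,
    tcs_field=None,
    tc_hotspot_fraction: float = 0.5,
) -> dict:
    """Boolean per-cell hotspot masks.

    HSSS: scalar shear stress above ``f_s * NPSS0`` (default 15 Pa);
    LRT: residence time above ``f_t * RT0`` (default 0.35 s);
    tc: clot level above ``tc_hotspot_fraction`` of its maximum (empty when
    no clots formed).
    """
    th = thresholds or Thresholds()
    f_s, f_t = display_fractions
    masks = {
        "hsss": np.asarray(sss_field, float) > f_s * th.NPSS0,
        "lrt": np.asarray(rt_field, float) > f_t * th.RT0,
    }
    if tcs_field is not None:
        tc = np.asarray(tcs_field, float)
        peak = float(tc.max())
        masks["tc"] = tc > tc_hotspot_fraction * peak if peak > 0 else tc > np.inf
    return masks


def downstream_of(mask, flow: FlowField, grid: StructuredGrid2D) -> np.ndarray:
    """Cells reachable from ``mask`` by following positive face fluxes.

    Breadth-first search over the cell adjacency graph with an edge from a
    cell to its neighbor wherever the volumetric face flux is directed into
    the neighbor; the seed cells themselves are included.
    """
    mask = np.asarray(mask, bool)
    fluid = grid.fluid
    reach = mask & fluid
    queue = deque(map(tuple, np.argwhere(reach)))
    fx, fy = flow.flux_x, flow.flux_y
    while queue:
        j, i = queue.popleft()
        steps = (
            (j, i + 1, fx[j, i + 1] > 0),
            (j, i - 1, fx[j, i] < 0),
            (j + 1, i, fy[j + 1, i] > 0),
            (j - 1, i, fy[j, i] < 0),
        )
        for jn, inn, goes in steps:
            if not goes or not (0 <= jn < grid.ny and 0 <= inn < grid.nx):
                continue
            if fluid[jn, inn] and not reach[jn, inn]:
                reach[jn, inn] = True
                queue.append((jn, inn))
    return reach


def region_report(
    state,
    grid: StructuredGrid2D,
    flow: FlowField | None = None,
    thresholds: Thresholds | None = None,
    display_fractions=DEFAULT_DISPLAY_FRACTIONS,
) -> RiskReport:
    """Per-region clot amounts, normalized risk, and hotspot masks.

    Regions are the user-assigned ``grid.region_label`` cell sets (cells
    labelled < 0 are unassigned); with fewer than two regions, or regions of
    identical clot burden, the normalized column is omitted rather than
    returning NaNs.
    """
    fluid = grid.fluid
    if grid.region_label is None:
        labels = np.where(fluid, 0, -1)
    else:
        labels = np.asarray(grid.region_label)
    region_ids = sorted(int(r) for r in np.unique(labels[fluid & (labels >= 0)]))
    if len(region_ids) < 1:
        raise InvalidInputError("region_report needs at least one labelled region")
    V = grid.cell_volume
    region_tcs = {
        r: float(np.sum(state.TCs[(labels == r) & fluid]) * V) for r in region_ids
    }
    normalized = None
    if len(region_ids) >= 2:
        try:
            norm = normalize_risk([region_tcs[r] for r in region_ids])
            normalized = {r: float(v) for r, v in zip(region_ids, norm)}
        except DegenerateNormalizationError:
            normalized = None
    vol_avg = float(np.mean(state.TCs[fluid]))

    if flow is not None:
        from .closures import scalar_shear_stress

        sss = scalar_shear_stress(flow.grad_v, flow.mu_eff)
        sss[~fluid] = 0.0
        masks = hotspot_masks(
            sss, state.RT, thresholds, display_fractions, tcs_field=state.TCs
        )
        ap, ap_area = outlet_ap_percent(state, flow, grid)
    else:
        masks = hotspot_masks(
            np.zeros_like(state.RT),
            state.RT,
            thresholds,
            display_fractions,
            tcs_field=state.TCs,
        )
        ap = ap_area = float("nan")
    return RiskReport(
        outlet_ap_percent=ap,
        outlet_ap_percent_area=ap_area,
        volume_avg_tcs=vol_avg,
        region_tcs=region_tcs,
        region_risk_normalized=normalized,
        hotspot_masks=masks,
    )
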