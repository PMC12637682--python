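"""Brute-force reference implementations used as independent cross-checks.

Everything here favours transparency over speed: plain per-frame loops,
exhaustive grid searches, and textbook formulas.  The analysis modules never
call these for production work; tests and validation scripts compare the
fast implementations against them.
"""

from __future__ import annotations

import heapq
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np

from .io_core import ChannelGeometry, IonTrajectory
from .permeation import PermeationEvent


# ---------------------------------------------------------------------------
# exhaustive per-frame permeation state machine
# ---------------------------------------------------------------------------

def oracle_events(traj: IonTrajectory, geom: ChannelGeometry,
                  buffer: float = 0.0) -> List[PermeationEvent]:
    """Frame-by-frame state machine over every ion and frame.

    Semantically identical to :func:`ionflux.permeation.detect_events` but
    written as a direct loop with per-frame state, with no shortcuts.
    """
    times = traj.times
    events: List[PermeationEvent] = []
    for i in range(traj.n_ions):
        last_outside = None   # (side, image, frame)
        pending = None        # dict(side, image, entry_frame, ok)
        for f in range(traj.n_frames):
            lx, ly, lz = traj.box[f]
            z = traj.unwrapped[i, f, 2]
            u = int(np.floor((z + lz / 2.0) / lz))
            zl = z - u * lz
            dx = traj.positions[i, f, 0] - geom.axis_origin[0]
            dy = traj.positions[i, f, 1] - geom.axis_origin[1]
            dx -= lx * round(dx / lx)
            dy -= ly * round(dy / ly)
            r = float(np.hypot(dx, dy))
            if zl > geom.z_upper + buffer:
                side = 2
            elif zl < geom.z_lower - buffer:
                side = 0
            else:
                side = 1
            if side == 1:
                if pending is None or pending["image"] != u:
                    if last_outside is not None and last_outside[1] == u \
                            and last_outside[2] == f - 1:
                        pending = {"side": last_outside[0], "image": u,
                                   "entry_frame": f - 1, "ok": True}
                    else:
                        pending = {"side": None, "image": u,
                                   "entry_frame": None, "ok": True}
                if geom.z_lower <= zl <= geom.z_upper and r > geom.r_pore:
                    pending["ok"] = False
            else:
                if pending is not None:
                    if (pending["side"] is not None and pending["image"] == u
                            and pending["side"] != side and pending["ok"]):
                        direction = "inward" if pending["side"] == 2 else "outward"
                        events.append(PermeationEvent(
                            ion_id=traj.ion_ids[i],
                            entry_ns=float(times[pending["entry_frame"]]),
                            exit_ns=float(times[f]), direction=direction,
                            entry_frame=pending["entry_frame"],
                            exit_frame=f))
                elif last_outside is not None and last_outside[2] == f - 1 \
                        and last_outside[1] == u and last_outside[0] != side:
                    direction = "inward" if last_outside[0] == 2 else "outward"
                    events.append(PermeationEvent(
                        ion_id=traj.ion_ids[i], entry_ns=float(times[f - 1]),
                        exit_ns=float(times[f]), direction=direction,
                        entry_frame=f - 1, exit_frame=f))
                pending = None
                last_outside = (side, u, f)
    events.sort(key=lambda e: (e.exit_ns, str(e.ion_id)))
    return events


def oracle_cumulative_crossings(traj: IonTrajectory, geom: ChannelGeometry
                                ) -> np.ndarray:
    """Cumulative gross crossing count at every frame time."""
    events = oracle_events(traj, geom)
    out = np.zeros(traj.n_frames, dtype=int)
    for ev in events:
        out[np.searchsorted(traj.times, ev.exit_ns):] += 1
    return out


# ---------------------------------------------------------------------------
# maximal-sphere radius by dense grid search
# ---------------------------------------------------------------------------

def grid_search_plane_radius(positions: np.ndarray, radii: np.ndarray,
                             center: np.ndarray, normal: np.ndarray,
                             extent: float = 10.0, step: float = 0.05
                             ) -> float:
    """Largest clearance radius in a plane by exhaustive 2D grid search.

    Maximizes min_i(|c − x_i| − R_i) over centers c on a dense lattice in
    the plane through ``center`` with unit ``normal``.
    """
    normal = np.asarray(normal, float)
    normal = normal / np.linalg.norm(normal)
    a = np.array([1.0, 0.0, 0.0])
    if abs(normal @ a) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(normal, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(normal, e1)
    # atoms too far from the plane can never set the minimum clearance at
    # the scales probed here; keep the search exact up to a generous bound
    dist_plane = np.abs((positions - center) @ normal)
    keep = dist_plane - radii < 2.0 * extent
    pos = positions[keep]
    rad = radii[keep]
    ticks = np.arange(-extent, extent + step / 2, step)
    uu, vv = np.meshgrid(ticks, ticks, indexing="ij")
    pts = (center[None, :] + uu.ravel()[:, None] * e1[None, :]
           + vv.ravel()[:, None] * e2[None, :])
    best = -np.inf
    for chunk in np.array_split(pts, max(1, len(pts) // 2000)):
        d = np.linalg.norm(chunk[:, None, :] - pos[None, :, :], axis=2)
        clearance = (d - rad[None, :]).min(axis=1)
        best = max(best, float(clearance.max()))
    return best


# ---------------------------------------------------------------------------
# minimax path (Dijkstra) saddle-height oracle
# ---------------------------------------------------------------------------

def dijkstra_minimax_saddle(f_fn: Callable, a: Sequence[float], b: Sequence[float],
                            bounds: Tuple[float, float, float, float],
                            step: float = 0.02) -> float:
    """Height of the lowest possible maximum along any path from a to b.

    Evaluates ``f_fn`` on a dense grid over ``bounds`` = (x_lo, x_hi, y_lo,
    y_hi) and runs a Dijkstra-style search with 8-neighbour moves where the
    cost of a path is the maximum grid value visited.  The result is the
    exact grid saddle height, the natural lower bound any minimum-energy
    path's peak must attain.
    """
    x_lo, x_hi, y_lo, y_hi = bounds
    xs = np.arange(x_lo, x_hi + step / 2, step)
    ys = np.arange(y_lo, y_hi + step / 2, step)
    xx, yy = np.meshgrid(xs, ys, indexing="ij")
    grid = np.asarray(f_fn(xx, yy), dtype=float)
    nx, ny = grid.shape

    def node_of(p):
        ix = int(round((p[0] - x_lo) / step))
        iy = int(round((p[1] - y_lo) / step))
        return (min(max(ix, 0), nx - 1), min(max(iy, 0), ny - 1))

    start, goal = node_of(a), node_of(b)
    best = np.full(grid.shape, np.inf)
    best[start] = grid[start]
    heap = [(grid[start], start)]
    moves = [(dx, dy) for dx in (-1, 0, 1) for dy in (-1, 0, 1)
             if (dx, dy) != (0, 0)]
    while heap:
        cost, (ix, iy) = heapq.heappop(heap)
        if cost > best[ix, iy]:
            continue
        if (ix, iy) == goal:
            return float(cost)
        for dx, dy in moves:
            jx, jy = ix + dx, iy + dy
            if 0 <= jx < nx and 0 <= jy < ny:
                c = max(cost, grid[jx, jy])
                if c < best[jx, jy]:
                    best[jx, jy] = c
                    heapq.heappush(heap, (c, (jx, jy)))
    raise RuntimeError("goal unreachable on oracle grid")


# ---------------------------------------------------------------------------
# textbook statistics oracles
# ---------------------------------------------------------------------------

def anova_f_direct(groups: Sequence[np.ndarray]) -> float:
    """One-way ANOVA F from explicit between/within sums of squares."""
    groups = [np.asarray(g, float) for g in groups]
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = len(all_vals) - len(groups)
    if ss_within == 0:
        raise ZeroDivisionError("zero within-group variance")
    return float((ss_between / df_b) / (ss_within / df_w))


def paired_t_direct(a: np.ndarray, b: np.ndarray) -> Tuple[float, float]:
    """Closed-form paired t statistic and two-sided p with n−1 df."""
    from scipy import stats

    d = np.asarray(a, float) - np.asarray(b, float)
    n = len(d)
    sd = d.std(ddof=1)
    t = d.mean() / (sd / np.sqrt(n))
    p = 2 * stats.t.sf(abs(t), n - 1)
    return float(t), float(p)


def line_integral_surface(fx: np.ndarray, fy: np.ndarray, hx: float, hy: float
                          ) -> np.ndarray:
    """Reconstruct a surface from its (negative-force) gradient by direct
    line integration along the first row and down the columns.

    Exact for curl-free discrete gradients; used as the oracle for the
    least-squares gradient integrator.  ``fx``/``fy`` are mean forces, so
    the surface gradient is their negative.
    """
    nx, ny = fx.shape
    f = np.zeros((nx, ny))
    for j in range(1, ny):
        f[0, j] = f[0, j - 1] - hy * (fy[0, j - 1] + fy[0, j]) / 2.0
    for i in range(1, nx):
        f[i, :] = f[i - 1, :] - hx * (fx[i - 1, :] + fx[i, :]) / 2.0
    return f - f.min()
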