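"""Synthetic generators with known ground truth.

This module stands in for the expensive inputs of the analysis pipeline:

* :func:`langevin_channel_sim` — overdamped (Brownian) ions in an idealized
  channel geometry under an applied uniform field, emulating fixed-field
  computational-electrophysiology campaigns at transmembrane potentials of
  ±250, ±100 and 0 mV with replicates;
* :func:`scripted_trajectory` — ions following prescribed waypoints, for
  exact event/pathway oracles;
* :func:`markov_patch_trace` — two-state single-channel current traces
  sampled at 20 kHz with Gaussian noise;
* :func:`synthetic_pore_structure` — atom clouds whose open pore radius is
  analytic by construction.

All generators are bit-reproducible for a fixed seed.  Ions are
non-interacting; there is no explicit water or lipid.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np

from .io_core import AtomSet, ChannelGeometry, IonTrajectory, KB_KCAL
from .permeation import PermeationEvent, PA_PER_CROSSING_PER_NS
from . import reference

#: kcal/mol gained by a unit charge crossing 1 mV.
MV_E_KCAL = 0.0230605419


# ---------------------------------------------------------------------------
# specs and ground truth
# ---------------------------------------------------------------------------

@dataclass
class SimSpec:
    """Parameters of the Brownian channel simulator.

    ``mode="tube"`` confines all ions to the pore cylinder at every z — a
    uniform-cross-section periodic tube whose current–voltage relation is
    exactly linear, so the programmed conductance has a closed form (see
    :attr:`programmed_gamma_pS`).  ``mode="channel"`` adds the full wall
    set: membrane slab, vestibule shell with an apical aperture and lateral
    fenestration holes, and the vestibule ceiling.
    """

    geometry: ChannelGeometry = dc_field(default_factory=ChannelGeometry)
    mode: str = "tube"
    u_profile: Optional[Tuple[Sequence[float], Sequence[float]]] = None
    diffusion: float = 20.0       # Å²/ns
    temperature: float = 300.0    # K
    e_z: float = 0.0              # mV/Å
    z_ion: int = 1
    n_ions: int = 20
    duration: float = 150.0       # ns
    timestep: float = 0.002       # ns
    box: Tuple[float, float, float] = (40.0, 40.0, 80.0)
    wall_k: float = 5.0           # kcal/mol/Å²
    pore_wall_margin: float = 2.0  # Å inside r_pore where the soft wall sits
    fen_frac: float = 0.6         # fraction of each sector open as a hole
    save_every: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.timestep <= 0 or self.diffusion <= 0:
            raise ValueError("timestep and diffusion must be positive")
        if self.duration / self.timestep < 1:
            raise ValueError("duration must cover at least one step")
        if self.mode not in ("tube", "channel"):
            raise ValueError("mode must be 'tube' or 'channel'")

    @property
    def kt(self) -> float:
        return KB_KCAL * self.temperature

    @property
    def programmed_gamma_pS(self) -> float:
        """Exact conductance of the tube in Ohmic mode (flat U).

        Uniform density is the exact stationary state of drift–diffusion in
        a uniform tube with periodic z at any field, so each ion crosses at
        rate v/L_z with v = (D/k_BT)·z·e·E_z and
        γ = 1000·n·D·z²·(e·mV)·(pA per crossing/ns)/(k_BT·L_z²).
        """
        lz = self.box[2]
        return (1000.0 * self.n_ions * self.diffusion * self.z_ion ** 2
                * MV_E_KCAL * PA_PER_CROSSING_PER_NS / (self.kt * lz ** 2))

    @property
    def dv_m(self) -> float:
        return self.e_z * self.box[2]


@dataclass
class GroundTruthLog:
    """True crossing events (and pathways) emitted by a generator."""

    events: List[PermeationEvent]
    programmed_gamma_pS: Optional[float] = None
    meta: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.events.sort(key=lambda e: (e.exit_ns, str(e.ion_id)))


@dataclass
class PatchSpec:
    """Parameters of the two-state single-channel trace generator."""

    gamma_pS: float = 90.0
    holding_potentials: Tuple[float, ...] = (-120.0, -100.0, -80.0,
                                             80.0, 100.0, 120.0)
    k_open: float = 50.0      # s⁻¹, closed → open
    k_close: float = 50.0     # s⁻¹, open → closed
    baseline_pA: float = 0.0
    noise_sd_pA: float = 1.0
    sampling_hz: float = 20000.0
    duration_s: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_open <= 0 or self.k_close <= 0:
            raise ValueError("rates must be positive")
        if self.sampling_hz <= 0:
            raise ValueError("sampling rate must be positive")


# ---------------------------------------------------------------------------
# wall forces
# ---------------------------------------------------------------------------

def _wall_forces(pos: np.ndarray, spec: SimSpec) -> np.ndarray:
    """Soft flat-bottom confinement forces for the current positions.

    Each forbidden region contributes a harmonic push along the shortest
    exit direction; penetrations stay shallow for β·D·k·dt ≲ 0.5.  The pore
    confinement sits ``pore_wall_margin`` inside the detection radius
    ``r_pore`` so thermal penetration of the soft wall never carries an ion
    past the radius the event definition checks.
    """
    g = spec.geometry
    k = spec.wall_k
    r_wall = max(g.r_pore - spec.pore_wall_margin, 0.5 * g.r_pore)
    x, y, z = pos[:, 0], pos[:, 1], pos[:, 2]
    r = np.hypot(x, y)
    f = np.zeros_like(pos)
    with np.errstate(invalid="ignore", divide="ignore"):
        ux = np.where(r > 0, x / np.maximum(r, 1e-12), 0.0)
        uy = np.where(r > 0, y / np.maximum(r, 1e-12), 0.0)

    if spec.mode == "tube":
        pen = r - r_wall
        m = pen > 0
        f[m, 0] -= k * pen[m] * ux[m]
        f[m, 1] -= k * pen[m] * uy[m]
        return f

    # membrane slab: z in (z_lower, z_upper), r > r_wall
    m = (z > g.z_lower) & (z < g.z_upper) & (r > r_wall)
    if m.any():
        dr = r[m] - r_wall
        dz_lo = z[m] - g.z_lower
        dz_up = g.z_upper - z[m]
        dz = np.minimum(dz_lo, dz_up)
        rad = dr <= dz
        idx = np.flatnonzero(m)
        ir = idx[rad]
        f[ir, 0] -= k * dr[rad] * ux[ir]
        f[ir, 1] -= k * dr[rad] * uy[ir]
        lo_closer = (~rad) & (dz_lo < dz_up)
        hi_closer = (~rad) & ~(dz_lo < dz_up)
        f[idx[lo_closer], 2] -= k * dz_lo[lo_closer]
        f[idx[hi_closer], 2] += k * dz_up[hi_closer]

    # ECD shell with fenestration holes; extends down through the membrane
    # band so it seals against the slab (no gap to sneak under)
    t = g.wall_thickness
    in_shell = (z > g.z_lower) & (z < g.z_apical) & (r > g.r_vest) & (r < g.r_vest + t)
    if in_shell.any():
        az = np.mod(np.arctan2(y, x), 2 * np.pi)
        w = 2 * np.pi / g.n_sectors
        a = np.mod(az - g.sector_phase, w)
        hole = ((z >= g.z_fen_lo) & (z <= g.z_fen_hi)
                & (np.abs(a - w / 2) < spec.fen_frac * w / 2))
        m = in_shell & ~hole
        if m.any():
            pen_in = r[m] - g.r_vest
            pen_out = (g.r_vest + t) - r[m]
            idx = np.flatnonzero(m)
            inner = pen_in <= pen_out
            f[idx[inner], 0] -= k * pen_in[inner] * ux[idx[inner]]
            f[idx[inner], 1] -= k * pen_in[inner] * uy[idx[inner]]
            f[idx[~inner], 0] += k * pen_out[~inner] * ux[idx[~inner]]
            f[idx[~inner], 1] += k * pen_out[~inner] * uy[idx[~inner]]

    # vestibule ceiling: annulus between apical aperture and shell
    m = (z > g.z_vest_hi) & (z < g.z_apical) & (r >= g.r_apical) & (r <= g.r_vest)
    if m.any():
        dn = z[m] - g.z_vest_hi
        up = g.z_apical - z[m]
        idx = np.flatnonzero(m)
        lo = dn <= up
        f[idx[lo], 2] -= k * dn[lo]
        f[idx[~lo], 2] += k * up[~lo]
    return f


def _init_positions(spec: SimSpec, rng: np.random.Generator) -> np.ndarray:
    """Uniform start positions in the accessible region (rejection sampling)."""
    lx, ly, lz = spec.box
    if spec.mode == "tube":
        r_wall = max(spec.geometry.r_pore - spec.pore_wall_margin,
                     0.5 * spec.geometry.r_pore)
        rr = r_wall * np.sqrt(rng.uniform(size=spec.n_ions))
        th = rng.uniform(0, 2 * np.pi, size=spec.n_ions)
        z = rng.uniform(-lz / 2, lz / 2, size=spec.n_ions)
        return np.column_stack([rr * np.cos(th), rr * np.sin(th), z])
    out = np.empty((0, 3))
    while len(out) < spec.n_ions:
        cand = rng.uniform([-lx / 2, -ly / 2, -lz / 2],
                           [lx / 2, ly / 2, lz / 2],
                           size=(4 * spec.n_ions, 3))
        ok = np.all(_wall_forces(cand, spec) == 0.0, axis=1)
        out = np.vstack([out, cand[ok]])
    return out[:spec.n_ions]


# ---------------------------------------------------------------------------
# Brownian channel simulator
# ---------------------------------------------------------------------------

def langevin_channel_sim(spec: SimSpec) -> Tuple[IonTrajectory, GroundTruthLog]:
    """Overdamped Langevin ions in the model channel under a uniform field.

    Update rule per coordinate: x ← x + (D/k_BT)·F·dt + √(2·D·dt)·η with
    F = −∇U(z) + z_ion·e·E_z + soft-wall confinement, periodic in all three
    directions (an ion leaving one bulk re-enters the other, as in a
    fixed-field simulation cell).  The ground-truth log holds every true
    crossing, with pathway labels recorded at step resolution from the
    aperture/fenestration passages of each ion.
    """
    rng = np.random.default_rng(spec.seed)
    g = spec.geometry
    box = np.asarray(spec.box)
    n_steps = int(round(spec.duration / spec.timestep))
    beta = 1.0 / spec.kt
    sig = np.sqrt(2.0 * spec.diffusion * spec.timestep)
    mob = beta * spec.diffusion * spec.timestep
    fz_field = spec.z_ion * spec.e_z * MV_E_KCAL

    if spec.u_profile is not None:
        zk = np.asarray(spec.u_profile[0], float)
        uk = np.asarray(spec.u_profile[1], float)
        slopes = np.diff(uk) / np.diff(zk)
    pos = _init_positions(spec, rng)
    n_saved = n_steps // spec.save_every + 1
    saved = np.empty((spec.n_ions, n_saved, 3))
    saved[:, 0] = pos
    passages: List[tuple] = []  # (time, ion, kind, sector, entering)
    w = 2 * np.pi / g.n_sectors
    last_region = np.zeros(spec.n_ions, dtype=np.int8)  # 0 none, 1 bulk, 2 vest
    last_pos = pos.copy()

    for step in range(1, n_steps + 1):
        f = _wall_forces(pos, spec)
        f[:, 2] += fz_field
        if spec.u_profile is not None:
            zi = np.clip(np.searchsorted(zk, pos[:, 2]) - 1, 0, len(slopes) - 1)
            inside = (pos[:, 2] >= zk[0]) & (pos[:, 2] <= zk[-1])
            f[inside, 2] -= slopes[zi[inside]]
        disp = mob * f + sig * rng.standard_normal(pos.shape)
        if np.abs(disp).max() > box.min() / 2:
            raise RuntimeError("divergent step: reduce the timestep")
        new = pos + disp
        new = (new + box / 2) % box - box / 2
        if spec.mode == "channel":
            t_now = step * spec.timestep
            # region tracking with full-shell hysteresis: a passage is a
            # flip between extracellular bulk (above the ceiling or beyond
            # the outer shell surface) and the vestibule interior — grazing
            # the fenestration cylinder without traversing the shell never
            # registers.
            r_new = np.hypot(new[:, 0], new[:, 1])
            zc = new[:, 2]
            r_outer = g.r_fen + g.wall_thickness
            bulk_now = (zc > g.z_apical) | ((zc > g.z_upper) & (r_new > r_outer))
            vest_now = (zc > g.z_upper) & (zc < g.z_vest_hi) & (r_new < g.r_fen)
            intra_now = zc < g.z_lower
            region_now = np.where(bulk_now, 1,
                                  np.where(vest_now, 2,
                                           np.where(intra_now, 3, 0)))
            flips = np.flatnonzero((region_now != 0)
                                   & (last_region != 0)
                                   & (region_now != last_region)
                                   & (region_now != 3) & (last_region != 3))
            for i in flips:
                mid = (last_pos[i] + new[i]) / 2
                entering = region_now[i] == 2
                if mid[2] > (g.z_fen_hi + g.z_vest_hi) / 2:
                    passages.append((t_now, i, "apical", None, entering))
                else:
                    az = np.mod(np.arctan2(mid[1], mid[0]), 2 * np.pi)
                    sector = int(np.floor(np.mod(az - g.sector_phase,
                                                 2 * np.pi) / w))
                    passages.append((t_now, i, "lateral",
                                     min(sector, g.n_sectors - 1), entering))
            definite = region_now != 0
            last_region[definite] = region_now[definite]
            last_pos[definite] = new[definite]
        pos = new
        if step % spec.save_every == 0:
            saved[:, step // spec.save_every] = pos

    times = np.arange(n_saved) * spec.timestep * spec.save_every
    times[0] = 0.0
    traj = IonTrajectory(times=times, box=np.tile(box, (n_saved, 1)),
                         positions=saved, ion_ids=np.arange(spec.n_ions),
                         z_ion=spec.z_ion,
                         species="NA" if spec.z_ion > 0 else "CL")
    events = reference.oracle_events(traj, g)
    if spec.mode == "channel":
        _attach_pathways(events, passages, traj)
    gamma = spec.programmed_gamma_pS if (spec.mode == "tube"
                                         and spec.u_profile is None) else None
    return traj, GroundTruthLog(events=events, programmed_gamma_pS=gamma,
                                meta={"spec": spec})


def _attach_pathways(events: Sequence[PermeationEvent], passages: List[tuple],
                     traj: IonTrajectory) -> None:
    """Label events with the ECD passage adjacent to the gate crossing.

    The passage must fall between an ion's neighbouring crossings, so a
    vestibule entry that preceded an intervening crossing can never be
    reused for a later event (such events stay unassigned).
    """
    by_ion: dict = {}
    for p in passages:
        by_ion.setdefault(p[1], []).append(p)
    ev_by_ion: dict = {}
    for ev in sorted(events, key=lambda e: e.entry_ns):
        ev_by_ion.setdefault(ev.ion_id, []).append(ev)
    id_to_idx = {iid: i for i, iid in enumerate(traj.ion_ids)}
    for ion_id, evs in ev_by_ion.items():
        plist = by_ion.get(id_to_idx.get(ion_id, ion_id), [])
        for k, ev in enumerate(evs):
            lo = evs[k - 1].exit_ns if k > 0 else -np.inf
            hi = evs[k + 1].entry_ns if k + 1 < len(evs) else np.inf
            chosen = None
            if ev.direction == "inward":
                for p in plist:
                    if lo <= p[0] <= ev.entry_ns + 1e-12 and p[4]:
                        chosen = p
            else:
                for p in plist:
                    if ev.exit_ns - 1e-12 <= p[0] <= hi and not p[4]:
                        chosen = p
                        break
            if chosen is not None:
                ev.pathway = chosen[2]
                ev.sector = chosen[3]


# ---------------------------------------------------------------------------
# scripted trajectories
# ---------------------------------------------------------------------------

def scripted_trajectory(paths: Sequence[Tuple[Sequence[float], np.ndarray]],
                        dt: float = 0.1,
                        box: Tuple[float, float, float] = (40.0, 40.0, 80.0),
                        geometry: Optional[ChannelGeometry] = None,
                        z_ion: int = 1) -> Tuple[IonTrajectory, GroundTruthLog]:
    """Ions moving along prescribed waypoints, linearly interpolated at dt.

    Each element of ``paths`` is ``(times, waypoints)`` with waypoints an
    (M, 3) array; coordinates are held constant outside an ion's time range.
    True events come from the exhaustive per-frame oracle on the emitted
    frames; pathway labels are derived analytically from the waypoint
    segments (aperture-plane and fenestration-cylinder crossings).
    """
    geometry = geometry or ChannelGeometry()
    t_end = max(float(np.max(t)) for t, _ in paths)
    times = np.arange(0.0, t_end + dt / 2, dt)
    n_ions = len(paths)
    pos = np.empty((n_ions, len(times), 3))
    for i, (t, wp) in enumerate(paths):
        t = np.asarray(t, float)
        wp = np.asarray(wp, float)
        if not np.all(np.isfinite(wp)):
            raise ValueError("waypoints must be finite")
        for d in range(3):
            pos[i, :, d] = np.interp(times, t, wp[:, d])
    traj = IonTrajectory(times=times, box=np.tile(box, (len(times), 1)),
                         positions=pos, ion_ids=np.arange(n_ions), z_ion=z_ion)
    events = reference.oracle_events(traj, geometry)
    passages: List[tuple] = []
    for i, (t, wp) in enumerate(paths):
        passages.extend(_route_passages(i, np.asarray(t, float),
                                        np.asarray(wp, float), geometry))
    passages.sort(key=lambda p: p[0])
    _attach_pathways(events, passages, traj)
    return traj, GroundTruthLog(events=events)


def _route_passages(ion: int, t: np.ndarray, wp: np.ndarray,
                    geom: ChannelGeometry) -> List[tuple]:
    """Analytic aperture/fenestration crossings of a waypoint polyline."""
    out: List[tuple] = []
    w = 2 * np.pi / geom.n_sectors
    for a, b, ta, tb in zip(wp[:-1], wp[1:], t[:-1], t[1:]):
        dz = b[2] - a[2]
        if (a[2] - geom.z_apical) * (b[2] - geom.z_apical) < 0:
            s = (geom.z_apical - a[2]) / dz
            p = a + s * (b - a)
            if np.hypot(p[0], p[1]) < geom.r_apical:
                out.append((ta + s * (tb - ta), ion, "apical", None, dz < 0))
        ra, rb = np.hypot(a[0], a[1]), np.hypot(b[0], b[1])
        if (ra - geom.r_fen) * (rb - geom.r_fen) < 0:
            # locate the radial crossing by bisection on the segment
            lo, hi = 0.0, 1.0
            f = lambda s: np.hypot(*(a[:2] + s * (b[:2] - a[:2]))) - geom.r_fen
            for _ in range(50):
                mid = (lo + hi) / 2
                if f(lo) * f(mid) <= 0:
                    hi = mid
                else:
                    lo = mid
            s = (lo + hi) / 2
            p = a + s * (b - a)
            if geom.z_fen_lo <= p[2] <= geom.z_fen_hi:
                az = np.mod(np.arctan2(p[1], p[0]), 2 * np.pi)
                sector = int(np.floor(np.mod(az - geom.sector_phase,
                                             2 * np.pi) / w))
                out.append((ta + s * (tb - ta), ion, "lateral",
                            min(sector, geom.n_sectors - 1), rb < geom.r_fen))
    return out


def ohmic_campaign(voltages: Sequence[float] = (-250.0, -100.0, 0.0,
                                                100.0, 250.0),
                   n_replicates: int = 3, duration: float = 150.0,
                   seed: int = 0, **spec_kwargs):
    """A fixed-field campaign over the standard voltage ladder.

    Runs the tube-mode (exactly Ohmic) simulator for ``n_replicates``
    independent replicates at each transmembrane potential and yields
    ``(dv_m, replicate, trajectory, ground_truth)`` tuples.  The programmed
    conductance is the closed-form tube value.
    """
    base = SimSpec(**spec_kwargs) if spec_kwargs else SimSpec()
    for v in voltages:
        for rep in range(n_replicates):
            kw = dict(base.__dict__)
            kw.update(mode="tube", duration=duration,
                      e_z=v / base.box[2],
                      seed=seed + 101 * rep + int(round(abs(v))) * 13
                      + (7 if v < 0 else 0))
            spec = SimSpec(**kw)
            traj, log = langevin_channel_sim(spec)
            yield v, rep, traj, log


def mixed_route_paths(n_events: int, seed: int = 0,
                      geometry: Optional[ChannelGeometry] = None,
                      p_apical: float = 0.3):
    """Waypoint routes for a crowd of single-crossing ions with known truth.

    Each ion performs exactly one full crossing, inward or outward with
    equal probability, through the apical aperture with probability
    ``p_apical`` and otherwise through a uniformly chosen fenestration
    sector (within the open part of the hole).  Returns (paths, labels)
    where labels[i] = (direction, pathway, sector).
    """
    g = geometry or ChannelGeometry()
    rng = np.random.default_rng(seed)
    w = 2 * np.pi / g.n_sectors
    paths, labels = [], []
    for i in range(n_events):
        outward = rng.uniform() < 0.5
        apical = rng.uniform() < p_apical
        jig = lambda s=1.0: rng.uniform(-s, s)
        z_mid_fen = 0.5 * (g.z_fen_lo + g.z_fen_hi) + jig(2.0)
        below = np.array([jig(), jig(), g.z_lower - 6.0 + jig(2.0)])
        gate_bot = np.array([jig(), jig(), g.z_lower - 1.5])
        gate_top = np.array([jig(), jig(), g.z_upper + 1.5])
        vest_mid = np.array([jig(3.0), jig(3.0),
                             0.5 * (g.z_vest_lo + g.z_vest_hi)])
        if apical:
            r_in = 0.4 * g.r_apical
            th = rng.uniform(0, 2 * np.pi)
            neck = np.array([r_in * np.cos(th), r_in * np.sin(th),
                             g.z_vest_hi + 1.0])
            above = np.array([r_in * np.cos(th), r_in * np.sin(th),
                              g.z_apical + 5.0 + jig(2.0)])
            ecd_leg = [neck, above]
            sector = None
        else:
            sector = int(rng.integers(g.n_sectors))
            th = (g.sector_phase + (sector + 0.5) * w
                  + rng.uniform(-0.3, 0.3) * spec_hole_half(g))
            inner = np.array([8.0 * np.cos(th), 8.0 * np.sin(th), z_mid_fen])
            outer = np.array([(g.r_fen + g.wall_thickness + 4.0) * np.cos(th),
                              (g.r_fen + g.wall_thickness + 4.0) * np.sin(th),
                              z_mid_fen])
            ecd_leg = [inner, outer]
        route = [below, gate_bot, gate_top, vest_mid] + ecd_leg
        if not outward:
            route = route[::-1]
        t = np.linspace(0.0, 10.0, len(route))
        paths.append((t, np.vstack(route)))
        labels.append(("outward" if outward else "inward",
                       "apical" if apical else "lateral", sector))
    return paths, labels


def spec_hole_half(g: ChannelGeometry, fen_frac: float = 0.6) -> float:
    """Half-angle of the open part of one fenestration sector (rad)."""
    return fen_frac * (2 * np.pi / g.n_sectors) / 2.0




def analytic_open_radius(profile: Callable, z: float,
                         z_range: Tuple[float, float], vdw: float = 1.5,
                         dense: float = 0.01) -> float:
    """Exact on-axis open radius of the ring construction at height z.

    The largest sphere centred on the axis at z touching a channel of
    radius profile(z') has radius  min_z' sqrt((profile(z')+vdw)^2 +
    (z'-z)^2) - vdw; for flat or locally-minimal profiles this reduces to
    profile(z).
    """
    zs = np.arange(z_range[0], z_range[1] + dense / 2, dense)
    rr = np.array([float(profile(zz)) for zz in zs]) + vdw
    return float(np.min(np.sqrt(rr ** 2 + (zs - z) ** 2)) - vdw)


# ---------------------------------------------------------------------------
# single-channel trace generator
# ---------------------------------------------------------------------------

def markov_patch_trace(spec: PatchSpec, holding_mV: Optional[float] = None):
    """Two-state continuous-time Markov trace sampled at the recording rate.

    Open-state current is baseline + γ·V (pS·mV → pA via 10⁻³); Gaussian
    noise of the configured SD is added to every sample.  Returns the
    :class:`~ionflux.ephys.Recording` and a ground-truth dict with the true
    single-channel current, per-sample state, and open probability.
    """
    from .ephys import Recording

    v = float(spec.holding_potentials[0] if holding_mV is None else holding_mV)
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.sampling_hz))
    p_open = spec.k_open / (spec.k_open + spec.k_close)
    state = np.empty(n, dtype=np.int8)
    cur_state = int(rng.uniform() < p_open)
    t_pos = 0
    t_clock = 0.0
    while t_pos < n:
        rate = spec.k_close if cur_state else spec.k_open
        dwell = rng.exponential(1.0 / rate)
        t_next = t_clock + dwell
        i_next = min(n, int(np.floor(t_next * spec.sampling_hz)) + 1)
        state[t_pos:i_next] = cur_state
        t_pos = i_next
        t_clock = t_next
        cur_state = 1 - cur_state
    i_open = spec.gamma_pS * v * 1e-3  # pA
    current = spec.baseline_pA + state * i_open
    if spec.noise_sd_pA > 0:
        current = current + spec.noise_sd_pA * rng.standard_normal(n)
    rec = Recording(current=current, rate_hz=spec.sampling_hz,
                    holding_mV=v, patch_id=f"synth-{spec.seed}",
                    construct="synthetic")
    truth = {"i_true_pA": i_open, "p_open": p_open, "state": state,
             "gamma_pS": spec.gamma_pS}
    return rec, truth


def patch_campaign(spec: PatchSpec):
    """One trace per holding potential (seeds offset per potential)."""
    out = []
    for j, v in enumerate(spec.holding_potentials):
        s = PatchSpec(**{**spec.__dict__, "seed": spec.seed + 1000 * j + 1})
        out.append(markov_patch_trace(s, holding_mV=v))
    return out


# ---------------------------------------------------------------------------
# analytic pore structures
# ---------------------------------------------------------------------------

def synthetic_pore_structure(profile: Callable[[np.ndarray], np.ndarray],
                             z_range: Tuple[float, float] = (-10.0, 10.0),
                             ring_spacing: float = 0.25,
                             vdw: float = 1.5) -> AtomSet:
    """Atom rings realizing a prescribed radius profile.

    Atoms of vdW radius ``vdw`` sit at radial distance profile(z) + vdw;
    in-ring gaps are kept below the vdW radius so the clearance at the ring
    centre is governed by the ring, not the gaps.  The on-axis clearance at
    height z equals profile(z) wherever the profile is flat or at a local
    minimum; where it slopes, narrower neighbouring rings clip the
    inscribed sphere, and the exact value is :func:`analytic_open_radius`.
    """
    z_lo, z_hi = z_range
    zs = np.arange(z_lo, z_hi + ring_spacing / 2, ring_spacing)
    pts = []
    for j, z in enumerate(zs):
        r = float(profile(z))
        if r <= 0:
            raise ValueError("profile radius must be positive")
        ring_r = r + vdw
        n_at = max(8, int(np.ceil(2 * np.pi * ring_r / (0.8 * vdw))))
        th = np.arange(n_at) * 2 * np.pi / n_at + (j % 2) * np.pi / n_at
        pts.append(np.column_stack([ring_r * np.cos(th), ring_r * np.sin(th),
                                    np.full(n_at, z)]))
    pts = np.vstack(pts)
    return AtomSet(positions=pts, labels=np.full(len(pts), "PSE"),
                   radii=np.full(len(pts), vdw))
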