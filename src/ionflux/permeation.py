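"""Permeation-event detection, pathway classification, and I–V analysis.

A permeation event is a complete traversal of the transmembrane gate slab
(``z_lower``–``z_upper`` of a :class:`~ionflux.io_core.ChannelGeometry`)
during which every frame spent between the gate planes lies within the pore
cylinder.  Counts become currents (net signed crossings per unit time), and
per-polarity ordinary least squares on the I–V points gives the outward and
inward slope conductances γ_o and γ_i whose quotient is the rectification
ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .io_core import ChannelGeometry, IonTrajectory, E_CHARGE, KB_KCAL

logger = logging.getLogger("ionflux.permeation")

#: pA carried by one crossing per ns of a unit charge.
PA_PER_CROSSING_PER_NS = E_CHARGE * 1e21  # C/ns → pA; = 160.2176634


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class PermeationEvent:
    """One full channel crossing."""

    ion_id: object
    entry_ns: float
    exit_ns: float
    direction: str  # "outward" | "inward"
    pathway: str = "unassigned"  # "apical" | "lateral" | "unassigned"
    sector: Optional[int] = None
    entry_frame: Optional[int] = None
    exit_frame: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.entry_ns < self.exit_ns:
            raise ValueError("event entry time must precede exit time")
        if self.direction not in ("outward", "inward"):
            raise ValueError(f"bad direction {self.direction!r}")


@dataclass
class CurrentEstimate:
    """Current at one voltage from one replicate."""

    dv_m: float  # mV
    current: float  # pA
    n_out: int
    n_in: int
    time_ns: float
    replicate: int = 0


@dataclass
class IVDataset:
    """Per-voltage, per-replicate currents for one structure/construct."""

    points: List[CurrentEstimate]
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.points) < 1:
            raise ValueError("IVDataset needs at least one point")

    def voltages(self) -> np.ndarray:
        return np.array([p.dv_m for p in self.points])

    def currents(self) -> np.ndarray:
        return np.array([p.current for p in self.points])


@dataclass
class ConductanceFit:
    """Per-polarity slope conductances with standard errors.

    γ_o comes from all points with ΔV_m ≥ 0, γ_i from all points with
    ΔV_m ≤ 0 (0 mV replicates enter both fits); slopes are plain OLS, not
    forced through the origin.
    """

    gamma_o: float  # pS
    se_o: float
    intercept_o: float
    gamma_i: float  # pS
    se_i: float
    intercept_i: float
    ratio: float = field(init=False)

    def __post_init__(self) -> None:
        self.ratio = rectification_ratio(self.gamma_o, self.gamma_i)


# ---------------------------------------------------------------------------
# event detection
# ---------------------------------------------------------------------------

def _frame_states(traj: IonTrajectory, geom: ChannelGeometry, buffer: float
                  ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-ion per-frame side code, periodic image index, and radial-bad flag.

    Side codes: 0 below the gate, 1 inside the (buffered) gate band, 2 above.
    The image index folds the unwrapped z back onto the primary cell so a
    passage through the periodic boundary is never mistaken for a gate
    crossing.
    """
    z = traj.unwrapped[:, :, 2]
    lz = traj.box[:, 2][None, :]
    u = np.floor((z + lz / 2.0) / lz)
    z_local = z - u * lz
    side = np.ones(z.shape, dtype=np.int8)
    side[z_local > geom.z_upper + buffer] = 2
    side[z_local < geom.z_lower - buffer] = 0
    # radial check applies only strictly between the gate planes
    lx = traj.box[:, 0][None, :]
    ly = traj.box[:, 1][None, :]
    dx = traj.positions[:, :, 0] - geom.axis_origin[0]
    dy = traj.positions[:, :, 1] - geom.axis_origin[1]
    dx -= lx * np.round(dx / lx)
    dy -= ly * np.round(dy / ly)
    r = np.hypot(dx, dy)
    in_gate = (z_local >= geom.z_lower) & (z_local <= geom.z_upper)
    bad = in_gate & (r > geom.r_pore)
    return side, u.astype(np.int64), bad


def detect_events(traj: IonTrajectory, geom: ChannelGeometry,
                  buffer: float = 0.0) -> List[PermeationEvent]:
    """Detect full gate traversals.

    An event is recorded when an ion passes from beyond one gate plane to
    beyond the other while every frame spent between the planes lies within
    ``r_pore`` of the axis.  Partial entries that return to the entry side
    produce nothing.  ``buffer`` (Å) optionally widens the band an ion must
    clear before it counts as outside, suppressing single-frame jitter
    double counts (2 Å is a reasonable value); the default is strict plane
    passage.
    """
    span = traj.box[:, 2].min()
    if not (-span / 2 < geom.z_lower < geom.z_upper < span / 2):
        raise ValueError("gate planes must lie inside the primary box cell")
    side_all, u_all, bad_all = _frame_states(traj, geom, buffer)
    times = traj.times
    events: List[PermeationEvent] = []
    for i in range(traj.n_ions):
        side, u, bad = side_all[i], u_all[i], bad_all[i]
        cum_bad = np.concatenate([[0], np.cumsum(bad)])
        change = np.flatnonzero((np.diff(side) != 0) | (np.diff(u) != 0)) + 1
        starts = np.concatenate([[0], change])
        last_outside = None       # (side, image, frame of last sample there)
        gate_origin = None        # (side, image, entry frame) or None
        gate_start = None
        prev_end = -1
        for k, s0 in enumerate(starts):
            s_end = starts[k + 1] - 1 if k + 1 < len(starts) else len(side) - 1
            sd, im = int(side[s0]), int(u[s0])
            if sd == 1:
                gate_start = s0
                if last_outside is not None and last_outside[1] == im \
                        and last_outside[2] == s0 - 1:
                    gate_origin = last_outside
                else:
                    gate_origin = None
            else:
                if gate_start is not None:
                    # leaving the gate band
                    if (gate_origin is not None and gate_origin[1] == im
                            and gate_origin[0] != sd
                            and cum_bad[s0] - cum_bad[gate_start] == 0):
                        direction = "inward" if gate_origin[0] == 2 else "outward"
                        events.append(PermeationEvent(
                            ion_id=traj.ion_ids[i],
                            entry_ns=float(times[gate_origin[2]]),
                            exit_ns=float(times[s0]),
                            direction=direction,
                            entry_frame=gate_origin[2], exit_frame=int(s0)))
                elif (last_outside is not None and last_outside[2] == s0 - 1
                        and last_outside[1] == im and last_outside[0] != sd):
                    # direct jump across the whole gate between two frames
                    direction = "inward" if last_outside[0] == 2 else "outward"
                    events.append(PermeationEvent(
                        ion_id=traj.ion_ids[i],
                        entry_ns=float(times[s0 - 1]),
                        exit_ns=float(times[s0]),
                        direction=direction,
                        entry_frame=int(s0 - 1), exit_frame=int(s0)))
                gate_start = None
                gate_origin = None
                last_outside = (sd, im, s_end)
            prev_end = s_end
    events.sort(key=lambda e: (e.exit_ns, str(e.ion_id)))
    return events


# ---------------------------------------------------------------------------
# pathway classification
# ---------------------------------------------------------------------------

def _ecd_region_masks(traj: IonTrajectory, geom: ChannelGeometry
                      ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-ion per-frame masks: extracellular bulk / ECD vestibule /
    intracellular side."""
    z = traj.unwrapped[:, :, 2]
    lz = traj.box[:, 2][None, :]
    u = np.floor((z + lz / 2.0) / lz)
    z_local = z - u * lz
    r = geom.radial(traj.positions)
    r_outer = geom.r_fen + geom.wall_thickness
    bulk = (z_local > geom.z_apical) | (
        (z_local > geom.z_upper) & (z_local <= geom.z_apical) & (r > r_outer))
    vest = (z_local > geom.z_upper) & (z_local <= geom.z_vest_hi) & (r < geom.r_vest)
    intra = z_local < geom.z_lower
    return bulk, vest, intra


def _transition_window(event: PermeationEvent, traj: IonTrajectory,
                       geom: ChannelGeometry) -> Optional[Tuple[int, int]]:
    """Frame range [lo, hi] of the bulk↔vestibule transit adjacent to the
    TMD crossing: from the last bulk frame to the first vestibule frame
    before the gate entry for inward events, and the mirror image after the
    gate exit for outward events."""
    ion_idx = int(np.flatnonzero(traj.ion_ids == event.ion_id)[0])
    bulk, vest, intra = _ecd_region_masks(traj, geom)
    b, v, ic = bulk[ion_idx], vest[ion_idx], intra[ion_idx]
    if event.direction == "inward":
        f_entry = event.entry_frame if event.entry_frame is not None else int(
            np.searchsorted(traj.times, event.entry_ns))
        idx = np.flatnonzero(b[:f_entry + 1])
        if len(idx) == 0:
            return None
        fb = int(idx[-1])
        if ic[fb:f_entry + 1].any():
            # the ion reached the vestibule from the intracellular side,
            # not from extracellular bulk — no ECD transit exists
            return None
        iv = np.flatnonzero(v[fb + 1:f_entry + 1])
        fv = int(iv[0]) + fb + 1 if len(iv) else f_entry
        return fb, fv
    f_exit = event.exit_frame if event.exit_frame is not None else int(
        np.searchsorted(traj.times, event.exit_ns))
    idx = np.flatnonzero(b[f_exit:]) + f_exit
    if len(idx) == 0:
        return None
    fb = int(idx[0])
    if ic[f_exit:fb + 1].any():
        return None
    iv = np.flatnonzero(v[f_exit:fb])
    fv = int(iv[-1]) + f_exit if len(iv) else f_exit
    return fv, fb


def _classify_window(event: PermeationEvent, traj: IonTrajectory,
                     geom: ChannelGeometry
                     ) -> Tuple[str, Optional[int]]:
    window = _transition_window(event, traj, geom)
    if window is None:
        logger.info("event %s: no bulk↔vestibule transition found", event)
        return "unassigned", None
    lo, hi = window
    ion_idx = int(np.flatnonzero(traj.ion_ids == event.ion_id)[0])
    z = traj.unwrapped[ion_idx, lo:hi + 1, 2]
    lz = traj.box[lo:hi + 1, 2]
    zl = z - np.floor((z + lz / 2) / lz) * lz
    r = geom.radial(traj.positions[ion_idx, lo:hi + 1])
    apical = (zl >= geom.z_vest_hi) & (zl <= geom.z_apical + 2.0) \
        & (r < geom.r_apical)
    lateral = (zl >= geom.z_fen_lo) & (zl <= geom.z_fen_hi) \
        & (r >= geom.r_fen - 1e-9)
    vest_end_first = event.direction == "outward"

    def sector_of(mask):
        # frame of the fenestration passage closest to the vestibule side
        f = int(np.flatnonzero(mask)[0 if vest_end_first else -1])
        pos = traj.positions[ion_idx, lo + f]
        az = float(geom.azimuth(pos))
        width = 2.0 * np.pi / geom.n_sectors
        s = int(np.floor(((az - geom.sector_phase) % (2 * np.pi)) / width))
        return min(s, geom.n_sectors - 1)

    if lateral.any() and not apical.any():
        return "lateral", sector_of(lateral)
    if apical.any() and not lateral.any():
        return "apical", None
    if apical.any() and lateral.any():
        fa = np.flatnonzero(apical)[0 if vest_end_first else -1]
        fl = np.flatnonzero(lateral)[0 if vest_end_first else -1]
        closer_lateral = (fl > fa) != vest_end_first
        if closer_lateral:
            return "lateral", sector_of(lateral)
        return "apical", None
    logger.info("event %s: transit not classifiable", event)
    return "unassigned", None


def classify_pathway(event: PermeationEvent, traj: IonTrajectory,
                     geom: ChannelGeometry) -> str:
    """Label an event apical or lateral.

    The ion's transit between extracellular bulk and the ECD vestibule —
    the last one before the gate entry for inward events, the first one
    after the gate exit for outward events — is located; frames of the
    transit passing through the apical aperture (inside ``r_apical`` above
    the vestibule ceiling) mark it apical, frames beyond the fenestration
    inner radius within the fenestration band mark it lateral, and a
    transit showing neither stays unassigned (and is logged), never
    silently dropped.
    """
    pathway, sector = _classify_window(event, traj, geom)
    event.pathway = pathway
    if sector is not None:
        event.sector = sector
    return pathway


def assign_fenestration(event: PermeationEvent, traj: IonTrajectory,
                        geom: ChannelGeometry) -> int:
    """Azimuthal sector (0..n_sectors−1) of a lateral event's fenestration
    passage, in equal sectors offset by the configured phase angle."""
    if event.pathway != "lateral":
        raise ValueError("fenestration sectors are defined for lateral events only")
    pathway, sector = _classify_window(event, traj, geom)
    if pathway != "lateral" or sector is None:
        raise ValueError("no fenestration passage found for event")
    event.sector = sector
    return sector


def classify_events(events: Sequence[PermeationEvent], traj: IonTrajectory,
                    geom: ChannelGeometry) -> List[PermeationEvent]:
    """Classify every event's pathway and, for lateral ones, the sector."""
    for ev in events:
        classify_pathway(ev, traj, geom)
        if ev.pathway == "lateral":
            assign_fenestration(ev, traj, geom)
    return list(events)


# ---------------------------------------------------------------------------
# currents and conductances
# ---------------------------------------------------------------------------

def estimate_current(events: Sequence[PermeationEvent], time_ns: float,
                     z_ion: int = 1, dv_m: float = 0.0, replicate: int = 0,
                     gross: bool = False) -> CurrentEstimate:
    """Current from crossing counts: I(pA) = z_ion·e·(N_out − N_in)/T.

    Outward cation flux is positive.  ``gross`` replaces the net signed
    count with N_out + N_in (crossings regardless of direction), matching
    the looser reading of "events per total simulation time".
    """
    if time_ns <= 0:
        raise ValueError("simulated time must be positive")
    n_out = sum(1 for e in events if e.direction == "outward")
    n_in = sum(1 for e in events if e.direction == "inward")
    count = (n_out + n_in) if gross else (n_out - n_in)
    current = z_ion * count * PA_PER_CROSSING_PER_NS / time_ns
    return CurrentEstimate(dv_m=dv_m, current=current, n_out=n_out,
                           n_in=n_in, time_ns=time_ns, replicate=replicate)


def _polarity_fit(v: np.ndarray, i: np.ndarray) -> Tuple[float, float, float]:
    if len(np.unique(v)) < 2:
        raise ValueError("need >= 2 distinct voltages on each polarity")
    res = stats.linregress(v, i)
    # slope pA/mV → pS  (1 pA/mV = 1 nS = 1000 pS)
    return res.slope * 1000.0, (res.stderr or 0.0) * 1000.0, res.intercept


def fit_conductance(iv: IVDataset) -> ConductanceFit:
    """Per-polarity OLS slope conductances.

    All replicate points at ΔV_m ≥ 0 give γ_o, all points at ΔV_m ≤ 0 give
    γ_i (the 0 mV points enter both); the fit is not forced through the
    origin and the slope standard error comes from the regression.
    """
    v, i = iv.voltages(), iv.currents()
    go, seo, bo = _polarity_fit(v[v >= 0], i[v >= 0])
    gi, sei, bi = _polarity_fit(v[v <= 0], i[v <= 0])
    return ConductanceFit(gamma_o=go, se_o=seo, intercept_o=bo,
                          gamma_i=gi, se_i=sei, intercept_i=bi)


def iv_from_trajectories(entries, geom: ChannelGeometry, z_ion: int = 1,
                         label: str = "") -> IVDataset:
    """Build an I–V dataset by running detection on replicate trajectories.

    ``entries`` yields (ΔV_m, replicate, trajectory) or (ΔV_m, replicate,
    trajectory, extra) tuples.
    """
    points = []
    for entry in entries:
        dv_m, rep, traj = entry[0], entry[1], entry[2]
        events = detect_events(traj, geom)
        points.append(estimate_current(events, traj.duration, z_ion=z_ion,
                                       dv_m=dv_m, replicate=rep))
    return IVDataset(points=points, label=label)


def rectification_ratio(gamma_o: float, gamma_i: float) -> float:
    """γ_o/γ_i; 1 means Ohmic."""
    if gamma_i == 0:
        raise ZeroDivisionError("rectification ratio undefined for γ_i = 0")
    return gamma_o / gamma_i


# ---------------------------------------------------------------------------
# trajectory statistics
# ---------------------------------------------------------------------------

def vestibule_return_events(traj: IonTrajectory, geom: ChannelGeometry,
                            events: Optional[Sequence[PermeationEvent]] = None
                            ) -> int:
    """Count outward crossings that return inward without reaching bulk.

    Diagnoses vestibule-trapped ions: an ion crosses the gate outward, fails
    to exit the ECD, and recrosses inward.  Pairs of consecutive
    opposite-direction crossings by the same ion with no extracellular-bulk
    visit in between are counted.
    """
    if events is None:
        events = detect_events(traj, geom)
    bulk, _, _ = _ecd_region_masks(traj, geom)
    count = 0
    by_ion: dict = {}
    for ev in sorted(events, key=lambda e: e.exit_ns):
        by_ion.setdefault(ev.ion_id, []).append(ev)
    for ion_id, evs in by_ion.items():
        ion_idx = int(np.flatnonzero(traj.ion_ids == ion_id)[0])
        for e1, e2 in zip(evs[:-1], evs[1:]):
            if e1.direction == "outward" and e2.direction == "inward":
                f1 = e1.exit_frame if e1.exit_frame is not None else int(
                    np.searchsorted(traj.times, e1.exit_ns))
                f2 = e2.entry_frame if e2.entry_frame is not None else int(
                    np.searchsorted(traj.times, e2.entry_ns))
                if not bulk[ion_idx, f1:f2 + 1].any():
                    count += 1
    return count


def number_density_profile(trajs, geom: ChannelGeometry, bin_width: float = 1.0,
                           bulk_band: Tuple[float, float] = (30.0, 38.0),
                           count_radius: Optional[float] = None):
    """Ion number density vs z, normalized to the mean density in a bulk band.

    Returns (bin centers, mean ratio, SD over replicates).  ``trajs`` may be
    one trajectory or a list (replicates).  ``count_radius`` optionally
    restricts counting to a cylinder about the axis.
    """
    if isinstance(trajs, IonTrajectory):
        trajs = [trajs]
    lo, hi = bulk_band
    if not hi > lo:
        raise ValueError("empty bulk band")
    lz_min = min(t.box[:, 2].min() for t in trajs)
    edges = np.arange(-lz_min / 2, lz_min / 2 + bin_width / 2, bin_width)
    centers = (edges[:-1] + edges[1:]) / 2
    profiles = []
    for t in trajs:
        z = t.unwrapped[:, :, 2]
        lz = t.box[:, 2][None, :]
        zl = z - np.floor((z + lz / 2) / lz) * lz
        if count_radius is not None:
            r = geom.radial(t.positions)
            zl = zl[r <= count_radius]
        counts, _ = np.histogram(zl.ravel(), bins=edges)
        dens = counts / (t.n_frames * bin_width)
        bulk_mask = (centers >= lo) & (centers <= hi)
        if not bulk_mask.any():
            raise ValueError("bulk band contains no bins")
        bulk_dens = dens[bulk_mask].mean()
        if bulk_dens == 0:
            raise ValueError("no ions in the bulk band; cannot normalize")
        profiles.append(dens / bulk_dens)
    profiles = np.asarray(profiles)
    return centers, profiles.mean(axis=0), profiles.std(axis=0, ddof=0)


def pore_crossing_count_timeseries(traj: IonTrajectory, geom: ChannelGeometry,
                                   events: Optional[Sequence[PermeationEvent]] = None
                                   ) -> Tuple[np.ndarray, np.ndarray]:
    """Cumulative gross crossings vs time (non-decreasing step function
    sampled at the trajectory frames; a crossing counts at its exit time)."""
    if events is None:
        events = detect_events(traj, geom)
    exit_times = np.sort([e.exit_ns for e in events])
    cumulative = np.searchsorted(exit_times, traj.times, side="right")
    return traj.times.copy(), cumulative.astype(int)


def pore_water_count(traj: IonTrajectory, geom: ChannelGeometry) -> np.ndarray:
    """Per-frame count of particles inside the gate slab's pore cylinder.

    Intended for a trajectory of water oxygens, but counts whatever the
    trajectory holds.
    """
    z = traj.unwrapped[:, :, 2]
    lz = traj.box[:, 2][None, :]
    zl = z - np.floor((z + lz / 2) / lz) * lz
    r = geom.radial(traj.positions)
    inside = (zl >= geom.z_lower) & (zl <= geom.z_upper) & (r <= geom.r_pore)
    return inside.sum(axis=0)
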