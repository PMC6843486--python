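"""Geometric observables of host-guest inclusion trajectories.

All observables address the annotated groups of an
:class:`~cycloplex.core.AnnotatedSystem`:

* signed center-of-mass distance of each guest ring along the host axis,
  with the wide (O2/O3, secondary-hydroxyl) rim on the positive side and
  the narrow (primary) rim negative;
* binding-mode classification of a trace against the rim box and a
  dissociation threshold;
* adjacent-unit rim distances dO3-2 = |O3(n) - O2(n+1)| and
  dO4-4 = |O4(n) - O4(n+1)| with cyclic indexing, plus the fraction of
  observations compatible with an intramolecular wide-rim hydrogen bond
  (dO3-2 <= 3.5 A);
* native host-guest contacts (heavy-atom pairs within a cutoff) over an
  analysis window, summarized across replicates as mean +- SEM;
* solvent-accessible surface area of the guest in the context of the full
  complex (Shrake-Rupley with a deterministic sphere lattice).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core import AnnotatedSystem, AnnotationError, Trajectory
from .synthetic import DISSOCIATION_THRESHOLD

__all__ = [
    "DistanceTrace",
    "RimGeometryTrace",
    "ContactSummary",
    "SasaTrace",
    "GeometryError",
    "ParameterError",
    "host_axis",
    "signed_ring_distance",
    "classify_binding_mode",
    "rim_distances",
    "hbond_fraction",
    "native_contacts",
    "guest_sasa",
    "shrake_rupley",
    "sphere_points",
]

HBOND_CUTOFF = 3.5  # A, wide-rim O3-O2 hydrogen-bond criterion
CONTACT_CUTOFF = 3.0  # A, native-contact criterion
RIM_HALF_HEIGHT = 3.95  # A, rim box bound


class GeometryError(ValueError):
    """The geometry is degenerate for the requested observable."""


class ParameterError(ValueError):
    """A required per-atom parameter is missing."""


@dataclass
class DistanceTrace:
    values: np.ndarray  # per-frame signed distance, A
    label: str
    replicate_id: str = "MD1"
    time_per_frame: float = float("nan")  # ns

    def to_frame(self) -> pd.DataFrame:
        n = len(self.values)
        return pd.DataFrame(
            {
                "frame": np.arange(n),
                "time_ns": np.arange(n) * self.time_per_frame,
                "value": self.values,
                "label": self.label,
                "replicate": self.replicate_id,
            }
        )


@dataclass
class RimGeometryTrace:
    d32: np.ndarray  # (n_frames, n_units) O3(n)-O2(n+1)
    d44: np.ndarray  # (n_frames, n_units) O4(n)-O4(n+1)
    replicate_id: str = "MD1"
    time_per_frame: float = float("nan")


@dataclass
class ContactSummary:
    per_frame: dict  # replicate_id -> int array over window frames
    mean_total: float  # grand mean of total contacts (over replicate means)
    sem_total: float
    mean_per_unit: float  # total contacts / n_units, mean over replicates
    sem_per_unit: float
    per_unit_counts: np.ndarray  # mean contacts touching each unit
    cutoff: float
    n_units: int
    mode: str = "total_over_units"


@dataclass
class SasaTrace:
    values: np.ndarray  # per-frame guest SASA, A^2
    probe_radius: float
    n_sphere_points: int
    replicate_id: str = "MD1"


# ---------------------------------------------------------------------------
# axis and signed distances


def host_axis(system: AnnotatedSystem, frame: np.ndarray) -> np.ndarray:
    """Unit vector along the host cavity axis.

    The axis is the principal eigenvector (smallest-variance direction) of
    the glycosidic O4 ring, oriented so that the wide-rim O2/O3 centroid
    lies on the positive side.
    """
    n = system.n_units
    o4 = frame[[system.rim_oxygen("O4", k) for k in range(1, n + 1)]]
    centered = o4 - o4.mean(axis=0)
    cov = centered.T @ centered
    w, v = np.linalg.eigh(cov)
    # collinear O4 atoms leave the normal direction undefined
    if w[1] <= 1e-8 * max(w[2], 1.0):
        raise GeometryError("O4 ring is degenerate (collinear); host axis undefined")
    axis = v[:, 0]
    wide_ids = [system.rim_oxygen(kind, k)
                for k in range(1, n + 1) for kind in ("O2", "O3")]
    wide_centroid = frame[wide_ids].mean(axis=0)
    if np.dot(axis, wide_centroid - o4.mean(axis=0)) < 0:
        axis = -axis
    return axis


def _com(system: AnnotatedSystem, frame: np.ndarray, idx: np.ndarray) -> np.ndarray:
    m = system.masses[idx]
    return (frame[idx] * m[:, None]).sum(axis=0) / m.sum()


def signed_ring_distance(
    system: AnnotatedSystem,
    trajectory: Trajectory,
    ring: str = "A",
    *,
    host_core_group: str | None = None,
    wide_rim_positive: bool = True,
) -> DistanceTrace:
    """Signed axis projection of a guest ring's mass center.

    ``ring`` may be "A", "Q" or any annotated group label (e.g. "guest" for
    the whole-guest center).  The host center uses the ``host_core`` group
    when present (host without substituents), else all host atoms.
    ``wide_rim_positive`` picks the sign convention: by default the wide
    (secondary, O2/O3) rim is the positive side; flipping it negates every
    value.
    """
    label = {"A": "guest_ring_A", "Q": "guest_ring_Q"}.get(ring, ring)
    ring_idx = system.group(label)
    if host_core_group is None:
        host_core_group = "host_core" if "host_core" in system.groups else "host"
    host_idx = system.group(host_core_group)
    sign = 1.0 if wide_rim_positive else -1.0
    vals = np.empty(trajectory.n_frames)
    for t in range(trajectory.n_frames):
        frame = trajectory.coords[t]
        axis = sign * host_axis(system, frame)
        vals[t] = np.dot(_com(system, frame, ring_idx)
                         - _com(system, frame, host_idx), axis)
    return DistanceTrace(values=vals, label=f"d({label})",
                         replicate_id=trajectory.replicate_id,
                         time_per_frame=trajectory.time_per_frame)


def classify_binding_mode(
    trace: DistanceTrace,
    window=None,
    *,
    rim_half_height: float = RIM_HALF_HEIGHT,
    dissociation_threshold: float = DISSOCIATION_THRESHOLD,
) -> str:
    """Classify the window-mean signed distance.

    |mean| <= rim_half_height/2 -> "inside"; beyond the dissociation
    threshold -> "dissociated"; otherwise "wide_rim"/"narrow_rim" by sign.
    """
    v = trace.values if window is None else np.asarray(trace.values)[window]
    if len(v) == 0:
        raise ValueError("empty classification window")
    m = float(np.mean(v))
    if abs(m) > dissociation_threshold:
        return "dissociated"
    if abs(m) <= 0.5 * rim_half_height:
        return "inside"
    return "wide_rim" if m > 0 else "narrow_rim"


# ---------------------------------------------------------------------------
# rim geometry


def rim_distances(system: AnnotatedSystem, trajectory: Trajectory) -> RimGeometryTrace:
    """Adjacent-unit O3(n)-O2(n+1) and O4(n)-O4(n+1) distances, cyclic."""
    n = system.n_units
    o2 = np.array([system.rim_oxygen("O2", k) for k in range(1, n + 1)])
    o3 = np.array([system.rim_oxygen("O3", k) for k in range(1, n + 1)])
    o4 = np.array([system.rim_oxygen("O4", k) for k in range(1, n + 1)])
    nxt = np.roll(np.arange(n), -1)  # unit n pairs with unit n+1 mod n
    c = trajectory.coords
    d32 = np.linalg.norm(c[:, o3, :] - c[:, o2[nxt], :], axis=2)
    d44 = np.linalg.norm(c[:, o4, :] - c[:, o4[nxt], :], axis=2)
    return RimGeometryTrace(d32=d32, d44=d44,
                            replicate_id=trajectory.replicate_id,
                            time_per_frame=trajectory.time_per_frame)


def hbond_fraction(trace: RimGeometryTrace, cutoff: float = HBOND_CUTOFF):
    """Fraction of frame x pair observations with dO3-2 <= cutoff.

    Returns (per_pair_fractions, overall_fraction).
    """
    hit = trace.d32 <= cutoff
    return hit.mean(axis=0), float(hit.mean())


# ---------------------------------------------------------------------------
# native contacts


def _heavy(system: AnnotatedSystem, idx: np.ndarray) -> np.ndarray:
    return idx[system.elements[idx] != "H"]


def _contact_pairs(frame, host_idx, guest_idx, cutoff):
    """(guest atom, host atom) index pairs within cutoff, via a KD tree."""
    tree = cKDTree(frame[host_idx])
    hits = tree.query_ball_point(frame[guest_idx], r=cutoff)
    return [(gi, host_idx[j]) for gi, row in zip(guest_idx, hits) for j in row]


def native_contacts(
    system: AnnotatedSystem,
    trajectories,
    *,
    cutoff: float = CONTACT_CUTOFF,
    window_ns: float = 20.0,
    mode: str = "total_over_units",
) -> ContactSummary:
    """Host-guest heavy-atom contact counts over the trailing window.

    ``mode`` controls the per-unit number: ``total_over_units`` divides the
    total contact count by the number of units (the default), while
    ``mean_of_units`` averages the per-unit counts of contacts touching
    each unit.  Mean +- SEM are taken across replicate means (n =
    replicates; a single trajectory reports SEM 0).
    """
    if isinstance(trajectories, Trajectory):
        trajectories = [trajectories]
    if mode not in ("total_over_units", "mean_of_units"):
        raise ValueError(f"unknown per-unit mode {mode!r}")
    n_units = system.n_units
    host_idx = _heavy(system, system.group("host"))
    guest_idx = _heavy(system, system.group("guest"))
    unit_of = np.full(system.n_atoms, -1)
    for k in range(1, n_units + 1):
        unit_of[system.group(f"unit_{k}")] = k - 1

    per_frame: dict = {}
    rep_totals = []
    rep_unit_means = []
    unit_accum = np.zeros(n_units)
    n_frames_total = 0
    for traj in trajectories:
        win = traj.last_window(window_ns)
        if len(win) == 0:
            raise ValueError("analysis window contains no frames")
        counts = np.empty(len(win), dtype=int)
        unit_counts = np.zeros((len(win), n_units), dtype=int)
        for i, t in enumerate(win):
            pairs = _contact_pairs(traj.coords[t], host_idx, guest_idx, cutoff)
            counts[i] = len(pairs)
            for _, hj in pairs:
                unit_counts[i, unit_of[hj]] += 1
        per_frame[traj.replicate_id] = counts
        rep_totals.append(counts.mean())
        rep_unit_means.append(unit_counts.mean(axis=0).mean())
        unit_accum += unit_counts.mean(axis=0)
        n_frames_total += len(win)
    rep_totals = np.array(rep_totals)
    rep_unit = (rep_totals / n_units if mode == "total_over_units"
                else np.array(rep_unit_means))
    n_rep = len(rep_totals)

    def sem(a):
        return float(a.std(ddof=1) / np.sqrt(len(a))) if len(a) > 1 else 0.0

    return ContactSummary(
        per_frame=per_frame,
        mean_total=float(rep_totals.mean()),
        sem_total=sem(rep_totals),
        mean_per_unit=float(rep_unit.mean()),
        sem_per_unit=sem(rep_unit),
        per_unit_counts=unit_accum / n_rep,
        cutoff=cutoff,
        n_units=n_units,
        mode=mode,
    )


# ---------------------------------------------------------------------------
# solvent-accessible surface area


def sphere_points(n: int) -> np.ndarray:
    """Deterministic, nearly uniform unit-sphere lattice (golden spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def shrake_rupley(
    coords: np.ndarray,
    radii: np.ndarray,
    *,
    probe_radius: float = 1.4,
    n_points: int = 960,
    subset=None,
) -> np.ndarray:
    """Per-atom solvent-accessible area (A^2) of ``subset`` atoms within the
    context of all atoms, by point counting on expanded spheres."""
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if np.any(~np.isfinite(radii)):
        bad = int(np.nonzero(~np.isfinite(radii))[0][0])
        raise ParameterError(f"atom {bad} has no radius")
    n_atoms = len(coords)
    subset = np.arange(n_atoms) if subset is None else np.asarray(subset)
    pts = sphere_points(n_points)
    expanded = radii + probe_radius
    tree = cKDTree(coords)
    max_r = expanded.max()
    areas = np.zeros(len(subset))
    for out_i, i in enumerate(subset):
        r_i = expanded[i]
        surf = coords[i] + r_i * pts  # (n_points, 3)
        neigh = [j for j in tree.query_ball_point(coords[i], r_i + max_r)
                 if j != i]
        if neigh:
            d2 = ((surf[:, None, :] - coords[neigh][None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (expanded[neigh] ** 2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[out_i] = 4.0 * np.pi * r_i * r_i * frac
    return areas


def guest_sasa(
    system: AnnotatedSystem,
    trajectory: Trajectory,
    *,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
    context: str = "complex",
) -> SasaTrace:
    """Per-frame SASA of the guest atoms.

    ``context="complex"`` lets host atoms occlude the guest surface (the
    solvent-exposure of the bound guest); ``context="guest"`` computes the
    isolated-guest area.
    """
    guest_idx = system.group("guest")
    if context == "complex":
        sel = np.arange(system.n_atoms)
    elif context == "guest":
        sel = guest_idx
    else:
        raise ValueError(f"unknown context {context!r}")
    radii = system.radii
    vals = np.empty(trajectory.n_frames)
    sub_pos = (np.searchsorted(sel, guest_idx) if context == "complex"
               else np.arange(len(guest_idx)))
    for t in range(trajectory.n_frames):
        areas = shrake_rupley(
            trajectory.coords[t][sel], radii[sel],
            probe_radius=probe_radius, n_points=n_sphere_points,
            subset=sub_pos,
        )
        vals[t] = areas.sum()
    return SasaTrace(values=vals, probe_radius=probe_radius,
                     n_sphere_points=n_sphere_points,
                     replicate_id=trajectory.replicate_id)
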