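"""Synthetic host-guest systems and synthetic experimental data.

Everything downstream of this module is testable without any external data:
it builds a toy cyclodextrin-like host (n pseudo-glucopyranose units on a
ring, each carrying the O2/O3 wide-rim, O4 glycosidic and O6 narrow-rim
oxygens), a rigid two-ring guest (an aromatic A ring fused to a quinone Q
ring, naphthoquinone-like), and generates

* inclusion trajectories in which the guest's position along the host axis
  follows a mean-reverting (Ornstein-Uhlenbeck) walk — stable near the wide
  rim, stable near the narrow rim, or escaping the cavity — while the host
  rim oxygens are re-placed each frame so the (dO3-2, dO4-4) ring-geometry
  pair is drawn exactly from a configured Gaussian mixture;
* A_L-type phase-solubility series, linear in host concentration with
  multiplicative Gaussian noise; and
* 4PL dose-response series with additive Gaussian noise.

Every generator records its ground truth and is bit-reproducible from its
seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .assay import DoseResponseSeries, four_pl
from .core import AnnotatedSystem, Trajectory
from .solubility import SolubilitySeries

__all__ = [
    "ToyHostSpec",
    "ScenarioSpec",
    "SolubilitySimSpec",
    "DoseResponseSimSpec",
    "RimMixtureComponent",
    "build_toy_complex",
    "simulate_inclusion_trajectory",
    "simulate_phase_solubility",
    "simulate_dose_response",
    "DEFAULT_RIM_MIXTURES",
    "DISSOCIATION_THRESHOLD",
]

#: |axis coordinate| beyond which the guest is considered dissociated (A).
#: The rim box itself spans +-3.95 A; 8 A is one cavity height past it.
DISSOCIATION_THRESHOLD = 8.0


@dataclass(frozen=True)
class ToyHostSpec:
    """Geometry of the toy macrocyclic host.

    ``rim_half_height`` is half the torus height: the wide (O2/O3) rim sits
    at +rim_half_height along the axis and the narrow (O6) rim at
    -rim_half_height, mirroring the ~7.9 A rim-to-rim span of a natural
    seven-unit cyclodextrin.
    """

    n_units: int = 7
    ring_radius: float = 4.2  # A, radial position of the unit backbone
    rim_half_height: float = 3.95  # A
    substitution_tag: str = "none"  # {"none", "dimethyl", "hydroxypropyl"}

    def __post_init__(self) -> None:
        if self.n_units < 3:
            raise ValueError("a macrocycle needs at least 3 units")
        if self.ring_radius <= 0 or self.rim_half_height <= 0:
            raise ValueError("ring_radius and rim_half_height must be positive")
        if self.substitution_tag not in ("none", "dimethyl", "hydroxypropyl"):
            raise ValueError(f"unknown substitution_tag {self.substitution_tag!r}")


@dataclass(frozen=True)
class RimMixtureComponent:
    """One Gaussian component of the (dO3-2, dO4-4) rim-geometry mixture."""

    weight: float
    mean_x: float  # dO3-2, A
    sd_x: float
    mean_y: float  # dO4-4, A
    sd_y: float


#: Scenario -> mixture over (dO3-2, dO4-4).  Bound hosts live mostly in the
#: compact H-bonded basin (M1-like, dO3-2 ~3.5 A); the dissociating/free
#: host also visits the glucopyranose-flip basins at dO3-2 ~5 A (M2-like at
#: dO4-4 ~4.85 A, M3-like at dO4-4 ~6 A).
DEFAULT_RIM_MIXTURES = {
    "stable_wide": (
        RimMixtureComponent(0.80, 3.5, 0.35, 4.5, 0.15),
        RimMixtureComponent(0.20, 5.0, 0.20, 4.85, 0.15),
    ),
    "stable_narrow": (
        RimMixtureComponent(0.85, 3.5, 0.35, 4.5, 0.15),
        RimMixtureComponent(0.15, 5.0, 0.20, 4.85, 0.15),
    ),
    "dissociating": (
        RimMixtureComponent(0.50, 3.5, 0.35, 4.5, 0.15),
        RimMixtureComponent(0.30, 5.0, 0.20, 4.85, 0.15),
        RimMixtureComponent(0.20, 5.0, 0.20, 6.0, 0.20),
    ),
}


@dataclass(frozen=True)
class ScenarioSpec:
    """One simulated binding scenario.

    ``ou_mean`` is the stationary mean of the guest's axis coordinate
    (positive = wide-rim side), ``ou_relaxation`` the OU relaxation time in
    frames, ``noise_sigma`` the stationary standard deviation in A.
    """

    scenario: str = "stable_wide"  # {stable_wide, stable_narrow, dissociating}
    n_frames: int = 1800
    timestep_label: float = 0.05  # ns per frame -> 90 ns by default
    ou_mean: float = 2.0  # A
    ou_relaxation: float = 50.0  # frames
    noise_sigma: float = 0.6  # A
    seed: int = 0
    rim_mixture: tuple = ()  # empty -> DEFAULT_RIM_MIXTURES[scenario]
    dissociation_target: float = 12.0  # A, ramp endpoint for "dissociating"

    def __post_init__(self) -> None:
        if self.scenario not in ("stable_wide", "stable_narrow", "dissociating"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.ou_relaxation <= 0:
            raise ValueError("ou_relaxation must be positive")

    @property
    def mixture(self) -> tuple:
        return self.rim_mixture or DEFAULT_RIM_MIXTURES[self.scenario]


@dataclass(frozen=True)
class SolubilitySimSpec:
    S0_true: float = 9e-6  # M, intrinsic guest solubility
    Kc_true: float = 562.0  # M^-1
    cd_concentrations: tuple = (0.0, 0.002, 0.004, 0.006, 0.008, 0.010)  # M
    noise_cv: float = 0.0  # coefficient of variation of each reading
    temperature: float = 303.15  # K
    seed: int = 0

    def __post_init__(self) -> None:
        if self.S0_true <= 0 or self.Kc_true < 0:
            raise ValueError("S0_true must be > 0 and Kc_true >= 0")
        if any(c < 0 for c in self.cd_concentrations):
            raise ValueError("host concentrations must be >= 0")


@dataclass(frozen=True)
class DoseResponseSimSpec:
    ic50_true: float = 10.0  # uM
    hill: float = 1.0
    top: float = 100.0  # % viability
    bottom: float = 0.0
    doses: tuple = (1.0, 3.0, 10.0, 30.0, 100.0)  # uM
    noise_sd: float = 0.0  # % viability
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ic50_true <= 0:
            raise ValueError("ic50_true must be positive")
        if self.bottom >= self.top:
            raise ValueError("bottom must be below top")


# ---------------------------------------------------------------------------
# structure builder

_HOST_NET_CHARGE = 0.0
_GUEST_NET_CHARGE = 0.0

# per-element parameters for the toy force field
_RADII = {"C": 1.70, "O": 1.52}
_LJ_EPS = {"C": 0.086, "O": 0.210}  # kcal/mol
_LJ_RMIN_HALF = {"C": 1.908, "O": 1.661}  # A

# raw (pre-normalization) partial charges by atom role; each unit sums to 0
_HOST_CHARGES = {"C1": 0.35, "C4": 0.35, "O2": -0.15, "O3": -0.15,
                 "O4": -0.25, "O6": -0.15}

#: azimuthal offset of O3 within its unit, as a fraction of the unit angle.
#: O2 sits at the unit angle, so the O3(n)-O2(n+1) gap is (1 - this) units.
_O3_FRACTION = 0.30
#: wide-rim oxygens sit this much further out than the glycosidic O4 ring
_RIM_RADIAL_EXTRA = 0.5


def _normalize_charges(q: np.ndarray, net: float) -> np.ndarray:
    return q + (net - q.sum()) / len(q)


def build_toy_complex(
    host: ToyHostSpec = ToyHostSpec(),
    *,
    host_net_charge: float = _HOST_NET_CHARGE,
    guest_net_charge: float = _GUEST_NET_CHARGE,
) -> tuple[AnnotatedSystem, np.ndarray]:
    """Build the annotated toy complex and its reference coordinates.

    Returns the system plus a single coordinate frame (n_atoms, 3) in which
    the host is centered on the origin with its axis along +z (wide rim on
    the +z side) and the guest sits at the cavity center.
    """
    n = host.n_units
    h = host.rim_half_height
    r_bb = host.ring_radius
    r4 = 4.5 / (2.0 * math.sin(math.pi / n))  # glycosidic ring: dO4-4 = 4.5 A
    r23 = r4 + _RIM_RADIAL_EXTRA

    names: list[str] = []
    elements: list[str] = []
    coords: list[tuple[float, float, float]] = []
    charges: list[float] = []
    groups: dict[str, list[int]] = {"host": [], "guest": [],
                                    "guest_ring_A": [], "guest_ring_Q": []}

    def add_atom(name, element, xyz, q):
        idx = len(names)
        names.append(name)
        elements.append(element)
        coords.append(tuple(xyz))
        charges.append(q)
        return idx

    two_pi = 2.0 * math.pi
    for k in range(n):  # units are 1-based in labels
        th = two_pi * k / n
        dth = two_pi / n
        unit: list[int] = []

        def ring_xyz(radius, angle, z):
            return (radius * math.cos(angle), radius * math.sin(angle), z)

        i_c1 = add_atom("C1", "C", ring_xyz(r_bb, th, 0.8), _HOST_CHARGES["C1"])
        i_c4 = add_atom("C4", "C", ring_xyz(r_bb, th, -0.8), _HOST_CHARGES["C4"])
        i_o2 = add_atom("O2", "O", ring_xyz(r23, th, h), _HOST_CHARGES["O2"])
        i_o3 = add_atom("O3", "O", ring_xyz(r23, th + _O3_FRACTION * dth, h),
                        _HOST_CHARGES["O3"])
        i_o4 = add_atom("O4", "O", ring_xyz(r4, th + 0.5 * dth, 0.0),
                        _HOST_CHARGES["O4"])
        i_o6 = add_atom("O6", "O", ring_xyz(r_bb - 0.5, th, -h),
                        _HOST_CHARGES["O6"])
        unit = [i_c1, i_c4, i_o2, i_o3, i_o4, i_o6]
        groups[f"unit_{k + 1}"] = unit
        groups[f"O2_{k + 1}"] = [i_o2]
        groups[f"O3_{k + 1}"] = [i_o3]
        groups[f"O4_{k + 1}"] = [i_o4]
        groups["host"].extend(unit)

    # guest: two fused hexagons (bond length 1.4 A) in the x-z plane,
    # long axis along z so each ring has its own axis coordinate.
    bond = 1.4
    half = bond * math.sqrt(3.0) / 2.0  # 1.212
    hex_angles = [-120, -60, 0, 60, 120, 180]

    def hexagon(center_z):
        return [(bond * math.cos(math.radians(a)), 0.0,
                 center_z + bond * math.sin(math.radians(a)))
                for a in hex_angles]

    ring_a = hexagon(-half)  # aromatic ring, deeper (narrow-rim) side
    ring_q = hexagon(+half)  # quinone ring, wide-rim side
    guest_idx: dict[tuple, int] = {}

    def key_of(xyz):
        return tuple(round(c, 6) for c in xyz)

    shared_keys = {key_of(p) for p in ring_a} & {key_of(p) for p in ring_q}

    def guest_atom(name, element, xyz, q):
        key = key_of(xyz)
        if key in guest_idx:  # fused-edge carbon already placed
            return guest_idx[key]
        idx = add_atom(name, element, xyz, q)
        guest_idx[key] = idx
        groups["guest"].append(idx)
        return idx

    # fused-edge carbons first, with names marking them as shared (CS*) so
    # ring membership survives a round-trip through atom names alone
    for j, key in enumerate(sorted(shared_keys)):
        guest_atom(f"CS{j + 1}", "C", key, 0.05)
    ia = iq = 0
    for xyz in ring_a:
        if key_of(xyz) not in shared_keys:
            ia += 1
            guest_atom(f"CA{ia}", "C", xyz, 0.05)
        groups["guest_ring_A"].append(guest_idx[key_of(xyz)])
    for xyz in ring_q:
        if key_of(xyz) not in shared_keys:
            iq += 1
            guest_atom(f"CQ{iq}", "C", xyz, 0.05)
        groups["guest_ring_Q"].append(guest_idx[key_of(xyz)])
    # quinone oxygens on the outward wide-rim edge of the Q ring
    for j, a in enumerate((60, 120)):
        xyz = ((bond + 1.25) * math.cos(math.radians(a)), 0.0,
               half + (bond + 1.25) * math.sin(math.radians(a)))
        guest_atom(f"OQ{j + 1}", "O", xyz, -0.25)

    names_a = np.array(names)
    elements_a = np.array(elements)
    q = np.array(charges)
    host_idx = np.array(groups["host"])
    gst_idx = np.array(groups["guest"])
    q[host_idx] = _normalize_charges(q[host_idx], host_net_charge)
    q[gst_idx] = _normalize_charges(q[gst_idx], guest_net_charge)

    system = AnnotatedSystem(
        names=names_a,
        elements=elements_a,
        radii=np.array([_RADII[e] for e in elements_a]),
        charges=q,
        lj_eps=np.array([_LJ_EPS[e] for e in elements_a]),
        lj_rmin_half=np.array([_LJ_RMIN_HALF[e] for e in elements_a]),
        groups={k: np.array(sorted(v), dtype=int) for k, v in groups.items()},
    )
    xyz = np.array(coords, dtype=float)
    # recenter so the host mass-weighted center sits exactly at the origin:
    # signed axis distances then read directly as guest offsets.
    masses = system.masses
    m_h = masses[host_idx]
    xyz -= (xyz[host_idx] * m_h[:, None]).sum(axis=0) / m_h.sum()
    # and the guest mass center at the origin too, so a rigid translation of
    # +d along the axis reads back as a signed distance of exactly +d
    m_g = masses[gst_idx]
    xyz[gst_idx] -= (xyz[gst_idx] * m_g[:, None]).sum(axis=0) / m_g.sum()
    system.validate()
    return system, xyz


# ---------------------------------------------------------------------------
# trajectory generator


def _sample_mixture(rng: np.random.Generator, mixture, size: int):
    """Per-frame (dO3-2, dO4-4) targets drawn from the Gaussian mixture."""
    w = np.array([c.weight for c in mixture], dtype=float)
    w /= w.sum()
    comp = rng.choice(len(mixture), size=size, p=w)
    x = np.empty(size)
    y = np.empty(size)
    for i, c in enumerate(mixture):
        sel = comp == i
        k = int(sel.sum())
        x[sel] = rng.normal(c.mean_x, c.sd_x, k)
        y[sel] = rng.normal(c.mean_y, c.sd_y, k)
    # keep distances physical
    return np.clip(x, 0.5, None), np.clip(y, 0.5, None)


def simulate_inclusion_trajectory(
    system: AnnotatedSystem,
    base_coords: np.ndarray,
    spec: ScenarioSpec,
    *,
    replicate_id: str = "MD1",
) -> Trajectory:
    """Generate one synthetic inclusion trajectory.

    The guest translates rigidly along the host axis following a discrete
    Ornstein-Uhlenbeck process with stationary mean ``ou_mean`` (for the
    dissociating scenario the mean ramps to ``dissociation_target`` over the
    first 60% of frames and holds there).  Host rim oxygens are re-placed
    every frame so that all n (dO3-2, dO4-4) pairs equal that frame's draw
    from the scenario's Gaussian mixture.
    """
    rng = np.random.default_rng(spec.seed)
    n_frames = spec.n_frames
    n_units = system.n_units

    # --- guest axis coordinate -------------------------------------------
    if spec.scenario == "dissociating":
        ramp_end = max(1, int(0.6 * n_frames))
        mu = np.concatenate([
            np.linspace(spec.ou_mean, spec.dissociation_target, ramp_end),
            np.full(n_frames - ramp_end, spec.dissociation_target),
        ])
    else:
        mu = np.full(n_frames, spec.ou_mean)
    phi = math.exp(-1.0 / spec.ou_relaxation)
    innov_sd = spec.noise_sigma * math.sqrt(1.0 - phi * phi)
    z = np.empty(n_frames)
    z[0] = mu[0] + spec.noise_sigma * rng.standard_normal()
    eps = rng.standard_normal(n_frames)
    for t in range(1, n_frames):
        z[t] = mu[t] + phi * (z[t - 1] - mu[t]) + innov_sd * eps[t]

    # --- rim geometry targets --------------------------------------------
    x32, y44 = _sample_mixture(rng, spec.mixture, n_frames)

    dth = 2.0 * math.pi / n_units
    sin_half = math.sin(math.pi / n_units)
    r4_t = y44 / (2.0 * sin_half)
    r23_t = r4_t + _RIM_RADIAL_EXTRA
    # dO3-2 targets are met in two regimes.  In-plane: the O3 azimuth swings
    # so the chord to O2(n+1) equals the target, dO3-2 = 2*r23*sin(gap/2)
    # with gap = (1 - frac)*dth, keeping frac >= _O3_FRACTION so O3 never
    # collides with its own unit's O2.  Beyond the azimuthal reach, O3
    # puckers out of the rim plane by dz (the glucopyranose-flip motif that
    # lengthens dO3-2 in real hosts); O6 shifts by -dz so the host mass
    # center stays fixed.
    chord_cap = 2.0 * r23_t * np.sin((1.0 - _O3_FRACTION) * dth / 2.0)
    chord = np.minimum(x32, chord_cap)
    gap = 2.0 * np.arcsin(np.clip(chord / (2.0 * r23_t), 0.0, 1.0))
    o3_frac_t = 1.0 - gap / dth
    o3_dz_t = np.sqrt(np.maximum(x32 * x32 - chord * chord, 0.0))

    guest = system.group("guest")
    unit_angles = np.arange(n_units) * dth
    # wide-rim height: recover from the base coordinates (already centered)
    o2_ids = np.array([system.rim_oxygen("O2", k + 1) for k in range(n_units)])
    o3_ids = np.array([system.rim_oxygen("O3", k + 1) for k in range(n_units)])
    o4_ids = np.array([system.rim_oxygen("O4", k + 1) for k in range(n_units)])
    o6_ids = np.array([
        int(np.intersect1d(system.group(f"unit_{k + 1}"),
                           np.nonzero(system.names == "O6")[0])[0])
        for k in range(n_units)
    ])
    z_rim = base_coords[o2_ids, 2].mean()
    z_gly = base_coords[o4_ids, 2].mean()
    z_o6 = base_coords[o6_ids, 2].mean()

    coords = np.repeat(base_coords[None, :, :], n_frames, axis=0)
    cos_u, sin_u = np.cos(unit_angles), np.sin(unit_angles)  # (n_units,)
    # O2 at the unit angle on the wide rim
    coords[:, o2_ids, 0] = r23_t[:, None] * cos_u
    coords[:, o2_ids, 1] = r23_t[:, None] * sin_u
    coords[:, o2_ids, 2] = z_rim
    # O3 offset by the per-frame azimuthal fraction, puckered by dz;
    # O6 counter-shifts so the host mass center never moves
    a3 = unit_angles[None, :] + o3_frac_t[:, None] * dth
    coords[:, o3_ids, 0] = r23_t[:, None] * np.cos(a3)
    coords[:, o3_ids, 1] = r23_t[:, None] * np.sin(a3)
    coords[:, o3_ids, 2] = z_rim + o3_dz_t[:, None]
    coords[:, o6_ids, 2] = z_o6 - o3_dz_t[:, None]
    # O4 glycosidic ring mid-angle, radius set by the dO4-4 target
    a4 = unit_angles[None, :] + 0.5 * dth
    coords[:, o4_ids, 0] = r4_t[:, None] * np.cos(a4)
    coords[:, o4_ids, 1] = r4_t[:, None] * np.sin(a4)
    coords[:, o4_ids, 2] = z_gly
    # rigid guest translation along the axis
    coords[:, guest, 2] += z[:, None]

    return Trajectory(coords=coords, time_per_frame=spec.timestep_label,
                      replicate_id=replicate_id)


def simulate_replicates(
    system: AnnotatedSystem,
    base_coords: np.ndarray,
    spec: ScenarioSpec,
    n_replicates: int = 3,
) -> list[Trajectory]:
    """Independent replicates; replicate r uses seed ``spec.seed + r``."""
    out = []
    for r in range(n_replicates):
        rspec = ScenarioSpec(**{**spec.__dict__, "seed": spec.seed + r})
        out.append(
            simulate_inclusion_trajectory(
                system, base_coords, rspec, replicate_id=f"MD{r + 1}"
            )
        )
    return out


# ---------------------------------------------------------------------------
# experimental-data generators


def al_slope(kc: float, s0: float) -> float:
    """Slope of an A_L isotherm for a 1:1 complex: Kc*S0 / (1 + Kc*S0)."""
    return kc * s0 / (1.0 + kc * s0)


def simulate_phase_solubility(spec: SolubilitySimSpec) -> SolubilitySeries:
    """A_L-type series: guest = S0 + slope*[CD] with multiplicative noise."""
    rng = np.random.default_rng(spec.seed)
    cd = np.array(spec.cd_concentrations, dtype=float)
    clean = spec.S0_true + al_slope(spec.Kc_true, spec.S0_true) * cd
    noisy = clean * (1.0 + spec.noise_cv * rng.standard_normal(len(cd)))
    return SolubilitySeries(cd_conc=cd, guest_conc=noisy,
                            temperature=spec.temperature)


def simulate_dose_response(spec: DoseResponseSimSpec) -> DoseResponseSeries:
    """4PL viability readings with additive Gaussian noise."""
    rng = np.random.default_rng(spec.seed)
    d = np.array(spec.doses, dtype=float)
    clean = four_pl(d, spec.ic50_true, spec.hill, spec.top, spec.bottom)
    noisy = clean + spec.noise_sd * rng.standard_normal(len(d))
    return DoseResponseSeries(dose=d, viability=noisy)
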