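"""Core containers shared by every analysis stage.

An :class:`AnnotatedSystem` couples per-atom force-field style parameters
(radius, partial charge, Lennard-Jones well depth and size) with a group map
that names the pieces every downstream observable needs: the host macrocycle
and its glucopyranose-like units, the rim oxygens O2/O3/O4 of each unit, the
guest and its two rings (aromatic A ring, quinone Q ring).

A :class:`Trajectory` is a plain stack of coordinate frames in Angstrom with
a time step in nanoseconds and a replicate label; nothing else is assumed
about where the frames came from.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AnnotatedSystem",
    "Trajectory",
    "AnnotationError",
    "ATOMIC_MASSES",
]

#: Monoisotopic-ish masses (amu) for the elements the toy builder emits.
ATOMIC_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
}


class AnnotationError(ValueError):
    """A required group label or per-atom parameter is missing."""


@dataclass
class AnnotatedSystem:
    """Atoms plus the named groups all analyses address.

    Attributes
    ----------
    names, elements : array of str, length n_atoms
    radii : intrinsic atomic radii, Angstrom
    charges : partial charges, elementary charge units
    lj_eps : Lennard-Jones well depth, kcal/mol
    lj_rmin_half : half the LJ minimum-energy distance, Angstrom
    groups : mapping of label -> sorted int array of 0-based atom indices.
        Required labels: ``host``, ``guest``, ``guest_ring_A``,
        ``guest_ring_Q``, ``unit_1`` .. ``unit_n`` and ``O2_k``/``O3_k``/
        ``O4_k`` for each unit ``k``.
    """

    names: np.ndarray
    elements: np.ndarray
    radii: np.ndarray
    charges: np.ndarray
    lj_eps: np.ndarray
    lj_rmin_half: np.ndarray
    groups: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    @property
    def masses(self) -> np.ndarray:
        return np.array([ATOMIC_MASSES.get(e, 12.011) for e in self.elements])

    @property
    def n_units(self) -> int:
        return sum(1 for g in self.groups if g.startswith("unit_"))

    def group(self, label: str) -> np.ndarray:
        try:
            return self.groups[label]
        except KeyError:
            raise AnnotationError(f"missing required group label {label!r}") from None

    def rim_oxygen(self, kind: str, unit: int) -> int:
        """Index of the single O2/O3/O4 atom of 1-based unit ``unit``."""
        label = f"{kind}_{unit}"
        idx = self.group(label)
        if len(idx) != 1:
            raise AnnotationError(
                f"group {label!r} must contain exactly one atom, has {len(idx)}"
            )
        return int(idx[0])

    def validate(self) -> None:
        """Check the group-map invariants; raise :class:`AnnotationError`."""
        n = self.n_atoms
        for label, idx in self.groups.items():
            if len(idx) and (idx.min() < 0 or idx.max() >= n):
                raise AnnotationError(f"group {label!r} references unknown atoms")
        for label in ("host", "guest", "guest_ring_A", "guest_ring_Q"):
            self.group(label)
        nu = self.n_units
        if nu == 0:
            raise AnnotationError("no unit_k groups present")
        host = set(self.group("host").tolist())
        covered: set[int] = set()
        for k in range(1, nu + 1):
            u = set(self.group(f"unit_{k}").tolist())
            if u & covered:
                raise AnnotationError(f"unit_{k} overlaps a previous unit")
            if not u <= host:
                raise AnnotationError(f"unit_{k} contains non-host atoms")
            covered |= u
            for kind in ("O2", "O3", "O4"):
                self.rim_oxygen(kind, k)
        if covered != host:
            raise AnnotationError("unit groups do not partition the host atoms")


@dataclass
class Trajectory:
    """Ordered coordinate frames (Angstrom) with time metadata."""

    coords: np.ndarray  # (n_frames, n_atoms, 3)
    time_per_frame: float  # ns per frame
    replicate_id: str = "MD1"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[-1] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("trajectory contains non-finite coordinates")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def times_ns(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.time_per_frame

    def last_window(self, duration_ns: float) -> np.ndarray:
        """Frame indices of the trailing ``duration_ns`` of the run."""
        t = self.times_ns
        t_end = t[-1] if self.n_frames else 0.0
        # small epsilon so an exact multiple of the timestep is inclusive
        return np.nonzero(t >= t_end - duration_ns - 1e-9)[0]
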