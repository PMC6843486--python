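"""Multi-model PDB trajectory I/O with annotation sidecars.

The coordinate carrier is a standard fixed-column multi-model PDB (one
MODEL/ENDMDL block per frame, chain A = host, chain B = guest, occupancy
1.00, B-factor 0.00), read and written through MDAnalysis.  PDB cannot
carry charges, radii or Lennard-Jones parameters losslessly, so these
travel in a sidecar CSV (``<path>.params.csv`` with columns
atom_id,name,element,radius,charge,eps,rmin_half; atom_id is 1-based) and
the group annotation in a JSON sidecar (``<path>.groups.json``).

When the JSON sidecar is absent, :func:`read_trajectory` can rebuild the
groups from the toy naming convention (host residues named GPU carrying
O2/O3/O4 oxygens, guest residue MGU with CA*/CQ* ring carbons and CS*
fused-edge carbons); anything unparseable is reported, never guessed.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .core import AnnotatedSystem, AnnotationError, Trajectory

__all__ = [
    "write_trajectory",
    "read_trajectory",
    "FormatError",
    "write_replicates",
]


class FormatError(ValueError):
    """The coordinate file violates the multi-model PDB contract."""


_DEFAULT_RADII = {"H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}

HOST_RESNAME = "GPU"  # pseudo-glucopyranose unit
GUEST_RESNAME = "MGU"


def _sidecar_paths(path: Path) -> tuple[Path, Path]:
    return (path.with_suffix(path.suffix + ".params.csv"),
            path.with_suffix(path.suffix + ".groups.json"))


def _build_universe(system: AnnotatedSystem, coords: np.ndarray):
    import MDAnalysis as mda
    from MDAnalysis.coordinates.memory import MemoryReader

    n_units = system.n_units
    host = set(system.group("host").tolist())
    resindex = np.zeros(system.n_atoms, dtype=int)
    for k in range(1, n_units + 1):
        resindex[system.group(f"unit_{k}")] = k - 1
    resindex[system.group("guest")] = n_units
    u = mda.Universe.empty(
        n_atoms=system.n_atoms,
        n_residues=n_units + 1,
        atom_resindex=resindex,
        residue_segindex=np.zeros(n_units + 1, dtype=int),
        trajectory=False,
    )
    u.add_TopologyAttr("names", list(system.names))
    u.add_TopologyAttr("elements", list(system.elements))
    u.add_TopologyAttr(
        "resnames", [HOST_RESNAME] * n_units + [GUEST_RESNAME])
    u.add_TopologyAttr("resids", list(range(1, n_units + 1)) + [1])
    chain = np.where([i in host for i in range(system.n_atoms)], "A", "B")
    u.add_TopologyAttr("chainIDs", list(chain))
    u.add_TopologyAttr("occupancies", np.ones(system.n_atoms))
    u.add_TopologyAttr("tempfactors", np.zeros(system.n_atoms))
    u.load_new(np.asarray(coords, dtype=np.float32), format=MemoryReader)
    return u


def write_trajectory(
    system: AnnotatedSystem,
    trajectory: Trajectory,
    path,
    *,
    sidecars: bool = True,
) -> Path:
    """Write a multi-model PDB plus parameter/group sidecars."""
    path = Path(path)
    if not np.all(np.isfinite(trajectory.coords)):
        raise ValueError("refusing to write non-finite coordinates")
    if trajectory.n_frames == 0:
        path.write_text(
            "REMARK   empty trajectory (zero frames)\nEND\n", encoding="ascii")
    else:
        import MDAnalysis as mda

        u = _build_universe(system, trajectory.coords)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            with mda.Writer(str(path), multiframe=True,
                            n_atoms=system.n_atoms) as w:
                for _ in u.trajectory:
                    w.write(u.atoms)
    if sidecars:
        params_path, groups_path = _sidecar_paths(path)
        pd.DataFrame(
            {
                "atom_id": np.arange(1, system.n_atoms + 1),
                "name": system.names,
                "element": system.elements,
                "radius": system.radii,
                "charge": system.charges,
                "eps": system.lj_eps,
                "rmin_half": system.lj_rmin_half,
            }
        ).to_csv(params_path, index=False)
        meta = {
            "time_per_frame_ns": trajectory.time_per_frame,
            "replicate_id": trajectory.replicate_id,
            "groups": {k: np.asarray(v).tolist()
                       for k, v in system.groups.items()},
        }
        groups_path.write_text(json.dumps(meta, indent=1), encoding="ascii")
    return path


def write_replicates(system, trajectories, stem) -> list[Path]:
    """One PDB per replicate, suffixed with the replicate id."""
    stem = Path(stem)
    out = []
    for traj in trajectories:
        p = stem.with_name(f"{stem.stem}_{traj.replicate_id}.pdb")
        out.append(write_trajectory(system, traj, p))
    return out


def _groups_from_names(names, resnames, resids, chains) -> dict:
    """Rebuild the group map from the toy naming convention."""
    groups: dict[str, list] = {"host": [], "guest": [],
                               "guest_ring_A": [], "guest_ring_Q": []}
    problems: list[str] = []
    unit_ids = sorted({int(r) for r, rn in zip(resids, resnames)
                       if rn == HOST_RESNAME})
    unit_rank = {u: k + 1 for k, u in enumerate(unit_ids)}
    for i, (name, rn, rid) in enumerate(zip(names, resnames, resids)):
        if rn == HOST_RESNAME:
            k = unit_rank[int(rid)]
            groups["host"].append(i)
            groups.setdefault(f"unit_{k}", []).append(i)
            if name in ("O2", "O3", "O4"):
                groups.setdefault(f"{name}_{k}", []).append(i)
        elif rn == GUEST_RESNAME:
            groups["guest"].append(i)
            if name.startswith(("CA", "CS")):
                groups["guest_ring_A"].append(i)
            if name.startswith(("CQ", "CS")):
                groups["guest_ring_Q"].append(i)
        else:
            problems.append(f"atom {i + 1} ({name}): unknown residue {rn!r}")
    for k in unit_rank.values():
        for kind in ("O2", "O3", "O4"):
            label = f"{kind}_{k}"
            if label not in groups:
                problems.append(f"missing {kind}_unit_{k} ({label})")
    if problems:
        raise AnnotationError(
            "annotation incomplete: " + "; ".join(problems))
    return {k: np.array(sorted(v), dtype=int) for k, v in groups.items()}


def read_trajectory(path, naming_convention: str = "toy"):
    """Read a multi-model PDB (plus sidecars) back into a system+trajectory.

    Group annotation comes from ``<path>.groups.json`` when present,
    otherwise it is rebuilt from ``naming_convention`` ("toy").  Atom order
    follows the file.  Missing parameter sidecars fall back to per-element
    radii with zero charges (geometry remains usable; energetics will not
    be meaningful).

    Returns
    -------
    (AnnotatedSystem, Trajectory)
    """
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path))
            coords = np.stack([u.atoms.positions.copy().astype(float)
                               for _ in u.trajectory])
    except FileNotFoundError:
        raise
    except Exception as exc:  # MDA raises assorted errors on bad MODELs
        raise FormatError(f"cannot parse {path}: {exc}") from exc

    names = [a.name for a in u.atoms]
    resnames = [a.resname for a in u.atoms]
    resids = [a.resid for a in u.atoms]
    chains = [getattr(a, "chainID", "") for a in u.atoms]
    try:
        elements = [str(e) for e in u.atoms.elements]
    except Exception:
        elements = [n[0] for n in names]

    params_path, groups_path = _sidecar_paths(path)
    n = len(names)
    if params_path.exists():
        df = pd.read_csv(params_path).sort_values("atom_id")
        if len(df) != n:
            raise FormatError(
                f"parameter sidecar has {len(df)} rows for {n} atoms")
        radii = df["radius"].to_numpy(float)
        charges = df["charge"].to_numpy(float)
        eps = df["eps"].to_numpy(float)
        rmin_half = df["rmin_half"].to_numpy(float)
    else:
        radii = np.array([_DEFAULT_RADII.get(e, 1.7) for e in elements])
        charges = np.zeros(n)
        eps = np.full(n, 0.1)
        rmin_half = radii.copy()

    time_per_frame = float("nan")
    replicate_id = path.stem
    if groups_path.exists():
        meta = json.loads(groups_path.read_text(encoding="ascii"))
        groups = {k: np.array(v, dtype=int) for k, v in meta["groups"].items()}
        time_per_frame = float(meta.get("time_per_frame_ns", float("nan")))
        replicate_id = meta.get("replicate_id", replicate_id)
    elif naming_convention == "toy":
        groups = _groups_from_names(names, resnames, resids, chains)
    else:
        raise ValueError(f"unknown naming convention {naming_convention!r}")

    system = AnnotatedSystem(
        names=np.array(names),
        elements=np.array(elements),
        radii=radii,
        charges=charges,
        lj_eps=eps,
        lj_rmin_half=rmin_half,
        groups=groups,
    )
    system.validate()
    return system, Trajectory(coords=coords, time_per_frame=time_per_frame,
                              replicate_id=replicate_id)
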