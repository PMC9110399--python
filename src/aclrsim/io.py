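"""Plain-text readers/writers for landmarks, ligament parameters, plans
and laxity curves.

Meshes go through trimesh (STL/PLY/OBJ); everything else is small
structured text: whitespace-delimited tables for curves and landmarks,
YAML for ligament parameter files and surgery plans.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import trimesh
import yaml

from .errors import InvalidParameterError
from .ligament_mechanics import LigamentBundle, SpringLaw, stiffness_from_EA
from .surgery_planning import LandmarkSet, SurgeryPlan, Tunnel, build_path

__all__ = [
    "load_mesh",
    "save_mesh",
    "read_landmarks",
    "write_landmarks",
    "read_laxity_curve",
    "write_laxity_curve",
    "read_ligament_params",
    "write_ligament_params",
    "read_plan",
    "write_plan",
    "write_manifest",
    "read_protocol",
]

_LANDMARK_ORDER = ("tibia_entry", "tibia_footprint", "femur_footprint", "femur_exit")


def load_mesh(path) -> trimesh.Trimesh:
    """Load a surface mesh (mm units) and drop degenerate faces."""
    mesh = trimesh.load(str(path), force="mesh")
    mesh.update_faces(mesh.nondegenerate_faces())
    mesh.remove_unreferenced_vertices()
    return mesh


def save_mesh(mesh: trimesh.Trimesh, path):
    mesh.export(str(path))


def write_landmarks(landmarks: LandmarkSet, path):
    """One ``label x y z`` line per landmark."""
    with open(path, "w") as fh:
        for name in _LANDMARK_ORDER:
            p = getattr(landmarks, name)
            fh.write(f"{name} {p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")


def read_landmarks(path) -> LandmarkSet:
    values = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 4:
            raise InvalidParameterError(f"bad landmark line: {line!r}")
        values[parts[0]] = np.array([float(x) for x in parts[1:]])
    missing = [n for n in _LANDMARK_ORDER if n not in values]
    if missing:
        raise InvalidParameterError(f"missing landmarks: {missing}")
    return LandmarkSet(**{n: values[n] for n in _LANDMARK_ORDER})


def write_laxity_curve(rows, path):
    """Rows of (flexion deg, anterior force N, displacement mm)."""
    np.savetxt(
        path,
        np.atleast_2d(np.asarray(rows, dtype=float)),
        header="flexion_deg\tforce_N\tdisplacement_mm",
        delimiter="\t",
    )


def read_laxity_curve(path) -> np.ndarray:
    rows = np.atleast_2d(np.loadtxt(path))
    if rows.shape[1] != 3:
        raise InvalidParameterError("laxity curve must have 3 columns")
    return rows


def write_ligament_params(bundles, path):
    """Serialize bundles as a YAML list (name, k or E/A, strains, points)."""
    out = []
    for b in bundles:
        out.append(
            {
                "name": b.name,
                "k": float(b.law.k),
                "eps_l": float(b.law.eps_l),
                "eps_r": float(b.law.eps_r),
                "origins": np.asarray(b.origins).tolist(),
                "insertions": np.asarray(b.insertions).tolist(),
            }
        )
    Path(path).write_text(yaml.safe_dump(out, sort_keys=False))


def read_ligament_params(path):
    data = yaml.safe_load(Path(path).read_text())
    bundles = []
    for rec in data:
        if "k" in rec:
            k = float(rec["k"])
        elif "E" in rec and "A" in rec:
            k = stiffness_from_EA(float(rec["E"]), float(rec["A"]))
        else:
            raise InvalidParameterError(
                f"ligament {rec.get('name')!r} needs either k or E and A"
            )
        bundles.append(
            LigamentBundle(
                name=rec["name"],
                origins=np.asarray(rec["origins"], dtype=float),
                insertions=np.asarray(rec["insertions"], dtype=float),
                law=SpringLaw(
                    k=k,
                    eps_l=float(rec.get("eps_l", 0.03)),
                    eps_r=float(rec.get("eps_r", 0.0)),
                ),
            )
        )
    return bundles


def write_plan(plan: SurgeryPlan, path):
    data = {
        "technique": plan.technique,
        "tunnels": [
            {
                "label": t.label,
                "radius": float(t.radius),
                "landmarks": {
                    n: getattr(t.path.landmarks, n).tolist() for n in _LANDMARK_ORDER
                },
                "control_points": t.path.control_points.tolist(),
            }
            for t in plan.tunnels
        ],
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def write_manifest(model, path):
    """Summarize a knee model as YAML: variant, bundles, grafts, constants."""
    data = {
        "variant": model.variant,
        "ligaments": [
            {
                "name": b.name,
                "n_springs": int(b.n_springs),
                "k": float(b.law.k),
                "eps_l": float(b.law.eps_l),
                "eps_r": float(b.law.eps_r),
            }
            for b in model.ligaments
        ],
        "grafts": [
            {
                "material": g.spec.material,
                "radius": float(g.spec.radius),
                "n_bundles": int(g.spec.n_bundles),
                "pretension": g.pretension,
                "fixation_angle": g.fixation_angle,
            }
            for g in model.grafts
        ],
        "constants": {
            k: v for k, v in model.constants.items() if not k.startswith("_")
        },
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def read_protocol(path):
    """Load a simulation protocol from a YAML config.

    Format: a mapping with ``name`` and ``steps``; each step has
    ``prescribed`` (DoF name -> value), optional ``force`` (3-vector, N)
    and ``ramp_substeps``.
    """
    from .laxity_sim import Protocol, ProtocolStep

    data = yaml.safe_load(Path(path).read_text())
    steps = [
        ProtocolStep(
            prescribed=dict(s.get("prescribed", {})),
            force=np.asarray(s.get("force", [0.0, 0.0, 0.0]), dtype=float),
            ramp_substeps=int(s.get("ramp_substeps", 10)),
            name=s.get("name", f"step-{i + 1}"),
        )
        for i, s in enumerate(data["steps"])
    ]
    return Protocol(steps=steps, name=data.get("name", "protocol"))


def read_plan(path) -> SurgeryPlan:
    data = yaml.safe_load(Path(path).read_text())
    tunnels = []
    for t in data["tunnels"]:
        ls = LandmarkSet(**{n: np.asarray(t["landmarks"][n]) for n in _LANDMARK_ORDER})
        tunnels.append(Tunnel(build_path(ls), float(t["radius"]), t.get("label", "AM")))
    return SurgeryPlan(data["technique"], tunnels)
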