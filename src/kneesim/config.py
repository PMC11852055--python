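"""YAML model/trial configuration: save generated fixtures, load for runs."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from kneesim.contact import Material, build_default_pairs
from kneesim.errors import ConfigurationError
from kneesim.fdk import Trial
from kneesim.fixtures import ActivityTrial, KneeGeometry
from kneesim.kinematics import JointDefinition
from kneesim.ligaments import LigamentBundle
from kneesim.mesh import read_stl, write_stl
from kneesim.model import KneeModel
from kneesim.recruitment import MuscleUnit

SURFACE_KEYS = (
    "femoral_cartilage",
    "medial_tibial_cartilage",
    "lateral_tibial_cartilage",
    "medial_meniscus",
    "lateral_meniscus",
    "patellar_cartilage",
)


def save_model(geometry: KneeGeometry, outdir: str | Path) -> Path:
    """Write STL surfaces plus a ``model.yaml`` binding all tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    compartments: dict[str, list[str]] = {}
    for key, mesh in {**geometry.surfaces, **geometry.bones}.items():
        write_stl(mesh, outdir / f"{key}.stl")
        compartments[key] = mesh.compartment.tolist()
    doc = {
        "subject": {
            "mass_kg": geometry.params.subject_mass_kg,
            "height_m": geometry.params.subject_height_m,
        },
        "surfaces": {k: f"{k}.stl" for k in SURFACE_KEYS},
        "bones": {k: f"{k}.stl" for k in geometry.bones},
        "compartments": {k: compartments[k] for k in SURFACE_KEYS},
        "joint": {
            "center": geometry.joint.center.tolist(),
            "patella_center": geometry.joint.patella_center.tolist(),
            "tendon_origin_patella": geometry.joint.tendon_origin_patella.tolist(),
            "tendon_insertion_tibia": geometry.joint.tendon_insertion_tibia.tolist(),
            "tendon_reference_length": geometry.joint.tendon_reference_length,
        },
        "ligaments": [
            {
                "name": b.name,
                "group": b.group,
                "k": b.k,
                "eps_r": b.eps_r,
                "eps_l": b.eps_l,
                "origin_body": b.origin_body,
                "origin_point": b.origin_point.tolist(),
                "insertion_body": b.insertion_body,
                "insertion_point": b.insertion_point.tolist(),
            }
            for b in geometry.ligament_bundles
        ],
        "muscles": [
            {
                "name": m.name,
                "vol0_cm3": m.vol0,
                "lf0_cm": m.lf0,
                "mu_n_per_cm2": m.mu,
                "v_i": m.v_i,
                "path": [[b, p.tolist()] for b, p in m.path],
            }
            for m in geometry.muscles
        ],
        "materials": {
            key: {"E_mpa": mat.E, "v": mat.v, "h_mm": mat.h}
            for key, mat in _materials_for().items()
        },
    }
    path = outdir / "model.yaml"
    path.write_text(yaml.safe_dump(doc, sort_keys=False))
    return path


def _materials_for() -> dict[str, Material]:
    from kneesim.contact import DEFAULT_MATERIALS

    return DEFAULT_MATERIALS


def load_model(model_yaml: str | Path, moment_lever_mm: float = 10.0) -> KneeModel:
    """Rebuild a :class:`KneeModel` from ``model.yaml`` and its STL files."""
    model_yaml = Path(model_yaml)
    doc = yaml.safe_load(model_yaml.read_text())
    base = model_yaml.parent
    surfaces = {}
    for key in SURFACE_KEYS:
        rel = doc.get("surfaces", {}).get(key)
        if rel is None:
            raise ConfigurationError(f"model.yaml lacks surface entry {key!r}")
        mesh = read_stl(base / rel)
        tags = doc.get("compartments", {}).get(key)
        if tags is not None and len(tags) == mesh.n_faces:
            mesh.compartment = np.asarray(tags, dtype="<U7")
        mesh.label = key
        surfaces[key] = mesh
    materials = {
        key: Material(E=m["E_mpa"], v=m["v"], h=m["h_mm"])
        for key, m in doc.get("materials", {}).items()
    } or None
    joint = JointDefinition(
        center=doc["joint"]["center"],
        patella_center=doc["joint"]["patella_center"],
        tendon_origin_patella=doc["joint"]["tendon_origin_patella"],
        tendon_insertion_tibia=doc["joint"]["tendon_insertion_tibia"],
        tendon_reference_length=doc["joint"]["tendon_reference_length"],
    )
    bundles = [
        LigamentBundle(
            name=b["name"],
            group=b["group"],
            k=b["k"],
            eps_r=b["eps_r"],
            eps_l=b.get("eps_l", 0.03),
            origin_body=b["origin_body"],
            origin_point=np.asarray(b["origin_point"], float),
            insertion_body=b["insertion_body"],
            insertion_point=np.asarray(b["insertion_point"], float),
        )
        for b in doc["ligaments"]
    ]
    muscles = [
        MuscleUnit(
            name=m["name"],
            vol0=m["vol0_cm3"],
            lf0=m["lf0_cm"],
            mu=m.get("mu_n_per_cm2", 27.0),
            v_i=m.get("v_i", 1.0),
            path=[(b, np.asarray(p, float)) for b, p in m["path"]],
        )
        for m in doc["muscles"]
    ]
    pairs = build_default_pairs(surfaces, materials)
    return KneeModel(
        joint=joint,
        pairs=pairs,
        pair_bodies=["tibia", "tibia", "tibia", "tibia", "patella"],
        pair_compartments=["medial", "lateral", "medial", "lateral", "none"],
        ligament_bundles=bundles,
        muscles=muscles,
        subject_mass_kg=doc["subject"]["mass_kg"],
        moment_lever_mm=moment_lever_mm,
        surfaces=surfaces,
    )


def save_trial(trial_fixture: ActivityTrial, outdir: str | Path) -> Path:
    """Write marker/GRF/flexion streams plus a ``trial.yaml`` manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    trial_fixture.write(outdir)
    act = trial_fixture.activity
    doc = {
        "activity": act,
        "seed": trial_fixture.seed,
        "subject_mass_kg": trial_fixture.params.subject_mass_kg,
        "marker_rate_hz": trial_fixture.params.marker_rate_hz,
        "grf_rate_hz": trial_fixture.params.grf_rate_hz,
        "ankle_height_mm": trial_fixture.params.ankle_height_mm,
        "shank_foot_mass_fraction": trial_fixture.params.shank_foot_mass_fraction,
        "markers_file": f"{act}_markers.txt",
        "grf_file": f"{act}_grf.txt",
        "flexion_file": f"{act}_flexion.txt",
        "drive": {
            "times_s": trial_fixture.trial.times.tolist(),
            "flexion_deg": trial_fixture.trial.flexion_deg.tolist(),
            "external_force_n": trial_fixture.trial.external_force.tolist(),
            "external_moment_nmm": trial_fixture.trial.external_moment.tolist(),
        },
    }
    path = outdir / f"{act}_trial.yaml"
    path.write_text(yaml.safe_dump(doc, sort_keys=False))
    return path


def load_trial(trial_yaml: str | Path) -> Trial:
    doc = yaml.safe_load(Path(trial_yaml).read_text())
    drive = doc["drive"]
    return Trial(
        activity=doc["activity"],
        times=np.asarray(drive["times_s"], float),
        flexion_deg=np.asarray(drive["flexion_deg"], float),
        external_force=np.asarray(drive["external_force_n"], float),
        external_moment=np.asarray(drive["external_moment_nmm"], float),
    )
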