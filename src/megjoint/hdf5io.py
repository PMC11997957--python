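"""HDF5 container for simulated experiments and source estimates.

One experiment = one HDF5 file: mesh, sensor array, stimulus layout,
ground truth, per-subject forward/noise/evoked data, and the generator
metadata (including every derived seed).  Estimates are stored in a
separate group so inversion results can be appended to the container.
"""

from __future__ import annotations

import json

import h5py
import numpy as np

from .forward import Leadfield, SensorArray
from .mesh import Mesh
from .simulate import (
    Experiment,
    ExperimentConfig,
    GroundTruth,
    StimulusLayout,
    SubjectModel,
    make_stimulus_layout,
)
from .sources import SourceEstimate

__all__ = ["save_experiment", "load_experiment", "save_estimates", "load_estimates"]


def _write_json_attr(group, key: str, obj) -> None:
    group.attrs[key] = json.dumps(obj)


def _read_json_attr(group, key: str):
    return json.loads(group.attrs[key])


def save_experiment(path: str, exp: Experiment) -> None:
    with h5py.File(path, "w") as f:
        exp.mesh.to_hdf5(f.create_group("mesh"))
        exp.sensors.to_hdf5(f.create_group("sensors"))
        lay = f.create_group("layout")
        _write_json_attr(
            lay, "params",
            {
                "rings": exp.layout.rings,
                "wedges": exp.layout.wedges,
                "radii_deg": [exp.layout.regions[0].inner_deg]
                + [r.outer_deg for r in exp.layout.regions[: exp.layout.rings * exp.layout.wedges : exp.layout.wedges]],
            },
        )
        tr = f.create_group("truth")
        keys = np.array([[ri, h] for (ri, h) in exp.truth.targets], dtype=np.int64)
        vals = np.array([exp.truth.targets[(ri, h)] for (ri, h) in exp.truth.targets],
                        dtype=np.int64)
        tr.create_dataset("target_keys", data=keys)
        tr.create_dataset("target_vertices", data=vals)
        _write_json_attr(tr, "anchors", {str(k): int(v) for k, v in exp.truth.anchors.items()})
        tr.attrs["amplitude"] = exp.truth.amplitude
        tr.attrs["peak_time_ms"] = exp.truth.peak_time_ms

        subs = f.create_group("subjects")
        for s in exp.subjects:
            g = subs.create_group(f"subject_{s.subject_id:03d}")
            g.attrs["subject_id"] = s.subject_id
            lf = g.create_group("leadfield")
            lf.create_dataset("matrix", data=s.leadfield.matrix)
            lf.create_dataset("source_positions", data=s.leadfield.source_positions)
            lf.create_dataset("source_orientations", data=s.leadfield.source_orientations)
            lf.create_dataset("sphere_center", data=s.leadfield.sphere_center)
            g.create_dataset("noise_cov", data=s.noise_cov)
            g.create_dataset("times", data=s.times)
            ev = g.create_group("evoked")
            for ridx, Y in s.evoked.items():
                ev.create_dataset(f"region_{ridx:03d}", data=Y)
            _write_json_attr(g, "info", s.info)
        _write_json_attr(f, "metadata", exp.metadata)


def load_experiment(path: str) -> Experiment:
    with h5py.File(path, "r") as f:
        mesh = Mesh.from_hdf5(f["mesh"])
        sensors = SensorArray.from_hdf5(f["sensors"])
        lp = _read_json_attr(f["layout"], "params")
        layout = make_stimulus_layout(
            rings=lp["rings"], wedges=lp["wedges"], radii_deg=tuple(lp["radii_deg"])
        )
        tr = f["truth"]
        keys = tr["target_keys"][()]
        vals = tr["target_vertices"][()]
        truth = GroundTruth(
            targets={(int(k[0]), int(k[1])): int(v) for k, v in zip(keys, vals)},
            anchors={int(k): int(v) for k, v in _read_json_attr(tr, "anchors").items()},
            amplitude=float(tr.attrs["amplitude"]),
            peak_time_ms=float(tr.attrs["peak_time_ms"]),
        )
        subjects = []
        for name in sorted(f["subjects"]):
            g = f["subjects"][name]
            lf = g["leadfield"]
            leadfield = Leadfield(
                matrix=lf["matrix"][()],
                sensors=sensors,
                sphere_center=lf["sphere_center"][()],
                source_positions=lf["source_positions"][()],
                source_orientations=lf["source_orientations"][()],
            )
            evoked = {
                int(k.split("_")[1]): g["evoked"][k][()] for k in g["evoked"]
            }
            subjects.append(
                SubjectModel(
                    subject_id=int(g.attrs["subject_id"]),
                    leadfield=leadfield,
                    noise_cov=g["noise_cov"][()],
                    evoked=evoked,
                    times=g["times"][()],
                    info=_read_json_attr(g, "info"),
                )
            )
        metadata = _read_json_attr(f, "metadata")
    config = ExperimentConfig(**{
        k: (tuple(v) if isinstance(v, list) else v)
        for k, v in metadata["config"].items()
    })
    return Experiment(mesh, sensors, layout, truth, subjects, config, metadata)


def save_estimates(
    path: str, estimates: dict[str, SourceEstimate], group_name: str = "estimates"
) -> None:
    with h5py.File(path, "a") as f:
        if group_name in f:
            del f[group_name]
        g = f.create_group(group_name)
        for key, est in estimates.items():
            est.to_hdf5(g.create_group(key))


def load_estimates(
    path: str, group_name: str = "estimates"
) -> dict[str, SourceEstimate]:
    with h5py.File(path, "r") as f:
        g = f[group_name]
        return {k: SourceEstimate.from_hdf5(g[k]) for k in g}
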