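"""Recording container I/O (HDF5 / NPZ) and JSON model serialization.

Layout of the recording container (HDF5 groups; the NPZ fallback flattens
the same keys with ``/`` separators):

    /stimulus/values           (T, C) float
    /stimulus/schedule         (n, 2) float start/end ms + labels
    /stimulus/repeat_windows   (m, 2) float
    /current/trials/0          continuous current trace (optional)
    /spikes/trials/0           continuous spike times, ms (optional)
    /meta                      version, provenance (JSON string), dt, mean

Round-trips are lossless: arrays bitwise, metadata exact. Model files are
JSON; bases are stored by their defining parameters (knots, sizes) and the
deterministic constructors rebuild identical matrices, so reloaded models
predict bit-identically.
"""

from __future__ import annotations

import json

import h5py
import numpy as np

from .basis import pyramid_basis_2d, temporal_basis, tent_basis
from .containers import Recording
from .kinetics import LNKParams
from .params import (
    AddSParams,
    DivSParams,
    LNParams,
    Nonlinearity1D,
    Surface2DParams,
    TemporalFilter,
)
from .spiking import DivSSubunit, HistoryFilter, LinearSubunit, SpikingParams
from .stimulus import Stimulus

__all__ = [
    "SchemaError",
    "write_recording",
    "read_recording",
    "save_model",
    "load_model",
    "model_to_dict",
    "model_from_dict",
]

SCHEMA_VERSION = "1"


class SchemaError(ValueError):
    """Recording or model file does not match the expected schema."""


# ---------------------------------------------------------------- recordings

def write_recording(rec: Recording, path: str) -> None:
    """Write a recording container (HDF5, or NPZ when path ends in .npz)."""
    if str(path).endswith(".npz"):
        _write_npz(rec, path)
        return
    with h5py.File(path, "w") as f:
        g = f.create_group("stimulus")
        g.create_dataset("values", data=rec.stimulus.values)
        g.attrs["dt"] = rec.stimulus.dt
        g.attrs["mean_level"] = rec.stimulus.mean_level
        sched = np.array([[s, e] for s, e, _ in rec.stimulus.schedule], dtype=float)
        labels = np.array([lab for _, _, lab in rec.stimulus.schedule], dtype="S4")
        g.create_dataset("schedule", data=sched.reshape(-1, 2))
        g.create_dataset("schedule_labels", data=labels)
        g.create_dataset(
            "repeat_windows",
            data=np.array(rec.stimulus.repeat_windows, dtype=float).reshape(-1, 2),
        )
        if rec.current is not None:
            f.create_group("current/trials").create_dataset("0", data=rec.current)
        if rec.spike_times is not None:
            f.create_group("spikes/trials").create_dataset("0", data=rec.spike_times)
        m = f.create_group("meta")
        m.attrs["version"] = SCHEMA_VERSION
        m.attrs["provenance"] = json.dumps(rec.provenance)


def read_recording(path: str) -> Recording:
    """Read a recording container; raises SchemaError on malformed files."""
    if str(path).endswith(".npz"):
        return _read_npz(path)
    with h5py.File(path, "r") as f:
        if "meta" not in f:
            raise SchemaError("missing /meta group")
        version = f["meta"].attrs.get("version")
        if version != SCHEMA_VERSION:
            raise SchemaError(
                f"unsupported schema version {version!r} (expected {SCHEMA_VERSION!r})"
            )
        if "stimulus" not in f:
            raise SchemaError("missing /stimulus group")
        g = f["stimulus"]
        sched_arr = g["schedule"][()]
        labels = [s.decode() for s in g["schedule_labels"][()]]
        schedule = [
            (float(s), float(e), lab) for (s, e), lab in zip(sched_arr, labels)
        ]
        windows = [tuple(map(float, w)) for w in g["repeat_windows"][()]]
        stim = Stimulus(
            values=g["values"][()],
            dt=float(g.attrs["dt"]),
            mean_level=float(g.attrs["mean_level"]),
            schedule=schedule,
            repeat_windows=windows,
        )
        current = f["current/trials/0"][()] if "current" in f else None
        spikes = f["spikes/trials/0"][()] if "spikes" in f else None
        provenance = json.loads(f["meta"].attrs.get("provenance", "{}"))
    return Recording(stimulus=stim, current=current, spike_times=spikes, provenance=provenance)


def _write_npz(rec: Recording, path: str) -> None:
    data = {
        "stimulus/values": rec.stimulus.values,
        "stimulus/dt": np.array(rec.stimulus.dt),
        "stimulus/mean_level": np.array(rec.stimulus.mean_level),
        "stimulus/schedule": np.array(
            [[s, e] for s, e, _ in rec.stimulus.schedule], dtype=float
        ).reshape(-1, 2),
        "stimulus/schedule_labels": np.array(
            [lab for _, _, lab in rec.stimulus.schedule], dtype="U4"
        ),
        "stimulus/repeat_windows": np.array(
            rec.stimulus.repeat_windows, dtype=float
        ).reshape(-1, 2),
        "meta/version": np.array(SCHEMA_VERSION),
        "meta/provenance": np.array(json.dumps(rec.provenance)),
    }
    if rec.current is not None:
        data["current/trials/0"] = rec.current
    if rec.spike_times is not None:
        data["spikes/trials/0"] = rec.spike_times
    np.savez(path, **data)


def _read_npz(path: str) -> Recording:
    with np.load(path, allow_pickle=False) as f:
        keys = set(f.files)
        if "meta/version" not in keys:
            raise SchemaError("missing meta/version")
        if str(f["meta/version"]) != SCHEMA_VERSION:
            raise SchemaError(f"unsupported schema version {f['meta/version']!r}")
        if "stimulus/values" not in keys:
            raise SchemaError("missing stimulus group")
        schedule = [
            (float(s), float(e), str(lab))
            for (s, e), lab in zip(f["stimulus/schedule"], f["stimulus/schedule_labels"])
        ]
        stim = Stimulus(
            values=f["stimulus/values"],
            dt=float(f["stimulus/dt"]),
            mean_level=float(f["stimulus/mean_level"]),
            schedule=schedule,
            repeat_windows=[tuple(map(float, w)) for w in f["stimulus/repeat_windows"]],
        )
        current = f["current/trials/0"] if "current/trials/0" in keys else None
        spikes = f["spikes/trials/0"] if "spikes/trials/0" in keys else None
        prov = json.loads(str(f["meta/provenance"]))
    return Recording(stimulus=stim, current=current, spike_times=spikes, provenance=prov)


# ------------------------------------------------------------------- models

def _filter_to_dict(filt: TemporalFilter) -> dict:
    b = filt.basis
    return {
        "basis": {"n_funcs": b.n_funcs, "t_max": b.t_max, "dt": b.dt},
        "coeffs": filt.coeffs.tolist(),
        "unit_norm": filt.unit_norm,
    }


def _filter_from_dict(d: dict) -> TemporalFilter:
    b = temporal_basis(**d["basis"])
    return TemporalFilter(b, np.array(d["coeffs"]), unit_norm=d["unit_norm"])


def _nl_to_dict(nl: Nonlinearity1D) -> dict:
    return {
        "knots": nl.basis.knots.tolist(),
        "weights": nl.weights.tolist(),
        "constraint": nl.constraint,
    }


def _nl_from_dict(d: dict) -> Nonlinearity1D:
    return Nonlinearity1D(tent_basis(np.array(d["knots"])), np.array(d["weights"]), d["constraint"])


def model_to_dict(params, fit_log=None) -> dict:
    """Serialize any parameter container to a JSON-compatible dict."""
    kind = getattr(params, "kind", None)
    d: dict = {"schema_version": SCHEMA_VERSION, "kind": kind}
    if fit_log is not None:
        d["fit_log"] = list(map(float, fit_log))
    if isinstance(params, LNParams):
        d.update(
            filter=_filter_to_dict(params.filter),
            nonlinearity=_nl_to_dict(params.nonlinearity),
            offset=params.offset,
        )
    elif isinstance(params, (DivSParams, AddSParams)):
        d.update(
            exc_filter=_filter_to_dict(params.exc_filter),
            exc_nl=_nl_to_dict(params.exc_nl),
            sup_filter=_filter_to_dict(params.sup_filter),
            sup_nl=_nl_to_dict(params.sup_nl),
            offset=params.offset,
        )
    elif isinstance(params, Surface2DParams):
        d.update(
            exc_filter=_filter_to_dict(params.exc_filter),
            sup_filter=_filter_to_dict(params.sup_filter),
            grid_x=params.surface_basis.grid_x.tolist(),
            grid_y=params.surface_basis.grid_y.tolist(),
            weights=params.weights.tolist(),
        )
    elif isinstance(params, LNKParams):
        d.update(
            filter=_filter_to_dict(params.filter),
            input_nl=_nl_to_dict(params.input_nl),
            k_ai=params.k_ai,
            k_ir=params.k_ir,
            gain=params.gain,
            offset=params.offset,
        )
    elif isinstance(params, SpikingParams):
        subs = []
        for su in params.subunits:
            if isinstance(su, LinearSubunit):
                subs.append({"kind": "linear", "filter": _filter_to_dict(su.filter)})
            else:
                subs.append(
                    {
                        "kind": "divs",
                        "exc_filter": _filter_to_dict(su.exc_filter),
                        "exc_nl": _nl_to_dict(su.exc_nl),
                        "sup_filter": _filter_to_dict(su.sup_filter),
                        "sup_nl": _nl_to_dict(su.sup_nl),
                    }
                )
        d.update(subunits=subs, theta=params.theta)
        if params.history is not None:
            d["history"] = {
                "basis": params.history.basis.tolist(),
                "coeffs": params.history.coeffs.tolist(),
            }
    else:
        raise ValueError(f"cannot serialize model of type {type(params).__name__}")
    return d


def model_from_dict(d: dict):
    """Rebuild a parameter container from :func:`model_to_dict` output."""
    if d.get("schema_version") != SCHEMA_VERSION:
        raise SchemaError(f"unsupported model schema version {d.get('schema_version')!r}")
    kind = d.get("kind")
    if kind == "ln":
        return LNParams(
            filter=_filter_from_dict(d["filter"]),
            nonlinearity=_nl_from_dict(d["nonlinearity"]),
            offset=d["offset"],
        )
    if kind in ("divs", "adds"):
        cls = DivSParams if kind == "divs" else AddSParams
        return cls(
            exc_filter=_filter_from_dict(d["exc_filter"]),
            exc_nl=_nl_from_dict(d["exc_nl"]),
            sup_filter=_filter_from_dict(d["sup_filter"]),
            sup_nl=_nl_from_dict(d["sup_nl"]),
            offset=d["offset"],
        )
    if kind == "2d":
        return Surface2DParams(
            exc_filter=_filter_from_dict(d["exc_filter"]),
            sup_filter=_filter_from_dict(d["sup_filter"]),
            surface_basis=pyramid_basis_2d(np.array(d["grid_x"]), np.array(d["grid_y"])),
            weights=np.array(d["weights"]),
        )
    if kind == "lnk":
        return LNKParams(
            filter=_filter_from_dict(d["filter"]),
            input_nl=_nl_from_dict(d["input_nl"]),
            k_ai=d["k_ai"],
            k_ir=d["k_ir"],
            gain=d["gain"],
            offset=d["offset"],
        )
    if kind == "spiking":
        subs = []
        for s in d["subunits"]:
            if s["kind"] == "linear":
                subs.append(LinearSubunit(_filter_from_dict(s["filter"])))
            else:
                subs.append(
                    DivSSubunit(
                        exc_filter=_filter_from_dict(s["exc_filter"]),
                        exc_nl=_nl_from_dict(s["exc_nl"]),
                        sup_filter=_filter_from_dict(s["sup_filter"]),
                        sup_nl=_nl_from_dict(s["sup_nl"]),
                    )
                )
        hist = None
        if "history" in d:
            hist = HistoryFilter(np.array(d["history"]["basis"]), np.array(d["history"]["coeffs"]))
        return SpikingParams(subunits=subs, theta=d["theta"], history=hist)
    raise SchemaError(f"unknown model kind {kind!r}")


def save_model(params, path: str, fit_log=None) -> None:
    with open(path, "w") as f:
        json.dump(model_to_dict(params, fit_log), f)


def load_model(path: str):
    with open(path) as f:
        return model_from_dict(json.load(f))
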