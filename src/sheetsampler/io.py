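"""Plain-text serialization of parameters, models and spike events.

Matrices are written as dense tab-delimited numeric text, row-major, with 17
significant digits (lossless for float64); metadata goes to a JSON sidecar.
Spike events are written as ``t_ms<TAB>population<TAB>unit_id`` with a header
line and 0-based unit ids.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .model import GenerativeModel, NetworkParameters
from .topology import Topology

__all__ = [
    "save_network_params",
    "load_network_params",
    "save_model",
    "load_model",
    "save_topology",
    "load_topology",
    "save_spike_events",
    "load_spike_events",
    "save_checkpoint",
    "load_checkpoint",
]

_FMT = "%.17g"


def _write(path: Path, arr: np.ndarray) -> None:
    np.savetxt(path, np.atleast_2d(arr), fmt=_FMT, delimiter="\t")


def _read(path: Path) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path, delimiter="\t"))


def save_network_params(directory, params: NetworkParameters) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    for name in ("V", "V0", "A", "A0", "b", "Wexc", "Winh"):
        _write(d / f"{name}.tsv", getattr(params, name))
    (d / "meta.json").write_text(json.dumps(
        {"kind": "network", "family": params.family,
         "K": params.K, "N": params.N}, indent=1))


def load_network_params(directory) -> NetworkParameters:
    d = Path(directory)
    meta = json.loads((d / "meta.json").read_text())
    arrs = {name: _read(d / f"{name}.tsv") for name in
            ("V", "V0", "A", "A0", "b", "Wexc", "Winh")}
    for name in ("V0", "A", "A0", "b"):
        arrs[name] = arrs[name].ravel()
    return NetworkParameters(family=meta["family"], **arrs)


def save_model(directory, model: GenerativeModel) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    _write(d / "params.tsv", model.params)
    _write(d / "pi0.tsv", model.defaults)
    _write(d / "Wexc.tsv", model.Wexc_hat)
    _write(d / "Winh.tsv", model.Winh_hat)
    _write(d / "bhat.tsv", model.bhat)
    (d / "meta.json").write_text(json.dumps(
        {"kind": "model", "family": model.family, "sigma2": model.sigma2,
         "K": model.K, "N": model.N}, indent=1))


def load_model(directory) -> GenerativeModel:
    d = Path(directory)
    meta = json.loads((d / "meta.json").read_text())
    return GenerativeModel(
        family=meta["family"],
        params=_read(d / "params.tsv"),
        defaults=_read(d / "pi0.tsv").ravel(),
        Wexc_hat=_read(d / "Wexc.tsv"),
        Winh_hat=_read(d / "Winh.tsv"),
        bhat=_read(d / "bhat.tsv").ravel(),
        sigma2=meta.get("sigma2", 1.0),
    )


def _mask_to_pairs(mask: np.ndarray) -> list[list[int]]:
    return [[int(a), int(b)] for a, b in np.argwhere(np.triu(mask, k=1))]


def _pairs_to_mask(pairs, K: int) -> np.ndarray:
    M = np.zeros((K, K), dtype=bool)
    for a, b in pairs:
        M[a, b] = M[b, a] = True
    return M


def save_topology(path, topology: Topology) -> None:
    """Serialize a topology: index sets as integer lists, masks as pair lists."""
    doc = {
        "kind": "topology",
        "input_shape": list(topology.input_shape),
        "neuron_shape": list(topology.neuron_shape),
        "torus": bool(topology.torus),
        "afferent_fields": topology.aff_idx.tolist(),
        "inhibition_pairs": _mask_to_pairs(topology.inh_mask),
        "excitatory_pairs": _mask_to_pairs(topology.exc_mask),
        "neuron_coords": topology.neuron_coords.tolist(),
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_topology(path) -> Topology:
    doc = json.loads(Path(path).read_text())
    aff = np.asarray(doc["afferent_fields"], dtype=np.int64)
    K = aff.shape[0]
    return Topology(
        input_shape=tuple(doc["input_shape"]),
        neuron_shape=tuple(doc["neuron_shape"]),
        aff_idx=aff,
        inh_mask=_pairs_to_mask(doc["inhibition_pairs"], K),
        exc_mask=_pairs_to_mask(doc["excitatory_pairs"], K),
        torus=doc["torus"],
        neuron_coords=np.asarray(doc["neuron_coords"], dtype=np.int64),
    )


def save_spike_events(path, events: np.ndarray, K: int,
                      dt: float = 0.001) -> None:
    """Write events (step, unit) as columnar text; units >= K are inputs."""
    with open(path, "w") as fh:
        fh.write("t_ms\tpopulation\tunit_id\n")
        for step, unit in np.asarray(events):
            if unit < K:
                fh.write(f"{step * dt * 1000:.3f}\tnetwork\t{int(unit)}\n")
            else:
                fh.write(f"{step * dt * 1000:.3f}\tinput\t{int(unit) - K}\n")


def load_spike_events(path, K: int, dt: float = 0.001) -> np.ndarray:
    out = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            t_ms, pop, unit = line.split("\t")
            step = int(round(float(t_ms) / (dt * 1000)))
            unit = int(unit)
            out.append((step, unit if pop == "network" else unit + K))
    return np.asarray(out, dtype=np.int64).reshape(-1, 2)


def save_checkpoint(directory, V, b, Wexc, b_sleep, step: int) -> None:
    """Learning checkpoint: (V, b, W^exc, sleep biases, step)."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    _write(d / "V.tsv", V)
    _write(d / "b.tsv", b)
    _write(d / "Wexc.tsv", Wexc)
    if b_sleep is not None:
        _write(d / "b_sleep.tsv", b_sleep)
    (d / "meta.json").write_text(json.dumps({"kind": "checkpoint",
                                             "step": int(step)}))


def load_checkpoint(directory) -> dict:
    d = Path(directory)
    meta = json.loads((d / "meta.json").read_text())
    out = {"step": meta["step"],
           "V": _read(d / "V.tsv"),
           "b": _read(d / "b.tsv").ravel(),
           "Wexc": _read(d / "Wexc.tsv")}
    if (d / "b_sleep.tsv").exists():
        out["b_sleep"] = _read(d / "b_sleep.tsv").ravel()
    return out
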