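"""Configuration parsing and structured run outputs.

Runs are written as a directory of plain text artifacts -- weight matrices
as delimited text, rasters and order-parameter series as TSV, the summary
and manifest as JSON.  Matrices are only 100x100 and inspecting their block
structure by eye is a primary debugging tool, so no binary container is
used.  The manifest records a SHA-256 digest per file; :func:`read_run`
verifies them and raises :class:`IntegrityError` on any mismatch.

Configuration files are YAML with a flat key set; missing keys fall back
to the model's default parameter table (N=100 with 80 excitatory / 20
inhibitory neurons, g=1, stimulus amplitude 3, eps_slow=1e-5,
eps_fast=0.1, dt=0.01, excitabilities of mean 1.5 and standard deviation
0.01, noise of standard deviation 0.1).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .core import SimulationConfig, SpikeRaster
from .observables import OrderParameterSeries
from .plasticity import PlasticityRule


class ConfigError(ValueError):
    """Malformed or out-of-range configuration input."""


class IntegrityError(RuntimeError):
    """A run directory does not match its manifest."""


#: default parameter table
CONFIG_DEFAULTS: dict = {
    "N": 100,
    "n_inhibitory": 20,
    "mode": "ei",
    "g": 1.0,
    "dt": 0.01,
    "noise_variance": 0.01,
    "eta_mean": 1.5,
    "eta_variance": 1e-4,
    "seed": None,
    "kernel": "asymmetric_exponential",
    "eps_slow": 1e-5,
    "eps_fast": 0.1,
    "gate_threshold": 0.1,
    "amplitude": 3.0,
    "block_len": 20.0,
    "n_blocks": 50,
    "rest_before": 200.0,
    "gap": 0.0,
    "strict_alternation": False,
    "consolidation_rho": 100.0,
    "consolidation_duration": 2000.0,
}

_SIM_KEYS = ("g", "dt", "noise_variance", "eta_mean", "eta_variance", "seed")
_RULE_KEYS = ("kernel", "eps_slow", "eps_fast", "gate_threshold")
_SCHEDULE_KEYS = (
    "N",
    "n_inhibitory",
    "mode",
    "amplitude",
    "block_len",
    "n_blocks",
    "rest_before",
    "gap",
    "strict_alternation",
    "consolidation_rho",
    "consolidation_duration",
)


def load_config(path=None) -> tuple[SimulationConfig, PlasticityRule, dict]:
    """Read a YAML config file; missing keys take the defaults above.

    Returns the integration config, the plasticity rule and a dict of the
    remaining (network/schedule/consolidation) parameters.  Unknown keys
    and out-of-range values raise :class:`ConfigError` naming the key.
    """
    merged = dict(CONFIG_DEFAULTS)
    if path is not None:
        try:
            text = Path(path).read_text()
            data = yaml.safe_load(text) or {}
        except (OSError, yaml.YAMLError) as exc:
            raise ConfigError(f"cannot read config file {path}: {exc}") from exc
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        for key in data:
            if key not in CONFIG_DEFAULTS:
                raise ConfigError(f"unknown configuration key {key!r}")
        merged.update(data)

    try:
        config = SimulationConfig(**{k: merged[k] for k in _SIM_KEYS})
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc
    try:
        rule = PlasticityRule(
            **{k: merged[k] for k in _RULE_KEYS}, dale_mode=merged["mode"]
        )
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc
    params = {k: merged[k] for k in _SCHEDULE_KEYS}
    if not 0 <= params["n_inhibitory"] <= params["N"]:
        raise ConfigError("n_inhibitory must lie in [0, N]")
    return config, rule, params


@dataclass
class RunRecord:
    """Everything needed to reproduce and audit a run."""

    config: dict
    boundaries: dict = field(default_factory=dict)
    summary: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)  # filename -> sha256
    matrices: dict = field(default_factory=dict)  # name -> ndarray
    raster: SpikeRaster | None = None
    series: OrderParameterSeries | None = None


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_matrix(path, matrix: np.ndarray, meta: dict | None = None) -> None:
    """Weight snapshot as delimited text (row = post-synaptic index).

    An optional JSON sidecar ``<path>.json`` carries the metadata record.
    """
    np.savetxt(path, np.asarray(matrix), fmt="%.17g", delimiter="\t")
    if meta is not None:
        Path(str(path) + ".json").write_text(json.dumps(meta, indent=1))


def read_matrix(path) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path, delimiter="\t"))


def write_raster(path, raster: SpikeRaster) -> None:
    """Spike raster as two-column TSV: time, neuron_index."""
    with open(path, "w") as fh:
        fh.write("time\tneuron\n")
        for t, i in zip(raster.times, raster.neurons):
            fh.write(f"{t:.6f}\t{i}\n")


def read_raster(path) -> SpikeRaster:
    with open(path) as fh:
        rows = fh.readlines()[1:]
    if not rows:
        return SpikeRaster()
    data = np.loadtxt(rows, delimiter="\t", ndmin=2)
    return SpikeRaster(data[:, 0], data[:, 1].astype(np.int64))


def write_series(path, series: OrderParameterSeries) -> None:
    """Order-parameter series as TSV: time, R_n, Psi_n per order."""
    cols = [series.times]
    names = ["time"]
    for k, n in enumerate(series.orders):
        cols += [series.R[:, k], series.Psi[:, k]]
        names += [f"R{n}", f"Psi{n}"]
    np.savetxt(
        path,
        np.column_stack(cols),
        fmt="%.8g",
        delimiter="\t",
        header="\t".join(names),
        comments="",
    )


def read_series(path) -> OrderParameterSeries:
    with open(path) as fh:
        names = fh.readline().strip().split("\t")
    data = np.loadtxt(path, delimiter="\t", skiprows=1, ndmin=2)
    orders = tuple(int(n[1:]) for n in names[1::2])
    return OrderParameterSeries(
        times=data[:, 0], R=data[:, 1::2], Psi=data[:, 2::2], orders=orders
    )


def write_run(run_dir, record: RunRecord) -> None:
    """Write a run directory with a manifest of SHA-256 digests."""
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    files = []

    (run_dir / "config.json").write_text(json.dumps(record.config, indent=1))
    files.append("config.json")
    (run_dir / "summary.json").write_text(
        json.dumps({"boundaries": record.boundaries, **record.summary}, indent=1)
    )
    files.append("summary.json")
    for name, mat in record.matrices.items():
        fname = f"weights_{name}.tsv"
        write_matrix(run_dir / fname, mat)
        files.append(fname)
    if record.raster is not None:
        write_raster(run_dir / "raster.tsv", record.raster)
        files.append("raster.tsv")
    if record.series is not None:
        write_series(run_dir / "series.tsv", record.series)
        files.append("series.tsv")

    record.manifest = {f: _sha256(run_dir / f) for f in files}
    (run_dir / "manifest.json").write_text(json.dumps(record.manifest, indent=1))


def read_run(run_dir) -> RunRecord:
    """Read a run directory back, verifying the manifest."""
    run_dir = Path(run_dir)
    manifest_path = run_dir / "manifest.json"
    if not manifest_path.exists():
        raise IntegrityError(f"missing manifest in {run_dir}")
    manifest = json.loads(manifest_path.read_text())
    for fname, digest in manifest.items():
        path = run_dir / fname
        if not path.exists():
            raise IntegrityError(f"manifest entry {fname!r} is missing")
        if _sha256(path) != digest:
            raise IntegrityError(f"file {fname!r} does not match its digest")

    config = json.loads((run_dir / "config.json").read_text())
    summary = json.loads((run_dir / "summary.json").read_text())
    boundaries = summary.pop("boundaries", {})
    record = RunRecord(
        config=config, boundaries=boundaries, summary=summary, manifest=manifest
    )
    for fname in manifest:
        if fname.startswith("weights_"):
            record.matrices[fname[len("weights_") : -4]] = read_matrix(
                run_dir / fname
            )
    if "raster.tsv" in manifest:
        record.raster = read_raster(run_dir / "raster.tsv")
    if "series.tsv" in manifest:
        record.series = read_series(run_dir / "series.tsv")
    return record
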