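"""Result serialization: kymographs, phase diagrams, run manifests.

Text outputs carry full double precision (17 significant digits) so that a
save -> load round trip is bit-exact and repeated runs diff cleanly.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .metrics import PhaseDiagram
from .solver import Grid1D, Kymograph

__all__ = [
    "write_kymograph",
    "read_kymograph",
    "write_kymograph_npz",
    "read_kymograph_npz",
    "write_series",
    "write_phase_diagram",
    "read_phase_diagram",
    "scenario_hash",
    "RunManifest",
]

_FMT = "%.17g"


def write_kymograph(kymo: Kymograph, path: str | Path) -> None:
    """Columnar text dump: time_s, x_um, then one concentration column per
    species (uM)."""
    n_sp, n_t, n_x = kymo.conc.shape
    times = np.repeat(kymo.times, n_x)
    x = np.tile(kymo.grid.cell_centers, n_t)
    cols = [times, x] + [kymo.conc[i].ravel() for i in range(n_sp)]
    header = "time_s\tx_um\t" + "\t".join(kymo.species)
    np.savetxt(
        path,
        np.column_stack(cols),
        fmt=_FMT,
        delimiter="\t",
        header=header,
        comments="",
    )


def read_kymograph(path: str | Path) -> Kymograph:
    """Reload a text kymograph written by :func:`write_kymograph`."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if header[:2] != ["time_s", "x_um"]:
        raise ValueError("not a kymograph file: bad header")
    species = tuple(header[2:])
    data = np.loadtxt(path, skiprows=1, delimiter="\t")
    times = np.unique(data[:, 0])
    x = np.unique(data[:, 1])
    n_t, n_x = len(times), len(x)
    if n_t * n_x != data.shape[0]:
        raise ValueError("kymograph file is not a complete time x space grid")
    dx = x[1] - x[0] if n_x > 1 else 1.0
    conc = np.empty((len(species), n_t, n_x))
    for i in range(len(species)):
        conc[i] = data[:, 2 + i].reshape(n_t, n_x)
    grid = Grid1D(L=dx * n_x, n_cells=n_x)
    return Kymograph(
        species=species,
        grid=grid,
        times=times,
        conc=conc,
        series_times=times,
        series=conc[species.index("JNK*"), :, -1] if "JNK*" in species else np.array([]),
        dt=float("nan"),
    )


def write_kymograph_npz(kymo: Kymograph, path: str | Path) -> None:
    """Optional binary container with the same named arrays."""
    np.savez_compressed(
        path,
        species=np.array(kymo.species),
        times=kymo.times,
        x=kymo.grid.cell_centers,
        conc=kymo.conc,
        series_times=kymo.series_times,
        series=kymo.series,
        dt=np.array(kymo.dt),
    )


def read_kymograph_npz(path: str | Path) -> Kymograph:
    with np.load(path, allow_pickle=False) as npz:
        x = npz["x"]
        dx = x[1] - x[0] if len(x) > 1 else 1.0
        return Kymograph(
            species=tuple(str(s) for s in npz["species"]),
            grid=Grid1D(L=dx * len(x), n_cells=len(x)),
            times=npz["times"],
            conc=npz["conc"],
            series_times=npz["series_times"],
            series=npz["series"],
            dt=float(npz["dt"]),
        )


def write_series(times: np.ndarray, series: np.ndarray, path: str | Path) -> None:
    np.savetxt(
        path,
        np.column_stack([times, series]),
        fmt=_FMT,
        delimiter="\t",
        header="time_s\tjnk_star_uM",
        comments="",
    )


def write_phase_diagram(diagram: PhaseDiagram, path: str | Path) -> None:
    """Long-format text table with baseline metadata in comment lines."""
    with open(path, "w") as fh:
        fh.write(f"# baseline_rate_per_s\t{diagram.baseline_rate:.17g}\n")
        fh.write(f"# baseline_peak_uM\t{diagram.baseline_peak:.17g}\n")
        fh.write(f"# theta\t{diagram.theta:.17g}\n")
        fh.write(f"# pe_threshold\t{diagram.pe_threshold:.17g}\n")
        fh.write("sigma\tpe\trate_per_s\tamplification\tregion\tt_max_s\tpeak_uM\n")
        for i, s in enumerate(diagram.sigma_axis):
            for j, p in enumerate(diagram.pe_axis):
                fh.write(
                    f"{s:.17g}\t{p:.17g}\t{diagram.rate[i, j]:.17g}\t"
                    f"{diagram.amplification[i, j]:.17g}\t{diagram.region[i, j]}\t"
                    f"{diagram.t_max[i, j]:.17g}\t{diagram.peak[i, j]:.17g}\n"
                )


def read_phase_diagram(path: str | Path) -> PhaseDiagram:
    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, val = line[1:].split()
            meta[key] = float(val)
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t", float_precision="round_trip")
    sigma_axis = np.unique(df["sigma"].to_numpy())
    pe_axis = np.unique(df["pe"].to_numpy())
    shape = (len(sigma_axis), len(pe_axis))
    if shape[0] * shape[1] != len(df):
        raise ValueError("phase-diagram file is not a complete grid")
    grids = {}
    si = {v: i for i, v in enumerate(sigma_axis)}
    pi = {v: i for i, v in enumerate(pe_axis)}
    for col in ("rate_per_s", "amplification", "t_max_s", "peak_uM"):
        g = np.full(shape, np.nan)
        for _, row in df.iterrows():
            g[si[row["sigma"]], pi[row["pe"]]] = row[col]
        grids[col] = g
    region = np.zeros(shape, dtype=int)
    for _, row in df.iterrows():
        region[si[row["sigma"]], pi[row["pe"]]] = int(row["region"])
    return PhaseDiagram(
        sigma_axis=sigma_axis,
        pe_axis=pe_axis,
        rate=grids["rate_per_s"],
        amplification=grids["amplification"],
        region=region,
        t_max=grids["t_max_s"],
        peak=grids["peak_uM"],
        baseline_rate=meta.get("baseline_rate_per_s", float("nan")),
        baseline_peak=meta.get("baseline_peak_uM", float("nan")),
        theta=meta.get("theta", 2.0),
        pe_threshold=meta.get("pe_threshold", 1.0),
    )


def scenario_hash(config_dict: dict) -> str:
    """Stable content hash of a scenario (invariant to key order)."""
    canon = json.dumps(config_dict, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


class RunManifest:
    """Provenance record written next to every command's outputs."""

    def __init__(self, scenario_dict: dict, command: str, parameters: dict):
        from . import __version__

        self._t0 = time.time()
        self.data = {
            "command": command,
            "code_version": __version__,
            "scenario_hash": scenario_hash(scenario_dict),
            "grid": scenario_dict.get("grid"),
            "transport": scenario_dict.get("transport"),
            "parameters": parameters,
            "outputs": [],
            "log": [],
        }

    def log(self, message: str) -> None:
        self.data["log"].append(message)

    def add_output(self, path: str | Path) -> None:
        self.data["outputs"].append(str(path))

    def write(self, path: str | Path) -> None:
        self.data["wall_clock_s"] = round(time.time() - self._t0, 3)
        self.data["finished_utc"] = time.strftime("%Y-%m-%dT%H:%M:%SZ", time.gmtime())
        with open(path, "w") as fh:
            json.dump(self.data, fh, indent=2)
            fh.write("\n")
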