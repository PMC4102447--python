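"""Plain-text file formats: COLVAR/HILLS dialects, PMF and FES grids, reports.

All files are whitespace-delimited text with ``#!``/``#`` header lines.
Floats are written with 17 significant digits so that write→read round-trips
reproduce the parsed values bit-for-bit.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .metad import FreeEnergySurface, Hill, HillsLog, WellTemperedSchedule
from .sampling import Trajectory
from .umbrella import Profile1D, UmbrellaWindow

__all__ = [
    "write_colvar", "read_colvar", "write_hills", "read_hills",
    "write_profile", "read_profile", "write_fes", "read_fes",
    "write_window", "read_window", "write_keyvalues", "read_keyvalues",
    "write_histogram",
]

_FMT = "%.17g"


def _fmt_row(values) -> str:
    return " ".join(_FMT % v for v in values)


# -- COLVAR ---------------------------------------------------------------

def write_colvar(path, traj: Trajectory, cv_names: Optional[list[str]] = None) -> None:
    """PLUMED-style COLVAR: `#! FIELDS time cv1 cv2 ...` then float rows."""
    if cv_names is None:
        cv_names = list(traj.cv_values.keys())
    cols = [traj.times] + [traj.cv_values[n] for n in cv_names]
    with open(path, "w") as fh:
        fh.write("#! FIELDS time " + " ".join(cv_names) + "\n")
        for row in zip(*cols):
            fh.write(_fmt_row(row) + "\n")


def read_colvar(path) -> tuple[list[str], np.ndarray]:
    """Returns (field names, data array of shape (n_rows, n_fields))."""
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#! FIELDS"):
            raise ValueError(f"{path}: missing '#! FIELDS' header")
        names = header.split()[2:]
        data = np.loadtxt(fh, ndmin=2)
    if data.shape[1] != len(names):
        raise ValueError(f"{path}: column count does not match FIELDS header")
    return names, data


# -- HILLS ----------------------------------------------------------------

def write_hills(path, log: HillsLog, temperature: float = 310.0) -> None:
    """PLUMED-dialect HILLS file with schedule and grid metadata lines.

    ``temperature`` only sets the per-row ``biasf`` column (γ = ΔT/T); the
    authoritative ΔT is stored in the header.
    """
    ncv = log.n_cvs
    names = list(log.cv_names)
    fields = (["time"] + names + [f"sigma_{n}" for n in names] + ["height", "biasf"])
    sched = log.schedule
    with open(path, "w") as fh:
        fh.write("#! FIELDS " + " ".join(fields) + "\n")
        fh.write(f"#! SET omega {_FMT % sched.omega}\n")
        fh.write(f"#! SET tau {_FMT % sched.tau}\n")
        fh.write(f"#! SET delta_T {_FMT % sched.delta_T}\n")
        for i, n in enumerate(names):
            lo, hi = log.cv_ranges[i]
            fh.write(
                f"#! SET range_{n} {_FMT % lo} {_FMT % hi} {log.bin_counts[i]}\n"
            )
        biasf = sched.delta_T / temperature
        for h in log.hills:
            row = [h.time, *h.center, *h.widths, h.height]
            fh.write(_fmt_row(row) + " " + _FMT % (biasf) + "\n")


def read_hills(path) -> HillsLog:
    meta = {}
    ranges = {}
    rows = []
    names: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#! FIELDS"):
                toks = line.split()[2:]
                ncv = (len(toks) - 3) // 2
                names = toks[1: 1 + ncv]
            elif line.startswith("#! SET range_"):
                toks = line.split()
                ranges[toks[2].removeprefix("range_")] = (
                    float(toks[3]), float(toks[4]), int(toks[5])
                )
            elif line.startswith("#! SET"):
                toks = line.split()
                meta[toks[2]] = float(toks[3])
            else:
                rows.append([float(t) for t in line.split()])
    if not names:
        raise ValueError(f"{path}: missing FIELDS header")
    ncv = len(names)
    sigmas = tuple(rows[0][1 + ncv: 1 + 2 * ncv]) if rows else (1.0,) * ncv
    schedule = WellTemperedSchedule(
        omega=meta.get("omega", 1.0), tau=meta.get("tau", 1.0),
        delta_T=meta.get("delta_T", 3100.0), sigmas=sigmas,
    )
    log = HillsLog(
        schedule=schedule,
        cv_names=tuple(names),
        cv_ranges=tuple((ranges[n][0], ranges[n][1]) for n in names),
        bin_counts=tuple(ranges[n][2] for n in names),
    )
    for r in rows:
        log.append(Hill(
            time=r[0],
            center=tuple(r[1: 1 + ncv]),
            widths=tuple(r[1 + ncv: 1 + 2 * ncv]),
            height=r[1 + 2 * ncv],
        ))
    return log


# -- 1-D profiles ----------------------------------------------------------

def write_profile(path, profile: Profile1D, rc_name: str = "rc") -> None:
    cols = [profile.rc, profile.free_energy]
    names = [rc_name, "free_energy"]
    if profile.uncertainty is not None:
        cols.append(profile.uncertainty)
        names.append("stderr")
    with open(path, "w") as fh:
        fh.write("#! FIELDS " + " ".join(names) + "\n")
        for row in zip(*cols):
            fh.write(_fmt_row(row) + "\n")


def read_profile(path) -> Profile1D:
    names, data = read_colvar(path)
    unc = data[:, 2] if data.shape[1] > 2 else None
    return Profile1D(rc=data[:, 0], free_energy=data[:, 1], uncertainty=unc)


# -- 2-D FES grids ---------------------------------------------------------

def write_fes(path, fes: FreeEnergySurface) -> None:
    """Plain text (cv1 [cv2] free_energy visited) with grid metadata header."""
    names = list(fes.cv_names) or [f"cv{i+1}" for i in range(len(fes.axes))]
    with open(path, "w") as fh:
        fh.write("#! FIELDS " + " ".join(names) + " free_energy visited\n")
        for i, ax in enumerate(fes.axes):
            fh.write(
                f"#! SET axis_{names[i]} {_FMT % ax[0]} {_FMT % ax[-1]} {ax.size}\n"
            )
        if len(fes.axes) == 1:
            for x, f, v in zip(fes.axes[0], fes.free_energy, fes.visited):
                fh.write(_fmt_row([x, f]) + f" {int(v)}\n")
        else:
            for i, x in enumerate(fes.axes[0]):
                for j, y in enumerate(fes.axes[1]):
                    fh.write(_fmt_row([x, y, fes.free_energy[i, j]])
                             + f" {int(fes.visited[i, j])}\n")
    return None


def read_fes(path) -> FreeEnergySurface:
    axes_meta = []
    names = []
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#! FIELDS"):
                toks = line.split()[2:]
                names = toks[:-2]
            elif line.startswith("#! SET axis_"):
                toks = line.split()
                axes_meta.append((float(toks[3]), float(toks[4]), int(toks[5])))
            else:
                rows.append([float(t) for t in line.split()])
    axes = [np.linspace(lo, hi, n) for lo, hi, n in axes_meta]
    data = np.asarray(rows)
    shape = tuple(a.size for a in axes)
    fe = data[:, len(axes)].reshape(shape)
    visited = data[:, len(axes) + 1].reshape(shape).astype(bool)
    return FreeEnergySurface(axes=axes, free_energy=fe, visited=visited,
                             cv_names=tuple(names))


# -- umbrella windows ------------------------------------------------------

def write_window(path, window: UmbrellaWindow) -> None:
    with open(path, "w") as fh:
        fh.write(f"#! FIELDS {window.cv}\n")
        fh.write(f"#! SET center {_FMT % window.center}\n")
        fh.write(f"#! SET k {_FMT % window.k}\n")
        fh.write(f"#! SET sim_length {_FMT % window.sim_length}\n")
        for v in window.samples:
            fh.write((_FMT % v) + "\n")


def read_window(path) -> UmbrellaWindow:
    meta = {}
    vals = []
    cv = "cv"
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("#! FIELDS"):
                cv = line.split()[2]
            elif line.startswith("#! SET"):
                toks = line.split()
                meta[toks[2]] = float(toks[3])
            elif line:
                vals.append(float(line))
    return UmbrellaWindow(cv=cv, center=meta["center"], k=meta["k"],
                          samples=np.asarray(vals), sim_length=meta.get("sim_length", 0.0))


# -- key-value report files -------------------------------------------------

def write_keyvalues(path, mapping: dict) -> None:
    """Line-oriented `key = value` file; floats at full precision."""
    with open(path, "w") as fh:
        for k, v in mapping.items():
            if isinstance(v, float):
                fh.write(f"{k} = {_FMT % v}\n")
            else:
                fh.write(f"{k} = {v}\n")


def read_keyvalues(path) -> dict:
    out: dict = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            k, _, v = line.partition("=")
            v = v.strip()
            try:
                out[k.strip()] = int(v) if v.lstrip("+-").isdigit() else float(v)
            except ValueError:
                out[k.strip()] = v
    return out


def write_histogram(path, hist) -> None:
    """Two-column text: bin_center, density (or counts when unnormalised)."""
    y = hist.normalized_density if hist.normalized_density is not None else hist.counts
    with open(path, "w") as fh:
        fh.write("#! FIELDS bin_center density\n")
        for c, v in zip(hist.bin_centers, y):
            fh.write(_fmt_row([c, v]) + "\n")
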