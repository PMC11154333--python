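"""Channel-table file format and run reports.

Channel files are plain CSV: comma separator, ``.`` decimal, UTF-8,
mandatory header.  Every column name carries a unit suffix
(``time_s``, ``angle_C0_rad``, ``oc_fx_N``, ...), the first column is
always ``time_s`` and must be strictly increasing, and missing values
are rejected.  A provenance block of ``#``-prefixed key-value comment
lines (command, config hash, seed, versions) precedes the header and
survives a write/read round-trip.  Numbers are written with 17
significant digits so float64 values round-trip exactly.

Angles are stored in radians in files; degree output is a
display-level concern of the command-line interface.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

__all__ = [
    "ChannelTable", "ChannelFileError", "MalformedHeaderError",
    "NonMonotoneTimeError", "MissingValueError",
    "read_channels", "write_channels", "result_to_table",
    "table_to_motion", "run_report",
]

# longest-suffix-first so e.g. "m_per_s2" wins over "s2"/"m"
KNOWN_UNITS = (
    "m_per_s2", "rad_per_s2", "m_per_s", "rad_per_s", "Nm", "N",
    "rad", "deg", "mm", "m", "g", "s", "J", "W", "1",
)


class ChannelFileError(ValueError):
    """Base class for channel-file format errors."""


class MalformedHeaderError(ChannelFileError):
    """Missing/duplicate columns or unparseable unit suffixes."""


class NonMonotoneTimeError(ChannelFileError):
    """The time column is not strictly increasing."""


class MissingValueError(ChannelFileError):
    """NaN or empty cells in the numeric block."""


def unit_of(column: str) -> str:
    """Unit suffix of a column name; raises if none is recognized."""
    for u in KNOWN_UNITS:
        if column.endswith("_" + u):
            return u
    raise MalformedHeaderError(f"column {column!r} has no recognized "
                               "unit suffix")


@dataclass
class ChannelTable:
    """Uniformly sampled, unit-annotated channel matrix with provenance."""

    columns: tuple                 # names incl. leading "time_s"
    data: np.ndarray               # (m, n) float64
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] != len(self.columns):
            raise MalformedHeaderError("column count does not match data")
        if len(set(self.columns)) != len(self.columns):
            raise MalformedHeaderError("duplicate column names")
        if not self.columns or self.columns[0] != "time_s":
            raise MalformedHeaderError("missing time column: first column "
                                       "must be 'time_s'")
        for c in self.columns:
            unit_of(c)
        if np.any(~np.isfinite(self.data)):
            raise MissingValueError("table contains NaN/inf values")
        t = self.data[:, 0]
        if len(t) > 1 and np.any(np.diff(t) <= 0):
            raise NonMonotoneTimeError("time column is not strictly "
                                       "increasing")

    @property
    def time(self) -> np.ndarray:
        return self.data[:, 0]

    def __getitem__(self, column: str) -> np.ndarray:
        try:
            j = self.columns.index(column)
        except ValueError:
            raise KeyError(column) from None
        return self.data[:, j]

    def __contains__(self, column: str) -> bool:
        return column in self.columns


def write_channels(table: ChannelTable, path) -> None:
    """Write a channel table as commented CSV (17 significant digits)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for key, value in table.metadata.items():
            fh.write(f"# {key}: {value}\n")
        fh.write(",".join(table.columns) + "\n")
        np.savetxt(fh, table.data, fmt="%.17g", delimiter=",")


def read_channels(path) -> ChannelTable:
    """Read a commented-CSV channel table; validates all invariants."""
    path = Path(path)
    metadata = {}
    header = None
    body = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                text = line.lstrip("#").strip()
                if ":" in text:
                    key, _, value = text.partition(":")
                    metadata[key.strip()] = value.strip()
                continue
            if header is None:
                header = tuple(c.strip() for c in line.split(","))
                if any(not c for c in header):
                    raise MalformedHeaderError("empty column name in header")
                continue
            body.append(line)
    if header is None:
        raise MalformedHeaderError("file has no header line")
    if not body:
        raise MissingValueError("file has no data rows")
    try:
        data = np.loadtxt(_io.StringIO("\n".join(body)), delimiter=",",
                          ndmin=2)
    except ValueError as exc:
        raise MissingValueError(f"unparseable numeric block: {exc}") from exc
    return ChannelTable(columns=header, data=data, metadata=metadata)


def result_to_table(result, metadata: Optional[dict] = None) -> ChannelTable:
    """Standard channel set of a simulation result.

    Columns: time, per-body absolute angles (rad), head CG resultant
    acceleration (g), occipital-condyle loads, OC displacement relative
    to the base when the slider element is present, and the energy
    ledger terms.
    """
    cols = ["time_s"]
    data = [result.time]
    for name in result.body_names:
        if name == "Ca":
            continue
        cols.append(f"angle_{name.replace('/', '')}_rad")
        data.append(result.angle_channel(name))
    cols += ["head_acc_resultant_g", "oc_fx_N", "oc_fz_N", "oc_my_Nm"]
    data += [result.head_acc_resultant_g, result.oc_fx, result.oc_fz,
             result.oc_my]
    if result.model.prismatic is not None:
        oc = result.oc_displacement_rel_t1()
        cols += ["oc_dx_m", "oc_dz_m"]
        data += [oc[:, 0], oc[:, 1]]
    cols += ["kinetic_J", "potential_J", "dissipated_J", "work_input_J"]
    data += [result.kinetic, result.potential, result.dissipated,
             result.work_input]
    meta = {"model": result.model.name,
            "config_hash": result.model.config_hash()}
    if metadata:
        meta.update(metadata)
    return ChannelTable(columns=tuple(cols),
                        data=np.column_stack(data), metadata=meta)


def table_to_motion(table: ChannelTable):
    """Build a :class:`whipneck.dynamics.PrescribedMotion` from a table
    with columns ``time_s, x_m, z_m`` and optional ``rot_rad``."""
    from .dynamics import PrescribedMotion
    for c in ("x_m", "z_m"):
        if c not in table:
            raise MalformedHeaderError(f"motion table needs column {c!r}")
    rot = table["rot_rad"] if "rot_rad" in table else None
    return PrescribedMotion(time=table.time.copy(), x=table["x_m"].copy(),
                            z=table["z_m"].copy(), rotation=rot)


def motion_to_table(motion, metadata: Optional[dict] = None) -> ChannelTable:
    cols = ["time_s", "x_m", "z_m"]
    data = [motion.time, motion.x, motion.z]
    if motion.rotation is not None:
        cols.append("rot_rad")
        data.append(motion.rotation)
    return ChannelTable(tuple(cols), np.column_stack(data),
                        dict(metadata or {}))


def run_report(result, criteria, out_path, timestamp: str = "") -> Path:
    """Key-value run summary plus the full channel table.

    Writes the summary to ``out_path`` and the channel CSV next to it
    (same stem, ``.channels.csv``).  Re-running with identical inputs
    reproduces the files byte-for-byte apart from the ``timestamp``
    line.
    """
    out_path = Path(out_path)
    channels = result_to_table(result)
    channels_path = out_path.with_suffix(".channels.csv")
    write_channels(channels, channels_path)

    i_fx = int(np.argmax(np.abs(result.oc_fx)))
    i_fz = int(np.argmax(np.abs(result.oc_fz)))
    i_my = int(np.argmax(np.abs(result.oc_my)))
    lines = [
        f"timestamp: {timestamp}",
        f"model: {result.model.name}",
        f"config_hash: {result.model.config_hash()}",
        f"t_end_s: {result.time[-1]:.17g}",
        f"hic36: {criteria.hic36:.17g}",
        f"hic_window_s: {criteria.hic_window[0]:.17g} "
        f"{criteria.hic_window[1]:.17g}",
        f"n_ep: {criteria.n_ep:.17g}",
        f"n_fp: {criteria.n_fp:.17g}",
        f"n_ea: {criteria.n_ea:.17g}",
        f"n_fa: {criteria.n_fa:.17g}",
        f"peak_head_acc_g: {float(np.max(result.head_acc_resultant_g)):.17g}",
        f"peak_oc_fx_N: {result.oc_fx[i_fx]:.17g}",
        f"peak_oc_fz_N: {result.oc_fz[i_fz]:.17g}",
        f"peak_oc_my_Nm: {result.oc_my[i_my]:.17g}",
        f"energy_residual_rel: {result.energy_residual_rel():.17g}",
        f"channels: {channels_path.name}",
    ]
    out_path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return out_path
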