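"""Shared in-memory containers and text/TIFF I/O.

Conventions used throughout the package:

* images are ``float64`` arrays in ``(time, channel, row, col)`` order
  (an optional leading z axis appears only on input to :func:`~smaddyn.quantify.max_project`);
* pixel coordinates are 0-based ``(row, col)``; physical coordinates ``(x, y)`` are in µm
  with ``x`` along columns and ``y`` along rows;
* all tabular data are :class:`pandas.DataFrame` objects written as CSV/TSV.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "ImageStack",
    "Colony",
    "RadialProfile",
    "Trajectory",
    "CountMatrix",
]


@dataclass
class ImageStack:
    """Multi-channel, multi-frame pixel data with physical pixel size.

    ``data`` has shape ``(n_frames, n_channels, height, width)``. ``channel_names``
    identifies the role of each channel (by convention ``"H2B"`` for the constitutive
    nuclear marker and ``"reporter"`` for the SMAD translocation reporter; fixed-sample
    stacks use ``"DAPI"`` in place of H2B).
    """

    data: np.ndarray
    pixel_size_um: float = 1.0
    channel_names: tuple = ("H2B", "reporter")
    times_hr: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(
                f"ImageStack data must be (t, c, y, x); got shape {self.data.shape}"
            )
        if self.data.shape[1] != len(self.channel_names):
            raise ValueError("channel_names length does not match channel axis")
        if self.times_hr is not None:
            self.times_hr = np.asarray(self.times_hr, dtype=float)
            if self.times_hr.shape[0] != self.data.shape[0]:
                raise ValueError("times_hr length does not match frame axis")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self):
        return self.data.shape

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"no channel named {name!r}; have {self.channel_names}")

    def channel(self, name: str) -> np.ndarray:
        """All frames of one channel, shape ``(t, y, x)``."""
        return self.data[:, self.channel_index(name)]

    def frame(self, t: int) -> dict:
        """One frame as ``{channel_name: 2-D array}``."""
        return {c: self.data[t, i] for i, c in enumerate(self.channel_names)}

    def copy_with(self, data: np.ndarray) -> "ImageStack":
        return ImageStack(
            data=data,
            pixel_size_um=self.pixel_size_um,
            channel_names=self.channel_names,
            times_hr=None if self.times_hr is None else self.times_hr.copy(),
            meta=dict(self.meta),
        )

    def save(self, path) -> None:
        """Write a multi-page TIFF plus a JSON parameter sidecar."""
        path = Path(path)
        tifffile.imwrite(path, self.data.astype(np.float32))
        sidecar = {
            "pixel_size_um": self.pixel_size_um,
            "channel_names": list(self.channel_names),
            "times_hr": None if self.times_hr is None else list(map(float, self.times_hr)),
            "meta": _jsonable(self.meta),
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path) -> "ImageStack":
        path = Path(path)
        data = tifffile.imread(path).astype(float)
        sidecar_path = path.with_suffix(path.suffix + ".json")
        if sidecar_path.exists():
            sc = json.loads(sidecar_path.read_text())
            return cls(
                data=data,
                pixel_size_um=sc["pixel_size_um"],
                channel_names=tuple(sc["channel_names"]),
                times_hr=None if sc["times_hr"] is None else np.asarray(sc["times_hr"]),
                meta=sc.get("meta", {}),
            )
        return cls(data=data, channel_names=tuple(f"ch{i}" for i in range(data.shape[1])))


@dataclass
class Colony:
    """Fitted colony circle in physical units."""

    center_um: tuple  # (x, y)
    radius_um: float
    fit_residual_um: float = 0.0

    def __post_init__(self):
        if self.radius_um <= 0:
            raise ValueError("colony radius must be positive")


@dataclass
class RadialProfile:
    """Binned readout vs distance from the colony edge.

    Bins are half-open ``[a, b)`` except the last, which is closed. When the profile is
    an average over several colonies, ``sd`` is the sample standard deviation across
    colonies; for a single colony it is across cells.
    """

    bin_edges: np.ndarray  # µm from colony edge, len n_bins + 1
    mean: np.ndarray
    sd: np.ndarray
    n_cells: np.ndarray
    n_colonies: int = 1
    readout: str = ""
    clipped_cells: int = 0

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        self.n_cells = np.asarray(self.n_cells)
        n = len(self.bin_edges) - 1
        if not (len(self.mean) == len(self.sd) == len(self.n_cells) == n):
            raise ValueError("profile arrays inconsistent with bin_edges")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_lo_um": self.bin_edges[:-1],
                "bin_hi_um": self.bin_edges[1:],
                "mean": self.mean,
                "sd": self.sd,
                "n_cells": self.n_cells,
                "n_colonies": self.n_colonies,
            }
        )


@dataclass
class Trajectory:
    """Per-condition population time series of one readout (no cell tracking)."""

    times_hr: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n_cells: np.ndarray
    readout: str = "nc_ratio"
    condition: str = ""
    dose_ng_ml: float = float("nan")

    def __post_init__(self):
        self.times_hr = np.asarray(self.times_hr, dtype=float)
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        self.n_cells = np.asarray(self.n_cells)
        if np.any(np.diff(self.times_hr) <= 0):
            raise ValueError("trajectory times must be strictly increasing")
        if not (len(self.mean) == len(self.sd) == len(self.n_cells) == len(self.times_hr)):
            raise ValueError("trajectory arrays must share a length")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_hr": self.times_hr,
                "mean": self.mean,
                "sd": self.sd,
                "n_cells": self.n_cells,
                "readout": self.readout,
                "condition": self.condition,
                "dose_ng_ml": self.dose_ng_ml,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Trajectory":
        df = df.sort_values("time_hr")
        return cls(
            times_hr=df["time_hr"].to_numpy(),
            mean=df["mean"].to_numpy(),
            sd=df["sd"].to_numpy(),
            n_cells=df["n_cells"].to_numpy(),
            readout=str(df["readout"].iloc[0]) if "readout" in df else "",
            condition=str(df["condition"].iloc[0]) if "condition" in df else "",
            dose_ng_ml=float(df["dose_ng_ml"].iloc[0]) if "dose_ng_ml" in df else float("nan"),
        )


@dataclass
class CountMatrix:
    """Genes × samples normalized counts with time/condition sample metadata.

    ``samples`` has one row per column of ``counts`` with columns
    ``sample`` (matching ``counts.columns``), ``time_hr`` and ``condition``
    (``"treated"`` or ``"control"``). ``gene_classes``, when present, carries
    simulation ground-truth labels.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    gene_classes: pd.Series | None = None

    def __post_init__(self):
        if list(self.counts.columns) != list(self.samples["sample"]):
            raise ValueError("counts columns must match samples['sample'] order")

    def columns_for(self, condition: str) -> list:
        sel = self.samples[self.samples["condition"] == condition]
        return list(sel.sort_values("time_hr")["sample"])

    def times_for(self, condition: str) -> np.ndarray:
        sel = self.samples[self.samples["condition"] == condition]
        return np.sort(sel["time_hr"].to_numpy().astype(float))

    def to_tsv(self, path) -> None:
        """TSV with a '#'-prefixed sample-metadata header block."""
        path = Path(path)
        buf = io.StringIO()
        for _, row in self.samples.iterrows():
            buf.write(f"# sample={row['sample']}\ttime_hr={row['time_hr']}\tcondition={row['condition']}\n")
        self.counts.to_csv(buf, sep="\t", index_label="gene")
        path.write_text(buf.getvalue())

    @classmethod
    def from_tsv(cls, path) -> "CountMatrix":
        path = Path(path)
        meta_rows = []
        body = []
        for line in path.read_text().splitlines():
            if line.startswith("#"):
                fields = dict(kv.split("=", 1) for kv in line[1:].strip().split("\t"))
                meta_rows.append(
                    {
                        "sample": fields["sample"],
                        "time_hr": float(fields["time_hr"]),
                        "condition": fields["condition"],
                    }
                )
            else:
                body.append(line)
        counts = pd.read_csv(io.StringIO("\n".join(body)), sep="\t", index_col="gene")
        return cls(counts=counts, samples=pd.DataFrame(meta_rows))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
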