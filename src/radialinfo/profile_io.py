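"""Line-scan I/O: the raw data model consumed by every downstream stage.

A *line scan* is a multichannel fluorescence intensity trace extracted along
the medial→lateral axis of a cochlear cross-section and exported from image
software as CSV (one row per position).  Positions are stored internally in
µm with the medial edge at 0; intensities are arbitrary fluorescence units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

STAGES = ("E12.5", "E13.5", "E14.5")
COMPARTMENTS = ("psd", "mesenchyme", "roof")

#: canonical lowercase channel vocabulary; unknown names are carried through.
CHANNEL_ALIASES = {
    "psmad": "psmad",
    "psmad1/5/9": "psmad",
    "psmad159": "psmad",
    "psmad1_5_9": "psmad",
    "sox2": "sox2",
    "nuclear": "nuclear",
    "dapi": "nuclear",
    "topro": "nuclear",
    "to-pro-3": "nuclear",
    "bmp4_mrna": "bmp4_mrna",
    "bmp4": "bmp4_mrna",
    "fst_mrna": "fst_mrna",
    "fst": "fst_mrna",
}

_POSITION_NAMES = {"position", "pos", "x", "distance", "position_um", "x_um"}


class FormatError(ValueError):
    """Input file does not have the expected CSV structure."""


class ValidationError(ValueError):
    """Input data violates a line-scan invariant."""


def normalize_channel_name(name: str) -> str:
    key = name.strip().lower()
    return CHANNEL_ALIASES.get(key, key)


@dataclass
class LineScan:
    """Raw multichannel intensity trace for one cochlea section.

    Invariants (checked on construction): positions start at 0 and strictly
    increase; every channel matches the position length; intensities are
    finite and non-negative.
    """

    sample_id: str
    stage: str
    compartment: str
    position: np.ndarray  # µm, medial edge = 0
    channels: dict[str, np.ndarray]
    pixel_size: float = field(default=np.nan)  # µm per sample point

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.stage not in STAGES:
            raise ValidationError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if self.compartment not in COMPARTMENTS:
            raise ValidationError(
                f"unknown compartment {self.compartment!r}; expected one of {COMPARTMENTS}"
            )
        if self.position.ndim != 1 or self.position.size < 2:
            raise ValidationError("position must be a 1-D sequence of length >= 2")
        if self.position[0] != 0.0:
            raise ValidationError("first position must be 0 (medial edge)")
        if not np.all(np.diff(self.position) > 0):
            bad = int(np.flatnonzero(np.diff(self.position) <= 0)[0]) + 1
            raise ValidationError(f"positions not strictly increasing at row {bad}")
        self.channels = {
            normalize_channel_name(k): np.asarray(v, dtype=float)
            for k, v in self.channels.items()
        }
        if not self.channels:
            raise ValidationError("line scan needs at least one intensity channel")
        for name, values in self.channels.items():
            if values.shape != self.position.shape:
                raise ValidationError(
                    f"channel {name!r} has length {values.size}, expected {self.position.size}"
                )
            if not np.all(np.isfinite(values)):
                bad = int(np.flatnonzero(~np.isfinite(values))[0])
                raise ValidationError(f"channel {name!r} non-finite at row {bad}")
            if np.any(values < 0):
                bad = int(np.flatnonzero(values < 0)[0])
                raise ValidationError(f"channel {name!r} negative intensity at row {bad}")
        if not np.isfinite(self.pixel_size):
            self.pixel_size = float(np.median(np.diff(self.position)))

    @property
    def length_um(self) -> float:
        return float(self.position[-1])

    @property
    def n_points(self) -> int:
        return int(self.position.size)

    def channel(self, name: str) -> np.ndarray:
        return self.channels[normalize_channel_name(name)]


def read_metadata_sidecar(path: str | Path) -> dict:
    """Read a YAML/JSON sidecar {sample_id, stage, compartment, pixel_size_um, ...}."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def read_linescan_csv(
    path: str | Path,
    sample_id: str | None = None,
    stage: str | None = None,
    compartment: str = "psd",
    pixel_size: float | None = None,
    position_unit: str = "um",
    metadata: str | Path | Mapping | None = None,
) -> LineScan:
    """Read a line-scan CSV (one header row; a position column + >=1 intensity columns).

    Column order is immaterial.  ``position_unit`` may be ``"um"`` or
    ``"pixel"``; pixel-indexed positions require ``pixel_size`` (µm/px) and
    are converted to µm.  ``metadata`` (mapping or YAML/JSON sidecar path)
    can supply sample_id/stage/compartment/pixel_size_um/position_unit.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta: dict = {}
    if metadata is not None:
        meta = dict(metadata) if isinstance(metadata, Mapping) else read_metadata_sidecar(metadata)
    sample_id = sample_id or meta.get("sample_id") or path.stem
    stage = stage or meta.get("stage")
    compartment = meta.get("compartment", compartment)
    pixel_size = pixel_size if pixel_size is not None else meta.get("pixel_size_um")
    position_unit = meta.get("position_unit", position_unit)
    if stage is None:
        raise ValidationError("stage must be given (argument or metadata sidecar)")

    try:
        frame = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - surface as a format problem
        raise FormatError(f"could not parse {path} as CSV: {exc}") from exc
    pos_cols = [c for c in frame.columns if str(c).strip().lower() in _POSITION_NAMES]
    if not pos_cols:
        raise FormatError(f"{path}: no position column (expected one of {sorted(_POSITION_NAMES)})")
    if not all(np.issubdtype(frame[c].dtype, np.number) for c in frame.columns):
        raise FormatError(f"{path}: non-numeric cells present")

    position = frame[pos_cols[0]].to_numpy(dtype=float)
    if position_unit == "pixel":
        if pixel_size is None:
            raise ValidationError("pixel-indexed positions require pixel_size (µm/px)")
        position = position * float(pixel_size)
    elif position_unit != "um":
        raise ValidationError(f"unknown position_unit {position_unit!r}")
    channels = {
        str(c): frame[c].to_numpy(dtype=float) for c in frame.columns if c not in pos_cols
    }
    return LineScan(
        sample_id=str(sample_id),
        stage=str(stage),
        compartment=str(compartment),
        position=position,
        channels=channels,
        pixel_size=float(pixel_size) if pixel_size is not None else np.nan,
    )


def write_linescan_csv(scan: LineScan, path: str | Path) -> None:
    """Write a LineScan back to CSV (position_um column + one column per channel)."""
    frame = pd.DataFrame({"position_um": scan.position})
    for name, values in scan.channels.items():
        frame[name] = values
    frame.to_csv(path, index=False)


# --- profile tables -------------------------------------------------------

def write_profile_table(ensemble, path: str | Path) -> None:
    """Write a :class:`~radialinfo.preprocess.ProfileEnsemble` as a CSV table.

    Columns: ``x`` (relative position grid), one column per sample, ``mean``
    and ``sd``.  Metadata (channel/stage/anchor flag) is kept in leading
    ``#``-comment lines so the file round-trips through
    :func:`read_profile_table`.
    """
    if ensemble.n_samples == 0:
        raise ValueError("cannot write an empty ensemble")
    path = Path(path)
    header = (
        f"# channel={ensemble.channel}\n"
        f"# stage={ensemble.stage}\n"
        f"# anchor_min={ensemble.anchor_min}\n"
    )
    frame = pd.DataFrame({"x": ensemble.x})
    for sid, row in zip(ensemble.sample_ids, ensemble.samples):
        frame[f"sample:{sid}"] = row
    frame["mean"] = ensemble.mean
    frame["sd"] = ensemble.sd
    with open(path, "w") as fh:
        fh.write(header)
        frame.to_csv(fh, index=False)


def read_profile_table(path: str | Path):
    """Inverse of :func:`write_profile_table`."""
    from .preprocess import ProfileEnsemble  # local import avoids a cycle

    path = Path(path)
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value.strip()
    frame = pd.read_csv(path, comment="#")
    sample_cols = [c for c in frame.columns if str(c).startswith("sample:")]
    if not sample_cols:
        raise FormatError(f"{path}: no sample columns")
    stage = meta.get("stage")
    return ProfileEnsemble(
        x=frame["x"].to_numpy(dtype=float),
        samples=np.vstack([frame[c].to_numpy(dtype=float) for c in sample_cols]),
        channel=meta.get("channel", "unknown"),
        stage=None if stage in (None, "None") else stage,
        sample_ids=[c.split(":", 1)[1] for c in sample_cols],
        anchor_min=meta.get("anchor_min", "True") == "True",
    )
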