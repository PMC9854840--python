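"""Reading and writing TPS landmark files.

The TPS dialect accepted here is the one produced by common 2-D digitizing
tools: records start with ``LM=k``, followed by ``k`` lines of ``x y``
coordinates (y-up), optionally followed by ``IMAGE=``, ``ID=`` and
``SCALE=`` lines.  A ``SCALE=`` factor multiplies the record's coordinates.
Specimen identifiers come from ``ID=``, else the ``IMAGE=`` stem, else the
record's sequential index.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .scheme import LandmarkScheme

__all__ = ["Configuration", "TPSError", "read_tps", "write_tps"]


class TPSError(ValueError):
    """Malformed TPS content."""


@dataclass
class Configuration:
    """A single digitized specimen: ``k`` landmarks in image units."""

    specimen_id: str
    coords: np.ndarray  # (k, 2) float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be a (k, 2) array")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"specimen {self.specimen_id!r}: non-finite coordinates")

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[0]


def read_tps(path, scheme: Optional[LandmarkScheme] = None) -> list[Configuration]:
    """Parse a TPS file into a list of :class:`Configuration`.

    Parameters
    ----------
    path : path-like
        TPS text file.
    scheme : LandmarkScheme, optional
        When given, every record must have exactly ``scheme.n_landmarks``
        landmarks; a mismatch raises :class:`TPSError` naming the record.
    """
    with open(path) as fh:
        lines = fh.readlines()

    configs: list[Configuration] = []
    i = 0
    record_no = 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.upper().startswith("LM="):
            raise TPSError(f"record {record_no + 1}: expected 'LM=' line, got {line!r}")
        record_no += 1
        try:
            k = int(line.split("=", 1)[1])
        except ValueError as exc:
            raise TPSError(f"record {record_no}: bad LM count in {line!r}") from exc
        i += 1
        coords = np.empty((k, 2))
        for j in range(k):
            if i >= len(lines):
                raise TPSError(f"record {record_no}: truncated after {j} coordinates")
            parts = lines[i].split()
            if len(parts) != 2:
                raise TPSError(
                    f"record {record_no}: landmark {j + 1}: expected 'x y', "
                    f"got {lines[i].rstrip()!r}"
                )
            try:
                coords[j] = [float(parts[0]), float(parts[1])]
            except ValueError as exc:
                raise TPSError(
                    f"record {record_no}: landmark {j + 1}: non-numeric coordinate "
                    f"in {lines[i].rstrip()!r}"
                ) from exc
            i += 1
        spec_id = None
        image = None
        scale = None
        meta: dict = {}
        while i < len(lines):
            tag = lines[i].strip()
            if not tag:
                i += 1
                continue
            upper = tag.upper()
            if upper.startswith("LM="):
                break
            if upper.startswith("ID="):
                spec_id = tag.split("=", 1)[1].strip()
            elif upper.startswith("IMAGE="):
                image = tag.split("=", 1)[1].strip()
            elif upper.startswith("SCALE="):
                try:
                    scale = float(tag.split("=", 1)[1])
                except ValueError as exc:
                    raise TPSError(f"record {record_no}: bad SCALE line {tag!r}") from exc
            else:
                # tolerate unknown KEY=value lines, keep them as metadata
                if "=" in tag:
                    key, val = tag.split("=", 1)
                    meta[key.strip().lower()] = val.strip()
                else:
                    raise TPSError(f"record {record_no}: unexpected line {tag!r}")
            i += 1
        if scheme is not None and k != scheme.n_landmarks:
            raise TPSError(
                f"record {record_no}: has LM={k}, scheme expects "
                f"{scheme.n_landmarks}"
            )
        if scale is not None:
            coords = coords * scale
            meta["scale"] = scale
        if image is not None:
            meta["image"] = image
        if spec_id is None or spec_id == "":
            if image:
                spec_id = os.path.splitext(os.path.basename(image))[0]
            else:
                spec_id = str(record_no)
        configs.append(Configuration(specimen_id=spec_id, coords=coords, metadata=meta))

    if not configs:
        raise TPSError(f"no TPS records found in {path}")
    return configs


def write_tps(configs: list[Configuration], path) -> None:
    """Write configurations as TPS records (LM=, coordinates, ID=)."""
    with open(path, "w") as fh:
        for cfg in configs:
            fh.write(f"LM={cfg.n_landmarks}\n")
            for x, y in cfg.coords:
                fh.write(f"{x:.10f} {y:.10f}\n")
            fh.write(f"ID={cfg.specimen_id}\n")
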