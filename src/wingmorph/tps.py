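"""Reading and writing TPS landmark files and specimen/measurement tables.

The TPS dialect supported is the point-data subset written by common 2D
digitizing tools: ``LM=`` blocks of ``x y`` coordinate lines followed by
optional ``IMAGE=``, ``ID=`` and ``SCALE=`` keys. Coordinates are stored
unscaled; the ``SCALE`` factor (physical units per coordinate unit) is kept
on the configuration and applied only when a caller explicitly asks for
physical units. ``CURVES``/``POINTS`` outline data are ignored with a
warning. This is the only module that touches bytes on disk.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "LandmarkConfiguration",
    "read_tps",
    "write_tps",
    "read_measurements",
    "MEASUREMENT_COLUMNS",
]


@dataclass
class LandmarkConfiguration:
    """One photo's digitized landmarks with provenance.

    Coordinates are in raw digitizing units (y-up Cartesian); ``scale``
    converts them to physical units (e.g. mm per unit) on request.
    """

    coords: np.ndarray
    image_id: str = ""
    individual_id: str = ""
    fixation: int = 0
    scale: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be a (k, 2) array")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if self.scale is not None and self.scale <= 0:
            raise ValueError("scale must be positive")

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[0]

    def scaled_coords(self) -> np.ndarray:
        """Coordinates in physical units (requires a scale)."""
        if self.scale is None:
            raise ValueError(
                f"configuration {self.image_id!r} has no scale factor")
        return self.coords * self.scale


def read_tps(path) -> list[LandmarkConfiguration]:
    """Parse a TPS file into a list of landmark configurations.

    One configuration is produced per ``LM=`` block; no block is ever
    silently dropped. Raises ``ValueError`` naming the offending block (and
    line) on a wrong landmark count or a malformed number.
    """
    path = Path(path)
    configs: list[LandmarkConfiguration] = []
    block_lm: int | None = None
    coords: list[tuple[float, float]] = []
    meta: dict = {}

    def flush(lineno):
        nonlocal block_lm, coords, meta
        if block_lm is None:
            return
        if len(coords) != block_lm:
            raise ValueError(
                f"{path}: block {len(configs) + 1} (ending near line "
                f"{lineno}) declares LM={block_lm} but has {len(coords)} "
                "coordinate lines")
        configs.append(LandmarkConfiguration(
            coords=np.array(coords, dtype=float).reshape(block_lm, 2),
            image_id=meta.get("IMAGE", ""),
            individual_id=meta.get("ID", ""),
            fixation=int(meta["FIXATION"]) if "FIXATION" in meta else 0,
            scale=float(meta["SCALE"]) if "SCALE" in meta else None,
        ))
        block_lm, coords, meta = None, [], {}

    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            upper = line.upper()
            if upper.startswith("LM="):
                flush(lineno)
                try:
                    block_lm = int(line.split("=", 1)[1])
                except ValueError as exc:
                    raise ValueError(
                        f"{path}:{lineno}: malformed LM count "
                        f"{line!r}") from exc
                continue
            if "=" in line and not _looks_numeric(line):
                key, value = line.split("=", 1)
                key = key.strip().upper()
                if key in ("CURVES", "POINTS"):
                    logger.warning("%s:%d: ignoring unsupported key %s",
                                   path, lineno, key)
                else:
                    meta[key] = value.strip()
                continue
            if block_lm is None:
                raise ValueError(
                    f"{path}:{lineno}: coordinate line outside an LM block")
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 'x y', got {line!r}")
            try:
                coords.append((float(parts[0]), float(parts[1])))
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: malformed coordinate {line!r}"
                ) from exc
    flush(lineno="EOF")
    return configs


def _looks_numeric(line: str) -> bool:
    try:
        [float(p) for p in line.split()]
        return True
    except ValueError:
        return False


def write_tps(configs: list[LandmarkConfiguration], path) -> None:
    """Write configurations as a TPS file (full precision, '.' decimals).

    All configurations must share a landmark count. An empty list produces
    an empty file.
    """
    counts = {c.n_landmarks for c in configs}
    if len(counts) > 1:
        raise ValueError(
            f"heterogeneous landmark counts {sorted(counts)}; refusing to "
            "write a mixed TPS file")
    lines: list[str] = []
    for cfg in configs:
        lines.append(f"LM={cfg.n_landmarks}")
        for x, y in cfg.coords:
            lines.append(f"{float(x)!r} {float(y)!r}")
        lines.append(f"IMAGE={cfg.image_id}")
        lines.append(f"ID={cfg.individual_id}")
        if cfg.fixation:
            lines.append(f"FIXATION={cfg.fixation}")
        if cfg.scale is not None:
            lines.append(f"SCALE={float(cfg.scale)!r}")
        lines.append("")
    Path(path).write_text("\n".join(lines), encoding="utf-8")


MEASUREMENT_COLUMNS = [
    "individual_id", "species", "hand_wing_length", "arm_wing_length",
    "wing_span", "arm_wing_area", "hand_wing_area", "tail_area",
    "wing_area", "mass_g", "forearm_mm",
]

_POSITIVE_COLUMNS = MEASUREMENT_COLUMNS[2:]


def read_measurements(path) -> pd.DataFrame:
    """Read the specimen measurement CSV (lengths mm, areas mm², mass g).

    Validates that all required columns are present and all lengths/areas/
    masses are strictly positive; errors name the missing column or the
    offending row.
    """
    df = pd.read_csv(path)
    for col in MEASUREMENT_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing column {col}")
    for col in _POSITIVE_COLUMNS:
        bad = df.index[~(df[col] > 0)]
        if len(bad):
            raise ValueError(
                f"non-positive {col} in row(s) {list(bad)}")
    return df[MEASUREMENT_COLUMNS + [c for c in df.columns
                                     if c not in MEASUREMENT_COLUMNS]]
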