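"""ROI atlas handling and resting-state network definitions.

The default parcellation is the 90-region AAL atlas (45 regions per
hemisphere, left/right homologues alternating: odd ids left, even ids
right).  Region order in the atlas table defines the row/column order of
every matrix in the package: 0-based indices internally, 1-based AAL ids
in files.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .exceptions import AtlasLookupError, FormatError

_ATLAS_COLUMNS = ["id", "label", "abbreviation", "x", "y", "z"]

#: Expected member counts of the packaged default networks.
DEFAULT_NETWORK_SIZES = {"VN": 12, "DMN": 12, "AN": 18, "SN": 10}


@dataclass(frozen=True)
class AtlasTable:
    """ROI table: one row per region, row order = matrix index order.

    ``table`` has columns id, label, abbreviation, x, y, z with MNI centre
    coordinates in millimetres.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if list(t.columns) != _ATLAS_COLUMNS:
            raise FormatError(f"atlas columns must be {_ATLAS_COLUMNS}, got {list(t.columns)}")
        if len(t) == 0:
            raise FormatError("atlas table is empty")
        if t["label"].duplicated().any():
            dupes = sorted(t.loc[t["label"].duplicated(), "label"])
            raise FormatError(f"duplicate atlas labels: {dupes}")
        if t["id"].duplicated().any():
            raise FormatError("duplicate atlas region ids")
        ids = t["id"].to_numpy()
        if not (ids == range(1, len(t) + 1)).all():
            raise FormatError("atlas region ids must be contiguous 1..n in row order")

    @property
    def n_regions(self) -> int:
        return len(self.table)

    @property
    def labels(self) -> list[str]:
        return self.table["label"].tolist()

    @property
    def coordinates(self):
        """MNI centre coordinates as an (n, 3) float array."""
        return self.table[["x", "y", "z"]].to_numpy(dtype=float)

    def index_of(self, label: str) -> int:
        """0-based row index of an atlas label."""
        matches = self.table.index[self.table["label"] == label]
        if len(matches) == 0:
            raise AtlasLookupError(f"label {label!r} not found in atlas")
        return int(matches[0])


@dataclass(frozen=True)
class NetworkDefinition:
    """A named resting-state network given as a list of atlas labels."""

    name: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise FormatError(f"network {self.name!r} has no members")
        object.__setattr__(self, "members", tuple(self.members))


def load_atlas(path: str | Path | None = None) -> AtlasTable:
    """Read an atlas CSV (header id,label,abbreviation,x,y,z).

    With no path the packaged AAL-90 table is loaded.  Raises
    :class:`FormatError` on duplicate labels, non-numeric coordinates, or
    missing columns.
    """
    if path is None:
        with resources.files("restconn.data").joinpath("aal90.csv").open() as fh:
            raw = pd.read_csv(fh)
    else:
        raw = pd.read_csv(path)
    if list(raw.columns) != _ATLAS_COLUMNS:
        raise FormatError(
            f"atlas file must have columns {_ATLAS_COLUMNS}, got {list(raw.columns)}"
        )
    for col in ("x", "y", "z"):
        coerced = pd.to_numeric(raw[col], errors="coerce")
        if coerced.isna().any():
            bad = raw.loc[coerced.isna(), "label"].tolist()
            raise FormatError(f"non-numeric {col} coordinate for regions {bad}")
        raw[col] = coerced
    raw["id"] = pd.to_numeric(raw["id"], errors="raise").astype(int)
    raw["label"] = raw["label"].astype(str)
    return AtlasTable(raw.reset_index(drop=True))


def load_networks(path: str | Path | None = None) -> dict[str, NetworkDefinition]:
    """Read network definitions from YAML/JSON (name -> label list).

    With no path the packaged defaults (VN, DMN, AN, SN) are loaded.
    """
    if path is None:
        with resources.files("restconn.data").joinpath("networks.yaml").open() as fh:
            raw = yaml.safe_load(fh)
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise FormatError("network config must map network name -> member label list")
    return {name: NetworkDefinition(name, tuple(members)) for name, members in raw.items()}


def resolve_members(atlas: AtlasTable, net: NetworkDefinition) -> list[int]:
    """Sorted, duplicate-free 0-based atlas indices of a network's members.

    Raises :class:`AtlasLookupError` naming the first unknown label.
    """
    indices = {atlas.index_of(label) for label in net.members}
    return sorted(indices)
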