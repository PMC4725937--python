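"""Bundled data files: synthetic placeholder marker universes, the default
pKa table, and the transcribed clean-contig summary table used by the
consistency checks."""

from __future__ import annotations

from importlib import resources
from pathlib import Path

__all__ = ["data_path", "default_marker_set", "default_marker_path"]


def data_path(name: str) -> Path:
    return Path(str(resources.files(__package__) / name))


def default_marker_path(size: int) -> Path:
    if size not in (104, 191):
        raise ValueError("bundled placeholder universes have 104 or 191 IDs")
    return data_path(f"synthetic_markers_{size}.txt")


def default_marker_set(size: int = 104):
    from ..io import read_marker_list

    return read_marker_list(default_marker_path(size), name=f"synthetic_{size}")
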