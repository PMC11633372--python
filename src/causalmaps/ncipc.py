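"""Helpers for the NCIPC causal map of ACEs and adolescent suicide.

The CDC National Center for Injury Prevention and Control released a
causal map linking adverse childhood experiences to youth suicide
(361 factors, 946 signed influences).  The map is deposited on the
Open Science Framework at https://osf.io/7nxp4/ and can be downloaded
without registration; it is not bundled here because it is third-party
data.  Download the edge list, convert it to the ``source,target,
polarity`` CSV dialect (or GraphML) if needed, and place it at
``data/ncipc_map.csv`` (or pass an explicit path) to run the
reproduction checks.
"""

from __future__ import annotations

import urllib.request
from pathlib import Path

from .model import CausalMap
from .io import load_map

__all__ = ["NCIPC_OSF_URL", "default_ncipc_path", "fetch_ncipc", "load_ncipc"]

NCIPC_OSF_URL = "https://osf.io/7nxp4/"

# published headline statistics, used only to sanity-check a loaded file
EXPECTED_NODES = 361
EXPECTED_EDGES = 946


def default_ncipc_path(root: str | Path = ".") -> Path:
    """The conventional local location of the NCIPC map file."""
    for candidate in ("data/ncipc_map.csv", "data/ncipc_map.graphml"):
        path = Path(root) / candidate
        if path.exists():
            return path
    return Path(root) / "data/ncipc_map.csv"


def fetch_ncipc(url: str, dest: str | Path) -> Path:
    """Download the NCIPC map file from a direct URL.

    The OSF project page (:data:`NCIPC_OSF_URL`) is not itself a file;
    pass the direct download link of the deposited edge list.  Requires
    network access.
    """
    dest = Path(dest)
    dest.parent.mkdir(parents=True, exist_ok=True)
    with urllib.request.urlopen(url, timeout=60) as response:  # noqa: S310
        dest.write_bytes(response.read())
    return dest


def load_ncipc(path: str | Path | None = None, strict: bool = True) -> CausalMap:
    """Load a local copy of the NCIPC map and sanity-check its size.

    With ``strict`` (default) the loaded map must have the published
    361 nodes and 946 edges; a mismatch usually means the file was
    exported with duplicate rows or a different schema.
    """
    path = Path(path) if path is not None else default_ncipc_path()
    if not path.exists():
        raise FileNotFoundError(
            f"NCIPC map not found at {path}; download it from {NCIPC_OSF_URL} "
            "and save it as source,target,polarity CSV (see module docstring)"
        )
    cmap = load_map(path, name="NCIPC")
    if strict and (cmap.n, cmap.m) != (EXPECTED_NODES, EXPECTED_EDGES):
        raise ValueError(
            f"{path}: expected {EXPECTED_NODES} nodes / {EXPECTED_EDGES} edges, "
            f"got {cmap.n} / {cmap.m}"
        )
    return cmap
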