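"""SWC neuron reconstructions: container, validation, and text I/O.

SWC is the standard 7-column plain-text format for neuronal morphology:
``id type x y z radius parent_id``, coordinates in µm, ``parent_id == -1``
for the root. Type codes: 1 soma, 3 (basal) dendrite.

The axis convention maps anatomical axes to coordinate columns; the default
is rostrocaudal (RC) = x, dorsoventral (DV) = y, mediolateral (ML) = z. A
YAML sidecar (``<file>.yaml`` with an ``axes:`` mapping) can override it.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

__all__ = ["Morphology", "SWCError", "read_swc", "write_swc"]

DEFAULT_AXES = {"RC": 0, "DV": 1, "ML": 2}
_AXIS_NAMES = {"x": 0, "y": 1, "z": 2}


class SWCError(ValueError):
    """Raised for malformed SWC files (orphans, cycles, multiple roots)."""


@dataclass
class Morphology:
    """A validated SWC tree.

    Attributes are parallel arrays over nodes; ``parent`` holds SWC parent
    ids (-1 for the root), not array indices.
    """

    ids: np.ndarray
    types: np.ndarray
    xyz: np.ndarray  # (n, 3) µm
    radius: np.ndarray  # µm
    parent: np.ndarray
    axes: dict = field(default_factory=lambda: dict(DEFAULT_AXES))

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=np.int64)
        self.types = np.asarray(self.types, dtype=np.int64)
        self.xyz = np.asarray(self.xyz, dtype=np.float64).reshape(-1, 3)
        self.radius = np.asarray(self.radius, dtype=np.float64)
        self.parent = np.asarray(self.parent, dtype=np.int64)
        self.validate()

    # ------------------------------------------------------------- structure

    @property
    def n_nodes(self) -> int:
        return self.ids.size

    def index_of(self) -> dict:
        return {int(i): k for k, i in enumerate(self.ids)}

    def validate(self) -> None:
        if self.n_nodes == 0:
            raise SWCError("empty morphology")
        if len(set(self.ids.tolist())) != self.n_nodes:
            raise SWCError("duplicate node ids")
        if np.any(self.radius <= 0):
            raise SWCError("non-positive radius")
        if not np.all(np.isfinite(self.xyz)):
            raise SWCError("non-finite coordinates")
        roots = np.flatnonzero(self.parent == -1)
        if roots.size != 1:
            raise SWCError(f"expected exactly one root, found {roots.size}")
        idx = self.index_of()
        for line_no, (nid, pid) in enumerate(zip(self.ids, self.parent), 1):
            if pid == -1:
                continue
            if int(pid) not in idx:
                raise SWCError(f"line {line_no}: dangling parent id {pid}")
            if int(pid) == int(nid):
                raise SWCError(f"line {line_no}: self-parent")
        # cycle check: walk each node to the root
        for nid in self.ids:
            seen = set()
            cur = int(nid)
            while cur != -1:
                if cur in seen:
                    raise SWCError(f"cycle involving node {cur}")
                seen.add(cur)
                cur = int(self.parent[idx[cur]])

    def edges(self) -> np.ndarray:
        """(n_edges, 2) array of (child_index, parent_index) into arrays."""
        idx = self.index_of()
        out = [
            (k, idx[int(p)])
            for k, p in enumerate(self.parent)
            if p != -1
        ]
        return np.asarray(out, dtype=np.int64).reshape(-1, 2)

    def edge_lengths(self) -> np.ndarray:
        e = self.edges()
        if e.size == 0:
            return np.zeros(0)
        d = self.xyz[e[:, 0]] - self.xyz[e[:, 1]]
        return np.linalg.norm(d, axis=1)

    def axis_coord(self, name: str) -> np.ndarray:
        """Node coordinates along a named anatomical axis (RC/DV/ML)."""
        return self.xyz[:, self.axes[name]]

    def soma_index(self) -> int:
        soma = np.flatnonzero(self.types == 1)
        if soma.size == 0:
            # fall back to the root node
            return int(np.flatnonzero(self.parent == -1)[0])
        return int(soma[0])

    def children_counts(self) -> np.ndarray:
        idx = self.index_of()
        counts = np.zeros(self.n_nodes, dtype=np.int64)
        for p in self.parent:
            if p != -1:
                counts[idx[int(p)]] += 1
        return counts


def read_swc(path, axes: dict | None = None) -> Morphology:
    """Parse and validate an SWC file.

    Axis convention comes from (in priority order) the ``axes`` argument, a
    ``<path>.yaml`` sidecar with an ``axes: {RC: x, ...}`` mapping, or the
    default RC=x, DV=y, ML=z.
    """
    rows = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise SWCError(f"line {line_no}: expected 7 columns")
            try:
                rows.append(
                    (
                        int(parts[0]),
                        int(parts[1]),
                        float(parts[2]),
                        float(parts[3]),
                        float(parts[4]),
                        float(parts[5]),
                        int(parts[6]),
                    )
                )
            except ValueError as exc:
                raise SWCError(f"line {line_no}: {exc}") from exc
    if not rows:
        raise SWCError("no SWC records found")
    arr = np.asarray(rows, dtype=np.float64)
    if axes is None:
        axes = _sidecar_axes(path)
    return Morphology(
        ids=arr[:, 0].astype(np.int64),
        types=arr[:, 1].astype(np.int64),
        xyz=arr[:, 2:5],
        radius=arr[:, 5],
        parent=arr[:, 6].astype(np.int64),
        axes=axes or dict(DEFAULT_AXES),
    )


def _sidecar_axes(path) -> dict | None:
    sidecar = str(path) + ".yaml"
    if not os.path.exists(sidecar):
        return None
    import yaml

    with open(sidecar) as fh:
        cfg = yaml.safe_load(fh) or {}
    mapping = cfg.get("axes")
    if not mapping:
        return None
    return {k: _AXIS_NAMES[str(v).lower()] for k, v in mapping.items()}


def write_swc(m: Morphology, path) -> None:
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent\n")
        for nid, t, (x, y, z), r, p in zip(
            m.ids, m.types, m.xyz, m.radius, m.parent
        ):
            fh.write(
                f"{nid} {t} {float(x)!r} {float(y)!r} {float(z)!r} "
                f"{float(r)!r} {p}\n"
            )
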