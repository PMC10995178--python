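"""File formats: JSON cell-outline snapshots, CSV lineage maps, ASCII PLY
meshes with a per-face integer ``cell_label`` attribute.

The JSON schema (version 1)::

    {
      "format": "organgrowth-snapshot",
      "version": 1,
      "time_dai": 4.0,
      "cells": [
        {"label": 1, "vertices": [[x, y], ...],
         "region": "valve", "state": "proliferative",
         "vertex_ids": [0, 1, 2, ...]}        # optional
      ],
      "adjacency": [[1, 2], ...]
    }

Floats are serialized with ``repr`` precision, so write→read round-trips
are lossless up to float round-off.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np
from shapely.geometry import Polygon
from shapely.ops import unary_union

from organgrowth.core_model import CellPolygon, LineageMap, TissueSnapshot

__all__ = [
    "read_snapshot",
    "write_snapshot",
    "read_lineage",
    "write_lineage",
    "read_snapshot_ply",
    "write_snapshot_ply",
]

_FORMAT = "organgrowth-snapshot"


def write_snapshot(snapshot: TissueSnapshot, path) -> None:
    doc = {
        "format": _FORMAT,
        "version": 1,
        "time_dai": snapshot.time_dai,
        "cells": [
            {
                "label": c.label,
                "vertices": [[float(x), float(y)] for x, y in c.vertices],
                "region": c.region,
                "state": c.state,
                **(
                    {"vertex_ids": list(c.vertex_ids)}
                    if c.vertex_ids is not None
                    else {}
                ),
            }
            for _, c in sorted(snapshot.cells.items())
        ],
        "adjacency": [list(pair) for pair in sorted(snapshot.adjacency)],
    }
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def read_snapshot(path) -> TissueSnapshot:
    path = Path(path)
    if path.suffix.lower() == ".ply":
        return read_snapshot_ply(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise ValueError(f"{path}: not valid JSON ({e})") from e
    if doc.get("format") != _FORMAT:
        raise ValueError(f"{path}: unrecognized format {doc.get('format')!r}")
    cells: Dict[int, CellPolygon] = {}
    for i, rec in enumerate(doc.get("cells", [])):
        try:
            cells[int(rec["label"])] = CellPolygon(
                label=int(rec["label"]),
                vertices=np.array(rec["vertices"], dtype=float),
                region=rec.get("region", "none"),
                state=rec.get("state", "proliferative"),
                vertex_ids=tuple(rec["vertex_ids"]) if "vertex_ids" in rec else None,
            )
        except (KeyError, ValueError, TypeError) as e:
            raise ValueError(f"{path}: malformed cell record #{i}: {e}") from e
    return TissueSnapshot(
        time_dai=float(doc["time_dai"]),
        cells=cells,
        adjacency={tuple(p) for p in doc.get("adjacency", [])},
    )


def write_lineage(lineage: LineageMap, path) -> None:
    lines = [f"# t0={lineage.t0!r}", f"# t1={lineage.t1!r}", "child,parent"]
    for child, parent in sorted(lineage.parent_of.items()):
        lines.append(f"{child},{parent}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_lineage(path) -> LineageMap:
    path = Path(path)
    t0 = t1 = None
    parent_of: Dict[int, int] = {}
    for ln, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if body.startswith("t0="):
                t0 = float(body[3:])
            elif body.startswith("t1="):
                t1 = float(body[3:])
            continue
        if line.lower().startswith("child"):
            continue
        try:
            child_s, parent_s = line.split(",")
            parent_of[int(child_s)] = int(parent_s)
        except ValueError as e:
            raise ValueError(f"{path}:{ln}: malformed lineage row {line!r}") from e
    if t0 is None or t1 is None:
        raise ValueError(f"{path}: missing '# t0=' / '# t1=' header comments")
    return LineageMap(t0=t0, t1=t1, parent_of=parent_of)


# ---------------------------------------------------------------------------
# PLY with a per-face integer "cell_label" attribute


def read_snapshot_ply(path, time_dai: float = 0.0) -> TissueSnapshot:
    """Read an ASCII PLY whose faces carry a ``cell_label`` property.

    Faces sharing a label are merged; each cell's outline is the exterior
    boundary of the face union. Adjacency is derived from mesh edges used
    by faces of two different labels.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or lines[0].strip() != "ply":
        raise ValueError(f"{path}: not a PLY file")
    n_vert = n_face = None
    label_prop = None
    header_end = None
    elem = None
    face_props: List[str] = []
    for i, line in enumerate(lines[1:], start=1):
        tok = line.split()
        if not tok:
            continue
        if tok[0] == "format" and tok[1] != "ascii":
            raise ValueError(f"{path}: only ascii PLY is supported")
        if tok[0] == "element":
            elem = tok[1]
            if elem == "vertex":
                n_vert = int(tok[2])
            elif elem == "face":
                n_face = int(tok[2])
        elif tok[0] == "property" and elem == "face":
            face_props.append(tok[-1])
        elif tok[0] == "end_header":
            header_end = i
            break
    if header_end is None or n_vert is None or n_face is None:
        raise ValueError(f"{path}: incomplete PLY header")
    if "cell_label" not in face_props:
        raise ValueError(f"{path}: face element lacks a 'cell_label' property")
    scalar_after_list = face_props.index("cell_label") - face_props.index(
        "vertex_indices" if "vertex_indices" in face_props else "vertex_index"
    )

    body = lines[header_end + 1 :]
    verts = np.array(
        [[float(v) for v in body[i].split()[:2]] for i in range(n_vert)]
    )
    faces: List[Tuple[List[int], int]] = []
    for i in range(n_face):
        tok = body[n_vert + i].split()
        k = int(tok[0])
        idx = [int(t) for t in tok[1 : 1 + k]]
        label = int(tok[k + scalar_after_list])
        faces.append((idx, label))

    by_label: Dict[int, List[Polygon]] = {}
    for idx, label in faces:
        by_label.setdefault(label, []).append(Polygon(verts[idx]))
    cells: Dict[int, CellPolygon] = {}
    for label in sorted(by_label):
        union = unary_union(by_label[label])
        if union.geom_type != "Polygon":
            raise ValueError(f"{path}: faces of label {label} do not form one polygon")
        coords = np.array(union.exterior.coords[:-1])
        if Polygon(coords).exterior.is_ccw is False:
            coords = coords[::-1]
        cells[label] = CellPolygon(label=label, vertices=coords)

    edge_labels: Dict[Tuple[int, int], set] = {}
    for idx, label in faces:
        for j in range(len(idx)):
            e = tuple(sorted((idx[j], idx[(j + 1) % len(idx)])))
            edge_labels.setdefault(e, set()).add(label)
    adjacency = {
        tuple(sorted(labs)) for labs in edge_labels.values() if len(labs) == 2
    }
    return TissueSnapshot(time_dai=time_dai, cells=cells, adjacency=adjacency)


def write_snapshot_ply(snapshot: TissueSnapshot, path) -> None:
    """Write each cell outline as one PLY polygon face tagged with its label."""
    verts: List[Tuple[float, float]] = []
    lookup: Dict[Tuple[float, float], int] = {}
    faces: List[Tuple[List[int], int]] = []
    for lab in snapshot.labels:
        cyc = []
        for x, y in snapshot.cells[lab].vertices:
            key = (float(x), float(y))
            if key not in lookup:
                lookup[key] = len(verts)
                verts.append(key)
            cyc.append(lookup[key])
        faces.append((cyc, lab))
    out = [
        "ply",
        "format ascii 1.0",
        f"element vertex {len(verts)}",
        "property float x",
        "property float y",
        f"element face {len(faces)}",
        "property list uchar int vertex_indices",
        "property int cell_label",
        "end_header",
    ]
    out += [f"{x!r} {y!r}" for x, y in verts]
    out += [f"{len(c)} " + " ".join(map(str, c)) + f" {lab}" for c, lab in faces]
    Path(path).write_text("\n".join(out) + "\n")
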