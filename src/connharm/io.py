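"""On-disk formats.

Surfaces are read from FreeSurfer binary geometry, GIFTI ``.surf.gii`` or
OFF; network label maps from FreeSurfer ``.annot`` or per-vertex integer
TSV; fibre endpoints from TSV (six coordinate columns, or two 0-based
vertex-index columns).  Graphs are stored in a self-describing JSON
container that keeps the local / long-range edge classes and any
tractography provenance.  Per-vertex scalar outputs go to TSV (or GIFTI
``.func.gii``) aligned to the stored vertex order.

Vertex order is the single source of alignment between all artifacts and
all vertex indexing on disk is 0-based.  Every writer uses fixed floating
point formatting so identical inputs give byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidInputError, ParseError
from .graph import ConnectomeGraph, FiberEndpoints, SurfaceMesh
from .harmonics import HarmonicBasis
from .match import BinaryCorticalMap

__all__ = [
    "read_surface",
    "write_surface",
    "read_endpoints",
    "write_endpoint_pairs",
    "write_endpoint_coords",
    "read_labels",
    "write_labels",
    "save_graph",
    "load_graph",
    "save_basis",
    "load_basis",
    "save_simulation",
    "load_simulation",
    "write_manifest",
    "read_params_config",
]

_FLOAT_FMT = "%.17g"  # round-trips float64 exactly


# ---------------------------------------------------------------- surfaces


def _read_off(path: Path) -> SurfaceMesh:
    tokens: list[str] = []
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline().strip()
        if not first.startswith("OFF"):
            raise ParseError(f"{path}: missing OFF header")
        rest = first[3:].strip()
        if rest:
            tokens.extend(rest.split())
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                tokens.extend(line.split())
    try:
        nv, nf = int(tokens[0]), int(tokens[1])
        pos = 3  # counts line is "nv nf ne"
        verts = np.array(tokens[pos : pos + 3 * nv], dtype=np.float64).reshape(nv, 3)
        pos += 3 * nv
        faces = []
        for _ in range(nf):
            k = int(tokens[pos])
            if k != 3:
                raise ParseError(f"{path}: only triangular faces supported, got {k}-gon")
            faces.append([int(t) for t in tokens[pos + 1 : pos + 4]])
            pos += 1 + k
    except (IndexError, ValueError) as exc:
        raise ParseError(f"{path}: truncated or malformed OFF file ({exc})") from exc
    return SurfaceMesh(vertices=verts, faces=np.asarray(faces, dtype=np.int64).reshape(-1, 3))


def _write_off(path: Path, mesh: SurfaceMesh) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("OFF\n")
        fh.write(f"{mesh.n_vertices} {mesh.faces.shape[0]} 0\n")
        for v in mesh.vertices:
            fh.write(" ".join(_FLOAT_FMT % x for x in v) + "\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def read_surface(path) -> SurfaceMesh:
    """Read a surface mesh (OFF, GIFTI ``.gii``, or FreeSurfer binary).

    The stored vertex order is preserved exactly.
    """
    path = Path(path)
    if not path.exists():
        raise InvalidInputError(f"surface file not found: {path}")
    suffix = path.suffix.lower()
    if suffix == ".off":
        return _read_off(path)
    if suffix == ".gii":
        import nibabel as nib

        img = nib.load(str(path))
        try:
            coords = img.agg_data("NIFTI_INTENT_POINTSET")
            faces = img.agg_data("NIFTI_INTENT_TRIANGLE")
        except Exception as exc:
            raise ParseError(f"{path}: no pointset/triangle arrays in GIFTI file") from exc
        return SurfaceMesh(
            vertices=np.asarray(coords, dtype=np.float64),
            faces=np.asarray(faces, dtype=np.int64),
        )
    # fall back to FreeSurfer binary geometry (lh.white etc.)
    import nibabel.freesurfer as fsio

    try:
        coords, faces = fsio.read_geometry(str(path))
    except Exception as exc:
        raise ParseError(f"{path}: not a readable surface file ({exc})") from exc
    return SurfaceMesh(
        vertices=np.asarray(coords, dtype=np.float64), faces=np.asarray(faces, dtype=np.int64)
    )


def write_surface(path, mesh: SurfaceMesh) -> None:
    """Write a mesh as OFF or GIFTI, chosen by file suffix."""
    path = Path(path)
    if path.suffix.lower() == ".off":
        _write_off(path, mesh)
        return
    if path.suffix.lower() == ".gii":
        import nibabel as nib

        darrays = [
            nib.gifti.GiftiDataArray(
                mesh.vertices.astype(np.float32), intent="NIFTI_INTENT_POINTSET"
            ),
            nib.gifti.GiftiDataArray(
                mesh.faces.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE"
            ),
        ]
        nib.save(nib.gifti.GiftiImage(darrays=darrays), str(path))
        return
    raise InvalidInputError(f"unsupported surface output format: {path.suffix!r}")


# ---------------------------------------------------------------- endpoints


def read_endpoints(path):
    """Read a fibre endpoint table.

    Six numeric columns ``x1 y1 z1 x2 y2 z2`` give a
    :class:`~connharm.graph.FiberEndpoints`; two integer columns give a
    0-based vertex-index pair array directly.  Header lines starting with
    '#' carry optional provenance (``# key = value``).
    """
    path = Path(path)
    meta = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#") and "=" in line:
                key, _, val = line[1:].partition("=")
                meta[key.strip()] = val.strip()
    try:
        table = pd.read_csv(path, sep="\t", comment="#", header=None)
    except Exception as exc:
        raise ParseError(f"{path}: unreadable endpoint table ({exc})") from exc
    if table.shape[1] == 6:
        arr = table.to_numpy(dtype=np.float64)
        kwargs = {}
        for key, cast in (
            ("fa_threshold", float),
            ("min_length_mm", float),
            ("max_angle_deg", float),
            ("seeds_per_vertex", int),
        ):
            if key in meta:
                kwargs[key] = cast(meta[key])
        return FiberEndpoints(start=arr[:, :3], end=arr[:, 3:], **kwargs)
    if table.shape[1] == 2:
        return table.to_numpy(dtype=np.int64)
    raise ParseError(f"{path}: expected 6 coordinate or 2 index columns, found {table.shape[1]}")


def write_endpoint_pairs(path, pairs: np.ndarray) -> None:
    """Write 0-based vertex-index pairs as two-column TSV."""
    pairs = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# 0-based vertex index pairs\n")
        for a, b in pairs:
            fh.write(f"{a}\t{b}\n")


def write_endpoint_coords(path, fibers: FiberEndpoints) -> None:
    """Write endpoint coordinates as six-column TSV with provenance comments."""
    with open(path, "w", encoding="utf-8") as fh:
        for key in ("fa_threshold", "min_length_mm", "max_angle_deg", "seeds_per_vertex"):
            val = getattr(fibers, key)
            if val is not None:
                fh.write(f"# {key} = {val}\n")
        for s, e in zip(fibers.start, fibers.end):
            fh.write("\t".join(_FLOAT_FMT % x for x in (*s, *e)) + "\n")


# ---------------------------------------------------------------- label maps


def read_labels(path, n: int) -> list[BinaryCorticalMap]:
    """Read per-vertex network labels as one binary map per label.

    Accepts FreeSurfer ``.annot`` or a single-column integer TSV of length
    ``n``.  Label 0 is the unassigned/medial-wall class and produces no
    map; its vertices count as background in every map.
    """
    path = Path(path)
    if path.suffix.lower() == ".annot":
        import nibabel.freesurfer as fsio

        try:
            labels, _, names = fsio.read_annot(str(path))
        except Exception as exc:
            raise ParseError(f"{path}: unreadable annot file ({exc})") from exc
        if labels.shape[0] != n:
            raise InvalidInputError(
                f"{path}: expected {n} vertices, found {labels.shape[0]}"
            )
        maps = []
        for lab in np.unique(labels):
            if lab <= 0:  # 0 / unknown stays background
                continue
            name = names[lab].decode() if lab < len(names) else f"label{lab}"
            maps.append(BinaryCorticalMap(values=(labels == lab).astype(np.int8), name=name))
        return maps
    try:
        values = np.loadtxt(path, dtype=np.int64, comments="#", ndmin=1)
    except Exception as exc:
        raise ParseError(f"{path}: unreadable label table ({exc})") from exc
    if values.ndim != 1 or values.shape[0] != n:
        raise InvalidInputError(
            f"{path}: expected {n} per-vertex labels, found shape {values.shape}"
        )
    maps = []
    for lab in np.unique(values):
        if lab == 0:
            continue
        maps.append(
            BinaryCorticalMap(values=(values == lab).astype(np.int8), name=f"label{lab}")
        )
    return maps


def write_labels(path, maps: list[BinaryCorticalMap]) -> None:
    """Write binary maps back to a single-column integer label TSV.

    Map ``i`` (0-based in the list) becomes label ``i + 1``; vertices in no
    map get label 0.  Maps must be disjoint.
    """
    if not maps:
        raise InvalidInputError("no maps to write")
    n = maps[0].n
    out = np.zeros(n, dtype=np.int64)
    for i, m in enumerate(maps):
        if m.n != n:
            raise InvalidInputError("maps have inconsistent lengths")
        if (out[m.values == 1] != 0).any():
            raise InvalidInputError("maps overlap; cannot encode as a single label column")
        out[m.values == 1] = i + 1
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# per-vertex integer labels; 0 = unassigned\n")
        for v in out:
            fh.write(f"{v}\n")


# ---------------------------------------------------------------- graphs


def save_graph(path, graph: ConnectomeGraph, provenance: dict | None = None) -> None:
    """Write a graph as a self-describing JSON container (edge classes kept)."""
    doc = {
        "format": "connharm-graph",
        "version": 1,
        "n": int(graph.n),
        "local_edges": graph.local_edges.tolist(),
        "long_range_edges": graph.long_range_edges.tolist(),
        "provenance": provenance or {},
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, sort_keys=True, indent=None, separators=(",", ":"))
        fh.write("\n")


def load_graph(path) -> ConnectomeGraph:
    with open(path, "r", encoding="utf-8") as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ParseError(f"{path}: malformed graph container ({exc})") from exc
    if doc.get("format") != "connharm-graph":
        raise ParseError(f"{path}: not a connharm graph container")
    return ConnectomeGraph(
        n=int(doc["n"]),
        local_edges=np.asarray(doc["local_edges"], dtype=np.int64).reshape(-1, 2),
        long_range_edges=np.asarray(doc["long_range_edges"], dtype=np.int64).reshape(-1, 2),
    )


# ---------------------------------------------------------------- bases


def save_basis(outdir, basis: HarmonicBasis) -> None:
    """Write eigenvalues and per-vertex eigenvector maps as TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    np.savetxt(outdir / "eigenvalues.tsv", basis.eigenvalues, fmt=_FLOAT_FMT, delimiter="\t")
    np.savetxt(outdir / "eigenvectors.tsv", basis.eigenvectors, fmt=_FLOAT_FMT, delimiter="\t")
    meta = {"normalization": basis.normalization, "n": basis.n, "k": basis.k}
    if basis.vertex_mask is not None:
        meta["vertex_mask_indices"] = np.flatnonzero(basis.vertex_mask).tolist()
        meta["n_full"] = int(basis.vertex_mask.shape[0])
    with open(outdir / "basis.json", "w", encoding="utf-8") as fh:
        json.dump(meta, fh, sort_keys=True)
        fh.write("\n")


def load_basis(outdir) -> HarmonicBasis:
    outdir = Path(outdir)
    try:
        with open(outdir / "basis.json", "r", encoding="utf-8") as fh:
            meta = json.load(fh)
        vals = np.loadtxt(outdir / "eigenvalues.tsv", ndmin=1)
        vecs = np.loadtxt(outdir / "eigenvectors.tsv", ndmin=2)
    except (OSError, json.JSONDecodeError, ValueError) as exc:
        raise ParseError(f"{outdir}: unreadable basis directory ({exc})") from exc
    mask = None
    if "vertex_mask_indices" in meta:
        mask = np.zeros(int(meta["n_full"]), dtype=bool)
        mask[np.asarray(meta["vertex_mask_indices"], dtype=np.int64)] = True
    return HarmonicBasis(
        eigenvalues=vals, eigenvectors=vecs, normalization=meta["normalization"], vertex_mask=mask
    )


# ---------------------------------------------------------------- simulations


def save_simulation(outdir, result) -> None:
    """Write E/I trajectories as ``.npy`` arrays plus a params JSON."""
    from dataclasses import asdict

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    np.save(outdir / "E.npy", result.E)
    np.save(outdir / "I.npy", result.I)
    np.save(outdir / "t.npy", result.t)
    with open(outdir / "params.json", "w", encoding="utf-8") as fh:
        json.dump({"params": asdict(result.params), "log": result.log}, fh, sort_keys=True)
        fh.write("\n")


def load_simulation(outdir):
    from .neuralfield import NeuralFieldParams, SimulationResult

    outdir = Path(outdir)
    try:
        E = np.load(outdir / "E.npy")
        I = np.load(outdir / "I.npy")
        t = np.load(outdir / "t.npy")
        with open(outdir / "params.json", "r", encoding="utf-8") as fh:
            doc = json.load(fh)
    except (OSError, ValueError, json.JSONDecodeError) as exc:
        raise ParseError(f"{outdir}: unreadable simulation directory ({exc})") from exc
    return SimulationResult(
        E=E, I=I, t=t, params=NeuralFieldParams(**doc["params"]), log=doc.get("log", {})
    )


# ---------------------------------------------------------------- config / manifest


def write_manifest(outdir, config: dict) -> None:
    """Write the resolved run configuration plus library versions.

    Deliberately contains no timestamps, so reruns with identical inputs
    produce byte-identical manifests.
    """
    import scipy

    from . import __version__

    doc = {
        "config": config,
        "versions": {
            "connharm": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
        },
    }
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(doc, fh, sort_keys=True, indent=2)
        fh.write("\n")


def read_params_config(path) -> dict:
    """Read a ``key = value`` neural-field parameter file.

    Keys mirror :class:`~connharm.neuralfield.NeuralFieldParams` field names
    (sigma_ee, ..., alpha_ee, ..., d_e, d_i, tau_s, a, theta, dt, t_end,
    seed, scheme, ...); '#' starts a comment.
    """
    from .neuralfield import NeuralFieldParams

    fields = NeuralFieldParams.__dataclass_fields__
    out: dict = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ParseError(f"{path}:{lineno}: expected 'key = value'")
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if key not in fields:
                raise ParseError(f"{path}:{lineno}: unknown parameter {key!r}")
            if key in ("init", "scheme"):
                out[key] = val
            elif key in ("seed", "record_stride", "diffusion_steps"):
                out[key] = int(val)
            else:
                out[key] = float(val)
    return out
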