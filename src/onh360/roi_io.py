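"""Reading and writing optic cup/disc outline polygons.

Two on-disk dialects are supported:

* the ImageJ/Fiji binary ``.roi`` format (single files or ``.zip``
  bundles), as emitted when a grader hand-traces a boundary and saves
  the region of interest;
* a plain long-format CSV with one vertex per row.

The ``.roi`` files carry only geometry, so image/eye/structure/grader
metadata travels in a sidecar *manifest* CSV mapping each ROI file name
to its ``(image_id, eye, structure, grader_id)``.  A clinical table
(per subject/eye VCDR, age, gender, status, allele counts) is loaded
into :class:`ClinicalRecord` rows.
"""

from __future__ import annotations

import io
import struct
import zipfile
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Eye",
    "Structure",
    "Resolution",
    "Outline",
    "GradedImage",
    "ClinicalRecord",
    "RoiFormatError",
    "UnsupportedRoiTypeError",
    "read_imagej_roi",
    "read_imagej_roi_bytes",
    "write_imagej_roi",
    "read_roi_zip",
    "write_roi_zip",
    "read_outline_csv",
    "write_outline_csv",
    "read_manifest",
    "load_graded_images",
    "read_clinical_csv",
]


class Eye(str, Enum):
    OD = "OD"
    OS = "OS"


class Structure(str, Enum):
    CUP = "cup"
    DISC = "disc"


class Resolution(str, Enum):
    """Which grader source an image's downstream profile is built from."""

    BOTH_GRADERS = "both_graders"
    GRADER_1 = "grader_1"
    GRADER_2 = "grader_2"
    ADJUDICATOR = "adjudicator"


@dataclass
class Outline:
    """A closed polygon traced by one grader for one anatomical structure.

    Vertices are in image pixel coordinates: origin at the upper-left
    corner of the photo, x increasing rightward, y increasing downward.
    The polygon is implicitly closed (last vertex connects to first).
    """

    image_id: str
    eye: Eye
    structure: Structure
    grader_id: str
    vertices: np.ndarray  # (n, 2) float array of (x, y)

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise ValueError("vertices must be an (n, 2) array of (x, y)")
        if v.shape[0] < 3:
            raise ValueError("an outline needs at least 3 vertices")
        if not np.all(np.isfinite(v)):
            raise ValueError("outline coordinates must be finite")
        if np.any(v < 0):
            raise ValueError("outline coordinates must be non-negative")
        self.eye = Eye(self.eye)
        self.structure = Structure(self.structure)
        self.vertices = v

    @property
    def n_vertices(self) -> int:
        return int(self.vertices.shape[0])


@dataclass
class GradedImage:
    """All outlines drawn for one stereo-disc photo (normally 2 graders x 2 structures)."""

    image_id: str
    eye: Eye
    outlines: list[Outline] = field(default_factory=list)
    gradable: bool = True
    resolution: Resolution = Resolution.BOTH_GRADERS

    def __post_init__(self) -> None:
        self.eye = Eye(self.eye)
        self.resolution = Resolution(self.resolution)
        seen = set()
        for o in self.outlines:
            key = (o.grader_id, o.structure)
            if key in seen:
                raise ValueError(
                    f"duplicate outline for grader {o.grader_id!r} structure {o.structure.value}"
                )
            seen.add(key)

    def graders(self) -> list[str]:
        out: list[str] = []
        for o in self.outlines:
            if o.grader_id not in out:
                out.append(o.grader_id)
        return out

    def get(self, grader_id: str, structure: Structure | str) -> Outline:
        structure = Structure(structure)
        for o in self.outlines:
            if o.grader_id == grader_id and o.structure == structure:
                return o
        raise KeyError(f"no {structure.value} outline from grader {grader_id!r}")

    def has(self, grader_id: str, structure: Structure | str) -> bool:
        try:
            self.get(grader_id, structure)
            return True
        except KeyError:
            return False

    def add(self, outline: Outline) -> None:
        if self.has(outline.grader_id, outline.structure):
            raise ValueError(
                f"duplicate outline for grader {outline.grader_id!r} "
                f"structure {outline.structure.value}"
            )
        self.outlines.append(outline)


@dataclass
class ClinicalRecord:
    subject_id: str
    eye: Eye
    clinical_vcdr: float
    age: float
    gender: str
    status: str  # case / control / suspect
    allele_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.eye = Eye(self.eye)
        if not (0.0 <= self.clinical_vcdr <= 1.0):
            raise ValueError("clinical_vcdr must lie in [0, 1]")
        for snp, c in self.allele_counts.items():
            if c not in (0, 1, 2):
                raise ValueError(f"allele count for {snp} must be 0, 1 or 2")


# ---------------------------------------------------------------------------
# ImageJ ROI binary format
# ---------------------------------------------------------------------------

class RoiFormatError(ValueError):
    """Malformed or truncated ImageJ ROI data."""


class UnsupportedRoiTypeError(RoiFormatError):
    """The ROI is not a polygon-family type (polygon / freehand / traced)."""


# ImageJ RoiDecoder type codes
_ROI_TYPE_NAMES = {
    0: "polygon",
    1: "rect",
    2: "oval",
    3: "line",
    4: "freeline",
    5: "polyline",
    6: "noRoi",
    7: "freehand",
    8: "traced",
    9: "angle",
    10: "point",
}
_POLYGON_TYPES = {0, 7, 8}
_OPT_SUBPIXEL = 128  # options flag: SUB_PIXEL_RESOLUTION
_HEADER_SIZE = 64


def read_imagej_roi_bytes(data: bytes, *, name: str = "<bytes>") -> np.ndarray:
    """Decode one ImageJ ``.roi`` blob into an (n, 2) vertex array.

    Supports header versions >= 218 and the polygon family (polygon,
    freehand, traced), with the optional subpixel float block.  Vertex
    order is preserved exactly as stored.
    """
    if len(data) < _HEADER_SIZE:
        raise RoiFormatError(f"{name}: truncated ROI file ({len(data)} bytes)")
    if data[:4] != b"Iout":
        raise RoiFormatError(f"{name}: not an ImageJ ROI file (bad magic)")
    version = struct.unpack(">h", data[4:6])[0]
    if version < 218:
        raise RoiFormatError(f"{name}: unsupported ROI header version {version}")
    roi_type = data[6]
    if roi_type not in _POLYGON_TYPES:
        tname = _ROI_TYPE_NAMES.get(roi_type, f"code {roi_type}")
        raise UnsupportedRoiTypeError(f"{name}: unsupported ROI type {tname!r}")
    top, left, bottom, right, n = struct.unpack(">5h", data[8:18])
    if n <= 0:
        raise RoiFormatError(f"{name}: ROI declares {n} coordinates")
    options = struct.unpack(">h", data[50:52])[0]
    need = _HEADER_SIZE + 4 * n
    if len(data) < need:
        raise RoiFormatError(f"{name}: truncated coordinate block")
    xs = np.frombuffer(data, dtype=">i2", count=n, offset=_HEADER_SIZE).astype(float)
    ys = np.frombuffer(data, dtype=">i2", count=n, offset=_HEADER_SIZE + 2 * n).astype(float)
    verts = np.column_stack([xs + left, ys + top])
    if options & _OPT_SUBPIXEL and version >= 222:
        off = _HEADER_SIZE + 4 * n
        if len(data) >= off + 8 * n:
            xf = np.frombuffer(data, dtype=">f4", count=n, offset=off).astype(float)
            yf = np.frombuffer(data, dtype=">f4", count=n, offset=off + 4 * n).astype(float)
            verts = np.column_stack([xf, yf])
    return verts


def read_imagej_roi(
    path: str | Path,
    *,
    image_id: str = "",
    eye: Eye | str = Eye.OD,
    structure: Structure | str = Structure.DISC,
    grader_id: str = "",
) -> Outline:
    """Read a single ``.roi`` file.

    Eye/structure/grader metadata is not stored inside ``.roi`` files;
    the caller supplies it (normally from the manifest CSV).
    """
    path = Path(path)
    verts = read_imagej_roi_bytes(path.read_bytes(), name=path.name)
    return Outline(
        image_id=image_id or path.stem,
        eye=eye,
        structure=structure,
        grader_id=grader_id,
        vertices=verts,
    )


def _encode_roi(vertices: np.ndarray) -> bytes:
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
        raise ValueError("need an (n>=3, 2) vertex array")
    n = v.shape[0]
    if n > 32767:
        raise ValueError("too many vertices for the ROI short-count field")
    integral = bool(np.allclose(v, np.round(v)))
    xi = np.floor(v[:, 0]).astype(int) if not integral else np.round(v[:, 0]).astype(int)
    yi = np.floor(v[:, 1]).astype(int) if not integral else np.round(v[:, 1]).astype(int)
    left, top = int(xi.min()), int(yi.min())
    right, bottom = int(xi.max()) + 1, int(yi.max()) + 1
    header = bytearray(_HEADER_SIZE)
    header[0:4] = b"Iout"
    struct.pack_into(">h", header, 4, 227)  # version
    header[6] = 0  # polygon
    struct.pack_into(">5h", header, 8, top, left, bottom, right, n)
    options = 0 if integral else _OPT_SUBPIXEL
    struct.pack_into(">h", header, 50, options)
    body = bytearray()
    body += np.asarray(xi - left, dtype=">i2").tobytes()
    body += np.asarray(yi - top, dtype=">i2").tobytes()
    if not integral:
        body += np.asarray(v[:, 0], dtype=">f4").tobytes()
        body += np.asarray(v[:, 1], dtype=">f4").tobytes()
    return bytes(header) + bytes(body)


def write_imagej_roi(outline: Outline, path: str | Path) -> Path:
    """Write an outline as an ImageJ ``.roi`` file.

    Integer-vertex outlines round-trip bit-exactly; fractional vertices
    are stored in the subpixel float block (float32, well within the
    1/256 px contract).
    """
    path = Path(path)
    path.write_bytes(_encode_roi(outline.vertices))
    return path


def read_roi_zip(path: str | Path) -> list[tuple[str, np.ndarray]]:
    """Read every ``.roi`` entry of a zip bundle, preserving archive order."""
    out: list[tuple[str, np.ndarray]] = []
    with zipfile.ZipFile(path) as zf:
        for info in zf.infolist():
            if not info.filename.lower().endswith(".roi"):
                continue
            out.append((info.filename, read_imagej_roi_bytes(zf.read(info), name=info.filename)))
    return out


def write_roi_zip(entries: Iterable[tuple[str, np.ndarray]], path: str | Path) -> Path:
    path = Path(path)
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        for name, verts in entries:
            if not name.lower().endswith(".roi"):
                name = name + ".roi"
            zf.writestr(name, _encode_roi(verts))
    return path


# ---------------------------------------------------------------------------
# CSV dialects
# ---------------------------------------------------------------------------

_OUTLINE_COLUMNS = ["image_id", "eye", "structure", "grader_id", "vertex_index", "x", "y"]


def read_outline_csv(path: str | Path) -> list[Outline]:
    """Read the long-format outline CSV (one vertex per row).

    Rows are grouped by ``(image_id, eye, structure, grader_id)`` and
    vertices ordered by ``vertex_index``; duplicate indices within a
    group are an error.
    """
    df = pd.read_csv(path)
    missing = [c for c in _OUTLINE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"outline CSV missing columns: {', '.join(missing)}")
    for col in ("x", "y"):
        if not np.issubdtype(df[col].dtype, np.number):
            raise ValueError(f"non-numeric coordinate in column {col!r}")
    outlines: list[Outline] = []
    keys = ["image_id", "eye", "structure", "grader_id"]
    for key, grp in df.groupby(keys, sort=False):
        if grp["vertex_index"].duplicated().any():
            raise ValueError(f"duplicate vertex_index within group {key}")
        grp = grp.sort_values("vertex_index")
        outlines.append(
            Outline(
                image_id=str(key[0]),
                eye=Eye(key[1]),
                structure=Structure(key[2]),
                grader_id=str(key[3]),
                vertices=grp[["x", "y"]].to_numpy(dtype=float),
            )
        )
    return outlines


def write_outline_csv(outlines: Sequence[Outline], path: str | Path) -> Path:
    rows = []
    for o in outlines:
        for i, (x, y) in enumerate(o.vertices):
            rows.append(
                {
                    "image_id": o.image_id,
                    "eye": o.eye.value,
                    "structure": o.structure.value,
                    "grader_id": o.grader_id,
                    "vertex_index": i,
                    "x": x,
                    "y": y,
                }
            )
    path = Path(path)
    pd.DataFrame(rows, columns=_OUTLINE_COLUMNS).to_csv(path, index=False)
    return path


_MANIFEST_COLUMNS = ["filename", "image_id", "eye", "structure", "grader_id"]


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in _MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest CSV missing columns: {', '.join(missing)}")
    return df


def load_graded_images(roi_zip: str | Path, manifest: str | Path | pd.DataFrame) -> list[GradedImage]:
    """Assemble :class:`GradedImage` objects from an ROI bundle + manifest.

    Every manifest row must name an entry of the zip; zip entries absent
    from the manifest are ignored.
    """
    mf = manifest if isinstance(manifest, pd.DataFrame) else read_manifest(manifest)
    entries = dict(read_roi_zip(roi_zip))
    images: dict[tuple[str, str], GradedImage] = {}
    for row in mf.itertuples(index=False):
        if row.filename not in entries:
            raise FileNotFoundError(f"manifest names {row.filename!r}, absent from bundle")
        key = (row.image_id, row.eye)
        if key not in images:
            images[key] = GradedImage(image_id=row.image_id, eye=Eye(row.eye))
        images[key].add(
            Outline(
                image_id=row.image_id,
                eye=Eye(row.eye),
                structure=Structure(row.structure),
                grader_id=row.grader_id,
                vertices=entries[row.filename],
            )
        )
    return list(images.values())


def read_clinical_csv(path: str | Path) -> list[ClinicalRecord]:
    """Load the clinical table.

    Required columns: subject_id, eye, clinical_vcdr, age, gender,
    status.  Any column named ``snp_*`` is treated as an allele count
    (0/1/2) for that SNP.
    """
    df = pd.read_csv(path)
    required = ["subject_id", "eye", "clinical_vcdr", "age", "gender", "status"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"clinical CSV missing columns: {', '.join(missing)}")
    snp_cols = [c for c in df.columns if c.startswith("snp_")]
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        records.append(
            ClinicalRecord(
                subject_id=str(d["subject_id"]),
                eye=Eye(d["eye"]),
                clinical_vcdr=float(d["clinical_vcdr"]),
                age=float(d["age"]),
                gender=str(d["gender"]),
                status=str(d["status"]),
                allele_counts={c: int(d[c]) for c in snp_cols},
            )
        )
    return records
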