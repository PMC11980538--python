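"""Stage I: recursive scan discovery, reading, and sequence classification.

Accepts three input layouts:

* plain directories of NIfTI files,
* BIDS-organised trees (``sub-*/[ses-*/]<modality>/*.nii[.gz]`` with optional
  JSON sidecars and ``.bval`` tables),
* raw Bruker study folders (``2dseq`` reconstructions accompanied by
  line-oriented ``visu_pars``/``method`` parameter files; only the minimal
  field set needed for QC is parsed — matrix, extent, protocol name,
  repetitions, b-value table).

Every discovered candidate ends up exactly once in the manifest, either as a
classified :class:`ScanRecord` or in the excluded list with a reason
(localizers, unreadable files, unresolvable sequence type).
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .config import (
    ANATOMICAL_KEYWORDS,
    DIFFUSION_KEYWORDS,
    FUNCTIONAL_KEYWORDS,
)
from .image import VoxelImage

log = logging.getLogger(__name__)

SEQUENCE_CLASSES = ("anatomical", "diffusion", "functional", "excluded")

#: filename fragments that mark non-quantifiable scouting scans
LOCALIZER_KEYWORDS = ("localizer", "tripilot", "scout")


class ReaderError(RuntimeError):
    """Raised when an image file or its metadata cannot be read."""


@dataclass
class ScanRecord:
    """One discovered scan and the minimal metadata QC needs."""

    path: Path
    subject_id: str
    sequence_class: str
    source_format: str  # nifti | bids | bruker
    sequence_name: str
    n_volumes: int
    voxel_size_mm: tuple[float, float, float]
    session_id: str | None = None
    bvalues: list[float] | None = None

    def __post_init__(self) -> None:
        self.path = Path(self.path)
        if self.sequence_class not in SEQUENCE_CLASSES:
            raise ValueError(f"unknown sequence class {self.sequence_class!r}")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel sizes must be positive")


@dataclass
class Manifest:
    """Outcome of the parsing stage: records plus explicit exclusions."""

    root: Path
    records: list[ScanRecord] = field(default_factory=list)
    excluded: list[tuple[Path, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def by_class(self, sequence_class: str) -> list[ScanRecord]:
        return [r for r in self.records if r.sequence_class == sequence_class]


def classify_sequence(
    sequence_name: str,
    bvalues: list[float] | None = None,
    n_volumes: int = 1,
    *,
    anatomical_keywords: tuple[str, ...] = ANATOMICAL_KEYWORDS,
    diffusion_keywords: tuple[str, ...] = DIFFUSION_KEYWORDS,
    functional_keywords: tuple[str, ...] = FUNCTIONAL_KEYWORDS,
    functional_min_volumes: int = 10,
) -> str:
    """Assign anatomical / diffusion / functional / excluded.

    A multi-entry b-value table is decisive evidence of a diffusion scan and
    overrides name matching.  Otherwise case-insensitive substring keywords
    decide, with diffusion > functional > anatomical precedence (echo-planar
    protocols reuse anatomical-sounding tokens more often than the reverse).
    A 4D series without any evidence but with at least
    ``functional_min_volumes`` repetitions defaults to functional.
    """
    if bvalues is not None and len(bvalues) >= 2:
        return "diffusion"
    name = (sequence_name or "").lower()
    if any(k in name for k in diffusion_keywords):
        return "diffusion"
    if any(k in name for k in functional_keywords):
        return "functional"
    if any(k in name for k in anatomical_keywords):
        return "anatomical"
    if n_volumes >= functional_min_volumes:
        return "functional"
    return "excluded"


def _is_localizer(name: str) -> bool:
    low = name.lower()
    return any(k in low for k in LOCALIZER_KEYWORDS)


def _check_axis_order(dims: tuple[int, ...], path: Path) -> None:
    """Reject a suspected x-z-y permuted matrix (slice axis in the middle).

    Coronal sections put the (small) slice count on the third axis; a middle
    axis that is far smaller than both in-plane axes (e.g. 256 x 40 x 256)
    indicates a permuted header that must be fixed manually — silent
    reordering would corrupt every downstream geometry assumption.
    """
    if len(dims) < 3:
        return
    x, y, z = dims[:3]
    if y * 4 <= min(x, z) and z > y:
        raise ReaderError(
            f"{path}: matrix {x}x{y}x{z} looks x-z-y permuted "
            "(slice axis in the middle); please reorder the data manually"
        )


# ---------------------------------------------------------------------------
# NIfTI / BIDS
# ---------------------------------------------------------------------------

_BIDS_SUB_RE = re.compile(r"sub-([A-Za-z0-9]+)")
_BIDS_SES_RE = re.compile(r"ses-([A-Za-z0-9]+)")


def _nifti_stem(path: Path) -> str:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return name[: -len(suffix)]
    return path.stem


def _read_bval_file(path: Path) -> list[float] | None:
    """BIDS-style whitespace-separated b-value table next to the image."""
    bval_path = path.parent / (_nifti_stem(path) + ".bval")
    if not bval_path.exists():
        return None
    tokens = bval_path.read_text().split()
    return [float(t) for t in tokens] if tokens else None


def _read_sidecar(path: Path) -> dict:
    sidecar = path.parent / (_nifti_stem(path) + ".json")
    if sidecar.exists():
        try:
            return json.loads(sidecar.read_text())
        except (OSError, json.JSONDecodeError):
            log.warning("unreadable sidecar %s", sidecar)
    return {}


def _record_from_nifti(path: Path, root: Path, **clf_kwargs) -> ScanRecord:
    try:
        img = nib.load(str(path))
        shape = tuple(int(d) for d in img.shape)
        zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    except Exception as exc:  # nibabel raises a zoo of types on corrupt input
        raise ReaderError(f"{path}: cannot read NIfTI header ({exc})") from exc
    if len(shape) < 3 or any(d < 1 for d in shape):
        raise ReaderError(f"{path}: unsupported matrix {shape}")
    _check_axis_order(shape, path)
    if any(z <= 0 for z in zooms):
        raise ReaderError(f"{path}: missing or non-positive voxel sizes")

    n_volumes = shape[3] if len(shape) > 3 else 1
    bvalues = _read_bval_file(path)
    sidecar = _read_sidecar(path)

    rel = path.relative_to(root).as_posix()
    sub = _BIDS_SUB_RE.search(rel)
    ses = _BIDS_SES_RE.search(rel)
    is_bids = sub is not None
    subject = sub.group(1) if sub else path.parent.name or _nifti_stem(path)
    stem = _nifti_stem(path)
    sequence_name = str(
        sidecar.get("SeriesDescription") or sidecar.get("ProtocolName") or stem
    )

    sequence_class = classify_sequence(sequence_name, bvalues, n_volumes, **clf_kwargs)
    return ScanRecord(
        path=path,
        subject_id=str(subject),
        session_id=ses.group(1) if ses else None,
        sequence_class=sequence_class,
        source_format="bids" if is_bids else "nifti",
        sequence_name=sequence_name,
        n_volumes=n_volumes,
        voxel_size_mm=zooms,
        bvalues=bvalues,
    )


# ---------------------------------------------------------------------------
# Bruker (minimal parameter-file subset)
# ---------------------------------------------------------------------------

_PARAM_RE = re.compile(r"^##\$?([A-Za-z0-9_]+)=(.*)$")


def parse_bruker_params(path: Path) -> dict[str, object]:
    """Parse a line-oriented ``##$KEY=value`` Bruker parameter file.

    Array parameters are declared as ``##$KEY=( n )`` with the values on the
    following lines; ``<...>`` wraps free-text strings.  Only scalar floats,
    ints, strings and flat numeric arrays are decoded — nested structures the
    QC math never touches are kept as raw strings.
    """
    params: dict[str, object] = {}
    lines = path.read_text(errors="replace").splitlines()
    i = 0
    while i < len(lines):
        m = _PARAM_RE.match(lines[i])
        if not m:
            i += 1
            continue
        key, rhs = m.group(1), m.group(2).strip()
        if rhs.startswith("(") and rhs.endswith(")"):
            # array declaration: collect value lines until the next ## entry
            chunks: list[str] = []
            i += 1
            while i < len(lines) and not lines[i].startswith("##") \
                    and not lines[i].startswith("$$"):
                chunks.append(lines[i].strip())
                i += 1
            joined = " ".join(chunks)
            params[key] = _decode_value(joined)
            continue
        params[key] = _decode_value(rhs)
        i += 1
    return params


def _decode_value(text: str):
    text = text.strip()
    if text.startswith("<") and text.endswith(">"):
        return text[1:-1]
    tokens = text.split()
    if not tokens:
        return text
    try:
        values = [float(t) for t in tokens]
    except ValueError:
        return text
    if len(values) == 1:
        v = values[0]
        return int(v) if v == int(v) else v
    return values


_BRUKER_DTYPES = {
    "_16BIT_SGN_INT": np.dtype("<i2"),
    "_32BIT_SGN_INT": np.dtype("<i4"),
    "_32BIT_FLOAT": np.dtype("<f4"),
}


def _bruker_metadata(folder: Path) -> dict[str, object]:
    """Merge the minimal fields from visu_pars and method files."""
    meta: dict[str, object] = {}
    for name in ("visu_pars", "method", "acqp"):
        fp = folder / name
        if fp.exists():
            try:
                meta.update(parse_bruker_params(fp))
            except OSError as exc:
                raise ReaderError(f"{fp}: unreadable parameter file ({exc})") from exc
    return meta


def _as_int_list(value) -> list[int]:
    if isinstance(value, (int, float)):
        return [int(value)]
    return [int(v) for v in value]


def _record_from_bruker(folder: Path, root: Path, **clf_kwargs) -> ScanRecord:
    meta = _bruker_metadata(folder)
    if "VisuCoreSize" not in meta or "VisuCoreExtent" not in meta:
        raise ReaderError(
            f"{folder}: missing necessary metadata (VisuCoreSize/VisuCoreExtent)"
        )
    matrix = _as_int_list(meta["VisuCoreSize"])
    extent = meta["VisuCoreExtent"]
    extent = [float(extent)] if isinstance(extent, (int, float)) else list(extent)
    if len(matrix) != 3 or len(extent) != 3:
        raise ReaderError(f"{folder}: only 3D matrices supported, got {matrix}")
    _check_axis_order(tuple(matrix), folder)
    voxel = tuple(e / m for e, m in zip(extent, matrix))
    if any(v <= 0 for v in voxel):
        raise ReaderError(f"{folder}: non-positive voxel size {voxel}")

    seq_name = str(meta.get("VisuAcquisitionProtocol") or meta.get("Method") or "")
    bvalues = meta.get("PVM_DwEffBval")
    if isinstance(bvalues, (int, float)):
        bvalues = [float(bvalues)]
    data_file = folder / "2dseq"
    dtype = _BRUKER_DTYPES.get(str(meta.get("VisuCoreWordType")), np.dtype("<i2"))
    n_frame_voxels = int(np.prod(matrix))
    try:
        n_total = data_file.stat().st_size // dtype.itemsize
    except OSError as exc:
        raise ReaderError(f"{data_file}: unreadable ({exc})") from exc
    if n_total % n_frame_voxels:
        raise ReaderError(
            f"{folder}: 2dseq size does not match matrix {matrix}; "
            "check for a permuted or truncated reconstruction"
        )
    n_volumes = n_total // n_frame_voxels
    if bvalues is not None and len(bvalues) != n_volumes:
        raise ReaderError(
            f"{folder}: b-table has {len(bvalues)} entries for {n_volumes} volumes"
        )
    subject = str(meta.get("VisuSubjectId") or folder.parent.name or folder.name)
    sequence_class = classify_sequence(seq_name, bvalues, n_volumes, **clf_kwargs)
    return ScanRecord(
        path=folder,
        subject_id=subject,
        sequence_class=sequence_class,
        source_format="bruker",
        sequence_name=seq_name,
        n_volumes=n_volumes,
        voxel_size_mm=voxel,
        bvalues=bvalues,
    )


# ---------------------------------------------------------------------------
# discovery and reading
# ---------------------------------------------------------------------------


def scan_input_tree(root: str | Path, format_hint: str | None = None) -> Manifest:
    """Recursively discover scans under ``root`` into a :class:`Manifest`.

    Candidates are NIfTI files and Bruker reconstruction folders (containing
    a ``2dseq``).  Localizer-type scans and files whose required metadata is
    missing or unreadable land in the excluded list with a reason; a single
    bad file never aborts the walk.  Ordering is lexicographic by path so
    repeated runs produce identical manifests.
    """
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"input root {root} is not a readable directory")

    candidates: list[tuple[Path, str]] = []
    if format_hint != "bruker":
        for path in sorted(root.rglob("*.nii")) + sorted(root.rglob("*.nii.gz")):
            candidates.append((path, "nifti"))
    if format_hint in (None, "bruker"):
        for path in sorted(root.rglob("2dseq")):
            candidates.append((path.parent, "bruker"))
    candidates.sort(key=lambda item: str(item[0]))

    manifest = Manifest(root=root)
    seen_keys: dict[tuple[str, str, str], int] = {}
    for path, kind in candidates:
        label = path.name if kind == "nifti" else f"{path.parent.name}/{path.name}"
        if _is_localizer(label):
            manifest.excluded.append((path, "localizer scan"))
            continue
        try:
            if kind == "nifti":
                record = _record_from_nifti(path, root)
            else:
                record = _record_from_bruker(path, root)
        except ReaderError as exc:
            manifest.excluded.append((path, str(exc)))
            continue
        if record.sequence_class == "excluded":
            manifest.excluded.append(
                (path, f"unresolved sequence type {record.sequence_name!r}")
            )
            continue
        # duplicate subject/sequence collisions get a running index so report
        # joins stay unique
        key = (record.subject_id, record.session_id or "", record.sequence_name)
        count = seen_keys.get(key, 0)
        if count:
            record.subject_id = f"{record.subject_id}_{count + 1}"
        seen_keys[key] = count + 1
        manifest.records.append(record)
    return manifest


def read_image(record: ScanRecord) -> VoxelImage:
    """Load the voxel data for one scan record into a :class:`VoxelImage`."""
    if record.source_format in ("nifti", "bids"):
        try:
            img = nib.load(str(record.path))
            data = np.asarray(img.dataobj, dtype=np.float64)
        except Exception as exc:
            raise ReaderError(f"{record.path}: cannot read image ({exc})") from exc
        data = np.squeeze(data)
        if data.ndim not in (3, 4):
            raise ReaderError(f"{record.path}: unsupported dimensionality {data.ndim}")
        _check_axis_order(data.shape, record.path)
        # magnitude data: negative values only arise from scaling round-off
        data = np.clip(data, 0.0, None)
        return VoxelImage(data, record.voxel_size_mm, record.bvalues)

    if record.source_format == "bruker":
        meta = _bruker_metadata(record.path)
        matrix = _as_int_list(meta["VisuCoreSize"])
        dtype = _BRUKER_DTYPES.get(str(meta.get("VisuCoreWordType")), np.dtype("<i2"))
        raw = np.fromfile(record.path / "2dseq", dtype=dtype).astype(np.float64)
        n_frame = int(np.prod(matrix))
        n_volumes = raw.size // n_frame
        if n_volumes * n_frame != raw.size:
            raise ReaderError(f"{record.path}: 2dseq size mismatch")
        shape = tuple(matrix) + ((n_volumes,) if n_volumes > 1 else ())
        data = raw.reshape(shape, order="F")
        data = np.clip(data, 0.0, None)
        return VoxelImage(data, record.voxel_size_mm, record.bvalues)

    raise ReaderError(f"unknown source format {record.source_format!r}")
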