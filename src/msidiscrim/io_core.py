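"""Data model and file I/O shared by all pipeline stages.

Formats
-------
* Spectra: imzML (continuous mode, minimal profile) or a plain-text
  per-pixel table ("x y" header line followed by "mz<TAB>intensity" pairs,
  blocks separated by blank lines).
* ROI masks, feature tables and candidate mass lists: TSV.

Coordinates are 0-based integer raster indices; the raster pitch in
micrometres is carried as metadata only.
"""

from __future__ import annotations

import logging
import struct
import uuid
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

log = logging.getLogger("msidiscrim")

ROI_LABELS = ("cancer", "epithelium", "unassigned")

#: float format guaranteeing exact text round-trip of IEEE doubles
_FLOAT_FMT = "%.17g"


class ValidationError(ValueError):
    """Input violates a documented invariant."""


class ParseError(ValueError):
    """Malformed record in an input file."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpectraDataset:
    """Pixel-indexed spectra on a common m/z grid.

    Attributes
    ----------
    mz_axis : (n_bins,) strictly increasing m/z grid in Da.
    intensities : (n_pixels, n_bins) nonnegative intensity matrix.
    coords : (n_pixels, 2) integer raster indices (x, y).
    specimen_id : free-text specimen identifier.
    domain : ``"peptide"`` or ``"lipid"``.
    mass_range : (low, high) instrument mass range in Da.
    raster_um : raster pitch in micrometres (metadata only).
    """

    mz_axis: np.ndarray
    intensities: np.ndarray
    coords: np.ndarray
    specimen_id: str = "specimen"
    domain: str = "peptide"
    mass_range: tuple[float, float] = (800.0, 4000.0)
    raster_um: float = 100.0

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz_axis, dtype=float)
        inten = np.asarray(self.intensities, dtype=float)
        coords = np.asarray(self.coords, dtype=int)
        object.__setattr__(self, "mz_axis", mz)
        object.__setattr__(self, "intensities", inten)
        object.__setattr__(self, "coords", coords)
        if self.domain not in ("peptide", "lipid"):
            raise ValidationError(f"unknown domain {self.domain!r}")
        if mz.ndim != 1 or mz.size == 0:
            raise ValidationError("mz_axis must be a nonempty 1-D array")
        if np.any(np.diff(mz) <= 0):
            raise ValidationError("mz_axis must be strictly increasing")
        lo, hi = self.mass_range
        if mz[0] < lo - 1e-9 or mz[-1] > hi + 1e-9:
            raise ValidationError("mz_axis extends outside mass_range")
        if inten.shape != (coords.shape[0], mz.size):
            raise ValidationError(
                f"intensities shape {inten.shape} inconsistent with "
                f"{coords.shape[0]} pixels x {mz.size} bins"
            )
        if inten.size and np.min(inten) < 0:
            raise ValidationError("negative intensity")
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise ValidationError("coords must be (n_pixels, 2)")
        if len(np.unique(coords, axis=0)) != coords.shape[0]:
            raise ValidationError("duplicate pixel coordinates")

    @property
    def n_pixels(self) -> int:
        return self.coords.shape[0]

    @property
    def n_bins(self) -> int:
        return self.mz_axis.size

    def tic(self) -> np.ndarray:
        """Total ion current per pixel (sum of intensities)."""
        return self.intensities.sum(axis=1)

    def with_intensities(self, intensities: np.ndarray) -> "SpectraDataset":
        return replace(self, intensities=intensities)

    def subset_pixels(self, index: np.ndarray) -> "SpectraDataset":
        return replace(
            self, intensities=self.intensities[index], coords=self.coords[index]
        )


@dataclass(frozen=True)
class RoiMask:
    """Per-pixel region-of-interest labels aligned with a dataset's pixels."""

    labels: np.ndarray  # (n_pixels,) array of strings from ROI_LABELS

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=object)
        object.__setattr__(self, "labels", labels)
        bad = set(labels.tolist()) - set(ROI_LABELS)
        if bad:
            raise ValidationError(f"unknown ROI labels: {sorted(bad)}")

    def counts(self) -> dict[str, int]:
        return {lab: int(np.sum(self.labels == lab)) for lab in ROI_LABELS}

    def subset(self, index: np.ndarray) -> "RoiMask":
        return RoiMask(self.labels[index])

    def require_two_groups(self) -> None:
        c = self.counts()
        if c["cancer"] == 0 or c["epithelium"] == 0:
            raise ValidationError(
                "comparative stages need at least one cancer and one "
                f"epithelium pixel (counts: {c})"
            )


@dataclass(frozen=True)
class CandidateMassList:
    """Candidate identities for mass matching."""

    ids: np.ndarray
    masses: np.ndarray  # Da; peptide: observed MH+; lipid: neutral mass
    kind: str  # "peptide" | "lipid"
    class_labels: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        ids = np.asarray(self.ids, dtype=object)
        masses = np.asarray(self.masses, dtype=float)
        object.__setattr__(self, "ids", ids)
        object.__setattr__(self, "masses", masses)
        if self.class_labels is None:
            object.__setattr__(
                self, "class_labels", np.array([""] * ids.size, dtype=object)
            )
        else:
            object.__setattr__(
                self, "class_labels", np.asarray(self.class_labels, dtype=object)
            )
        if self.kind not in ("peptide", "lipid"):
            raise ValidationError(f"unknown candidate kind {self.kind!r}")
        if ids.size != masses.size:
            raise ValidationError("ids and masses length mismatch")
        if masses.size and np.min(masses) <= 0:
            raise ValidationError("candidate masses must be > 0")
        if len(set(ids.tolist())) != ids.size:
            raise ValidationError("candidate ids must be unique")


@dataclass(frozen=True)
class FeatureTable:
    """Molecular-component abundances: component x pixel matrix."""

    component_ids: np.ndarray  # (n_components,) centre m/z values
    abundances: np.ndarray  # (n_components, n_pixels), >= 0 finite
    domain: str = "peptide"

    def __post_init__(self) -> None:
        ids = np.asarray(self.component_ids, dtype=float)
        ab = np.asarray(self.abundances, dtype=float)
        object.__setattr__(self, "component_ids", ids)
        object.__setattr__(self, "abundances", ab)
        if ab.ndim != 2 or ab.shape[0] != ids.size:
            raise ValidationError("abundances must be (n_components, n_pixels)")
        if not np.all(np.isfinite(ab)):
            raise ValidationError("non-finite abundance")

    @property
    def n_components(self) -> int:
        return self.component_ids.size

    @property
    def n_pixels(self) -> int:
        return self.abundances.shape[1]


# ---------------------------------------------------------------------------
# pixel ordering
# ---------------------------------------------------------------------------


def row_major_order(coords: np.ndarray) -> np.ndarray:
    """Permutation sorting pixels row-major: by y, then x."""
    coords = np.asarray(coords, dtype=int)
    return np.lexsort((coords[:, 0], coords[:, 1]))


# ---------------------------------------------------------------------------
# spectra I/O
# ---------------------------------------------------------------------------


def load_dataset(path: str | Path, format: str | None = None, **meta) -> SpectraDataset:
    """Load spectra from ``imzml`` or ``text_table`` files.

    Heterogeneous per-pixel m/z axes are rejected here because the in-memory
    model is grid-based; resample exports upstream if needed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "imzml" if path.suffix.lower() == ".imzml" else "text_table"
    if format == "imzml":
        return _load_imzml(path, **meta)
    if format == "text_table":
        return _load_text_table(path, **meta)
    raise ValueError(f"unknown format {format!r}")


def save_dataset(dataset: SpectraDataset, path: str | Path) -> None:
    """Write a dataset as imzML (``.imzml``) or text table (anything else)."""
    path = Path(path)
    if path.suffix.lower() == ".imzml":
        _save_imzml(dataset, path)
    else:
        _save_text_table(dataset, path)


def _load_text_table(path: Path, **meta) -> SpectraDataset:
    blocks: list[tuple[int, int, np.ndarray, np.ndarray]] = []
    cur_xy: tuple[int, int] | None = None
    cur_mz: list[float] = []
    cur_int: list[float] = []

    def flush() -> None:
        if cur_xy is not None:
            blocks.append(
                (cur_xy[0], cur_xy[1], np.array(cur_mz), np.array(cur_int))
            )

    expect_header = True  # first line of the file / after a blank line
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                expect_header = True
                continue
            if line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected two fields")
            if expect_header:
                try:
                    x, y = int(parts[0]), int(parts[1])
                except ValueError as exc:
                    raise ParseError(
                        f"{path}:{lineno}: expected integer 'x y' pixel header"
                    ) from exc
                flush()
                cur_xy = (x, y)
                cur_mz, cur_int = [], []
                expect_header = False
            else:
                try:
                    a, b = float(parts[0]), float(parts[1])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: {exc}") from exc
                if b < 0:
                    raise ValidationError(
                        f"{path}:{lineno}: negative intensity at pixel {cur_xy}"
                    )
                cur_mz.append(a)
                cur_int.append(b)
    flush()
    if not blocks:
        raise ParseError(f"{path}: no pixels found")
    xy = np.array([(b[0], b[1]) for b in blocks], dtype=int)
    if len(np.unique(xy, axis=0)) != xy.shape[0]:
        raise ValidationError(f"{path}: duplicate pixel coordinates")
    axis = blocks[0][2]
    for x, y, mz, _ in blocks[1:]:
        if mz.size != axis.size or not np.array_equal(mz, axis):
            raise ParseError(
                f"{path}: pixel ({x},{y}) has a different m/z axis; "
                "resample before loading"
            )
    order = row_major_order(xy)
    inten = np.stack([blocks[i][3] for i in order])
    meta.setdefault("mass_range", (float(axis[0]), float(axis[-1])))
    return SpectraDataset(axis, inten, xy[order], **meta)


def _save_text_table(dataset: SpectraDataset, path: Path) -> None:
    with open(path, "w") as fh:
        for p in range(dataset.n_pixels):
            x, y = dataset.coords[p]
            fh.write(f"{x} {y}\n")
            for mz, v in zip(dataset.mz_axis, dataset.intensities[p]):
                fh.write(f"{_FLOAT_FMT % mz}\t{_FLOAT_FMT % v}\n")
            fh.write("\n")


# --- minimal imzML (continuous mode, float64, no compression) --------------

_IMZML_NS = "http://psi.hupo.org/ms/mzml"


def _save_imzml(dataset: SpectraDataset, path: Path) -> None:
    ibd_path = path.with_suffix(".ibd")
    file_uuid = uuid.uuid4()
    mz_bytes = np.ascontiguousarray(dataset.mz_axis, dtype="<f8").tobytes()
    with open(ibd_path, "wb") as ibd:
        ibd.write(file_uuid.bytes)
        ibd.write(mz_bytes)
        offset = 16 + len(mz_bytes)
        offsets = []
        for p in range(dataset.n_pixels):
            arr = np.ascontiguousarray(dataset.intensities[p], dtype="<f8").tobytes()
            ibd.write(arr)
            offsets.append(offset)
            offset += len(arr)

    root = ET.Element("mzML", xmlns=_IMZML_NS, version="1.1")
    fdesc = ET.SubElement(root, "fileDescription")
    fc = ET.SubElement(fdesc, "fileContent")
    ET.SubElement(
        fc, "cvParam", accession="IMS:1000030", name="continuous", value=""
    )
    ET.SubElement(
        fc,
        "cvParam",
        accession="IMS:1000080",
        name="universally unique identifier",
        value="{" + str(file_uuid) + "}",
    )
    meta = ET.SubElement(root, "referenceableParamGroupList")
    grp = ET.SubElement(meta, "referenceableParamGroup", id="dataset")
    ET.SubElement(grp, "userParam", name="specimen_id", value=dataset.specimen_id)
    ET.SubElement(grp, "userParam", name="domain", value=dataset.domain)
    ET.SubElement(
        grp,
        "userParam",
        name="mass_range",
        value=f"{_FLOAT_FMT % dataset.mass_range[0]} {_FLOAT_FMT % dataset.mass_range[1]}",
    )
    ET.SubElement(grp, "userParam", name="raster_um", value=_FLOAT_FMT % dataset.raster_um)
    run = ET.SubElement(root, "run", id="run0")
    speclist = ET.SubElement(
        run, "spectrumList", count=str(dataset.n_pixels + 1)
    )
    # index 0: shared m/z array
    mzspec = ET.SubElement(speclist, "spectrum", id="mzArray", index="0")
    ET.SubElement(
        mzspec,
        "binaryDataArray",
        encodedLength="0",
        offset="16",
        arrayLength=str(dataset.n_bins),
        kind="mz",
    )
    for p in range(dataset.n_pixels):
        x, y = dataset.coords[p]
        spec = ET.SubElement(
            speclist, "spectrum", id=f"pixel_{p}", index=str(p + 1)
        )
        pos = ET.SubElement(spec, "scanList")
        scan = ET.SubElement(pos, "scan")
        ET.SubElement(
            scan, "cvParam", accession="IMS:1000050", name="position x", value=str(int(x))
        )
        ET.SubElement(
            scan, "cvParam", accession="IMS:1000051", name="position y", value=str(int(y))
        )
        ET.SubElement(
            spec,
            "binaryDataArray",
            encodedLength="0",
            offset=str(offsets[p]),
            arrayLength=str(dataset.n_bins),
            kind="intensity",
        )
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="utf-8")


def _load_imzml(path: Path, **meta) -> SpectraDataset:
    ibd_path = path.with_suffix(".ibd")
    if not ibd_path.exists():
        raise FileNotFoundError(ibd_path)
    tree = ET.parse(path)
    root = tree.getroot()

    def findall(elem, tag):
        return elem.iter(f"{{{_IMZML_NS}}}{tag}") if root.tag.startswith("{") else elem.iter(tag)

    params = {}
    for up in findall(root, "userParam"):
        params[up.get("name")] = up.get("value")
    n_bins = None
    pixels: list[tuple[int, int, int]] = []  # (x, y, offset)
    mz_offset = 16
    for spec in findall(root, "spectrum"):
        bda = next(iter(findall(spec, "binaryDataArray")))
        n_bins = int(bda.get("arrayLength"))
        if bda.get("kind") == "mz" or spec.get("id") == "mzArray":
            mz_offset = int(bda.get("offset"))
            continue
        x = y = None
        for cv in findall(spec, "cvParam"):
            if cv.get("accession") == "IMS:1000050":
                x = int(cv.get("value"))
            elif cv.get("accession") == "IMS:1000051":
                y = int(cv.get("value"))
        if x is None or y is None:
            raise ParseError(f"{path}: spectrum {spec.get('id')} lacks position")
        pixels.append((x, y, int(bda.get("offset"))))
    if n_bins is None or not pixels:
        raise ParseError(f"{path}: no spectra found")
    with open(ibd_path, "rb") as ibd:
        raw = ibd.read()
    axis = np.frombuffer(raw, dtype="<f8", count=n_bins, offset=mz_offset).copy()
    xy = np.array([(p[0], p[1]) for p in pixels], dtype=int)
    if len(np.unique(xy, axis=0)) != xy.shape[0]:
        raise ValidationError(f"{path}: duplicate pixel coordinates")
    order = row_major_order(xy)
    inten = np.empty((len(pixels), n_bins))
    for row, i in enumerate(order):
        inten[row] = np.frombuffer(
            raw, dtype="<f8", count=n_bins, offset=pixels[i][2]
        )
    kw = dict(meta)
    if "mass_range" in params and "mass_range" not in kw:
        lo, hi = params["mass_range"].split()
        kw["mass_range"] = (float(lo), float(hi))
    else:
        kw.setdefault("mass_range", (float(axis[0]), float(axis[-1])))
    for key in ("specimen_id", "domain"):
        if key in params:
            kw.setdefault(key, params[key])
    if "raster_um" in params:
        kw.setdefault("raster_um", float(params["raster_um"]))
    return SpectraDataset(axis, inten, xy[order], **kw)


# ---------------------------------------------------------------------------
# ROI masks
# ---------------------------------------------------------------------------


def load_roi_mask(path: str | Path, dataset: SpectraDataset) -> RoiMask:
    """Read an ``x<TAB>y<TAB>label`` TSV; uncovered pixels become unassigned."""
    df = pd.read_csv(path, sep="\t", header=None, names=["x", "y", "label"],
                     comment="#", skip_blank_lines=True)
    if df["label"].dtype != object:
        raise ParseError(f"{path}: third column must be a label")
    bad = set(df["label"]) - set(ROI_LABELS)
    if bad:
        raise ValidationError(f"{path}: unknown ROI labels {sorted(bad)}")
    lookup = {(int(r.x), int(r.y)): r.label for r in df.itertuples()}
    labels = np.array(
        [lookup.get((int(x), int(y)), "unassigned") for x, y in dataset.coords],
        dtype=object,
    )
    mask = RoiMask(labels)
    log.info("ROI mask %s: %s", path, mask.counts())
    return mask


def save_roi_mask(mask: RoiMask, coords: np.ndarray, path: str | Path) -> None:
    with open(path, "w") as fh:
        for (x, y), lab in zip(coords, mask.labels):
            fh.write(f"{int(x)}\t{int(y)}\t{lab}\n")


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------


def save_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Write TSV: header row of component m/z, one row per pixel."""
    if table.n_components == 0 or table.n_pixels == 0:
        raise ValidationError("refusing to save an empty feature table")
    header = "\t".join(_FLOAT_FMT % mz for mz in table.component_ids)
    with open(path, "w") as fh:
        fh.write(f"# domain={table.domain}\n")
        fh.write(header + "\n")
        np.savetxt(fh, table.abundances.T, delimiter="\t", fmt=_FLOAT_FMT)


def load_feature_table(path: str | Path) -> FeatureTable:
    domain = "peptide"
    with open(path) as fh:
        first = fh.readline().strip()
        if first.startswith("#"):
            if "domain=" in first:
                domain = first.split("domain=")[1].strip()
            header = fh.readline().strip()
        else:
            header = first
        ids = np.array([float(t) for t in header.split("\t")])
        data = np.loadtxt(fh, delimiter="\t", ndmin=2)
    return FeatureTable(ids, data.T, domain=domain)


# ---------------------------------------------------------------------------
# candidate mass lists
# ---------------------------------------------------------------------------


def load_candidate_masses(path: str | Path, kind: str) -> CandidateMassList:
    """Read ``id<TAB>mass<TAB>kind<TAB>class`` TSV, keeping rows of ``kind``."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["id", "mass", "kind", "class"],
        comment="#", dtype={"id": str, "class": str},
    )
    df = df[df["kind"] == kind]
    return CandidateMassList(
        df["id"].to_numpy(dtype=object),
        df["mass"].to_numpy(dtype=float),
        kind,
        df["class"].fillna("").to_numpy(dtype=object),
    )


def save_candidate_masses(candidates: CandidateMassList, path: str | Path) -> None:
    with open(path, "w") as fh:
        for cid, mass, cls in zip(
            candidates.ids, candidates.masses, candidates.class_labels
        ):
            fh.write(f"{cid}\t{_FLOAT_FMT % mass}\t{candidates.kind}\t{cls}\n")
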