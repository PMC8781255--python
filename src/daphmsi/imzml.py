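"""Minimal imzML 1.1 reading and writing.

imzML stores an mzML-like XML index whose binary arrays live in a
companion ``.ibd`` file.  This module writes *processed*-mode files
(one m/z array per pixel, which is what centroided DESI-MSI data are)
and reads both processed and continuous mode.  Profile-mode input is
rejected unless ``allow_profile=True`` — the whole downstream workflow
operates on centroided peak lists.

Study metadata (treatment, time point, acquisition order) is not an
imzML concept; it travels in a sidecar YAML manifest keyed by
section id (:func:`read_manifest` / :func:`write_manifest`).
"""

from __future__ import annotations

import hashlib
import os
import uuid as _uuid
import xml.etree.ElementTree as ET
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import yaml

from .core import Section, Spectrum

NS = "http://psi.hupo.org/ms/mzml"

# CV accessions used for reading/writing.
ACC_POSITION_X = "IMS:1000050"
ACC_POSITION_Y = "IMS:1000051"
ACC_OFFSET = "IMS:1000102"
ACC_LENGTH = "IMS:1000103"
ACC_ENCODED_LENGTH = "IMS:1000104"
ACC_CONTINUOUS = "IMS:1000030"
ACC_PROCESSED = "IMS:1000031"
ACC_MZ_ARRAY = "MS:1000514"
ACC_INTENSITY_ARRAY = "MS:1000515"
ACC_FLOAT32 = "MS:1000521"
ACC_FLOAT64 = "MS:1000523"
ACC_CENTROID = "MS:1000127"
ACC_PROFILE = "MS:1000128"
ACC_NO_COMPRESSION = "MS:1000576"

_DTYPES = {ACC_FLOAT32: np.dtype("<f4"), ACC_FLOAT64: np.dtype("<f8")}


class ImzmlError(ValueError):
    """Malformed or unsupported imzML input."""


def _cv(parent, accession, name, value="", unit=None):
    attrs = {
        "cvRef": accession.split(":")[0],
        "accession": accession,
        "name": name,
        "value": str(value),
    }
    ET.SubElement(parent, "cvParam", attrs)


def write_imzml(section: Section, path) -> None:
    """Write a Section as processed-mode imzML (``path`` + sibling ``.ibd``).

    m/z arrays are stored as 64-bit floats, intensities as 32-bit floats,
    uncompressed, per the imzML 1.1 external-binary convention.
    """
    if section.n_pixels == 0:
        raise ValueError(f"refusing to write empty section {section.section_id!r}")
    path = Path(path)
    ibd_path = path.with_suffix(".ibd")

    file_uuid = _uuid.uuid5(_uuid.NAMESPACE_URL, f"daphmsi:{section.section_id}")
    records = []  # (coord, mz_offset, n, mz_enc, int_offset, int_enc)
    with open(ibd_path, "wb") as ibd:
        ibd.write(file_uuid.bytes)
        offset = 16
        for coord, spec in section.items():
            mz_bytes = spec.mz.astype("<f8").tobytes()
            int_bytes = spec.intensity.astype("<f4").tobytes()
            records.append((coord, offset, len(spec), len(mz_bytes),
                            offset + len(mz_bytes), len(int_bytes)))
            ibd.write(mz_bytes)
            ibd.write(int_bytes)
            offset += len(mz_bytes) + len(int_bytes)
    with open(ibd_path, "rb") as fh:
        sha1 = hashlib.sha1(fh.read()).hexdigest()

    root = ET.Element("mzML", {"xmlns": NS, "version": "1.1"})
    cv_list = ET.SubElement(root, "cvList", {"count": "3"})
    for cid, uri in [
        ("MS", "https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"),
        ("UO", "http://obo.cvs.sourceforge.net/obo/obo/ontology/phenotype/unit.obo"),
        ("IMS", "https://raw.githubusercontent.com/imzML/imzML/master/imagingMS.obo"),
    ]:
        ET.SubElement(cv_list, "cv", {"id": cid, "fullName": cid, "URI": uri})

    file_desc = ET.SubElement(root, "fileDescription")
    content = ET.SubElement(file_desc, "fileContent")
    _cv(content, ACC_PROCESSED, "processed")
    _cv(content, ACC_CENTROID, "centroid spectrum")
    _cv(content, "IMS:1000080", "universally unique identifier",
        "{" + str(file_uuid) + "}")
    _cv(content, "IMS:1000091", "ibd SHA-1", sha1)

    rpg_list = ET.SubElement(root, "referenceableParamGroupList", {"count": "2"})
    mz_group = ET.SubElement(rpg_list, "referenceableParamGroup", {"id": "mzArray"})
    _cv(mz_group, ACC_MZ_ARRAY, "m/z array")
    _cv(mz_group, ACC_FLOAT64, "64-bit float")
    _cv(mz_group, ACC_NO_COMPRESSION, "no compression")
    _cv(mz_group, "IMS:1000101", "external data", "true")
    int_group = ET.SubElement(rpg_list, "referenceableParamGroup",
                              {"id": "intensityArray"})
    _cv(int_group, ACC_INTENSITY_ARRAY, "intensity array")
    _cv(int_group, ACC_FLOAT32, "32-bit float")
    _cv(int_group, ACC_NO_COMPRESSION, "no compression")
    _cv(int_group, "IMS:1000101", "external data", "true")

    n_rows, n_cols = section.grid_shape
    scan_settings_list = ET.SubElement(root, "scanSettingsList", {"count": "1"})
    scan_settings = ET.SubElement(scan_settings_list, "scanSettings",
                                  {"id": "scansettings1"})
    _cv(scan_settings, "IMS:1000042", "max count of pixel x", n_cols)
    _cv(scan_settings, "IMS:1000043", "max count of pixel y", n_rows)
    _cv(scan_settings, "IMS:1000046", "pixel size", section.pixel_size_um)

    run = ET.SubElement(root, "run", {"id": section.section_id})
    spectrum_list = ET.SubElement(run, "spectrumList",
                                  {"count": str(len(records)),
                                   "defaultDataProcessingRef": "dp1"})
    for i, (coord, mz_off, n, mz_enc, int_off, int_enc) in enumerate(records):
        x, y = coord
        spectrum = ET.SubElement(
            spectrum_list, "spectrum",
            {"id": f"spectrum={i + 1}", "index": str(i), "defaultArrayLength": str(n)},
        )
        _cv(spectrum, ACC_CENTROID, "centroid spectrum")
        scan_list = ET.SubElement(spectrum, "scanList", {"count": "1"})
        scan = ET.SubElement(scan_list, "scan")
        _cv(scan, ACC_POSITION_X, "position x", x)
        _cv(scan, ACC_POSITION_Y, "position y", y)
        bda_list = ET.SubElement(spectrum, "binaryDataArrayList", {"count": "2"})
        for ref, off, enc in [("mzArray", mz_off, mz_enc),
                              ("intensityArray", int_off, int_enc)]:
            bda = ET.SubElement(bda_list, "binaryDataArray", {"encodedLength": "0"})
            ET.SubElement(bda, "referenceableParamGroupRef", {"ref": ref})
            _cv(bda, ACC_OFFSET, "external offset", off)
            _cv(bda, ACC_LENGTH, "external array length", n)
            _cv(bda, ACC_ENCODED_LENGTH, "external encoded length", enc)
            ET.SubElement(bda, "binary")
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, xml_declaration=True, encoding="utf-8")


def _collect_cv(elem, groups) -> Dict[str, str]:
    """Accession -> value for an element, resolving param-group refs."""
    params: Dict[str, str] = {}
    for ref in elem.findall(f"{{{NS}}}referenceableParamGroupRef"):
        params.update(groups.get(ref.get("ref"), {}))
    for cv in elem.findall(f"{{{NS}}}cvParam"):
        params[cv.get("accession")] = cv.get("value", "")
    return params


def read_imzml(path, allow_profile: bool = False) -> Section:
    """Read an imzML file (+ sibling ``.ibd``) into a Section.

    Handles processed and continuous binary modes.  Raises
    :class:`ImzmlError` for a missing binary companion, malformed XML,
    profile-mode data (unless ``allow_profile``), or out-of-grid pixels
    (the error names the offending pixel).
    """
    path = Path(path)
    ibd_path = path.with_suffix(".ibd")
    if not ibd_path.exists():
        raise ImzmlError(f"missing binary companion file {ibd_path}")
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise ImzmlError(f"malformed imzML XML in {path}: {exc}") from exc

    groups: Dict[str, Dict[str, str]] = {}
    for group in root.iter(f"{{{NS}}}referenceableParamGroup"):
        groups[group.get("id")] = {
            cv.get("accession"): cv.get("value", "")
            for cv in group.findall(f"{{{NS}}}cvParam")
        }

    content = root.find(f"{{{NS}}}fileDescription/{{{NS}}}fileContent")
    content_params = _collect_cv(content, groups) if content is not None else {}
    continuous = ACC_CONTINUOUS in content_params
    if ACC_PROFILE in content_params and not allow_profile:
        raise ImzmlError(
            f"{path} contains profile-mode spectra; this workflow requires "
            "centroided data (pass allow_profile=True to override)"
        )

    n_rows = n_cols = None
    pixel_size = None
    for cv in root.iter(f"{{{NS}}}cvParam"):
        acc = cv.get("accession")
        if acc == "IMS:1000042":
            n_cols = int(cv.get("value"))
        elif acc == "IMS:1000043":
            n_rows = int(cv.get("value"))
        elif acc == "IMS:1000046":
            pixel_size = float(cv.get("value"))

    spectra: Dict[tuple, Spectrum] = {}
    shared_mz: Optional[np.ndarray] = None
    with open(ibd_path, "rb") as ibd:
        for spectrum in root.iter(f"{{{NS}}}spectrum"):
            sparams = _collect_cv(spectrum, groups)
            if ACC_PROFILE in sparams and not allow_profile:
                raise ImzmlError(f"profile-mode spectrum in {path}")
            scan = spectrum.find(f"{{{NS}}}scanList/{{{NS}}}scan")
            scan_params = _collect_cv(scan, groups)
            try:
                x = int(scan_params[ACC_POSITION_X])
                y = int(scan_params[ACC_POSITION_Y])
            except KeyError as exc:
                raise ImzmlError(
                    f"spectrum {spectrum.get('id')!r} lacks pixel coordinates"
                ) from exc
            arrays = {}
            for bda in spectrum.find(f"{{{NS}}}binaryDataArrayList").findall(
                    f"{{{NS}}}binaryDataArray"):
                params = _collect_cv(bda, groups)
                dtype = None
                for acc, dt in _DTYPES.items():
                    if acc in params:
                        dtype = dt
                if dtype is None:
                    raise ImzmlError("binary array with unknown data type")
                offset = int(params[ACC_OFFSET])
                length = int(params[ACC_LENGTH])
                ibd.seek(offset)
                data = np.frombuffer(ibd.read(length * dtype.itemsize), dtype=dtype)
                if data.size != length:
                    raise ImzmlError(
                        f"truncated ibd read for pixel ({x}, {y}) in {ibd_path}"
                    )
                kind = "mz" if ACC_MZ_ARRAY in params else "intensity"
                arrays[kind] = data.astype(np.float64)
            if continuous:
                if "mz" in arrays:
                    shared_mz = arrays["mz"]
                mz = shared_mz
            else:
                mz = arrays.get("mz")
            if mz is None or "intensity" not in arrays:
                raise ImzmlError(f"pixel ({x}, {y}) lacks m/z or intensity array")
            if n_rows is not None and n_cols is not None:
                if not (1 <= x <= n_cols and 1 <= y <= n_rows):
                    raise ImzmlError(
                        f"pixel ({x}, {y}) outside declared grid "
                        f"{n_cols} x {n_rows} in {path}"
                    )
            spectra[(x, y)] = Spectrum(mz, arrays["intensity"])

    if n_rows is None or n_cols is None:
        n_cols = max(x for x, _ in spectra)
        n_rows = max(y for _, y in spectra)
    return Section(
        section_id=path.stem,
        spectra=spectra,
        grid_shape=(n_rows, n_cols),
        pixel_size_um=pixel_size if pixel_size else 35.0,
    )


# ---------------------------------------------------------------------------
# Sidecar study manifest

MANIFEST_FIELDS = ("section_id", "file", "subject_id", "time_point_h",
                   "treatment", "acquisition_index", "is_blank")


def write_manifest(entries: Sequence[dict], path) -> None:
    """Write the study manifest (one record per imzML file) as YAML."""
    cleaned = []
    for e in entries:
        missing = set(MANIFEST_FIELDS) - set(e)
        if missing:
            raise ValueError(f"manifest entry missing fields: {sorted(missing)}")
        cleaned.append({k: e[k] for k in MANIFEST_FIELDS})
    with open(path, "w") as fh:
        yaml.safe_dump({"sections": cleaned}, fh, sort_keys=False)


def read_manifest(path) -> List[dict]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return list(doc["sections"])


def load_section(entry: dict, base_dir=None) -> Section:
    """Read the imzML file named by a manifest entry and attach its
    study metadata."""
    file_path = Path(entry["file"])
    if base_dir is not None and not file_path.is_absolute():
        file_path = Path(base_dir) / file_path
    section = read_imzml(file_path)
    section.section_id = entry["section_id"]
    section.subject_id = entry.get("subject_id")
    section.is_blank = bool(entry.get("is_blank", False))
    if not section.is_blank:
        section.time_point_h = entry.get("time_point_h")
        section.treatment = entry.get("treatment")
    section.acquisition_index = int(entry.get("acquisition_index", 0))
    return section
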