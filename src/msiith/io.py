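"""Readers and writers: internal HDF5 cohort container, continuous-mode
imzML ingestion, and the clinical metadata CSV.

The internal container stores the mass axis once, one dense intensity matrix
per ROI, and the clinical table as string datasets — round-trips are
bit-identical.  The imzML support is a deliberately small subset of the
standard (continuous mode, 64-bit little-endian arrays, no compression),
enough to ingest exported MALDI peptide images and to build test fixtures.
"""

from __future__ import annotations

import csv
import logging
import math
import os
import re
import struct
import uuid
import xml.etree.ElementTree as ET
from pathlib import Path
from typing import List, Optional

import h5py
import numpy as np

from .datatypes import ClinicalRecord, CohortDataset, MassAxis, ROIDataset

logger = logging.getLogger("msiith")

CLINICAL_COLUMNS = [
    "patient_id",
    "outcome",
    "nodal",
    "n_stage",
    "t_stage",
    "stage",
    "grade",
    "er",
    "pr",
    "tils_percent",
]


# --------------------------------------------------------------------------
# Clinical metadata
# --------------------------------------------------------------------------


def read_clinical_table(path) -> List[ClinicalRecord]:
    """Parse the clinical CSV into validated records.

    The file must carry a header with the documented column names
    (``tils_percent`` may be empty).  Validation errors name the offending
    row and value.
    """
    path = Path(path)
    records: List[ClinicalRecord] = []
    seen = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = [c for c in CLINICAL_COLUMNS[:-1] if c not in (reader.fieldnames or [])]
        if missing:
            raise ValueError(f"clinical table missing required columns: {missing}")
        for i, row in enumerate(reader, start=2):  # header is line 1
            tils_raw = (row.get("tils_percent") or "").strip()
            tils = float(tils_raw) if tils_raw else None
            try:
                rec = ClinicalRecord(
                    patient_id=row["patient_id"].strip(),
                    outcome=row["outcome"].strip(),
                    nodal=row["nodal"].strip(),
                    n_stage=row["n_stage"].strip(),
                    t_stage=row["t_stage"].strip(),
                    stage=row["stage"].strip(),
                    grade=row["grade"].strip(),
                    er=row["er"].strip(),
                    pr=row["pr"].strip(),
                    tils_percent=tils,
                )
            except ValueError as exc:
                raise ValueError(f"row {i}: {exc}") from exc
            if rec.patient_id in seen:
                raise ValueError(f"row {i}: duplicate patient_id {rec.patient_id!r}")
            seen.add(rec.patient_id)
            records.append(rec)
    return records


def write_clinical_table(records, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CLINICAL_COLUMNS)
        for rec in records:
            tils = "" if rec.tils_percent is None else repr(rec.tils_percent)
            writer.writerow(
                [
                    rec.patient_id,
                    rec.outcome,
                    rec.nodal,
                    rec.n_stage,
                    rec.t_stage,
                    rec.stage,
                    rec.grade,
                    rec.er,
                    rec.pr,
                    tils,
                ]
            )


def example_clinical_path() -> Path:
    """Path of the bundled 59-patient example clinical table."""
    return Path(__file__).parent / "data" / "example_clinical.csv"


# --------------------------------------------------------------------------
# Internal HDF5 container
# --------------------------------------------------------------------------


def write_cohort(cohort: CohortDataset, path, overwrite: bool = False) -> None:
    """Serialize a cohort to a single HDF5 container."""
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace it")
    with h5py.File(path, "w") as f:
        f.attrs["format"] = "msiith-cohort"
        f.attrs["version"] = 1
        f.create_dataset("axis", data=cohort.axis.values)
        grp = f.create_group("rois")
        for roi in cohort.rois:
            g = grp.create_group(roi.roi_id)
            g.attrs["patient_id"] = roi.patient_id
            g.create_dataset("coordinates", data=roi.coordinates)
            g.create_dataset(
                "intensities",
                data=roi.intensities,
                chunks=(min(256, roi.n_pixels), roi.intensities.shape[1]),
            )
        meta = f.create_group("metadata")
        rows = []
        for rec in cohort.metadata:
            tils = "" if rec.tils_percent is None else repr(rec.tils_percent)
            rows.append(
                [
                    rec.patient_id,
                    rec.outcome,
                    rec.nodal,
                    rec.n_stage,
                    rec.t_stage,
                    rec.stage,
                    rec.grade,
                    rec.er,
                    rec.pr,
                    tils,
                ]
            )
        meta.create_dataset(
            "clinical", data=np.array(rows, dtype=h5py.string_dtype("utf-8"))
        )


def _read_internal(path) -> CohortDataset:
    with h5py.File(path, "r") as f:
        if f.attrs.get("format") != "msiith-cohort":
            raise ValueError(f"{path} is not an msiith cohort container")
        axis = MassAxis(f["axis"][:])
        rois = []
        for roi_id in sorted(f["rois"]):
            g = f["rois"][roi_id]
            roi = ROIDataset(
                roi_id=roi_id,
                patient_id=g.attrs["patient_id"],
                coordinates=g["coordinates"][:],
                intensities=g["intensities"][:],
                axis=axis,
            )
            if roi.axis != axis:
                raise ValueError(f"ROI {roi_id!r} axis mismatch in container")
            rois.append(roi.sorted_by_position())
        records = []
        for row in f["metadata"]["clinical"][:]:
            vals = [v.decode() if isinstance(v, bytes) else str(v) for v in row]
            tils = float(vals[9]) if vals[9] else None
            records.append(ClinicalRecord(*vals[:9], tils_percent=tils))
    return CohortDataset(rois, records)


def read_cohort(path, format: str = "internal") -> CohortDataset:
    """Load a cohort from the internal container or an imzML directory.

    For ``format="imzml"`` the path is a directory with one ``.imzML`` file
    per ROI (named ``<roi_id>.imzML``) plus a ``clinical.csv`` metadata
    table; ROI patient assignment comes from a ``rois.csv`` mapping file
    (columns ``roi_id,patient_id``) or, absent that, roi_id == patient_id.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "internal":
        return _read_internal(path)
    if format == "imzml":
        return _read_imzml_dir(path)
    raise ValueError(f"unknown cohort format {format!r}")


# --------------------------------------------------------------------------
# imzML (continuous mode, uncompressed 64-bit arrays)
# --------------------------------------------------------------------------

_NS = "{http://psi.hupo.org/ms/mzml}"

# accession -> meaning used by the reader
_ACC_POS_X = "IMS:1000050"
_ACC_POS_Y = "IMS:1000051"
_ACC_OFFSET = "IMS:1000102"
_ACC_LENGTH = "IMS:1000103"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INT_ARRAY = "MS:1000515"


def _cv_value(elem, accession) -> Optional[str]:
    for cv in elem.iter(_NS + "cvParam"):
        if cv.get("accession") == accession:
            return cv.get("value")
    return None


def read_imzml(imzml_path, roi_id=None, patient_id=None) -> ROIDataset:
    """Read one continuous-mode imzML/ibd pair into an ROI dataset.

    Coordinates in imzML are 1-based; they are shifted to the package's
    0-based grid convention.
    """
    imzml_path = Path(imzml_path)
    ibd_path = imzml_path.with_suffix(".ibd")
    if not ibd_path.exists():
        raise FileNotFoundError(f"missing binary data file {ibd_path}")
    tree = ET.parse(imzml_path)
    root = tree.getroot()
    spectra = list(root.iter(_NS + "spectrum"))
    if not spectra:
        raise ValueError(f"no spectra in {imzml_path}")

    with open(ibd_path, "rb") as fh:
        ibd = fh.read()

    def read_array(offset, length):
        return np.frombuffer(ibd, dtype="<f8", count=length, offset=offset)

    axis_values = None
    coords = []
    rows = []
    for sp in spectra:
        x = y = None
        for scan in sp.iter(_NS + "scan"):
            sx = _cv_value(scan, _ACC_POS_X)
            sy = _cv_value(scan, _ACC_POS_Y)
            if sx is not None:
                x = int(sx)
            if sy is not None:
                y = int(sy)
        if x is None or y is None:
            raise ValueError("spectrum without position cvParams")
        mz_arr = int_arr = None
        for bda in sp.iter(_NS + "binaryDataArray"):
            offset = _cv_value(bda, _ACC_OFFSET)
            length = _cv_value(bda, _ACC_LENGTH)
            ref = bda.find(_NS + "referenceableParamGroupRef")
            kind = ref.get("ref") if ref is not None else None
            if kind is None:
                kind = "mzArray" if _cv_value(bda, _ACC_MZ_ARRAY) else "intensityArray"
            arr = read_array(int(offset), int(length))
            if kind == "mzArray":
                mz_arr = arr
            else:
                int_arr = arr
        if int_arr is None or mz_arr is None:
            raise ValueError("spectrum missing m/z or intensity array")
        if axis_values is None:
            axis_values = mz_arr
        coords.append((x - 1, y - 1))
        rows.append(int_arr)

    rid = roi_id if roi_id is not None else imzml_path.stem
    pid = patient_id if patient_id is not None else rid
    roi = ROIDataset(
        roi_id=rid,
        patient_id=pid,
        coordinates=np.array(coords, dtype=np.int64),
        intensities=np.vstack(rows),
        axis=MassAxis(axis_values),
    )
    return roi.sorted_by_position()


def write_imzml(roi: ROIDataset, imzml_path) -> None:
    """Write an ROI as a continuous-mode imzML/ibd pair (test/export helper)."""
    imzml_path = Path(imzml_path)
    ibd_path = imzml_path.with_suffix(".ibd")
    file_uuid = uuid.uuid4()

    mz_bytes = roi.axis.values.astype("<f8").tobytes()
    with open(ibd_path, "wb") as fh:
        fh.write(file_uuid.bytes)
        mz_offset = fh.tell()
        fh.write(mz_bytes)
        int_offsets = []
        for row in roi.intensities:
            int_offsets.append(fh.tell())
            fh.write(row.astype("<f8").tobytes())

    C = len(roi.axis)
    lines = [
        '<?xml version="1.0" encoding="ISO-8859-1"?>',
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1">',
        "  <referenceableParamGroupList count=\"2\">",
        '    <referenceableParamGroup id="mzArray">',
        '      <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value=""/>',
        '      <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>',
        "    </referenceableParamGroup>",
        '    <referenceableParamGroup id="intensityArray">',
        '      <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value=""/>',
        '      <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>',
        "    </referenceableParamGroup>",
        "  </referenceableParamGroupList>",
        "  <fileDescription><fileContent>",
        f'    <cvParam cvRef="IMS" accession="IMS:1000030" name="continuous" value=""/>',
        f'    <cvParam cvRef="IMS" accession="IMS:1000080" name="universally unique identifier" value="{{{file_uuid}}}"/>',
        "  </fileContent></fileDescription>",
        f'  <run id="{roi.roi_id}">',
        f'    <spectrumList count="{roi.n_pixels}">',
    ]
    for i, ((x, y), off) in enumerate(zip(roi.coordinates, _offsets_of(roi, mz_offset))):
        lines += [
            f'      <spectrum id="spectrum={i}" index="{i}">',
            "        <scanList count=\"1\"><scan>",
            f'          <cvParam cvRef="IMS" accession="IMS:1000050" name="position x" value="{int(x) + 1}"/>',
            f'          <cvParam cvRef="IMS" accession="IMS:1000051" name="position y" value="{int(y) + 1}"/>',
            "        </scan></scanList>",
            '        <binaryDataArrayList count="2">',
            '          <binaryDataArray encodedLength="0">',
            '            <referenceableParamGroupRef ref="mzArray"/>',
            f'            <cvParam cvRef="IMS" accession="IMS:1000102" name="external offset" value="{mz_offset}"/>',
            f'            <cvParam cvRef="IMS" accession="IMS:1000103" name="external array length" value="{C}"/>',
            "            <binary/>",
            "          </binaryDataArray>",
            '          <binaryDataArray encodedLength="0">',
            '            <referenceableParamGroupRef ref="intensityArray"/>',
            f'            <cvParam cvRef="IMS" accession="IMS:1000102" name="external offset" value="{off}"/>',
            f'            <cvParam cvRef="IMS" accession="IMS:1000103" name="external array length" value="{C}"/>',
            "            <binary/>",
            "          </binaryDataArray>",
            "        </binaryDataArrayList>",
            "      </spectrum>",
        ]
    lines += ["    </spectrumList>", "  </run>", "</mzML>"]
    imzml_path.write_text("\n".join(lines))


def _offsets_of(roi: ROIDataset, mz_offset: int):
    C = len(roi.axis)
    start = mz_offset + 8 * C
    return [start + i * 8 * C for i in range(roi.n_pixels)]


def _read_imzml_dir(path: Path) -> CohortDataset:
    files = sorted(path.glob("*.imzML")) + sorted(path.glob("*.imzml"))
    if not files:
        raise ValueError(f"no ROIs found in {path}")
    clinical = path / "clinical.csv"
    if not clinical.exists():
        raise FileNotFoundError(f"missing clinical metadata table {clinical}")
    records = read_clinical_table(clinical)
    mapping = {}
    roi_map = path / "rois.csv"
    if roi_map.exists():
        with open(roi_map, newline="") as fh:
            for row in csv.DictReader(fh):
                mapping[row["roi_id"].strip()] = row["patient_id"].strip()
    known = {r.patient_id for r in records}
    rois = []
    for f in files:
        rid = f.stem
        pid = mapping.get(rid, rid)
        if pid not in known:
            raise ValueError(f"no clinical metadata for ROI {rid!r} (patient {pid!r})")
        rois.append(read_imzml(f, roi_id=rid, patient_id=pid))
    axis = rois[0].axis
    for roi in rois:
        if roi.axis != axis:
            raise ValueError(f"ROI {roi.roi_id!r} axis differs from cohort axis")
    return CohortDataset(rois, records)
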