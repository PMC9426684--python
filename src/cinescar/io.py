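"""Study serialisation: NIfTI volumes + JSON sidecar, optional DICOM export.

A study is written as two NIfTI files (cine frames stacked along the third
axis; LGE as a single slice), one NIfTI label volume per modality, and a
JSON sidecar carrying trigger times, pixel spacing, the binary label and
the true misalignment parameters.  ``export_dicom`` writes one secondary-
capture DICOM file per cine frame with TriggerTime and PixelSpacing
populated.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import nibabel as nib
import numpy as np

from .phantom import CineSequence, LgeRecord, PhantomConfig, Study
from .transforms import AffineParams


def _nifti(data: np.ndarray, spacing: tuple[float, float]) -> nib.Nifti1Image:
    affine = np.diag([spacing[0], spacing[1], 1.0, 1.0])
    return nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)


def save_study(study: Study, out_dir) -> Path:
    """Write one study to ``out_dir``; returns the sidecar path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spacing = study.cine.pixel_spacing_mm
    cine = np.stack(study.cine.frames, axis=-1)
    masks = np.stack(study.masks, axis=-1)
    nib.save(_nifti(cine, spacing), out / "cine.nii.gz")
    nib.save(_nifti(masks, spacing), out / "cine_masks.nii.gz")
    nib.save(_nifti(study.lge.image[..., None], spacing), out / "lge.nii.gz")
    nib.save(_nifti(study.lge.true_mask[..., None], spacing), out / "lge_mask.nii.gz")
    sidecar = {
        "subject_id": study.cine.subject_id,
        "slice_id": study.cine.slice_id,
        "trigger_times_ms": list(map(float, study.cine.trigger_times_ms)),
        "pixel_spacing_mm": list(spacing),
        "lge_trigger_time_ms": study.lge.trigger_time_ms,
        "label": int(study.label),
        "true_misalignment": asdict(study.lge.true_misalignment),
        "config": {
            k: (asdict(v) if isinstance(v, AffineParams) else v)
            for k, v in asdict(study.config).items()
        },
    }
    path = out / "study.json"
    path.write_text(json.dumps(sidecar, indent=2))
    return path


def load_study(study_dir) -> Study:
    """Read a study written by :func:`save_study`."""
    d = Path(study_dir)
    meta = json.loads((d / "study.json").read_text())
    cine_vol = np.asarray(nib.load(d / "cine.nii.gz").dataobj)
    mask_vol = np.asarray(nib.load(d / "cine_masks.nii.gz").dataobj)
    lge_img = np.asarray(nib.load(d / "lge.nii.gz").dataobj)[..., 0]
    lge_mask = np.asarray(nib.load(d / "lge_mask.nii.gz").dataobj)[..., 0].astype(np.uint8)
    spacing = tuple(meta["pixel_spacing_mm"])
    cine = CineSequence(
        frames=[cine_vol[..., t].astype(float) for t in range(cine_vol.shape[-1])],
        trigger_times_ms=meta["trigger_times_ms"],
        pixel_spacing_mm=spacing,
        subject_id=meta["subject_id"],
        slice_id=meta["slice_id"],
    )
    masks = [mask_vol[..., t].astype(np.uint8) for t in range(mask_vol.shape[-1])]
    mis = meta["true_misalignment"]
    lge = LgeRecord(
        image=lge_img.astype(float),
        trigger_time_ms=meta["lge_trigger_time_ms"],
        true_mask=lge_mask,
        true_misalignment=AffineParams(
            translation=tuple(mis["translation"]),
            rotation_deg=mis["rotation_deg"],
            scale=tuple(mis["scale"]),
            shear=mis["shear"],
        ),
    )
    cfg_raw = dict(meta["config"])
    cfg_raw["lge_misalignment"] = AffineParams(
        translation=tuple(cfg_raw["lge_misalignment"]["translation"]),
        rotation_deg=cfg_raw["lge_misalignment"]["rotation_deg"],
        scale=tuple(cfg_raw["lge_misalignment"]["scale"]),
        shear=cfg_raw["lge_misalignment"]["shear"],
    )
    cfg_raw["scar_sector_deg"] = tuple(cfg_raw["scar_sector_deg"])
    config = PhantomConfig(**cfg_raw)
    return Study(cine=cine, masks=masks, lge=lge, label=meta["label"], config=config)


def export_dicom(study: Study, out_dir) -> list:
    """Write one secondary-capture DICOM per cine frame (TriggerTime set)."""
    import pydicom
    from pydicom.dataset import FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid()
    paths = []
    for t, (frame, tt) in enumerate(zip(study.cine.frames, study.cine.trigger_times_ms)):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = pydicom.Dataset()
        ds.file_meta = meta
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = series_uid
        ds.PatientID = study.cine.subject_id
        ds.Modality = "MR"
        ds.TriggerTime = float(tt)
        ds.PixelSpacing = [float(s) for s in study.cine.pixel_spacing_mm]
        ds.InstanceNumber = t + 1
        arr = np.clip(frame * 1000.0, 0, 65535).astype(np.uint16)
        ds.Rows, ds.Columns = arr.shape
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.PixelData = arr.tobytes()
        path = out / f"frame{t:02d}.dcm"
        ds.save_as(path, enforce_file_format=True)
        paths.append(path)
    return paths
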