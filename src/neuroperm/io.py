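"""Plain-text and NIfTI I/O for study tables, time courses and maps."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .connectivity import FcMatrix, TimecourseMatrix
from .simulate import SubjectRecord

__all__ = [
    "write_participants_tsv",
    "read_participants_tsv",
    "write_timecourse_tsv",
    "read_timecourse_tsv",
    "write_fc_tsv",
    "read_fc_tsv",
    "save_nifti",
    "write_json",
]


def write_participants_tsv(subjects: Sequence[SubjectRecord], path) -> None:
    df = pd.DataFrame(
        [(s.subject_id, s.genotype, s.sex, s.litter_id, s.timepoint)
         for s in subjects],
        columns=["subject_id", "genotype", "sex", "litter_id", "timepoint"])
    df.to_csv(path, sep="\t", index=False)


def read_participants_tsv(path) -> list[SubjectRecord]:
    df = pd.read_csv(path, sep="\t")
    return [SubjectRecord(r.subject_id, r.genotype, r.sex, r.litter_id,
                          r.timepoint) for r in df.itertuples()]


def write_timecourse_tsv(tc: TimecourseMatrix, path) -> None:
    """One session per file: T rows x R columns, header = ROI names."""
    pd.DataFrame(tc.values, columns=tc.roi_names).to_csv(
        path, sep="\t", index=False, float_format="%.10g")


def read_timecourse_tsv(path, **meta) -> TimecourseMatrix:
    df = pd.read_csv(path, sep="\t")
    return TimecourseMatrix(values=df.to_numpy(dtype=float),
                            roi_names=list(df.columns), **meta)


def write_fc_tsv(fc: FcMatrix, path) -> None:
    pd.DataFrame(fc.z, index=fc.roi_names, columns=fc.roi_names).to_csv(
        path, sep="\t", float_format="%.10g")


def read_fc_tsv(path, **meta) -> FcMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return FcMatrix(z=df.to_numpy(dtype=float), roi_names=list(df.columns),
                    **meta)


def read_lookup_tsv(path) -> dict[int, str]:
    """Atlas label lookup: TSV with 'label' and 'name' columns."""
    df = pd.read_csv(path, sep="\t")
    return {int(r.label): str(r.name) for r in df.itertuples()}


def save_nifti(values: np.ndarray, path, voxel_size: float = 0.15) -> None:
    """Write a 3D array as NIfTI with isotropic voxel size (mm)."""
    import nibabel as nib

    affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(values, dtype=np.float32), affine),
             str(path))


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True,
                                     default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, frozenset):
        return sorted(o)
    raise TypeError(f"not JSON serialisable: {type(o)}")
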