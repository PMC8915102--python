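"""Cohort persistence: NIfTI volumes plus a CSV manifest.

A cohort on disk is one directory holding, per case, nine DW volumes, one
T2W volume and the two binary masks as ``.nii.gz``, indexed by a single
``manifest.csv`` with columns ``case_id, label, psa``, one path column per
fixed volume and one ``dw_<b>`` column per b-value.  ``write_cohort`` /
``read_cohort`` round-trip losslessly (volumes are stored as float64, masks
as uint8).
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .phantom import ProstateCase

__all__ = ["write_cohort", "read_cohort"]

MANIFEST_NAME = "manifest.csv"


def _b_tag(b: float) -> str:
    return str(int(b)) if float(b).is_integer() else str(b)


def _save(volume: np.ndarray, path: Path, spacing=(1.0, 1.0, 1.0)) -> None:
    affine = np.diag(list(spacing) + [1.0])
    if volume.dtype == bool:
        img = nib.Nifti1Image(volume.astype(np.uint8), affine)
    else:
        img = nib.Nifti1Image(np.asarray(volume, dtype=np.float64), affine)
    nib.save(img, str(path))


def write_cohort(cases: list[ProstateCase], out_dir: str | Path) -> Path:
    """Write all volumes and the manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ids = [c.case_id for c in cases]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate case_ids: {dupes}")

    rows = []
    for case in cases:
        row: dict[str, object] = {
            "case_id": case.case_id,
            "label": case.label,
            "psa": case.psa,
        }
        named = {
            "t2w": case.t2w_volume,
            "prostate_mask": case.prostate_mask,
            "lesion_mask": case.lesion_mask,
        }
        for b in sorted(case.dw_volumes):
            named[f"dw_{_b_tag(b)}"] = case.dw_volumes[b]
        for key, vol in named.items():
            fname = f"{case.case_id}_{key}.nii.gz"
            _save(vol, out_dir / fname)
            row[key] = fname
        rows.append(row)

    manifest = out_dir / MANIFEST_NAME
    columns = ["case_id", "label", "psa"]
    if rows:
        columns += [k for k in rows[0] if k not in columns]
    pd.DataFrame(rows, columns=columns).to_csv(manifest, index=False)
    return manifest


def read_cohort(manifest_path: str | Path) -> list[ProstateCase]:
    """Load a cohort written by :func:`write_cohort`."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    df = pd.read_csv(manifest_path)
    cases = []
    for _, row in df.iterrows():
        load = lambda key: np.asanyarray(nib.load(str(base / row[key])).dataobj)
        dw = {
            float(col.split("_", 1)[1]): load(col).astype(float)
            for col in df.columns
            if col.startswith("dw_")
        }
        case = ProstateCase(
            case_id=str(row["case_id"]),
            dw_volumes=dw,
            t2w_volume=load("t2w").astype(float),
            prostate_mask=load("prostate_mask").astype(bool),
            lesion_mask=load("lesion_mask").astype(bool),
            psa=float(row["psa"]),
            label=str(row["label"]),
        )
        case.validate()
        cases.append(case)
    return cases
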