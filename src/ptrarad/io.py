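"""On-disk interchange: NIfTI images/masks, CSV tables, JSON catalogs."""

from __future__ import annotations

import json
import os

import numpy as np

from . import deepfeat, handcrafted
from .phantom import SyntheticCohort


def write_cohort(cohort: SyntheticCohort, out_dir: str) -> None:
    """Write each case as NIfTI (image + both masks) plus a CSV outcome table."""
    import nibabel as nib

    os.makedirs(out_dir, exist_ok=True)
    for case in cohort.cases:
        affine = np.eye(4)
        nib.save(nib.Nifti1Image(case.image.astype(np.float32), affine),
                 os.path.join(out_dir, f"{case.case_id}_image.nii"))
        nib.save(nib.Nifti1Image(case.roi1.astype(np.uint8), affine),
                 os.path.join(out_dir, f"{case.case_id}_roi1.nii"))
        nib.save(nib.Nifti1Image(case.roi2.astype(np.uint8), affine),
                 os.path.join(out_dir, f"{case.case_id}_roi2.nii"))
    cohort.outcome_frame().to_csv(os.path.join(out_dir, "outcomes.csv"), index=False)


def write_feature_table(table, path_wide: str, path_long: str | None = None) -> None:
    """Wide (cases x features) and optional long (case, feature, value) CSVs."""
    table.to_csv(path_wide)
    if path_long:
        long = table.reset_index(names="case_id").melt(
            id_vars="case_id", var_name="feature", value_name="value"
        )
        long.to_csv(path_long, index=False)


def write_catalog(path: str) -> None:
    """Export the frozen 116 + 78 feature catalog as JSON."""
    payload = {
        "handcrafted": handcrafted.catalog(),
        "deep": deepfeat.deep_catalog(),
        "n_handcrafted": len(handcrafted.catalog()),
        "n_deep": len(deepfeat.deep_catalog()),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
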