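"""End-to-end study orchestration: cohort -> features -> selection -> signatures.

Ties the modules together the way the analysis is meant to run: preprocess
every case (histogram alignment against a pooled cohort reference, optional
resampling, X/XL/XH variants), extract 116 handcrafted + 78 deep features
per region, screen, consensus-cluster, LASSO-shrink, tune the five model
families, evaluate by LOOCV, and fuse the renal and perirenal signatures
with logistic regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import deepfeat, handcrafted, model, preprocess, select
from .phantom import SyntheticCohort

REGIONS = ("renal", "perirenal")  # ROI1, ROI2


@dataclass
class RegionResult:
    region: str
    screen: pd.DataFrame
    retained: list
    consensus: object
    lasso: object
    signature: object


@dataclass
class StudyResult:
    features: dict  # region -> cases x 194 DataFrame
    labels: np.ndarray
    regions: dict  # region -> RegionResult
    combined: object
    majority_accuracy: float = np.nan
    notes: dict = field(default_factory=dict)


def extract_features(
    cohort: SyntheticCohort,
    encoder,
    selected_channels=None,
    target_spacing: float | None = None,
    sigma_smooth: float = preprocess.DEFAULT_SMOOTH_SIGMA,
    align: bool = True,
) -> dict[str, pd.DataFrame]:
    """Per-region 194-column feature tables for a cohort.

    ``target_spacing=None`` keeps the native grid (scaled-down studies);
    pass 0.5 to resample per the standard protocol.  The trunk runs once per
    case and is reused for both regions.
    """
    reference = (
        preprocess.pooled_reference([c.image for c in cohort.cases]) if align else None
    )
    if selected_channels is None:
        selected_channels = deepfeat.select_information_dense_maps(encoder)
    tables = {r: {} for r in REGIONS}
    for case in cohort.cases:
        study, masks = preprocess.preprocess_case(
            case.image,
            {"renal": case.roi1, "perirenal": case.roi2},
            spacing=1.0,
            reference=reference,
            target_spacing=target_spacing if target_spacing else 1.0,
            sigma_smooth=sigma_smooth,
        )
        for region in REGIONS:
            hand, _ = handcrafted.extract_handcrafted(study, masks[region])
            deep, _ = deepfeat.extract_deep(encoder, study, masks[region], selected_channels)
            tables[region][case.case_id] = pd.concat([hand, deep])
    return {r: pd.DataFrame(tables[r]).T for r in REGIONS}


def select_features(
    table: pd.DataFrame,
    labels: np.ndarray,
    seed: int = 0,
    consensus_resamples: int = 500,
    search_resamples: int | None = None,
    compute_auc: bool = False,
    lasso_c_grid=None,
):
    """Screen -> consensus medoids -> LASSO; returns (screen, retained, consensus, lasso, order).

    If fewer than two features survive the P < 0.1 gate, the two smallest-P
    features are used so the funnel can proceed (flagged in the result).  If
    LASSO selects nothing, medoid features ordered by screen P value are
    used as the ranking.
    """
    z = select.zscore(table)
    screen = select.univariate_screen(z, labels, compute_auc=compute_auc)
    retained = screen.index[screen["retained"]].tolist()
    if len(retained) < 2:
        retained = screen["p"].nsmallest(2).index.tolist()
    cons = select.choose_k_and_medoids(
        z[retained],
        resamples=consensus_resamples,
        search_resamples=search_resamples,
        seed=seed,
    )
    medoids = cons.medoids
    if len(medoids) >= 2:
        lasso = select.lasso_select(z[medoids], labels, c_grid=lasso_c_grid, seed=seed)
        order = lasso.selected
    else:
        lasso = None
        order = medoids
    if not order:
        order = sorted(medoids, key=lambda f: screen.loc[f, "p"])
    return z, screen, retained, cons, lasso, order


def run_study(
    cohort: SyntheticCohort,
    encoder,
    seed: int = 0,
    grids: dict | None = None,
    target_spacing: float | None = None,
    consensus_resamples: int = 500,
    search_resamples: int | None = None,
    folds: int = 10,
    compute_auc: bool = False,
    features: dict | None = None,
    max_features: int | None = 8,
    n_boot: int = 2000,
    lasso_c_grid=None,
) -> StudyResult:
    """Full pipeline on one cohort; ``features`` may carry precomputed tables."""
    grids = grids or model.DEFAULT_GRIDS
    labels = cohort.labels
    if features is None:
        features = extract_features(cohort, encoder, target_spacing=target_spacing)
    regions = {}
    for region in REGIONS:
        z, screen, retained, cons, lasso, order = select_features(
            features[region],
            labels,
            seed=seed,
            consensus_resamples=consensus_resamples,
            search_resamples=search_resamples,
            compute_auc=compute_auc,
            lasso_c_grid=lasso_c_grid,
        )
        sig = model.build_signature(
            region,
            z,
            labels,
            order,
            folds=folds,
            seed=seed,
            grids=grids,
            max_features=max_features,
            n_boot=n_boot,
        )
        regions[region] = RegionResult(region, screen, retained, cons, lasso, sig)
    combined = model.combine_signatures(
        regions["renal"].signature.oof_scores,
        regions["perirenal"].signature.oof_scores,
        labels,
        names=("renal", "perirenal"),
        seed=seed,
    )
    return StudyResult(
        features=features,
        labels=labels,
        regions=regions,
        combined=combined,
        majority_accuracy=model.majority_class_loocv_accuracy(labels),
    )
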