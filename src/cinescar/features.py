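"""Assembly of the per-study feature table from cine studies.

Three engineered feature families are extracted from contrast-free cine
frames:

* optical-flow displacement maps over the canonical frame pairs, later
  compressed by PCA (:class:`cinescar.motion.FlowPCAFeaturizer`, fitted on
  the training split only);
* the rate-of-myocardial-area-change series (one value per frame pair);
* radiomics of the myocardium at the ED, ES and middle frames.

Rows are slice-location samples; the binary label is 1 when the LGE ground
truth contains scar.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .motion import FlowConfig, FlowPCAFeaturizer, area_change_series, displacement_maps
from .radiomics import RadiomicsConfig, extract_radiomics_row

FEATURE_SETS = ("flow", "area", "radiomics")


@dataclass
class StudyFeatures:
    """Raw per-study features before cohort-level PCA compression."""

    flow_maps: np.ndarray  # (n_pairs, H, W)
    area_rates: np.ndarray  # (n_pairs,)
    radiomics: dict
    label: int


def extract_study_features(
    study,
    flow_cfg: FlowConfig | None = None,
    radiomics_cfg: RadiomicsConfig | None = None,
) -> StudyFeatures:
    """Extract flow maps, area-change rates and radiomics for one study."""
    flow_cfg = flow_cfg or FlowConfig()
    maps = displacement_maps(study.cine, flow_cfg)
    area = area_change_series(
        study.masks,
        study.cine.trigger_times_ms,
        k=flow_cfg.skip_interval,
        spacing_mm=study.cine.pixel_spacing_mm,
    )
    rad = extract_radiomics_row(study.cine, study.masks, radiomics_cfg)
    return StudyFeatures(
        flow_maps=maps,
        area_rates=np.asarray(area.values),
        radiomics=rad,
        label=study.label,
    )


@dataclass
class FeatureTable:
    """Cohort feature matrix with named columns and binary labels."""

    table: pd.DataFrame
    labels: np.ndarray
    feature_sets: tuple

    @property
    def feature_names(self) -> list:
        return list(self.table.columns)


def build_feature_table(
    study_features: list,
    feature_sets=FEATURE_SETS,
    featurizer: FlowPCAFeaturizer | None = None,
    fit_indices=None,
) -> tuple[FeatureTable, FlowPCAFeaturizer | None]:
    """Assemble the cohort table from per-study features.

    ``feature_sets`` selects any subset of {"flow", "area", "radiomics"}
    (the three ablation configurations combine them).  When flow features
    are requested, the PCA featurizer is fitted on ``fit_indices`` (default:
    all rows — pass the training indices to avoid leakage) unless an
    already-fitted ``featurizer`` is supplied.
    """
    unknown = set(feature_sets) - set(FEATURE_SETS)
    if unknown:
        raise ValueError(f"unknown feature sets: {sorted(unknown)}")
    labels = np.array([sf.label for sf in study_features], dtype=int)
    columns: dict = {}
    if "flow" in feature_sets:
        maps = np.stack([sf.flow_maps for sf in study_features])
        if featurizer is None or not hasattr(featurizer, "pcas_"):
            featurizer = featurizer or FlowPCAFeaturizer()
            fit_maps = maps if fit_indices is None else maps[np.asarray(fit_indices)]
            featurizer.fit(fit_maps)
        rows = featurizer.transform(maps)
        for j, name in enumerate(featurizer.feature_names()):
            columns[name] = rows[:, j]
    if "area" in feature_sets:
        rates = np.stack([sf.area_rates for sf in study_features])
        for j in range(rates.shape[1]):
            columns[f"area_rate_{j}"] = rates[:, j]
    if "radiomics" in feature_sets:
        rad = pd.DataFrame([sf.radiomics for sf in study_features])
        for name in rad.columns:
            columns[name] = rad[name].to_numpy()
    table = pd.DataFrame(columns)
    return FeatureTable(table=table, labels=labels, feature_sets=tuple(feature_sets)), featurizer
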