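"""Suitability mapping and habitat-area accounting.

Fitted niche models are projected onto the harmonized predictor stack to
give a probability-of-occurrence surface per species, clipped to the 1-km
reef buffer. Habitat is called *suitable* where the predicted probability
exceeds 0.5; areas are tallied per subregion (cell counts x cell area) and
reported alongside the percent of the model extent that is suitable.

Species enter modelling only if their prevalence is at least 10 % of the
sites (rare-species models are unstable); an explicit exception list lets
conservation-priority species through the filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .brt_engine import BoostedTreesClassifier
from .predictor_stack import PredictorStack
from .raster import RasterGrid

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


@dataclass
class SuitabilityMap:
    """Probability surface and its > 0.5 suitable-habitat mask."""

    probability: RasterGrid
    species: str
    threshold: float = 0.5

    def suitable_mask(self, threshold: float | None = None) -> np.ndarray:
        """Boolean suitable-cell mask (strictly above the threshold)."""
        t = self.threshold if threshold is None else threshold
        p = self.probability.masked()
        return np.nan_to_num(p, nan=-1.0) > t


@dataclass
class AreaReport:
    species: str
    subregion_names: list[str]
    suitable_km2: list[float]
    extent_km2: list[float]
    unassigned_km2: float = 0.0

    @property
    def total_suitable_km2(self) -> float:
        return float(sum(self.suitable_km2)) + self.unassigned_km2

    @property
    def total_extent_km2(self) -> float:
        return float(sum(self.extent_km2))

    @property
    def percent_suitable(self) -> float:
        return 100.0 * self.total_suitable_km2 / self.total_extent_km2


def extend_labels_nearest(
    labels: RasterGrid, target_mask: np.ndarray
) -> RasterGrid:
    """Extend subregion labels to cover a target mask by nearest label.

    The reef buffer reaches ~1 km beyond the labelled reef band; buffer
    cells inherit the label of the nearest labelled cell so every modelled
    cell belongs to a subregion.
    """
    from scipy import ndimage

    valid = labels.valid_mask()
    if not valid.any():
        raise PipelineError("no labelled cells to extend from")
    _, (ri, ci) = ndimage.distance_transform_edt(
        ~valid, return_indices=True)
    out = np.full(labels.shape, labels.nodata)
    out[target_mask] = labels.data[ri[target_mask], ci[target_mask]]
    out[valid] = labels.data[valid]
    return labels.with_data(out)


def species_prevalence(
    sites: pd.DataFrame, species: Sequence[str]
) -> dict[str, float]:
    """Fraction of sites where each species is present."""
    return {s: float(sites[s].mean()) for s in species}


def filter_species(
    prevalence: Mapping[str, float],
    min_prevalence: float = 0.10,
    exceptions: Sequence[str] = (),
) -> list[str]:
    """Species retained for modelling.

    Keeps species whose prevalence (fraction of sites occupied) is at least
    ``min_prevalence``, adds the listed exceptions (without double
    counting), and drops single-class species (prevalence 0 or 1), which
    cannot be modelled. Preserves the input ordering.
    """
    kept = []
    for name, p in prevalence.items():
        if p <= 0.0 or p >= 1.0:
            continue
        if p >= min_prevalence or name in exceptions:
            kept.append(name)
    if not kept:
        raise PipelineError("no species pass the prevalence filter")
    return kept


def project_model(
    model: BoostedTreesClassifier, stack: PredictorStack
) -> SuitabilityMap:
    """Predict occurrence probability on every valid cell of the stack.

    A cell is predicted only where every model predictor is valid; any
    nodata predictor makes the cell nodata in the output.
    """
    grid = stack.grid
    valid = np.ones(grid.shape, dtype=bool)
    for name in model.feature_names_:
        valid &= stack[name].valid_mask()
    rows, cols = np.where(valid)
    X = np.column_stack(
        [stack[name].data[rows, cols] for name in model.feature_names_]
    )
    out = np.full(grid.shape, grid.nodata)
    if len(rows):
        out[rows, cols] = model.predict_proba(X)[:, 1]
    prob = RasterGrid(out, grid.cell_size_km, grid.nodata)
    species = getattr(model, "species_name_", "species")
    return SuitabilityMap(probability=prob, species=species)


def suitable_area(
    suitability: SuitabilityMap,
    subregions: RasterGrid,
    cell_area_km2: float | None = None,
    subregion_names: Sequence[str] | None = None,
) -> AreaReport:
    """Suitable and extent areas per subregion.

    Extent = valid probability cells; suitable = cells strictly above the
    threshold. Valid cells without a subregion label are tallied under an
    ``unassigned`` bucket and flagged in the log.
    """
    prob = suitability.probability
    if cell_area_km2 is None:
        cell_area_km2 = prob.cell_size_km**2
    valid = prob.valid_mask()
    suit = suitability.suitable_mask()
    labels = subregions.data
    label_valid = subregions.valid_mask()

    ids = sorted(int(v) for v in np.unique(labels[label_valid]))
    if subregion_names is None:
        subregion_names = [f"subregion_{i:02d}" for i in ids]
    suitable_km2, extent_km2 = [], []
    for i in ids:
        in_sub = label_valid & (labels == i)
        extent_km2.append(float((valid & in_sub).sum()) * cell_area_km2)
        suitable_km2.append(float((suit & in_sub).sum()) * cell_area_km2)
    unassigned = float((suit & ~label_valid).sum()) * cell_area_km2
    if (valid & ~label_valid).any():
        logger.warning(
            "%s: %d valid cells lack a subregion label",
            suitability.species, int((valid & ~label_valid).sum()),
        )
    return AreaReport(
        species=suitability.species,
        subregion_names=list(subregion_names),
        suitable_km2=suitable_km2,
        extent_km2=extent_km2,
        unassigned_km2=unassigned,
    )


def make_reports(
    diagnostics: Mapping[str, dict],
    area_reports: Mapping[str, AreaReport],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-species summary table and per-subregion area table.

    The summary table carries presence (%), AUC and percent suitable per
    species. The area table has one species row per subregion column,
    ranked by total suitable area (descending); its final rows give the
    model extent per subregion, the per-subregion mean over the modelled
    species, and the subregion rank by that mean (ties rank the
    lower-index column first).
    """
    if not area_reports:
        raise PipelineError("no species results to report")
    order = sorted(
        area_reports,
        key=lambda s: -area_reports[s].total_suitable_km2,
    )
    summary = pd.DataFrame(
        [
            {
                "species": s,
                "presence_pct": diagnostics.get(s, {}).get("presence_pct"),
                "auc": diagnostics.get(s, {}).get("auc"),
                "suitable_pct": area_reports[s].percent_suitable,
                "total_suitable_km2": area_reports[s].total_suitable_km2,
            }
            for s in order
        ]
    )

    first = area_reports[order[0]]
    cols = first.subregion_names
    rows = {
        s: area_reports[s].suitable_km2 + [area_reports[s].total_suitable_km2]
        for s in order
    }
    table = pd.DataFrame.from_dict(
        rows, orient="index", columns=cols + ["total_km2"]
    )
    extent_row = first.extent_km2 + [first.total_extent_km2]
    table.loc["model_extent"] = extent_row
    species_mean = table.loc[order, cols].mean(axis=0)
    table.loc["species_mean"] = list(species_mean) + [float("nan")]
    # rank 1 = largest mean; ties -> lower column index first
    rank = (-species_mean).argsort(kind="stable").argsort() + 1
    table.loc["rank"] = list(rank.astype(float)) + [float("nan")]
    return summary, table
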