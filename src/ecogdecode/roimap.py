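"""Electrode-to-ROI mapping by 3-D Gaussian proximity.

Each electrode receives a weight ``exp(-d^2 / (2 sigma^2))`` toward
every ROI centroid (so an electrode exactly at a centroid scores 1).
Electrodes are assigned to their highest-weight ROI when that weight
clears a threshold, and ROIs retaining fewer electrodes than a minimum
density are discarded (their electrodes become unassigned), iterating
until stable.  Neither sigma nor the threshold has a canonical value
in this analysis style; the defaults (sigma = 10 mm, threshold =
exp(-2), i.e. a ~2 sigma radius) are configuration choices recorded in
output metadata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .containers import FeatureTable
from .synth import ElectrodeLayout

__all__ = ["RoiProjection", "RoiAssignment", "projection_matrix",
           "assign_rois", "roi_feature_slice", "DEFAULT_SIGMA_MM",
           "DEFAULT_THRESHOLD"]

logger = logging.getLogger(__name__)

DEFAULT_SIGMA_MM = 10.0
DEFAULT_THRESHOLD = float(np.exp(-2.0))


@dataclass(frozen=True)
class RoiProjection:
    """Electrodes x ROIs Gaussian proximity weights in (0, 1]."""

    matrix: np.ndarray
    roi_names: tuple[str, ...]
    sigma_mm: float

    @property
    def n_electrodes(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class RoiAssignment:
    """Thresholded nearest-ROI labels with the density rule applied."""

    electrode_roi: tuple[str | None, ...]
    retained_rois: tuple[str, ...]
    density: dict[str, int] = field(default_factory=dict)
    min_density: int = 3
    threshold: float = DEFAULT_THRESHOLD

    def electrodes_of(self, roi: str) -> np.ndarray:
        """Indices (layout order) of electrodes assigned to ``roi``."""
        if roi not in self.retained_rois:
            raise KeyError(f"ROI {roi!r} is not retained")
        return np.flatnonzero([r == roi for r in self.electrode_roi])


def projection_matrix(layout: ElectrodeLayout,
                      sigma_mm: float = DEFAULT_SIGMA_MM) -> RoiProjection:
    """Gaussian proximity weights of every electrode to every ROI."""
    if sigma_mm <= 0:
        raise ValueError("sigma_mm must be positive")
    names = tuple(layout.roi_names)
    if not names:
        raise ValueError("layout has no ROI centroids")
    cents = np.stack([layout.roi_centroids[n] for n in names])
    d2 = ((layout.positions[:, None, :] - cents[None, :, :]) ** 2).sum(axis=2)
    w = np.exp(-d2 / (2.0 * sigma_mm ** 2))
    return RoiProjection(matrix=w, roi_names=names, sigma_mm=sigma_mm)


def assign_rois(proj: RoiProjection, threshold: float = DEFAULT_THRESHOLD,
                min_density: int = 3) -> RoiAssignment:
    """Nearest-ROI assignment with thresholding and the density rule.

    An electrode goes to its argmax-weight ROI (ties broken by ROI list
    order) if that weight clears ``threshold``.  ROIs with fewer than
    ``min_density`` assigned electrodes are dropped and their
    electrodes unassigned, iterating until a fixed point.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    if min_density < 1:
        raise ValueError("min_density must be >= 1")
    w = proj.matrix
    best = np.argmax(w, axis=1)  # first max wins: ROI list order tie-break
    best_w = w[np.arange(w.shape[0]), best]
    assigned: list[str | None] = [
        proj.roi_names[j] if bw >= threshold else None
        for j, bw in zip(best, best_w)
    ]
    alive = set(proj.roi_names)
    while True:
        counts = {r: 0 for r in alive}
        for r in assigned:
            if r in counts:
                counts[r] += 1
        dead = {r for r, c in counts.items() if c < min_density}
        if not dead:
            break
        alive -= dead
        assigned = [r if r in alive else None for r in assigned]
    retained = tuple(r for r in proj.roi_names if r in alive)
    density = {r: sum(1 for a in assigned if a == r) for r in retained}
    if not retained:
        logger.warning("no ROI satisfies the density rule; empty assignment")
    return RoiAssignment(electrode_roi=tuple(assigned), retained_rois=retained,
                         density=density, min_density=min_density,
                         threshold=threshold)


def roi_feature_slice(table: FeatureTable, assignment: RoiAssignment,
                      roi: str, band: str) -> tuple[np.ndarray, np.ndarray]:
    """Kept-bin feature matrix for one (ROI, band) combination.

    Returns ``(X, labels)`` where ``X`` is kept-bins x n_roi_electrodes
    (columns in layout order) and ``labels`` the per-row behavioral
    labels (None array when the table is unlabeled).
    """
    cols = assignment.electrodes_of(roi)
    k = table.band_table.index(band)
    rows = table.kept_indices()
    X = table.values[np.ix_(rows, cols)][:, :, k]
    labels = (table.labels[rows] if table.labels is not None
              else np.full(rows.size, None, dtype=object))
    return X, labels
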