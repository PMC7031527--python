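"""Exposure-conditioned lesion volumetrics and the dose-response fit.

Post-processing of the dosimetric solution against pre/post-treatment
lesion masks:

* exposure histograms of the field magnitude over the lesion at the
  signal peak (extremes, arg-extreme voxels, histogram mode);
* slicing of both lesions in the coil d/f/t frame at fixed spacing;
* volume-ratio tables over exposure ranges (V_post/V_pre per range,
  the "slash" marker where neither lesion occupies a range);
* lower-bound-threshold ratio curves: for threshold x, the percent of
  post-treatment volume lying in regions exposed to at least x,
  relative to the pre-treatment volume exposed to at least x;
* a pooled decaying-exponential dose-response fit f(x) = M exp(a x),
  exposed as a model/results pair with parameter covariance and a
  summary table.

"Exposed volume" is voxel count times voxel volume at voxel centers
(no partial-volume weighting), matching the binary-mask resolution of
the inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .coil import CoilFrame
from .errors import ConfigurationError, InvariantViolation

logger = logging.getLogger(__name__)

__all__ = [
    "ExposureSummary",
    "RatioTable",
    "DoseResponseData",
    "DoseResponseModel",
    "DoseResponseResults",
    "SliceComparison",
    "exposure_summary",
    "coil_frame_slices",
    "ratio_by_range",
    "ratio_by_threshold",
    "default_thresholds",
    "pool_cases",
    "fit_dose_response",
]


# ---------------------------------------------------------------------
# exposure histogram


@dataclass
class ExposureSummary:
    """Field-magnitude statistics over a mask at the signal peak."""

    voxel_values: np.ndarray
    bin_edges: np.ndarray
    counts: np.ndarray
    mode_value: float
    min_value: float
    max_value: float
    min_voxel_index: tuple
    max_voxel_index: tuple

    def __post_init__(self):
        if int(self.counts.sum()) != len(self.voxel_values):
            raise InvariantViolation("histogram counts do not sum to mask size")
        # Bin centers sit on an anchored grid, so the mode may fall up
        # to half a bin outside the raw value range.
        half_bin = 0.5 * float(self.bin_edges[1] - self.bin_edges[0])
        if not (self.min_value - half_bin <= self.mode_value
                <= self.max_value + half_bin):
            raise InvariantViolation("histogram mode outside the value range")


def exposure_summary(field_volume, mask, bin_width: float = 0.05) -> ExposureSummary:
    """Histogram of field magnitudes over mask voxels.

    ``bin_width`` is in the field's own units (default 0.05, i.e.
    0.05 mT for B in mT).  Bin edges are anchored at integer multiples
    of the bin width so histograms of shifted coils share a grid.
    """
    field_volume = np.asarray(field_volume, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if field_volume.shape != mask.shape:
        raise ConfigurationError("field and mask grids are not congruent")
    if not np.any(mask):
        raise ConfigurationError("exposure summary of an empty mask")
    if bin_width <= 0:
        raise ConfigurationError("bin_width must be positive")
    values = field_volume[mask]
    idx = np.argwhere(mask)
    vmin = float(values.min())
    vmax = float(values.max())
    lo = np.floor(vmin / bin_width) * bin_width
    hi = np.ceil(vmax / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    n_bins = int(round((hi - lo) / bin_width))
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(values, bins=edges)
    mode = float(0.5 * (edges[np.argmax(counts)] + edges[np.argmax(counts) + 1]))
    return ExposureSummary(
        voxel_values=values,
        bin_edges=edges,
        counts=counts,
        mode_value=mode,
        min_value=vmin,
        max_value=vmax,
        min_voxel_index=tuple(int(v) for v in idx[int(np.argmin(values))]),
        max_voxel_index=tuple(int(v) for v in idx[int(np.argmax(values))]),
    )


# ---------------------------------------------------------------------
# coil-frame slicing


_PLANE_AXIS = {"d": 2, "f": 0, "t": 1}


@dataclass
class SliceComparison:
    """Per-slice pre/post areas (mm^2) along one coil-frame direction."""

    plane: str
    spacing_mm: float
    offsets_mm: np.ndarray
    pre_areas_mm2: np.ndarray
    post_areas_mm2: np.ndarray
    contours_pre: dict = field(default_factory=dict)
    contours_post: dict = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "plane": self.plane,
            "offset_mm": self.offsets_mm,
            "pre_area_mm2": self.pre_areas_mm2,
            "post_area_mm2": self.post_areas_mm2,
        })


def _slab_contours(inplane_mm, pixel_mm):
    """Contour polylines (mm, in-plane coil coordinates) of a voxel cloud."""
    from skimage import measure

    if len(inplane_mm) == 0:
        return []
    origin = inplane_mm.min(axis=0) - 2 * pixel_mm
    ij = np.round((inplane_mm - origin) / pixel_mm).astype(int)
    img = np.zeros(ij.max(axis=0) + 5, dtype=float)
    img[ij[:, 0] + 2, ij[:, 1] + 2] = 1.0
    contours = measure.find_contours(img, 0.5)
    return [(c - 2.0) * pixel_mm + origin for c in contours]


def coil_frame_slices(
    mask_pre,
    mask_post,
    phantom,
    frame: CoilFrame,
    plane: str = "d",
    spacing_mm: float = 5.0,
    with_contours: bool = True,
) -> SliceComparison:
    """Cut both lesions into slabs along a coil-frame direction.

    Slabs are ``spacing_mm`` thick, centered at integer multiples of
    the spacing measured from the coil plane (d) or from the coil
    center planes (f, t).  Slice area is slab volume divided by the
    spacing.
    """
    if plane not in _PLANE_AXIS:
        raise ConfigurationError(f"plane must be one of d/f/t, got {plane!r}")
    if spacing_mm <= phantom.voxel_size:
        raise ConfigurationError("slice spacing must exceed the voxel size")
    axis = _PLANE_AXIS[plane]
    inplane_axes = [a for a in range(3) if a != axis]
    voxel_vol = phantom.voxel_volume_mm3

    coords = {}
    for name, mask in (("pre", mask_pre), ("post", mask_post)):
        pts = phantom.mask_voxel_centers_mm(np.asarray(mask, dtype=bool))
        coords[name] = frame.to_coil(pts)

    alls = np.concatenate([coords["pre"][:, axis], coords["post"][:, axis]])
    k_min = int(np.floor(alls.min() / spacing_mm))
    k_max = int(np.ceil(alls.max() / spacing_mm))
    offsets = spacing_mm * np.arange(k_min, k_max + 1)

    pre_areas = np.zeros(len(offsets))
    post_areas = np.zeros(len(offsets))
    contours_pre, contours_post = {}, {}
    for i, off in enumerate(offsets):
        lo, hi = off - spacing_mm / 2.0, off + spacing_mm / 2.0
        for name, areas, contours in (
            ("pre", pre_areas, contours_pre),
            ("post", post_areas, contours_post),
        ):
            c = coords[name]
            in_slab = (c[:, axis] >= lo) & (c[:, axis] < hi)
            areas[i] = in_slab.sum() * voxel_vol / spacing_mm
            if with_contours:
                contours[float(off)] = _slab_contours(
                    c[in_slab][:, inplane_axes], phantom.voxel_size
                )
    return SliceComparison(plane, spacing_mm, offsets, pre_areas, post_areas,
                           contours_pre, contours_post)


# ---------------------------------------------------------------------
# ratio tables and threshold curves

DEFAULT_B_EDGES_MT = (1.0, 1.3, 1.7, 2.0, np.inf)
DEFAULT_J_EDGES_MA_M2 = (5.0, 10.0, 20.0, 50.0, np.inf)


@dataclass
class RatioTable:
    """V_post/V_pre per exposure range; None marks the table's "slash".

    A ratio above 1 means the lesion enlarged within regions exposed to
    that range; below 1, it shrank.  None appears when neither the pre-
    nor the post-treatment lesion occupies the range.
    """

    edges: np.ndarray
    v_pre_mm3: np.ndarray
    v_post_mm3: np.ndarray
    ratios: list
    quantity: str = "B_mT"

    @property
    def ranges(self):
        return list(zip(self.edges[:-1], self.edges[1:]))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "quantity": self.quantity,
            "range_low": self.edges[:-1],
            "range_high": self.edges[1:],
            "v_pre_mm3": self.v_pre_mm3,
            "v_post_mm3": self.v_post_mm3,
            "ratio": [np.nan if r is None else r for r in self.ratios],
        })


def ratio_by_range(mask_pre, mask_post, field_volume, edges=DEFAULT_B_EDGES_MT,
                   voxel_volume_mm3: float = 1.0,
                   quantity: str = "B_mT") -> RatioTable:
    """Volume ratio per contiguous exposure range [edges[i], edges[i+1]).

    ``v_pre`` counts pre-treatment lesion voxels whose field falls in
    the range; ``v_post`` counts post-treatment voxels lying in regions
    (anywhere in the head) whose field falls in the range.
    """
    pre = np.asarray(mask_pre, dtype=bool)
    post = np.asarray(mask_post, dtype=bool)
    fieldv = np.asarray(field_volume, dtype=float)
    if not (pre.shape == post.shape == fieldv.shape):
        raise ConfigurationError("masks and field are not congruent")
    if not np.any(pre):
        raise ConfigurationError("pre-treatment mask is empty")
    edges = np.asarray(edges, dtype=float)
    if len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ConfigurationError("edges must be increasing with >= 2 entries")
    v_pre, v_post, ratios = [], [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        in_range = (fieldv >= lo) & (fieldv < hi)
        n_pre = int((pre & in_range).sum())
        n_post = int((post & in_range).sum())
        v_pre.append(n_pre * voxel_volume_mm3)
        v_post.append(n_post * voxel_volume_mm3)
        if n_pre == 0 and n_post == 0:
            ratios.append(None)
        elif n_pre == 0:
            ratios.append(np.inf)
        else:
            ratios.append(n_post / n_pre)
    return RatioTable(edges, np.array(v_pre), np.array(v_post), ratios,
                      quantity=quantity)


@dataclass
class DoseResponseData:
    """(threshold, percent-ratio) points, optionally tagged by case."""

    thresholds: np.ndarray
    ratios_percent: np.ndarray
    case_ids: np.ndarray
    quantity: str = "B_mT"

    def __post_init__(self):
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        self.ratios_percent = np.asarray(self.ratios_percent, dtype=float)
        self.case_ids = np.asarray(self.case_ids)
        if not (len(self.thresholds) == len(self.ratios_percent)
                == len(self.case_ids)):
            raise InvariantViolation("dose-response arrays differ in length")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "case_id": self.case_ids,
            "quantity": self.quantity,
            "threshold": self.thresholds,
            "ratio_percent": self.ratios_percent,
        })


def default_thresholds(field_volume, mask_pre, step: float = 0.1,
                       upper_percentile: float = 90.0) -> np.ndarray:
    """Threshold grid over the exposure range of the pre-treatment lesion.

    Regular grid (step in field units) from the lesion's minimum
    exposure up to the given percentile; the top few percent of voxels
    are excluded because tail thresholds select too few voxels for a
    stable ratio.
    """
    values = np.asarray(field_volume, dtype=float)[np.asarray(mask_pre, dtype=bool)]
    lo = np.ceil(values.min() / step) * step
    hi = np.percentile(values, upper_percentile)
    if hi <= lo:
        return np.array([lo])
    return np.arange(lo, hi + 1e-12, step)


def ratio_by_threshold(mask_pre, mask_post, field_volume, thresholds,
                       case_id="case", voxel_volume_mm3: float = 1.0,
                       quantity: str = "B_mT") -> DoseResponseData:
    """Percent volume ratio for lower-bound exposure thresholds.

    For each threshold x: 100 * V_post(field >= x) / V_pre(field >= x),
    where V_pre counts pre-lesion voxels exposed to at least x and
    V_post counts post-lesion voxels lying in head regions exposed to
    at least x.  Thresholds whose V_pre is zero are dropped (logged).
    """
    pre = np.asarray(mask_pre, dtype=bool)
    post = np.asarray(mask_post, dtype=bool)
    fieldv = np.asarray(field_volume, dtype=float)
    if not (pre.shape == post.shape == fieldv.shape):
        raise ConfigurationError("masks and field are not congruent")
    if not np.any(pre):
        raise ConfigurationError("pre-treatment mask is empty")
    thresholds = np.atleast_1d(np.asarray(thresholds, dtype=float))
    kept_t, ratios = [], []
    pre_vals = fieldv[pre]
    post_vals = fieldv[post]
    for t in thresholds:
        n_pre = int((pre_vals >= t).sum())
        if n_pre == 0:
            logger.info("threshold %g dropped: no pre-treatment volume "
                        "exposed at or above it", t)
            continue
        n_post = int((post_vals >= t).sum())
        kept_t.append(t)
        ratios.append(100.0 * n_post / n_pre)
    return DoseResponseData(
        np.array(kept_t), np.array(ratios),
        np.array([case_id] * len(kept_t), dtype=object),
        quantity=quantity,
    )


def pool_cases(cases) -> DoseResponseData:
    """Concatenate per-case threshold/ratio series (no averaging)."""
    cases = list(cases)
    if not cases:
        raise ConfigurationError("no cases to pool")
    quantity = cases[0].quantity
    for c in cases:
        if c.quantity != quantity:
            raise ConfigurationError("cannot pool different quantities")
    return DoseResponseData(
        np.concatenate([c.thresholds for c in cases]),
        np.concatenate([c.ratios_percent for c in cases]),
        np.concatenate([c.case_ids for c in cases]),
        quantity=quantity,
    )


# ---------------------------------------------------------------------
# exponential dose-response model


class DoseResponseModel:
    """Decaying-exponential dose-response model f(x) = M exp(a x).

    ``x`` is the lower-bound exposure threshold (mT for B, mA/m^2 for
    J) and f the percent volume ratio.  Fitting is nonlinear least
    squares seeded by a log-linear regression, hence deterministic for
    given data.

    Examples
    --------
    >>> model = DoseResponseModel([1.0, 1.5, 2.0], [72.0, 61.0, 52.0])
    >>> res = model.fit()
    >>> round(res.M, 1), round(res.a, 3)
    (99.7, -0.326)
    """

    def __init__(self, thresholds, ratios_percent, case_ids=None,
                 quantity="B_mT"):
        x = np.asarray(thresholds, dtype=float)
        y = np.asarray(ratios_percent, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise ConfigurationError("thresholds/ratios must be matching 1-D")
        if len(x) < 3:
            raise ConfigurationError("dose-response fit needs >= 3 points")
        if len(np.unique(x)) < 2:
            raise ConfigurationError(
                "dose-response fit needs >= 2 distinct thresholds"
            )
        if case_ids is None:
            case_ids = np.array(["case"] * len(x), dtype=object)
        self.thresholds = x
        self.ratios_percent = y
        self.case_ids = np.asarray(case_ids)
        self.quantity = quantity

    @classmethod
    def from_data(cls, data: DoseResponseData) -> "DoseResponseModel":
        return cls(data.thresholds, data.ratios_percent, data.case_ids,
                   quantity=data.quantity)

    @staticmethod
    def _f(x, M, a):
        return M * np.exp(a * x)

    def _initial_guess(self):
        pos = self.ratios_percent > 0
        if pos.sum() >= 2 and len(np.unique(self.thresholds[pos])) >= 2:
            slope, intercept = np.polyfit(
                self.thresholds[pos], np.log(self.ratios_percent[pos]), 1
            )
            return float(np.exp(intercept)), float(slope)
        return float(np.mean(self.ratios_percent[pos])) if pos.any() else 1.0, 0.0

    def fit(self) -> "DoseResponseResults":
        p0 = self._initial_guess()
        popt, pcov = optimize.curve_fit(
            self._f, self.thresholds, self.ratios_percent, p0=p0, maxfev=20_000
        )
        return DoseResponseResults(self, popt, pcov)


class DoseResponseResults:
    """Fit results: estimates, covariance, residuals, summary table."""

    param_names = ("M", "a")

    def __init__(self, model: DoseResponseModel, params, cov):
        self.model = model
        self.params = np.asarray(params, dtype=float)
        self.cov_params = np.asarray(cov, dtype=float)
        self.fittedvalues = model._f(model.thresholds, *self.params)
        self.resid = model.ratios_percent - self.fittedvalues
        self.nobs = len(model.thresholds)

    @property
    def M(self) -> float:
        return float(self.params[0])

    @property
    def a(self) -> float:
        return float(self.params[1])

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params))

    def predict(self, thresholds) -> np.ndarray:
        return self.model._f(np.asarray(thresholds, dtype=float), *self.params)

    def threshold_for_ratio(self, ratio_percent: float) -> float:
        """Exposure at which the fitted curve crosses a given percent."""
        if self.a == 0:
            raise ConfigurationError("flat fit: ratio never crosses")
        return float(np.log(ratio_percent / self.M) / self.a)

    def to_dict(self) -> dict:
        return {
            "M": self.M,
            "a": self.a,
            "cov": self.cov_params.tolist(),
            "bse": self.bse.tolist(),
            "n_points": int(self.nobs),
            "quantity": self.model.quantity,
        }

    def summary(self) -> str:
        se = self.bse
        rmse = float(np.sqrt(np.mean(self.resid ** 2)))
        lines = [
            "Exponential dose-response fit: ratio% = M * exp(a * x)",
            f"quantity x: {self.model.quantity}    n points: {self.nobs}"
            f"    cases: {len(np.unique(self.model.case_ids))}",
            "-" * 58,
            f"{'param':>6} {'estimate':>12} {'std err':>12}",
            f"{'M':>6} {self.M:>12.4f} {se[0]:>12.4f}",
            f"{'a':>6} {self.a:>12.4f} {se[1]:>12.4f}",
            "-" * 58,
            f"residual RMSE: {rmse:.3f} percentage points",
        ]
        return "\n".join(lines)


def fit_dose_response(data: DoseResponseData) -> DoseResponseResults:
    """Fit the pooled exponential dose-response curve."""
    return DoseResponseModel.from_data(data).fit()
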