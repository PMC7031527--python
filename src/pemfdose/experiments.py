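"""Canned desk-scale experiments used for validation and reporting.

These functions wire the package's pieces into the standard study
design: a layered head phantom, three lesion cases of different size
and depth (one large mid-depth lesion, one small shallow, one small
deep - so the cases sample distinct exposure levels), a coil placed
against the scalp and auto-centered on each lesion, exposure at the
band-limited signal peak, stochastic lesion evolution under a known
exponential dose-response law, and the pooled fit that attempts to
recover that law.  Pooling cases whose individual exposure ranges are
narrow but mutually offset is what makes the threshold-ratio fit
nearly unbiased; a single wide lesion would not identify the slope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import analysis as an
from . import coil as cm
from . import phantom as ph
from . import signal as sg

__all__ = [
    "RecoveryCase",
    "DEFAULT_CASES",
    "build_study_phantom",
    "case_exposure_mT",
    "band_limited_peak_current",
    "recovery_experiment",
]


@dataclass(frozen=True)
class RecoveryCase:
    """One synthetic patient: lesion geometry and its generator seed."""

    case_id: str
    centroid_mm: tuple
    radii_mm: tuple
    lesion_seed: int


# Three cases echoing the study design: a large mid-depth lesion
# exposed to a wide field range, a small shallow lesion at high
# exposure, and a small deep lesion at low exposure.
DEFAULT_CASES = (
    RecoveryCase("AA", (28.0, 0.0, 5.0), (24.0, 20.0, 20.0), 11),
    RecoveryCase("BB", (42.0, 0.0, -2.0), (18.0, 15.0, 15.0), 22),
    RecoveryCase("CC", (4.0, 0.0, 10.0), (18.0, 15.0, 15.0), 33),
)

HEAD_RADIUS_MM = 80.0
VOXEL_MM = 2.0
APPROACH_DIRECTION = (1.0, 0.0, 0.1)
STANDOFF_MM = 5.0
PEAK_CURRENT_A = 240.0


def build_study_phantom(voxel_mm: float = VOXEL_MM) -> ph.VoxelPhantom:
    """Desk-scale layered head used by the canned experiments."""
    return ph.build_layered_head(radius_mm=HEAD_RADIUS_MM, voxel_size_mm=voxel_mm)


def band_limited_peak_current(n_harmonics: int = 12,
                              spec: sg.PulsedSignalSpec | None = None) -> float:
    """Peak of the band-limited pulse reconstructed from n harmonics + DC."""
    spec = spec or sg.PulsedSignalSpec()
    t, i = sg.synthesize_pulse(spec)
    band = (spec.repetition_frequency,
            n_harmonics * spec.repetition_frequency,
            spec.repetition_frequency)
    h = sg.decompose(t, i, band)
    return float(np.max(np.abs(sg.reconstruct_waveform(h, t))))


def case_exposure_mT(phantom, lesion_mask, brain_mask,
                     peak_current_A: float = PEAK_CURRENT_A,
                     direction=APPROACH_DIRECTION,
                     standoff_mm: float = STANDOFF_MM):
    """Place the coil for one case and map |B| (mT) at the signal peak.

    Returns ``(field_mT_volume, coil)``; the field is defined over the
    brain (zero elsewhere), evaluated at voxel centers, scaled to the
    peak drive current.
    """
    coil = cm.place_coil(phantom, lesion_mask=lesion_mask,
                         direction=direction, standoff_mm=standoff_mm)
    pts = phantom.mask_voxel_centers_mm(brain_mask)
    b = cm.biot_savart_B(coil, pts, 1.0)
    field = np.zeros(phantom.shape)
    field[np.asarray(brain_mask, dtype=bool)] = (
        np.linalg.norm(b, axis=1) * 1e3 * peak_current_A
    )
    return field, coil


@dataclass
class RecoveryResult:
    m_true: float
    a_true: float
    fitted_M: np.ndarray  # per replicate
    fitted_a: np.ndarray
    total_lesion_voxels: int

    @property
    def median_M_error(self) -> float:
        return float(np.median(np.abs(self.fitted_M - self.m_true)
                               / self.m_true))

    @property
    def median_a_error(self) -> float:
        return float(np.median(np.abs(self.fitted_a - self.a_true)
                               / abs(self.a_true)))


def recovery_experiment(
    seed: int = 0,
    n_replicates: int = 20,
    m_true: float = 80.0,
    a_true: float = -0.3,
    n_harmonics: int = 12,
    cases=DEFAULT_CASES,
    voxel_mm: float = VOXEL_MM,
    threshold_step_mT: float = 0.1,
) -> RecoveryResult:
    """End-to-end parameter recovery on the synthetic study design.

    Builds the phantom and the three lesion cases once, computes each
    case's band-limited peak exposure, then for each replicate evolves
    every lesion under the known law (every lesion voxel treated, no
    untreated growth - the experiment validates the analysis chain
    against the pure law), pools the per-case threshold-ratio curves
    and fits the exponential model.  The geometry is fixed; ``seed``
    offsets only the stochastic evolution.
    """
    phantom = build_study_phantom(voxel_mm)
    brain = np.isin(phantom.labels, ph.BRAIN_LABELS)
    peak = band_limited_peak_current(n_harmonics)

    fields, lesions = {}, {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # boundary clipping is acceptable here
        for case in cases:
            lesion = ph.generate_lesion(
                phantom, case.centroid_mm, case.radii_mm,
                irregularity=0.25, seed=case.lesion_seed,
            )
            field, _ = case_exposure_mT(phantom, lesion, brain,
                                        peak_current_A=peak)
            fields[case.case_id] = field
            lesions[case.case_id] = lesion

    rng = np.random.default_rng(seed)
    fitted_M, fitted_a = [], []
    for _ in range(n_replicates):
        pooled = []
        for case in cases:
            cid = case.case_id
            pair = ph.evolve_lesion(
                lesions[cid], fields[cid], m_true=m_true, a_true=a_true,
                exposure_floor_mT=0.0, growth_rate_untreated=0.0,
                seed=int(rng.integers(2 ** 31)), brain_mask=brain,
            )
            thr = an.default_thresholds(fields[cid], pair.pre_mask,
                                        step=threshold_step_mT)
            pooled.append(an.ratio_by_threshold(
                pair.pre_mask, pair.post_mask, fields[cid], thr,
                case_id=cid, voxel_volume_mm3=phantom.voxel_volume_mm3,
            ))
        res = an.fit_dose_response(an.pool_cases(pooled))
        fitted_M.append(res.M)
        fitted_a.append(res.a)

    return RecoveryResult(
        m_true=m_true,
        a_true=a_true,
        fitted_M=np.array(fitted_M),
        fitted_a=np.array(fitted_a),
        total_lesion_voxels=int(sum(l.sum() for l in lesions.values())),
    )
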