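"""Leave-one-out evaluation on a phantom cohort.

Mirrors the standard evaluation protocol at phantom scale: the template
database is built from one subject's ground truth, every other subject is
segmented with it, and the segmentations are scored against their own
analytic truth with the full metric suite (Dice, mean centerline distance, Hausdorff, regional
CSA). The cohort's default conditions — voxel spacing, cord radii around
4-5 mm with a cervical enlargement, gentle sagittal curvature, additive
noise, rootlet streaks, and (in one subject) obliterated CSF segments —
follow the imaging conditions the method was designed for.
"""

from __future__ import annotations

import numpy as np

from .io import gradient_magnitude
from .matching import SegmentOptions, segment
from .metrics import (dice, hausdorff, mean_centerline_distance,
                      region_from_markers, regional_csa, cohort_report)
from .phantom import (CenterlineParams, PhantomCase, PhantomConfig,
                      generate_phantom)
from .profiles import build_template_db
from .spline import SplineModel, fit_spline

#: world length of the default cohort grids: (200-1) * 0.3 mm
_L = 59.7


def default_cohort_configs(seed: int = 0,
                           grid_shape=(63, 63, 200)) -> list[PhantomConfig]:
    """Six phantom configurations: subject 0 is the template-database
    subject; subject 3 is a straight 5 mm cylinder (the CSA reference);
    subject 4 carries obliterated-CSF segments (the smoothing stress case)."""
    L = (grid_shape[2] - 1) * 0.3
    f = L / _L  # keep knot positions proportional if the grid length changes
    specs = [
        dict(centerline_params=CenterlineParams(amplitude_mm=2.0,
                                                wavelength_mm=120.0),
             radius_profile=((0.0, 3.6), (30.0 * f, 5.2), (L, 3.8))),
        dict(centerline_params=CenterlineParams(amplitude_mm=1.5,
                                                wavelength_mm=120.0,
                                                phase=1.0),
             radius_profile=((0.0, 4.0), (25.0 * f, 4.8), (L, 4.0))),
        dict(centerline_params=CenterlineParams(amplitude_mm=2.5,
                                                wavelength_mm=90.0),
             radius_profile=((0.0, 3.8), (35.0 * f, 4.9), (L, 4.2))),
        dict(centerline_params=CenterlineParams(amplitude_mm=0.0),
             radius_profile=((0.0, 5.0), (L, 5.0))),
        dict(centerline_params=CenterlineParams(amplitude_mm=1.0,
                                                wavelength_mm=140.0),
             radius_profile=((0.0, 4.3), (30.0 * f, 4.9), (L, 3.9)),
             obliteration_intervals=((22.0 * f, 27.0 * f),
                                     (38.0 * f, 43.0 * f))),
        dict(centerline_params=CenterlineParams(amplitude_mm=2.0,
                                                wavelength_mm=150.0,
                                                phase=2.0),
             radius_profile=((0.0, 3.9), (28.0 * f, 4.6), (L, 4.1))),
    ]
    return [
        PhantomConfig(grid_shape=tuple(grid_shape), seed=seed + 17 * i, **sp)
        for i, sp in enumerate(specs)
    ]


def markings_from_truth(case: PhantomCase, jitter_mm: float = 0.2,
                        seed: int = 0) -> np.ndarray:
    """Emulate manual centerline markings: the truth centerline samples with
    a small seeded in-plane jitter (manual clicks are near, not on, the
    axis)."""
    rng = np.random.default_rng(seed)
    pts = case.truth_centerline.copy()
    if jitter_mm > 0:
        pts[:, :2] += rng.normal(0.0, jitter_mm, size=(len(pts), 2))
    return pts


def truth_spline(case: PhantomCase, n_control: int = 100) -> SplineModel:
    """Reference centerline spline fit through the analytic truth samples."""
    return fit_spline(case.truth_centerline,
                      n_control=min(n_control, len(case.truth_centerline)))


def score_segmentation(case: PhantomCase, result) -> dict:
    """Score one segmentation against its phantom's analytic truth."""
    ref = truth_spline(case)
    sz = case.volume.spacing[2]
    ks = np.flatnonzero(result.mask.data.sum(axis=(0, 1))
                        & case.truth_mask.data.sum(axis=(0, 1)))
    zs = ks * sz
    scores = {
        "dice": dice(result.mask, case.truth_mask),
        "md": mean_centerline_distance(result.refined_spline, ref, zs),
        "hd": hausdorff(result.mask, case.truth_mask),
    }
    regions = []
    for label, mk in case.rootlet_markers.items():
        reg = region_from_markers(ref, mk["rostral"], mk["caudal"],
                                  label=label)
        regions.append({
            "label": label,
            "csa_a": regional_csa(result.mask, ref, reg),
            "csa_b": regional_csa(case.truth_mask, ref, reg),
        })
    scores["regions"] = regions
    return scores


def run_loo_cohort(configs: list[PhantomConfig] | None = None,
                   db_subject: int = 0, seed: int = 0,
                   options: SegmentOptions | None = None,
                   cases: list[PhantomCase] | None = None) -> dict:
    """Build the template DB from one phantom and segment all the others.

    Returns per-subject scores plus the aggregated cohort report.
    """
    configs = configs if configs is not None else default_cohort_configs(seed)
    options = options or SegmentOptions()
    if cases is None:
        cases = [generate_phantom(c) for c in configs]
    db_case = cases[db_subject]
    grad = gradient_magnitude(db_case.volume)
    db = build_template_db(grad, db_case.truth_mask,
                           subject_id=f"phantom{db_subject}")
    per_subject = []
    regional = []
    for i, case in enumerate(cases):
        if i == db_subject:
            continue
        markings = markings_from_truth(case, seed=seed + 1000 + i)
        result = segment(case.volume, markings, db, options)
        scores = score_segmentation(case, result)
        regional.extend(scores.pop("regions"))
        scores["subject"] = i
        scores["n_fallback"] = result.meta["n_fallback"]
        per_subject.append(scores)
    report = cohort_report(per_subject, regional)
    return {"per_subject": per_subject, "report": report,
            "db_subject": db_subject, "n_templates": int(db.n_profiles)}


def run_loo_rotation(configs: list[PhantomConfig] | None = None,
                     seed: int = 0,
                     options: SegmentOptions | None = None) -> dict:
    """The full rotated protocol: every subject takes a turn as the
    template-database subject and all others are segmented against it
    (n subjects -> n*(n-1) segmentations), then one aggregated report."""
    configs = configs if configs is not None else default_cohort_configs(seed)
    cases = [generate_phantom(c) for c in configs]
    runs = []
    all_pairs = []
    for db_subject in range(len(configs)):
        res = run_loo_cohort(configs, db_subject=db_subject, seed=seed,
                             options=options, cases=cases)
        runs.append(res)
        all_pairs.extend(res["per_subject"])
    report = cohort_report(all_pairs)
    return {"runs": runs, "report": report,
            "n_segmentations": len(all_pairs)}
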