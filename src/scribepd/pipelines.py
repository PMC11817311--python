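"""End-to-end helpers chaining generation, features, representation and CV.

These wrappers are thin glue used by the command-line interface, the
test suite and the reproduction script; every individual stage lives in
its own module.
"""

from __future__ import annotations

import numpy as np

from scribepd.dynamic_features import IN_AIR, ON_SURFACE, extract_all
from scribepd.evaluation import CVReport, FoldPlan, SVMGrid, make_folds, run_svm_cv
from scribepd.io_formats import Condition, TabletRecording
from scribepd.static_representation import (
    GMMSpec,
    StaticVector,
    build_frame_matrix,
    early_fusion,
    functionals,
    gmm_supervector,
)

FEATURE_SETS = ("pressure", "kinematic", "fusion")


def _matrices_for_set(rec: TabletRecording, feature_set: str):
    fms = extract_all(rec)
    if feature_set == "pressure":
        return [fms["pressure"]]
    if feature_set == "kinematic":
        return [fms[ON_SURFACE], fms[IN_AIR]]
    if feature_set == "fusion":
        return [fms["pressure"], fms[ON_SURFACE], fms[IN_AIR]]
    raise ValueError(f"unknown feature set {feature_set!r}; "
                     f"expected one of {FEATURE_SETS}")


def subject_vector(rec: TabletRecording, feature_set: str = "pressure",
                   mode: str = "functionals",
                   gmm_spec: "GMMSpec | None" = None) -> StaticVector:
    """Static representation of one recording.

    ``mode`` is "functionals" or "gmm"; ``feature_set`` picks pressure,
    kinematic (on-surface + in-air) or their early fusion.
    """
    fms = _matrices_for_set(rec, feature_set)
    if mode == "functionals":
        vec = functionals(fms[0])
        for fm in fms[1:]:
            vec = early_fusion(vec, functionals(fm))
        if len(fms) > 1:
            return StaticVector(vec.names, vec.values, "fusion")
        return vec
    if mode == "gmm":
        if gmm_spec is None:
            raise ValueError("gmm mode needs a GMMSpec")
        frames, names, scalars = build_frame_matrix(fms)
        return gmm_supervector(frames, gmm_spec, feature_names=names,
                               scalars=scalars)
    raise ValueError(f"unknown mode {mode!r}; expected 'functionals' or 'gmm'")


def cohort_design(recs: list[TabletRecording]) -> tuple[list[str], np.ndarray]:
    """(subject ids, binary labels with PD = 1) of a recording list."""
    ids = [r.subject_id for r in recs]
    y = np.array([int(r.condition is Condition.PD) for r in recs])
    return ids, y


def cohort_matrix(recs: list[TabletRecording], feature_set: str = "pressure",
                  mode: str = "functionals",
                  gmm_spec: "GMMSpec | None" = None
                  ) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Stack per-subject static vectors into (X, dimension names, y)."""
    vecs = [subject_vector(r, feature_set, mode, gmm_spec) for r in recs]
    names = vecs[0].names
    for v, r in zip(vecs, recs):
        if v.names != names:
            raise ValueError(
                f"subject {r.subject_id}: dimension labels differ from the "
                "first subject's")
    X = np.vstack([v.values for v in vecs])
    _, y = cohort_design(recs)
    return X, names, y


def evaluate_cohort(recs: list[TabletRecording], feature_set: str = "pressure",
                    mode: str = "functionals",
                    gmm_spec: "GMMSpec | None" = None,
                    plan: "FoldPlan | None" = None,
                    grid: "SVMGrid | None" = None, seed: int = 0,
                    name: "str | None" = None) -> CVReport:
    """One dynamic-branch pipeline end to end on in-memory recordings."""
    X, _, y = cohort_matrix(recs, feature_set, mode, gmm_spec)
    if plan is None:
        ids, y2 = cohort_design(recs)
        plan = make_folds((ids, y2), seed=seed)
    return run_svm_cv(X, y, plan, grid=grid, seed=seed,
                      name=name or f"{feature_set}-{mode}")
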