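"""End-to-end study analysis: preprocessing -> GLM -> reproducibility.

Works either in memory on simulated recordings (:func:`analyze_study`)
or from a study manifest listing SNIRF files on disk
(:func:`run_pipeline`), which writes the result tables as TSV.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .glm import ARIRLSParams, ActivationVector, fit_session
from .preprocess import PreprocessParams, preprocess_recording
from .repro import (pair_scores, physio_change, subject_repro,
                    summarize_medians, variability_regression)
from .snirf_io import read_snirf
from .synth import RawRecording

__all__ = ["StudyManifest", "PipelineResult", "analyze_session",
           "analyze_study", "run_pipeline"]


@dataclass
class StudyManifest:
    """Declarative description of a study to analyse from disk."""

    sessions: list[dict]                 # subject, session, condition, day,
                                         # time_of_day, path
    pre_params: PreprocessParams = field(default_factory=PreprocessParams)
    glm_params: ARIRLSParams = field(default_factory=ARIRLSParams)
    drift_order: int = 3
    rois: dict[str, list[int]] | None = None  # None -> probe defaults

    def __post_init__(self):
        keys = [(s.get("subject"), s.get("session")) for s in self.sessions]
        if len(set(keys)) != len(keys):
            raise ValueError("(subject, session) pairs must be unique")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyManifest":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        pre = PreprocessParams(**doc.get("pre_params", {}))
        raw_glm = doc.get("glm_params", {})
        glm = ARIRLSParams(**raw_glm)
        base = Path(path).parent
        sessions = doc["sessions"]
        for s in sessions:
            s["path"] = str((base / s["path"]).resolve())
        return cls(sessions=sessions, pre_params=pre, glm_params=glm,
                   drift_order=doc.get("drift_order", 3),
                   rois=doc.get("rois"))


@dataclass
class PipelineResult:
    glm_table: pd.DataFrame
    activation: dict[tuple[str, str], ActivationVector]  # (subject, session)
    pair_table: pd.DataFrame
    subject_table: pd.DataFrame
    median_table: pd.DataFrame
    regression: pd.DataFrame | None
    params_hash: str
    log: list = field(default_factory=list)


def _params_hash(pre: PreprocessParams, glm: ARIRLSParams,
                 drift_order: int) -> str:
    blob = json.dumps({"pre": asdict(pre), "glm": asdict(glm),
                       "drift_order": drift_order}, sort_keys=True)
    return hashlib.sha1(blob.encode()).hexdigest()[:12]


def analyze_session(raw: RawRecording,
                    pre_params: PreprocessParams = PreprocessParams(),
                    glm_params: ARIRLSParams = ARIRLSParams(),
                    drift_order: int = 3):
    """Preprocess one recording and fit its GLM.

    Returns (HbRecording, per-channel results, ActivationVector).
    """
    hb = preprocess_recording(raw, pre_params)
    results, vec = fit_session(hb, drift_order=drift_order, params=glm_params)
    return hb, results, vec


def _comparison_groups(sessions: list[dict]) -> dict[str, list[int]]:
    """Split one subject-condition's sessions into comparison groups.

    ``across_days``: sessions at the same time of day on different days;
    ``same_day``: sessions on day 1 at different times (when present).
    """
    groups: dict[str, list[int]] = {}
    across = [i for i, s in enumerate(sessions)
              if s.get("time_of_day", "morning") == "morning"]
    if len(across) >= 2:
        groups["across_days"] = across
    same = [i for i, s in enumerate(sessions) if int(s.get("day", 1)) == 1]
    if len(same) >= 2:
        groups["same_day"] = same
    if not groups and len(sessions) >= 2:
        groups["all"] = list(range(len(sessions)))
    return groups


def analyze_study(recordings: list[RawRecording],
                  pre_params: PreprocessParams = PreprocessParams(),
                  glm_params: ARIRLSParams = ARIRLSParams(),
                  drift_order: int = 3,
                  rois: dict[str, list[int]] | None = None) -> PipelineResult:
    """Run the full pipeline over a collection of session recordings."""
    glm_rows = []
    activation: dict[tuple[str, str], ActivationVector] = {}
    sess_meta: dict[tuple[str, str], dict] = {}
    log = []
    phash = _params_hash(pre_params, glm_params, drift_order)
    for rec in recordings:
        subj = str(rec.meta.get("subject", "S?"))
        sess = str(rec.meta.get("session", f"sess{len(activation) + 1}"))
        hb, results, vec = analyze_session(rec, pre_params, glm_params,
                                           drift_order)
        vec.session = sess
        activation[(subj, sess)] = vec
        sess_meta[(subj, sess)] = {
            "condition": rec.meta.get("condition", ""),
            "day": rec.meta.get("day", 1),
            "time_of_day": rec.meta.get("time_of_day", "morning"),
            "hr": rec.physio.hr if rec.physio else np.nan,
            "map": rec.physio.map if rec.physio else np.nan,
        }
        log.append(("session", subj, sess,
                    {"pruned": sorted(hb.pruned), "params_hash": phash}))
        for ch, res in results.items():
            for chrom, r in res.items():
                glm_rows.append({
                    "subject": subj, "session": sess, "channel": ch,
                    "chromophore": chrom, "beta": r.beta, "se": r.se,
                    "t": r.t, "p": r.p, "ar_order": r.ar_order,
                    "converged": r.converged, "params_hash": phash})

    probe = recordings[0].probe
    roi_defs: dict[str, list[int] | None] = {"whole": None}
    for name, chans in (rois or probe.rois).items():
        roi_defs[name] = list(chans)

    pair_rows, subj_rows = [], []
    subjects = sorted({k[0] for k in activation})
    for subj in subjects:
        sess_keys = [k for k in activation if k[0] == subj]
        metas = [sess_meta[k] for k in sess_keys]
        condition = metas[0]["condition"]
        for gname, idx in _comparison_groups(metas).items():
            vecs = [activation[sess_keys[i]] for i in idx]
            cond_label = f"{condition}_{gname}" if condition else gname
            hr = physio_change([metas[i]["hr"] for i in idx])
            mp = physio_change([metas[i]["map"] for i in idx])
            for roi, chans in roi_defs.items():
                for a, b in combinations(vecs, 2):
                    s = pair_scores(a, b, chans, roi=roi, subject=subj)
                    pair_rows.append({
                        "subject": subj, "condition": cond_label, "roi": roi,
                        "session_i": s.pair[0], "session_j": s.pair[1],
                        "a_i": s.a_i, "a_j": s.a_j,
                        "a_overlap": s.a_overlap, "r_q": s.r_q, "r_o": s.r_o})
                rep = subject_repro(vecs, chans, roi=roi, subject=subj,
                                    condition=cond_label,
                                    d_hr_pct=hr, d_map_pct=mp)
                subj_rows.append({
                    "subject": subj, "condition": cond_label, "roi": roi,
                    "r_q_mean": rep.r_q_mean, "r_q_se": rep.r_q_se,
                    "r_o_mean": rep.r_o_mean, "r_o_se": rep.r_o_se,
                    "v_q": rep.v_q, "n_pairs": rep.n_pairs,
                    "d_hr_pct": hr, "d_map_pct": mp,
                    "params_hash": phash})

    subject_table = pd.DataFrame(subj_rows)
    median_table = summarize_medians(subject_table) if len(subject_table) else \
        pd.DataFrame()
    regression = None
    whole = subject_table[subject_table["roi"] == "whole"] \
        if len(subject_table) else pd.DataFrame()
    if len(whole) >= 4 and whole["d_hr_pct"].nunique() > 1 \
            and whole["d_map_pct"].nunique() > 1:
        try:
            regression = variability_regression(whole)
        except ValueError:
            regression = None
    return PipelineResult(
        glm_table=pd.DataFrame(glm_rows), activation=activation,
        pair_table=pd.DataFrame(pair_rows), subject_table=subject_table,
        median_table=median_table, regression=regression,
        params_hash=phash, log=log)


def run_pipeline(manifest: StudyManifest, out_dir: str | Path) -> PipelineResult:
    """Load every session in the manifest, analyse, and write TSV tables."""
    recordings = []
    for s in manifest.sessions:
        rec = read_snirf(s["path"])
        rec.meta.update({k: s[k] for k in
                         ("subject", "session", "condition", "day",
                          "time_of_day") if k in s})
        recordings.append(rec)
    result = analyze_study(recordings, manifest.pre_params,
                           manifest.glm_params, manifest.drift_order,
                           manifest.rois)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.glm_table.to_csv(out / "glm.tsv", sep="\t", index=False)
    result.pair_table.to_csv(out / "pair_scores.tsv", sep="\t", index=False)
    result.subject_table.to_csv(out / "subject_summary.tsv", sep="\t",
                                index=False)
    result.median_table.to_csv(out / "medians.tsv", sep="\t", index=False)
    if result.regression is not None:
        result.regression.to_csv(out / "variability_regression.tsv",
                                 sep="\t", index=False)
    act_rows = []
    for (subj, sess), vec in result.activation.items():
        for ch, v in zip(vec.channel_ids, vec.values):
            act_rows.append({"subject": subj, "session": sess,
                             "channel": int(ch), "active": int(v)})
    pd.DataFrame(act_rows).to_csv(out / "activation.tsv", sep="\t",
                                  index=False)
    return result
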