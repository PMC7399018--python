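"""Study-level simulation experiments.

Self-contained experiment runners used to characterize the pipeline on
synthetic studies with known ground truth: false-positive calibration of
the dual-chromophore classifier, AR-IRLS parameter recovery, and the
guided-vs-standard placement contrast.  All of them are seeded and run
at reduced problem sizes chosen to finish in minutes on one core; sizes
are arguments, so larger replications are one call away.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .glm import ARIRLSParams, ar_irls_fit, build_design, fit_session
from .pipeline import analyze_study
from .preprocess import preprocess_recording
from .probe import make_probe
from .synth import (EvokedSpec, StudyDesign, make_stim_schedule,
                    simulate_session, simulate_study)

__all__ = ["null_activation_rates", "ar_irls_recovery",
           "placement_contrast", "mbll_round_trip_error"]


def null_activation_rates(n_channel_sessions: int = 500, seed: int = 0,
                          layout: str = "compact", n_blocks: int = 10,
                          alpha: float = 0.05) -> dict:
    """False-positive calibration on null sessions.

    Simulates task-free sessions (zero evoked response, full shared
    superficial physiology, background hemodynamics, noise), runs the
    complete pipeline, and counts how often a long channel is declared
    active by the dual-chromophore rule versus by an HbO-only rule
    (p < alpha and beta > 0).
    """
    probe = make_probe(layout)
    n_long = len(probe.long_idx)
    # a couple of spare sessions in case pruning drops some channels
    n_sessions = int(np.ceil(n_channel_sessions / n_long)) + 2
    ss = np.random.SeedSequence(seed)
    dual = hbo_only = total = 0
    params = ARIRLSParams(alpha=alpha)
    for sess_ss in ss.spawn(n_sessions):
        child = sess_ss.spawn(2)
        sched = make_stim_schedule(n_blocks, 2.0, 10.0, 20.0, seed=child[0])
        rec = simulate_session(
            probe, sched, EvokedSpec(amp_hbo=0.0, amp_hbr=0.0),
            seed=child[1])
        hb = preprocess_recording(rec)
        results, vec = fit_session(hb, params=params)
        for ch, res in results.items():
            total += 1
            o, d = res["hbo"], res["hbr"]
            if o.p < alpha and d.p < alpha and o.beta > 0 and d.beta < 0:
                dual += 1
            if o.p < alpha and o.beta > 0:
                hbo_only += 1
        if total >= n_channel_sessions:
            break
    return {"dual_rate": dual / total, "hbo_only_rate": hbo_only / total,
            "n": total}


def ar_irls_recovery(n_reps: int = 200, seed: int = 0, n_samples: int = 2000,
                     phi: float = 0.8, beta_true: float = 1.0,
                     noise_sd: float = 0.5, fs: float = 8.9) -> dict:
    """Parameter recovery of the AR-prewhitened robust GLM.

    Task responses with AR(1) noise; reports the fraction of fits whose
    task coefficient lands within 3 SE of truth and the mean absolute
    lag-1 autocorrelation of the whitened residuals.
    """
    from .glm import _ar_fit_aic, _whiten
    ss = np.random.SeedSequence(seed)
    hits = 0
    lag1 = []
    for rep_ss in ss.spawn(n_reps):
        child = rep_ss.spawn(2)
        rng = np.random.default_rng(child[0])
        sched = make_stim_schedule(max(2, int(n_samples / fs / 20)),
                                   2.0, 10.0, 20.0, seed=child[1])
        design = build_design(sched, fs, n_samples,
                              short_series=rng.standard_normal(n_samples),
                              drift_order=1)
        noise = lfilter([1.0], [1.0, -phi],
                        rng.standard_normal(n_samples)) * noise_sd
        y = design.X[:, design.task_col] * beta_true + noise
        r = ar_irls_fit(y, design, fs=fs)
        if abs(r.beta - beta_true) < 3 * r.se:
            hits += 1
        resid = y - design.X @ r.betas
        ph = _ar_fit_aic(resid, int(round(4 * fs)))
        w = _whiten(resid, ph)
        lag1.append(np.corrcoef(w[1:], w[:-1])[0, 1])
    return {"coverage_3se": hits / n_reps,
            "whitened_lag1_autocorr": float(np.mean(np.abs(lag1))),
            "n": n_reps}


def _condition_median(condition: str, seed, layout: str, n_blocks: int,
                      n_subjects: int, n_days: int, roi: str,
                      glm_params: ARIRLSParams) -> dict:
    design = StudyDesign(n_subjects=n_subjects, n_days=n_days,
                         condition=condition, layout=layout,
                         n_blocks=n_blocks)
    recs = simulate_study(design, seed=seed)
    res = analyze_study(recs, glm_params=glm_params)
    t = res.subject_table
    out = {}
    for r in ("whole", roi):
        sub = t[t.roi == r]
        out[f"r_o_{r}"] = float(sub.r_o_mean.median())
        out[f"r_q_{r}"] = float(sub.r_q_mean.median())
    return out


def placement_contrast(n_seed_sets: int = 10, seed: int = 0,
                       layout: str = "compact", n_blocks: int = 30,
                       n_subjects: int = 5, n_days: int = 3,
                       roi: str = "navigated",
                       glm_params: ARIRLSParams | None = None
                       ) -> pd.DataFrame:
    """Guided vs standard placement, replicated over seed sets.

    For each seed set, simulates one guided-placement and one
    standard-placement study (same design otherwise), runs the full
    pipeline, and records the across-subject median R_q / R_o for the
    whole probe and the target ROI.
    """
    glm_params = glm_params or ARIRLSParams()
    ss = np.random.SeedSequence(seed)
    rows = []
    for k, set_ss in enumerate(ss.spawn(n_seed_sets)):
        g_ss, s_ss = set_ss.spawn(2)
        g = _condition_median("guided", g_ss, layout, n_blocks, n_subjects,
                              n_days, roi, glm_params)
        s = _condition_median("standard", s_ss, layout, n_blocks, n_subjects,
                              n_days, roi, glm_params)
        rows.append({
            "seed_set": k,
            "guided_r_o_roi": g[f"r_o_{roi}"],
            "standard_r_o_roi": s[f"r_o_{roi}"],
            "guided_r_q_roi": g[f"r_q_{roi}"],
            "standard_r_q_roi": s[f"r_q_{roi}"],
            "guided_r_o_whole": g["r_o_whole"],
            "standard_r_o_whole": s["r_o_whole"],
            "guided_wins": g[f"r_o_{roi}"] > s[f"r_o_{roi}"],
        })
    return pd.DataFrame(rows)


def mbll_round_trip_error(seed: int = 0, layout: str = "compact") -> dict:
    """Forward simulation -> OD -> Beer-Lambert inversion, noiseless.

    Returns the maximum absolute concentration error (uM) against the
    injected ground truth over the three strongest channels.
    """
    from .glm import gamma_hrf
    from .preprocess import intensity_to_od, od_to_hb
    from .synth import NoiseParams, PhysioParams
    probe = make_probe(layout)
    ss = np.random.SeedSequence(seed)
    c1, c2 = ss.spawn(2)
    sched = make_stim_schedule(5, 2.0, 10.0, 12.0, seed=c1)
    quiet = PhysioParams(cardiac_amp=0, resp_amp=0, mayer_amp=0, drift_amp=0,
                         background_hbo=0, background_hbr=0)
    none = NoiseParams(intensity_noise=0, spike_rate=0, shift_prob=0)
    rec = simulate_session(probe, sched, EvokedSpec(session_amp_sd=0),
                           quiet, none, seed=c2)
    hb = od_to_hb(intensity_to_od(rec, prune=False))
    gt = rec.ground_truth
    fs, n_t = rec.fs, rec.n_times
    box = sched.boxcar(n_t, fs)
    kern = gamma_hrf(np.arange(0, 30, 1 / fs))
    ev = np.convolve(box, kern)[:n_t]
    ev = ev / ev.max()
    err = 0.0
    for ch in np.argsort(gt.amp_hbo)[-3:]:
        for amp, chrom in ((gt.amp_hbo[ch], "hbo"), (gt.amp_hbr[ch], "hbr")):
            true = amp * ev
            got = hb.series(int(ch), chrom)
            err = max(err, float(np.max(np.abs(
                (got - got.mean()) - (true - true.mean())))))
    return {"max_error_uM": err, "n": n_t}
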