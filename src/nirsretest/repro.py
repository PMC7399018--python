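"""Test-retest reproducibility statistics for activation maps.

Two indices compare the activation of a pair of sessions over a set of
channels (a region of interest): the size index

    R_q = 1 - |A_i - A_j| / (A_i + A_j)

and the Dice-type overlap index

    R_o = 2 * A_overlap / (A_i + A_j),

where A_i is the number of active channels in session i and A_overlap
the number of channels active in both.  When neither session has any
active channel both indices are defined as 0.  The complement
v_q = 1 - mean(R_q) measures variability and is regressed on relative
heart-rate and arterial-pressure changes to ask how much of it systemic
physiology explains.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .glm import ActivationVector, GLMChannelResult, classify_activation

__all__ = [
    "SessionPairScore", "SubjectRepro", "FrequencyVector",
    "pair_scores", "subject_repro", "frequency_map", "summarize_medians",
    "variability_regression", "group_betas", "physio_change",
]


@dataclass(frozen=True)
class SessionPairScore:
    subject: str
    pair: tuple[str, str]
    roi: str
    a_i: int
    a_j: int
    a_overlap: int
    r_q: float
    r_o: float


@dataclass(frozen=True)
class SubjectRepro:
    subject: str
    condition: str
    roi: str
    r_q_mean: float
    r_q_se: float
    r_o_mean: float
    r_o_se: float
    v_q: float
    n_pairs: int
    d_hr_pct: float | None = None
    d_map_pct: float | None = None


@dataclass(frozen=True)
class FrequencyVector:
    subject: str
    roi: str
    channel_ids: np.ndarray
    counts: np.ndarray
    n_sessions: int

    @property
    def frequency(self) -> np.ndarray:
        return self.counts / self.n_sessions


def _roi_mask(vec: ActivationVector, roi_channels) -> np.ndarray:
    if roi_channels is None:
        return np.ones(len(vec.channel_ids), dtype=bool)
    roi = np.atleast_1d(np.asarray(roi_channels))
    if not np.all(np.isin(roi, vec.channel_ids)):
        raise ValueError("ROI contains channels outside the activation vector")
    return np.isin(vec.channel_ids, roi)


def pair_scores(b_i: ActivationVector, b_j: ActivationVector,
                roi_channels=None, roi: str = "whole",
                subject: str = "") -> SessionPairScore:
    """Size and overlap reproducibility of one session pair."""
    if (len(b_i.channel_ids) != len(b_j.channel_ids)
            or np.any(b_i.channel_ids != b_j.channel_ids)):
        raise ValueError("activation vectors have mismatched channel sets")
    mask = _roi_mask(b_i, roi_channels)
    vi = b_i.values[mask].astype(bool)
    vj = b_j.values[mask].astype(bool)
    a_i, a_j = int(vi.sum()), int(vj.sum())
    a_ov = int((vi & vj).sum())
    tot = a_i + a_j
    if tot == 0:
        r_q = r_o = 0.0
    else:
        r_q = 1.0 - abs(a_i - a_j) / tot
        r_o = 2.0 * a_ov / tot
    return SessionPairScore(subject=subject, pair=(b_i.session, b_j.session),
                            roi=roi, a_i=a_i, a_j=a_j, a_overlap=a_ov,
                            r_q=r_q, r_o=r_o)


def subject_repro(sessions: list[ActivationVector], roi_channels=None,
                  roi: str = "whole", subject: str = "",
                  condition: str = "", d_hr_pct: float | None = None,
                  d_map_pct: float | None = None) -> SubjectRepro:
    """Mean and SE of R_q / R_o over all session pairs of one subject."""
    if len(sessions) < 2:
        raise ValueError("need at least 2 sessions")
    scores = [pair_scores(a, b, roi_channels, roi, subject)
              for a, b in combinations(sessions, 2)]
    rq = np.array([s.r_q for s in scores])
    ro = np.array([s.r_o for s in scores])
    n = len(scores)
    se = (lambda v: float(v.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0)
    return SubjectRepro(
        subject=subject, condition=condition, roi=roi,
        r_q_mean=float(rq.mean()), r_q_se=se(rq),
        r_o_mean=float(ro.mean()), r_o_se=se(ro),
        v_q=float(1.0 - rq.mean()), n_pairs=n,
        d_hr_pct=d_hr_pct, d_map_pct=d_map_pct)


def frequency_map(sessions: list[ActivationVector], roi_channels=None,
                  roi: str = "whole", subject: str = "") -> FrequencyVector:
    """Per-channel count of sessions in which the channel was active."""
    if not sessions:
        raise ValueError("need at least 1 session")
    first = sessions[0]
    for s in sessions[1:]:
        if np.any(s.channel_ids != first.channel_ids):
            raise ValueError("activation vectors have mismatched channel sets")
    mask = _roi_mask(first, roi_channels)
    counts = np.sum([s.values[mask] for s in sessions], axis=0)
    return FrequencyVector(subject=subject, roi=roi,
                           channel_ids=first.channel_ids[mask],
                           counts=counts.astype(int),
                           n_sessions=len(sessions))


def summarize_medians(table: pd.DataFrame,
                      group_cols=("condition", "roi"),
                      value_cols=("r_q_mean", "r_o_mean",
                                  "d_hr_pct", "d_map_pct")) -> pd.DataFrame:
    """Across-subject medians per group (condition x ROI).

    The median of an even-sized group is the midpoint of the two middle
    order statistics.  Empty groups are omitted.
    """
    cols = [c for c in value_cols if c in table.columns]
    group_cols = [c for c in group_cols if c in table.columns]
    if not group_cols:
        return table[cols].median().to_frame().T
    return (table.groupby(list(group_cols), dropna=False)[cols]
            .median().reset_index())


def variability_regression(table: pd.DataFrame, covariates_as: str = "fraction"
                           ) -> pd.DataFrame:
    """OLS of v_q on heart-rate and arterial-pressure changes.

    Model: v_q = alpha + beta * dHR + gamma * dMAP, with an intercept.
    ``covariates_as`` selects the covariate scale: ``"fraction"``
    divides the tabulated percent changes by 100, ``"percent"`` uses
    them as printed.  Returns a coefficient table with SE and two-sided
    p-values.
    """
    need = {"v_q", "d_hr_pct", "d_map_pct"}
    if not need.issubset(table.columns):
        raise ValueError(f"table must contain columns {sorted(need)}")
    df = table.dropna(subset=sorted(need))
    if len(df) < 4:
        raise ValueError("need at least 4 rows for the 3-parameter model")
    scale = 0.01 if covariates_as == "fraction" else 1.0
    X = np.column_stack([df["d_hr_pct"].to_numpy() * scale,
                         df["d_map_pct"].to_numpy() * scale])
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(df)), X])) < 3:
        raise ValueError("collinear covariates")
    fit = sm.OLS(df["v_q"].to_numpy(), sm.add_constant(X)).fit()
    return pd.DataFrame({
        "term": ["alpha", "beta_dHR", "gamma_dMAP"],
        "estimate": fit.params,
        "se": fit.bse,
        "p": fit.pvalues,
    })


def physio_change(values: np.ndarray, how: str = "range_over_mean") -> float:
    """Relative physiological change over a condition's sessions, percent.

    ``range_over_mean``: 100 * (max - min) / mean of the session values
    (each session value being the mean of its pre/post readings).
    """
    v = np.asarray(values, dtype=float)
    if how != "range_over_mean":
        raise ValueError(f"unknown convention {how!r}")
    if len(v) < 2:
        return 0.0
    return float(100.0 * (v.max() - v.min()) / v.mean())


def group_betas(tables: list[dict[int, dict[str, GLMChannelResult]]],
                channel_ids: np.ndarray, alpha: float = 0.05):
    """Inverse-variance weighted group-level coefficients per channel.

    beta_g = sum(beta_i / SE_i^2) / sum(1 / SE_i^2) and
    SE_g = (sum 1/SE_i^2)^(-1/2), per chromophore; group activation uses
    the same dual-chromophore rule as the session level with the Wald
    normal approximation for the group p-value.
    """
    rows = []
    group_results: dict[int, dict[str, GLMChannelResult]] = {}
    for ch in channel_ids:
        entry = {}
        for chrom in ("hbo", "hbr"):
            bs, ses = [], []
            for tab in tables:
                if ch in tab and chrom in tab[ch]:
                    r = tab[ch][chrom]
                    if r.se == 0:
                        raise ValueError(
                            f"zero SE for channel {ch} ({chrom}); cannot weight")
                    bs.append(r.beta)
                    ses.append(r.se)
            if not bs:
                continue
            w = 1.0 / np.asarray(ses) ** 2
            bg = float(np.sum(w * bs) / np.sum(w))
            seg = float(np.sum(w) ** -0.5)
            z = bg / seg
            from scipy import stats as _st
            pg = float(2.0 * _st.norm.sf(abs(z)))
            entry[chrom] = GLMChannelResult(
                beta=bg, se=seg, t=z, p=pg, ar_order=0, converged=True,
                n_iter=0, weight_mean=1.0, dof=len(bs) - 1)
            rows.append({"channel": int(ch), "chromophore": chrom,
                         "beta": bg, "se": seg, "z": z, "p": pg,
                         "n": len(bs)})
        if entry:
            group_results[int(ch)] = entry
    vec = classify_activation(group_results, channel_ids, session="group",
                              alpha=alpha)
    return pd.DataFrame(rows), vec
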