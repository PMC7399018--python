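"""Bundled reference tables.

``reference_subject_scores`` returns the per-subject test-retest summary
of a published 10-subject finger-tapping fNIRS study (five subjects per
placement condition, three to five sessions each): mean size (R_q) and
overlap (R_o) reproducibility per region of interest, and the relative
heart-rate / mean-arterial-pressure changes across the compared
sessions.  It is used as a worked example for the median summaries and
the systemic-physiology variability regression.
"""

from __future__ import annotations

import io

import pandas as pd

__all__ = ["reference_subject_scores"]

# condition: standard placement compared within the same day / across
# days (whole probe), and standard vs guided placement across days per
# ROI.  d_hr_pct / d_map_pct are only tabulated for the whole-probe
# standard-placement comparisons.
_SCORES_TSV = """\
subject	condition	roi	r_q_mean	r_o_mean	d_hr_pct	d_map_pct
1	standard_same_day	whole	0.00	0.00	11.8	3.1
2	standard_same_day	whole	0.41	0.17	12.5	14.2
3	standard_same_day	whole	0.73	0.45	20.7	5.5
4	standard_same_day	whole	0.89	0.36	6.8	13.2
5	standard_same_day	whole	0.90	0.68	9.5	4.7
1	standard_across_days	whole	0.00	0.00	8.9	8.3
2	standard_across_days	whole	0.13	0.00	6.8	5.1
3	standard_across_days	whole	0.66	0.31	14.5	8.3
4	standard_across_days	whole	0.71	0.04	4.0	8.3
5	standard_across_days	whole	0.94	0.71	9.0	5.1
1	guided_across_days	whole	0.54	0.08
2	guided_across_days	whole	0.71	0.51
3	guided_across_days	whole	0.34	0.32
4	guided_across_days	whole	0.75	0.36
5	guided_across_days	whole	0.90	0.49
1	standard_across_days	left	0.00	0.00
2	standard_across_days	left	0.13	0.00
3	standard_across_days	left	0.11	0.11
4	standard_across_days	left	0.29	0.00
5	standard_across_days	left	0.94	0.77
1	guided_across_days	left	0.69	0.07
2	guided_across_days	left	0.63	0.56
3	guided_across_days	left	0.39	0.37
4	guided_across_days	left	0.82	0.43
5	guided_across_days	left	0.83	0.65
1	standard_across_days	navigated	0.00	0.00
2	standard_across_days	navigated	0.17	0.00
3	standard_across_days	navigated	0.17	0.17
4	standard_across_days	navigated	0.00	0.00
5	standard_across_days	navigated	0.89	0.89
1	guided_across_days	navigated	0.13	0.00
2	guided_across_days	navigated	0.70	0.70
3	guided_across_days	navigated	0.44	0.44
4	guided_across_days	navigated	0.85	0.59
5	guided_across_days	navigated	0.87	0.73
"""


def reference_subject_scores() -> pd.DataFrame:
    """Per-subject reproducibility summary of the reference study.

    Columns: subject, condition, roi, r_q_mean, r_o_mean, d_hr_pct,
    d_map_pct (the last two only for the whole-probe standard rows), plus
    v_q = 1 - r_q_mean.
    """
    df = pd.read_csv(io.StringIO(_SCORES_TSV), sep="\t")
    df["v_q"] = 1.0 - df["r_q_mean"]
    return df
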