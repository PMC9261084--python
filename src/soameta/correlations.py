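"""Pearson correlations between task measures and clinical scales.

Patients are rated on the PANSS (positive, negative, general, total);
controls on the SPQ-B schizotypy questionnaire (cognitive-perceptual,
interpersonal, disorganization, total).  Each (measure x scale) cell gets a
Pearson r with an uncorrected two-sided p — mirroring the exploratory,
uncorrected report such tables receive — plus a Holm-adjusted column for
users who want family-wise control.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

MEASURES = ("d_prime", "criterion_c", "gamma")

SCALES = {
    "control": ["spqb_cogper", "spqb_inter", "spqb_disorg", "spqb_total"],
    "psychosis": ["panss_positive", "panss_negative", "panss_general", "panss_total"],
}


def clinical_correlations(summaries: pd.DataFrame, measures=MEASURES) -> pd.DataFrame:
    """Correlation table from a per-participant summary frame.

    ``summaries`` needs ``group``, the measure columns and the clinical
    scale columns.  Cells with fewer than 3 complete pairs or a constant
    vector are flagged (r = NaN, note set) rather than dropped silently.
    """
    rows = []
    for group, scales in SCALES.items():
        sub = summaries[summaries["group"] == group]
        for scale in scales:
            for measure in measures:
                if measure not in sub.columns or scale not in sub.columns:
                    continue
                x = sub[measure].to_numpy(float)
                y = sub[scale].to_numpy(float)
                ok = np.isfinite(x) & np.isfinite(y)
                n = int(ok.sum())
                row = {"group": group, "measure": measure, "scale": scale, "n": n,
                       "r": np.nan, "p": np.nan, "note": ""}
                if n < 3:
                    row["note"] = "fewer than 3 complete pairs"
                elif np.all(x[ok] == x[ok][0]) or np.all(y[ok] == y[ok][0]):
                    row["note"] = "constant vector; r undefined"
                else:
                    r, p = stats.pearsonr(x[ok], y[ok])
                    row["r"], row["p"] = float(r), float(p)
                rows.append(row)
    table = pd.DataFrame(rows)
    ok = table["p"].notna()
    table["p_holm"] = np.nan
    if ok.any():
        table.loc[ok, "p_holm"] = multipletests(table.loc[ok, "p"], method="holm")[1]
    return table
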