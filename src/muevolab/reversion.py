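"""Colony phenotype classification and reversion-rate statistics.

Colonies picked from terminal populations are streaked on four selective
media: unsupplemented minimal plates (MMAB), MMAB with tryptophan, MMAB
with tyrosine, and rich LB. Growth on all four marks a phenotypic
revertant (prototroph); growth only with the required amino acid (and on
LB) identifies the surviving auxotroph; any other pattern is ambiguous.
A fifth MMAB+Trp+Tyr plate, used when physically separating coculture
partners, never changes a call and is simply ignored if present.

Reversion proportions are compared between mono- and coevolved groups
with a plain two-sided Pearson chi-square (df = 1, no continuity
correction).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

PHENOTYPES = ("PROTOTROPH_REVERTANT", "TRP_AUXOTROPH", "TYR_AUXOTROPH",
              "AMBIGUOUS")

LOWER_DETECTION_CFU = 2.5e4
UPPER_DETECTION_CFU = 2.5e6


def classify_colony(mmab: bool, mmab_trp: bool, mmab_tyr: bool, lb: bool) -> str:
    """Map one colony's growth flags to a phenotype call.

    Raises ValueError for a colony that fails to grow on LB (not viable).
    """
    if not lb:
        raise ValueError("colony did not grow on LB: not viable, cannot classify")
    if mmab and mmab_trp and mmab_tyr:
        return "PROTOTROPH_REVERTANT"
    if mmab_trp and not mmab and not mmab_tyr:
        return "TRP_AUXOTROPH"
    if mmab_tyr and not mmab and not mmab_trp:
        return "TYR_AUXOTROPH"
    return "AMBIGUOUS"


def classify_screen(screen: pd.DataFrame) -> pd.DataFrame:
    """Classify every colony of a colonies table; adds a ``call`` column."""
    calls = [classify_colony(r.mmab, r.mmab_trp, r.mmab_tyr, r.lb)
             for r in screen.itertuples()]
    out = screen.copy()
    out["call"] = calls
    return out


def reversion_table(calls: pd.DataFrame, group_col: str = "group", *,
                    lower_detection: float = LOWER_DETECTION_CFU) -> pd.DataFrame:
    """Aggregate phenotype calls into per-group reversion counts.

    Ambiguous colonies are excluded from the denominator but counted.
    A group with zero detected revertants is flagged ``below_detection``
    (its true revertant frequency is only bounded by the screen's lower
    detection limit, never exactly zero); its proportion is reported NaN.
    """
    if group_col not in calls.columns:
        raise ValueError(f"calls table needs a {group_col!r} column")
    rows = []
    for grp, sub in calls.groupby(group_col, sort=False):
        n_rev = int((sub["call"] == "PROTOTROPH_REVERTANT").sum())
        n_aux = int(sub["call"].isin(["TRP_AUXOTROPH", "TYR_AUXOTROPH"]).sum())
        n_amb = int((sub["call"] == "AMBIGUOUS").sum())
        if n_rev + n_aux == 0:
            raise ValueError(f"group {grp!r}: all colonies ambiguous")
        below = n_rev == 0
        prop = np.nan if below else n_rev / (n_rev + n_aux)
        rows.append({"group": grp, "n_auxotroph": n_aux, "n_revertant": n_rev,
                     "n_ambiguous": n_amb, "proportion_revertant": prop,
                     "below_detection": below,
                     "detection_note": (f"< {lower_detection:.2g} CFU/ml"
                                        if below else "")})
    return pd.DataFrame(rows)


def chi2_2x2(a: int, b: int, c: int, d: int) -> tuple[float, int, float]:
    """Two-sided Pearson chi-square on a 2x2 table, no continuity correction.

    Returns (chi2, df=1, p). Raises ValueError if any margin is zero.
    """
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("chi-square undefined: a table margin is zero")
    res = stats.chi2_contingency(table, correction=False)
    return float(res.statistic), 1, float(res.pvalue)


def compare_reversion(table: pd.DataFrame, group_a: str, group_b: str
                      ) -> dict:
    """Chi-square comparison of revertant/auxotroph counts between two groups."""
    t = table.set_index("group")
    for g in (group_a, group_b):
        if g not in t.index:
            raise ValueError(f"group {g!r} not in reversion table")
    chi2, df, p = chi2_2x2(int(t.loc[group_a, "n_revertant"]),
                           int(t.loc[group_a, "n_auxotroph"]),
                           int(t.loc[group_b, "n_revertant"]),
                           int(t.loc[group_b, "n_auxotroph"]))
    return {"group_a": group_a, "group_b": group_b,
            "chi2": chi2, "df": df, "p": p}
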