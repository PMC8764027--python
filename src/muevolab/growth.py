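"""Growth-curve metrics, MIC calling, delta-MIC, and group comparisons.

The maximum growth rate follows the mean-curve procedure: growth curves of
all replicates in a treatment are averaged per time point, the pair of
consecutive time points with the maximal raw increase of the mean curve is
located, and each replicate's rate is then computed over that shared
interval. Both the raw slope (CFU ml^-1 h^-1) and the specific log-slope
(h^-1) are reported, since either reading of "maximum growth rate" is
defensible.

MIC is called per replicate as the first concentration whose OD600 stays
below 0.01; replicates never crossing are censored at the top of the grid.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

MIC_OD_THRESHOLD = 0.01


def max_growth_rate(curves: pd.DataFrame, *, strain: str | None = None
                    ) -> pd.DataFrame:
    """Per-replicate maximum growth rate over the mean curve's steepest interval.

    ``curves`` is a growth_curves table (one treatment). Returns one row per
    replicate with the shared interval (t1, t2), the raw slope, the
    specific log-slope ``(ln CFU(t2) - ln CFU(t1)) / (t2 - t1)``, and the
    72-h yield. Replicates with zero CFU inside the interval get NaN rates
    and ``rate_defined = False``.
    """
    df = curves if strain is None else curves[curves["strain"] == strain]
    if df.empty:
        raise ValueError("no growth-curve rows to analyse")
    wide = df.pivot_table(index="replicate_id", columns="time_h",
                          values="cfu_per_ml", aggfunc="sum")
    if wide.isna().any().any():
        raise ValueError("replicates do not share a common time grid")
    times = wide.columns.to_numpy(dtype=float)
    mean_curve = wide.mean(axis=0).to_numpy()
    increases = np.diff(mean_curve)
    i = int(np.argmax(increases))  # first maximal increase
    t1, t2 = float(times[i]), float(times[i + 1])
    c1 = wide.iloc[:, i].to_numpy(dtype=float)
    c2 = wide.iloc[:, i + 1].to_numpy(dtype=float)
    ok = (c1 > 0) & (c2 > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_slope = np.where(ok, (np.log(np.maximum(c2, 1e-300))
                                  - np.log(np.maximum(c1, 1e-300))) / (t2 - t1),
                             np.nan)
    raw_slope = (c2 - c1) / (t2 - t1)
    t_end = times[-1]
    return pd.DataFrame({
        "replicate_id": wide.index,
        "t1": t1, "t2": t2,
        "max_rate": log_slope,
        "max_rate_raw": raw_slope,
        "rate_defined": ok,
        "yield_end": wide.iloc[:, -1].to_numpy(dtype=float),
        "t_end": t_end,
    }).reset_index(drop=True)


@dataclass(frozen=True)
class MICCall:
    replicate_id: str
    mic: float          # NaN when censored
    censored: bool
    grid_max: float


def call_mic(plate: pd.DataFrame) -> pd.DataFrame:
    """Call the MIC per replicate: first concentration with OD600 < 0.01.

    Replicates whose OD never drops below the threshold are censored at
    the top of their concentration grid (``mic`` = NaN, ``censored`` =
    True). Non-monotone dose responses are taken literally (first
    crossing).
    """
    rows = []
    for rid, sub in plate.groupby("replicate_id", sort=False):
        sub = sub.sort_values("concentration")
        conc = sub["concentration"].to_numpy(dtype=float)
        od = sub["od600"].to_numpy(dtype=float)
        below = od < MIC_OD_THRESHOLD
        if below.any():
            rows.append({"replicate_id": rid,
                         "mic": float(conc[int(np.argmax(below))]),
                         "censored": False, "grid_max": float(conc[-1])})
        else:
            rows.append({"replicate_id": rid, "mic": np.nan,
                         "censored": True, "grid_max": float(conc[-1])})
    return pd.DataFrame(rows)


def delta_mic(derived: pd.DataFrame, ancestral: pd.DataFrame) -> pd.DataFrame:
    """Resistance gain: derived MIC minus the ancestral group median MIC.

    Ancestral and derived replicates are unpaired, so each uncensored
    derived replicate is compared against the ancestral group's median MIC.
    Censored replicates are excluded with a warning; the numbers excluded
    are attached as frame attributes.
    """
    anc_ok = ancestral[~ancestral["censored"]]
    der_ok = derived[~derived["censored"]]
    n_excl = (len(ancestral) - len(anc_ok)) + (len(derived) - len(der_ok))
    if n_excl:
        warnings.warn(f"delta_mic: excluded {n_excl} censored MIC value(s)")
    if anc_ok.empty or der_ok.empty:
        raise ValueError("delta_mic needs uncensored MICs in both groups")
    anc_median = float(anc_ok["mic"].median())
    out = pd.DataFrame({"replicate_id": der_ok["replicate_id"].to_numpy(),
                        "delta": der_ok["mic"].to_numpy(dtype=float) - anc_median})
    out.attrs["ancestral_median"] = anc_median
    out.attrs["n_excluded"] = n_excl
    return out


def _mwu(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    if np.ptp(np.concatenate([x, y])) == 0:
        return len(x) * len(y) / 2.0, 1.0  # all observations identical
    method = "exact" if min(len(x), len(y)) <= 8 else "asymptotic"
    try:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    except ValueError:
        res = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="asymptotic")
    return float(res.statistic), float(min(res.pvalue, 1.0))


def pairwise_compare(groups: dict[str, np.ndarray], alpha: float = 0.05
                     ) -> pd.DataFrame:
    """All-pairs two-sided Mann-Whitney U with Benjamini-Hochberg correction.

    Returns a tidy frame (group_a, group_b, U, p_raw, p_bh) with a compact
    letter display attached as ``result.attrs['letters']``: groups share a
    letter iff their BH-adjusted p is at or above ``alpha``.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    for k, v in groups.items():
        if len(np.asarray(v)) < 2:
            raise ValueError(f"group {k!r} needs at least 2 observations")
    pairs = list(itertools.combinations(labels, 2))
    stats_u, raw = [], []
    for a, b in pairs:
        u, p = _mwu(np.asarray(groups[a], dtype=float),
                    np.asarray(groups[b], dtype=float))
        stats_u.append(u)
        raw.append(p)
    p_bh = multipletests(raw, method="fdr_bh")[1]
    out = pd.DataFrame({"group_a": [a for a, _ in pairs],
                        "group_b": [b for _, b in pairs],
                        "U": stats_u, "p_raw": raw, "p_bh": p_bh})
    out.attrs["letters"] = compact_letters(labels, out, alpha=alpha)
    return out


def compact_letters(labels: list[str], table: pd.DataFrame,
                    alpha: float = 0.05) -> dict[str, str]:
    """Assign display letters from the non-significance graph.

    Each maximal clique of the graph whose edges join groups with adjusted
    p >= alpha receives one letter, so two groups share a letter iff they
    are not significantly different. Cliques are ordered deterministically
    by their first member.
    """
    g = nx.Graph()
    g.add_nodes_from(labels)
    for _, row in table.iterrows():
        if row["p_bh"] >= alpha:
            g.add_edge(row["group_a"], row["group_b"])
    order = {lab: i for i, lab in enumerate(labels)}
    cliques = sorted((sorted(c, key=order.get) for c in nx.find_cliques(g)),
                     key=lambda c: [order[x] for x in c])
    letters: dict[str, str] = {lab: "" for lab in labels}
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for i, clique in enumerate(cliques):
        ch = alphabet[i % len(alphabet)] * (1 + i // len(alphabet))
        for lab in clique:
            letters[lab] += ch
    return letters
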