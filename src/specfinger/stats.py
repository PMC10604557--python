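"""One-way ANOVA and Tukey HSD comparisons of deconvolved band quantities.

Band relative areas (and centers) are compared across disease groups with a
classic between/within variance decomposition and Tukey's studentized-range
post-hoc test at the 5% level (Tukey-Kramer harmonic-mean rule for unequal
group sizes).  Group means are summarized with a compact letter display:
groups sharing no letter differ significantly.  With two groups Tukey
reduces to a pooled t-type comparison but is kept under the same interface
for uniform reporting.

No multiplicity correction is applied *across* bands; each matched band is
tested on its own (a documented limitation).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateInputError
from .deconv import GroupDeconvolution


@dataclass
class AnovaResult:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float


def _check_groups(groups: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    if len(groups) < 2:
        raise DegenerateInputError("need >= 2 groups")
    out = {}
    for name, vals in groups.items():
        v = np.asarray(vals, float)
        if v.size < 2:
            raise DegenerateInputError(f"group {name!r} needs >= 2 values")
        if not np.all(np.isfinite(v)):
            raise DegenerateInputError(f"group {name!r} contains non-finite values")
        out[name] = v
    return out


def one_way_anova(groups: dict[str, np.ndarray]) -> AnovaResult:
    """Classic one-factor ANOVA; F = MS_between / MS_within."""
    g = _check_groups(groups)
    vals = list(g.values())
    k = len(vals)
    n = sum(v.size for v in vals)
    if np.ptp(np.concatenate(vals)) == 0:
        # every observation identical: no variance at all => F = 0, p = 1
        return AnovaResult(0.0, k - 1, n - k, 1.0)
    f, p = sps.f_oneway(*vals)
    return AnovaResult(float(f), k - 1, n - k, float(p))


@dataclass
class TukeyResult:
    pairwise: pd.DataFrame     # group_a, group_b, mean_diff, p_value, significant
    letters: dict[str, str]    # compact letter display
    alpha: float


def _letters(names: list[str], means: dict[str, float],
             differs: set[tuple[str, str]]) -> dict[str, str]:
    """Greedy clique cover of the 'not significantly different' graph.

    Groups are processed in descending mean order; each joins every existing
    letter column compatible with all its members, else opens a new column.
    """
    ordered = sorted(names, key=lambda nm: -means[nm])
    columns: list[list[str]] = []
    for nm in ordered:
        placed = False
        for col in columns:
            if all((nm, other) not in differs and (other, nm) not in differs for other in col):
                col.append(nm)
                placed = True
        if not placed:
            columns.append([nm])
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {nm: "" for nm in names}
    for li, col in enumerate(columns):
        for nm in col:
            out[nm] += alphabet[li]
    return out


def tukey_hsd(groups: dict[str, np.ndarray], alpha: float = 0.05) -> TukeyResult:
    """Tukey HSD pairwise comparisons plus a compact letter display."""
    g = _check_groups(groups)
    names = list(g.keys())
    vals = [g[nm] for nm in names]
    means = {nm: float(np.mean(g[nm])) for nm in names}
    pooled_within = sum(np.sum((v - v.mean()) ** 2) for v in vals)

    rows = []
    differs: set[tuple[str, str]] = set()
    if pooled_within == 0:
        # degenerate: zero within-group variance; equal means are identical,
        # unequal means differ with certainty
        for a, b in combinations(names, 2):
            p = 1.0 if means[a] == means[b] else 0.0
            sig = p < alpha
            if sig:
                differs.add((a, b))
            rows.append({"group_a": a, "group_b": b,
                         "mean_diff": means[a] - means[b], "p_value": p,
                         "significant": sig})
    else:
        res = sps.tukey_hsd(*vals)
        for i, j in combinations(range(len(names)), 2):
            a, b = names[i], names[j]
            p = float(res.pvalue[i, j])
            sig = p < alpha
            if sig:
                differs.add((a, b))
            rows.append({"group_a": a, "group_b": b,
                         "mean_diff": means[a] - means[b], "p_value": p,
                         "significant": sig})
    return TukeyResult(pd.DataFrame(rows), _letters(names, means, differs), alpha)


def compare_band_tables(group_a: GroupDeconvolution, group_b: GroupDeconvolution,
                        alpha: float = 0.05, match_tol: float = 10.0) -> pd.DataFrame:
    """Band-by-band comparison of two deconvolved cohorts.

    Bands are paired greedily by nearest mean center within ``match_tol``
    cm^-1 (so e.g. 1588 vs 1581 and 1639 vs 1635 pair up while a 1565 band
    with no counterpart stays unpaired).  Matched pairs get an ANOVA/Tukey
    comparison of per-sample relative areas and centers; unmatched bands are
    flagged as unique to their group.  The report is symmetric under
    swapping the group order.
    """
    ca = group_a.clusters
    cb = group_b.clusters
    pairs = []
    dists = sorted(
        (abs(x.center_mean - y.center_mean), i, j)
        for i, x in enumerate(ca) for j, y in enumerate(cb)
    )
    used_a: set[int] = set()
    used_b: set[int] = set()
    for d, i, j in dists:
        if d > match_tol:
            break
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((i, j))

    la, lb = group_a.label, group_b.label
    rows = []
    for i, j in sorted(pairs, key=lambda ij: ca[ij[0]].center_mean):
        x, y = ca[i], cb[j]
        area_cmp = tukey_hsd({la: x.pct_areas, lb: y.pct_areas}, alpha)
        center_cmp = tukey_hsd({la: x.centers, lb: y.centers}, alpha)
        rows.append({
            "band": 0.5 * (x.center_mean + y.center_mean),
            f"center_{la}": x.center_mean, f"center_{lb}": y.center_mean,
            f"pct_area_{la}": float(np.mean(x.pct_areas)),
            f"pct_area_{lb}": float(np.mean(y.pct_areas)),
            "area_p": float(area_cmp.pairwise["p_value"].iloc[0]),
            "area_significant": bool(area_cmp.pairwise["significant"].iloc[0]),
            "center_p": float(center_cmp.pairwise["p_value"].iloc[0]),
            "center_significant": bool(center_cmp.pairwise["significant"].iloc[0]),
            "unique_to": "",
        })
    for i, x in enumerate(ca):
        if i not in used_a:
            rows.append({"band": x.center_mean, f"center_{la}": x.center_mean,
                         f"center_{lb}": np.nan,
                         f"pct_area_{la}": float(np.mean(x.pct_areas)),
                         f"pct_area_{lb}": np.nan,
                         "area_p": np.nan, "area_significant": False,
                         "center_p": np.nan, "center_significant": False,
                         "unique_to": la})
    for j, y in enumerate(cb):
        if j not in used_b:
            rows.append({"band": y.center_mean, f"center_{la}": np.nan,
                         f"center_{lb}": y.center_mean,
                         f"pct_area_{la}": np.nan,
                         f"pct_area_{lb}": float(np.mean(y.pct_areas)),
                         "area_p": np.nan, "area_significant": False,
                         "center_p": np.nan, "center_significant": False,
                         "unique_to": lb})
    df = pd.DataFrame(rows).sort_values("band", kind="stable").reset_index(drop=True)
    return df
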