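"""Pre/post rehabilitation comparison of gait feature tables.

For each numeric gait metric shared by the pre- and post-intervention
tables, subjects are paired by ID and a two-tailed paired-samples t-test is
applied; the report carries the mean difference (Post - Pre), its 95%
confidence interval, and the p-value, with significance at p < 0.05.
Metrics are reported without multiplicity correction by default (an
optional Holm adjustment is available).
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["rehab_compare"]


def _holm(pvals: np.ndarray) -> np.ndarray:
    order = np.argsort(pvals)
    m = len(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adj[idx] = min(running, 1.0)
    return adj


def rehab_compare(
    pre: pd.DataFrame,
    post: pd.DataFrame,
    paired_by: str = "subject_id",
    metrics: Optional[Sequence[str]] = None,
    alpha: float = 0.05,
    holm: bool = False,
) -> pd.DataFrame:
    """Paired pre/post comparison, one row per metric.

    Subjects present in only one table are listed in a warning and excluded.
    Columns: metric, n, mean_pre, mean_post, mean_diff, ci_low, ci_high,
    p_value (and p_holm if requested), significant.
    """
    pre_ids = set(pre[paired_by])
    post_ids = set(post[paired_by])
    unmatched = sorted(pre_ids ^ post_ids)
    if unmatched:
        warnings.warn(
            f"excluding unmatched subjects: {unmatched}", stacklevel=2
        )
    common = sorted(pre_ids & post_ids)
    if not common:
        raise ValueError("no paired subjects")
    pre_m = pre.set_index(paired_by).loc[common]
    post_m = post.set_index(paired_by).loc[common]

    if metrics is None:
        metrics = [
            c
            for c in pre.columns
            if c != paired_by
            and c in post.columns
            and pd.api.types.is_numeric_dtype(pre[c])
        ]

    rows = []
    for metric in metrics:
        a = pre_m[metric].to_numpy(dtype=float)
        b = post_m[metric].to_numpy(dtype=float)
        ok = ~(np.isnan(a) | np.isnan(b))
        a, b = a[ok], b[ok]
        n = a.size
        diff = b - a
        mean_diff = float(diff.mean()) if n else np.nan
        if n >= 2 and np.any(diff != diff[0]):
            res = stats.ttest_rel(b, a)
            p = float(res.pvalue)
            se = diff.std(ddof=1) / np.sqrt(n)
            tcrit = stats.t.ppf(1 - alpha / 2, df=n - 1)
            ci = (mean_diff - tcrit * se, mean_diff + tcrit * se)
        elif n >= 2:
            # identical differences: zero variance, CI collapses to the point
            p = 1.0 if diff[0] == 0 else 0.0
            ci = (mean_diff, mean_diff)
        else:
            p, ci = np.nan, (np.nan, np.nan)
        rows.append(
            {
                "metric": metric,
                "n": n,
                "mean_pre": float(a.mean()) if n else np.nan,
                "mean_post": float(b.mean()) if n else np.nan,
                "mean_diff": mean_diff,
                "ci_low": ci[0],
                "ci_high": ci[1],
                "p_value": p,
            }
        )
    out = pd.DataFrame(rows)
    if holm:
        out["p_holm"] = _holm(out["p_value"].to_numpy())
        out["significant"] = out["p_holm"] < alpha
    else:
        out["significant"] = out["p_value"] < alpha
    return out
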