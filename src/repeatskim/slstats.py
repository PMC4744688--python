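"""Single/low-copy (S/L) fraction sizes and their correlation with genome
size via Kendall's tau-b.

The S/L fraction is the part of a genome historically estimated by DNA
reassociation kinetics to be single- or low-copy.  Given a species'
percentage of S/L DNA, its 1C genome size (Mb) and its ploidy, the module
derives the S/L fraction in Mb on both the 1C and the monoploid (1Cx) scale
and tests its association with genome size using the tie-corrected rank
correlation tau-b.
"""

from __future__ import annotations

from collections import Counter

import numpy as np
import pandas as pd
from scipy import stats


def build_sl_table(raw: pd.DataFrame) -> pd.DataFrame:
    """One derived record per species from raw reassociation rows.

    Expected columns: species, sl_percent, one_c_mb, ploidy (extra columns,
    e.g. family, are carried through by first value).  Exact duplicate rows
    are dropped first; remaining multiple estimates per species are averaged
    on the percentage scale before any Mb derivation.
    """
    required = {"species", "sl_percent", "one_c_mb", "ploidy"}
    missing = required - set(raw.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    df = raw.drop_duplicates()
    if (df.sl_percent <= 0).any() or (df.sl_percent > 100).any():
        raise ValueError("sl_percent must be in (0, 100]")
    if (df.one_c_mb <= 0).any():
        raise ValueError("one_c_mb must be positive")
    if (df.ploidy <= 0).any():
        raise ValueError("ploidy must be positive")
    agg = {"sl_percent": "mean", "one_c_mb": "first", "ploidy": "first"}
    for col in df.columns:
        if col not in agg and col != "species":
            agg[col] = "first"
    out = df.groupby("species", as_index=False, sort=True).agg(agg)
    out["sl_mb_1c"] = out.sl_percent / 100.0 * out.one_c_mb
    out["one_cx_mb"] = 2.0 * out.one_c_mb / out.ploidy
    out["sl_mb_1cx"] = out.sl_percent / 100.0 * out.one_cx_mb
    return out


def kendall_tau_b(x, y) -> tuple[float, float]:
    """Kendall's tau-b with tie corrections and its two-sided p-value from
    the tie-corrected normal approximation.

    tau_b = (C - D) / sqrt((n0 - n1)(n0 - n2)) with n0 = n(n-1)/2 and
    n1, n2 the tie terms of x and y.  Raises on all-tied input, where the
    statistic is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y):
        raise ValueError("x and y must have equal length")
    if n < 2:
        raise ValueError("need at least two observations")
    conc = disc = 0
    for i in range(n - 1):
        for j in range(i + 1, n):
            s = np.sign(x[i] - x[j]) * np.sign(y[i] - y[j])
            if s > 0:
                conc += 1
            elif s < 0:
                disc += 1
    tx = Counter(x.tolist())
    ty = Counter(y.tolist())
    n0 = n * (n - 1) / 2
    n1 = sum(t * (t - 1) / 2 for t in tx.values())
    n2 = sum(t * (t - 1) / 2 for t in ty.values())
    denom = np.sqrt((n0 - n1) * (n0 - n2))
    if denom == 0:
        raise ValueError("tau-b undefined: all values tied in x or y")
    tau = (conc - disc) / denom

    # tie-corrected variance of C - D (normal approximation)
    v0 = n * (n - 1) * (2 * n + 5)
    vt = sum(t * (t - 1) * (2 * t + 5) for t in tx.values())
    vu = sum(t * (t - 1) * (2 * t + 5) for t in ty.values())
    v1 = (
        sum(t * (t - 1) for t in tx.values())
        * sum(t * (t - 1) for t in ty.values())
        / (2.0 * n * (n - 1))
    )
    v2 = 0.0
    if n > 2:
        v2 = (
            sum(t * (t - 1) * (t - 2) for t in tx.values())
            * sum(t * (t - 1) * (t - 2) for t in ty.values())
            / (9.0 * n * (n - 1) * (n - 2))
        )
    var = (v0 - vt - vu) / 18.0 + v1 + v2
    if var <= 0:
        return float(tau), 1.0
    z = (conc - disc) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(tau), float(min(p, 1.0))


def correlation_report(
    table: pd.DataFrame,
    sl_cols: tuple[str, ...] = ("sl_mb_1c", "sl_mb_1cx"),
    size_cols: tuple[str, ...] = ("one_c_mb", "one_cx_mb"),
    group_col: str | None = None,
    min_group_n: int = 5,
) -> pd.DataFrame:
    """tau-b of S/L fraction size against genome size, overall and
    (optionally) per group with at least ``min_group_n`` species."""
    pairs = list(zip(sl_cols, size_cols))
    rows = []

    def add(grouping: str, sub: pd.DataFrame) -> None:
        for sl_col, size_col in pairs:
            tau, p = kendall_tau_b(sub[sl_col].values, sub[size_col].values)
            rows.append(
                {
                    "grouping": grouping,
                    "n": len(sub),
                    "sl_col": sl_col,
                    "size_col": size_col,
                    "tau_b": tau,
                    "p_value": p,
                }
            )

    add("all", table)
    if group_col is not None:
        for name, sub in table.groupby(group_col, sort=True):
            if len(sub) >= min_group_n:
                add(str(name), sub)
    return pd.DataFrame(rows)
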