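"""Reading and writing DMU x period input-output panels.

Wide format: columns ``dmu``, ``period``, then ``in:<name>`` and
``out:<name>`` columns.  Long format: ``dmu, period, variable, role,
value`` with role in {input, output}.  Loading validates completeness and
strict positivity; zeros are rejected unless an epsilon replacement is
requested (the indicators are positive counts and ratios, and efficiency
against a zero input is undefined).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .dea import PanelDataset, PanelError

__all__ = ["read_panel_csv", "read_panel_long_csv", "write_panel_csv"]


def _assemble(df: pd.DataFrame, input_names, output_names, epsilon: float | None) -> PanelDataset:
    dmus = list(dict.fromkeys(df["dmu"]))
    periods = sorted(set(df["period"]), key=str)
    dup = df.duplicated(subset=["dmu", "period"])
    if dup.any():
        rows = df.loc[dup, ["dmu", "period"]].values.tolist()
        raise PanelError(f"duplicate (dmu, period) rows: {rows[:5]}")
    expected = len(dmus) * len(periods)
    if len(df) != expected:
        have = {(d, p) for d, p in zip(df["dmu"], df["period"])}
        missing = [(d, p) for d in dmus for p in periods if (d, p) not in have]
        raise PanelError(f"incomplete panel; missing cells: {missing[:10]}")

    cols = [f"in:{n}" for n in input_names] + [f"out:{n}" for n in output_names]
    for c in cols:
        vals = pd.to_numeric(df[c], errors="coerce")
        if vals.isna().any():
            row = df.loc[vals.isna()].iloc[0]
            raise PanelError(f"non-numeric value in column {c!r} at dmu={row['dmu']} period={row['period']}")
        df[c] = vals

    if epsilon is not None:
        for c in cols:
            df[c] = df[c].astype(float)
            positive = df[c][df[c] > 0]
            if len(positive) == 0:
                raise PanelError(f"column {c!r} has no positive values to anchor epsilon")
            df.loc[df[c] <= 0, c] = epsilon * positive.mean()
    else:
        for c in cols:
            bad = df[df[c] <= 0]
            if len(bad):
                row = bad.iloc[0]
                raise PanelError(
                    f"non-positive value {row[c]!r} in column {c!r} at "
                    f"dmu={row['dmu']} period={row['period']} (use an epsilon replacement to load anyway)"
                )

    n, T, m, s = len(dmus), len(periods), len(input_names), len(output_names)
    x = np.empty((n, T, m))
    y = np.empty((n, T, s))
    df = df.set_index(["dmu", "period"])
    for j, d in enumerate(dmus):
        for t, p in enumerate(periods):
            row = df.loc[(d, p)]
            x[j, t, :] = [row[f"in:{nm}"] for nm in input_names]
            y[j, t, :] = [row[f"out:{nm}"] for nm in output_names]
    return PanelDataset(dmus, [str(p) for p in periods], list(input_names), list(output_names), x, y)


def read_panel_csv(path: str | Path, epsilon: float | None = None) -> PanelDataset:
    """Load a wide-format panel CSV.

    ``epsilon``, if given, replaces non-positive cells by
    ``epsilon * column mean of positive values`` (default behaviour is to
    reject them, naming the offending cell).
    """
    df = pd.read_csv(path, dtype={"dmu": str, "period": str})
    required = {"dmu", "period"}
    if not required <= set(df.columns):
        raise PanelError(f"panel CSV must have columns {sorted(required)}; got {list(df.columns)}")
    input_names = [c[3:] for c in df.columns if c.startswith("in:")]
    output_names = [c[4:] for c in df.columns if c.startswith("out:")]
    if not input_names or not output_names:
        raise PanelError("panel CSV needs at least one 'in:<name>' and one 'out:<name>' column")
    return _assemble(df, input_names, output_names, epsilon)


def read_panel_long_csv(path: str | Path, epsilon: float | None = None) -> PanelDataset:
    """Load a long-format panel CSV (dmu, period, variable, role, value)."""
    df = pd.read_csv(path, dtype={"dmu": str, "period": str, "variable": str, "role": str})
    required = {"dmu", "period", "variable", "role", "value"}
    if not required <= set(df.columns):
        raise PanelError(f"long panel CSV must have columns {sorted(required)}")
    bad_roles = set(df["role"]) - {"input", "output"}
    if bad_roles:
        raise PanelError(f"unknown roles {sorted(bad_roles)}; expected 'input' or 'output'")
    wide = df.pivot_table(
        index=["dmu", "period"], columns=["role", "variable"], values="value", aggfunc="first"
    )
    input_names = sorted(c for r, c in wide.columns if r == "input")
    output_names = sorted(c for r, c in wide.columns if r == "output")
    flat = wide.copy()
    flat.columns = [("in:" if r == "input" else "out:") + c for r, c in wide.columns]
    flat = flat.reset_index()
    return _assemble(flat, input_names, output_names, epsilon)


def write_panel_csv(panel: PanelDataset, path: str | Path) -> None:
    """Write a panel in the wide CSV format read by :func:`read_panel_csv`."""
    rows = []
    for j, d in enumerate(panel.dmu_ids):
        for t, p in enumerate(panel.period_ids):
            row = {"dmu": d, "period": p}
            row.update({f"in:{n}": panel.x[j, t, i] for i, n in enumerate(panel.input_names)})
            row.update({f"out:{n}": panel.y[j, t, r] for r, n in enumerate(panel.output_names)})
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")
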