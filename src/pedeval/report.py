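"""Report tables: the rendered face of both pipeline stages."""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import pandas as pd

from .dea import PanelSummary, MalmquistRecord

__all__ = ["ReportTable", "render_report", "malmquist_report", "records_frame"]


class ReportError(ValueError):
    pass


@dataclass
class ReportTable:
    """A rectangular numeric table with optional footer rows.

    Rendering precision defaults to 4 decimals, the conventional printing
    of productivity indices.
    """

    title: str
    frame: pd.DataFrame
    footer: pd.DataFrame | None = None
    precision: int = 4

    def __post_init__(self) -> None:
        if self.frame.empty:
            raise ReportError("report table has no cells")
        if self.footer is not None and list(self.footer.columns) != list(self.frame.columns):
            raise ReportError("footer columns must match table columns")

    def combined(self) -> pd.DataFrame:
        if self.footer is None:
            return self.frame
        return pd.concat([self.frame, self.footer])


def render_report(table: ReportTable, format: str = "csv") -> str:
    """Render as ``csv`` or aligned ``text``; lossless at the set precision."""
    df = table.combined().round(table.precision)
    if format == "csv":
        buf = io.StringIO()
        df.to_csv(buf, float_format=f"%.{table.precision}f")
        return buf.getvalue()
    if format == "text":
        body = df.to_string(float_format=lambda v: f"{v:.{table.precision}f}")
        return f"{table.title}\n{body}\n"
    raise ReportError(f"unsupported format {format!r}; use 'csv' or 'text'")


def records_frame(records: list[MalmquistRecord], value: str = "pi") -> pd.DataFrame:
    """Pivot index records into a DMU x period-pair DataFrame."""
    cols: dict[str, dict[str, float]] = {}
    for r in records:
        label = f"{r.period_t}=>{r.period_t1}"
        cols.setdefault(label, {})[r.dmu] = getattr(r, "inverse_index" if value == "inverse" else "pi")
    frame = pd.DataFrame(cols)
    order = list(dict.fromkeys(r.dmu for r in records))
    return frame.loc[order]


def malmquist_report(
    summary: PanelSummary, frame: pd.DataFrame, title: str = "Malmquist productivity index"
) -> ReportTable:
    """Index matrix with an Average column and Average/Max/Min/SD footer."""
    body = frame.copy()
    body["Average"] = frame.mean(axis=1)
    footer = pd.DataFrame(
        {
            **{c: [summary.per_pair_mean[c], summary.per_pair_max[c],
                   summary.per_pair_min[c], summary.per_pair_sd[c]]
               for c in frame.columns},
            "Average": [summary.grand_mean,
                        body["Average"].max(), body["Average"].min(),
                        body["Average"].std(ddof=1)],
        },
        index=["Average", "Max", "Min", "SD"],
    )
    return ReportTable(title=title, frame=body, footer=footer)
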