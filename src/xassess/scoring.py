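"""Min-max scaling of raw metrics and the composite benchmark scores.

Raw metric values are comparable only within a task, so each metric column
is min-max scaled across all strategies of the task — *including* the
unintegrated references, which anchor the scale so that algorithms that
barely improve on no integration cannot look artificially strong.

The species-mixing score is the mean of the applicable scaled batch
metrics {PCR, bASW, GC, kBET}; the biology-conservation score the mean of
the applicable scaled {cASW, NMI, ARI, isoF1} (a trajectory metric, when
present as a ``Traj`` column, joins this mean). The integrated score
weights them 0.4 / 0.6:

    integrated = 0.4 · species_mixing + 0.6 · biology_conservation

Strategies missing every batch metric (graph-only outputs) get no
species-mixing or integrated score and are excluded from ranking, but
their other values are still reported. ALCS is reported alongside the
scores, never inside them.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from xassess.errors import ValidationError
from xassess.metrics import BATCH_METRICS, BIO_METRICS

SM_WEIGHT = 0.4
BC_WEIGHT = 0.6

REPORT_SCHEMA_VERSION = "1.0"


def minmax_scale_metrics(raw: pd.DataFrame) -> pd.DataFrame:
    """Per-column min-max scaling over all strategies (unintegrated included).

    A constant column scales to 0.5 everywhere (an uninformative metric
    should not separate strategies); NaN (not-applicable) entries stay NaN;
    columns with fewer than two defined values are dropped with a warning.
    """
    scaled = pd.DataFrame(index=raw.index)
    for col in raw.columns:
        values = pd.to_numeric(raw[col], errors="coerce")
        defined = values.dropna()
        if len(defined) < 2:
            warnings.warn(
                f"metric column {col!r} has fewer than two defined values; dropped",
                stacklevel=2,
            )
            continue
        lo, hi = defined.min(), defined.max()
        if hi == lo:
            scaled[col] = np.where(values.notna(), 0.5, np.nan)
        else:
            scaled[col] = (values - lo) / (hi - lo)
    return scaled


def _applicable_mean(row: pd.Series, metrics: tuple[str, ...]) -> float:
    values = [row[m] for m in metrics if m in row.index and pd.notna(row[m])]
    if not values:
        return float("nan")
    return float(np.mean(values))


def species_mixing_score(scaled_row: pd.Series) -> float:
    """Mean of the applicable scaled batch metrics; NaN if none apply."""
    return _applicable_mean(scaled_row, BATCH_METRICS)


def biology_conservation_score(scaled_row: pd.Series) -> float:
    """Mean of the applicable scaled biology metrics (plus Traj when present)."""
    return _applicable_mean(scaled_row, BIO_METRICS + ("Traj",))


def integrated_score(sm: float, bc: float) -> float:
    """Weighted composite: 0.4 × species mixing + 0.6 × biology conservation."""
    return SM_WEIGHT * sm + BC_WEIGHT * bc


@dataclass
class MetricReport:
    """Raw and scaled metric tables with composite scores and ranks."""

    raw: pd.DataFrame
    scaled: pd.DataFrame
    scores: pd.DataFrame  # species_mixing, biology_conservation, integrated, rank
    unintegrated: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        payload = {
            "schema_version": REPORT_SCHEMA_VERSION,
            "unintegrated": self.unintegrated,
            "raw": _frame_to_payload(self.raw),
            "scaled": _frame_to_payload(self.scaled),
            "scores": _frame_to_payload(self.scores),
        }
        return json.dumps(payload, indent=2, sort_keys=True, allow_nan=True)

    @classmethod
    def from_json(cls, text: str) -> "MetricReport":
        payload = json.loads(text)
        return cls(
            raw=_frame_from_payload(payload["raw"]),
            scaled=_frame_from_payload(payload["scaled"]),
            scores=_frame_from_payload(payload["scores"]),
            unintegrated=list(payload["unintegrated"]),
        )

    def write(self, out_base: str | Path) -> tuple[Path, Path]:
        out_base = Path(out_base)
        out_base.parent.mkdir(parents=True, exist_ok=True)
        csv_path = out_base.with_suffix(".csv")
        json_path = out_base.with_suffix(".json")
        table = pd.concat(
            [self.raw.add_prefix("raw_"), self.scaled.add_prefix("scaled_"), self.scores],
            axis=1,
        )
        table.to_csv(csv_path, index_label="strategy", float_format="%.10g")
        json_path.write_text(self.to_json())
        return csv_path, json_path


def _frame_to_payload(df: pd.DataFrame) -> dict:
    records = {}
    for strategy, row in df.iterrows():
        records[str(strategy)] = {
            str(k): (
                None
                if pd.isna(v)
                else bool(v)
                if isinstance(v, (bool, np.bool_))
                else float(v)
                if isinstance(v, (int, float, np.floating, np.integer))
                else v
            )
            for k, v in row.items()
        }
    return {
        "columns": [str(c) for c in df.columns],
        "index": [str(i) for i in df.index],
        "rows": records,
    }


def _frame_from_payload(payload: dict) -> pd.DataFrame:
    df = pd.DataFrame.from_dict(payload["rows"], orient="index")
    return df.reindex(index=payload["index"], columns=payload["columns"])


def rank_report(
    raw: pd.DataFrame, unintegrated: list[str] | None = None
) -> MetricReport:
    """Scale a raw strategies × metrics table and rank by integrated score.

    ``unintegrated`` names the reference rows: they participate in scaling
    but are flagged and excluded from ranking, as are strategies whose
    species-mixing score is undefined. Ties on the integrated score break
    by higher biology conservation, then strategy id.
    """
    if raw.empty:
        raise ValidationError("empty metric table: nothing to score")
    unintegrated = list(unintegrated or [])
    scaled = minmax_scale_metrics(raw)
    scores = pd.DataFrame(index=raw.index)
    scores["species_mixing"] = [species_mixing_score(r) for _, r in scaled.iterrows()]
    scores["biology_conservation"] = [
        biology_conservation_score(r) for _, r in scaled.iterrows()
    ]
    scores["integrated"] = [
        integrated_score(sm, bc) if pd.notna(sm) and pd.notna(bc) else float("nan")
        for sm, bc in zip(scores["species_mixing"], scores["biology_conservation"])
    ]
    scores["is_unintegrated"] = [s in unintegrated for s in scores.index]

    rankable = scores.loc[
        ~scores["is_unintegrated"] & scores["integrated"].notna()
    ].copy()
    rankable = rankable.sort_values(
        by=["integrated", "biology_conservation"],
        ascending=[False, False],
        kind="stable",
    )
    # residual ties break by strategy id (stable sort over pre-sorted index)
    rankable = rankable.loc[
        sorted(rankable.index, key=lambda s: (
            -rankable.at[s, "integrated"],
            -rankable.at[s, "biology_conservation"],
            str(s),
        ))
    ]
    scores["rank"] = np.nan
    scores.loc[rankable.index, "rank"] = np.arange(1, len(rankable) + 1, dtype=float)

    order = list(rankable.index) + [s for s in scores.index if s not in rankable.index]
    return MetricReport(
        raw=raw.loc[order],
        scaled=scaled.loc[order],
        scores=scores.loc[order],
        unintegrated=unintegrated,
    )
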