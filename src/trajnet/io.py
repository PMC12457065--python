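"""Panel table I/O and questionnaire scoring.

The panel dialect is one CSV row per subject:

    id, gender, age, trauma,
    RE_1..DR_1, RE_2..DR_2, RE_3..DR_3,
    total_1, total_2, total_3 [, true_class]

A companion JSON sidecar (same stem, ``.meta.json``) can record the
generating specification and seed.  The reader rejects missing cells — the
survey platform the data dialect models could not submit incomplete
questionnaires — and optionally enforces a bounded score range.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .simulate import COVARIATES, NODES


class PanelValidationError(ValueError):
    """Panel file violates the dialect (missing columns/cells, bad ranges)."""


def required_columns(n_waves: int = 3) -> list[str]:
    cols = ["id", *COVARIATES]
    for w in range(1, n_waves + 1):
        cols += [f"{n}_{w}" for n in NODES]
    cols += [f"total_{w}" for w in range(1, n_waves + 1)]
    return cols


def write_panel(panel: pd.DataFrame, path, meta: Mapping | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    panel.to_csv(path, index=False)
    if meta is not None:
        sidecar = path.with_suffix(".meta.json")
        sidecar.write_text(json.dumps(meta, indent=2, sort_keys=True, default=_jsonify))


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def read_panel(
    path,
    column_map: Mapping[str, str] | None = None,
    n_waves: int = 3,
    bounds: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Read and validate a panel CSV.

    ``column_map`` renames alternate source columns onto the canonical
    dialect (e.g. {"reexp_w1": "RE_1"}).  ``bounds=(lo, hi)`` additionally
    enforces the bounded score range on cluster and total columns.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing_cols = [c for c in required_columns(n_waves) if c not in df.columns]
    if missing_cols:
        raise PanelValidationError(f"missing required columns: {missing_cols}")
    na = df[required_columns(n_waves)].isna()
    if na.to_numpy().any():
        rows, cols = np.nonzero(na.to_numpy())
        offenders = [
            f"row {int(r)}, column {na.columns[c]!r}" for r, c in zip(rows, cols)
        ][:10]
        raise PanelValidationError("missing values at: " + "; ".join(offenders))
    if df["id"].duplicated().any():
        raise PanelValidationError("duplicate subject ids")
    if bounds is not None:
        lo, hi = bounds
        cluster_cols = [f"{n}_{w}" for w in range(1, n_waves + 1) for n in NODES]
        vals = df[cluster_cols + [f"total_{w}" for w in range(1, n_waves + 1)]]
        bad = (vals < lo) | (vals > hi)
        if bad.to_numpy().any():
            r, c = np.nonzero(bad.to_numpy())
            raise PanelValidationError(
                f"{len(r)} score(s) outside [{lo}, {hi}], first at row {int(r[0])}, "
                f"column {bad.columns[c[0]]!r}"
            )
    return df


def score_itq_clusters(items: pd.DataFrame, n_waves: int = 3) -> pd.DataFrame:
    """Score a 12-item-per-wave table into the six cluster columns.

    Each cluster is measured by two items named ``<cluster>1_<wave>`` and
    ``<cluster>2_<wave>`` on a 0-4 Likert scale; cluster score = item mean
    (keeping the 0-4 scale), per-wave total = mean of the six cluster
    scores.  Returns a copy with cluster and total columns appended.
    """
    out = items.copy()
    for w in range(1, n_waves + 1):
        for node in NODES:
            cols = [f"{node}1_{w}", f"{node}2_{w}"]
            for c in cols:
                if c not in items.columns:
                    raise PanelValidationError(f"missing item column {c!r}")
                v = items[c]
                if v.isna().any() or not v.isin([0, 1, 2, 3, 4]).all():
                    raise PanelValidationError(f"item column {c!r} has values outside 0..4")
            out[f"{node}_{w}"] = items[cols].mean(axis=1)
        out[f"total_{w}"] = out[[f"{n}_{w}" for n in NODES]].mean(axis=1)
    return out
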