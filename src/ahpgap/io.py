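"""Readers and writers for the pipeline's text formats.

All tabular inputs are plain UTF-8 CSV with comma delimiters.  Ratio
entries may be written as integers, decimals (with "." or "," as the
decimal mark — both are accepted on input, "." is always emitted), exact
fractions such as ``1/7``, or questionnaire answer labels; fractions are
parsed exactly before float conversion so reciprocity survives
round-trips.  The hierarchy definition is a YAML or JSON mapping with keys
``goal`` / ``criteria`` / ``alternatives``.
"""

from __future__ import annotations

import json
from fractions import Fraction
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .aggregation import RespondentJudgments
from .hierarchy import DecisionHierarchy, PairwiseMatrix, build_hierarchy, saaty_value
from .indicators import ScorePanel

__all__ = [
    "parse_ratio",
    "read_hierarchy_config",
    "read_matrix_csv",
    "write_matrix_csv",
    "read_judgments_csv",
    "write_judgments_csv",
    "read_likert_csv",
    "read_timesteps_csv",
]


def parse_ratio(text: str | float | int) -> Fraction:
    """Parse a ratio entry: number, decimal-comma number, fraction, or label."""
    if isinstance(text, str):
        text = text.strip()
        if "/" not in text and "," in text and text.replace(",", ".").count(".") == 1:
            candidate = text.replace(",", ".")
            try:
                return Fraction(candidate).limit_denominator(10_000)
            except ValueError:
                pass
    return saaty_value(text)


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON config mapping (YAML is a JSON superset)."""
    config = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if not isinstance(config, Mapping):
        raise ValueError(f"config {path} is not a mapping")
    return dict(config)


def read_hierarchy_config(path: str | Path) -> DecisionHierarchy:
    """Load a hierarchy definition from a YAML or JSON file."""
    return build_hierarchy(load_config(path))


def read_score_panels(config: Mapping) -> dict[str, ScorePanel]:
    """Extract per-alternative expert score panels from a config mapping.

    The hierarchy config may carry a ``scores`` key mapping each
    alternative to ``{safety: {...}, legal: {...}, investment,
    purchase_cost}``; absent key means no panels.
    """
    panels = {}
    for alt, entry in (config.get("scores") or {}).items():
        panels[str(alt)] = ScorePanel(
            safety=dict(entry.get("safety") or {}),
            legal=dict(entry.get("legal") or {}),
            investment=float(entry.get("investment", 0.0)),
            purchase_cost=float(entry.get("purchase_cost", 1.0)),
        )
    return panels


def read_matrix_csv(path: str | Path) -> PairwiseMatrix:
    """Read a pairwise comparison matrix with a label header row/column."""
    df = pd.read_csv(path, index_col=0, dtype=str)
    labels = [str(c) for c in df.columns]
    if [str(i) for i in df.index] != labels:
        raise ValueError(f"matrix {path}: row labels do not match column labels")
    values = np.array(
        [[float(parse_ratio(df.iloc[i, j])) for j in range(len(labels))]
         for i in range(len(labels))]
    )
    return PairwiseMatrix(tuple(labels), values)


def write_matrix_csv(matrix: PairwiseMatrix, path: str | Path) -> None:
    """Write a matrix as CSV with label header row/column.

    Entries are emitted as exact fractions where the value is (within
    1e-12) a ratio of small integers, otherwise as repr floats; either
    form round-trips through :func:`read_matrix_csv` exactly.
    """
    def fmt(x: float) -> str:
        frac = Fraction(x).limit_denominator(1_000)
        if abs(float(frac) - x) < 1e-12:
            return str(frac)
        return repr(x)

    lines = ["," + ",".join(matrix.labels)]
    for lab, row in zip(matrix.labels, matrix.values):
        lines.append(lab + "," + ",".join(fmt(v) for v in row))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_judgments_csv(path: str | Path) -> list[RespondentJudgments]:
    """Read per-respondent pairwise judgments.

    Columns: ``respondent_id``, ``node``, ``child_a``, ``child_b``,
    ``answer``; answers may be numeric ratios, fractions, or questionnaire
    answer labels ("Much more important" etc.).
    """
    df = pd.read_csv(path, dtype=str)
    required = {"respondent_id", "node", "child_a", "child_b", "answer"}
    missing = required - set(df.columns)
    if missing:
        raise KeyError(f"judgments CSV missing column(s): {sorted(missing)}")
    by_resp: dict[str, RespondentJudgments] = {}
    for row in df.itertuples(index=False):
        rj = by_resp.setdefault(
            str(row.respondent_id), RespondentJudgments(str(row.respondent_id))
        )
        key = (str(row.node), str(row.child_a), str(row.child_b))
        if key in rj.judgments:
            raise ValueError(f"duplicate judgment {key} for respondent {row.respondent_id}")
        rj.judgments[key] = float(parse_ratio(row.answer))
    return list(by_resp.values())


def write_judgments_csv(
    judgments: Sequence[RespondentJudgments], path: str | Path
) -> None:
    rows = [
        {"respondent_id": rj.respondent_id, "node": node,
         "child_a": a, "child_b": b, "answer": _ratio_text(v)}
        for rj in judgments
        for (node, a, b), v in rj.judgments.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def _ratio_text(v: float) -> str:
    frac = Fraction(v).limit_denominator(1_000)
    return str(frac) if abs(float(frac) - v) < 1e-12 else repr(v)


def read_likert_csv(path: str | Path) -> pd.DataFrame:
    """Read raw questionnaire answers (respondent_id, item_id, category)."""
    df = pd.read_csv(path)
    required = {"respondent_id", "item_id", "category"}
    missing = required - set(df.columns)
    if missing:
        raise KeyError(f"Likert CSV missing column(s): {sorted(missing)}")
    return df


def read_timesteps_csv(path: str | Path) -> pd.DataFrame:
    """Read the operational series (timestep, alternative, record fields)."""
    df = pd.read_csv(path)
    for col in ("timestep", "alternative"):
        if col not in df.columns:
            raise KeyError(f"timestep CSV missing column {col!r}")
    return df


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(obj, indent=2, sort_keys=False, default=_jsonable) + "\n",
        encoding="utf-8",
    )


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
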