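"""Table-shaped report writers (TSV and Markdown)."""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def format_or(estimate: float, lo: float, hi: float) -> str:
    return f"{estimate:.2f} ({lo:.2f}, {hi:.2f})"


def write_table(df: pd.DataFrame, path, title: str = "") -> None:
    """Write a report table as <path>.tsv and <path>.md."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path.with_suffix(".tsv"), sep="\t", index=False, float_format="%.6g")
    lines = [f"# {title}", ""] if title else []
    lines.append(_pipe_table(df))
    path.with_suffix(".md").write_text("\n".join(lines) + "\n")


def _pipe_table(df: pd.DataFrame) -> str:
    def fmt(v):
        if isinstance(v, float):
            return "" if pd.isna(v) else f"{v:.3f}"
        return "" if v is None else str(v)

    header = "| " + " | ".join(map(str, df.columns)) + " |"
    rule = "|" + "|".join("---" for _ in df.columns) + "|"
    body = ["| " + " | ".join(fmt(v) for v in row) + " |"
            for row in df.itertuples(index=False)]
    return "\n".join([header, rule, *body])


def or_results_frame(results: dict) -> pd.DataFrame:
    """Flatten a {label: ORResult} mapping into a report table."""
    rows = []
    for label, r in results.items():
        rows.append({
            "label": label, "or": r.estimate, "ci_low": r.ci_low,
            "ci_high": r.ci_high, "p": r.p, "n_cases": r.n_cases,
            "n_controls": r.n_controls, "model": r.model_label, "note": r.note,
        })
    return pd.DataFrame(rows)
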