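"""CSV/TSV/JSON formats for group summaries, effects and fit results.

Group-level data travel as UTF-8 CSV with one row per acclimation group;
missing values are empty fields.  Effects, rejects, matrices and fit
summaries are written as CSV/TSV plus JSON, with a run-metadata JSON
recording seeds, package version and a config hash so runs are
reproducible bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from darrmeta.effects import EffectSize, GroupStat
from darrmeta.model import FitResult
from darrmeta.pipeline import effects_to_frame

__all__ = [
    "read_groups", "write_groups", "write_effects", "write_rejects",
    "write_matrix_tsv", "write_fit", "write_run_metadata", "ensure_outdir",
]

logger = logging.getLogger(__name__)

MANDATORY_COLUMNS = ["study_id", "species", "temperature", "mean_ht"]
_FIELDS = [f.name for f in dataclasses.fields(GroupStat)]
_FLOAT_FIELDS = {"temperature", "mean_ht", "sd", "se", "heating_rate"}
_INT_FIELDS = {"n", "year"}
_BOOL_FIELDS = {"sd_imputed", "risk_of_bias"}


def read_groups(path) -> tuple[list[GroupStat], dict]:
    """Read group-level rows from CSV with row-level validation.

    Unknown columns produce a warning; missing mandatory columns raise.
    Returns (rows, report) where the report counts rows read and lists
    per-row validation failures (those rows are excluded from the
    output, never silently dropped).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    if df.empty and df.columns.empty:
        raise ValueError(f"{path}: empty file")
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory columns {missing}")
    unknown = [c for c in df.columns if c not in _FIELDS]
    if unknown:
        warnings.warn(f"{path}: ignoring unknown columns {unknown}", stacklevel=2)
    rows: list[GroupStat] = []
    failures: list[dict] = []
    for i, rec in enumerate(df.to_dict("records")):
        kwargs = {}
        try:
            for name in _FIELDS:
                raw = rec.get(name, "")
                if raw == "" or raw is None:
                    continue
                if name in _FLOAT_FIELDS:
                    kwargs[name] = float(raw)
                elif name in _INT_FIELDS:
                    kwargs[name] = int(float(raw))
                elif name in _BOOL_FIELDS:
                    kwargs[name] = str(raw).strip().lower() in ("1", "true", "yes")
                else:
                    kwargs[name] = str(raw)
            # newick convention: species names use underscores
            kwargs["species"] = kwargs.get("species", "").strip().replace(" ", "_")
            rows.append(GroupStat(**kwargs))
        except (ValueError, TypeError, KeyError) as exc:
            failures.append({"row": i, "error": str(exc)})
    report = {"rows_read": len(df), "rows_valid": len(rows), "failures": failures}
    if failures:
        logger.warning("%s: %d row(s) failed validation", path, len(failures))
    return rows, report


def _group_record(g: GroupStat) -> dict:
    d = dataclasses.asdict(g)
    return {k: ("" if v is None else v) for k, v in d.items()}


def write_groups(rows: Sequence[GroupStat], path) -> None:
    pd.DataFrame([_group_record(g) for g in rows], columns=_FIELDS).to_csv(
        path, index=False, encoding="utf-8"
    )


def write_effects(effects: Sequence[EffectSize], path) -> None:
    effects_to_frame(effects).to_csv(path, index=False, encoding="utf-8")


def write_rejects(rejects: Sequence[tuple[GroupStat, str]], path) -> None:
    recs = []
    for g, reason in rejects:
        rec = _group_record(g)
        rec["reject_reason"] = reason
        recs.append(rec)
    pd.DataFrame(recs, columns=_FIELDS + ["reject_reason"]).to_csv(
        path, index=False, encoding="utf-8"
    )


def write_matrix_tsv(names: Sequence[str], matrix: np.ndarray, path) -> None:
    pd.DataFrame(matrix, index=list(names), columns=list(names)).to_csv(
        path, sep="\t", encoding="utf-8"
    )


def write_fit(fit: FitResult, stem: Path, extra: dict | None = None) -> None:
    """Serialize a fit as <stem>.json plus a flat <stem>_coefficients.tsv."""
    payload = fit.summary()
    if extra:
        payload.update(extra)
    Path(f"{stem}.json").write_text(
        json.dumps(payload, indent=2, default=float), encoding="utf-8"
    )
    pd.DataFrame(payload["coefficients"]).to_csv(
        f"{stem}_coefficients.tsv", sep="\t", index=False, encoding="utf-8"
    )


def ensure_outdir(path, force: bool = False) -> Path:
    """Create the output directory; refuse to reuse a non-empty one
    without force."""
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    if not force and any(out.iterdir()):
        raise FileExistsError(
            f"{out} is not empty; pass force=True/--force to overwrite"
        )
    return out


def write_run_metadata(outdir, config: dict) -> None:
    from darrmeta import __version__

    blob = json.dumps(config, sort_keys=True, default=str)
    meta = {
        "package_version": __version__,
        "config": config,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
    }
    Path(outdir, "run_metadata.json").write_text(
        json.dumps(meta, indent=2, default=str), encoding="utf-8"
    )
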