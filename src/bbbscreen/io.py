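"""CSV/JSON schemas for the pipeline's inputs and outputs.

Dialect: comma-separated UTF-8 with a mandatory header, ``.`` decimal, an
empty cell for a missing value, the ``BLQ`` literal in amount/concentration
columns for below-quantification measurements, and ``\\`` for an undefined
efflux ratio.  Reading then writing any schema is lossless, including the
sentinels.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .assay import (
    BLQ,
    CellLine,
    Direction,
    Inhibitor,
    PermeabilitySummary,
    TransportRecord,
    is_blq,
)
from .brainpk import CompoundInVivo
from .ivivc import IVIVCModel, ValidationResult
from .mechanism import MechanismCall

TRANSPORT_COLUMNS = [
    "compound_id", "cell_line", "direction", "replicate", "c0_uM",
    "c_donor_final_uM", "receiver_amount_nmol", "v_donor_mL", "v_receiver_mL",
    "area_cm2", "duration_s", "lysate_amount_nmol", "inhibitor",
]


import numpy as np


def _cell(value) -> str:
    if value is None:
        return ""
    if is_blq(value):
        return "BLQ"
    if isinstance(value, (float, np.floating)):
        return repr(float(value))
    return str(value)


def _parse_amount(cell: str):
    if cell == "":
        return None
    if cell == "BLQ":
        return BLQ
    return float(cell)


def write_transport_csv(records: Iterable[TransportRecord], path: str | Path) -> Path:
    rows = []
    for r in records:
        rows.append({
            "compound_id": r.compound_id,
            "cell_line": r.cell_line.value,
            "direction": r.direction.value,
            "replicate": r.replicate_id,
            "c0_uM": _cell(r.c0_donor),
            "c_donor_final_uM": _cell(r.c_donor_final),
            "receiver_amount_nmol": _cell(r.receiver_amount),
            "v_donor_mL": _cell(r.v_donor),
            "v_receiver_mL": _cell(r.v_receiver),
            "area_cm2": _cell(r.area),
            "duration_s": _cell(r.duration),
            "lysate_amount_nmol": _cell(r.lysate_amount),
            "inhibitor": r.inhibitor.value,
        })
    path = Path(path)
    pd.DataFrame(rows, columns=TRANSPORT_COLUMNS).to_csv(path, index=False)
    return path


def read_transport_csv(path: str | Path) -> list[TransportRecord]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(TRANSPORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"transport.csv missing columns: {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        records.append(
            TransportRecord(
                compound_id=row["compound_id"],
                cell_line=CellLine(row["cell_line"]),
                direction=Direction(row["direction"]),
                c0_donor=float(row["c0_uM"]),
                c_donor_final=_parse_amount(row["c_donor_final_uM"]),
                receiver_amount=_parse_amount(row["receiver_amount_nmol"]),
                v_donor=None if row["v_donor_mL"] == "" else float(row["v_donor_mL"]),
                v_receiver=None if row["v_receiver_mL"] == "" else float(row["v_receiver_mL"]),
                area=float(row["area_cm2"]),
                duration=float(row["duration_s"]),
                lysate_amount=_parse_amount(row["lysate_amount_nmol"]),
                inhibitor=Inhibitor(row["inhibitor"] or "none"),
                replicate_id=int(row["replicate"]),
            )
        )
    return records


def write_summary_csv(summaries: Sequence[PermeabilitySummary], path: str | Path) -> Path:
    rows = []
    for s in summaries:
        rows.append({
            "compound_id": s.compound_id,
            "cell_line": s.cell_line.value,
            "papp_ab": _cell(s.papp_ab),
            "papp_ab_sd": _cell(s.papp_ab_sd),
            "papp_ba": _cell(s.papp_ba),
            "papp_ba_sd": _cell(s.papp_ba_sd),
            "recovery_ab": _cell(s.recovery_ab),
            "recovery_ba": _cell(s.recovery_ba),
            "recovery_lysate_corrected": _cell(s.recovery_lysate_corrected),
            "er": "\\" if s.er is None else _cell(s.er),
            "n_replicates": s.n_replicates,
            "qc_pass": "" if s.qc_pass is None else s.qc_pass,
            "trapping_flag": s.trapping_flag,
            "corrected_by_bafA1": s.corrected_by_bafA1,
        })
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def write_mechanism_csv(calls: Sequence[MechanismCall], path: str | Path) -> Path:
    rows = [{
        "compound_id": c.compound_id,
        "category": c.category.value,
        "papp_used": _cell(c.papp_used),
        "er_used": "\\" if c.er_used is None else _cell(c.er_used),
        "corrected_by_bafA1": c.corrected_by_bafA1,
        "recovery_pass": c.recovery_pass,
    } for c in calls]
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def write_invivo_csv(records: Sequence[CompoundInVivo], path: str | Path) -> Path:
    rows = [{
        "compound_id": r.compound_id,
        "kp_brain": _cell(r.kp_brain),
        "fu_plasma": _cell(r.fu_plasma),
        "fu_brain": _cell(r.fu_brain),
        "kp_uu_brain": _cell(r.kp_uu_brain),
        "kp_uu_recomputed": _cell(r.kp_uu_recomputed),
        "source": r.source,
        "discrepant": r.discrepant,
    } for r in records]
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def write_validation_csv(results: Sequence[ValidationResult], path: str | Path) -> Path:
    rows = [{
        "compound_id": r.compound_id,
        "observed_kpuu": _cell(r.observed_kpuu),
        "predicted_kpuu": _cell(r.predicted_kpuu),
        "fold_error": _cell(r.fold_error),
        "within_2fold": r.within_2fold,
    } for r in results]
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def write_model_json(model: IVIVCModel, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "slope": model.slope,
        "intercept": model.intercept,
        "pearson_r": model.pearson_r,
        "transform": model.transform,
        "cell_line_used": model.cell_line_used,
        "seed": model.seed,
        "training_ids": model.training_ids,
    }
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
    return path


def write_manifest(paths: Sequence[Path], out_dir: str | Path) -> Path:
    """MANIFEST.json listing artifact names and sha256 hashes."""
    out_dir = Path(out_dir)
    entries = {}
    for p in sorted(paths, key=lambda p: p.name):
        entries[p.name] = hashlib.sha256(Path(p).read_bytes()).hexdigest()
    manifest = out_dir / "MANIFEST.json"
    manifest.write_text(json.dumps(entries, indent=2, sort_keys=True) + "\n")
    return manifest
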