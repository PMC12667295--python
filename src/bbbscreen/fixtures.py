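"""Packaged reference dataset: 41 drugs profiled bidirectionally in the
MOCK and MDR1 monolayers (permeability, recovery, efflux ratio) and their
in vivo protein binding / brain partitioning.

Values are stored exactly as tabulated — Papp and ER at their printed
precision, BLQ cells as the ``BLQ`` literal, undefined efflux ratios as
``\\`` — so the fixture doubles as a round-trip test of the table
conventions.  A checksum guards against silent edits.
"""

from __future__ import annotations

import hashlib
from importlib import resources

import pandas as pd

from .assay import BLQ, CellLine, PermeabilitySummary
from .brainpk import (
    CompoundInVivo,
    default_fu_rule,
    reconcile_kp_uu,
)
from .ivivc import PoolMember
from .mechanism import Thresholds, classify, recovery_filter

_CHECKSUMS = {
    "table1.csv": "cf6ef85c676c162de2c255c3e3712832b0be63a530549c12eebddafac022d48d",
    "table2.csv": "4cd06df782183c79a6a4b3ba6344f64e57a4a2bf55c336f93622a5fd99553cc0",
}


class FixtureIntegrityError(RuntimeError):
    pass


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("bbbscreen.data").joinpath(name)
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _CHECKSUMS[name]:
        raise FixtureIntegrityError(f"{name}: checksum mismatch ({digest})")
    from io import BytesIO

    return pd.read_csv(BytesIO(raw), dtype=str, keep_default_na=False)


def load_table1() -> pd.DataFrame:
    """Raw bidirectional-transport table (82 rows: 41 compounds x 2 lines)."""
    return _read("table1.csv")


def load_table2() -> pd.DataFrame:
    """Raw protein-binding / brain-exposure table (41 rows), printed strings."""
    return _read("table2.csv")


def _num(cell: str):
    if cell == "" or cell is None:
        return None
    if cell == "BLQ":
        return BLQ
    return float(cell)


def table1_summaries() -> list[PermeabilitySummary]:
    """The fixture as typed permeability summaries (n = 3 wells each)."""
    out = []
    for _, row in load_table1().iterrows():
        out.append(
            PermeabilitySummary(
                compound_id=row["compound_id"],
                cell_line=CellLine(row["cell_line"]),
                papp_ab=_num(row["papp_ab"]),
                papp_ba=_num(row["papp_ba"]),
                er=None if row["er"] == "\\" else float(row["er"]),
                recovery_ab=_num(row["recovery_ab"]),
                recovery_ba=_num(row["recovery_ba"]),
                papp_ab_sd=None if row["papp_ab_sd"] == "" else float(row["papp_ab_sd"]),
                papp_ba_sd=None if row["papp_ba_sd"] == "" else float(row["papp_ba_sd"]),
                recovery_ab_sd=_num(row["recovery_ab_sd"]),
                recovery_ba_sd=_num(row["recovery_ba_sd"]),
                n_replicates=3,
            )
        )
    return out


def table2_invivo() -> list[CompoundInVivo]:
    """In vivo records with printed Kp,uu reconciled against recomputation.

    Compounds with printed binding percentages get a recomputed Kp,uu and a
    discrepancy flag when it disagrees with the printed value beyond one
    unit of the last printed digit; rows without binding data are literature
    values as printed.
    """
    out = []
    for _, row in load_table2().iterrows():
        fu_plasma = default_fu_rule(row["pb_plasma"]) if row["pb_plasma"] else None
        fu_brain = default_fu_rule(row["pb_brain"]) if row["pb_brain"] else None
        out.append(
            reconcile_kp_uu(
                compound_id=row["compound_id"],
                kp_brain=float(row["kp_brain"]),
                fu_plasma=fu_plasma,
                fu_brain=fu_brain,
                kp_uu_printed=row["kp_uu_brain"],
            )
        )
    return out


def load_fixtures() -> tuple[list[PermeabilitySummary], list[CompoundInVivo]]:
    """(41 x 2 permeability summaries, 41 in vivo records)."""
    return table1_summaries(), table2_invivo()


def build_pool(
    cell_line: CellLine = CellLine.MDR1,
    thresholds: Thresholds | None = None,
) -> list[PoolMember]:
    """Eligible IVIVC pool: recovery-passing compounds with Papp and Kp,uu.

    Strata labels are the mechanism categories called from the MDR1 fixture
    values.  For the MOCK pool the Papp comes from the MOCK summary but the
    category (stratum) stays the MDR1 call, so paired splits are comparable;
    compounds whose Papp(A-B) is BLQ in the requested line are dropped (no
    logarithm exists for them).
    """
    thresholds = thresholds or Thresholds()
    cell_line = CellLine(cell_line)
    summaries, invivo = load_fixtures()
    passing = set(recovery_filter(summaries, thresholds).passing)
    kpuu = {r.compound_id: r.kp_uu_brain for r in invivo}
    mdr1 = {s.compound_id: s for s in summaries if s.cell_line is CellLine.MDR1}
    chosen = {s.compound_id: s for s in summaries if s.cell_line is cell_line}
    pool = []
    for cid in mdr1:
        if cid not in passing or cid not in kpuu or kpuu[cid] is None:
            continue
        papp = chosen[cid].papp_ab
        if papp is BLQ or papp is None:
            continue
        category = classify(mdr1[cid], thresholds).category.value
        pool.append(PoolMember(compound_id=cid, papp=papp, kpuu=kpuu[cid], category=category))
    return pool
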